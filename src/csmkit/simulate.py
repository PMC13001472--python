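"""Ground-truth transcript pools and read simulation.

Emulates the measurable outcome of Csm cleavage plus RtcB religation: a pool
of full-length species — the intact transcript, each predicted religation
product (6/12/18/24-nt microexcisions, macroexcisions, trans chimeras) and
optionally an unrelated off-target transcript — sampled at specified
fractions and sequenced as fixed-length reads with i.i.d. substitution
errors.  Every read carries its ground-truth label (species, start, strand)
in its name and in a sidecar table, so classifier and quantifier output can
be scored exactly.

The error model is substitution-only by default so that raw-mode (exact
k-mer) classification tests stay exact; a single-base indel mode exists
solely to exercise the alignment-mode classifier.  No platform-specific
error profile (homopolymer compression, quality-dependent rates) or
coverage bias is modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .model import (
    Junction,
    JunctionLibrary,
    ParameterError,
    reverse_complement,
)

logger = logging.getLogger(__name__)

OFF_TARGET = "off_target"
INTACT = "intact"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth composition and read-generation parameters.

    ``species_fractions`` maps species ids (``intact``, junction ids,
    ``off_target``) to probabilities summing to 1.
    """

    species_fractions: Mapping[str, float]
    n_reads: int = 20_000
    read_length: int = 150
    substitution_error_rate: float = 0.005
    indel_error_rate: float = 0.0
    mixed_strand: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        fr = dict(self.species_fractions)
        if not fr:
            raise ParameterError("species_fractions is empty")
        if any(v < 0 for v in fr.values()):
            raise ParameterError("species fractions must be non-negative")
        total = sum(fr.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"species fractions sum to {total}, expected 1")
        if self.n_reads <= 0:
            raise ParameterError("n_reads must be positive")
        if not 0 <= self.substitution_error_rate < 0.25:
            raise ParameterError("substitution_error_rate must be in [0, 0.25)")
        if not 0 <= self.indel_error_rate < 0.25:
            raise ParameterError("indel_error_rate must be in [0, 0.25)")


@dataclass(frozen=True)
class SimRead:
    read_id: str
    species: str
    start: int  # 0-based start on the species reference
    strand: str  # '+' or '-'
    seq: str

    @property
    def name(self) -> str:
        """FASTQ name encoding the ground truth."""
        return f"{self.read_id}|{self.species}|{self.start}|{self.strand}"


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def build_species_references(
    lib: JunctionLibrary,
    intact_reference: str,
    intact_name: str = INTACT,
    donors: Optional[Mapping[str, str]] = None,
) -> Dict[str, str]:
    """Full-length sequence of every species a junction library predicts.

    cis species are the intact reference with ``[left_pos, right_pos)``
    excised; trans species are the acceptor prefix up to the cut followed by
    the processed donor transcript (leftover + body), looked up in
    ``donors`` by the junction's right transcript id.
    """
    refs: Dict[str, str] = {intact_name: intact_reference}
    for j in lib.junctions:
        if j.kind in ("cis_micro", "cis_macro"):
            refs[j.id] = intact_reference[: j.left_pos] + intact_reference[j.right_pos :]
        else:  # trans
            if donors is None or j.right_transcript not in donors:
                raise ParameterError(
                    f"trans junction {j.id} needs donor sequence "
                    f"{j.right_transcript!r}"
                )
            refs[j.id] = (
                intact_reference[: j.left_pos]
                + donors[j.right_transcript][j.right_pos :]
            )
    return refs


def simulate_reads(
    config: SimConfig, species_refs: Mapping[str, str]
) -> List[SimRead]:
    """Draw reads i.i.d.: species by fraction, start uniform, errors i.i.d.

    Identical seed and inputs give identical output.  An ``off_target``
    species without a provided reference is generated as a random sequence.
    Species shorter than the read length are skipped (with a warning) and
    their probability redistributed over the rest.
    """
    rng = np.random.default_rng(config.seed)
    refs = dict(species_refs)
    fractions = dict(config.species_fractions)
    if OFF_TARGET in fractions and OFF_TARGET not in refs:
        refs[OFF_TARGET] = random_sequence(
            max(2 * config.read_length, 500), rng
        )

    usable: Dict[str, float] = {}
    for sp, frac in fractions.items():
        if sp not in refs:
            raise ParameterError(f"no reference for species {sp!r}")
        if len(refs[sp]) < config.read_length:
            logger.warning(
                "species %s (%d nt) shorter than read length %d: skipped",
                sp, len(refs[sp]), config.read_length,
            )
            continue
        if frac > 0:
            usable[sp] = frac
    if not usable:
        raise ParameterError("no species long enough to sequence")
    names = sorted(usable)
    probs = np.array([usable[n] for n in names])
    probs = probs / probs.sum()

    picks = rng.choice(len(names), size=config.n_reads, p=probs)
    reads: List[SimRead] = []
    for i, pick in enumerate(picks):
        sp = names[pick]
        ref = refs[sp]
        start = int(rng.integers(0, len(ref) - config.read_length + 1))
        seq = _apply_errors(ref[start : start + config.read_length], config, rng)
        strand = "+"
        if config.mixed_strand and rng.random() < 0.5:
            seq = reverse_complement(seq)
            strand = "-"
        reads.append(SimRead(f"read{i}", sp, start, strand, seq))
    return reads


def _apply_errors(seq: str, config: SimConfig, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    e = config.substitution_error_rate
    if e > 0:
        hits = np.nonzero(rng.random(arr.size) < e)[0]
        for i in hits:
            # substitute with one of the three other bases
            others = _BASES[_BASES != arr[i]]
            arr[i] = others[rng.integers(0, 3)]
    out = arr.tobytes().decode()
    ie = config.indel_error_rate
    if ie > 0:
        chars: List[str] = []
        for ch in out:
            r = rng.random()
            if r < ie / 2:
                continue  # deletion
            chars.append(ch)
            if ie / 2 <= r < ie:
                chars.append(str(random_sequence(1, rng)))  # insertion
        out = "".join(chars)
    return out


def write_fastq(reads: List[SimRead], path) -> None:
    """Phred-33 FASTQ with constant quality 'I' (Q40)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_truth(reads: List[SimRead], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {"read_id": r.read_id, "species": r.species, "start": r.start,
             "strand": r.strand}
            for r in reads
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ground-truth alignments
# ---------------------------------------------------------------------------

def true_alignment(
    read: SimRead, lib: JunctionLibrary, intact_name: str = INTACT
) -> Optional[Tuple[int, str]]:
    """(reference_start, CIGAR) of a read on the intact reference, from truth.

    cis-species coordinates map to the intact reference directly before the
    deletion and shifted by the deletion length after it; a read straddling
    the seam gets an M-D-M CIGAR.  Off-target and trans reads have no
    placement on the intact reference (returns None → emit unmapped).
    Reverse-strand reads are placed by their forward-strand footprint.
    """
    L = len(read.seq)
    if read.species == intact_name:
        return read.start, f"{L}M"
    try:
        j = lib.get(read.species)
    except KeyError:
        return None
    if j.deletion_length is None:
        return None
    lp, d = j.left_pos, j.deletion_length
    p = read.start
    if p + L <= lp:
        return p, f"{L}M"
    if p >= lp:
        return p + d, f"{L}M"
    m1 = lp - p
    return p, f"{m1}M{d}D{L - m1}M"


def write_sam(
    reads: List[SimRead],
    lib: JunctionLibrary,
    intact_reference: str,
    path,
    reference_name: str = "amplicon",
    intact_name: str = INTACT,
) -> None:
    """Ground-truth SAM on the intact reference (uncompressed, headered).

    Error-free reads get exact placements; the substitution error model does
    not change CIGARs (substitutions stay M).  Unplaceable reads are written
    as unmapped records.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": reference_name, "LN": len(intact_reference)}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=pysam.AlignmentHeader.from_dict(header)) as fh:
        for r in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.name
            placement = true_alignment(r, lib, intact_name)
            seq = r.seq if r.strand == "+" else reverse_complement(r.seq)
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            if placement is None:
                a.is_unmapped = True
            else:
                a.reference_id = 0
                a.reference_start, cigar = placement
                a.cigarstring = cigar
                a.mapping_quality = 60
                a.is_reverse = r.strand == "-"
            fh.write(a)


# ---------------------------------------------------------------------------
# synthetic reporter construct
# ---------------------------------------------------------------------------

_SAFE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def toy_stop_reporter(
    seed: int = 0,
    n_upstream_codons: int = 80,
    n_downstream_codons: int = 80,
    utr5: int = 30,
    utr3: int = 30,
) -> Tuple[str, Tuple[int, int]]:
    """A synthetic tandem-fluorophore reporter: ORF1—premature stop—ORF2.

    Mimics an mCherry-stop-eGFP construct: excising the premature stop codon
    in frame fuses the two ORFs.  Returns ``(sequence, orf_interval)`` where
    the half-open ORF interval covers ATG through the premature TAA stop
    inclusive.  Codons are sampled uniformly from non-stop codons, so the
    upstream ORF is open by construction; this is a synthetic stand-in, not
    a real fluorophore sequence.
    """
    rng = np.random.default_rng(seed)

    def codons(n: int) -> str:
        return "".join(
            _SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), size=n)
        )

    five = random_sequence(utr5, rng)
    orf1 = "ATG" + codons(n_upstream_codons) + "TAA"
    orf2 = codons(n_downstream_codons) + "TAA"
    three = random_sequence(utr3, rng)
    seq = five + orf1 + orf2 + three
    orf_start = utr5
    orf_end = utr5 + len(orf1)  # end of the premature stop
    return seq, (orf_start, orf_end)
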