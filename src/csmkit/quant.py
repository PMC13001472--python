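"""Junction-spanning read classification and abundance quantification.

A read over the target region is *intact*, a specific *junction* species, or
*unassigned*.  Two classification modes share one index:

raw mode (:func:`classify_read`)
    Exact matching.  A read is a junction hit when it contains that
    junction's seam 2k-mer (``anchor_k`` nt on each side of the seam) *and*
    the surrounding species observation window; intact when it contains the
    full intact window (first cut − k to last cut + k of the uncut
    reference); otherwise unassigned.  Every species' observation window
    has the same length (cut span + 2k, centred on the seam for junction
    species), so a read's chance of being countable is identical across
    categories — without this, seam windows would be shorter than the
    intact window and junction reads would survive partial overlaps and
    sequencing errors more often, inflating the religated fraction.  Both
    strands are scanned.  Exact matching is deliberate: deterministic, and
    the anchors are long enough that chance hits are negligible; it is not
    error-tolerant — use alignment mode for noisy long reads.

alignment mode (:func:`classify_alignment`)
    CIGAR-gap matching on aligned records.  Deletion-type gaps (D and N —
    spliced aligners emit N for long gaps) are matched against library
    junctions by exact length and a start-shift tolerance that absorbs
    aligner left/right-shifting at microhomologous seams.

Species abundances are reported as fractions of the *target-site-spanning
depth*: the denominator is intact + all junction counts, excluding reads
that span neither (so partial overlaps cannot dilute the estimate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .model import (
    Junction,
    JunctionLibrary,
    ParameterError,
    cut_span,
    junction_reference,
    reverse_complement,
)

logger = logging.getLogger(__name__)

INTACT = "intact"
UNASSIGNED = "unassigned"

# CIGAR ops consuming the reference (pysam numeric codes)
_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X
_GAP_OPS = {2, 3}  # D, N

_CIGAR_CODE = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "P": 6, "=": 7, "X": 8}


@dataclass(frozen=True)
class ReadClass:
    """Classification of one read: exactly one category."""

    read_id: str
    category: str  # "intact", "junction:<id>" or "unassigned"
    junction_ids: Tuple[str, ...] = ()  # >1 when the matched context is ambiguous
    evidence: Optional[str] = None


@dataclass
class JunctionIndex:
    """Exact-match index: seam 2k-mers, species windows, intact window.

    ``entries`` keys are the seam 2k-mers; ``windows`` holds each junction's
    full observation window (same length as the intact window, centred on
    the seam) as ``(window, seam_offset)`` where ``seam_offset`` is the
    index of the seam 2k-mer within the window.
    """

    anchor_k: int
    entries: Dict[str, Tuple[str, ...]]
    windows: Dict[str, Tuple[str, int]]
    intact_window: str
    intact_start: int  # reference coordinate of intact_window[0]
    reference_name: str
    ambiguous_keys: frozenset = frozenset()

    @property
    def intact_end(self) -> int:
        return self.intact_start + len(self.intact_window)


def build_index(
    lib: JunctionLibrary,
    intact_reference: str,
    anchor_k: int = 12,
    reference_name: Optional[str] = None,
) -> JunctionIndex:
    """Index a junction library for read classification.

    One 2k-mer per junction (from :func:`junction_reference` at
    ``anchor_k``); colliding 2k-mers (possible with repeats or
    microhomology) map to all their junction ids and are flagged so the
    quantifier can split their counts.  The intact window runs from
    ``first cut - anchor_k`` to ``last cut + anchor_k`` on the uncut
    reference, so a read containing it demonstrably carries no deletion.
    """
    if anchor_k < 6:
        raise ParameterError(f"anchor_k must be >= 6, got {anchor_k}")
    if not lib.junctions:
        raise ParameterError("cannot index an empty junction library")
    names = {j.left_transcript for j in lib.junctions}
    if reference_name is None:
        if len(names) != 1:
            raise ParameterError(
                f"library spans transcripts {sorted(names)}; pass reference_name"
            )
        reference_name = next(iter(names))

    work = JunctionLibrary(list(lib.junctions), anchor_k, dict(lib.references))
    if reference_name not in work.references:
        work.references[reference_name] = intact_reference

    cis = [j for j in lib.junctions if j.kind != "trans"]
    if cis:
        first_cut, last_cut = cut_span(cis)
    else:  # trans-only library: span of acceptor cut positions
        lefts = [j.left_pos for j in lib.junctions]
        first_cut, last_cut = min(lefts), max(lefts)
    w0 = first_cut - anchor_k
    w1 = last_cut + anchor_k
    if w0 < 0 or w1 > len(intact_reference):
        raise ParameterError(
            f"intact window [{w0},{w1}) exceeds reference bounds"
        )
    window_len = w1 - w0  # every species window has this length
    left_ext = window_len // 2
    right_ext = window_len - left_ext

    entries: Dict[str, Tuple[str, ...]] = {}
    windows: Dict[str, Tuple[str, int]] = {}
    for j in work.junctions:
        key = junction_reference(j, work)
        # species sequence around the seam: left flank up to the cP end,
        # then the retained 3' fragment from the 5'-OH end
        left_ref = work.references[j.left_transcript]
        right_ref = work.references[j.right_transcript]
        if j.left_pos - left_ext < 0 or j.right_pos + right_ext > len(right_ref):
            raise ParameterError(
                f"junction {j.id}: species window of {window_len} nt does not "
                "fit its references"
            )
        window = (
            left_ref[j.left_pos - left_ext : j.left_pos]
            + right_ref[j.right_pos : j.right_pos + right_ext]
        )
        windows[j.id] = (window, left_ext - anchor_k)
        if key in entries:
            logger.warning("ambiguous junction context %s", key)
            entries[key] = entries[key] + (j.id,)
        else:
            entries[key] = (j.id,)
    ambiguous = frozenset(k for k, ids in entries.items() if len(ids) > 1)

    return JunctionIndex(
        anchor_k=anchor_k,
        entries=entries,
        windows=windows,
        intact_window=intact_reference[w0:w1],
        intact_start=w0,
        reference_name=reference_name,
        ambiguous_keys=ambiguous,
    )


def _scan(seq: str, index: JunctionIndex) -> Optional[Tuple[int, Tuple[str, ...]]]:
    """First seam hit (read order) whose full species window is present."""
    k2 = 2 * index.anchor_k
    entries = index.entries
    for i in range(len(seq) - k2 + 1):
        ids = entries.get(seq[i : i + k2])
        if ids is None:
            continue
        confirmed = []
        for jid in ids:
            window, seam_off = index.windows[jid]
            lo = i - seam_off
            if lo >= 0 and seq[lo : lo + len(window)] == window:
                confirmed.append(jid)
        if confirmed:
            return i, tuple(confirmed)
    return None


def classify_read(
    seq: str, index: JunctionIndex, read_id: str = "read"
) -> ReadClass:
    """Classify a raw read by exact window containment.

    First seam 2k-mer in read order whose full species window is present
    wins; the reverse complement is scanned when the forward strand yields
    nothing.  Reads spanning no species window are unassigned, so they
    never enter the quantification denominator.
    """
    if not seq:
        logger.warning("empty read %s", read_id)
        return ReadClass(read_id, UNASSIGNED, evidence="empty read")
    seq = seq.upper()
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        hit = _scan(s, index)
        if hit is not None:
            pos, ids = hit
            cat = f"junction:{ids[0]}" if len(ids) == 1 else "junction:" + "|".join(ids)
            return ReadClass(
                read_id, cat, junction_ids=ids,
                evidence=f"kmer@{pos}({strand})",
            )
        if index.intact_window in s:
            return ReadClass(read_id, INTACT, evidence=f"intact-window({strand})")
    return ReadClass(read_id, UNASSIGNED)


def _parse_cigar(cigar: str) -> List[Tuple[int, int]]:
    """CIGAR string → pysam-style (op, length) tuples; raises on junk."""
    out: List[Tuple[int, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        elif ch in _CIGAR_CODE and num:
            out.append((_CIGAR_CODE[ch], int(num)))
            num = ""
        else:
            raise ValueError(f"unparseable CIGAR {cigar!r}")
    if num:
        raise ValueError(f"unparseable CIGAR {cigar!r}")
    return out


def reference_gaps(
    cigartuples: Sequence[Tuple[int, int]], reference_start: int
) -> Tuple[List[Tuple[int, int]], int]:
    """Deletion-type gaps ([gstart, gend) spans) and the reference end."""
    gaps = []
    pos = reference_start
    for op, length in cigartuples:
        if op in _GAP_OPS:
            gaps.append((pos, pos + length))
        if op in _REF_CONSUMING:
            pos += length
    return gaps, pos


def classify_alignment(
    record,
    index: JunctionIndex,
    lib: JunctionLibrary,
    shift_tol: int = 3,
) -> ReadClass:
    """Classify an aligned record (pysam ``AlignedSegment``) by CIGAR gaps.

    A gap ``[gstart, gend)`` matches junction *j* iff its length equals
    ``j.deletion_length`` and ``|gstart - j.left_pos| <= shift_tol``
    (nearest start wins; ties 5'-most).  Junction and intact calls both
    require the record's reference footprint to span the full intact window
    (the same spanning contract as raw mode); anything else is unassigned.
    """
    read_id = record.query_name or "read"
    if record.is_unmapped:
        return ReadClass(read_id, UNASSIGNED, evidence="unmapped")
    if record.reference_name != index.reference_name:
        return ReadClass(
            read_id, UNASSIGNED, evidence=f"reference {record.reference_name}"
        )
    cig = record.cigartuples
    if not cig:
        return ReadClass(read_id, UNASSIGNED, evidence="no CIGAR")
    gaps, ref_end = reference_gaps(cig, record.reference_start)
    spanning = (
        record.reference_start <= index.intact_start
        and ref_end >= index.intact_end
    )
    if not spanning:
        return ReadClass(read_id, UNASSIGNED, evidence="non-spanning")

    cis = [j for j in lib.junctions if j.deletion_length is not None]
    for gstart, gend in gaps:
        matches = [
            j for j in cis
            if j.deletion_length == gend - gstart
            and abs(gstart - j.left_pos) <= shift_tol
        ]
        if matches:
            best = min(matches, key=lambda j: (abs(gstart - j.left_pos), j.left_pos))
            return ReadClass(
                read_id, f"junction:{best.id}", junction_ids=(best.id,),
                evidence=f"gap[{gstart},{gend})",
            )
    if not gaps:
        return ReadClass(read_id, INTACT, evidence="spanning, gap-free")
    return ReadClass(read_id, UNASSIGNED, evidence="unmatched gap")


def classify_fastq(path, index: JunctionIndex) -> List[ReadClass]:
    """Classify every read of a FASTQ file in raw mode."""
    from Bio import SeqIO

    return [
        classify_read(str(rec.seq), index, read_id=rec.id)
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def classify_sam(
    path, index: JunctionIndex, lib: JunctionLibrary, shift_tol: int = 3
) -> Tuple[List[ReadClass], int]:
    """Classify every record of a SAM file; returns (classes, n_skipped)."""
    import pysam

    out: List[ReadClass] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        names = set(fh.references)
        if index.reference_name not in names:
            raise ParameterError(
                f"SAM references {sorted(names)} lack library reference "
                f"{index.reference_name!r}"
            )
        for record in fh.fetch(until_eof=True):
            if record.is_secondary or record.is_supplementary:
                skipped += 1
                continue
            try:
                out.append(classify_alignment(record, index, lib, shift_tol))
            except ValueError:
                skipped += 1
    if skipped:
        logger.info("skipped %d records", skipped)
    return out, skipped


@dataclass
class QuantResult:
    """Per-species counts and fractions over target-site-spanning depth.

    ``denominator = intact + sum(junction counts)``; unassigned reads are
    excluded from it, so fractions answer "of transcripts whose status at
    the target site is observable, what fraction is each species?".
    Ambiguous hits contribute fractional counts (split equally).
    """

    junction_counts: Dict[str, float]
    intact_count: float
    unassigned_count: int
    denominator: float
    fractions: Dict[str, float]
    intact_fraction: Optional[float]
    religated_fraction: Optional[float]
    undefined: bool = False

    def to_frame(self, lib: Optional[JunctionLibrary] = None) -> pd.DataFrame:
        rows = []
        for jid, count in sorted(self.junction_counts.items()):
            kind = deletion = None
            if lib is not None:
                try:
                    j = lib.get(jid)
                    kind, deletion = j.kind, j.deletion_length
                except KeyError:
                    pass
            rows.append(
                {
                    "id": jid,
                    "kind": kind,
                    "deletion_length": deletion,
                    "count": count,
                    "fraction": self.fractions.get(jid),
                }
            )
        rows.append(
            {
                "id": INTACT,
                "kind": INTACT,
                "deletion_length": 0,
                "count": self.intact_count,
                "fraction": self.intact_fraction,
            }
        )
        return pd.DataFrame(rows)

    def summary(self) -> Dict:
        return {
            "denominator": self.denominator,
            "intact_count": self.intact_count,
            "unassigned_count": self.unassigned_count,
            "intact_fraction": self.intact_fraction,
            "religated_fraction": self.religated_fraction,
            "junction_counts": dict(sorted(self.junction_counts.items())),
            "fractions": dict(sorted(self.fractions.items())),
            "undefined": self.undefined,
        }


def quantify(classifications: Iterable[ReadClass]) -> QuantResult:
    """Aggregate read classifications into normalized species abundances."""
    junction_counts: Dict[str, float] = {}
    intact = 0.0
    unassigned = 0
    for rc in classifications:
        if rc.category == INTACT:
            intact += 1
        elif rc.junction_ids:
            share = 1.0 / len(rc.junction_ids)
            for jid in rc.junction_ids:
                junction_counts[jid] = junction_counts.get(jid, 0.0) + share
        else:
            unassigned += 1
    denominator = intact + sum(junction_counts.values())
    if denominator == 0:
        logger.warning("no target-site-spanning reads: fractions undefined")
        return QuantResult(
            junction_counts=junction_counts,
            intact_count=intact,
            unassigned_count=unassigned,
            denominator=0.0,
            fractions={},
            intact_fraction=None,
            religated_fraction=None,
            undefined=True,
        )
    fractions = {jid: c / denominator for jid, c in junction_counts.items()}
    return QuantResult(
        junction_counts=junction_counts,
        intact_count=intact,
        unassigned_count=unassigned,
        denominator=denominator,
        fractions=fractions,
        intact_fraction=intact / denominator,
        religated_fraction=sum(junction_counts.values()) / denominator,
    )
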