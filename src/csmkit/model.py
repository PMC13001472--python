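"""Csm cleavage geometry and religation-junction enumeration.

The type III-A CRISPR-Csm complex cleaves a crRNA-complementary RNA at
regularly spaced scissile phosphates — one per Csm3 backbone subunit, 6 nt
apart — leaving a 2',3'-cyclic phosphate on the upstream fragment and a
5'-hydroxyl on the downstream fragment.  Those end chemistries are the RtcB
ligase substrate, so any pair of cut ends can re-join.  This module encodes
the cleavage geometry (:class:`TargetSite` → :func:`predict_cut_sites`) and
enumerates every re-ligation product it predicts:

* *cis* microexcision — re-joining across cuts of one target site, deleting
  a multiple of the cut spacing (6, 12, 18 or 24 nt for the default 5-cut
  complex);
* *cis* macroexcision — re-joining across cuts of two target sites on the
  same transcript, deleting the intervening stretch;
* *trans* ligation ("spligation") — joining the upstream fragment of a
  cleaved acceptor transcript to a donor transcript carrying a 5'-OH end.

Coordinates are 0-based, half-open, transcript-relative on the sense strand
(DNA alphabet).  A cut position names the first base 3' of the scissile
phosphate, so the retained 5' fragment is ``[0, position)`` and a cis
deletion length is simply ``right_pos - left_pos``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Dict, Iterable, List, Mapping, Optional, Tuple

if TYPE_CHECKING:  # pragma: no cover
    from .design import DonorDesign

logger = logging.getLogger(__name__)

# End chemistries left by Csm cleavage; constants of the nuclease mechanism.
CYCLIC_PHOSPHATE = "2',3'-cyclic phosphate"
HYDROXYL_5P = "5'-hydroxyl"

#: Donor 5'-end mechanisms that yield a ligatable 5'-hydroxyl.
FIVE_PRIME_OH_MECHANISMS = frozenset(
    {"csm_site", "rzb_hammerhead", "other_ribozyme", "cas6_hairpin"}
)

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA-alphabet sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParameterError(ValueError):
    """A model parameter violates its documented constraint."""


class ChemistryError(ValueError):
    """Incompatible end chemistries for RtcB ligation."""


@dataclass(frozen=True)
class TargetSite:
    """The crRNA-complementary interval on a transcript plus cleavage model.

    Parameters
    ----------
    transcript_id :
        Name of the targeted transcript.
    start, end :
        0-based half-open interval of the protospacer on the transcript.
    spacer :
        crRNA spacer sequence — the reverse complement of
        ``reference[start:end]`` (DNA alphabet).
    n_cuts :
        Number of scissile phosphates placed by the complex (default 5:
        the observed deletion set {6, 12, 18, 24} implies five cleavable
        registers).
    spacing :
        Distance between adjacent cuts in nt (default 6, the Csm3 subunit
        periodicity).
    cut_offset :
        Distance from ``start`` to the first (5'-most) scissile phosphate.
        The cleavage register relative to the crRNA ends is not a measured
        constant; the default 4 centres the 24-nt cut span in a 32-nt site.
    """

    transcript_id: str
    start: int
    end: int
    spacer: str
    n_cuts: int = 5
    spacing: int = 6
    cut_offset: int = 4

    def __post_init__(self) -> None:
        if self.n_cuts < 1:
            raise ParameterError(f"n_cuts must be >= 1, got {self.n_cuts}")
        if self.spacing <= 0:
            raise ParameterError(f"spacing must be > 0, got {self.spacing}")
        if self.cut_offset < 0:
            raise ParameterError(f"cut_offset must be >= 0, got {self.cut_offset}")
        if self.start < 0 or self.end <= self.start:
            raise ParameterError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.end - self.start != len(self.spacer):
            raise ParameterError(
                f"spacer length {len(self.spacer)} != site length {self.end - self.start}"
            )
        span = self.cut_offset + (self.n_cuts - 1) * self.spacing
        if span > self.end - self.start:
            raise ParameterError(
                f"cut span {span} nt exceeds site length {self.end - self.start} nt "
                "(cut_offset + (n_cuts-1)*spacing must fit inside the site)"
            )

    @classmethod
    def from_reference(
        cls,
        transcript_id: str,
        reference: str,
        start: int,
        end: int,
        *,
        n_cuts: int = 5,
        spacing: int = 6,
        cut_offset: int = 4,
    ) -> "TargetSite":
        """Build a site whose spacer is derived from the reference interval."""
        if end > len(reference):
            raise ParameterError(
                f"site end {end} beyond reference length {len(reference)}"
            )
        spacer = reverse_complement(reference[start:end])
        return cls(transcript_id, start, end, spacer, n_cuts, spacing, cut_offset)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class CutSite:
    """A scissile phosphate: ``position`` is the first base 3' of the cut."""

    transcript_id: str
    position: int
    rank: int
    innermost_distance: float
    upstream_end: str = CYCLIC_PHOSPHATE
    downstream_end: str = HYDROXYL_5P


@dataclass(frozen=True)
class Junction:
    """A predicted re-ligation product joining two cut ends.

    ``left_pos`` is the exclusive end of the retained 5' fragment (the
    2',3'-cP side); ``right_pos`` the inclusive start of the retained 3'
    fragment (the 5'-OH side).  For cis kinds both positions are on one
    transcript and ``deletion_length == right_pos - left_pos``.
    """

    id: str
    kind: str  # cis_micro | cis_macro | trans
    left_transcript: str
    left_pos: int
    right_transcript: str
    right_pos: int
    deletion_length: Optional[int] = None
    frame_delta: Optional[int] = None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("cis_micro", "cis_macro", "trans"):
            raise ParameterError(f"unknown junction kind {self.kind!r}")
        if self.kind in ("cis_micro", "cis_macro"):
            if self.left_transcript != self.right_transcript:
                raise ParameterError("cis junction must join one transcript")
            if self.right_pos <= self.left_pos:
                raise ParameterError("cis junction requires right_pos > left_pos")
            if self.deletion_length != self.right_pos - self.left_pos:
                raise ParameterError(
                    "cis deletion_length must equal right_pos - left_pos"
                )


@dataclass
class JunctionLibrary:
    """A set of predicted junctions with flanking sequence context.

    ``flank_k`` is the anchor length used on each side of the seam when the
    junction-context 2k-mer is extracted; ``references`` maps transcript ids
    to full sequences.
    """

    junctions: List[Junction]
    flank_k: int = 12
    references: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.flank_k < 1:
            raise ParameterError(f"flank_k must be >= 1, got {self.flank_k}")
        ids = [j.id for j in self.junctions]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ParameterError(f"duplicate junction ids: {dup}")
        for j in self.junctions:
            for tid, pos, side in (
                (j.left_transcript, j.left_pos, "left"),
                (j.right_transcript, j.right_pos, "right"),
            ):
                if tid not in self.references:
                    continue
                ref = self.references[tid]
                if side == "left" and pos - self.flank_k < 0:
                    raise ParameterError(
                        f"junction {j.id}: < {self.flank_k} nt of left flank"
                    )
                if side == "right" and pos + self.flank_k > len(ref):
                    raise ParameterError(
                        f"junction {j.id}: < {self.flank_k} nt of right flank"
                    )

    def __len__(self) -> int:
        return len(self.junctions)

    def __iter__(self):
        return iter(self.junctions)

    def get(self, junction_id: str) -> Junction:
        for j in self.junctions:
            if j.id == junction_id:
                return j
        raise KeyError(junction_id)

    def annotate_ambiguous(self) -> "JunctionLibrary":
        """Flag junctions whose 2k-mer contexts collide (repeats/microhomology).

        All colliding junctions are retained; the quantifier later splits
        counts for an ambiguous context equally among its junctions.
        """
        contexts: Dict[str, List[Junction]] = {}
        for j in self.junctions:
            contexts.setdefault(junction_reference(j, self), []).append(j)
        flagged = []
        for j in self.junctions:
            ctx = junction_reference(j, self)
            amb = len(contexts[ctx]) > 1
            flagged.append(
                Junction(
                    j.id, j.kind, j.left_transcript, j.left_pos,
                    j.right_transcript, j.right_pos, j.deletion_length,
                    j.frame_delta, ambiguous=amb,
                )
            )
        return JunctionLibrary(flagged, self.flank_k, self.references)


def predict_cut_sites(site: TargetSite) -> List[CutSite]:
    """Scissile phosphate positions for one target site, 5'→3'.

    Cut *i* sits at ``start + cut_offset + i*spacing``; ``innermost_distance``
    is the distance to the site midpoint (the innermost cut — minimal
    distance, ties broken 5'-ward — is where the dominant 6-nt deletion
    species is centred).
    """
    return [
        CutSite(
            transcript_id=site.transcript_id,
            position=site.start + site.cut_offset + i * site.spacing,
            rank=i,
            innermost_distance=abs(
                site.start + site.cut_offset + i * site.spacing - site.midpoint
            ),
        )
        for i in range(site.n_cuts)
    ]


def innermost_cut(site: TargetSite) -> CutSite:
    """The cut closest to the site midpoint; ties resolve 5'-ward."""
    cuts = predict_cut_sites(site)
    return min(cuts, key=lambda c: (c.innermost_distance, c.position))


def _cis_id(kind: str, transcript: str, left: int, right: int) -> str:
    tag = "micro" if kind == "cis_micro" else "macro"
    return f"{tag}:{transcript}:{left}-{right}"


def enumerate_micro_junctions(
    site: TargetSite,
    references: Optional[Mapping[str, str]] = None,
    flank_k: int = 12,
) -> JunctionLibrary:
    """All cis microexcision species from one target site.

    One junction per unordered pair of distinct cuts: re-ligation of the
    fragment 5' of the upstream cut to the fragment 3' of the downstream
    cut deletes the intervening ``(j - i) * spacing`` nt.  With the default
    five cuts this yields ten species with deletion lengths
    {6 ×4, 12 ×3, 18 ×2, 24 ×1}.  Deletions are multiples of 6, hence
    multiples of 3: microexcision always preserves reading frame.
    """
    refs = dict(references) if references else {}
    if site.n_cuts < 2:
        logger.warning(
            "site on %s has n_cuts=%d < 2: no religation species",
            site.transcript_id, site.n_cuts,
        )
        return JunctionLibrary([], flank_k, refs)
    cuts = predict_cut_sites(site)
    junctions = []
    for i in range(len(cuts)):
        for j in range(i + 1, len(cuts)):
            left, right = cuts[i].position, cuts[j].position
            junctions.append(
                Junction(
                    id=_cis_id("cis_micro", site.transcript_id, left, right),
                    kind="cis_micro",
                    left_transcript=site.transcript_id,
                    left_pos=left,
                    right_transcript=site.transcript_id,
                    right_pos=right,
                    deletion_length=right - left,
                    frame_delta=(right - left) % 3,
                )
            )
    junctions.sort(key=lambda x: (x.deletion_length, x.left_pos))
    return JunctionLibrary(junctions, flank_k, refs)


def enumerate_macro_junctions(
    site_a: TargetSite,
    site_b: TargetSite,
    references: Optional[Mapping[str, str]] = None,
    flank_k: int = 12,
) -> JunctionLibrary:
    """All cis macroexcision species across two sites on one transcript.

    One junction per (cut in the 5' site) × (cut in the 3' site) pair;
    placing two default sites ~300 nt apart predicts central deletions of
    ~300 nt, the long-excision regime.
    """
    if site_a.transcript_id != site_b.transcript_id:
        raise ParameterError(
            "sites on different transcripts cannot religate in cis; "
            "use predict_trans_junction for cross-molecule products"
        )
    if site_a.end > site_b.start:
        raise ParameterError(
            f"site_a [{site_a.start},{site_a.end}) must lie entirely 5' of "
            f"site_b [{site_b.start},{site_b.end})"
        )
    refs = dict(references) if references else {}
    junctions = []
    for ca in predict_cut_sites(site_a):
        for cb in predict_cut_sites(site_b):
            junctions.append(
                Junction(
                    id=_cis_id(
                        "cis_macro", site_a.transcript_id, ca.position, cb.position
                    ),
                    kind="cis_macro",
                    left_transcript=site_a.transcript_id,
                    left_pos=ca.position,
                    right_transcript=site_b.transcript_id,
                    right_pos=cb.position,
                    deletion_length=cb.position - ca.position,
                    frame_delta=(cb.position - ca.position) % 3,
                )
            )
    junctions.sort(key=lambda x: (x.deletion_length, x.left_pos))
    return JunctionLibrary(junctions, flank_k, refs)


def predict_trans_junction(
    acceptor_cut: CutSite,
    donor: "DonorDesign",
    orf_start: Optional[int] = None,
    donor_id: Optional[str] = None,
) -> Junction:
    """The chimeric species from ligating a donor 5'-OH end onto a cut acceptor.

    The acceptor contributes ``[0, acceptor_cut.position)`` (ending in
    2',3'-cP); the donor contributes its full predicted transcript —
    mechanism-derived leftover nucleotides followed by the body — starting
    at its predicted 5' terminus (``right_pos = 0``).  ``frame_delta`` is
    ``(cut position - orf_start) mod 3`` when an ORF start is supplied: 0
    means the donor body is appended in frame (placing the cut at the 5'
    end of an in-frame stop codon gives 0).
    """
    if donor.mechanism not in FIVE_PRIME_OH_MECHANISMS:
        raise ChemistryError(
            f"donor mechanism {donor.mechanism!r} does not generate a "
            f"5'-hydroxyl end; RtcB requires 5'-OH (one of "
            f"{sorted(FIVE_PRIME_OH_MECHANISMS)})"
        )
    frame_delta = None
    if orf_start is not None:
        frame_delta = (acceptor_cut.position - orf_start) % 3
    did = donor_id or getattr(donor, "name", "donor")
    return Junction(
        id=f"trans:{acceptor_cut.transcript_id}:{acceptor_cut.position}^{did}:0",
        kind="trans",
        left_transcript=acceptor_cut.transcript_id,
        left_pos=acceptor_cut.position,
        right_transcript=did,
        right_pos=0,
        deletion_length=None,
        frame_delta=frame_delta,
    )


def junction_reference(j: Junction, lib: JunctionLibrary) -> str:
    """The 2k-mer sequence context across a junction seam.

    ``flank_k`` nt ending at ``left_pos`` on the left transcript followed by
    ``flank_k`` nt starting at ``right_pos`` on the right transcript — the
    sequence a seam-spanning read contains and the intact reference does not.
    """
    k = lib.flank_k
    for tid, side in ((j.left_transcript, "left"), (j.right_transcript, "right")):
        if tid not in lib.references:
            raise ParameterError(
                f"junction {j.id}: no reference sequence for {tid!r}"
            )
    left_ref = lib.references[j.left_transcript]
    right_ref = lib.references[j.right_transcript]
    if j.left_pos - k < 0 or j.right_pos + k > len(right_ref):
        raise ParameterError(
            f"junction {j.id}: insufficient flank for flank_k={k}"
        )
    return left_ref[j.left_pos - k : j.left_pos] + right_ref[j.right_pos : j.right_pos + k]


def cut_span(junctions: Iterable[Junction]) -> Tuple[int, int]:
    """(first cut, last cut) positions covered by a set of cis junctions."""
    lefts = [j.left_pos for j in junctions]
    rights = [j.right_pos for j in junctions]
    if not lefts:
        raise ParameterError("empty junction collection has no cut span")
    return min(lefts), max(rights)
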