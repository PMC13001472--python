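"""crRNA spacer and donor-construct design.

Guides are designed by placing a target-site window on the sense strand of a
reference transcript; the spacer is the reverse complement of the window.
Design helpers cover the three experimental layouts:

* tiling guides across a region (e.g. across a stop-codon neighbourhood),
* stop-codon excision — selecting placements whose predicted microexcision
  species delete the whole stop codon while preserving the downstream frame,
* scissile-phosphate placement — inverting the cut-position formula so a cut
  of a chosen rank lands on a requested phosphate (e.g. the 5' end of a stop
  codon, the layout used for in-frame donor tagging).

Donor design configures how the donor transcript acquires the 5'-hydroxyl
end RtcB needs: a Csm target site on the donor, a self-cleaving ribozyme, or
a Cas6-processed crRNA hairpin.  Mechanisms other than the RzB hammerhead
ribozyme leave mechanism-derived nucleotides on the donor 5' end, which
shift the chimeric junction and the reading frame of the appended body.

Guides are not filtered for GC content, secondary structure or
transcriptome-wide specificity; apply any such filter to the returned
designs before use.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

from .model import (
    CutSite,
    Junction,
    JunctionLibrary,
    ParameterError,
    TargetSite,
    enumerate_micro_junctions,
    innermost_cut,
    predict_cut_sites,
    reverse_complement,
)

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")

#: Default mechanism-derived 5'-leftover nucleotide counts.  These are
#: configuration, not measured constants: the hammerhead RzB self-cleaves at
#: its own 3' boundary and leaves nothing, Cas6 processing leaves the
#: canonical 8-nt repeat-derived 5' tag, and other cis-cleaving ribozymes
#: need structure nucleotides 5' of the cleavage site (5 is a placeholder).
DEFAULT_LEFTOVER_TABLE: Dict[str, int] = {
    "csm_site": 0,
    "rzb_hammerhead": 0,
    "other_ribozyme": 5,
    "cas6_hairpin": 8,
}


@dataclass(frozen=True)
class GuideDesign:
    """A designed crRNA spacer with its predicted cleavage/religation outcome."""

    spacer: str
    site: TargetSite
    predicted_species: JunctionLibrary
    predominant_cut: CutSite
    removes_stop: bool = False
    frame_safe: bool = False
    #: deletion length of the best stop-spanning species (None if none spans)
    stop_species_deletion: Optional[int] = None


@dataclass(frozen=True)
class DonorDesign:
    """A donor transcript and its 5'-hydroxyl generation mechanism.

    The predicted donor transcript after 5'-end processing is
    ``leftover_seq + body``; position 0 of that concatenation is the
    predicted 5' terminus that ligates onto the acceptor's 2',3'-cP end.
    """

    mechanism: str
    leftover_5p_nt: int
    body: str
    leftover_seq: str = ""
    name: str = "donor"

    def __post_init__(self) -> None:
        if self.mechanism == "rzb_hammerhead" and self.leftover_5p_nt != 0:
            raise ParameterError(
                "rzb_hammerhead leaves no 5' leftover nucleotides"
            )
        if self.leftover_5p_nt < 0:
            raise ParameterError("leftover_5p_nt must be non-negative")
        if len(self.leftover_seq) != self.leftover_5p_nt:
            raise ParameterError(
                f"leftover_seq length {len(self.leftover_seq)} != "
                f"leftover_5p_nt {self.leftover_5p_nt}"
            )

    @property
    def transcript(self) -> str:
        """Predicted donor transcript after 5'-end processing."""
        return self.leftover_seq + self.body


def _build_design(
    reference: str,
    transcript_id: str,
    start: int,
    site_length: int,
    *,
    n_cuts: int,
    spacing: int,
    cut_offset: int,
    flank_k: int,
    stop_interval: Optional[Tuple[int, int]] = None,
) -> GuideDesign:
    site = TargetSite.from_reference(
        transcript_id, reference, start, start + site_length,
        n_cuts=n_cuts, spacing=spacing, cut_offset=cut_offset,
    )
    species = enumerate_micro_junctions(
        site, references={transcript_id: reference}, flank_k=flank_k
    )
    removes_stop = False
    frame_safe = False
    stop_del: Optional[int] = None
    if stop_interval is not None:
        s0, s1 = stop_interval
        spanning = [
            j for j in species
            if j.left_pos <= s0 and j.right_pos >= s1
        ]
        if spanning:
            removes_stop = True
            stop_del = min(j.deletion_length for j in spanning)
            frame_safe = all(j.deletion_length % 3 == 0 for j in spanning)
    return GuideDesign(
        spacer=site.spacer,
        site=site,
        predicted_species=species,
        predominant_cut=innermost_cut(site),
        removes_stop=removes_stop,
        frame_safe=frame_safe,
        stop_species_deletion=stop_del,
    )


def tile_guides(
    reference: str,
    region: Tuple[int, int],
    site_length: int = 32,
    step: int = 1,
    *,
    transcript_id: str = "ref",
    n_cuts: int = 5,
    spacing: int = 6,
    cut_offset: int = 4,
    flank_k: int = 12,
    stop_interval: Optional[Tuple[int, int]] = None,
) -> List[GuideDesign]:
    """One design per placement of a ``site_length`` window tiled across region.

    Windows start at ``region[0]``, ``region[0] + step``, ... while they fit
    inside the region.  Each design carries its cut sites and predicted
    microexcision species.
    """
    r0, r1 = region
    if r0 < 0 or r1 > len(reference) or r1 <= r0:
        raise ParameterError(f"region [{r0},{r1}) outside reference")
    if step < 1:
        raise ParameterError(f"step must be >= 1, got {step}")
    if r1 - r0 < site_length:
        logger.warning(
            "region length %d < site_length %d: no placements", r1 - r0, site_length
        )
        return []
    designs = []
    for start in range(r0, r1 - site_length + 1, step):
        designs.append(
            _build_design(
                reference, transcript_id, start, site_length,
                n_cuts=n_cuts, spacing=spacing, cut_offset=cut_offset,
                flank_k=flank_k, stop_interval=stop_interval,
            )
        )
    return designs


def design_stop_excision(
    reference: str,
    orf: Tuple[int, int],
    *,
    transcript_id: str = "ref",
    site_length: int = 32,
    step: int = 1,
    n_cuts: int = 5,
    spacing: int = 6,
    cut_offset: int = 4,
    flank_k: int = 12,
) -> List[GuideDesign]:
    """Designs whose predicted microexcision removes the ORF's stop codon.

    Every window placement that keeps the stop codon inside the cut span is
    scored; only placements with at least one cis species deleting the whole
    stop codon are returned, ranked so that designs whose *innermost* 6-nt
    (single-spacing) species spans the stop come first — the dominant
    observed product — then by the deletion length needed, then position.
    With spacing 6 every returned design is frame-safe (6k ≡ 0 mod 3).
    """
    o0, o1 = orf
    if o1 - o0 < 3 or (o1 - o0) % 3 != 0:
        raise ParameterError(f"ORF [{o0},{o1}) is not a whole number of codons")
    stop = reference[o1 - 3 : o1]
    if stop not in STOP_CODONS:
        raise ParameterError(
            f"ORF does not end in an in-frame stop codon (found {stop!r})"
        )
    stop_interval = (o1 - 3, o1)
    # candidate windows: any placement keeping the stop codon within reach of
    # the cut span
    lo = max(0, stop_interval[1] - site_length)
    hi = min(len(reference) - site_length, stop_interval[0])
    if hi < lo:
        return []
    candidates = tile_guides(
        reference, (lo, min(hi + site_length, len(reference))),
        site_length=site_length, step=step, transcript_id=transcript_id,
        n_cuts=n_cuts, spacing=spacing, cut_offset=cut_offset,
        flank_k=flank_k, stop_interval=stop_interval,
    )
    hits = [d for d in candidates if d.removes_stop and d.frame_safe]

    def rank_key(d: GuideDesign):
        # innermost single-spacing species spanning the stop ranks best
        inner = d.predominant_cut.position
        innermost_six_spans = any(
            j.deletion_length == spacing
            and j.left_pos <= stop_interval[0]
            and j.right_pos >= stop_interval[1]
            and (j.left_pos == inner or j.right_pos == inner)
            for j in d.predicted_species
        )
        return (not innermost_six_spans, d.stop_species_deletion, d.site.start)

    return sorted(hits, key=rank_key)


def place_scissile_at(
    reference: str,
    phosphate_pos: int,
    predominant_rank: Optional[int] = None,
    *,
    transcript_id: str = "ref",
    site_length: int = 32,
    n_cuts: int = 5,
    spacing: int = 6,
    cut_offset: int = 4,
    flank_k: int = 12,
) -> GuideDesign:
    """The unique placement putting the cut of ``predominant_rank`` at a position.

    Inverts the cut-position formula: ``site.start = phosphate_pos -
    cut_offset - rank*spacing``.  The default rank is the innermost cut,
    ``ceil((n_cuts - 1) / 2)`` — the register of the dominant 6-nt species —
    but any rank below ``n_cuts`` may be requested.
    """
    if predominant_rank is None:
        predominant_rank = (n_cuts - 1 + 1) // 2  # ceil((n_cuts-1)/2)
    if not 0 <= predominant_rank < n_cuts:
        raise ParameterError(
            f"predominant_rank {predominant_rank} not in [0, {n_cuts})"
        )
    start = phosphate_pos - cut_offset - predominant_rank * spacing
    if start < 0 or start + site_length > len(reference):
        raise ParameterError(
            f"placement [{start},{start + site_length}) runs off the reference "
            f"(length {len(reference)})"
        )
    design = _build_design(
        reference, transcript_id, start, site_length,
        n_cuts=n_cuts, spacing=spacing, cut_offset=cut_offset, flank_k=flank_k,
    )
    cuts = predict_cut_sites(design.site)
    assert cuts[predominant_rank].position == phosphate_pos
    return GuideDesign(
        spacer=design.spacer,
        site=design.site,
        predicted_species=design.predicted_species,
        predominant_cut=cuts[predominant_rank],
        removes_stop=design.removes_stop,
        frame_safe=design.frame_safe,
        stop_species_deletion=design.stop_species_deletion,
    )


def design_donor(
    body: str,
    mechanism: str,
    leftover_table: Optional[Mapping[str, int]] = None,
    *,
    leftover_seq: Optional[str] = None,
    name: str = "donor",
    warn_frame: bool = True,
) -> DonorDesign:
    """Configure a donor construct's 5'-hydroxyl generation mechanism.

    ``leftover_table`` maps each mechanism to the nucleotides it leaves on
    the processed donor 5' end (forced to 0 for the RzB hammerhead, which
    cleaves exactly at its 3' boundary).  When the leftover count is not a
    multiple of 3 and the body is meant to continue an acceptor reading
    frame, a frame warning is emitted.
    """
    if not body:
        raise ParameterError("donor body must be non-empty")
    table = dict(DEFAULT_LEFTOVER_TABLE)
    if leftover_table:
        table.update(leftover_table)
    if mechanism not in table:
        raise ParameterError(
            f"unknown donor mechanism {mechanism!r}; valid options: "
            f"{sorted(table)}"
        )
    n_left = 0 if mechanism == "rzb_hammerhead" else table[mechanism]
    if leftover_seq is None:
        # mechanism-derived sequence is construct-specific; placeholder Gs
        leftover_seq = "G" * n_left
    if len(leftover_seq) != n_left:
        raise ParameterError(
            f"leftover_seq length {len(leftover_seq)} != configured count {n_left}"
        )
    if warn_frame and n_left % 3 != 0:
        warnings.warn(
            f"mechanism {mechanism!r} leaves {n_left} nt (not a multiple of 3): "
            "an in-frame body will be appended out of frame",
            stacklevel=2,
        )
    return DonorDesign(
        mechanism=mechanism,
        leftover_5p_nt=n_left,
        body=body,
        leftover_seq=leftover_seq,
        name=name,
    )


def chimera_in_frame(
    acceptor_cut_pos: int, orf_start: int, leftover_5p_nt: int
) -> bool:
    """Whether a chimeric ORF reads through in frame.

    With the donor body beginning in frame 0 of itself, the chimera is in
    frame iff ``(acceptor_cut_pos - orf_start) mod 3 ==
    (3 - leftover_5p_nt mod 3) mod 3``.
    """
    return (acceptor_cut_pos - orf_start) % 3 == (3 - leftover_5p_nt % 3) % 3
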