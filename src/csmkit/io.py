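"""Format plumbing: FASTA, BED, and junction-library TSV/FASTA.

All coordinates in outputs are 0-based, half-open.  Cut sites are written as
6-column BED (name = ``site_id:rank``, score = rank, strand = ``+``);
junction libraries round-trip through a TSV whose ``context`` column holds
the seam 2k-mer.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import CutSite, Junction, JunctionLibrary, junction_reference

JUNCTION_TSV_COLUMNS = [
    "id", "kind", "left_transcript", "left_pos",
    "right_transcript", "right_pos", "deletion_length", "frame_delta",
    "ambiguous", "context",
]


def read_fasta(path) -> Dict[str, str]:
    """FASTA → {record id: uppercase sequence}; raises on malformed input."""
    refs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.seq:
            raise ValueError(f"malformed FASTA: empty record {rec.id!r} in {path}")
        refs[rec.id] = str(rec.seq).upper()
    if not refs:
        raise ValueError(f"malformed FASTA: no records in {path}")
    return refs


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_cut_sites_bed(
    cuts: Iterable[CutSite], path, site_id: str = "site"
) -> None:
    with open(path, "w") as fh:
        for c in cuts:
            fh.write(
                f"{c.transcript_id}\t{c.position}\t{c.position + 1}\t"
                f"{site_id}:{c.rank}\t{c.rank}\t+\n"
            )


def junction_table(lib: JunctionLibrary) -> pd.DataFrame:
    """Junction library as a DataFrame (contexts included when resolvable)."""
    rows = []
    for j in lib.junctions:
        try:
            ctx = junction_reference(j, lib)
        except Exception:
            ctx = ""
        rows.append(
            {
                "id": j.id,
                "kind": j.kind,
                "left_transcript": j.left_transcript,
                "left_pos": j.left_pos,
                "right_transcript": j.right_transcript,
                "right_pos": j.right_pos,
                "deletion_length": j.deletion_length,
                "frame_delta": j.frame_delta,
                "ambiguous": j.ambiguous,
                "context": ctx,
            }
        )
    return pd.DataFrame(rows, columns=JUNCTION_TSV_COLUMNS)


def write_junction_tsv(lib: JunctionLibrary, path) -> None:
    junction_table(lib).to_csv(path, sep="\t", index=False)


def write_junction_fasta(lib: JunctionLibrary, path) -> None:
    write_fasta(
        {j.id: junction_reference(j, lib) for j in lib.junctions}, path
    )


def read_junction_tsv(
    path,
    references: Optional[Mapping[str, str]] = None,
    flank_k: int = 12,
) -> JunctionLibrary:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    junctions: List[Junction] = []
    for _, row in df.iterrows():
        deletion = row.get("deletion_length")
        frame = row.get("frame_delta")
        junctions.append(
            Junction(
                id=row["id"],
                kind=row["kind"],
                left_transcript=row["left_transcript"],
                left_pos=int(row["left_pos"]),
                right_transcript=row["right_transcript"],
                right_pos=int(row["right_pos"]),
                deletion_length=None if pd.isna(deletion) else int(deletion),
                frame_delta=None if pd.isna(frame) else int(frame),
                ambiguous=bool(row.get("ambiguous", False)),
            )
        )
    return JunctionLibrary(
        junctions, flank_k, dict(references) if references else {}
    )
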