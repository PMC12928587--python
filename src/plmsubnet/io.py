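"""Readers and writers for the package's on-disk formats.

Sequences travel as FASTA (record id = first whitespace-delimited header
token); structural annotations as a TSV with columns ``id``, ``cath_label``
and ``ss8`` and/or ``ss3`` (8-state strings are reduced on read); split
manifests as a two-column TSV.  All tabular I/O goes through pandas.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotations import (
    AnnotationError,
    DomainRecord,
    SplitAssignment,
    reduce_dssp,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "write_annotations",
    "attach_annotations",
    "load_dataset",
    "read_split",
    "write_split",
]


def read_fasta(path: str | Path) -> list[DomainRecord]:
    """Read sequences; the record id is the first token of the header."""
    return [
        DomainRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: list[DomainRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the annotation TSV; reduces ``ss8`` to ``ss3`` when needed."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "id" not in df.columns:
        raise AnnotationError("annotation table must have an 'id' column")
    if "ss3" not in df.columns and "ss8" in df.columns:
        df["ss3"] = df["ss8"].map(lambda s: reduce_dssp(s) if s else "")
    return df


def write_annotations(records: list[DomainRecord], path: str | Path) -> None:
    rows = [
        {"id": r.id, "cath_label": r.cath_label or "", "ss3": r.ss3 or ""}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def attach_annotations(
    records: list[DomainRecord], annot: pd.DataFrame
) -> list[DomainRecord]:
    """Join an annotation table onto FASTA records by id."""
    table = annot.set_index("id")
    out = []
    for r in records:
        if r.id not in table.index:
            out.append(r)
            continue
        row = table.loc[r.id]
        cath = row.get("cath_label", "") or None
        ss3 = row.get("ss3", "") or None
        out.append(DomainRecord(id=r.id, sequence=r.sequence, cath_label=cath, ss3=ss3))
    return out


def load_dataset(fasta: str | Path, annot: str | Path | None = None) -> list[DomainRecord]:
    records = read_fasta(fasta)
    if annot is not None:
        records = attach_annotations(records, read_annotations(annot))
    return records


def read_split(path: str | Path, seed: int = -1) -> SplitAssignment:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SplitAssignment(
        assignment=dict(zip(df["id"], df["partition"])), seed=seed
    )


def write_split(split: SplitAssignment, path: str | Path) -> None:
    pd.DataFrame(
        [{"id": i, "partition": p} for i, p in split.assignment.items()]
    ).to_csv(path, sep="\t", index=False)
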