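"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions
-----------
External alignment coordinates (BLAST tabular dialect) are 1-based
inclusive; everything internal to the package uses 0-based half-open
indices. The conversion happens in this module only, so no other module
needs to reason about the off-by-one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentHit",
    "read_fasta",
    "write_fasta",
    "read_tabular_hits",
    "write_tabular_hits",
    "read_presence_matrix",
    "write_presence_matrix",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_config",
]


@dataclass
class AlignmentHit:
    """One local alignment between a query and a subject sequence.

    Coordinates follow the BLAST outfmt-6 convention: 1-based, inclusive,
    with subject_start > subject_end for reverse-strand hits. Query
    coordinates are normalized so query_start <= query_end; the original
    orientation is preserved in ``subject_start``/``subject_end``.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int = 0
    gap_opens: int = 0
    query_start: int = 1
    query_end: int = 1
    subject_start: int = 1
    subject_end: int = 1
    e_value: float = 0.0
    bit_score: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )
        if self.e_value < 0:
            raise ValueError(f"negative e_value {self.e_value}")
        if self.query_start > self.query_end:
            # normalize query interval; remember strand via subject coords
            self.query_start, self.query_end = self.query_end, self.query_start
            self.subject_start, self.subject_end = (
                self.subject_end,
                self.subject_start,
            )

    @property
    def reverse_strand(self) -> bool:
        return self.subject_start > self.subject_end

    @property
    def query_interval(self) -> tuple[int, int]:
        """Query span as a 0-based half-open interval."""
        return self.query_start - 1, self.query_end


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Raises ``ValueError`` naming the offending record on duplicates or
    empty sequences.
    """
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
        records[rec.id] = seq
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> Path:
    path = Path(path)
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)
    return path


_OUTFMT6_COLS = 12


def read_tabular_hits(path: str | Path) -> list[AlignmentHit]:
    """Parse BLAST outfmt-6 (12 tab-separated columns) into AlignmentHits."""
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != _OUTFMT6_COLS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_OUTFMT6_COLS} columns, "
                    f"got {len(parts)}"
                )
            try:
                hit = AlignmentHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    percent_identity=float(parts[2]),
                    alignment_length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    query_start=int(parts[6]),
                    query_end=int(parts[7]),
                    subject_start=int(parts[8]),
                    subject_end=int(parts[9]),
                    e_value=float(parts[10]),
                    bit_score=float(parts[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_tabular_hits(hits: Iterable[AlignmentHit], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.3f}",
                        h.alignment_length,
                        h.mismatches,
                        h.gap_opens,
                        h.query_start,
                        h.query_end,
                        h.subject_start,
                        h.subject_end,
                        f"{h.e_value:.3g}",
                        f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )
    return path


def read_presence_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x genome presence/count matrix.

    Accepts either a plain TSV with gene ids in the first column and one
    column per genome (0/1 or counts), or a Roary-style
    ``gene_presence_absence.csv`` where genome columns contain gene names
    (non-empty cell = present).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dupes[:5]}")
    if "Annotation" in df.columns:  # Roary dialect: drop metadata columns
        meta_cols = [
            c
            for c in df.columns
            if c
            in {
                "Non-unique Gene name",
                "Annotation",
                "No. isolates",
                "No. sequences",
                "Avg sequences per isolate",
                "Genome Fragment",
                "Order within Fragment",
                "Accessory Fragment",
                "Accessory Order with Fragment",
                "QC",
                "Min group size nuc",
                "Max group size nuc",
                "Avg group size nuc",
            }
        ]
        df = df.drop(columns=meta_cols)
        mat = df.notna() & (df != "")
        return mat.astype(int)
    try:
        mat = df.fillna("0").astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric presence matrix {path}: {exc}") from exc
    if (mat.values < 0).any():
        raise ValueError(f"negative counts in presence matrix {path}")
    return mat.astype(int)


def write_presence_matrix(matrix: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_csv(path, sep="\t")
    return path


def read_distance_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"distance matrix {path} row/column labels disagree")
    return list(df.index), df.values.astype(float)


def write_distance_matrix(
    labels: Iterable[str], matrix: np.ndarray, path: str | Path
) -> Path:
    labels = list(labels)
    path = Path(path)
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path, sep="\t")
    return path


def read_config(path: str | Path) -> dict[str, str]:
    """Read a plain ``key = value`` config file; '#' starts a comment."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            cfg[key] = value
    return cfg
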