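"""Readers and writers for every external file the pipeline touches.

All interval inputs are normalised to 0-based half-open coordinates at read
time, chromosome names are taken verbatim, and files are tab-separated with a
required header and ``#`` comment lines ignored.  Validation is strict: a
malformed file is a hard error naming the offending record, never a silent
reinterpretation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

__all__ = [
    "GuideRecord",
    "CountMatrix",
    "CopyNumberSegment",
    "SvRecord",
    "SvType",
    "read_guide_library",
    "read_segments",
    "read_counts",
    "read_sv_bedpe",
    "read_expression",
    "read_gene_list",
    "read_gene_annotation",
    "write_results",
]


@dataclass(frozen=True)
class GuideRecord:
    """One sgRNA: its identifier, target gene and genomic location (0-based, half-open)."""

    guide_id: str
    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"guide {self.guide_id!r}: empty chromosome name")
        if self.start >= self.end:
            raise ValueError(
                f"guide {self.guide_id!r}: start ({self.start}) must be < end ({self.end})"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class CopyNumberSegment:
    """A genomic interval (0-based, half-open) with an absolute copy number."""

    chrom: str
    start: int
    end: int
    copy_number: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.copy_number < 0:
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end}: "
                f"negative copy number {self.copy_number}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class SvType(str, Enum):
    TANDEM_DUPLICATION = "tandem_duplication"
    DELETION = "deletion"
    INVERSION = "inversion"
    TRANSLOCATION = "translocation"


@dataclass(frozen=True)
class SvRecord:
    """A structural-variant call as a breakpoint pair with an optional assembly score."""

    sv_type: SvType
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    assembly_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sv_type in (SvType.TANDEM_DUPLICATION, SvType.DELETION):
            if self.chrom1 != self.chrom2:
                raise ValueError(
                    f"{self.sv_type.value} must be intra-chromosomal, "
                    f"got {self.chrom1} / {self.chrom2}"
                )
            if self.pos1 >= self.pos2:
                raise ValueError(
                    f"{self.sv_type.value} at {self.chrom1}: pos1 ({self.pos1}) "
                    f"must be < pos2 ({self.pos2})"
                )


class CountMatrix:
    """Raw sgRNA counts (guides x samples) with a designated plasmid control column."""

    def __init__(self, counts: pd.DataFrame, plasmid_id: str):
        if plasmid_id not in counts.columns:
            raise ValueError(
                f"plasmid column {plasmid_id!r} not among samples: "
                f"{list(counts.columns)}"
            )
        if counts.columns.duplicated().any():
            dups = counts.columns[counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate guide ids: {dups}")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        self.plasmid_id = plasmid_id

    @property
    def guides(self) -> List[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> List[str]:
        return list(self.counts.columns)

    @property
    def shape(self):
        return self.counts.shape

    def subset_guides(self, guide_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(guide_ids)], self.plasmid_id)


def _read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, skipinitialspace=True)


def _require_columns(df: pd.DataFrame, cols, path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_guide_library(path: str) -> List[GuideRecord]:
    """Read a guide-library TSV (guide_id, gene, chrom, start, end) in file order."""
    df = _read_tsv(path)
    _require_columns(df, ["guide_id", "gene", "chrom", "start", "end"], path)
    records: List[GuideRecord] = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gid = str(row.guide_id).strip()
        if gid in seen:
            raise ValueError(f"{path}: duplicate guide_id {gid!r}")
        seen.add(gid)
        start, end = int(row.start), int(row.end)
        if start >= end:
            raise ValueError(
                f"{path} line {i}: guide {gid!r} start ({start}) >= end ({end})"
            )
        records.append(
            GuideRecord(gid, str(row.gene).strip(), str(row.chrom).strip(), start, end)
        )
    return records


def read_segments(path: str) -> Dict[str, List[CopyNumberSegment]]:
    """Read a BED-like copy-number segmentation, sorted per chromosome.

    Columns: chrom, start, end, copy_number.  Overlapping segments within a
    chromosome are rejected.
    """
    df = _read_tsv(path)
    _require_columns(df, ["chrom", "start", "end", "copy_number"], path)
    segs = [
        CopyNumberSegment(
            str(r.chrom).strip(), int(r.start), int(r.end), float(r.copy_number)
        )
        for r in df.itertuples(index=False)
    ]
    return group_segments(segs)


def group_segments(segments) -> Dict[str, List[CopyNumberSegment]]:
    """Group segments by chromosome, sort by start, and reject overlaps."""
    by_chrom: Dict[str, List[CopyNumberSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, lst in by_chrom.items():
        lst.sort(key=lambda s: s.start)
        for a, b in zip(lst, lst[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping segments on {chrom}: "
                    f"[{a.start}, {a.end}) and [{b.start}, {b.end})"
                )
    return by_chrom


def read_counts(path: str, plasmid_id: str) -> CountMatrix:
    """Read a counts TSV: first column guide_id, one column per sample."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    out = {}
    for col in df.columns:
        converted = []
        for gid, v in df[col].items():
            try:
                iv = int(str(v).strip())
            except (ValueError, TypeError):
                raise ValueError(
                    f"{path}: non-integer count {v!r} at guide {gid!r}, sample {col!r}"
                ) from None
            if iv < 0:
                raise ValueError(
                    f"{path}: negative count {iv} at guide {gid!r}, sample {col!r}"
                )
            converted.append(iv)
        out[col] = converted
    counts = pd.DataFrame(out, index=df.index.astype(str), dtype=np.int64)
    counts.index.name = "guide_id"
    return CountMatrix(counts, plasmid_id)


def read_sv_bedpe(path: str) -> List[SvRecord]:
    """Read a BEDPE-like SV table (sv_type, chrom1, pos1, chrom2, pos2, assembly_score).

    A blank assembly-score field is parsed as absent (``None``), never as zero.
    """
    df = _read_tsv(path)
    _require_columns(df, ["sv_type", "chrom1", "pos1", "chrom2", "pos2"], path)
    records: List[SvRecord] = []
    for row in df.itertuples(index=False):
        token = str(row.sv_type).strip()
        try:
            sv_type = SvType(token)
        except ValueError:
            raise ValueError(
                f"{path}: unknown sv_type {token!r}; expected one of "
                f"{[t.value for t in SvType]}"
            ) from None
        score: Optional[float] = None
        if "assembly_score" in df.columns:
            raw = getattr(row, "assembly_score")
            if raw is not None and not (isinstance(raw, float) and np.isnan(raw)):
                text = str(raw).strip()
                if text:
                    score = float(text)
        records.append(
            SvRecord(sv_type, str(row.chrom1).strip(), int(row.pos1),
                     str(row.chrom2).strip(), int(row.pos2), score)
        )
    return records


def read_expression(path: str) -> pd.DataFrame:
    """Read a gene x sample RPKM table (first column gene)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: RPKM values must be non-negative")
    return df


def read_gene_list(path: str) -> set:
    """Read a plain-text gene list, one symbol per line; '#' comments ignored."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                genes.add(sym)
    return genes


def read_gene_annotation(path: str) -> pd.DataFrame:
    """Read a gene annotation TSV (gene, chrom, start, end), indexed by gene."""
    df = _read_tsv(path)
    _require_columns(df, ["gene", "chrom", "start", "end"], path)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].str.strip().to_numpy(),
            "start": df["start"].astype(int).to_numpy(),
            "end": df["end"].astype(int).to_numpy(),
        },
        index=pd.Index(df["gene"].str.strip().to_numpy()),
    )
    out.index.name = "gene"
    if (out["start"] >= out["end"]).any():
        bad = out.index[out["start"] >= out["end"]][0]
        raise ValueError(f"{path}: gene {bad!r} has start >= end")
    if out.index.duplicated().any():
        bad = out.index[out.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene {bad!r}")
    return out


_FLOAT_FMT = "%.8g"


def write_results(result, outdir: str) -> Dict[str, str]:
    """Write the three result tables of a per-sample correction run.

    Produces ``guide_level.tsv``, ``gene_level.tsv`` and ``segments.tsv`` under
    *outdir*; missing values are written as empty strings.  Returns the paths.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "guide": os.path.join(outdir, "guide_level.tsv"),
        "gene": os.path.join(outdir, "gene_level.tsv"),
        "segment": os.path.join(outdir, "segments.tsv"),
    }
    result.guide_table.to_csv(
        paths["guide"], sep="\t", float_format=_FLOAT_FMT, na_rep="", index=False
    )
    result.gene_table.to_csv(
        paths["gene"], sep="\t", float_format=_FLOAT_FMT, na_rep="", index=False
    )
    result.segment_table.to_csv(
        paths["segment"], sep="\t", float_format=_FLOAT_FMT, na_rep="", index=False
    )
    return paths
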