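"""Interval arithmetic over copy-number segments.

Gene and chromosome copy numbers are size-weighted means of the overlapping
segments; the copy-number ratio divides the gene (or segment) copy number by
its chromosome's copy number.  A ratio near 1 marks whole-chromosome events
(including whole-chromosome duplications), above 1 focal amplification, below
1 focal deletion.  Ploidy is the genome-wide size-weighted mean copy number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

import pandas as pd

from .io_formats import CopyNumberSegment

logger = logging.getLogger(__name__)

__all__ = [
    "RatioRecord",
    "PloidyEstimate",
    "weighted_interval_cn",
    "chromosome_cn",
    "copy_number_ratio",
    "ploidy",
    "classify_nonexpressed",
    "gene_ratio_table",
]


@dataclass(frozen=True)
class RatioRecord:
    gene: str
    gene_cn: float
    chrom: str
    chrom_cn: float
    ratio: float
    covered_bp: int


@dataclass(frozen=True)
class PloidyEstimate:
    sample: str
    ploidy: float
    chrom_cn: Dict[str, float] = field(default_factory=dict)

    def chrom_cn_group(self, chrom: str, cap: int = 5) -> str:
        """Integer-rounded chromosome-copies stratum label ('1'..'4', '5+')."""
        n = round(self.chrom_cn[chrom])
        return f"{cap}+" if n >= cap else str(int(n))


def weighted_interval_cn(
    segments: Iterable[CopyNumberSegment], chrom: str, start: int, end: int
) -> Tuple[Optional[float], int]:
    """Size-weighted mean copy number of segments overlapping [start, end).

    Returns ``(cn, covered_bp)``; ``(None, 0)`` when no segment overlaps —
    "no coverage" is distinguished from copy number zero.
    """
    if start >= end:
        raise ValueError(f"empty interval [{start}, {end})")
    num = 0.0
    covered = 0
    for seg in segments:
        if seg.chrom != chrom:
            continue
        ov = min(seg.end, end) - max(seg.start, start)
        if ov > 0:
            num += seg.copy_number * ov
            covered += ov
    if covered == 0:
        return None, 0
    return num / covered, covered


def chromosome_cn(segments: Iterable[CopyNumberSegment], chrom: str) -> float:
    """Size-weighted mean copy number over all segments of one chromosome."""
    num = 0.0
    denom = 0
    for seg in segments:
        if seg.chrom == chrom:
            num += seg.copy_number * seg.length
            denom += seg.length
    if denom == 0:
        raise ValueError(f"no segments on chromosome {chrom!r}")
    return num / denom


def copy_number_ratio(gene_cn: float, chrom_cn: float) -> float:
    """Gene copy number divided by chromosome copy number."""
    if chrom_cn <= 0:
        raise ValueError(f"chromosome copy number must be > 0, got {chrom_cn}")
    return gene_cn / chrom_cn


def ploidy(segments: Iterable[CopyNumberSegment], sample: str = "") -> PloidyEstimate:
    """Genome-wide size-weighted mean copy number, plus per-chromosome values."""
    segs = list(segments)
    if not segs:
        raise ValueError("no segments supplied")
    chroms = sorted({s.chrom for s in segs})
    per_chrom = {c: chromosome_cn(segs, c) for c in chroms}
    num = sum(s.copy_number * s.length for s in segs)
    denom = sum(s.length for s in segs)
    return PloidyEstimate(sample, num / denom, per_chrom)


def classify_nonexpressed(
    expr: pd.DataFrame, sample: str, threshold: float = 1.0
) -> Set[str]:
    """Genes with RPKM strictly below *threshold* in *sample* (default < 1)."""
    if sample not in expr.columns:
        raise ValueError(f"sample {sample!r} not in expression table")
    vals = expr[sample]
    return set(vals.index[vals < threshold])


def gene_ratio_table(
    segments: Iterable[CopyNumberSegment],
    genes: pd.DataFrame,
    expr: Optional[pd.DataFrame] = None,
    sample: Optional[str] = None,
) -> List[RatioRecord]:
    """One RatioRecord per covered gene; uncovered genes are omitted and logged.

    *genes* is an annotation frame indexed by gene with chrom/start/end columns.
    """
    segs = list(segments)
    chrom_cache: Dict[str, float] = {}
    out: List[RatioRecord] = []
    skipped: List[str] = []
    for gene, row in genes.iterrows():
        cn, covered = weighted_interval_cn(segs, row["chrom"], row["start"], row["end"])
        if cn is None:
            skipped.append(str(gene))
            continue
        if row["chrom"] not in chrom_cache:
            chrom_cache[row["chrom"]] = chromosome_cn(segs, row["chrom"])
        ccn = chrom_cache[row["chrom"]]
        out.append(
            RatioRecord(str(gene), cn, row["chrom"], ccn,
                        copy_number_ratio(cn, ccn), covered)
        )
    if skipped:
        logger.info("omitted %d gene(s) without segment coverage: %s%s",
                    len(skipped), skipped[:10], "..." if len(skipped) > 10 else "")
    return out
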