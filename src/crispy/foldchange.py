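"""Raw sgRNA counts to log2 fold changes versus the plasmid control.

The pipeline is: discard guides poorly represented in the plasmid library
(raw plasmid count below 30 by default), library-size normalise every sample
to the mean raw library size, take log2 of (count + pseudocount) against the
plasmid column, average guides to gene level, and optionally rescale so the
known-essential genes average a fold change of -1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, GuideRecord

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationConfig",
    "FoldChangeTable",
    "size_factor_normalize",
    "filter_low_plasmid",
    "log2_foldchange",
    "gene_level",
    "scale_to_essentials",
    "replicate_correlation",
    "average_replicates",
    "counts_to_gene_foldchange",
]


@dataclass
class NormalizationConfig:
    pseudocount: float = 1.0
    min_plasmid_count: int = 30

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.min_plasmid_count < 0:
            raise ValueError("min_plasmid_count must be >= 0")


@dataclass
class FoldChangeTable:
    """Log2 fold changes at guide or gene level (rows: ids, columns: samples)."""

    level: str  # "guide" | "gene"
    fc: pd.DataFrame

    def __post_init__(self) -> None:
        if self.level not in ("guide", "gene"):
            raise ValueError(f"level must be 'guide' or 'gene', got {self.level!r}")
        if not np.isfinite(self.fc.to_numpy()).all():
            raise ValueError("fold changes must be finite")
        if self.fc.index.duplicated().any():
            raise ValueError("duplicate ids in fold-change table")

    @property
    def ids(self) -> List[str]:
        return list(self.fc.index)

    @property
    def samples(self) -> List[str]:
        return list(self.fc.columns)


def size_factor_normalize(cm: CountMatrix) -> pd.DataFrame:
    """Scale each sample so its total equals the mean raw library size."""
    totals = cm.counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"sample(s) with zero total counts: {zero}")
    target = totals.mean()
    return cm.counts * (target / totals)


def filter_low_plasmid(cm: CountMatrix, cfg: Optional[NormalizationConfig] = None) -> CountMatrix:
    """Drop guides whose *raw* plasmid count is below ``min_plasmid_count``."""
    cfg = cfg or NormalizationConfig()
    plasmid = cm.counts[cm.plasmid_id]
    keep = plasmid >= cfg.min_plasmid_count
    dropped = plasmid.index[~keep].tolist()
    if dropped:
        logger.info(
            "dropped %d guide(s) with plasmid count < %d: %s%s",
            len(dropped), cfg.min_plasmid_count, dropped[:10],
            "..." if len(dropped) > 10 else "",
        )
    if not keep.any():
        raise ValueError(
            f"all guides removed by the plasmid-count filter "
            f"(min_plasmid_count={cfg.min_plasmid_count})"
        )
    return CountMatrix(cm.counts.loc[keep], cm.plasmid_id)


def log2_foldchange(
    norm: pd.DataFrame, plasmid_id: str, pseudocount: float = 1.0
) -> FoldChangeTable:
    """Guide-level log2 fold change of each sample against the plasmid column.

    fc[g, s] = log2(norm[g, s] + pseudocount) - log2(norm[g, plasmid] + pseudocount).
    The plasmid column is excluded from the output.
    """
    if plasmid_id not in norm.columns:
        raise ValueError(f"plasmid column {plasmid_id!r} not in matrix")
    shifted = norm + pseudocount
    if (shifted.to_numpy() <= 0).any():
        raise ValueError(
            "zero normalized count with pseudocount=0; use pseudocount > 0"
        )
    logs = np.log2(shifted)
    fc = logs.drop(columns=[plasmid_id]).sub(logs[plasmid_id], axis=0)
    return FoldChangeTable("guide", fc)


def gene_level(fct: FoldChangeTable, library: Iterable[GuideRecord]) -> FoldChangeTable:
    """Average guide fold changes to gene level (arithmetic mean per gene)."""
    if fct.level != "guide":
        raise ValueError("gene_level expects a guide-level table")
    gene_of = {g.guide_id: g.gene for g in library}
    missing = [gid for gid in fct.ids if gid not in gene_of]
    if missing:
        raise ValueError(f"guide(s) missing from library: {missing[:10]}")
    genes = pd.Series([gene_of[gid] for gid in fct.ids], index=fct.fc.index)
    agg = fct.fc.groupby(genes, sort=True).mean()
    agg.index.name = "gene"
    return FoldChangeTable("gene", agg)


def scale_to_essentials(fct: FoldChangeTable, essential: Iterable[str]) -> FoldChangeTable:
    """Rescale so the mean fold change over present essential genes is exactly -1."""
    present = [g for g in fct.ids if g in set(essential)]
    if not present:
        raise ValueError("no essential genes present in the fold-change table")
    mean_ess = fct.fc.loc[present].to_numpy().mean()
    if mean_ess >= 0:
        raise ValueError(
            f"mean essential fold change is {mean_ess:.4f} >= 0: screen QC failure"
        )
    return FoldChangeTable(fct.level, fct.fc / abs(mean_ess))


def replicate_correlation(fc_a: pd.Series, fc_b: pd.Series) -> float:
    """Pearson correlation of two gene fold-change vectors over shared genes."""
    shared = fc_a.index.intersection(fc_b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared gene ids, got {len(shared)}")
    return float(np.corrcoef(fc_a.loc[shared], fc_b.loc[shared])[0, 1])


def average_replicates(
    fct: FoldChangeTable, replicate_map: Dict[str, List[str]]
) -> FoldChangeTable:
    """Average per-replicate columns into one column per cell line.

    ``replicate_map`` maps cell-line id -> list of replicate column names.
    """
    cols = {}
    for line, reps in replicate_map.items():
        missing = [r for r in reps if r not in fct.fc.columns]
        if missing:
            raise ValueError(f"replicate column(s) {missing} absent for {line!r}")
        cols[line] = fct.fc[reps].mean(axis=1)
    return FoldChangeTable(fct.level, pd.DataFrame(cols, index=fct.fc.index))


def counts_to_gene_foldchange(
    cm: CountMatrix,
    library: Iterable[GuideRecord],
    cfg: Optional[NormalizationConfig] = None,
) -> FoldChangeTable:
    """Convenience: filter, normalise, fold-change and aggregate in one call."""
    cfg = cfg or NormalizationConfig()
    filtered = filter_low_plasmid(cm, cfg)
    norm = size_factor_normalize(filtered)
    guide_fc = log2_foldchange(norm, cm.plasmid_id, cfg.pseudocount)
    return gene_level(guide_fc, library)
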