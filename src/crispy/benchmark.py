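"""Recall curves and AURC-based bias quantification.

Genes are ranked by fold change from most depleted to least; the recall
curve of a gene set is the fraction of the set recovered within the top k
ranks, and the AURC is the mean recall over all N ranks.  An AURC near 0.5
means no enrichment, near 1 means the set concentrates among the strongest
depletions.  Stratifying non-expressed genes by copy number, copy-number
ratio, ploidy or chromosome copies quantifies the gene-independent bias a
correction should remove.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RecallResult",
    "StratifiedAurc",
    "recall_curve",
    "essential_recall",
    "stratified_aurc",
    "compare_corrections",
    "cn_stratum",
    "ratio_stratum",
    "DEFAULT_RATIO_BINS",
]

# bin edges follow the ratio grouping style {<1, [1,2), [2,3), [3,4), >=4}
DEFAULT_RATIO_BINS: Tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)

MIN_STRATUM_GENES = 5


@dataclass
class RecallResult:
    ranked_ids: List[str]
    gene_set: str
    curve: np.ndarray
    aurc: float


@dataclass(frozen=True)
class StratifiedAurc:
    stratum: str
    sample: str
    aurc: float
    n_genes: int


def recall_curve(fc: pd.Series, gene_set: Iterable[str], label: str = "") -> RecallResult:
    """Recall curve and AURC of *gene_set* across genes ranked ascending by fc.

    Ties in fold change are broken by stable lexicographic gene order.  The
    AURC is the mean of recall(k) over k = 1..N with N the ranked universe.
    """
    members = set(gene_set) & set(fc.index)
    if not members:
        raise ValueError(f"gene set {label!r} has no overlap with the ranking")
    order = fc.sort_index(kind="stable").sort_values(kind="stable")
    ranked = list(order.index)
    hits = np.array([g in members for g in ranked], dtype=float)
    curve = np.cumsum(hits) / hits.sum()
    return RecallResult(ranked, label, curve, float(curve.mean()))


def essential_recall(fc: pd.Series, essential: Iterable[str]) -> float:
    """AURC of the known-essential gene set: the screen's recall QC metric."""
    return recall_curve(fc, essential, label="essential").aurc


def stratified_aurc(
    fc: pd.Series,
    strata: Dict[str, str],
    restrict: Optional[Set[str]] = None,
    sample: str = "",
    min_genes: int = MIN_STRATUM_GENES,
) -> List[StratifiedAurc]:
    """AURC per stratum of (stratum members ∩ restrict) against the full ranking.

    *strata* maps gene -> stratum label (e.g. copy-number group or ratio bin);
    *restrict* is typically the sample's non-expressed gene set.  Strata with
    fewer than *min_genes* genes in the ranking are skipped with a log entry.
    """
    universe = set(fc.index)
    by_label: Dict[str, Set[str]] = {}
    for gene, label in strata.items():
        if gene in universe and (restrict is None or gene in restrict):
            by_label.setdefault(label, set()).add(gene)
    out = []
    for label in sorted(by_label):
        genes = by_label[label]
        if len(genes) < min_genes:
            logger.info("stratum %r skipped: only %d gene(s)", label, len(genes))
            continue
        rc = recall_curve(fc, genes, label=label)
        out.append(StratifiedAurc(label, sample, rc.aurc, len(genes)))
    return out


def compare_corrections(
    fc_a: pd.Series,
    fc_b: pd.Series,
    strata: Dict[str, str],
    restrict: Optional[Set[str]] = None,
    sample: str = "",
) -> pd.DataFrame:
    """Paired AURCs of two rankings (e.g. original vs corrected) per stratum."""
    if set(fc_a.index) != set(fc_b.index):
        raise ValueError("the two fold-change vectors must share one gene universe")
    res_a = {r.stratum: r for r in stratified_aurc(fc_a, strata, restrict, sample)}
    res_b = {r.stratum: r for r in stratified_aurc(fc_b, strata, restrict, sample)}
    rows = []
    for label in sorted(set(res_a) & set(res_b)):
        rows.append(
            {
                "stratum": label,
                "sample": sample,
                "aurc_a": res_a[label].aurc,
                "aurc_b": res_b[label].aurc,
                "n_genes": res_a[label].n_genes,
            }
        )
    return pd.DataFrame(rows, columns=["stratum", "sample", "aurc_a", "aurc_b", "n_genes"])


def cn_stratum(cn: float, cap: int = 10) -> str:
    """Copy-number stratum label: floor of the continuous CN, capped at '10+'."""
    n = math.floor(cn)
    return f"{cap}+" if n >= cap else str(int(n))


def ratio_stratum(ratio: float, bins: Sequence[float] = DEFAULT_RATIO_BINS) -> str:
    """Ratio-bin label for the given bin edges (default {<1,[1,2),[2,3),[3,4),>=4})."""
    edges = sorted(bins)
    if ratio < edges[0]:
        return f"<{edges[0]:g}"
    for lo, hi in zip(edges, edges[1:]):
        if lo <= ratio < hi:
            return f"[{lo:g},{hi:g})"
    return f">={edges[-1]:g}"
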