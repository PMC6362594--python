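"""Per-sample Gaussian-process correction of copy-number-driven fold-change bias.

The model regresses the mean sgRNA log2 fold change of each copy-number
segment on the segment's copy-number ratio (segment copies / chromosome
copies) with the kernel

    K(x, x') = sigma^2 * exp(-(x - x')^2 / (2 theta^2)) + psi * 1[x == x']

i.e. a constant-scaled squared-exponential (RBF) plus white noise.  The
length scale theta is bounded in [1e-5, 10] ratio units; hyperparameters are
fitted per sample by maximising the log marginal likelihood with three random
restarts.  Segments with fewer than 10 sgRNAs are excluded from training only
— every guide still receives a bias prediction — and the predicted bias is
subtracted from the original guide-level fold changes.

Fitting per sample means cell-specific context (ploidy, global screen
efficacy) is absorbed by the model rather than borrowed across samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .copy_number import chromosome_cn
from .foldchange import FoldChangeTable, gene_level
from .io_formats import CopyNumberSegment, GuideRecord

logger = logging.getLogger(__name__)

__all__ = [
    "KernelConfig",
    "SegmentStat",
    "BiasModel",
    "CrispyResult",
    "assign_guides_to_segments",
    "segment_stats",
    "fit_bias_model",
    "predict_bias",
    "correct_sample",
    "run_sample",
]

DEFAULT_MIN_GUIDES = 10


@dataclass
class KernelConfig:
    """Hyperparameter bounds and optimizer settings for the segment-level GP."""

    theta_bounds: Tuple[float, float] = (1e-5, 10.0)
    sigma2_bounds: Tuple[float, float] = (1e-3, 10.0)
    psi_bounds: Tuple[float, float] = (1e-3, 10.0)
    n_restarts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in [
            ("theta_bounds", self.theta_bounds),
            ("sigma2_bounds", self.sigma2_bounds),
            ("psi_bounds", self.psi_bounds),
        ]:
            if not (0 < lo < hi):
                raise ValueError(f"{name} must satisfy 0 < lower < upper, got {(lo, hi)}")


@dataclass(frozen=True)
class SegmentStat:
    """Per-segment training candidate: ratio, mean fold change, guide support."""

    segment: CopyNumberSegment
    segment_id: str
    ratio: float
    mean_fc: float
    n_guides: int
    eligible: bool


@dataclass
class BiasModel:
    """A fitted per-sample GP bias model with its training data."""

    train_x: np.ndarray
    train_y: np.ndarray
    sigma2: float
    theta: float
    psi: float
    log_marginal_likelihood: float
    _gp: GaussianProcessRegressor = field(repr=False)


@dataclass
class CrispyResult:
    """Corrected fold changes for one sample plus the fitted model and tables."""

    sample: str
    guide_table: pd.DataFrame
    gene_table: pd.DataFrame
    segment_table: pd.DataFrame
    model: BiasModel


def segment_id(seg: CopyNumberSegment) -> str:
    return f"{seg.chrom}:{seg.start}-{seg.end}"


def assign_guides_to_segments(
    library: Iterable[GuideRecord],
    segments: Dict[str, List[CopyNumberSegment]],
) -> Dict[str, CopyNumberSegment]:
    """Map each guide to the segment containing its midpoint (half-open).

    Guides whose midpoint falls in no segment are left unassigned and logged.
    """
    out: Dict[str, CopyNumberSegment] = {}
    unassigned = []
    for g in library:
        segs = segments.get(g.chrom, [])
        mid = g.midpoint
        hit = None
        for s in segs:  # sorted, non-overlapping
            if s.start <= mid < s.end:
                hit = s
                break
            if s.start > mid:
                break
        if hit is None:
            unassigned.append(g.guide_id)
        else:
            out[g.guide_id] = hit
    if unassigned:
        logger.info("%d guide(s) fall outside all segments: %s%s",
                    len(unassigned), unassigned[:10],
                    "..." if len(unassigned) > 10 else "")
    return out


def segment_stats(
    fc: pd.Series,
    guide_to_segment: Dict[str, CopyNumberSegment],
    segments: Dict[str, List[CopyNumberSegment]],
    min_guides: int = DEFAULT_MIN_GUIDES,
) -> List[SegmentStat]:
    """Per-segment guide count, mean fold change and copy-number ratio.

    *fc* is one sample's guide-level fold-change vector.  Segments with fewer
    than *min_guides* assigned guides are flagged ineligible for training.
    """
    all_segs = [s for lst in segments.values() for s in lst]
    chrom_cn_cache = {c: chromosome_cn(all_segs, c) for c in segments}
    assigned: Dict[CopyNumberSegment, List[float]] = {}
    for gid, seg in guide_to_segment.items():
        if gid in fc.index:
            assigned.setdefault(seg, []).append(float(fc[gid]))
    stats = []
    for chrom in sorted(segments):
        for seg in segments[chrom]:
            vals = assigned.get(seg, [])
            if not vals:
                continue
            ratio = seg.copy_number / chrom_cn_cache[chrom]
            stats.append(
                SegmentStat(seg, segment_id(seg), ratio,
                            float(np.mean(vals)), len(vals),
                            len(vals) >= min_guides)
            )
    return stats


def _build_kernel(cfg: KernelConfig):
    return (
        ConstantKernel(1.0, constant_value_bounds=cfg.sigma2_bounds)
        * RBF(length_scale=1.0, length_scale_bounds=cfg.theta_bounds)
        + WhiteKernel(noise_level=0.1, noise_level_bounds=cfg.psi_bounds)
    )


def fit_bias_model(
    stats: Iterable[SegmentStat], cfg: Optional[KernelConfig] = None
) -> BiasModel:
    """Fit the segment-level GP on eligible segments only.

    Requires at least 3 eligible segments spanning at least 2 distinct ratio
    values; otherwise the per-sample fit is refused.
    """
    cfg = cfg or KernelConfig()
    eligible = [s for s in stats if s.eligible]
    x = np.array([s.ratio for s in eligible], dtype=float)
    y = np.array([s.mean_fc for s in eligible], dtype=float)
    if len(eligible) < 3 or len(np.unique(x)) < 2:
        raise ValueError(
            f"insufficient segments for per-sample fit: {len(eligible)} eligible, "
            f"{len(np.unique(x))} distinct ratio value(s)"
        )
    if np.ptp(x) < 0.05:
        logger.warning(
            "degenerate ratio spread (%.3g): fit collapses toward constant + noise",
            np.ptp(x),
        )
    gp = GaussianProcessRegressor(
        kernel=_build_kernel(cfg),
        n_restarts_optimizer=cfg.n_restarts,
        random_state=cfg.seed,
        normalize_y=False,
    )
    with warnings.catch_warnings():
        # hyperparameters legitimately sit on the stated bounds (theta in
        # particular is capped by design); the optimizer's bound warnings are
        # expected, not actionable
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        gp.fit(x.reshape(-1, 1), y)
    k = gp.kernel_
    return BiasModel(
        train_x=x,
        train_y=y,
        sigma2=float(k.k1.k1.constant_value),
        theta=float(k.k1.k2.length_scale),
        psi=float(k.k2.noise_level),
        log_marginal_likelihood=float(gp.log_marginal_likelihood_value_),
        _gp=gp,
    )


def predict_bias(model: BiasModel, x) -> Tuple[np.ndarray, np.ndarray]:
    """Predictive mean and standard deviation of the bias at ratios *x*.

    The mean is the latent (noise-free) GP posterior mean; extrapolation
    beyond the training range is permitted and logged.
    """
    x = np.asarray(x, dtype=float).ravel()
    lo, hi = model.train_x.min(), model.train_x.max()
    n_out = int(np.sum((x < lo) | (x > hi)))
    if n_out:
        logger.info("predicting at %d ratio value(s) outside the training "
                    "range [%.3g, %.3g]", n_out, lo, hi)
    mean, sd = model._gp.predict(x.reshape(-1, 1), return_std=True)
    return np.asarray(mean), np.asarray(sd)


def correct_sample(
    fc: pd.Series,
    guide_to_segment: Dict[str, CopyNumberSegment],
    stats: List[SegmentStat],
    model: BiasModel,
    library: Optional[Iterable[GuideRecord]] = None,
    sample: str = "",
) -> CrispyResult:
    """Subtract the predicted segment bias from every assigned guide.

    Unassigned guides pass through with bias 0 and ``assigned=False``.
    Gene-level corrected fold changes are re-aggregated from the corrected
    guide values when a library is supplied.
    """
    ratio_of = {s.segment_id: s.ratio for s in stats}
    seg_ids, ratios, assigned_flags = [], [], []
    for gid in fc.index:
        seg = guide_to_segment.get(gid)
        if seg is None or segment_id(seg) not in ratio_of:
            seg_ids.append("")
            ratios.append(np.nan)
            assigned_flags.append(False)
        else:
            sid = segment_id(seg)
            seg_ids.append(sid)
            ratios.append(ratio_of[sid])
            assigned_flags.append(True)

    bias = np.zeros(len(fc))
    mask = np.array(assigned_flags)
    if mask.any():
        # one prediction per distinct segment ratio, broadcast to guides
        uniq = np.unique(np.array(ratios)[mask])
        pred, _ = predict_bias(model, uniq)
        lookup = dict(zip(uniq, pred))
        bias[mask] = [lookup[r] for r in np.array(ratios)[mask]]

    corrected = fc.to_numpy() - bias
    lib_list = list(library) if library is not None else None
    gene_of = {g.guide_id: g.gene for g in lib_list} if lib_list else {}
    guide_table = pd.DataFrame(
        {
            "guide_id": fc.index,
            "gene": [gene_of.get(gid, "") for gid in fc.index],
            "segment_id": seg_ids,
            "ratio": ratios,
            "original_fc": fc.to_numpy(),
            "predicted_bias": bias,
            "corrected_fc": corrected,
            "assigned": assigned_flags,
        }
    )

    if lib_list:
        corr_fct = FoldChangeTable(
            "guide", pd.DataFrame({sample or "corrected": corrected}, index=fc.index)
        )
        gene_fct = gene_level(corr_fct, lib_list)
        gene_table = gene_fct.fc.reset_index()
        gene_table.columns = ["gene", "corrected_fc"]
    else:
        gene_table = pd.DataFrame(columns=["gene", "corrected_fc"])

    segment_table = pd.DataFrame(
        {
            "segment_id": [s.segment_id for s in stats],
            "chrom": [s.segment.chrom for s in stats],
            "start": [s.segment.start for s in stats],
            "end": [s.segment.end for s in stats],
            "copy_number": [s.segment.copy_number for s in stats],
            "ratio": [s.ratio for s in stats],
            "n_guides": [s.n_guides for s in stats],
            "mean_fc": [s.mean_fc for s in stats],
            "eligible": [s.eligible for s in stats],
        }
    )
    return CrispyResult(sample, guide_table, gene_table, segment_table, model)


def run_sample(
    fc: pd.Series,
    library: List[GuideRecord],
    segments: Dict[str, List[CopyNumberSegment]],
    min_guides: int = DEFAULT_MIN_GUIDES,
    cfg: Optional[KernelConfig] = None,
    sample: str = "",
) -> CrispyResult:
    """Full per-sample pipeline: assign, summarise, fit, correct."""
    mapping = assign_guides_to_segments(library, segments)
    stats = segment_stats(fc, mapping, segments, min_guides=min_guides)
    model = fit_bias_model(stats, cfg)
    return correct_sample(fc, mapping, stats, model, library=library, sample=sample)
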