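"""Match tandem-duplication and deletion SV calls to copy-number segments.

A confident call (assembly score present, type tandem duplication or
deletion) matches a segment when both of its breakpoints fall within a
tolerance (10 kb by default, inclusive) of the segment's start and end on the
same chromosome.  Matched classes are then compared on copy-number ratio and
mean fold change with Welch's unequal-variance t test: focal tandem
duplications are expected to sit above ratio 1 and deletions below it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

import numpy as np
from scipy import stats as sps

from .io_formats import CopyNumberSegment, SvRecord, SvType

logger = logging.getLogger(__name__)

__all__ = [
    "SvSegmentMatch",
    "filter_confident_svs",
    "match_sv_to_segments",
    "sv_class_comparison",
    "DEFAULT_TOLERANCE_BP",
]

DEFAULT_TOLERANCE_BP = 10_000

_MATCHABLE = (SvType.TANDEM_DUPLICATION, SvType.DELETION)


@dataclass(frozen=True)
class SvSegmentMatch:
    sv: SvRecord
    segment: CopyNumberSegment
    start_offset: int  # sv.pos1 - segment.start
    end_offset: int  # sv.pos2 - segment.end


def filter_confident_svs(svs: Iterable[SvRecord]) -> List[SvRecord]:
    """Keep only tandem duplications and deletions with an assembly score."""
    kept = [
        sv
        for sv in svs
        if sv.sv_type in _MATCHABLE and sv.assembly_score is not None
    ]
    return kept


def match_sv_to_segments(
    svs: Iterable[SvRecord],
    segments: Dict[str, List[CopyNumberSegment]],
    tolerance_bp: int = DEFAULT_TOLERANCE_BP,
) -> List[SvSegmentMatch]:
    """All (SV, segment) pairs whose breakpoints agree within the tolerance.

    Both |pos1 - segment.start| and |pos2 - segment.end| must be <= tolerance
    (inclusive) on the SV's chromosome.  All qualifying pairs are returned.
    """
    out: List[SvSegmentMatch] = []
    for sv in svs:
        if sv.sv_type not in _MATCHABLE:
            continue
        for seg in segments.get(sv.chrom1, []):
            d_start = sv.pos1 - seg.start
            d_end = sv.pos2 - seg.end
            if abs(d_start) <= tolerance_bp and abs(d_end) <= tolerance_bp:
                out.append(SvSegmentMatch(sv, seg, d_start, d_end))
    return out


def sv_class_comparison(
    matches: Iterable[SvSegmentMatch],
    ratios: Dict[str, float],
    fc: Optional[Dict[str, float]] = None,
) -> dict:
    """Per-class medians and Welch's t test between tandem dups and deletions.

    *ratios* (and optional *fc*) map segment id "chrom:start-end" to the
    segment's copy-number ratio (mean fold change).  Returns per-class n,
    median ratio/fc and a Welch's two-sided t test per metric; classes with
    fewer than 2 members have their statistics omitted with a log entry.
    """
    def seg_id(seg: CopyNumberSegment) -> str:
        return f"{seg.chrom}:{seg.start}-{seg.end}"

    values: Dict[str, Dict[str, List[float]]] = {
        "tandem_duplication": {"ratio": [], "fc": []},
        "deletion": {"ratio": [], "fc": []},
    }
    matches = list(matches)
    for m in matches:
        cls = m.sv.sv_type.value
        sid = seg_id(m.segment)
        if sid in ratios:
            values[cls]["ratio"].append(ratios[sid])
        if fc is not None and sid in fc:
            values[cls]["fc"].append(fc[sid])

    summary: dict = {
        "n_pairs": len(matches),
        "n_unique_svs": len({m.sv for m in matches}),
        "classes": {},
        "tests": {},
    }
    for cls, d in values.items():
        summary["classes"][cls] = {
            "n": len(d["ratio"]),
            "median_ratio": float(np.median(d["ratio"])) if d["ratio"] else None,
            "median_fc": float(np.median(d["fc"])) if d["fc"] else None,
        }

    for metric in ("ratio", "fc"):
        a = np.asarray(values["tandem_duplication"][metric], dtype=float)
        b = np.asarray(values["deletion"][metric], dtype=float)
        if len(a) < 2 or len(b) < 2:
            logger.info("Welch test on %s omitted: class with < 2 members", metric)
            continue
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            if np.mean(a) == np.mean(b):
                summary["tests"][metric] = {"t": 0.0, "p": 1.0, "degenerate": True}
            else:
                summary["tests"][metric] = {
                    "t": float(np.sign(np.mean(a) - np.mean(b)) * np.inf),
                    "p": 0.0,
                    "degenerate": True,
                }
            continue
        t, p = sps.ttest_ind(a, b, equal_var=False)
        summary["tests"][metric] = {"t": float(t), "p": float(p), "degenerate": False}
    return summary
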