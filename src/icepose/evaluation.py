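"""Statistical reporting: per-parameter error summaries, pixel-size
stratification, rank-based group comparison, detection reports and
annotation-variability analysis.

Error distributions of the pose parameters are heavy-tailed, so summaries
are the median with the 10th and 90th percentiles (linear-interpolation
definition), never means and standard deviations.  Group differences
between pixel-size strata (< 0.3, 0.3-0.5, > 0.5 mm) are tested with the
two-sided Mann-Whitney U rank test, starred at p < 0.05 (*) and
p < 0.01 (**).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import Pose5DoF, PoseError, wrap_angle_diff

__all__ = [
    "ErrorSummary",
    "VariabilityReport",
    "PARAMETER_UNITS",
    "summarize_errors",
    "stratify_by_pixel_size",
    "compare_pixel_groups",
    "user_variability",
    "detection_report",
    "error_table",
]

PARAMETER_UNITS: Dict[str, str] = {
    "x": "mm",
    "y": "mm",
    "position": "mm",
    "theta": "deg",
    "alpha": "deg",
    "phi": "deg",
}

#: Stratum labels in display order.
STRATA = ("<0.3", "0.3-0.5", ">0.5")


@dataclass(frozen=True)
class ErrorSummary:
    """Median and [p10, p90] of one parameter's absolute errors."""

    parameter: str
    n: int
    median: float
    p10: float
    p90: float
    units: str
    stratum: str = "all"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("summary requires n >= 1")
        if not (self.p10 <= self.median <= self.p90):
            raise ValueError("percentiles must be ordered p10 <= median <= p90")

    def format(self, digits: int = 1) -> str:
        """'median [p10, p90]' layout used throughout the reports."""
        return (f"{self.median:.{digits}f} "
                f"[{self.p10:.{digits}f}, {self.p90:.{digits}f}]")


@dataclass(frozen=True)
class VariabilityReport:
    """Annotation variability per parameter: inter-user, intra-user, and
    user error versus ground truth, each summarized as median [p10, p90]."""

    inter_user: Dict[str, ErrorSummary]
    intra_user: Dict[str, ErrorSummary]
    user_error: Dict[str, ErrorSummary]


def _summary(values: Sequence[float], parameter: str, stratum: str) -> ErrorSummary:
    v = np.asarray(values, dtype=np.float64)
    if v.size < 1:
        raise ValueError(f"no values to summarize for {parameter}")
    p10, med, p90 = np.percentile(v, [10, 50, 90])  # linear interpolation
    return ErrorSummary(
        parameter=parameter,
        n=int(v.size),
        median=float(med),
        p10=float(p10),
        p90=float(p90),
        units=PARAMETER_UNITS.get(parameter, ""),
        stratum=stratum,
    )


def summarize_errors(
    errors: Sequence[PoseError],
    stratum: str = "all",
    include_tilt: bool = True,
    pooled_position: bool = True,
) -> Dict[str, ErrorSummary]:
    """Per-parameter median [p10, p90] summaries of absolute pose errors.

    ``pooled_position`` additionally emits a 'position' row pooling the x
    and y errors; ``include_tilt=False`` drops phi (mirroring reports where
    tilt could not be validated).
    """
    if not errors:
        raise ValueError("summarize_errors requires at least one error")
    cols: Dict[str, List[float]] = {"x": [], "y": [], "theta": [], "alpha": [], "phi": []}
    for e in errors:
        d = e.as_dict()
        for k in cols:
            cols[k].append(d[k])
    if not include_tilt:
        del cols["phi"]
    out = {k: _summary(v, k, stratum) for k, v in cols.items()}
    if pooled_position:
        out["position"] = _summary(cols["x"] + cols["y"], "position", stratum)
    return out


def stratify_by_pixel_size(pixel_sizes: Sequence[float]) -> Dict[str, np.ndarray]:
    """Partition sample indices into the three pixel-size groups (mm).

    Boundaries at 0.3 and 0.5 mm are assigned to the middle group; every
    sample lands in exactly one group.
    """
    ps = np.asarray(pixel_sizes, dtype=np.float64)
    lo = ps < 0.3
    hi = ps > 0.5
    mid = ~(lo | hi)
    return {
        "<0.3": np.flatnonzero(lo),
        "0.3-0.5": np.flatnonzero(mid),
        ">0.5": np.flatnonzero(hi),
    }


def compare_pixel_groups(
    errors_a: Sequence[float], errors_b: Sequence[float]
) -> Tuple[float, str]:
    """Two-sided Mann-Whitney U test between two error samples.

    Returns (p-value, stars) with '**' for p < 0.01, '*' for p < 0.05 and
    'n.s.' otherwise.  Groups smaller than 3 cannot support the test and
    are reported as n.s. with a warning.
    """
    a = np.asarray(errors_a, dtype=np.float64)
    b = np.asarray(errors_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size < 3 or b.size < 3:
        warnings.warn("group smaller than 3; comparison reported as n.s.")
        return 1.0, "n.s."
    if np.array_equal(a, b) or (np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]):
        return 1.0, "n.s."
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if p < 0.01:
        return p, "**"
    if p < 0.05:
        return p, "*"
    return p, "n.s."


# ---------------------------------------------------------------------------
# annotation variability


_PERIODS = {"theta": 360.0, "alpha": 180.0}


def _param_diff(name: str, a: float, b: float, pixel_size: float) -> float:
    if name in ("x", "y"):
        return abs(a - b) * pixel_size
    if name in _PERIODS:
        return wrap_angle_diff(a, b, _PERIODS[name])
    return abs(a - b)


def _circular_mean(values: Sequence[float], period: float) -> float:
    ang = np.asarray(values, dtype=np.float64) * (2 * math.pi / period)
    s, c = np.sin(ang).mean(), np.cos(ang).mean()
    return (math.degrees(math.atan2(s, c)) * (period / 360.0)) % period


def _mean_annotation(name: str, values: Sequence[float]) -> float:
    if name == "theta":
        return _circular_mean(values, 360.0)
    if name == "alpha":
        m = _circular_mean([v + 90.0 for v in values], 180.0) - 90.0
        return m
    return float(np.mean(values))


_PARAMS = ("x", "y", "theta", "alpha", "phi")


def user_variability(
    inter_annotations: Mapping[str, Sequence[Pose5DoF]],
    intra_annotations: Mapping[str, Sequence[Pose5DoF]],
    truths: Sequence[Pose5DoF],
    pixel_sizes: Sequence[float],
) -> VariabilityReport:
    """Annotation-variability analysis on a common sample set.

    ``inter_annotations`` maps each user to one annotation per sample;
    ``intra_annotations`` maps each repeat of a single user to one
    annotation per sample.  Inter-user variability pools, per sample, the
    absolute pairwise differences between users (with the angular wrap
    metrics); intra-user variability does the same across repeats; the user
    error compares the mean of the repeats (circular means for the angles)
    to ground truth.  Position differences are reported in mm via each
    sample's pixel size.
    """
    if len(inter_annotations) < 2:
        raise ValueError("inter-user variability requires >= 2 users")
    if len(intra_annotations) < 2:
        raise ValueError("intra-user variability requires >= 2 repeats")
    n = len(truths)
    for name, ann in list(inter_annotations.items()) + list(intra_annotations.items()):
        if len(ann) != n:
            raise ValueError(f"annotation set {name!r} has {len(ann)} samples, expected {n}")

    def pairwise(annsets: Mapping[str, Sequence[Pose5DoF]]) -> Dict[str, List[float]]:
        out: Dict[str, List[float]] = {p: [] for p in _PARAMS}
        keys = sorted(annsets)
        for i in range(n):
            for a in range(len(keys)):
                for b in range(a + 1, len(keys)):
                    pa, pb = annsets[keys[a]][i], annsets[keys[b]][i]
                    for p in _PARAMS:
                        out[p].append(
                            _param_diff(p, getattr(pa, p), getattr(pb, p), pixel_sizes[i])
                        )
        return out

    inter = pairwise(inter_annotations)
    intra = pairwise(intra_annotations)

    err: Dict[str, List[float]] = {p: [] for p in _PARAMS}
    repeats = sorted(intra_annotations)
    for i in range(n):
        for p in _PARAMS:
            mean_ann = _mean_annotation(p, [getattr(intra_annotations[r][i], p)
                                            for r in repeats])
            err[p].append(_param_diff(p, mean_ann, getattr(truths[i], p), pixel_sizes[i]))

    def summarize(d: Mapping[str, Sequence[float]]) -> Dict[str, ErrorSummary]:
        return {p: _summary(v, p, "all") for p, v in d.items()}

    return VariabilityReport(
        inter_user=summarize(inter),
        intra_user=summarize(intra),
        user_error=summarize(err),
    )


# ---------------------------------------------------------------------------
# tabular reports


def detection_report(metrics_per_split: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Precision/recall/F1 table, one row per evaluated split."""
    rows = []
    for split, m in metrics_per_split.items():
        rows.append(
            {
                "test_data": split,
                "precision": round(m["precision"], 2),
                "recall": round(m["recall"], 2),
                "f1": round(m["f1"], 2),
                "iou_threshold": m.get("iou_threshold", 0.4),
            }
        )
    return pd.DataFrame(rows)


def error_table(
    summaries: Mapping[str, Mapping[str, ErrorSummary]], digits: int = 1
) -> pd.DataFrame:
    """Stacked 'median [p10, p90]' table: rows = strata, cols = parameters."""
    rows = []
    for stratum, per_param in summaries.items():
        row = {"pixel_size": stratum}
        for p, s in per_param.items():
            row[f"{p} ({s.units})"] = s.format(digits)
            row[f"{p}_n"] = s.n
        rows.append(row)
    return pd.DataFrame(rows)


def plot_error_violins(errors_by_param: Mapping[str, Sequence[float]], out_path) -> None:
    """Optional violin rendering of error distributions (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(errors_by_param)
    fig, ax = plt.subplots(figsize=(1.8 * len(names) + 1, 4))
    parts = ax.violinplot([np.asarray(errors_by_param[n]) for n in names],
                          showmedians=True, quantiles=[[0.25, 0.75]] * len(names))
    ax.set_xticks(range(1, len(names) + 1), names)
    ax.set_ylabel("absolute error")
    fig.tight_layout()
    fig.savefig(str(out_path), dpi=150)
    plt.close(fig)
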