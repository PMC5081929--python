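"""Data-driven RPKM expression threshold estimation.

A gene is called expressed when its RPKM exceeds a threshold estimated
from the data themselves: the point where the density of exon expression
levels crosses the density of intergenic-region expression levels.  Both
densities are Gaussian-kernel estimates of log10(RPKM) (zeros excluded);
the crossing is sought between the two global modes, and when several
sign changes exist the valley crossing (minimal summed density) is taken.
Per-dataset thresholds are then averaged across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

DEFAULT_GRID_POINTS = 512
MIN_VALUES = 50


@dataclass(frozen=True)
class ThresholdEstimate:
    """One dataset's exon/intergenic density-crossing threshold."""

    dataset_id: str
    threshold_rpkm: float
    n_exon: int
    n_intergenic: int
    crossing_log10: float


def _positive_log10(values, label: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    arr = arr[arr > 0]
    if arr.size < MIN_VALUES:
        raise ValueError(
            f"{label}: need >= {MIN_VALUES} strictly positive values, got {arr.size}"
        )
    return np.log10(arr)


def estimate_threshold(
    exon_rpkm,
    intergenic_rpkm,
    grid_points: int = DEFAULT_GRID_POINTS,
    bandwidth: str | float = "silverman",
    dataset_id: str = "dataset",
) -> ThresholdEstimate:
    """Threshold RPKM as the exon/intergenic density intersection.

    Parameters
    ----------
    exon_rpkm, intergenic_rpkm
        Raw RPKM values for exonic and intergenic regions; zeros dropped.
    grid_points
        Number of evaluation points spanning [min - 1, max + 1] of the
        pooled log10 values.
    bandwidth
        scipy ``gaussian_kde`` bandwidth method; Silverman's rule by
        default, or a numeric factor.
    """
    log_ex = _positive_log10(exon_rpkm, "exon_rpkm")
    log_ig = _positive_log10(intergenic_rpkm, "intergenic_rpkm")
    pooled = np.concatenate([log_ex, log_ig])
    grid = np.linspace(pooled.min() - 1.0, pooled.max() + 1.0, grid_points)

    f_ex = gaussian_kde(log_ex, bw_method=bandwidth)(grid)
    f_ig = gaussian_kde(log_ig, bw_method=bandwidth)(grid)

    mode_ex = int(np.argmax(f_ex))
    mode_ig = int(np.argmax(f_ig))
    if grid[mode_ex] <= grid[mode_ig]:
        raise ValueError(
            "exon/intergenic distributions inverted: exon mode "
            f"({grid[mode_ex]:.3f}) does not exceed intergenic mode ({grid[mode_ig]:.3f}) "
            "on the log10 scale"
        )

    lo, hi = mode_ig, mode_ex
    diff = f_ex - f_ig
    seg = diff[lo : hi + 1]
    sign_change = np.nonzero(np.diff(np.sign(seg)) != 0)[0]
    if sign_change.size == 0:
        raise ValueError("distributions do not intersect between their modes")

    # valley crossing: among sign changes, minimize the summed density
    total = f_ex + f_ig
    cand = sign_change + lo
    best = cand[np.argmin(total[cand])]
    # linear interpolation of the zero of diff within [best, best+1]
    d0, d1 = diff[best], diff[best + 1]
    frac = 0.0 if d1 == d0 else d0 / (d0 - d1)
    crossing = float(grid[best] + frac * (grid[best + 1] - grid[best]))

    return ThresholdEstimate(
        dataset_id=dataset_id,
        threshold_rpkm=float(10.0 ** crossing),
        n_exon=int(log_ex.size),
        n_intergenic=int(log_ig.size),
        crossing_log10=crossing,
    )


def average_thresholds(estimates: list[ThresholdEstimate]) -> float:
    """Arithmetic mean of per-dataset thresholds."""
    if not estimates:
        raise ValueError("cannot average an empty list of threshold estimates")
    return float(np.mean([e.threshold_rpkm for e in estimates]))
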