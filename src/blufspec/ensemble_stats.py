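"""Frame-ensemble averages with bootstrapped confidence intervals.

Scalar observables computed along an MD ensemble (chemical shifts,
carbonyl stretch frequencies, excitation energies) are summarized by
their frame average and a percentile-bootstrap 95% confidence interval.
Frames are resampled as i.i.d. draws by default, which ignores serial
correlation; a circular block bootstrap is available for correlated
series.  Dark-minus-light differences bootstrap each ensemble
independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import argrelmax

from .errors import ValidationError

__all__ = [
    "ObservableSeries",
    "IntervalEstimate",
    "bootstrap_mean_ci",
    "difference_ci",
    "MultimodalityReport",
    "multimodality_report",
]


@dataclass
class ObservableSeries:
    """One scalar observable per MD frame for one protein state."""

    values: np.ndarray
    label: str = ""
    state: str = "dark"
    replica: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"series {self.label!r} contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class IntervalEstimate:
    """Mean with a 95% bootstrap confidence interval."""

    mean: float
    lower: float
    upper: float
    n: int
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if not (self.lower <= self.mean + 1e-12 and self.mean - 1e-12 <= self.upper):
            raise ValidationError("interval does not bracket the mean")

    @property
    def half_width(self) -> float:
        return 0.5 * (self.upper - self.lower)


def _as_series(x: ObservableSeries | np.ndarray) -> ObservableSeries:
    return x if isinstance(x, ObservableSeries) else ObservableSeries(np.asarray(x))


def _boot_means(
    values: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    block_length: int | None,
) -> np.ndarray:
    n = len(values)
    if block_length is None or block_length <= 1:
        idx = rng.integers(0, n, size=(n_boot, n))
        return values[idx].mean(axis=1)
    # circular block bootstrap: concatenate whole blocks until n frames
    n_blocks = -(-n // block_length)
    starts = rng.integers(0, n, size=(n_boot, n_blocks))
    offs = np.arange(block_length)
    idx = (starts[:, :, None] + offs[None, None, :]).reshape(n_boot, -1)[:, :n] % n
    return values[idx].mean(axis=1)


def bootstrap_mean_ci(
    series: ObservableSeries | np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    block_length: int | None = None,
) -> IntervalEstimate:
    """Percentile-bootstrap 95% CI for the frame mean.

    Resamples frames with replacement ``n_boot`` times; the interval is
    the (2.5, 97.5) percentile range of the resampled means.  A constant
    series legitimately yields a zero-width interval.  ``block_length``
    switches to a circular block bootstrap for serially correlated data.
    """
    series = _as_series(series)
    if series.n < 2:
        raise ValidationError("CI computation needs at least 2 frames")
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    means = _boot_means(series.values, n_boot, rng, block_length)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return IntervalEstimate(
        mean=float(series.values.mean()),
        lower=float(min(lo, series.values.mean())),
        upper=float(max(hi, series.values.mean())),
        n=series.n,
        n_boot=n_boot,
        seed=seed,
    )


def difference_ci(
    a: ObservableSeries | np.ndarray,
    b: ObservableSeries | np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    block_length: int | None = None,
) -> IntervalEstimate:
    """Bootstrap CI for mean(a) - mean(b) with independent resampling."""
    a, b = _as_series(a), _as_series(b)
    if a.n < 2 or b.n < 2:
        raise ValidationError("CI computation needs at least 2 frames per series")
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    seed_a, seed_b = np.random.SeedSequence(seed).spawn(2)
    means_a = _boot_means(
        a.values, n_boot, np.random.default_rng(seed_a), block_length
    )
    means_b = _boot_means(
        b.values, n_boot, np.random.default_rng(seed_b), block_length
    )
    diffs = means_a - means_b
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    point = float(a.values.mean() - b.values.mean())
    return IntervalEstimate(
        mean=point,
        lower=float(min(lo, point)),
        upper=float(max(hi, point)),
        n=min(a.n, b.n),
        n_boot=n_boot,
        seed=seed,
    )


@dataclass
class MultimodalityReport:
    """Histogram plus kernel-density mode count for one series."""

    hist_counts: np.ndarray
    hist_edges: np.ndarray
    kde_grid: np.ndarray
    kde_density: np.ndarray
    mode_count: int
    bandwidth: float


def multimodality_report(
    series: ObservableSeries | np.ndarray,
    bandwidth: float | None = None,
    bins: int = 50,
    grid_points: int = 1024,
) -> MultimodalityReport:
    """Descriptive check for multiple slowly-exchanging conformations.

    A Gaussian kernel density estimate is evaluated on a regular grid and
    its local maxima above 1% of the global maximum are counted.  The
    default bandwidth is Scott's rule; pass an explicit bandwidth (same
    units as the data) to probe a known separation scale.
    """
    series = _as_series(series)
    if series.n < 50:
        raise ValidationError("multimodality report needs >= 50 frames")
    v = series.values
    if bandwidth is None:
        bandwidth = float(v.std(ddof=1)) * series.n ** (-1.0 / 5.0)
    if bandwidth <= 0:
        raise ValidationError("bandwidth must be positive")
    grid = np.linspace(v.min() - 3 * bandwidth, v.max() + 3 * bandwidth, grid_points)
    z = (grid[:, None] - v[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (
        series.n * bandwidth * np.sqrt(2 * np.pi)
    )
    peaks = argrelmax(dens)[0]
    peaks = peaks[dens[peaks] > 0.01 * dens.max()]
    counts, edges = np.histogram(v, bins=bins)
    return MultimodalityReport(
        hist_counts=counts,
        hist_edges=edges,
        kde_grid=grid,
        kde_density=dens,
        mode_count=int(len(peaks)),
        bandwidth=float(bandwidth),
    )
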