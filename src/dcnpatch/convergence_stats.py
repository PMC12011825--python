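"""Convergence-driven rate decoding statistics.

A deep-nuclear neuron is represented as a counter of afferent spikes in
millisecond bins; postsynaptic integration is proxied by a short rolling
mean of consecutive counts.  These functions quantify how faithfully the
combined spike count tracks the underlying shared rate as a function of the
Purkinje-to-DCN convergence ratio: coefficient of variation, bin-to-bin
jitter, and cycle-to-cycle pairwise correlation (reliability).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .rate_profiles import RateProfile
from .spike_generator import SpikeRaster, generate_ensemble

__all__ = [
    "BinnedCounts",
    "bin_counts",
    "rolling_mean",
    "jitter",
    "coefficient_of_variation",
    "mean_pairwise_correlation",
    "reliability_curve",
    "convergence_sweep",
]


@dataclass
class BinnedCounts:
    """Summed spike counts per time bin across converging afferents."""

    counts: np.ndarray
    n_afferents: int
    bin_ms: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def bin_counts(raster: SpikeRaster, bin_ms: float = 1.0) -> BinnedCounts:
    """Count spikes across all cells in consecutive bins of ``bin_ms``."""
    steps_per_bin = bin_ms / raster.dt
    if abs(steps_per_bin - round(steps_per_bin)) > 1e-9:
        raise ValueError("bin_ms must be an integer multiple of dt")
    spb = int(round(steps_per_bin))
    if raster.n_steps % spb != 0:
        raise ValueError("bin_ms must divide the raster duration")
    n_bins = raster.n_steps // spb
    counts = raster.summed_train().reshape(n_bins, spb).sum(axis=1)
    return BinnedCounts(counts, n_afferents=raster.n_cells, bin_ms=bin_ms)


def rolling_mean(series, window: int, edge_policy: str = "valid") -> np.ndarray:
    """Trailing arithmetic mean over ``window`` consecutive samples.

    With the default ``"valid"`` edge policy the output has
    ``len(series) - window + 1`` samples (no padding is invented at the
    edges).
    """
    x = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > x.size:
        raise ValueError("window larger than series")
    if edge_policy != "valid":
        raise ValueError(f"unsupported edge policy {edge_policy!r}")
    if window == 1:
        return x.copy()
    c = np.cumsum(np.concatenate(([0.0], x)))
    return (c[window:] - c[:-window]) / window


def jitter(counts: BinnedCounts | np.ndarray, n_afferents: int | None = None) -> float:
    """Mean absolute bin-to-bin count difference, as % of the convergence ratio.

    Defined as ``mean(|c[k+1]-c[k]|) / n_afferents * 100`` over consecutive
    1 ms bins of a cycle.  Accepts a :class:`BinnedCounts` (raw counts) or a
    plain array (e.g. integrated counts) plus ``n_afferents``.
    """
    if isinstance(counts, BinnedCounts):
        values = np.asarray(counts.counts, dtype=float)
        n_afferents = counts.n_afferents
    else:
        values = np.asarray(counts, dtype=float)
        if n_afferents is None:
            raise ValueError("n_afferents required for a plain array")
    if n_afferents < 1:
        raise ValueError("n_afferents must be >= 1")
    if values.size < 2:
        raise ValueError("need at least 2 bins")
    return float(np.mean(np.abs(np.diff(values))) / n_afferents * 100.0)


def coefficient_of_variation(series) -> float:
    """SD / mean (population SD); undefined (NaN) for zero mean."""
    x = np.asarray(series, dtype=float)
    m = x.mean()
    if m == 0:
        return float("nan")
    return float(x.std() / m)


def mean_pairwise_correlation(series_matrix) -> tuple[float, float]:
    """Mean and SD of Pearson r over all pairs of rows."""
    m = np.asarray(series_matrix, dtype=float)
    if m.shape[0] < 2:
        raise ValueError("need at least 2 series")
    r = np.corrcoef(m)
    pairs = [r[i, j] for i, j in combinations(range(m.shape[0]), 2)]
    return float(np.mean(pairs)), float(np.std(pairs))


def _cycle_series(
    profile: RateProfile,
    ratio: int,
    duration_ms: float,
    dt: float,
    refractory_ms: float,
    window: int,
    integrate: bool,
    seed,
) -> np.ndarray:
    raster = generate_ensemble(profile, ratio, duration_ms, dt, refractory_ms, seed)
    counts = bin_counts(raster, 1.0)
    if integrate:
        return rolling_mean(counts.counts, window)
    return np.asarray(counts.counts, dtype=float)


def reliability_curve(
    convergence_ratios,
    n_cycles: int,
    profile: RateProfile,
    duration_ms: float = 200.0,
    dt: float = 0.05,
    refractory_ms: float = 1.0,
    window: int = 2,
    integrate: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Cycle-to-cycle reliability versus convergence ratio.

    For each ratio, ``n_cycles`` independent cycles are simulated and the
    Pearson correlation is taken over all cycle pairs of the binned (by
    default rolling-mean-integrated) count series.  Returns a DataFrame with
    columns ``ratio, mean_corr, sd_corr``.
    """
    if n_cycles < 2:
        raise ValueError("n_cycles must be >= 2")
    ratios = [int(r) for r in convergence_ratios]
    if any(r < 1 for r in ratios):
        raise ValueError("convergence ratios must be >= 1")
    root = np.random.SeedSequence(seed)
    children = iter(root.spawn(len(ratios) * n_cycles))
    rows = []
    for ratio in ratios:
        series = np.stack(
            [
                _cycle_series(
                    profile, ratio, duration_ms, dt, refractory_ms, window,
                    integrate, next(children),
                )
                for _ in range(n_cycles)
            ]
        )
        mean_r, sd_r = mean_pairwise_correlation(series)
        rows.append({"ratio": ratio, "mean_corr": mean_r, "sd_corr": sd_r})
    return pd.DataFrame(rows)


def convergence_sweep(
    convergence_ratios,
    n_cycles: int,
    profile: RateProfile,
    duration_ms: float = 200.0,
    dt: float = 0.05,
    refractory_ms: float = 1.0,
    window: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-ratio CV and jitter (raw and integrated), averaged over cycles.

    Returns one row per ratio with columns ``ratio, cv, jitter_raw,
    jitter_raw_sd, jitter_integrated, jitter_integrated_sd`` where the CV
    and jitters are means over ``n_cycles`` independent cycles.
    """
    ratios = [int(r) for r in convergence_ratios]
    root = np.random.SeedSequence(seed)
    children = iter(root.spawn(len(ratios) * n_cycles))
    rows = []
    for ratio in ratios:
        cvs, j_raw, j_int = [], [], []
        for _ in range(n_cycles):
            raster = generate_ensemble(
                profile, ratio, duration_ms, dt, refractory_ms, next(children)
            )
            counts = bin_counts(raster, 1.0)
            cvs.append(coefficient_of_variation(counts.counts))
            j_raw.append(jitter(counts))
            j_int.append(jitter(rolling_mean(counts.counts, window), ratio))
        rows.append(
            {
                "ratio": ratio,
                "cv": float(np.mean(cvs)),
                "jitter_raw": float(np.mean(j_raw)),
                "jitter_raw_sd": float(np.std(j_raw)),
                "jitter_integrated": float(np.mean(j_int)),
                "jitter_integrated_sd": float(np.std(j_int)),
            }
        )
    return pd.DataFrame(rows)
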