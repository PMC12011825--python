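"""Unit-quantum inhibitory charge entry to the DCN soma.

Every afferent spike triggers a stereotyped quantum of inhibitory current:
a fast rise to a peak amplitude of 1 (the unit of current) followed by an
exponential decay with constant ``tau``.  Temporally overlapping quanta sum
linearly — the quantum and its dynamics are inviolable, with no saturation
or voltage dependence.  Current is accumulated per 0.05 ms timestep; a
short trailing rolling mean stands in for fast but non-instantaneous charge
expulsion from the soma, which dampens jitter.

The physiologically reported decay constant is ~2.5 ms; the default sweep
brackets it with {1.25, 2.5, 5, 7.5} ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rate_profiles import constant
from .spike_generator import SpikeRaster, generate_ensemble

__all__ = [
    "DEFAULT_TAUS",
    "QuantumKernel",
    "CurrentTrace",
    "make_kernel",
    "superpose",
    "rolling_current",
    "linearity_sweep",
    "linearity_r2",
    "interspike_interval_ms",
    "total_boutons",
    "population_fraction_pct",
]

DEFAULT_TAUS = (1.25, 2.5, 5.0, 7.5)


@dataclass
class QuantumKernel:
    """Unit-current waveform evoked by one spike (peak amplitude 1)."""

    samples: np.ndarray
    tau_ms: float
    rise_ms: float
    dt: float

    @property
    def integral(self) -> float:
        """Charge per quantum: sum(samples) * dt."""
        return float(self.samples.sum() * self.dt)


@dataclass
class CurrentTrace:
    """Summed inhibitory current per timestep, in unit-current units."""

    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def duration_ms(self) -> float:
        return self.values.size * self.dt

    def mean(self) -> float:
        return float(self.values.mean())

    def cv(self) -> float:
        m = self.values.mean()
        return float(self.values.std() / m) if m != 0 else float("nan")


def make_kernel(
    tau_ms: float,
    rise_ms: float = 0.05,
    dt: float = 0.05,
    truncate: float = 1e-6,
) -> QuantumKernel:
    """Build the unit quantum: linear rise over ``rise_ms``, then exp decay.

    The waveform is sampled so the peak sample equals exactly 1 and the
    decay satisfies ``value(t_peak + tau) = 1/e``; the tail is truncated
    where it falls below ``truncate`` of the peak, giving bounded support
    for exact discrete convolution.
    """
    if tau_ms <= 0:
        raise ValueError("tau_ms must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if rise_ms < 0:
        raise ValueError("rise_ms must be non-negative")
    rise_steps = int(round(rise_ms / dt))
    if rise_steps > 0:
        rise = np.arange(1, rise_steps + 1) / rise_steps
    else:
        rise = np.array([1.0])
    n_decay = int(np.ceil(tau_ms / dt * np.log(1.0 / truncate)))
    decay = np.exp(-np.arange(1, n_decay + 1) * dt / tau_ms)
    decay = decay[decay >= truncate]
    samples = np.concatenate([rise, decay])
    return QuantumKernel(samples, tau_ms=tau_ms, rise_ms=rise_steps * dt, dt=dt)


def superpose(
    raster: SpikeRaster, kernel: QuantumKernel, keep_tail: bool = False
) -> CurrentTrace:
    """Linearly superpose one quantum per spike across the whole raster.

    Equivalent to convolving the summed spike train with the kernel.  With
    ``keep_tail=False`` (default) the trace is cut to the raster duration;
    ``keep_tail=True`` keeps the decaying tail after the last timestep so
    that total charge is conserved exactly.
    """
    if abs(raster.dt - kernel.dt) > 1e-12:
        raise ValueError("raster and kernel timestep mismatch")
    summed = raster.summed_train().astype(float)
    full = np.convolve(summed, kernel.samples)
    values = full if keep_tail else full[: raster.n_steps]
    return CurrentTrace(values, dt=raster.dt)


def rolling_current(trace: CurrentTrace, window_ms: float) -> CurrentTrace:
    """Trailing rolling mean of the current over ``window_ms`` ("valid" edges)."""
    if window_ms < trace.dt:
        raise ValueError("window_ms must be >= dt")
    w = int(round(window_ms / trace.dt))
    if w == 1:
        return CurrentTrace(trace.values.copy(), dt=trace.dt)
    c = np.cumsum(np.concatenate(([0.0], trace.values)))
    return CurrentTrace((c[w:] - c[:-w]) / w, dt=trace.dt)


def linearity_sweep(
    rates=None,
    taus=DEFAULT_TAUS,
    n_cells: int = 40,
    duration_ms: float = 200.0,
    dt: float = 0.05,
    refractory_ms: float = 1.0,
    rise_ms: float = 0.05,
    window_ms: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean current and CV versus discharge probability (firing rate).

    For each rate a fresh ensemble is simulated and, for each decay
    constant, the 200 ms mean and CV of the (optionally rolled) current
    trace are tabulated.  The mean rate of charge entry is linear in the
    discharge probability; fit with :func:`linearity_r2`.
    """
    if rates is None:
        rates = np.arange(50, 201)  # 50..200 Hz inclusive, 1 Hz steps
    rates = np.asarray(list(rates), dtype=float)
    if rates.size == 0:
        raise ValueError("empty rate list")
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    kernels = {tau: make_kernel(tau, rise_ms=rise_ms, dt=dt) for tau in taus}
    root = np.random.SeedSequence(seed)
    children = iter(root.spawn(rates.size))
    rows = []
    for rate in rates:
        raster = generate_ensemble(
            constant(rate), n_cells, duration_ms, dt, refractory_ms, next(children)
        )
        for tau, kernel in kernels.items():
            trace = superpose(raster, kernel)
            if window_ms is not None:
                trace = rolling_current(trace, window_ms)
            rows.append(
                {
                    "tau_ms": tau,
                    "rate_hz": float(rate),
                    "mean_current": trace.mean(),
                    "cv": trace.cv(),
                }
            )
    return pd.DataFrame(rows)


def linearity_r2(sweep: pd.DataFrame) -> pd.DataFrame:
    """Least-squares R^2 of mean_current vs rate, one row per tau."""
    rows = []
    for tau, grp in sweep.groupby("tau_ms"):
        fit = stats.linregress(grp["rate_hz"], grp["mean_current"])
        rows.append(
            {
                "tau_ms": float(tau),
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r2": fit.rvalue**2,
            }
        )
    return pd.DataFrame(rows)


# -- bouton-anatomy arithmetic ------------------------------------------------

def interspike_interval_ms(rate_hz: float) -> float:
    """Mean interspike interval (ms) at a constant rate: 1000/rate."""
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    return 1000.0 / rate_hz


def total_boutons(n_afferents: int = 40, boutons_per_afferent: int = 30) -> int:
    """Total boutons covering a DCN soma (afferents x boutons each)."""
    if n_afferents < 0 or boutons_per_afferent < 0:
        raise ValueError("counts must be non-negative")
    return n_afferents * boutons_per_afferent


def population_fraction_pct(k: int, population: int) -> float:
    """``k`` cells as a percentage of a population."""
    if population <= 0:
        raise ValueError("population must be positive")
    return 100.0 * k / population
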