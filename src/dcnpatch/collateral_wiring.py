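"""Binomial analytics and resampling model of DCN recurrent collaterals.

With a group of ``n`` DCNs and presynaptic divergence 1:``z`` (each
presynaptic cell contacts ``z`` of the ``n`` DCNs at random), a given DCN
receives contact from each of ``m`` presynaptic cells independently with
probability ``p = z/n``, so the number of contacts ``y`` it receives is
Binomial(m, p):

    P(y) = (z/n)^y * (1 - z/n)^(m-y) * C(m, y)

and the probability that exactly ``x`` of the ``n`` DCNs each receive at
least ``y`` contacts treats DCNs as independent:

    P(x; >=y) = q^x * (1-q)^(n-x) * C(n, x),   q = 1 - sum_{j<y} P(j).

The independence across DCNs is an approximation (the total number of
contacts is fixed at m*z); :func:`simulate_wiring_counts` is the exact
Monte-Carlo wiring model against which the analytic forms can be checked.

The module also simulates the per-millisecond spike-count distribution
across a nuclear group and the narrowing of that distribution when each
DCN averages the values of a random sample of its neighbours (recurrent
collaterals, nucleo-nuclear divergence assumed 1:5 → sample size 5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .convergence_stats import rolling_mean
from .nuclear_group import WiringConfig, sample_wiring
from .rate_profiles import constant
from .spike_generator import generate_ensemble

__all__ = [
    "CollateralConfig",
    "contact_pmf",
    "prob_at_least",
    "joint_prob_x_dcns",
    "expected_contacted",
    "simulate_wiring_counts",
    "CountDistribution",
    "dcn_count_distribution",
    "resample_means",
]


@dataclass(frozen=True)
class CollateralConfig:
    """Group size ``n``, divergence ``z`` and presynaptic count ``m``."""

    n: int = 50
    z: int = 5
    m: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.z <= self.n):
            raise ValueError("need 0 < z <= n")
        if self.m < 0:
            raise ValueError("m must be non-negative")

    @property
    def p(self) -> float:
        """Per-presynaptic-cell contact probability z/n."""
        return self.z / self.n


def contact_pmf(y: int, config: CollateralConfig) -> float:
    """P(a given DCN receives contact from exactly ``y`` of ``m`` cells)."""
    if y < 0 or y > config.m:
        raise ValueError("y must be in [0, m]")
    return float(binom.pmf(y, config.m, config.p))


def prob_at_least(y: int, config: CollateralConfig) -> float:
    """P(a given DCN receives contact from at least ``y`` of ``m`` cells)."""
    if y < 0 or y > config.m:
        raise ValueError("y must be in [0, m]")
    if y == 0:
        return 1.0
    return float(binom.sf(y - 1, config.m, config.p))


def joint_prob_x_dcns(x: int, y: int, config: CollateralConfig) -> float:
    """P(exactly ``x`` of the ``n`` DCNs receive >= ``y`` contacts).

    Uses the printed independence-across-DCNs form (Binomial(n, q) with
    q = prob_at_least(y)); the wiring constraint that total contacts equal
    m*z makes this approximate — compare :func:`simulate_wiring_counts`.
    """
    if x < 0 or x > config.n:
        raise ValueError("x must be in [0, n]")
    return float(binom.pmf(x, config.n, prob_at_least(y, config)))


def expected_contacted(y: int, config: CollateralConfig) -> tuple[float, int]:
    """Expected number of DCNs with >= ``y`` contacts, (exact, rounded)."""
    value = config.n * prob_at_least(y, config)
    return value, int(round(value))


def simulate_wiring_counts(
    config: CollateralConfig,
    n_reps: int,
    seed: int | np.random.SeedSequence = 0,
    chunk: int = 10_000,
) -> np.ndarray:
    """Monte-Carlo wiring: contacts per DCN, shape (n_reps, n).

    Each repetition wires ``m`` presynaptic cells, each contacting a
    uniformly random ``z``-subset of the ``n`` DCNs (without replacement
    within a cell, independently across cells), and counts contacts per
    DCN.  This is the exact model that the binomial forms approximate.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty((n_reps, config.n), dtype=np.int16)
    done = 0
    while done < n_reps:
        k = min(chunk, n_reps - done)
        # random z-subset per cell: indices of the z smallest uniforms
        u = rng.random((k, config.m, config.n))
        picks = np.argpartition(u, config.z - 1, axis=-1)[..., : config.z]
        contacts = np.zeros((k, config.m, config.n), dtype=np.int16)
        np.put_along_axis(contacts, picks, 1, axis=-1)
        out[done : done + k] = contacts.sum(axis=1)
        done += k
    return out


@dataclass
class CountDistribution:
    """Per-DCN spike counts for one 1 ms bin, raw and rolling-mean values."""

    raw: np.ndarray
    rolled: np.ndarray
    rate_hz: float
    bin_ms: float = 1.0


def dcn_count_distribution(
    rate_hz: float = 147.5,
    n_pc: int = 400,
    convergence: int = 40,
    n_dcn: int = 50,
    bin_index: int = 4,
    bin_ms: float = 1.0,
    window: int = 2,
    dt: float = 0.05,
    refractory_ms: float = 1.0,
    seed: int = 0,
) -> CountDistribution:
    """Spikes received by each DCN of a group in one millisecond bin.

    Simulates the afferent population at a constant rate (the default
    147.5 Hz is one timestep of a step cycle), wires each of ``n_dcn``
    cells to a random ``convergence``-subset, and returns the per-DCN
    count in bin ``bin_index`` alongside the trailing ``window``-bin
    rolling-mean value ending at that bin.  The raw counts' idealised
    counterpart is Binomial(convergence * bin_ms/dt, rate*dt/1000).
    """
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    if bin_index + 1 < window:
        raise ValueError("bin_index must allow a full trailing window")
    root = np.random.SeedSequence(seed)
    raster_seed, wiring_seed = root.spawn(2)
    n_bins = bin_index + 1
    raster = generate_ensemble(
        constant(rate_hz), n_pc, n_bins * bin_ms, dt, refractory_ms, raster_seed
    )
    spb = int(round(bin_ms / dt))
    per_cell_bins = raster.spikes.reshape(n_pc, n_bins, spb).sum(axis=2)
    wiring = sample_wiring(
        WiringConfig(n_pc=n_pc, n_dcn=n_dcn, convergence=convergence), wiring_seed
    )
    per_dcn_bins = per_cell_bins[wiring].sum(axis=1)  # (n_dcn, n_bins)
    raw = per_dcn_bins[:, bin_index].astype(float)
    rolled = np.array(
        [rolling_mean(row, window)[-1] for row in per_dcn_bins.astype(float)]
    )
    return CountDistribution(raw=raw, rolled=rolled, rate_hz=rate_hz, bin_ms=bin_ms)


def resample_means(
    values,
    resample_count: int = 50,
    sample_size: int = 5,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Means of random samples (with replacement) from a distribution.

    Models each DCN averaging the values of ``sample_size`` random
    neighbours; the distribution of sample means is narrower than the
    source (SE = SD/sqrt(sample_size) for near-normal sources).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty source distribution")
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    if resample_count < 1:
        raise ValueError("resample_count must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.choice(x, size=(resample_count, sample_size), replace=True)
    return draws.mean(axis=1)
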