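"""Ensembles of Purkinje-cell spike trains as Bernoulli processes.

Each cell spikes independently in each timestep with a shared, possibly
time-varying probability (the synchronized microzone rate code), subject to
an absolute refractory period.  Identical seeds give bit-identical rasters;
cells draw from per-cell substreams spawned deterministically from the root
seed, so adding cells never perturbs existing trains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rate_profiles import RateProfile, spike_probabilities

__all__ = ["SpikeRaster", "generate_ensemble"]


@dataclass
class SpikeRaster:
    """Binary spike matrix (cells x timesteps) on a regular time grid."""

    spikes: np.ndarray
    dt: float
    refractory_ms: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes, dtype=np.uint8)
        if self.spikes.ndim != 2:
            raise ValueError("spikes must be 2-D (cells x timesteps)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_cells(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_steps * self.dt

    def spike_steps(self, cell: int) -> np.ndarray:
        """Timestep indices at which ``cell`` spiked."""
        return np.flatnonzero(self.spikes[cell])

    def summed_train(self) -> np.ndarray:
        """Total spikes per timestep across all cells."""
        return self.spikes.sum(axis=0).astype(np.int64)


def _uniforms(seed, n_cells: int, n_steps: int) -> np.ndarray:
    """Per-cell uniform substreams, stacked (cells x steps)."""
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    u = np.empty((n_cells, n_steps), dtype=np.float64)
    for i, child in enumerate(root.spawn(n_cells)):
        u[i] = np.random.default_rng(child).random(n_steps)
    return u


def generate_ensemble(
    profile: RateProfile,
    n_cells: int,
    duration_ms: float,
    dt: float = 0.05,
    refractory_ms: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
) -> SpikeRaster:
    """Simulate ``n_cells`` independent spike trains with a shared rate.

    At timestep ``k`` every cell spikes with probability
    ``rate_to_probability(evaluate_rate(profile, k*dt), dt)`` unless it is
    within ``refractory_ms`` of its own previous spike.  Two spikes exactly
    ``refractory_ms`` apart are permitted (the constraint is "no closer
    than").

    Returns a :class:`SpikeRaster`; fixed seed implies a bit-identical
    raster.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if refractory_ms < 0:
        raise ValueError("refractory_ms must be non-negative")

    n_steps = int(round(duration_ms / dt))
    if abs(n_steps * dt - duration_ms) > 1e-9 * max(1.0, duration_ms):
        raise ValueError("duration_ms must be an integer multiple of dt")

    p = spike_probabilities(profile, n_steps, dt)
    u = _uniforms(seed, n_cells, n_steps)

    refr_steps = int(round(refractory_ms / dt))
    if refr_steps <= 1:
        # Bernoulli at every step (a refractory shorter than one step is void)
        spikes = (u < p).astype(np.uint8)
    else:
        spikes = np.zeros((n_cells, n_steps), dtype=np.uint8)
        last = np.full(n_cells, -refr_steps, dtype=np.int64)
        for k in range(n_steps):
            fire = (u[:, k] < p[k]) & (k - last >= refr_steps)
            spikes[fire, k] = 1
            last[fire] = k
    seed_out = seed if isinstance(seed, (int, np.integer)) else None
    return SpikeRaster(spikes, dt=dt, refractory_ms=refractory_ms, seed=seed_out)
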