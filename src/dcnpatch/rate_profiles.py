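"""Time-varying firing-rate profiles and spike-probability conversion.

A Purkinje cell is modelled as a random spike generator whose instantaneous
firing rate ``N`` (Hz) sets the probability of a spike in each simulation
timestep: ``p = N * dt / 1000`` for a timestep of ``dt`` milliseconds
(``N / 20,000`` on the canonical 0.05 ms grid).  During locomotion the rate
passes cyclically through a range; here a cycle is idealised as a sinusoid

    N(t) = b + a * sin(2*pi*t/lambda + phase0)

with baseline ``b`` (Hz), amplitude ``a`` (Hz, the half-range either side of
``b``) and wavelength ``lambda`` (ms).  Constant-rate profiles are the
degenerate case used for steady-state ("unchanging spike probability")
simulations.

Some figure conventions express the sinusoid as ``y = a*sin(z*x/pi) + b``
with a wavelength-adjusting parameter ``z``; with ``x`` in milliseconds that
is the same curve with ``lambda = 2*pi**2 / z``, and converters between the
two parameterisations are provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RateProfile",
    "constant",
    "sinusoid",
    "evaluate_rate",
    "rate_to_probability",
    "spike_probabilities",
    "wavelength_from_z",
    "z_from_wavelength",
]


@dataclass(frozen=True)
class RateProfile:
    """An instantaneous firing-rate function of time.

    Parameters
    ----------
    kind:
        ``"constant"`` or ``"sinusoid"``.
    rate_hz:
        The rate for constant profiles (ignored otherwise).
    baseline_hz, amplitude_hz, wavelength_ms, phase0:
        Sinusoid parameters ``b``, ``a``, ``lambda`` and the start phase in
        radians (0 = start at baseline, rising).
    """

    kind: str
    rate_hz: float = 0.0
    baseline_hz: float = 0.0
    amplitude_hz: float = 0.0
    wavelength_ms: float = 200.0
    phase0: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sinusoid"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.kind == "constant":
            if self.rate_hz < 0:
                raise ValueError("rate_hz must be non-negative")
        else:
            if self.wavelength_ms <= 0:
                raise ValueError("wavelength_ms must be positive")
            if self.amplitude_hz < 0:
                raise ValueError("amplitude_hz must be non-negative")
            if self.baseline_hz - self.amplitude_hz < 0:
                raise ValueError(
                    "baseline_hz - amplitude_hz < 0: instantaneous rate "
                    "would be negative"
                )

    @property
    def min_rate_hz(self) -> float:
        if self.kind == "constant":
            return self.rate_hz
        return self.baseline_hz - self.amplitude_hz

    @property
    def max_rate_hz(self) -> float:
        if self.kind == "constant":
            return self.rate_hz
        return self.baseline_hz + self.amplitude_hz


def constant(rate_hz: float) -> RateProfile:
    """A profile with a fixed instantaneous rate (Hz)."""
    return RateProfile("constant", rate_hz=float(rate_hz))


def sinusoid(
    amplitude_hz: float,
    baseline_hz: float,
    wavelength_ms: float,
    phase0: float = 0.0,
) -> RateProfile:
    """A sinusoidal rate ``b + a*sin(2*pi*t/lambda + phase0)``."""
    return RateProfile(
        "sinusoid",
        baseline_hz=float(baseline_hz),
        amplitude_hz=float(amplitude_hz),
        wavelength_ms=float(wavelength_ms),
        phase0=float(phase0),
    )


def evaluate_rate(profile: RateProfile, t_ms):
    """Instantaneous rate (Hz) at time ``t_ms`` (ms, scalar or array)."""
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if profile.kind == "constant":
        out = np.broadcast_to(np.float64(profile.rate_hz), t.shape).copy()
    else:
        out = profile.baseline_hz + profile.amplitude_hz * np.sin(
            2.0 * np.pi * t / profile.wavelength_ms + profile.phase0
        )
    return float(out) if out.ndim == 0 else out


def rate_to_probability(rate_hz, dt_ms: float):
    """Per-timestep spike probability ``rate*dt/1000``, clamped to <= 1.

    For the canonical ``dt = 0.05`` ms this is ``N / 20,000`` for a rate of
    ``N`` Hz.
    """
    if dt_ms <= 0:
        raise ValueError("dt_ms must be positive")
    rate = np.asarray(rate_hz, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be non-negative")
    p = np.minimum(rate * dt_ms / 1000.0, 1.0)
    return float(p) if p.ndim == 0 else p


def spike_probabilities(profile: RateProfile, n_steps: int, dt_ms: float) -> np.ndarray:
    """Per-timestep spike probabilities on the grid ``t_k = k*dt``."""
    t = np.arange(n_steps) * dt_ms
    return np.atleast_1d(rate_to_probability(evaluate_rate(profile, t), dt_ms))


def wavelength_from_z(z: float) -> float:
    """Wavelength (ms) of ``sin(z*x/pi)`` with ``x`` in ms: ``2*pi**2/z``."""
    if z <= 0:
        raise ValueError("z must be positive")
    return 2.0 * np.pi**2 / z


def z_from_wavelength(wavelength_ms: float) -> float:
    """Inverse of :func:`wavelength_from_z` (the mapping is an involution)."""
    if wavelength_ms <= 0:
        raise ValueError("wavelength_ms must be positive")
    return 2.0 * np.pi**2 / wavelength_ms
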