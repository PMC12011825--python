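"""Phase shift from short-term plasticity: a sinusoid plus its derivative.

During behaviour the net effect of short-term depression and facilitation
at the Purkinje-DCN synapse is modelled as proportional to the rate of
change of the afferent rate — the derivative of the rate curve.  For a
sinusoidal rate f(t) = a*sin(2*pi*t/lambda) + b, the modulation received by
the nuclear group is the weighted sum

    g(t) = f(t) + w * f'(t)

with w (ms) scaling the relative influence of plasticity.  Since the
derivative of a sine leads it by a quarter cycle, g is a sine of the same
wavelength shifted earlier (to the left) by

    phi = atan(2*pi*w / lambda)        (radians),

i.e. shift_ms = phi * lambda / (2*pi) -> w as lambda -> inf: the shift is
nearly constant in milliseconds across wavelengths, adjusting automatically
in degrees.  Both this closed form and a numeric estimator (circular
cross-correlation peak with parabolic sub-sample interpolation) are
provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PhaseModel",
    "PhaseShiftResult",
    "rate_curve",
    "combined_curve",
    "analytic_shift",
    "measure_shift",
    "wavelength_sweep",
]


@dataclass(frozen=True)
class PhaseModel:
    """Sinusoid amplitude/baseline, wavelength and derivative weight."""

    a: float = 50.0
    b: float = 75.0
    wavelength_ms: float = 200.0
    w: float = 0.0

    def __post_init__(self) -> None:
        if self.wavelength_ms <= 0:
            raise ValueError("wavelength_ms must be positive")
        if self.w < 0:
            raise ValueError("w must be non-negative")


@dataclass(frozen=True)
class PhaseShiftResult:
    """Leftward shift in degrees, milliseconds and percent of wavelength."""

    shift_degrees: float
    shift_ms: float
    shift_pct: float
    wavelength_ms: float
    w: float | None = None


def rate_curve(model: PhaseModel, t_ms) -> np.ndarray:
    """f(t) = a*sin(2*pi*t/lambda) + b."""
    t = np.asarray(t_ms, dtype=float)
    return model.a * np.sin(2.0 * np.pi * t / model.wavelength_ms) + model.b


def combined_curve(model: PhaseModel, t_ms) -> np.ndarray:
    """g(t) = f(t) + w*f'(t), with the exact analytic derivative."""
    t = np.asarray(t_ms, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    omega = 2.0 * np.pi / model.wavelength_ms
    f = rate_curve(model, t)
    df = model.a * omega * np.cos(2.0 * np.pi * t / model.wavelength_ms)
    return f + model.w * df


def _result(shift_ms: float, wavelength_ms: float, w: float | None) -> PhaseShiftResult:
    return PhaseShiftResult(
        shift_degrees=360.0 * shift_ms / wavelength_ms,
        shift_ms=shift_ms,
        shift_pct=100.0 * shift_ms / wavelength_ms,
        wavelength_ms=wavelength_ms,
        w=w,
    )


def analytic_shift(w: float, wavelength_ms: float) -> PhaseShiftResult:
    """Closed-form leftward shift atan(2*pi*w/lambda) of f + w*f'."""
    if wavelength_ms <= 0:
        raise ValueError("wavelength_ms must be positive")
    phi = np.arctan(2.0 * np.pi * w / wavelength_ms)
    return _result(float(phi * wavelength_ms / (2.0 * np.pi)), wavelength_ms, w)


def measure_shift(
    reference,
    shifted,
    wavelength_ms: float,
    dt_ms: float | None = None,
    w: float | None = None,
) -> PhaseShiftResult:
    """Estimate the leftward shift of ``shifted`` relative to ``reference``.

    Both series must share one grid covering an integer number of
    wavelengths (endpoint excluded, so the grid is circular).  If ``dt_ms``
    is omitted the grid is assumed to span exactly one wavelength.  The
    estimator removes the means, takes the circular cross-correlation peak
    and refines it by parabolic interpolation; a positive result means
    ``shifted`` peaks earlier in time.
    """
    ref = np.asarray(reference, dtype=float)
    shf = np.asarray(shifted, dtype=float)
    if ref.shape != shf.shape or ref.ndim != 1:
        raise ValueError("series must be 1-D and sampled on the same grid")
    n = ref.size
    if n < 4:
        raise ValueError("grid too coarse")
    if dt_ms is None:
        dt_ms = wavelength_ms / n
    period_samples = wavelength_ms / dt_ms
    if n * dt_ms < wavelength_ms - 1e-9:
        raise ValueError("grid must cover at least one wavelength")

    x = ref - ref.mean()
    y = shf - shf.mean()
    # c[k] = sum_i y[i] * x[(i+k) % n]; if y[i] = x[i+d] the peak is at k=d,
    # d being the leftward shift in samples.
    c = np.fft.irfft(np.conj(np.fft.rfft(y)) * np.fft.rfft(x), n)
    k = int(np.argmax(c))
    cm, c0, cp = c[(k - 1) % n], c[k], c[(k + 1) % n]
    denom = cm - 2.0 * c0 + cp
    frac = 0.0 if denom == 0 else 0.5 * (cm - cp) / denom
    d = k + frac
    # wrap into (-period/2, period/2]
    d = d % period_samples
    if d > period_samples / 2:
        d -= period_samples
    return _result(float(d * dt_ms), wavelength_ms, w)


def wavelength_sweep(
    ws=(1.0, 2.5, 5.0, 10.0),
    wavelengths=(100.0, 200.0, 400.0, 800.0),
    a: float = 50.0,
    b: float = 75.0,
    n_points: int = 4096,
) -> pd.DataFrame:
    """Numeric and analytic shifts over a grid of weights and wavelengths.

    Returns columns ``wavelength_ms, w, shift_degrees, shift_ms, shift_pct``
    (numeric estimate) plus ``shift_degrees_analytic, shift_ms_analytic``.
    """
    if any(lam <= 0 for lam in wavelengths):
        raise ValueError("wavelengths must be positive")
    rows = []
    for lam in wavelengths:
        t = np.arange(n_points) * (lam / n_points)
        for w in ws:
            model = PhaseModel(a=a, b=b, wavelength_ms=lam, w=w)
            ref = rate_curve(model, t)
            comb = combined_curve(model, t)
            num = measure_shift(ref, comb, lam, dt_ms=lam / n_points, w=w)
            ana = analytic_shift(w, lam)
            rows.append(
                {
                    "wavelength_ms": lam,
                    "w": w,
                    "shift_degrees": num.shift_degrees,
                    "shift_ms": num.shift_ms,
                    "shift_pct": num.shift_pct,
                    "shift_degrees_analytic": ana.shift_degrees,
                    "shift_ms_analytic": ana.shift_ms,
                }
            )
    return pd.DataFrame(rows)
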