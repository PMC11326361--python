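"""Single-harmonic cosinor regression at a fixed 24-h period.

The model is ``y = m + a*cos(2*pi*t/24) + b*sin(2*pi*t/24)``, fit by ordinary
least squares. Amplitude ``A = sqrt(a^2 + b^2)`` is half the peak-to-trough
difference in log2 units, so the linear peak-to-trough fold change is
``2**(2A)``. The acrophase ``phi = (24/2pi) * atan2(b, a) mod 24`` is the peak
time in hours. Significance is an F-test against the intercept-only model with
(2, n-3) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

PERIOD_H = 24.0
_OMEGA = 2.0 * np.pi / PERIOD_H


class NotEstimableError(ValueError):
    """The cosinor fit is not estimable (too few samples or degenerate times)."""


@dataclass(frozen=True)
class HarmonicFit:
    """Result of a cosinor fit on one gene in one sample group."""

    n: int
    mesor: float
    coef_cos: float
    coef_sin: float
    amplitude: float     # log2 units, half peak-to-trough
    phase: float         # peak time, hours in [0, 24)
    p_value: float       # F-test vs intercept-only
    rss: float

    @property
    def log2_ptt(self) -> float:
        """Peak-to-trough difference on the log2 scale."""
        return 2.0 * self.amplitude

    @property
    def fc_ptt(self) -> float:
        """Linear peak-to-trough fold change, 2**(2A) >= 1."""
        return float(2.0 ** (2.0 * self.amplitude))


def design_matrix(times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    return np.column_stack([np.ones_like(t), np.cos(_OMEGA * t), np.sin(_OMEGA * t)])


def fit_harmonic(times, values) -> HarmonicFit:
    """Cosinor OLS fit of log2 expression on time-of-day.

    Raises :class:`NotEstimableError` when n < 4 or the harmonic design is
    singular (all times equal modulo 24).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and values have different lengths")
    n = len(t)
    if n < 4:
        raise NotEstimableError(f"need n >= 4 samples, got {n}")
    X = design_matrix(t)
    if np.linalg.matrix_rank(X) < 3:
        raise NotEstimableError("degenerate time design (all times equal mod 24)")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    m, a, b = (float(v) for v in beta)
    amplitude = float(np.hypot(a, b))
    phase = float((np.arctan2(b, a) / _OMEGA) % PERIOD_H)
    if tss <= 0.0:
        f_stat, p = 0.0, 1.0
    else:
        df2 = n - 3
        denom = rss / df2
        if denom <= 0.0:
            p = 0.0
        else:
            f_stat = ((tss - rss) / 2.0) / denom
            p = float(stats.f.sf(max(f_stat, 0.0), 2, df2))
    return HarmonicFit(n=n, mesor=m, coef_cos=a, coef_sin=b,
                       amplitude=amplitude, phase=phase, p_value=p, rss=rss)


def is_rhythmic(fit: HarmonicFit, p_max: float = 1e-4, fc_min: float = 1.5) -> bool:
    """Rhythmicity call: p <= p_max AND peak-to-trough fold change >= fc_min.

    Both thresholds are inclusive (ties pass).
    """
    return fit.p_value <= p_max and fit.fc_ptt >= fc_min


def phase_difference(phi1: float, phi2: float) -> float:
    """Circular distance between two acrophases, hours in [0, 12]."""
    d = abs(float(phi1) - float(phi2)) % PERIOD_H
    return min(d, PERIOD_H - d)


def cosinor_signal(times, mesor: float, amplitude: float, phase: float) -> np.ndarray:
    """Evaluate ``mesor + A*cos(2*pi*(t - phi)/24)`` — the generating model."""
    t = np.asarray(times, dtype=float)
    return mesor + amplitude * np.cos(_OMEGA * (t - phase))
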