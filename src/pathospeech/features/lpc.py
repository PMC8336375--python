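"""All-pole linear prediction and its weighted variants (order 38).

Four solvers over one frame of speech:

- plain LP: biased autocorrelation + Toeplitz solve (Levinson-Durbin
  normal equations).
- WLP: weighted covariance equations minimizing sum w(n) e^2(n) with
  the short-time-energy weight w(n) = sum_{i=1..M} x^2(n-i), M = order.
- SWLP: WLP with a stabilized weight recursion built from square-root
  energy factors; any remaining pole at or outside the unit circle is
  reflected to its conjugate reciprocal, so the model is always stable.
- XLP: per-lag weighting z_k(n) = w_k(n) x(n-k) with
  w_k(n) = (|x(n)| + |x(n-k)|) / 2, solved on the z terms.

Singular normal equations fall back to a ridge of 1e-8 * trace (logged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_toeplitz

WEIGHTINGS = ("none", "wlp", "swlp", "xlp")


@dataclass
class LPModel:
    order: int
    coefficients: np.ndarray   # a_1..a_p in x(n) ~ sum a_k x(n-k)
    weighting: str
    gain: float

    @property
    def pole_radii(self) -> np.ndarray:
        poly = np.concatenate([[1.0], -self.coefficients])
        return np.abs(np.roots(poly))

    @property
    def is_stable(self) -> bool:
        return bool((self.pole_radii < 1.0).all())

    def envelope_db(self, n_points: int, sample_rate: float
                    ) -> tuple[np.ndarray, np.ndarray]:
        """(freqs_hz, dB magnitude) of gain / A(e^{jw}) on [0, Nyquist]."""
        w = np.linspace(0.0, np.pi, n_points)
        k = np.arange(1, self.order + 1)
        a = 1.0 - (self.coefficients * np.exp(-1j * np.outer(w, k))).sum(axis=1)
        mag = np.abs(self.gain) / np.maximum(np.abs(a), 1e-12)
        return w * sample_rate / (2 * np.pi), 20.0 * np.log10(np.maximum(mag, 1e-12))


def _solve_ridge(R: np.ndarray, r: np.ndarray) -> np.ndarray:
    try:
        a = np.linalg.solve(R, r)
        if np.isfinite(a).all():
            return a
    except np.linalg.LinAlgError:
        pass
    warnings.warn("singular LP normal equations; applying ridge 1e-8 * trace")
    ridge = 1e-8 * np.trace(R) / R.shape[0] + 1e-30
    return np.linalg.solve(R + ridge * np.eye(R.shape[0]), r)


def _weighted_covariance(x: np.ndarray, w: np.ndarray, p: int) -> np.ndarray:
    """Solve sum_n w(n) (x(n) - sum_k a_k x(n-k))^2 over n = p..N-1."""
    n = x.size
    lagged = np.stack([x[p - k:n - k] for k in range(1, p + 1)])  # (p, n-p)
    wl = lagged * w[p:]
    R = wl @ lagged.T
    r = wl @ x[p:]
    return _solve_ridge(R, r)


def _ste_weight(x: np.ndarray, m: int) -> np.ndarray:
    """w(n) = sum_{i=1..m} x^2(n-i), zero history before the frame."""
    sq = np.concatenate([np.zeros(m), x ** 2])
    c = np.concatenate([[0.0], np.cumsum(sq)])
    n = x.size
    idx = np.arange(n) + m
    return c[idx] - c[idx - m]


def _swlp_weight(x: np.ndarray, m: int) -> np.ndarray:
    """Stabilized weight: square-root STE recursion with a positive floor.

    g(n) = max(sqrt(w(n)), eps) where w is the STE weight; the recursion
    ratio g(n)/g(n-1) is clamped to 1 from above so no step amplifies
    the partial-correlation magnitudes (the stabilizing property).
    """
    g = np.sqrt(_ste_weight(x, m))
    floor = max(g.max(), 1.0) * 1e-6
    g = np.maximum(g, floor)
    for i in range(1, g.size):
        if g[i] > g[i - 1]:
            g[i] = g[i - 1]
    return g ** 2


def _reflect_unstable_poles(a: np.ndarray) -> np.ndarray:
    poly = np.concatenate([[1.0], -a])
    roots = np.roots(poly)
    radii = np.abs(roots)
    if (radii < 1.0).all():
        return a
    bad = radii >= 1.0
    roots[bad] = roots[bad] / (radii[bad] ** 2 * (1.0 + 1e-9))
    new_poly = np.real(np.poly(roots))
    return -new_poly[1:] / new_poly[0]


def lp_family(frame: np.ndarray, order: int = 38, weighting: str = "none") -> LPModel:
    """Fit one all-pole model to a (windowed) frame of samples."""
    x = np.asarray(frame, dtype=np.float64)
    p = int(order)
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    if x.size <= 2 * p:
        raise ValueError(f"frame length {x.size} must exceed 2 * order = {2 * p}")

    if weighting == "none":
        full = np.correlate(x, x, mode="full")
        r = full[x.size - 1:x.size + p] / x.size   # biased autocorrelation
        if r[0] <= 0:
            a = np.zeros(p)
        else:
            a = solve_toeplitz((r[:p], r[:p]), r[1:p + 1])
        gain = float(np.sqrt(max(r[0] - a @ r[1:p + 1], 0.0)))
        return LPModel(order=p, coefficients=a, weighting=weighting, gain=gain)

    if weighting == "xlp":
        lags = np.stack([x[p - k:x.size - k] for k in range(0, p + 1)])  # (p+1, n-p)
        absl = np.abs(lags)
        w = 0.5 * (absl[0] + absl)        # w_k(n) = (|x(n)| + |x(n-k)|)/2
        z = w * lags
        R = z[1:] @ z[1:].T
        r = z[1:] @ z[0]
        a = _solve_ridge(R, r)
    else:
        w = _ste_weight(x, p) if weighting == "wlp" else _swlp_weight(x, p)
        a = _weighted_covariance(x, w, p)
        if weighting == "swlp":
            a = _reflect_unstable_poles(a)

    resid = x[p:] - np.stack([x[p - k:x.size - k] for k in range(1, p + 1)]).T @ a
    gain = float(np.sqrt(np.mean(resid ** 2)))
    return LPModel(order=p, coefficients=np.asarray(a), weighting=weighting, gain=gain)
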