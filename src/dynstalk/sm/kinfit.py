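"""Hyperbolic saturation fits for ATPase and microtubule-affinity data.

Both assays share one law: the observed rate (or bound fraction) rises
hyperbolically with microtubule concentration from a basal value to a
plateau,

    k_obs = (A - b) * [MT] / (K + [MT]) + b,

where A is k_cat (ATPase) or B_M (maximum binding), K is K_M or K_d in µM
tubulin dimer, and b is the microtubule-independent basal rate/fraction.
A motor whose ATPase no longer responds to microtubules yields flat data:
the amplitude and K are then unidentifiable and are reported as such rather
than as numbers, with only the basal value quoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from ..synth.kinetics import hyperbola

__all__ = ["SaturationFit", "fit_saturation"]


@dataclass
class SaturationFit:
    role: str                 # atpase | affinity
    amplitude: float          # k_cat or B_M; None when unidentifiable
    K: float                  # K_M or K_d (µM); None when unidentifiable
    basal: float              # k_basal
    se_amplitude: float
    se_K: float
    se_basal: float
    rss: float
    n: int
    identifiable: bool
    residuals: np.ndarray = field(repr=False, default=None)

    def predict(self, x):
        if not self.identifiable:
            return np.full_like(np.asarray(x, dtype=float), self.basal)
        return hyperbola(x, self.amplitude, self.K, self.basal)


def fit_saturation(x, y, role="atpase"):
    """Least-squares fit of the saturation law with non-negativity bounds.

    Requires at least 4 distinct concentrations including x = 0 (which pins
    the basal term). Initialization: basal from the zero-concentration mean,
    amplitude from the maximum response, K from the half-rise concentration.
    Standard errors come from the residual covariance (J^T J)^-1 * s².
    Flat data (no resolvable curvature) is reported with
    ``identifiable=False``: the basal value is the mean response and
    amplitude/K are None.
    """
    if role not in ("atpase", "affinity"):
        raise ValueError("role must be 'atpase' or 'affinity'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("x and y must be finite")
    distinct = np.unique(x)
    if distinct.size < 4:
        raise ValueError(f"need >= 4 distinct concentrations, got {distinct.size}")
    if 0.0 not in distinct:
        raise ValueError("a zero-concentration point is required to pin the basal term")

    n = x.size
    b0 = float(y[x == 0].mean())
    a0 = float(max(y.max(), b0 + 1e-6))
    half = b0 + 0.5 * (a0 - b0)
    above = distinct[[y[x == xc].mean() >= half for xc in distinct]]
    k0 = float(above.min()) if above.size and above.min() > 0 else \
        float(np.median(distinct[distinct > 0]))

    def resid(p):
        return hyperbola(x, p[0], p[1], p[2]) - y

    sol = least_squares(
        resid, x0=[a0, k0, max(b0, 0.0)],
        bounds=([0.0, 1e-12, 0.0], [np.inf, np.inf, np.inf]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    amplitude, K, basal = sol.x
    residuals = resid(sol.x)
    rss = float(np.sum(residuals ** 2))

    # Identifiability: does the hyperbola explain anything beyond a constant?
    const = float(y.mean())
    rss_const = float(np.sum((y - const) ** 2))
    scale = max(np.abs(y).max(), 1e-12)
    flat = (
        rss_const <= (1e-10 * scale) ** 2 * n
        or (rss_const - rss) <= 1e-9 * max(rss_const, (1e-9 * scale) ** 2)
        or abs(amplitude - basal) <= 1e-7 * scale
    )
    if flat:
        return SaturationFit(
            role=role, amplitude=None, K=None, basal=const,
            se_amplitude=np.nan, se_K=np.nan,
            se_basal=float(np.sqrt(rss_const / max(n - 1, 1) / n)),
            rss=rss_const, n=n, identifiable=False,
            residuals=y - const,
        )

    dof = max(n - 3, 1)
    s2 = rss / dof
    J = sol.jac
    try:
        cov = np.linalg.inv(J.T @ J) * s2
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        ses = np.full(3, np.nan)
    return SaturationFit(
        role=role, amplitude=float(amplitude), K=float(K), basal=float(basal),
        se_amplitude=float(ses[0]), se_K=float(ses[1]), se_basal=float(ses[2]),
        rss=rss, n=n, identifiable=True, residuals=residuals,
    )
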