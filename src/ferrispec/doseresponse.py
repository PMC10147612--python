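"""Dose-response and oxygen-saturation curve fitting.

Two small nonlinear models cover the quantitative readouts of an
erythroid-culture iron titration:

* hemoglobin per cell versus medium iron follows simple saturation
  (hyperbolic, Michaelis-Menten form)

      Hb(c) = Hb_max * c / (EC50 + c)

  fitted by unweighted nonlinear least squares on the untransformed
  scale (the data are reported untransformed);

* hemoglobin-oxygen saturation versus oxygen partial pressure is
  summarized by a Hill curve

      S(p) = p^n / (P50^n + p^n)

  whose P50 (pressure at half saturation) is the figure of merit.  A
  model-free P50 from monotone interpolation of the measured curve is
  reported alongside as a cross-check that does not assume the Hill
  form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, ValidationError

__all__ = [
    "DoseResponseDataset",
    "DoseResponseFit",
    "OxygenSaturationCurve",
    "HillFit",
    "fit_hyperbolic",
    "predict_hb",
    "fit_hill",
    "interpolated_p50",
]


@dataclass(frozen=True)
class DoseResponseDataset:
    """Paired (medium chelated-iron concentration, hemoglobin per cell).

    ``fe_conc`` in umol/L, ``hb`` in pg/cell.  At least three distinct
    concentrations are required for the two-parameter fit.
    """

    fe_conc: np.ndarray
    hb: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.fe_conc, dtype=float)
        h = np.asarray(self.hb, dtype=float)
        if c.shape != h.shape or c.ndim != 1:
            raise ValidationError("fe_conc and hb must be equal-length 1-D arrays")
        if np.any(c < 0) or np.any(h < 0):
            raise ValidationError("concentrations and hemoglobin must be >= 0")
        object.__setattr__(self, "fe_conc", c)
        object.__setattr__(self, "hb", h)

    @property
    def n_obs(self) -> int:
        return self.fe_conc.size


@dataclass(frozen=True)
class DoseResponseFit:
    """Hyperbolic fit result: plateau Hb_max (pg/cell), EC50 (umol/L)."""

    hb_max: float
    ec50: float
    rss: float
    converged: bool
    n_obs: int


@dataclass(frozen=True)
class OxygenSaturationCurve:
    """Measured (pO2 mmHg, fractional saturation in [0, 1]) pairs."""

    po2: np.ndarray
    saturation: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.po2, dtype=float)
        s = np.asarray(self.saturation, dtype=float)
        if p.shape != s.shape or p.ndim != 1:
            raise ValidationError("po2 and saturation must be equal-length 1-D arrays")
        if np.any(p < 0):
            raise ValidationError("po2 must be >= 0")
        if np.any((s < 0) | (s > 1)):
            raise ValidationError("saturation must lie in [0, 1]")
        object.__setattr__(self, "po2", p)
        object.__setattr__(self, "saturation", s)


@dataclass(frozen=True)
class HillFit:
    """Hill fit result: P50 (mmHg), Hill coefficient, and the
    interpolation-based P50 cross-check."""

    p50: float
    hill_n: float
    rss: float
    p50_interpolated: float
    converged: bool
    n_obs: int


def fit_hyperbolic(data: DoseResponseDataset) -> DoseResponseFit:
    """Least-squares fit of Hb = Hb_max * c / (EC50 + c).

    Initialization is data-driven and deterministic: Hb_max starts at
    the largest observed Hb, EC50 at the positive concentration whose
    response is nearest half of that.  A zero-concentration point is
    legitimate (the model pins it to zero; any observed Hb there ends
    up in the residual).

    Raises
    ------
    FitError
        Fewer than three distinct concentrations, no positive
        concentration, all-zero responses, or optimizer failure.
    """
    c, h = data.fe_conc, data.hb
    if np.unique(c).size < 3:
        raise FitError("need at least three distinct concentrations")
    if not np.any(c > 0):
        raise FitError("need at least one positive concentration")
    if np.all(h == 0):
        raise FitError("all responses are zero; the model is degenerate")

    hb0 = float(h.max())
    pos = c > 0
    ec0 = float(c[pos][np.argmin(np.abs(h[pos] - hb0 / 2.0))])
    if ec0 <= 0:
        ec0 = float(np.median(c[pos]))

    def resid(theta):
        hb_max, ec50 = theta
        return hb_max * c / (ec50 + c) - h

    res = least_squares(
        resid,
        x0=[hb0, ec0],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not res.success:
        raise FitError(f"hyperbolic fit failed: {res.message}")
    hb_max, ec50 = map(float, res.x)
    return DoseResponseFit(
        hb_max=hb_max,
        ec50=ec50,
        rss=float(np.sum(res.fun**2)),
        converged=True,
        n_obs=data.n_obs,
    )


def predict_hb(fit: DoseResponseFit, conc) -> np.ndarray | float:
    """Model prediction Hb_max * c / (EC50 + c); monotone in ``conc``."""
    c = np.asarray(conc, dtype=float)
    out = fit.hb_max * c / (fit.ec50 + c)
    return float(out) if out.ndim == 0 else out


def interpolated_p50(curve: OxygenSaturationCurve) -> float:
    """Model-free P50: linear interpolation at the first upward crossing
    of saturation 0.5 along increasing pO2.

    Raises :class:`FitError` when the curve never crosses half
    saturation.
    """
    order = np.argsort(curve.po2, kind="stable")
    p, s = curve.po2[order], curve.saturation[order]
    if s.min() > 0.5 or s.max() < 0.5:
        raise FitError("saturation curve does not cross 0.5")
    idx = np.nonzero(s >= 0.5)[0][0]
    if idx == 0:
        return float(p[0])
    p0, p1 = p[idx - 1], p[idx]
    s0, s1 = s[idx - 1], s[idx]
    if s1 == s0:
        return float(0.5 * (p0 + p1))
    return float(p0 + (0.5 - s0) * (p1 - p0) / (s1 - s0))


def fit_hill(curve: OxygenSaturationCurve) -> HillFit:
    """Least-squares Hill fit S = p^n / (P50^n + p^n).

    The interpolated P50 seeds the optimizer and is carried in the
    result as an assumption-free cross-check.  Requires the measured
    saturations to span 0.5.
    """
    p50_0 = interpolated_p50(curve)  # raises if the curve never crosses 0.5
    p, s = curve.po2, curve.saturation

    def resid(theta):
        lp50, ln = theta
        p50, n = np.exp(lp50), np.exp(ln)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(p > 0, (p / p50) ** n, 0.0)
        return ratio / (1.0 + ratio) - s

    res = least_squares(
        resid,
        x0=[np.log(max(p50_0, 1e-6)), np.log(2.7)],
        method="lm",
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    if not res.success:
        raise FitError(f"Hill fit failed: {res.message}")
    p50, hill_n = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    return HillFit(
        p50=p50,
        hill_n=hill_n,
        rss=float(np.sum(res.fun**2)),
        p50_interpolated=p50_0,
        converged=True,
        n_obs=p.size,
    )
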