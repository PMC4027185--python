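"""Michaelis-Menten kinetics: fitting, derived constants, group comparison.

Initial velocities v (uM s^-1) measured over a substrate concentration series
S (mM) are fit by nonlinear least squares to v = Vmax * S / (Km + S).  The
turnover number kcat (s^-1) is either supplied directly or derived as
Vmax / [E] from the enzyme molar concentration; catalytic efficiency
kcat/Km is reported in s^-1 uM^-1 (Km converted mM -> uM).  Replicate fits of
two enzymes are compared with an equal-variance two-sample Student's t-test.

Velocities are taken as already converted to uM s^-1; converting raw
absorbance slopes requires an extinction coefficient the caller must supply
(see :func:`linear_slope`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats


def mm_velocity(Vmax: float, Km: float, S) -> "float | np.ndarray":
    """Michaelis-Menten initial velocity: Vmax * S / (Km + S)."""
    if Km <= 0:
        raise ValueError("Km must be > 0")
    S = np.asarray(S, dtype=float)
    out = Vmax * S / (Km + S)
    return float(out) if out.ndim == 0 else out


@dataclass
class VelocityDataset:
    """Initial-velocity measurements for one enzyme.

    ``points`` is a list of (S in mM, v in uM s^-1, replicate id).
    ``enzyme_molar_conc`` (uM), if known, allows kcat = Vmax / [E].
    """

    enzyme: str
    points: List[Tuple[float, float, int]]
    enzyme_molar_conc: Optional[float] = None

    def __post_init__(self):
        for S, v, _rep in self.points:
            if S <= 0:
                raise ValueError("substrate concentrations must be > 0")
            if v < 0:
                raise ValueError("velocities must be >= 0")

    @property
    def S(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def v(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def validate_for_fit(self) -> None:
        if len({p[0] for p in self.points}) < 3:
            raise ValueError("need >= 3 distinct substrate concentrations")


@dataclass
class KineticsFit:
    """Fitted Km/Vmax with uncertainties and derived constants."""

    enzyme: str
    Km: Optional[float] = None          # mM
    Km_se: Optional[float] = None
    Vmax: Optional[float] = None        # uM s^-1
    Vmax_se: Optional[float] = None
    kcat: Optional[float] = None        # s^-1
    kcat_over_Km: Optional[float] = None  # s^-1 uM^-1
    n_points: int = 0
    converged: bool = False
    rss: Optional[float] = None
    below_detection: bool = False

    @classmethod
    def undetectable(cls, enzyme: str) -> "KineticsFit":
        """Activity below assay background ('U' rows); never encoded as zeros."""
        return cls(enzyme=enzyme, below_detection=True, converged=False)


def fit_mm(data: VelocityDataset, init_strategy: str = "halfmax",
           seed: int = 0) -> KineticsFit:
    """Least-squares (Vmax, Km) fit with Jacobian-based standard errors.

    ``halfmax`` initialisation: Vmax0 = max(v), Km0 = the S nearest Vmax0/2.
    On non-convergence two jittered restarts (deterministic per ``seed``) are
    attempted; if all fail the best-effort fit is returned with
    ``converged=False``.
    """
    data.validate_for_fit()
    S, v = data.S, data.v
    if init_strategy == "halfmax":
        vmax0 = float(v.max()) or 1.0
        km0 = float(S[np.argmin(np.abs(v - vmax0 / 2))])
    elif init_strategy == "median":
        vmax0 = float(np.median(v)) * 2 or 1.0
        km0 = float(np.median(S))
    else:
        raise ValueError(f"unknown init_strategy {init_strategy!r}")
    km0 = km0 if km0 > 0 else float(S.min())

    def model(S, Vmax, Km):
        return Vmax * S / (Km + S)

    rng = np.random.default_rng(seed)
    attempts = [(vmax0, km0)]
    attempts += [(vmax0 * float(rng.uniform(0.5, 2.0)),
                  km0 * float(rng.uniform(0.5, 2.0))) for _ in range(2)]
    popt = pcov = None
    converged = False
    for p0 in attempts:
        try:
            popt, pcov = optimize.curve_fit(
                model, S, v, p0=p0, bounds=([0, 1e-12], [np.inf, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=10000)
            converged = True
            break
        except RuntimeError:
            continue
    if popt is None:
        return KineticsFit(enzyme=data.enzyme, n_points=len(S), converged=False)
    Vmax, Km = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.diag(pcov))
    resid = v - model(S, *popt)
    fit = KineticsFit(
        enzyme=data.enzyme,
        Km=Km, Km_se=float(perr[1]),
        Vmax=Vmax, Vmax_se=float(perr[0]),
        n_points=len(S),
        converged=converged,
        rss=float(np.sum(resid ** 2)),
    )
    if data.enzyme_molar_conc:
        fit.kcat = Vmax / data.enzyme_molar_conc
    return fit


def derive_efficiency(fit: KineticsFit, kcat: Optional[float] = None,
                      enzyme_molar_conc: Optional[float] = None) -> KineticsFit:
    """Populate kcat (supplied or Vmax/[E]) and kcat/Km (s^-1 uM^-1).

    Km is in mM, so the efficiency divides by Km * 1000 (uM).
    """
    if kcat is not None:
        fit.kcat = kcat
    elif fit.kcat is None:
        if enzyme_molar_conc:
            if fit.Vmax is None:
                raise ValueError("no Vmax to derive kcat from")
            fit.kcat = fit.Vmax / enzyme_molar_conc
        else:
            raise ValueError("kcat not supplied and no enzyme concentration to derive it")
    if fit.Km is None or fit.Km <= 0:
        raise ValueError("fit has no positive Km")
    fit.kcat_over_Km = fit.kcat / (fit.Km * 1000.0)
    return fit


def compare_fits(fits_a: Sequence[KineticsFit], fits_b: Sequence[KineticsFit],
                 parameter: str = "Km") -> Tuple[float, float, int]:
    """Equal-variance two-sample Student's t-test on a fitted parameter.

    Returns (t statistic, two-sided p-value, degrees of freedom).
    """
    if parameter not in ("Km", "Vmax"):
        raise ValueError("parameter must be 'Km' or 'Vmax'")
    xa = [getattr(f, parameter) for f in fits_a]
    xb = [getattr(f, parameter) for f in fits_b]
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need >= 2 fits per group")
    if any(x is None for x in xa + xb):
        raise ValueError("all fits must carry the compared parameter")
    res = stats.ttest_ind(xa, xb, equal_var=True)
    return float(res.statistic), float(res.pvalue), len(xa) + len(xb) - 2


def linear_slope(t: Sequence[float], y: Sequence[float],
                 extinction_coeff: Optional[float] = None) -> float:
    """Least-squares slope of y over t (the linear part of a time curve).

    With ``extinction_coeff`` the absorbance slope is converted to a
    concentration rate (slope / extinction_coeff); the coefficient is the
    caller's responsibility.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    slope = float(np.polyfit(t, y, 1)[0])
    if extinction_coeff is not None:
        slope /= extinction_coeff
    return slope
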