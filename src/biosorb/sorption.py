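"""Batch sorption science: uptake arithmetic, isotherms, kinetics,
thermodynamics.

All model fits use the classical linearized forms, matching how such
data are analysed and plotted in the biosorption literature:

* Langmuir:     Ce/qe = 1/(Q0*b) + Ce/Q0      (Ce/qe vs Ce)
* Freundlich:   log qe = log KF + (1/n) log Ce (log qe vs log Ce)
* pseudo-1st:   log(qe - qt) = log qe - ks*t/2.303
* pseudo-2nd:   t/qt = 1/(k2'*qe^2) + t/qe, with initial rate h = k2'*qe^2
* Van 't Hoff:  ln Kc = -dH/(R*T) + dS/R, and dG(T) = -R*T*ln Kc

A nonlinear least-squares refinement is available for the isotherms but
the linearized fit is the canonical result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize as sp_optimize
from scipy import stats

from .errors import DegenerateDataWarning, DomainError

__all__ = [
    "IsothermFit",
    "KineticFit",
    "ThermoResult",
    "uptake_and_removal",
    "fit_langmuir",
    "fit_freundlich",
    "fit_pfo",
    "fit_pso",
    "vant_hoff",
    "R_GAS",
]

R_GAS = 8.314  # J/(mol K)


def uptake_and_removal(
    Ci: float, Ct: float, V: float, W: float
) -> tuple[float, float]:
    """Uptake qt = (Ci - Ct) * V / W (mg/g) and % removal = (Ci - Ct)/Ci * 100.

    ``V`` is solution volume (L), ``W`` biosorbent mass (g).
    """
    if W <= 0:
        raise DomainError("biosorbent mass W must be > 0")
    if Ci <= 0:
        raise DomainError("initial concentration Ci must be > 0")
    if not 0 <= Ct <= Ci:
        raise DomainError(f"Ct={Ct} must lie in [0, Ci={Ci}]")
    qt = (Ci - Ct) * V / W
    removal = (Ci - Ct) / Ci * 100.0
    return qt, removal


@dataclass
class IsothermFit:
    """Parameters of a linearized isotherm fit.

    Langmuir fills (Qo, b); Freundlich fills (KF, inv_n); the other
    pair is None.  ``r2`` refers to the linearized coordinates.
    """

    model: str  # "langmuir" | "freundlich"
    Qo: float | None = None  # mg/g
    b: float | None = None  # L/mg
    KF: float | None = None  # mg/g
    inv_n: float | None = None
    r2: float = np.nan


def _check_positive_pairs(x, y, names):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expected two equal-length 1-d sequences")
    if len(x) < 3:
        raise ValueError(f"need at least 3 points, got {len(x)}")
    bad = np.nonzero((x <= 0) | (y <= 0))[0]
    if bad.size:
        raise DomainError(
            f"nonpositive {names} at point indices {bad.tolist()}"
        )
    return x, y


def fit_langmuir(
    Ce: Sequence[float], qe: Sequence[float], nonlinear: bool = False
) -> IsothermFit:
    """Langmuir fit on the linearized coordinates Ce/qe vs Ce.

    slope = 1/Q0, intercept = 1/(Q0*b).  With ``nonlinear=True`` the
    linearized estimate seeds a nonlinear least-squares refinement of
    qe = Q0*b*Ce/(1 + b*Ce).
    """
    Ce, qe = _check_positive_pairs(Ce, qe, "(Ce, qe)")
    res = stats.linregress(Ce, Ce / qe)
    Qo = 1.0 / res.slope
    b = res.slope / res.intercept
    r2 = res.rvalue**2
    if nonlinear:
        def model(C, Qo_, b_):
            return Qo_ * b_ * C / (1.0 + b_ * C)
        (Qo, b), _ = sp_optimize.curve_fit(model, Ce, qe, p0=[Qo, b], maxfev=10000)
        resid = qe - model(Ce, Qo, b)
        r2 = 1.0 - np.sum(resid**2) / np.sum((qe - qe.mean()) ** 2)
    return IsothermFit(model="langmuir", Qo=float(Qo), b=float(b), r2=float(r2))


def fit_freundlich(
    Ce: Sequence[float], qe: Sequence[float], nonlinear: bool = False
) -> IsothermFit:
    """Freundlich fit on log10 qe vs log10 Ce (slope 1/n, intercept log KF)."""
    Ce, qe = _check_positive_pairs(Ce, qe, "(Ce, qe)")
    res = stats.linregress(np.log10(Ce), np.log10(qe))
    KF = 10.0**res.intercept
    inv_n = res.slope
    r2 = res.rvalue**2
    if nonlinear:
        def model(C, KF_, inv_n_):
            return KF_ * C**inv_n_
        (KF, inv_n), _ = sp_optimize.curve_fit(
            model, Ce, qe, p0=[KF, inv_n], maxfev=10000
        )
        resid = qe - model(Ce, KF, inv_n)
        r2 = 1.0 - np.sum(resid**2) / np.sum((qe - qe.mean()) ** 2)
    return IsothermFit(model="freundlich", KF=float(KF), inv_n=float(inv_n), r2=float(r2))


@dataclass
class KineticFit:
    """Parameters of a linearized kinetic fit.

    Pseudo-first-order fills (ks, qe); pseudo-second-order fills
    (k2p, qe, h) with the identity h = k2p * qe**2 holding exactly.
    """

    model: str  # "pfo" | "pso"
    ks: float | None = None  # 1/min
    k2p: float | None = None  # g/mg/min
    qe: float = np.nan  # mg/g
    h: float | None = None  # mg/g/min
    r2: float = np.nan


def fit_pfo(
    t: Sequence[float], qt: Sequence[float], qe_obs: float
) -> KineticFit:
    """Pseudo-first-order fit: log10(qe_obs - qt) vs t.

    Points with qt >= qe_obs (log undefined) are excluded with a warning.
    """
    t = np.asarray(t, dtype=float)
    qt = np.asarray(qt, dtype=float)
    keep = qt < qe_obs
    if not keep.all():
        warnings.warn(
            f"excluded {int((~keep).sum())} point(s) with qt >= qe_obs "
            "(log(qe - qt) undefined)",
            DegenerateDataWarning,
            stacklevel=2,
        )
    t, qt = t[keep], qt[keep]
    if len(t) < 3:
        raise ValueError("need at least 3 usable points for the PFO fit")
    res = stats.linregress(t, np.log10(qe_obs - qt))
    ks = -res.slope * 2.303
    qe_fit = 10.0**res.intercept
    return KineticFit(model="pfo", ks=float(ks), qe=float(qe_fit), r2=float(res.rvalue**2))


def fit_pso(t: Sequence[float], qt: Sequence[float]) -> KineticFit:
    """Pseudo-second-order fit: t/qt vs t.

    slope = 1/qe, intercept = 1/(k2'*qe^2); h = k2'*qe^2 = 1/intercept.
    A (near-)zero intercept means the data carry no rate information
    (already at equilibrium); the fit is flagged degenerate with
    k2' = h = inf.
    """
    t = np.asarray(t, dtype=float)
    qt = np.asarray(qt, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 points for the PSO fit")
    if np.any(qt[t > 0] <= 0):
        raise DomainError("qt must be > 0 at t > 0 for the PSO linearization")
    mask = t > 0
    res = stats.linregress(t[mask], t[mask] / qt[mask])
    qe = 1.0 / res.slope
    if res.intercept <= np.finfo(float).eps * np.abs(t[mask] / qt[mask]).max():
        warnings.warn(
            "PSO intercept ~ 0: series is equilibrium-only, rate constant "
            "is unidentifiable",
            DegenerateDataWarning,
            stacklevel=2,
        )
        return KineticFit(model="pso", k2p=np.inf, qe=float(qe), h=np.inf,
                          r2=float(res.rvalue**2))
    h = 1.0 / res.intercept
    k2p = h / qe**2  # enforces h = k2p * qe^2 exactly
    return KineticFit(model="pso", k2p=float(k2p), qe=float(qe), h=float(h),
                      r2=float(res.rvalue**2))


@dataclass
class ThermoResult:
    """Van 't Hoff analysis over a temperature series.

    Per-temperature Gibbs energies come straight from dG = -R*T*ln Kc;
    the enthalpy and entropy come from the regression of ln Kc on 1/T.
    Units follow the kJ convention: dH, dG in kJ/mol, dS in kJ/(mol K).
    """

    T: np.ndarray  # K
    Kc: np.ndarray
    dG: np.ndarray  # kJ/mol, per temperature
    dH: float  # kJ/mol
    dS: float  # kJ/(mol K)
    r2_vanthoff: float


def vant_hoff(T: Sequence[float], Kc: Sequence[float]) -> ThermoResult:
    """Thermodynamic parameters from equilibrium constants at >= 3 temperatures.

    ``T`` in kelvin; values below 200 are interpreted as Celsius and
    converted.  Requires Kc > 0.
    """
    T = np.asarray(T, dtype=float)
    Kc = np.asarray(Kc, dtype=float)
    if len(T) < 3:
        raise ValueError("need at least 3 temperatures")
    T = np.where(T < 200.0, T + 273.15, T)
    if np.any(Kc <= 0):
        raise DomainError("all Kc must be > 0")
    dG = -R_GAS * T * np.log(Kc) / 1000.0
    res = stats.linregress(1.0 / T, np.log(Kc))
    dH = -res.slope * R_GAS / 1000.0
    dS = res.intercept * R_GAS / 1000.0
    return ThermoResult(
        T=T, Kc=Kc, dG=dG, dH=float(dH), dS=float(dS), r2_vanthoff=float(res.rvalue**2)
    )
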