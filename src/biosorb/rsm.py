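"""Quadratic response-surface fitting, ANOVA and constrained maximization.

The response model is the full second-order polynomial in coded factor
units,

    Y = b0 + sum_i bi Xi + sum_i bii Xi^2 + sum_{i<j} bij Xi Xj,

with 15 terms for four factors.  Fitting is ordinary least squares;
the residual sum of squares is further split into lack of fit and pure
error using replicated design points (the centre replicates of a CCD),
which is the standard adequacy check for a designed experiment.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .dataset import FACTORS, CCDDataset, FactorSpec
from .errors import SingularDesignError

__all__ = [
    "QuadraticSurface",
    "AnovaRow",
    "FitStats",
    "fit_quadratic",
    "predict_surface",
    "maximize_surface",
    "published_quadratic",
    "INTERACTION_PAIRS",
]

#: Order of the two-factor interaction coefficients.
INTERACTION_PAIRS: tuple[tuple[int, int], ...] = tuple(
    itertools.combinations(range(4), 2)
)

TERM_NAMES = (
    ["const"]
    + [f"x{i+1}" for i in range(4)]
    + [f"x{i+1}^2" for i in range(4)]
    + [f"x{a+1}*x{b+1}" for a, b in INTERACTION_PAIRS]
)


@dataclass
class QuadraticSurface:
    """Coefficients of the 15-term quadratic response model in coded units."""

    beta0: float
    linear: np.ndarray  # (4,)
    quadratic: np.ndarray  # (4,)
    interaction: np.ndarray  # (6,), ordered as INTERACTION_PAIRS
    factor_specs: tuple[FactorSpec, ...] = FACTORS

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float)
        self.quadratic = np.asarray(self.quadratic, dtype=float)
        self.interaction = np.asarray(self.interaction, dtype=float)
        if self.linear.shape != (4,) or self.quadratic.shape != (4,):
            raise ValueError("linear and quadratic must each hold 4 coefficients")
        if self.interaction.shape != (6,):
            raise ValueError("interaction must hold 6 coefficients")

    @property
    def coefficients(self) -> np.ndarray:
        """All 15 coefficients in design-matrix column order."""
        return np.concatenate(
            ([self.beta0], self.linear, self.quadratic, self.interaction)
        )

    def predict(self, x: Sequence[float] | np.ndarray) -> float | np.ndarray:
        """Evaluate the polynomial at coded point(s) ``x`` (shape (4,) or (n, 4))."""
        X = np.atleast_2d(np.asarray(x, dtype=float))
        y = design_matrix(X) @ self.coefficients
        return float(y[0]) if np.ndim(x) == 1 else y

    def predict_actual(self, x_actual: Sequence[float] | np.ndarray):
        """Evaluate at actual-unit point(s), coding internally."""
        centers = np.array([f.center for f in self.factor_specs])
        steps = np.array([f.step for f in self.factor_specs])
        return self.predict((np.asarray(x_actual, dtype=float) - centers) / steps)

    # ---- JSON artifact ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "linear": self.linear.tolist(),
            "quadratic": self.quadratic.tolist(),
            "interaction": self.interaction.tolist(),
            "interaction_pairs": [list(p) for p in INTERACTION_PAIRS],
            "factors": [
                {
                    "name": f.name,
                    "units": f.units,
                    "center": f.center,
                    "step": f.step,
                    "axial_level": f.axial_level,
                }
                for f in self.factor_specs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticSurface":
        specs = tuple(
            FactorSpec(f["name"], f["units"], f["center"], f["step"], f["axial_level"])
            for f in d["factors"]
        )
        return cls(
            beta0=float(d["beta0"]),
            linear=np.array(d["linear"]),
            quadratic=np.array(d["quadratic"]),
            interaction=np.array(d["interaction"]),
            factor_specs=specs,
        )


@dataclass(frozen=True)
class AnovaRow:
    source: str
    df: int
    ss: float
    ms: float | None = None
    f: float | None = None
    p: float | None = None


@dataclass
class FitStats:
    """Goodness-of-fit summary of a quadratic surface fit."""

    r2: float
    adj_r2: float
    mean_pct_error: float  # mean absolute percentage error, %
    anova: list[AnovaRow] = field(default_factory=list)

    def anova_by_source(self) -> dict[str, AnovaRow]:
        return {row.source: row for row in self.anova}

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "mean_pct_error": self.mean_pct_error,
            "anova": [
                {
                    "source": r.source,
                    "df": r.df,
                    "SS": r.ss,
                    "MS": r.ms,
                    "F": r.f,
                    "p": r.p,
                }
                for r in self.anova
            ],
        }


def design_matrix(C: np.ndarray) -> np.ndarray:
    """15-column second-order design matrix from an (n, 4) coded matrix."""
    C = np.asarray(C, dtype=float)
    cols = [np.ones(len(C))]
    cols += [C[:, j] for j in range(4)]
    cols += [C[:, j] ** 2 for j in range(4)]
    cols += [C[:, a] * C[:, b] for a, b in INTERACTION_PAIRS]
    return np.column_stack(cols)


def _collinear_terms(D: np.ndarray) -> list[str]:
    """Names of columns that are linearly dependent on earlier ones."""
    bad = []
    rank = 0
    for j in range(D.shape[1]):
        r = np.linalg.matrix_rank(D[:, : j + 1])
        if r == rank:
            bad.append(TERM_NAMES[j])
        rank = r
    return bad


def fit_quadratic(dataset: CCDDataset) -> tuple[QuadraticSurface, FitStats]:
    """Least-squares fit of the full quadratic model in coded units.

    Returns the surface plus fit statistics: R², adjusted R², mean
    absolute percentage error, and an ANOVA table with the residual
    split into lack of fit and pure error (from replicated runs).
    """
    n = len(dataset)
    if n < 15:
        raise ValueError(f"need at least 15 runs to fit 15 parameters, got {n}")
    C = dataset.coded_matrix()
    y = dataset.response()
    D = design_matrix(C)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise SingularDesignError(_collinear_terms(D))

    res = sm.OLS(y, D).fit()
    beta = res.params
    surface = QuadraticSurface(
        beta0=float(beta[0]),
        linear=beta[1:5],
        quadratic=beta[5:9],
        interaction=beta[9:15],
        factor_specs=dataset.factors,
    )

    fitted = res.fittedvalues
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_reg = ss_tot - ss_res
    df_reg, df_res = 14, n - 15

    # pure error: pooled within-group SS over replicated design points
    groups: dict[tuple, list[float]] = {}
    for row, yi in zip(np.round(C, 9), y):
        groups.setdefault(tuple(row), []).append(yi)
    ss_pe = sum(
        float(np.sum((np.array(v) - np.mean(v)) ** 2))
        for v in groups.values()
        if len(v) > 1
    )
    df_pe = sum(len(v) - 1 for v in groups.values() if len(v) > 1)
    ss_lof = ss_res - ss_pe
    df_lof = df_res - df_pe

    def _row(src, df, ss, df_err=None, ms_err=None):
        ms = ss / df if df > 0 else None
        f = p = None
        if ms is not None and ms_err not in (None, 0) and df_err:
            f = ms / ms_err
            p = float(stats.f.sf(f, df, df_err))
        return AnovaRow(src, df, ss, ms, f, p)

    ms_res = ss_res / df_res if df_res > 0 else None
    ms_pe = ss_pe / df_pe if df_pe > 0 else None
    anova = [
        _row("regression", df_reg, ss_reg, df_res, ms_res),
        _row("residual", df_res, ss_res),
        _row("lack_of_fit", df_lof, ss_lof, df_pe, ms_pe),
        _row("pure_error", df_pe, ss_pe),
        AnovaRow("total", n - 1, ss_tot),
    ]

    with np.errstate(divide="ignore", invalid="ignore"):
        mape = float(np.mean(np.abs((y - fitted) / y)) * 100.0)
    stats_ = FitStats(
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        mean_pct_error=mape,
        anova=anova,
    )
    return surface, stats_


def predict_surface(surface: QuadraticSurface, x: Sequence[float]) -> float:
    """Evaluate the surface at a coded 4-vector."""
    return float(surface.predict(np.asarray(x, dtype=float)))


def maximize_surface(
    surface: QuadraticSurface,
    bounds: Sequence[tuple[float, float]] = ((-2, 2),) * 4,
) -> tuple[np.ndarray, float]:
    """Box-constrained maximum of the surface by multi-start local search.

    Starts from every corner of the box plus its centre, runs bounded
    Nelder-Mead from each, and returns the best (x*, y*); exact ties are
    broken toward the smallest coded L2 norm of x*.
    """
    bounds = [tuple(map(float, b)) for b in bounds]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    neg = lambda x: -surface.predict(x)
    starts = [np.array(c) for c in itertools.product(*bounds)]
    starts.append((lo + hi) / 2.0)
    best_x, best_y = None, -np.inf
    for x0 in starts:
        r = optimize.minimize(
            neg,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        x = np.clip(r.x, lo, hi)
        yv = float(surface.predict(x))
        better = yv > best_y + 1e-12
        tie = abs(yv - best_y) <= 1e-12 and (
            best_x is None or np.linalg.norm(x) < np.linalg.norm(best_x)
        )
        if better or tie:
            best_x, best_y = x, yv
    return best_x, best_y


def published_quadratic() -> QuadraticSurface:
    """The quadratic model reported by the original As(III) biosorption
    study (coded units).  Reference data for comparison; note it does not
    coincide with a refit of the bundled CCD table."""
    return QuadraticSurface(
        beta0=94.00,
        linear=np.array([9.87, 0.017, 3.57, -5.98]),
        quadratic=np.array([-8.68, -22.35, -4.3, -7.23]),
        interaction=np.array([-1.85, 5.75, -2.22, -0.53, 0.33, -1.3]),
    )
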