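"""Packed-bed (up-flow column) breakthrough analysis.

Given the outlet concentration history Ct(t) of a fixed-bed sorption
column, this module locates the breakthrough and exhaustion times,
integrates the breakthrough curve for the total metal sorbed, and
derives the standard column performance quantities: treated volumes,
metal fed, uptake, percentage removal, empty-bed contact time, sorbent
usage rate, elution efficiency and the BDST critical bed height.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError, DegenerateDataWarning

__all__ = [
    "ColumnConfig",
    "BreakthroughSeries",
    "ColumnMetrics",
    "effluent_volume",
    "find_breakthrough",
    "metal_fed",
    "total_sorbed",
    "uptake",
    "column_removal",
    "elution_efficiency",
    "ebct",
    "usage_rate",
    "bdst_critical_height",
    "analyze",
]


@dataclass(frozen=True)
class ColumnConfig:
    """Geometry and operating conditions of the packed bed."""

    diameter: float  # cm
    Z: float  # bed height, cm
    Q: float  # flow rate, mL/min
    C0: float  # inlet concentration, mg/L
    M: float  # sorbent mass, g
    Cb: float  # breakthrough threshold concentration, mg/L
    rho: float | None = None  # packed density, g/cm^3

    def __post_init__(self) -> None:
        for name in ("diameter", "Z", "Q", "C0", "M", "Cb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.Cb >= self.C0:
            raise ValueError("breakthrough threshold Cb must be < C0")

    @property
    def cross_section(self) -> float:
        """Cross-sectional area Ac = pi (d/2)^2, cm^2."""
        return math.pi * (self.diameter / 2.0) ** 2

    @property
    def bed_volume(self) -> float:
        """Vc = Ac * Z, mL (1 cm^3 = 1 mL)."""
        return self.cross_section * self.Z

    @property
    def linear_velocity(self) -> float:
        """Superficial velocity u = Q/Ac, cm/min."""
        return self.Q / self.cross_section


@dataclass
class BreakthroughSeries:
    """Outlet concentration history (t ascending, 0 <= Ct <= C0)."""

    t: np.ndarray  # min
    Ct: np.ndarray  # mg/L

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.Ct = np.asarray(self.Ct, dtype=float)
        if self.t.shape != self.Ct.shape or self.t.ndim != 1:
            raise ValueError("t and Ct must be equal-length 1-d arrays")
        if len(self.t) >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.Ct < 0):
            raise ValueError("Ct must be nonnegative")


def effluent_volume(Q: float, t: float) -> float:
    """Veff = Q * t (mL), the volume passed through the column by time t."""
    if Q < 0 or t < 0:
        raise DomainError("Q and t must be nonnegative")
    return Q * t


def _first_crossing(t: np.ndarray, C: np.ndarray, level: float) -> float | None:
    """First time C(t) reaches `level`, linearly interpolated; None if never."""
    at = np.nonzero(C >= level)[0]
    if at.size == 0:
        return None
    i = at[0]
    if i == 0 or C[i] == level:
        return float(t[i])
    t0, t1, c0, c1 = t[i - 1], t[i], C[i - 1], C[i]
    return float(t0 + (level - c0) / (c1 - c0) * (t1 - t0))


def find_breakthrough(
    series: BreakthroughSeries,
    C0: float,
    Cb: float,
    Ce_frac: float = 0.95,
) -> tuple[float | None, float | None]:
    """(tb, te): first times the outlet reaches Cb and Ce_frac*C0.

    Crossings between samples are linearly interpolated.  A threshold the
    series never reaches yields None in that slot (column not broken
    through / not exhausted) rather than an exception.
    """
    tb = _first_crossing(series.t, series.Ct, Cb)
    te = _first_crossing(series.t, series.Ct, Ce_frac * C0)
    return tb, te


def metal_fed(C0: float, Q: float, te: float) -> float:
    """Total metal fed X = C0 * Q * te / 1000 (mg)."""
    if C0 < 0 or Q < 0 or te < 0:
        raise DomainError("C0, Q and te must be nonnegative")
    return C0 * Q * te / 1000.0


def total_sorbed(series: BreakthroughSeries, C0: float, Q: float) -> float:
    """Metal sorbed up to the end of the series (mg): the area between the
    inlet level and the breakthrough curve, qtot = Q/1000 * int (C0 - Ct) dt,
    integrated by the trapezoidal rule."""
    if np.any(series.Ct > C0 * (1 + 1e-9)):
        raise DomainError("Ct exceeds C0 in the series")
    return float(Q / 1000.0 * np.trapezoid(C0 - series.Ct, series.t))


def uptake(qtot: float, M: float) -> float:
    """Column uptake capacity q = qtot / M (mg/g)."""
    if M <= 0:
        raise DomainError("sorbent mass M must be > 0")
    return qtot / M


def column_removal(qtot: float, X: float) -> float:
    """Percentage removal over the run: qtot / X * 100."""
    if X <= 0:
        raise DomainError("metal fed X must be > 0")
    return qtot / X * 100.0


def elution_efficiency(md: float, qtot: float) -> float:
    """Elution efficiency E = md / qtot * 100 (%), md = metal desorbed (mg)."""
    if qtot <= 0:
        raise DomainError("qtot must be > 0")
    return md / qtot * 100.0


def ebct(diameter: float, Z: float, Q: float) -> float:
    """Empty-bed contact time Ac*Z/Q (min)."""
    if diameter <= 0 or Z < 0 or Q <= 0:
        raise DomainError("diameter and Q must be > 0, Z >= 0")
    return math.pi * (diameter / 2.0) ** 2 * Z / Q


def usage_rate(M: float, Vb: float) -> float:
    """Sorbent usage rate Ur = M / Vb, in g per litre treated at breakthrough."""
    if M <= 0 or Vb <= 0:
        raise DomainError("M and Vb must be > 0")
    return M / Vb * 1000.0


def bdst_critical_height(
    u: float, ka: float, N0: float, C0: float, Cb: float
) -> float:
    """BDST critical bed height Z0 = u/(ka*N0) * ln(C0/Cb - 1) (cm).

    The minimum depth with nonzero service time at threshold Cb.  For
    Cb >= C0/2 the logarithm's argument drops to <= 1 and Z0 <= 0; the
    value is returned with a degeneracy warning.
    """
    if not (C0 > Cb > 0):
        raise DomainError("need C0 > Cb > 0")
    if u <= 0 or ka <= 0 or N0 <= 0:
        raise DomainError("u, ka and N0 must be > 0")
    z0 = u / (ka * N0) * math.log(C0 / Cb - 1.0)
    if z0 <= 0:
        warnings.warn(
            "Cb >= C0/2: BDST critical height is non-positive (degenerate)",
            DegenerateDataWarning,
            stacklevel=2,
        )
    return z0


@dataclass
class ColumnMetrics:
    """Derived performance quantities of one column run."""

    tb: float | None  # min
    te: float | None  # min
    Vb: float | None  # mL
    Ve: float | None  # mL
    X: float | None  # mg fed up to te
    qtot: float  # mg sorbed
    q: float  # mg/g
    removal: float | None  # %
    EBCT: float  # min
    Ur: float | None  # g/L
    Nb: float | None  # bed volumes treated at breakthrough
    u: float  # cm/min
    E: float | None = None  # elution efficiency, %
    md: float | None = None  # mg desorbed
    exhausted: bool = True

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "tb", "te", "Vb", "Ve", "X", "qtot", "q", "removal",
            "EBCT", "Ur", "Nb", "u", "E", "md", "exhausted")}


def analyze(
    config: ColumnConfig,
    series: BreakthroughSeries,
    Ce_frac: float = 0.95,
    elution_series: BreakthroughSeries | None = None,
) -> ColumnMetrics:
    """Full breakthrough analysis of one column run.

    When the curve never reaches exhaustion, X and removal are reported
    as None and ``exhausted`` is False; qtot then covers the sampled
    span only.  An optional elution series (outlet concentration during
    regeneration) adds the desorbed mass and elution efficiency.
    """
    tb, te = find_breakthrough(series, config.C0, config.Cb, Ce_frac)
    Vb = effluent_volume(config.Q, tb) if tb is not None else None
    Ve = effluent_volume(config.Q, te) if te is not None else None
    X = metal_fed(config.C0, config.Q, te) if te is not None else None
    qtot = total_sorbed(series, config.C0, config.Q)
    q = uptake(qtot, config.M)
    removal = column_removal(qtot, X) if X else None
    Nb = Vb / config.bed_volume if Vb is not None else None
    Ur = usage_rate(config.M, Vb) if Vb else None
    md = E = None
    if elution_series is not None:
        # desorbed mass: area under the elution curve
        md = float(config.Q / 1000.0 * np.trapezoid(elution_series.Ct, elution_series.t))
        E = elution_efficiency(md, qtot)
    return ColumnMetrics(
        tb=tb, te=te, Vb=Vb, Ve=Ve, X=X, qtot=qtot, q=q, removal=removal,
        EBCT=ebct(config.diameter, config.Z, config.Q),
        Ur=Ur, Nb=Nb, u=config.linear_velocity, E=E, md=md,
        exhausted=te is not None,
    )
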