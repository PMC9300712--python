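"""Synthetic data generators mirroring each analysis stage's model.

Every generator is a pure function of its parameters and seed, and a
noiseless call returns points lying exactly on the generating model, so
each fitting routine can be closed-loop tested (generate -> refit ->
recover) without any external data.  The generated objects always
satisfy the invariants of the consuming types (responses within
[0, 100], outlet concentrations within [0, C0], strictly increasing
time grids).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .dataset import FACTORS, CCDDataset, CCDRun, FactorSpec
from .rsm import QuadraticSurface

__all__ = [
    "SyntheticSpec",
    "ccd_design_codes",
    "simulate_ccd",
    "simulate_isotherm",
    "simulate_kinetics",
    "simulate_vanthoff",
    "simulate_breakthrough",
    "breakthrough_crossing_time",
    "simulate",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Declarative description of one synthetic dataset."""

    kind: str  # ccd | isotherm | kinetics | vanthoff | breakthrough
    true_params: dict[str, Any] = field(default_factory=dict)
    noise_sd: float = 0.0
    n: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.kind not in (
            "ccd", "isotherm", "kinetics", "vanthoff", "breakthrough"
        ):
            raise ValueError(f"unknown kind {self.kind!r}")


def ccd_design_codes() -> tuple[np.ndarray, list[str]]:
    """The 31-point four-factor CCD geometry in coded units, ordered as
    16 factorial (+-1), 8 axial (+-2) then 7 centre replicates, with the
    train/test split pattern of the bundled study table (5 factorial and
    2 axial points held out for testing)."""
    rows = []
    for signs in np.ndindex(2, 2, 2, 2):
        rows.append([1.0 if s else -1.0 for s in signs])
    for j in range(4):
        for a in (-2.0, 2.0):
            v = [0.0] * 4
            v[j] = a
            rows.append(v)
    rows += [[0.0] * 4] * 7
    codes = np.array(rows)
    # hold out the same design points the bundled table holds out
    test_points = {
        (-1.0, 1.0, 1.0, 1.0),
        (1.0, 1.0, 1.0, 1.0),
        (0.0, -2.0, 0.0, 0.0),
        (-1.0, -1.0, -1.0, 1.0),
        (-1.0, 1.0, 1.0, -1.0),
        (0.0, 0.0, 0.0, -2.0),
        (1.0, -1.0, -1.0, -1.0),
    }
    split = [
        "test" if tuple(r) in test_points else "train" for r in codes
    ]
    return codes, split


def simulate_ccd(
    surface: QuadraticSurface,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CCDDataset:
    """CCD dataset whose responses are surface values plus Gaussian noise.

    Responses are clipped to [0, 100] so the result is always a valid
    percentage-removal table (relevant only at large noise levels).
    """
    rng = np.random.default_rng(seed)
    codes, split = ccd_design_codes()
    specs = surface.factor_specs
    centers = np.array([f.center for f in specs])
    steps = np.array([f.step for f in specs])
    actual = centers + codes * steps
    y = np.asarray(surface.predict(codes), dtype=float)
    y = y + rng.normal(0.0, noise_sd, size=len(y))
    y = np.clip(y, 0.0, 100.0)
    runs = [
        CCDRun(
            dose=a[0], ph=a[1], temp=a[2], conc=a[3],
            removal_obs=yi, split=s,
        )
        for a, yi, s in zip(actual, y, split)
    ]
    return CCDDataset(tuple(specs), runs)


def simulate_isotherm(
    Qo: float,
    b: float,
    Ce_max: float = 1.1,
    n: int = 20,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """(Ce, qe) points on a Langmuir isotherm qe = Q0*b*Ce/(1 + b*Ce)."""
    rng = np.random.default_rng(seed)
    Ce = np.linspace(Ce_max / n, Ce_max, n)
    qe = Qo * b * Ce / (1.0 + b * Ce)
    qe = np.maximum(qe + rng.normal(0.0, noise_sd, size=n), np.finfo(float).tiny)
    return Ce, qe


def simulate_kinetics(
    k2p: float,
    qe: float,
    t_max: float = 135.0,
    n: int = 20,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """(t, qt) points on a pseudo-second-order curve
    qt = qe^2 k2' t / (1 + qe k2' t)."""
    rng = np.random.default_rng(seed)
    t = np.linspace(t_max / n, t_max, n)
    qt = qe**2 * k2p * t / (1.0 + qe * k2p * t)
    qt = np.maximum(qt + rng.normal(0.0, noise_sd, size=n), np.finfo(float).tiny)
    return t, qt


def simulate_vanthoff(
    dH: float,
    dS: float,
    T: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """(T, Kc) with ln Kc = -dH/(R T) + dS/R; dH in kJ/mol, dS in kJ/(mol K).

    Default temperatures are the six study levels 293-318 K; noise acts
    on ln Kc.
    """
    from .sorption import R_GAS

    rng = np.random.default_rng(seed)
    if T is None:
        T = np.array([293.0, 298.0, 303.0, 308.0, 313.0, 318.0])
    T = np.asarray(T, dtype=float)
    lnKc = -dH * 1000.0 / (R_GAS * T) + dS * 1000.0 / R_GAS
    lnKc = lnKc + rng.normal(0.0, noise_sd, size=len(T))
    return T, np.exp(lnKc)


def simulate_breakthrough(
    C0: float = 1.0,
    t50: float = 1000.0,
    rate: float = 0.01,
    t_max: float = 2500.0,
    n: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """(t, Ct) on a logistic breakthrough front
    Ct = C0 / (1 + exp(-rate*(t - t50))), clipped to [0, C0]."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_max, n)
    Ct = C0 / (1.0 + np.exp(-rate * (t - t50)))
    Ct = np.clip(Ct + rng.normal(0.0, noise_sd, size=n), 0.0, C0)
    return t, Ct


def breakthrough_crossing_time(
    level: float, C0: float, t50: float, rate: float
) -> float:
    """Closed-form time at which the noiseless logistic front reaches
    outlet concentration ``level``: the inverse of the logistic."""
    if not 0 < level < C0:
        raise ValueError("level must lie strictly between 0 and C0")
    return t50 - np.log(C0 / level - 1.0) / rate


def simulate(spec: SyntheticSpec):
    """Dispatch a :class:`SyntheticSpec` to the matching generator."""
    p = dict(spec.true_params)
    if spec.kind == "ccd":
        surface = p.pop("surface")
        if isinstance(surface, dict):
            surface = QuadraticSurface.from_dict(surface)
        return simulate_ccd(surface, noise_sd=spec.noise_sd, seed=spec.seed, **p)
    if spec.kind == "isotherm":
        return simulate_isotherm(n=spec.n, noise_sd=spec.noise_sd, seed=spec.seed, **p)
    if spec.kind == "kinetics":
        return simulate_kinetics(n=spec.n, noise_sd=spec.noise_sd, seed=spec.seed, **p)
    if spec.kind == "vanthoff":
        return simulate_vanthoff(noise_sd=spec.noise_sd, seed=spec.seed, **p)
    return simulate_breakthrough(n=spec.n, noise_sd=spec.noise_sd, seed=spec.seed, **p)
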