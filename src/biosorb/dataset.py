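"""Central composite design (CCD) data model and I/O.

The package's canonical worked example is a 31-run rotatable CCD for
As(III) biosorption on an iron-impregnated immobilised fungal biosorbent:
four factors (biomass dose, pH, temperature, initial As(III)
concentration), 16 factorial points (coded ±1), 8 axial points (coded ±2)
and 7 centre replicates, with the percentage removal observed in each run
plus the regression- and neural-network-predicted removals reported by the
original study.  ``builtin_table2`` loads that table from packaged data.

Coded units place the design centre at 0 and one factorial step at ±1;
all response-surface fitting in :mod:`biosorb.rsm` happens in coded units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError

__all__ = [
    "FactorSpec",
    "CCDRun",
    "CCDDataset",
    "FACTORS",
    "builtin_table2",
    "code",
    "decode",
    "read_ccd_csv",
    "write_ccd_csv",
]

#: CSV column order for CCD tables (the last three are optional on read).
CSV_COLUMNS = [
    "dose_g_per_L",
    "pH",
    "temp_C",
    "conc_mg_per_L",
    "removal_pct",
    "removal_reg_pct",
    "removal_ann_pct",
    "split",
]
REQUIRED_COLUMNS = CSV_COLUMNS[:5]


@dataclass(frozen=True)
class FactorSpec:
    """One process factor of the design.

    ``actual = center + coded * step`` maps coded design units onto
    actual (physical) units; ``axial_level`` is the coded magnitude of
    the axial (star) points, 2 for this rotatable four-factor design.
    """

    name: str
    units: str
    center: float
    step: float
    axial_level: int = 2

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"factor {self.name!r}: step must be > 0")

    def code(self, actual: float) -> float:
        return (actual - self.center) / self.step

    def decode(self, coded: float) -> float:
        return self.center + coded * self.step

    def levels(self) -> tuple[float, ...]:
        """The five actual-unit levels (−α, −1, 0, +1, +α)."""
        a = self.axial_level
        return tuple(self.decode(c) for c in (-a, -1, 0, 1, a))


def code(actual: float, spec: FactorSpec) -> float:
    """Coded value of an actual-unit factor level."""
    return spec.code(actual)


def decode(coded: float, spec: FactorSpec) -> float:
    """Actual-unit value of a coded factor level."""
    return spec.decode(coded)


#: Factor definitions of the bundled As(III) biosorption CCD.
FACTORS: tuple[FactorSpec, ...] = (
    FactorSpec("dose", "g/L", center=0.7, step=0.3),
    FactorSpec("pH", "", center=6.0, step=2.0),
    FactorSpec("temp", "degC", center=35.0, step=5.0),
    FactorSpec("conc", "mg/L", center=0.7, step=0.3),
)


@dataclass(frozen=True)
class CCDRun:
    """A single experimental run of the design.

    ``removal_reg``/``removal_ann`` carry the original study's regression
    and neural-network predicted removals when available; they are
    reference data, not outputs of this package's own fits.
    """

    dose: float
    ph: float
    temp: float
    conc: float
    removal_obs: float
    removal_reg: float | None = None
    removal_ann: float | None = None
    split: str = "train"

    def __post_init__(self) -> None:
        if not 0.0 <= self.removal_obs <= 100.0:
            raise ValueError(
                f"removal_obs={self.removal_obs} outside [0, 100]"
            )
        if self.split not in ("train", "test"):
            raise ValueError(f"split must be 'train' or 'test', got {self.split!r}")

    @property
    def factor_values(self) -> tuple[float, float, float, float]:
        return (self.dose, self.ph, self.temp, self.conc)


@dataclass
class CCDDataset:
    """An ordered collection of CCD runs plus the factor definitions."""

    factors: tuple[FactorSpec, ...] = FACTORS
    runs: list[CCDRun] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.runs)

    def __iter__(self):
        return iter(self.runs)

    # ---- array views -------------------------------------------------

    def actual_matrix(self) -> np.ndarray:
        """(n, 4) factor values in actual units."""
        return np.array([r.factor_values for r in self.runs], dtype=float)

    def coded_matrix(self) -> np.ndarray:
        """(n, 4) factor values in coded units."""
        X = self.actual_matrix()
        centers = np.array([f.center for f in self.factors])
        steps = np.array([f.step for f in self.factors])
        return (X - centers) / steps

    def response(self) -> np.ndarray:
        return np.array([r.removal_obs for r in self.runs], dtype=float)

    def split_mask(self, split: str) -> np.ndarray:
        return np.array([r.split == split for r in self.runs], dtype=bool)

    def subset(self, split: str) -> "CCDDataset":
        return CCDDataset(self.factors, [r for r in self.runs if r.split == split])

    def center_mask(self, tol: float = 1e-9) -> np.ndarray:
        """Rows with every factor at the design centre (coded 0)."""
        return np.all(np.abs(self.coded_matrix()) < tol, axis=1)

    # ---- pandas bridge ----------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose_g_per_L": [r.dose for r in self.runs],
                "pH": [r.ph for r in self.runs],
                "temp_C": [r.temp for r in self.runs],
                "conc_mg_per_L": [r.conc for r in self.runs],
                "removal_pct": [r.removal_obs for r in self.runs],
                "removal_reg_pct": [r.removal_reg for r in self.runs],
                "removal_ann_pct": [r.removal_ann for r in self.runs],
                "split": [r.split for r in self.runs],
            }
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, factors: tuple[FactorSpec, ...] = FACTORS
    ) -> "CCDDataset":
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        runs = []
        for idx, row in df.iterrows():
            vals = {}
            for col in REQUIRED_COLUMNS:
                try:
                    vals[col] = float(row[col])
                except (TypeError, ValueError) as exc:
                    raise ParseError(
                        f"row {idx}: column {col!r} value {row[col]!r} is not numeric"
                    ) from exc
            def _opt(col):
                if col not in df.columns:
                    return None
                v = row[col]
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    return None
                try:
                    return float(v)
                except (TypeError, ValueError) as exc:
                    raise ParseError(
                        f"row {idx}: column {col!r} value {v!r} is not numeric"
                    ) from exc
            runs.append(
                CCDRun(
                    dose=vals["dose_g_per_L"],
                    ph=vals["pH"],
                    temp=vals["temp_C"],
                    conc=vals["conc_mg_per_L"],
                    removal_obs=vals["removal_pct"],
                    removal_reg=_opt("removal_reg_pct"),
                    removal_ann=_opt("removal_ann_pct"),
                    split=str(row["split"]) if "split" in df.columns else "train",
                )
            )
        return cls(factors, runs)


def read_ccd_csv(path: str | Path) -> CCDDataset:
    """Read a CCD table from CSV (schema: see ``CSV_COLUMNS``)."""
    df = pd.read_csv(path)
    return CCDDataset.from_frame(df)


def write_ccd_csv(dataset: CCDDataset, path: str | Path) -> None:
    """Write a CCD table to CSV, round-trippable with :func:`read_ccd_csv`."""
    dataset.to_frame().to_csv(path, index=False)


def builtin_table2() -> CCDDataset:
    """The packaged 31-run As(III) biosorption CCD with observed and
    study-predicted removal columns and the original train/test split
    (24 training, 7 testing runs)."""
    with resources.files("biosorb.data").joinpath("table2.csv").open("r") as fh:
        df = pd.read_csv(fh)
    return CCDDataset.from_frame(df)
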