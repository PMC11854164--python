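"""Box-Behnken designs and coded/actual factor-space conversion.

A three-factor Box-Behnken design (BBD) consists of the 12 midpoints of the
edges of the coded cube (all ±1/±1 combinations over the three factor pairs,
third factor at its center) plus replicated center points.  All response-
surface modelling downstream happens in *coded* units, where each factor is
rescaled to [-1, 1] by centering and dividing by its half-range.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignPoint",
    "Dataset",
    "UnsupportedDesignError",
    "DegenerateFactorError",
    "build_bbd",
    "code",
    "decode",
    "yield_percent",
    "CSV_COLUMNS",
]

CSV_COLUMNS = ["std", "pH", "enzyme_pct", "time_min", "yield_pct"]


class UnsupportedDesignError(ValueError):
    """Raised for design requests outside the supported 3-factor BBD family."""


class DegenerateFactorError(ValueError):
    """Raised when a factor has zero half-range and cannot be coded."""


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its low / center / high actual levels.

    ``low`` and ``high`` map to coded -1 and +1; ``center`` maps to coded 0.
    A center that is not the midpoint of (low, high) makes the coding
    non-affine, so it is warned about (but accepted, since published designs
    occasionally print asymmetric levels).
    """

    name: str
    low: float
    center: float
    high: float
    unit: str = ""

    def __post_init__(self) -> None:
        if not (self.low < self.center < self.high):
            raise ValueError(
                f"factor {self.name!r}: require low < center < high, "
                f"got ({self.low}, {self.center}, {self.high})"
            )
        midpoint = 0.5 * (self.low + self.high)
        if abs(self.center - midpoint) > 1e-9:
            warnings.warn(
                f"factor {self.name!r}: center {self.center} is not the midpoint "
                f"{midpoint} of (low, high); coded levels will be asymmetric",
                stacklevel=2,
            )

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)


@dataclass(frozen=True)
class DesignPoint:
    """One experimental run: coded and actual settings plus optional response."""

    std_order: int
    coded: tuple[float, float, float]
    actual: tuple[float, float, float]
    observed_yield: float | None = None

    def __post_init__(self) -> None:
        if self.std_order < 1:
            raise ValueError("std_order must be a positive integer")
        if self.observed_yield is not None and self.observed_yield < 0:
            # real yields are non-negative; Gaussian-noise simulations can
            # dip below zero at low-yield corners and are kept unclipped so
            # refits stay unbiased
            warnings.warn(
                f"run {self.std_order}: negative observed yield "
                f"{self.observed_yield:.3f} %", stacklevel=2
            )


@dataclass
class Dataset:
    """A designed experiment: three factors and an ordered list of runs."""

    factors: tuple[FactorSpec, FactorSpec, FactorSpec]
    points: list[DesignPoint] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.factors) != 3:
            raise UnsupportedDesignError(
                f"exactly 3 factors are supported, got {len(self.factors)}"
            )
        self.factors = tuple(self.factors)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.points)

    @property
    def coded_matrix(self) -> np.ndarray:
        return np.array([p.coded for p in self.points], dtype=float)

    @property
    def actual_matrix(self) -> np.ndarray:
        return np.array([p.actual for p in self.points], dtype=float)

    @property
    def yields(self) -> np.ndarray:
        """Observed yields (NaN where missing)."""
        return np.array(
            [np.nan if p.observed_yield is None else p.observed_yield for p in self.points],
            dtype=float,
        )

    def observed(self) -> "Dataset":
        """Subset of runs that carry an observed yield."""
        pts = [p for p in self.points if p.observed_yield is not None]
        return Dataset(self.factors, pts, label=self.label)

    def with_yields(self, values: Sequence[float]) -> "Dataset":
        if len(values) != len(self.points):
            raise ValueError("one yield value per design point required")
        pts = [replace(p, observed_yield=float(v)) for p, v in zip(self.points, values)]
        return Dataset(self.factors, pts, label=self.label)

    # ---------------------------------------------------------------- I/O

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write runs as CSV and factor specs as a JSON sidecar.

        The sidecar defaults to ``<path>.factors.json``.
        """
        path = Path(path)
        rows = []
        for p in self.points:
            rows.append(
                {
                    "std": p.std_order,
                    "pH": p.actual[0],
                    "enzyme_pct": p.actual[1],
                    "time_min": p.actual[2],
                    "yield_pct": "" if p.observed_yield is None else p.observed_yield,
                }
            )
        pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
        sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".factors.json")
        spec = [
            {"name": f.name, "low": f.low, "center": f.center, "high": f.high, "unit": f.unit}
            for f in self.factors
        ]
        sidecar.write_text(json.dumps(spec, indent=1) + "\n")

    @classmethod
    def from_csv(
        cls, path: str | Path, sidecar: str | Path | None = None, label: str = ""
    ) -> "Dataset":
        path = Path(path)
        sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".factors.json")
        factors = tuple(
            FactorSpec(**spec) for spec in json.loads(sidecar.read_text())
        )
        try:
            df = pd.read_csv(path)
        except pd.errors.ParserError as exc:  # surface the offending line
            raise ValueError(f"malformed CSV {path}: {exc}") from exc
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        points = []
        for _, row in df.iterrows():
            actual = (float(row["pH"]), float(row["enzyme_pct"]), float(row["time_min"]))
            obs = row["yield_pct"]
            points.append(
                DesignPoint(
                    std_order=int(row["std"]),
                    coded=code(actual, factors),
                    actual=actual,
                    observed_yield=None if pd.isna(obs) else float(obs),
                )
            )
        return cls(factors, points, label=label or path.stem)


def code(
    actual: Sequence[float], factors: Sequence[FactorSpec]
) -> tuple[float, float, float]:
    """Map actual factor settings to coded units via (x - center)/half-range."""
    out = []
    for x, f in zip(actual, factors, strict=True):
        if f.half_range <= 0:
            raise DegenerateFactorError(f"factor {f.name!r} has zero half-range")
        out.append((x - f.center) / f.half_range)
    return tuple(out)


def decode(
    coded: Sequence[float], factors: Sequence[FactorSpec]
) -> tuple[float, float, float]:
    """Exact inverse of :func:`code`."""
    out = []
    for z, f in zip(coded, factors, strict=True):
        if f.half_range <= 0:
            raise DegenerateFactorError(f"factor {f.name!r} has zero half-range")
        out.append(f.center + z * f.half_range)
    return tuple(out)


def yield_percent(m1: float, m2: float) -> float:
    """Extraction yield in percent: 100 * dried-extract mass / raw-material mass."""
    if m2 <= 0:
        raise ValueError(f"raw-material mass must be positive, got {m2}")
    if m1 < 0:
        raise ValueError(f"extract mass must be non-negative, got {m1}")
    return 100.0 * m1 / m2


# coded (+-1, +-1) combinations within one factor pair, in standard order
_PAIR_LEVELS = ((-1.0, -1.0), (1.0, -1.0), (-1.0, 1.0), (1.0, 1.0))
_PAIRS = ((0, 1), (0, 2), (1, 2))


def build_bbd(
    factors: Sequence[FactorSpec], n_center: int, label: str = "bbd"
) -> Dataset:
    """Construct a 3-factor Box-Behnken design in standard order.

    The 12 edge points enumerate the pairs (A,B), (A,C), (B,C); within each
    pair the levels run (-1,-1), (+1,-1), (-1,+1), (+1,+1) with the third
    factor at 0.  ``n_center`` replicated center runs follow.
    """
    if len(factors) != 3:
        raise UnsupportedDesignError(
            f"Box-Behnken construction implemented for exactly 3 factors, got {len(factors)}"
        )
    if n_center < 1:
        raise ValueError("n_center must be >= 1")
    factors = tuple(factors)
    points: list[DesignPoint] = []
    std = 1
    for i, j in _PAIRS:
        for li, lj in _PAIR_LEVELS:
            coded = [0.0, 0.0, 0.0]
            coded[i], coded[j] = li, lj
            coded_t = (coded[0], coded[1], coded[2])
            points.append(
                DesignPoint(std_order=std, coded=coded_t, actual=decode(coded_t, factors))
            )
            std += 1
    center = decode((0.0, 0.0, 0.0), factors)
    for _ in range(n_center):
        points.append(DesignPoint(std_order=std, coded=(0.0, 0.0, 0.0), actual=center))
        std += 1
    return Dataset(factors, points, label=label)
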