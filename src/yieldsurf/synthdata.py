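"""Synthetic response-surface datasets and packaged reference fixtures.

The generator emulates the data-generating process the analysis assumes: a
true second-order surface in coded units plus i.i.d. homoscedastic Gaussian
noise, with replicated center points receiving independent draws.  The
packaged fixtures hold the reference study's printed 17-run Box-Behnken
dataset (and the handful of single-factor yields quoted in its prose) so
every stage is testable without downloads.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .design import Dataset, DesignPoint, FactorSpec, build_bbd, decode
from .rsm import model_matrix

__all__ = [
    "SurfaceTruth",
    "Fixture",
    "generate",
    "generate_mixed33",
    "load_fixture",
    "fixture_path",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("bbd17", "single_factor")


@dataclass(frozen=True)
class SurfaceTruth:
    """True coded-unit quadratic coefficients plus a noise level."""

    coefficients: tuple[float, ...]  # 10 values, ordered as rsm.TERMS
    noise_sd: float
    factors: tuple[FactorSpec, FactorSpec, FactorSpec]

    def __post_init__(self) -> None:
        if len(self.coefficients) != 10:
            raise ValueError("exactly 10 quadratic coefficients required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def surface(self, coded: np.ndarray) -> np.ndarray:
        return model_matrix(coded) @ np.asarray(self.coefficients)


@dataclass
class Fixture:
    """A packaged dataset plus immutable reference annotations.

    Each annotation value carries a ``source`` tag: ``reported`` values were
    printed in the reference study, ``derived`` values were recomputed here
    from its printed data.
    """

    name: str
    dataset: Dataset
    annotations: dict = field(default_factory=dict)


def generate(truth: SurfaceTruth, design: Dataset, seed: int = 0) -> Dataset:
    """Observed yields = true surface + N(0, noise_sd²), independently per run."""
    coded = design.coded_matrix
    if np.any(np.abs(coded) > 1 + 1e-9):
        raise ValueError("design points must lie within the coded cube")
    rng = np.random.default_rng(seed)
    y = truth.surface(coded) + rng.normal(0.0, truth.noise_sd, size=len(design))
    return design.with_yields(y)


#: coded single-factor grids appended to the BBD to mimic a mixed 33-run set:
#: univariate sweeps through the center, mapped into the coded cube
_AXIAL_LEVELS = {
    0: (-1.0, -1.0 / 3.0, 1.0 / 3.0, 1.0),  # pH: 4 off-center levels
    1: (-1.0, -0.5, 0.0, 0.5, 1.0),  # enzyme: 5 levels
    2: (-1.0, -0.5, 0.0, 0.5, 1.0),  # time: 5 levels
}


def generate_mixed33(truth: SurfaceTruth, seed: int = 0) -> Dataset:
    """A 33-run set: the 17-run BBD plus 16 single-factor (axial) runs.

    The axial block sweeps one factor at a time through the coded cube with
    the others at center (4 pH levels, 5 enzyme levels, 5 time levels) and
    adds 2 further center replicates.
    """
    bbd = build_bbd(truth.factors, n_center=5, label="mixed33")
    points = list(bbd.points)
    std = len(points) + 1
    for k, levels in _AXIAL_LEVELS.items():
        for lv in levels:
            coded = [0.0, 0.0, 0.0]
            coded[k] = lv
            coded_t = (coded[0], coded[1], coded[2])
            points.append(
                DesignPoint(std, coded_t, decode(coded_t, truth.factors))
            )
            std += 1
    for _ in range(2):
        points.append(
            DesignPoint(std, (0.0, 0.0, 0.0), decode((0.0, 0.0, 0.0), truth.factors))
        )
        std += 1
    design = Dataset(truth.factors, points, label="mixed33")
    assert len(design) == 33
    return generate(truth, design, seed)


# ----------------------------------------------------------------- fixtures


def fixture_path(filename: str) -> Path:
    return Path(str(resources.files("yieldsurf").joinpath("data", filename)))


def fixture_checksum(filename: str) -> str:
    return hashlib.sha256(fixture_path(filename).read_bytes()).hexdigest()


def load_fixture(name: str) -> Fixture:
    """Load a packaged fixture: ``bbd17`` (the 17-run designed experiment
    with observed yields) or ``single_factor`` (prose-quoted univariate
    yields with their condition settings)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    annotations = json.loads(fixture_path(f"{name}.annotations.json").read_text())
    if name == "bbd17":
        dataset = Dataset.from_csv(
            fixture_path("bbd17.csv"),
            fixture_path("bbd17.factors.json"),
            label="bbd17",
        )
        return Fixture(name, dataset, annotations)
    # single_factor: univariate runs; time/pH/enzyme columns present, but the
    # temperature rows vary a factor outside the three modelled ones
    df = pd.read_csv(fixture_path("single_factor.csv"))
    factors = tuple(
        FactorSpec(**spec)
        for spec in json.loads(fixture_path("bbd17.factors.json").read_text())
    )
    points = []
    for i, row in df.iterrows():
        actual = (float(row["pH"]), float(row["enzyme_pct"]), float(row["time_min"]))
        coded = tuple(
            (a - f.center) / f.half_range for a, f in zip(actual, factors)
        )
        points.append(
            DesignPoint(i + 1, coded, actual, observed_yield=float(row["yield_pct"]))
        )
    dataset = Dataset(factors, points, label="single_factor")
    return Fixture(name, dataset, annotations)
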