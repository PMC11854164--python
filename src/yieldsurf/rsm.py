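"""Second-order response-surface fitting, ANOVA and surface optimization.

The model is the full 10-term quadratic in coded units

    Y = b0 + b1 A + b2 B + b3 C + b12 AB + b13 AC + b23 BC
           + b11 A^2 + b22 B^2 + b33 C^2

fit by ordinary least squares.  The ANOVA uses partial (Type III) sums of
squares — for each single-degree term SS = coef^2 / c_jj with c_jj the
corresponding diagonal entry of (X'X)^-1 — and splits the residual into
lack of fit and pure error using replicated design points.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .design import Dataset

__all__ = [
    "TERMS",
    "QuadraticModel",
    "AnovaRow",
    "AnovaTable",
    "SingularFitError",
    "fit_quadratic",
    "model_matrix",
    "predict",
    "anova",
    "r_squared",
    "diagnostics",
    "Diagnostics",
    "perturbation_curves",
    "optimize_surface",
    "SurfaceOptimum",
]

#: column order of the model matrix
TERMS = ("Intercept", "A", "B", "C", "AB", "AC", "BC", "A2", "B2", "C2")
N_TERMS = 10


class SingularFitError(ValueError):
    """Raised when the quadratic design matrix is rank deficient."""


def model_matrix(coded: np.ndarray) -> np.ndarray:
    """10-column quadratic model matrix [1, A, B, C, AB, AC, BC, A², B², C²]."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    A, B, C = coded[:, 0], coded[:, 1], coded[:, 2]
    return np.column_stack(
        [np.ones(len(coded)), A, B, C, A * B, A * C, B * C, A * A, B * B, C * C]
    )


@dataclass
class QuadraticModel:
    """Fitted second-order model in coded units plus residual summaries."""

    coef: np.ndarray  # length 10, ordered as TERMS
    n: int
    fitted: np.ndarray
    residuals: np.ndarray
    xtx_inv: np.ndarray  # (X'X)^{-1}, reused by ANOVA and diagnostics
    coded: np.ndarray  # n x 3 design actually fit

    @property
    def b0(self) -> float:
        return float(self.coef[0])

    @property
    def b_lin(self) -> np.ndarray:
        return self.coef[1:4]

    @property
    def b_int(self) -> np.ndarray:
        return self.coef[4:7]

    @property
    def b_quad(self) -> np.ndarray:
        return self.coef[7:10]

    @property
    def hessian(self) -> np.ndarray:
        """Hessian of the fitted surface (2 * quadratic-form matrix)."""
        b12, b13, b23 = self.b_int
        b11, b22, b33 = self.b_quad
        return np.array(
            [
                [2 * b11, b12, b13],
                [b12, 2 * b22, b23],
                [b13, b23, 2 * b33],
            ]
        )

    def __call__(self, coded_point: Sequence[float]) -> float | np.ndarray:
        return predict(self, coded_point)


def fit_quadratic(data: Dataset) -> QuadraticModel:
    """Ordinary least squares fit of the full quadratic on the coded design."""
    obs = data.observed()
    if len(obs) < N_TERMS:
        raise ValueError(
            f"need >= {N_TERMS} runs with observed yield, got {len(obs)}"
        )
    X = model_matrix(obs.coded_matrix)
    y = obs.yields
    rank = np.linalg.matrix_rank(X)
    if rank < N_TERMS:
        # name the columns involved in the near-null space
        _, s, vt = np.linalg.svd(X)
        null = vt[rank:]
        involved = sorted(
            {TERMS[j] for row in null for j in np.nonzero(np.abs(row) > 1e-8)[0]}
        )
        raise SingularFitError(
            f"design matrix rank {rank} < {N_TERMS}; collinear columns: {involved}"
        )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    return QuadraticModel(
        coef=coef,
        n=len(obs),
        fitted=fitted,
        residuals=y - fitted,
        xtx_inv=np.linalg.inv(X.T @ X),
        coded=obs.coded_matrix,
    )


def predict(model: QuadraticModel, coded_point) -> float | np.ndarray:
    """Evaluate the fitted polynomial at one or more coded points."""
    pt = np.asarray(coded_point, dtype=float)
    out = model_matrix(pt) @ model.coef
    return float(out[0]) if pt.ndim == 1 else out


# --------------------------------------------------------------------- ANOVA


@dataclass(frozen=True)
class AnovaRow:
    term: str
    ss: float
    df: int
    ms: float | None
    f: float | None
    p: float | None
    signif: str = ""


@dataclass
class AnovaTable:
    rows: list[AnovaRow] = field(default_factory=list)

    def __getitem__(self, term: str) -> AnovaRow:
        for row in self.rows:
            if row.term == term:
                return row
        raise KeyError(term)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(r) for r in self.rows])

    def to_tsv(
        self,
        path: str | Path,
        ss_decimals: int = 2,
        f_decimals: int = 2,
        p_decimals: int = 4,
    ) -> None:
        lines = ["Source\tSum of Squares\tdf\tMean Square\tF Value\tp-Value"]
        for r in self.rows:
            fmt = lambda v, d: "" if v is None else f"{v:.{d}f}"
            lines.append(
                "\t".join(
                    [
                        r.term,
                        fmt(r.ss, ss_decimals),
                        str(r.df),
                        fmt(r.ms, ss_decimals),
                        fmt(r.f, f_decimals),
                        (fmt(r.p, p_decimals) + (" " + r.signif if r.signif else ""))
                        if r.p is not None
                        else "",
                    ]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n")

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps([vars(r) for r in self.rows], indent=1)
        if path is not None:
            Path(path).write_text(doc + "\n")
        return doc


def _signif(p: float | None) -> str:
    if p is None:
        return ""
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""


def _f_and_p(ss: float, df: int, ms_err: float, df_err: int):
    """F and upper-tail p for a term against an error mean square."""
    ms = ss / df
    if ms_err == 0:
        # perfect fit: F undefined/infinite, flagged via inf
        return (math.inf if ms > 0 else None), (0.0 if ms > 0 else None)
    f = ms / ms_err
    return f, float(stats.f.sf(f, df, df_err))


def anova(model: QuadraticModel, data: Dataset) -> AnovaTable:
    """Full ANOVA with partial (Type III) term SS and lack-of-fit split.

    For single-degree terms SS = coef^2 / c_jj, where c_jj is the term's
    diagonal entry of (X'X)^-1; on the orthogonal linear/interaction part of
    a BBD this reduces to the closed forms 8*b^2 and 4*b^2.  Pure error is
    the within-group sum of squares over replicated design points.
    """
    obs = data.observed()
    y = obs.yields
    n = len(obs)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(model.residuals**2))
    ss_model = ss_total - ss_res
    df_model, df_res = N_TERMS - 1, n - N_TERMS
    if ss_res <= 1e-12 * max(ss_total, 1.0):  # numerically perfect fit
        ss_res = 0.0
        ss_model = ss_total
    ms_res = ss_res / df_res if df_res > 0 else math.nan

    rows: list[AnovaRow] = []
    f, p = _f_and_p(ss_model, df_model, ms_res, df_res)
    rows.append(AnovaRow("Model", ss_model, df_model, ss_model / df_model, f, p, _signif(p)))
    for j in range(1, N_TERMS):
        ss_j = float(model.coef[j] ** 2 / model.xtx_inv[j, j])
        f, p = _f_and_p(ss_j, 1, ms_res, df_res)
        rows.append(AnovaRow(TERMS[j], ss_j, 1, ss_j, f, p, _signif(p)))
    rows.append(AnovaRow("Residual", ss_res, df_res, ms_res, None, None))

    # pure error from replicate groups
    groups: dict[tuple, list[float]] = {}
    for pt, yi in zip(obs.points, y):
        groups.setdefault(tuple(round(c, 12) for c in pt.coded), []).append(yi)
    reps = [v for v in groups.values() if len(v) > 1]
    if reps:
        ss_pe = float(sum(np.sum((np.array(v) - np.mean(v)) ** 2) for v in reps))
        df_pe = sum(len(v) - 1 for v in reps)
        ss_lof = ss_res - ss_pe
        df_lof = df_res - df_pe
        ms_pe = ss_pe / df_pe if df_pe > 0 else math.nan
        if df_lof > 0:
            f, p = _f_and_p(ss_lof, df_lof, ms_pe, df_pe)
            rows.append(
                AnovaRow("Lack of Fit", ss_lof, df_lof, ss_lof / df_lof, f, p, _signif(p))
            )
        rows.append(AnovaRow("Pure Error", ss_pe, df_pe, ms_pe, None, None))
    else:
        warnings.warn(
            "no replicated design points: lack-of-fit decomposition unavailable",
            stacklevel=2,
        )
    rows.append(AnovaRow("Cor Total", ss_total, n - 1, None, None, None))
    return AnovaTable(rows)


def r_squared(model: QuadraticModel, data: Dataset) -> float:
    """Coefficient of determination SS(Model)/SS(Cor Total)."""
    y = data.observed().yields
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total == 0:
        raise ValueError("zero total sum of squares: R^2 undefined")
    ss_res = float(np.sum(model.residuals**2))
    return 1.0 - ss_res / ss_total


# --------------------------------------------------------------- diagnostics


@dataclass
class Diagnostics:
    leverage: np.ndarray
    cooks_d: np.ndarray
    studentized: np.ndarray
    #: (sorted studentized residual, standard normal quantile) pairs
    normal_prob: np.ndarray


def diagnostics(model: QuadraticModel, data: Dataset) -> Diagnostics:
    """Leverage, Cook's distance, internally studentized residuals and
    normal-probability coordinates (Blom plotting positions)."""
    obs = data.observed()
    X = model_matrix(obs.coded_matrix)
    H = X @ model.xtx_inv @ X.T
    h = np.diag(H).copy()
    if np.any(h >= 1 - 1e-12):
        raise ValueError("leverage of 1 encountered: infinite influence point")
    df_res = model.n - N_TERMS
    s2 = float(np.sum(model.residuals**2)) / df_res
    r = model.residuals
    student = r / np.sqrt(s2 * (1 - h))
    cooks = r**2 * h / (N_TERMS * s2 * (1 - h) ** 2)
    order = np.argsort(student)
    i = np.arange(1, model.n + 1)
    quantiles = stats.norm.ppf((i - 0.375) / (model.n + 0.25))
    return Diagnostics(
        leverage=h,
        cooks_d=cooks,
        studentized=student,
        normal_prob=np.column_stack([student[order], quantiles]),
    )


def perturbation_curves(
    model: QuadraticModel,
    reference: Sequence[float] = (0.0, 0.0, 0.0),
    n_grid: int = 41,
) -> dict[str, np.ndarray]:
    """Yield along each coded axis through the reference point.

    Returns, per factor label, an (n_grid, 2) array of (coded level, yield).
    """
    grid = np.linspace(-1.0, 1.0, n_grid)
    ref = np.asarray(reference, dtype=float)
    curves = {}
    for k, name in enumerate("ABC"):
        pts = np.tile(ref, (n_grid, 1))
        pts[:, k] = grid
        curves[name] = np.column_stack([grid, predict(model, pts)])
    return curves


# -------------------------------------------------------------- optimization


@dataclass(frozen=True)
class SurfaceOptimum:
    coded_point: tuple[float, float, float]
    value: float
    #: 'interior-stationary' when the stationary point is the in-bounds
    #: maximizer, 'boundary-grid' when found by grid refinement, with a
    #: 'saddle' / 'singular' qualifier when the Hessian forced the fallback
    kind: str


def _grid_refine_max(
    fun: Callable[[np.ndarray], np.ndarray],
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
    resolution: float = 1e-3,
    coarse: int = 21,
) -> tuple[np.ndarray, float]:
    lo, hi = bounds_lo.astype(float).copy(), bounds_hi.astype(float).copy()
    while True:
        axes = [np.linspace(lo[k], hi[k], coarse) for k in range(3)]
        G = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        vals = fun(G)
        i = int(np.argmax(vals))
        best_x, best_v = G[i], float(vals[i])
        step = (hi - lo) / (coarse - 1)
        if np.all(step <= resolution):
            return best_x, best_v
        lo = np.clip(best_x - step, bounds_lo, bounds_hi)
        hi = np.clip(best_x + step, bounds_lo, bounds_hi)


def optimize_surface(
    model: QuadraticModel,
    bounds: Sequence[tuple[float, float]] = ((-1, 1), (-1, 1), (-1, 1)),
    resolution: float = 1e-3,
) -> SurfaceOptimum:
    """Maximize the fitted quadratic over a coded box.

    Solves the stationary system ∇Y = 0; if the stationary point lies inside
    the box and the Hessian is negative definite it is the maximizer.
    Otherwise (saddle, ridge, or exterior stationary point) the maximum is
    located by deterministic coarse-to-fine grid refinement down to the
    stated resolution in coded units.
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    H = model.hessian
    kind = "boundary-grid"
    try:
        stationary = np.linalg.solve(H, -model.b_lin)
        eigvals = np.linalg.eigvalsh(H)
        if np.all(eigvals < 0):
            if np.all(stationary >= lo - 1e-12) and np.all(stationary <= hi + 1e-12):
                x = np.clip(stationary, lo, hi)
                return SurfaceOptimum(tuple(x), float(predict(model, x)), "interior-stationary")
        else:
            kind = "boundary-grid (saddle/ridge)"
    except np.linalg.LinAlgError:
        kind = "boundary-grid (singular Hessian)"
    fun = lambda pts: predict(model, pts)
    x, v = _grid_refine_max(fun, lo, hi, resolution=resolution)
    return SurfaceOptimum(tuple(x), v, kind)
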