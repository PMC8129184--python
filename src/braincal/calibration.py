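"""Two-stage inverse calibration by grid bracketing + golden-section search.

Stage 1 calibrates the median quasi-static infinitesimal shear modulus
``mu0_med`` with the non-linearity coefficient fixed at alpha = 2 (Neo-Hookean
shear response, so mu_med = mu0_med), driving the model with a low-severity
rotation (axial, 20 rad/s, 60 ms) whose small deformations are insensitive to
alpha.  Stage 2 calibrates alpha with a higher-severity rotation (coronal,
40 rad/s, 30 ms), rebuilding every candidate card set through
``mu_i = 2 * gamma_i * mu0_med / alpha`` so the previously calibrated
infinitesimal modulus is preserved exactly.  Both stages maximize the mean
wcCORA across subjects; the bracket comes from a coarse grid and the interior
search uses the golden ratio phi = (sqrt(5) - 1) / 2 with interior-point
reuse, terminating when the bracket width falls below the stage tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "PHI",
    "STAGE1_CASE",
    "STAGE2_CASE",
    "StageResult",
    "CalibrationConfig",
    "SearchTrace",
    "BracketError",
    "CachedObjective",
    "bracket_from_grid",
    "golden_search",
    "calibrate_stage1",
    "calibrate_stage2",
    "run_calibration",
]

PHI = (np.sqrt(5.0) - 1.0) / 2.0

#: Stage-1 case: low severity, insensitive to the non-linearity coefficient.
STAGE1_CASE = ("axial", 20.0, 60.0)
#: Stage-2 case: higher severity, sensitive to the non-linearity coefficient.
STAGE2_CASE = ("coronal", 40.0, 30.0)


class BracketError(RuntimeError):
    """The grid maximum sits on a boundary; no bracket exists.  Extend the grid."""


@dataclass
class CalibrationConfig:
    stage1_grid: tuple[float, ...] = (0.25, 0.7, 1.15, 1.6, 2.05, 2.6)
    stage1_tol: float = 0.1
    stage2_grid: tuple[float, ...] = (2.0, 6.0, 10.0)
    stage2_tol: float = 0.2
    duration_ms: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        for grid in (self.stage1_grid, self.stage2_grid):
            if np.any(np.diff(grid) <= 0):
                raise ValueError("grids must be strictly increasing")
        if self.stage1_tol <= 0 or self.stage2_tol <= 0:
            raise ValueError("tolerances must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CalibrationConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("stage1_grid", "stage2_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SearchTrace:
    """Bracket history plus an evaluation ledger.

    ``iterations`` records (a, b, x1, x2, f1, f2) per golden iteration;
    ``evaluations`` records every objective query as (x, f, reused) where
    reused marks cache hits that did not cost a forward-model run.
    """

    iterations: list[dict] = field(default_factory=list)
    evaluations: list[tuple[float, float, bool]] = field(default_factory=list)
    argmax: float = np.nan
    f_max: float = np.nan

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    @property
    def n_unique_evaluations(self) -> int:
        return sum(1 for _, _, reused in self.evaluations if not reused)

    def to_dict(self) -> dict:
        return {
            "iterations": self.iterations,
            "evaluations": [
                {"x": x, "f": f, "reused": r} for x, f, r in self.evaluations
            ],
            "argmax": self.argmax,
            "f_max": self.f_max,
            "n_iterations": self.n_iterations,
            "n_unique_evaluations": self.n_unique_evaluations,
        }


class CachedObjective:
    """Objective wrapper caching results by parameter value rounded to 1e-9,
    so golden-section interior-point reuse costs no extra forward runs."""

    def __init__(self, fn: Callable[[float], float]):
        self._fn = fn
        self.cache: dict[float, float] = {}
        self.ledger: list[tuple[float, float, bool]] = []

    @staticmethod
    def _key(x: float) -> float:
        return round(float(x), 9)

    def __call__(self, x: float) -> float:
        key = self._key(x)
        reused = key in self.cache
        if not reused:
            self.cache[key] = float(self._fn(x))
        f = self.cache[key]
        self.ledger.append((float(x), f, reused))
        return f

    @property
    def n_unique(self) -> int:
        return len(self.cache)

    def best(self) -> tuple[float, float]:
        x = max(self.cache, key=self.cache.get)
        return x, self.cache[x]


def bracket_from_grid(
    objective: Callable[[float], float], grid: Sequence[float]
) -> tuple[float, float]:
    """Evaluate the objective at every grid point and bracket the maximum
    with its two neighbours.  A boundary maximum raises BracketError."""
    grid = [float(g) for g in grid]
    if len(grid) < 3:
        raise ValueError("grid must have at least 3 points")
    values = [objective(g) for g in grid]
    i = int(np.argmax(values))
    if i == 0 or i == len(grid) - 1:
        raise BracketError(
            f"grid maximum at boundary point {grid[i]}; extend the grid beyond it"
        )
    return grid[i - 1], grid[i + 1]


def golden_search(
    objective: Callable[[float], float],
    a: float,
    b: float,
    tol: float,
    trace: SearchTrace | None = None,
) -> tuple[float, SearchTrace]:
    """Maximize a unimodal objective on [a, b] by golden-section search.

    Interior points ``x1 = a + (1 - phi)(b - a)`` and ``x2 = a + phi(b - a)``;
    if f(x1) >= f(x2) the interval becomes [a, x2], otherwise [x1, b] (ties
    take the first branch).  Termination is checked after each interval
    update: the search stops once b - a < tol and returns the best *evaluated*
    parameter, not the interval midpoint.  When ``objective`` is a
    CachedObjective, each iteration after the first costs exactly one new
    forward evaluation.
    """
    if not (a < b):
        raise ValueError("require a < b")
    if not (tol > 0):
        raise ValueError("tol must be positive")
    if not isinstance(objective, CachedObjective):
        objective = CachedObjective(objective)
    trace = trace or SearchTrace()
    start = len(objective.ledger)
    while (b - a) >= tol:
        x1 = a + (1.0 - PHI) * (b - a)
        x2 = a + PHI * (b - a)
        f1 = objective(x1)
        f2 = objective(x2)
        if not (np.isfinite(f1) and np.isfinite(f2)):
            trace.evaluations = list(objective.ledger[start:])
            raise RuntimeError(f"non-finite objective in [{a}, {b}]; trace attached")
        trace.iterations.append(
            {"a": a, "b": b, "x1": x1, "x2": x2, "f1": f1, "f2": f2}
        )
        if f1 >= f2:
            b = x2
        else:
            a = x1
    trace.evaluations = list(objective.ledger[start:])
    if not trace.evaluations:
        # Interval narrower than tol from the outset: evaluate the midpoint.
        xm = 0.5 * (a + b)
        objective(xm)
        trace.evaluations = list(objective.ledger[start:])
    best_x, best_f = max(
        ((x, f) for x, f, _ in trace.evaluations), key=lambda p: p[1]
    )
    trace.argmax, trace.f_max = best_x, best_f
    return best_x, trace


def _find_case(bundle, axis: str, peak: float, duration: float):
    case = bundle.find_case(axis, peak, duration)
    if case is None:
        raise ValueError(f"bundle lacks the required case {axis} {peak} rad/s {duration} ms")
    return case


def _stage_objective(model, bundle, case_id: str, duration_ms: float):
    """Joint objective over subjects for one case as a function of the card
    parameters (mu0_med, alpha) supplied by the stage closure."""
    from .rating import joint_objective

    def f(mu0_med: float, alpha: float) -> float:
        scores = []
        for subject in bundle.subject_names:
            score = model.rate_subject_case(
                subject, case_id, bundle, mu0_med=mu0_med, alpha=alpha,
                duration_ms=duration_ms,
            )
            scores.append(score)
        return joint_objective(scores)

    return f


@dataclass
class StageResult:
    value: float
    trace: SearchTrace
    grid_evaluations: list[tuple[float, float]]

    @property
    def total_evaluations(self) -> int:
        """Unique forward-model evaluations: grid + golden (with reuse)."""
        seen = {round(x, 9) for x, _ in self.grid_evaluations}
        n = len(seen)
        for x, _, reused in self.trace.evaluations:
            key = round(x, 9)
            if not reused and key not in seen:
                seen.add(key)
                n += 1
        return n

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "grid_evaluations": [{"x": x, "f": f} for x, f in self.grid_evaluations],
            "trace": self.trace.to_dict(),
            "total_evaluations": self.total_evaluations,
        }


def _run_stage(
    objective_1d: Callable[[float], float],
    grid: Sequence[float],
    tol: float,
) -> StageResult:
    cached = CachedObjective(objective_1d)
    a, b = bracket_from_grid(cached, grid)
    grid_evals = [(x, f) for x, f, _ in cached.ledger]
    x_star, trace = golden_search(cached, a, b, tol)
    # The calibrated value is the best point among everything evaluated,
    # bracketing grid included.
    best_x, best_f = cached.best()
    trace.argmax, trace.f_max = best_x, best_f
    return StageResult(value=best_x, trace=trace, grid_evaluations=grid_evals)


def calibrate_stage1(model, bundle, config: CalibrationConfig) -> StageResult:
    """Calibrate mu0_med (kPa) at alpha = 2 on the low-severity axial case."""
    case = _find_case(bundle, *STAGE1_CASE)
    f2d = _stage_objective(model, bundle, case, config.duration_ms)
    return _run_stage(
        lambda mu: f2d(mu0_med=mu, alpha=2.0), config.stage1_grid, config.stage1_tol
    )


def calibrate_stage2(
    model, bundle, mu0_med: float, config: CalibrationConfig
) -> StageResult:
    """Calibrate alpha on the higher-severity coronal case, preserving mu0_med."""
    case = _find_case(bundle, *STAGE2_CASE)
    f2d = _stage_objective(model, bundle, case, config.duration_ms)
    return _run_stage(
        lambda al: f2d(mu0_med=mu0_med, alpha=al), config.stage2_grid, config.stage2_tol
    )


def run_calibration(model, bundle, config: CalibrationConfig | None = None) -> dict:
    """Execute the full staged calibration and verification protocol.

    1. Calibrate mu0_med on the low-severity axial case (alpha = 2).
    2. Intermediate verification: rate the held-out low-severity cases.
    3. Calibrate alpha while preserving mu0_med.
    4. Comprehensive verification: rate the entire case matrix.

    Returns a JSON-serializable report with search traces, per-case wcCORA,
    and summary statistics.  Any stage failure aborts with the partial report
    attached to the raised exception.
    """
    config = config or CalibrationConfig()
    report: dict = {"config": {
        "stage1_grid": list(config.stage1_grid), "stage1_tol": config.stage1_tol,
        "stage2_grid": list(config.stage2_grid), "stage2_tol": config.stage2_tol,
        "duration_ms": config.duration_ms, "seed": config.seed,
    }}
    try:
        s1 = calibrate_stage1(model, bundle, config)
        report["stage1"] = s1.to_dict()
        mu0 = s1.value

        # Intermediate verification: remaining low-severity (20 rad/s, 60 ms)
        # cases under the stage-1 (alpha = 2) material.
        inter = {}
        for axis in ("coronal", "sagittal"):
            case = bundle.find_case(axis, 20.0, 60.0)
            if case is None:
                continue
            inter[case] = {
                subj: model.rate_subject_case(
                    subj, case, bundle, mu0_med=mu0, alpha=2.0,
                    duration_ms=config.duration_ms,
                )
                for subj in bundle.subject_names
            }
        report["stage1_verification"] = inter

        s2 = calibrate_stage2(model, bundle, mu0, config)
        report["stage2"] = s2.to_dict()
        alpha = s2.value

        verification = {}
        scores = []
        for case in bundle.case_ids:
            verification[case] = {}
            for subj in bundle.subject_names:
                sc = model.rate_subject_case(
                    subj, case, bundle, mu0_med=mu0, alpha=alpha,
                    duration_ms=config.duration_ms,
                )
                verification[case][subj] = sc
                scores.append(sc)
        scores = np.asarray(scores)
        report["verification"] = verification
        report["calibrated"] = {"mu0_med_kpa": mu0, "alpha": alpha}
        report["summary"] = {
            "n_cases": int(scores.size),
            "wccora_mean": float(scores.mean()),
            "wccora_sd": float(scores.std(ddof=1)) if scores.size > 1 else 0.0,
            "wccora_range": [float(scores.min()), float(scores.max())],
        }
    except Exception as exc:
        exc.partial_report = report  # type: ignore[attr-defined]
        raise
    return report
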