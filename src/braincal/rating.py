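"""CORA-style objective rating of paired displacement time histories.

A single-axis score combines a cross-correlation group (shape, size, phase)
with a corridor rating::

    score = w_corr * (w_shape*R_shape + w_size*R_size + w_phase*R_phase)
          + w_corridor * R_corridor

The per-receiver 3-axis composite (cCORA) weights axis scores by the peak
reference magnitude per axis; the case-level score (wcCORA) weights receiver
cCORA scores by each receiver's maximum resultant reference displacement
(beta); the multi-subject joint objective is the plain mean of per-subject
wcCORA values.  All scores live in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CoraParams",
    "TimeSignal",
    "ReceiverRecord",
    "CoraScore",
    "ReceiverRating",
    "CaseRating",
    "cora_score",
    "composite_cora",
    "weighted_overall",
    "rate_case",
    "joint_objective",
    "resample_pair",
]

AXES = ("x", "y", "z")


@dataclass(frozen=True)
class CoraParams:
    """Rating constants.  ``delta_max`` is the maximum cross-correlation shift
    as a fraction of the evaluation window; corridor half-widths are ``a0``
    (inner) and ``b0`` (outer) times the peak absolute reference; the
    evaluation window spans the samples where |ref| >= ``window_threshold``
    times its peak.  ``magnitude`` selects how cCORA axis weights measure
    signal size ("peak" or "rms")."""

    w_corr: float = 0.5
    w_corridor: float = 0.5
    w_shape: float = 0.5
    w_size: float = 0.25
    w_phase: float = 0.25
    delta_max: float = 0.12
    a0: float = 0.05
    b0: float = 0.5
    window_threshold: float = 0.03
    magnitude: str = "peak"


DEFAULT_PARAMS = CoraParams()


@dataclass
class TimeSignal:
    """Uniformly sampled displacement history: t in ms, y in mm."""

    t: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.y.shape:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if self.t.size < 10:
            raise ValueError("signal must have at least 10 samples")
        steps = np.diff(self.t)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be uniform")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.y))):
            raise ValueError("signal values must be finite")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class ReceiverRecord:
    """Paired reference (experiment) and test (model) signals per axis."""

    id: str
    ref: Mapping[str, TimeSignal]
    test: Mapping[str, TimeSignal]

    def __post_init__(self) -> None:
        axes = [a for a in AXES if a in self.ref]
        if not axes:
            raise ValueError("record needs at least one axis")
        t0 = self.ref[axes[0]].t
        for a in axes:
            if a not in self.test:
                raise ValueError(f"missing test signal for axis {a!r}")
            for sig in (self.ref[a], self.test[a]):
                if sig.t.shape != t0.shape or not np.allclose(sig.t, t0):
                    raise ValueError("all axes must share one time grid")

    @property
    def beta(self) -> float:
        """Maximum resultant reference displacement (mm), recomputed."""
        axes = [a for a in AXES if a in self.ref]
        res = np.sqrt(sum(self.ref[a].y ** 2 for a in axes))
        return float(res.max())


@dataclass(frozen=True)
class CoraScore:
    score: float
    r_shape: float
    r_size: float
    r_phase: float
    r_corridor: float
    shift_ms: float


@dataclass
class ReceiverRating:
    id: str
    axis_scores: dict[str, CoraScore]
    axis_weights: dict[str, float]
    ccora: float
    beta: float


@dataclass
class CaseRating:
    receivers: list[ReceiverRating]
    alphas: list[float]
    wccora: float


class ZeroReferenceError(ValueError):
    """Reference signal has no energy; the axis cannot be rated."""


def _normalized_xcorr(r: np.ndarray, s: np.ndarray, max_shift: int) -> tuple[float, float]:
    """Max normalized cross-correlation over shifts |d| <= max_shift and its
    argmax shift (samples).

    The integer-shift maximum is refined by parabolic interpolation through
    its neighbours, giving a sub-sample shift estimate so that shape and
    phase ratings vary continuously with the test signal.  Ties resolve to
    the smallest |d| (negative before positive).
    """
    n = r.size

    def corr_at(d: int) -> float:
        if d >= 0:
            a, b = r[: n - d], s[d:]
        else:
            a, b = r[-d:], s[: n + d]
        if a.size < 2:
            return -np.inf
        denom = np.sqrt(np.dot(a, a) * np.dot(b, b))
        return float(np.dot(a, b) / denom) if denom > 0 else 0.0

    order = [0]
    for k in range(1, max_shift + 1):
        order.extend([-k, k])
    vals = {d: corr_at(d) for d in order}
    best_d = max(order, key=lambda d: vals[d])
    best_c = vals[best_d]
    if not np.isfinite(best_c):
        return 0.0, 0.0
    # Sub-sample refinement when the peak is interior.
    dm, dp = best_d - 1, best_d + 1
    if dm >= -max_shift and dp <= max_shift:
        cm = vals.get(dm, corr_at(dm))
        cp = vals.get(dp, corr_at(dp))
        denom = cm - 2.0 * best_c + cp
        if np.isfinite(cm) and np.isfinite(cp) and denom < 0:
            frac = 0.5 * (cm - cp) / denom
            if -0.5 <= frac <= 0.5:
                return best_c - 0.25 * (cm - cp) * frac, best_d + frac
    return best_c, float(best_d)


def cora_score(
    ref: TimeSignal, test: TimeSignal, params: CoraParams = DEFAULT_PARAMS
) -> CoraScore:
    """Rate one test signal against one reference signal on a shared grid."""
    if ref.t.shape != test.t.shape or not np.allclose(ref.t, test.t):
        raise ValueError("ref and test must share a time grid; resample first")
    peak = float(np.abs(ref.y).max())
    if peak == 0.0:
        raise ZeroReferenceError("reference signal has zero energy")
    # Evaluation window: first to last sample where |ref| clears the threshold.
    above = np.flatnonzero(np.abs(ref.y) >= params.window_threshold * peak)
    i0, i1 = int(above[0]), int(above[-1])
    r = ref.y[i0 : i1 + 1]
    s = test.y[i0 : i1 + 1]
    n = r.size
    dt = ref.dt

    max_shift = int(np.floor(params.delta_max * n))
    cmax, dstar = _normalized_xcorr(r, s, max_shift)
    r_shape = max(0.0, cmax)
    if max_shift > 0:
        r_phase = float(np.clip(1.0 - abs(dstar) / (params.delta_max * n), 0.0, 1.0))
    else:
        r_phase = 1.0

    e_ref = float(np.dot(r, r) * dt)
    e_test = float(np.dot(s, s) * dt)
    if max(e_ref, e_test) > 0:
        r_size = min(e_ref, e_test) / max(e_ref, e_test)
    else:
        r_size = 1.0

    inner = params.a0 * peak
    outer = params.b0 * peak
    dev = np.abs(s - r)
    corr_samples = np.where(
        dev <= inner,
        1.0,
        np.where(dev >= outer, 0.0, ((outer - dev) / (outer - inner)) ** 2),
    )
    r_corridor = float(corr_samples.mean())

    score = params.w_corr * (
        params.w_shape * r_shape + params.w_size * r_size + params.w_phase * r_phase
    ) + params.w_corridor * r_corridor
    return CoraScore(
        score=float(np.clip(score, 0.0, 1.0)),
        r_shape=r_shape,
        r_size=r_size,
        r_phase=r_phase,
        r_corridor=r_corridor,
        shift_ms=dstar * dt,
    )


def composite_cora(
    record: ReceiverRecord, params: CoraParams = DEFAULT_PARAMS
) -> ReceiverRating:
    """Magnitude-weighted 3-axis composite score for one receiver.

    Axis weights are the peak (or rms) absolute reference magnitude per axis,
    normalized to sum to 1.  A zero-energy axis receives weight 0 and is not
    rated.
    """
    axes = [a for a in AXES if a in record.ref]
    mags = {}
    for a in axes:
        y = record.ref[a].y
        mags[a] = float(np.abs(y).max()) if params.magnitude == "peak" else float(
            np.sqrt(np.mean(y**2))
        )
    total = sum(mags.values())
    if total == 0:
        raise ZeroReferenceError("all reference axes have zero energy")
    scores: dict[str, CoraScore] = {}
    weights: dict[str, float] = {}
    ccora = 0.0
    for a in axes:
        w = mags[a] / total
        weights[a] = w
        if w == 0.0:
            continue
        sc = cora_score(record.ref[a], record.test[a], params)
        scores[a] = sc
        ccora += w * sc.score
    return ReceiverRating(
        id=record.id,
        axis_scores=scores,
        axis_weights=weights,
        ccora=float(ccora),
        beta=record.beta,
    )


def weighted_overall(
    ccoras: Sequence[float], betas: Sequence[float]
) -> tuple[float, list[float]]:
    """wcCORA = sum_i alpha_i * cCORA_i with alpha_i = beta_i / sum(beta)."""
    c = np.asarray(ccoras, dtype=float)
    b = np.asarray(betas, dtype=float)
    if c.size == 0 or c.shape != b.shape:
        raise ValueError("need matching non-empty ccora and beta lists")
    if np.any(b < 0):
        raise ValueError("beta values must be non-negative")
    total = b.sum()
    if total == 0:
        raise ValueError("all receiver betas are zero")
    alphas = b / total
    return float(np.dot(alphas, c)), list(alphas)


def rate_case(
    records: Sequence[ReceiverRecord], params: CoraParams = DEFAULT_PARAMS
) -> CaseRating:
    """Rate all receivers of one rotation case and combine into wcCORA."""
    ratings = [composite_cora(r, params) for r in records]
    wccora, alphas = weighted_overall(
        [r.ccora for r in ratings], [r.beta for r in ratings]
    )
    return CaseRating(receivers=ratings, alphas=alphas, wccora=wccora)


def joint_objective(wccora_by_subject: Sequence[float]) -> float:
    """Mean wcCORA across subjects (the joint calibration objective)."""
    v = np.asarray(wccora_by_subject, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one subject score")
    return float(v.mean())


def resample_pair(
    ref: TimeSignal, test: TimeSignal, dt_target: float | None = None
) -> tuple[TimeSignal, TimeSignal]:
    """Linearly interpolate both signals onto a common uniform grid over the
    overlap of their time ranges."""
    t0 = max(ref.t[0], test.t[0])
    t1 = min(ref.t[-1], test.t[-1])
    if t1 <= t0:
        raise ValueError("signals have no overlapping time range")
    if dt_target is None:
        dt_target = min(ref.dt, test.dt)
    n = int(np.floor((t1 - t0) / dt_target)) + 1
    if n < 10:
        raise ValueError("overlap too short for the target sampling")
    t = t0 + dt_target * np.arange(n)
    return (
        TimeSignal(t=t, y=np.interp(t, ref.t, ref.y)),
        TimeSignal(t=t, y=np.interp(t, test.t, test.y)),
    )
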