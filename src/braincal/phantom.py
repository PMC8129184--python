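"""Desk-scale lumped-parameter phantom and synthetic-data generator.

This module supplies the forward model and the synthetic experiment data
that the calibration machinery exercises.  It is explicitly NOT a continuum
finite-element head model: it is a deliberately small spring-mass surrogate
with the statistical and mechanical structure the analysis assumes —

* a rigid spherical "skull" shell driven by 6-DOF-style rotational pulses
  (here: single-axis half-sine angular-velocity pulses, 20-40 rad/s peak,
  30-60 ms duration),
* an interior lattice of point masses connected by springs whose force law
  is the Ogden-QLV shear response from :mod:`braincal.constitutive`, with
  per-spring stiffness scaled by the node-pair mean relative stiffness
  gamma taken from a (synthetic) MRE label volume,
* receiver nodes whose skull-frame displacement histories stand in for
  sonomicrometry records.

Units are kg / mm / ms throughout (stresses internally in GPa), so forces
integrate directly with densities in kg/mm^3 and moduli given in kPa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import Delaunay

from .constitutive import BRAIN_PRONY, PronySeries
from .heterogeneity import (
    MaterialCardSet,
    RelativeStiffnessLabels,
    StiffnessVolume,
    bin_relative_stiffness,
    build_material_cards,
    truncate_and_normalize,
)
from .rating import AXES, TimeSignal

__all__ = [
    "RotationPulse",
    "PhantomConfig",
    "ExperimentBundle",
    "PhantomForwardModel",
    "InstabilityError",
    "make_pulse",
    "default_case_matrix",
    "build_phantom",
    "simulate",
    "generate_synthetic_mre",
    "make_dataset",
    "make_strain_truth",
    "write_bundle",
    "read_bundle",
]

#: kPa expressed in the kg-mm-ms stress unit (GPa).
KPA = 1e-6

AXIS_INDEX = {"coronal": 0, "sagittal": 1, "axial": 2}
AXIS_LETTER = {"coronal": "x", "sagittal": "y", "axial": "z"}


class InstabilityError(RuntimeError):
    """Time integration diverged; reduce dt below the reported bound."""


@dataclass(frozen=True)
class RotationPulse:
    """Half-sine angular-velocity pulse about one anatomical axis.

    omega(t) = peak * sin(pi * t / duration) on [0, duration], 0 after;
    the total rotation angle is 2 * peak * duration / pi (peak in rad/s,
    duration in ms).
    """

    axis: str
    peak: float
    duration: float

    def __post_init__(self) -> None:
        if self.axis not in AXIS_INDEX:
            raise ValueError(f"axis must be one of {sorted(AXIS_INDEX)}")
        if self.peak < 0:
            raise ValueError("peak must be non-negative")
        if not (self.duration > 0):
            raise ValueError("duration must be positive")

    @property
    def case_id(self) -> str:
        return f"{AXIS_LETTER[self.axis]}-{self.peak:g}-{self.duration:g}"

    def omega(self, t_ms: np.ndarray) -> np.ndarray:
        """Angular velocity (rad/ms) at time t (ms)."""
        t = np.asarray(t_ms, dtype=float)
        w = (self.peak * 1e-3) * np.sin(np.pi * t / self.duration)
        return np.where((t >= 0) & (t <= self.duration), w, 0.0)

    def omega_dot(self, t_ms: np.ndarray) -> np.ndarray:
        """Angular acceleration (rad/ms^2)."""
        t = np.asarray(t_ms, dtype=float)
        wd = (self.peak * 1e-3) * (np.pi / self.duration) * np.cos(
            np.pi * t / self.duration
        )
        return np.where((t >= 0) & (t <= self.duration), wd, 0.0)

    def angle(self, t_ms: np.ndarray) -> np.ndarray:
        """Rotation angle (rad) by exact integration of the half-sine."""
        t = np.asarray(t_ms, dtype=float)
        d = self.duration
        total = 2.0 * (self.peak * 1e-3) * d / np.pi
        inside = (self.peak * 1e-3) * (d / np.pi) * (1.0 - np.cos(np.pi * t / d))
        return np.where(t <= 0, 0.0, np.where(t <= d, inside, total))


def make_pulse(axis: str, peak: float, duration: float) -> RotationPulse:
    """Construct a rotation pulse; peak in rad/s, duration in ms."""
    return RotationPulse(axis=axis, peak=peak, duration=duration)


def default_case_matrix() -> list[RotationPulse]:
    """The 12-case verification matrix: 3 directions x {20, 40} rad/s x
    {30, 60} ms."""
    return [
        make_pulse(axis, peak, duration)
        for axis in ("coronal", "sagittal", "axial")
        for peak in (20.0, 40.0)
        for duration in (30.0, 60.0)
    ]


@dataclass
class PhantomConfig:
    """Geometry, connectivity and discretization of one phantom subject."""

    positions: np.ndarray          # (n, 3) interior node positions, mm
    anchors: np.ndarray            # (n_a, 3) fixed shell anchor points, mm
    springs: np.ndarray            # (m, 2) endpoint ids; anchors follow nodes
    rest_lengths: np.ndarray       # (m,)
    areas: np.ndarray              # (m,) effective cross-sections, mm^2
    gamma: np.ndarray              # (n,) per-node relative stiffness
    labels: np.ndarray             # (n,) per-node bin index (1-based)
    masses: np.ndarray             # (n,) kg
    receiver_ids: np.ndarray       # (k,) indices of receiver nodes
    radius: float                  # shell radius, mm
    dt: float = 0.05               # integration step, ms
    mass_damping: float = 0.005    # 1/ms, small fixed ambient damping
    dt_stable: float = np.nan      # stability bound for the stiffest card

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    @property
    def n_springs(self) -> int:
        return self.springs.shape[0]


def _lattice_in_sphere(n_nodes: int, radius: float, rng: np.random.Generator):
    """Jittered cubic lattice with exactly n_nodes points inside the sphere."""
    target_v = 4.0 / 3.0 * np.pi * radius**3 / n_nodes
    h = target_v ** (1.0 / 3.0)
    inner = radius - 0.45 * h
    for _ in range(60):
        k = int(np.ceil(inner / h))
        ax = h * np.arange(-k, k + 1)
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        pts = pts[np.linalg.norm(pts, axis=1) <= inner]
        if pts.shape[0] >= n_nodes:
            break
        h *= 0.97
        inner = radius - 0.45 * h
    else:
        raise RuntimeError("could not place requested node count")
    jitter = rng.uniform(-0.25 * h, 0.25 * h, size=pts.shape)
    pts = pts + jitter
    # Pull any jittered point back inside the interior radius.
    norms = np.linalg.norm(pts, axis=1)
    outside = norms > inner
    pts[outside] *= (inner / norms[outside])[:, None] * 0.999
    order = rng.permutation(pts.shape[0])
    return pts[order[:n_nodes]], h


def build_phantom(
    labels: RelativeStiffnessLabels,
    n_nodes: int = 150,
    radius: float = 70.0,
    n_receivers: int = 12,
    seed: int = 0,
    dt: float = 0.05,
    density: float = 1.123e-6,
    stiffness_scale: float = 1.0,
) -> PhantomConfig:
    """Build a phantom subject: jittered-lattice nodes in a sphere, Delaunay
    node-node springs, shell anchors for boundary nodes, gamma per node from
    the relative-stiffness label volume, mass from tributary volume."""
    if labels.affine is None:
        raise ValueError("labels need an affine to map node positions to voxels")
    rng = np.random.default_rng(seed)
    pts, h = _lattice_in_sphere(n_nodes, radius, rng)

    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for i in range(4):
            for j in range(i + 1, 4):
                a, b = int(simplex[i]), int(simplex[j])
                edges.add((min(a, b), max(a, b)))
    edges = np.array(sorted(edges))
    lengths = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    keep = lengths <= 2.2 * h  # prune sliver tetrahedra edges
    edges, lengths = edges[keep], lengths[keep]

    # Anchor boundary nodes to the rigid shell: one radial spring each, plus
    # oblique springs to the two nearest neighbouring anchor points so that
    # tangential (rotational) motion of the interior relative to the shell
    # is elastically resisted — otherwise a rigid rotation of the whole
    # interior is a near-zero-stiffness pendulum mode.
    boundary = np.flatnonzero(np.linalg.norm(pts, axis=1) > radius - 1.4 * h)
    if boundary.size == 0:
        boundary = np.argsort(-np.linalg.norm(pts, axis=1))[: max(6, n_nodes // 10)]
    anchors = pts[boundary] / np.linalg.norm(pts[boundary], axis=1, keepdims=True) * radius
    anchor_ids = n_nodes + np.arange(boundary.size)
    anchor_edges = [np.column_stack([boundary, anchor_ids])]
    if boundary.size >= 3:
        from scipy.spatial import cKDTree

        tree = cKDTree(anchors)
        _, nearest = tree.query(anchors, k=3)  # self + two neighbours
        for col in (1, 2):
            anchor_edges.append(
                np.column_stack([boundary, n_nodes + nearest[:, col]])
            )
    anchor_edges = np.vstack(anchor_edges)
    anchor_lengths = np.linalg.norm(
        anchors[anchor_edges[:, 1] - n_nodes] - pts[anchor_edges[:, 0]], axis=1
    )

    springs = np.vstack([edges, anchor_edges])
    rest = np.concatenate([lengths, anchor_lengths])
    if np.any(rest <= 0):
        raise RuntimeError("degenerate zero-length spring")

    # Per-node relative stiffness from the label volume.
    inv = np.linalg.inv(labels.affine)
    homog = np.column_stack([pts, np.ones(n_nodes)])
    vox = (homog @ inv.T)[:, :3]
    idx = np.clip(
        np.round(vox).astype(int), 0, np.array(labels.labels.shape) - 1
    )
    node_labels = labels.labels[idx[:, 0], idx[:, 1], idx[:, 2]].astype(int)
    # Nodes falling outside the imaged brain default to the median bin.
    median_bin = int(np.argmin(np.abs(np.asarray(labels.centers) - 1.0))) + 1
    node_labels[node_labels == 0] = median_bin
    gamma = np.asarray(labels.centers)[node_labels - 1]

    v_trib = 4.0 / 3.0 * np.pi * radius**3 / n_nodes
    masses = np.full(n_nodes, density * v_trib)
    # Spring cross-sections from the affine lattice-continuum estimate for a
    # central-force network, mu_eff = (1/15V) sum_e k_e L_e^2 with
    # k_e = A_e mu / L_e: with the default stiffness_scale = 1 a uniform A
    # makes mu_eff equal the card mu exactly; the scale is exposed only for
    # sensitivity studies.
    volume = 4.0 / 3.0 * np.pi * radius**3
    areas = np.full(springs.shape[0], stiffness_scale * 15.0 * volume / rest.sum())

    receivers = rng.choice(n_nodes, size=min(n_receivers, n_nodes), replace=False)
    receivers = np.sort(receivers)

    cfg = PhantomConfig(
        positions=pts,
        anchors=anchors,
        springs=springs,
        rest_lengths=rest,
        areas=areas,
        gamma=gamma,
        labels=node_labels,
        masses=masses,
        receiver_ids=receivers,
        radius=radius,
        dt=dt,
    )
    return cfg


def _integrate_numpy(
    x0, anchors, i_idx, j_idx, inv_rest, mu_spring, alpha, area_k,
    decay, ramp, ghat_inf, inv_mass, c_damp, ax_i, p_i, q_i,
    omega_t, omega_dot_t, dt, n_steps, every, rec, u_out, traj,
    record_traj, disp_limit,
):
    """Semi-implicit Euler integration of the phantom in the rotating frame.

    Reference implementation; :func:`_integrate_jit` is its numba-compiled
    twin and must stay numerically identical.  Fills ``u_out`` (and ``traj``
    when requested) in place; returns the step index at which the solution
    diverged, or -1 on success.
    """
    n = x0.shape[0]
    m = i_idx.shape[0]
    x = x0.copy()
    v = np.zeros_like(x)
    H = np.zeros((m, decay.size))
    te_prev = np.zeros(m)
    P = np.vstack([x, anchors])
    Hbuf = np.empty_like(H)
    cross = np.empty_like(x)
    interior = j_idx < n
    j_int = j_idx[interior]
    out_i = 0
    for step in range(n_steps + 1):
        if step % every == 0:
            u = x - x0
            u_out[out_i] = u[rec]
            if record_traj:
                traj[out_i] = u
            out_i += 1
        if step == n_steps:
            break
        P[:n] = x
        d = P[j_idx] - P[i_idx]
        L = np.sqrt(np.einsum("ij,ij->i", d, d))
        eps = L * inv_rest - 1.0
        root = np.sqrt(eps * eps + 4.0)
        l1 = 0.5 * (eps + root)
        la = l1**alpha
        te = mu_spring * (la - 1.0 / la) / root
        H *= decay
        np.multiply((te - te_prev)[:, None], ramp, out=Hbuf)
        H += Hbuf
        te_prev = te
        sig = ghat_inf * te + H.sum(axis=1)

        f_spring = (area_k * sig / L)[:, None] * d  # force on node i toward j
        F = np.zeros_like(x)
        np.add.at(F, i_idx, f_spring)
        np.subtract.at(F, j_int, f_spring[interior])
        a = F * inv_mass[:, None]

        # Fictitious accelerations about the single pulse axis e:
        # -wd (e x r) + w^2 r_perp - 2 w (e x v), all in the shell frame.
        w = omega_t[step]
        wd = omega_dot_t[step]
        if w != 0.0 or wd != 0.0:
            cross[:, ax_i] = 0.0
            cross[:, p_i] = wd * x[:, q_i] + 2.0 * w * v[:, q_i]
            cross[:, q_i] = -wd * x[:, p_i] - 2.0 * w * v[:, p_i]
            a += cross
            w2 = w * w
            a[:, p_i] += w2 * x[:, p_i]
            a[:, q_i] += w2 * x[:, q_i]
        a -= c_damp * v

        v += dt * a
        x += dt * v

        if step % 200 == 0 and np.max(np.abs(x - x0)) > disp_limit:
            return step
    return -1


try:  # compiled twin of _integrate_numpy; numpy path is the fallback
    import numba

    @numba.njit(cache=True, fastmath=False)
    def _integrate_jit(
        x0, anchors, i_idx, j_idx, inv_rest, mu_spring, alpha, area_k,
        decay, ramp, ghat_inf, inv_mass, c_damp, ax_i, p_i, q_i,
        omega_t, omega_dot_t, dt, n_steps, every, rec, u_out, traj,
        record_traj, disp_limit,
    ):  # pragma: no cover - exercised via simulate()
        n = x0.shape[0]
        m = i_idx.shape[0]
        nt = decay.shape[0]
        x = x0.copy()
        v = np.zeros((n, 3))
        na = anchors.shape[0]
        P = np.empty((n + na, 3))
        for i in range(na):
            for c in range(3):
                P[n + i, c] = anchors[i, c]
        H = np.zeros((m, nt))
        te_prev = np.zeros(m)
        F = np.empty((n, 3))
        out_i = 0
        for step in range(n_steps + 1):
            if step % every == 0:
                for r in range(rec.shape[0]):
                    for c in range(3):
                        u_out[out_i, r, c] = x[rec[r], c] - x0[rec[r], c]
                if record_traj:
                    for i in range(n):
                        for c in range(3):
                            traj[out_i, i, c] = x[i, c] - x0[i, c]
                out_i += 1
            if step == n_steps:
                break
            for i in range(n):
                for c in range(3):
                    P[i, c] = x[i, c]
                    F[i, c] = 0.0
            for e in range(m):
                i = i_idx[e]
                j = j_idx[e]
                dx = P[j, 0] - P[i, 0]
                dy = P[j, 1] - P[i, 1]
                dz = P[j, 2] - P[i, 2]
                L = np.sqrt(dx * dx + dy * dy + dz * dz)
                eps = L * inv_rest[e] - 1.0
                root = np.sqrt(eps * eps + 4.0)
                l1 = 0.5 * (eps + root)
                la = l1**alpha
                te = mu_spring[e] * (la - 1.0 / la) / root
                dte = te - te_prev[e]
                s = ghat_inf * te
                for k in range(nt):
                    H[e, k] = decay[k] * H[e, k] + ramp[k] * dte
                    s += H[e, k]
                te_prev[e] = te
                f = area_k[e] * s / L
                fx = f * dx
                fy = f * dy
                fz = f * dz
                F[i, 0] += fx
                F[i, 1] += fy
                F[i, 2] += fz
                if j < n:
                    F[j, 0] -= fx
                    F[j, 1] -= fy
                    F[j, 2] -= fz
            w = omega_t[step]
            wd = omega_dot_t[step]
            w2 = w * w
            for i in range(n):
                a0 = F[i, 0] * inv_mass[i] - c_damp * v[i, 0]
                a1 = F[i, 1] * inv_mass[i] - c_damp * v[i, 1]
                a2 = F[i, 2] * inv_mass[i] - c_damp * v[i, 2]
                acc = (a0, a1, a2)
                ap = acc[p_i] + wd * x[i, q_i] + 2.0 * w * v[i, q_i] + w2 * x[i, p_i]
                aq = acc[q_i] - wd * x[i, p_i] - 2.0 * w * v[i, p_i] + w2 * x[i, q_i]
                aa = acc[ax_i]
                v[i, p_i] += dt * ap
                v[i, q_i] += dt * aq
                v[i, ax_i] += dt * aa
                for c in range(3):
                    x[i, c] += dt * v[i, c]
            if step % 200 == 0:
                mx = 0.0
                for i in range(n):
                    for c in range(3):
                        dd = abs(x[i, c] - x0[i, c])
                        if dd > mx:
                            mx = dd
                if mx > disp_limit:
                    return step
        return -1

except Exception:  # pragma: no cover
    _integrate_jit = None


def _stability_bound(phantom: PhantomConfig, cards: MaterialCardSet) -> float:
    """Conservative explicit-integration step bound (ms) for the stiffest
    spring/lightest node, using the instantaneous tangent modulus with a
    margin for large-strain Ogden stiffening."""
    mu0_inst = cards.mu0_med * max(cards.centers)
    if cards.cards[0].reference == "quasi_static":
        mu0_inst /= cards.prony.g_inf
    k = phantom.areas * KPA * mu0_inst / phantom.rest_lengths
    # Count spring stiffness per node.
    n = phantom.n_nodes
    k_node = np.zeros(n)
    for (i, j), kk in zip(phantom.springs, k):
        k_node[i] += kk
        if j < n:
            k_node[j] += kk
    omega_max = np.sqrt(2.0 * (k_node / phantom.masses).max())
    stiffening = max(8.0, abs(cards.alpha))  # large-strain tangent margin
    return 2.0 / (omega_max * np.sqrt(stiffening))


def simulate(
    phantom: PhantomConfig,
    pulse: RotationPulse,
    cards: MaterialCardSet,
    T: float = 200.0,
    output_dt: float = 0.5,
    return_trajectory: bool = False,
):
    """Integrate the phantom through a rotation pulse.

    The rigid shell follows the pulse exactly; the equations of motion are
    written in the shell-fixed (rotating) frame, so the shell anchors stay
    put and the interior nodes feel Euler, centrifugal and Coriolis
    accelerations in addition to the QLV spring forces.  Semi-implicit
    (symplectic) Euler integration.

    Returns ``{receiver_id: {axis: TimeSignal}}`` of skull-frame relative
    displacements (mm), or additionally the full node displacement history
    if ``return_trajectory``.
    """
    dt = phantom.dt
    bound = _stability_bound(phantom, cards)
    if dt > bound:
        raise InstabilityError(
            f"dt = {dt} ms exceeds the stability bound {bound:.4g} ms "
            f"for the stiffest material card"
        )
    present = np.unique(phantom.labels)
    if np.any(present > len(cards.centers)) or np.any(present < 1):
        raise ValueError("cards do not cover all labels present in the phantom")

    n = phantom.n_nodes
    m = phantom.n_springs
    i_idx = phantom.springs[:, 0]
    j_idx = phantom.springs[:, 1]
    j_is_anchor = j_idx >= n
    anchor_pos = phantom.anchors

    # Node-pair mean relative stiffness scales each spring's Ogden mu.
    gamma_j = np.where(j_is_anchor, phantom.gamma[i_idx], phantom.gamma[np.minimum(j_idx, n - 1)])
    gamma_pair = 0.5 * (phantom.gamma[i_idx] + gamma_j)
    alpha = cards.alpha
    mu_spring = 2.0 * gamma_pair * cards.mu0_med / alpha  # kPa

    # Effective relaxation spectrum (quasi-static convention rescales by g_inf).
    prony = cards.prony
    g = np.asarray(prony.g)
    tau = np.asarray(prony.tau)
    if cards.cards[0].reference == "quasi_static":
        ghat_inf = 1.0
        ghat = g / prony.g_inf
    else:
        ghat_inf = prony.g_inf
        ghat = g
    decay = np.exp(-dt / tau)
    ramp = ghat * (tau / dt) * (1.0 - decay)

    ax_i = AXIS_INDEX[pulse.axis]
    # Component indices for cross products with the rotation axis e:
    # e x r = (-r[q], r[p]) on the plane (p, q) perpendicular to the axis.
    p_i, q_i = (ax_i + 1) % 3, (ax_i + 2) % 3

    n_steps = int(round(T / dt))
    every = max(1, int(round(output_dt / dt)))
    t_grid = dt * np.arange(n_steps + 1)
    omega_t = pulse.omega(t_grid)
    omega_dot_t = pulse.omega_dot(t_grid)

    area_k = phantom.areas * KPA
    inv_mass = 1.0 / phantom.masses
    c_damp = phantom.mass_damping
    inv_rest = 1.0 / phantom.rest_lengths

    n_out = len(range(0, n_steps + 1, every))
    rec = phantom.receiver_ids.astype(np.int64)
    u_out = np.empty((n_out, rec.size, 3))
    traj = np.empty((n_out, n, 3)) if return_trajectory else np.empty((1, 1, 3))

    args = (
        phantom.positions.astype(float),
        anchor_pos.astype(float),
        i_idx.astype(np.int64),
        j_idx.astype(np.int64),
        inv_rest,
        mu_spring,
        float(alpha),
        area_k,
        decay,
        ramp,
        float(ghat_inf),
        inv_mass,
        float(c_damp),
        ax_i,
        p_i,
        q_i,
        omega_t,
        omega_dot_t,
        float(dt),
        n_steps,
        every,
        rec,
        u_out,
        traj,
        bool(return_trajectory),
        2.0 * phantom.radius,
    )
    diverged = (_integrate_jit if _integrate_jit is not None else _integrate_numpy)(*args)
    if diverged >= 0:
        raise InstabilityError(
            f"displacement diverged at t = {diverged * dt:.1f} ms; "
            f"stability bound is dt < {bound:.4g} ms"
        )

    t_out = dt * np.arange(0, n_steps + 1, every, dtype=float)
    signals = {
        f"r{k:02d}": {
            ax: TimeSignal(t=t_out, y=u_out[:, r, a].copy())
            for a, ax in enumerate(AXES)
        }
        for r, k in zip(range(rec.size), rec)
    }
    if return_trajectory:
        return signals, t_out, traj
    return signals


def generate_synthetic_mre(
    shape: tuple[int, int, int] = (64, 64, 64),
    median_kpa: float = 2.53,
    sd_kpa: float = 0.99,
    smoothness: float = 2.0,
    seed: int = 0,
    spacing: float = 2.0,
    mask_radius_frac: float = 0.47,
) -> StiffnessVolume:
    """Synthetic MRE stiffness volume emulating the brain template statistics.

    A spatially smoothed lognormal field inside a spherical brain mask,
    rescaled so the sample median equals ``median_kpa`` exactly and the
    marginal log-variance matches the requested sd (lognormal moment
    relation).  Deterministic per seed.  ``sd_kpa = 0`` yields a constant
    (degenerate) field.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    if any(s <= 0 for s in shape):
        raise ValueError("shape must be positive")
    z = rng.standard_normal(shape)
    if smoothness > 0:
        z = gaussian_filter(z, smoothness, mode="nearest")
    grids = np.meshgrid(*(np.arange(s) - (s - 1) / 2.0 for s in shape), indexing="ij")
    r = np.sqrt(sum(g * g for g in grids)) * spacing
    mask = r <= mask_radius_frac * min(shape) * spacing
    vals = np.full(shape, np.nan)
    if sd_kpa > 0:
        zm = z[mask]
        zm = (zm - zm.mean()) / zm.std()
        # For a lognormal with median m: sd = m*exp(s^2/2)*sqrt(exp(s^2)-1);
        # solving for exp(s^2) gives the closed form below.
        ratio = sd_kpa / median_kpa
        ex = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * ratio * ratio))
        sigma_log = np.sqrt(np.log(ex))
        field = np.exp(sigma_log * zm)
        field *= median_kpa / np.median(field)
        vals[mask] = field
    else:
        vals[mask] = median_kpa
    offset = -(np.asarray(shape) - 1) / 2.0 * spacing
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = offset
    return StiffnessVolume(values=vals, spacing=(spacing,) * 3, affine=affine)


@dataclass
class SubjectData:
    phantom: PhantomConfig
    centers: tuple[float, ...]
    records: dict  # case_id -> receiver_id -> axis -> TimeSignal


@dataclass
class ExperimentBundle:
    """Per-subject, per-case reference receiver signals plus provenance."""

    subjects: dict[str, SubjectData]
    cases: dict[str, RotationPulse]
    provenance: dict

    @property
    def subject_names(self) -> list[str]:
        return sorted(self.subjects)

    @property
    def case_ids(self) -> list[str]:
        return sorted(self.cases)

    def find_case(self, axis: str, peak: float, duration: float) -> str | None:
        for cid, pulse in self.cases.items():
            if (
                pulse.axis == axis
                and abs(pulse.peak - peak) < 1e-9
                and abs(pulse.duration - duration) < 1e-9
            ):
                return cid
        return None


def make_dataset(
    true_mu0_med: float = 1.125,
    true_alpha: float = 6.67,
    noise_rel: float = 0.0,
    n_subjects: int = 3,
    cases: Sequence[RotationPulse] | None = None,
    seed: int = 0,
    n_nodes: int = 150,
    n_receivers: int = 12,
    radius: float = 70.0,
    duration_ms: float = 200.0,
    output_dt: float = 0.5,
    mre_shape: tuple[int, int, int] = (48, 48, 48),
    mre_spacing: float = 3.0,
    prony: PronySeries | None = None,
    reference: str = "quasi_static",
) -> ExperimentBundle:
    """Generate a synthetic multi-subject experiment bundle.

    Each subject gets its own phantom geometry and its own synthetic MRE
    volume (emulating inter-subject anatomical and stiffness variation);
    every case is simulated with material cards built from the true
    parameters, and independent Gaussian noise with standard deviation
    ``noise_rel`` times the case's peak resultant displacement is added per
    axis sample.  Fully deterministic for a fixed seed.
    """
    prony = prony or BRAIN_PRONY
    if cases is None:
        cases = default_case_matrix()
    case_map = {p.case_id: p for p in cases}
    root = np.random.default_rng(seed)
    subject_seeds = root.integers(2**31 - 1, size=(n_subjects, 3))

    provenance = {
        "true_mu0_med": true_mu0_med,
        "true_alpha": true_alpha,
        "noise_rel": noise_rel,
        "n_subjects": n_subjects,
        "seed": seed,
        "n_nodes": n_nodes,
        "n_receivers": n_receivers,
        "radius": radius,
        "duration_ms": duration_ms,
        "output_dt": output_dt,
        "mre_shape": list(mre_shape),
        "mre_spacing": mre_spacing,
        "reference": reference,
        "case_ids": sorted(case_map),
    }

    subjects: dict[str, SubjectData] = {}
    for s in range(n_subjects):
        mre_seed, geom_seed, noise_seed = (int(v) for v in subject_seeds[s])
        vol = generate_synthetic_mre(
            shape=tuple(mre_shape), spacing=mre_spacing, seed=mre_seed
        )
        normalized, median, lo, hi = truncate_and_normalize(vol)
        labels = bin_relative_stiffness(
            normalized, lo, hi, n_bins=10, median_kpa=median, affine=vol.affine
        )
        phantom = build_phantom(
            labels,
            n_nodes=n_nodes,
            radius=radius,
            n_receivers=n_receivers,
            seed=geom_seed,
        )
        cards = build_material_cards(
            labels.centers, true_mu0_med, true_alpha, prony, reference=reference
        )
        noise_rng = np.random.default_rng(noise_seed)
        records = {}
        for cid in sorted(case_map):
            signals = simulate(
                phantom, case_map[cid], cards, T=duration_ms, output_dt=output_dt
            )
            if noise_rel > 0:
                peak = max(
                    float(
                        np.sqrt(
                            sum(sig[ax].y ** 2 for ax in AXES)
                        ).max()
                    )
                    for sig in signals.values()
                )
                sd = noise_rel * peak
                for sig in signals.values():
                    for ax in AXES:
                        y = sig[ax].y + sd * noise_rng.standard_normal(sig[ax].y.shape)
                        sig[ax] = TimeSignal(t=sig[ax].t, y=y)
            records[cid] = signals
        subjects[f"S{s:02d}"] = SubjectData(
            phantom=phantom, centers=labels.centers, records=records
        )

    return ExperimentBundle(subjects=subjects, cases=case_map, provenance=provenance)


class PhantomForwardModel:
    """Forward model adapter used by the calibration stages.

    Rebuilds the per-bin material-card set for every candidate
    ``(mu0_med, alpha)``, simulates the requested subject/case on that
    subject's own phantom geometry, and rates the simulated receiver
    displacements against the bundle's reference signals with wcCORA.
    """

    def __init__(
        self,
        prony: PronySeries | None = None,
        reference: str = "quasi_static",
        output_dt: float = 0.5,
    ):
        self.prony = prony or BRAIN_PRONY
        self.reference = reference
        self.output_dt = output_dt

    def simulate_subject_case(
        self, bundle: ExperimentBundle, subject: str, case_id: str,
        mu0_med: float, alpha: float, duration_ms: float = 200.0,
    ):
        subj = bundle.subjects[subject]
        cards = build_material_cards(
            subj.centers, mu0_med, alpha, self.prony, reference=self.reference
        )
        return simulate(
            subj.phantom, bundle.cases[case_id], cards,
            T=duration_ms, output_dt=self.output_dt,
        )

    def rate_subject_case(
        self, subject: str, case_id: str, bundle: ExperimentBundle,
        mu0_med: float, alpha: float, duration_ms: float = 200.0,
    ) -> float:
        from .rating import ReceiverRecord, rate_case

        sim = self.simulate_subject_case(
            bundle, subject, case_id, mu0_med, alpha, duration_ms
        )
        refs = bundle.subjects[subject].records[case_id]
        records = []
        for rid in sorted(refs):
            ref_sigs = refs[rid]
            test_sigs = sim[rid]
            # Truncate the model window to the experimental record length.
            nref = min(ref_sigs["x"].t.size, test_sigs["x"].t.size)
            records.append(
                ReceiverRecord(
                    id=rid,
                    ref={a: TimeSignal(ref_sigs[a].t[:nref], ref_sigs[a].y[:nref]) for a in AXES},
                    test={a: TimeSignal(test_sigs[a].t[:nref], test_sigs[a].y[:nref]) for a in AXES},
                )
            )
        return rate_case(records).wccora


def make_strain_truth(
    phantom: PhantomConfig,
    pulse: RotationPulse,
    cards: MaterialCardSet,
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    T: float = 200.0,
):
    """Voxelized displacement field at peak deformation plus a synthetic
    3-region label volume (stand-ins for gray matter, white matter and the
    cerebellum), for exercising the strain-metric pipeline.

    Returns ``(displacement (X,Y,Z,3) mm, region labels, mask, affine)``.
    """
    from scipy.interpolate import LinearNDInterpolator

    signals, t_out, traj = simulate(
        phantom, pulse, cards, T=T, return_trajectory=True
    )
    mean_disp = np.linalg.norm(traj, axis=2).mean(axis=1)
    k_peak = int(np.argmax(mean_disp))
    u_nodes = traj[k_peak]

    pts = np.vstack([phantom.positions, phantom.anchors])
    u = np.vstack([u_nodes, np.zeros_like(phantom.anchors)])

    R = phantom.radius
    shape = tuple(int(s) for s in grid_shape)
    spacing = 2.0 * R / (min(shape) - 1)
    axes = [spacing * (np.arange(s) - (s - 1) / 2.0) for s in shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    coords = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    if not np.any(np.linalg.norm(coords, axis=1) <= R):
        raise ValueError("grid does not cover the phantom")

    interp = LinearNDInterpolator(pts, u, fill_value=np.nan)
    field = interp(coords).reshape(*shape, 3)
    rmap = np.sqrt(gx * gx + gy * gy + gz * gz)
    mask = (rmap <= 0.95 * R) & np.all(np.isfinite(field), axis=-1)
    field[~mask] = np.nan

    # Synthetic regional parcellation covering the mask exactly:
    # "cerebellum" below, "gray" at the periphery, "white" in the core.
    regions = np.zeros(shape, dtype=np.int16)
    cereb = mask & (gz < -0.45 * R)
    gray = mask & ~cereb & (rmap > 0.6 * R)
    white = mask & ~cereb & ~gray
    regions[cereb] = 3
    regions[gray] = 1
    regions[white] = 2

    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = [axes[0][0], axes[1][0], axes[2][0]]
    return field, regions, mask, affine


# ---------------------------------------------------------------------------
# Bundle directory round trip: subject/case/receiver_<id>.csv + manifest.json
# ---------------------------------------------------------------------------

def write_bundle(bundle: ExperimentBundle, directory: str | Path) -> None:
    import pandas as pd

    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {
        "provenance": bundle.provenance,
        "cases": {
            cid: {"axis": p.axis, "peak_rad_s": p.peak, "duration_ms": p.duration}
            for cid, p in bundle.cases.items()
        },
        "subjects": bundle.subject_names,
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for subj in bundle.subject_names:
        for cid, recs in bundle.subjects[subj].records.items():
            d = root / subj / cid
            d.mkdir(parents=True, exist_ok=True)
            for rid, sigs in recs.items():
                df = pd.DataFrame(
                    {
                        "time_ms": sigs["x"].t,
                        "x_mm": sigs["x"].y,
                        "y_mm": sigs["y"].y,
                        "z_mm": sigs["z"].y,
                    }
                )
                df.to_csv(d / f"receiver_{rid}.csv", index=False)


def read_bundle_signals(directory: str | Path) -> tuple[dict, dict, dict]:
    """Read back the signal payload of a bundle directory.

    Returns ``(records, cases, provenance)`` where records maps
    subject -> case -> receiver -> axis -> TimeSignal.  Phantom geometry is
    not stored on disk; regenerate it from the provenance via make_dataset
    when the forward model is needed.
    """
    import pandas as pd

    root = Path(directory)
    manifest = json.loads((root / "manifest.json").read_text())
    cases = {
        cid: RotationPulse(axis=c["axis"], peak=c["peak_rad_s"], duration=c["duration_ms"])
        for cid, c in manifest["cases"].items()
    }
    records: dict = {}
    for subj in manifest["subjects"]:
        records[subj] = {}
        for cid in cases:
            d = root / subj / cid
            if not d.is_dir():
                continue
            recs = {}
            for f in sorted(d.glob("receiver_*.csv")):
                rid = f.stem.replace("receiver_", "")
                df = pd.read_csv(f)
                t = df["time_ms"].to_numpy()
                recs[rid] = {
                    "x": TimeSignal(t, df["x_mm"].to_numpy()),
                    "y": TimeSignal(t, df["y_mm"].to_numpy()),
                    "z": TimeSignal(t, df["z_mm"].to_numpy()),
                }
            records[subj][cid] = recs
    return records, cases, manifest["provenance"]


def read_bundle(directory: str | Path) -> ExperimentBundle:
    """Regenerate a full bundle (geometry included) from a directory's stored
    provenance; the regenerated signals are bit-identical to the stored ones."""
    _, _, provenance = read_bundle_signals(directory)
    prov = dict(provenance)
    case_ids = prov.pop("case_ids")
    cases = [
        p for p in default_case_matrix() if p.case_id in case_ids
    ]
    missing = set(case_ids) - {p.case_id for p in cases}
    for cid in sorted(missing):
        letter, peak, dur = cid.split("-")
        axis = {v: k for k, v in AXIS_LETTER.items()}[letter]
        cases.append(make_pulse(axis, float(peak), float(dur)))
    prov["mre_shape"] = tuple(prov["mre_shape"])
    return make_dataset(cases=cases, **prov)
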