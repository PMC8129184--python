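"""Ogden hyperelastic + quasi-linear viscoelastic (QLV) material engine.

The brain parenchyma is modelled with Fung's quasi-linear viscoelasticity:
the stress relaxation response separates into a normalized function of time,
``g(t)``, and an instantaneous elastic function of strain, ``T^e(eps)``::

    R(eps, t) = g(t) * T^e(eps)

``T^e`` derives from a one-term incompressible Ogden strain energy density

    W(l1, l2, l3) = (mu / alpha) * (l1**alpha + l2**alpha + l3**alpha - 3)

with shear-modulus coefficient ``mu`` (kPa) and dimensionless non-linearity
coefficient ``alpha``.  The infinitesimal shear modulus (initial slope of the
shear stress-strain curve) is ``mu0 = mu * alpha / 2``.  The reduced
relaxation function is a Prony series

    g(t) = g_inf + sum_i g_i * exp(-t / tau_i),   g_inf + sum_i g_i = 1.

Two modulus reference conventions are supported.  ``"instantaneous"`` is the
textbook QLV form: the Ogden curve is the t -> 0+ response and the long-term
modulus is ``g_inf * mu0``.  ``"quasi_static"`` (the default) rescales the
relaxation function by ``1 / g_inf`` so that the *long-term* shear modulus
equals ``mu0``; reported brain stiffnesses are quasi-static values under this
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "OgdenParams",
    "PronySeries",
    "MaterialCard",
    "BRAIN_PRONY",
    "DEFAULT_TAU_GRID_MS",
    "infinitesimal_shear_modulus",
    "mu_from_infinitesimal",
    "instantaneous_stress",
    "reduced_relaxation",
    "complex_modulus",
    "tan_delta",
    "fit_prony",
    "qlv_stress_history",
    "single_element_curves",
    "PronyFitError",
]

Mode = Literal["tension", "compression", "simple_shear"]
Reference = Literal["quasi_static", "instantaneous"]

#: Decade grid of Prony time constants (ms) used for brain-tissue fits.
DEFAULT_TAU_GRID_MS: tuple[float, ...] = (10.0, 1.0, 0.1, 0.01)


class PronyFitError(RuntimeError):
    """Raised when a Prony-series fit is infeasible or fails to converge."""


@dataclass(frozen=True)
class OgdenParams:
    """One-term Ogden parameters: ``mu`` in kPa, ``alpha`` dimensionless."""

    mu: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.mu > 0):
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.alpha == 0:
            raise ValueError("alpha must be nonzero")


@dataclass(frozen=True)
class PronySeries:
    """Normalized relaxation spectrum: coefficients ``g`` with time constants
    ``tau`` (ms) and long-term coefficient ``g_inf``; g_inf + sum(g) == 1."""

    g: tuple[float, ...]
    tau: tuple[float, ...]
    g_inf: float

    def __post_init__(self) -> None:
        g = tuple(float(v) for v in self.g)
        tau = tuple(float(v) for v in self.tau)
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "g_inf", float(self.g_inf))
        if len(g) != len(tau):
            raise ValueError("g and tau must have equal length")
        if any(v < 0 for v in g) or self.g_inf < 0:
            raise ValueError("Prony coefficients must be non-negative")
        if any(t <= 0 for t in tau):
            raise ValueError("tau values must be strictly positive")
        total = self.g_inf + sum(g)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"g_inf + sum(g) must equal 1, got {total!r}")

    @classmethod
    def from_g(cls, g: Sequence[float], tau: Sequence[float]) -> "PronySeries":
        """Build a series deriving ``g_inf`` from the normalization constraint."""
        g = tuple(float(v) for v in g)
        return cls(g=g, tau=tuple(float(v) for v in tau), g_inf=1.0 - sum(g))

    def sorted(self) -> "PronySeries":
        """Return a copy with tau strictly decreasing (export order)."""
        order = np.argsort(self.tau)[::-1]
        return PronySeries(
            g=tuple(self.g[i] for i in order),
            tau=tuple(self.tau[i] for i in order),
            g_inf=self.g_inf,
        )


#: Four-term brain-parenchyma relaxation spectrum on the decade tau grid
#: (g_inf = 1 - sum(g) = 0.0337), fitted to literature tan(delta) data.
BRAIN_PRONY = PronySeries.from_g(
    g=(0.8619, 0.0383, 0.0412, 0.0249), tau=DEFAULT_TAU_GRID_MS
)


@dataclass(frozen=True)
class MaterialCard:
    """Complete Ogden-QLV material definition for one part.

    Units follow the solver convention kg / mm / ms: density in kg/mm^3,
    moduli in kPa.  ``reference`` selects whether ``ogden.mu`` describes the
    quasi-static (long-term) or the instantaneous response.
    """

    ogden: OgdenParams
    prony: PronySeries
    density: float = 1.123e-6
    poisson: float = 0.499999
    reference: Reference = "quasi_static"

    def __post_init__(self) -> None:
        if not (self.density > 0):
            raise ValueError("density must be positive")
        if not (0 < self.poisson < 0.5):
            raise ValueError("poisson must lie in (0, 0.5)")
        if self.reference not in ("quasi_static", "instantaneous"):
            raise ValueError(f"unknown reference {self.reference!r}")

    def to_dict(self) -> dict:
        p = self.prony.sorted()
        return {
            "mu_kpa": self.ogden.mu,
            "alpha": self.ogden.alpha,
            "g": list(p.g),
            "tau_ms": list(p.tau),
            "g_inf": p.g_inf,
            "density_kg_mm3": self.density,
            "poisson": self.poisson,
            "reference": self.reference,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialCard":
        return cls(
            ogden=OgdenParams(mu=d["mu_kpa"], alpha=d["alpha"]),
            prony=PronySeries(g=tuple(d["g"]), tau=tuple(d["tau_ms"]), g_inf=d["g_inf"]),
            density=d.get("density_kg_mm3", 1.123e-6),
            poisson=d.get("poisson", 0.499999),
            reference=d.get("reference", "quasi_static"),
        )


def infinitesimal_shear_modulus(ogden: OgdenParams) -> float:
    """Initial slope of the shear stress-strain curve, mu0 = mu * alpha / 2 (kPa)."""
    return 0.5 * ogden.mu * ogden.alpha


def mu_from_infinitesimal(mu0: float, alpha: float) -> float:
    """Invert mu0 = mu*alpha/2 for the Ogden coefficient: mu = 2*mu0/alpha."""
    if alpha == 0:
        raise ValueError("alpha must be nonzero")
    if not (mu0 > 0):
        raise ValueError("mu0 must be positive")
    return 2.0 * mu0 / alpha


def _uniaxial_nominal_stress(lam: np.ndarray, ogden: OgdenParams) -> np.ndarray:
    # Incompressible uniaxial: l1 = lam, l2 = l3 = lam**-0.5.
    # Nominal stress T = dW/dlam with the pressure eliminated.
    a = ogden.alpha
    return ogden.mu * (lam ** (a - 1.0) - lam ** (-a / 2.0 - 1.0))


def _simple_shear_stress(gamma: np.ndarray, ogden: OgdenParams) -> np.ndarray:
    # Plane simple shear of amount gamma: in-plane principal stretches l1,
    # 1/l1 with l1 - 1/l1 = gamma, out-of-plane stretch 1.
    a = ogden.alpha
    root = np.sqrt(gamma * gamma + 4.0)
    l1 = 0.5 * (gamma + root)
    return ogden.mu * (l1**a - l1 ** (-a)) / root


def instantaneous_stress(
    mode: Mode, strain: float | np.ndarray, ogden: OgdenParams
) -> float | np.ndarray:
    """Instantaneous (elastic) nominal stress in kPa.

    ``strain`` is the engineering strain (tension/compression) or the shear
    amount gamma (simple shear).  Compression uses lam = 1 - |strain| on the
    same uniaxial formula, so compressive stress comes out negative.
    """
    eps = np.asarray(strain, dtype=float)
    scalar = eps.ndim == 0
    eps = np.atleast_1d(eps)
    if mode == "tension":
        if np.any(eps <= -1):
            raise ValueError("tension strain must exceed -1")
        out = _uniaxial_nominal_stress(1.0 + eps, ogden)
    elif mode == "compression":
        if np.any(np.abs(eps) >= 1):
            raise ValueError("|compression strain| must be below 1")
        out = _uniaxial_nominal_stress(1.0 - np.abs(eps), ogden)
    elif mode == "simple_shear":
        out = _simple_shear_stress(eps, ogden)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(out[0]) if scalar else out


def reduced_relaxation(t: float | np.ndarray, prony: PronySeries) -> float | np.ndarray:
    """g(t) = g_inf + sum_i g_i exp(-t / tau_i); t in ms, t >= 0."""
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("t must be non-negative")
    scalar = tt.ndim == 0
    tt = np.atleast_1d(tt)[..., None]
    g = np.asarray(prony.g)
    tau = np.asarray(prony.tau)
    out = prony.g_inf + np.sum(g * np.exp(-tt / tau), axis=-1)
    return float(out[0]) if scalar else out


def _normalized_complex(freq: np.ndarray, prony: PronySeries) -> tuple[np.ndarray, np.ndarray]:
    # s_i = omega * tau_i with omega in rad/s and tau in ms.
    s = 2.0 * np.pi * freq[..., None] * (np.asarray(prony.tau) * 1e-3)
    g = np.asarray(prony.g)
    storage = prony.g_inf + np.sum(g * s * s / (1.0 + s * s), axis=-1)
    loss = np.sum(g * s / (1.0 + s * s), axis=-1)
    return storage, loss


def complex_modulus(
    freq: float | np.ndarray,
    ogden: OgdenParams,
    prony: PronySeries,
    reference: Reference = "quasi_static",
) -> tuple[float | np.ndarray, float | np.ndarray]:
    """Storage and loss shear moduli (kPa) at frequency ``freq`` (Hz).

    The normalized spectrum is scaled by mu0 under the instantaneous
    convention, or by mu0 / g_inf under the quasi-static convention so the
    long-term (f -> 0) modulus equals mu0.
    """
    f = np.asarray(freq, dtype=float)
    if np.any(f <= 0):
        raise ValueError("freq must be positive")
    scalar = f.ndim == 0
    f = np.atleast_1d(f)
    storage, loss = _normalized_complex(f, prony)
    mu0 = infinitesimal_shear_modulus(ogden)
    if reference == "quasi_static":
        if prony.g_inf <= 0:
            raise ValueError("quasi_static reference requires g_inf > 0")
        scale = mu0 / prony.g_inf
    elif reference == "instantaneous":
        scale = mu0
    else:
        raise ValueError(f"unknown reference {reference!r}")
    sp, lo = scale * storage, scale * loss
    if scalar:
        return float(sp[0]), float(lo[0])
    return sp, lo


def tan_delta(freq: float | np.ndarray, prony: PronySeries) -> float | np.ndarray:
    """Loss/storage ratio of the normalized spectrum; independent of stiffness."""
    f = np.asarray(freq, dtype=float)
    if np.any(f <= 0):
        raise ValueError("freq must be positive")
    scalar = f.ndim == 0
    f = np.atleast_1d(f)
    storage, loss = _normalized_complex(f, prony)
    out = loss / storage
    return float(out[0]) if scalar else out


def fit_prony(
    data: Iterable[tuple[float, float]] | np.ndarray,
    n_terms: int = 4,
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID_MS,
) -> PronySeries:
    """Fit Prony coefficients to (frequency Hz, tan delta) data by least squares.

    Time constants are fixed to ``tau_grid`` (first ``n_terms`` entries); only
    the coefficients ``g_i`` are optimized, subject to g_i >= 0 and
    g_inf + sum(g_i) = 1.  A bounded linear solve of the equivalent form
    ``loss - tan_delta * storage = 0`` seeds an SLSQP polish of the true
    squared tan-delta residual.
    """
    arr = np.asarray(list(data) if not isinstance(data, np.ndarray) else data, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise PronyFitError("data must be a non-empty list of (freq_hz, tan_delta)")
    tau = tuple(float(t) for t in tau_grid[:n_terms])
    if len(tau) != n_terms:
        raise PronyFitError(f"tau_grid provides {len(tau)} values; {n_terms} required")
    if arr.shape[0] < n_terms + 1:
        raise PronyFitError(f"need at least {n_terms + 1} data points, got {arr.shape[0]}")
    freqs, td = arr[:, 0], arr[:, 1]
    if np.any(freqs <= 0):
        raise PronyFitError("frequencies must be positive")

    s = 2.0 * np.pi * freqs[:, None] * (np.asarray(tau) * 1e-3)
    S = s * s / (1.0 + s * s)  # per-term storage kernel
    L = s / (1.0 + s * s)      # per-term loss kernel

    # Linearized residual: loss(g) - td * storage(g) with g_inf = 1 - sum(g)
    # is linear in g:  sum_i g_i (L_i - td*S_i + td) - td.
    A = L - td[:, None] * S + td[:, None]
    res = optimize.lsq_linear(A, td, bounds=(0.0, 1.0))
    g0 = np.clip(res.x, 0.0, 1.0)
    if g0.sum() > 1.0:
        g0 = g0 / g0.sum()

    def objective(g: np.ndarray) -> float:
        g_inf = 1.0 - g.sum()
        storage = g_inf + S @ g
        loss = L @ g
        return float(np.sum((loss / storage - td) ** 2))

    result = optimize.minimize(
        objective,
        g0,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n_terms,
        constraints=[{"type": "ineq", "fun": lambda g: 1.0 - g.sum()}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    if not result.success and objective(result.x) > objective(g0):
        result.x = g0
    g = np.clip(result.x, 0.0, None)
    if g.sum() > 1.0:
        g = g / g.sum()
    return PronySeries.from_g(tuple(g), tau)


def _effective_prony(card: MaterialCard) -> tuple[float, np.ndarray, np.ndarray]:
    """Relaxation function ghat used by the hereditary integral.

    Returns (ghat_inf, ghat_coeffs, tau).  quasi_static rescales by 1/g_inf so
    ghat(inf) = 1 and the long-term response equals the static Ogden curve.
    """
    p = card.prony
    g = np.asarray(p.g)
    tau = np.asarray(p.tau)
    if card.reference == "quasi_static":
        if p.g_inf <= 0:
            raise ValueError("quasi_static reference requires g_inf > 0")
        return 1.0, g / p.g_inf, tau
    return p.g_inf, g, tau


def qlv_stress_history(
    strain_history: np.ndarray,
    mode: Mode,
    card: MaterialCard,
    dt: float,
) -> np.ndarray:
    """QLV stress response (kPa) to a uniformly sampled strain history.

    Evaluates the hereditary integral
    ``sigma(t) = int_0^t ghat(t - s) dT^e/ds ds`` with the exact recursive
    exponential (internal variable) update per Prony term, assuming the
    elastic stress is piecewise linear within each step.
    """
    eps = np.asarray(strain_history, dtype=float)
    if eps.ndim != 1:
        raise ValueError("strain_history must be 1-D")
    if not (dt > 0):
        raise ValueError("dt must be positive")
    if eps.size and eps[0] != 0.0:
        raise ValueError("strain history must start at 0")
    te = np.atleast_1d(instantaneous_stress(mode, eps, card.ogden))
    ghat_inf, ghat, tau = _effective_prony(card)
    decay = np.exp(-dt / tau)
    # Exact step response of each internal variable to a linear ramp of T^e.
    ramp = ghat * (tau / dt) * (1.0 - decay)
    sigma = np.empty_like(te)
    sigma[0] = (ghat_inf + ghat.sum()) * te[0]
    h = np.zeros_like(tau)
    for n in range(1, te.size):
        h = decay * h + ramp * (te[n] - te[n - 1])
        sigma[n] = ghat_inf * te[n] + h.sum()
    return sigma


def single_element_curves(
    card: MaterialCard,
    mode: Mode,
    rate: float,
    max_strain: float = 0.5,
    n_points: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Constant engineering-strain-rate loading curve (strain, stress kPa).

    ``rate`` is in 1/s (the characterization protocol uses 0.5, 5 and 30 1/s
    to 50% strain).  The ramp is integrated with the QLV hereditary integral
    on a fine internal grid and sampled at ``n_points`` strain levels.
    """
    if not (rate > 0):
        raise ValueError("rate must be positive")
    if n_points < 100:
        raise ValueError("n_points must be at least 100")
    rate_ms = rate * 1e-3
    t_end = max_strain / rate_ms
    # Internal grid fine enough for the nonlinearity of T^e within a step;
    # the exponential update itself is exact for piecewise-linear T^e.
    n_steps = max(20 * n_points, 2000)
    t = np.linspace(0.0, t_end, n_steps + 1)
    eps = rate_ms * t
    sigma = qlv_stress_history(eps, mode, card, dt=t[1] - t[0])
    idx = np.linspace(0, n_steps, n_points).round().astype(int)
    return eps[idx], sigma[idx]
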