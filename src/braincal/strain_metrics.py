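"""Voxelwise maximum principal strain (MPS) and deformation summaries.

Given a voxelized displacement field u (mm) on a grid with known spacing,
the displacement gradient is formed by central differences (one-sided at
mask edges), the deformation gradient is F = I + grad(u), and the
Green-Lagrange strain is E = (F^T F - I) / 2.  MPS is the largest
eigenvalue of E (a rigid rotation therefore produces exactly zero strain);
an alternative "stretch" definition, largest principal stretch minus one,
is available behind a flag.  Summary metrics follow the tagged-MRI
comparison protocol: the 95th-percentile MPS (MPS-95, linear-interpolation
percentile) and the volume fraction of voxels exceeding a strain threshold
(default 2%), globally and per labelled region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "DisplacementField",
    "StrainField",
    "strain_from_displacement",
    "mps95",
    "exceedance_fraction",
    "regional_summary",
]


@dataclass
class DisplacementField:
    """(X, Y, Z, 3) displacement vectors in mm with a boolean brain mask."""

    u: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.u.ndim != 4 or self.u.shape[-1] != 3:
            raise ValueError("u must have shape (X, Y, Z, 3)")
        if self.mask.shape != self.u.shape[:3]:
            raise ValueError("mask shape must match the grid")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.u[self.mask])):
            raise ValueError("displacements must be finite inside the mask")


@dataclass
class StrainField:
    """Voxelwise MPS values; NaN outside the valid mask."""

    mps: np.ndarray
    mask: np.ndarray
    definition: str = "green_lagrange"


def _masked_derivative(comp: np.ndarray, mask: np.ndarray, axis: int, h: float):
    """d(comp)/dx_axis with central differences where both neighbours are in
    the mask, one-sided where only one is, and invalid where neither is."""
    plus = np.roll(comp, -1, axis=axis)
    minus = np.roll(comp, 1, axis=axis)
    mplus = np.roll(mask, -1, axis=axis)
    mminus = np.roll(mask, 1, axis=axis)
    # roll wraps around; kill the wrapped boundary slices
    idx_lo = [slice(None)] * comp.ndim
    idx_lo[axis] = -1
    mplus[tuple(idx_lo[: mask.ndim])] = False
    idx_hi = [slice(None)] * comp.ndim
    idx_hi[axis] = 0
    mminus[tuple(idx_hi[: mask.ndim])] = False

    d = np.full(comp.shape, np.nan)
    both = mask & mplus & mminus
    only_plus = mask & mplus & ~mminus
    only_minus = mask & ~mplus & mminus
    d[both] = (plus[both] - minus[both]) / (2.0 * h)
    d[only_plus] = (plus[only_plus] - comp[only_plus]) / h
    d[only_minus] = (comp[only_minus] - minus[only_minus]) / h
    valid = both | only_plus | only_minus
    return d, valid


def strain_from_displacement(
    field: DisplacementField,
    definition: Literal["green_lagrange", "stretch"] = "green_lagrange",
) -> StrainField:
    """Compute voxelwise maximum principal strain from a displacement field.

    Voxels whose gradient cannot be formed along every axis (isolated or
    fully edge-bounded in some direction) are excluded from the output mask.
    """
    mask = field.mask
    for axis in range(3):
        if mask.any() and mask.sum(axis=axis).max() < 3:
            raise ValueError("mask must span at least 3 voxels in every direction")
    if not mask.any():
        raise ValueError("empty mask")

    grad = np.full(mask.shape + (3, 3), np.nan)
    valid = mask.copy()
    for a in range(3):        # displacement component
        for b in range(3):    # derivative direction
            d, ok = _masked_derivative(field.u[..., a], mask, b, field.spacing[b])
            grad[..., a, b] = d
            valid &= ok

    F = grad[valid] + np.eye(3)
    C = np.einsum("...ba,...bc->...ac", F, F)  # F^T F
    eig = np.linalg.eigvalsh(C)[..., -1]
    if definition == "green_lagrange":
        mps_vals = 0.5 * (eig - 1.0)
    elif definition == "stretch":
        mps_vals = np.sqrt(np.maximum(eig, 0.0)) - 1.0
    else:
        raise ValueError(f"unknown definition {definition!r}")

    out = np.full(mask.shape, np.nan)
    out[valid] = mps_vals
    return StrainField(mps=out, mask=valid, definition=definition)


def mps95(strain: StrainField, mask: np.ndarray | None = None) -> float:
    """95th percentile of MPS over the mask (linear interpolation)."""
    m = strain.mask if mask is None else (strain.mask & np.asarray(mask, dtype=bool))
    vals = strain.mps[m]
    if vals.size == 0:
        raise ValueError("empty mask")
    if vals.size < 20:
        raise ValueError("need at least 20 voxels for MPS-95")
    return float(np.percentile(vals, 95.0))


def exceedance_fraction(
    strain: StrainField, threshold: float = 0.02, mask: np.ndarray | None = None
) -> float:
    """Fraction of masked voxels with MPS strictly above the threshold."""
    m = strain.mask if mask is None else (strain.mask & np.asarray(mask, dtype=bool))
    vals = strain.mps[m]
    if vals.size == 0:
        raise ValueError("empty mask")
    return float(np.mean(vals > threshold))


def regional_summary(
    strain: StrainField, labels: np.ndarray, region_names: dict[int, str] | None = None
) -> dict[str, dict[str, float]]:
    """MPS-95 and 2%-exceedance fraction per labelled region plus global.

    ``labels`` is an integer volume aligned with the strain grid (0 = outside
    any region)."""
    labels = np.asarray(labels)
    if labels.shape != strain.mps.shape:
        raise ValueError("label grid does not align with the strain grid")
    out: dict[str, dict[str, float]] = {
        "global": {
            "mps95": mps95(strain),
            "exceedance_2pct": exceedance_fraction(strain),
        }
    }
    for lab in np.unique(labels[labels > 0]):
        name = (region_names or {}).get(int(lab), f"region_{int(lab)}")
        m = labels == lab
        if not (strain.mask & m).any():
            continue
        out[name] = {
            "mps95": mps95(strain, m),
            "exceedance_2pct": exceedance_fraction(strain, mask=m),
        }
    return out
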