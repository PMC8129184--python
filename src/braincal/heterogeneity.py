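"""Relative-stiffness binning of MRE volumes and heterogeneous card sets.

An MRE stiffness volume (kPa per voxel) is truncated between a low and a
high percentile (defaults 15/98: the low tail is contaminated by CSF-like
values, the high tail by inversion edge artifacts), normalized by the median
of the retained values, and grouped into ``n_bins`` equal-width relative-
stiffness bins.  Each bin centre ``gamma_i`` then scales a shared Ogden-QLV
material: ``mu_i = 2 * gamma_i * mu0_med / alpha``, which preserves the
relative *infinitesimal* stiffness gradient for any alpha (at alpha = 2 it
reduces to the linear relation ``mu_i = gamma_i * mu_med``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .constitutive import (
    MaterialCard,
    OgdenParams,
    PronySeries,
    Reference,
    infinitesimal_shear_modulus,
    mu_from_infinitesimal,
)

__all__ = [
    "StiffnessVolume",
    "RelativeStiffnessLabels",
    "MaterialCardSet",
    "truncate_and_normalize",
    "bin_relative_stiffness",
    "build_material_cards",
    "read_volume",
    "write_volume",
    "write_labels",
    "read_labels",
]


@dataclass
class StiffnessVolume:
    """Voxelwise stiffness in kPa; absent (non-brain) voxels are NaN."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.affine = np.asarray(self.affine, dtype=float)
        present = self.mask
        if np.any(self.values[present] < 0):
            raise ValueError("stiffness values must be non-negative")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class RelativeStiffnessLabels:
    """Bin labels 1..n_bins per brain voxel (0 outside the brain)."""

    labels: np.ndarray
    centers: tuple[float, ...]
    truncation: tuple[float, float]
    median_kpa: float
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        c = np.asarray(self.centers, dtype=float)
        if c.size == 0 or np.any(np.diff(c) <= 0):
            raise ValueError("centers must be non-empty and strictly increasing")
        self.centers = tuple(c)

    @property
    def n_bins(self) -> int:
        return len(self.centers)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def gamma_of(self, labels: np.ndarray) -> np.ndarray:
        """Map a label array (1-based; 0 allowed outside) to gamma values."""
        lut = np.concatenate([[np.nan], np.asarray(self.centers)])
        return lut[np.asarray(labels, dtype=int)]


@dataclass
class MaterialCardSet:
    """Per-bin Ogden-QLV cards sharing one relaxation spectrum.

    Card i satisfies infinitesimal_shear_modulus(card.ogden) = gamma_i * mu0_med.
    """

    mu0_med: float
    alpha: float
    centers: tuple[float, ...]
    prony: PronySeries
    cards: tuple[MaterialCard, ...]

    def card_for_label(self, label: int) -> MaterialCard:
        return self.cards[label - 1]

    def to_dict(self) -> dict:
        return {
            "mu0_med_kpa": self.mu0_med,
            "alpha": self.alpha,
            "centers": list(self.centers),
            "cards": [c.to_dict() for c in self.cards],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MaterialCardSet":
        d = json.loads(Path(path).read_text())
        cards = tuple(MaterialCard.from_dict(c) for c in d["cards"])
        return cls(
            mu0_med=d["mu0_med_kpa"],
            alpha=d["alpha"],
            centers=tuple(d["centers"]),
            prony=cards[0].prony,
            cards=cards,
        )


def truncate_and_normalize(
    vol: StiffnessVolume, low_pct: float = 15.0, high_pct: float = 98.0
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Truncate a stiffness volume between percentiles and normalize by the
    retained median.

    Returns ``(normalized, median_kpa, excluded_low, excluded_high)`` where
    ``normalized`` divides *all* present voxels by the median of the values in
    the half-open percentile band (low, high]; the excluded masks mark voxels
    outside the band for extreme-bin assignment downstream.  Percentiles use
    linear interpolation between order statistics.
    """
    present = vol.mask
    vals = vol.values[present]
    if vals.size < 100:
        raise ValueError(f"need at least 100 present voxels, got {vals.size}")
    if np.all(vals == vals.flat[0]):
        raise ValueError("degenerate (constant) stiffness volume")
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("percentiles must satisfy 0 <= low < high <= 100")
    lo = np.percentile(vals, low_pct)
    hi = np.percentile(vals, high_pct)
    retained = vals[(vals > lo) & (vals <= hi)]
    if retained.size == 0:
        raise ValueError("truncation retained no voxels")
    median = float(np.median(retained))
    normalized = vol.values / median
    excluded_low = present & (vol.values <= lo)
    excluded_high = present & (vol.values > hi)
    return normalized, median, excluded_low, excluded_high


def bin_relative_stiffness(
    normalized: np.ndarray,
    excluded_low: np.ndarray,
    excluded_high: np.ndarray,
    n_bins: int = 10,
    median_kpa: float = np.nan,
    truncation: tuple[float, float] = (15.0, 98.0),
    affine: np.ndarray | None = None,
) -> RelativeStiffnessLabels:
    """Bin normalized stiffness into ``n_bins`` equal-width relative bins.

    Bins span [min, max] of the *retained* normalized values with midpoint
    centres.  Values on a bin edge go to the upper bin; the retained maximum
    goes to bin ``n_bins``.  Excluded-low voxels are assigned to bin 1 and
    excluded-high voxels to bin ``n_bins``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    normalized = np.asarray(normalized, dtype=float)
    present = np.isfinite(normalized)
    retained_mask = present & ~excluded_low & ~excluded_high
    rvals = normalized[retained_mask]
    if rvals.size == 0:
        raise ValueError("no retained voxels to bin")
    lo, hi = float(rvals.min()), float(rvals.max())
    if hi <= lo:
        raise ValueError("retained normalized values are constant; cannot bin")
    width = (hi - lo) / n_bins
    centers = tuple(lo + (i + 0.5) * width for i in range(n_bins))
    labels = np.zeros(normalized.shape, dtype=np.int16)
    # floor puts an edge value in the upper bin (half-open convention);
    # the clip sends the retained maximum to bin n_bins.
    idx = np.floor((normalized[retained_mask] - lo) / width).astype(int) + 1
    labels[retained_mask] = np.clip(idx, 1, n_bins)
    labels[excluded_low] = 1
    labels[excluded_high] = n_bins
    return RelativeStiffnessLabels(
        labels=labels,
        centers=centers,
        truncation=truncation,
        median_kpa=median_kpa,
        affine=affine,
    )


def build_material_cards(
    labels: RelativeStiffnessLabels | Sequence[float],
    mu0_med: float,
    alpha: float,
    prony: PronySeries,
    density: float = 1.123e-6,
    poisson: float = 0.499999,
    reference: Reference = "quasi_static",
) -> MaterialCardSet:
    """Build one Ogden-QLV card per relative-stiffness centre.

    ``mu_i = 2 * gamma_i * mu0_med / alpha`` so every card's infinitesimal
    shear modulus equals ``gamma_i * mu0_med`` regardless of alpha.
    """
    if isinstance(labels, RelativeStiffnessLabels):
        centers = labels.centers
    else:
        centers = tuple(float(c) for c in labels)
    if len(centers) == 0:
        raise ValueError("empty centers")
    cards = tuple(
        MaterialCard(
            ogden=OgdenParams(mu=mu_from_infinitesimal(g * mu0_med, alpha), alpha=alpha),
            prony=prony,
            density=density,
            poisson=poisson,
            reference=reference,
        )
        for g in centers
    )
    for g, card in zip(centers, cards):
        assert abs(infinitesimal_shear_modulus(card.ogden) - g * mu0_med) < 1e-9
    return MaterialCardSet(
        mu0_med=mu0_med, alpha=alpha, centers=centers, prony=prony, cards=cards
    )


def read_volume(path: str | Path, absent: str = "nan") -> StiffnessVolume:
    """Read a NIfTI stiffness volume.

    ``absent`` states how non-brain voxels are encoded in the file: "nan"
    keeps NaN voxels absent; "zero" additionally treats exact zeros as absent.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if absent == "zero":
        data = np.where(data == 0, np.nan, data)
    elif absent != "nan":
        raise ValueError(f"absent must be 'nan' or 'zero', got {absent!r}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return StiffnessVolume(values=data, spacing=spacing, affine=np.asarray(img.affine))


def write_volume(vol: StiffnessVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.values.astype(np.float64), vol.affine), str(path))


def write_labels(labels: RelativeStiffnessLabels, path: str | Path) -> None:
    """Write the label volume (0 outside the brain) plus a JSON sidecar with
    centres, truncation and median."""
    affine = labels.affine if labels.affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(labels.labels.astype(np.int16), affine), str(path))
    meta = {
        "centers": list(labels.centers),
        "truncation": list(labels.truncation),
        "median_kpa": labels.median_kpa,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_labels(path: str | Path) -> RelativeStiffnessLabels:
    img = nib.load(str(path))
    meta = json.loads(Path(str(path) + ".json").read_text())
    return RelativeStiffnessLabels(
        labels=np.asarray(img.get_fdata()).astype(np.int16),
        centers=tuple(meta["centers"]),
        truncation=tuple(meta["truncation"]),
        median_kpa=meta["median_kpa"],
        affine=np.asarray(img.affine),
    )
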