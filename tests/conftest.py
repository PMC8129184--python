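"""Shared fixtures: small synthetic volumes, phantoms and bundles.

Everything is generated programmatically at session scope so the expensive
phantom simulations are reused across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from braincal.constitutive import BRAIN_PRONY
from braincal.heterogeneity import (
    bin_relative_stiffness,
    build_material_cards,
    truncate_and_normalize,
)
from braincal.phantom import (
    build_phantom,
    generate_synthetic_mre,
    make_dataset,
    make_pulse,
)


@pytest.fixture(scope="session")
def mre_volume():
    return generate_synthetic_mre(shape=(32, 32, 32), spacing=4.5, seed=42)


@pytest.fixture(scope="session")
def labels(mre_volume):
    normalized, median, lo, hi = truncate_and_normalize(mre_volume)
    return bin_relative_stiffness(
        normalized, lo, hi, n_bins=10, median_kpa=median, affine=mre_volume.affine
    )


@pytest.fixture(scope="session")
def small_phantom(labels):
    return build_phantom(labels, n_nodes=48, n_receivers=6, seed=7)


@pytest.fixture(scope="session")
def brain_cards(labels):
    return build_material_cards(labels.centers, 1.125, 6.67, BRAIN_PRONY)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Two-subject, two-case zero-noise bundle on small phantoms."""
    cases = [make_pulse("axial", 20, 60), make_pulse("coronal", 40, 30)]
    return make_dataset(
        n_subjects=2, n_nodes=48, n_receivers=6, cases=cases, seed=33,
        mre_shape=(24, 24, 24), mre_spacing=6.0,
    )
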