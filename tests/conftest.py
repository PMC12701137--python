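import numpy as np
import pytest

from leukoselect.synthetic import (
    CellGeometry,
    StainParams,
    SyntheticDatasetSpec,
)

NOISELESS_STAIN = StainParams(color_jitter_sd=0.0, pixel_noise_sd=0.0)


def noiseless_geometry(radius=30.0, nucleus_fraction=0.55):
    """Deterministic disk-cell geometry: no size jitter, no irregularity, no grain."""
    return CellGeometry(
        cell_radius_mean=radius,
        cell_radius_sd=0.0,
        nucleus_fraction_mean=nucleus_fraction,
        nucleus_fraction_sd=0.0,
        boundary_irregularity=0.0,
        texture_grain=0.0,
    )


def make_table(seed, n=60, d=4, n_informative=2, shift=2.0):
    """Two-class feature table: first columns carry a class mean shift, rest pure noise."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(0.0, 1.0, size=(n, d))
    X[y == 1, :n_informative] += shift
    return X, y


@pytest.fixture
def small_spec():
    return SyntheticDatasetSpec(n_healthy=6, n_blast=6, seed=11)
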