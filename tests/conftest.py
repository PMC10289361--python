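"""Shared fixtures: synthetic phantoms at the sizes the experiments use.

The expensive 101-stone phantom and its cross-validation reports are
session-scoped so the parameter-recovery and method-comparison tests share
one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import lithoseg as ls
from lithoseg.optimize import MeasurementCache, cross_validate


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom() -> ls.PhantomDataset:
    """12 stones, default imaging conditions."""
    return ls.make_phantom(12, ls.PhantomConfig(seed=11))


@pytest.fixture(scope="session")
def small_cache(small_phantom) -> MeasurementCache:
    return MeasurementCache(small_phantom.volume, small_phantom.annotations)


@pytest.fixture(scope="session")
def clean_sphere_volume():
    """A blur-free, noise-free rendered sphere: radius 5 mm, 600 HU, 0.7 mm grid."""
    cfg = ls.PhantomConfig(psf_sigma_mm=0.0, noise_sd_hu=0.0, seed=0)
    shape = ls.StoneShape(np.full(3, 10.5), np.full(3, 5.0))
    occ = ls.rasterize_partial_volume(shape, (31, 31, 31), np.full(3, 0.7), np.zeros(3), 8)
    vol = ls.render_ct(occ, cfg, 600.0)
    ann = ls.Annotation("sphere", (10.5, 10.5, 10.5), 7.5)
    return vol, ann, shape


@pytest.fixture(scope="session")
def phantom101() -> ls.PhantomDataset:
    """The full-scale synthetic experiment: 101 stones, default conditions."""
    return ls.make_phantom(101, ls.PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def cache101(phantom101) -> MeasurementCache:
    return MeasurementCache(phantom101.volume, phantom101.annotations)


@pytest.fixture(scope="session")
def cv_reports(phantom101, cache101):
    """100-repetition 80/21 cross-validation reports for all four methods."""
    return {
        method: cross_validate(
            method, cache101, phantom101.raters,
            n_reps=100, train_size=80, val_size=21, seed=1,
        )
        for method in ls.Method
    }
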