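"""Shared fixtures: phantoms and ROI geometry generated at test time."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import lesioncbf as lc
from lesioncbf.core_io import SphereRoi, sphere_mask
from lesioncbf.qc import DEFAULT_ACC_CENTER, DEFAULT_ROI_RADIUS_MM

#: air-sphere centre used throughout the tests: a corner pocket of the grid
#: well outside the brain ellipsoid
AIR_CENTER = (44.0, -44.0, 44.0)


@pytest.fixture(scope="session")
def default_phantom() -> lc.Phantom:
    """One default-noise subject reused by read-only tests."""
    return lc.make_phantom(lc.PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def quiet_phantom() -> lc.Phantom:
    """Zero-noise, zero-excursion subject for exact-inversion checks."""
    spec = lc.PhantomSpec(
        seed=11, noise_sd_asl=0.0, noise_sd_anat=0.0, n_excursion_frames=0
    )
    return lc.make_phantom(spec)


@pytest.fixture(scope="session")
def qc_rois(default_phantom):
    """ACC tissue sphere, air sphere, and their GM/WM intersections."""
    ph = default_phantom
    acc = sphere_mask(ph.truth.cbf, SphereRoi(DEFAULT_ACC_CENTER, DEFAULT_ROI_RADIUS_MM), "acc")
    air = sphere_mask(ph.truth.cbf, SphereRoi(AIR_CENTER, DEFAULT_ROI_RADIUS_MM), "air")
    return {
        "acc": acc,
        "air": air,
        "acc_gm": acc.intersect(ph.tissues["GM"], "acc_gm"),
        "acc_wm": acc.intersect(ph.tissues["WM"], "acc_wm"),
    }


def small_spec(**overrides) -> lc.PhantomSpec:
    """A fast 32^3 @ 4 mm spec for tests that only need coarse geometry."""
    base = dict(
        shape=(32, 32, 32),
        spacing=(4.0, 4.0, 4.0),
        n_pairs=8,
        n_excursion_frames=0,
        seed=0,
    )
    base.update(overrides)
    return lc.PhantomSpec(**base)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
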