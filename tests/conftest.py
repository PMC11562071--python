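"""Shared fixtures: small toy datasets and fitted models, built once per
session so the expensive pieces (sampling, fitting) are reused."""

import numpy as np
import pytest

import pipchain as pc
from pipchain.chemio import DatasetFile
from pipchain.fitting import FitConfig, fit_model


@pytest.fixture(scope="session")
def butane_zigzag():
    return pc.build_alkane(4)


@pytest.fixture(scope="session")
def butane_toyff():
    return pc.ToyFF(4)


def butane_whole_fragment():
    """Whole-molecule 'fragment' for butane under the methyl/methylene
    permutation scheme: carbons as singletons, H classes 3/2/2/3."""
    return pc.FragmentSpec(
        center=0,
        atoms=[0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13],
        symmetry=(1, 1, 1, 1, 3, 2, 2, 3))


@pytest.fixture(scope="session")
def butane_dataset():
    """Thermal + near-minimum displacement frames of toy butane."""
    ds1 = pc.sample_dataset(pc.DEFAULT_TOY_PARAMS, 4, pc.SamplerConfig(
        mode="thermal_md", n_frames=1500, seed=11, ceiling_cm=30_000))
    ds2 = pc.sample_dataset(pc.DEFAULT_TOY_PARAMS, 4, pc.SamplerConfig(
        mode="mode_displacement", n_frames=800, seed=12,
        displacement_scale=1.0, ceiling_cm=30_000))
    return DatasetFile(ds1.geometries + ds2.geometries)


@pytest.fixture(scope="session")
def butane_fragmented_model(butane_dataset):
    """Order-2 whole-molecule fragmented model fitted to toy butane."""
    skeleton = pc.build_union_basis([butane_whole_fragment()], 2,
                                    pc.MorseSpec(2.0), 14)
    fitted, report = fit_model(skeleton, butane_dataset,
                               FitConfig(seed=0, energy_ceiling_cm=30_000))
    return fitted


@pytest.fixture(scope="session")
def butane_model_minimum(butane_fragmented_model, butane_zigzag):
    """The fitted model's own (verified) minimum, found by mode-following
    descent from the zigzag construction."""
    from pipchain import units
    from pipchain.pes_eval import find_minimum
    masses = [units.ATOMIC_MASS_AMU[e] for e in butane_zigzag.elements]
    gm, e, freqs = find_minimum(butane_fragmented_model, butane_zigzag,
                                masses, tol=1e-8)
    assert freqs[0] > 0
    return gm


def random_butane_geometries(n, scale=0.1, seed=0):
    g0 = pc.build_alkane(4)
    rng = np.random.default_rng(seed)
    return [g0.with_coords(g0.coords + rng.normal(scale=scale,
                                                  size=g0.coords.size))
            for _ in range(n)]
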