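"""Shared fixtures: small phantoms, studies and the desk-scale experiment.

Everything is generated programmatically; expensive artifacts are
session-scoped so independent tests can share them.
"""

import numpy as np
import pytest

from osteoplan import drr, metrics as mx, nets, phantom as ph
from osteoplan import pipeline as pp


@pytest.fixture(scope="session")
def leg_vol_7_8():
    """Single right leg, 7 deg varus / 8 deg slope, 2 mm voxels."""
    params = ph.PhantomParams(varus_angle=7.0, slope_angle=8.0,
                              voxel_spacing=2.0)
    vol, truth = ph.generate_leg(params, "right")
    return params, vol, truth


@pytest.fixture(scope="session")
def prox_tibia_mesh_7_8(leg_vol_7_8):
    params, vol, _ = leg_vol_7_8
    lv = nets.LabelVolume(
        (vol.labels == ph.PROX_TIBIA_RIGHT).astype(np.uint8),
        vol.spacing, vol.origin)
    mesh = mx.marching_cubes(lv)
    landmarks = {k: v.copy() for k, v in vol.landmarks["right"].items()}
    return mesh, landmarks


@pytest.fixture(scope="session")
def subject_vol():
    """Two-leg standing subject at 4 mm voxels (default parameters)."""
    p = ph.PhantomParams(voxel_spacing=4.0)
    vol, truths = ph.generate_subject(p, p.replace(varus_angle=7.0))
    return vol, truths


@pytest.fixture(scope="session")
def small_studies():
    """Eight-patient study set with recon targets, desk detector."""
    cfg = pp.PipelineConfig(seed=11, n_patients=8)
    cohort, studies, split = pp.build_desk_cohort(cfg)
    return cfg, cohort, studies, split


@pytest.fixture(scope="session")
def desk_results():
    """The 40-phantom desk-scale learning experiment (shared; ~10 min)."""
    cfg = pp.PipelineConfig(seed=0, n_patients=40)
    return pp.run_desk_experiment(cfg, with_separation_net=True)
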