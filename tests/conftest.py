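import numpy as np
import pytest

import fcortools as ft
from fcortools.config import GroupConfig, PipelineConfig, SynthConfig


@pytest.fixture
def small_grid():
    return ft.make_box_grid((10, 10, 8), voxel_size_mm=3.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory):
    """A planted-hub cohort at study scale, run through the full pipeline.

    Three connector hubs, each mixing 2 of 6 networks, patient-group
    attenuation 0.5, n = 20/20 on a ~5000-voxel grid. Shared by the hub
    recovery, hub-level statistics and classification checks.
    """
    cfg = PipelineConfig(seed=0, outdir=str(tmp_path_factory.mktemp("recovery")))
    cfg.synth = SynthConfig(dims=(17, 17, 17), n_networks=6, n_hubs=3,
                            networks_per_hub=2, n_per_group=20, frames=193,
                            attenuation=0.5)
    cfg.group = GroupConfig(n_permutations=500)
    return ft.run_pipeline(cfg)


def match_hubs_to_planted(result, max_dist_mm=6.0):
    """Map found hubs to planted hubs within ``max_dist_mm`` of the centre."""
    grid = result.grid
    planted = {h.label: grid.voxel_to_world(grid.mask_coords[h.members[0]])[0]
               for h in result.truth.hubs}
    matches = {}
    for hub in result.hubs:
        dists = {lab: float(np.linalg.norm(hub.peak_world_mm - mm))
                 for lab, mm in planted.items()}
        lab, d = min(dists.items(), key=lambda kv: kv[1])
        if d <= max_dist_mm:
            matches[hub.label] = (lab, d)
    return planted, matches
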