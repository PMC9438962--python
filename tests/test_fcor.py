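import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fcortools as ft
from fcortools.core import BoldSeries, RSNTemplateSet
from fcortools.errors import DegenerateSeedError, ParameterError


def brute_force_bh(p, q):
    """Literal step-up loop, independent of the vectorized implementation."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= q * i / m:
            k = i
    reject = np.zeros(m, bool)
    if k:
        reject = p <= p[order[k - 1]]
    return reject


class TestBhFdr:
    def test_worked_example_one_rejection(self):
        assert ft.bh_fdr(np.array([0.001, 0.2, 0.9]), 0.01).tolist() == \
            [True, False, False]

    def test_all_ones_none_rejected(self):
        assert not ft.bh_fdr(np.ones(7), 0.05).any()

    def test_all_zeros_all_rejected(self):
        assert ft.bh_fdr(np.zeros(7), 0.05).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ParameterError):
            ft.bh_fdr(np.array([0.1, 1.5]), 0.05)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20),
           st.sampled_from([0.01, 0.05, 0.2]))
    def test_matches_brute_force_step_up(self, p, q):
        p = np.asarray(p)
        assert np.array_equal(ft.bh_fdr(p, q), brute_force_bh(p, q))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            mine = ft.bh_fdr(p, 0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(mine, ref)


def _series(data):
    return BoldSeries(data=data, tr_s=2.0)


class TestSeedFcMap:
    def test_identical_copy_voxel_connected(self, rng):
        x = rng.standard_normal(60)
        data = np.vstack([x, x.copy(), rng.standard_normal((30, 60))])
        fc = ft.seed_fc_map(_series(data), seed=0, q=0.01)
        assert fc.connected[0] and fc.connected[1]

    def test_anticorrelated_voxel_excluded(self, rng):
        x = rng.standard_normal(60)
        data = np.vstack([x, -x, rng.standard_normal((30, 60))])
        fc = ft.seed_fc_map(_series(data), seed=0, q=0.01)
        assert not fc.connected[1]
        assert fc.r_values[1] == pytest.approx(-1.0)

    def test_constant_seed_rejected(self, rng):
        data = np.vstack([np.ones(40), rng.standard_normal((5, 40))])
        with pytest.raises(DegenerateSeedError):
            ft.seed_fc_map(_series(data), seed=0)


def _templates(grid, masks_cols, names=None):
    names = names or [f"t{i}" for i in range(masks_cols.shape[1])]
    return RSNTemplateSet(grid, names, masks_cols)


class TestFcorValue:
    def test_analytic_cases(self, small_grid, rng):
        V = small_grid.n_voxels
        connected = np.zeros(V, bool)
        connected[:200] = True
        fc = ft.FcMap(seed=0, connected=connected, q_threshold=0.01)
        full = np.zeros(V, bool); full[:50] = True          # inside the map
        none = np.zeros(V, bool); none[300:350] = True       # outside the map
        part = np.zeros(V, bool); part[150:350] = True       # 50 of 200 overlap
        assert ft.fcor_value(fc, full) == 1.0
        assert ft.fcor_value(fc, none) == 0.0
        assert ft.fcor_value(fc, part) == 0.25

    def test_monotone_in_fc_map_inclusion(self, small_grid, rng):
        V = small_grid.n_voxels
        inner = rng.random(V) < 0.2
        outer = inner | (rng.random(V) < 0.2)
        tpl = rng.random(V) < 0.3
        f1 = ft.fcor_value(ft.FcMap(0, inner, 0.01), tpl)
        f2 = ft.fcor_value(ft.FcMap(0, outer, 0.01), tpl)
        assert f1 <= f2

    def test_empty_template_rejected(self, small_grid):
        fc = ft.FcMap(0, np.ones(small_grid.n_voxels, bool), 0.01)
        with pytest.raises(ParameterError):
            ft.fcor_value(fc, np.zeros(small_grid.n_voxels, bool))


@pytest.fixture(scope="module")
def tiny():
    grid = ft.make_box_grid((6, 6, 8))  # 288 voxels
    rng = np.random.default_rng(77)
    data = rng.standard_normal((grid.n_voxels, 40))
    # plant a few correlated blocks so FC maps are non-trivial
    base = rng.standard_normal(40)
    data[:30] += 1.5 * base
    data[100:130] += 1.5 * rng.standard_normal(40)
    masks = np.zeros((grid.n_voxels, 3), bool)
    masks[:40, 0] = True
    masks[90:140, 1] = True
    masks[200:, 2] = True
    return grid, _series(data), _templates(grid, masks)


class TestWholeBrainFcor:
    def test_equals_per_voxel_seed_loop(self, tiny):
        grid, bold, templates = tiny
        maps = ft.whole_brain_fcor(bold, templates, q=0.01, dtype=np.float64)
        for v in range(0, grid.n_voxels, 7):
            fc = ft.seed_fc_map(bold, v, q=0.01)
            for j, name in enumerate(templates.names):
                assert maps.raw[v, j] == pytest.approx(
                    ft.fcor_value(fc, templates.masks[:, j]), abs=1e-12)

    def test_chunk_size_invariance(self, tiny):
        _, bold, templates = tiny
        a = ft.whole_brain_fcor(bold, templates, chunk_size=1)
        b = ft.whole_brain_fcor(bold, templates, chunk_size=512)
        assert np.array_equal(a.raw, b.raw)
        assert np.array_equal(a.z, b.z)

    def test_z_fields_standardized(self, tiny):
        _, bold, templates = tiny
        maps = ft.whole_brain_fcor(bold, templates)
        assert np.abs(maps.z.mean(axis=0)).max() < 1e-6
        assert np.abs(maps.z.std(axis=0) - 1).max() < 1e-6

    def test_template_order_permutation_permutes_columns(self, tiny):
        _, bold, templates = tiny
        maps = ft.whole_brain_fcor(bold, templates)
        perm = templates.reordered(templates.names[::-1])
        maps_p = ft.whole_brain_fcor(bold, perm)
        assert np.array_equal(maps_p.raw, maps.raw[:, ::-1])

    def test_constant_voxels_get_zero_fcor(self, tiny):
        grid, bold, templates = tiny
        data = bold.data.copy()
        data[5] = 3.0  # constant voxel
        maps = ft.whole_brain_fcor(_series(data), templates)
        assert maps.constant_voxels[5]
        assert np.all(maps.raw[5] == 0)

    def test_noise_free_network_voxels_reach_full_overlap(self):
        grid = ft.make_box_grid((8, 8, 6))
        truth = ft.make_sim_truth(grid, n_networks=2, n_hubs=1, seed=1,
                                  noise_sd=0.0)
        bold, _ = ft.make_subject(truth, "control", frames=96, seed=2,
                                  drift_amp=0, motion_artifact_amp=0,
                                  nuisance_amp=0)
        maps = ft.whole_brain_fcor(bold, truth.templates, q=0.01)
        for j in range(2):
            inside = truth.templates.masks[:, j]
            assert maps.raw[inside, j].min() >= 0.999


class TestRoiProfile:
    def test_profile_peaks_at_seeded_network(self):
        grid = ft.make_box_grid((8, 8, 6))
        truth = ft.make_sim_truth(grid, n_networks=3, n_hubs=1, seed=3,
                                  networks_per_hub=2, noise_sd=0.8)
        bolds = [ft.make_subject(truth, "control", frames=96, seed=s)[0]
                 for s in range(6)]
        roi = np.nonzero(truth.templates.masks[:, 1])[0][:5]
        profile = ft.roi_fc_profile(bolds, roi, truth.templates, grid,
                                    n_permutations=200, seed=0)
        assert max(profile, key=profile.get) == "net02"

    def test_pure_noise_cohort_flat_profile(self, small_grid, rng):
        masks = np.zeros((small_grid.n_voxels, 2), bool)
        masks[:60, 0] = True
        masks[60:130, 1] = True
        templates = _templates(small_grid, masks)
        bolds = [_series(rng.standard_normal((small_grid.n_voxels, 80)))
                 for _ in range(6)]
        profile = ft.roi_fc_profile(bolds, np.arange(400, 410), templates,
                                    small_grid, n_permutations=200, seed=1)
        assert max(profile.values()) <= 0.05

    def test_single_subject_rejected(self, small_grid, rng):
        masks = np.zeros((small_grid.n_voxels, 1), bool)
        masks[:10, 0] = True
        with pytest.raises(ParameterError):
            ft.roi_fc_profile([_series(rng.standard_normal((small_grid.n_voxels, 60)))],
                              np.arange(5), _templates(small_grid, masks),
                              small_grid)
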