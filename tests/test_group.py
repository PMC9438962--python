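import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fcortools as ft
from fcortools import group_inference as gi
from fcortools.errors import DesignError, ParameterError


def _design(n_per_group, rng=None, covariates=True):
    n = 2 * n_per_group
    rng = rng or np.random.default_rng(0)
    group = np.r_[np.zeros(n_per_group), np.ones(n_per_group)]
    if covariates:
        cov = rng.standard_normal((n, 2))
        cov -= cov.mean(0)
        names = ["age", "mean_fd"]
    else:
        cov, names = np.empty((n, 0)), []
    return gi.GroupDesign(group=group, covariates=cov, covariate_names=names,
                          subject_ids=[f"s{i}" for i in range(n)])


class TestGlm:
    def test_matches_textbook_pooled_t_without_covariates(self, rng):
        design = _design(12, covariates=False)
        maps = rng.standard_normal((24, 5))
        stat = ft.glm_group_t(maps, design, "patient>control")
        for v in range(5):
            ref = stats.ttest_ind(maps[12:, v], maps[:12, v], equal_var=True)
            assert stat.t[v] == pytest.approx(ref.statistic, rel=1e-10)
        assert stat.df == 22

    def test_matches_full_ols_with_covariates(self, rng):
        import statsmodels.api as sm
        design = _design(10, rng)
        maps = rng.standard_normal((20, 3))
        stat = ft.glm_group_t(maps, design, "patient>control")
        X = design.matrix()
        for v in range(3):
            fit = sm.OLS(maps[:, v], X).fit()
            assert stat.t[v] == pytest.approx(fit.tvalues[1], rel=1e-8)
        assert stat.df == 20 - 4

    def test_contrast_antisymmetry(self, rng):
        design = _design(8, rng)
        maps = rng.standard_normal((16, 30))
        a = ft.glm_group_t(maps, design, "control>patient")
        b = ft.glm_group_t(maps, design, "patient>control")
        assert np.allclose(a.t, -b.t)

    def test_invariant_to_covariate_rescaling(self, rng):
        design = _design(9, rng)
        maps = rng.standard_normal((18, 10))
        a = ft.glm_group_t(maps, design, "control>patient")
        scaled = gi.GroupDesign(group=design.group,
                                covariates=design.covariates * [100.0, 0.01],
                                covariate_names=design.covariate_names,
                                subject_ids=design.subject_ids)
        b = ft.glm_group_t(maps, scaled, "control>patient")
        assert np.allclose(a.t, b.t)

    def test_null_t_centred_on_zero(self, rng):
        design = _design(40, covariates=False)
        maps = rng.standard_normal((80, 2000))
        stat = ft.glm_group_t(maps, design, "control>patient")
        assert abs(stat.t.mean()) < 0.05
        assert stat.t.std() == pytest.approx(1.0, abs=0.08)

    def test_collinear_design_names_offender(self, rng):
        n = 16
        group = np.r_[np.zeros(8), np.ones(8)]
        age = rng.standard_normal(n)
        cov = np.column_stack([age, 2.0 * age])  # exact collinearity
        design = gi.GroupDesign(group=group, covariates=cov - cov.mean(0),
                                covariate_names=["age", "age_times_two"],
                                subject_ids=[str(i) for i in range(n)])
        with pytest.raises(DesignError, match="age_times_two"):
            ft.glm_group_t(rng.standard_normal((n, 3)), design)

    def test_ledd_imputed_zero_for_controls(self):
        frame = pd.DataFrame({
            "subject_id": ["a", "b", "c", "d"],
            "group": ["control", "control", "patient", "patient"],
            "age": [60.0, 65.0, 62.0, 70.0],
            "sex": ["male", "female", "male", "female"],
            "mean_fd": [0.2, 0.25, 0.22, 0.3],
            "ledd": [np.nan, np.nan, 400.0, 600.0],
        })
        design = gi.GroupDesign.from_clinical(ft.ClinicalTable(frame))
        j = design.covariate_names.index("ledd")
        raw = design.covariates[:, j] + 250.0  # centred back
        assert np.allclose(raw[:2], 0.0)


class TestClusterFwe:
    def test_planted_blob_recovered_as_one_cluster(self, small_grid, rng):
        n = 15
        design = _design(n, rng)
        maps = rng.standard_normal((2 * n, small_grid.n_voxels))
        blob = np.arange(200, 230)  # 30 voxels, flat-index contiguous rows
        maps[n:, blob] += 2.0       # strong patient increase
        stat, cs = ft.cluster_fwe(maps, design, small_grid,
                                  direction="patient>control",
                                  n_permutations=300, seed=4)
        assert len(cs.clusters) == 1
        members = set(cs.clusters[0].members.tolist())
        assert set(blob.tolist()) <= members
        assert cs.clusters[0].peak_voxel in set(blob.tolist())
        # every member passes the cluster-defining threshold
        t_cdt = stats.t.isf(cs.cdt_p, stat.df)
        assert (stat.t[cs.clusters[0].members] >= t_cdt).all()

    def test_subthreshold_voxels_never_clustered(self, small_grid, rng):
        design = _design(10, rng)
        maps = rng.standard_normal((20, small_grid.n_voxels))
        stat, cs = ft.cluster_fwe(maps, design, small_grid,
                                  n_permutations=150, seed=2)
        t_cdt = stats.t.isf(cs.cdt_p, stat.df)
        for cl in cs.clusters:
            assert (stat.t[cl.members] >= t_cdt).all()

    def test_null_data_usually_yields_empty_set(self, small_grid, rng):
        design = _design(10, rng)
        hits = 0
        for seed in range(5):
            maps = np.random.default_rng(seed).standard_normal(
                (20, small_grid.n_voxels))
            _, cs = ft.cluster_fwe(maps, design, small_grid,
                                   n_permutations=200, seed=seed)
            hits += bool(cs.clusters)
        assert hits <= 1


class TestConjunctionAndHubs:
    def _cluster_set(self, members_list, n_voxels, direction="control>patient"):
        clusters = [gi.Cluster(members=np.asarray(m), size=len(m),
                               peak_voxel=int(m[0]), peak_value=5.0)
                    for m in members_list]
        return gi.ClusterSet(clusters=clusters, cdt_p=0.001, fwe_p=0.05,
                             critical_size=1, direction=direction)

    def test_counts_add_across_templates(self, small_grid):
        V = small_grid.n_voxels
        sets = {f"t{i}": self._cluster_set([[5, 6, 7]], V) for i in range(3)}
        sets["t3"] = self._cluster_set([[7, 8]], V)
        conj = ft.conjunction(sets, V, "control>patient")
        assert conj.counts[5] == 3 and conj.counts[7] == 4
        assert conj.counts.max() <= len(sets)

    def test_empty_sets_give_zero_map(self, small_grid):
        sets = {"a": self._cluster_set([], small_grid.n_voxels)}
        conj = ft.conjunction(sets, small_grid.n_voxels, "control>patient")
        assert not conj.counts.any()

    def test_mixed_directions_rejected(self, small_grid):
        V = small_grid.n_voxels
        sets = {"a": self._cluster_set([[1]], V, "control>patient"),
                "b": self._cluster_set([[2]], V, "patient>control")}
        with pytest.raises(ParameterError, match="direction"):
            ft.conjunction(sets, V, "control>patient")

    def test_single_component_single_hub(self, small_grid):
        counts = np.zeros(small_grid.n_voxels, int)
        counts[[300, 301, 302]] = [2, 9, 3]
        conj = gi.ConjunctionMap(counts=counts, direction="control>patient",
                                 n_templates=14)
        hubs = ft.find_hubs(conj, small_grid, top_k=5)
        assert len(hubs) == 1
        assert hubs[0].peak_voxel == 301
        assert hubs[0].n_networks == 9

    def test_equal_peaks_ranked_by_size(self, small_grid):
        counts = np.zeros(small_grid.n_voxels, int)
        big = np.arange(0, 40)        # 40-voxel component
        lone = np.array([600, 601, 602, 603, 604, 605, 606, 607, 608, 609])
        counts[big] = 3
        counts[lone] = 3
        conj = gi.ConjunctionMap(counts=counts, direction="control>patient",
                                 n_templates=14)
        hubs = ft.find_hubs(conj, small_grid, top_k=2)
        assert hubs[0].component_size == 40
        assert hubs[1].component_size == 10

    def test_no_multi_network_voxel_yields_empty_list(self, small_grid):
        counts = np.zeros(small_grid.n_voxels, int)
        counts[10] = 1
        conj = gi.ConjunctionMap(counts=counts, direction="control>patient",
                                 n_templates=14)
        assert ft.find_hubs(conj, small_grid) == []

    def test_hub_roi_is_sphere_within_mask(self, small_grid):
        counts = np.zeros(small_grid.n_voxels, int)
        counts[400:403] = 2
        conj = gi.ConjunctionMap(counts=counts, direction="control>patient",
                                 n_templates=14)
        hub = ft.find_hubs(conj, small_grid, radius_mm=3.0)[0]
        assert 1 <= hub.roi_voxels.size <= 7
        assert hub.peak_voxel in hub.roi_voxels.tolist()


class TestOneSample:
    def test_positive_mean_block_survives(self, small_grid, rng):
        maps = rng.standard_normal((12, small_grid.n_voxels))
        maps[:, 100:130] += 2.0
        cs = ft.one_sample_cluster_fwe(maps, small_grid, n_permutations=300,
                                       seed=0)
        surviving = cs.membership(small_grid.n_voxels)
        assert surviving[100:130].mean() > 0.9
        assert surviving.sum() < 100
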