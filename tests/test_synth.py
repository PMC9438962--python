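import numpy as np
import pytest
from scipy import ndimage, stats

import fcortools as ft
from fcortools.core import VolumeGrid
from fcortools.errors import CapacityError, ParameterError


class TestTemplates:
    def test_fourteen_disjoint_contiguous_templates(self):
        grid = ft.make_box_grid((24, 28, 24))
        tpl = ft.make_templates(grid, 14, seed=7)
        assert tpl.n_templates == 14
        # pairwise disjoint: no voxel belongs to two templates
        assert tpl.masks.sum(axis=1).max() <= 1
        # sizes within a factor of 3
        assert tpl.sizes.max() <= 3 * tpl.sizes.min()
        # spatial contiguity of every template (26-neighbourhood)
        for i in range(14):
            vol = grid.unmask(tpl.masks[:, i].astype(np.uint8)) > 0
            _, n = ndimage.label(vol, ndimage.generate_binary_structure(3, 3))
            assert n == 1

    def test_two_isolated_blobs_become_one_template_each(self):
        mask = np.zeros((8, 4, 4), bool)
        mask[:3] = True     # blob A
        mask[5:] = True     # blob B, separated by an empty plane
        grid = VolumeGrid((8, 4, 4), np.diag([3.0, 3, 3, 1]), mask)
        tpl = ft.make_templates(grid, 2, seed=0)
        for i in range(2):
            vol = grid.unmask(tpl.masks[:, i].astype(np.uint8)) > 0
            sides = {int(c[0] < 4) for c in np.argwhere(vol)}
            assert len(sides) == 1  # each template stays inside one blob

    def test_capacity_error_on_tiny_mask(self):
        grid = ft.make_box_grid((2, 2, 2))
        with pytest.raises(CapacityError):
            ft.make_templates(grid, 4, seed=0)


class TestTimecourses:
    def test_band_power_and_decorrelation(self):
        x = ft.make_network_timecourses(3, frames=193, tr_s=2.5,
                                        band=(0.01, 0.1), seed=5)
        assert x.shape == (193, 3)
        assert np.allclose(x.mean(0), 0, atol=1e-9)
        assert np.allclose(x.std(0), 1, atol=1e-9)
        # periodogram oracle: fraction of spectral power inside the band
        freqs = np.fft.rfftfreq(193, 2.5)
        power = np.abs(np.fft.rfft(x, axis=0)) ** 2
        inband = power[(freqs >= 0.01) & (freqs <= 0.1)].sum(0) / power.sum(0)
        assert (inband >= 0.9).all()
        r = np.corrcoef(x.T)
        off = r[np.triu_indices(3, 1)]
        assert (np.abs(off) < 0.3).all()

    def test_same_seed_reproduces(self):
        a = ft.make_network_timecourses(4, 96, seed=3)
        b = ft.make_network_timecourses(4, 96, seed=3)
        assert np.array_equal(a, b)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            ft.make_network_timecourses(2, 96, tr_s=2.5, band=(0.01, 0.3))


@pytest.fixture(scope="module")
def truth():
    grid = ft.make_box_grid((12, 12, 10))
    return ft.make_sim_truth(grid, n_networks=4, n_hubs=2, seed=2, noise_sd=0.0)


class TestSubject:
    def test_noise_free_template_voxel_matches_its_network(self, truth):
        bold, _ = ft.make_subject(truth, "control", frames=96, seed=0,
                                  drift_amp=0, motion_artifact_amp=0,
                                  nuisance_amp=0)
        courses = None  # regenerate the network courses from the same seed path
        rng = np.random.default_rng(0)
        courses = ft.make_network_timecourses(
            truth.templates.n_templates, 96, 2.5, (0.01, 0.1),
            seed=int(rng.integers(2 ** 31)))
        v = int(np.nonzero(truth.templates.masks[:, 1])[0][0])
        r = np.corrcoef(bold.data[v], courses[:, 1])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_hub_voxel_equal_weights_gives_inverse_sqrt2_correlation(self):
        # noise-free closed form: r = a / sqrt(a^2 + a^2) = 1/sqrt(2)
        grid = ft.make_box_grid((12, 12, 10))
        tr = ft.make_sim_truth(grid, n_networks=4, n_hubs=1, seed=4,
                               noise_sd=0.0, hub_weight=0.7)
        bold, _ = ft.make_subject(tr, "control", frames=193, seed=1,
                                  drift_amp=0, motion_artifact_amp=0,
                                  nuisance_amp=0)
        rng = np.random.default_rng(1)
        courses = ft.make_network_timecourses(4, 193, 2.5, (0.01, 0.1),
                                              seed=int(rng.integers(2 ** 31)))
        hub = tr.hubs[0]
        v = int(hub.members[0])
        for net in hub.networks:
            j = tr.templates.names.index(net)
            r = np.corrcoef(bold.data[v], courses[:, j])[0, 1]
            # the two band-limited courses are only approximately orthogonal
            assert r == pytest.approx(1 / np.sqrt(2), abs=0.08)

    def test_full_attenuation_decouples_hub_from_network(self, truth):
        tr = ft.make_sim_truth(truth.grid, n_networks=4, n_hubs=1, seed=4,
                               noise_sd=1.0, attenuation=0.0)
        bold, nuis = ft.make_subject(tr, "patient", frames=193, seed=6,
                                     severity=1.0, drift_amp=0,
                                     motion_artifact_amp=0, nuisance_amp=0)
        hub = tr.hubs[0]
        net_idx = tr.templates.names.index(hub.networks[0])
        tpl_mean = bold.data[tr.templates.masks[:, net_idx]].mean(0)
        r = np.corrcoef(bold.data[int(hub.members[0])], tpl_mean)[0, 1]
        assert abs(r) < 0.2

    def test_unknown_group_rejected(self, truth):
        with pytest.raises(ParameterError, match="group"):
            ft.make_subject(truth, "case", frames=96, seed=0)

    def test_motion_traces_realistic_mean_fd(self, truth):
        fds = []
        for seed in range(6):
            bold, _ = ft.make_subject(truth, "control", frames=193, seed=seed)
            fds.append(ft.mean_fd(bold.motion))
        assert 0.08 < float(np.mean(fds)) < 0.35


class TestCohort:
    def test_zero_clinical_effect_equalizes_motor_scores(self):
        grid = ft.make_box_grid((10, 10, 8))
        tr = ft.make_sim_truth(grid, n_networks=3, n_hubs=1, seed=0,
                               networks_per_hub=2, clinical_effect=0.0)
        _, clinical, _ = ft.make_cohort(tr, n_per_group=30, frames=64, seed=9)
        pats = clinical.frame[clinical.frame.group == "patient"]
        items = [c for c in clinical.updrs_columns()]
        totals = pats[items].sum(axis=1).to_numpy(float)
        # with no planted effect the item totals are low-rate Poisson noise
        assert totals.mean() < 3.0

    def test_manifest_records_planted_structure(self):
        grid = ft.make_box_grid((10, 10, 8))
        tr = ft.make_sim_truth(grid, n_networks=3, n_hubs=1, seed=0)
        bolds, clinical, manifest = ft.make_cohort(tr, 3, frames=64, seed=1)
        assert len(bolds) == 6
        assert set(manifest["templates"]) == set(tr.templates.names)
        assert manifest["hubs"][0]["networks"] == list(tr.hubs[0].networks)
        assert len(manifest["subjects"]) == 6
        assert all(s["deficit"] == 0 for s in manifest["subjects"][:3])

    def test_same_seed_bitwise_identical_cohort(self):
        grid = ft.make_box_grid((8, 8, 6))
        tr = ft.make_sim_truth(grid, n_networks=2, n_hubs=1, seed=0)
        a, ca, _ = ft.make_cohort(tr, 2, frames=64, seed=5)
        b, cb, _ = ft.make_cohort(tr, 2, frames=64, seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x.data, y.data)
            assert np.array_equal(x.motion, y.motion)
        assert ca.frame.equals(cb.frame)

    def test_null_cohort_voxelwise_rejection_rate_nominal(self):
        """With attenuation 1 everywhere the group contrast is null, so
        voxel-wise one-sided tests at alpha reject at about alpha."""
        grid = ft.make_box_grid((10, 10, 8))
        tr = ft.make_sim_truth(grid, n_networks=3, n_hubs=1, seed=3,
                               networks_per_hub=2, attenuation=1.0)
        rates = []
        for seed in (21, 22, 23):
            bolds, clinical, _ = ft.make_cohort(tr, 8, frames=96, seed=seed)
            from fcortools.config import PipelineConfig
            cfg = PipelineConfig()
            cleaned = [ft.pipeline.clean_subject(b, cfg) for b in bolds]
            maps = [ft.whole_brain_fcor(b, tr.templates) for b in cleaned]
            design = ft.GroupDesign.from_clinical(clinical)
            z = np.stack([m.z_map("net01") for m in maps])
            stat = ft.glm_group_t(z, design, "control>patient")
            crit = stats.t.isf(0.05, stat.df)
            rates.append(float((stat.t >= crit).mean()))
        assert 0.01 < float(np.mean(rates)) < 0.12
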