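"""Monte-Carlo calibration suites for the inferential machinery.

These functions re-run the pipeline's statistical path on synthetic null (or
parametrically varied) cohorts and return empirical operating
characteristics: the family-wise rejection rate of the permutation
cluster-extent test under a null cohort, the false-discovery behaviour of the
per-seed BH threshold, and the response of the FCOR statistic to the planted
mixing weight.
"""

from __future__ import annotations

import numpy as np

from . import synth
from .config import PipelineConfig
from .core import BoldSeries
from .fcor import seed_fc_map, whole_brain_fcor
from .group_inference import GroupDesign, cluster_fwe
from .pipeline import clean_subject, make_box_grid


def cluster_fwe_null_rejection_rate(
        n_reps: int = 100, n_per_group: int = 12, dims=(14, 14, 12),
        frames: int = 96, n_networks: int = 3, n_permutations: int = 500,
        cdt_p: float = 0.001, fwe_p: float = 0.05,
        smooth_fwhm_mm: float = 6.0, noise_sd: float = 5.0,
        seed: int = 0) -> float:
    """Family-wise rejection rate of the cluster-extent test on null cohorts.

    Every repetition draws a fresh cohort with attenuation fixed at 1 (so
    patients and controls share one distribution), runs cleaning, whole-brain
    FCOR and the covariate-adjusted group contrast on one template's z maps,
    and records whether any cluster survives. A calibrated test rejects in
    about ``fwe_p`` of repetitions.

    The null cohorts are spatially smoothed (as the inputs of a cluster-extent
    analysis are in practice): on unsmoothed fields the max-cluster-size null
    collapses onto a few small integers and the attained level falls well
    below nominal, which is a property of the statistic, not of this
    implementation.
    """
    grid = make_box_grid(dims)
    # noise is scaled up to compensate for the smoothing kernel (which
    # shrinks white-noise SD about five-fold), keeping per-voxel SNR in the
    # regime where the maps carry rich spatial variation
    truth = synth.make_sim_truth(grid, n_networks=n_networks, n_hubs=1,
                                 networks_per_hub=2, attenuation=1.0,
                                 noise_sd=noise_sd, seed=seed)
    cfg = PipelineConfig(seed=seed)
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(2 * n_reps)
    rejections = 0
    for rep in range(n_reps):
        cohort_seed = int(rep_seeds[2 * rep].generate_state(1)[0] % (2 ** 31))
        perm_seed = int(rep_seeds[2 * rep + 1].generate_state(1)[0] % (2 ** 31))
        bolds, clinical, _ = synth.make_cohort(truth, n_per_group,
                                               frames=frames, seed=cohort_seed,
                                               smooth_fwhm_mm=smooth_fwhm_mm)
        maps = []
        for bold in bolds:
            cleaned = clean_subject(bold, cfg)
            maps.append(whole_brain_fcor(cleaned, truth.templates))
        z = np.stack([m.z_map(truth.templates.names[0]) for m in maps])
        design = GroupDesign.from_clinical(clinical)
        _, cs = cluster_fwe(z, design, grid, direction="control>patient",
                            cdt_p=cdt_p, fwe_p=fwe_p,
                            n_permutations=n_permutations, seed=perm_seed)
        rejections += bool(cs.clusters)
    return rejections / n_reps


def seed_fc_fdr_null_calibration(
        n_sims: int = 200, n_voxels: int = 1500, frames: int = 60,
        q: float = 0.01, seed: int = 0) -> dict:
    """False-discovery behaviour of a seed FC map under the global null.

    All voxels are independent white noise, so every connection besides the
    seed itself is false. Returns the mean false-discovery proportion over
    simulations and the count of simulations with any false connection; BH at
    level q keeps the mean FDP at or below about q.
    """
    rng = np.random.default_rng(seed)
    fdps = np.zeros(n_sims)
    any_false = 0
    for i in range(n_sims):
        data = rng.standard_normal((n_voxels, frames))
        fc = seed_fc_map(BoldSeries(data=data, tr_s=2.0), seed=0, q=q)
        n_disc = int(fc.connected.sum())
        n_false = n_disc - int(fc.connected[0])
        fdps[i] = n_false / n_disc if n_disc else 0.0
        any_false += n_false > 0
    return {"mean_fdp": float(fdps.mean()), "sims_with_false": int(any_false),
            "n_sims": n_sims}


def fcor_weight_curve(weights=(0.0, 0.25, 0.5, 0.75, 1.0),
                      n_replicates: int = 20, dims=(8, 8, 6),
                      frames: int = 193, noise_sd: float = 1.0,
                      companion_weight: float = 0.8,
                      seed: int = 0) -> np.ndarray:
    """Mean FCOR of a hub voxel against one network as its mixing weight grows.

    One probe voxel mixes ``a`` of network 1 plus a fixed companion weight of
    network 2; the rest of the grid carries the two templates. The returned
    per-weight means estimate E[FCOR(probe, template 1)], which is
    non-decreasing in ``a``.
    """
    grid = make_box_grid(dims)
    templates = synth.make_templates(grid, 2, seed=seed)
    free = ~templates.masks.any(axis=1)
    probe = int(np.nonzero(free)[0][0])
    mixing = np.zeros((grid.n_voxels, 2))
    mixing[templates.masks[:, 0], 0] = 1.0
    mixing[templates.masks[:, 1], 1] = 1.0
    rng = np.random.default_rng(seed)
    means = np.zeros(len(weights))
    for wi, a in enumerate(weights):
        mix = mixing.copy()
        mix[probe] = [a, companion_weight]
        vals = np.zeros(n_replicates)
        for rep in range(n_replicates):
            courses = synth.make_network_timecourses(
                2, frames, seed=int(rng.integers(2 ** 31)))
            data = mix @ courses.T + noise_sd * rng.standard_normal(
                (grid.n_voxels, frames))
            fc = seed_fc_map(BoldSeries(data=data, tr_s=2.5), probe, q=0.01)
            tpl = templates.masks[:, 0]
            vals[rep] = np.count_nonzero(fc.connected & tpl) / tpl.sum()
        means[wi] = vals.mean()
    return means
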