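"""End-to-end orchestration: cohort -> cleaning -> FCOR -> hubs -> clinical.

``run_pipeline`` executes every stage in memory and writes tables (TSV),
manifests (JSON) and, on request, NIfTI maps into the output directory.
Re-running with the same configuration and seed reproduces identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical_models, confounds, fcor, group_inference, hub_profiles, io, synth
from .config import PipelineConfig
from .core import BoldSeries, ClinicalTable, RSNTemplateSet, VolumeGrid
from .errors import ConfigError

log = logging.getLogger(__name__)


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:12]


def make_box_grid(dims, voxel_size_mm: float = 3.0) -> VolumeGrid:
    """An all-in-mask box grid with isotropic voxels, origin at the corner."""
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    return VolumeGrid(dims=tuple(dims), affine=affine,
                      mask=np.ones(tuple(dims), dtype=bool))


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline produced."""

    grid: VolumeGrid
    templates: RSNTemplateSet
    clinical: ClinicalTable
    fcor_maps: list = field(default_factory=list)
    hubs: list = field(default_factory=list)
    conjunctions: dict = field(default_factory=dict)
    cluster_sets: dict = field(default_factory=dict)
    features: pd.DataFrame | None = None
    ranksum: pd.DataFrame | None = None
    summary: dict = field(default_factory=dict)
    truth: synth.SimTruth | None = None
    manifest: dict | None = None


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def build_cohort(cfg: PipelineConfig):
    """Synthesize or load the cohort; returns (grid, templates, bolds,
    clinical, nuisance-by-subject, truth, manifest)."""
    if cfg.synth.enabled:
        s = cfg.synth
        grid = make_box_grid(s.dims, s.voxel_size_mm)
        truth = synth.make_sim_truth(
            grid, n_networks=s.n_networks, n_hubs=s.n_hubs,
            networks_per_hub=s.networks_per_hub,
            template_weight=s.template_weight, hub_weight=s.hub_weight,
            attenuation=s.attenuation, noise_sd=s.noise_sd,
            clinical_effect=s.clinical_effect, seed=cfg.seed)
        bolds, clinical, manifest = synth.make_cohort(
            truth, n_per_group=s.n_per_group, frames=s.frames, seed=cfg.seed,
            tr_s=s.tr_s, band=cfg.clean.band_hz, severity_sd=s.severity_sd,
            smooth_fwhm_mm=s.smooth_fwhm_mm)
        nuisance = {sid: manifest["nuisance"][sid] for sid in manifest["nuisance"]}
        return grid, truth.templates, bolds, clinical, nuisance, truth, manifest
    inp = cfg.inputs
    grid = io.read_mask(inp.mask)
    templates = io.read_templates(dict(inp.templates), grid)
    clinical = ClinicalTable.from_tsv(inp.clinical)
    motion_paths = list(inp.motion) or [None] * len(inp.bold)
    if len(motion_paths) != len(inp.bold):
        raise ConfigError("inputs.motion must match inputs.bold in length")
    bolds = [io.read_bold(p, grid, tr_s=inp.tr_s, motion_path=m)
             for p, m in zip(inp.bold, motion_paths)]
    return grid, templates, bolds, clinical, {}, None, None


def clean_subject(bold: BoldSeries, cfg: PipelineConfig,
                  nuisance: dict | None = None) -> BoldSeries:
    nuisance = nuisance or {}
    kwargs = {}
    if cfg.clean.use_tissue_signals and nuisance:
        kwargs = {k: np.asarray(nuisance[k]) for k in ("wm", "csf", "global")
                  if k in nuisance}
        if "global" in kwargs:
            kwargs["global_sig"] = kwargs.pop("global")
    conf = confounds.build_confounds(bold.motion, **kwargs)
    low, high = cfg.clean.band_hz
    cleaned = confounds.clean(bold, conf, low, high,
                              filter_design=cfg.clean.filter_design,
                              order=cfg.clean.order)
    log.info("cleaned %s: %d confounds, band %s Hz, data hash %s",
             bold.subject_id, conf.columns.shape[1], cfg.clean.band_hz,
             _hash_array(cleaned.data))
    return cleaned


def fcor_stage(cleaned: list[BoldSeries], templates: RSNTemplateSet,
               cfg: PipelineConfig) -> list[fcor.FcorMaps]:
    maps = []
    for bold in cleaned:
        m = fcor.whole_brain_fcor(bold, templates, q=cfg.fcor.fdr_q,
                                  sidedness=cfg.fcor.fdr_sidedness,
                                  chunk_size=cfg.fcor.chunk_size)
        maps.append(m)
    log.info("FCOR maps for %d subjects x %d templates (q=%g)",
             len(maps), templates.n_templates, cfg.fcor.fdr_q)
    return maps


def group_stage(fcor_maps, templates: RSNTemplateSet, clinical: ClinicalTable,
                grid: VolumeGrid, cfg: PipelineConfig):
    """Per-template directed contrasts, conjunctions and hub extraction."""
    design = group_inference.GroupDesign.from_clinical(clinical)
    zstacks = {
        name: np.stack([m.z_map(name) for m in fcor_maps])
        for name in templates.names
    }
    ss = np.random.SeedSequence(cfg.seed)
    perm_seeds = iter(s.generate_state(1)[0] % (2 ** 31)
                      for s in ss.spawn(2 * templates.n_templates))
    cluster_sets: dict[str, dict] = {}
    conjunctions = {}
    all_hubs = []
    for direction in cfg.group.directions:
        per_template = {}
        for name in templates.names:
            _, cs = group_inference.cluster_fwe(
                zstacks[name], design, grid, direction=direction,
                cdt_p=cfg.group.cdt_p, fwe_p=cfg.group.fwe_p,
                n_permutations=cfg.group.n_permutations,
                seed=int(next(perm_seeds)),
                connectivity=cfg.group.cluster_connectivity)
            per_template[name] = cs
        cluster_sets[direction] = per_template
        conj = group_inference.conjunction(per_template, grid.n_voxels, direction)
        conjunctions[direction] = conj
        all_hubs.extend(group_inference.find_hubs(
            conj, grid, top_k=cfg.group.top_k_hubs,
            radius_mm=cfg.group.hub_radius_mm,
            min_count=cfg.group.min_conjunction_count))
    # rank across directions and keep the overall top k
    all_hubs.sort(key=lambda h: (-h.n_networks, -h.component_size,
                                 tuple(h.peak_world_mm)))
    hubs = all_hubs[:cfg.group.top_k_hubs]
    for i, h in enumerate(hubs):
        h.label = f"hub{i + 1:02d}"
    return design, cluster_sets, conjunctions, hubs


def clinical_stage(features: pd.DataFrame, clinical: ClinicalTable,
                   cfg: PipelineConfig) -> dict:
    """Classification, PCA scoring and clinical associations."""
    out: dict = {}
    groups = clinical.frame.set_index("subject_id").loc[features.index, "group"]
    labels = groups.to_numpy()
    try:
        out["svm_accuracy_pct"] = clinical_models.svm_cv_accuracy(
            features, labels, c=cfg.clinical.svm_c, folds=cfg.clinical.cv_folds,
            seed=cfg.seed, standardize=cfg.clinical.standardize)
    except Exception as exc:  # fold infeasible for tiny smoke cohorts
        log.warning("classification skipped: %s", exc)
        out["svm_accuracy_pct"] = None
    scores = clinical_models.composite_scores(clinical)
    patient_feats = features.loc[labels == "patient"]
    assoc = {}
    if len(patient_feats) >= 3 and patient_feats.shape[1] >= 2 \
            and np.any(patient_feats.to_numpy() - patient_feats.to_numpy().mean(0)):
        loadings, comp_scores, var_frac = clinical_models.pca_first_component(
            patient_feats)
        out["pca_variance_fraction"] = var_frac
        merged = scores.set_index("subject_id").reindex(patient_feats.index)
        for target in ("updrs3_total", "tremor", "pigd"):
            y = merged[target].to_numpy(dtype=float)
            keep = ~np.isnan(y)
            if keep.sum() >= 3 and np.ptp(comp_scores[keep]) > 0 \
                    and np.ptp(y[keep]) > 0:
                r, p = clinical_models.pearson_assoc(comp_scores[keep], y[keep])
                assoc[target] = {"r": r, "p": p, "n": int(keep.sum())}
    out["pc1_associations"] = assoc
    return out


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig, outdir=None) -> PipelineResult:
    cfg.validate()
    outdir = Path(outdir if outdir is not None else cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")

    grid, templates, bolds, clinical, nuisance, truth, manifest = build_cohort(cfg)
    log.info("cohort: %d subjects, %d in-mask voxels, %d templates",
             len(bolds), grid.n_voxels, templates.n_templates)
    clinical.to_tsv(outdir / "clinical.tsv")
    if manifest is not None:
        (outdir / "truth_manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))

    cleaned = [clean_subject(b, cfg, nuisance.get(b.subject_id)) for b in bolds]
    fcor_maps = fcor_stage(cleaned, templates, cfg)
    if cfg.write_maps:
        mapdir = outdir / "fcor_maps"
        mapdir.mkdir(exist_ok=True)
        for m in fcor_maps:
            io.write_volume(grid, m.raw.astype(np.float32),
                            mapdir / f"{m.subject_id}_fcor.nii.gz")
        pd.DataFrame({"volume": range(templates.n_templates),
                      "template": templates.names}).to_csv(
            mapdir / "template_index.tsv", sep="\t", index=False)

    design, cluster_sets, conjunctions, hubs = group_stage(
        fcor_maps, templates, clinical, grid, cfg)
    group_inference.hubs_table(hubs).to_csv(outdir / "hubs.tsv", sep="\t",
                                            index=False, float_format="%.10g")
    if cfg.write_maps:
        for direction, conj in conjunctions.items():
            tag = direction.replace(">", "_gt_")
            io.write_volume(grid, conj.counts.astype(np.float32),
                            outdir / f"conjunction_{tag}.nii.gz")

    result = PipelineResult(grid=grid, templates=templates, clinical=clinical,
                            fcor_maps=fcor_maps, hubs=hubs,
                            conjunctions=conjunctions, cluster_sets=cluster_sets,
                            truth=truth, manifest=manifest)
    summary: dict = {
        "n_subjects": len(bolds),
        "n_voxels": grid.n_voxels,
        "templates": templates.names,
        "n_hubs": len(hubs),
        "critical_sizes": {
            d: {n: cs.critical_size for n, cs in per.items()}
            for d, per in cluster_sets.items()},
    }
    if hubs:
        features = hub_profiles.extract_hub_features(
            fcor_maps, hubs, use_z=cfg.hub_stats.use_z_features)
        features.to_csv(outdir / "hub_features.tsv", sep="\t",
                        float_format="%.10g")
        groups = clinical.frame.set_index("subject_id").loc[
            features.index, "group"].to_numpy()
        ranksum = hub_profiles.ranksum_by_network(features, groups,
                                                  q=cfg.hub_stats.fdr_q)
        ranksum.to_csv(outdir / "hub_ranksum.tsv", sep="\t", index=False,
                       float_format="%.10g")
        result.features = features
        result.ranksum = ranksum
        summary["n_features"] = int(features.shape[1])
        summary["n_significant_pairs"] = int(ranksum["significant"].sum())
        summary.update(clinical_stage(features, clinical, cfg))
    result.summary = summary
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                    sort_keys=True, default=str))
    return result
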