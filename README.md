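# fcortools

Voxel-wise connector-hub analysis of resting-state BOLD fMRI built around
the **functional connectivity overlap ratio (FCOR)** — for neuroimaging
researchers who want a tested, reproducible implementation of the full
analysis chain from confound-cleaned 4-D volumes to hub-level statistics,
classification and clinical association, with a synthetic-cohort generator
that plants ground truth for every stage.

## The statistic

For a seed voxel $v$, a whole-brain FC map is the set of voxels whose
Pearson correlation with $v$'s cleaned time course is positive and survives
Benjamini–Hochberg FDR control at $q<0.01$ across the brain. The FCOR of $v$
against a resting-state network (RSN) template $T_N$ is

$$\mathrm{FCOR}(v,N)=\frac{|\mathrm{FC\,map}(v)\cap T_N|}{|T_N|}\in[0,1],$$

the fraction of the network that is connected to the voxel. Whole-brain FCOR
maps (one per template, z-scored across the brain within subject) are
compared between groups voxel-wise (one-sided t with age, sex, head-motion
and medication covariates; cluster-extent FWE by permutation at CDT
$p=0.001$, FWEc $p<0.05$). Binarized per-template contrast maps are summed
into conjunction maps; peaks touching ≥ 2 networks define **connector
hubs**, whose mean FCOR per template (5 hubs × 14 templates = 70 features)
feeds rank-sum group comparisons (FDR $q<0.05$), a linear SVM (C = 1,
10-fold CV) and PCA-based clinical associations.

## Worked example

`examples/02_seed_fc_and_fcor.py` simulates one subject on a 12×12×10 grid
whose planted hub voxel mixes two of four networks, cleans the series
(24-parameter motion regression + tissue signals, 0.01–0.1 Hz band-pass) and
prints the hub seed's FCOR profile:

```
cleaned series: 1440 voxels x 193 frames; mean frame-wise displacement 0.197 mm

seed = hub voxel 674 (mixes ('net01', 'net02'))
FC map: 402 of 1440 voxels connected (positive r, BH-FDR q < 0.01)
  FCOR vs net01: 0.856 <- hub network
  FCOR vs net02: 0.994 <- hub network
  FCOR vs net03: 0.000
  FCOR vs net04: 0.094
```

The seed's FC map covers 86% and 99% of the two templates it actually
mixes and essentially none of the others — FCOR reads out network
membership voxel by voxel. `examples/04_summary_table_tests.py` shows the
pooled two-sample t from published group summary statistics:

```
age (years): t(196) = -0.29, p = 0.77
cognition (ACE-R): t(196) = -5.20, p = 4.9e-07
```

matched groups on age, strongly lower cognitive scores in patients. The
other examples run the cohort generator (`01`) and the full pipeline with
hub recovery, rank-sum tables and SVM accuracy (`03`).

A thin CLI wraps the same stages for shell use:

```bash
fcortools simulate --config cfg.yaml --out cohort/
fcortools clean    --config cfg.yaml --cohort cohort/ --out cleaned/
fcortools fcor     --config cfg.yaml --cohort cohort/ --cleaned cleaned/ --out maps/
fcortools run-all  --config cfg.yaml --seed 7
```

Every analysis threshold (FDR q, CDT p, FWE p, SVM C, folds, sphere radius,
band edges, permutations, connectivity) is a config key defaulting to the
reference protocol's value.

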