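# Methods

## The statistic

For a seed voxel $v$ with cleaned time course $x_v(t)$, the seed's functional
connectivity (FC) map is the set of in-mask voxels $u$ whose Pearson
correlation $r_{vu}$ is **positive** and survives Benjamini–Hochberg (BH)
false-discovery-rate control at level $q = 0.01$ across all in-mask voxels.
P-values come from the t-transform $t = r\sqrt{\mathrm{df}/(1-r^2)}$ with
$\mathrm{df} = T - 2$ for $T$ frames, two-sided by default (a one-sided
dialect is a config key; with the positivity rule the two differ only in the
effective level). Negative correlations are excluded throughout, the usual
practice when the global signal has been regressed. The seed itself
($r = 1$) is always part of its own map.

The functional connectivity overlap ratio against a binary network template
$T_N$ is

$$\mathrm{FCOR}(v, N) \;=\; \frac{|\,\mathrm{FC\ map}(v) \cap T_N\,|}{|T_N|}
\;\in\; [0, 1],$$

0 meaning no connection to the network and 1 that the entire template is
connected. Repeating over all seeds gives one whole-brain FCOR map per
template; each map is z-scored across the in-mask voxels *within subject* so
maps are comparable between participants. Group statistics consume the
z maps; hub-level feature extraction uses the raw $[0,1]$ maps, matching the
scale on which hub profiles are usually displayed (a config switch selects
z features instead).

### Fast exact BH over all seeds

Running BH per seed naively costs a sort of $V$ p-values for each of $V$
seeds. Because the two-sided p is strictly decreasing in $|r|$, the step-up
rule "reject the $k$ smallest p with $p_{(i)} \le qi/m$" is equivalent to
"reject the $k$ largest $|r|$ with $|r|_{(i)} \ge r_{\mathrm{crit}}(i)$",
where the critical ladder $r_{\mathrm{crit}}(i)$ depends only on $(m,
\mathrm{df}, q)$ and is computed once. The per-seed work is then one sort
plus a vectorised comparison, and the whole computation is chunked over
seeds (results are independent of chunk size). A test asserts exact
agreement with a literal per-voxel loop of the seed-map routine on a small
grid, and the BH routine itself is property-tested against a brute-force
step-up loop and an independent library implementation. Constant voxels get
FCOR 0 and a flag.

## Temporal cleaning

Nuisance regression uses the 24-parameter motion expansion — the six
rigid-body parameters, their backward-difference derivatives (first element
0), and the squares of both — plus, when available, white-matter, CSF and
global signals with their derivatives (30 columns). Residuals are ordinary
least squares with an intercept, so cleaned series are exactly mean-zero and
orthogonal to every confound column; rank-deficient designs fall back to the
pseudoinverse with a logged warning.

Band-pass filtering to 0.01–0.1 Hz follows regression (the conventional
sequence; a config key switches to a single simultaneous projection in which
the out-of-band Fourier components join the confound design). The default
filter is a zero-phase forward–backward order-2 Butterworth; an ideal
frequency-domain mask is available as a dialect and is also the basis of the
synthetic generator, so in that configuration the analysis band and the
simulated signal band coincide exactly. Finite-series zero-phase filtering
rings near the series edges; the residual sample mean this leaves is removed
so the mean-zero contract holds, and the pass/stop-band contract (retention
≥ 0.9 in band, ≤ 0.1 at twice the upper edge) refers to steady-state
behaviour away from the edges.

Degrees of freedom for the r-to-p transform are *not* reduced for the
confound regression ($\mathrm{df} = T-2$, logged, configurable): with ~30
regressors in ~193 frames the difference is small and this matches the
common seed-based practice.

Frame-wise displacement uses the Power formulation: per frame, the sum of
absolute backward differences of the three translations (mm) plus the three
rotations converted to arc length on a 50 mm sphere; its mean is the
head-motion covariate.

## Group inference and hub identification

Per template, subjects' z maps enter a voxel-wise OLS with intercept, group
indicator and centred covariates (age, sex, mean FD, LEDD; LEDD imputed 0
for controls, who take no medication). The directed group contrast is a
one-sided t; both directions (control>patient, patient>control) are
evaluated.

Cluster-extent family-wise error control is by permutation rather than
Gaussian random-field theory: the cluster-defining threshold is the
one-sided t quantile at $p = 0.001$; clusters are connected components
(26-neighbourhood by default, configurable to 6 or 18); the critical extent
is the smallest size $s$ whose permutation p-value
$(1 + \#\{\text{null max} \ge s\})/(1 + B) \le 0.05$ under $B$ group-label
permutations. Covariates are refit per permutation via the
Frisch–Waugh–Lovell identity (data residualised against covariates once,
only the permuted group column re-residualised), which is algebraically the
full-design refit — a test asserts equality of the t field with a
full-model OLS. The permutation route was chosen because it is
assumption-free and exactly testable by Monte-Carlo calibration at desk
scale; random-field cluster p-values are a non-goal. The one-sample variant
(used to verify hub connectivity profiles in controls) flips signs instead
of permuting labels.

Surviving clusters are binarised per template and summed into a conjunction
map per direction; a voxel's value counts the templates whose group
difference reaches it. Connector-hub candidates are connected components of
{count ≥ 2} ("multiple networks"); components are ranked by (peak count,
size) descending with a lexicographic world-coordinate tie-break, and each
of the top five gets a 3 mm spherical ROI at its peak (voxel centres within
the radius, boundary inclusive — 7 voxels for a voxel-centred peak on the
3 mm grid, clipped at mask edges).

Hub features are the per-subject mean raw FCOR of each hub ROI against each
template (5 × 14 = 70 features in the canonical configuration). Group
differences per (hub, template) pair use the two-sided Wilcoxon rank-sum
with midranks and tie correction; BH at $q = 0.05$ runs across the joint
family of all pairs (per-hub families are a config option; the family in use
is recorded on the result table).

## Clinical models

Tremor-dominant score = sum of MDS-UPDRS items 2.10, 3.15–3.18; PIGD = sum
of 2.12, 2.13, 3.10–3.12; Part-III total sums all available 3.x items. Any
missing constituent flags the score missing and the patient drops out of
associations, mirroring the exclusion rule of incomplete motor scores.

Classification is a linear soft-margin SVM with $C = 1$ under stratified
10-fold cross-validation (single split, seeded; `folds = n` selects
leave-one-out); accuracy pools correct/total over held-out folds, and
per-feature standardisation is fit inside training folds only. PCA of the
patient feature table takes the leading right singular vector of the
centred matrix (valid for $n < p$), with the largest-magnitude loading made
positive as a deterministic sign rule; component scores are the centred
projections. Associations are Pearson r with two-sided t-transform p-values,
reported uncorrected, as is conventional for exploratory clinical
correlations. Group comparisons available only as printed mean (SD, n) pairs
are recomputed with the pooled-variance two-sample t (equal to Welch's
statistic when group sizes are equal).

## The synthetic cohort generator

The generator exists so every downstream stage can be tested against planted
ground truth. One subject's data is

$$x_v(t) = \sum_k a_{vk}\, s_k(t) + \text{drift}_v(t) +
\text{motion artefact}_v(t) + \sigma\,\varepsilon_v(t),$$

with $s_k$ unit-variance network time courses built by masking white
Gaussian noise to 0.01–0.1 Hz in the frequency domain (so the signals live
exactly in the analysis band), $\varepsilon$ white Gaussian noise, low-order
polynomial drift, and a motion-coupled artefact built from the simulated
motion traces. An optional spatial Gaussian smoothing step
(``smooth_fwhm_mm``) emulates the 6-mm-FWHM smoothing real inputs carry from
upstream preprocessing; the default generator emits the raw mixing model, so
the closed-form expectations (a hub voxel's correlation with each of its two
equally weighted networks is exactly $1/\sqrt2$ in the noise-free limit, and
so on) hold without correction terms. Motion traces are mean-reverting AR(1) walks capped at
±0.5 mm whose step sizes are set so the mean frame-wise displacement is
about 0.2 mm, a typical value for elderly participants. White-matter, CSF
and global nuisance series are generated explicitly and handed to the
cleaning stage. Templates are grown as contiguous, pairwise-disjoint regions
by round-robin breadth-first search from farthest-point seeds (near-equal
sizes, about half the mask covered).

Connector hubs are small blobs (radius 1.5 voxels, 19 voxels on an interior
site) placed *outside* every template, each loading on two or more networks
with weight $a$; placing hubs outside the templates they connect keeps the
FCOR numerator (seed map ∩ template) and the seed location disjoint, which
sharpens recovery tests. In the patient group each (hub, network) loading is
multiplied by an attenuation factor in $[0,1]$ (controls are always 1),
scaled per subject by a severity draw (truncated normal, SD 0.10) and
clipped back to $[0,1]$. Patient motor item scores are Poisson draws whose
total rate grows with the subject's mean attenuation deficit
(`clinical_effect` simulated points per unit deficit, default 50), split
across the ten composite items plus three extra Part-III items; controls
carry no motor scores. Demographics (age, sex, ACE-R, LEDD) are drawn to
resemble an elderly matched case-control sample; sex is balanced and
independent of group so the covariate path is exercised without
confounding.

### Choice of effect sizes

No real-data effect size exists for group FCOR differences, so the defaults
were fixed by design analysis, once: with template weight 1, hub weight 0.8
and noise SD 1.5, a control hub voxel's correlation with its networks'
template voxels sits comfortably above the BH threshold while the
0.5-attenuated patient value falls below it — FCOR is a thresholded
statistic, so a contrast only exists when the attenuation moves the
correlation across the significance boundary. At noise SD 1.0 both groups
saturate (FCOR ≈ 1) and the planted difference is invisible; that regime is
retained for noise-free closed-form tests only. The 19-voxel hub blob
(radius 1.5 voxels) gives the cluster-defining threshold several voxels to
exceed jointly for both mixed networks while keeping every blob voxel within
2 voxels of the planted centre.

Spatial smoothing interacts with this design in opposite directions, which
is why it is an option rather than part of the default conditions. For the
planted-hub recovery suite smoothing is left off: smoothed noise is shared
across neighbouring voxels, which inflates the between-subject variance of
single-voxel FCOR (the whole template's correlations move together within a
subject) and makes voxel-level detection of the planted contrast erratic.
For the cluster-extent FWE calibration smoothing is turned on: cluster-size
inference presupposes spatially smooth statistic maps, and on rough fields
the permutation null of the maximum cluster size degenerates to a few small
integers — the attainable test level then falls far below nominal
(measured ≈ 0.015–0.023), a conservatism of the statistic itself. With 6-mm
smoothed null cohorts the attained level is close to nominal
(measured ≈ 0.03–0.05) and the calibration check is meaningful.

### What the generator does not emulate

No hemodynamic response function, no spatial autocorrelation beyond the
template/hub block structure (real smoothed BOLD is spatially smooth
everywhere), no physiological (cardiac/respiratory) noise, no scanner
drift beyond low-order polynomials, no registration error, and
templates/hubs are identical across subjects (no anatomical variability).
Passing tests therefore demonstrate that the statistical machinery is
correct and calibrated under the stated model — not that the pipeline is
robust to the artefacts of real acquisitions.

## Numerical choices

- Whole-brain FCOR runs in float32 by default (float64 available and used by
  the brute-force equality test); the correlation matrix is never
  materialised beyond one seed chunk.
- Fisher z for ROI r maps clips $|r|$ at $1 - 10^{-7}$ before arctanh.
- Degenerate inputs: constant seed → error; constant partner voxels →
  p = 1, never connected; zero-variance feature columns → rank-sum p = 1
  with a flag; zero-variance PCA input → error.
- Ties: BH ties share a fate; rank-sum uses midranks with tie correction;
  hub ranking breaks ties by (peak count, component size, lexicographic
  world coordinate).
- Determinism: every stochastic stage consumes an explicit seed; per-subject
  and per-permutation seeds are spawned from the config seed, so a pipeline
  re-run is bit-identical.

## Problem sizes in the test and acceptance suites

The statistical calibration checks are exchangeability-based, so their
nominal levels do not depend on problem size; the suites run them at sizes
chosen to keep a full run on one CPU within minutes:

- Hub-recovery cohort: 17³ = 4913 voxels, 6 networks, 3 hubs, n = 20/20,
  193 frames, 500 permutations, unsmoothed.
- Cluster-FWE null calibration: 100 Monte-Carlo repetitions of n = 12/12
  cohorts on a 14×14×12 (2352-voxel) grid with 96 frames, 6-mm smoothing
  and 500 permutations per repetition.
- Seed-map FDR null calibration: 200 simulations of 1500 independent
  voxels, 60 frames.
- Weight-response curve: 5 mixing weights × 20 replicates on an 8×8×6 grid.

## Known limitations

- The permutation critical extent is conservative at small B because
  attainable p-values are multiples of $1/(B+1)$.
- Hub selection and the subsequent hub-level rank-sum tests share the same
  data (selection bias); the planted-truth tests quantify this only
  indirectly, via the false-positive rate among non-attenuated pairs.
- With real data the FCOR denominators depend on the user-supplied atlas
  masks; the canonical 14-template configuration is reproduced here only in
  synthetic stand-ins.
- The simultaneous-projection cleaning dialect is exact only for the
  frequency-mask filter; combined with the Butterworth dialect the band
  edges differ slightly from the sequential order.
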