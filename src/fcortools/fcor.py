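"""The functional connectivity overlap ratio (FCOR).

For a seed voxel, a whole-brain FC map is the set of voxels whose Pearson
correlation with the seed is positive and survives Benjamini-Hochberg FDR
control at level q across all in-mask voxels. The FCOR of the seed against a
network template is the fraction of the template's voxels contained in that
FC map, so it ranges from 0 (no connection) to 1 (the entire template is
connected). Repeating over all seeds yields a whole-brain FCOR map per
template; per-template maps are z-scored across the brain to allow
between-subject comparison.

``whole_brain_fcor`` avoids per-seed p-value sorting by precomputing, for the
fixed (m, df, q), the BH critical ladder in |r| units: the two-sided p of the
t-transformed correlation is strictly decreasing in |r|, so the step-up rule
"reject the k smallest p with p_(i) <= q i/m" becomes "reject the k largest
|r| with |r|_(i) >= r_crit(i)". This makes the inner loop a sort plus one
vectorized comparison and is algebraically identical to running
:func:`seed_fc_map` per voxel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .core import BoldSeries, RSNTemplateSet, VolumeGrid
from .errors import DegenerateSeedError, ParameterError, ShapeError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FDR control
# ---------------------------------------------------------------------------

def bh_fdr(p: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection at level ``q``.

    Rejects the k smallest p-values where k = max{i : p_(i) <= (i/m) q};
    tied p-values share a fate.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ParameterError("p must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ParameterError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    ok = ranked <= q * np.arange(1, m + 1) / m
    if not ok.any():
        return np.zeros(m, dtype=bool)
    thresh = ranked[np.nonzero(ok)[0].max()]
    return p <= thresh


def r_to_p(r: np.ndarray, df: int, sidedness: str = "two") -> np.ndarray:
    """p-value of a Pearson correlation via the t-transform with ``df``
    degrees of freedom. ``sidedness='one'`` tests r > 0."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    t = np.where(np.abs(r) >= 1.0, np.sign(r) * np.inf, t)
    if sidedness == "two":
        p = 2.0 * special.stdtr(df, -np.abs(t))
    elif sidedness == "one":
        p = special.stdtr(df, -t)
    else:
        raise ParameterError(f"unknown sidedness '{sidedness}'")
    return np.where(np.isnan(r), 1.0, np.clip(p, 0.0, 1.0))


def bh_critical_r(m: int, df: int, q: float, sidedness: str = "two") -> np.ndarray:
    """|r| critical ladder for BH at level q over m correlation tests:
    position i (1-based) rejects iff the i-th largest |r| >= r_crit[i-1]."""
    p_targets = q * np.arange(1, m + 1) / m
    if sidedness == "two":
        t_crit = special.stdtrit(df, 1.0 - p_targets / 2.0)
    else:
        t_crit = special.stdtrit(df, 1.0 - p_targets)
    return (t_crit / np.sqrt(df + t_crit ** 2)).astype(np.float64)


# ---------------------------------------------------------------------------
# Seed-level FC maps
# ---------------------------------------------------------------------------

@dataclass
class FcMap:
    """A seed's thresholded FC map over the in-mask voxels."""

    seed: int | str
    connected: np.ndarray
    q_threshold: float
    r_values: np.ndarray | None = None


def standardize_rows(data: np.ndarray, dtype=np.float64):
    """Row-wise z-scoring (population SD). Returns (Z, constant_rows);
    constant rows are zeroed and flagged."""
    X = np.asarray(data, dtype=dtype)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    constant = sd[:, 0] <= 0
    sd[constant] = 1.0
    Z = (X - mu) / sd
    Z[constant] = 0.0
    return Z, constant


def seed_fc_map(bold: BoldSeries, seed: int, q: float = 0.01,
                sidedness: str = "two", df: int | None = None) -> FcMap:
    """Whole-brain FC map of one seed voxel.

    Pearson r of the seed course against every in-mask voxel, p-values from
    the t-transform with df = frames - 2, BH across all voxels at level q;
    connected voxels are those significant with r > 0. The seed itself has
    r = 1 and is always included.
    """
    if bold.n_frames < 8:
        raise ParameterError("seed FC maps need at least 8 frames")
    if not 0 <= seed < bold.n_voxels:
        raise ParameterError(f"seed {seed} outside 0..{bold.n_voxels - 1}")
    Z, constant = standardize_rows(bold.data)
    if constant[seed]:
        raise DegenerateSeedError(f"seed voxel {seed} has a constant time course")
    r = Z @ Z[seed] / bold.n_frames
    r[constant] = np.nan
    r[seed] = 1.0
    df = bold.n_frames - 2 if df is None else df
    p = r_to_p(r, df, sidedness)
    connected = bh_fdr(p, q) & (np.nan_to_num(r) > 0)
    return FcMap(seed=seed, connected=connected, q_threshold=q, r_values=r)


def fcor_value(fc: FcMap, template: np.ndarray) -> float:
    """|connected ∩ template| / |template| for one binary template."""
    template = np.asarray(template, dtype=bool)
    if template.shape != fc.connected.shape:
        raise ShapeError("template and FC map live on different grids")
    size = int(template.sum())
    if size == 0:
        raise ParameterError("template has no voxels")
    return float(np.count_nonzero(fc.connected & template) / size)


# ---------------------------------------------------------------------------
# Whole-brain FCOR maps
# ---------------------------------------------------------------------------

@dataclass
class FcorMaps:
    """Per-subject whole-brain FCOR fields, raw and z-scored, per network."""

    subject_id: str
    names: list[str]
    raw: np.ndarray  # (V, k) in [0, 1]
    z: np.ndarray    # (V, k), mean 0 / SD 1 over the mask
    constant_voxels: np.ndarray = field(default=None)  # flags, FCOR forced to 0

    def raw_map(self, name: str) -> np.ndarray:
        return self.raw[:, self.names.index(name)]

    def z_map(self, name: str) -> np.ndarray:
        return self.z[:, self.names.index(name)]


def zscore_maps(raw: np.ndarray) -> np.ndarray:
    mu = raw.mean(axis=0, keepdims=True)
    sd = raw.std(axis=0, keepdims=True)
    flat = sd[0] <= 0
    if flat.any():
        log.warning("FCOR map constant across the brain for %d template(s)", flat.sum())
    sd = np.where(sd <= 0, 1.0, sd)
    z = (raw - mu) / sd
    z[:, flat] = 0.0
    return z


def whole_brain_fcor(bold: BoldSeries, templates: RSNTemplateSet, q: float = 0.01,
                     *, sidedness: str = "two", chunk_size: int = 1024,
                     dtype=np.float32) -> FcorMaps:
    """FCOR of every in-mask voxel against every template, plus z-scored maps.

    Computation is chunked over seed voxels; results are independent of the
    chunk size. Constant voxels receive FCOR 0 against every template and are
    flagged.
    """
    V, T = bold.n_voxels, bold.n_frames
    if T < 8:
        raise ParameterError("whole-brain FCOR needs at least 8 frames")
    if templates.masks.shape[0] != V:
        raise ShapeError("templates and series live on different grids")
    df = T - 2
    r_crit = bh_critical_r(V, df, q, sidedness).astype(dtype)
    Z, constant = standardize_rows(bold.data, dtype=dtype)
    if constant.any():
        log.warning("%d constant voxel(s): FCOR set to 0", int(constant.sum()))
    indicator = templates.masks.astype(dtype)
    inv_sizes = (1.0 / templates.sizes).astype(dtype)
    raw = np.zeros((V, templates.n_templates), dtype=np.float64)
    m = V
    for start in range(0, V, max(1, int(chunk_size))):
        stop = min(start + max(1, int(chunk_size)), V)
        R = Z[start:stop] @ Z.T
        R /= dtype(T)
        rows = np.arange(start, stop)
        R[rows - start, rows] = 1.0  # each seed correlates 1 with itself
        if sidedness == "two":
            A = np.abs(R)
        else:
            A = R.copy()
        A[:, constant] = -np.inf  # constant partners: p = 1, never rejected
        S = np.sort(A, axis=1)[:, ::-1]
        ok = S >= r_crit[None, :]
        any_ok = ok.any(axis=1)
        # index of the LAST position satisfying the step-up condition
        last = m - 1 - np.argmax(ok[:, ::-1], axis=1)
        thr = S[np.arange(stop - start), last]
        connected = (A >= thr[:, None]) & (R > 0)
        connected[~any_ok] = False
        raw[start:stop] = (connected.astype(dtype) @ indicator) * inv_sizes
        del R, A, S, connected
    raw[constant] = 0.0
    z = zscore_maps(raw)
    return FcorMaps(subject_id=bold.subject_id, names=list(templates.names),
                    raw=raw, z=z, constant_voxels=constant)


# ---------------------------------------------------------------------------
# Group-level ROI connectivity profile
# ---------------------------------------------------------------------------

def roi_fc_profile(bolds: list[BoldSeries], roi_voxels: np.ndarray,
                   templates: RSNTemplateSet, grid: VolumeGrid,
                   cdt_p: float = 0.001, fwe_p: float = 0.05,
                   n_permutations: int = 1000, seed: int = 0,
                   connectivity: int = 26) -> dict[str, float]:
    """Connectivity profile of a spherical ROI in a (control) group.

    Per subject: mean ROI time course -> whole-brain r map -> Fisher z. A
    one-sided one-sample t over subjects is thresholded with permutation
    (sign-flip) cluster-extent FWE control, and the FCOR of the surviving map
    is returned per template.
    """
    from .group_inference import one_sample_cluster_fwe  # local: avoid cycle

    if len(bolds) < 2:
        raise ParameterError("an ROI profile needs at least 2 subjects")
    roi_voxels = np.asarray(roi_voxels, dtype=int)
    if roi_voxels.size == 0:
        raise ParameterError("ROI is empty after masking")
    zmaps = []
    for bold in bolds:
        Z, constant = standardize_rows(bold.data)
        course = np.asarray(bold.data, dtype=float)[roi_voxels].mean(axis=0)
        course = course - course.mean()
        sd = course.std()
        if sd <= 0:
            raise DegenerateSeedError("ROI mean course is constant")
        r = Z @ (course / sd) / bold.n_frames
        r[constant] = 0.0
        zmaps.append(np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7)))
    zmaps = np.asarray(zmaps)
    clusters = one_sample_cluster_fwe(zmaps, grid, cdt_p=cdt_p, fwe_p=fwe_p,
                                      n_permutations=n_permutations, seed=seed,
                                      connectivity=connectivity)
    surviving = np.zeros(grid.n_voxels, dtype=bool)
    for cl in clusters.clusters:
        surviving[cl.members] = True
    fc = FcMap(seed="roi", connected=surviving, q_threshold=np.nan)
    return {name: fcor_value(fc, templates[name]) for name in templates.names}
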