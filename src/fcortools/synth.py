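"""Synthetic resting-state cohorts with planted networks and connector hubs.

The generative model is a linear mixing of band-limited network time courses:

    x_v(t) = sum_k a_vk s_k(t) + drift_v(t) + motion artefact + noise_sd * eps

Template voxels load on their own network only; connector-hub voxels sit
*outside* every template and load on two or more networks, so their FC maps
overlap several templates at once. In the patient group the hub loadings are
multiplied by per-(hub, network) attenuation factors in [0, 1] (controls are
always 1), scaled per subject by a severity draw; simulated motor scores grow
with the subject's attenuation deficit, so clinical associations have a
planted direction. Motion traces are smooth mean-reverting random walks whose
mean frame-wise displacement is realistic (~0.2 mm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .confounds import mean_fd
from .core import (PIGD_ITEMS, TREMOR_ITEMS, BoldSeries, ClinicalTable,
                   RSNTemplateSet, VolumeGrid)
from .errors import CapacityError, ParameterError

log = logging.getLogger(__name__)

#: Extra Part-III items generated besides the composite-score constituents.
EXTRA_PART3_ITEMS = ("3.1", "3.2", "3.3")

DEFAULT_TR_S = 2.5
DEFAULT_FRAMES = 193  # acquisition length after discarding equilibration frames
DEFAULT_BAND = (0.01, 0.1)
#: FWHM of the spatial smoothing upstream preprocessing would apply; the
#: default generator emits the raw mixing model (no spatial smoothing).
DEFAULT_SMOOTH_FWHM_MM = 0.0


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def make_templates(grid: VolumeGrid, k: int, seed: int,
                   fill_fraction: float = 0.5) -> RSNTemplateSet:
    """Grow ``k`` contiguous, pairwise-disjoint templates inside the mask.

    Seeds are chosen by greedy farthest-point sampling; regions then grow by
    round-robin breadth-first search (6-connectivity) until each reaches
    ``fill_fraction / k`` of the mask, which keeps sizes close to equal.
    """
    if k < 2:
        raise ParameterError("need at least 2 templates")
    V = grid.n_voxels
    target = max(1, int(fill_fraction * V / k))
    if V < 4 * k:
        raise CapacityError(f"mask of {V} voxels cannot host {k} templates")
    rng = np.random.default_rng(seed)
    coords = grid.mask_coords.astype(float) * grid.voxel_size_mm
    # farthest-point seeding
    first = int(rng.integers(V))
    seeds = [first]
    d = np.linalg.norm(coords - coords[first], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        seeds.append(nxt)
        d = np.minimum(d, np.linalg.norm(coords - coords[nxt], axis=1))
    # round-robin BFS growth on the voxel lattice
    flat = grid.flat_index()
    ijk = grid.mask_coords
    owner = np.full(V, -1, dtype=int)
    frontiers: list[list[int]] = []
    sizes = np.zeros(k, dtype=int)
    for t, s in enumerate(seeds):
        owner[s] = t
        sizes[t] = 1
        frontiers.append([s])
    neigh_offsets = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                              [0, -1, 0], [0, 0, 1], [0, 0, -1]])
    active = True
    while active:
        active = False
        for t in range(k):
            if sizes[t] >= target or not frontiers[t]:
                continue
            new_frontier = []
            for v in frontiers[t]:
                for off in neigh_offsets:
                    nb = ijk[v] + off
                    if np.any(nb < 0) or np.any(nb >= grid.dims):
                        continue
                    w = flat[tuple(nb)]
                    if w >= 0 and owner[w] < 0:
                        owner[w] = t
                        sizes[t] += 1
                        new_frontier.append(int(w))
                        if sizes[t] >= target:
                            break
                if sizes[t] >= target:
                    break
            frontiers[t] = new_frontier
            if new_frontier and sizes[t] < target:
                active = True
    if sizes.min() == 0 or sizes.max() > 3 * sizes.min():
        raise CapacityError(
            f"mask geometry yields unbalanced templates (sizes {sizes.tolist()})")
    masks = np.zeros((V, k), dtype=bool)
    for t in range(k):
        masks[owner == t, t] = True
    names = [f"net{t + 1:02d}" for t in range(k)]
    return RSNTemplateSet(grid, names, masks)


# ---------------------------------------------------------------------------
# Time courses
# ---------------------------------------------------------------------------

def make_network_timecourses(k: int, frames: int, tr_s: float = DEFAULT_TR_S,
                             band: tuple[float, float] = DEFAULT_BAND,
                             seed: int = 0) -> np.ndarray:
    """(frames, k) unit-variance, band-limited, approximately uncorrelated
    network signals, built by masking white Gaussian noise to the band in the
    frequency domain."""
    if frames < 64:
        raise ParameterError("need at least 64 frames for band-limited signals")
    low, high = band
    nyquist = 0.5 / tr_s
    if not (0 < low < high < nyquist):
        raise ParameterError(f"band {band} outside (0, Nyquist={nyquist:.4f})")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(frames, tr_s)
    keep = (freqs >= low) & (freqs <= high)
    if keep.sum() < 2:
        raise ParameterError("band holds fewer than 2 Fourier components")
    white = rng.standard_normal((frames, k))
    spec = np.fft.rfft(white, axis=0)
    spec[~keep] = 0.0
    x = np.fft.irfft(spec, n=frames, axis=0)
    x -= x.mean(axis=0)
    x /= x.std(axis=0)
    return x


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class PlantedHub:
    label: str
    members: np.ndarray          # in-mask flat indices
    networks: tuple[str, ...]    # the networks it mixes


@dataclass
class SimTruth:
    """Planted structure of a synthetic cohort."""

    grid: VolumeGrid
    templates: RSNTemplateSet
    mixing: np.ndarray                       # (V, k), a_vk >= 0
    hubs: list[PlantedHub]
    attenuation: dict[tuple[str, str], float]  # (hub, network) -> [0, 1]
    noise_sd: float = 1.5
    clinical_effect: float = 50.0
    hub_weight_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        for key, f in self.attenuation.items():
            if not 0.0 <= f <= 1.0:
                raise ParameterError(f"attenuation {key} = {f} outside [0, 1]")
        for hub in self.hubs:
            w = self.mixing[hub.members]
            n_strong = (w > self.hub_weight_threshold).sum(axis=1)
            if (n_strong < 2).any():
                raise ParameterError(
                    f"hub {hub.label} has voxels mixing fewer than 2 networks")

    @property
    def hub_voxels(self) -> np.ndarray:
        if not self.hubs:
            return np.empty(0, dtype=int)
        return np.unique(np.concatenate([h.members for h in self.hubs]))

    def attenuated_pairs(self) -> list[tuple[str, str]]:
        return [k for k, f in self.attenuation.items() if f < 1.0]


def make_sim_truth(grid: VolumeGrid, n_networks: int = 6, n_hubs: int = 3,
                   networks_per_hub: int = 2, template_weight: float = 1.0,
                   hub_weight: float = 0.8, attenuation: float = 0.5,
                   noise_sd: float = 1.5, clinical_effect: float = 50.0,
                   seed: int = 0, hub_radius_vox: float = 1.5,
                   templates: RSNTemplateSet | None = None) -> SimTruth:
    """Assemble a :class:`SimTruth`: disjoint templates, hub blobs placed
    outside all templates, and patient-group attenuation on every
    (hub, network) pair each hub mixes."""
    if networks_per_hub < 2:
        raise ParameterError("connector hubs must mix at least 2 networks")
    if networks_per_hub > n_networks:
        raise ParameterError("networks_per_hub cannot exceed n_networks")
    if templates is None:
        templates = make_templates(grid, n_networks, seed=seed)
    elif templates.n_templates != n_networks:
        raise ParameterError("supplied templates do not match n_networks")
    V = grid.n_voxels
    in_any = templates.masks.any(axis=1)
    mixing = np.zeros((V, n_networks))
    for t in range(n_networks):
        mixing[templates.masks[:, t], t] = template_weight

    # hub placement: blobs (a voxel plus its in-mask face neighbours) outside
    # every template, mutually separated
    rng = np.random.default_rng(seed + 1)
    flat = grid.flat_index()
    ijk = grid.mask_coords
    coords_mm = ijk.astype(float) * grid.voxel_size_mm
    free = ~in_any
    span = int(np.floor(hub_radius_vox))
    rng_off = range(-span, span + 1)
    offsets = np.array([[i, j, l] for i in rng_off for j in rng_off for l in rng_off
                        if 0 < i * i + j * j + l * l <= hub_radius_vox ** 2])
    # prefer centres whose full blob neighbourhood is free and in-mask, so hub
    # blobs are complete spheres away from the mask edge
    centre_ok = free.copy()
    for v in np.nonzero(free)[0]:
        for off in offsets:
            nb = ijk[v] + off
            if np.any(nb < 0) or np.any(nb >= grid.dims):
                centre_ok[v] = False
                break
            w = flat[tuple(nb)]
            if w < 0 or not free[w]:
                centre_ok[v] = False
                break
    if centre_ok.sum() < n_hubs:
        centre_ok = free.copy()
    hubs: list[PlantedHub] = []
    taken = np.zeros(V, dtype=bool)
    min_sep = (2.0 * hub_radius_vox + 2.0) * float(np.max(grid.voxel_size_mm))
    candidates = np.nonzero(centre_ok)[0]
    rng.shuffle(candidates)
    for h in range(n_hubs):
        centre = None
        for c in candidates:
            if taken[c] or not free[c]:
                continue
            if hubs and min(np.linalg.norm(coords_mm[c] - coords_mm[p.members[0]])
                            for p in hubs) < min_sep:
                continue
            centre = int(c)
            break
        if centre is None:
            raise CapacityError("not enough free space outside templates for hubs")
        members = [centre]
        for off in offsets:
            nb = ijk[centre] + off
            if np.any(nb < 0) or np.any(nb >= grid.dims):
                continue
            w = flat[tuple(nb)]
            if w >= 0 and free[w] and not taken[w]:
                members.append(int(w))
        members = np.asarray(members, dtype=int)
        taken[members] = True
        nets = tuple(templates.names[(h * networks_per_hub + j) % n_networks]
                     for j in range(networks_per_hub))
        if len(set(nets)) < networks_per_hub:
            nets = tuple(rng.choice(templates.names, networks_per_hub,
                                    replace=False))
        for name in nets:
            mixing[members, templates.names.index(name)] = hub_weight
        hubs.append(PlantedHub(label=f"planted{h + 1}", members=members,
                               networks=nets))
    atten = {(h.label, n): float(attenuation) for h in hubs for n in h.networks}
    return SimTruth(grid=grid, templates=templates, mixing=mixing, hubs=hubs,
                    attenuation=atten, noise_sd=noise_sd,
                    clinical_effect=clinical_effect)


# ---------------------------------------------------------------------------
# Subjects and cohorts
# ---------------------------------------------------------------------------

def _motion_traces(frames: int, rng: np.random.Generator,
                   trans_step_mm: float = 0.055, rot_step_rad: float = 0.00055,
                   rho: float = 0.95) -> np.ndarray:
    """Smooth mean-reverting random walks: AR(1) per parameter, translations
    capped at +-0.5 mm."""
    steps = rng.standard_normal((frames, 6))
    steps[:, :3] *= trans_step_mm
    steps[:, 3:] *= rot_step_rad
    m = np.zeros((frames, 6))
    for t in range(1, frames):
        m[t] = rho * m[t - 1] + steps[t]
    m[:, :3] = np.clip(m[:, :3], -0.5, 0.5)
    return m


def subject_attenuation(truth: SimTruth, severity: float) -> dict[tuple[str, str], float]:
    """Per-subject factors: the planted deficit (1 - factor) scaled by a
    severity draw, clipped back into [0, 1]."""
    return {key: float(np.clip(1.0 - severity * (1.0 - f), 0.0, 1.0))
            for key, f in truth.attenuation.items()}


def make_subject(truth: SimTruth, group: str, frames: int = DEFAULT_FRAMES,
                 seed: int = 0, tr_s: float = DEFAULT_TR_S,
                 band: tuple[float, float] = DEFAULT_BAND,
                 subject_id: str = "sub", severity: float = 1.0,
                 drift_amp: float = 0.3, motion_artifact_amp: float = 0.1,
                 nuisance_amp: float = 0.2,
                 smooth_fwhm_mm: float = DEFAULT_SMOOTH_FWHM_MM) -> tuple[BoldSeries, dict]:
    """Simulate one subject.

    Returns the BOLD series (with motion traces attached) and a dict of known
    nuisance series (``wm``, ``csf``, ``global``) for confound regression.
    Patients get their hub mixing weights multiplied by the subject's
    attenuation factors; controls use the planted weights unchanged. A
    positive ``smooth_fwhm_mm`` applies Gaussian spatial smoothing to the
    assembled volumes, emulating smoothed acquisitions; the default emits the
    raw mixing model so closed-form expectations hold exactly.
    """
    if group not in ("patient", "control"):
        raise ParameterError(f"unknown group label '{group}'")
    rng = np.random.default_rng(seed)
    k = truth.templates.n_templates
    V = truth.grid.n_voxels
    courses = make_network_timecourses(k, frames, tr_s, band,
                                       seed=int(rng.integers(2 ** 31)))
    A = truth.mixing.copy()
    factors = {}
    if group == "patient":
        factors = subject_attenuation(truth, severity)
        for hub in truth.hubs:
            for net in hub.networks:
                A[hub.members, truth.templates.names.index(net)] *= \
                    factors[(hub.label, net)]
    X = A @ courses.T
    if truth.noise_sd > 0:
        X += truth.noise_sd * rng.standard_normal((V, frames))
    # low-order drift (removed by the band-pass) and motion-coupled artefact
    t = np.linspace(-1, 1, frames)
    drift_basis = np.vstack([t, 1.5 * t ** 2 - 0.5])
    X += drift_amp * rng.standard_normal((V, 2)) @ drift_basis
    motion = _motion_traces(frames, rng)
    m_std = (motion - motion.mean(0)) / np.where(motion.std(0) > 0, motion.std(0), 1)
    X += motion_artifact_amp * rng.standard_normal((V, 6)) @ m_std.T
    # shared physiological nuisance series (known to the cleaning stage)
    nuis = make_network_timecourses(3, frames, tr_s, (0.005, min(0.15, 0.45 / tr_s)),
                                    seed=int(rng.integers(2 ** 31)))
    wm, csf, glob = nuis.T
    X += nuisance_amp * glob[None, :]
    X += nuisance_amp * rng.standard_normal((V, 1)) * wm[None, :] * 0.5
    X += nuisance_amp * rng.standard_normal((V, 1)) * csf[None, :] * 0.5
    if smooth_fwhm_mm > 0:
        sigma = smooth_fwhm_mm / 2.355 / np.asarray(truth.grid.voxel_size_mm)
        vol = truth.grid.unmask(X)
        vol = ndimage.gaussian_filter(vol, sigma=tuple(sigma) + (0.0,))
        X = truth.grid.mask_field(vol)
    bold = BoldSeries(data=X, tr_s=tr_s, motion=motion, subject_id=subject_id)
    return bold, {"wm": wm, "csf": csf, "global": glob, "factors": factors}


def make_cohort(truth: SimTruth, n_per_group: int, frames: int = DEFAULT_FRAMES,
                seed: int = 0, tr_s: float = DEFAULT_TR_S,
                band: tuple[float, float] = DEFAULT_BAND,
                severity_sd: float = 0.10,
                **subject_kwargs) -> tuple[list[BoldSeries], ClinicalTable, dict]:
    """Simulate a balanced cohort plus its clinical table and truth manifest.

    Patient motor scores are driven by the subject's mean attenuation deficit
    (``clinical_effect`` points of simulated MDS-UPDRS Part III per unit
    deficit) distributed over tremor, PIGD and extra Part-III items; controls
    carry no motor scores. Demographics are drawn to resemble an elderly
    case-control sample.
    """
    if n_per_group < 2:
        raise ParameterError("need at least 2 subjects per group")
    ss = np.random.SeedSequence(seed)
    subj_seeds = ss.spawn(2 * n_per_group)
    rng = np.random.default_rng(ss.spawn(1)[0])
    bolds: list[BoldSeries] = []
    rows = []
    nuisances = {}
    item_names = list(TREMOR_ITEMS) + list(PIGD_ITEMS) + list(EXTRA_PART3_ITEMS)
    weights = rng.dirichlet(np.full(len(item_names), 4.0))
    manifest_subjects = []
    for i in range(2 * n_per_group):
        group = "control" if i < n_per_group else "patient"
        sid = f"{'c' if group == 'control' else 'p'}{i % n_per_group + 1:03d}"
        severity = float(np.clip(rng.normal(1.0, severity_sd), 0.25, 1.75)) \
            if group == "patient" else 0.0
        bold, nuis = make_subject(
            truth, group, frames=frames,
            seed=int(np.random.default_rng(subj_seeds[i]).integers(2 ** 31)),
            tr_s=tr_s, band=band, subject_id=sid, severity=severity,
            **subject_kwargs)
        bolds.append(bold)
        nuisances[sid] = nuis
        row = {
            "subject_id": sid, "group": group,
            "age": float(np.round(rng.normal(67.5, 8.8), 1)),
            "sex": "male" if rng.random() < 0.5 else "female",
            "mean_fd": mean_fd(bold.motion),
        }
        if group == "patient":
            factors = nuis["factors"]
            deficit = float(np.mean([1.0 - f for f in factors.values()])) \
                if factors else 0.0
            total_motor = max(0.0, truth.clinical_effect * deficit
                              + rng.normal(0.0, 2.0))
            items = rng.poisson(np.maximum(0.0, total_motor * weights))
            for name, score in zip(item_names, items):
                row[f"updrs_{name}"] = int(score)
            row["ledd"] = float(np.clip(rng.normal(427.7, 299.6), 0.0, None))
            row["ace_r"] = int(np.clip(np.round(rng.normal(91.66, 6.05)), 0, 100))
            manifest_subjects.append({"subject_id": sid, "severity": severity,
                                      "deficit": deficit,
                                      "factors": {f"{h}|{n}": v for (h, n), v
                                                  in factors.items()}})
        else:
            row["ledd"] = np.nan
            row["ace_r"] = int(np.clip(np.round(rng.normal(95.22, 3.12)), 0, 100))
            manifest_subjects.append({"subject_id": sid, "severity": 0.0,
                                      "deficit": 0.0, "factors": {}})
        rows.append(row)
    clinical = ClinicalTable(pd.DataFrame(rows))
    manifest = {
        "seed": int(seed),
        "n_per_group": int(n_per_group),
        "frames": int(frames),
        "tr_s": float(tr_s),
        "band_hz": [float(band[0]), float(band[1])],
        "noise_sd": float(truth.noise_sd),
        "clinical_effect": float(truth.clinical_effect),
        "severity_sd": float(severity_sd),
        "templates": {n: int(s) for n, s in
                      zip(truth.templates.names, truth.templates.sizes)},
        "hubs": [{
            "label": h.label,
            "networks": list(h.networks),
            "members": [int(v) for v in h.members],
            "peak_voxel": int(h.members[0]),
        } for h in truth.hubs],
        "attenuation": {f"{h}|{n}": float(f) for (h, n), f
                        in truth.attenuation.items()},
        "subjects": manifest_subjects,
    }
    manifest["nuisance"] = {sid: {k: np.asarray(v).tolist()
                                  for k, v in nuis.items() if k != "factors"}
                            for sid, nuis in nuisances.items()}
    return bolds, clinical, manifest
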