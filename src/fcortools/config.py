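"""Structured pipeline configuration.

Every analysis threshold is a config key and defaults to the value of the
reference protocol: FC-map FDR q = 0.01, cluster-defining threshold
p = 0.001, cluster-level FWE p = 0.05, hub-comparison FDR q = 0.05, SVM
C = 1 with 10-fold CV, 3 mm hub spheres, and a 0.01-0.1 Hz band.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class SynthConfig:
    enabled: bool = True
    dims: tuple[int, int, int] = (16, 16, 14)
    voxel_size_mm: float = 3.0
    n_networks: int = 6
    n_hubs: int = 3
    networks_per_hub: int = 2
    n_per_group: int = 10
    frames: int = 193
    tr_s: float = 2.5
    template_weight: float = 1.0
    hub_weight: float = 0.8
    attenuation: float = 0.5
    noise_sd: float = 1.5
    smooth_fwhm_mm: float = 0.0
    clinical_effect: float = 50.0
    severity_sd: float = 0.10


@dataclass
class InputConfig:
    """Real-data inputs; used when synthetic generation is disabled."""
    mask: str | None = None
    bold: list[str] = field(default_factory=list)
    motion: list[str] = field(default_factory=list)
    templates: dict[str, str] = field(default_factory=dict)
    clinical: str | None = None
    tr_s: float | None = None


@dataclass
class CleanConfig:
    band_hz: tuple[float, float] = (0.01, 0.1)
    filter_design: str = "butter"     # or "fft"
    order: str = "regress_then_filter"  # or "simultaneous"
    use_tissue_signals: bool = True


@dataclass
class FcorConfig:
    fdr_q: float = 0.01
    fdr_sidedness: str = "two"
    chunk_size: int = 1024
    zscore_within_subject: bool = True


@dataclass
class GroupConfig:
    cdt_p: float = 0.001
    fwe_p: float = 0.05
    n_permutations: int = 1000
    cluster_connectivity: int = 26
    top_k_hubs: int = 5
    hub_radius_mm: float = 3.0
    min_conjunction_count: int = 2
    directions: tuple[str, ...] = ("control>patient", "patient>control")


@dataclass
class HubStatsConfig:
    fdr_q: float = 0.05
    use_z_features: bool = False


@dataclass
class ClinicalConfig:
    svm_c: float = 1.0
    cv_folds: int = 10
    standardize: bool = True


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "fcor_out"
    write_maps: bool = False
    synth: SynthConfig = field(default_factory=SynthConfig)
    inputs: InputConfig = field(default_factory=InputConfig)
    clean: CleanConfig = field(default_factory=CleanConfig)
    fcor: FcorConfig = field(default_factory=FcorConfig)
    group: GroupConfig = field(default_factory=GroupConfig)
    hub_stats: HubStatsConfig = field(default_factory=HubStatsConfig)
    clinical: ClinicalConfig = field(default_factory=ClinicalConfig)

    def validate(self) -> None:
        if not self.synth.enabled:
            missing = []
            if not self.inputs.mask:
                missing.append("inputs.mask")
            if not self.inputs.bold:
                missing.append("inputs.bold")
            if not self.inputs.templates:
                missing.append("inputs.templates")
            if not self.inputs.clinical:
                missing.append("inputs.clinical")
            if missing:
                raise ConfigError(f"missing configuration keys: {missing}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        sections = {f.name: f.type for f in fields(cls)}
        for name, value in raw.items():
            if name not in sections:
                raise ConfigError(f"unknown configuration section/key '{name}'")
            default = getattr(cls(), name)
            if hasattr(default, "__dataclass_fields__"):
                known = default.__dataclass_fields__
                bad = set(value) - set(known)
                if bad:
                    raise ConfigError(f"unknown keys in '{name}': {sorted(bad)}")
                merged = {**asdict(default), **value}
                for key in ("dims", "band_hz", "directions"):
                    if key in merged and isinstance(merged[key], list):
                        merged[key] = tuple(merged[key])
                kwargs[name] = type(default)(**merged)
            else:
                kwargs[name] = value
        return cls(**kwargs)
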