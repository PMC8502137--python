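"""Pipeline configuration.

One nested dataclass mirrors the YAML config file; every stage receives
its own section.  Defaults encode the analysis conventions of the
pipeline: the GISTIC-style amplitude thresholds (0.1) and cap (1.5), the
q-value bound 0.25, the clonality filter (depth >= 20, copy-neutral band
2 +/- 0.25, at most 10 mixture components), the cosine-matching
threshold 0.9, the SMG FDR 0.25 and the 10% essential-alteration
frequency floor.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml


@dataclass
class SigConfig:
    k_min: int = 2
    k_max: int = 6
    n_restarts: int = 10
    seed: int = 0
    cos_threshold: float = 0.9
    n_sig_clusters: int = 3


@dataclass
class CnvConfig:
    amp_thresh: float = 0.1
    del_thresh: float = 0.1
    cap: float = 1.5
    high_level: float = 0.9
    q_thresh: float = 0.25
    n_perm: int = 200
    n_cnv_clusters: int = 3


@dataclass
class ClonalityConfig:
    min_depth: int = 20
    max_clusters: int = 10
    cn_margin: float = 0.25
    major_clone_min_frac: float = 0.15


@dataclass
class NeoConfig:
    peptide_lengths: list[int] = field(default_factory=lambda: [8, 9, 10, 11])
    ic50_threshold_nM: float = 500.0
    binder_fraction: float = 0.1
    n_nea_clusters: int = 2


@dataclass
class SmgConfig:
    fdr: float = 0.25
    min_freq: float = 0.10


@dataclass
class IntegrateConfig:
    k: int = 4
    n_resamples: int = 1000
    subsample_frac: float = 0.8
    seed: int = 0


@dataclass
class PredictorConfig:
    laplace_alpha: float = 1.0
    n_folds: int = 10
    seed: int = 0


@dataclass
class PipelineConfig:
    sig: SigConfig = field(default_factory=SigConfig)
    cnv: CnvConfig = field(default_factory=CnvConfig)
    clonality: ClonalityConfig = field(default_factory=ClonalityConfig)
    neo: NeoConfig = field(default_factory=NeoConfig)
    smg: SmgConfig = field(default_factory=SmgConfig)
    integrate: IntegrateConfig = field(default_factory=IntegrateConfig)
    predictor: PredictorConfig = field(default_factory=PredictorConfig)

    def __post_init__(self) -> None:
        if self.sig.k_min < 1 or self.sig.k_max < self.sig.k_min:
            raise ValueError("sig rank range must satisfy 1 <= k_min <= k_max")
        if not 0 < self.sig.cos_threshold <= 1:
            raise ValueError("cos_threshold must be in (0, 1]")
        for name in ("amp_thresh", "del_thresh", "cap", "high_level"):
            if getattr(self.cnv, name) <= 0:
                raise ValueError(f"cnv.{name} must be positive")
        if not 0 < self.cnv.q_thresh < 1 or not 0 < self.smg.fdr < 1:
            raise ValueError("q-value bounds must be in (0, 1)")
        if self.clonality.max_clusters < 1 or self.integrate.k < 1:
            raise ValueError("cluster counts must be >= 1")
        if not 0 < self.integrate.subsample_frac <= 1:
            raise ValueError("subsample_frac must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def _from_dict(cls, data: dict):
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if is_dataclass(f.type) if isinstance(f.type, type) else False:
            value = _from_dict(f.type, value)
        kwargs[f.name] = value
    return cls(**kwargs)


_SECTIONS = {
    "sig": SigConfig,
    "cnv": CnvConfig,
    "clonality": ClonalityConfig,
    "neo": NeoConfig,
    "smg": SmgConfig,
    "integrate": IntegrateConfig,
    "predictor": PredictorConfig,
}


def load_config(path) -> PipelineConfig:
    """Load a YAML config; unspecified fields keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = cls(**raw[name])
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path) -> None:
    """Write the fully resolved config beside run outputs."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
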