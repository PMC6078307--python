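"""Pipeline configuration: YAML round-trip, validation, hashing."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass

import yaml

from .association import FAMILY_KEYS
from .connectome import ANAT_NORMS
from .graph_metrics import DISTANCE_TRANSFORMS
from .synthetic_data import CohortSpec


@dataclass
class PipelineConfig:
    """All knobs for one end-to-end run."""

    seed: int = 0
    cohort: CohortSpec = None
    z_threshold: float = 0.3
    anat_norm: str = "sum"
    distance: str = "inverse"
    binary_degree: bool = False
    family_key: str = "block_pair_modality"
    threshold_mode: str = "p"
    alpha: float = 0.05
    covariates: tuple = ("age", "sex")

    def __post_init__(self) -> None:
        if self.cohort is None:
            self.cohort = CohortSpec(seed=self.seed)
        elif isinstance(self.cohort, dict):
            kw = dict(self.cohort)
            kw.setdefault("seed", self.seed)
            for key in ("effect_map", "ts_planted_edges",
                        "fiber_planted_edges"):
                if key in kw:
                    kw[key] = tuple(tuple(e) for e in kw[key])
            self.cohort = CohortSpec(**kw)
        self.validate()

    def validate(self) -> None:
        if self.z_threshold < 0:
            raise ValueError("z_threshold must be nonnegative")
        if self.anat_norm not in ANAT_NORMS:
            raise ValueError(f"anat_norm must be one of {ANAT_NORMS}")
        if self.distance not in DISTANCE_TRANSFORMS:
            raise ValueError(
                f"distance must be one of {DISTANCE_TRANSFORMS}")
        if self.family_key not in FAMILY_KEYS:
            raise ValueError(f"family_key must be one of {FAMILY_KEYS}")
        if self.threshold_mode not in ("p", "q"):
            raise ValueError("threshold_mode must be 'p' or 'q'")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("effect_map", "ts_planted_edges", "fiber_planted_edges"):
            d["cohort"][key] = [list(e) for e in d["cohort"][key]]
        d["cohort"]["age_range"] = list(d["cohort"]["age_range"])
        d["covariates"] = list(self.covariates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "covariates" in d:
            d["covariates"] = tuple(d["covariates"])
        if isinstance(d.get("cohort"), dict):
            c = dict(d["cohort"])
            if "age_range" in c:
                c["age_range"] = tuple(c["age_range"])
            d["cohort"] = c
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d or {})

    def digest(self) -> str:
        """Stable content hash, for provenance manifests."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
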