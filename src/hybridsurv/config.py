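"""Run configuration: defaults, YAML loading, per-stage seed derivation.

Every stage derives its random stream from the global seed by hashing the
stage name, so any stage can be rerun in isolation and reproduce the full
pipeline's behaviour bit for bit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["RunConfig", "load_config", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed < 2**31 derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """All stage parameters with their defaults.

    ``mode`` selects the preprocessing order: ``paper-literal`` standardizes
    and imputes the whole table before the stratified split; ``strict`` fits
    those steps on training rows only.
    """

    seed: int = 42
    mode: str = "paper-literal"
    # simulate
    n_birds: int = 600
    detection_prob: float = 0.8
    base_survival_rate: float = 0.309
    missing_frac_behaviour: float = 0.28
    n_loci: int = 1495
    # labeling
    study_days: int = 300
    occasion_days: int = 10
    cjs_mode: str = "cohort"
    # featureprep
    test_frac: float = 0.2
    corr_threshold: float = 0.7
    max_missing: float = 0.25
    k_impute: int = 5
    # model
    n_candidates: int = 50
    smote_k: int = 5
    cv_folds: int = 5
    # evaluation / interpretation
    delta_f1_cutoff: float = 0.1
    interaction_repeats: int = 1
    shap_background: int = 25
    # network
    n_boot: int = 10_000
    network_alpha: float = 0.05
    stage_seeds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("paper-literal", "strict"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if not 0.0 < self.test_frac < 1.0:
            raise ValueError("test_frac must lie strictly between 0 and 1")
        if self.cjs_mode not in ("cohort", "per_bird"):
            raise ValueError(f"unknown cjs_mode: {self.cjs_mode!r}")
        for stage in ("simulate", "label", "prep", "train", "evaluate", "interpret", "network"):
            self.stage_seeds.setdefault(stage, stage_seed(self.seed, stage))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    """Load a YAML config; unknown keys are rejected."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
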