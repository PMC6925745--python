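"""Configuration objects shared by the model API, validation and CLI."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class LearnConfig:
    """Settings for structure learning and CPT estimation."""

    score: str = "bic"
    max_parents: int = 3
    pseudo_count: float = 1.0
    restarts: int = 1
    seed: int = 0
    whitelist: list[tuple] = field(default_factory=list)
    blacklist: list[tuple] = field(default_factory=list)

    def validate(self) -> None:
        if self.score != "bic":
            raise ValueError(f"unsupported score {self.score!r}")
        if self.max_parents < 0:
            raise ValueError("max_parents must be >= 0")
        if self.pseudo_count < 0:
            raise ValueError("pseudo_count must be >= 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class AnalysisConfig:
    """Settings for the sensitivity analyses.

    Defaults reproduce the published configuration: binary accident
    target, sector stratification, the six ergonomic/psychosocial study
    variables, and suppression of categories observed fewer than 25
    times (which drops physical-effort "always").
    """

    target: str = "V1"
    positive: str = "yes"
    sector: str = "V2"
    study_variables: tuple[str, ...] = (
        "V24", "V25", "V26", "V27", "V28", "V29"
    )
    min_support: int = 25
    baseline_mode: str = "prior"  # prior | sector-prior for stratified sweeps


@dataclass
class ValidationConfig:
    """Settings for cross-validated ROC/AUC evaluation."""

    k: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
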