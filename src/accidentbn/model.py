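"""Model/Results interface over the accident-risk network.

`AccidentRiskModel` binds a categorical survey to a codebook and a
learning configuration; `fit()` learns (or accepts) a structure,
estimates CPTs, and returns an `AccidentRiskResults` carrying the
fitted network together with the sensitivity, validation and reporting
methods of the published analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .bn.dag import Dag
from .bn.fit import fit_cpts
from .bn.inference import posterior
from .bn.model import DiscreteBN
from .bn.structure import bic_score, learn_structure
from .codebook import Codebook, CodebookError, default_codebook
from .config import AnalysisConfig, LearnConfig, ValidationConfig
from .sensitivity import (
    SectorSensitivityTable,
    SensitivityTable,
    category_suppression,
    one_variable_table,
    prior_probability,
    sector_conditioned_table,
    two_variable_table,
)
from .survey import SurveyTable, filter_target_nonresponse
from .validation import RocResult, cross_validated_auc


class AccidentRiskModel:
    """Discrete Bayesian-network model of occupational-accident risk.

    Parameters
    ----------
    survey : SurveyTable
        Categorical worker records. Records with DK/NA on the target
        are dropped at construction (the published analysis keeps 8880
        of 8892 respondents).
    learn : LearnConfig, optional
        Structure-learning and estimation settings.
    analysis : AnalysisConfig, optional
        Target/positive-category/sector/study-variable settings.
    """

    def __init__(
        self,
        survey: SurveyTable,
        learn: LearnConfig | None = None,
        analysis: AnalysisConfig | None = None,
    ):
        self.analysis = analysis or AnalysisConfig()
        self.learn_config = learn or LearnConfig()
        self.learn_config.validate()
        if self.analysis.target not in survey.codebook:
            raise CodebookError(f"unknown target {self.analysis.target!r}")
        self.n_raw = survey.n
        self.survey = filter_target_nonresponse(survey, self.analysis.target)
        self.n_dropped = self.n_raw - self.survey.n

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        codebook: Codebook | None = None,
        **kwargs,
    ) -> "AccidentRiskModel":
        """Build a model from a DataFrame of integer category codes."""
        codebook = codebook or default_codebook()
        return cls(SurveyTable(codebook, data.copy()), **kwargs)

    def fit(self, structure: Dag | None = None) -> "AccidentRiskResults":
        """Learn the DAG (unless one is given) and estimate the CPTs."""
        cfg = self.learn_config
        if structure is None:
            structure = learn_structure(
                self.survey,
                score=cfg.score,
                max_parents=cfg.max_parents,
                seed=cfg.seed,
                restarts=cfg.restarts,
                whitelist=cfg.whitelist or None,
                blacklist=cfg.blacklist or None,
            )
        bn = fit_cpts(structure, self.survey, pseudo_count=cfg.pseudo_count)
        return AccidentRiskResults(model=self, bn=bn)


@dataclass
class AccidentRiskResults:
    """A fitted accident-risk network and the analyses built on it."""

    model: AccidentRiskModel
    bn: DiscreteBN
    _suppressed: dict = field(default_factory=dict, init=False, repr=False)

    @property
    def dag(self) -> Dag:
        return self.bn.dag

    @property
    def survey(self) -> SurveyTable:
        return self.model.survey

    @property
    def target(self) -> str:
        return self.model.analysis.target

    @property
    def positive(self) -> str:
        return self.model.analysis.positive

    # -- inference ---------------------------------------------------

    def posterior(self, target: str | None = None, evidence: dict | None = None):
        return posterior(self.bn, target or self.target, evidence)

    def prior_percent(self) -> float:
        """A-priori accident probability, in percent."""
        return prior_probability(self.bn, self.target, self.positive)

    def direct_neighbors(self, var_id: str | None = None) -> set[str]:
        """Variables directly linked (parent or child) to ``var_id``."""
        return self.bn.direct_neighbors(var_id or self.target)

    def bic(self) -> float:
        return bic_score(self.survey, self.dag)

    # -- sensitivity sweeps -----------------------------------------

    def suppressed_categories(self, var_id: str) -> list[str]:
        key = var_id
        if key not in self._suppressed:
            self._suppressed[key] = category_suppression(
                self.survey, var_id, self.model.analysis.min_support
            )
        return self._suppressed[key]

    def one_variable_sweep(
        self, var_id: str, baseline: float | None = None
    ) -> SensitivityTable:
        return one_variable_table(
            self.bn,
            self.target,
            var_id,
            baseline=baseline,
            positive=self.positive,
            suppressed=self.suppressed_categories(var_id),
            table=self.survey,
        )

    def sector_sweep(
        self, sweeps: list[tuple[str, int]] | None = None
    ) -> SectorSensitivityTable:
        """Sector-stratified sweep; defaults to each study variable at
        its highest-probability non-suppressed category."""
        if sweeps is None:
            sweeps = []
            for var_id in self.model.analysis.study_variables:
                tab = self.one_variable_sweep(var_id)
                best = max(
                    (r for r in tab.rows if r.status == "ok"),
                    key=lambda r: r.p_accident,
                )
                sweeps.append((var_id, best.evidence[var_id]))
        return sector_conditioned_table(
            self.bn,
            self.target,
            self.model.analysis.sector,
            sweeps,
            positive=self.positive,
        )

    def two_variable_sweep(
        self,
        var_a: str,
        var_b: str,
        sector_code: int | None = None,
    ) -> SensitivityTable:
        sector = (
            (self.model.analysis.sector, sector_code)
            if sector_code is not None
            else None
        )
        return two_variable_table(
            self.bn,
            self.target,
            var_a,
            var_b,
            sector=sector,
            min_support=self.model.analysis.min_support,
            positive=self.positive,
            suppressed_a=self.suppressed_categories(var_a),
            suppressed_b=self.suppressed_categories(var_b),
            table=self.survey,
        )

    # -- validation --------------------------------------------------

    def cross_validate(
        self, validation: ValidationConfig | None = None
    ) -> RocResult:
        cfg = validation or ValidationConfig()
        cfg.validate()
        return cross_validated_auc(
            self.survey,
            learn_config=self.model.learn_config,
            k=cfg.k,
            seed=cfg.seed,
            target=self.target,
            positive=self.positive,
        )

    # -- summary -----------------------------------------------------

    def summary(self) -> str:
        """Plain-text overview of the fitted network."""
        a = self.model.analysis
        lines = [
            "Accident-risk Bayesian network",
            "=" * 38,
            f"records (after target filtering): {self.survey.n}"
            + (f"  (dropped {self.model.n_dropped})" if self.model.n_dropped else ""),
            f"nodes: {len(self.dag.nodes)}   edges: {len(self.dag.edges)}",
            f"target: {a.target} ({a.positive})   sector: {a.sector}",
            f"BIC: {self.bic():.1f}",
            f"a-priori P({a.target}={a.positive}): {self.prior_percent():.2f}%",
            f"direct neighbors of {a.target}: "
            + (", ".join(sorted(self.direct_neighbors())) or "(none)"),
            "edges:",
        ]
        for u, v in sorted(self.dag.edges):
            lines.append(f"  {u} -> {v}")
        return "\n".join(lines)
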