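"""Evidence-sweep sensitivity analyses of accident probability.

The fitted network's a-priori accident probability is the no-evidence
posterior of the target. Sweeping the categories of one working
condition (optionally within a production sector), or of two conditions
jointly, yields conditional accident probabilities and their deltas
versus a baseline: the global prior for plain sweeps, the matching
per-sector prior for sector-conditioned sweeps. Rarely used categories
can be suppressed (the published analysis drops physical-effort
"always", observed only 24 times), and grid cells without training
support are reported as "—" rather than as numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bn.model import DiscreteBN, ImpossibleEvidenceError
from .bn.inference import posterior
from .codebook import CodebookError
from .survey import SurveyTable, round_half_up

#: Default minimum training-row support for a sweep cell; calibrated so
#: the physical-effort "always" category (24 respondents) is suppressed.
DEFAULT_MIN_SUPPORT = 25


@dataclass
class SensitivityRow:
    """One evidence configuration of a sweep."""

    evidence: dict
    labels: dict
    p_accident: float | None  # percent, unrounded
    delta: float | None  # percent vs baseline, unrounded
    support: int | None = None
    status: str = "ok"  # ok | no_support


@dataclass
class SensitivityTable:
    """A one- or two-variable evidence sweep against a fitted network."""

    target: str
    positive_label: str
    baseline_percent: float
    rows: list[SensitivityRow]
    swept: tuple[str, ...]
    sector: tuple[str, int] | None = None
    suppressed: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            rec = dict(row.labels)
            rec["% ACC"] = (
                round_half_up(row.p_accident, 2)
                if row.p_accident is not None
                else None
            )
            rec["% VAR"] = (
                round_half_up(row.delta, 2) if row.delta is not None else None
            )
            rec["support"] = row.support
            rec["status"] = row.status
            recs.append(rec)
        return pd.DataFrame(recs)


def _positive_index(bn: DiscreteBN, target: str, positive) -> int:
    var = bn.codebook[target]
    if isinstance(positive, str):
        return var.categories.index(positive)
    return int(positive) - 1


def prior_probability(bn: DiscreteBN, target: str, positive=1) -> float:
    """A-priori probability (in percent) of the positive target category."""
    post = posterior(bn, target, {})
    return 100.0 * float(post.distribution[_positive_index(bn, target, positive)])


def _support(table: SurveyTable | None, evidence: dict) -> int | None:
    if table is None:
        return None
    mask = np.ones(table.n, dtype=bool)
    for var_id, code in evidence.items():
        mask &= table.column(var_id) == code
    return int(mask.sum())


def category_suppression(
    table: SurveyTable, var_id: str, min_n: int = DEFAULT_MIN_SUPPORT
) -> list[str]:
    """Substantive categories of ``var_id`` observed fewer than ``min_n``
    times, by label."""
    from .survey import category_counts

    var = table.codebook[var_id]
    counts = category_counts(table, var_id)
    return [lab for lab in var.categories if counts[lab] < min_n]


def _delta(p: float, baseline: float) -> float:
    return p - baseline


def one_variable_table(
    bn: DiscreteBN,
    target: str,
    var_id: str,
    baseline: float | None = None,
    positive=1,
    suppressed: list[str] | None = None,
    table: SurveyTable | None = None,
    min_support: int = 0,
) -> SensitivityTable:
    """Sweep the categories of one variable as evidence.

    One row per non-suppressed substantive category, ordered by code;
    deltas are versus ``baseline`` (default: the network's prior).
    """
    if var_id == target:
        raise CodebookError("cannot sweep the target variable itself")
    var = bn.codebook[var_id]
    tvar = bn.codebook[target]
    if baseline is None:
        baseline = prior_probability(bn, target, positive)
    suppressed = list(suppressed or [])
    pos_idx = _positive_index(bn, target, positive)
    rows = []
    for code in range(1, var.n_categories + 1):
        label = var.categories[code - 1]
        if label in suppressed:
            continue
        evidence = {var_id: code}
        support = _support(table, evidence)
        try:
            post = posterior(bn, target, evidence)
            p = 100.0 * float(post.distribution[pos_idx])
        except ImpossibleEvidenceError:
            p = None
        if p is None or (support is not None and support < min_support):
            rows.append(
                SensitivityRow(evidence, {var_id: label}, None, None,
                               support, "no_support")
            )
        else:
            rows.append(
                SensitivityRow(evidence, {var_id: label}, p,
                               _delta(p, baseline), support, "ok")
            )
    return SensitivityTable(
        target=target,
        positive_label=tvar.categories[pos_idx],
        baseline_percent=baseline,
        rows=rows,
        swept=(var_id,),
        suppressed={var_id: suppressed} if suppressed else {},
    )


@dataclass
class SectorSensitivityTable:
    """Per-sector conditional accident probabilities for selected
    (variable, category) sweeps; the header row carries sector priors."""

    target: str
    sector_var: str
    priors: dict  # column label -> a-priori percent
    values: pd.DataFrame  # rows: (variable, category label); cols: Total + sectors
    deltas: pd.DataFrame  # same shape, vs the matching column prior


def sector_conditioned_table(
    bn: DiscreteBN,
    target: str,
    sector_var: str,
    sweeps: list[tuple[str, int]],
    positive=1,
) -> SectorSensitivityTable:
    """Accident probability for chosen evidence, overall and by sector.

    ``sweeps`` lists (variable id, category code) pairs. Each cell is
    100*P(target=positive | sector=s, var=c); the "Total" column drops
    the sector conditioning. Deltas are versus the same column's prior.
    """
    svar = bn.codebook[sector_var]
    if svar.n_categories < 2:
        raise CodebookError("sector variable needs >= 2 categories")
    pos_idx = _positive_index(bn, target, positive)
    columns = ["Total"] + list(svar.categories)
    priors = {"Total": prior_probability(bn, target, positive)}
    for s_code, s_label in enumerate(svar.categories, start=1):
        post = posterior(bn, target, {sector_var: s_code})
        priors[s_label] = 100.0 * float(post.distribution[pos_idx])
    values, deltas, index = [], [], []
    for var_id, code in sweeps:
        if var_id in (sector_var, target):
            raise CodebookError(
                f"cannot sweep {var_id} in a sector-conditioned table"
            )
        var = bn.codebook[var_id]
        row_v, row_d = [], []
        for col in columns:
            evidence = {var_id: code}
            if col != "Total":
                evidence[sector_var] = svar.categories.index(col) + 1
            post = posterior(bn, target, evidence)
            p = 100.0 * float(post.distribution[pos_idx])
            row_v.append(p)
            row_d.append(_delta(p, priors[col]))
        values.append(row_v)
        deltas.append(row_d)
        index.append((var_id, var.categories[code - 1]))
    idx = pd.MultiIndex.from_tuples(index, names=["variable", "category"])
    return SectorSensitivityTable(
        target=target,
        sector_var=sector_var,
        priors=priors,
        values=pd.DataFrame(values, index=idx, columns=columns),
        deltas=pd.DataFrame(deltas, index=idx, columns=columns),
    )


def two_variable_table(
    bn: DiscreteBN,
    target: str,
    var_a: str,
    var_b: str,
    sector: tuple[str, int] | None = None,
    min_support: int = DEFAULT_MIN_SUPPORT,
    positive=1,
    suppressed_a: list[str] | None = None,
    suppressed_b: list[str] | None = None,
    table: SurveyTable | None = None,
    baseline: float | None = None,
) -> SensitivityTable:
    """Joint sweep over the categories of two variables.

    Cells whose evidence has training support below ``min_support`` (or
    probability zero under the network) get status ``no_support`` and
    render as a dash.
    """
    names = {target, var_a, var_b} | ({sector[0]} if sector else set())
    if len(names) != (4 if sector else 3):
        raise CodebookError("target, swept variables and sector must differ")
    va, vb = bn.codebook[var_a], bn.codebook[var_b]
    tvar = bn.codebook[target]
    pos_idx = _positive_index(bn, target, positive)
    base_evidence = {sector[0]: sector[1]} if sector else {}
    if baseline is None:
        if sector:
            post = posterior(bn, target, dict(base_evidence))
            baseline = 100.0 * float(post.distribution[pos_idx])
        else:
            baseline = prior_probability(bn, target, positive)
    sup_a = set(suppressed_a or [])
    sup_b = set(suppressed_b or [])
    rows = []
    for ca in range(1, va.n_categories + 1):
        la = va.categories[ca - 1]
        if la in sup_a:
            continue
        for cb in range(1, vb.n_categories + 1):
            lb = vb.categories[cb - 1]
            if lb in sup_b:
                continue
            evidence = dict(base_evidence)
            evidence[var_a] = ca
            evidence[var_b] = cb
            labels = {var_a: la, var_b: lb}
            if sector:
                labels[sector[0]] = bn.codebook[sector[0]].categories[sector[1] - 1]
            support = _support(table, evidence)
            try:
                post = posterior(bn, target, evidence)
                p = 100.0 * float(post.distribution[pos_idx])
            except ImpossibleEvidenceError:
                p = None
            if p is None or (support is not None and support < min_support):
                rows.append(
                    SensitivityRow(evidence, labels, None, None,
                                   support, "no_support")
                )
            else:
                rows.append(
                    SensitivityRow(evidence, labels, p, _delta(p, baseline),
                                   support, "ok")
                )
    return SensitivityTable(
        target=target,
        positive_label=tvar.categories[pos_idx],
        baseline_percent=baseline,
        rows=rows,
        swept=(var_a, var_b),
        sector=sector,
        suppressed={
            k: sorted(v)
            for k, v in ((var_a, sup_a), (var_b, sup_b))
            if v
        },
    )
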