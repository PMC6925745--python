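import numpy as np
import pandas as pd
import pytest

from accidentbn.bn import Dag, posterior
from accidentbn.bn.model import Cpt, DiscreteBN
from accidentbn.codebook import CodebookError
from accidentbn.sensitivity import (
    category_suppression,
    one_variable_table,
    prior_probability,
    sector_conditioned_table,
    two_variable_table,
)
from accidentbn.survey import SurveyTable

from oracles import random_bn, toy_codebook


@pytest.fixture(scope="module")
def random_net():
    return random_bn(np.random.default_rng(7), 5)


class TestPrior:
    def test_constructed_marginal_recovered(self):
        cb = toy_codebook([2])
        bn = DiscreteBN(
            cb, Dag(cb.ids), {"X1": Cpt("X1", (), np.array([0.0738, 0.9262]))}
        )
        assert prior_probability(bn, "X1", 1) == pytest.approx(7.38, abs=0.01)

    def test_point_mass(self):
        cb = toy_codebook([2])
        bn = DiscreteBN(
            cb, Dag(cb.ids), {"X1": Cpt("X1", (), np.array([1.0, 0.0]))}
        )
        assert prior_probability(bn, "X1", 1) == 100.0
        assert prior_probability(bn, "X1", 2) == 0.0

    def test_positive_category_by_label(self, truth_bn):
        assert prior_probability(truth_bn, "V1", "yes") == pytest.approx(
            prior_probability(truth_bn, "V1", 1)
        )


class TestOneVariableSweep:
    def test_delta_plus_baseline_reconstructs_probability(self, random_net):
        baseline = prior_probability(random_net, "X1", 1)
        table = one_variable_table(random_net, "X1", "X3", baseline=baseline)
        for row in table.rows:
            assert row.p_accident - row.delta == pytest.approx(baseline, abs=1e-12)

    def test_rows_match_direct_posterior(self, random_net):
        table = one_variable_table(random_net, "X1", "X4")
        for row in table.rows:
            expected = 100 * posterior(random_net, "X1", row.evidence)[1]
            assert row.p_accident == pytest.approx(expected, abs=1e-12)

    def test_law_of_total_probability_ties_sweep_to_prior(self, random_net):
        """sum_c P(target|v=c) P(v=c) equals the prior marginal."""
        table = one_variable_table(random_net, "X1", "X2")
        weights = posterior(random_net, "X2", {}).distribution
        mix = sum(
            row.p_accident * w for row, w in zip(table.rows, weights)
        )
        assert mix == pytest.approx(
            prior_probability(random_net, "X1", 1), abs=1e-10
        )

    def test_sweeping_target_rejected(self, random_net):
        with pytest.raises(CodebookError):
            one_variable_table(random_net, "X1", "X1")

    def test_suppressed_category_dropped(self, truth_bn):
        table = one_variable_table(
            truth_bn, "V1", "V24", suppressed=["always"]
        )
        labels = [r.labels["V24"] for r in table.rows]
        assert labels == ["often", "at times", "rarely", "never"]

    def test_monotone_ground_truth_sweep(self, truth_bn):
        """The generating network raises accident risk with physical
        effort, so the sweep decreases from always to never."""
        table = one_variable_table(truth_bn, "V1", "V24")
        probs = [r.p_accident for r in table.rows]
        assert all(a > b for a, b in zip(probs, probs[1:]))


class TestSectorTable:
    def test_cells_equal_two_item_posteriors(self, random_net):
        out = sector_conditioned_table(
            random_net, "X1", "X2", [("X3", 1), ("X4", 2)]
        )
        for (var, cat), row in out.values.iterrows():
            code = random_net.codebook[var].code_of(cat)
            for col in out.values.columns:
                evidence = {var: code}
                if col != "Total":
                    evidence["X2"] = (
                        random_net.codebook["X2"].code_of(col)
                    )
                expected = 100 * posterior(random_net, "X1", evidence)[1]
                assert row[col] == pytest.approx(expected, abs=1e-12)

    def test_total_column_equals_unconditioned_sweep(self, random_net):
        out = sector_conditioned_table(random_net, "X1", "X2", [("X3", 2)])
        sweep = one_variable_table(random_net, "X1", "X3")
        assert out.values.loc[("X3", "c2"), "Total"] == pytest.approx(
            sweep.rows[1].p_accident, abs=1e-12
        )

    def test_deltas_use_matching_sector_prior(self, random_net):
        out = sector_conditioned_table(random_net, "X1", "X2", [("X3", 1)])
        for col in out.values.columns:
            assert out.deltas.iloc[0][col] == pytest.approx(
                out.values.iloc[0][col] - out.priors[col], abs=1e-12
            )

    def test_sweeping_the_sector_itself_rejected(self, random_net):
        with pytest.raises(CodebookError):
            sector_conditioned_table(random_net, "X1", "X2", [("X2", 1)])


class TestTwoVariableGrid:
    def test_cells_equal_direct_posteriors(self, random_net):
        grid = two_variable_table(
            random_net, "X1", "X3", "X4", min_support=0
        )
        for row in grid.rows:
            expected = 100 * posterior(random_net, "X1", row.evidence)[1]
            assert row.p_accident == pytest.approx(expected, abs=1e-12)

    def test_sector_conditioned_cells(self, random_net):
        grid = two_variable_table(
            random_net, "X1", "X3", "X4", sector=("X2", 1), min_support=0
        )
        for row in grid.rows:
            assert row.evidence["X2"] == 1
            expected = 100 * posterior(random_net, "X1", row.evidence)[1]
            assert row.p_accident == pytest.approx(expected, abs=1e-12)

    def test_min_support_zero_on_positive_bn_has_no_dashes(self, random_net):
        grid = two_variable_table(random_net, "X1", "X3", "X4", min_support=0)
        assert all(r.status == "ok" for r in grid.rows)

    def test_unsupported_combination_dashes(self, truth_bn):
        # a training table in which (V24=1, V27=5) never occurs
        cb = truth_bn.codebook
        frame = pd.DataFrame({v: np.ones(50, dtype=int) for v in cb.ids})
        frame["V24"] = [2] * 50
        table = SurveyTable(cb, frame)
        grid = two_variable_table(
            truth_bn, "V1", "V24", "V27", min_support=1, table=table
        )
        by_labels = {
            (r.labels["V24"], r.labels["V27"]): r for r in grid.rows
        }
        assert by_labels[("always", "never")].status == "no_support"
        assert by_labels[("always", "never")].p_accident is None
        assert by_labels[("often", "always")].status == "ok"

    def test_overlapping_roles_rejected(self, random_net):
        with pytest.raises(CodebookError):
            two_variable_table(random_net, "X1", "X3", "X3")
        with pytest.raises(CodebookError):
            two_variable_table(
                random_net, "X1", "X3", "X4", sector=("X3", 1)
            )


class TestSuppression:
    def test_published_counts_suppress_always(self, codebook):
        # rebuild the physical-effort marginal exactly from the codebook
        counts = codebook["V24"].reference_counts
        col = np.concatenate(
            [np.full(k, c + 1) for c, k in enumerate(counts)]
        ).astype(int)
        frame = pd.DataFrame({v: np.ones(len(col), dtype=int) for v in codebook.ids})
        frame["V24"] = col
        table = SurveyTable(codebook, frame)
        assert category_suppression(table, "V24", min_n=30) == ["always"]
        assert category_suppression(table, "V24", min_n=25) == ["always"]
        assert category_suppression(table, "V24", min_n=0) == []

    def test_flags_match_direct_tally(self, raw_survey):
        from accidentbn.survey import category_counts

        for vid in ("V24", "V29"):
            var = raw_survey.codebook[vid]
            counts = category_counts(raw_survey, vid)
            expected = [
                lab for lab in var.categories if counts[lab] < 100
            ]
            assert category_suppression(raw_survey, vid, 100) == expected
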