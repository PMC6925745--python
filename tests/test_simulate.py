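import numpy as np
import pytest

from accidentbn.simulate import (
    GeneratorError,
    GeneratorSpec,
    build_ground_truth,
    default_generator_spec,
    implied_marginals,
    inject_nonresponse,
    mask_exact,
    recovery_experiment,
    sample_survey,
)
from accidentbn.survey import filter_target_nonresponse

from oracles import toy_codebook


def _toy_spec(effects=(), n=100, seed=0, **kwargs):
    cb = toy_codebook([2, 3, 4])
    targets = {
        "X1": np.array([0.3, 0.7]),
        "X2": np.array([0.2, 0.3, 0.5]),
        "X3": np.array([0.1, 0.2, 0.3, 0.4]),
    }
    return GeneratorSpec(
        codebook=cb, marginal_targets=targets, effects=list(effects),
        n=n, seed=seed, target="X1", **kwargs
    )


class TestSpecValidation:
    def test_targets_must_be_distributions(self):
        spec_args = _toy_spec().__dict__.copy()
        spec_args["marginal_targets"] = dict(spec_args["marginal_targets"])
        spec_args["marginal_targets"]["X1"] = np.array([0.5, 0.6])
        with pytest.raises(GeneratorError, match="X1"):
            GeneratorSpec(**spec_args)

    def test_cyclic_effects_rejected(self):
        from accidentbn.simulate import Effect

        with pytest.raises(Exception):
            _toy_spec(effects=[
                Effect("X1", "X2", np.ones((2, 3))),
                Effect("X2", "X1", np.ones((3, 2))),
            ])

    def test_nonresponse_rate_needs_dkna_or_target(self):
        with pytest.raises(GeneratorError, match="X2"):
            _toy_spec(nonresponse_rates={"X2": 0.1})

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(GeneratorError):
            _toy_spec(nonresponse_rates={"X1": 1.5})


class TestGroundTruth:
    def test_no_effects_marginals_exact(self):
        spec = _toy_spec()
        truth = build_ground_truth(spec)
        for var, target in spec.marginal_targets.items():
            np.testing.assert_allclose(
                implied_marginals(truth)[var], target, atol=1e-12
            )

    def test_effects_still_hit_marginals(self):
        from accidentbn.simulate import Effect

        spec = _toy_spec(effects=[
            Effect("X2", "X1", np.array([[3.0, 1], [1.5, 1], [1.0, 1]])),
            Effect("X2", "X3", np.tile([[2.0, 1.5, 1.0, 0.5]], (3, 1))),
        ])
        truth = build_ground_truth(spec)
        marg = implied_marginals(truth)
        for var, target in spec.marginal_targets.items():
            assert np.abs(marg[var] - target).max() < 1e-3

    def test_effect_actually_tilts_conditionals(self):
        from accidentbn.bn import posterior
        from accidentbn.simulate import Effect

        spec = _toy_spec(effects=[
            Effect("X2", "X1", np.array([[3.0, 1], [1.5, 1], [1.0, 1]])),
        ])
        truth = build_ground_truth(spec)
        p = [posterior(truth, "X1", {"X2": c})[1] for c in (1, 2, 3)]
        assert p[0] > p[1] > p[2]

    def test_default_spec_accident_prior(self, truth_bn):
        assert implied_marginals(truth_bn)["V1"][0] == pytest.approx(
            0.0738, abs=1e-3
        )

    def test_shape_mismatch_reported(self):
        from accidentbn.simulate import Effect

        spec = _toy_spec(effects=[Effect("X2", "X1", np.ones((2, 2)))])
        with pytest.raises(GeneratorError, match="X2->X1"):
            build_ground_truth(spec)


class TestSampling:
    def test_zero_records(self, truth_bn):
        assert sample_survey(truth_bn, 0, seed=0).n == 0

    def test_same_seed_identical(self, truth_bn):
        a = sample_survey(truth_bn, 500, seed=4)
        b = sample_survey(truth_bn, 500, seed=4)
        assert a.equals(b)
        c = sample_survey(truth_bn, 500, seed=5)
        assert not a.equals(c)

    def test_frequencies_concentrate_on_implied_marginals(self, truth_bn):
        n = 100000
        table = sample_survey(truth_bn, n, seed=8)
        marg = implied_marginals(truth_bn)
        for vid in ("V1", "V2", "V24", "V27", "V14"):
            var = table.codebook[vid]
            col = table.column(vid)
            for idx, p in enumerate(marg[vid]):
                code = 0 if (var.dkna and idx == var.n_categories) else idx + 1
                freq = (col == code).mean()
                bound = 3 * np.sqrt(p * (1 - p) / n) + 1e-9
                assert abs(freq - p) <= bound, (vid, code)


class TestNonresponse:
    def test_zero_rates_identity(self, truth_bn, generator_spec):
        table = sample_survey(truth_bn, 200, seed=1)
        assert inject_nonresponse(table, generator_spec).equals(table)

    def test_target_masking_rate_matches_field_survey(self, truth_bn):
        spec = default_generator_spec(n=8892, seed=3)
        spec.nonresponse_rates = {"V1": 12 / 8892}
        table = sample_survey(truth_bn, 8892, seed=3)
        masked = inject_nonresponse(table, spec)
        count = int((masked.column("V1") == 0).sum())
        lam = 12.0
        assert abs(count - lam) <= 3 * np.sqrt(lam)

    def test_masking_then_filter_removes_all(self, truth_bn):
        spec = default_generator_spec(n=2000, seed=5)
        spec.nonresponse_rates = {"V1": 0.05}
        table = inject_nonresponse(
            sample_survey(truth_bn, 2000, seed=5), spec
        )
        filtered = filter_target_nonresponse(table, "V1")
        assert (filtered.column("V1") != 0).all()

    def test_mask_exact_count(self, truth_bn):
        table = sample_survey(truth_bn, 1000, seed=6)
        masked = mask_exact(table, "V1", 12, seed=7)
        assert int((masked.column("V1") == 0).sum()) == 12


class TestRecovery:
    def test_self_consistency_on_chain(self):
        from accidentbn.simulate import Effect

        spec = _toy_spec(effects=[
            Effect("X1", "X2", np.array([[4.0, 1.0, 0.5], [1.0, 1.0, 1.0]])),
            Effect("X2", "X3", np.array([
                [4.0, 2.0, 1.0, 0.5],
                [1.0, 1.0, 1.0, 1.0],
                [0.5, 1.0, 2.0, 4.0],
            ])),
        ])
        report = recovery_experiment(spec, n_list=[30000], seeds=[0, 1, 2])
        assert report.skeleton_recall == 1.0

    def test_mean_cpt_error_shrinks_with_n(self, generator_spec):
        report = recovery_experiment(
            generator_spec, n_list=[1000, 4000, 16000], seeds=[0, 1, 2]
        )
        means = report.runs.groupby("n")["mean_cpt_error"].mean()
        assert means.loc[16000] <= means.loc[1000] + 1e-6

    def test_empty_seed_list_rejected(self, generator_spec):
        with pytest.raises(GeneratorError):
            recovery_experiment(generator_spec, seeds=[])
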