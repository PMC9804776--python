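import numpy as np
import pytest

from phylometa import mlmeta
from phylometa.mlmeta import (
    ModelSpec,
    RandomTermStruct,
    RankDeficiencyError,
    build_design,
    build_model,
    drop_random_term,
    fit_reml,
    heterogeneity,
    lrt_random_effect,
    typical_sampling_variance,
    wald_tests,
)
from phylometa.phylo import PhyloCorrelation

from conftest import make_record
from reml_oracle import brute_force_reml


def _single_term_spec(y, v):
    n = len(y)
    return ModelSpec(
        y=np.asarray(y, float),
        v=np.asarray(v, float),
        X=np.ones((n, 1)),
        fixed_names=["intercept"],
        random_terms=[RandomTermStruct("estimate", np.eye(n))],
    )


class TestFitREML:
    def test_two_study_closed_form(self):
        # For two estimates with equal v the REML optimum is exactly
        # mu = mean(y), tau2 = (y1 - y2)^2 / 2 - v.
        fit = fit_reml(_single_term_spec([0.4, 0.6], [0.01, 0.01]))
        assert fit.beta[0] == pytest.approx(0.5, abs=1e-10)
        assert fit.components["estimate"] == pytest.approx(0.01, abs=1e-8)

    def test_identical_responses_give_zero_components(self):
        fit = fit_reml(_single_term_spec([0.3] * 6, [0.01] * 6))
        assert fit.components["estimate"] == pytest.approx(0.0, abs=1e-10)
        assert fit.beta[0] == pytest.approx(0.3, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle_one_component(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 12)
        v = rng.uniform(0.005, 0.05, n)
        y = 0.4 + rng.normal(0, 0.25, n) + rng.normal(0, np.sqrt(v))
        spec = _single_term_spec(y, v)
        fit = fit_reml(spec)
        oracle, oracle_ll = brute_force_reml(spec)
        assert fit.components["estimate"] == pytest.approx(oracle[0], abs=1e-4)
        assert fit.loglik >= oracle_ll - 1e-6

    @pytest.mark.parametrize("seed", [4, 5, 6])
    def test_matches_brute_force_oracle_two_components(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        studies = [f"s{i % 4}" for i in range(n)]
        Z = np.array([[1.0 if studies[i] == f"s{j}" else 0.0 for j in range(4)]
                      for i in range(n)])
        u = rng.normal(0, 0.3, 4)
        v = rng.uniform(0.005, 0.03, n)
        y = 0.5 + Z @ u + rng.normal(0, 0.1, n) + rng.normal(0, np.sqrt(v))
        spec = ModelSpec(
            y=y, v=v, X=np.ones((n, 1)), fixed_names=["intercept"],
            random_terms=[
                RandomTermStruct("study", Z @ Z.T),
                RandomTermStruct("estimate", np.eye(n)),
            ],
        )
        fit = fit_reml(spec)
        oracle, oracle_ll = brute_force_reml(spec)
        for est, orc in zip(
            [fit.components["study"], fit.components["estimate"]], oracle
        ):
            assert est == pytest.approx(orc, abs=1e-4)
        assert fit.loglik >= oracle_ll - 1e-6

    def test_matches_metafor_on_frozen_fixture(self, small_dataset):
        # Expected values computed once with metafor::rma.mv (REML) on the
        # identical seed-11 dataset; see tests/oracles/metafor_crosscheck.R.
        records, _, A = small_dataset
        fit = fit_reml(build_model(records, A=A))
        assert fit.components["study"] == pytest.approx(0.02022644, abs=2e-6)
        assert fit.components["phylogeny"] == pytest.approx(0.02420262, abs=2e-6)
        assert fit.components["species"] == pytest.approx(0.01977811, abs=2e-6)
        assert fit.components["estimate"] == pytest.approx(0.002361926, abs=2e-6)
        assert fit.beta[0] == pytest.approx(0.5660325, abs=1e-5)
        assert fit.beta_se[0] == pytest.approx(0.1302326, abs=1e-5)
        assert fit.loglik == pytest.approx(11.2961, abs=2e-3)

    def test_phylogeny_with_identity_matrix_equals_species_term(self):
        records = [
            make_record(estimate_id=f"e{i}", study_id=f"s{i // 3}",
                        species=f"sp{i % 4}", h2=0.3 + 0.05 * (i % 5), se=0.08)
            for i in range(12)
        ]
        A = PhyloCorrelation.identity([f"sp{i}" for i in range(4)])
        f_phylo = fit_reml(
            build_model(records, random_terms=("phylogeny", "estimate"), A=A)
        )
        f_species = fit_reml(build_model(records, random_terms=("species", "estimate")))
        assert f_phylo.components["phylogeny"] == pytest.approx(
            f_species.components["species"], abs=1e-6
        )
        assert f_phylo.loglik == pytest.approx(f_species.loglik, abs=1e-8)

    def test_shift_equivariance(self, small_dataset):
        records, _, A = small_dataset
        spec = build_model(records, A=A)
        shifted = ModelSpec(
            y=spec.y + 2.0, v=spec.v, X=spec.X,
            fixed_names=spec.fixed_names, random_terms=spec.random_terms,
        )
        base, moved = fit_reml(spec), fit_reml(shifted)
        assert moved.beta[0] == pytest.approx(base.beta[0] + 2.0, abs=1e-6)
        for name in base.components:
            assert moved.components[name] == pytest.approx(
                base.components[name], abs=1e-6
            )

    def test_scale_equivariance(self, small_dataset):
        records, _, A = small_dataset
        spec = build_model(records, A=A)
        c = 3.0
        scaled = ModelSpec(
            y=c * spec.y, v=c**2 * spec.v, X=spec.X,
            fixed_names=spec.fixed_names, random_terms=spec.random_terms,
        )
        base, moved = fit_reml(spec), fit_reml(scaled)
        assert moved.beta[0] == pytest.approx(c * base.beta[0], abs=1e-6)
        for name in base.components:
            assert moved.components[name] == pytest.approx(
                c**2 * base.components[name], rel=1e-3, abs=1e-6
            )


class TestBuildModel:
    def test_intercept_only_counts(self, small_dataset):
        records, _, A = small_dataset
        spec = build_model(records, A=A)
        assert spec.X.shape == (len(records), 1)
        assert spec.term_names == ["study", "phylogeny", "species", "estimate"]

    def test_full_moderator_design_has_twelve_columns(self, paper_scale_dataset):
        records, _, A, _ = paper_scale_dataset
        X, names = build_design(records, mlmeta.MODERATORS)
        assert X.shape[1] == 12
        assert names[0] == "intercept"
        # treatment coding: reference levels never appear as columns
        assert not any("TRF_southern" in n or "[adult]" in n for n in names)

    def test_reference_level_override(self, paper_scale_dataset):
        records, _, A, _ = paper_scale_dataset
        _, names = build_design(
            records, ["statistical_method"], references={"statistical_method": "SNP"}
        )
        assert "statistical_method[correlation]" in names
        assert "statistical_method[SNP]" not in names

    def test_single_level_moderator_is_rank_deficient(self):
        records = [
            make_record(estimate_id=f"e{i}", environmental_setting="natural")
            for i in range(5)
        ]
        with pytest.raises(ValueError, match="absent"):
            build_design(records, ["environmental_setting"])

    def test_aliased_columns_named(self):
        # two perfectly confounded moderators
        records = [
            make_record(
                estimate_id=f"e{i}",
                environmental_setting="artificial" if i % 2 else "natural",
                repeated_measurement="yes" if i % 2 else "no",
            )
            for i in range(8)
        ]
        with pytest.raises(RankDeficiencyError, match="aliased"):
            build_design(records, ["environmental_setting", "repeated_measurement"])

    def test_missing_phylo_matrix(self, small_dataset):
        records, _, _ = small_dataset
        with pytest.raises(ValueError, match="correlation matrix"):
            build_model(records, random_terms=("phylogeny",), A=None)


class TestHeterogeneity:
    def test_equal_variances_return_common_value(self):
        assert typical_sampling_variance([0.01] * 4) == pytest.approx(0.01)
        assert typical_sampling_variance([0.37] * 9) == pytest.approx(0.37)

    def test_hand_computed_two_values(self):
        # w = {100, 25}: (2-1) * 125 / (125^2 - 10625) = 0.025
        assert typical_sampling_variance([0.01, 0.04]) == pytest.approx(0.025)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            typical_sampling_variance([0.01])

    def test_direct_decomposition(self):
        fit = _fake_fit({"study": 0.6, "phylogeny": 0.2, "species": 0.1,
                         "estimate": 0.05})
        report = heterogeneity(fit, sigma_m2=0.05)
        assert report.i2 == pytest.approx(0.95)
        assert report.proportions["study"] == pytest.approx(0.6)
        assert sum(report.proportions.values()) == pytest.approx(1.0, abs=1e-10)

    def test_no_heterogeneity(self):
        fit = _fake_fit({"estimate": 0.0})
        report = heterogeneity(fit, sigma_m2=0.02)
        assert report.i2 == pytest.approx(0.0)

    def test_all_zero_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            heterogeneity(_fake_fit({"estimate": 0.0}), sigma_m2=0.0)


class TestWald:
    def test_published_style_coefficient(self):
        fit = _fake_fit({}, beta=[0.390], se=[0.182])
        row = wald_tests(fit).iloc[0]
        assert row["z"] == pytest.approx(2.14, abs=0.01)
        assert row["p"] == pytest.approx(0.032, abs=0.002)
        assert row["ci_low"] == pytest.approx(0.033, abs=0.002)
        assert row["ci_high"] == pytest.approx(0.747, abs=0.002)

    def test_null_coefficient(self):
        row = wald_tests(_fake_fit({}, beta=[0.0], se=[0.1])).iloc[0]
        assert row["z"] == 0.0
        assert row["p"] == pytest.approx(1.0)

    def test_boundary_of_significance(self):
        row = wald_tests(_fake_fit({}, beta=[1.959963984540054 * 0.1], se=[0.1])).iloc[0]
        assert row["p"] == pytest.approx(0.05, abs=1e-10)


class TestLRT:
    def test_zero_component_gives_null_result(self):
        spec = _single_term_spec([0.3] * 8, [0.01] * 8)
        two = ModelSpec(
            y=spec.y, v=spec.v, X=spec.X, fixed_names=spec.fixed_names,
            random_terms=[
                RandomTermStruct("study", np.ones((8, 8))),
                RandomTermStruct("estimate", np.eye(8)),
            ],
        )
        full = fit_reml(two)
        reduced = fit_reml(drop_random_term(two, "study"))
        out = lrt_random_effect(full, reduced)
        assert out["statistic"] == pytest.approx(0.0, abs=1e-6)
        assert out["p"] == pytest.approx(1.0, abs=1e-4)

    def test_strong_component_detected(self, small_dataset):
        records, _, A = small_dataset
        spec = build_model(records, A=A)
        full = fit_reml(spec)
        reduced = fit_reml(drop_random_term(spec, "study"))
        out = lrt_random_effect(full, reduced)
        assert out["statistic"] >= 0.0
        assert 0.0 <= out["p"] <= 1.0
        boundary = lrt_random_effect(full, reduced, boundary_mixture=True)
        if out["statistic"] > 0:
            assert boundary["p"] == pytest.approx(out["p"] / 2)

    def test_mismatched_models_rejected(self, small_dataset):
        records, _, A = small_dataset
        spec = build_model(records, A=A)
        full = fit_reml(spec)
        other = build_model(records, moderators=["environmental_setting"], A=A)
        with pytest.raises(ValueError):
            lrt_random_effect(full, fit_reml(drop_random_term(other, "study")))


def _fake_fit(components, beta=(0.0,), se=(1.0,)):
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    n = 4
    spec = ModelSpec(
        y=np.zeros(n), v=np.full(n, 0.01), X=np.ones((n, 1)),
        fixed_names=["intercept"],
        random_terms=[RandomTermStruct(name, np.eye(n)) for name in components],
    )
    return mlmeta.FitResult(
        spec=spec, components=dict(components), beta=beta, beta_se=se,
        beta_cov=np.diag(se**2), fixed_names=[f"b{i}" for i in range(len(beta))],
        loglik=0.0, converged=True, n_iter=1,
    )
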