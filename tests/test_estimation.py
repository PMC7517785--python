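"""Likelihood correctness, EM behaviour, model nesting, identification."""

import numpy as np
import pytest
from scipy.special import expit

from lgcdm import (
    AttributeGrowthParameters,
    ItemParameters,
    LongitudinalResponses,
    ModelSpec,
    QMatrix,
    TimeCoding,
    check_local_identification,
    fit,
    information_criteria,
    person_loglik,
    posterior_mode_penalty,
)
from lgcdm.simulation import simulate_dataset

from _oracles import brute_person_loglik


def _random_instance(rng):
    """A random small model + response array for oracle comparison."""
    J = int(rng.integers(1, 4))
    K = int(rng.integers(1, 3))
    T = int(rng.integers(1, 4))
    q = np.zeros((J, K), int)
    for j in range(J):
        q[j, rng.integers(0, K)] = 1
    if rng.random() < 0.5:
        q[rng.integers(0, J)] = 1
    family = rng.choice(
        ["lg_uncond", "lg_cond", "rdina", "rdina_cov"]
        if T >= 2
        else ["rdina", "rdina_cov"]
    )
    has_cov = family in ("lg_cond", "rdina_cov")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spec = ModelSpec(
            family=family,
            qmatrix=QMatrix(q),
            time_coding=TimeCoding(np.arange(T, dtype=float)),
            covariate_names=("z",) if has_cov else (),
            quadrature=5,
        )
    item = ItemParameters(f=rng.normal(0, 1, J), d=rng.normal(1, 1, J))
    attr = AttributeGrowthParameters(
        b=rng.normal(0, 1, K),
        sigma0=abs(rng.normal(0, 0.6)),
        sigma1=abs(rng.normal(0, 0.3)),
        h=rng.normal(0, 0.3, K) if has_cov else None,
        h0=rng.normal(0, 0.2) if family == "lg_cond" else 0.0,
        h1=rng.normal(0, 0.2) if family == "lg_cond" else 0.0,
        eps_sd=float(rng.choice([0.0, 1.0])) if family.startswith("lg") else 0.0,
    )
    y = (rng.random((T, J)) < 0.5).astype(float)
    if rng.random() < 0.3:
        y[rng.integers(0, T), rng.integers(0, J)] = np.nan
    z = float(rng.integers(0, 2))
    return spec, item, attr, y, z, has_cov


class TestPersonLoglik:
    def test_matches_brute_force_on_random_instances(self):
        """Vectorized marginal likelihood vs independent enumeration."""
        rng = np.random.default_rng(2024)
        for _ in range(120):
            spec, item, attr, y, z, has_cov = _random_instance(rng)
            got = person_loglik(spec, item, attr, y, z_i=z if has_cov else None)
            want = brute_person_loglik(spec, item, attr, y, z)
            assert got == pytest.approx(want, abs=1e-10)

    def test_degenerate_two_class_mixture(self):
        """One item, one attribute, no mixing: closed-form latent class lik."""
        spec = ModelSpec(
            family="rdina",
            qmatrix=QMatrix(np.array([[1]])),
            time_coding=TimeCoding(np.array([0.0])),
        )
        item = ItemParameters(f=[-1.0], d=[2.0])
        attr = AttributeGrowthParameters(b=[0.4], sigma0=0, sigma1=0, eps_sd=0)
        p_master = expit(0.4)
        for y in (0.0, 1.0):
            lik1 = expit(1.0) if y == 1 else 1 - expit(1.0)
            lik0 = expit(-1.0) if y == 1 else 1 - expit(-1.0)
            want = np.log(p_master * lik1 + (1 - p_master) * lik0)
            got = person_loglik(spec, item, attr, np.array([[y]]))
            assert got == pytest.approx(want, abs=1e-12)

    def test_total_probability_sums_to_one(self):
        import itertools

        spec = ModelSpec(
            family="lg_uncond",
            qmatrix=QMatrix(np.array([[1], [1]])),
            time_coding=TimeCoding(np.array([0.0, 1.0])),
            quadrature=5,
        )
        item = ItemParameters(f=[-1.0, 0.5], d=[2.0, 1.0])
        attr = AttributeGrowthParameters(b=[0.3], sigma0=0.5, sigma1=0.2)
        total = sum(
            np.exp(
                person_loglik(
                    spec, item, attr, np.array(bits, dtype=float).reshape(2, 2)
                )
            )
            for bits in itertools.product([0, 1], repeat=4)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_nonfinite_parameter_names_block(self):
        spec = ModelSpec(
            family="rdina",
            qmatrix=QMatrix(np.array([[1]])),
            time_coding=TimeCoding(np.array([0.0])),
        )
        item = ItemParameters(f=[np.nan], d=[1.0])
        attr = AttributeGrowthParameters(b=[0.0])
        with pytest.raises(FloatingPointError, match="'f'"):
            person_loglik(spec, item, attr, np.array([[1.0]]))


class TestFit:
    def test_em_history_is_monotone(self, small_design, small_data):
        res = fit(
            small_design.spec, small_data, n_starts=1, polish=False,
            compute_se=False, max_em_iter=60,
        )
        hist = np.asarray(res.em_history)
        assert np.all(np.diff(hist) >= -1e-8)

    def test_nested_conditional_matches_unconditional(self, small_design, small_data):
        """Fixing every covariate effect at zero reproduces the simpler model."""
        from dataclasses import replace

        unc = fit(small_design.spec, small_data, n_starts=1, compute_se=False)
        cond_spec = ModelSpec(
            family="lg_cond",
            qmatrix=small_design.spec.qmatrix,
            time_coding=small_design.spec.time_coding,
            covariate_names=("z",),
            quadrature=small_design.spec.quadrature,
            eps_sd=small_design.spec.eps_sd,
            constraints={"h": 0.0, "h0": 0.0, "h1": 0.0},
        )
        data_z = LongitudinalResponses(
            y=small_data.y, occasion_codes=small_data.occasion_codes,
            z=np.tile([0.0, 1.0], small_data.n_persons // 2),
        )
        cond = fit(cond_spec, data_z, n_starts=1, compute_se=False)
        assert cond.n_params == unc.n_params
        assert cond.loglik == pytest.approx(unc.loglik, abs=1e-6)

    def test_pm_with_huge_prior_matches_ml(self, small_design, small_data):
        from dataclasses import replace

        pm = fit(
            replace(small_design.spec, estimation="pm"), small_data,
            n_starts=1, prior_sd=1e6, compute_se=False,
        )
        ml = fit(
            replace(small_design.spec, estimation="ml"), small_data,
            n_starts=1, compute_se=False,
        )
        assert pm.loglik == pytest.approx(ml.loglik, abs=1e-4)

    def test_all_zero_responses_finite_under_pm(self, small_qmatrix):
        spec = ModelSpec(
            family="rdina", qmatrix=small_qmatrix,
            time_coding=TimeCoding(np.array([0.0])), estimation="pm",
        )
        data = LongitudinalResponses(
            y=np.zeros((20, 1, 6)), occasion_codes=np.array([0.0])
        )
        with pytest.warns(UserWarning):
            res = fit(spec, data, n_starts=1, compute_se=False)
        assert res.converged
        assert np.all(np.isfinite(res.item_params.f))
        assert np.all(np.isfinite(res.attr_params.b))

    def test_growth_model_needs_two_occasions(self, small_qmatrix):
        with pytest.raises(ValueError, match="at least 2"):
            ModelSpec(
                family="lg_uncond", qmatrix=small_qmatrix,
                time_coding=TimeCoding(np.array([0.0])),
            )

    def test_unknown_option_rejected(self, small_design, small_data):
        with pytest.raises(TypeError, match="unknown fit options"):
            fit(small_design.spec, small_data, bogus=1)

    def test_seeded_fit_is_reproducible(self, small_design, small_data):
        a = fit(small_design.spec, small_data, n_starts=3, seed=7, compute_se=False)
        b = fit(small_design.spec, small_data, n_starts=3, seed=7, compute_se=False)
        assert a.loglik == b.loglik
        np.testing.assert_array_equal(a.item_params.f, b.item_params.f)
        np.testing.assert_array_equal(a.attr_params.b, b.attr_params.b)

    def test_quadrature_refinement_stable(self, small_design, small_data):
        """The maximized loglik barely moves when nodes increase."""
        from dataclasses import replace

        res7 = fit(
            replace(small_design.spec, quadrature=9), small_data,
            n_starts=1, compute_se=False,
        )
        res15 = fit(
            replace(small_design.spec, quadrature=15), small_data,
            n_starts=1, compute_se=False,
        )
        assert res15.loglik == pytest.approx(res7.loglik, abs=1e-3)

    def test_standard_errors_shrink_with_n(self, small_design):
        from dataclasses import replace

        small = replace(small_design, n_persons=150)
        big = replace(small_design, n_persons=900)
        d1, _ = simulate_dataset(small, seed=5)
        d2, _ = simulate_dataset(big, seed=5)
        r1 = fit(small_design.spec, d1, n_starts=1)
        r2 = fit(small_design.spec, d2, n_starts=1)
        se1 = r1.std_errors["free"]
        se2 = r2.std_errors["free"]
        assert np.nanmedian(se2) < np.nanmedian(se1)


class TestInformationCriteria:
    def test_textbook_values(self):
        aic, _ = information_criteria(-100.0, 5, 10)
        assert aic == pytest.approx(210.0)
        _, bic = information_criteria(-100.0, 5, 100)
        assert bic == pytest.approx(200.0 + 5 * np.log(100))
        aic0, bic0 = information_criteria(-100.0, 0, 50)
        assert aic0 == bic0 == pytest.approx(200.0)

    def test_requires_positive_n(self):
        with pytest.raises(ValueError):
            information_criteria(-10.0, 2, 0)


class TestPosteriorModePenalty:
    def test_maximal_at_zero_and_concave(self):
        at0 = posterior_mode_penalty(np.zeros(3), 3.0)
        assert at0 > posterior_mode_penalty(np.array([1.0, 0, 0]), 3.0)
        # concavity along one coordinate
        f = lambda x: posterior_mode_penalty(np.array([x]), 3.0)  # noqa: E731
        xs = np.linspace(-2, 2, 9)
        vals = np.array([f(x) for x in xs])
        assert np.all(np.diff(vals, 2) < 0)

    def test_rejects_nonpositive_sd(self):
        with pytest.raises(ValueError):
            posterior_mode_penalty(np.zeros(2), 0.0)


class TestLocalIdentification:
    def test_overparameterized_single_item(self):
        """One binary item carries one probability; three parameters cannot
        be locally identified."""
        spec = ModelSpec(
            family="rdina", qmatrix=QMatrix(np.array([[1]])),
            time_coding=TimeCoding(np.array([0.0])),
        )
        item = ItemParameters(f=[-1.0], d=[2.0])
        attr = AttributeGrowthParameters(b=[0.2])
        rank, n_free, full = check_local_identification(spec, item, attr)
        assert not full
        assert rank < n_free == 3

    def test_zero_loading_gives_rank_deficit_of_one(self, small_qmatrix):
        """At sigma1 = 0 the slope-loading direction is locally flat."""
        spec = ModelSpec(
            family="lg_uncond", qmatrix=small_qmatrix,
            time_coding=TimeCoding(np.array([0.0, 1.0])), quadrature=5,
            eps_sd=0.0,
        )
        item = ItemParameters(f=np.full(6, -1.4), d=np.full(6, 2.6))
        attr = AttributeGrowthParameters(
            b=[-0.3, 0.4], sigma0=0.5, sigma1=0.0, eps_sd=0.0
        )
        rank, n_free, full = check_local_identification(spec, item, attr)
        assert not full
        assert rank == n_free - 1

    def test_small_growth_model_identified(self, small_design):
        item = small_design.item_params
        attr = small_design.attr_params
        rank, n_free, full = check_local_identification(
            small_design.spec, item, attr
        )
        assert full
        assert rank == n_free
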