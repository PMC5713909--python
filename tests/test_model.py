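"""Design construction, Pólya-Gamma augmentation, sampler correctness."""

import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy.special import logsumexp

from trostar.model import (
    ModelConfig,
    PosteriorDraws,
    build_design,
    fit_star,
    summarize_fixed,
)
from trostar.polya_gamma import pg_draw, pg_mean, pg_var
from trostar.records import SchoolRecord, StudentRecord


def _student(i, school="S0", y=0, w=1.0, **over):
    base = dict(
        sex="girls", race3="black", grade="6th", family_sol="living_comfortably",
        visited_stores="no", recall_marketing="no", recall_warning="no",
    )
    base.update(over)
    return StudentRecord(
        student_id=f"T{i}", school_id=school, outcome=y, samp_weight=w, **base
    )


def _schools(n=4, tro=0):
    return [
        SchoolRecord(
            f"S{k}", float(k), float(2 * k * k + 1), tro,
            75.0 + 2 * k, 5e4 + 1500.0 * k, 20.0 - k, 10,
        )
        for k in range(n)
    ]


class TestPolyaGamma:
    @pytest.mark.parametrize("b,c", [(1.0, 0.0), (1.0, 2.5), (0.4, -1.5), (3.2, 5.0)])
    def test_moments_match_closed_form(self, b, c, rng):
        n = 200_000
        x = pg_draw(rng, np.full(n, b), np.full(n, c))
        m, v = float(pg_mean(b, c)), float(pg_var(b, c))
        assert x.mean() == pytest.approx(m, abs=4 * np.sqrt(v / n))
        assert x.var() == pytest.approx(v, rel=0.02)

    def test_positive_and_shape_validation(self, rng):
        x = pg_draw(rng, np.ones(100), rng.normal(size=100))
        assert np.all(x > 0)
        with pytest.raises(ValueError, match="positive"):
            pg_draw(rng, np.array([0.0]), np.array([1.0]))


class TestBuildDesign:
    def test_reference_cell_is_all_zero_dummy_row(self):
        cfg = ModelConfig()
        d = build_design([_student(0)], _schools(), cfg)
        assert d.X[0, 1 : 1 + d.n_beta].sum() == 0.0  # all dummies zero
        assert d.X[0, 0] == 1.0  # intercept

    def test_school_weighting_reciprocal_of_enrolment(self):
        # 50 students, weight 2.0 -> pre-normalization weight 2/50 = 0.04
        students = [_student(i, "S0", w=2.0) for i in range(50)] + [
            _student(99, "S1", w=2.0)
        ]
        cfg = ModelConfig()
        d = build_design(students, _schools(), cfg)
        # normalization preserves ratios: each S0 record carries 1/50 of S1's
        assert d.weights[0] / d.weights[-1] == pytest.approx(0.04 / 2.0)
        assert d.weights.sum() == pytest.approx(d.n_records)

    def test_duplicating_a_school_keeps_its_total_weight_share(self):
        students = [_student(i, f"S{i % 4}") for i in range(40)]
        cfg = ModelConfig()
        d1 = build_design(students, _schools(), cfg)
        share1 = d1.weights[d1.school_index == 0].sum() / d1.weights.sum()
        doubled = students + [
            replace(s, student_id=s.student_id + "b")
            for s in students
            if s.school_id == "S0"
        ]
        d2 = build_design(doubled, _schools(), cfg)
        share2 = d2.weights[d2.school_index == 0].sum() / d2.weights.sum()
        assert share2 == pytest.approx(share1, rel=1e-12)

    def test_dropping_race_removes_exactly_two_columns(self):
        full = ModelConfig()
        reduced = ModelConfig(
            covariate_set=tuple(c for c in full.covariate_set if c != "race3")
        )
        students = [_student(i, f"S{i % 4}") for i in range(8)]
        d_full = build_design(students, _schools(), full)
        d_red = build_design(students, _schools(), reduced)
        assert d_full.n_beta - d_red.n_beta == 2

    def test_missing_fields_and_unknown_school_rejected(self):
        cfg = ModelConfig()
        bad = _student(0)
        bad.family_sol = None
        with pytest.raises(ValueError, match="missing outcome/family_sol"):
            build_design([bad], _schools(), cfg)
        with pytest.raises(ValueError, match="unknown school"):
            build_design([_student(0, school="nope")], _schools(), cfg)

    def test_zip_covariates_standardized(self):
        students = [_student(i, f"S{i % 4}") for i in range(40)]
        d = build_design(students, _schools(), ModelConfig())
        Z = d.X[:, 1 + d.n_beta :]
        assert d.n_gamma == 3
        # per-school means 0, sd 1 across the 4 schools
        uniq = Z[np.unique(d.school_index, return_index=True)[1]]
        np.testing.assert_allclose(uniq.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(uniq.std(axis=0), 1.0, atol=1e-12)


def _intercept_only_fit(n=200, p_true=0.5, seed=1, sampler="pg", n_iter=4000):
    r = np.random.default_rng(3)
    y = (r.random(n) < p_true).astype(int)
    students = [
        _student(i, f"S{i % 4}", y=int(y[i])) for i in range(n)
    ]
    cfg = ModelConfig(
        covariate_set=(), include_zip_covariates=False, n_iter=n_iter,
        n_burn=n_iter // 4, seed=seed, use_school_weighting=False,
        sampler=sampler, rwm_scale=0.3,
    )
    d = build_design(students, _schools(), cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit_star(d, None, cfg)
    return y, draws


def _alpha_quadrature(y, prior_sd=100.0):
    """Exact posterior of the intercept by 1-D grid quadrature."""
    n, s = len(y), int(y.sum())
    grid = np.linspace(-4, 4, 40001)
    ll = s * grid - n * np.logaddexp(0, grid) - 0.5 * grid**2 / prior_sd**2
    w = np.exp(ll - logsumexp(ll))
    mean = float((grid * w).sum())
    sd = float(np.sqrt(((grid - mean) ** 2 * w).sum()))
    return mean, sd


class TestFitStar:
    def test_intercept_only_matches_quadrature_oracle(self):
        y, draws = _intercept_only_fit()
        mean_o, sd_o = _alpha_quadrature(y)
        ess = draws.accept_info["ess"]["intercept"]
        mc_se = draws.alpha.std() / np.sqrt(ess)
        assert draws.alpha.mean() == pytest.approx(mean_o, abs=3 * mc_se)
        assert draws.alpha.std() == pytest.approx(sd_o, rel=0.1)

    def test_metropolis_fallback_agrees_with_gibbs(self):
        y, pg = _intercept_only_fit(sampler="pg")
        _, rwm = _intercept_only_fit(sampler="rwm", n_iter=8000)
        mean_o, _ = _alpha_quadrature(y)
        assert rwm.alpha.mean() == pytest.approx(mean_o, abs=0.08)
        assert rwm.accept_info["accept_rate"] > 0.05

    def test_seeded_determinism(self, small_county):
        cfg = ModelConfig(n_iter=200, n_burn=50, seed=11)
        d = build_design(small_county.students, small_county.schools, cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_star(d, small_county.graph, cfg)
            b = fit_star(d, small_county.graph, cfg)
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.f, b.f)
        np.testing.assert_array_equal(a.tau2, b.tau2)

    def test_every_retained_f_draw_sums_to_zero(self, small_fit):
        _, draws = small_fit
        np.testing.assert_allclose(draws.f.sum(axis=1), 0.0, atol=1e-8)
        assert np.all(draws.tau2 > 0)

    def test_centring_shift_preserves_exposed_linear_predictor(self, rng):
        # the re-centring (f - c, alpha + c) leaves eta of TRO-exposed
        # records unchanged: alpha + c + (f_j - c) = alpha + f_j
        f = rng.standard_normal(10)
        alpha = 0.7
        c = f.mean()
        eta_before = alpha + f
        eta_after = (alpha + c) + (f - c)
        np.testing.assert_allclose(eta_after, eta_before, atol=1e-15)

    def test_draw_count_follows_iteration_plan(self, small_fit):
        _, draws = small_fit
        assert draws.n_draws == (600 - 200) // 1
        assert set(draws.accept_info["rhat"]) == set(
            ["intercept"] + draws.beta_names + draws.gamma_names
        )

    def test_no_exposure_drops_spatial_term_with_warning(self):
        students = [_student(i, f"S{i % 4}", y=i % 2) for i in range(40)]
        cfg = ModelConfig(n_iter=150, n_burn=50)
        d = build_design(students, _schools(tro=0), cfg)
        with pytest.warns(UserWarning, match="spatial term dropped"):
            draws = fit_star(d, None, cfg)
        assert draws.f is None


class TestSummarizeFixed:
    def _draws(self, chain, name="grade_10th"):
        n = len(chain)
        return PosteriorDraws(
            alpha=np.zeros(n),
            beta=np.asarray(chain)[:, None],
            gamma=np.empty((n, 0)),
            f=None,
            tau2=None,
            beta_names=[name],
            gamma_names=[],
            school_ids=[],
        )

    def test_constant_chain(self):
        (s,) = summarize_fixed(self._draws(np.full(200, np.log(2.0))))
        assert (s.aor, s.cri_low, s.cri_high) == (
            pytest.approx(2.0), pytest.approx(2.0), pytest.approx(2.0),
        )
        assert s.significant

    def test_symmetric_chain_not_significant(self, rng):
        chain = rng.standard_normal(5000)
        chain = np.concatenate([chain, -chain])  # exactly symmetric about 0
        (s,) = summarize_fixed(self._draws(chain))
        assert s.cri_low < 1.0 < s.cri_high
        assert not s.significant

    def test_lognormal_quantiles_closed_form(self, rng):
        chain = rng.standard_normal(100_000)
        (s,) = summarize_fixed(self._draws(chain))
        assert s.cri_low == pytest.approx(np.exp(-1.959964), rel=0.02)
        assert s.cri_high == pytest.approx(np.exp(1.959964), rel=0.02)

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_fixed(self._draws(np.empty(0)))
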