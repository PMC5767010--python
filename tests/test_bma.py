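"""BMA posterior machinery: brute-force oracle, selection rules, invariants."""

import numpy as np
import pytest
import statsmodels.api as sm

from bmaselect import (
    BMAConfig,
    ModelSpec,
    build_analysis_matrix,
    candidate_models,
    generate_cohort,
    null_config,
    posterior_probabilities,
    run_bma,
    select_max_posterior,
    select_median_probability,
)
from bmaselect.bma import fit_logistic
from bmaselect.logistic import ModelFit
from bmaselect.simulate import GeneratorConfig


def _stub_fit(size: int, bic: float) -> ModelFit:
    return ModelFit(coef=np.zeros(1), columns=["(intercept)"], loglik=-bic / 2,
                    df=size + 1, bic=bic, converged=True)


class TestPosteriorArithmetic:
    def test_equal_bic_equal_size_split_evenly(self):
        fits = [
            (ModelSpec((0,)), _stub_fit(1, 100.0)),
            (ModelSpec((1,)), _stub_fit(1, 100.0)),
        ]
        res = posterior_probabilities(fits, BMAConfig(), n=100, p=2)
        probs = [post for _, _, post in res.models]
        assert np.allclose(probs, [0.5, 0.5])

    def test_posteriors_sum_to_one(self, signal_matrix4):
        res = run_bma(signal_matrix4, BMAConfig(search="exhaustive"))
        assert abs(sum(p for _, _, p in res.models) - 1.0) < 1e-12

    def test_occam_window_drops_weak_models(self):
        # posterior odds 1 : exp(-5) ~ 1:148 > 20 -> second model dropped
        fits = [
            (ModelSpec(()), _stub_fit(0, 100.0)),
            (ModelSpec((0,)), _stub_fit(1, 110.0)),
        ]
        res = posterior_probabilities(fits, BMAConfig(occam_ratio=20), n=100, p=1)
        assert len(res.models) == 1
        assert res.models[0][0].included == ()

    def test_max_model_tie_prefers_smaller(self):
        fits = [
            (ModelSpec((0,)), _stub_fit(1, 100.0)),
            (ModelSpec(()), _stub_fit(0, 100.0)),
        ]
        res = posterior_probabilities(fits, BMAConfig(), n=100, p=1)
        assert select_max_posterior(res).included == ()

    def test_median_rule_strictly_above_half(self):
        # two models tie: variable 0 sits at probability exactly 1/2 -> excluded
        fits = [
            (ModelSpec((0,)), _stub_fit(1, 100.0)),
            (ModelSpec(()), _stub_fit(0, 100.0)),
        ]
        res = posterior_probabilities(fits, BMAConfig(), n=100, p=1)
        assert res.variable_probs["x0"] == pytest.approx(0.5)
        assert select_median_probability(res).included == ()

    def test_nonconverged_fits_dropped(self):
        bad = _stub_fit(1, 90.0)
        bad.converged = False
        fits = [(ModelSpec((0,)), bad), (ModelSpec(()), _stub_fit(0, 100.0))]
        res = posterior_probabilities(fits, BMAConfig(), n=100, p=1)
        assert [s.included for s, _, _ in res.models] == [()]
        with pytest.raises(RuntimeError):
            posterior_probabilities([(ModelSpec((0,)), bad)], BMAConfig(), n=100, p=1)


class TestCandidateSearch:
    def test_exhaustive_p3_gives_8_specs(self, tiny_matrix):
        sub = tiny_matrix
        # restrict to 3 candidates by building specs manually
        specs = candidate_models(_restrict(sub, 3), BMAConfig(search="exhaustive"))
        assert len(specs) == 8
        assert len({s.included for s in specs}) == 8

    def test_leaps_candidates_bounded(self, default_matrix):
        cfg = BMAConfig(search="leaps")
        specs = candidate_models(default_matrix, cfg)
        p = len(default_matrix.candidate_idx)
        assert p == 23
        assert 2**p == 8_388_608  # full space the screen searches
        assert 1 <= len(specs) <= cfg.nbest * (p + 1)

    def test_leaps_contains_exhaustively_retained_models(self, specs10):
        cohort, _ = generate_cohort(null_config(n=900, seed=1))
        m = build_analysis_matrix(cohort, specs10)
        r_ex = run_bma(m, BMAConfig(search="exhaustive"))
        leaps_specs = {s.included for s in candidate_models(m, BMAConfig(search="leaps"))}
        for spec, _, _ in r_ex.models:
            assert spec.included in leaps_specs


def _restrict(matrix, p):
    """Keep the first p candidate columns (plus forced) of a matrix."""
    import copy

    keep = np.r_[matrix.candidate_idx[:p], matrix.forced_idx]
    m = copy.copy(matrix)
    m.X = matrix.X[:, keep]
    m.columns = [matrix.columns[i] for i in keep]
    m.is_forced = matrix.is_forced[keep]
    return m


class TestBruteForceOracle:
    def test_p4_posteriors_match_independent_enumeration(self, signal_matrix4):
        """Exact fits of all 16 models, posterior arithmetic redone in-test."""
        m = signal_matrix4
        res = run_bma(m, BMAConfig(search="exhaustive"))

        # independent: statsmodels fits, BIC, Occam window, renormalize
        n, p = m.n, 4
        records = {}
        for mask in range(16):
            S = tuple(i for i in range(4) if mask >> i & 1)
            cols = np.r_[m.forced_idx, m.candidate_idx[list(S)]].astype(int)
            X = sm.add_constant(m.X[:, cols])
            fit = sm.Logit(m.y, X).fit(disp=0, method="newton")
            bic = -2 * fit.llf + (len(cols) + 1) * np.log(n)
            records[S] = bic
        bmin = min(records.values())
        post = {S: np.exp(-0.5 * (b - bmin)) for S, b in records.items()}  # pi=0.5 flat
        best = max(post.values())
        post = {S: v for S, v in post.items() if best / v <= 20.0}
        tot = sum(post.values())
        post = {S: v / tot for S, v in post.items()}

        got = {s.included: pr for s, _, pr in res.models}
        assert set(got) == set(post)
        for S in post:
            assert abs(got[S] - post[S]) < 1e-10
        # variable probabilities follow
        for i in range(4):
            name = m.candidate_names[i]
            expect = sum(v for S, v in post.items() if i in S)
            assert abs(res.variable_probs[name] - expect) < 1e-10


class TestPipeline:
    def test_planted_strong_predictor_certain(self):
        cfg = GeneratorConfig(
            n=2000, true_coefs={"ntprobnp_plasma": 0.9}, miss_rate=0.0, seed=17
        )
        cohort, _ = generate_cohort(cfg)
        from bmaselect.cohort import default_predictor_specs

        schema = [s for s in default_predictor_specs()
                  if s.name in ("ntprobnp_plasma", "il6_plasma", "bnp_plasma")]
        m = build_analysis_matrix(cohort, schema)
        res = run_bma(m, BMAConfig(search="exhaustive"))
        assert res.variable_probs["ntprobnp_plasma"] > 0.99

    def test_null_median_model_mostly_empty(self, specs10):
        empties = 0
        for s in range(10):
            cohort, _ = generate_cohort(null_config(n=900, seed=300 + s))
            m = build_analysis_matrix(cohort, specs10)
            res = run_bma(m, BMAConfig(search="leaps"))
            empties += res.median_model.size == 0
        assert empties > 5

    def test_deterministic_rerun(self, signal_matrix4):
        a = run_bma(signal_matrix4, BMAConfig(search="exhaustive"))
        b = run_bma(signal_matrix4, BMAConfig(search="exhaustive"))
        assert a.max_model == b.max_model
        assert a.variable_probs == b.variable_probs
        assert [(s.included, p) for s, _, p in a.models] == [
            (s.included, p) for s, _, p in b.models
        ]

    def test_prior_to_one_forces_full_model(self, signal_matrix4):
        res = run_bma(signal_matrix4, BMAConfig(search="exhaustive", prior_pi=0.999))
        full = tuple(range(4))
        assert res.max_model.included == full
        assert res.models[0][2] > 0.9

    def test_bic_consistency_null_posterior_grows_with_n(self, specs10):
        posts = []
        for n in (200, 2000, 20000):
            cohort, _ = generate_cohort(null_config(n=n, seed=77))
            m = build_analysis_matrix(cohort, specs10[:5])
            # wide-open window so the whole posterior is visible
            res = run_bma(m, BMAConfig(search="exhaustive", occam_ratio=1e12))
            posts.append(res.posterior_of(ModelSpec(())) or 0.0)
        assert posts[0] < posts[1] < posts[2]

    def test_variable_prob_bounds(self, signal_matrix4):
        res = run_bma(signal_matrix4, BMAConfig(search="exhaustive"))
        for i, name in enumerate(res.candidate_names):
            vp = res.variable_probs[name]
            containing = [p for s, _, p in res.models if i in s.included]
            lower = max(containing) if containing else 0.0
            assert lower - 1e-12 <= vp <= 1.0 + 1e-12

    def test_forced_columns_never_searched(self, signal_matrix4):
        res = run_bma(signal_matrix4, BMAConfig(search="exhaustive"))
        for spec, fit, _ in res.models:
            assert set(spec.included) <= set(range(4))
            # every retained fit carries the center indicator block
            assert any(c.startswith("center_") for c in fit.columns)


def test_fit_logistic_df_identity(signal_matrix4):
    fit = fit_logistic(signal_matrix4, ModelSpec((0, 2)))
    n_forced = len(signal_matrix4.forced_idx)
    assert fit.df == 1 + n_forced + 2
    assert np.isclose(fit.bic, -2 * fit.loglik + fit.df * np.log(signal_matrix4.n))
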