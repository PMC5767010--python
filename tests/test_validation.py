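"""Bootstrap optimism correction, shifted CIs, cross-outcome scoring, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from bmaselect import (
    BMASelector,
    FixedSelector,
    ValidationConfig,
    apparent_performance,
    bootstrap_optimism,
    build_analysis_matrix,
    center_adjusted_auc,
    cross_outcome_auc,
    diagnostics,
    generate_cohort,
    optimism_shifted_ci,
    tiny_config,
)
from bmaselect.simulate import GeneratorConfig


@pytest.fixture(scope="module")
def medium_matrix():
    cfg = GeneratorConfig(n=900, true_coefs={"ntprobnp_plasma": 0.7}, miss_rate=0.0, seed=41)
    cohort, _ = generate_cohort(cfg)
    from bmaselect.cohort import default_predictor_specs

    schema = default_predictor_specs()[:8]
    cohort.data  # complete by construction
    return build_analysis_matrix(cohort, schema), cohort


class TestApparent:
    def test_fixed_mask_apparent_equals_model_auc(self, medium_matrix):
        m, _ = medium_matrix
        sel = FixedSelector(mask=(0, 1))
        mask, fit, perf = apparent_performance(m, sel)
        assert mask == (0, 1)
        fitted = FixedSelector(mask=(0, 1)).fit(m)
        direct = center_adjusted_auc(fitted.decision_function(m), m.y, m.center).auc
        assert perf.auc == pytest.approx(direct)

    def test_empty_selection_scores_half(self, medium_matrix):
        m, _ = medium_matrix
        mask, _, perf = apparent_performance(m, FixedSelector(mask=()))
        assert mask == ()
        assert perf.auc == 0.5


class TestBootstrap:
    def test_corrected_identity_and_reproducibility(self, medium_matrix):
        m, _ = medium_matrix
        cfg = ValidationConfig(n_boot=30, seed=7)
        sel = BMASelector(search="leaps")
        a = bootstrap_optimism(m, sel, cfg)
        b = bootstrap_optimism(m, sel, cfg)
        assert a.primary.corrected_auc == pytest.approx(
            a.primary.apparent_auc - a.primary.mean_optimism
        )
        pd.testing.assert_frame_equal(a.per_replicate, b.per_replicate)
        assert a.primary.ci == b.primary.ci

    def test_fixed_mask_has_negligible_optimism(self, medium_matrix):
        """Without data-driven selection, refit-only optimism is tiny."""
        m, _ = medium_matrix
        rep = bootstrap_optimism(m, FixedSelector(mask=(4,)),
                                 ValidationConfig(n_boot=200, seed=3))
        assert abs(rep.primary.mean_optimism) < 0.01

    def test_replicate_count_recorded(self, medium_matrix):
        m, _ = medium_matrix
        rep = bootstrap_optimism(m, FixedSelector(mask=(0,)),
                                 ValidationConfig(n_boot=25, seed=1))
        assert len(rep.per_replicate) + rep.n_skipped == 25

    def test_stratified_resampling_keeps_every_center(self, medium_matrix):
        m, _ = medium_matrix
        from bmaselect.validation import _resample_indices

        rng = np.random.default_rng(0)
        idx = _resample_indices(rng, m.center, stratify=True)
        assert set(m.center[idx]) == set(m.center)
        assert len(idx) == m.n
        # per-center counts preserved exactly
        for c in set(m.center):
            assert (m.center[idx] == c).sum() == (m.center == c).sum()


class TestShiftedCI:
    def test_ci_recomputable_from_replicates(self, medium_matrix):
        m, _ = medium_matrix
        rep = bootstrap_optimism(m, FixedSelector(mask=(2,)),
                                 ValidationConfig(n_boot=40, seed=5))
        lo, hi = optimism_shifted_ci(rep)
        boot = rep.per_replicate.boot_apparent_auc
        o = rep.primary.mean_optimism
        assert lo == pytest.approx(max(0.0, boot.quantile(0.025) - o))
        assert hi == pytest.approx(min(1.0, boot.quantile(0.975) - o))
        assert lo <= rep.primary.corrected_auc <= hi or not (
            boot.quantile(0.025) <= rep.primary.apparent_auc <= boot.quantile(0.975)
        )

    def test_too_few_replicates_error(self, medium_matrix):
        m, _ = medium_matrix
        rep = bootstrap_optimism(m, FixedSelector(mask=(0,)),
                                 ValidationConfig(n_boot=5, seed=2))
        with pytest.raises(ValueError, match="replicates"):
            optimism_shifted_ci(rep)


class TestCrossOutcome:
    def test_identical_secondary_gives_identical_validation(self, medium_matrix):
        m, _ = medium_matrix
        rep = bootstrap_optimism(m, FixedSelector(mask=(1,)),
                                 ValidationConfig(n_boot=20, seed=9),
                                 secondary_y=m.y.copy())
        sec = cross_outcome_auc(rep)
        assert sec.apparent_auc == pytest.approx(rep.primary.apparent_auc)
        assert sec.mean_optimism == pytest.approx(rep.primary.mean_optimism)

    def test_zero_coefficient_combination_scores_half(self, medium_matrix):
        m, _ = medium_matrix
        rep = bootstrap_optimism(m, FixedSelector(mask=()),
                                 ValidationConfig(n_boot=20, seed=9),
                                 secondary_y=m.y.copy())
        assert rep.primary.apparent_auc == 0.5
        assert cross_outcome_auc(rep).apparent_auc == 0.5

    def test_nested_severe_outcome_close_to_mild(self):
        """Shared latent severity: severe-AKI AUC tracks the mild-AKI AUC."""
        from bmaselect import complete_case_filter, default_config

        cohort, _ = generate_cohort(default_config(seed=13))
        filtered, _ = complete_case_filter(cohort)
        m = build_analysis_matrix(filtered)
        sev = filtered.data["severe_aki"].to_numpy(dtype=float)
        rep = bootstrap_optimism(m, BMASelector(search="leaps"),
                                 ValidationConfig(n_boot=30, seed=1), secondary_y=sev)
        assert abs(cross_outcome_auc(rep).apparent_auc - rep.primary.apparent_auc) < 0.05

    def test_missing_secondary_raises(self, medium_matrix):
        m, _ = medium_matrix
        rep = bootstrap_optimism(m, FixedSelector(mask=(0,)),
                                 ValidationConfig(n_boot=20, seed=4))
        with pytest.raises(ValueError):
            cross_outcome_auc(rep)


class TestDiagnostics:
    def test_table_shapes_on_tiny_cohort(self, specs4):
        cohort, _ = generate_cohort(tiny_config(seed=5))
        m = build_analysis_matrix(cohort, specs4)
        sel = BMASelector(search="exhaustive")
        rep = diagnostics(m, sel, ValidationConfig(n_boot=15, seed=0))
        p = len(specs4)
        assert rep.loo_variable_probs.shape == (60, p + 1)  # + observation column
        assert rep.boot_variable_probs.shape == (15, p + 1)
        assert len(rep.boot_selected_posterior) == 15
        assert len(rep.boot_selected_auc) == 15

    def test_duplicated_observation_gives_identical_loo_rows(self, specs4):
        cohort, _ = generate_cohort(tiny_config(seed=5))
        df = cohort.data.copy()
        df.loc[len(df)] = df.loc[0]
        df.loc[len(df) - 1, "subject_id"] = "DUP"
        from bmaselect import Cohort

        m = build_analysis_matrix(Cohort(df, cohort.predictor_names), specs4)
        rep = diagnostics(m, BMASelector(search="exhaustive"),
                          ValidationConfig(n_boot=1, seed=0))
        first = rep.loo_variable_probs.iloc[0, 1:]
        dup = rep.loo_variable_probs.iloc[len(df) - 1, 1:]
        assert np.allclose(first.to_numpy(float), dup.to_numpy(float))

    def test_loo_cap_enforced(self, default_matrix):
        with pytest.raises(ValueError, match="cap"):
            diagnostics(default_matrix, BMASelector(), loo_cap=100)
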