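"""Metrics, exact intervals, subgroup margins, cross-tabs and PCA."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thyromsi.errors import ParameterError
from thyromsi.evaluate import (
    ConfusionCounts,
    confusion,
    diagnostic_metrics,
    exact_binomial_ci,
    filter_subgroup,
    pca_explore,
    printed_percent,
    round_half_up,
    subgroup_report,
    three_level_agreement,
    three_level_table,
)
from thyromsi.synthetic import CohortConfig, cohort_design


class TestConfusion:
    def test_basic_tabulation(self):
        c = confusion(["malignant", "malignant", "benign"], ["malignant", "benign", "benign"])
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 0)

    def test_all_correct_has_no_errors(self):
        c = confusion(["malignant", "benign"], ["malignant", "benign"])
        assert c.fp == 0 and c.fn == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            confusion([], [])

    def test_unknown_truth_rejected(self):
        with pytest.raises(ParameterError, match="truth"):
            confusion(["benign"], ["borderline"])


class TestMetrics:
    def test_validation_scale_counts(self):
        rep = diagnostic_metrics(ConfusionCounts(28, 18, 87, 37))
        p = rep.printed()
        assert p == {"sensitivity": 43.1, "specificity": 82.9, "ppv": 60.9,
                     "npv": 70.2, "accuracy": 67.7}

    def test_adequate_cellularity_counts(self):
        rep = diagnostic_metrics(ConfusionCounts(26, 7, 31, 8))
        p = rep.printed()
        assert p == {"sensitivity": 76.5, "specificity": 81.6, "ppv": 78.8,
                     "npv": 79.5, "accuracy": 79.2}

    def test_zero_denominator_is_undefined_not_zero(self):
        rep = diagnostic_metrics(ConfusionCounts(0, 0, 10, 0))
        assert rep.specificity == 1.0
        assert rep.sensitivity is None and rep.ppv is None
        assert rep.printed()["sensitivity"] is None

    def test_accuracy_identity_holds_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(0, 40, 4)
            if tp + fp + tn + fn == 0:
                continue
            rep = diagnostic_metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            P, N = tp + fn, tn + fp
            if P and N:
                assert rep.accuracy == pytest.approx(
                    (rep.sensitivity * P + rep.specificity * N) / (P + N)
                )

    def test_ci_brackets_point_estimate(self):
        rep = diagnostic_metrics(ConfusionCounts(12, 5, 30, 7))
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            v = getattr(rep, name)
            lo, hi = getattr(rep, f"ci_{name}")
            assert lo <= v <= hi


class TestExactCI:
    def test_boundaries_at_zero_and_n(self):
        lo, hi = exact_binomial_ci(0, 15)
        assert lo == 0.0 and hi < 1.0
        lo, hi = exact_binomial_ci(15, 15)
        assert lo > 0.0 and hi == 1.0

    def test_analytic_lower_bound_for_perfect_run(self):
        lo, hi = exact_binomial_ci(20, 20)
        assert lo == pytest.approx(0.025 ** (1 / 20))

    def test_matches_statsmodels_beta_method(self):
        proportion = pytest.importorskip("statsmodels.stats.proportion")
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(1, 200))
            k = int(rng.integers(0, n + 1))
            lo, hi = exact_binomial_ci(k, n)
            slo, shi = proportion.proportion_confint(k, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(0.0 if k == 0 else slo, abs=1e-10)
            assert hi == pytest.approx(1.0 if k == n else shi, abs=1e-10)

    def test_inverts_binomial_tail_tests(self):
        # CI bounds are where the binomial tail probability equals alpha/2
        for k, n in ((7, 30), (1, 10), (45, 50)):
            lo, hi = exact_binomial_ci(k, n)
            assert stats.binom.sf(k - 1, n, lo) == pytest.approx(0.025, abs=1e-9)
            assert stats.binom.cdf(k, n, hi) == pytest.approx(0.025, abs=1e-9)

    def test_coverage_is_conservative(self):
        # Clopper-Pearson is conservative: exact coverage at p=0.7, n=30 is
        # 97.4%, so empirical coverage over 2000 draws sits at or above the
        # nominal 95% (and below 99%)
        p, n = 0.7, 30
        rng = np.random.default_rng(11)
        draws = rng.binomial(n, p, size=2000)
        bounds = {k: exact_binomial_ci(k, n) for k in np.unique(draws)}
        cover = np.mean([bounds[k][0] <= p <= bounds[k][1] for k in draws])
        assert 0.95 <= cover <= 0.99

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            exact_binomial_ci(5, 3)
        with pytest.raises(ParameterError):
            exact_binomial_ci(-1, 3)


class TestRounding:
    @pytest.mark.parametrize(
        "frac,expected",
        [(30 / 38, 79.0), (87 / 126, 69.1), (92 / 141, 65.3),
         (28 / 65, 43.1), (33 / 48, 68.8), (115 / 170, 67.7)],
    )
    def test_printed_percent_two_stage_half_up(self, frac, expected):
        assert printed_percent(frac) == expected

    def test_round_half_up_is_half_up(self):
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(0.35, 1) == 0.4


@pytest.fixture(scope="module")
def manifest():
    return cohort_design(CohortConfig()).to_frame()


@pytest.fixture(scope="module")
def validation(manifest):
    return manifest[manifest.dataset == "validation"]


class TestSubgroups:
    def test_borderline_exclusion_leaves_141(self, validation):
        kept = filter_subgroup(validation, "borderline_excluded")
        assert len(kept) == 141

    def test_adequate_subgroup_is_72_with_design_margins(self, validation):
        kept = filter_subgroup(validation, "adequate")
        assert len(kept) == 72
        counts = kept.cytology_class.value_counts()
        assert counts["TIR2"] == 17 and counts["TIR3"] == 23
        assert counts["TIR4"] == 9 and counts["TIR5"] == 23

    def test_composed_filters(self, validation):
        kept = filter_subgroup(validation, "adequate+indeterminate")
        assert len(kept) == 32  # 23 TIR3 + 9 TIR4

    def test_unknown_subgroup_rejected(self, validation):
        with pytest.raises(ParameterError, match="unknown"):
            filter_subgroup(validation, "left-handed")

    def test_empty_subgroup_reports_none(self, validation):
        diag = pd.DataFrame({
            "sample_id": validation.sample_id,
            "call_pixel": "benign",
        })
        poor_only = validation.copy()
        poor_only["cellularity"] = "poor"
        with pytest.warns(UserWarning, match="empty"):
            rep = subgroup_report(diag, poor_only, "adequate")
        assert rep is None

    def test_report_on_subgroup(self, validation):
        rng = np.random.default_rng(0)
        diag = pd.DataFrame({
            "sample_id": validation.sample_id,
            "call_pixel": np.where(validation.truth_label == "malignant",
                                   "malignant", "benign"),
        })
        rep = subgroup_report(diag, validation, "borderline_excluded")
        assert rep.counts.total == 141
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0


class TestThreeLevelTable:
    def _frames(self, rows):
        manifest = pd.DataFrame(
            [{"sample_id": f"S{i}", "cytology_class": "TIR3",
              "truth_label": t, "subtype": s, "cellularity": "good"}
             for i, (s, t, _) in enumerate(rows)]
        )
        diag = pd.DataFrame(
            [{"sample_id": f"S{i}", "call_three_level": c}
             for i, (_, _, c) in enumerate(rows)]
        )
        return diag, manifest

    def test_row_sums_and_conservation(self):
        rows = (
            [("HP", "benign", "benign")] * 4
            + [("HP", "benign", "malignant")] * 1
            + [("PTC", "malignant", "malignant")] * 3
            + [("PTC", "malignant", "gray")] * 1
        )
        diag, manifest = self._frames(rows)
        tab = three_level_table(diag, manifest)
        assert int(tab.to_numpy().sum()) == len(rows)
        assert int(tab.loc[("benign", "HP")].sum()) == 5
        assert int(tab.loc[("malignant", "PTC")].sum()) == 4

    def test_all_gray_column(self):
        rows = [("HP", "benign", "gray")] * 3 + [("PTC", "malignant", "gray")] * 2
        diag, manifest = self._frames(rows)
        tab = three_level_table(diag, manifest)
        assert int(tab["gray"].sum()) == 5
        assert int(tab["benign"].sum()) == 0 and int(tab["malignant"].sum()) == 0

    def test_malignant_agreement_with_gray(self):
        rows = (
            [("PTC", "malignant", "malignant")] * 6
            + [("PTC", "malignant", "gray")] * 1
            + [("PTC", "malignant", "benign")] * 1
            + [("MTC", "malignant", "malignant")] * 3
            + [("HP", "benign", "benign")] * 2
        )
        diag, manifest = self._frames(rows)
        tab = three_level_table(diag, manifest)
        assert three_level_agreement(tab, "malignant", count_gray=True) == pytest.approx(10 / 11)
        assert three_level_agreement(tab, "malignant", count_gray=False) == pytest.approx(9 / 11)


class TestPca:
    def test_two_group_duplicates_separate_on_first_component(self):
        a = np.array([1.0, 0.0, 2.0, 5.0])
        b = np.array([0.0, 3.0, 1.0, 0.0])
        X = np.vstack([a] * 5 + [b] * 5) + np.random.default_rng(0).normal(0, 1e-6, (10, 4))
        scores, evr = pca_explore(X)
        assert evr.sum() == pytest.approx(1.0)
        first = scores[:, 0]
        assert (first[:5].max() < first[5:].min()) or (first[5:].max() < first[:5].min())

    def test_eigenvalue_spectrum_rotation_invariant(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 6))
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        # rotate after standardization so scaling does not re-mix variances
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        cov1 = np.linalg.eigvalsh(np.cov(Z.T))
        cov2 = np.linalg.eigvalsh(np.cov((Z @ Q).T))
        np.testing.assert_allclose(np.sort(cov1), np.sort(cov2), atol=1e-9)

    def test_zero_variance_columns_dropped_with_warning(self):
        X = np.random.default_rng(1).normal(size=(10, 3))
        X[:, 1] = 4.2
        with pytest.warns(UserWarning, match="zero-variance"):
            scores, evr = pca_explore(X)
        assert scores.shape[0] == 10

    def test_tight_benign_loose_malignant_clustering(self):
        rng = np.random.default_rng(5)
        benign = rng.normal(0, 0.05, size=(10, 8)) + np.linspace(1, 2, 8)
        malignant = rng.normal(0, 1.0, size=(10, 8)) + rng.uniform(0, 3, size=(10, 1))
        X = np.vstack([benign, malignant])
        scores, _ = pca_explore(X)
        s2 = scores[:, :2]

        def mean_pairwise(S):
            d = np.linalg.norm(S[:, None] - S[None, :], axis=-1)
            return d[np.triu_indices(len(S), 1)].mean()

        assert mean_pairwise(s2[:10]) < mean_pairwise(s2[10:])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ParameterError):
            pca_explore(np.ones((1, 5)))
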