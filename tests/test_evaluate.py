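"""AUROC / ROC / DeLong / correlation / subset evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from afmissense.evaluate import (
    DEFAULT_ORIENTATIONS,
    Orientation,
    SingleClassError,
    SubsetSpec,
    auroc,
    correlate,
    evaluate_all,
    roc_points,
    subset_by_confidence,
)
from afmissense.simulate import SimulationConfig, simulate_variant_scores


def brute_force_auc(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos, neg = s[y == 1], s[y == 0]
    comp = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    return comp.mean()


class TestAuroc:
    def test_perfect_separation(self):
        r = auroc([1, 2, 3, 4], [0, 0, 1, 1], Orientation.HIGHER_IS_PATHOGENIC)
        assert r.auc == 1.0

    def test_tied_scores_count_half(self):
        # benign [1,2], pathogenic [2,3]: 4 pairs, 3 concordant + 1 tie/2
        r = auroc([1, 2, 2, 3], [0, 0, 1, 1], Orientation.HIGHER_IS_PATHOGENIC)
        assert r.auc == 0.875

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            y = np.zeros(n, int)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            if y.sum() in (0, n):
                continue
            s = rng.integers(0, 5, n).astype(float)  # heavy ties
            r = auroc(s, y, Orientation.HIGHER_IS_PATHOGENIC)
            assert r.auc == pytest.approx(brute_force_auc(s, y), abs=1e-12)

    def test_score_negation_complements_auc(self, rng):
        s = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        a = auroc(s, y, Orientation.HIGHER_IS_PATHOGENIC).auc
        b = auroc(-s, y, Orientation.HIGHER_IS_PATHOGENIC).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_auto_orientation_flips_and_records(self, rng):
        s = np.r_[rng.normal(2, 1, 30), rng.normal(0, 1, 30)]
        y = np.r_[np.zeros(30, int), np.ones(30, int)]  # pathogenic scores LOWER
        r = auroc(s, y, Orientation.AUTO)
        assert r.auc >= 0.5
        assert r.orientation is Orientation.LOWER_IS_PATHOGENIC
        fixed = auroc(s, y, Orientation.HIGHER_IS_PATHOGENIC)
        assert abs(r.auc - 0.5) == pytest.approx(abs(fixed.auc - 0.5), abs=1e-12)

    def test_delong_ci_matches_proc_reference(self):
        """Frozen oracle: R pROC ci.auc(..., method='delong') on this exact
        seeded dataset gives auc 0.7805714286, CI (0.6598285659, 0.9013142913)."""
        rng = np.random.default_rng(2024)
        y = np.r_[np.ones(25, int), np.zeros(35, int)]
        s = np.where(y == 1, rng.normal(1.0, 1, 60), rng.normal(0, 1, 60)).round(3)
        r = auroc(s, y, Orientation.HIGHER_IS_PATHOGENIC)
        assert r.auc == pytest.approx(0.7805714286, abs=1e-9)
        assert r.ci_low == pytest.approx(0.6598285659, abs=1e-9)
        assert r.ci_high == pytest.approx(0.9013142913, abs=1e-9)
        assert r.ci_low <= r.auc <= r.ci_high

    def test_null_scores_give_auc_near_half(self, rng):
        aucs = []
        for _ in range(200):
            s = rng.normal(size=100)
            y = np.r_[np.ones(40, int), np.zeros(60, int)]
            aucs.append(auroc(s, y, Orientation.HIGHER_IS_PATHOGENIC).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_delong_ci_width_shrinks_with_n(self, rng):
        widths = []
        for n in (50, 200, 800):
            s = np.r_[rng.normal(1, 1, n), rng.normal(0, 1, n)]
            y = np.r_[np.ones(n, int), np.zeros(n, int)]
            r = auroc(s, y, Orientation.HIGHER_IS_PATHOGENIC)
            widths.append(r.ci_high - r.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_bootstrap_ci_contains_point_estimate(self, rng):
        s = np.r_[rng.normal(1, 1, 40), rng.normal(0, 1, 40)]
        y = np.r_[np.ones(40, int), np.zeros(40, int)]
        r = auroc(s, y, Orientation.HIGHER_IS_PATHOGENIC, ci_method="bootstrap",
                  n_boot=200, seed=5)
        assert r.ci_low <= r.auc <= r.ci_high

    def test_single_class_is_error(self):
        with pytest.raises(SingleClassError):
            auroc([1.0, 2.0], [1, 1], Orientation.AUTO)

    def test_identical_scores_degenerate(self):
        r = auroc([3.0, 3.0, 3.0, 3.0], [0, 1, 0, 1], Orientation.AUTO)
        assert r.auc == 0.5 and r.degenerate_ci

    def test_missing_values_excluded_pairwise(self):
        s = [np.nan, 1.0, 2.0, 3.0, 4.0]
        y = [1, 0, 0, 1, 1]
        r = auroc(s, y, Orientation.HIGHER_IS_PATHOGENIC)
        assert r.n_pathogenic == 2 and r.n_benign == 2


class TestRocPoints:
    def test_endpoints_and_perfect_curve(self):
        pts = roc_points([1, 2, 3, 4], [0, 0, 1, 1])
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert any((fpr == 0.0 and tpr == 1.0) for fpr, tpr in pts)

    def test_constant_scores_are_the_diagonal(self):
        pts = roc_points([5, 5, 5, 5], [0, 1, 0, 1])
        assert pts.tolist() == [[0.0, 0.0], [1.0, 1.0]]
        assert np.trapezoid(pts[:, 1], pts[:, 0]) == 0.5

    def test_trapezoid_area_equals_pairwise_auc(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            y = np.zeros(n, int)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            if y.sum() in (0, n):
                continue
            s = rng.integers(0, 4, n).astype(float)
            pts = roc_points(s, y)
            area = np.trapezoid(pts[:, 1], pts[:, 0])
            assert area == pytest.approx(brute_force_auc(s, y), abs=1e-12)


class TestCorrelate:
    def frame(self, rng, n=30):
        x = rng.normal(size=n)
        return pd.DataFrame(
            {
                "label": rng.integers(0, 2, n),
                "plddt": x,
                "rasa": -x,
                "ddg_mcsm": x + rng.normal(0, 0.5, n),
            }
        )

    def test_diagonal_and_antithetic_pair(self, rng):
        cm = correlate(self.frame(rng), method="spearman")
        assert np.allclose(np.diag(cm.matrix), 1.0)
        assert cm.matrix.loc["plddt", "rasa"] == pytest.approx(-1.0)
        assert cm.matrix.equals(cm.matrix.T)

    def test_hand_case_matches_scipy(self):
        df = pd.DataFrame(
            {"label": [0] * 5, "plddt": [1, 2, 3, 4, 5.0], "rasa": [2, 1, 4, 3, 5.0]}
        )
        cm = correlate(df, descriptors=["plddt", "rasa"], method="spearman")
        expected = stats.spearmanr(df["plddt"], df["rasa"]).statistic
        assert cm.matrix.loc["plddt", "rasa"] == pytest.approx(expected, abs=1e-12)

    def test_insufficient_pairs_flagged_absent(self, rng):
        df = self.frame(rng, n=10)
        df.loc[df.index[:8], "ddg_mcsm"] = np.nan
        cm = correlate(df, min_pairs=3)
        assert np.isnan(cm.matrix.loc["plddt", "ddg_mcsm"])
        assert cm.n_pairs.loc["plddt", "ddg_mcsm"] == 2

    def test_label_stratified_returns_both_classes(self, rng):
        out = correlate(self.frame(rng), stratify_by_label=True)
        assert set(out) == {"benign", "pathogenic"}


class TestSubsets:
    def test_confidence_threshold_is_inclusive(self):
        df = pd.DataFrame({"plddt": [30.0, 50.0, 90.0], "label": [0, 1, 1]})
        kept, counts = subset_by_confidence(df, 50)
        assert kept["plddt"].tolist() == [50.0, 90.0]
        assert counts == {"pathogenic": 2, "benign": 0}

    def test_zero_threshold_is_identity(self):
        df = pd.DataFrame({"plddt": [30.0, 50.0], "label": [0, 1]})
        kept, _ = subset_by_confidence(df, 0)
        assert len(kept) == 2

    def test_all_below_threshold_warns_empty(self):
        df = pd.DataFrame({"plddt": [30.0], "label": [1]})
        kept, counts = subset_by_confidence(df, 50)
        assert kept.empty and counts == {"pathogenic": 0, "benign": 0}


class TestEvaluateAll:
    def test_subset_evaluation_commutes_with_prefiltering(self):
        table = simulate_variant_scores(SimulationConfig(seed=11)).table
        spec = SubsetSpec(name="plddt50", min_plddt=50.0)
        report = evaluate_all(table, [spec])
        pre = evaluate_all(spec.apply(table))
        for desc, res in report.results["plddt50"].items():
            assert res.auc == pytest.approx(pre.results["total"][desc].auc, abs=1e-12)

    def test_report_covers_descriptors_and_counts(self):
        table = simulate_variant_scores(SimulationConfig(seed=2)).table
        report = evaluate_all(table, [SubsetSpec(name="plddt50", min_plddt=50.0)])
        assert set(report.results) == {"total", "plddt50"}
        assert "ddg_mcsm" in report.results["total"]
        assert report.subset_counts["total"] == {"pathogenic": 445, "benign": 647}
        long = report.to_table()
        assert {"subset", "descriptor", "auc"} <= set(long.columns)

    def test_empty_subset_list_reports_total_only(self):
        table = simulate_variant_scores(SimulationConfig(seed=2)).table
        report = evaluate_all(table)
        assert list(report.results) == ["total"]

    def test_default_orientations_match_field_conventions(self):
        assert DEFAULT_ORIENTATIONS["plddt"] is Orientation.HIGHER_IS_PATHOGENIC
        assert DEFAULT_ORIENTATIONS["rasa"] is Orientation.LOWER_IS_PATHOGENIC
        assert DEFAULT_ORIENTATIONS["ddg_mcsm"] is Orientation.LOWER_IS_PATHOGENIC
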