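import json
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import concordance_auc, exhaustive_youden
from fluencyscreen.psychometrics import (
    DegenerateInputError,
    ancova_compare,
    auc,
    baseline_compare,
    cronbach_alpha,
    cutoff_metrics,
    delong_auc_variance,
    delong_compare,
    partial_pearson,
    roc_curve,
    test_retest,
    youden_optimal_cutoff,
)


def labelled(n_cases, n_controls):
    return np.array(["case"] * n_cases + ["control"] * n_controls)


class TestROCandAUC:
    def test_perfect_separation(self):
        scores = [2, 3, 0, 1]
        labels = labelled(2, 2)
        assert auc(scores, labels) == 1.0
        curve = roc_curve(scores, labels)
        assert curve.auc == pytest.approx(1.0)

    def test_no_discrimination(self):
        assert auc([5, 5, 5, 5], labelled(2, 2)) == 0.5

    def test_tied_pair_instance(self):
        # cases {2,3}, controls {1,2.5}: 3 concordant pairs + 1 discordant
        assert auc([2, 3, 1, 2.5], labelled(2, 2)) == pytest.approx(0.75)

    def test_orientation_reversal_complements_auc(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        labels = labelled(15, 25)
        assert auc(scores, labels, "higher") + auc(
            scores, labels, "lower"
        ) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            auc([1, 2], np.array(["case", "case"]))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_concordance_oracle_and_trapezoid(self, seed):
        """Rank AUC == all-pairs concordance count == trapezoid area."""
        rng = np.random.default_rng(seed)
        m, n = rng.integers(3, 15, size=2)
        scores = np.round(rng.normal(size=m + n), 1)  # coarse -> ties occur
        labels = labelled(m, n)
        a = auc(scores, labels)
        assert a == pytest.approx(concordance_auc(scores, labels == "case"))
        assert roc_curve(scores, labels).auc == pytest.approx(a)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        scores = rng.normal(size=120) + np.r_[np.ones(50), np.zeros(70)]
        labels = labelled(50, 70)
        assert auc(scores, labels) == pytest.approx(
            roc_auc_score(labels == "case", scores)
        )


class TestYouden:
    def test_perfect_separation_toy(self):
        curve = roc_curve([2, 3, 0, 1], labelled(2, 2))
        best = youden_optimal_cutoff(curve)
        assert best.youden == pytest.approx(1.0)
        assert 1 < best.cutoff < 2

    def test_all_identical_scores(self):
        best = youden_optimal_cutoff(roc_curve([5, 5, 5, 5], labelled(2, 2)))
        assert best.youden == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        m, n = rng.integers(5, 12, size=2)
        scores = np.round(rng.normal(size=m + n), 1)
        labels = labelled(m, n)
        best = youden_optimal_cutoff(roc_curve(scores, labels))
        j, sens, thr = exhaustive_youden(scores, labels == "case")
        assert best.youden == pytest.approx(j)
        assert best.sensitivity == pytest.approx(sens)

    def test_lower_is_case_orientation(self):
        # cases score low; positive call is score <= cutoff
        curve = roc_curve([1, 2, 8, 9], labelled(2, 2), orientation="lower")
        best = youden_optimal_cutoff(curve)
        assert best.youden == pytest.approx(1.0)
        assert 2 < best.cutoff < 8


class TestCutoffMetrics:
    @pytest.mark.parametrize(
        "sens, spec, ppv, npv",
        [
            (0.780, 0.770, 0.772, 0.778),
            (0.660, 0.640, 0.647, 0.653),
            (0.870, 0.880, 0.879, 0.871),
        ],
    )
    def test_published_rows_reproduced(self, sens, spec, ppv, npv):
        m = cutoff_metrics(sens, spec, 100, 100)
        assert round(m.ppv, 3) == ppv
        assert round(m.npv, 3) == npv

    def test_perfect_test(self):
        m = cutoff_metrics(1.0, 1.0, 40, 60)
        assert m.ppv == 1.0 and m.npv == 1.0

    def test_zero_denominator_flags_nan(self):
        m = cutoff_metrics(0.0, 1.0, 10, 10)  # no positives at all
        assert math.isnan(m.ppv) and not math.isnan(m.npv)

    @pytest.mark.parametrize("seed", range(10))
    def test_prevalence_identity(self, seed):
        rng = np.random.default_rng(seed)
        sens, spec = rng.uniform(0.05, 0.95, size=2)
        m_cases, n_controls = rng.integers(5, 200, size=2)
        m = cutoff_metrics(sens, spec, m_cases, n_controls)
        tp = sens * m_cases
        fp = (1 - spec) * n_controls
        assert m.ppv * (tp + fp) == pytest.approx(tp)
        tn = spec * n_controls
        fn = (1 - sens) * m_cases
        assert m.npv * (tn + fn) == pytest.approx(tn)


class TestDeLong:
    def test_self_comparison_is_null(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=60)
        labels = labelled(25, 35)
        comp = delong_compare(s, s, labels)
        assert comp.z == 0.0 and comp.p == 1.0

    def test_antisymmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        labels = labelled(30, 30)
        a = rng.normal(size=60) + np.r_[np.ones(30), np.zeros(30)]
        b = rng.normal(size=60) + 0.5 * np.r_[np.ones(30), np.zeros(30)]
        ab = delong_compare(a, b, labels)
        ba = delong_compare(b, a, labels)
        assert ab.z == pytest.approx(-ba.z)
        assert ab.p == pytest.approx(ba.p)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            delong_compare([1, 2, 3], [1, 2], labelled(2, 1))

    def test_variance_matches_simulation(self):
        """Structural-components AUC variance tracks the empirical variance."""
        rng = np.random.default_rng(5)
        m = n = 60
        aucs, variances = [], []
        for _ in range(400):
            s = rng.normal(size=m + n) + np.r_[np.ones(m), np.zeros(n)]
            a, v = delong_auc_variance(s, labelled(m, n))
            aucs.append(a)
            variances.append(v)
        assert np.mean(variances) == pytest.approx(np.var(aucs), rel=0.15)

    def test_matches_r_proc_reference(self, tmp_path):
        """Same z and p as pROC's paired DeLong test on a fixed dataset."""
        rscript = shutil.which("Rscript")
        assert rscript is not None, "Rscript expected on PATH"
        rng = np.random.default_rng(42)
        m = n = 40
        latent = np.r_[np.ones(m), np.zeros(n)]
        a = 1.2 * latent + rng.normal(size=m + n)
        b = 0.8 * latent + rng.normal(size=m + n)
        df = pd.DataFrame({"case": np.r_[np.ones(m), np.zeros(n)].astype(int),
                           "a": a, "b": b})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = (
            "suppressMessages(library(pROC));"
            f"d <- read.csv('{csv}');"
            "ra <- roc(d$case, d$a, direction='<', quiet=TRUE);"
            "rb <- roc(d$case, d$b, direction='<', quiet=TRUE);"
            "t <- roc.test(ra, rb, method='delong', paired=TRUE);"
            "cat(t$statistic, t$p.value, auc(ra), auc(rb))"
        )
        out = subprocess.run([rscript, "-e", script], capture_output=True,
                             text=True, check=True, timeout=300)
        z_r, p_r, auc_a_r, auc_b_r = map(float, out.stdout.split())
        comp = delong_compare(a, b, df["case"].to_numpy() == 1)
        assert comp.auc_a == pytest.approx(auc_a_r)
        assert comp.auc_b == pytest.approx(auc_b_r)
        assert comp.z == pytest.approx(z_r, abs=1e-6)
        assert comp.p == pytest.approx(p_r, abs=1e-6)


class TestCronbach:
    def test_two_standardized_items_closed_form(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        y = 0.6 * x + 0.8 * rng.normal(size=200)
        items = np.column_stack([
            (x - x.mean()) / x.std(ddof=1),
            (y - y.mean()) / y.std(ddof=1),
        ])
        r = float(np.corrcoef(x, y)[0, 1])
        assert cronbach_alpha(items) == pytest.approx(2 * r / (1 + r))

    def test_identical_items_give_one(self):
        x = np.arange(10.0)
        items = np.column_stack([x, x, x])
        assert cronbach_alpha(items) == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(3)
        items = rng.normal(size=(5000, 4))
        assert abs(cronbach_alpha(items)) < 0.05

    def test_invariance_to_shift_and_joint_scaling(self):
        rng = np.random.default_rng(4)
        items = rng.normal(size=(50, 5)) + rng.normal(size=(50, 1))
        a = cronbach_alpha(items)
        shifted = items + np.array([10, -3, 0, 7, 2.5])
        assert cronbach_alpha(shifted) == pytest.approx(a)
        assert cronbach_alpha(3.7 * items) == pytest.approx(a)

    def test_agrees_with_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(6)
        items = pd.DataFrame(rng.normal(size=(40, 6))
                             + rng.normal(size=(40, 1)))
        a_pg = pg.cronbach_alpha(items)[0]
        assert cronbach_alpha(items.to_numpy()) == pytest.approx(a_pg)

    def test_zero_total_variance_is_nan(self):
        items = np.column_stack([np.ones(5), -np.ones(5)])
        assert math.isnan(cronbach_alpha(items))


class TestFluencyItemMatrix:
    @pytest.fixture(scope="class")
    @staticmethod
    def transcripts(lexicon):
        import numpy as np

        from fluencyscreen.simulate import default_profiles, generate_transcript

        profile = default_profiles().control
        rng = np.random.default_rng(17)
        return [
            generate_transcript(profile, lexicon, rng,
                                ability=float(0.3 * rng.normal()))
            for _ in range(60)
        ]

    def test_time_bin_items_sum_to_total(self, transcripts, lexicon):
        from fluencyscreen.psychometrics import fluency_item_matrix
        from fluencyscreen.scoring import compute_index_scores

        items = fluency_item_matrix(transcripts, lexicon)
        assert items.shape == (60, 6)
        totals = [compute_index_scores(t, lexicon).total for t in transcripts]
        assert items.sum(axis=1).tolist() == totals

    def test_time_bin_alpha_reflects_shared_ability(self, transcripts, lexicon):
        from fluencyscreen.psychometrics import fluency_item_matrix

        a = cronbach_alpha(fluency_item_matrix(transcripts, lexicon))
        assert 0.0 < a < 1.0

    def test_index_score_items_shape(self, transcripts, lexicon):
        from fluencyscreen.psychometrics import fluency_item_matrix

        items = fluency_item_matrix(transcripts[:10], lexicon,
                                    items="index_scores")
        assert items.shape == (10, 7)

    def test_untimed_transcripts_rejected(self, lexicon):
        from fluencyscreen.psychometrics import fluency_item_matrix
        from fluencyscreen.scoring import Transcript

        untimed = [Transcript.from_tokens(["dog", "cat"])]
        with pytest.raises(ValueError, match="timed"):
            fluency_item_matrix(untimed, lexicon)


class TestPartialPearson:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        r, p = partial_pearson(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert r == pytest.approx(r_ref)
        assert p == pytest.approx(p_ref)

    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = partial_pearson(x, x)
        assert r == pytest.approx(1.0) and p == 0.0

    def test_confounder_removed(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=500)
        x = z + 0.3 * rng.normal(size=500)
        y = z + 0.3 * rng.normal(size=500)
        r_marginal, _ = partial_pearson(x, y)
        r_partial, p = partial_pearson(x, y, z)
        assert r_marginal > 0.7
        assert abs(r_partial) < 0.15
        assert p > 0.01

    def test_two_route_equality_with_residualized_inputs(self):
        rng = np.random.default_rng(9)
        n = 60
        cov = rng.normal(size=(n, 2))
        x = cov @ [1.0, -0.5] + rng.normal(size=n)
        y = cov @ [0.3, 0.7] + rng.normal(size=n)
        design = np.column_stack([np.ones(n), cov])
        rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        r_route1, _ = partial_pearson(x, y, cov)
        r_route2 = float(np.corrcoef(rx, ry)[0, 1])
        assert r_route1 == pytest.approx(r_route2)

    def test_agrees_with_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(40, 4)),
                          columns=["x", "y", "c1", "c2"])
        df["y"] += df["x"] + df["c1"]
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        p_col = "p_val" if "p_val" in ref.columns else "p-val"
        r, p = partial_pearson(df["x"], df["y"], df[["c1", "c2"]])
        assert r == pytest.approx(float(ref["r"].iloc[0]))
        assert p == pytest.approx(float(ref[p_col].iloc[0]))

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(11)
        z = rng.normal(size=30)
        cov = np.column_stack([z, 2 * z])
        with pytest.raises(ValueError, match="rank deficient"):
            partial_pearson(rng.normal(size=30), rng.normal(size=30), cov)


class TestAncova:
    def test_no_covariates_equals_t_squared(self):
        rng = np.random.default_rng(12)
        y = np.r_[rng.normal(size=20) + 1, rng.normal(size=25)]
        group = labelled(20, 25)
        res = ancova_compare(y, group)
        t, p = stats.ttest_ind(y[:20], y[20:], equal_var=True)
        assert res.f == pytest.approx(t**2)
        assert res.p == pytest.approx(p)

    def test_covariate_explains_group_difference(self):
        # group difference entirely mediated by the covariate
        rng = np.random.default_rng(13)
        n = 200
        cov = np.r_[rng.normal(size=n) + 2, rng.normal(size=n)]
        y = 1.5 * cov + 0.1 * rng.normal(size=2 * n)
        res = ancova_compare(y, labelled(n, n), cov)
        assert res.p > 0.05
        raw = ancova_compare(y, labelled(n, n))
        assert raw.p < 1e-10

    def test_adjusted_means_at_covariate_means(self):
        rng = np.random.default_rng(14)
        n = 100
        cov = rng.normal(size=2 * n)
        y = 2.0 + 1.0 * np.r_[np.ones(n), np.zeros(n)] + 0.5 * cov \
            + 0.3 * rng.normal(size=2 * n)
        res = ancova_compare(y, labelled(n, n), cov)
        diff = res.adjusted_means["case"] - res.adjusted_means["control"]
        assert diff == pytest.approx(1.0, abs=0.15)


class TestBaseline:
    def test_identical_groups_null(self):
        x = np.arange(10.0)
        df = pd.DataFrame({
            "group": ["case"] * 10 + ["control"] * 10,
            "v": np.r_[x, x],
        })
        out = baseline_compare(df, continuous=["v"])
        assert out.loc[0, "statistic"] == pytest.approx(0.0)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_published_administration_order_contingency(self):
        """43/57 vs 29/71 first-administration split is significant (~0.04)."""
        rows = (
            [("case", 1)] * 43 + [("case", 0)] * 57
            + [("control", 1)] * 29 + [("control", 0)] * 71
        )
        df = pd.DataFrame(rows, columns=["group", "tcvft_first"])
        out = baseline_compare(df, categorical=["tcvft_first"])
        assert out.loc[0, "p"] < 0.05
        assert out.loc[0, "p"] == pytest.approx(0.039, abs=0.002)

    def test_hand_computed_t_on_toy_sample(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        df = pd.DataFrame({"group": labelled(3, 3), "v": a + b})
        out = baseline_compare(df, continuous=["v"])
        # textbook pooled t: (2-4)/sqrt(sp2*(1/3+1/3)), sp2 = (2*1+2*4)/4
        sp2 = (2 * 1.0 + 2 * 4.0) / 4
        t_hand = (2.0 - 4.0) / math.sqrt(sp2 * (2 / 3))
        assert out.loc[0, "statistic"] == pytest.approx(t_hand)


class TestRetest:
    def _frame(self, x1, x2, n=None):
        n = len(x1)
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "age": rng.uniform(60, 90, n),
            "education_years": rng.uniform(0, 18, n),
            "score_1": x1,
            "score_2": x2,
        })

    def test_identical_administrations(self):
        x = np.random.default_rng(1).normal(size=25)
        r, p, n = test_retest(self._frame(x, x), "score")
        # second administration identical to the first
        assert r == pytest.approx(1.0) and n == 25

    def test_independent_administrations_near_zero(self):
        rng = np.random.default_rng(2)
        r, _, _ = test_retest(self._frame(rng.normal(size=2000),
                                          rng.normal(size=2000)), "score")
        assert abs(r) < 0.08

    def test_known_reliability_within_fisher_band(self):
        """rho=0.8 at n=20 recovers r inside the analytic sampling band."""
        rng = np.random.default_rng(3)
        n, rho = 20, 0.8
        z = rng.normal(size=n)
        x1 = math.sqrt(rho) * z + math.sqrt(1 - rho) * rng.normal(size=n)
        x2 = math.sqrt(rho) * z + math.sqrt(1 - rho) * rng.normal(size=n)
        r, _, _ = test_retest(self._frame(x1, x2), "score")
        # 99% Fisher-z interval around atanh(rho), se = 1/sqrt(n-3-k)
        half = 2.576 / math.sqrt(n - 3 - 2)
        lo, hi = math.tanh(math.atanh(rho) - half), math.tanh(math.atanh(rho) + half)
        assert lo < r < hi

    def test_listwise_exclusion_counts(self):
        x = np.arange(10.0)
        frame = self._frame(x, x)
        frame.loc[3, "score_2"] = np.nan
        r, _, n = test_retest(frame, "score")
        assert n == 9

    def test_scores_argument_selects_columns(self):
        frame = self._frame(np.arange(8.0), np.arange(8.0))
        frame = frame.rename(columns={"score_1": "tcvft_total_1",
                                      "score_2": "tcvft_total_2"})
        r, _, _ = test_retest(frame, "tcvft_total")
        assert r == pytest.approx(1.0)
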