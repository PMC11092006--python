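import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neuromse import prognostics as prog


def simulate_cohort_frame(rng, n=300, effect=0.0):
    """Plain covariate frame + binary outcome for regression tests."""
    X = pd.DataFrame(
        {
            "age": rng.normal(58, 13, n),
            "wfns": rng.integers(1, 6, n).astype(float),
            "mfisher": rng.integers(1, 5, n).astype(float),
            "dci": (rng.random(n) < 0.26).astype(float),
            "mse": rng.normal(25, 4, n),
        }
    )
    lp = (
        0.04 * (X["age"] - 58)
        + 0.35 * (X["wfns"] - 3)
        + 0.25 * (X["mfisher"] - 3)
        + 0.8 * X["dci"]
        + effect * (X["mse"] - 25)
    )
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    return X, y


class TestTTest:
    def test_identical_groups(self):
        t, df, p = prog.t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_pooled_variance_hand_computation(self):
        t, df, p = prog.t_test([1, 2, 3], [4, 5, 6], equal_var=True)
        assert abs(t) == pytest.approx(3.674, abs=0.001)
        assert df == 4

    def test_swapping_groups_flips_sign_only(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 25)
        t1, _, p1 = prog.t_test(a, b)
        t2, _, p2 = prog.t_test(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)


class TestAnova:
    def test_identical_groups_null(self):
        groups = {k: [1.0, 2.0, 3.0] for k in "abcd"}
        F, p, pm = prog.anova_pairwise(groups)
        assert F == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(pm.values, 1.0, atol=1e-6)

    def test_constructed_separation_detected(self, rng):
        lo = {k: rng.normal(0, 1, 30) for k in ("g1", "g2")}
        hi = {k: rng.normal(5, 1, 30) for k in ("g3", "g4")}
        F, p, pm = prog.anova_pairwise({**lo, **hi})
        assert pm.loc["g1", "g3"] < 0.001
        assert pm.loc["g1", "g2"] > 0.05 and pm.loc["g3", "g4"] > 0.05

    def test_pairwise_matrix_symmetric(self, rng):
        groups = {k: rng.normal(i, 1, 15) for i, k in enumerate("abcd")}
        _, _, pm = prog.anova_pairwise(groups)
        np.testing.assert_allclose(pm.values, pm.values.T)

    def test_tiny_group_dropped(self, rng):
        groups = {"a": rng.normal(0, 1, 10), "b": rng.normal(1, 1, 10), "c": [1.0]}
        _, _, pm = prog.anova_pairwise(groups)
        assert "c" not in pm.index


class TestRocAuc:
    @staticmethod
    def brute_force_auc(scores, labels):
        pos = [s for s, l in zip(scores, labels) if l == 1]
        neg = [s for s, l in zip(scores, labels) if l == 0]
        total = 0.0
        for p in pos:
            for q in neg:
                total += 1.0 if p > q else (0.5 if p == q else 0.0)
        return total / (len(pos) * len(neg))

    def test_perfect_separation(self):
        auc, ci = prog.roc_auc([1, 2, 3, 4], [0, 0, 1, 1])
        assert auc == 1.0

    def test_spec_micro_examples(self):
        auc, _ = prog.roc_auc([1, 3, 2, 4], [0, 1, 0, 1])
        assert auc == 1.0
        auc2, _ = prog.roc_auc([1, 3, 2, 4], [0, 1, 1, 0])
        assert auc2 == 0.5

    def test_equals_pair_enumeration_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = rng.integers(0, 12, n).astype(float)  # many ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            auc, _ = prog.roc_auc(scores, labels)
            assert auc == pytest.approx(self.brute_force_auc(scores, labels))

    def test_label_inversion_symmetry(self, rng):
        scores = rng.normal(0, 1, 80)
        labels = rng.integers(0, 2, 80)
        a1, _ = prog.roc_auc(scores, labels)
        a2, _ = prog.roc_auc(scores, 1 - labels)
        assert a1 == pytest.approx(1 - a2)

    def test_ci_contains_point_estimate(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 40), rng.normal(1, 1, 40)])
        labels = np.repeat([0, 1], 40)
        auc, (lo, hi) = prog.roc_auc(scores, labels)
        assert 0 <= lo <= auc <= hi <= 1


class TestDeLongCompare:
    def test_identical_scores(self, rng):
        s = rng.normal(0, 1, 50)
        labels = rng.integers(0, 2, 50)
        labels[:5], labels[-5:] = 0, 1
        delta, p = prog.delong_compare(s, s, labels)
        assert delta == 0.0 and p == 1.0

    def test_swap_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 60), rng.normal(0, 1, 60)
        labels = np.repeat([0, 1], 30)
        d1, p1 = prog.delong_compare(a, b, labels)
        d2, p2 = prog.delong_compare(b, a, labels)
        assert d1 == pytest.approx(-d2) and p1 == pytest.approx(p2)

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(4)
        labels = np.repeat([0, 1], 30)
        signal = labels * 0.8
        a = signal + rng.normal(0, 1, 60)
        b = 0.5 * signal + rng.normal(0, 1, 60)
        delta, p = prog.delong_compare(a, b, labels)
        # oracle: swap the paired scores subject-wise at random
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            swap = rng.random(60) < 0.5
            ap = np.where(swap, b, a)
            bp = np.where(swap, a, b)
            d_perm = (
                prog._delong_components(ap, labels)[0].mean()
                - prog._delong_components(bp, labels)[0].mean()
            )
            if abs(d_perm) >= abs(delta):
                count += 1
        p_perm = count / n_perm
        assert p == pytest.approx(p_perm, abs=0.08)


class TestYouden:
    @staticmethod
    def brute_force(scores, labels):
        uniq = np.unique(scores)
        cands = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else uniq
        best_j, best_thr = -np.inf, None
        for thr in cands:
            pred = scores < thr
            sens = np.mean(pred[labels == 1])
            spec = np.mean(~pred[labels == 0])
            j = sens + spec - 1
            if j > best_j + 1e-12:
                best_j, best_thr = j, thr
        return best_thr, best_j

    def test_perfect_separation(self):
        out = prog.youden_threshold([1, 2, 9, 10], [1, 1, 0, 0], event_low=True)
        assert out["youden"] == pytest.approx(1.0)
        assert out["sensitivity"] == out["specificity"] == out["accuracy"] == 1.0

    def test_matches_exhaustive_search(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 40))
            scores = rng.integers(0, 15, n).astype(float)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            out = prog.youden_threshold(scores, labels, event_low=True)
            thr, j = self.brute_force(scores, labels)
            assert out["youden"] == pytest.approx(j)
            assert out["threshold"] == pytest.approx(thr)

    def test_degenerate_scores_zero_index(self):
        out = prog.youden_threshold([5.0] * 10, [0, 1] * 5, event_low=True)
        assert out["youden"] == pytest.approx(0.0)


class TestLogisticFit:
    def test_two_by_two_odds_ratio_exact(self):
        # 2x2 table a=20 exposed events, b=10, c=10, d=20 -> OR = ad/bc = 4
        x = np.repeat([1, 1, 0, 0], [20, 10, 10, 20])
        y = np.repeat([1, 0, 1, 0], [20, 10, 10, 20])
        fit = prog.logistic_fit(pd.DataFrame({"x": x}), y)
        assert fit.odds_ratios.loc["x", "OR"] == pytest.approx(4.0, abs=1e-6)

    def test_null_model_cis_contain_one(self):
        rng = np.random.default_rng(21)
        X, _ = simulate_cohort_frame(rng, n=2000)
        y = rng.integers(0, 2, 2000)
        fit = prog.logistic_fit(X, y)
        for term in fit.terms:
            row = fit.odds_ratios.loc[term]
            assert row["lo"] <= 1.0 <= row["hi"]

    def test_matches_newton_from_zero_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(60, 200))
            X = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=list("abc"))
            lp = 0.5 * X["a"] - 0.3 * X["b"]
            y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
            if y.min() == y.max():
                continue
            fit = prog.logistic_fit(X, y)
            # independent Newton iteration starting from zero
            Xd = np.column_stack([np.ones(n), X.to_numpy()])
            beta = np.zeros(4)
            for _ in range(60):
                p = 1 / (1 + np.exp(-Xd @ beta))
                grad = Xd.T @ (y - p)
                H = Xd.T @ (Xd * (p * (1 - p))[:, None])
                step = np.linalg.solve(H, grad)
                beta = beta + step
                if np.max(np.abs(grad)) < 1e-10:
                    break
            ours = fit.params[["const", "a", "b", "c"]].to_numpy()
            np.testing.assert_allclose(ours, beta, atol=1e-8)

    def test_separation_flagged(self):
        x = np.array([0, 1, 2, 3, 10, 11, 12, 13], dtype=float)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        fit = prog.logistic_fit(pd.DataFrame({"x": x}), y)
        assert fit.separation

    def test_singular_design_names_columns(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=50)})
        X["b"] = 2 * X["a"]
        y = rng.integers(0, 2, 50)
        with pytest.raises(ValueError, match="collinear"):
            prog.logistic_fit(X, y)


class TestModelMetrics:
    def test_null_model_r2_zero(self):
        assert prog.nagelkerke_r2(llf=-60.0, llnull=-60.0, n=100) == pytest.approx(0.0)

    def test_brier_perfect_and_uninformative(self, rng):
        y = rng.integers(0, 2, 100).astype(float)
        assert np.mean((y - y) ** 2) == 0.0
        assert np.mean((np.full(100, 0.5) - y) ** 2) == pytest.approx(0.25)

    def test_r2_invariant_to_predictor_rescaling(self, rng):
        X, y = simulate_cohort_frame(rng, n=400, effect=-0.2)
        fit1 = prog.logistic_fit(X, y)
        X2 = X.copy()
        X2["mse"] = X2["mse"] * 10 + 3
        fit2 = prog.logistic_fit(X2, y)
        assert fit1.nagelkerke_r2 == pytest.approx(fit2.nagelkerke_r2, abs=1e-6)


class TestHosmerLemeshow:
    def test_matches_direct_formula_oracle(self, rng):
        y = rng.integers(0, 2, 200).astype(float)
        probs = np.clip(rng.random(200), 0.05, 0.95)
        stat, df, p = prog.hosmer_lemeshow(y, probs, g=10)
        order = np.argsort(probs, kind="stable")
        ys, ps = y[order], probs[order]
        oracle = 0.0
        for k in range(10):
            a, b = k * 20, (k + 1) * 20
            obs, exp = ys[a:b].sum(), ps[a:b].sum()
            pbar = exp / 20
            oracle += (obs - exp) ** 2 / (20 * pbar * (1 - pbar))
        assert stat == pytest.approx(oracle)
        assert df == 8

    def test_well_calibrated_probs_not_rejected(self):
        rng = np.random.default_rng(17)
        probs = rng.uniform(0.1, 0.9, 2000)
        y = (rng.random(2000) < probs).astype(float)
        _, _, p = prog.hosmer_lemeshow(y, probs)
        assert p > 0.01


class TestExternalValidation:
    def test_shrunken_predictions_give_slope_two(self):
        rng = np.random.default_rng(3)
        n = 4000
        x = rng.normal(0, 1, n)
        lp_true = 1.2 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-lp_true))).astype(int)
        fit = prog.logistic_fit(pd.DataFrame({"x": x}), y, ["x"])
        shrunk = prog.ModelFit(**{**fit.__dict__})
        shrunk.params = fit.params * 0.5  # logits halved
        report = prog.external_validate(shrunk, pd.DataFrame({"x": x}), y)
        assert report.calibration_slope == pytest.approx(2.0, abs=0.25)

    def test_report_fields_coherent(self, rng):
        X, y = simulate_cohort_frame(rng, n=500, effect=-0.2)
        fit = prog.logistic_fit(X, y)
        Xv, yv = simulate_cohort_frame(rng, n=400, effect=-0.2)
        report = prog.external_validate(fit, Xv, yv)
        assert 0 <= report.auc <= 1
        assert report.hl_df >= 1 and 0 <= report.hl_p <= 1


class TestOrdinal:
    @staticmethod
    def simulate_po(rng, n, beta=(-0.4, 0.5), cuts=(-1.0, 0.2, 1.3)):
        X = pd.DataFrame(rng.normal(0, 1, (n, 2)), columns=["a", "b"])
        lp = beta[0] * X["a"] + beta[1] * X["b"]
        latent = lp + rng.logistic(size=n)
        y = np.searchsorted(np.asarray(cuts), latent)
        return X, y

    def test_null_common_or_ci_contains_one(self):
        rng = np.random.default_rng(5)
        X, _ = self.simulate_po(rng, 500)
        y = rng.integers(0, 4, 500)
        fit = prog.polr_fit(X, y)
        for t in fit.terms:
            assert fit.odds_ratios.loc[t, "lo"] <= 1 <= fit.odds_ratios.loc[t, "hi"]

    def test_parameter_recovery_and_increasing_thresholds(self):
        rng = np.random.default_rng(6)
        X, y = self.simulate_po(rng, 2000)
        fit = prog.polr_fit(X, y)
        assert fit.coefs["a"] == pytest.approx(-0.4, abs=0.15)
        assert fit.coefs["b"] == pytest.approx(0.5, abs=0.15)
        assert np.all(np.diff(fit.thresholds) > 0)

    def test_brant_accepts_proportional_data(self):
        rng = np.random.default_rng(8)
        X, y = self.simulate_po(rng, 1500)
        out = prog.brant_test(X, y)
        assert out["omnibus"]["p"] > 0.05
        assert set(out["per_predictor"]) == {"a", "b"}

    def test_brant_rejects_constructed_violation(self):
        rng = np.random.default_rng(9)
        n = 2000
        X = pd.DataFrame({"a": rng.normal(0, 1, n)})
        # slope changes sign across cutoffs: gross violation
        z1 = (rng.random(n) < 1 / (1 + np.exp(-(0.8 * X["a"] + 1.0)))).astype(int)
        z2 = (rng.random(n) < 1 / (1 + np.exp(-(-0.8 * X["a"] - 0.5)))).astype(int)
        y = z1 + np.minimum(z1, z2)
        out = prog.brant_test(X, y)
        assert out["omnibus"]["p"] < 0.05

    def test_per_predictor_df_bookkeeping(self):
        rng = np.random.default_rng(10)
        X, y = self.simulate_po(rng, 800)
        out = prog.brant_test(X, y)
        J = out["n_cutoffs"]
        assert out["omnibus"]["df"] == (J - 1) * len(X.columns)
        for t in out["per_predictor"].values():
            assert t["df"] == J - 1


class TestSlidingDichotomy:
    def test_cutoffs_depend_on_risk_group(self):
        risk = np.array([0.1, 0.1, 0.5, 0.5, 0.9, 0.9])
        gose = np.array([7, 6, 5, 4, 3, 2])
        unfav, group = prog.sliding_dichotomy_outcome(risk, gose)
        # low risk: favorable only for GOSE 7-8
        assert unfav[0] == 0 and unfav[1] == 1
        # intermediate: favorable for GOSE 5-8
        assert unfav[2] == 0 and unfav[3] == 1
        # high risk: favorable for GOSE 3-8
        assert unfav[4] == 0 and unfav[5] == 1

    def test_matches_hand_rolled_oracle_on_30_patients(self):
        rng = np.random.default_rng(30)
        n = 30
        X = pd.DataFrame(
            {
                "age": rng.normal(58, 12, n).round(1),
                "wfns": rng.integers(1, 6, n).astype(float),
                "mfisher": rng.integers(1, 5, n).astype(float),
                "dci": (rng.random(n) < 0.3).astype(float),
            }
        )
        gose = rng.integers(1, 9, n)
        mse = rng.normal(24, 4, n)
        while len(np.unique(prog.unfavorable(gose))) < 2:
            gose = rng.integers(1, 9, n)
        result = prog.sliding_dichotomy(X, gose, mse)

        # oracle: explicit loops, statsmodels only for the two fits
        import statsmodels.api as sm

        y = np.array([1 if g <= 4 else 0 for g in gose])
        base = sm.Logit(y, sm.add_constant(X.to_numpy())).fit(disp=False)
        risk = np.asarray(base.predict(sm.add_constant(X.to_numpy())))
        q1, q2 = np.quantile(risk, [1 / 3, 2 / 3])
        unfav = []
        for r_i, g in zip(risk, gose):
            if r_i <= q1:
                cut = 7
            elif r_i <= q2:
                cut = 5
            else:
                cut = 3
            unfav.append(1 if g < cut else 0)
        unfav = np.array(unfav)
        refit = sm.Logit(unfav, sm.add_constant(mse)).fit(disp=False)
        assert result["or"] == pytest.approx(np.exp(refit.params[1]), abs=1e-6)
        np.testing.assert_array_equal(result["adjusted_unfavorable"], unfav)

    def test_protective_metric_gives_or_below_one(self):
        rng = np.random.default_rng(31)
        n = 400
        X = pd.DataFrame(
            {
                "age": rng.normal(58, 12, n),
                "wfns": rng.integers(1, 6, n).astype(float),
                "mfisher": rng.integers(1, 5, n).astype(float),
                "dci": (rng.random(n) < 0.3).astype(float),
            }
        )
        mse = rng.normal(25, 4, n)
        lp = 0.3 * (X["wfns"] - 3) - 0.25 * (mse - 25)
        latent = lp + rng.logistic(size=n)
        gose = np.clip(8 - np.digitize(latent, np.linspace(-2, 2, 7)), 1, 8)
        result = prog.sliding_dichotomy(X, gose, mse)
        assert result["or"] < 1.0
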