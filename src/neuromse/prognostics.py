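"""Statistical association of MSE metrics with 12-month functional outcome.

Outcome coding
--------------
The extended Glasgow Outcome Scale (GOSE, 1-8) is analyzed three ways:

* dichotomized — unfavorable = GOSE 1-4 (coded 1), favorable = GOSE 5-8;
* ordinal — four groups: Dead/Vegetative (1-2), Severe Disability (3-4),
  Moderate Disability (5-6), Good Recovery (7-8);
* sliding dichotomy — the favorable/unfavorable cut for each patient depends
  on their baseline prognostic risk group.

Because unfavorable outcome is the event and higher complexity is
protective, MSE odds ratios below 1 indicate the expected direction in every
framework.

The battery comprises univariable t-tests and ROC analysis with DeLong
confidence intervals and Youden-index operating points, one-way ANOVA with
Tukey pairwise comparisons across the four ordinal groups,
covariate-adjusted logistic regression (age, WFNS, mFisher, DCI) with
Nagelkerke R^2 and Brier score, bootstrap optimism correction (Harrell),
external validation (discrimination, Hosmer-Lemeshow fit, calibration
intercept and slope), proportional-odds regression with the Brant-Wald
assumption check, and the sliding-dichotomy analysis.

Ordinary model fits go through statsmodels; the ROC/DeLong machinery,
Hosmer-Lemeshow test, Brant-Wald test, optimism bootstrap, and sliding
dichotomy are implemented here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "wfns", "mfisher", "dci")

ORDINAL_GROUP_LABELS = ("Dead/Vegetative", "Severe", "Moderate", "Good")


def unfavorable(gose) -> np.ndarray:
    """1 for GOSE 1-4 (unfavorable), 0 for GOSE 5-8."""
    return (np.asarray(gose) <= 4).astype(int)


def ordinal_group(gose) -> np.ndarray:
    """0 Dead/Vegetative (1-2), 1 Severe (3-4), 2 Moderate (5-6), 3 Good (7-8)."""
    return (np.asarray(gose, dtype=int) - 1) // 2


def ordinal_worseness(gose) -> np.ndarray:
    """Ordinal outcome on a worse-is-higher scale (0 Good .. 3 Dead/Veg)."""
    return 3 - ordinal_group(gose)


# ---------------------------------------------------------------------------
# univariable


def t_test(a, b, equal_var: bool = False):
    """Two-sided independent t-test; Welch by default.

    Returns ``(t, df, p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            n = len(a) + len(b) - 2
            return 0.0, float(n), 1.0
        raise ValueError("both groups degenerate with differing means")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def anova_pairwise(groups: dict):
    """One-way ANOVA F-test plus Tukey HSD pairwise comparisons.

    ``groups`` maps group label to a sample.  Groups with fewer than two
    observations are dropped with a warning.  Returns
    ``(F, p, pairwise_p)`` where ``pairwise_p`` is a symmetric DataFrame.
    """
    kept = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) >= 2}
    dropped = set(groups) - set(kept)
    if dropped:
        logger.warning("anova: dropping groups with n<2: %s", sorted(dropped))
    if len(kept) < 2:
        raise ValueError("need at least two groups with n >= 2")
    labels = list(kept)
    samples = [kept[k] for k in labels]
    if all(s.std() == 0 for s in samples) and len({s.mean() for s in samples}) == 1:
        F, p = 0.0, 1.0
        pm = pd.DataFrame(1.0, index=labels, columns=labels)
        return F, p, pm
    F, p = stats.f_oneway(*samples)
    tk = stats.tukey_hsd(*samples)
    pm = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    for i in range(len(labels)):
        for j in range(len(labels)):
            if i != j:
                pm.iloc[i, j] = tk.pvalue[i, j]
    return float(F), float(p), pm


# ---------------------------------------------------------------------------
# ROC / DeLong


def _delong_components(scores, labels):
    """Structural components (V10 per case, V01 per control) of the AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome classes must be present")
    m, n = len(pos), len(neg)
    # midrank formulation (handles ties): psi(x, y) = 1{x>y} + 0.5*1{x==y}
    all_scores = np.concatenate([pos, neg])
    rank_all = stats.rankdata(all_scores)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    return v10, v01


def roc_auc(scores, labels):
    """AUC (Mann-Whitney probability, tie-corrected) with DeLong 95% CI.

    The CI is computed on the logit scale and the bounds are clipped to
    [0, 1]; degenerate variance collapses the CI onto the point estimate.
    Returns ``(auc, (lo, hi))``.
    """
    v10, v01 = _delong_components(scores, labels)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.975)
    if se == 0 or auc in (0.0, 1.0):
        lo = hi = auc
        if se > 0:  # auc at boundary: fall back to linear-scale clipped CI
            lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
        return auc, (lo, hi)
    logit = np.log(auc / (1 - auc))
    se_logit = se / (auc * (1 - auc))
    lo = 1 / (1 + np.exp(-(logit - z * se_logit)))
    hi = 1 / (1 + np.exp(-(logit + z * se_logit)))
    return auc, (float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))


def delong_compare(scores_a, scores_b, labels):
    """Paired DeLong test for the difference between two correlated AUCs.

    Returns ``(delta_auc, p)`` with ``delta = auc_a - auc_b``; zero variance
    of the difference yields p = 1 with a warning.
    """
    va10, va01 = _delong_components(scores_a, labels)
    vb10, vb01 = _delong_components(scores_b, labels)
    auc_a, auc_b = va10.mean(), vb10.mean()
    delta = float(auc_a - auc_b)
    m, n = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10]))
    s01 = np.cov(np.vstack([va01, vb01]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0:
        if delta != 0:
            logger.warning("delong_compare: zero variance with nonzero delta")
        return delta, 1.0
    z = delta / np.sqrt(var)
    return delta, float(2 * stats.norm.sf(abs(z)))


def youden_threshold(scores, labels, event_low: bool = True):
    """Operating point maximizing the Youden index (sens + spec - 1).

    Candidate thresholds are midpoints between adjacent distinct scores.
    ``event_low=True`` classifies the event when the score is *below* the
    threshold — the right direction for MSE, where low complexity predicts
    unfavorable outcome.  Ties in the index break toward the smallest
    threshold.

    Returns a dict with threshold, sensitivity, specificity, ppv, npv,
    accuracy and the index value.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both outcome classes must be present")
    uniq = np.unique(scores)
    cands = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else np.array([uniq[0]])
    best = None
    for thr in cands:
        pred = scores < thr if event_low else scores > thr
        tp = int(np.sum(pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1
        if best is None or j > best["youden"] + 1e-12:
            best = {
                "threshold": float(thr),
                "sensitivity": sens,
                "specificity": spec,
                "ppv": tp / (tp + fp) if tp + fp else np.nan,
                "npv": tn / (tn + fn) if tn + fn else np.nan,
                "accuracy": (tp + tn) / len(labels),
                "youden": j,
            }
    return best


# ---------------------------------------------------------------------------
# logistic regression


@dataclass
class ModelFit:
    """Fitted logistic model with discrimination and calibration summaries."""

    terms: list[str]  # exog column order, excluding the constant
    params: pd.Series  # includes "const"
    bse: pd.Series
    pvalues: pd.Series
    odds_ratios: pd.DataFrame  # columns OR, lo, hi per non-constant term
    auc: float
    auc_ci: tuple[float, float]
    nagelkerke_r2: float
    brier: float
    n: int
    llf: float
    llnull: float
    linear_predictor: np.ndarray
    fitted_probs: np.ndarray
    separation: bool = False

    def predict_linear(self, X: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(X), self.params["const"], dtype=float)
        for term in self.terms:
            lp += self.params[term] * X[term].to_numpy(dtype=float)
        return lp

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.predict_linear(X)))


def _design(X: pd.DataFrame, terms=None) -> pd.DataFrame:
    if terms is None:
        terms = list(X.columns)
    mat = X[list(terms)].astype(float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(mat)), mat.to_numpy()]))
    if rank < len(terms) + 1:
        corr = mat.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax() if len(terms) > 1 else (terms[0],)
        raise ValueError(f"singular design; near-collinear columns: {worst}")
    return sm.add_constant(mat, has_constant="add")


def logistic_fit(X: pd.DataFrame, y, terms=None) -> ModelFit:
    """Maximum-likelihood logistic regression of a binary outcome.

    Fits by Newton iterations (iteratively reweighted least squares) with
    Wald confidence intervals.  Perfect separation is detected and flagged
    on the returned fit rather than raised.
    """
    y = np.asarray(y).astype(float)
    exog = _design(X, terms)
    terms = [c for c in exog.columns if c != "const"]
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.Logit(y, exog)
        try:
            res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=False)
        except Exception:
            res = model.fit(method="bfgs", maxiter=500, disp=False)
        for w in caught:
            if "separation" in str(w.message).lower() or "Maximum Likelihood" in str(
                w.message
            ):
                separation = True
    if np.any(np.abs(res.params) > 50):
        separation = True
    if separation:
        logger.warning("logistic_fit: possible separation; coefficients diverging")
    params = pd.Series(res.params, index=exog.columns)
    bse = pd.Series(res.bse, index=exog.columns)
    pvalues = pd.Series(res.pvalues, index=exog.columns)
    z = stats.norm.ppf(0.975)
    rows = {}
    for term in terms:
        beta, se = params[term], bse[term]
        rows[term] = {
            "OR": np.exp(beta),
            "lo": np.exp(beta - z * se),
            "hi": np.exp(beta + z * se),
            "p": pvalues[term],
        }
    or_table = pd.DataFrame(rows).T
    probs = np.asarray(res.predict(exog))
    lp = np.asarray(exog.to_numpy() @ res.params)
    auc, auc_ci = roc_auc(probs, y.astype(int))
    r2 = nagelkerke_r2(res.llf, res.llnull, len(y))
    brier = float(np.mean((probs - y) ** 2))
    return ModelFit(
        terms=terms,
        params=params,
        bse=bse,
        pvalues=pvalues,
        odds_ratios=or_table,
        auc=auc,
        auc_ci=auc_ci,
        nagelkerke_r2=r2,
        brier=brier,
        n=len(y),
        llf=float(res.llf),
        llnull=float(res.llnull),
        linear_predictor=lp,
        fitted_probs=probs,
        separation=separation,
    )


def nagelkerke_r2(llf: float, llnull: float, n: int) -> float:
    """Cox-Snell R^2 rescaled to a 0-1 range."""
    cox_snell = 1.0 - np.exp(2.0 * (llnull - llf) / n)
    max_cs = 1.0 - np.exp(2.0 * llnull / n)
    if max_cs <= 0:
        return 0.0
    return float(cox_snell / max_cs)


def model_metrics(fit: ModelFit) -> tuple[float, float]:
    """(Nagelkerke R^2, Brier score) of a fitted model."""
    return fit.nagelkerke_r2, fit.brier


def _binary_loglik(y, probs):
    eps = 1e-12
    p = np.clip(probs, eps, 1 - eps)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


# ---------------------------------------------------------------------------
# internal validation (Harrell optimism bootstrap)


def bootstrap_validate(X: pd.DataFrame, y, terms=None, B: int = 1000, seed: int = 0):
    """Optimism-corrected AUC, Nagelkerke R^2 and Brier score.

    For each of ``B`` bootstrap resamples the model is refit and evaluated
    both on the resample and on the original data; optimism is the mean
    excess of the former over the latter, and the corrected estimate is the
    apparent performance minus the optimism.  Resamples with a single
    outcome class are redrawn (logged).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    y = np.asarray(y).astype(float)
    apparent = logistic_fit(X, y, terms)
    terms = apparent.terms
    rng = np.random.default_rng(seed)
    n = len(y)
    llnull_orig = _binary_loglik(y, np.full(n, y.mean()))
    opt = {"auc": [], "r2": [], "brier": []}
    redraws = 0
    for _ in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if 0 < yb.sum() < n:
                break
            redraws += 1
        Xb = X.iloc[idx].reset_index(drop=True)
        try:
            boot = logistic_fit(Xb, yb, terms)
        except Exception:
            redraws += 1
            continue
        probs_orig = boot.predict_proba(X)
        auc_orig, _ = roc_auc(probs_orig, y.astype(int))
        llf_orig = _binary_loglik(y, probs_orig)
        r2_orig = nagelkerke_r2(llf_orig, llnull_orig, n)
        brier_orig = float(np.mean((probs_orig - y) ** 2))
        opt["auc"].append(boot.auc - auc_orig)
        opt["r2"].append(boot.nagelkerke_r2 - r2_orig)
        opt["brier"].append(boot.brier - brier_orig)
    if redraws:
        logger.info("bootstrap_validate: %d degenerate resamples redrawn", redraws)
    optimism = {k: float(np.mean(v)) for k, v in opt.items()}
    return {
        "apparent": {"auc": apparent.auc, "r2": apparent.nagelkerke_r2,
                     "brier": apparent.brier},
        "optimism": optimism,
        "corrected": {
            "auc": apparent.auc - optimism["auc"],
            "r2": apparent.nagelkerke_r2 - optimism["r2"],
            "brier": apparent.brier - optimism["brier"],
        },
        "B": B,
    }


# ---------------------------------------------------------------------------
# external validation


def hosmer_lemeshow(y, probs, g: int = 10):
    """Hosmer-Lemeshow goodness-of-fit over risk deciles.

    Groups with zero expected events are merged with their neighbor
    (logged).  Returns ``(statistic, df, p)``.
    """
    y = np.asarray(y).astype(float)
    probs = np.asarray(probs, dtype=float)
    order = np.argsort(probs, kind="stable")
    y_s, p_s = y[order], probs[order]
    edges = [int(round(k * len(y) / g)) for k in range(g + 1)]
    groups = [
        (y_s[a:b], p_s[a:b]) for a, b in zip(edges[:-1], edges[1:]) if b > a
    ]
    merged: list[tuple[np.ndarray, np.ndarray]] = []
    for yg, pg in groups:
        if merged and (pg.sum() == 0 or (1 - pg).sum() == 0):
            logger.info("hosmer_lemeshow: merging group with zero expected count")
            py, pp = merged[-1]
            merged[-1] = (np.concatenate([py, yg]), np.concatenate([pp, pg]))
        else:
            merged.append((yg, pg))
    stat = 0.0
    for yg, pg in merged:
        ng = len(yg)
        obs = yg.sum()
        exp = pg.sum()
        pbar = exp / ng
        denom = ng * pbar * (1 - pbar)
        if denom > 0:
            stat += (obs - exp) ** 2 / denom
    df = max(len(merged) - 2, 1)
    return float(stat), df, float(stats.chi2.sf(stat, df))


@dataclass
class ValidationReport:
    auc: float
    auc_ci: tuple[float, float]
    hl_statistic: float
    hl_df: int
    hl_p: float
    calibration_intercept: float
    calibration_slope: float
    n: int


def external_validate(fit: ModelFit, X_val: pd.DataFrame, y_val, g: int = 10) -> ValidationReport:
    """Apply a frozen model to an independent cohort.

    Reports discrimination (AUC with DeLong CI), Hosmer-Lemeshow fit over
    ``g`` risk groups, and the calibration intercept and slope from a
    logistic recalibration of the observed outcome on the frozen linear
    predictor (ideal values 0 and 1).
    """
    y_val = np.asarray(y_val).astype(int)
    lp = fit.predict_linear(X_val)
    probs = 1.0 / (1.0 + np.exp(-lp))
    auc, auc_ci = roc_auc(probs, y_val)
    hl_stat, hl_df, hl_p = hosmer_lemeshow(y_val, probs, g)
    recal = sm.Logit(y_val, sm.add_constant(lp)).fit(disp=False)
    return ValidationReport(
        auc=auc,
        auc_ci=auc_ci,
        hl_statistic=hl_stat,
        hl_df=hl_df,
        hl_p=hl_p,
        calibration_intercept=float(recal.params[0]),
        calibration_slope=float(recal.params[1]),
        n=len(y_val),
    )


# ---------------------------------------------------------------------------
# ordinal analysis


@dataclass
class PolrFit:
    """Proportional-odds fit; odds ratios are for a *worse* outcome."""

    terms: list[str]
    coefs: pd.Series
    bse: pd.Series
    odds_ratios: pd.DataFrame  # OR, lo, hi, p per term
    thresholds: np.ndarray
    llf: float
    n: int
    model_data: tuple = field(default=None, repr=False)


def polr_fit(X: pd.DataFrame, y_ordinal, terms=None, bootstrap_ci: int = 0,
             seed: int = 0) -> PolrFit:
    """Proportional-odds logistic regression on a worse-is-higher ordinal outcome.

    The common odds ratio per predictor is for the odds of a *worse*
    outcome, so protective predictors (like MSE) give OR < 1, consistent
    with the dichotomized analysis.  Empty outcome categories are collapsed
    with their lower neighbor (logged).  ``bootstrap_ci`` > 0 replaces the
    Wald CI with a percentile bootstrap of that many replicates.
    """
    y = np.asarray(y_ordinal, dtype=int)
    levels = np.unique(y)
    if len(levels) < 3:
        raise ValueError("need at least three populated outcome levels")
    # re-index to consecutive codes, collapsing silent gaps
    remap = {lv: i for i, lv in enumerate(levels)}
    if len(levels) != y.max() - y.min() + 1:
        logger.info("polr_fit: collapsing empty outcome categories")
    y_c = np.array([remap[v] for v in y])
    if terms is None:
        terms = list(X.columns)
    exog = X[list(terms)].astype(float)
    model = OrderedModel(y_c, exog, distr="logit")
    res = model.fit(method="bfgs", maxiter=500, disp=False)
    k = len(terms)
    coefs = pd.Series(res.params[:k], index=terms)
    bse = pd.Series(res.bse[:k], index=terms)
    pvals = pd.Series(res.pvalues[:k], index=terms)
    z = stats.norm.ppf(0.975)
    rows = {
        t: {
            "OR": np.exp(coefs[t]),
            "lo": np.exp(coefs[t] - z * bse[t]),
            "hi": np.exp(coefs[t] + z * bse[t]),
            "p": pvals[t],
        }
        for t in terms
    }
    if bootstrap_ci:
        rng = np.random.default_rng(seed)
        boots = {t: [] for t in terms}
        n = len(y_c)
        for _ in range(bootstrap_ci):
            idx = rng.integers(0, n, size=n)
            yb = y_c[idx]
            if len(np.unique(yb)) < 3:
                continue
            try:
                rb = OrderedModel(yb, exog.iloc[idx], distr="logit").fit(
                    method="bfgs", maxiter=200, disp=False
                )
            except Exception:
                continue
            for i, t in enumerate(terms):
                boots[t].append(rb.params[i])
        for t in terms:
            if len(boots[t]) >= 50:
                lo, hi = np.percentile(boots[t], [2.5, 97.5])
                rows[t]["lo"], rows[t]["hi"] = np.exp(lo), np.exp(hi)
    thresholds = model.transform_threshold_params(res.params)[1:-1]
    return PolrFit(
        terms=list(terms),
        coefs=coefs,
        bse=bse,
        odds_ratios=pd.DataFrame(rows).T,
        thresholds=np.asarray(thresholds, dtype=float),
        llf=float(res.llf),
        n=len(y_c),
        model_data=(y_c, exog),
    )


def brant_test(X: pd.DataFrame, y_ordinal, terms=None):
    """Brant-Wald test of the proportional-odds assumption.

    Fits the cutoff-specific binary logits ``1{y > j}`` and tests equality
    of their slopes via a Wald statistic using the between-model covariance
    of the estimates.  Returns a dict with the omnibus ``(statistic, df, p)``
    and a per-predictor table.  Cutoffs whose binary logit fails to converge
    are excluded (logged).
    """
    y = np.asarray(y_ordinal, dtype=int)
    levels = np.sort(np.unique(y))
    if len(levels) < 3:
        raise ValueError("need at least three outcome levels")
    if terms is None:
        terms = list(X.columns)
    exog = sm.add_constant(X[list(terms)].astype(float), has_constant="add")
    Xmat = exog.to_numpy(dtype=float)
    n, p1 = Xmat.shape
    p = p1 - 1
    betas, pis = [], []
    for cut in levels[:-1]:
        z = (y > cut).astype(float)
        try:
            res = sm.Logit(z, exog).fit(method="newton", maxiter=100, disp=False)
            if not np.all(np.isfinite(res.params)):
                raise ValueError("non-finite estimates")
        except Exception:
            logger.warning("brant_test: cutoff %s excluded (non-convergent)", cut)
            continue
        betas.append(np.asarray(res.params))
        pis.append(np.asarray(res.predict(exog)))
    J = len(betas)  # number of usable cutoffs
    if J < 2:
        raise ValueError("fewer than two convergent cutoff models")
    # between-model covariance of the stacked coefficient vectors
    xtwx_inv = []
    for j in range(J):
        w = pis[j] * (1 - pis[j])
        xtwx_inv.append(np.linalg.inv(Xmat.T @ (Xmat * w[:, None])))
    V = np.zeros((J * p, J * p))
    for j in range(J):
        for l in range(j, J):
            w_jl = pis[l] - pis[j] * pis[l]  # j <= l implies pi_l <= pi_j
            mid = Xmat.T @ (Xmat * w_jl[:, None])
            block = xtwx_inv[j] @ mid @ xtwx_inv[l]
            V[j * p : (j + 1) * p, l * p : (l + 1) * p] = block[1:, 1:]
            if l != j:
                V[l * p : (l + 1) * p, j * p : (j + 1) * p] = block[1:, 1:].T
    beta_star = np.concatenate([b[1:] for b in betas])
    # contrasts: slopes of model 1 minus each later model, per predictor
    D = np.zeros(((J - 1) * p, J * p))
    row = 0
    for j in range(1, J):
        for k in range(p):
            D[row, k] = 1.0
            D[row, j * p + k] = -1.0
            row += 1
    omnibus_stat = _wald(D, beta_star, V)
    omnibus_df = (J - 1) * p
    per_pred = {}
    for k, term in enumerate(terms):
        Dk = np.zeros((J - 1, J * p))
        for j in range(1, J):
            Dk[j - 1, k] = 1.0
            Dk[j - 1, j * p + k] = -1.0
        stat_k = _wald(Dk, beta_star, V)
        per_pred[term] = {
            "statistic": stat_k,
            "df": J - 1,
            "p": float(stats.chi2.sf(stat_k, J - 1)),
        }
    return {
        "omnibus": {
            "statistic": omnibus_stat,
            "df": omnibus_df,
            "p": float(stats.chi2.sf(omnibus_stat, omnibus_df)),
        },
        "per_predictor": per_pred,
        "n_cutoffs": J,
    }


def _wald(D, beta, V):
    d = D @ beta
    cov = D @ V @ D.T
    return float(d @ np.linalg.solve(cov, d))


# ---------------------------------------------------------------------------
# sliding dichotomy


def sliding_dichotomy_outcome(risk: np.ndarray, gose: np.ndarray):
    """Risk-adjusted unfavorable indicator under the sliding dichotomy.

    Patients are split into three prognostic groups of roughly equal size by
    tertiles of predicted baseline risk (boundary ties go to the lower-risk
    group).  Favorable outcome is GOSE 7-8 in the low-risk group, 5-8 in the
    intermediate group, and 3-8 in the high-risk group.

    Returns ``(unfavorable_indicator, group)`` with group 0 = low risk.
    """
    risk = np.asarray(risk, dtype=float)
    gose = np.asarray(gose, dtype=int)
    q1, q2 = np.quantile(risk, [1 / 3, 2 / 3])
    group = np.where(risk <= q1, 0, np.where(risk <= q2, 1, 2))
    favorable_cut = np.choose(group, [7, 5, 3])  # minimum favorable GOSE
    unfav = (gose < favorable_cut).astype(int)
    return unfav, group


def sliding_dichotomy(X: pd.DataFrame, gose, mse_values, covariates=DEFAULT_COVARIATES,
                      bootstrap_ci: int = 0, seed: int = 0):
    """Association of an MSE metric with baseline-risk-adjusted outcome.

    A covariate-only logistic model (age, WFNS, mFisher, DCI) provides each
    patient's predicted risk of unfavorable outcome; the risk tertiles
    define per-group favorable cutoffs; the adjusted unfavorable indicator
    is then regressed on the MSE metric alone.  Returns ``(or, (lo, hi), p)``
    plus the group assignment, as a dict.
    """
    gose = np.asarray(gose, dtype=int)
    y = unfavorable(gose)
    base = logistic_fit(X, y, list(covariates))
    unfav_adj, group = sliding_dichotomy_outcome(base.fitted_probs, gose)
    mse = np.asarray(mse_values, dtype=float)
    if unfav_adj.min() == unfav_adj.max():
        raise ValueError("adjusted outcome is degenerate")
    dfm = pd.DataFrame({"mse": mse})
    fit = logistic_fit(dfm, unfav_adj, ["mse"])
    row = fit.odds_ratios.loc["mse"]
    lo, hi = float(row["lo"]), float(row["hi"])
    if bootstrap_ci:
        rng = np.random.default_rng(seed)
        coefs = []
        n = len(gose)
        for _ in range(bootstrap_ci):
            idx = rng.integers(0, n, size=n)
            if unfav_adj[idx].min() == unfav_adj[idx].max():
                continue
            try:
                fb = logistic_fit(dfm.iloc[idx].reset_index(drop=True),
                                  unfav_adj[idx], ["mse"])
            except Exception:
                continue
            coefs.append(fb.params["mse"])
        if len(coefs) >= 50:
            lo, hi = np.exp(np.percentile(coefs, [2.5, 97.5]))
    return {
        "or": float(row["OR"]),
        "ci": (lo, hi),
        "p": float(row["p"]),
        "group": group,
        "adjusted_unfavorable": unfav_adj,
        "baseline_fit": base,
        "mse_fit": fit,
    }
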