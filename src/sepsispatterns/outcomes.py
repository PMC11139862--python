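"""Relating latent pattern values to 28-day mortality and covariates.

Stages: the known-outcome subject filter, per-timepoint logistic AUROC and
the prognostic/dynamic pattern dichotomy, random-forest variable importance
under repeated stratified cross-validation, additive AUROC over a pattern
ordering, per-pattern odds ratios, Welch/Benjamini-Hochberg differential
expression, and Spearman correlation of patterns with clinical covariates.

AUROC is always computed with the rank (Mann-Whitney) formulation with
average ranks for ties, so it is invariant to any monotone transform of the
scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split
from statsmodels.stats.multitest import multipletests

from .containers import ACUTE_TIMEPOINTS, ExpressionMatrix


class OutcomeModelError(ValueError):
    pass


def filter_known_outcome(meta: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Restrict to sepsis samples with known 28-day mortality.

    Removes healthy donors and sepsis subjects with outcome ``unknown``.
    Returns the filtered metadata and the number of retained subjects.
    """
    keep = (meta["group"] == "sepsis") & meta["outcome"].isin(["survived", "died"])
    out = meta.loc[keep].copy()
    n_subjects = out["subject_id"].nunique()
    if n_subjects == 0:
        raise OutcomeModelError("no sepsis subjects with known 28-day outcome")
    return out, n_subjects


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    ``labels`` are 0/1 (1 = case/died); tied scores get average ranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise OutcomeModelError("AUROC needs both outcome classes")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def scale_patterns(P: pd.DataFrame) -> pd.DataFrame:
    """Scale and centre each pattern row to mean 0, SD 1 (ddof=1).

    Zero-variance rows become all zeros with a warning. Idempotent.
    """
    arr = P.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise OutcomeModelError("scaling needs at least 2 samples")
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant pattern row(s) scaled to zeros")
    sd[sd == 0] = 1.0
    return pd.DataFrame((arr - mu) / sd, index=P.index, columns=P.columns)


@dataclass
class LogisticAurocFit:
    auroc: float
    n_died: int
    n_survived: int
    converged: bool
    params: pd.Series | None
    reliable: bool


def _encode_sex(values) -> np.ndarray:
    return np.asarray([1.0 if v == "M" else 0.0 for v in values])


def _logistic_scores(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool, pd.Series | None]:
    """Unpenalised logit scores; sklearn ridge fallback when the MLE fails
    (perfect separation still yields usable ranking scores)."""
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", False))
            if converged and np.isfinite(fit.params).all():
                return np.asarray(fit.fittedvalues), True, pd.Series(fit.params)
        except Exception:
            pass
    lr = LogisticRegression(C=1e4, max_iter=2000)
    lr.fit(X, y)
    return lr.decision_function(X), False, None


def pattern_logistic_auroc(
    P: pd.DataFrame,
    meta: pd.DataFrame,
    pattern: int | str,
    timepoint: str,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> LogisticAurocFit:
    """AUROC of one pattern for 28-day mortality at one timepoint.

    Fits ``died ~ pattern + age + sex`` (in-sample logistic regression) on
    the known-outcome sepsis samples collected at ``timepoint`` and scores
    the AUROC of the model's linear predictor. ``pattern`` may be a 1-based
    index or a row name of ``P``.
    """
    sub, _ = filter_known_outcome(meta)
    sub = sub[sub["timepoint"] == timepoint]
    sub = sub[sub["sample_id"].isin(P.columns)]
    y = (sub["outcome"] == "died").to_numpy(dtype=int)
    n_died, n_surv = int(y.sum()), int((1 - y).sum())
    if n_died < 2 or n_surv < 2:
        raise OutcomeModelError(
            f"timepoint {timepoint!r} has {n_died} died / {n_surv} survived; "
            "need >= 2 per class")
    row = (P.index[pattern - 1] if isinstance(pattern, (int, np.integer))
           else pattern)
    x = P.loc[row, sub["sample_id"]].to_numpy(dtype=float)
    cols = [x]
    for c in covariates:
        cols.append(_encode_sex(sub[c]) if c == "sex"
                    else sub[c].to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.ptp(x) == 0:
        # constant pattern carries no information; covariate-only ranking
        # would misattribute covariate signal to the pattern
        return LogisticAurocFit(0.5, n_died, n_surv, True, None,
                                min(n_died, n_surv) >= 5)
    scores, converged, params = _logistic_scores(X, y)
    return LogisticAurocFit(
        auroc=auroc(scores, y), n_died=n_died, n_survived=n_surv,
        converged=converged, params=params,
        reliable=min(n_died, n_surv) >= 5)


def auroc_table(
    P: pd.DataFrame,
    meta: pd.DataFrame,
    timepoints: tuple[str, ...] = ACUTE_TIMEPOINTS,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> pd.DataFrame:
    """Patterns x timepoints AUROC matrix (the mortality heatmap).

    Cells with fewer than 5 subjects in either outcome class are flagged in
    the companion ``attrs['reliable']`` boolean frame; per-timepoint class
    counts sit in ``attrs['n_died']`` / ``attrs['n_survived']``.
    """
    vals = pd.DataFrame(index=P.index, columns=list(timepoints), dtype=float)
    rel = pd.DataFrame(False, index=P.index, columns=list(timepoints))
    n_died: dict[str, int] = {}
    n_surv: dict[str, int] = {}
    for tp in timepoints:
        for pat in P.index:
            fit = pattern_logistic_auroc(P, meta, pat, tp, covariates)
            vals.loc[pat, tp] = fit.auroc
            rel.loc[pat, tp] = fit.reliable
            n_died[tp], n_surv[tp] = fit.n_died, fit.n_survived
    vals.attrs["reliable"] = rel
    vals.attrs["n_died"] = n_died
    vals.attrs["n_survived"] = n_surv
    return vals


def classify_patterns(
    table: pd.DataFrame,
    threshold: float = 0.70,
    acute_timepoints: tuple[str, ...] = ACUTE_TIMEPOINTS,
) -> pd.Series:
    """Label each pattern prognostic / dynamic / uninformative.

    ``table`` is the patterns x timepoints AUROC matrix. A pattern is
    *prognostic* when its enrolment (0h) AUROC reaches ``threshold``,
    *dynamic* when it reaches the threshold only from 48 h onward, otherwise
    *uninformative*.
    """
    if "0h" not in table.columns:
        raise OutcomeModelError("AUROC table lacks the 0h enrolment column")
    late = [t for t in acute_timepoints
            if t in table.columns and t not in ("0h", "6h", "24h")]
    labels = {}
    for pat, row in table.iterrows():
        if row["0h"] >= threshold:
            labels[pat] = "prognostic"
        elif late and (row[late] >= threshold).any():
            labels[pat] = "dynamic"
        else:
            labels[pat] = "uninformative"
    return pd.Series(labels, name="class")


@dataclass
class ImportanceResult:
    """Random-forest variable importance averaged over resplits.

    ``table``: per pattern mean Gini importance, SD, and rank (1 = most
    important). ``per_resplit``: resplit x pattern mean importances.
    ``heldout_auroc``: per-resplit AUROC of a forest fit on the 70% training
    portion and scored on the 30% test portion.
    """

    table: pd.DataFrame
    per_resplit: pd.DataFrame
    heldout_auroc: np.ndarray
    n_resplits: int

    @property
    def ordered_patterns(self) -> list:
        return self.table.sort_values("rank").index.tolist()


def rf_importance_pipeline(
    P0: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    seed: int = 0,
    n_resplits: int = 10,
    n_folds: int = 10,
    n_repeats: int = 10,
    n_trees: int = 500,
    test_size: float = 0.30,
) -> ImportanceResult:
    """Repeated 70/30 resplits; on each training portion, repeated
    stratified k-fold CV of a random-forest mortality classifier; Gini
    importances averaged over all folds, repeats and resplits.

    ``P0`` is subjects x patterns (one row per subject, typically the
    enrolment sample); ``labels`` is the binary died indicator.
    """
    X = P0.to_numpy(dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise OutcomeModelError("labels contain a single class")
    if len(y) < 20:
        raise OutcomeModelError("need >= 20 subjects for the resampling scheme")
    per_resplit = np.zeros((n_resplits, X.shape[1]))
    heldout = np.zeros(n_resplits)
    for r in range(n_resplits):
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=test_size, stratify=y, random_state=seed + r)
        cv = RepeatedStratifiedKFold(
            n_splits=n_folds, n_repeats=n_repeats, random_state=seed + 1000 + r)
        imps = []
        for f, (tr, _) in enumerate(cv.split(X_tr, y_tr)):
            rf = RandomForestClassifier(
                n_estimators=n_trees, random_state=seed + 10_000 + r * 1000 + f,
                n_jobs=1)
            rf.fit(X_tr[tr], y_tr[tr])
            imps.append(rf.feature_importances_)
        per_resplit[r] = np.mean(imps, axis=0)
        rf_full = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed + 2000 + r, n_jobs=1)
        rf_full.fit(X_tr, y_tr)
        heldout[r] = auroc(rf_full.predict_proba(X_te)[:, 1], y_te)
    mean_imp = per_resplit.mean(axis=0)
    sd_imp = per_resplit.std(axis=0, ddof=1) if n_resplits > 1 else np.zeros_like(mean_imp)
    order = np.argsort(-mean_imp, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(order) + 1)
    table = pd.DataFrame(
        {"mean_importance": mean_imp, "sd": sd_imp, "rank": rank},
        index=P0.columns)
    return ImportanceResult(
        table=table,
        per_resplit=pd.DataFrame(per_resplit, columns=P0.columns),
        heldout_auroc=heldout,
        n_resplits=n_resplits,
    )


def additive_auroc(
    P0: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    ordered_patterns: list,
    seed: int = 0,
    n_resplits: int = 10,
    n_trees: int = 500,
    test_size: float = 0.30,
) -> pd.DataFrame:
    """Held-out AUROC as patterns are added one by one in importance order.

    For each prefix of ``ordered_patterns``, repeats the stratified 70/30
    resplit scheme and reports mean and SD of the test-set random-forest
    AUROC over resplits.
    """
    if not ordered_patterns:
        raise OutcomeModelError("ordered_patterns is empty")
    missing = [p for p in ordered_patterns if p not in P0.columns]
    if missing:
        raise OutcomeModelError(f"unknown patterns in ordering: {missing}")
    y = np.asarray(labels).astype(int)
    rows = []
    for m in range(1, len(ordered_patterns) + 1):
        cols = ordered_patterns[:m]
        X = P0[cols].to_numpy(dtype=float)
        aucs = np.zeros(n_resplits)
        for r in range(n_resplits):
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, test_size=test_size, stratify=y, random_state=seed + r)
            rf = RandomForestClassifier(
                n_estimators=n_trees, random_state=seed + 3000 + r, n_jobs=1)
            rf.fit(X_tr, y_tr)
            aucs[r] = auroc(rf.predict_proba(X_te)[:, 1], y_te)
        rows.append({
            "n_patterns": m, "last_added": cols[-1],
            "mean_auroc": aucs.mean(),
            "sd_auroc": aucs.std(ddof=1) if n_resplits > 1 else 0.0,
        })
    return pd.DataFrame(rows)


def pattern_odds_ratios(P_scaled: pd.DataFrame, labels) -> pd.DataFrame:
    """Univariate logistic odds ratio per 1 SD of pattern value.

    One logit fit per pattern column of the subjects x patterns matrix;
    OR = exp(beta) with Wald 95% CI exp(beta +/- 1.96 SE).
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise OutcomeModelError("labels contain a single class")
    rows = []
    for pat in P_scaled.columns:
        x = P_scaled[pat].to_numpy(dtype=float)
        X = sm.add_constant(x, has_constant="add")
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
                beta = fit.params[1]
                se = fit.bse[1]
                converged = bool(fit.mle_retvals.get("converged", False))
            except Exception:
                beta, se, converged = np.nan, np.nan, False
        rows.append({
            "pattern": pat,
            "odds_ratio": np.exp(beta),
            "ci_low": np.exp(beta - 1.96 * se),
            "ci_high": np.exp(beta + 1.96 * se),
            "converged": converged,
        })
    return pd.DataFrame(rows).set_index("pattern")


def welch_bh_diffexp(
    expr: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
) -> pd.DataFrame:
    """Per-gene Welch two-sample t-test (A vs B) with BH adjustment.

    Returns per gene: t statistic, two-sided p, BH-adjusted p, and a
    ``degenerate`` flag for zero-variance-in-both-groups genes (equal
    means: t=0, p=1; unequal means: p=0, flagged).
    """
    missing = [s for s in list(group_a) + list(group_b)
               if s not in expr.sample_ids]
    if missing:
        raise OutcomeModelError(f"samples not in expression matrix: {missing[:5]}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise OutcomeModelError("need >= 2 samples per group")
    Xa = expr.values[list(group_a)].to_numpy(dtype=float)
    Xb = expr.values[list(group_b)].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(Xa, Xb, axis=1, equal_var=False)
    va = Xa.var(axis=1, ddof=1)
    vb = Xb.var(axis=1, ddof=1)
    zero_var = (va == 0) & (vb == 0)
    equal_means = np.isclose(Xa.mean(axis=1), Xb.mean(axis=1))
    degenerate = zero_var & ~equal_means
    t = np.where(zero_var & equal_means, 0.0, t)
    p = np.where(zero_var & equal_means, 1.0, p)
    if degenerate.any():
        t = np.asarray(t, dtype=float).copy()
        p = np.asarray(p, dtype=float).copy()
        diff = (Xa.mean(axis=1) - Xb.mean(axis=1))[degenerate]
        t[degenerate] = np.sign(diff) * np.inf
        p[degenerate] = 0.0
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"t": t, "p": p, "p_adj": p_adj, "degenerate": degenerate},
        index=expr.gene_ids)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def correlate_patterns(
    P: pd.DataFrame,
    covariates: pd.DataFrame,
    min_complete: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlation of each pattern with each covariate column.

    ``P`` is patterns x samples; ``covariates`` is samples x covariates and
    may contain missing values (excluded pairwise). Pairs with fewer than
    ``min_complete`` complete observations, or a constant vector, yield NaN.
    Returns (rho, p) DataFrames, patterns x covariates.
    """
    shared = [s for s in P.columns if s in covariates.index]
    if len(shared) < min_complete:
        raise OutcomeModelError(
            f"only {len(shared)} samples shared between P and covariates")
    rho = pd.DataFrame(index=P.index, columns=covariates.columns, dtype=float)
    pval = pd.DataFrame(index=P.index, columns=covariates.columns, dtype=float)
    for pat in P.index:
        x_all = P.loc[pat, shared].to_numpy(dtype=float)
        for cov in covariates.columns:
            y_all = covariates.loc[shared, cov].to_numpy(dtype=float)
            ok = np.isfinite(x_all) & np.isfinite(y_all)
            if ok.sum() < min_complete:
                continue
            x, y = x_all[ok], y_all[ok]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue  # rho undefined for constant vectors
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r, p = stats.spearmanr(x, y)
            rho.loc[pat, cov] = r
            pval.loc[pat, cov] = p
    return rho, pval
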