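"""Exemplar-stratified genomic classification of lithium response.

Within each condition (ALL subjects, POOR exemplars, BEST exemplars) an
L2-penalized logistic regression (C = 1, fixed a priori so coefficient scales
are comparable) classifies responders from additively coded SNP dosages under
stratified k-fold cross-validation (k = 10 by default) or repeated stratified
shuffle-splits.  Per fold, variant missingness is mean-imputed and variants
are standardized using training-fold statistics only; per-fold coefficient
vectors are retained for the downstream enrichment analysis.

The primary metric is the Matthews correlation coefficient; accuracy,
ROC-AUC, Cohen's kappa, sensitivity, specificity, PPV and NPV are reported
alongside.  Conditions are compared on fold-wise MCC with a Kruskal–Wallis
omnibus test followed, when significant at α = 0.05, by pairwise two-sided
Mann–Whitney U tests at the Bonferroni threshold 0.05/3.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .data_model import GenotypeDataset
from .errors import ConvergenceError, ValidationError

logger = logging.getLogger(__name__)

METRICS = ("mcc", "accuracy", "auc", "kappa",
           "sensitivity", "specificity", "ppv", "npv")


@dataclass
class FoldResults:
    condition: str
    fold: int
    tp: int
    fp: int
    tn: int
    fn: int
    metrics: dict[str, float]
    coefficients: np.ndarray  # standardized scale, one entry per variant
    variant_ids: list[str]
    train_ids: tuple
    test_ids: tuple


@dataclass
class ConditionComparison:
    omnibus_h: float
    omnibus_p: float
    pairwise: dict[tuple[str, str], tuple[float, float]]  # (U, p)
    corrected_alpha: float
    summaries: pd.DataFrame  # per condition × metric: median and IQR


def fit_l2_logistic(
    X: np.ndarray, y: np.ndarray, C: float = 1.0,
    max_iter: int = 2000, tol: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """L2-penalized logistic fit; returns (coefficients, intercept).

    The converged optimum is unique (strictly convex loss), so the result is
    deterministic given the data.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("logistic fit needs both classes present")
    if np.isnan(X).any():
        raise ValidationError("genotype matrix has missing entries; impute first")
    # sklearn's default penalty is already the L2 ridge this protocol fixes
    model = LogisticRegression(C=C, solver="lbfgs", max_iter=max_iter, tol=tol)
    model.fit(X, y)
    if model.n_iter_[0] >= max_iter:
        grad_norm = _logistic_grad_norm(X, y, model, C)
        raise ConvergenceError(
            f"logistic regression did not converge in {max_iter} iterations "
            f"(gradient norm {grad_norm:.2e})"
        )
    return model.coef_[0], float(model.intercept_[0])


def _logistic_grad_norm(X, y, model, C) -> float:
    z = X @ model.coef_[0] + model.intercept_[0]
    resid = 1 / (1 + np.exp(-z)) - (np.asarray(y) == model.classes_[1])
    grad = X.T @ resid + model.coef_[0] / C
    return float(np.linalg.norm(grad))


def compute_metrics(y_true, y_prob, threshold: float = 0.5) -> dict[str, float]:
    """Confusion-matrix metric suite at the given probability threshold.

    MCC uses the convention 0 when any marginal factor vanishes; PPV/NPV are
    NaN (flagged undefined) when their denominator is empty; AUC is the
    probability a random positive outranks a random negative with ties
    counted 1/2, NaN when y_true is single-class.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    if ((y_prob < 0) | (y_prob > 1)).any():
        raise ValidationError("probabilities must lie in [0, 1]")
    y_pred = (y_prob >= threshold).astype(int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    n = tp + fp + tn + fn

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0

    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if (tp + fn) else np.nan
    specificity = tn / (tn + fp) if (tn + fp) else np.nan
    ppv = tp / (tp + fp) if (tp + fp) else np.nan
    npv = tn / (tn + fn) if (tn + fn) else np.nan

    po = accuracy
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    kappa = (po - pe) / (1 - pe) if pe < 1 else 0.0

    n_pos = int((y_true == 1).sum())
    n_neg = n - n_pos
    if n_pos and n_neg:
        ranks = stats.rankdata(y_prob)
        auc = (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    else:
        auc = np.nan

    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "mcc": float(mcc), "accuracy": float(accuracy), "auc": float(auc),
        "kappa": float(kappa), "sensitivity": float(sensitivity),
        "specificity": float(specificity), "ppv": float(ppv), "npv": float(npv),
    }


def _eval_split(
    dosages: np.ndarray, y: np.ndarray, ids: np.ndarray,
    train: np.ndarray, test: np.ndarray,
    condition: str, fold: int, C: float,
) -> FoldResults:
    """Impute/standardize with training statistics only, fit, score the test fold."""
    assert len(np.intersect1d(train, test)) == 0
    X_train = dosages[train].copy()
    X_test = dosages[test].copy()
    means = np.nanmean(X_train, axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    for X in (X_train, X_test):
        nan_pos = np.isnan(X)
        X[nan_pos] = np.take(means, np.nonzero(nan_pos)[1])
    sd = X_train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    X_train = (X_train - means) / sd
    X_test = (X_test - means) / sd

    coef, intercept = fit_l2_logistic(X_train, y[train], C=C)
    prob = 1.0 / (1.0 + np.exp(-(X_test @ coef + intercept)))
    m = compute_metrics(y[test], prob)
    return FoldResults(
        condition=condition, fold=fold,
        tp=m["tp"], fp=m["fp"], tn=m["tn"], fn=m["fn"],
        metrics={k: m[k] for k in METRICS},
        coefficients=coef, variant_ids=[],
        train_ids=tuple(ids[train]), test_ids=tuple(ids[test]),
    )


def _prepare(geno: GenotypeDataset, labels: pd.Series):
    ids = labels.index
    dosages = geno.dosages.loc[ids].to_numpy(dtype=float)
    y = labels.to_numpy(dtype=int)
    return dosages, y, np.asarray(ids), list(geno.dosages.columns)


def stratified_kfold_eval(
    geno: GenotypeDataset,
    labels: pd.Series,
    condition: str,
    k: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> list[FoldResults]:
    """Class-stratified k-fold evaluation; k is reduced (with a warning) when a
    class has fewer than k members, erroring below k = 2."""
    dosages, y, ids, variant_ids = _prepare(geno, labels)
    min_class = int(np.bincount(y).min()) if len(np.unique(y)) == 2 else 0
    if min_class < 2:
        raise ValidationError("each class needs >= 2 members for stratified CV")
    k_eff = min(k, min_class)
    if k_eff < k:
        logger.warning("condition %s: reducing k from %d to %d", condition, k, k_eff)
    splitter = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=int(seed) % 2**31)
    results = []
    for fold, (train, test) in enumerate(splitter.split(dosages, y)):
        res = _eval_split(dosages, y, ids, train, test, condition, fold, C)
        res.variant_ids = variant_ids
        results.append(res)
    return results


def shuffle_split_eval(
    geno: GenotypeDataset,
    labels: pd.Series,
    condition: str,
    n_splits: int = 10,
    test_size: float = 0.1,
    seed: int = 0,
    C: float = 1.0,
) -> list[FoldResults]:
    """Repeated stratified shuffle-split protocol (test-set-size sensitivity)."""
    if not 0 < test_size < 1:
        raise ValidationError("test_size must lie in (0, 1)")
    if n_splits < 1:
        raise ValidationError("n_splits must be >= 1")
    dosages, y, ids, variant_ids = _prepare(geno, labels)
    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, test_size=test_size, random_state=int(seed) % 2**31
    )
    results = []
    for fold, (train, test) in enumerate(splitter.split(dosages, y)):
        res = _eval_split(dosages, y, ids, train, test, condition, fold, C)
        res.variant_ids = variant_ids
        results.append(res)
    return results


def fold_metric(results: list[FoldResults], metric: str = "mcc") -> np.ndarray:
    return np.array([r.metrics[metric] for r in results], dtype=float)


def condition_summary(results_by_condition: dict[str, list[FoldResults]]) -> pd.DataFrame:
    """Median and IQR of every metric per condition (the reporting format)."""
    rows = []
    for condition, results in results_by_condition.items():
        for metric in METRICS:
            values = fold_metric(results, metric)
            values = values[~np.isnan(values)]
            if len(values) == 0:
                median = q1 = q3 = np.nan
            else:
                median = float(np.median(values))
                q1, q3 = (float(q) for q in np.percentile(values, [25, 75]))
            rows.append({"condition": condition, "metric": metric,
                         "median": median, "iqr_low": q1, "iqr_high": q3})
    return pd.DataFrame(rows)


def compare_conditions(
    results_by_condition: dict[str, list[FoldResults]],
    metric: str = "mcc",
    alpha: float = 0.05,
) -> ConditionComparison:
    """Kruskal–Wallis omnibus on fold-wise MCC, gated pairwise Mann–Whitney tests.

    Pairwise tests run only when the omnibus p-value is below ``alpha``; their
    threshold is α divided by the number of pairs (0.05/3 for three
    conditions).  With two conditions the omnibus is the two-group
    Kruskal–Wallis, which is the rank test itself.
    """
    names = list(results_by_condition)
    if len(names) < 2:
        raise ValidationError("compare_conditions needs >= 2 conditions")
    samples = [fold_metric(results_by_condition[n], metric) for n in names]
    for n, s in zip(names, samples):
        if len(s) < 2:
            raise ValidationError(f"condition {n} has fewer than 2 folds")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0  # all fold metrics identical: no evidence of difference
    else:
        h, p = stats.kruskal(*samples)
    pairwise: dict[tuple[str, str], tuple[float, float]] = {}
    n_pairs = len(names) * (len(names) - 1) // 2
    corrected = alpha / n_pairs
    if p < alpha:
        for (na, sa), (nb, sb) in combinations(zip(names, samples), 2):
            u, pu = stats.mannwhitneyu(sa, sb, alternative="two-sided")
            pairwise[(na, nb)] = (float(u), float(pu))
    return ConditionComparison(
        omnibus_h=float(h), omnibus_p=float(p),
        pairwise=pairwise, corrected_alpha=corrected,
        summaries=condition_summary(results_by_condition),
    )


def coefficient_matrix(results: list[FoldResults]) -> pd.DataFrame:
    """Folds × variants coefficient matrix from one condition's results."""
    if not results:
        raise ValidationError("no fold results")
    return pd.DataFrame(
        np.vstack([r.coefficients for r in results]),
        index=[r.fold for r in results],
        columns=results[0].variant_ids,
    )
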