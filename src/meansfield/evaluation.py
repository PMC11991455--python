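"""Within-session cross-validated scoring and meta-analytic statistics.

Pipelines are compared by AUC-ROC under stratified 5-fold cross-validation
with folds fixed across pipelines (same labels, k, seed ⇒ same folds, so
every pipeline sees identical splits).  Per-database paired comparisons use
an exact one-sided sign-permutation test for fewer than 20 subjects and the
one-sided Wilcoxon signed-rank test (normal approximation, tie-corrected
variance, continuity correction) otherwise.  Database-level p-values are
combined with the weighted Liptak (Stouffer) function using sqrt(number of
subjects) weights, and effect sizes as standardized mean differences (SMD)
aggregated by the same weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "stratified_kfold",
    "auc_roc",
    "cross_val_auc",
    "benchmark",
    "paired_permutation_test",
    "wilcoxon_signed_rank",
    "compare_pipelines_p",
    "liptak_combine",
    "smd_meta",
    "MetaAnalysisResult",
]

#: subject-count cutoff between the exact permutation test and Wilcoxon
PERMUTATION_MAX_N = 20


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (one fold index per trial).

    A pure function of (labels, k, seed): every pipeline evaluated with the
    same arguments sees identical folds.  Class proportions per fold are
    within one trial of the global proportions.
    """
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"every class needs at least k={k} members (smallest has {counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return assignment


def auc_roc(scores, labels) -> float:
    """AUC-ROC: P(score_pos > score_neg) + 0.5 P(score_pos = score_neg).

    Binary labels are taken in sorted order (larger label = positive).  For
    more than two classes, the one-versus-rest macro average of negated
    per-class distances is expected upstream; here we require binary input.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("AUC requires both classes present")
    if len(classes) == 2:
        return float(roc_auc_score((labels == classes[1]).astype(int), scores))
    # one-vs-rest macro average over per-class score columns
    scores = np.atleast_2d(scores)
    return float(
        np.mean(
            [
                roc_auc_score((labels == cls).astype(int), scores[:, i])
                for i, cls in enumerate(classes)
            ]
        )
    )


def cross_val_auc(estimator, X, y, k: int = 5, seed: int = 0) -> np.ndarray:
    """Per-fold test AUC of a cloned estimator under stratified k-fold CV."""
    X = np.asarray(X)
    y = np.asarray(y)
    folds = stratified_kfold(y, k=k, seed=seed)
    aucs = np.empty(k)
    for f in range(k):
        train, test = folds != f, folds == f
        est = clone(estimator).fit(X[train], y[train])
        scores = est.decision_function(X[test])
        aucs[f] = auc_roc(scores, y[test])
    return aucs


def family_cv_auc(
    X,
    y,
    k: int = 5,
    seed: int = 0,
    h_values=None,
    robust: bool = False,
) -> pd.DataFrame:
    """Per-fold AUC of MDM, MDMF, and MF with one shared means field per fold.

    All three classifiers are deterministic functions of the training split:
    MDM uses the field's geometric (h = 0) means, MDMF the minimum distance
    over the whole field, MF the discriminant over all squared distances, so
    one field per fold scores the entire family.  Returns a DataFrame with
    columns fold, mdm, mdmf, mf.
    """
    from .classifiers import MDM, MDMF, MF
    from .means import MeansField

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = stratified_kfold(y, k=k, seed=seed)
    rows = []
    for f in range(k):
        train, test = folds != f, folds == f
        mf = MF(h_values=h_values, robust=robust).fit(X[train], y[train])
        fld = mf.field_
        mdmf = MDMF(h_values=h_values)
        mdmf.field_, mdmf.classes_ = fld, mf.classes_
        mdm = MDM()
        mdm.field_ = MeansField(
            {(c, 0.0): fld.means[(c, 0.0)] for c in fld.classes},
            fld.classes,
            (0.0,),
        )
        mdm.classes_ = mf.classes_
        rows.append(
            {
                "fold": f,
                "mdm": auc_roc(mdm.decision_function(X[test]), y[test]),
                "mdmf": auc_roc(mdmf.decision_function(X[test]), y[test]),
                "mf": auc_roc(mf.decision_function(X[test]), y[test]),
            }
        )
    return pd.DataFrame(rows)


def benchmark(
    pipelines: dict,
    datasets: dict,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every pipeline on every dataset with shared folds.

    ``pipelines`` maps pipeline id -> unfitted estimator; ``datasets`` maps
    (database id, subject id, session id) -> (X, y) with X an SPD covariance
    stack.  Returns the long-format ScoreTable with one row per
    (database, subject, session, pipeline, fold).
    """
    rows = []
    for (db, subject, session), (X, y) in datasets.items():
        for name, est in pipelines.items():
            aucs = cross_val_auc(est, X, y, k=k, seed=seed)
            for fold, auc in enumerate(aucs):
                rows.append(
                    {
                        "database": db,
                        "subject": subject,
                        "session": session,
                        "pipeline": name,
                        "fold": fold,
                        "auc": auc,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# paired tests


def paired_permutation_test(diffs) -> float:
    """Exact one-sided paired sign-permutation test on ``n < 20`` differences.

    Enumerates all 2^n sign assignments of the paired differences; the
    p-value is the fraction of assignments whose mean is at least the
    observed mean (the identity assignment counts, so p >= 1/2^n).
    """
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    if n < 1:
        raise ValueError("need at least one difference")
    if n >= PERMUTATION_MAX_N:
        raise ValueError(
            f"n={n} >= {PERMUTATION_MAX_N}: use wilcoxon_signed_rank instead"
        )
    observed = diffs.mean()
    # all 2^n sign patterns via the binary expansion of 0..2^n-1
    codes = np.arange(2**n, dtype=np.uint32)
    signs = 1.0 - 2.0 * ((codes[:, None] >> np.arange(n)) & 1)
    means = signs @ diffs / n
    return float(np.mean(means >= observed - 1e-12 * max(1.0, abs(observed))))


def wilcoxon_signed_rank(diffs) -> float:
    """One-sided (positive location) Wilcoxon signed-rank p-value.

    Zeros are dropped, ties mid-ranked; the normal approximation uses the
    tie-corrected variance ``n(n+1)(2n+1)/24 - sum(t^3 - t)/48`` and a 0.5
    continuity correction.  All-zero input returns the degenerate p = 1.
    """
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(diffs))
    w_plus = ranks[diffs > 0].sum()
    mean = n * (n + 1) / 4.0
    _, t = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(t**3 - t) / 48.0
    if var <= 0:
        return 1.0 if w_plus <= mean else 0.0
    z = (w_plus - mean - 0.5) / np.sqrt(var)
    return float(stats.norm.sf(z))


def compare_pipelines_p(diffs) -> float:
    """Dispatch: exact permutation test below 20 subjects, Wilcoxon at or
    above (the within-database comparison rule)."""
    diffs = np.asarray(diffs, dtype=float)
    if len(diffs) < PERMUTATION_MAX_N:
        return paired_permutation_test(diffs)
    return wilcoxon_signed_rank(diffs)


def liptak_combine(pvals, weights) -> float:
    """Weighted Liptak (Stouffer) combination of one-sided p-values:
    ``z_i = Phi^{-1}(1 - p_i)``, combined ``z = sum w_i z_i / sqrt(sum w_i^2)``,
    returned as ``1 - Phi(z)``.  P-values are clipped to [1e-15, 1 - 1e-15]."""
    pvals = np.asarray(pvals, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if pvals.size == 0:
        raise ValueError("no p-values to combine")
    if pvals.shape != weights.shape:
        raise ValueError("pvals and weights must have equal length")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    p = np.clip(pvals, 1e-15, 1 - 1e-15)
    z = stats.norm.isf(p)
    combined = np.sum(weights * z) / np.sqrt(np.sum(weights**2))
    return float(stats.norm.sf(combined))


@dataclass
class MetaAnalysisResult:
    """Per-database effects and p-values plus their weighted combination.

    ``per_database`` has one row per database: smd, ci_low, ci_high, p,
    weight, n_subjects, degenerate (True when all paired differences were
    identical so the SMD is reported as 0 with an unbounded CI)."""

    per_database: pd.DataFrame
    combined_smd: float
    combined_p: float


def smd_meta(scores_a: dict, scores_b: dict) -> MetaAnalysisResult:
    """Paired meta-analysis of two pipelines across databases.

    ``scores_a``/``scores_b`` map database id -> per-subject score arrays
    (paired; e.g. subject-averaged AUCs).  Per database: SMD = mean(d)/sd(d)
    (sd with divisor n-1) with 95% CI ``SMD ± 1.96 sqrt(1/n + SMD²/(2n))``,
    and the dispatch p-value of :func:`compare_pipelines_p` on a - b.
    Databases are combined by weighted arithmetic mean of SMDs and weighted
    Liptak combination of p-values, both with weights sqrt(n_subjects).
    Databases with fewer than 2 subjects are excluded.
    """
    import warnings

    rows = []
    for db in scores_a:
        a = np.asarray(scores_a[db], dtype=float)
        b = np.asarray(scores_b[db], dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"database {db!r}: unpaired score arrays")
        n = len(a)
        if n < 2:
            warnings.warn(f"database {db!r} excluded: fewer than 2 subjects")
            continue
        d = a - b
        sd = d.std(ddof=1)
        degenerate = sd < 1e-15
        smd = 0.0 if degenerate else float(d.mean() / sd)
        if degenerate:
            ci = (-np.inf, np.inf)
        else:
            half = 1.96 * np.sqrt(1.0 / n + smd**2 / (2.0 * n))
            ci = (smd - half, smd + half)
        rows.append(
            {
                "database": db,
                "n_subjects": n,
                "smd": smd,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "p": compare_pipelines_p(d),
                "weight": np.sqrt(n),
                "degenerate": degenerate,
            }
        )
    if not rows:
        raise ValueError("no database with at least 2 subjects")
    table = pd.DataFrame(rows)
    w = table["weight"].to_numpy()
    combined_smd = float(np.sum(w * table["smd"].to_numpy()) / np.sum(w))
    combined_p = liptak_combine(table["p"].to_numpy(), w)
    return MetaAnalysisResult(table, combined_smd, combined_p)


def subject_scores(score_table: pd.DataFrame, pipeline: str) -> dict:
    """Per-database arrays of subject-level scores for one pipeline: fold
    AUCs are averaged within session, then sessions within subject."""
    sub = score_table[score_table["pipeline"] == pipeline]
    per_session = sub.groupby(["database", "subject", "session"])["auc"].mean()
    per_subject = per_session.groupby(["database", "subject"]).mean()
    return {
        db: grp.to_numpy()
        for db, grp in per_subject.groupby("database")
    }
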