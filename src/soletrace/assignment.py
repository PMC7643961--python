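"""Tracer-agnostic supervised assignment framework.

Individuals from known source subunits are assigned probabilistically by a
pooled-covariance linear discriminant analysis (LDA) inside a stratified
K-fold cross-validation (default K = 3): each fold in turn is the test set,
the remaining folds the baseline. All preprocessing — PCA dimension reduction
for genotype features, confound residualization for otolith features, and
centering — is fitted on the baseline rows only and applied to the test rows,
so no information leaks from test to training data.

The per-test outputs (membership probability rows, one prediction per
individual per cross-validation pass) are aggregated into a sampling-subunit
by predicted-subunit assignment matrix with mean and standard deviation taken
across all tests (folds x repetitions). With priors proportional to training
counts the framework reproduces the large-sample-class attraction seen with
unbalanced designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .shapestats import residualize

__all__ = [
    "FoldPlan",
    "AssignmentResult",
    "LdaModel",
    "make_folds",
    "pca_preprocess",
    "lda_train",
    "lda_posterior",
    "run_assignment",
    "assignment_matrix",
]


@dataclass
class FoldPlan:
    """Stratified fold ids (0..K-1) per individual."""

    fold_ids: np.ndarray
    K: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.fold_ids = np.asarray(self.fold_ids, dtype=int)


def make_folds(labels, K: int = 3, seed: int | None = None) -> FoldPlan:
    """Random partition into K folds, stratified within each subunit.

    Within every subunit the fold sizes differ by at most one, so each fold
    contains every subunit whenever that subunit has at least K members.
    """
    labels = np.asarray(labels)
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = np.random.default_rng(seed)
    fold_ids = np.full(len(labels), -1, dtype=int)
    for sub in np.unique(labels):
        idx = np.where(labels == sub)[0]
        if len(idx) < K:
            raise ValueError(f"subunit {sub} has {len(idx)} individuals, fewer than K={K}")
        idx = rng.permutation(idx)
        fold_ids[idx] = np.arange(len(idx)) % K
    return FoldPlan(fold_ids=fold_ids, K=K, seed=seed)


def pca_preprocess(
    train_X: np.ndarray,
    test_X: np.ndarray | None = None,
    var_threshold: float = 0.95,
    max_components: int | None = None,
):
    """PCA fitted on training rows only; retains the smallest component count
    reaching ``var_threshold`` cumulative variance (capped)."""
    train_X = np.asarray(train_X, dtype=float)
    if len(train_X) == 0:
        raise ValueError("empty training set")
    full = PCA(svd_solver="full")
    full.fit(train_X)
    cum = np.cumsum(full.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    if max_components is not None:
        n_comp = min(n_comp, max_components)
    n_comp = max(1, min(n_comp, len(full.explained_variance_)))
    pca = PCA(n_components=n_comp, svd_solver="full")
    train_scores = pca.fit_transform(train_X)
    test_scores = None if test_X is None else pca.transform(np.asarray(test_X, float))
    return train_scores, test_scores, pca


@dataclass
class LdaModel:
    """Pooled-covariance Gaussian LDA: class means, shared covariance, priors."""

    classes: list[str]
    means: np.ndarray  # (k, p)
    cov_inv: np.ndarray  # (p, p)
    log_det: float
    log_priors: np.ndarray


def lda_train(features: np.ndarray, labels, priors: str = "proportional") -> LdaModel:
    """Fit pooled-covariance LDA.

    Priors are proportional to training class counts by default (``priors=
    'uniform'`` for equal priors). The pooled within-class covariance uses
    n - k degrees of freedom. Raises if it is singular.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n, p = X.shape
    k = len(classes)
    if n - k < p:
        raise ValueError(
            f"n_train - n_classes ({n - k}) < n_features ({p}): reduce dimensions first"
        )
    means = np.stack([X[labels == c].mean(axis=0) for c in classes])
    pooled = np.zeros((p, p))
    for i, c in enumerate(classes):
        d = X[labels == c] - means[i]
        pooled += d.T @ d
    pooled /= n - k
    sign, log_det = np.linalg.slogdet(pooled)
    if sign <= 0 or not np.isfinite(log_det):
        raise ValueError("singular pooled covariance: use stronger dimension reduction")
    cov_inv = np.linalg.inv(pooled)
    if priors == "proportional":
        counts = np.array([np.sum(labels == c) for c in classes], dtype=float)
        pri = counts / counts.sum()
    elif priors == "uniform":
        pri = np.full(k, 1.0 / k)
    else:
        raise ValueError("priors must be 'proportional' or 'uniform'")
    return LdaModel(
        classes=[str(c) for c in classes],
        means=means,
        cov_inv=cov_inv,
        log_det=log_det,
        log_priors=np.log(pri),
    )


def lda_posterior(model: LdaModel, features: np.ndarray) -> np.ndarray:
    """Normalized Gaussian membership probabilities, one row per input."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.means.shape[1]:
        raise ValueError("feature dimension does not match the model")
    diffs = X[:, None, :] - model.means[None, :, :]  # (n, k, p)
    maha = np.einsum("nkp,pq,nkq->nk", diffs, model.cov_inv, diffs)
    log_post = model.log_priors[None, :] - 0.5 * maha
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    return post


@dataclass
class AssignmentResult:
    """Per-individual posteriors and the mean +/- sd assignment matrix."""

    posteriors: pd.DataFrame  # id, subunit, repeat, fold, P(<class>)..., predicted
    classes: list[str]
    matrix_mean: pd.DataFrame
    matrix_sd: pd.DataFrame
    fold_accuracy: pd.DataFrame  # repeat, fold, accuracy
    n_ties: int = 0

    @property
    def mean_self_assignment(self) -> float:
        m = self.matrix_mean
        return float(np.mean([m.loc[c, c] for c in self.classes]))


def run_assignment(
    features: np.ndarray,
    labels,
    K: int = 3,
    seed: int | None = None,
    preprocess: str = "none",
    n_repeats: int = 1,
    ids: list[str] | None = None,
    design: pd.DataFrame | None = None,
    var_threshold: float = 0.95,
    priors: str = "proportional",
    confound_terms: tuple[str, ...] = ("Length", "Sex", "Side"),
) -> AssignmentResult:
    """Stratified K-fold LDA assignment with fold-internal preprocessing.

    ``preprocess`` is ``'none'``, ``'pca'`` (genotype-style dimension
    reduction to ``var_threshold`` cumulative variance) or ``'residualize'``
    (otolith-style confound removal; requires ``design``). Each individual is
    predicted exactly once per cross-validation pass; ``n_repeats`` passes
    with different fold draws populate the sd of the assignment matrix.
    Posterior argmax ties are broken by class order and counted.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(str)
    if len(X) != len(labels):
        raise ValueError("features and labels must align")
    if ids is None:
        ids = [f"ind{i:04d}" for i in range(len(labels))]
    if preprocess == "residualize" and design is None:
        raise ValueError("residualize preprocessing requires a design table")
    # class order = order of first appearance (SW, NE, UK for the study
    # design); argmax ties break toward the earlier class and are counted
    classes = list(dict.fromkeys(labels.tolist()))
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(n_repeats)
    records = []
    acc_rows = []
    n_ties = 0
    for rep, rep_seed in enumerate(rep_seeds):
        plan = make_folds(labels, K=K, seed=int(rep_seed) % (2**31))
        for fold in range(K):
            test = plan.fold_ids == fold
            train = ~test
            if preprocess == "pca":
                cap = int(train.sum()) - len(classes)
                tr, te, _ = pca_preprocess(
                    X[train], X[test], var_threshold=var_threshold, max_components=cap
                )
            elif preprocess == "residualize":
                resid = residualize(X, design, terms=confound_terms, fit_rows=train)
                tr, te = resid[train], resid[test]
            elif preprocess == "none":
                mu = X[train].mean(axis=0)
                tr, te = X[train] - mu, X[test] - mu
            else:
                raise ValueError(f"unknown preprocess mode {preprocess!r}")
            model = lda_train(tr, labels[train], priors=priors)
            post = lda_posterior(model, te)
            # reorder posterior columns to the fixed class order
            order = [model.classes.index(c) for c in classes]
            post = post[:, order]
            top = post.max(axis=1, keepdims=True)
            ties = (np.isclose(post, top).sum(axis=1) > 1).sum()
            n_ties += int(ties)
            pred_idx = post.argmax(axis=1)
            preds = np.array(classes)[pred_idx]
            test_idx = np.where(test)[0]
            for row, i in enumerate(test_idx):
                rec = {
                    "id": ids[i],
                    "subunit": labels[i],
                    "repeat": rep,
                    "fold": fold,
                    "predicted": preds[row],
                }
                for ci, c in enumerate(classes):
                    rec[f"P({c})"] = post[row, ci]
                records.append(rec)
            acc_rows.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    "accuracy": float(np.mean(preds == labels[test])),
                }
            )
    post_df = pd.DataFrame(records)
    mat_mean, mat_sd = _matrices_from_posteriors(post_df, classes)
    return AssignmentResult(
        posteriors=post_df,
        classes=classes,
        matrix_mean=mat_mean,
        matrix_sd=mat_sd,
        fold_accuracy=pd.DataFrame(acc_rows),
        n_ties=n_ties,
    )


def _matrices_from_posteriors(
    post_df: pd.DataFrame, classes: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-test assignment fractions, averaged over tests (repeat x fold)."""
    cells: dict[tuple[str, str], list[float]] = {
        (s, p): [] for s in classes for p in classes
    }
    for (_, _), grp in post_df.groupby(["repeat", "fold"]):
        for s in classes:
            sub = grp[grp["subunit"] == s]
            if len(sub) == 0:
                continue
            for p in classes:
                cells[(s, p)].append(float(np.mean(sub["predicted"] == p)))
    mean = pd.DataFrame(0.0, index=classes, columns=classes)
    sd = pd.DataFrame(0.0, index=classes, columns=classes)
    for (s, p), vals in cells.items():
        if vals:
            mean.loc[s, p] = float(np.mean(vals))
            sd.loc[s, p] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return mean, sd


def assignment_matrix(
    results: list[AssignmentResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool tests from several AssignmentResults into one mean +/- sd matrix."""
    if not results:
        raise ValueError("need at least one AssignmentResult")
    classes = results[0].classes
    for r in results[1:]:
        if r.classes != classes:
            raise ValueError("inconsistent class sets across results")
    pooled = []
    for ri, r in enumerate(results):
        df = r.posteriors.copy()
        df["repeat"] = df["repeat"].astype(str) + f"_r{ri}"
        pooled.append(df)
    return _matrices_from_posteriors(pd.concat(pooled, ignore_index=True), classes)
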