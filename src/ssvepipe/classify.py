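"""Penalized logistic classification with paired-eye cross-validation.

The two eyes of a subject are correlated, so letting them land in different
cross-validation folds leaks subject identity from training into test data
and inflates performance estimates.  The grouped ("paired eyes") scheme keeps
every row of a subject in one fold; the ungrouped ("ignore pairing") scheme
assigns rows to folds at random and exists to quantify that inflation.

The model is elastic-net-regularized logistic regression in the glmnet
parameterization: minimize (1/n)·deviance + λ·(α‖β‖₁ + (1−α)/2·‖β‖₂²).
For each outer fold, predictors are standardized on the training rows only,
(α, λ) are chosen by inner cross-validated deviance on the training rows, and
the held-out rows are scored — every row receives exactly one out-of-fold
score.  Coefficients are reported from a full-data refit at the modal (α, λ).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .features import META_COLUMNS

__all__ = [
    "CVScheme",
    "ClassifierConfig",
    "ClassifierResult",
    "Metrics",
    "make_folds",
    "feature_subset",
    "predictor_columns",
    "fit_elastic_net_cv",
    "roc_auc",
    "performance",
]

logger = logging.getLogger(__name__)


@dataclass
class CVScheme:
    k: int
    assignment: np.ndarray  # fold index per row
    grouped: bool
    seed: int

    def __post_init__(self):
        counts = np.bincount(self.assignment, minlength=self.k)
        if (counts == 0).any():
            raise ValueError("every fold must be non-empty")


@dataclass
class ClassifierConfig:
    alpha_grid: tuple[float, ...] = (0.1, 0.5, 0.9, 1.0)
    lambda_path: tuple[float, ...] | None = None  # descending; data-driven if None
    n_lambda: int = 20
    lambda_min_ratio: float = 1e-3
    standardize: bool = True
    lambda_rule: str = "min"  # or "1se"
    inner_folds: int = 5
    max_iter: int = 2000
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if any(not (0.0 <= a <= 1.0) for a in self.alpha_grid):
            raise ValueError("elastic-net mixing α must lie in [0, 1]")
        if self.lambda_path is not None:
            lp = tuple(self.lambda_path)
            if any(l <= 0 for l in lp) or any(a < b for a, b in zip(lp, lp[1:])):
                raise ValueError("lambda_path must be positive and descending")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")


@dataclass
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float


@dataclass
class ClassifierResult:
    oof_scores: np.ndarray
    labels: np.ndarray
    fold_assignment: np.ndarray
    per_fold_params: list[tuple[float, float]]  # chosen (α, λ) per outer fold
    final_alpha: float
    final_lambda: float
    coefficients: pd.Series  # standardized coefficients (per-SD scale)
    intercept: float

    @property
    def retained(self) -> pd.Series:
        return self.coefficients != 0.0


# --------------------------------------------------------------------------
# folds and feature subsets
# --------------------------------------------------------------------------

def make_folds(
    table: pd.DataFrame, k: int = 10, grouped: bool = True, seed: int = 0, stratify: bool = True
) -> CVScheme:
    """Random k-fold assignment; grouped keeps all rows of a subject together.

    With ``stratify`` (default) the random assignment is label-balanced: units
    (subjects if grouped, rows otherwise) are shuffled within each class and
    dealt round-robin, so every fold sees a near-equal class prevalence.
    Without stratification, pooled out-of-fold scores carry fold-specific
    intercept offsets (training prevalence anti-correlates with the held-out
    fold's), which biases the pooled null AUC below 0.5.
    """
    n = len(table)
    if n < k:
        raise ValueError("more folds than rows")
    rng = np.random.default_rng(seed)

    def _deal(units: np.ndarray, labels: np.ndarray) -> dict:
        """Shuffle units (within class if stratified) and deal them to folds."""
        if stratify:
            order = []
            for lab in np.unique(labels):
                members = units[labels == lab]
                order.extend(members[rng.permutation(len(members))])
            order = np.asarray(order)
        else:
            order = units[rng.permutation(len(units))]
        return {u: i % k for i, u in enumerate(order)}

    if grouped:
        per_subject = table.groupby("subject_id", sort=False)["label"].first()
        uniq = per_subject.index.to_numpy()
        if len(uniq) < k:
            raise ValueError("more folds than subjects in a grouped scheme")
        fold_of = _deal(uniq, per_subject.to_numpy())
        assignment = np.array([fold_of[s] for s in table["subject_id"]])
    else:
        rows = np.arange(n)
        fold_of = _deal(rows, table["label"].to_numpy())
        assignment = np.array([fold_of[i] for i in rows])
    return CVScheme(k=k, assignment=assignment, grouped=grouped, seed=seed)


def predictor_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def feature_subset(
    table: pd.DataFrame,
    pathway: str = "both",
    domain: str = "both",
    include_demographics: bool = True,
) -> pd.DataFrame:
    """Restrict the SSVEP predictors to a pathway × feature-domain cell.

    amplitude → ρ columns only; phase → (cos, sin) columns only.  Metadata
    columns are always carried along.
    """
    pathway = pathway.upper() if pathway.lower() != "both" else "both"
    if pathway not in ("both", "ON", "OFF"):
        raise ValueError(f"unknown pathway {pathway!r}")
    if domain not in ("both", "amplitude", "phase"):
        raise ValueError(f"unknown domain {domain!r}")
    enc = {"amplitude": ("rho",), "phase": ("cos", "sin"), "both": ("rho", "cos", "sin")}[domain]
    keep = []
    for c in table.columns:
        parts = c.split("_")
        if len(parts) == 4 and parts[3] in ("rho", "cos", "sin"):
            if (pathway == "both" or parts[0] == pathway) and parts[3] in enc:
                keep.append(c)
    if not keep:
        raise ValueError("selection produced no SSVEP columns")
    demo = ["age", "sex_M", "sex_unknown"] if include_demographics else []
    meta = [c for c in META_COLUMNS if c in table.columns]
    return table[meta + demo + keep].copy()


# --------------------------------------------------------------------------
# AUC and threshold metrics
# --------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC with ties counted 1/2.

    Equals the probability that a random positive outranks a random negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def performance(scores, labels, threshold: float = 0.5) -> Metrics:
    """Threshold metrics (score ≥ threshold ⇒ predicted patient) plus AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    pos = labels == 1
    if pos.all() or (~pos).all():
        raise ValueError("metrics need both classes present")
    return Metrics(
        accuracy=float((pred == pos).mean()),
        sensitivity=float(pred[pos].mean()),
        specificity=float((~pred[~pos]).mean()),
        auc=roc_auc(scores, labels),
    )


# --------------------------------------------------------------------------
# elastic net
# --------------------------------------------------------------------------

def _lambda_path(X: np.ndarray, y: np.ndarray, config: ClassifierConfig) -> np.ndarray:
    if config.lambda_path is not None:
        return np.asarray(config.lambda_path, dtype=float)
    n = len(y)
    resid = y - y.mean()
    alpha_ref = max(min(config.alpha_grid), 1e-2)
    lam_max = np.max(np.abs(X.T @ resid)) / (n * alpha_ref)
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambda)


def _fit_path(X, y, alpha: float, lambdas: np.ndarray, config: ClassifierConfig):
    """Warm-started fits along a descending λ path; returns [(coef, intercept)]."""
    n = len(y)
    model = LogisticRegression(
        solver="saga",
        l1_ratio=alpha,
        warm_start=True,
        max_iter=config.max_iter,
        tol=config.tol,
        C=1.0,
        random_state=config.seed % (2**31),
    )
    out = []
    for lam in lambdas:
        model.C = 1.0 / (n * lam)
        model.fit(X, y)
        out.append((model.coef_[0].copy(), float(model.intercept_[0])))
    return out


def _deviance(coef, intercept, X, y) -> float:
    eta = X @ coef + intercept
    # stable -2·loglik per observation
    ll = y * eta - np.logaddexp(0.0, eta)
    return float(-2.0 * ll.mean())


def _inner_select(X, y, groups, config: ClassifierConfig, rng) -> tuple[float, float]:
    """Choose (α, λ) by inner-CV mean deviance on the training rows only."""
    lambdas = _lambda_path(X, y, config)
    k = min(config.inner_folds, len(np.unique(groups)) if groups is not None else len(y))
    if groups is not None:
        uniq = pd.unique(groups)
        perm = rng.permutation(len(uniq))
        fold_of = {uniq[perm[i]]: i % k for i in range(len(uniq))}
        fold = np.array([fold_of[g] for g in groups])
    else:
        perm = rng.permutation(len(y))
        fold = np.empty(len(y), dtype=int)
        fold[perm] = np.arange(len(y)) % k
    dev = np.zeros((len(config.alpha_grid), len(lambdas)))
    dev_sq = np.zeros_like(dev)
    for f in range(k):
        tr, te = fold != f, fold == f
        if y[tr].min() == y[tr].max() or te.sum() == 0:
            continue
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr, Xte = (X[tr] - mu) / sd, (X[te] - mu) / sd
        for ai, alpha in enumerate(config.alpha_grid):
            for li, (coef, b0) in enumerate(_fit_path(Xtr, y[tr], alpha, lambdas, config)):
                d = _deviance(coef, b0, Xte, y[te])
                dev[ai, li] += d
                dev_sq[ai, li] += d * d
    mean_dev = dev / k
    ai, li = np.unravel_index(np.argmin(mean_dev), mean_dev.shape)
    if config.lambda_rule == "1se":
        se = np.sqrt(np.maximum(dev_sq[ai] / k - mean_dev[ai] ** 2, 0.0)) / np.sqrt(k)
        limit = mean_dev[ai, li] + se[li]
        li = int(np.argmax(mean_dev[ai] <= limit))  # largest λ within 1 SE (path descends)
    return float(config.alpha_grid[ai]), float(lambdas[li])


def fit_elastic_net_cv(
    table: pd.DataFrame, scheme: CVScheme, config: ClassifierConfig | None = None
) -> ClassifierResult:
    """Nested cross-validated elastic-net logistic regression.

    Standardization and hyper-parameter selection see training rows only;
    each row is scored exactly once, by the fold that held it out.
    """
    config = config or ClassifierConfig()
    cols = predictor_columns(table)
    X_all = table[cols].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    groups = table["subject_id"].to_numpy() if scheme.grouped else None
    keep = X_all.std(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        logger.info("dropping %d zero-variance predictors: %s", len(dropped), dropped)
        cols = [c for c, k in zip(cols, keep) if k]
        X_all = X_all[:, keep]
    rng = np.random.default_rng(config.seed)
    oof = np.full(len(y), np.nan)
    per_fold = []
    for f in range(scheme.k):
        tr = scheme.assignment != f
        te = ~tr
        if te.sum() == 0:
            continue
        Xtr, ytr = X_all[tr], y[tr]
        mu, sd = (Xtr.mean(axis=0), Xtr.std(axis=0)) if config.standardize else (0.0, 1.0)
        sd = np.where(np.asarray(sd) == 0, 1.0, sd)
        Xtr_s = (Xtr - mu) / sd
        alpha, lam = _inner_select(Xtr, ytr, groups[tr] if groups is not None else None, config, rng)
        per_fold.append((alpha, lam))
        model = LogisticRegression(
            solver="saga", l1_ratio=alpha,
            C=1.0 / (len(ytr) * lam), max_iter=config.max_iter, tol=config.tol,
            random_state=config.seed % (2**31),
        )
        model.fit(Xtr_s, ytr)
        oof[te] = model.predict_proba((X_all[te] - mu) / sd)[:, 1]
    if np.isnan(oof).any():
        raise RuntimeError("some rows were never held out; check the CV scheme")
    # final full-data refit at the modal (α, λ) for coefficient reporting
    final_alpha, final_lambda = Counter(per_fold).most_common(1)[0][0]
    mu, sd = X_all.mean(axis=0), X_all.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X_all - mu) / sd if config.standardize else X_all
    model = LogisticRegression(
        solver="saga", l1_ratio=final_alpha,
        C=1.0 / (len(y) * final_lambda), max_iter=config.max_iter, tol=config.tol,
        random_state=config.seed % (2**31),
    )
    model.fit(Xs, y)
    coef = model.coef_[0]
    if not config.standardize:
        coef = coef * sd  # report per-SD (standardized) coefficients either way
    return ClassifierResult(
        oof_scores=oof,
        labels=y,
        fold_assignment=scheme.assignment,
        per_fold_params=per_fold,
        final_alpha=final_alpha,
        final_lambda=final_lambda,
        coefficients=pd.Series(coef, index=cols),
        intercept=float(model.intercept_[0]),
    )
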