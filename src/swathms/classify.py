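"""Principal-component logistic-regression diagnosis classifier.

A logistic regression on the first k Sqrt/Pareto PCA score components,
evaluated by leave-one-out cross-validation (LOOCV), with a label-permutation
test of the prediction-error count.

Two PCA policies are first-class: ``refit_per_fold`` (default) refits the PCA
on each training fold and projects the held-out sample with the training
centre/scale/loadings, avoiding information leakage; ``global`` fits the PCA
once on all samples and refits only the regression per fold (the cheaper
variant closer to fitting the PCA before cross-validating).  The regression
always carries a fixed small ridge penalty (``RIDGE_ALPHA``) so that per-fold
models remain comparable when a 19-sample training fold happens to be
linearly separable.

Because the PCA in either policy does not depend on the group labels, the
per-fold score decompositions are computed once and reused across label
permutations, making the permutation test cost one regression fit per fold
per permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .quantify import ProteinMatrix
from .stratify import sqrt_pareto_pca

__all__ = [
    "ClassifierResult",
    "PermutationResult",
    "pc_logistic_loocv",
    "permutation_test",
    "RIDGE_ALPHA",
]

#: fixed L2 penalty strength of the per-fold logistic regressions
#: (scikit-learn ``C`` = 1 / RIDGE_ALPHA)
RIDGE_ALPHA = 0.1

#: exhaustive label enumeration is used when the number of distinct
#: case/control arrangements does not exceed this bound
EXHAUSTIVE_LIMIT = 20_000

DECISION_THRESHOLD = 0.5


@dataclass
class ClassifierResult:
    """LOOCV output: held-out probabilities and the misclassification count."""

    k_components: int
    per_sample: pd.DataFrame  # sample_id, held_out_probability, predicted_label, true_label
    error_count: int
    pca_policy: str

    def __post_init__(self):
        probs = self.per_sample["held_out_probability"].to_numpy(float)
        if ((probs < 0) | (probs > 1)).any():
            raise ValueError("held-out probabilities must lie in [0, 1]")


@dataclass
class PermutationResult:
    """Label-permutation null of the LOOCV error.

    In sampled mode ``p_value`` is the +1-smoothed
    ``(1 + #{null <= observed}) / (n_permutations + 1)``; in exhaustive mode it
    is the exact fraction of all distinct label arrangements (which include
    the observed one) whose error is <= the observed error.
    """

    observed_error: int
    null_errors: np.ndarray
    n_permutations: int
    p_value: float
    seed: int | None
    method: str  # "sampled" | "exhaustive"


def _fit_ridge_logistic(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = RIDGE_ALPHA,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> np.ndarray:
    """Newton fit of L2-penalised logistic regression (intercept unpenalised).

    Minimises ``sum(log-loss) + (alpha/2)*||coef||^2``, the same objective as
    scikit-learn's ``LogisticRegression(C=1/alpha)``; a dedicated Newton
    solver because the permutation and panel-resampling tests refit this tiny
    model tens of thousands of times.  Returns ``[intercept, coef...]``.
    """
    n, k = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    w = np.zeros(k + 1)
    pen = np.concatenate([[0.0], np.full(k, alpha)])

    def objective(wv):
        z = np.clip(Xd @ wv, -35, 35)
        # log(1 + e^z) - y*z, numerically stable
        return float(
            np.sum(np.logaddexp(0.0, z) - y * z) + 0.5 * np.sum(pen * wv * wv)
        )

    obj = objective(w)
    for _ in range(max_iter):
        z = np.clip(Xd @ w, -35, 35)
        p = 1.0 / (1.0 + np.exp(-z))
        grad = Xd.T @ (p - y) + pen * w
        if np.max(np.abs(grad)) < tol:
            break
        W = np.clip(p * (1.0 - p), 1e-12, None)
        H = (Xd * W[:, None]).T @ Xd + np.diag(pen)
        step = np.linalg.solve(H, grad)
        # damped Newton: halve until the strictly convex objective decreases
        t = 1.0
        for _h in range(30):
            w_new = w - t * step
            obj_new = objective(w_new)
            if obj_new <= obj:
                break
            t *= 0.5
        if abs(obj - obj_new) < tol and np.max(np.abs(w - w_new)) < 1e-8:
            w = w_new
            break
        w, obj = w_new, obj_new
    return w


def _predict_proba(w: np.ndarray, X: np.ndarray) -> np.ndarray:
    z = np.clip(w[0] + X @ w[1:], -35, 35)
    return 1.0 / (1.0 + np.exp(-z))


def _fold_scores(
    matrix: ProteinMatrix, k_components: int, pca_policy: str
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-fold (training scores, held-out score) pairs, label-independent.

    Fold i holds out sample i (matrix column order).  Under ``global`` the
    decomposition is fitted once and rows are simply split; under
    ``refit_per_fold`` each fold refits the PCA on its 19 training samples and
    projects the held-out sample through the training transform.
    """
    n = matrix.data.shape[1]
    folds = []
    if pca_policy == "global":
        model = sqrt_pareto_pca(matrix)
        k = min(k_components, model.n_components)
        S = model.scores[:, :k]
        for i in range(n):
            train = np.delete(np.arange(n), i)
            folds.append((S[train], S[i : i + 1]))
    elif pca_policy == "refit_per_fold":
        cols = list(matrix.data.columns)
        for i in range(n):
            train_cols = cols[:i] + cols[i + 1 :]
            sub = ProteinMatrix(matrix.data[train_cols], "averaged")
            model = sqrt_pareto_pca(sub)
            k = min(k_components, model.n_components)  # small panels cap the rank
            held = ProteinMatrix(matrix.data[[cols[i]]], "averaged")
            folds.append((model.scores[:, :k], model.transform(held)[:, :k]))
    else:
        raise ConfigurationError(
            f"unknown pca_policy {pca_policy!r}; expected 'refit_per_fold' or 'global'"
        )
    return folds


def _loocv_errors(
    folds: list[tuple[np.ndarray, np.ndarray]], y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Held-out case probabilities and predictions for a given labelling."""
    probs = np.empty(len(folds))
    for i, (train_s, test_s) in enumerate(folds):
        y_train = np.delete(y, i)
        w = _fit_ridge_logistic(train_s, y_train.astype(float))
        probs[i] = _predict_proba(w, test_s)[0]
    pred = probs > DECISION_THRESHOLD
    return probs, pred


def _labels(matrix: ProteinMatrix, samples: pd.DataFrame) -> np.ndarray:
    grp = dict(zip(samples["sample_id"], samples["group"]))
    missing = [c for c in matrix.data.columns if c not in grp]
    if missing:
        raise ConfigurationError(f"samples without group metadata: {missing[:5]}")
    return np.array([1 if grp[c] == "case" else 0 for c in matrix.data.columns])


def pc_logistic_loocv(
    matrix: ProteinMatrix,
    samples: pd.DataFrame,
    k_components: int = 3,
    pca_policy: str = "refit_per_fold",
) -> ClassifierResult:
    """Leave-one-out cross-validated PC logistic regression.

    Each held-out sample receives the probability of being a case from a
    regression fitted on the remaining samples' first ``k_components`` PCA
    scores; the prediction threshold is fixed at 0.5.
    """
    if matrix.stage != "averaged":
        raise ValueError(f"expected a stage='averaged' matrix, got {matrix.stage!r}")
    y = _labels(matrix, samples)
    n = len(y)
    if (y == 1).sum() < 3 or (y == 0).sum() < 3:
        raise ValueError("need at least 3 samples per group for LOOCV classification")
    if not (1 <= k_components <= n - 2):
        raise ValueError(f"k_components must lie in [1, {n - 2}], got {k_components}")

    folds = _fold_scores(matrix, k_components, pca_policy)
    probs, pred = _loocv_errors(folds, y)
    per_sample = pd.DataFrame(
        {
            "sample_id": list(matrix.data.columns),
            "held_out_probability": probs,
            "predicted_label": np.where(pred, "case", "control"),
            "true_label": np.where(y == 1, "case", "control"),
        }
    )
    return ClassifierResult(
        k_components=k_components,
        per_sample=per_sample,
        error_count=int((pred != (y == 1)).sum()),
        pca_policy=pca_policy,
    )


def permutation_test(
    matrix: ProteinMatrix,
    samples: pd.DataFrame,
    k_components: int,
    observed: ClassifierResult,
    n_permutations: int = 2000,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation significance of the observed LOOCV error count.

    Group labels are shuffled over samples preserving group sizes and the full
    LOOCV is rerun for each arrangement; "more extreme" means a null error
    count <= the observed one.  When the number of distinct arrangements is at
    most ``EXHAUSTIVE_LIMIT`` they are enumerated exhaustively and the p-value
    is exact; otherwise ``n_permutations`` random shuffles are drawn and the
    +1-smoothed estimate returned.
    """
    if n_permutations < 1:
        raise ConfigurationError(f"n_permutations must be >= 1, got {n_permutations}")
    y = _labels(matrix, samples)
    n = len(y)
    n_case = int(y.sum())
    folds = _fold_scores(matrix, k_components, observed.pca_policy)

    def errors_for(y_perm: np.ndarray) -> int:
        _, pred = _loocv_errors(folds, y_perm)
        return int((pred != (y_perm == 1)).sum())

    n_arrangements = comb(n, n_case)
    if n_arrangements <= EXHAUSTIVE_LIMIT:
        null = np.empty(n_arrangements, dtype=int)
        for j, case_idx in enumerate(combinations(range(n), n_case)):
            y_perm = np.zeros(n, dtype=int)
            y_perm[list(case_idx)] = 1
            null[j] = errors_for(y_perm)
        p = float((null <= observed.error_count).mean())
        return PermutationResult(
            observed_error=observed.error_count,
            null_errors=null,
            n_permutations=n_arrangements,
            p_value=p,
            seed=seed,
            method="exhaustive",
        )

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations, dtype=int)
    for j in range(n_permutations):
        null[j] = errors_for(rng.permutation(y))
    p = float((1 + (null <= observed.error_count).sum()) / (n_permutations + 1))
    return PermutationResult(
        observed_error=observed.error_count,
        null_errors=null,
        n_permutations=n_permutations,
        p_value=p,
        seed=seed,
        method="sampled",
    )
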