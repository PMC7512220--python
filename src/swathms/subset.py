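"""Protein-panel specificity test by size-matched random resampling.

Asks whether a biologically defined panel (e.g. the mitochondrion-annotated
proteins) predicts case/control status better than random panels of the same
size: the LOOCV error of the PC-logistic classifier restricted to the panel is
compared against the error distribution over ``n_draws`` panels drawn
uniformly without replacement from the *other* (non-flagged) proteins.  The
empirical p-value is the +1-smoothed fraction of random panels doing as well
or better; mean held-out log-loss is reported alongside as a tie-aware
secondary statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import pc_logistic_loocv, _labels
from .errors import ConfigurationError
from .quantify import ProteinMatrix

__all__ = ["SubsetTestResult", "run_subset_test"]


@dataclass
class SubsetTestResult:
    """Panel LOOCV error vs the null over size-matched random panels."""

    flag_name: str
    subset_size: int
    subset_error: int
    subset_log_loss: float
    random_errors: np.ndarray
    random_log_losses: np.ndarray
    n_draws: int
    empirical_p: float
    seed: int | None


def _log_loss(result) -> float:
    p = result.per_sample["held_out_probability"].to_numpy(float).clip(1e-12, 1 - 1e-12)
    y = (result.per_sample["true_label"] == "case").to_numpy()
    return float(-(np.where(y, np.log(p), np.log1p(-p))).mean())


def run_subset_test(
    matrix: ProteinMatrix,
    samples: pd.DataFrame,
    annotations: pd.DataFrame,
    flag_name: str,
    k_components: int = 3,
    n_draws: int = 500,
    seed: int | None = None,
    pca_policy: str = "refit_per_fold",
    draw_from_all: bool = False,
) -> SubsetTestResult:
    """Compare a flagged protein panel against size-matched random panels.

    ``annotations`` must have a ``protein_id`` column and a 0/1 (or boolean)
    column named ``flag_name``; its proteins must all exist in the matrix.
    ``draw_from_all=True`` switches the null to draws from every protein
    instead of only the non-flagged ones (sensitivity variant).
    """
    if n_draws < 1:
        raise ConfigurationError(f"n_draws must be >= 1, got {n_draws}")
    if flag_name not in annotations.columns:
        raise ConfigurationError(f"annotation table has no column {flag_name!r}")
    unknown = set(annotations["protein_id"]) - set(matrix.data.index)
    if unknown:
        raise ConfigurationError(
            f"annotated proteins absent from matrix: {sorted(unknown)[:5]}"
        )
    flagged = list(
        annotations.loc[annotations[flag_name].astype(bool), "protein_id"]
    )
    if not flagged:
        raise ConfigurationError(f"flag {flag_name!r} selects no proteins")
    all_proteins = list(matrix.data.index)
    if len(flagged) >= len(all_proteins):
        raise ConfigurationError(
            f"flag {flag_name!r} selects every protein; no null panels possible"
        )
    pool = all_proteins if draw_from_all else [p for p in all_proteins if p not in set(flagged)]
    size = len(flagged)
    if size > len(pool):
        raise ConfigurationError(
            f"panel size {size} exceeds the {len(pool)} proteins available for null draws"
        )

    _labels(matrix, samples)  # validate metadata early

    subset_res = pc_logistic_loocv(
        matrix.restrict(flagged), samples, k_components, pca_policy
    )

    rng = np.random.default_rng(seed)
    pool_arr = np.asarray(pool, dtype=object)
    errors = np.empty(n_draws, dtype=int)
    losses = np.empty(n_draws)
    for j in range(n_draws):
        # sorted so the panel's protein order (an implementation detail of the
        # draw) cannot perturb the decomposition numerically
        panel = sorted(rng.choice(pool_arr, size=size, replace=False))
        res = pc_logistic_loocv(matrix.restrict(panel), samples, k_components, pca_policy)
        errors[j] = res.error_count
        losses[j] = _log_loss(res)

    p = float((1 + (errors <= subset_res.error_count).sum()) / (n_draws + 1))
    return SubsetTestResult(
        flag_name=flag_name,
        subset_size=size,
        subset_error=subset_res.error_count,
        subset_log_loss=_log_loss(subset_res),
        random_errors=errors,
        random_log_losses=losses,
        n_draws=n_draws,
        empirical_p=p,
        seed=seed,
    )
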