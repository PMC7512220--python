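"""Two-group differential protein abundance.

Per protein: a two-sided pooled-variance Student's t-test on the replicate-
averaged intensities (log10-transformed by default; MS intensities are
log-normal and the companion effect size is a log10 fold-change), with
log10_fc = log10(mean_case / mean_control) computed on the intensity scale.
No multiple-testing correction is applied in the primary path — the filter
grammar operates on raw p-values — but Benjamini–Hochberg q-values are
reported as an informational column.

Filters follow the strict-inequality grammar
``p < p_max AND (log10_fc > t OR log10_fc < -t)`` or, equivalently expressed
on the fold-change scale, ``fold_change > upper OR fold_change < lower``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import UndefinedFoldChangeWarning
from .quantify import ProteinMatrix

__all__ = ["FilterSpec", "t_test_protein", "apply_filter", "format_report"]

RESULT_COLUMNS = ["protein_id", "p_value", "log10_fc", "fold_change", "direction", "q_value"]


@dataclass(frozen=True)
class FilterSpec:
    """Significance filter: a p-value gate plus a symmetric effect-size gate.

    Exactly one of ``lfc_min_abs`` (threshold on |log10 fold-change|) or
    ``fc_bounds`` (``(upper_gate, lower_gate)`` on the fold-change scale) is
    active.  All inequalities are strict.
    """

    p_max: float
    lfc_min_abs: float | None = None
    fc_bounds: tuple[float, float] | None = None

    def __post_init__(self):
        if (self.lfc_min_abs is None) == (self.fc_bounds is None):
            raise ValueError("exactly one of lfc_min_abs / fc_bounds must be given")
        if not (0 < self.p_max <= 1):
            raise ValueError(f"p_max must lie in (0, 1], got {self.p_max}")
        if self.lfc_min_abs is not None and self.lfc_min_abs < 0:
            raise ValueError("lfc_min_abs must be non-negative")
        if self.fc_bounds is not None:
            upper, lower = self.fc_bounds
            if not (0 < lower < upper):
                raise ValueError(
                    f"fc_bounds must satisfy 0 < lower_gate < upper_gate, got {self.fc_bounds}"
                )

    @classmethod
    def primary(cls) -> "FilterSpec":
        """The stringent filter: P < 0.01 and |log10(fold-change)| > 0.2."""
        return cls(p_max=0.01, lfc_min_abs=0.2)

    @classmethod
    def relaxed(cls) -> "FilterSpec":
        """The relaxed filter: P < 0.05 and fold-change > 1.3 or < 0.75."""
        return cls(p_max=0.05, fc_bounds=(1.3, 0.75))

    def passes(self, p_value, log10_fc, fold_change) -> np.ndarray:
        """Vectorised strict-inequality membership test."""
        p_value = np.asarray(p_value, dtype=float)
        keep = p_value < self.p_max
        if self.lfc_min_abs is not None:
            lfc = np.asarray(log10_fc, dtype=float)
            keep &= (lfc > self.lfc_min_abs) | (lfc < -self.lfc_min_abs)
        else:
            upper, lower = self.fc_bounds
            fc = np.asarray(fold_change, dtype=float)
            keep &= (fc > upper) | (fc < lower)
        return keep


def t_test_protein(
    matrix: ProteinMatrix,
    samples: pd.DataFrame,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-protein two-sided pooled-variance t-test, case vs control.

    Parameters
    ----------
    matrix
        Replicate-averaged protein x sample matrix (stage ``averaged``).
    samples
        Metadata with columns ``sample_id`` and ``group`` (case/control).
    log_transform
        Test on log10 intensities (default) or on the raw intensity scale.

    Returns a DataFrame with one row per protein: ``p_value``, ``log10_fc``
    (log10 of the case/control mean-intensity ratio), ``fold_change``,
    ``direction`` (``unchanged`` until a filter assigns it) and an
    informational BH ``q_value``.  Proteins whose fold change is undefined
    (non-positive group mean, or non-finite log under ``log_transform``)
    get NaN statistics and a warning.
    """
    if matrix.stage != "averaged":
        raise ValueError(f"expected a stage='averaged' matrix, got {matrix.stage!r}")
    grp = dict(zip(samples["sample_id"], samples["group"]))
    case_cols = [c for c in matrix.data.columns if grp.get(c) == "case"]
    ctrl_cols = [c for c in matrix.data.columns if grp.get(c) == "control"]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need at least 2 samples per group for a t-test")

    X = matrix.data[case_cols].to_numpy(float)
    Y = matrix.data[ctrl_cols].to_numpy(float)

    mean_case = X.mean(axis=1)
    mean_ctrl = Y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log10(mean_case / mean_ctrl)
    fc = np.power(10.0, lfc)

    if log_transform:
        with np.errstate(divide="ignore", invalid="ignore"):
            Xt, Yt = np.log10(X), np.log10(Y)
    else:
        Xt, Yt = X, Y

    defined = (
        (mean_case > 0)
        & (mean_ctrl > 0)
        & np.isfinite(Xt).all(axis=1)
        & np.isfinite(Yt).all(axis=1)
    )
    p = np.full(matrix.data.shape[0], np.nan)
    if defined.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            t_res = stats.ttest_ind(Xt[defined], Yt[defined], axis=1, equal_var=True)
        pv = np.asarray(t_res.pvalue, dtype=float)
        # zero pooled variance: equal means -> p = 1; unequal means -> p = 0
        var0 = (Xt[defined].var(axis=1) == 0) & (Yt[defined].var(axis=1) == 0)
        eq = np.isclose(Xt[defined].mean(axis=1), Yt[defined].mean(axis=1))
        pv[var0 & eq] = 1.0
        pv[var0 & ~eq] = 0.0
        p[defined] = pv
    n_undef = int((~defined).sum())
    if n_undef:
        warnings.warn(
            f"{n_undef} protein(s) with undefined fold change (non-positive or "
            "non-finite intensities); statistics set to NaN",
            UndefinedFoldChangeWarning,
            stacklevel=2,
        )
        lfc[~defined] = np.nan
        fc[~defined] = np.nan

    # equal group means: define the effect as exactly zero (not -0.0 noise)
    equal_means = defined & np.isclose(mean_case, mean_ctrl, rtol=1e-12, atol=0.0)
    lfc[equal_means] = 0.0
    fc = np.power(10.0, lfc)

    q = np.full_like(p, np.nan)
    finite = np.isfinite(p)
    if finite.any():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "protein_id": matrix.data.index,
            "p_value": p,
            "log10_fc": lfc,
            "fold_change": fc,
            "direction": "unchanged",
            "q_value": q,
        }
    ).reset_index(drop=True)


def apply_filter(records: pd.DataFrame, spec: FilterSpec) -> pd.DataFrame:
    """Retain records passing the filter and set their direction.

    Idempotent: applying the same filter to its own output is a no-op.
    """
    keep = spec.passes(records["p_value"], records["log10_fc"], records["fold_change"])
    out = records.loc[np.asarray(keep, dtype=bool)].copy()
    effect = out["log10_fc"].to_numpy(float)
    out["direction"] = np.where(effect > 0, "increased", "decreased")
    return out.reset_index(drop=True)


def format_report(records: pd.DataFrame) -> pd.DataFrame:
    """Round for report files: p to 2 significant figures, effects to 2 dp."""
    out = records.copy()

    def sig2(x):
        if not np.isfinite(x) or x == 0:
            return x
        from math import floor, log10 as _log10

        return round(x, -int(floor(_log10(abs(x)))) + 1)

    out["p_value"] = [sig2(x) for x in out["p_value"]]
    out["log10_fc"] = out["log10_fc"].round(2)
    out["fold_change"] = out["fold_change"].round(2)
    return out
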