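"""Fragment-ion to protein quantification.

Implements the extraction-based DIA rollup: per protein, the peak intensities
of the 6 strongest fragment ions from each of its 10 strongest peptides are
summed into one protein intensity per run; runs are then rescaled to a common
total intensity (total-sum normalization) and technical replicates averaged
into one column per sample.

"Strongest" is defined as the cross-run summed intensity, computed once per
protein, so the same fragment set quantifies every run and columns stay
comparable.  Missing fragment observations contribute zero.  Ties in strength
are broken lexicographically on the feature identifier for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateRunError,
    ReferentialIntegrityError,
    ZeroIntensityWarning,
)

__all__ = [
    "ProteinMatrix",
    "rollup_protein_intensity",
    "total_sum_normalize",
    "average_replicates",
]

STAGES = ("raw", "normalized", "averaged")
_NEXT_STAGE = {"raw": "normalized", "normalized": "averaged"}

FRAGMENT_COLUMNS = ["protein_id", "peptide_id", "fragment_id", "run_id", "intensity"]
RUN_COLUMNS = ["run_id", "sample_id", "replicate_index"]
SAMPLE_COLUMNS = ["sample_id", "group"]


@dataclass
class ProteinMatrix:
    """A protein x column intensity matrix with a processing-stage tag.

    ``data`` has protein identifiers as the index and run identifiers (stages
    ``raw`` / ``normalized``) or sample identifiers (stage ``averaged``) as
    columns.  Values are non-negative intensities.
    """

    data: pd.DataFrame
    stage: str

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if (self.data.values < 0).any():
            raise ValueError("ProteinMatrix must not contain negative intensities")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def column_ids(self) -> list[str]:
        return list(self.data.columns)

    def advanced(self, data: pd.DataFrame, stage: str) -> "ProteinMatrix":
        """Build the successor-stage matrix, enforcing raw->normalized->averaged."""
        if _NEXT_STAGE.get(self.stage) != stage:
            raise ValueError(f"illegal stage transition {self.stage!r} -> {stage!r}")
        return ProteinMatrix(data, stage)

    def restrict(self, protein_ids) -> "ProteinMatrix":
        """Sub-matrix restricted to the given proteins, same stage."""
        missing = [p for p in protein_ids if p not in self.data.index]
        if missing:
            raise ReferentialIntegrityError(
                f"proteins not in matrix: {missing[:5]}{'...' if len(missing) > 5 else ''}"
            )
        return ProteinMatrix(self.data.loc[list(protein_ids)], self.stage)


def _check_runs(fragments: pd.DataFrame, runs: pd.DataFrame) -> None:
    known = set(runs["run_id"])
    seen = set(fragments["run_id"].unique().tolist())
    unknown = seen - known
    if unknown:
        raise ReferentialIntegrityError(
            f"fragment table refers to unknown run_id(s): {sorted(unknown)[:5]}"
        )


def rollup_protein_intensity(
    fragments: pd.DataFrame,
    runs: pd.DataFrame,
    top_peptides: int = 10,
    top_fragments: int = 6,
) -> ProteinMatrix:
    """Sum the top fragment ions of the top peptides into protein intensities.

    Per protein the ``top_fragments`` strongest fragments of each of the
    ``top_peptides`` strongest peptides are selected globally (strength =
    intensity summed across all runs) and their intensities summed per run.
    Returns a stage-``raw`` matrix with one column per run, in the order of
    the ``runs`` metadata table.
    """
    if len(fragments) == 0:
        raise ValueError("fragment table is empty")
    _check_runs(fragments, runs)

    # cross-run strength of every (protein, peptide, fragment)
    strength = (
        fragments.groupby(["protein_id", "peptide_id", "fragment_id"], observed=True)[
            "intensity"
        ]
        .sum()
        .reset_index()
    )
    # top fragments within each peptide (ties -> lexicographic fragment_id)
    strength = strength.sort_values(
        ["protein_id", "peptide_id", "intensity", "fragment_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    frag_rank = strength.groupby(["protein_id", "peptide_id"], observed=True).cumcount()
    top_frag = strength[frag_rank < top_fragments]

    # peptide strength = total of all its fragment intensities across runs
    pep_strength = (
        strength.groupby(["protein_id", "peptide_id"], observed=True)["intensity"]
        .sum()
        .reset_index()
        .sort_values(
            ["protein_id", "intensity", "peptide_id"],
            ascending=[True, False, True],
            kind="mergesort",
        )
    )
    pep_rank = pep_strength.groupby("protein_id", observed=True).cumcount()
    top_pep = pep_strength[pep_rank < top_peptides][["protein_id", "peptide_id"]]

    selected = top_frag.merge(top_pep, on=["protein_id", "peptide_id"])[
        ["protein_id", "peptide_id", "fragment_id"]
    ]
    chosen = fragments.merge(selected, on=["protein_id", "peptide_id", "fragment_id"])

    mat = (
        chosen.groupby(["protein_id", "run_id"], observed=True)["intensity"]
        .sum()
        .unstack("run_id", fill_value=0.0)
    )
    proteins = sorted(fragments["protein_id"].unique().tolist())
    mat = mat.reindex(index=proteins, columns=list(runs["run_id"]), fill_value=0.0)
    mat.index.name = "protein_id"
    mat.columns.name = None
    mat.columns = [str(c) for c in mat.columns]

    n_zero = int((mat.values == 0.0).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} (protein, run) cells had no observed fragments; set to 0",
            ZeroIntensityWarning,
            stacklevel=2,
        )
    return ProteinMatrix(mat.astype(float), "raw")


def total_sum_normalize(matrix: ProteinMatrix) -> ProteinMatrix:
    """Global normalization on the total sum of peak intensities.

    Each column is rescaled so its total equals the mean of all column totals;
    after normalization all column sums are equal and within-column intensity
    ratios are preserved exactly.
    """
    if matrix.stage != "raw":
        raise ValueError(f"expected a stage='raw' matrix, got {matrix.stage!r}")
    totals = matrix.data.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DegenerateRunError(
            f"run(s) with non-positive total intensity: {list(zero.index)}"
        )
    target = totals.mean()
    return matrix.advanced(matrix.data * (target / totals), "normalized")


def average_replicates(matrix: ProteinMatrix, runs: pd.DataFrame) -> ProteinMatrix:
    """Average technical-replicate runs into one column per sample.

    Column order follows the first appearance of each sample in ``runs``.
    """
    if matrix.stage != "normalized":
        raise ValueError(f"expected a stage='normalized' matrix, got {matrix.stage!r}")
    run_to_sample = dict(zip(runs["run_id"], runs["sample_id"]))
    missing = [c for c in matrix.data.columns if c not in run_to_sample]
    if missing:
        raise ReferentialIntegrityError(f"runs without sample mapping: {missing[:5]}")
    sample_order = list(dict.fromkeys(runs["sample_id"]))
    present = {run_to_sample[c] for c in matrix.data.columns}
    absent = [s for s in sample_order if s not in present]
    if absent:
        raise ValueError(f"sample(s) with zero runs in matrix: {absent[:5]}")
    grouped = matrix.data.T.groupby(
        matrix.data.columns.map(run_to_sample.get)
    ).mean().T
    grouped = grouped[[s for s in sample_order if s in grouped.columns]]
    return matrix.advanced(grouped, "averaged")
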