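"""Packaged transcriptions of the published differential-abundance tables.

``tables2_3.tsv`` holds the 60 proteins reported as differentially abundant
between all cases and controls under the stringent filter (38 increased, 22
decreased); ``table4.tsv`` holds the mitochondria-related proteins of the
subgroup comparison under the relaxed filter (P < 0.05, fold-change > 1.3 or
< 0.75).

The printed log10 fold-change column is rounded to two decimals, so values at
the 0.2 boundary (e.g. a printed 0.20 whose fold-change 1.59 implies
log10 = 0.2014) would wrongly fail a strict > 0.2 gate.
:func:`records_from_tables2_3` therefore derives ``log10_fc`` from the
higher-precision fold-change column; the printed log10 column is retained and
cross-checked by :func:`verify_fixtures` against ``|10^lfc - fc| <= 0.02``
(the two columns were rounded independently in print).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .differential import FilterSpec

__all__ = [
    "load_tables2_3",
    "load_table4",
    "records_from_tables2_3",
    "verify_fixtures",
    "FixtureReport",
]

ROUNDTRIP_TOL = 0.02


def _read(name: str) -> pd.DataFrame:
    with resources.files("swathms.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def _read_raw(name: str) -> pd.DataFrame:
    with resources.files("swathms.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def load_tables2_3() -> pd.DataFrame:
    """The 60-protein stringent-filter table (38 increased / 22 decreased)."""
    return _read("tables2_3.tsv")


def load_table4() -> pd.DataFrame:
    """The mitochondria-related relaxed-filter table of the subgroup comparison."""
    return _read("table4.tsv")


def records_from_tables2_3() -> pd.DataFrame:
    """Differential records built from the fixture, filter-ready.

    ``log10_fc`` is derived as log10 of the printed fold-change (three
    significant figures) rather than taken from the two-decimal printed log10
    column — see the module docstring.  ``direction`` is reset to
    ``unchanged`` so a filter can assign it.
    """
    t = load_tables2_3()
    return pd.DataFrame(
        {
            "protein_id": t["gene_name"],
            "p_value": t["p_value"].astype(float),
            "log10_fc": np.log10(t["fold_change"].astype(float)),
            "fold_change": t["fold_change"].astype(float),
            "direction": "unchanged",
        }
    )


def _print_slack(text: str) -> float:
    """Half a unit in the last printed decimal place of ``text``."""
    text = text.strip()
    if "." not in text:
        return 0.5
    return 0.5 * 10.0 ** (-(len(text) - text.index(".") - 1))


@dataclass
class FixtureReport:
    """Outcome of the fixture consistency checks."""

    n_rows_tables2_3: int
    n_rows_table4: int
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def verify_fixtures() -> FixtureReport:
    """Check every fixture row against its table's filter and roundtrip.

    Printed values are checked with half-ULP-of-printed-precision slack, so a
    row whose true (unrounded) value passed the published filter but prints at
    the threshold (e.g. fold-change 1.30 against the > 1.3 gate) is not a
    violation, while a genuinely failing value (e.g. p = 0.02 against
    p < 0.01) is.  Violations are reported, never raised.
    """
    violations: list = []

    t23 = load_tables2_3()
    t23_raw = _read_raw("tables2_3.tsv")
    primary = FilterSpec.primary()
    for i, row in t23.iterrows():
        p, lfc, fc = float(row["p_value"]), float(row["log10_fc"]), float(row["fold_change"])
        sp = _print_slack(t23_raw.loc[i, "p_value"])
        sf = _print_slack(t23_raw.loc[i, "fold_change"])
        gate_up = 10.0**primary.lfc_min_abs
        gate_dn = 10.0**-primary.lfc_min_abs
        if not (p < primary.p_max + sp):
            violations.append(f"tables2_3 {row['gene_name']}: p={p} fails p<{primary.p_max}")
        if not (fc > gate_up - sf or fc < gate_dn + sf):
            violations.append(
                f"tables2_3 {row['gene_name']}: fold_change={fc} fails |log10FC|>{primary.lfc_min_abs}"
            )
        # the printed log10 and fold-change columns were rounded independently:
        # compare the intervals implied by each column's printed precision
        sl = _print_slack(t23_raw.loc[i, "log10_fc"])
        lo_a, hi_a = 10.0 ** (lfc - sl), 10.0 ** (lfc + sl)
        lo_b, hi_b = fc - sf, fc + sf
        gap = max(0.0, lo_a - hi_b, lo_b - hi_a)
        if gap > ROUNDTRIP_TOL:
            violations.append(
                f"tables2_3 {row['gene_name']}: 10^{lfc} vs {fc} differ by {gap:.3f} "
                f"beyond printed precision + {ROUNDTRIP_TOL}"
            )
        expected_dir = "increased" if fc > 1 else "decreased"
        if row["direction"] != expected_dir:
            violations.append(
                f"tables2_3 {row['gene_name']}: direction {row['direction']} vs fold_change {fc}"
            )

    t4 = load_table4()
    t4_raw = _read_raw("table4.tsv")
    relaxed = FilterSpec.relaxed()
    upper, lower = relaxed.fc_bounds
    for i, row in t4.iterrows():
        p, fc = float(row["p_value"]), float(row["fold_change"])
        sp = _print_slack(t4_raw.loc[i, "p_value"])
        sf = _print_slack(t4_raw.loc[i, "fold_change"])
        if not (p < relaxed.p_max + sp):
            violations.append(f"table4 {row['protein_name']}: p={p} fails p<{relaxed.p_max}")
        if not (fc > upper - sf or fc < lower + sf):
            violations.append(
                f"table4 {row['protein_name']}: fold_change={fc} outside gates ({upper}, {lower})"
            )
        expected_dir = "increased" if fc > 1 else "decreased"
        if row["direction"] != expected_dir:
            violations.append(
                f"table4 {row['protein_name']}: direction {row['direction']} vs fold_change {fc}"
            )

    return FixtureReport(
        n_rows_tables2_3=len(t23), n_rows_table4=len(t4), violations=violations
    )
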