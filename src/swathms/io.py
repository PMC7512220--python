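"""Plain-text (TSV) input/output.

All tables are tab-separated with a header row.  Protein matrices carry their
processing stage in a ``# stage=...`` comment line above the header so the
stage tag round-trips.  Cohort / pipeline configuration files are flat
``key = value`` text (one pair per line, ``#`` comments).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ConfigurationError
from .quantify import ProteinMatrix

__all__ = [
    "write_fragments",
    "read_fragments",
    "write_table",
    "read_table",
    "write_matrix",
    "read_matrix",
    "read_key_value",
    "write_key_value",
]


def write_fragments(fragments: pd.DataFrame, path) -> None:
    fragments.to_csv(path, sep="\t", index=False)


def read_fragments(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "protein_id": "category",
            "peptide_id": "category",
            "fragment_id": "category",
            "run_id": "category",
        },
    )
    required = {"protein_id", "peptide_id", "fragment_id", "run_id", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"fragment table missing column(s): {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(matrix: ProteinMatrix, path) -> None:
    """Proteins as rows, column ids in the header, stage in a comment line."""
    with open(path, "w") as fh:
        fh.write(f"# stage={matrix.stage}\n")
        matrix.data.to_csv(fh, sep="\t", index_label="protein_id")


def read_matrix(path) -> ProteinMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# stage="):
            raise ConfigurationError(f"{path}: missing '# stage=' header line")
        stage = first.split("=", 1)[1]
        data = pd.read_csv(fh, sep="\t", index_col="protein_id")
    return ProteinMatrix(data, stage)


def read_key_value(path) -> dict:
    """Parse a flat ``key = value`` configuration file."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in out:
            raise ConfigurationError(f"{path}:{lineno}: duplicate key {key!r}")
        out[key] = value
    return out


def write_key_value(mapping: dict, path) -> None:
    with open(path, "w") as fh:
        for key, value in mapping.items():
            fh.write(f"{key} = {value}\n")
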