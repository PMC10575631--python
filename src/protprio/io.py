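"""Reading and writing the pipeline's delimited-text data products.

Everything is plain TSV/JSON so runs can be diffed and archived. Floats are
written with a fixed ``%.10g`` format so repeated runs with the same seed
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import StudyDesign, ValidationError

FLOAT_FORMAT = "%.10g"

PEPTIDE_COLUMNS = ["protein_id", "peptide_id", "sample_id", "spectral_count"]


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a protein x sample spectral-count matrix (first column = protein id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate protein ids in {path}: {dups[:5]}")
    if (df.values < 0).any():
        raise ValidationError(f"negative counts in {path}")
    df.index.name = None
    df.columns.name = None
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "protein_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FORMAT)


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Read long-format peptide evidence (protein, peptide, sample, count)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PEPTIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing peptide-table columns {missing}")
    bad = df.index[df["spectral_count"] < 0]
    if len(bad):
        # +2: header line plus 1-based file lines
        raise ValidationError(
            f"{path}: negative spectral_count at line {int(bad[0]) + 2}"
        )
    return df[PEPTIDE_COLUMNS]


def write_peptide_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path, contrasts: list[tuple[str, str]] | None = None) -> StudyDesign:
    """Read a two-column (sample, condition) design table.

    If no contrasts are given, the first condition encountered is taken as the
    reference and one contrast is formed against each other condition.
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["sample", "condition"]:
        raise ValidationError(f"{path}: design must have columns sample, condition")
    conditions = pd.Series(df["condition"].values, index=df["sample"].values)
    if contrasts is None:
        seen = list(dict.fromkeys(conditions))
        contrasts = [(seen[0], c) for c in seen[1:]]
    return StudyDesign(conditions=conditions, contrasts=contrasts)


def write_design(design: StudyDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
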