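"""Protein inference, detection filtering, and variance stabilization.

The ingest chain is: peptide evidence -> two-peptide protein inference ->
detection-based variation filter -> per-sample calibration + generalized-log
transform. The transform is the exact variance stabilizer for a quadratic
mean-variance law Var(X) = mu + phi*mu^2 (overdispersed spectral counts):

    g(y) = (2 / sqrt(phi)) * asinh(sqrt(phi * y)),   y = x / s_j

with per-sample scale s_j estimated by median-ratio calibration against a
geometric-mean pseudo-reference, and a single global phi estimated by
moments. g is monotone in x within each sample and maps 0 to 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import NormalizedMatrix, ValidationError


def aggregate_proteins(evidence: pd.DataFrame, min_peptides: int = 2) -> pd.DataFrame:
    """Collapse peptide evidence to proteins, applying the two-peptide rule.

    A protein is retained iff the number of distinct peptides observed for
    it (across all samples) is at least ``min_peptides``; its per-sample
    count is the sum of its peptides' counts. Follows the proteomic
    convention that single-peptide identifications are unreliable.
    """
    required = {"protein_id", "peptide_id", "sample_id", "spectral_count"}
    missing = required - set(evidence.columns)
    if missing:
        raise ValidationError(f"peptide table missing columns {sorted(missing)}")
    if len(evidence) == 0:
        return pd.DataFrame()
    if (evidence["spectral_count"] < 0).any():
        line = int(evidence.index[evidence["spectral_count"] < 0][0])
        raise ValidationError(f"negative spectral_count at table row {line}")
    n_pep = evidence.groupby("protein_id")["peptide_id"].nunique()
    keep = n_pep.index[n_pep >= min_peptides]
    sub = evidence[evidence["protein_id"].isin(keep)]
    matrix = (
        sub.pivot_table(
            index="protein_id",
            columns="sample_id",
            values="spectral_count",
            aggfunc="sum",
            fill_value=0,
        )
        .astype(np.int64)
    )
    matrix.index.name = None
    matrix.columns.name = None
    # preserve first-appearance sample order from the evidence table
    order = [s for s in dict.fromkeys(evidence["sample_id"]) if s in matrix.columns]
    return matrix.loc[sorted(matrix.index), order]


def variation_filter(matrix: pd.DataFrame, min_detected_samples: int = 4) -> pd.DataFrame:
    """Keep proteins detected (count > 0) in at least ``min_detected_samples`` samples."""
    if matrix.shape[1] == 0 or matrix.shape[0] == 0:
        raise ValidationError("variation_filter requires a non-empty matrix")
    if min_detected_samples > matrix.shape[1]:
        raise ValidationError(
            f"min_detected_samples={min_detected_samples} exceeds "
            f"{matrix.shape[1]} samples"
        )
    detected = (matrix.values > 0).sum(axis=1)
    return matrix.loc[detected >= min_detected_samples]


def _median_ratio_scales(matrix: pd.DataFrame) -> pd.Series:
    """Per-sample scale vs a geometric-mean pseudo-reference (nonzero cells only)."""
    x = matrix.values.astype(float)
    ref = np.expm1(np.mean(np.log1p(x), axis=1))
    scales = {}
    for j, sample in enumerate(matrix.columns):
        col = x[:, j]
        ok = (col > 0) & (ref > 0)
        if not ok.any():
            raise ValidationError(f"sample {sample!r} has no nonzero counts; cannot calibrate")
        scales[sample] = float(np.median(col[ok] / ref[ok]))
    return pd.Series(scales)


def estimate_dispersion(scaled: np.ndarray) -> float:
    """Moment estimate of phi in Var = mu + phi*mu^2, median across proteins."""
    m = scaled.mean(axis=1)
    v = scaled.var(axis=1, ddof=1)
    ok = m > 0
    if not ok.any():
        return 1e-6
    phi = np.median((v[ok] - m[ok]) / m[ok] ** 2)
    return float(max(phi, 1e-6))


def glog_normalize(matrix: pd.DataFrame, dispersion: float | None = None) -> NormalizedMatrix:
    """Calibrate samples and apply the generalized-log transform.

    Exact scalar rescalings between samples are removed by construction:
    if one column is c times another, their normalized values coincide.
    ``dispersion`` overrides the moment estimate (useful for testing).
    """
    if matrix.shape[0] == 0:
        raise ValidationError("cannot normalize an empty matrix")
    scales = _median_ratio_scales(matrix)
    scaled = matrix.values.astype(float) / scales.values[None, :]
    phi = estimate_dispersion(scaled) if dispersion is None else float(dispersion)
    if phi <= 0:
        raise ValidationError("dispersion must be positive")
    values = (2.0 / np.sqrt(phi)) * np.arcsinh(np.sqrt(phi * scaled))
    out = pd.DataFrame(values, index=matrix.index, columns=matrix.columns)
    return NormalizedMatrix(values=out, scale_factors=scales, dispersion=phi)
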