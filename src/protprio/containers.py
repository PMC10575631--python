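"""Shared lightweight containers used across the pipeline.

The canonical in-memory matrix is a :class:`pandas.DataFrame` with protein
identifiers as the index and sample identifiers as the columns; these
dataclasses wrap the pieces of metadata that travel with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


class ValidationError(ValueError):
    """Raised when an input table or configuration violates a contract."""


@dataclass
class StudyDesign:
    """Maps samples to condition labels and lists the contrasts to test.

    Parameters
    ----------
    conditions
        Series indexed by sample id with the condition label of each sample.
    contrasts
        Ordered ``(reference_condition, test_condition)`` pairs.
    """

    conditions: pd.Series
    contrasts: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.conditions = pd.Series(self.conditions)
        if self.conditions.index.duplicated().any():
            raise ValidationError("duplicate sample ids in design")
        labels = set(self.conditions)
        for ref, test in self.contrasts:
            for cond in (ref, test):
                if cond not in labels:
                    raise ValidationError(f"contrast condition {cond!r} not in design")
            if (self.conditions == ref).sum() < 2 or (self.conditions == test).sum() < 2:
                raise ValidationError(
                    f"contrast ({ref!r}, {test!r}) needs >=2 samples per side"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.conditions.index)

    def samples_for(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])

    def check_matrix(self, matrix: pd.DataFrame) -> None:
        """Every matrix column must appear exactly once in the design."""
        missing = set(matrix.columns) - set(self.conditions.index)
        if missing:
            raise ValidationError(f"samples missing from design: {sorted(missing)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.conditions.index, "condition": self.conditions.values}
        )


@dataclass
class NormalizedMatrix:
    """Variance-stabilized protein x sample matrix.

    ``values`` is on the generalized-log (arsinh-family) scale.
    ``scale_factors`` holds the per-sample calibration scale and
    ``dispersion`` the global quadratic overdispersion estimate used by the
    transform, so the transform is fully reproducible from the raw counts.
    """

    values: pd.DataFrame
    scale_factors: pd.Series
    dispersion: float

    @property
    def transform_params(self) -> dict:
        return {
            "scale_factors": self.scale_factors.to_dict(),
            "dispersion": self.dispersion,
        }


@dataclass
class SimTruth:
    """Ground truth recorded by the synthetic-data generator."""

    de_proteins: set[str] = field(default_factory=set)
    directions: dict[str, str] = field(default_factory=dict)
    planted_sets: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "de_proteins": sorted(self.de_proteins),
            "directions": {k: self.directions[k] for k in sorted(self.directions)},
            "planted_sets": sorted(self.planted_sets),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            de_proteins=set(d.get("de_proteins", [])),
            directions=dict(d.get("directions", {})),
            planted_sets=set(d.get("planted_sets", [])),
        )
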