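"""Core in-memory containers shared across the pipeline.

The expression matrix is a thin wrapper over a pandas DataFrame of float
abundances (proteins in rows, samples in columns) where ``NaN`` marks a
missing cell.  Abundances are assumed to be on the log2 scale already; the
library never log-transforms internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import DesignError


@dataclass
class ExpressionMatrix:
    """Proteins x samples abundance table with a missing-value mask.

    Parameters
    ----------
    values
        Float DataFrame; index = protein identifiers (made unique), columns =
        sample names.  ``NaN`` encodes a missing observation.
    namespace
        Identifier namespace of the row index, once detected or declared.
    duplicates
        Original identifiers that occurred more than once, mapped to their
        multiplicity.  Duplicate rows are kept and suffixed, never aggregated.
    labels
        Optional per-row table of identifier labels in other namespaces.
    """

    values: pd.DataFrame
    namespace: Optional[str] = None
    duplicates: dict[str, int] = field(default_factory=dict)
    labels: Optional[pd.DataFrame] = None

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the observation is missing."""
        return self.values.isna()

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def is_complete(self) -> bool:
        """True when no cell is missing."""
        return not bool(self.values.isna().any().any())

    def equals(self, other: "ExpressionMatrix") -> bool:
        """Value/mask/identifier equality (labels and namespace excluded)."""
        if list(self.values.index) != list(other.values.index):
            return False
        if list(self.values.columns) != list(other.values.columns):
            return False
        a, b = self.values, other.values
        same_mask = (a.isna() == b.isna()).all().all()
        close = ((a - b).abs().fillna(0) < 1e-12).all().all()
        return bool(same_mask and close)


@dataclass
class SampleDesign:
    """Sample-level design: condition per sample, optional subject pairing.

    Invariants enforced at construction: sample ids unique, every sample has
    a condition, and subject ids are either present for all samples or none.
    """

    samples: list[str]
    conditions: list[str]
    subjects: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise DesignError("sample ids must be unique")
        if len(self.conditions) != len(self.samples):
            raise DesignError("every sample needs a condition label")
        if self.subjects is not None:
            if len(self.subjects) != len(self.samples):
                raise DesignError(
                    "subject ids must be given for all samples or for none"
                )
            if any(s is None or s == "" for s in self.subjects):
                raise DesignError(
                    "subject ids must be given for all samples or for none"
                )

    @property
    def has_subjects(self) -> bool:
        return self.subjects is not None

    def condition_of(self, sample: str) -> str:
        return self.conditions[self.samples.index(sample)]

    def groups(self) -> dict[str, list[str]]:
        """Condition label -> list of sample ids, in input order."""
        out: dict[str, list[str]] = {}
        for s, c in zip(self.samples, self.conditions):
            out.setdefault(c, []).append(s)
        return out

    def subject_map(self) -> dict[str, str]:
        """Sample id -> subject id (requires subjects)."""
        if self.subjects is None:
            raise DesignError("design has no subject column")
        return dict(zip(self.samples, self.subjects))

    def to_frame(self) -> pd.DataFrame:
        data = {"sample": self.samples, "condition": self.conditions}
        if self.subjects is not None:
            data["subject"] = self.subjects
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleDesign":
        cols = {c.lower(): c for c in df.columns}
        if "sample" not in cols or "condition" not in cols:
            raise DesignError("design table needs 'sample' and 'condition' columns")
        subjects = None
        if "subject" in cols:
            col = df[cols["subject"]]
            if not col.isna().all():
                subjects = [str(x) for x in col]
        return cls(
            samples=[str(x) for x in df[cols["sample"]]],
            conditions=[str(x) for x in df[cols["condition"]]],
            subjects=subjects,
        )
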