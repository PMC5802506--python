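"""Core expression containers.

An :class:`ExpressionMatrix` is a features x samples numeric matrix plus
per-sample metadata (patient id and disease phase).  Matrices are tagged with
a scale (``"counts"`` for raw non-negative integer counts, ``"log2"`` for
log2-normalized values) so downstream stages can enforce their preconditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHASES = ("primary", "relapse", "reference")

COUNTS = "counts"
LOG2 = "log2"


@dataclass
class ExpressionMatrix:
    """Features x samples matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample id.
    sample_meta
        DataFrame indexed by sample id with columns ``patient`` and
        ``phase`` (one of ``primary``, ``relapse``, ``reference``).
    scale
        ``"counts"`` or ``"log2"``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    scale: str = COUNTS

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if self.scale not in (COUNTS, LOG2):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if self.scale == COUNTS:
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                raise ValueError("counts-scale matrix must hold non-negative integers")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        bad = set(self.sample_meta["phase"]) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phases: {sorted(bad)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_features(self, features) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(features)], self.sample_meta, self.scale)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(
            self.values[samples], self.sample_meta.loc[samples], self.scale
        )


@dataclass
class PairingTable:
    """Patient-level pairing of a primary with a relapse sample.

    Each sample may appear in at most one pair; samples without a partner
    (e.g. a relapse dropped in quality control) are simply absent from the
    table and thereby excluded from paired tests.
    """

    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        req = {"patient", "primary_sample", "relapse_sample"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"pairing table needs columns {sorted(req)}")
        all_samples = pd.concat(
            [self.records["primary_sample"], self.records["relapse_sample"]]
        )
        if all_samples.duplicated().any():
            raise ValueError("a sample appears in more than one pair")
        if self.records["patient"].duplicated().any():
            raise ValueError("a patient appears in more than one pair")

    def __len__(self) -> int:
        return len(self.records)

    def complete_pairs(self, sample_ids) -> "PairingTable":
        """Pairs whose two samples are both present in `sample_ids`."""
        present = set(sample_ids)
        keep = self.records["primary_sample"].isin(present) & self.records[
            "relapse_sample"
        ].isin(present)
        return PairingTable(self.records[keep].reset_index(drop=True))
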