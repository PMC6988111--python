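"""Shared data model for the proteotype-variation pipeline.

All abundance matrices are proteins x samples pandas DataFrames; missing
quantifications are NaN.  Protein and sample identifiers are plain strings
matched exactly (inputs are assumed pre-mapped to a single identifier space).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class Scale(str, enum.Enum):
    """Scale of an abundance matrix: raw intensities or log2 intensities."""

    LINEAR = "linear"
    LOG2 = "log2"


class ModuleCategory(str, enum.Enum):
    COMPLEX = "complex"
    PATHWAY = "pathway"
    COMPARTMENT = "compartment"
    CHROMOSOME = "chromosome"
    HOUSEKEEPING = "housekeeping"
    ESSENTIAL = "essential"
    INTERACTION = "interaction"


@dataclass
class AbundanceDataset:
    """One cohort's protein abundance matrix.

    Parameters
    ----------
    dataset_id : str
        Free-text identifier of the cohort / study.
    values : pandas.DataFrame
        proteins x samples matrix; NaN marks a missing quantification.
    scale : Scale
        ``linear`` (raw, strictly positive) or ``log2``.
    """

    dataset_id: str
    values: pd.DataFrame
    scale: Scale = Scale.LOG2

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein identifiers: {dupes[:5]}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dupes[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if self.scale is Scale.LINEAR and np.nanmin(arr, initial=np.inf) <= 0:
            raise ValueError(
                "scale=linear requires all non-missing values > 0 "
                "(found a non-positive entry)"
            )

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: pd.DataFrame, scale: Scale | None = None) -> "AbundanceDataset":
        return AbundanceDataset(
            dataset_id=self.dataset_id,
            values=values,
            scale=self.scale if scale is None else scale,
        )


@dataclass
class SampleMetadata:
    """Per-sample covariates (sex, diet, arbitrary extra factors).

    ``table`` is indexed by sample_id; factor columns hold categorical levels
    as strings, with "unknown" for unobserved values.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample_id in metadata")

    def levels(self, factor: str, samples: list[str] | None = None) -> pd.Series:
        s = self.table[factor]
        if samples is not None:
            s = s.reindex(samples)
        return s

    def factor_groups(self, factor: str, samples: list[str]) -> dict[str, list[str]]:
        """Samples per level of a factor, dropping "unknown"/missing."""
        s = self.levels(factor, samples)
        s = s[s.notna() & (s != "unknown")]
        return {lvl: list(s.index[s == lvl]) for lvl in sorted(s.unique())}


@dataclass
class ModuleCatalog:
    """Named protein sets of a single category (complexes, pathways, ...)."""

    category: ModuleCategory
    members: dict[str, frozenset[str]]
    well_defined: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.category = ModuleCategory(self.category)
        for mid, mem in self.members.items():
            if not mem:
                raise ValueError(f"module {mid!r} has no members")
            self.members[mid] = frozenset(mem)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def restrict(self, proteins: set[str]) -> "ModuleCatalog":
        """Catalog with members intersected with a quantified-protein set."""
        kept = {
            mid: mem & proteins
            for mid, mem in self.members.items()
            if mem & proteins
        }
        return ModuleCatalog(
            category=self.category,
            members=kept,
            well_defined={m: self.well_defined.get(m, False) for m in kept},
        )

    def all_members(self) -> frozenset[str]:
        out: set[str] = set()
        for mem in self.members.values():
            out |= mem
        return frozenset(out)


@dataclass
class InteractionTable:
    """Unordered protein pairs with a combined confidence score in [0, 1]."""

    scores: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for pair, sc in self.scores.items():
            if pair[0] == pair[1]:
                raise ValueError(f"self-pair {pair} not allowed")
            if not 0.0 <= sc <= 1.0:
                raise ValueError(f"score {sc} for pair {pair} outside [0, 1]")

    def pairs_above(self, cutoff: float) -> set[tuple[str, str]]:
        return {p for p, s in self.scores.items() if s > cutoff}


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order-independent pair key."""
    return (a, b) if a <= b else (b, a)
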