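"""Readers and writers for the pipeline's external table formats.

Formats
-------
* abundance matrix: TSV, header row of sample ids, first column protein ids,
  empty cells or "NA" for missing values
* sample metadata: TSV with a ``sample_id`` column plus factor columns
* module catalogs: GMT (module, description, members...) or long TSV
  (module_id, protein_id[, well_defined])
* interactions: 3-column TSV (protein1, protein2, combined_score),
  STRING-flat-file style; scores on a 0-1000 scale are rescaled to [0, 1]
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    AbundanceDataset,
    InteractionTable,
    ModuleCatalog,
    ModuleCategory,
    SampleMetadata,
    Scale,
    canonical_pair,
)

logger = logging.getLogger(__name__)

_NA_VALUES = ["", "NA", "NaN", "nan"]


def read_abundance_matrix(
    path: str | Path, dataset_id: str, scale: Scale | str = Scale.LOG2
) -> AbundanceDataset:
    """Read a proteins x samples abundance TSV into an AbundanceDataset.

    Raises a parse error naming the offending cell for malformed numerics and
    a validation error for duplicated identifiers or non-positive values under
    ``scale=linear``.
    """
    path = Path(path)
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    values = pd.DataFrame(
        index=raw.index.astype(str), columns=raw.columns.astype(str), dtype=float
    )
    for col in raw.columns:
        converted = pd.to_numeric(raw[col].replace(_NA_VALUES, np.nan), errors="coerce")
        bad = converted.isna() & ~raw[col].isin(_NA_VALUES)
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path.name}: malformed numeric cell at row {row!r}, column {col!r}"
            )
        values[col] = converted.to_numpy()
    return AbundanceDataset(dataset_id=dataset_id, values=values, scale=Scale(scale))


def write_abundance_matrix(dataset: AbundanceDataset, path: str | Path) -> None:
    dataset.values.to_csv(path, sep="\t", na_rep="", index_label="protein_id")


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in table.columns:
        raise ValueError("metadata file must have a 'sample_id' column")
    table = table.set_index("sample_id")
    table = table.replace("", "unknown")
    return SampleMetadata(table=table)


def write_sample_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.table.to_csv(path, sep="\t", index_label="sample_id")


def read_module_catalog(
    path: str | Path, category: ModuleCategory | str
) -> ModuleCatalog:
    """Read a module catalog from GMT or long-TSV, auto-detecting the dialect.

    A line whose third-and-later fields are member ids (>= 3 columns and not a
    recognized long-TSV header) is treated as GMT.  Empty modules are dropped
    with a warning.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    fields = first.split("\t")
    is_long = len(fields) in (2, 3) and (
        fields[:2] == ["module_id", "protein_id"] or len(fields) == 2
    )
    if path.suffix.lower() == ".gmt":
        is_long = False
    members: dict[str, set[str]] = {}
    well_defined: dict[str, bool] = {}
    if is_long:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if "module_id" not in df.columns:
            # headerless two/three column long format
            df = pd.read_csv(
                path,
                sep="\t",
                dtype=str,
                keep_default_na=False,
                header=None,
                names=["module_id", "protein_id", "well_defined"][: len(fields)],
            )
        for _, row in df.iterrows():
            members.setdefault(row["module_id"], set()).add(row["protein_id"])
            if "well_defined" in df.columns:
                well_defined[row["module_id"]] = str(row["well_defined"]).lower() in (
                    "1",
                    "true",
                    "yes",
                )
    else:
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    if line.strip():
                        raise ValueError(f"{path.name}: unrecognized module file dialect")
                    continue
                mid = parts[0]
                members.setdefault(mid, set()).update(p for p in parts[2:] if p)
    dropped = [m for m, mem in members.items() if not mem]
    for m in dropped:
        logger.warning("module %r has no members after parsing; dropped", m)
        del members[m]
    if not members:
        raise ValueError(f"{path.name}: no non-empty modules found")
    return ModuleCatalog(
        category=ModuleCategory(category),
        members={m: frozenset(mem) for m, mem in members.items()},
        well_defined=well_defined,
    )


def write_module_catalog_gmt(catalog: ModuleCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for mid in sorted(catalog.members):
            mem = sorted(catalog.members[mid])
            fh.write("\t".join([mid, catalog.category.value] + mem) + "\n")


def read_interactions(path: str | Path) -> InteractionTable:
    """Read a STRING-style interaction TSV (protein1, protein2, combined_score).

    Scores are auto-rescaled: if any score exceeds 1 the whole column is taken
    to be on the STRING 0-1000 convention and divided by 1000.  Unordered
    duplicates keep the maximum score; self-pairs are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    cols = list(df.columns)
    p1, p2, sc = cols[0], cols[1], cols[2]
    scores = df[sc].astype(float)
    if (scores > 1).any():
        scores = scores / 1000.0
    out: dict[tuple[str, str], float] = {}
    n_self = 0
    for a, b, s in zip(df[p1], df[p2], scores):
        if a == b:
            n_self += 1
            continue
        key = canonical_pair(str(a), str(b))
        if key not in out or s > out[key]:
            out[key] = float(s)
    if n_self:
        logger.warning("dropped %d self-interaction rows", n_self)
    return InteractionTable(scores=out)


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    rows = [
        {"protein1": a, "protein2": b, "combined_score": s}
        for (a, b), s in sorted(table.scores.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
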