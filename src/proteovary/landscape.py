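"""Stable/variable landscape of protein complexes across datasets.

The median pairwise Pearson correlation of a complex's quantified subunits
("median co-abundance") ranks complexes within each dataset; median rank
fractions across datasets aggregate into a landscape whose top quartile is
called stable and bottom quartile variable.  Decoy complexes (size-matched
random sets of module-free proteins) and within-protein permutations provide
the null references, and a permutation-based t-test quantifies cross-dataset
consistency of the ranking.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AbundanceDataset, ModuleCatalog
from .recovery import MIN_OVERLAP, pairwise_correlations
from .stats import observed_vs_null_ttest

logger = logging.getLogger(__name__)

MIN_MEMBERS = 5  # minimum quantified subunits for a complex to qualify


@dataclass
class ComplexCoabundance:
    dataset_id: str
    module_id: str
    n_members_quantified: int
    median_r: float
    rank: float = float("nan")  # 1 = most co-abundant; average rank on ties
    rank_fraction: float = float("nan")


@dataclass
class LandscapeRecord:
    module_id: str
    median_rank_fraction: float
    n_datasets: int
    label: str  # stable / variable / intermediate / NA


def complex_median_coabundance(
    dataset: AbundanceDataset,
    catalog: ModuleCatalog,
    min_members: int = MIN_MEMBERS,
    min_overlap: int = MIN_OVERLAP,
) -> list[ComplexCoabundance]:
    """Median within-complex pairwise r per complex, ranked within the dataset."""
    quantified = set(dataset.proteins)
    records: list[ComplexCoabundance] = []
    for mid, members in catalog.members.items():
        q = sorted(members & quantified)
        if len(q) < min_members:
            continue
        pairs = list(itertools.combinations(q, 2))
        corrs = pairwise_correlations(dataset, pairs, min_overlap=min_overlap)
        rs = [c.r for c in corrs]
        if not rs:
            continue
        records.append(
            ComplexCoabundance(
                dataset_id=dataset.dataset_id,
                module_id=mid,
                n_members_quantified=len(q),
                median_r=float(np.median(rs)),
            )
        )
    if records:
        med = pd.Series({r.module_id: r.median_r for r in records})
        ranks = med.rank(ascending=False, method="average")
        n = len(records)
        for r in records:
            r.rank = float(ranks[r.module_id])
            r.rank_fraction = float(ranks[r.module_id] / n)
    return records


def aggregate_landscape(
    per_dataset: list[list[ComplexCoabundance]],
) -> list[LandscapeRecord]:
    """Median rank fraction per complex across qualifying datasets, with
    quartile classes on the aggregated values (top 25% stable, bottom 25%
    variable).  Complexes qualifying in < 2 datasets get label NA."""
    if len(per_dataset) < 2:
        raise ValueError("landscape aggregation needs at least 2 datasets")
    fractions: dict[str, list[float]] = {}
    for records in per_dataset:
        for rec in records:
            fractions.setdefault(rec.module_id, []).append(rec.rank_fraction)
    out: list[LandscapeRecord] = []
    eligible = {m: v for m, v in fractions.items() if len(v) >= 2}
    medians = {m: float(np.median(v)) for m, v in eligible.items()}
    if medians:
        vals = np.array(list(medians.values()))
        lo, hi = np.percentile(vals, [25, 75])
    for mid, v in fractions.items():
        if mid not in eligible:
            out.append(LandscapeRecord(mid, float(np.median(v)), len(v), "NA"))
            continue
        m = medians[mid]
        if m <= lo:
            label = "stable"  # small rank fraction = high co-abundance
        elif m >= hi:
            label = "variable"
        else:
            label = "intermediate"
        out.append(LandscapeRecord(mid, m, len(v), label))
    out.sort(key=lambda r: (np.isnan(r.median_rank_fraction), r.median_rank_fraction))
    return out


def decoy_complexes(
    dataset: AbundanceDataset, catalog: ModuleCatalog, seed: int
) -> ModuleCatalog:
    """Size-matched artificial complexes drawn from module-free proteins."""
    rng = np.random.default_rng(seed)
    in_complex = catalog.all_members()
    free = sorted(set(dataset.proteins) - set(in_complex))
    sizes = {mid: len(m) for mid, m in catalog.members.items()}
    total_needed = sum(sizes.values())
    decoys: dict[str, frozenset[str]] = {}
    if total_needed <= len(free):
        pool = list(rng.permutation(free))
        for mid, size in sizes.items():
            decoys[f"decoy_{mid}"] = frozenset(pool[:size])
            pool = pool[size:]
    else:
        logger.warning(
            "only %d module-free proteins for %d decoy slots; sampling with "
            "replacement across decoys",
            len(free),
            total_needed,
        )
        for mid, size in sizes.items():
            decoys[f"decoy_{mid}"] = frozenset(
                rng.choice(free, size=min(size, len(free)), replace=False)
            )
    return ModuleCatalog(category=catalog.category, members=decoys)


def permute_within_protein(dataset: AbundanceDataset, seed: int) -> AbundanceDataset:
    """Independently permute each protein's values across samples.

    Missing entries travel with the permutation; per-protein marginals are
    preserved while all inter-protein correlation is destroyed.
    """
    rng = np.random.default_rng(seed)
    arr = dataset.values.to_numpy(dtype=float).copy()
    for i in range(arr.shape[0]):
        arr[i] = arr[i, rng.permutation(arr.shape[1])]
    return dataset.copy_with(
        pd.DataFrame(arr, index=dataset.values.index, columns=dataset.values.columns)
    )


def landscape_consistency(
    datasets: list[AbundanceDataset],
    catalog: ModuleCatalog,
    n_perm: int = 1000,
    seed: int = 0,
    min_members: int = MIN_MEMBERS,
) -> tuple[float, float, np.ndarray]:
    """Cross-dataset Spearman consistency of complex co-abundance ranks.

    Observed pairwise Spearman rho between datasets' complex rank vectors is
    compared (two-sided t) with a null built from within-protein permutations
    of every dataset, re-run through the same ranking.  Returns
    (mean observed rho, p, null rho array).
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets")

    def rank_vectors(dss: list[AbundanceDataset]) -> list[pd.Series]:
        out = []
        for ds in dss:
            recs = complex_median_coabundance(ds, catalog, min_members=min_members)
            out.append(pd.Series({r.module_id: r.rank_fraction for r in recs}))
        return out

    def pairwise_rho(vectors: list[pd.Series]) -> list[float]:
        rhos = []
        for a, b in itertools.combinations(vectors, 2):
            shared = a.index.intersection(b.index)
            if len(shared) < 3:
                continue
            rhos.append(float(stats.spearmanr(a[shared], b[shared]).statistic))
        return rhos

    observed = pairwise_rho(rank_vectors(datasets))
    if not observed:
        raise ValueError("no dataset pair shares enough complexes")
    rng = np.random.default_rng(seed)
    null: list[float] = []
    while len(null) < n_perm:
        permuted = [
            permute_within_protein(ds, int(rng.integers(2**31))) for ds in datasets
        ]
        null.extend(pairwise_rho(rank_vectors(permuted)))
    null_arr = np.array(null[:n_perm] if len(null) > n_perm else null)
    p = observed_vs_null_ttest(observed, null_arr)
    return float(np.mean(observed)), p, null_arr


def bias_diagnostic(
    dataset: AbundanceDataset,
    catalog: ModuleCatalog,
    n_bins: int = 4,
    min_members: int = MIN_MEMBERS,
) -> pd.DataFrame:
    """Median co-abundance per 25% bin of complex abundance and of variance.

    Complexes are rank-sorted by their median subunit abundance (and,
    separately, by median subunit variance) and split into equal-count bins;
    pairwise t-tests between bins flag abundance- or variance-driven bias in
    the co-abundance estimate.
    """
    records = complex_median_coabundance(dataset, catalog, min_members=min_members)
    if len(records) < 2 * n_bins:
        raise ValueError(f"need at least {2 * n_bins} qualifying complexes")
    quantified = set(dataset.proteins)
    rows = []
    for rec in records:
        members = sorted(catalog.members[rec.module_id] & quantified)
        sub = dataset.values.loc[members]
        rows.append(
            {
                "module_id": rec.module_id,
                "median_r": rec.median_r,
                "abundance": float(np.nanmedian(sub.to_numpy())),
                "variance": float(np.nanmedian(sub.var(axis=1, ddof=1))),
            }
        )
    df = pd.DataFrame(rows)
    out = []
    for key in ("abundance", "variance"):
        order = df[key].rank(method="first")
        df[f"{key}_bin"] = pd.qcut(order, n_bins, labels=False)
        groups = [g["median_r"].to_numpy() for _, g in df.groupby(f"{key}_bin")]
        for i, j in itertools.combinations(range(n_bins), 2):
            t, p = stats.ttest_ind(groups[i], groups[j], equal_var=False)
            out.append(
                {
                    "binned_by": key,
                    "bin_a": i,
                    "bin_b": j,
                    "median_r_a": float(np.median(groups[i])),
                    "median_r_b": float(np.median(groups[j])),
                    "t": float(t),
                    "p": float(p),
                }
            )
    return pd.DataFrame(out)
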