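"""Complex-stoichiometry decomposition.

Subtracting a complex's per-sample trimmed-mean subunit abundance (log2
space) from each subunit isolates stoichiometry from overall complex
abundance.  The variance of each subunit's complex-normalized profile,
standardized to a z-score within its complex, separates a complex into a
stable core and variable components; cross-dataset one-sided t-tests call
subunits that are consistently variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AbundanceDataset, ModuleCatalog
from .landscape import permute_within_protein
from .stats import benjamini_hochberg, observed_vs_null_ttest

logger = logging.getLogger(__name__)

TRIM = 0.25  # fraction trimmed from each end of the subunit values (IQR mean)
MIN_QUANTIFIED_SUBUNITS = 3  # per sample, for a defined complex reference
MIN_MEMBERS = 5
DISPLAY_Z = 1.5  # figure-style label threshold


@dataclass
class StoichiometryProfile:
    dataset_id: str
    per_complex: dict[str, pd.DataFrame]  # complex_id -> subunits x samples
    combined: pd.DataFrame  # proteins x samples, multi-complex averaged
    z_table: pd.DataFrame | None = None  # complex_id, protein_id, variance, z


@dataclass
class ComponentCall:
    complex_id: str
    protein_id: str
    label: str  # stable / variable / neutral
    p_value: float
    q_value: float = float("nan")
    z: float = float("nan")
    display_label: str = "neutral"


def trimmed_mean(values: np.ndarray, trim: float = TRIM) -> float:
    """Symmetric trimmed mean: sort, drop floor(trim*k) values per side, average."""
    v = np.sort(np.asarray(values, dtype=float))
    k = v.size
    cut = int(np.floor(trim * k))
    return float(v[cut : k - cut].mean())


def complex_normalize(
    dataset: AbundanceDataset,
    catalog: ModuleCatalog,
    trim: float = TRIM,
    min_quantified_subunits: int = MIN_QUANTIFIED_SUBUNITS,
    min_members: int = MIN_MEMBERS,
) -> StoichiometryProfile:
    """Normalize each subunit by its complex's per-sample trimmed mean.

    A sample's reference is defined only when >= ``min_quantified_subunits``
    subunits are quantified in it.  Proteins belonging to several complexes
    receive the average of their per-complex normalized values in the
    combined matrix.
    """
    quantified = set(dataset.proteins)
    per_complex: dict[str, pd.DataFrame] = {}
    for mid, members in catalog.members.items():
        subunits = sorted(members & quantified)
        if len(subunits) < min_members:
            continue
        sub = dataset.values.loc[subunits]
        arr = sub.to_numpy(dtype=float)
        ref = np.full(arr.shape[1], np.nan)
        for s in range(arr.shape[1]):
            col = arr[:, s]
            col = col[np.isfinite(col)]
            if col.size >= min_quantified_subunits:
                ref[s] = trimmed_mean(col, trim)
        per_complex[mid] = pd.DataFrame(
            arr - ref[None, :], index=sub.index, columns=sub.columns
        )
    # multi-complex proteins: average normalized value across their complexes
    all_proteins = sorted({p for df in per_complex.values() for p in df.index})
    combined = pd.DataFrame(
        np.nan, index=all_proteins, columns=dataset.values.columns, dtype=float
    )
    if all_proteins:
        acc = np.zeros((len(all_proteins), dataset.n_samples))
        cnt = np.zeros_like(acc)
        row = {p: i for i, p in enumerate(all_proteins)}
        for df in per_complex.values():
            vals = df.to_numpy(dtype=float)
            idx = [row[p] for p in df.index]
            finite = np.isfinite(vals)
            acc[idx] += np.where(finite, vals, 0.0)
            cnt[idx] += finite
        with np.errstate(invalid="ignore"):
            combined.loc[:, :] = np.where(cnt > 0, acc / cnt, np.nan)
    return StoichiometryProfile(
        dataset_id=dataset.dataset_id, per_complex=per_complex, combined=combined
    )


def subunit_variance_zscores(
    profile: StoichiometryProfile,
    min_sample_fraction: float = 0.5,
    min_subunits: int = 3,
) -> StoichiometryProfile:
    """Variance of each subunit's normalized values, standardized per complex.

    Subunits with normalized values in fewer than ``min_sample_fraction`` of
    samples are excluded; complexes with fewer than ``min_subunits`` eligible
    subunits are skipped.  An all-equal-variance complex gets z = 0.
    """
    rows = []
    for mid, df in profile.per_complex.items():
        frac = df.notna().mean(axis=1)
        eligible = df.loc[frac >= min_sample_fraction]
        if eligible.shape[0] < min_subunits:
            continue
        variances = eligible.var(axis=1, ddof=1)
        sd = variances.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            z = pd.Series(0.0, index=variances.index)
        else:
            z = (variances - variances.mean()) / sd
        for p in variances.index:
            rows.append(
                {
                    "complex_id": mid,
                    "protein_id": p,
                    "variance": float(variances[p]),
                    "z": float(z[p]),
                }
            )
    profile.z_table = pd.DataFrame(
        rows, columns=["complex_id", "protein_id", "variance", "z"]
    )
    return profile


def call_components_within_dataset(
    profile: StoichiometryProfile,
    alpha: float = 0.05,
    display_threshold: float = DISPLAY_Z,
) -> list[ComponentCall]:
    """Label subunits by one-sided standard-normal tail probability of z.

    Upper-tail p <= alpha -> variable, lower-tail p <= alpha -> stable, else
    neutral.  Display labels additionally flag |z| > ``display_threshold``.
    """
    if profile.z_table is None:
        raise ValueError("run subunit_variance_zscores first")
    calls = []
    for row in profile.z_table.itertuples():
        upper = float(stats.norm.sf(row.z))
        lower = float(stats.norm.cdf(row.z))
        if upper <= alpha:
            label, p = "variable", upper
        elif lower <= alpha:
            label, p = "stable", lower
        else:
            label, p = "neutral", min(upper, lower)
        if row.z > display_threshold:
            display = "variable"
        elif row.z < -display_threshold:
            display = "stable"
        else:
            display = "neutral"
        calls.append(
            ComponentCall(
                complex_id=row.complex_id,
                protein_id=row.protein_id,
                label=label,
                p_value=p,
                z=float(row.z),
                display_label=display,
            )
        )
    return calls


def cross_dataset_component_test(
    profiles: list[StoichiometryProfile],
) -> pd.DataFrame:
    """Consistently-variable subunit calls across datasets.

    Per (complex, protein) observed in >= 2 datasets: Welch one-sided t-test
    of the protein's z values against the pooled z of all other subunits of
    the same complex across all datasets (alternative: greater, i.e. more
    variable).  BH adjustment across all tested pairs.
    """
    z_long = pd.concat(
        [
            p.z_table.assign(dataset_id=p.dataset_id)
            for p in profiles
            if p.z_table is not None and not p.z_table.empty
        ],
        ignore_index=True,
    )
    rows = []
    for (mid, prot), grp in z_long.groupby(["complex_id", "protein_id"]):
        own = grp["z"].to_numpy()
        rec = {
            "complex_id": mid,
            "protein_id": prot,
            "n_datasets": own.size,
            "mean_z": float(own.mean()),
        }
        if own.size < 2:
            rec.update(p_value=np.nan)
        else:
            siblings = z_long[
                (z_long["complex_id"] == mid) & (z_long["protein_id"] != prot)
            ]["z"].to_numpy()
            if siblings.size < 2:
                rec.update(p_value=np.nan)
            else:
                res = stats.ttest_ind(
                    own, siblings, equal_var=False, alternative="greater"
                )
                rec.update(p_value=float(res.pvalue))
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["q_value"] = benjamini_hochberg(out["p_value"])
    return out


def _z_series(profile: StoichiometryProfile) -> pd.Series:
    zt = profile.z_table
    return pd.Series(
        zt["z"].to_numpy(),
        index=pd.MultiIndex.from_frame(zt[["complex_id", "protein_id"]]),
    )


def zscore_consistency(
    datasets: list[AbundanceDataset],
    catalog: ModuleCatalog,
    n_perm: int = 1000,
    seed: int = 0,
    min_shared: int = 10,
    **normalize_kwargs,
) -> tuple[float, float, np.ndarray]:
    """Cross-dataset consistency of subunit-variance z-score matrices.

    Observed pairwise Pearson r between matched (complex, subunit) z vectors,
    compared (two-sided t) with a null from within-protein permutations of
    the abundance data re-run through normalization and z-scoring.
    """
    import itertools as it

    def z_vectors(dss):
        out = []
        for ds in dss:
            prof = subunit_variance_zscores(
                complex_normalize(ds, catalog, **normalize_kwargs)
            )
            out.append(_z_series(prof))
        return out

    def pairwise_r(vectors):
        rs = []
        for a, b in it.combinations(vectors, 2):
            shared = a.index.intersection(b.index)
            if len(shared) < min_shared:
                continue
            rs.append(float(np.corrcoef(a[shared], b[shared])[0, 1]))
        return rs

    observed = pairwise_r(z_vectors(datasets))
    if not observed:
        raise ValueError("no dataset pair shares enough (complex, subunit) entries")
    rng = np.random.default_rng(seed)
    null: list[float] = []
    while len(null) < n_perm:
        permuted = [
            permute_within_protein(ds, int(rng.integers(2**31))) for ds in datasets
        ]
        null.extend(pairwise_r(z_vectors(permuted)))
    null_arr = np.asarray(null[:n_perm])
    p = observed_vs_null_ttest(observed, null_arr)
    return float(np.mean(observed)), p, null_arr
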