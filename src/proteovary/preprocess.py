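"""Sample-distribution diagnostics and normalization.

Each sample is screened with the Shapiro-Wilk test; datasets in which a
non-trivial fraction of samples deviate from normality are log2-transformed
(if still on linear scale) and quantile-normalized.  Quantile normalization
follows the classic algorithm: the k-th smallest value in every sample is
replaced by the mean of the k-th smallest values across samples.  Samples
with missing entries are normalized on their own rank grid against the mean
quantile curve by linear interpolation, so the missingness pattern is
preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AbundanceDataset, Scale

SHAPIRO_SUBSAMPLE = 5000


@dataclass
class NormalityReport:
    sample_id: str
    n_values: int
    shapiro_w: float  # NaN when untested
    p_value: float  # NaN when untested
    tested: bool


def assess_normality(
    dataset: AbundanceDataset, seed: int = 0
) -> list[NormalityReport]:
    """Shapiro-Wilk W and p per sample, on non-missing values.

    Samples with more than SHAPIRO_SUBSAMPLE values are subsampled (seeded);
    samples with fewer than 3 values are flagged untested.
    """
    rng = np.random.default_rng(seed)
    reports = []
    for sample in dataset.samples:
        vals = dataset.values[sample].dropna().to_numpy()
        if vals.size < 3:
            reports.append(
                NormalityReport(sample, int(vals.size), float("nan"), float("nan"), False)
            )
            continue
        if vals.size > SHAPIRO_SUBSAMPLE:
            vals = rng.choice(vals, size=SHAPIRO_SUBSAMPLE, replace=False)
        w, p = stats.shapiro(vals)
        reports.append(NormalityReport(sample, int(vals.size), float(w), float(p), True))
    return reports


def normality_report_frame(reports: list[NormalityReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "n_values": r.n_values,
                "shapiro_w": r.shapiro_w,
                "p_value": r.p_value,
                "tested": r.tested,
            }
            for r in reports
        ]
    )


def needs_normalization(
    reports: list[NormalityReport], p_cutoff: float = 0.01, fraction: float = 0.10
) -> bool:
    """Normalize when more than `fraction` of tested samples reject normality."""
    tested = [r for r in reports if r.tested]
    if not tested:
        return False
    n_reject = sum(r.p_value < p_cutoff for r in tested)
    return n_reject > fraction * len(tested)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization of a proteins x samples matrix.

    Complete samples end up with identical sorted value vectors.  Samples of
    unequal size (missing data) map their empirical quantiles onto the mean
    quantile curve by linear interpolation.  Ties within a sample receive the
    mean of the values they would have received.
    """
    arr = values.to_numpy(dtype=float)
    n_prot, n_samp = arr.shape
    counts = (~np.isnan(arr)).sum(axis=0)
    if (counts == 0).any():
        raise ValueError("cannot quantile-normalize a sample with no values")
    max_k = int(counts.max())
    grid = np.linspace(0.0, 1.0, max_k) if max_k > 1 else np.array([0.5])
    # mean quantile curve on the common grid
    curves = np.empty((n_samp, grid.size))
    for j in range(n_samp):
        col = np.sort(arr[~np.isnan(arr[:, j]), j])
        k = col.size
        if k == 1:
            curves[j] = col[0]
        else:
            q = np.linspace(0.0, 1.0, k)
            curves[j] = np.interp(grid, q, col)
    ref = curves.mean(axis=0)
    out = np.full_like(arr, np.nan)
    for j in range(n_samp):
        mask = ~np.isnan(arr[:, j])
        col = arr[mask, j]
        k = col.size
        q = np.linspace(0.0, 1.0, k) if k > 1 else np.array([0.5])
        target = np.interp(q, grid, ref)
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(k)
        assigned[order] = target
        # ties share the mean of their would-be values
        sorted_col = col[order]
        i = 0
        while i < k:
            j2 = i
            while j2 + 1 < k and sorted_col[j2 + 1] == sorted_col[i]:
                j2 += 1
            if j2 > i:
                assigned[order[i : j2 + 1]] = target[i : j2 + 1].mean()
            i = j2 + 1
        out[mask, j] = assigned
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def log_and_quantile_normalize(dataset: AbundanceDataset) -> AbundanceDataset:
    """log2 transform (linear-scale input only) followed by quantile normalization."""
    if dataset.scale is Scale.LINEAR:
        arr = dataset.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=np.inf) <= 0:
            raise ValueError("non-positive value under scale=linear")
        values = pd.DataFrame(
            np.log2(arr), index=dataset.values.index, columns=dataset.values.columns
        )
    else:
        values = dataset.values
    return dataset.copy_with(quantile_normalize(values), scale=Scale.LOG2)


def preprocess(
    dataset: AbundanceDataset,
    force_normalize: bool | None = None,
    p_cutoff: float = 0.01,
    fraction: float = 0.10,
    seed: int = 0,
) -> tuple[AbundanceDataset, list[NormalityReport]]:
    """Conditional normalization: applied only when the Shapiro-Wilk screen
    flags more than `fraction` of samples (or when forced)."""
    reports = assess_normality(dataset, seed=seed)
    if force_normalize is None:
        do_norm = needs_normalization(reports, p_cutoff=p_cutoff, fraction=fraction)
    else:
        do_norm = force_normalize
    if do_norm:
        out = log_and_quantile_normalize(dataset)
    elif dataset.scale is Scale.LINEAR:
        arr = dataset.values.to_numpy(dtype=float)
        out = dataset.copy_with(
            pd.DataFrame(
                np.log2(arr), index=dataset.values.index, columns=dataset.values.columns
            ),
            scale=Scale.LOG2,
        )
    else:
        out = dataset
    return out, reports


def filter_by_completeness(
    dataset: AbundanceDataset, min_fraction: float = 0.5
) -> AbundanceDataset:
    """Drop proteins quantified in fewer than ``min_fraction`` of samples."""
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    frac = dataset.values.notna().mean(axis=1)
    kept = dataset.values.loc[frac >= min_fraction]
    if kept.empty:
        raise ValueError("completeness filter removed every protein")
    return dataset.copy_with(kept)
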