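"""Recovery of known functional modules from protein co-abundance.

For a dataset and a module category (complex, pathway, interaction, ...),
protein pairs inside the same module are condition positives and an
equally-sized random sample of module-free pairs are condition negatives.
Pairwise Pearson correlations of log2 abundances are swept through descending
thresholds to build a ROC curve; the area under it (trapezoidal rule)
summarizes how well co-abundance recovers the category.  A repeated
subsampled one-sided Mann-Whitney U test gives a conservative companion
p-value.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AbundanceDataset,
    InteractionTable,
    ModuleCatalog,
    ModuleCategory,
    canonical_pair,
)

logger = logging.getLogger(__name__)

MIN_OVERLAP = 6  # minimum jointly-quantified samples for a pair correlation
HIGH_CONFIDENCE_SCORE = 0.7  # STRING combined-score cutoff for "high confidence"


@dataclass
class PairCorrelation:
    protein_a: str
    protein_b: str
    r: float
    n_overlap: int


@dataclass
class CovariationRecord:
    dataset_id: str
    category: str
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float = float("nan")
    n_positives: int = 0
    n_negatives: int = 0
    mwu_mean_p: float = float("nan")


def pairwise_correlations(
    dataset: AbundanceDataset,
    pairs,
    min_overlap: int = MIN_OVERLAP,
) -> list[PairCorrelation]:
    """Pearson r over jointly non-missing samples for each requested pair.

    Pairs with overlap below ``min_overlap`` or a zero-variance member are
    omitted (the latter with a warning).
    """
    pairs = list(pairs)
    arr = dataset.values.to_numpy(dtype=float)
    row = {p: i for i, p in enumerate(dataset.proteins)}
    ia = np.array([row[a] for a, b in pairs], dtype=int)
    ib = np.array([row[b] for a, b in pairs], dtype=int)
    x, y = arr[ia], arr[ib]
    mask = np.isfinite(x) & np.isfinite(y)
    n = mask.sum(axis=1)
    x0 = np.where(mask, x, 0.0)
    y0 = np.where(mask, y, 0.0)
    sx, sy = x0.sum(1), y0.sum(1)
    sxx, syy, sxy = (x0 * x0).sum(1), (y0 * y0).sum(1), (x0 * y0).sum(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vx = n * sxx - sx * sx
        vy = n * syy - sy * sy
        r = (n * sxy - sx * sy) / np.sqrt(vx * vy)
    out: list[PairCorrelation] = []
    n_zero_var = 0
    for k, (a, b) in enumerate(pairs):
        if n[k] < min_overlap:
            continue
        if vx[k] <= 0 or vy[k] <= 0:
            n_zero_var += 1
            continue
        out.append(PairCorrelation(a, b, float(np.clip(r[k], -1.0, 1.0)), int(n[k])))
    if n_zero_var:
        logger.warning("omitted %d pairs with a zero-variance member", n_zero_var)
    return out


def _module_pairs(catalog: ModuleCatalog, quantified: set[str]) -> set[tuple[str, str]]:
    pairs: set[tuple[str, str]] = set()
    for mem in catalog.members.values():
        q = sorted(mem & quantified)
        pairs.update(
            canonical_pair(a, b) for a, b in itertools.combinations(q, 2)
        )
    return pairs


def catalog_from_flags(
    flagged: set[str], category: ModuleCategory | str
) -> ModuleCatalog:
    """One-module catalog for flag-style categories (housekeeping, essential)."""
    return ModuleCatalog(
        category=ModuleCategory(category), members={str(category): frozenset(flagged)}
    )


def build_condition_sets(
    source: ModuleCatalog | InteractionTable,
    quantified,
    seed: int,
    complexes: ModuleCatalog | None = None,
    score_cutoff: float = HIGH_CONFIDENCE_SCORE,
) -> tuple[set[tuple[str, str]], list[tuple[str, str]]]:
    """Condition positives and an equally-sized seeded sample of negatives.

    Positives are within-module pairs of the category (for an interaction
    table: pairs above ``score_cutoff``); for pathways, pairs that co-occur in
    any complex are removed from the positives.  Negatives are drawn uniformly
    without replacement from quantified pairs belonging to no module of the
    category.
    """
    quantified = sorted(set(quantified))
    qset = set(quantified)
    if isinstance(source, InteractionTable):
        in_any = {
            canonical_pair(a, b)
            for (a, b) in source.scores
            if a in qset and b in qset
        }
        positives = {
            canonical_pair(a, b)
            for (a, b), s in source.scores.items()
            if s > score_cutoff and a in qset and b in qset
        }
        forbidden = in_any  # pairs with any reported interaction are not negatives
    else:
        positives = _module_pairs(source, qset)
        forbidden = set(positives)
        if source.category is ModuleCategory.PATHWAY and complexes is not None:
            complex_pairs = _module_pairs(complexes, qset)
            positives = positives - complex_pairs
            forbidden |= complex_pairs
    n_pos = len(positives)
    n_prot = len(quantified)
    total_pairs = n_prot * (n_prot - 1) // 2
    available = total_pairs - len(forbidden)
    if available < n_pos:
        raise ValueError(
            f"only {available} candidate negatives for {n_pos} positives"
        )
    rng = np.random.default_rng(seed)
    negatives: set[tuple[str, str]] = set()
    while len(negatives) < n_pos:
        draw = max(2 * (n_pos - len(negatives)), 100)
        ii = rng.integers(0, n_prot, size=draw)
        jj = rng.integers(0, n_prot, size=draw)
        for i, j in zip(ii, jj):
            if i == j:
                continue
            pair = canonical_pair(quantified[i], quantified[j])
            if pair in forbidden or pair in negatives:
                continue
            negatives.add(pair)
            if len(negatives) == n_pos:
                break
    return positives, sorted(negatives)


def roc_curve_points(
    pos_r, neg_r
) -> tuple[list[tuple[float, float]], float]:
    """ROC by descending threshold sweep over observed r values; trapezoid AUC.

    All pairs tied at a threshold cross it together, so ties contribute
    diagonal segments (equivalent to counting tied positive/negative pairs
    as half-concordant).
    """
    pos = np.asarray([v for v in pos_r if np.isfinite(v)], dtype=float)
    neg = np.asarray([v for v in neg_r if np.isfinite(v)], dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both positive and negative score lists must be non-empty")
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    # cumulative counts >= threshold via searchsorted on sorted arrays
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    tp = pos.size - np.searchsorted(pos_sorted, thresholds, side="left")
    fp = neg.size - np.searchsorted(neg_sorted, thresholds, side="left")
    tpr = np.concatenate([[0.0], tp / pos.size, [1.0]])
    fpr = np.concatenate([[0.0], fp / neg.size, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def subsampled_mwu(
    pos_r,
    neg_r,
    n_iter: int = 1000,
    n_sample: int = 1000,
    seed: int = 0,
) -> float:
    """Mean one-sided Mann-Whitney U p over repeated subsamples.

    Each iteration draws ``n_sample`` items from each list (with replacement
    when a list is shorter than ``n_sample``) and tests whether positives are
    shifted higher.
    """
    pos = np.asarray([v for v in pos_r if np.isfinite(v)], dtype=float)
    neg = np.asarray([v for v in neg_r if np.isfinite(v)], dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both lists must be non-empty")
    rng = np.random.default_rng(seed)
    ps = np.empty(n_iter)
    for i in range(n_iter):
        ps_pos = rng.choice(pos, size=n_sample, replace=pos.size < n_sample)
        ps_neg = rng.choice(neg, size=n_sample, replace=neg.size < n_sample)
        ps[i] = stats.mannwhitneyu(ps_pos, ps_neg, alternative="greater").pvalue
    return float(ps.mean())


def covariation_record(
    dataset: AbundanceDataset,
    source: ModuleCatalog | InteractionTable,
    category: str,
    seed: int,
    complexes: ModuleCatalog | None = None,
    min_overlap: int = MIN_OVERLAP,
    mwu_iter: int = 100,
    mwu_sample: int = 1000,
    min_positive_pairs: int = 100,
    score_cutoff: float = HIGH_CONFIDENCE_SCORE,
) -> CovariationRecord:
    """Full ROC/AUC + subsampled-MWU record for one dataset x category."""
    quantified = set(dataset.proteins)
    positives, negatives = build_condition_sets(
        source, quantified, seed=seed, complexes=complexes, score_cutoff=score_cutoff
    )
    rec = CovariationRecord(dataset_id=dataset.dataset_id, category=category)
    pos_corr = pairwise_correlations(dataset, sorted(positives), min_overlap)
    neg_corr = pairwise_correlations(dataset, negatives, min_overlap)
    rec.n_positives = len(pos_corr)
    rec.n_negatives = len(neg_corr)
    if rec.n_positives < min_positive_pairs:
        logger.warning(
            "dataset %s category %s: only %d positive pairs (< %d); AUC not reported",
            dataset.dataset_id,
            category,
            rec.n_positives,
            min_positive_pairs,
        )
        return rec
    pos_r = [c.r for c in pos_corr]
    neg_r = [c.r for c in neg_corr]
    rec.roc_points, rec.auc = roc_curve_points(pos_r, neg_r)
    rec.mwu_mean_p = subsampled_mwu(
        pos_r, neg_r, n_iter=mwu_iter, n_sample=mwu_sample, seed=seed + 1
    )
    return rec


def recovery_matrix(
    datasets: list[AbundanceDataset],
    categories: dict[str, ModuleCatalog | InteractionTable],
    seed: int,
    complexes: ModuleCatalog | None = None,
    min_positive_pairs: int = 100,
    **kwargs,
) -> pd.DataFrame:
    """AUC table (datasets x categories), columns ordered by mean AUC descending."""
    rows = {}
    for k, ds in enumerate(datasets):
        row = {}
        for j, (cat, source) in enumerate(sorted(categories.items())):
            rec = covariation_record(
                ds,
                source,
                cat,
                seed=seed + 1000 * k + j,
                complexes=complexes,
                min_positive_pairs=min_positive_pairs,
                **kwargs,
            )
            row[cat] = rec.auc
        rows[ds.dataset_id] = row
    table = pd.DataFrame(rows).T
    order = table.mean(axis=0, skipna=True).sort_values(ascending=False).index
    return table[order]
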