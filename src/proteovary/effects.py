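"""Variance in module abundance/stoichiometry explained by sex and diet.

Each module (complex or co-abundant pathway) response — its median abundance
or its complex-normalized subunit vectors — is predicted from binary-coded
sex / diet / sex+diet by ridge regression (penalty on the slopes only,
intercept unpenalized, regularization parameter 1) under a repeated 10-fold
cross-validation scheme.  The effect size is the median "global R^2":
1 - SS_res/SS_tot on the pooled out-of-fold predictions.  Significance comes
from re-running the identical pipeline on predictor-reshuffled data and
converting the resulting null R^2 distribution into an empirical FDR.

The closed-form ridge solve (slopes = (Xc'Xc + alpha I)^-1 Xc'y on centered
data) keeps the permutation loops fast; it is numerically identical to the
textbook estimator.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import AbundanceDataset, ModuleCatalog, SampleMetadata
from .landscape import permute_within_protein
from .recovery import MIN_OVERLAP, pairwise_correlations
from .stats import benjamini_hochberg, empirical_p

logger = logging.getLogger(__name__)

PREDICTOR_SETS = {"sex": ["sex"], "diet": ["diet"], "sex_plus_diet": ["sex", "diet"]}
PREDICTOR_CODES = {"sex": {"female": 0.0, "male": 1.0},
                   "diet": {"chow": 0.0, "high_fat": 1.0}}


@dataclass
class RidgeSpec:
    alpha: float = 1.0
    k_folds: int = 10
    n_repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


def ridge_fit(X: np.ndarray, y: np.ndarray, alpha: float = 1.0):
    """Ridge with unpenalized intercept: returns (intercept, slopes)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    beta = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(X.shape[1]), Xc.T @ (y - ym))
    return float(ym - xm @ beta), beta


def encode_predictors(
    metadata: SampleMetadata, samples: list[str], predictor_set: str
) -> tuple[np.ndarray, np.ndarray]:
    """Binary predictor matrix for the named set; returns (X, valid mask)."""
    factors = PREDICTOR_SETS[predictor_set]
    cols, valid = [], np.ones(len(samples), dtype=bool)
    for f in factors:
        codes = PREDICTOR_CODES.get(f)
        levels = metadata.levels(f, samples)
        if codes is None:
            uniq = sorted(x for x in levels.dropna().unique() if x != "unknown")
            if len(uniq) != 2:
                raise ValueError(f"factor {f!r} must have exactly 2 levels")
            codes = {uniq[0]: 0.0, uniq[1]: 1.0}
        cols.append(levels.map(codes).to_numpy(dtype=float))
        valid &= levels.isin(list(codes)).to_numpy()
    X = np.column_stack(cols)
    X[~valid] = np.nan
    return X, valid


def _stratified_folds(
    X: np.ndarray, k: int, rng: np.random.Generator, max_tries: int = 100
) -> np.ndarray:
    """Fold labels stratified by the predictor-level combination of each row.

    Redraws (up to ``max_tries``) if any training split misses a predictor
    level entirely.
    """
    n = X.shape[0]
    combo = [tuple(row) for row in X]
    for _ in range(max_tries):
        folds = np.empty(n, dtype=int)
        for c in set(combo):
            idx = np.array([i for i, v in enumerate(combo) if v == c])
            idx = rng.permutation(idx)
            folds[idx] = (np.arange(idx.size) + rng.integers(k)) % k
        ok = True
        for f in range(k):
            train = X[folds != f]
            if train.shape[0] < 2 or any(
                np.unique(train[:, j]).size < 2 for j in range(X.shape[1])
            ):
                ok = False
                break
        if ok:
            return folds
    raise ValueError("could not build folds with every predictor level in training")


def _cv_r2_once(
    X: np.ndarray, y: np.ndarray, spec: RidgeSpec, rng: np.random.Generator
) -> float:
    k = min(spec.k_folds, y.size)
    folds = _stratified_folds(X, k, rng)
    yhat = np.empty_like(y)
    for f in range(k):
        tr, te = folds != f, folds == f
        icpt, beta = ridge_fit(X[tr], y[tr], spec.alpha)
        yhat[te] = icpt + X[te] @ beta
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


def ridge_cv_r2(
    responses,
    X: np.ndarray,
    valid: np.ndarray,
    spec: RidgeSpec,
) -> float:
    """Median global R^2 over repeated fold assignments (and response vectors).

    ``responses`` is a sequence of sample-aligned vectors (one for an
    abundance readout; the complex's subunit vectors for stoichiometry).
    Missing entries are dropped casewise per vector.
    """
    rng = np.random.default_rng(spec.seed)
    per_response = []
    for y in responses:
        y = np.asarray(y, dtype=float)
        mask = np.isfinite(y) & valid
        if mask.sum() < 2 * spec.k_folds:
            # too few complete cases for a k-fold split
            k_eff = max(2, int(mask.sum() // 3))
            if mask.sum() < 6:
                continue
            local = RidgeSpec(spec.alpha, k_eff, spec.n_repeats, spec.seed)
        else:
            local = spec
        vals = [
            _cv_r2_once(X[mask], y[mask], local, rng) for _ in range(spec.n_repeats)
        ]
        vals = [v for v in vals if np.isfinite(v)]
        if vals:
            per_response.append(float(np.median(vals)))
    if not per_response:
        return float("nan")
    return float(np.median(per_response))


def select_coabundant_pathways(
    dataset: AbundanceDataset,
    pathways: ModuleCatalog,
    n_perm: int = 100,
    seed: int = 0,
    min_members: int = 5,
    fdr: float = 0.1,
    min_overlap: int = MIN_OVERLAP,
) -> ModuleCatalog:
    """Keep pathways whose median pairwise r beats a reshuffled-data null.

    Per pathway: the observed median pairwise Pearson r is compared with the
    same statistic on ``n_perm`` within-protein-permuted datasets; the
    plus-one empirical p-values are BH-adjusted and pathways with q below
    ``fdr`` are retained.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    quantified = set(dataset.proteins)

    def median_rs(ds: AbundanceDataset) -> dict[str, float]:
        out = {}
        for mid, members in pathways.members.items():
            q = sorted(members & quantified)
            if len(q) < min_members:
                continue
            corr = pairwise_correlations(
                ds, list(itertools.combinations(q, 2)), min_overlap
            )
            if corr:
                out[mid] = float(np.median([c.r for c in corr]))
        return out

    observed = median_rs(dataset)
    if not observed:
        return ModuleCatalog(category=pathways.category, members={})
    rng = np.random.default_rng(seed)
    null: dict[str, list[float]] = {m: [] for m in observed}
    for _ in range(n_perm):
        perm = permute_within_protein(dataset, int(rng.integers(2**31)))
        for mid, r in median_rs(perm).items():
            if mid in null:
                null[mid].append(r)
    mids = sorted(observed)
    pvals = [empirical_p(np.array(null[m]), observed[m]) for m in mids]
    qvals = benjamini_hochberg(pvals)
    kept = {m: pathways.members[m] for m, q in zip(mids, qvals) if q < fdr}
    return ModuleCatalog(category=pathways.category, members=kept)


def permutation_fdr(
    observed: dict[str, float],
    responses: dict[str, list[np.ndarray]],
    X: np.ndarray,
    valid: np.ndarray,
    spec: RidgeSpec,
    n_perm: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical p and BH FDR for observed module R^2 against permuted predictors.

    Per module the predictor rows are reshuffled across samples ``n_perm``
    times and the full ridge-CV pipeline re-run; empirical p uses the
    plus-one estimator, bounded below by 1/(n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for mid in sorted(observed):
        obs = observed[mid]
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(X.shape[0])
            local = RidgeSpec(
                spec.alpha, spec.k_folds, spec.n_repeats, int(rng.integers(2**31))
            )
            null[b] = ridge_cv_r2(
                responses[mid], X[perm], valid[perm], local
            )
        p = empirical_p(null[np.isfinite(null)], obs)
        rows.append({"module_id": mid, "r2": obs, "empirical_p": p})
    out = pd.DataFrame(rows)
    out["fdr_q"] = benjamini_hochberg(out["empirical_p"])
    return out


def effect_size_table(
    dataset: AbundanceDataset,
    metadata: SampleMetadata,
    complexes: ModuleCatalog,
    profile=None,
    pathways: ModuleCatalog | None = None,
    spec: RidgeSpec | None = None,
    n_perm: int = 0,
    include_proteins: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Full grid of effect-size records: module x predictor set x readout.

    Readouts: ``abundance`` (median module abundance per sample),
    ``stoichiometry`` (complex-normalized subunit vectors; needs ``profile``),
    and optionally per-protein ``protein`` records.  With ``n_perm > 0`` each
    cell also gets a permutation empirical p and BH FDR (adjusted within each
    readout x predictor-set stratum).
    """
    from .covariates import complex_median_abundance
    from .stoichiometry import complex_normalize

    spec = spec or RidgeSpec(seed=seed)
    samples = list(dataset.samples)
    responses: dict[tuple[str, str], list[np.ndarray]] = {}

    def add_module_responses(catalog: ModuleCatalog, prof) -> None:
        medians = complex_median_abundance(dataset, catalog)
        for mid in medians.index:
            responses[(mid, "abundance")] = [medians.loc[mid].to_numpy(dtype=float)]
        if prof is not None:
            for mid, df_c in prof.per_complex.items():
                responses[(mid, "stoichiometry")] = [
                    df_c.loc[p].to_numpy(dtype=float) for p in df_c.index
                ]

    add_module_responses(complexes, profile)
    if pathways is not None and len(pathways):
        add_module_responses(pathways, complex_normalize(dataset, pathways))
    if include_proteins:
        for p in dataset.proteins:
            responses[(p, "protein")] = [dataset.values.loc[p].to_numpy(dtype=float)]

    rows = []
    for pset in PREDICTOR_SETS:
        X, valid = encode_predictors(metadata, samples, pset)
        Xv = np.nan_to_num(X)
        for j, ((mid, readout), vecs) in enumerate(sorted(responses.items())):
            local = RidgeSpec(spec.alpha, spec.k_folds, spec.n_repeats, spec.seed + j)
            r2 = ridge_cv_r2(vecs, Xv, valid, local)
            rows.append(
                {
                    "module_id": mid,
                    "readout": readout,
                    "predictor_set": pset,
                    "r2": r2,
                    "variance_explained_pct": max(r2, 0.0) * 100.0
                    if np.isfinite(r2)
                    else np.nan,
                }
            )
    out = pd.DataFrame(rows)
    if n_perm > 0:
        out["empirical_p"] = np.nan
        out["fdr_q"] = np.nan
        for (pset, readout), grp in out.groupby(["predictor_set", "readout"]):
            X, valid = encode_predictors(metadata, samples, pset)
            Xv = np.nan_to_num(X)
            obs = {
                r.module_id: r.r2
                for r in grp.itertuples()
                if np.isfinite(r.r2)
            }
            resp = {m: responses[(m, readout)] for m in obs}
            pset_offset = sorted(PREDICTOR_SETS).index(pset)
            fdr = permutation_fdr(
                obs, resp, Xv, valid, spec, n_perm=n_perm, seed=seed + pset_offset
            )
            for r in fdr.itertuples():
                sel = (
                    (out["module_id"] == r.module_id)
                    & (out["predictor_set"] == pset)
                    & (out["readout"] == readout)
                )
                out.loc[sel, "empirical_p"] = r.empirical_p
                out.loc[sel, "fdr_q"] = r.fdr_q
    return out
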