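"""Sex- and diet-dependence of complex abundance and stoichiometry.

Abundance: per-complex median log2 abundance per sample, two-sided two-sample
t-tests per factor with Cohen's d effect sizes and BH adjustment.

Stoichiometry: per-subunit ordinary least squares on an additive
intercept + sex + diet design of the complex-normalized values, with
empirical-Bayes variance moderation.  The prior (d0, s0^2) is estimated by
the method of moments on log residual variances: the mean and variance of
log s^2 are matched to the moments of log of a scaled F / chi-square
variate, exactly the standard moderated-t construction.  Per-complex verdicts
combine component q-values with Fisher's method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .datatypes import AbundanceDataset, ModuleCatalog, SampleMetadata
from .stats import benjamini_hochberg, cohens_d, fisher_combine
from .stoichiometry import StoichiometryProfile

logger = logging.getLogger(__name__)

# declared level orders: effect sign = mean(level1) - mean(level2)
FACTOR_LEVELS = {"sex": ("male", "female"), "diet": ("high_fat", "chow")}
SIGNIFICANCE_Q = 0.01


def complex_median_abundance(
    dataset: AbundanceDataset,
    catalog: ModuleCatalog,
    min_quantified_fraction: float = 0.5,
    min_members: int = 5,
) -> pd.DataFrame:
    """Median log2 abundance of each complex per sample.

    Subunits quantified in fewer than ``min_quantified_fraction`` of samples
    are excluded before the median; complexes with fewer than ``min_members``
    eligible subunits are skipped.
    """
    quantified = set(dataset.proteins)
    rows = {}
    for mid, members in catalog.members.items():
        subunits = sorted(members & quantified)
        sub = dataset.values.loc[subunits]
        eligible = sub.loc[sub.notna().mean(axis=1) >= min_quantified_fraction]
        if eligible.shape[0] < min_members:
            continue
        rows[mid] = eligible.median(axis=0, skipna=True)
    return pd.DataFrame(rows).T if rows else pd.DataFrame(columns=dataset.samples)


def differential_module_abundance(
    module_medians: pd.DataFrame,
    metadata: SampleMetadata,
    factor: str,
    min_per_level: int = 3,
) -> pd.DataFrame:
    """Two-sided t-test + Cohen's d per module for a two-level factor.

    Returns module_id, factor, cohen_d, t_stat, p_value, q_value,
    significant (q < 0.01).  Effect sign follows the declared level order
    (male - female, high_fat - chow).
    """
    lvl1, lvl2 = FACTOR_LEVELS.get(factor, (None, None))
    groups = metadata.factor_groups(factor, list(module_medians.columns))
    if lvl1 is None:
        lvls = sorted(groups)
        if len(lvls) != 2:
            raise ValueError(f"factor {factor!r} must have exactly 2 levels")
        lvl1, lvl2 = lvls
    for lvl in (lvl1, lvl2):
        if len(groups.get(lvl, [])) < min_per_level:
            raise ValueError(
                f"factor {factor!r} level {lvl!r} has fewer than "
                f"{min_per_level} samples"
            )
    rows = []
    for mid in module_medians.index:
        x = module_medians.loc[mid, groups[lvl1]].dropna().to_numpy(dtype=float)
        y = module_medians.loc[mid, groups[lvl2]].dropna().to_numpy(dtype=float)
        if x.size < 2 or y.size < 2:
            rows.append((mid, np.nan, np.nan, np.nan))
            continue
        d = cohens_d(x, y)
        if np.isnan(d):
            logger.warning("module %s: zero pooled variance; p undefined", mid)
            rows.append((mid, np.nan, np.nan, np.nan))
            continue
        t, p = stats.ttest_ind(x, y)
        rows.append((mid, d, float(t), float(p)))
    out = pd.DataFrame(rows, columns=["module_id", "cohen_d", "t_stat", "p_value"])
    out.insert(1, "factor", factor)
    out["q_value"] = benjamini_hochberg(out["p_value"])
    out["significant"] = out["q_value"] < SIGNIFICANCE_Q
    return out


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df) -> tuple[float, float]:
    """Method-of-moments empirical-Bayes prior (d0, s0_sq) for variances.

    Under the hierarchical model s2_g ~ s0^2 * F(df_g, d0), the statistic
    e_g = log(s2_g) - digamma(df_g/2) + log(df_g/2) has mean
    log(s0^2) + digamma(d0/2) - log(d0/2) and excess variance trigamma(d0/2)
    beyond mean(trigamma(df_g/2)).  Matching the empirical mean and variance
    of e yields d0 and s0^2; a non-positive excess variance gives d0 = inf
    with s0^2 = exp(mean(e)).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        return float("inf"), float(np.median(s2)) if s2.size else float("nan")
    e = np.log(s2) - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(np.mean(polygamma(1, df / 2.0)))
    if evar <= 0:
        # no excess spread beyond sampling noise: common variance, pooled mean
        return float("inf"), float(s2.mean())
    d0 = 2.0 * trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderate_variances(
    s2: np.ndarray, df, d0: float, s0_sq: float
) -> np.ndarray:
    """Posterior (shrunken) variances (d0*s0^2 + df*s2) / (d0 + df)."""
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    if np.isinf(d0):
        return np.full_like(s2, s0_sq)
    return (d0 * s0_sq + df * s2) / (d0 + df)


@dataclass
class ModeratedFitResult:
    complex_id: str
    protein_id: str
    contrast: str
    log2_fc: float
    s2: float
    df_residual: float
    s2_posterior: float
    t_moderated: float
    df_total: float
    p_value: float
    q_value: float = float("nan")


def _design_matrix(
    metadata: SampleMetadata, samples: list[str], factors: list[str]
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Intercept + one binary dummy per factor; rows with unknown levels masked."""
    cols = [np.ones(len(samples))]
    names = ["intercept"]
    valid = np.ones(len(samples), dtype=bool)
    for f in factors:
        lvl1, lvl2 = FACTOR_LEVELS.get(f, (None, None))
        levels = metadata.levels(f, samples)
        if lvl1 is None:
            uniq = sorted(x for x in levels.dropna().unique() if x != "unknown")
            if len(uniq) != 2:
                raise ValueError(f"factor {f!r} must have exactly 2 levels")
            lvl2, lvl1 = uniq  # second sorted level coded 1
        code = np.where(levels == lvl1, 1.0, 0.0)
        valid &= levels.isin([lvl1, lvl2]).to_numpy()
        cols.append(code)
        names.append(f)
    return np.column_stack(cols), names, valid


def fit_moderated_contrasts(
    profile: StoichiometryProfile,
    metadata: SampleMetadata,
    factors: list[str] | None = None,
    contrasts: list[str] | None = None,
    min_sample_fraction: float = 0.5,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> pd.DataFrame:
    """Moderated-t contrasts on complex-normalized abundances.

    Per subunit (quantified-after-normalization in >= ``min_sample_fraction``
    of samples): OLS on the additive design, residual variance s2; the
    empirical-Bayes prior (d0, s0^2) fitted across all subunits shrinks s2 to
    a posterior variance; moderated t = contrast / (sqrt(s2_post)*SE factor)
    on d0 + df_residual degrees of freedom.  BH across all
    (complex, subunit, contrast) tests.  ``d0``/``s0_sq`` may be forced
    (d0 = 0 reproduces the ordinary t).
    """
    factors = factors or ["sex", "diet"]
    contrasts = contrasts or list(factors)
    samples = list(profile.combined.columns)
    X_full, names, valid = _design_matrix(metadata, samples, factors)
    fits = []  # (complex, protein, betas, se_factors, s2, df_res)
    for mid, df_c in profile.per_complex.items():
        for prot in df_c.index:
            y = df_c.loc[prot].to_numpy(dtype=float)
            mask = np.isfinite(y) & valid
            if mask.mean() < min_sample_fraction:
                continue
            X = X_full[mask]
            yv = y[mask]
            n, p = X.shape
            if n < p + 2:
                continue
            xtx = X.T @ X
            if np.linalg.matrix_rank(xtx) < p:
                raise ValueError(
                    f"collinear design for factors {factors} (complex {mid}, "
                    f"protein {prot})"
                )
            xtx_inv = np.linalg.inv(xtx)
            beta = xtx_inv @ (X.T @ yv)
            resid = yv - X @ beta
            df_res = n - p
            s2 = float(resid @ resid / df_res)
            se_factor = np.sqrt(np.diag(xtx_inv))
            fits.append((mid, prot, beta, se_factor, s2, float(df_res)))
    if not fits:
        return pd.DataFrame(
            columns=[
                "complex_id", "protein_id", "contrast", "log2_fc", "s2",
                "df_residual", "s2_posterior", "t_moderated", "df_total",
                "p_value", "q_value",
            ]
        )
    s2_arr = np.array([f[4] for f in fits])
    df_arr = np.array([f[5] for f in fits])
    if d0 is None or s0_sq is None:
        d0_est, s0_est = fit_variance_prior(s2_arr, df_arr)
        d0 = d0_est if d0 is None else d0
        s0_sq = s0_est if s0_sq is None else s0_sq
    if d0 == 0:
        s2_post = s2_arr.copy()
    else:
        s2_post = moderate_variances(s2_arr, df_arr, d0, s0_sq)
    rows = []
    for (mid, prot, beta, se_factor, s2, df_res), sp in zip(fits, s2_post):
        for c in contrasts:
            j = names.index(c)
            t = float(beta[j] / (np.sqrt(sp) * se_factor[j]))
            if np.isinf(d0):
                p = float(2.0 * stats.norm.sf(abs(t)))
                dft = float("inf")
            else:
                dft = df_res + d0
                p = float(2.0 * stats.t.sf(abs(t), dft))
            rows.append(
                ModeratedFitResult(
                    complex_id=mid,
                    protein_id=prot,
                    contrast=c,
                    log2_fc=float(beta[j]),
                    s2=s2,
                    df_residual=df_res,
                    s2_posterior=float(sp),
                    t_moderated=t,
                    df_total=dft,
                    p_value=p,
                )
            )
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["q_value"] = benjamini_hochberg(out["p_value"])
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    return out


def combine_complex_verdict(
    moderated: pd.DataFrame, use_q: bool = True
) -> pd.DataFrame:
    """Per-complex Fisher combination of component q-values (or raw p).

    fisher_chi2 = -2 sum(ln q_i), df = 2k, combined p from chi-square; BH over
    complexes gives combined_q.
    """
    col = "q_value" if use_q else "p_value"
    rows = []
    for (mid, contrast), grp in moderated.groupby(["complex_id", "contrast"]):
        vals = grp[col].dropna()
        if len(vals) < 2:
            continue
        chi2, df, p = fisher_combine(vals)
        rows.append(
            {
                "complex_id": mid,
                "contrast": contrast,
                "fisher_chi2": chi2,
                "df": df,
                "combined_p": p,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["combined_q"] = benjamini_hochberg(out["combined_p"])
    return out
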