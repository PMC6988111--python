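import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.optimize import brentq
from scipy.special import digamma, polygamma

from proteovary import CohortConfig, generate_cohort
from proteovary.covariates import (
    combine_complex_verdict,
    complex_median_abundance,
    differential_module_abundance,
    fit_moderated_contrasts,
    fit_variance_prior,
    moderate_variances,
)
from proteovary.datatypes import SampleMetadata
from proteovary.stats import benjamini_hochberg, cohens_d, fisher_combine
from proteovary.stoichiometry import StoichiometryProfile, complex_normalize


def oracle_variance_prior(s2, df):
    """Independently coded method-of-moments prior fit (brentq root solver)."""
    s2 = np.asarray(s2, float)
    df = np.broadcast_to(np.asarray(df, float), s2.shape)
    e = np.log(s2) - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(s2.mean())
    half = brentq(lambda x: polygamma(1, x) - evar, 1e-8, 1e8, xtol=1e-13, rtol=1e-14)
    d0 = 2.0 * half
    s0 = float(np.exp(emean + digamma(half) - np.log(half)))
    return d0, s0


def _null_profile(rng, n_complexes=20, n_subunits=10, n_samples=60, d0=4.0, s0=0.25):
    """Complex-normalized-style matrices with variances drawn from the
    scaled inverse-chi-square hierarchy (null: no covariate effects)."""
    per = {}
    samples = [f"S{i}" for i in range(n_samples)]
    for c in range(n_complexes):
        sd = np.sqrt(s0 * d0 / rng.chisquare(d0, size=n_subunits))
        rows = rng.normal(0, sd[:, None], size=(n_subunits, n_samples))
        per[f"C{c}"] = pd.DataFrame(
            rows, index=[f"C{c}_p{j}" for j in range(n_subunits)], columns=samples
        )
    combined = pd.DataFrame(columns=samples, dtype=float)
    return StoichiometryProfile("d", per, combined), samples


class TestComplexMedianAbundance:
    def test_median_and_eligibility(self):
        from proteovary.datatypes import (
            AbundanceDataset,
            ModuleCatalog,
            ModuleCategory,
            Scale,
        )

        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.normal(10, 1, size=(6, 10)),
                            index=list("ABCDEF"))
        vals.iloc[5, :6] = np.nan  # F quantified in 40% -> excluded everywhere
        vals.iloc[:5, 0] = [1.0, 2.0, 9.0, np.nan, np.nan]
        ds = AbundanceDataset("d", vals, Scale.LOG2)
        cat = ModuleCatalog(ModuleCategory.COMPLEX, {"C1": frozenset("ABCDEF")})
        med = complex_median_abundance(ds, cat)
        assert med.loc["C1", 0] == pytest.approx(2.0)  # median of [1,2,9]

        vals2 = vals.copy()
        vals2.iloc[:, 1] = np.nan
        ds2 = AbundanceDataset("d", vals2, Scale.LOG2)
        med2 = complex_median_abundance(ds2, cat)
        assert np.isnan(med2.loc["C1", 1])


class TestDifferentialAbundance:
    def test_identical_groups_null(self, balanced_metadata):
        meta = balanced_metadata([f"S{i}" for i in range(6)])
        med = pd.DataFrame(
            [[1.0, 1.0, 2.0, 2.0, 3.0, 3.0]], index=["M1"],
            columns=[f"S{i}" for i in range(6)],
        )
        out = differential_module_abundance(med, meta, "sex")
        assert out.loc[0, "cohen_d"] == pytest.approx(0.0)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_pooled_sd_worked_example(self):
        # groups [2,4] vs [1,3]: pooled sd = sqrt(2), d = 1/sqrt(2)
        assert cohens_d([2, 4], [1, 3]) == pytest.approx(1 / np.sqrt(2))

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(1, 1, 20), rng.normal(0, 1, 25)
        assert cohens_d(x, y) == pytest.approx(-cohens_d(y, x))

    def test_planted_sex_effect_detected(self):
        cfg = CohortConfig(
            n_samples=100, n_complexes=8, n_variable_subunits_per_complex=0,
            sex_effect_fractions={"cplx_001": 0.4}, n_background_proteins=10,
            n_pathways=0, n_datasets=1, seed=2,
        )
        cohort = generate_cohort(cfg)
        med = complex_median_abundance(cohort.datasets[0], cohort.complexes)
        out = differential_module_abundance(med, cohort.metadata, "sex")
        sig = set(out.loc[out["significant"], "module_id"])
        assert sig == {"cplx_001"}


class TestVariancePrior:
    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            df = float(rng.integers(3, 40))
            s2 = rng.chisquare(df, size=300) / df * rng.uniform(0.5, 2)
            d0_a, s0_a = fit_variance_prior(s2, df)
            d0_b, s0_b = oracle_variance_prior(s2, df)
            assert d0_a == pytest.approx(d0_b, rel=1e-6)
            assert s0_a == pytest.approx(s0_b, rel=1e-6)

    def test_recovers_generating_parameters(self):
        d0s, s0s = [], []
        rng = np.random.default_rng(4)
        for _ in range(10):
            v = 1.0 * 4 / rng.chisquare(4, size=500)
            s2 = v * rng.chisquare(6, size=500) / 6
            d0, s0 = fit_variance_prior(s2, 6.0)
            d0s.append(d0)
            s0s.append(s0)
        assert 2.5 <= np.median(d0s) <= 6.0
        assert 0.8 <= np.median(s0s) <= 1.25

    def test_posterior_interpolates(self):
        s2 = np.array([0.5, 1.0, 2.0])
        post = moderate_variances(s2, 10.0, d0=5.0, s0_sq=1.0)
        np.testing.assert_allclose(post, (5.0 * 1.0 + 10.0 * s2) / 15.0)

    def test_homogeneous_variances_give_infinite_prior(self):
        # equal observed variances: no excess spread -> d0 = inf, s2_post = s0
        s2 = np.full(100, 2.0)
        d0, s0 = fit_variance_prior(s2, 10.0)
        assert np.isinf(d0)
        post = moderate_variances(s2, 10.0, d0, s0)
        np.testing.assert_allclose(post, s0)


class TestModeratedContrasts:
    def test_d0_zero_equals_ordinary_t(self, balanced_metadata):
        rng = np.random.default_rng(5)
        prof, samples = _null_profile(rng, n_complexes=3, n_samples=40)
        meta = balanced_metadata(samples)
        out = fit_moderated_contrasts(prof, meta, d0=0.0, s0_sq=1.0)
        # recompute the ordinary t for one subunit via statsmodels OLS
        import statsmodels.api as sm

        row = out.iloc[0]
        y = prof.per_complex[row.complex_id].loc[row.protein_id]
        X = pd.DataFrame(
            {
                "intercept": 1.0,
                "sex": (meta.levels("sex", samples) == "male").astype(float).values,
                "diet": (meta.levels("diet", samples) == "high_fat").astype(float).values,
            },
            index=samples,
        )
        fit = sm.OLS(y, X).fit()
        assert row.t_moderated == pytest.approx(fit.tvalues[row.contrast], rel=1e-9)
        assert row.p_value == pytest.approx(fit.pvalues[row.contrast], rel=1e-9)

    def test_null_pvalues_uniform(self, balanced_metadata):
        rng = np.random.default_rng(6)
        prof, samples = _null_profile(rng, n_complexes=40, n_subunits=10)
        meta = balanced_metadata(samples)
        out = fit_moderated_contrasts(prof, meta, contrasts=["sex"])
        ks = stats.kstest(out["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_stoichiometric_shift_power(self):
        # 0.5 log2-unit shift on one subunit, n=96, subunit sd 0.3
        hits = 0
        for seed in range(10):
            cfg = CohortConfig(
                n_samples=96, n_complexes=10, n_variable_subunits_per_complex=0,
                latent_strength_range=(0.64, 0.64), noise_sd=0.5,
                stoichiometry_effects={"cplx_001": {"sex": 0.5}},
                n_background_proteins=5, n_pathways=0, n_datasets=1,
                missing_rate=0.0, seed=seed,
            )
            cohort = generate_cohort(cfg)
            prof = complex_normalize(cohort.datasets[0], cohort.complexes)
            out = fit_moderated_contrasts(prof, cohort.metadata)
            planted = cohort.truth.subunits.query("sex_shift != 0")["protein_id"].iloc[0]
            hit = out[
                (out.protein_id == planted) & (out.contrast == "sex")
            ]["q_value"]
            hits += bool((hit < 0.01).any())
        assert hits >= 9

    def test_matches_limma_squeeze(self, tmp_path):
        """Cross-check the variance moderation against limma::squeezeVar."""
        rng = np.random.default_rng(7)
        s2 = rng.chisquare(8, size=200) / 8 * rng.uniform(0.5, 2)
        df = 8.0
        d0, s0 = fit_variance_prior(s2, df)
        post = moderate_variances(s2, df, d0, s0)
        s2_file = tmp_path / "s2.txt"
        np.savetxt(s2_file, s2)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(limma))
            s2 <- scan("{s2_file}", quiet=TRUE)
            sq <- squeezeVar(s2, df=8)
            cat(sq$df.prior, sq$var.prior, sq$var.post[1:5], sep="\\n")
            """
        )
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        vals = [float(x) for x in res.stdout.split()]
        assert d0 == pytest.approx(vals[0], rel=1e-4)
        assert s0 == pytest.approx(vals[1], rel=1e-4)
        np.testing.assert_allclose(post[:5], vals[2:7], rtol=1e-4)


class TestFisherAndBH:
    def test_fisher_worked_examples(self):
        chi2, df, p = fisher_combine([0.5, 0.5])
        assert chi2 == pytest.approx(2.7726, abs=1e-3)
        assert df == 4
        assert p == pytest.approx(0.5966, abs=1e-3)
        chi2, df, p = fisher_combine([1.0, 1.0])
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_fisher_clamps_zero(self):
        chi2, df, p = fisher_combine([0.0, 0.5])
        assert np.isfinite(chi2) and p < 1e-100

    def test_bh_worked_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    @given(
        st.lists(st.floats(1e-12, 1.0, allow_nan=False), min_size=1, max_size=30)
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_bh_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        ours = benjamini_hochberg(pvals)
        ref = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)
        assert (ours >= np.asarray(pvals) - 1e-12).all()
        assert (ours <= 1.0).all()

    def test_verdict_flags_planted_complex(self, balanced_metadata):
        rng = np.random.default_rng(8)
        prof, samples = _null_profile(rng, n_complexes=20, n_samples=80)
        meta = balanced_metadata(samples)
        # plant a sex shift on one subunit of C0
        male = (meta.levels("sex", samples) == "male").to_numpy()
        prof.per_complex["C0"].iloc[0] += np.where(male, 1.0, 0.0)
        out = fit_moderated_contrasts(prof, meta)
        verdict = combine_complex_verdict(out)
        sex_verdict = verdict[verdict["contrast"] == "sex"]
        best = sex_verdict.loc[sex_verdict["combined_q"].idxmin(), "complex_id"]
        assert best == "C0"
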