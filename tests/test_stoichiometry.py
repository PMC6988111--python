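import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proteovary import CohortConfig, generate_cohort
from proteovary.datatypes import AbundanceDataset, ModuleCatalog, ModuleCategory, Scale
from proteovary.stoichiometry import (
    StoichiometryProfile,
    call_components_within_dataset,
    complex_normalize,
    cross_dataset_component_test,
    subunit_variance_zscores,
    trimmed_mean,
    zscore_consistency,
)


def _profile(per_complex, samples):
    combined = pd.DataFrame(columns=samples, dtype=float)
    return StoichiometryProfile("d", per_complex, combined)


class TestComplexNormalize:
    def test_interquartile_mean_worked_example(self):
        vals = pd.DataFrame(
            {"s1": [10.0, 11.0, 12.0, 13.0], "s2": [10.0, 11.0, 12.0, 13.0]},
            index=list("ABCD"),
        )
        ds = AbundanceDataset("d", vals, Scale.LOG2)
        cat = ModuleCatalog(ModuleCategory.COMPLEX, {"C1": frozenset("ABCD")})
        prof = complex_normalize(ds, cat, min_members=4)
        assert trimmed_mean([10, 11, 12, 13]) == 11.5
        np.testing.assert_allclose(
            prof.per_complex["C1"]["s1"].to_numpy(), [-1.5, -0.5, 0.5, 1.5]
        )

    def test_shift_invariance_exact(self):
        rng = np.random.default_rng(1)
        base = pd.DataFrame(rng.normal(20, 1, size=(6, 10)), index=list("ABCDEF"))
        cat = ModuleCatalog(ModuleCategory.COMPLEX, {"C1": frozenset("ABCDEF")})
        shifted = base.copy()
        shifted.iloc[:, 3] += 2.0  # complex-level shift in one sample
        a = complex_normalize(AbundanceDataset("d", base, Scale.LOG2), cat)
        b = complex_normalize(AbundanceDataset("d", shifted, Scale.LOG2), cat)
        np.testing.assert_allclose(
            a.per_complex["C1"].to_numpy(), b.per_complex["C1"].to_numpy(), atol=1e-12
        )

    def test_multi_complex_protein_averaged(self):
        # protein P normalized to -1 in c1 and +1 in c2 -> combined 0
        vals2 = pd.DataFrame(
            {"s1": [1.0, 2.0, 2.0, 2.0, 2.0, 0.0, 0.0, 0.0, 0.0]},
            index=["P", "a1", "a2", "a3", "a4", "b1", "b2", "b3", "b4"],
        )
        ds = AbundanceDataset("d", vals2, Scale.LOG2)
        cat = ModuleCatalog(
            ModuleCategory.COMPLEX,
            {"c1": frozenset(["P", "a1", "a2", "a3", "a4"]),
             "c2": frozenset(["P", "b1", "b2", "b3", "b4"])},
        )
        prof = complex_normalize(ds, cat)
        # c1 ref = trimmed mean [1,2,2,2,2] = 2 -> P-norm = -1
        # c2 ref = trimmed mean [0,0,0,0,1] = 0 -> P-norm = +1
        assert prof.per_complex["c1"].loc["P", "s1"] == pytest.approx(-1.0)
        assert prof.per_complex["c2"].loc["P", "s1"] == pytest.approx(1.0)
        assert prof.combined.loc["P", "s1"] == pytest.approx(0.0)

    def test_sparse_sample_gets_missing_reference(self):
        vals = pd.DataFrame(
            {"s1": [1.0, 2.0, np.nan, np.nan, np.nan], "s2": [1.0, 2.0, 3.0, 4.0, 5.0]},
            index=list("ABCDE"),
        )
        ds = AbundanceDataset("d", vals, Scale.LOG2)
        cat = ModuleCatalog(ModuleCategory.COMPLEX, {"C1": frozenset("ABCDE")})
        prof = complex_normalize(ds, cat, min_quantified_subunits=3)
        assert prof.per_complex["C1"]["s1"].isna().all()
        assert prof.per_complex["C1"]["s2"].notna().all()

    def test_normalization_removes_shared_factor_pc1(self):
        cfg = CohortConfig(
            n_samples=100, n_complexes=1, complex_size_range=(8, 8),
            latent_strength_range=(0.7, 0.7), n_variable_subunits_per_complex=0,
            n_background_proteins=0, n_pathways=0, n_datasets=1,
            missing_rate=0.0, seed=5,
        )
        cohort = generate_cohort(cfg)
        ds = cohort.datasets[0]
        prof = complex_normalize(ds, cohort.complexes)

        def pc1_share(mat):
            mat = mat - mat.mean(axis=1, keepdims=True)
            sv = np.linalg.svd(mat, compute_uv=False)
            return sv[0] ** 2 / np.sum(sv**2)

        raw = pc1_share(ds.values.to_numpy())
        norm = pc1_share(prof.per_complex[list(prof.per_complex)[0]].to_numpy())
        assert norm < raw


class TestVarianceZscores:
    def test_standardization_worked_example(self):
        rng = np.random.default_rng(2)
        rows = [rng.normal(0, np.sqrt(v), size=2000) for v in (1.0, 2.0, 3.0)]
        per = {"C1": pd.DataFrame(rows, index=list("ABC"))}
        prof = subunit_variance_zscores(_profile(per, list(range(2000))))
        z = prof.z_table.set_index("protein_id")["z"]
        # sample variances close to (1,2,3) -> z close to (-1,0,1)
        assert z["A"] == pytest.approx(-1.0, abs=0.1)
        assert z["C"] == pytest.approx(1.0, abs=0.1)
        assert prof.z_table["z"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_equal_variances_give_zero_z(self):
        row = np.array([1.0, -1.0, 2.0, -2.0])
        per = {"C1": pd.DataFrame([row, row, row], index=list("ABC"))}
        prof = subunit_variance_zscores(_profile(per, list(range(4))))
        assert (prof.z_table["z"] == 0).all()

    def test_small_complex_skipped(self):
        per = {"C1": pd.DataFrame(np.random.default_rng(0).normal(size=(2, 10)))}
        prof = subunit_variance_zscores(_profile(per, list(range(10))))
        assert prof.z_table.empty

    def test_noisiest_subunit_gets_max_z(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rows = [rng.normal(size=200) for _ in range(9)]
            rows.append(rng.normal(0, 2.0, size=200))  # 4x the variance
            per = {"C1": pd.DataFrame(rows, index=[f"p{i}" for i in range(10)])}
            prof = subunit_variance_zscores(_profile(per, list(range(200))))
            top = prof.z_table.loc[prof.z_table["z"].idxmax(), "protein_id"]
            hits += top == "p9"
        assert hits >= 19


class TestComponentCalls:
    def test_tail_rules(self):
        zt = pd.DataFrame(
            {
                "complex_id": ["C"] * 3,
                "protein_id": list("ABC"),
                "variance": [1.0, 1.0, 1.0],
                "z": [1.645, 0.0, -2.0],
            }
        )
        prof = _profile({}, [])
        prof.z_table = zt
        calls = {c.protein_id: c for c in call_components_within_dataset(prof)}
        assert calls["A"].label == "variable"
        assert calls["B"].label == "neutral"
        assert calls["C"].label == "stable"
        assert calls["A"].p_value == pytest.approx(stats.norm.sf(1.645))

    def test_display_threshold(self):
        zt = pd.DataFrame(
            {"complex_id": ["C"], "protein_id": ["A"], "variance": [1.0], "z": [1.6]}
        )
        prof = _profile({}, [])
        prof.z_table = zt
        call = call_components_within_dataset(prof)[0]
        assert call.display_label == "variable"  # |z| > 1.5


class TestCrossDataset:
    def test_planted_variable_subunits_recovered(self):
        cfg = CohortConfig(
            n_samples=150, n_complexes=10, n_variable_subunits_per_complex=1,
            n_background_proteins=10, n_pathways=0, n_datasets=4, seed=3,
        )
        cohort = generate_cohort(cfg)
        profs = [
            subunit_variance_zscores(complex_normalize(ds, cohort.complexes))
            for ds in cohort.datasets
        ]
        out = cross_dataset_component_test(profs)
        truth = cohort.truth.subunits.set_index("protein_id")["variable"]
        hits = set(out.loc[out["q_value"] < 0.05, "protein_id"])
        planted = set(truth[truth].index)
        assert len(hits & planted) / len(planted) >= 0.9
        assert len(hits - planted) <= 0.1 * max(len(hits), 1)

    def test_single_dataset_protein_untested(self):
        zt1 = pd.DataFrame(
            {
                "complex_id": ["C"] * 3,
                "protein_id": list("ABC"),
                "variance": [1.0] * 3,
                "z": [0.1, -0.1, 0.0],
            }
        )
        zt2 = zt1[zt1["protein_id"] != "A"].copy()
        p1, p2 = _profile({}, []), _profile({}, [])
        p1.z_table, p2.z_table = zt1, zt2
        p2.dataset_id = "d2"
        out = cross_dataset_component_test([p1, p2]).set_index("protein_id")
        assert np.isnan(out.loc["A", "p_value"])
        assert out.loc["B", "n_datasets"] == 2


class TestZscoreConsistency:
    def test_replicates_agree_above_null(self):
        cfg = CohortConfig(
            n_samples=120, n_complexes=12, n_variable_subunits_per_complex=1,
            variable_variance_multiplier=6.0, n_background_proteins=10,
            n_pathways=0, n_datasets=2, missing_rate=0.0, seed=6,
        )
        cohort = generate_cohort(cfg)
        r, p, null = zscore_consistency(
            cohort.datasets, cohort.complexes, n_perm=30, seed=2
        )
        assert r > 0
        assert p < 0.01
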