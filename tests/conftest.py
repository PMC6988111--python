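import numpy as np
import pandas as pd
import pytest

from proteovary import (
    AbundanceDataset,
    CohortConfig,
    ModuleCatalog,
    ModuleCategory,
    SampleMetadata,
    Scale,
    generate_cohort,
)


@pytest.fixture
def tiny_dataset():
    """3 proteins x 4 samples, log2 scale, one missing entry."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 3.0],
            "s2": [2.0, 4.0, 6.0],
            "s3": [3.0, 6.0, 9.0],
            "s4": [4.0, np.nan, 12.0],
        },
        index=["A", "B", "C"],
    )
    return AbundanceDataset(dataset_id="tiny", values=values, scale=Scale.LOG2)


@pytest.fixture
def toy_complexes():
    return ModuleCatalog(
        category=ModuleCategory.COMPLEX,
        members={"C1": frozenset({"A", "B", "C"})},
    )


@pytest.fixture
def balanced_metadata():
    def make(samples):
        n = len(samples)
        sex = ["male", "female"] * (n // 2) + ["male"] * (n % 2)
        diet = (["chow", "chow", "high_fat", "high_fat"] * ((n + 3) // 4))[:n]
        return SampleMetadata(
            table=pd.DataFrame(
                {"sex": sex[:n], "diet": diet},
                index=pd.Index(samples, name="sample_id"),
            )
        )

    return make


@pytest.fixture(scope="session")
def small_cohort():
    """Shared mid-size cohort with planted co-abundance and one variable
    subunit per complex; used by several module tests."""
    cfg = CohortConfig(
        n_samples=120,
        n_complexes=15,
        latent_strength_range=(0.5, 0.7),
        n_variable_subunits_per_complex=1,
        n_background_proteins=80,
        n_pathways=4,
        n_datasets=2,
        missing_rate=0.05,
        seed=7,
    )
    return generate_cohort(cfg)
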