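"""Synthetic proteome cohorts with planted, recoverable structure.

The generator emulates the data-generating process the analysis assumes:
log2-normal protein abundances in which each complex's subunits share a
latent per-sample abundance factor, variable subunits are decoupled from
their complex and given extra noise, sex and diet shift complex abundance
(via the latent factor) and individual-subunit stoichiometry (via per-subunit
log2 shifts), pathways repeat the construction with weaker co-variation,
background proteins are pure noise, and missingness is completely at random.
Multiple replicate datasets share the planted architecture but draw
independent noise, mimicking independent studies of the same biology.

Model, per subunit p of complex c and sample s (log2 space):

    y_p(s) = mu_p + lambda_p * f_c(s) + u_p * sex(s) + v_p * diet(s) + eps_p(s)
    f_c(s) = a_c * (sex(s)-1/2) + b_c * (diet(s)-1/2) + eta_c(s),  Var(f_c)=1

a_c and b_c are set so the configured fractions of Var(f_c) come from sex
and diet; lambda_p is scaled so the shared factor contributes the configured
fraction ("latent strength") of the subunit's total variance noise_sd^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
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


@dataclass
class CohortConfig:
    """Planted-structure parameters of a synthetic cohort.

    Variance fractions are on [0, 1); ``noise_sd`` is the total per-subunit
    standard deviation in log2 units, of which the latent factor claims the
    "latent strength" fraction.
    """

    n_samples: int = 200
    n_complexes: int = 50
    complex_size_range: tuple[int, int] = (5, 15)
    latent_strength_range: tuple[float, float] = (0.2, 0.8)
    n_variable_subunits_per_complex: int = 1
    variable_variance_multiplier: float = 4.0
    variable_latent_shrink: float = 0.0
    sex_effect_fractions: dict[str, float] = field(default_factory=dict)
    diet_effect_fractions: dict[str, float] = field(default_factory=dict)
    stoichiometry_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    n_background_proteins: int = 200
    n_pathways: int = 10
    pathway_size_range: tuple[int, int] = (5, 15)
    pathway_strength: float = 0.2
    missing_rate: float = 0.1
    noise_sd: float = 0.5
    mu_mean: float = 20.0
    mu_sd: float = 2.0
    n_datasets: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for d in (self.sex_effect_fractions, self.diet_effect_fractions):
            for v in d.values():
                if not 0.0 <= v < 1.0:
                    raise ValueError("effect fractions must be in [0, 1)")


@dataclass
class GroundTruth:
    """Planted parameters, serialized alongside the data."""

    complexes: pd.DataFrame  # module_id, latent_strength, sex_fraction, diet_fraction
    subunits: pd.DataFrame  # protein_id, module_id, variable, sex_shift, diet_shift
    pathways: pd.DataFrame  # module_id, strength


@dataclass
class SimulatedCohort:
    datasets: list[AbundanceDataset]
    metadata: SampleMetadata
    complexes: ModuleCatalog
    pathways: ModuleCatalog
    interactions: InteractionTable
    truth: GroundTruth
    config: CohortConfig


def _complex_id(i: int) -> str:
    return f"cplx_{i + 1:03d}"


def _pathway_id(i: int) -> str:
    return f"path_{i + 1:03d}"


def generate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate the cohort: replicate datasets, metadata, catalogs, truth.

    The architecture (module sizes, latent strengths, variable subunits,
    covariate coefficients, baseline abundances) is drawn once from the seed
    and shared by every replicate dataset; each dataset draws its own latent
    factors, residual noise and missingness mask.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    # balanced factorial sex x diet assignment, order shuffled
    sex = np.array(["male", "female"])[np.arange(n) % 2]
    diet = np.array(["high_fat", "chow"])[(np.arange(n) // 2) % 2]
    order = rng.permutation(n)
    sex, diet = sex[order], diet[order]
    samples = [f"S{i + 1:04d}" for i in range(n)]
    x_sex = (sex == "male").astype(float)
    x_diet = (diet == "high_fat").astype(float)
    xc_sex, xc_diet = x_sex - 0.5, x_diet - 0.5

    # --- architecture (shared across datasets) ---
    lo, hi = config.complex_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_complexes)
    strengths = rng.uniform(*config.latent_strength_range, size=config.n_complexes)
    cplx_rows, sub_rows = [], []
    members: dict[str, frozenset[str]] = {}
    arch = []  # per complex: (proteins, lambdas, eps_sd, u, v, a, b, eta_sd)
    for i in range(config.n_complexes):
        mid = _complex_id(i)
        size = int(sizes[i])
        prots = [f"{mid}_s{j + 1:02d}" for j in range(size)]
        s = float(strengths[i])
        sex_frac = float(config.sex_effect_fractions.get(mid, 0.0))
        diet_frac = float(config.diet_effect_fractions.get(mid, 0.0))
        if sex_frac + diet_frac >= 1.0:
            raise ValueError(f"variance budget exceeded for complex {mid}")
        a = 2.0 * np.sqrt(sex_frac)
        b = 2.0 * np.sqrt(diet_frac)
        eta_sd = np.sqrt(1.0 - sex_frac - diet_frac)
        lam = np.full(size, config.noise_sd * np.sqrt(s))
        eps_sd = np.full(size, config.noise_sd * np.sqrt(1.0 - s))
        variable = np.zeros(size, dtype=bool)
        n_var = min(config.n_variable_subunits_per_complex, size - 1)
        var_idx = rng.choice(size, size=n_var, replace=False)
        variable[var_idx] = True
        lam[var_idx] *= config.variable_latent_shrink
        eps_sd[var_idx] *= np.sqrt(config.variable_variance_multiplier)
        u = np.zeros(size)
        v = np.zeros(size)
        shifts = config.stoichiometry_effects.get(mid, {})
        shift_idx = None
        if shifts:
            # planted on the first non-variable subunit
            shift_idx = int(np.flatnonzero(~variable)[0])
            u[shift_idx] = float(shifts.get("sex", 0.0))
            v[shift_idx] = float(shifts.get("diet", 0.0))
        members[mid] = frozenset(prots)
        cplx_rows.append(
            {
                "module_id": mid,
                "latent_strength": s,
                "sex_fraction": sex_frac,
                "diet_fraction": diet_frac,
            }
        )
        for j, p in enumerate(prots):
            sub_rows.append(
                {
                    "protein_id": p,
                    "module_id": mid,
                    "variable": bool(variable[j]),
                    "sex_shift": float(u[j]),
                    "diet_shift": float(v[j]),
                }
            )
        arch.append((prots, lam, eps_sd, u, v, a, b, eta_sd))

    pw_members: dict[str, frozenset[str]] = {}
    pw_rows = []
    pw_arch = []
    plo, phi = config.pathway_size_range
    for i in range(config.n_pathways):
        mid = _pathway_id(i)
        size = int(rng.integers(plo, phi + 1))
        prots = [f"{mid}_m{j + 1:02d}" for j in range(size)]
        s = float(config.pathway_strength)
        lam = np.full(size, config.noise_sd * np.sqrt(s))
        eps_sd = np.full(size, config.noise_sd * np.sqrt(1.0 - s))
        pw_members[mid] = frozenset(prots)
        pw_rows.append({"module_id": mid, "strength": s})
        pw_arch.append((prots, lam, eps_sd))

    bg_prots = [f"bg_{j + 1:04d}" for j in range(config.n_background_proteins)]
    all_proteins = (
        [p for prots, *_ in arch for p in prots]
        + [p for prots, *_ in pw_arch for p in prots]
        + bg_prots
    )
    mu = pd.Series(
        rng.normal(config.mu_mean, config.mu_sd, size=len(all_proteins)),
        index=all_proteins,
    )

    # --- replicate datasets: independent eta, eps, missingness ---
    datasets = []
    for d in range(config.n_datasets):
        vals = np.empty((len(all_proteins), n))
        row = 0
        for (prots, lam, eps_sd, u, v, a, b, eta_sd) in arch:
            f = a * xc_sex + b * xc_diet + rng.normal(0.0, eta_sd, size=n)
            for j, p in enumerate(prots):
                vals[row] = (
                    mu[p]
                    + lam[j] * f
                    + u[j] * x_sex
                    + v[j] * x_diet
                    + rng.normal(0.0, eps_sd[j], size=n)
                )
                row += 1
        for (prots, lam, eps_sd) in pw_arch:
            f = rng.normal(0.0, 1.0, size=n)
            for j, p in enumerate(prots):
                vals[row] = mu[p] + lam[j] * f + rng.normal(0.0, eps_sd[j], size=n)
                row += 1
        for p in bg_prots:
            vals[row] = mu[p] + rng.normal(0.0, config.noise_sd, size=n)
            row += 1
        if config.missing_rate > 0:
            mask = rng.random(vals.shape) < config.missing_rate
            vals = np.where(mask, np.nan, vals)
        datasets.append(
            AbundanceDataset(
                dataset_id=f"sim_d{d + 1}",
                values=pd.DataFrame(vals, index=all_proteins, columns=samples),
                scale=Scale.LOG2,
            )
        )

    metadata = SampleMetadata(
        table=pd.DataFrame({"sex": sex, "diet": diet}, index=pd.Index(samples, name="sample_id"))
    )
    complexes = ModuleCatalog(
        category=ModuleCategory.COMPLEX,
        members=members,
        well_defined={m: True for m in members},
    )
    pathways = (
        ModuleCatalog(category=ModuleCategory.PATHWAY, members=pw_members)
        if pw_members
        else None
    )

    scores: dict[tuple[str, str], float] = {}
    for mem in members.values():
        mem = sorted(mem)
        for ai in range(len(mem)):
            for bi in range(ai + 1, len(mem)):
                scores[canonical_pair(mem[ai], mem[bi])] = 0.9
    n_pos = len(scores)
    tries = 0
    while sum(1 for s in scores.values() if s == 0.1) < n_pos and tries < 50 * n_pos:
        a, b = rng.choice(len(all_proteins), size=2, replace=False)
        pair = canonical_pair(all_proteins[a], all_proteins[b])
        if pair not in scores:
            scores[pair] = 0.1
        tries += 1
    interactions = InteractionTable(scores=scores)

    truth = GroundTruth(
        complexes=pd.DataFrame(cplx_rows),
        subunits=pd.DataFrame(sub_rows),
        pathways=pd.DataFrame(pw_rows, columns=["module_id", "strength"]),
    )
    return SimulatedCohort(
        datasets=datasets,
        metadata=metadata,
        complexes=complexes,
        pathways=pathways,
        interactions=interactions,
        truth=truth,
        config=config,
    )


def planted_r2(
    config: CohortConfig,
    module_id: str,
    predictor_set: str,
    n_virtual: int = 100_000,
    seed: int = 12345,
) -> float:
    """Theoretical variance fraction of a complex's median abundance explained
    by the predictor set, evaluated numerically on a large virtual cohort.

    The module's subunit values are regenerated at ``n_virtual`` samples and
    the per-sample median response is regressed (OLS) on the predictor
    dummies; the resulting population R^2 is the recovery target for the
    ridge effect-size estimator.
    """
    idx = None
    for i in range(config.n_complexes):
        if _complex_id(i) == module_id:
            idx = i
            break
    if idx is None:
        raise ValueError(f"unknown module {module_id!r}")
    rng = np.random.default_rng(seed)
    arch_rng = np.random.default_rng(config.seed)
    # reproduce the architecture draw for this complex
    lo, hi = config.complex_size_range
    sizes = arch_rng.integers(lo, hi + 1, size=config.n_complexes)
    strengths = arch_rng.uniform(*config.latent_strength_range, size=config.n_complexes)
    size = int(sizes[idx])
    s = float(strengths[idx])
    mid = module_id
    sex_frac = float(config.sex_effect_fractions.get(mid, 0.0))
    diet_frac = float(config.diet_effect_fractions.get(mid, 0.0))
    a = 2.0 * np.sqrt(sex_frac)
    b = 2.0 * np.sqrt(diet_frac)
    eta_sd = np.sqrt(1.0 - sex_frac - diet_frac)
    n = n_virtual
    x_sex = (np.arange(n) % 2).astype(float)
    x_diet = ((np.arange(n) // 2) % 2).astype(float)
    f = a * (x_sex - 0.5) + b * (x_diet - 0.5) + rng.normal(0.0, eta_sd, size=n)
    lam = config.noise_sd * np.sqrt(s)
    eps_sd = config.noise_sd * np.sqrt(1.0 - s)
    vals = lam * f[None, :] + rng.normal(0.0, eps_sd, size=(size, n))
    y = np.median(vals, axis=0)
    cols = {"sex": x_sex, "diet": x_diet}
    factors = {"sex": ["sex"], "diet": ["diet"], "sex_plus_diet": ["sex", "diet"]}[
        predictor_set
    ]
    X = np.column_stack([np.ones(n)] + [cols[f_] for f_ in factors])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(1.0 - resid.var() / y.var())


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> None:
    """Serialize the cohort in the pipeline's own TSV/GMT dialects."""
    from . import io as pio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds in cohort.datasets:
        pio.write_abundance_matrix(ds, out / f"{ds.dataset_id}.tsv")
    pio.write_sample_metadata(cohort.metadata, out / "metadata.tsv")
    pio.write_module_catalog_gmt(cohort.complexes, out / "complexes.gmt")
    if cohort.pathways is not None:
        pio.write_module_catalog_gmt(cohort.pathways, out / "pathways.gmt")
    pio.write_interactions(cohort.interactions, out / "interactions.tsv")
    cohort.truth.complexes.to_csv(out / "truth_complexes.tsv", sep="\t", index=False)
    cohort.truth.subunits.to_csv(out / "truth_subunits.tsv", sep="\t", index=False)
    cohort.truth.pathways.to_csv(out / "truth_pathways.tsv", sep="\t", index=False)
    cfg = asdict(cohort.config)
    cfg["complex_size_range"] = list(cfg["complex_size_range"])
    cfg["pathway_size_range"] = list(cfg["pathway_size_range"])
    cfg["latent_strength_range"] = list(cfg["latent_strength_range"])
    with open(out / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2)
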