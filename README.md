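# proteovary

Analysis of proteome variation across individuals: protein co-abundance,
protein-complex stoichiometry, and the share of both explained by sex and
diet.

Across cohorts of individuals — mouse crosses, human cell-line panels,
tumor collections — the abundances of proteins that assemble into the same
complex rise and fall together, while a minority of subunits drift
independently. `proteovary` is a toolkit for researchers who want to
quantify that structure in a proteins × samples abundance matrix:

- **Module recovery** — how well pairwise co-abundance (Pearson r of log2
  abundances) separates protein pairs inside known modules (complexes,
  pathways, interaction networks, compartments) from random pairs,
  summarized as a ROC curve and trapezoid AUC with a subsampled
  Mann–Whitney companion p-value.
- **Complex landscape** — complexes ranked by median within-complex
  co-abundance per dataset and aggregated across datasets into stable
  (top quartile) and variable (bottom quartile) classes, with decoy-complex
  and within-protein-permutation nulls and a permutation t-test of
  cross-dataset consistency.
- **Stoichiometry decomposition** — each subunit's log2 abundance minus its
  complex's per-sample trimmed-mean reference isolates composition from
  overall complex abundance; variance z-scores per complex call stable and
  variable components, and a cross-dataset one-sided t-test finds subunits
  that are consistently variable.
- **Covariate effects** — two-sided t-tests with Cohen's d on complex
  median abundances, and empirical-Bayes moderated-t contrasts (additive
  sex + diet design, variance shrinkage toward a method-of-moments prior
  (d₀, s₀²)) on complex-normalized values, with Fisher combination into
  per-complex verdicts.
- **Effect sizes** — cross-validated ridge regression (α = 1, 10-fold,
  pooled out-of-fold global R²) of module abundance and stoichiometry on
  sex, diet, and sex + diet, with a permutation-based empirical FDR.
- **Synthetic cohorts** — a generator that plants known latent co-abundance,
  variable subunits, and covariate effects, so every stage has a
  recoverable ground truth.

## Worked example

```python
from proteovary import CohortConfig, generate_cohort
from proteovary.recovery import covariation_record
from proteovary.stoichiometry import (
    complex_normalize, subunit_variance_zscores, cross_dataset_component_test,
)

cfg = CohortConfig(
    n_samples=200, n_complexes=50, latent_strength_range=(0.6, 0.6),
    n_variable_subunits_per_complex=1, n_datasets=3, seed=1,
)
cohort = generate_cohort(cfg)

rec = covariation_record(
    cohort.datasets[0], cohort.complexes, "complex", seed=1, mwu_iter=50
)
print(f"complex AUC = {rec.auc:.3f}  ({rec.n_positives} positive pairs)")

profiles = [
    subunit_variance_zscores(complex_normalize(ds, cohort.complexes))
    for ds in cohort.datasets
]
calls = cross_dataset_component_test(profiles)
hits = calls[calls.q_value < 0.05]
truth = set(cohort.truth.subunits.query("variable").protein_id)
print(f"variable subunits called: {len(hits)}, planted: {len(truth)}, "
      f"recovered: {len(set(hits.protein_id) & truth)}")
```

Output:

```
complex AUC = 0.908  (2969 positive pairs)
variable subunits called: 50, planted: 50, recovered: 50
```

An AUC of 0.91 means co-abundance separates within-complex pairs from
random pairs very well at the planted latent strength of 0.6 (the planted
variable subunit in each complex drags the AUC below the no-variable-subunit
ceiling); all 50
planted variable subunits (residual variance ×4, decoupled from their
complex) are recovered by the cross-dataset test at BH q < 0.05 with no
false calls.

The same stages are available as a CLI:

```bash
proteovary simulate --seed 1 --out sim/
proteovary recover --abundance sim/sim_d1.tsv --complexes sim/complexes.gmt \
    --interactions sim/interactions.tsv --seed 1 --out auc.tsv
proteovary all --seed 1 --out run/     # full pipeline on a synthetic cohort
```

## Layout

| module | contents |
| --- | --- |
| `proteovary.io` | TSV/GMT/STRING-style readers and writers |
| `proteovary.preprocess` | Shapiro–Wilk screen, log2 + quantile normalization, completeness filter |
| `proteovary.recovery` | pair correlations, condition sets, ROC/AUC, subsampled MWU |
| `proteovary.landscape` | complex co-abundance ranking, aggregation, decoys, permutation nulls |
| `proteovary.stoichiometry` | complex normalization, variance z-scores, component calls |
| `proteovary.covariates` | differential abundance, moderated-t contrasts, Fisher verdicts |
| `proteovary.effects` | ridge-CV effect sizes, pathway pre-filter, permutation FDR |
| `proteovary.simulate` | synthetic cohort generator and planted-R² oracle |
| `proteovary.cli` | `proteovary` command-line entry point |

See `docs/methods.md` for the statistical details and design choices.
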