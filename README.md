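# apopsens

Single-cell apoptosis-competency profiling from multiplexed
immunofluorescence cell tables.

Tumors evade therapy partly by suppressing intrinsic apoptosis, and bulk
measurements hide which cells — cancer, immune, or stromal — are actually
competent to die. `apopsens` takes segmented single-cell intensity tables
from multiplexed immunofluorescence of tissue microarray cores (or
generates seeded synthetic cohorts with the same statistical structure)
and computes, per cell:

1. **Slide batch correction** — upper-quantile normalization per
   (slide, marker), then a rankit-affine transform
   `z = (x − a)/b` fitted in a reference immune population
   (regulatory + helper T cells), then restoration to the intensity scale.
2. **Cell typing** — an ordered marker-gating hierarchy (epithelial →
   CD3⁺ T-cell subtypes → CD3⁻ leukocytes → stroma) annotates a training
   subset; a 2000-tree random forest on CD3, CD4, CD8, CD45, FOXP3,
   PCK26, AE1 classifies all cells, with out-of-bag per-class error.
3. **Molar calibration** — BAK, BAX, BCL2, BCL(X)L, MCL1 scaled against
   HeLa standards (`c = I/I_HeLa · c_HeLa`); PRO-CASPASE 3/9, SMAC, XIAP
   aligned to a reference cohort by median/IQR matching; APAF1 fixed at
   0.123 µM.
4. **MOMP sensitivity** — a mass-action ODE model of the BCL2 family: a
   BH3-only stress dose activates BAK/BAX, anti-apoptotic proteins
   sequester stress and activated effectors with member-specific Kd, and
   activated effectors dimerize irreversibly into pores. Readout:
   max pore% = 100·2(P_BAK+P_BAX)/(BAK₀+BAX₀) at a 200 nM reference
   dose; pore% < 10% ⇒ *low sensitivity*. The minimal dose reaching the
   threshold is found by bisection.
5. **Caspase activity** — an ODE model of executioner caspase activation
   downstream of MOMP: APAF1-limited apoptosome formation, caspase-9/-3
   maturation, XIAP inhibition and degradation, SMAC relief. Readout:
   substrate cleavage SC% at 60 min; SC% ≥ 25% ⇒ *high activity*.
6. **Heterogeneity statistics** — quartile COD (Q₃−Q₁)/(Q₃+Q₁), binary
   (log₂) and 0.1-SD-binned (ln) Shannon entropy, Moran's I with
   inverse-distance weights capped at 2000 px (I ≈ 1 spatial separation,
   ≈ 0 random, −1 checkerboard dispersion), and a seeded bootstrap
   (100,000 reps, seed 42) testing whether cores of the same tumor share
   cell-type composition.

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

```sh
apopsens run-all --seed 3 --outdir results/demo
```

runs the whole pipeline on a default synthetic cohort. In Python, at a
reduced size:

```python
from apopsens import GeneratorConfig, PipelineConfig, run_pipeline

mix = {"cancer": 0.55, "stroma": 0.20, "helper_T": 0.07,
       "regulatory_T": 0.06, "cytotoxic_T": 0.04, "other_immune": 0.08}
gen = GeneratorConfig(n_patients=5, cores_per_patient=(2, 2),
                      cells_per_core_mean=180, cells_per_core_sd=25,
                      type_mixture=mix, seed=0)
cfg = PipelineConfig(outdir="results/demo", seed=3, generator=gen,
                     training_frac=0.25, n_trees=200, min_train=5,
                     min_ref=20, min_population=50)
res = run_pipeline(cfg)
m = res["cells_with_readouts"]
immune = m[m.cell_type.isin(["helper_T", "cytotoxic_T",
                             "regulatory_T", "other_immune"])]
print(len(m), "cells")
print("immune: MOMP-low", round(immune.momp_low.mean(), 3),
      "caspase-high", round(immune.caspase_high.mean(), 3))
print("cancer: MOMP-low",
      round(m[m.cell_type == "cancer"].momp_low.mean(), 3))
```

prints

```
1782 cells
immune: MOMP-low 0.535 caspase-high 1.0
cancer: MOMP-low 0.002
```

i.e. the pipeline resolves the expected phenotypes: nearly all cancer
cells are predicted competent for mitochondrial permeabilization at the
reference stress dose, while the majority of immune cells are protected
(low MOMP sensitivity) yet caspase-competent — the `caspase_only`
quadrant. `results/demo/` contains the typed cohort, per-cell model
readouts, and a per-core summary with low/high fractions, quadrant
fractions, entropies and Moran's I per stratum.

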