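# Methods

`apopsens` quantifies apoptosis competency in tumor tissue from segmented
multiplexed-immunofluorescence single-cell tables. This note documents the
models, the conventions, and the design decisions a maintainer would need
to change them.

## Data model and record-level filters

A cohort is a flat table: one row per segmented cell with identifiers
(cell, position, core, slide, patient), pixel centroid coordinates, a
segmentation quality score in [0, 1], and one mean-intensity column per
panel marker (arbitrary units). The default panel carries nine apoptosis
proteins — BAK, BAX, BCL2, BCL(X)L, MCL1 feeding the MOMP model;
PRO-CASPASE 3, PRO-CASPASE 9, SMAC, XIAP feeding the caspase model — and
seven lineage markers (CD3, CD4, CD8, CD45, FOXP3, PCK26, AE1).

Cells within the image margins of their position are dropped before any
analysis: 15 px on the x-axis and 10 px on the y-axis, applied two-sided
(a margin is a property of the image frame, so both edges are trimmed).
Populations smaller than 100 cells are excluded from per-core
heterogeneity metrics; the boundary is inclusive (`>= 100`) by default
with a strict variant exposed, since both conventions appear in practice.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes so
every stage is testable without patient data:

- per-core cell counts from a truncated normal with mean 6492 and SD 1228;
- a Dirichlet-resampled per-core cell-type mixture around a cancer-
  dominated cohort mean (65.7% cancer, 23.6% stroma, ~10.7% immune split
  into helper/regulatory/cytotoxic T and other immune);
- lognormal marker intensities (non-negative, right-skewed, as in
  immunofluorescence) with cell-type-specific log-mean shifts. Lineage
  markers are separated by 4 log-SD between negative and positive
  populations, so phenotyping tests probe the pipeline rather than
  irreducible noise. Apoptosis markers encode the expected enrichment
  directions (BCL2 up in immune cells; BAK, XIAP, SMAC and both
  procaspases up in cancer cells; MCL1 low overall). The immune shifts
  were additionally chosen so that, under the default calibration and
  kinetic parameters, calibrated immune profiles sit mostly below the 10%
  pore threshold (protected phenotype: low effector load, high
  BCL2/BCL(X)L reserve), cancer profiles mostly above it, and stroma in
  between — the qualitative pattern the pipeline is meant to resolve;
- spatial layout: cancer cells clustered in Gaussian nests (default
  radius 220 px, 5 nests per core), immune and stromal cells dispersed
  uniformly; plus analytic lattice patterns (checkerboard, half-split,
  random) for spatial-statistics tests;
- QC scores from Beta(10, 0.7), skewed toward 1 (median ≈ 0.95); not used
  as a filter by default;
- slide-level batch distortions injected as per-(slide, marker) affine
  maps `x -> gain*x + offset`, clipped at 0, with the factors recorded in
  the ground truth.

What the generator does **not** emulate: segmentation errors, spatial
intensity gradients within a position, marker spillover/cross-talk, and
the true joint correlation structure of the nine apoptosis proteins
(cell-to-cell draws are independent given the cell type). Passing
recovery tests therefore demonstrate correctness of the computations
under the stated generative assumptions, not performance on real tissue.

## Batch correction

Two-stage, per slide and marker:

1. **Upper-quantile normalization.** Each (slide, marker) group is scaled
   so its 75th percentile equals the across-slide geometric mean of group
   quantiles for that marker (geometric mean keeps the correction
   scale-balanced; both the quantile and the target are configurable).
2. **Rankit-affine standardization.** Within a reference population —
   regulatory plus helper T cells, excluding cells within 5% of the image
   margins — the ordered normalized intensities are regressed on their
   rankits (expected standard-normal order statistics, Blom approximation
   `Phi^-1((i - 3/8)/(n + 1/4))`). The fitted intercept/slope (a, b) make
   the quantile–rankit line the unit diagonal, and `z = (x - a)/b` is
   applied to *all* cells of that slide and marker. At least 50 reference
   cells per slide are required by default; below that the fit is refused
   rather than silently degraded (tests at reduced cohort sizes lower the
   bound explicitly).
3. **Scale restoration.** One pooled OLS regression per marker of the
   normalized intensities on z maps the standardized values back to the
   intensity scale, floored at 0. Pooling (rather than per-slide
   restoration) is what makes the restored values comparable across
   slides.

Because batch correction needs a reference immune population before the
final classifier exists, gate annotation runs first with slide-dependent
thresholds (a global threshold is meaningless across slides carrying
multiplicative distortions); those preliminary labels define the
reference population.

Fitted slide gains are recoverable from the model: `b/f` (rankit slope
over UQ factor), normalized by its geometric mean across slides,
estimates each slide's relative gain up to the common reference spread.

## Cell typing

An ordered gating hierarchy labels a training subset: AE1 or PCK26
positive → cancer; else CD3+ cells split FOXP3+ → regulatory T (FOXP3
takes precedence over CD4), CD4+ → helper T, CD8+ → cytotoxic T, rest →
other immune; else CD3− cells positive for CD4, CD45 or CD8 → other
immune; else stroma. Double positives are resolved by hierarchy order and
flagged.

Positivity thresholds are data-driven: a two-component Gaussian mixture
on log-intensity, with the cut at the midpoint of the component means.
Two guards matter in practice: exact zeros (floored values) are excluded
from the fit, and when no second mode resolves (component separation
< 2 SD or a component weight < 0.5%) the threshold falls back to an
upper-tail rule (median + 3 robust SD) — Otsu-style splits fail outright
for markers positive in ~1% of cells (FOXP3, CD8). Otsu remains available
as an option.

A 2000-tree random forest (scikit-learn) is trained on the seven lineage
markers of a labeled subset (default 0.6% of cells, topped up so every
class reaches the 20-cell training minimum) and applied to all cells.
Out-of-bag votes give the per-class type-II (false-negative) error
reported with the model. On default synthetic mixtures the subtype errors
exceed the major-class errors, matching the expected ordering for
marker-based T-cell subtyping.

## Molar calibration

The five MOMP proteins are converted against cell-line standards:
`conc = intensity / HeLa_mean_intensity * HeLa_µM` per marker (positively
homogeneous in intensity). The four caspase-pathway proteins are aligned
to a reference cohort by a robust per-marker linear map sending the
observed (median, IQR) onto the reference (median µM, IQR µM); negatives
are floored. APAF1 is not imaged and is fixed at 0.123 µM, the limiting
apoptosome component. Per-core profiles aggregate intensities by median
within the core *before* conversion, so one outlier cell cannot move a
core profile.

The shipped `example_standards()` values are synthetic order-of-magnitude
stand-ins (documented as such); real analyses supply measured standards
via YAML. The alignment is cohort-global; per-slide alignment would
re-introduce the batch structure the correction just removed.

## MOMP model

Deterministic mass-action ODE network in µM and seconds. A BH3-only
"stress" species S (dose in nM at the interface) catalytically activates
the effectors (S + E → S + E*, rate `k_act`·[S][E]); the anti-apoptotics
A ∈ {BCL2, BCL(X)L, MCL1} reversibly bind S and both activated effectors
(association `k_on`, dissociation `k_on`·Kd); activated effectors
dimerize irreversibly into pores (rate `k_pore`·[E*]²). Readout:

    pore% (t) = 100 · 2·([P_BAK] + [P_BAX]) / ([BAK]₀ + [BAX]₀)

maximized over a 3 h horizon. A cell is **low-sensitivity** when pore%
stays strictly below 10% at the 200 nM reference stress dose. The minimal
dose reaching the threshold is found by bisection on the monotone
dose-response over [0, 10 µM] to 1 nM, with an explicit `unreachable`
sentinel (∞) when the bracket maximum fails.

Default kinetics (all YAML-configurable, chosen to express canonical
BCL2-family selectivity): `k_on` = 1, `k_act` = 0.1, `k_pore` = 0.05
µM⁻¹s⁻¹; Kd 0.02 µM for the tight pairs (BCL2–BAX*, MCL1–BAK*,
BCL(X)L–both), 1 µM for the weak pairs (BCL2–BAK*, MCL1–BAX*); 0.01 µM
for all anti-apoptotic–stress complexes. Treating stress as catalytic
(not consumed) makes the dose a well-defined control parameter for
bisection. Simulations use LSODA with rtol 1e-7 / atol 1e-10; every
conserved family (each effector, each anti-apoptotic, stress) closes to
better than 1e-5 µM on random profiles.

Not modeled (out of scope): BH3-only subtype identity, phosphorylation
states, mitochondrial vs cytosolic localization.

## Caspase model

Post-MOMP premise: cytochrome c is saturating at t = 0, so apoptosome
formation `APAF1 → Apop` (`k_apop` = 0.01 s⁻¹) is limited by APAF1 alone.
Apoptosomes bind procaspase-9 (association `k_bind9` = 1 µM⁻¹s⁻¹,
implemented irreversibly — the minimal network carries no dissociation
constant for this complex); the bound unit matures procaspase-3 at
`k_c9` = 0.1 µM⁻¹s⁻¹. XIAP reversibly inhibits caspase-3 (Kd 0.002 µM)
and the apoptosome·C9 unit (Kd 0.002 µM) and degrades the caspase-3 it
holds (`k_deg3` = 1e-3 s⁻¹, XIAP recycled); SMAC, fully cytosolic at
t = 0, sequesters XIAP (Kd 0.001 µM). Caspase-3 cleaves a normalized
substrate (Sub₀ = 1, `k_sub` = 1 µM⁻¹s⁻¹); the readout is

    SC% = 100 · cleavedSub(t_sc)

at t_sc = 60 min, **high** activity at SC% ≥ 25%. Neither the readout
time nor the cutoff is an established constant: both are prominent,
flagged config entries. The defaults give switch-like behavior over the
physiological 0.01–1 µM input range. Caspase-3 feedback cleavage of
procaspase-9 is deliberately omitted from the minimal network.

The joint label per cell is the pathway quadrant: both_high / momp_only /
caspase_only / both_low. On default synthetic cohorts the dominant immune
pattern is caspase_only (protected from MOMP, caspase-competent), the
dominant cancer pattern both_high.

## Heterogeneity statistics

- **Quartile COD** `(Q3 − Q1)/(Q3 + Q1)` with linear-interpolation
  quartiles; scale-invariant.
- **Binary Shannon entropy** of low/high state calls, log₂ (bits), with
  1e-10 added inside the logarithm as a guard against log 0.
- **Binned Shannon entropy** of protein levels: z-score, bin width 0.1 SD,
  natural log (nats), same epsilon.
- **Moran's I** `(N/W)·Σ w_ij (x_i−x̄)(x_j−x̄) / Σ (x_i−x̄)²` with
  inverse-distance weights `w_ij = 1/min(d_ij, 2000 px)` (zero diagonal;
  coincident centroids floored at 1 px), or binary rook adjacency for
  lattice patterns. Computed without outliers (Tukey fences, 1.5×IQR,
  per population, disable-able) and only on populations of ≥ 100 cells;
  smaller populations return a "not computed" sentinel. The checkerboard
  lattice with rook weights gives exactly −1 (perfect dispersion); the
  half-split pattern approaches +1; the permutation expectation is
  −1/(N−1).
- **Composition bootstrap**: observed statistic = mean within-patient
  Euclidean distance between core cell-type-fraction vectors (patients
  with ≥ 2 cores); null = the same statistic under random core
  re-pairings preserving group sizes; defaults 100,000 repetitions,
  seed 42; empirical p = fraction of null ≤ observed. Jensen–Shannon
  distance is available as an alternative metric.

Per-core summaries report, per stratum (cancer / pooled immune / stroma):
cell count, low/high fractions for both models, the four quadrant
fractions (summing to 1), binary entropies and Moran's I of both calls,
and COD plus binned entropy per apoptosis marker.

## Pipeline

`run_pipeline` executes: margin filter → slide-wise gate annotation →
batch correction (against the gate-called reference T cells) → random
forest typing (gate labels as training labels, corrected intensities as
features) → molar calibration → ODE simulations (per cell and/or per
core) → per-core heterogeneity summaries. Every stage logs cells in/out
(reconciled: in = out + excluded) to a JSON-lines file; all randomness
derives from one root seed through named substreams, so a rerun with the
same config reproduces every output table. Per-cell required-dose
bisection is opt-in (`do_required_dose`) since it multiplies simulation
cost ~15×.

## Problem sizes in the shipped tests

The test suite exercises the pipeline on seeded cohorts of ~1–17
thousand cells with 120–900 cells per core, an immune-enriched mixture
where the rankit fit needs reference cells at reduced scale, and reduced
forest sizes where tree count is not itself under test; the dose-coupling
analysis uses ≥ 1000 cancer-like profiles. These sizes were chosen as the
smallest at which the tested statistics are well-powered; all defaults
remain at the full-scale values documented above.

## Known limitations

- Kinetic constants are literature-anchored defaults, not fits; absolute
  pore%/SC% values depend on them, though the monotonicity, conservation
  and classification-boundary properties do not.
- The caspase readout time and SC cutoff are stand-ins (see above).
- Calibration accuracy is bounded by the supplied standards; the shipped
  example standards are synthetic.
- Moran's I with inverse-distance weights on a full core is O(n²) in
  memory/time; cores of ~6500 cells are the practical ceiling per call.
- The generator draws marker levels independently within a cell type; an
  optional correlated-sampling mode would be needed to study
  within-type covariance (e.g. BAK–BAX coupling) and is not implemented.
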