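# Methods

## Analysis model

The package treats drug-specific survival-marker discovery as a screen over
*cancer–drug patient groups*: all patients with one cancer type who were
exposed to one (canonically named) drug. Within a group, the predictor for
gene g is the binary high/low call obtained from a cohort-wide expression
threshold, and the outcome is right-censored overall survival. The test is
the two-sample log-rank statistic; multiplicity is controlled per group by
Benjamini–Hochberg. Significant genes are then aggregated into co-expressed
sets whose member-high fraction gives a set-level stratification, and sets
are annotated by hypergeometric TF-target over-representation.

Assumptions inherited from this design:

* expression is measured pre-treatment and is comparable across samples
  after log2(x+1) (FPKM-UQ-like normalization is taken as given);
* a single cohort-wide threshold per gene is meaningful, i.e. high/low is
  a property of the gene's bimodal expression distribution, not of the
  group;
* survival is an (imperfect) surrogate of drug response; no covariate
  adjustment is attempted — the log-rank comparison is marginal;
* censoring is non-informative.

## Survival encoding

Overall survival: deceased patients contribute (days-to-death, event);
all others contribute (days-to-last-follow-up, censored). Deceased patients
with no recorded days-to-death are dropped rather than imputed from
follow-up; rows with non-positive or missing times are dropped and counted
in the log. The time origin is whatever the clinical table encodes
(diagnosis for TCGA-shaped data); the field mapping is fixed in
`ingest.extract_survival` rather than guessed per cohort.

## Binarization

Values are sorted and fitted with a two-level step; the threshold
minimizes MSE = (Σ_low (x−μ_low)² + Σ_high (x−μ_high)²)/n over a candidate
grid of 200 rank-grid points (midpoints of the order statistics bracketing
200 evenly spaced ranks) plus 200 points evenly spaced strictly inside the
value range, deduplicated. Numerical choices:

* **"Low" is x ≤ t.** The closed side must be fixed somewhere; this choice
  makes a threshold at a tied value put the ties in the low arm.
* **Ties in MSE** break by (1) the more balanced split, (2) the candidate
  closest to the midpoint of its bracketing order-statistic gap, then (3)
  the smaller threshold. Step (2) matters: all candidates inside one
  inter-observation gap give the same split and the same MSE, and picking
  the gap midpoint (the canonical step location) rather than the gap's
  left edge centres the threshold between the expression components.
* **Degenerate genes** (constant vectors, or no candidate with both sides
  nonempty) get a NaN threshold and all-low calls; they are flagged, kept
  in the matrix, and excluded from testing — they can never yield ten high
  expressors.
* MSE is normalized by n, not n−2; a constant factor cannot change the
  argmin.
* For n ≤ 201 samples the rank grid covers every possible split, so the
  fitted MSE equals an exhaustive midpoint scan exactly; for larger n the
  grid is a 400-point approximation and the threshold is exact up to grid
  resolution.

The same routine (`binarize_scores`) thresholds gene-set fractions, so the
codebase contains exactly one thresholding algorithm.

## Log-rank test and direction

At each distinct event time, the high arm's observed deaths are compared
with the hypergeometric expectation and variance (which handles tied event
times); the statistic is (ΣO−E)²/ΣV on 1 df and the p-value is the χ²(1)
upper tail of the squared statistic — algebraically identical to the
two-sided normal form. Direction is the sign of Σ(O−E) for the high arm:
fewer observed deaths than expected means `high_better`. When ΣV = 0 (no
events, or every event time spans one arm only) the result is statistic 0,
p = 1, direction `tied`. Kaplan–Meier curves and plots delegate to
lifelines; the log-rank tabulation is implemented in-package because the
direction and the ΣV = 0 contract are part of the screen's semantics, and
it is cross-checked against lifelines in the tests. p-values are floored at
the smallest positive double so that p ∈ (0, 1] always holds.

BH adjustment uses `statsmodels.stats.multitest.fdrcorrection` and is
applied strictly within one cancer–drug group; there is no global
adjustment across groups.

## Co-occurrence clustering controller

The published sketch of co-occurrence clustering (gene graph → Louvain →
patient split → recurse) leaves the iteration control open; this package's
controller is a reconstruction in the same spirit, parameterized and
documented rather than claimed identical:

* Edges require Pearson χ² association p < `graph_alpha` (default 1e-3)
  **and** positive association (observed co-high above expectation), so
  mutually exclusive genes are never clustered as "co-expressed". Edge
  weight is the χ² statistic.
* Louvain runs at resolution 1.0 with an explicit seed (networkx's seeded
  implementation), so partitions are deterministic.
* Only communities of at least `min_set_size` genes (default 10) drive
  patient splits. Letting every chance two-gene community split the
  patients makes the recursion combinatorial without ever producing a
  reportable set.
* A branch stops when its patient subset is smaller than 2·`min_per_arm`,
  when the gene graph has no edges, when a split fails to shrink the
  subset, when the subset was already visited, or at recursion depth 10
  (a safety valve never reached in practice).
* Emitted sets are deduplicated by exact member identity; partial overlap
  between sets from different levels is allowed. Set ids are letters in
  discovery order (A, B, …, then AA).

Set scoring: the per-patient fraction of member genes called high is
thresholded with `binarize_scores`; a degenerate fraction vector (e.g. all
patients high for all members) yields a flagged, tied result. The
"percent of members more significant" statistic counts member genes whose
individual screen p is strictly smaller than the set's p, over all members.

## Enrichment

Hypergeometric upper tail (one-sided Fisher) of the overlap between a gene
set and each TF target set, both intersected with the universe first; gene
ids are upper-cased for matching. The universe defaults to the genes
actually tested for survival in the set's own group — the population the
set was drawn from — and can be widened to all genes in the matrix
(`enrichment_universe="all_genes"`, the implicit universe of web overlap
tools). BH runs within each gene set across TFs (default 5% FDR),
mirroring one overlap query per set; a global scope would be a one-line
change but mixes universes of different sizes.

## Synthetic cohorts

The generator emulates exactly the structure the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| `n_patients`, `n_genes` | 200, 500 | cohort size |
| `n_signal_genes`, `signal_hazard_ratio` | 5, 3.0 | independent bimodal genes whose latent high state multiplies the death hazard |
| `n_blocks`, `block_size`, `block_hazard_ratio` | 2, 20, 3.0 | co-expression blocks sharing a latent patient factor; the factor itself carries the hazard so members are survival-associated |
| `block_flip_prob` | 0.05 | per-gene probability of disagreeing with its block factor |
| `low_mean`, `high_mean`, `component_sd` | 2, 8, 0.5 | log2-scale mixture components |
| `bimodal_fraction` | 0.5 | fraction of genes given a two-component distribution |
| `baseline_hazard` | 1e-3 /day | exponential event hazard (median ≈ 690 days at baseline, a TCGA-like scale) |
| `censor_rate` | 5e-4 /day | independent exponential censoring (≈ 2/3 of patients die on study); 0 disables censoring |

Event times are exponential at hazard = baseline × Π HR over the
patient's high-state signal genes and high blocks. Expression is emitted
on linear scale (2^y − 1, floored at 0) so the ingest log transform is
exercised; clinical and exposure tables carry messy raw drug-name
variants, multi-drug patients, and duplicate rows.

What the generator does **not** emulate: TCGA's marginal expression
distributions and 60k-gene annotation, batch effects, informative
censoring, treatment-line structure, or correlated censoring and exposure.
Passing tests therefore demonstrate that the algorithms recover planted
structure under the stated generative model, not that real-cohort
discoveries are correct.

A property worth knowing when composing scenarios: multiplying many
independent HR-3 factors induces strong frailty — patients' hazards span
3^7 under the defaults — and frailty attenuates each factor's *marginal*
log-rank effect because high-hazard patients leave the risk set early.
Per-property simulations in the tests and the acceptance script therefore
plant only the structure under study (signal genes alone, or hazard blocks
alone); the combined default is used for the end-to-end smoke fixture.

## Problem sizes

Replicated checks run at desk scale, chosen so the whole suite completes
in minutes: 1,000 random instances (n ≤ 30) for log-rank oracle
equivalence; 50 seeds of n = 200 mixtures for threshold recovery; 50
null-cohort replicates (100 patients × 200 genes) for FDR calibration; 20
replicates of 200-patient single-group cohorts for sensitivity, block
recovery, and the set-level gain; 100 shuffled-universe permutations for
the enrichment null.

## Known limitations

* No Cox regression or covariate adjustment; the screen is marginal by
  design and confounding by stage, age, or co-therapy is untouched.
* A single cohort-wide threshold per gene assumes cross-sample
  comparability; strong batch effects would corrupt every downstream call.
* The log-rank screen has low power in small groups (the 20-patient and
  10-per-arm floors are hard limits, not cures).
* The clustering controller's stopping rules are one reasonable choice
  among several; sets near `min_set_size` can appear or vanish under a
  different controller.
* Patient-cluster structure is used only to discover gene sets and is not
  itself reported.
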