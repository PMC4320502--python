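# Methods

## Pipeline overview

The package turns two inputs — a purified-leukocyte reference matrix with a
class label per sample, and a bulk target matrix with control/disease
labels — into a per-cell-type infiltration call in four stages:
preprocessing (probe collapse, per-dataset standardization, cross-platform
gene alignment), marker selection (nearest shrunken centroids), metagene
scoring, and group comparison. A fifth module simulates both inputs so the
whole chain is testable without external downloads.

## Preprocessing conventions

* **Probe collapse.** For each gene the retained probe is the one with the
  highest mean over all samples of that dataset; ties keep the earlier
  probe in input order, so the operation is deterministic. Gene/probe
  identifiers are opaque strings; any probe→gene (or cross-species
  orthology) resolution happens outside the package through a user-supplied
  two-column map file.
* **Standardization.** Per gene, mean 0 and SD 1 with the *n − 1* sample
  denominator, computed over **all** samples of a dataset (control and
  disease together). Zero-variance genes become all-zero rows with a
  warning rather than an error: they contribute 0 to any metagene score,
  which is the neutral choice. A consequence of per-dataset standardization
  is that scores are comparable within a dataset but never across two
  datasets standardized separately; the score writer records a dataset id
  to make silent pooling harder.
* **Alignment.** Cross-platform comparison restricts both matrices to the
  intersection of their gene sets (row order following the first matrix).
  No imputation of genes absent on one platform is attempted.

## Nearest shrunken centroids

The standard NSC statistics are used: d<sub>ik</sub> = (x̄<sub>ik</sub> −
x̄<sub>i</sub>) / (m<sub>k</sub>(s<sub>i</sub> + s₀)) with pooled
within-class SD s<sub>i</sub> (denominator n − K), m<sub>k</sub> =
√(1/n<sub>k</sub> − 1/n), s₀ = median<sub>i</sub> s<sub>i</sub>, and
soft-thresholding d′ = sign(d)(|d| − Δ)₊ with shrunken centroids x̄<sub>i</sub> +
m<sub>k</sub>(s<sub>i</sub> + s₀)d′. The classifier minimises
Σ<sub>i</sub>(x<sub>i</sub> − x̄′<sub>ik</sub>)²/(s<sub>i</sub> + s₀)² −
2 log π<sub>k</sub>, with empirical priors and ties resolved in class order.
The degenerate-small design of the default reference (n<sub>k</sub> = 2,
K = 6, so s<sub>i</sub> has only n − K = 6 degrees of freedom) is supported
and tested; s₀ is what keeps the d-statistics stable there.

Design choices where more than one convention exists:

* **Ranking.** "Top k markers per class" ranks by **signed** d descending —
  a marker must be elevated in its class. Ranking by |d| (which would also
  admit strongly depleted genes) is available as `rank="abs"` but is not
  the default, since infiltration scoring needs positively expressed
  markers.
* **Disjoint panels.** Panels are made disjoint by greedy round-robin: in
  each round every class, in class order, claims its best unclaimed gene.
  This guarantees k·K distinct genes (150 with the defaults) and is
  deterministic. Exact ties in d rank lexicographically by gene id.
* **Shrinkage threshold.** No cross-validated Δ path is provided; panel
  size k is the model-complexity knob here, and `shrink()` (default Δ = 0)
  exists for the classifier.

## Metagene score and comparison

The score is the unweighted mean of standardized expression over the panel,
so it lives on the z scale; with perfectly specific markers and linear
mixing it is an affine function of the underlying cell fraction. Panel genes
missing from a target matrix are dropped by default (effective panel size
recorded and logged) because human-derived panels applied to another
platform or species necessarily lose genes; the strict `error` policy is
available. Scoring refuses matrices that do not look standardized (any gene
row mean beyond 1e-6).

Group comparison is a two-sided two-sample t-test per cell type — Student's
pooled-variance by default (df = n₁ + n₂ − 2), Welch by flag — with
significance at p ≤ 0.05 and the disease − control sign convention. No
multiplicity correction enters the primary call; a Benjamini–Hochberg
q-value column is emitted alongside as supplementary output. Zero-variance
degenerate inputs resolve by the limit of the statistic (equal constant
groups: t = 0, p = 1; distinct constant groups: |t| = ∞, p = 0).

## Synthetic data: what it emulates and what it does not

`simulate_reference` draws a per-gene baseline ~ N(7, 1) (an RMA-like log₂
scale; per-gene constants cancel out of both d-statistics and standardized
scores), assigns each class a disjoint random block of
`markers_per_class = 30` markers elevated by `marker_effect = 3` noise-SD
units, and adds i.i.d. N(0, `noise_sd = 1`) noise. The default layout is 6
classes × 2 replicates over 500 genes.

`simulate_cohort` models a biopsy as a convex mixture: leukocyte mean
fractions default to an equal split of the non-stromal half of the tissue
(0.5/6 ≈ 0.083 each, stromal remainder 0.5 in controls); a disease
`fraction_shift` raises named cell types' mean fractions, and the stromal
remainder absorbs the shift — infiltrate displaces stroma — so unshifted
leukocyte types keep their control means and are genuine nulls. Negative
shifted fractions clip to 0; if the leukocyte total exceeds 1 the vector is
renormalized onto the simplex (stromal 0). Per-sample fractions are drawn
from Dirichlet(concentration × group mean) with concentration 50 (mild
biological variability, fraction SD ≈ 0.04–0.06 at the default means).
Samples mix the noiseless class signatures on the log-like scale (an exact
linear-scale mixture followed by log₂ is available as `mixing="lognormal"`);
the stromal signature is the shared baseline plus its own unit-SD gene
effects on non-marker genes only, since leukocyte lineage markers being
silent outside their lineage — stroma included — is precisely what makes
them markers.

Measurement noise is `bulk_noise_sd = 0.3` per gene for cohorts, smaller
than the sorted-population `noise_sd = 1`: bulk hybridizations average far
more input material, and replicate-level SDs of ~0.2–0.5 log₂ units are
typical for RMA-processed arrays. A design power analysis fixed this before
any benchmark was run: with 25-gene panels the score-level noise is
0.3/√25 = 0.06, giving near-unit power for a +0.15 fraction shift at
n = 7 vs 8 while leaving the t-test's 5% type-I calibration untouched
(calibration does not depend on the noise scale).

What the simulation does **not** emulate: probe-level artifacts, batch
effects between series, correlated gene-gene noise, cross-species ortholog
loss, compositional correlations beyond the Dirichlet, or any cell-type
signature overlap (e.g. the real CD4/CD8 cross-reactivity). Passing tests
therefore demonstrate that the statistics do what they claim under the
stated generative model — not that marker panels derived from any real
reference are specific, which must be re-validated per dataset (the
self-recovery check exists for exactly that purpose).

## Problem sizes and numerics

The default study sizes (500 genes, 6 × 2 reference, 7 + 8 or 4 + 4
cohorts) keep every simulation light: the repeated-cohort benchmarks in the
test suite use 100 replicates for detection rates and 2000 for type-I
calibration, sizes at which a 5% rate is estimated to ±1 percentage point.
All randomness flows through `numpy.random.default_rng` seeds carried in
the simulation config, so identical seed + config is bit-identical.
Numerical tolerances: oracle equivalence at 1e-10, scoring identities at
1e-12, standardization at 1e-10 with idempotence at 1e-8.

## Known limitations

* Metagene scores are relative (z-scale within a dataset); the method
  detects *differences* in infiltration, not absolute cell fractions.
* With two replicates per reference class the d-statistics are noisy;
  panel recovery of true markers averages ~90% at a 3-SD effect, so real
  panels will carry some passenger genes. Scores average over 25 genes,
  which dampens but does not remove this.
* Student's t on n = 4 vs 4 (the small-cohort layout) has limited power for
  moderate shifts, as `analysis/05_operating_characteristics.py` makes
  explicit for the 7-vs-8 layout; small-cohort negative results are weak
  evidence of absence.
* Unequal-variance groups are better served by the Welch flag; the Student
  default mirrors the classical workflow this pipeline reproduces.
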