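# Methods

## The affinity model

TBP association with a proximal promoter is treated as three experimentally
motivated steps — one-dimensional sliding along the duplex, stopping at a
TATA-like site, and fixation of the complex by the ~90° DNA bend — and the
model scores each W-long window of the input as a linear combination of one
term per step:

    ln K_D(window) = b0 + b1·slide + b2·recognition + b3·bend   [ln nM]

* `slide` and `bend` are means over the window's W−1 dinucleotide steps of
  two 16-entry tables. The shipped sliding table holds unified
  nearest-neighbour duplex stacking free energies (kcal/mol, 37 °C): duplex
  stability is the natural sequence covariate for a protein tracking and
  deforming DNA non-specifically. The shipped bend table is a coarse 0–1
  deformability scale encoding the standard flexibility ordering
  (pyrimidine–purine ≫ purine–purine ≈ pyrimidine–pyrimidine >
  purine–pyrimidine; TA most bendable, GC stiffest). It is a
  package-authored scale, shipped as replaceable data like every other
  number in the model.
* `recognition` is the log-odds score of a 15-column TATA-box position
  weight matrix (base counts compiled from canonical TATA-box alignments;
  counts → log-odds with pseudocount 0.5 against a uniform background).
* The promoter's estimate is the **minimum** over all windows — one
  governing TBP site per proximal promoter — with the leftmost window
  reported on ties. Only the printed strand is scanned: the inputs are
  fixed, TSS-anchored promoter sequences, and TBP-site annotation in them is
  strand-specific.

The standard error attached to every estimate is a single constant: the
residual σ of the calibration regression (default 0.3 ln-units before any
calibration). This is deliberately the simplest reproducible error model —
one σ for all sequences — because the estimate itself is a regression
prediction.

### Calibration

`calibrate_model` fits (b0…b3) by ordinary least squares of observed
ln K_D on the three component scores at each sequence's governing window.
Because the governing window itself depends on the coefficients, the argmin
assignment and the refit alternate until the assignment is stable (or 50
rounds). The residual σ (floored at 10⁻⁶) becomes the new standard error.
At least 8 pairs are required, and a rank-deficient design (a component
constant across the data) raises rather than silently dropping terms.

Calibrated against the 238 WT rows of the packaged marker tables, the model
reaches Spearman ρ ≈ 0.80 against the printed WT ln K_D and reproduces the
printed direction of the allele effect (Δ) for ≈ 88% of rows — computed
fresh by `scripts/acceptance.py`, not quoted. The printed K_D values
themselves derive from a regression whose exact coefficients are not public,
so the shipped defaults are calibration targets, not ground truth; all
numeric content lives in data files.

## Allele comparison

Two estimates with standard errors are compared with the normal (Fisher Z)
test on the ln scale, two-tailed because affinity deficiency and excess are
treated symmetrically. The significance bins {10⁻⁶, 10⁻³, 10⁻², 0.05} bound
the p-value from above (the smallest bin containing p), and map one-to-one
onto ranks A–D with E for non-significant. The expression-change symbol Δ is
'>' when K_D falls significantly, '<' when it rises, and '=' otherwise —
'=' is an artifact-only symbol used for non-significant or exactly equal
pairs. One misprint-looking rank/bin combination exists per ~100 shipped
table rows; the fixture keeps them as printed and the consistency test
tolerates ≤ 3 such rows.

## Marker annotation

The mapping from expression direction to atherogenesis direction is *data*,
not code: a curated TSV with one rule per gene (direction on over- and on
under-expression, with the clinical/physiological rationale as citation
text). Some genes accelerate atherogenesis in both directions (e.g. MBL2,
F7, INS); both directions of one SNP can therefore carry opposite
annotations only through separate alleles, which the per-allele expansion
handles naturally. Non-significant comparisons and genes without a rule stay
unclassified.

Marker bookkeeping follows the source tables' own convention: one marker per
table row, even when a row lists several minor alleles (they share one
printed K_D and significance). The batch pipeline therefore reports one row
per input record by default (238 for the shipped tables) and exposes
`per_allele=True` (253 rows) for allele-resolved work.

## Selection-pattern statistics

Both tests are exact Binomial(n, ½) tail computations (summed pmf, log-space
accumulation for n > 1000):

* **Drift confidence** `1 − P(X ≥ n_< | n_> + n_<, ½)`: the acceptance
  probability of "TBP-site-damaging variants dominate", the genome-wide
  neutral-drift pattern (reference ratio 200:800, interrogable via the same
  tail at q = 0.2).
* **Equivalence tail** `P(X ≥ max(n_↑, n_↓) | n_↑ + n_↓, ½)`: a one-sided
  exact tail at the larger count, small when one atherogenesis direction
  clearly dominates.

These exact constructions were chosen because, verified by enumeration, they
reproduce every probability cell of the study's summary table from its own
printed integer counts — including the boundary cases (72, 73) → 0.50 and
(19, 15) → 0.30.

A caveat the package states openly: as a *test*, the equivalence tail at the
larger count is anticonservative under the null, since either arm can reach
the critical count — at n = 100 its true rejection rate at the 0.05 level is
2·P(X ≥ 59 | 100, ½) ≈ 0.089, not 0.05. It is retained because it is the
construction consistent with all published cells; the acceptance suite
measures (and reports) the actual rate rather than hiding it.

## Concordance statistics

Pearson r, Spearman R and Kendall τ use their standard implementations
(τ-b, tie-corrected — appropriate for K_D values quoted on a rounded nM
scale). Goodman–Kruskal γ = (C − D)/(C + D) over all unordered pair-of-pairs
with ties excluded is computed by direct pair counting, and its p-value by
seeded permutation of the measured coordinate: validation sets here have
n ≈ 5–10, far too small for asymptotics. Because γ's permutation
distribution is coarse and tie-rich at such n, the mid-p convention (ties at
half weight) is used; it keeps the null p-value distribution approximately
uniform where plain counting is visibly conservative. The allele-difference
scale (one (minor − ancestral) pair per SNP) removes the shared promoter
context and isolates the predicted shift.

## Synthetic cohorts

The generator emulates the *shape* of the study inputs: 70 bp uniform-
background promoters; one planted TATA-like site, placed uniformly within
TSS-relative −50..−20 (where the clinically annotated TBP-site SNPs
cluster), matching the PWM consensus per position with probability
`planted_site_strength` (default 0.85 — real TATA boxes deviate from the
consensus, and a perfect-consensus site would admit no affinity-raising
mutation); single-base variants placed inside or outside the site per
`in_site_fraction`; the minor allele chosen to raise affinity with
probability `prop_affinity_up`; and pseudo-measurements with i.i.d.
Gaussian noise on the ln scale (default σ = 0.3 ln-units, a realistic
gel-shift replicate spread).

One structural fact matters for interpretation: a mutation outside the
governing window cannot raise the promoter minimum, so "no change" is a
real, common outcome for out-of-site SNPs. Truth labels are therefore
ternary (up/down/equal), the wanted direction is realised by scanning up to
12 shuffled candidate positions within the drawn class, and generating
proportions are recovered *conditionally on directional SNPs*. What passing
synthetic tests show is that the statistics recover known generating
proportions through the full pipeline; they say nothing about linkage,
allele-frequency spectra, database ascertainment, or non-uniform genomic
background, none of which are emulated.

## Problem sizes and numerical choices

Default analyses use the shipped 238-row tables; synthetic checks use
cohorts of 300–500 SNPs and 6–10 seeded replicates, and the null
rejection-rate measurement uses 2000 binomial replicates at total 100 —
sizes at which every reported proportion has a standard error of a few
percent or less. Exact binomial tails are validated against rational-
arithmetic enumeration (n ≤ 25) and an independent survival-function route;
the vectorised window scan is validated against a naive double loop; γ
against exhaustive pair counting. Ties in the window minimum break to the
leftmost window; p-values are clamped away from exact 0 to keep the
significance-bin domain valid at extreme Z.

## Known limitations

* The functional form is structural: a linear combination of three step
  scores over a best window. The original regression's coefficients and
  error model are not public; after calibration the model reproduces ranks
  and directions well (ρ ≈ 0.8, ≈ 88% Δ agreement) but not the printed
  K_D values digit-for-digit, and does not attempt to.
* One gene set's printed atherogenesis-direction split disagrees between
  the source's per-row annotations and its own summary row; the fixture
  records the per-row annotations and the summary counts are carried as
  reference data, so both readings are available.
* No reverse-strand scanning, no multi-site aggregation, no cooperative or
  nucleosome effects, no multiple-testing correction across SNPs (per-SNP
  significance bins only, matching the source analysis).
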