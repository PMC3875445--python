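# Methods

## Study design the package models

The design is a four-library, two-compartment contrast without
replicates: small-RNA libraries from pooled tumour tissue (control L1,
ribonuclease-treated L2) and pooled blood serum (control L3, treated
L4) of tumour-bearing mice. Each library pools 20–30 animals, so each
condition × compartment is observed exactly once, at great depth. All
statistical machinery here is chosen for that regime; nothing in the
package estimates biological variance from replicates.

## Quantification

RPKM is computed literally as count / (length_kb × total_reads_millions).
The miRNA "size" is the mature length in nt from the input table
(default 22 when absent); mature lengths are used rather than hairpin
lengths because mature species are what stem-loop qPCR validates. A
miRBase-style GFF3 can supply lengths (`miRNA` features, `Name`/`ID`
attributes).

Composition percentages divide each read class by the library's **total**
reads — the only convention consistent with the published table's cells
(2.7%, 67.3%, …) despite that table's footnote wording about mapped
reads — and are rounded half-up to one decimal. One published cell
(control-tumour miRNA, printed 1.4%) is arithmetically 965017/71675921 =
1.346…% → 1.3%; the implementation follows arithmetic and the cell is
flagged here rather than reproduced.

## Differential abundance between two pooled libraries

With a single library per condition, the only tractable null is equal
relative abundance under multinomial/Poisson sampling at the two
depths. Conditional on a feature's total reads n = c₁ + c₂, the control
count is Hypergeometric(d₁+d₂, d₁, n). The default p-value is the
central exact two-sided value (twice the smaller tail, capped at 1).
Numerics: when n ≤ 10⁻³ (d₁+d₂) the hypergeometric is evaluated as
Binomial(n, d₁/(d₁+d₂)) — relative error O(n/depth), ~10⁻⁵ here — which
gives an O(1) cdf instead of an O(n) enumeration. A mid-p variant and a
likelihood-ratio G-test on the same 2×2 table are selectable
(`method="midp" | "lrt"`). All three are within the nominal-size band at
informative counts (measured 0.039 / 0.045 / 0.045 at the 2000-feature
Poisson null used in the acceptance checks) and are conservative, never
anti-conservative, at shallow counts.

Two caveats define what this test can and cannot mean:

- **Calibration is with respect to counting noise.** Overdispersion
  between libraries cannot be estimated from this design; the null
  calibration check therefore runs at the Poisson limit (dispersion 0).
  Under substantial extra-Poisson noise any replicate-free two-library
  test is anti-conservative — a fundamental limit of the design, not of
  the implementation.
- **"Affected"** = q ≤ 0.05 (Benjamini–Hochberg) AND fold ≥ 1.5,
  emulating "reliable change" tables. Features with fewer than 10 reads
  in both libraries are flagged `low_evidence` (mirroring the caveat
  that several published down-calls rested on very few reads).

Fold changes are RPKM ratios reported as value ≥ 1 plus direction.
Features with a zero count on either side get +0.5 added to both raw
counts before the ratio — finite folds, standard practice. Whether the
original analysis floor-adjusted its folds is unknowable from the
publication; the pseudocount is a config knob (`pseudocount`).

The original analysis used a read-mapping + Cufflinks stack on
colour-space reads; that stack is deliberately not reproduced (read
mapping is upstream of this package), and the conditional exact test is
the declared in-house replacement for two-library designs.

## TS/TF candidate prioritization

Implemented step-for-step as the selection-algorithm table describes:
sort by control abundance, superpose treated, compute L2/L1 and L3/L4
folds, keep the top-100 by L1 abundance, reject features absent from any
library, compute TS (= L1 + L3 score), TF (= sum of folds), rank by
TS/TF ascending, select 0 < TS/TF ≤ 20 with TF ≥ `min_tf`, annotate from
a curated list. Choices the source leaves open:

- "score" = RPKM in the respective **control** library (the table sorts
  by abundance score in RPKM).
- "high TF" is undefined; exposed as `min_tf`, default 4 — two
  compartment folds of ≥ 2 each, consistent with the reported 2–10×
  boost and 2–6× drop regimes.
- The "top 100 of L1 and L2" is read as top-100 by L1 abundance;
  `top_pool="union"` pools the top-100 of each instead.
- Ties in TS/TF break by TF descending, then feature id — full
  determinism.

TS scales with a common rescaling of all four libraries while TF does
not, so the TS/TF ≤ 20 window is tied to the RPKM scale of the input;
that is a property of the published statistic, not a bug. A consequence
visible on default synthetic data: when abundance and effect size are
drawn independently, top-100 features rarely clear the window — the
window presupposes the study's situation where its strongest responders
sat at moderate-to-high abundance.

The packaged annotation list (`data/oncomir_annotations.tsv`) covers the
nine validated candidates plus the let-7 family; it is a convenience
default, replaceable by any user TSV (feature_id, class, citation).

## Clustering

Z-scores use the sample standard deviation (ddof = 1); constant vectors
map to zeros with a warning. Gene and sample dendrograms are computed
independently on row-scaled and column-scaled values respectively.
UPGMA is implemented in-package so tie-breaking is specified: among
equal minimum average distances the pair with the lexicographically
smallest representative indices merges first (a cluster's representative
is its smallest original index), and leaves print smallest-representative
first. The Lance–Williams average-linkage update keeps every
inter-cluster distance equal to the mean over cross-cluster point pairs,
so the merge heights equal brute-force recomputation exactly; the test
suite verifies this on hundreds of random instances and cross-checks
heights against scipy's `linkage(..., "average")` on tie-free inputs.
Dendrograms export as Newick with branch length = parent height − child
height (leaves at height 0, so the tree is ultrametric).

## qPCR analysis

The Ct model throughout is Ct = intercept − log(quantity)/log(1+E).

- **Standard curves:** least squares of Ct on log₁₀(dilution) over ≥ 3
  distinct dilutions (the study used 10⁻², 10⁻³, 10⁻⁴);
  E = 10^(−1/slope) − 1, perfect doubling ⇔ slope −log₂10 ≈ −3.3219.
  Non-negative slopes and E outside (0, 1.2] flag the fit invalid.
- **Reference stability:** geNorm's M — for gene j the mean over other
  candidates k of the sd across samples of the pairwise log₂ expression
  ratio. Implemented from the published definition (single pass by
  default, classic iterative exclusion via `iterative=True`) because the
  source names only a "minimal M-value" criterion. M is invariant to
  per-gene additive Ct offsets. The minimal-M pair is the default
  normalizer, matching the study's choice of two references.
- **Relative expression:** efficiency-corrected on the log₂ scale —
  target log₂ quantity minus the arithmetic mean of reference log₂
  quantities (geometric mean on the linear scale), or minus log₂(serum
  volume) in serum mode (no spike-in modelling; the study used volume
  normalization for serum). With all E = 1 this is exactly 2^(−ΔΔCt).
  Whether the original quantification was efficiency-corrected is not
  stated; corrected is the default, plain ΔΔCt is the E = 1 special case.
- **Group comparison:** two-tailed unpaired Student's t (equal
  variances, per the study's wording; Welch via `equal_var=False`) on
  log₂ expression; stars at p < 0.05 / 0.01 / 0.001.

## Synthetic-data generator

The generator's defaults are the study's published structure: 615 / 617
detectable miRNAs, affected sets of 116↑ + 7↓ (tumour, 2–10×) and
137↓ + 2↑ (serum, 2–6×) with an 81-feature common core, per-library
miRNA-read yields equal to the published ones (0.56–1.4 million), and
read-class fractions equal to the published composition table.

Parameters and their rationale:

- `n_features` 720 — catalog size from which the 615/617 detectable sets
  are drawn; large enough that the affected-set arithmetic is satisfiable
  with margin under the abundance model.
- Base abundances log-normal, meanlog 3 / sdlog 2 on the RPKM scale.
- `affected_min_abundance` 50 RPKM — effects are assigned to features
  above this floor, because observed affected lists are conditioned on
  quantifiable abundance; below it, a 2-fold change is not detectable at
  the study's depths by any method.
- `library_depths` are expected **miRNA-mapped reads**. Count means are
  scaled so the control library's expected feature-read sum equals the
  depth, and the stored RPKM normalization total is derived
  (T = 10⁶ × depth / Σ base×length_kb over detectable features) so that
  E[RPKM] = base × effect holds exactly. Treated libraries' realized
  yields drift from the configured depth by the net treatment effect,
  as they would in reality.
- `dispersion` 0.005 — per-library negative-binomial overdispersion.
  Pooling n ≈ 20–30 animals attenuates between-animal variance roughly
  n-fold, so per-library extra-Poisson noise is small; moreover at
  dispersion ≳ 0.1 the irreducible between-library log₂ noise (≈ 0.65)
  would make 2-fold changes undetectable in principle, contradicting the
  study's own published detections. The parameter is free precisely
  because the pooled design makes the true variance unrecoverable.
- Read-class compositions: multinomial with total reads derived as
  depth / miRNA-fraction, classes {miRNA, mRNA, rRNA, filter, unmapped},
  mapped = the four specific classes summed (the published table's
  identity).
- qPCR plates: Ct from the model above, Gaussian Ct noise (default sd
  0.2 cycles), a per-sample loading factor (log₂ sd 0.5) common to all
  genes, six reference candidates of which two (`hprt1`, `rpl30` — the
  study's final choice) wobble with log₂ sd 0.05 and the rest 0.8, and
  standard-curve wells at factors 1, 10⁻², 10⁻³, 10⁻⁴.
- RNG: one master seed; `SeedSequence.spawn` children consumed in the
  order catalog → counts → compositions → qPCR. Identical seed + config
  is bit-identical output.

The nine-candidate validation scenario (`validation_scenario`) builds a
200-feature catalog directly, with the nine literature-named miRNAs at
base 50–90 RPKM, tumour boosts 8–10× and serum drops 4–6× — abundant
enough for the top-100 cut, affected enough for TS/TF ≤ 20 — over a
background of neutral and moderately affected unannotated features, at
10⁸ reads so sampling noise cannot blur the selection window.

**What the generator does not emulate:** read-level artifacts (adapters,
quality, colour-space), mapping ambiguity, cross-mapping between miRNA
family members, correlation between abundance and effect size, and any
real biological covariance structure across animals. Passing tests
demonstrate that the analysis code implements its declared statistics
correctly and recovers known structure under the stated noise model —
not that the original biological conclusions are reproduced from raw
data (the deposited reads are not used).

## Problem sizes in the checks

The acceptance checks run the differential stage at 10⁷ miRNA reads per
library on the default 720-feature catalog (recovery) and a
2000-feature Poisson null (calibration); clustering properties use 200
random instances of up to 6 items against exhaustive recomputation; the
qPCR recovery uses 6 replicates per group at Ct sd 0.2. All complete in
seconds.

## Known limitations

- No replicate-based dispersion estimation or batch correction (out of
  design scope); the significance calls inherit the pooled design's
  inability to see biological variance.
- The TS/TF window is scale-dependent (see above).
- Newick export encodes topology and heights but not merge order for
  tied heights.
- The composition summary treats classes as given; it does not remap
  reads.
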