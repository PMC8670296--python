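# Methods

This note documents the statistical procedures, the simulation model, the
numerical conventions, and the design choices that were genuinely open.

## Quantification

Per-gene percent methylation is the methylated fraction of amplifiable
copies, in percent: %M = 100·m/(m+u). A zero total (m+u = 0) is an
*undefined* measurement (assay dropout) and raises an error; recording it
as 0 %M would turn a failed assay into evidence of absent methylation, and
the package never imputes. The panel score is the cumulative methylation
index (CMI), the per-sample sum of %M over the panel's genes; it is linear,
so CMI of a disjoint union of panels is the sum of the parts, and bounded
by 100·|panel|.

%M (0–100, PCR-based) and array beta values (0–1) are deliberately distinct
types; they never mix in one matrix.

## Rank statistics

Group comparisons use the two-sided Mann–Whitney U test. U counts pairwise
wins plus half-ties, so U/(n₁n₂) is exactly the empirical ROC AUC; the test
suite asserts this identity on random instances, tying the rank test and the
ROC module together. Two modes are provided, since published p-values rarely
state which was used:

* **exact** — full enumeration of all C(n₁+n₂, n₁) group assignments over
  the observed pooled multiset (ties handled by enumeration); allowed up to
  pooled n = 20. Two-sided p doubles the smaller tail, capped at 1.
* **normal_approx** — midranks, tie-corrected variance, continuity
  correction of 0.5. For tie-free samples with n₁ = n₂ = 8 it agrees with
  the exact p within 0.02 (property-tested).

A constant pooled sample has zero rank variance; p = 1 by convention, with
an `all_tied` flag.

Five-number summaries (min, q25, median, q75, max) default to the rank
k = p·(n+1) convention with linear interpolation clamped to [1, n]
(Hyndman–Fan type 6, the convention of several commercial statistics
packages, and the one consistent with the packaged reference table). The
method is configurable (`linear`, `median_unbiased`) because quartile
conventions visibly change small-sample q75 values and therefore the
background filter.

## Marker selection

Three fixed stages, in this order:

1. **Significance**: keep genes with p < α (default 0.05) *and* carcinoma
   median ≥ normal median. The direction check matters: the selection
   criterion is "significantly higher in carcinoma", and without it a gene
   significantly higher in *normal* tissue would survive.
2. **Background**: discard genes whose normal-class q75 ≥ 10 %M. The
   boundary is inclusive — the packaged worked example contains a gene
   (COL6A2) whose normal q75 is exactly 10 and which must be eliminated.
3. **Ranking**: descending carcinoma q75; ties broken by descending
   carcinoma median, then lexicographic gene id, with every tie logged in
   the audit trail. The top k (default 6) form the panel.

Summaries can be injected directly (bypassing raw data), which makes the
published summary table a first-class fixture: the packaged reference
reproduces the 8-gene shortlist
TMEFF2 > GPX7 > MAL > ARHGEF7 > TWIST1 > AKR1B1 > HIN1 > GAS7 and the
6-gene panel exactly.

## ROC analysis and locked thresholds

Candidate thresholds are midpoints between consecutive distinct pooled
scores plus ±∞ sentinels; the decision rule is score ≥ t ⇒ carcinoma. With
midpoint candidates the ≥/> distinction is immaterial on observed data, and
on integer-valued scores all finite candidates end in .0 or .5 — the
convention that produces half-integer laboratory thresholds from
integer-reported %M data.

Locking maximizes training sensitivity subject to training specificity ≥ a
floor (default 0.90); the +∞ sentinel guarantees feasibility; among equally
sensitive feasible candidates the largest threshold wins (most
conservative). The resulting object is a frozen dataclass carrying its
training operating point and provenance; evaluation applies it verbatim and
cannot re-optimize on test data. On disk, `evaluate` only accepts threshold
files written by `lock`.

Confidence intervals: Clopper–Pearson (exact binomial) for sensitivity and
specificity; DeLong for the AUC, collapsing to a degenerate interval when
the DeLong variance is zero (e.g. AUC = 1), with a seeded stratified
bootstrap (2000 replicates) available as an alternative. Published CI
conventions for such panels vary by software and are not reproducible in
general; CI numerics here are documented behavior, not a claim of matching
any particular tool.

Predictive values use the prevalence-weighted formulas given in the README
at a default prevalence of 1%, reported in percent. PPV is undefined
(NaN + flag) when sensitivity = 0 and specificity = 1; NPV symmetrically.

## Clustering prescreen

The array prescreen clusters probes by unweighted average linkage (UPGMA)
on Euclidean distances over unadjusted beta values. The linkage is
implemented in-package so its conventions are explicit: inter-cluster
distance d(A∪B, C) = (|A|·d(A,C) + |B|·d(B,C))/(|A|+|B|); ties in the
minimum broken by lowest cluster-index pair and logged. It is verified
against both a brute-force recompute-everything oracle (all random n ≤ 8
instances tested) and scipy's average linkage. "Which average linkage" a
commercial tool uses is generally unstated; UPGMA (unweighted) is the
default here.

The candidate set is the flat cluster (cut by count or height) maximizing
the mean differential score (mean carcinoma beta − mean normal beta),
filtered per-probe at a minimum score. Expert picks outside the winning
cluster are supported through an explicit include-list rather than
automated — a visual judgment is not algorithmically recoverable.

## MSI association

Carcinomas with known microsatellite status are compared MSI vs MSS per
gene (and optionally on a panel CMI) with the Mann–Whitney test; unknowns
are excluded internally and deterministically. Raw p-values are primary,
matching common practice; a Bonferroni column is emitted alongside, labeled
as an extension, so the multiplicity over 13 genes stays visible.

## Simulation model

Each gene/class is modeled by the piecewise-linear quantile function through
(0, min), (0.25, q25), (0.5, median), (0.75, q75), (1, max) and sampled by
inverse transform. This was chosen over parametric fits (beta, lognormal)
because it reproduces published five-number summaries *by construction*,
including point masses when adjacent quantiles coincide, and confines every
draw to the published support. Defaults:

* cohort sizes 30 carcinoma / 23 normal (the reference training cohort);
* %M quantized to 1 %M steps and clipped to the spec support — the
  reference summaries are integer %M, so quantization emulates the assay's
  reporting precision. It is also what makes the background filter's
  boundary gene reproducible: under continuous sampling an empirical q75
  sitting exactly at the inclusive 10 %M cutoff falls on either side with
  probability ≈ ½ at any sample size, whereas the quantized distribution
  has an interior point mass at 10 and the empirical q75 converges there;
* a third of carcinomas labeled MSI (randomized placement, deterministic
  count), optional additive per-gene %M shifts in MSI tumors, clipped to
  [0, 100];
* ages truncated-normal, mean 69 (carcinoma) / 66 (normal), sd 8, range
  40–95 years;
* genes independent within class. Published data are marginal summaries
  only, so independence is the minimal assumption. Real tumors are
  correlated across markers, which would *increase* CMI class separation —
  passing separation tests under independence is therefore conservative in
  that one respect, but the simulation says nothing about batch effects,
  assay noise, or the true dependence structure, and panel performance on
  synthetic cohorts must not be read as a clinical performance estimate.

The plasma regime models the near-zero background of normal cell-free DNA:
per gene, normal %M is 0 with probability 0.9, otherwise Uniform(0, 2);
carcinoma signal is Gamma(1.2, 6) clipped to [0, 100]. These defaults are
invented operating conditions to exercise the plasma workflow (8-gene and
5-gene panels), explicitly not a fit to any assay chemistry.

The beta-matrix generator produces a block design (a differentially
methylated probe block vs a null block, Gaussian noise clipped to [0, 1])
whose truth is encoded in probe ids, for validating the clustering
prescreen.

The train/test split stratifies by class × age tertile, deals each stratum
alternately after shuffling (per-stratum sizes within ±1), and
re-randomizes up to 50 times until class-wise mean ages differ by ≤ 3
years, keeping the best draw otherwise. Missing ages degrade to class-only
stratification with a warning.

## Numerical choices and problem sizes

* Quartile-recovery checks sample n = 10⁵ per gene/class (±1 %M).
* The end-to-end selection test samples 5000 per class: the empirical
  carcinoma q75 of a gene with a steep upper quantile segment (HIN1:
  0/0/5/18/61) has a standard error of ~5 %M at n = 200 — the same order as
  the 3 %M gap between adjacent rank statistics — so the published ranking
  is only reliably recovered once that error is ≪ the smallest gap.
* MSI power/type-I suites use 120–200 seeded replicates at 20 MSI / 40 MSS.
  A +20 %M shift is detected with power ~1.0 (HIN1, ARHGEF7) down to ~0.84
  (GPX7, whose carcinoma IQR spans 1–53); recovery of the shifted gene set
  is therefore asserted by majority vote across replicates, and type-I
  error is asserted not to exceed the nominal α (the continuity-corrected
  rank test is conservative at these sizes).
* All simulations take a single integer seed; identical spec + seed gives
  bit-identical tables.

## Known limitations

* The reference quartile table for two genes (APC, HIST1H3C) carries
  transcription uncertainty (flagged in the data file); both are discarded
  by the significance filter on their p-values regardless, so no result
  depends on their quartiles.
* CI numerics (Clopper–Pearson, DeLong) are a documented convention, not a
  reproduction of any specific commercial tool.
* The clustering prescreen validates only on constructed fixtures; real
  450K matrices bring probe-level artifacts (cross-reactive probes, type
  I/II chemistry) that are out of scope.
* No cross-validation or optimism correction: the design is a single
  train-lock-test pass, as in the assay-development workflow it mirrors.
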