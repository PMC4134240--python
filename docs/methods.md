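# Methods

This note documents the statistical model behind `mirddct`, the choices
made where the underlying analysis convention is genuinely open, and what
the synthetic-data tests do and do not demonstrate.

## Measurement model

A qPCR array reports, per well, the cycle number Ct at which the
amplification signal crosses a fixed threshold; template abundance is
proportional to 2^−Ct, so Ct is a log2-scale measurement and one cycle is
one 2-fold change. Reactions that never cross threshold by the detection
limit (40 cycles by default) carry no quantitative information and are
treated as missing, *not* as Ct = 40: the limit is an instrument property,
and imputing it would bias low-abundance assays toward zero effect. Only
Ct strictly below the limit are kept.

## Normalization

Per sample, the reference is the arithmetic mean of the k = 3 chosen
endogenous-control Ct values. Because expression is 2^−Ct, the arithmetic
mean in Ct space is exactly the Ct of the geometric mean in expression
space — the standard multi-control reference. Then

* ΔCt = Ct(target) − Ct(reference), within one sample;
* ΔΔCt = ΔCt(lesion) − ΔCt(matched control tissue), within one patient;

so any sample-wide additive shift (loading, efficiency of that card)
cancels in ΔCt, and patient-level baseline differences cancel in ΔΔCt.
Negative ΔΔCt = up-regulated in the lesion; fold change = 2^|mean ΔΔCt|.

Open choices resolved here:

* **Stability metric.** "Most stable" control is not a standard quantity;
  we use the sample SD of a candidate's Ct across all samples (both
  tissue classes), the simplest defensible reading. Only the *selected
  set* enters downstream math, so a geNorm/NormFinder-style score could
  be substituted without touching anything else. Ties break by lower
  mean Ct, then lexicographic id, making selection deterministic.
* **Reference scope.** The reference is computed per sample ("in that
  tissue"), not per patient or per card.
* **Missing controls.** A sample missing any chosen control gets
  all-missing ΔCt (with a logged warning) rather than a fallback to
  fewer controls — the reference definition stays uniform across
  samples, at the cost of losing that sample.

## Pruning

Three per-assay reductions precede statistics: the detection-limit
censoring above; an annotation filter that maps array-era assay ids
through a frozen remap table (dead ids dropped, renamed ids replaced — a
file, not a live database query, because registry contents change between
releases and reproducibility demands a frozen relation); and a minimum
paired-detection rule — an assay needs a computable ΔΔCt in at least 9 of
18 pairs (⌈n/2⌉ for other designs). "Present in a pair" means both
tissues detected after normalization, because the test consumes paired
ΔΔCt values. Annotation is applied before detection counting; both are
per-assay predicates, so the retained set is order-independent.

## Directional shifted-null test

Per assay with observed ΔΔCt values d₁…dₙ:

* direction is chosen by the sign of the median (robust to the skewed,
  censoring-truncated tails these data have); an exact zero median means
  no test;
* for up-regulation the null is H₀: mean ΔΔCt ≥ −δ₀ with δ₀ = 1 log2
  unit, i.e. the null already concedes a 2-fold change, and
  t = (mean d + δ₀)/(SD(d)/√n) is referred to the lower tail of Student t
  with n−1 df (mirrored for down-regulation). Rejection therefore reads
  "deregulated by *more* than 2-fold", not merely "different". δ₀ is
  configurable (`delta0_log2`).
* sample SD uses the n−1 denominator throughout.

A one-sample Kolmogorov–Smirnov screen runs per assay on the
standardized residuals zᵢ = (dᵢ − mean d)/SD(d) against N(0, 1). The
screen is advisory: assays failing at `normality_alpha` are flagged in
the report, never excluded. (A literal reading of the source convention —
summing the centred residuals before the KS test — is degenerate, since
centred residuals sum to zero identically; testing the standardized
residuals is the only reading under which the screen is informative. A
pooled variant, one KS test over all assays' z-scores, would be a
reasonable alternative but is not implemented.)

Benjamini–Hochberg runs at α = 0.05 over the m assays actually tested
(direction ties and zero-variance assays are excluded from m). The
realized cutoff (rank/m)·α is reported to 4 significant digits; with 7
passing among m = 531 that is (7/531)·0.05 = 6.591·10⁻⁴, consistent with
a printed 0.00065 up to last-digit rounding — the pipeline reports its
computed value and never forces agreement with a rounded one.

## Heterogeneity clustering

Sample pairs are points in assay space with substantial, non-random
missingness. Distance is the pairwise-complete ("masked") Euclidean:
over co-observed coordinates O, d(x, y) = √((D/|O|)·Σ_{j∈O}(xⱼ−yⱼ)²),
rescaled to the full dimensionality D so sparsely co-observed pairs are
not artificially close; vectors with no co-observed coordinate are an
error, not distance zero.

K-median uses Lloyd-style alternation: assign to nearest center under
the masked distance, update each center coordinate to the median of its
members' observed values (missing when none). Median centers are robust
to the outlying values and absent cells that would bias mean-based
updates. Iteration stops at an assignment fixed point or `max_iter`
(default 100); an empty cluster is re-seeded at the point farthest from
its center. The whole procedure restarts `n_restarts` times (default 20)
from distinct seeded initializations (centers = k distinct points chosen
uniformly) and keeps the minimum-cost model; on random 8-point instances
with missing cells this matches exhaustive enumeration of all
bipartitions in ≈98% of cases (tested). Cost is the summed masked
distance of points to their own centers.

The number of clusters is the interior k maximizing the second
difference of the cost-vs-k curve over k = 1…6, ties toward smaller k —
the sharpest-bend formalization of the elbow heuristic. The elbow is
only as meaningful as the curve: in high-dimensional noise the cost
declines almost linearly with k, and a real bend at k = 2 requires the
between-group separation to dominate the per-cluster noise-absorption
gain (empirically, summed squared group separation ≳ 1500 log2² units
for 18 points in ~530 dimensions — see the generator discussion below).

Heat-map support (complete-linkage agglomeration on the same masked
distance, rows and columns independently) and pairwise-complete Pearson
correlation between two assays' profiles round out the module. Only leaf
orders and merge trees are produced; no graphics.

## Synthetic-data generator

`SimulationConfig` defaults are the emulated study's conditions: 531
assays (including 5 endogenous-control candidates), 18 pairs, 7 planted
log2 effects equal to the study's reported mean ΔΔCt values (−4.84,
−3.77, −3.05, −3.42, +6.70, +6.02, +4.56), baseline Ct uniform on 22–35
cycles, cycle noise SD 1.0 (controls 0.15), and soft probit censoring:
a reaction at cycle ct is lost with probability Φ((ct − 40)/1.5) and
always at ct ≥ 40. Effects are planted on lesion tissue only (control
tissue is the reference side of the pair), subtracting from Ct for
up-regulation.

The latent heterogeneity is a 13/5 sample split in which the 5-pair
minority subgroup carries an extra −4.0 log2 offset on 100 designated
assays. These two numbers were set by a design calculation, not by the
deregulated tip alone:

* the per-assay offset magnitude matches the within-cluster mean ΔΔCt
  range the emulated study reports (|ΔΔCt| ≈ 2.2–7.7);
* the footprint must be broad enough that the *sample partition* is
  identifiable: a 5-member cluster pays a center-estimation noise
  penalty of order D·(π/2)·σ²_ΔΔCt/5 ≈ 330 squared log2 units in D ≈ 528
  dimensions, and the elbow needs the k=1→2 cost drop to dominate the
  ~35-unit noise-absorption drops at larger k; both require a summed
  squared separation (100·4² = 1600) well above ~1500. A narrow
  footprint (e.g. 40 assays at −2.5) leaves the true split costlier than
  degenerate 17/1 partitions and no elbow at all — real genome-wide
  heterogeneity is likewise broader than its statistically significant
  tip;
* placing the offset on the minority group keeps each offset assay's
  overall mean ΔΔCt near −4·(5/18) ≈ −1.1, i.e. at the shifted null, so
  the heterogeneity block adds no overall BH-significant assays and the
  18-pair analysis recovers exactly the 7 planted effects — the
  signature of the emulated study.

What the generator does *not* model: PCR-efficiency variation
(Pfaffl-type corrections), inter-card batch effects, probe
cross-hybridization, or correlated noise between assays. Passing
recovery tests therefore shows the pipeline's statistics behave as
designed under idealized Gaussian cycle noise with realistic censoring —
not that real arrays meet those assumptions.

Known consequence of honest censoring: a strongly down-regulated assay
whose baseline lands near the limit loses most lesion wells and is
pruned by the 9-of-18 rule in a few percent of seeds (mirroring the
real assays observed in only 9–16 of 18 pairs), so planted-effect
recovery is asserted as ≥6 of 7 in ≥90% of seeds, not 7 of 7 always.

## Problem sizes used in the test suite

Simulation-based assertions run at the sizes that make their Monte-Carlo
error small relative to the asserted margin: type-I error at the null
boundary with 5,000 replicates per σ (3 MC SEs ≈ ±0.009 around α = 0.05);
BH vs a brute-force step-up oracle on 1,000 random p-vectors of length
≤ 12; K-median vs exhaustive enumeration on 60 random 8-point instances;
planted-effect recovery over 100 full-pipeline seeds; elbow + subgroup
recovery over 12 seeds (each requiring k = 2 and adjusted Rand ≥ 0.9
against truth — a deterministic, high-margin check per seed, so fewer
replicates suffice).

## Numerical and degenerate-input conventions

* Censoring tokens on input: empty cell, `Undetermined`, `N/A`
  (case-insensitive); output always writes `N/A`. Parsing never coerces
  a censoring token to a number.
* Direction ties (median exactly 0) and zero-variance assays are
  reported untested with blank t/df/p, sorted after all tested assays.
* BH with nothing passing reports rank 0, cutoff 0.
* `fold_change(0) = (1, none)`.
* All randomness (generator, K-median restarts) derives from explicit
  integer seeds recorded in the run manifest; reruns are byte-identical.

## Limitations

* The pipeline assumes pure ΔΔCt quantification (amplification
  efficiency exactly 2 per cycle); efficiency-corrected models are out
  of scope.
* Exact reproduction of a historical annotation filter depends on the
  frozen remap table supplied; the package ships none.
* The elbow criterion, restart policy and initialization are pipeline
  conventions, not properties of the emulated analysis; on data without
  a dominant two-group structure the selected k is noise-sensitive (a
  warning is logged when the cost curve is non-monotone).
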