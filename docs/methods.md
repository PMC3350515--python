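# Methods

This note documents the model, the conventions the implementation commits
to, what the synthetic-data generator does and does not emulate, and the
design choices made where the design was genuinely open.

## The score

For feature *j* with values x₁ⱼ…x_Nⱼ over both groups pooled
(N = n₁ + n₂, per-feature complete case, so N is feature-specific when
values are missing):

1. **Ranks.** Midranks over the pooled sample; missing values are excluded
   and consume no rank.
2. **U-transformation.** U = (R − 0.5)/N maps ranks into (0, 1).  This
   choice makes the mean of an untied full rank set exactly 0.5 and puts
   the pooled γ = 0.5 quantile at 0.5.  The classical alternative
   R/(N + 1) shares every qualitative property and is available via
   `u_transform(..., method="plus_one")`; nothing downstream depends on
   the choice beyond a rescaling of order 1/N.
3. **Factors.**
   * B = Ū₁ − Ū₂.  On the U scale |B| ≤ ½, equality iff the groups
     separate completely; over all group assignments of fixed sizes to
     untied data B takes exactly n₁·n₂ + 1 distinct values, which is why
     raw mode exists (below).
   * S: independent design — pooled sd,
     √(((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)) with s²ₘ the per-group
     *maximum-likelihood* (ddof = 0) variances; dependent design — ML sd
     of the within-pair U differences.  S is a descriptive dispersion
     scale, deliberately not an unbiased sd estimator; the ML convention
     is what makes the complete-separation reference value below exact.
   * O: independent — with q_γ the empirical γ-quantile of the pooled U
     sample (linear-interpolation quantile, γ = 0.5 default) and
     pₘ the fraction of group m's U values *strictly* greater than q_γ,
     O = (p₁ − p₂)/√(p̄(1−p̄)(1/n₁ + 1/n₂)), p̄ the pooled proportion.
     Strict ">" plus the interpolated quantile give the identity
     p̄ = 1 − γ up to the 1/N grid resolution on untied data, so O is
     approximately standard normal under exchangeability (empirical sd
     within 15% of 1 at n = 50 + 50).  p̄ ∈ {0, 1} yields O = 0.
     Dependent — among the n′ pairs with U₁ ≠ U₂ (ties dropped), p₁/p₂
     are the fractions of positive/negative differences and
     O = (p₁ − p₂)/√(0.25 · 2/n′); n′ = 0 yields O = 0.
4. **Combination.** MoR = c·|O|·B/S, c = 1 by default.  O and B both flip
   sign when the group order is reversed, so the raw product would be
   swap-invariant; taking |O| keeps the full three-factor magnitude while
   the sign — the direction of the difference — is carried exactly once.
   Degenerate features (a group empty, N < 2, or S = 0 in rank mode) get
   MoR = 0 and a flag rather than an exception or an infinity.

Reference value used throughout the tests: at complete separation with
n₁ = n₂ = 10, B = ½, S = 0.05·√(99/12) ≈ 0.14361, O = √20 ≈ 4.47214,
MoR ≈ 15.571.

**Raw mode.**  With very small samples and many continuous features the
rank scale quantizes B (n₁·n₂ + 1 values), producing ties along the chain.
`mode="raw"` computes B and S from the original values instead (mean
difference and pooled/paired ML sd); O stays rank-based — it is invariant
under strictly monotone transforms either way.  Raw mode trades outlier
robustness for resolution; with S = 0 but B ≠ 0 (constant groups at
different levels) the score is set to sign(B)·10⁶ and flagged, never a
silent infinity.

**Data types.**  Metric, ordinal and 0/1-coded binary features all pass
through the same rank/U pipeline.  Nominal features with more than two
categories are excluded from scoring with a warning: assigning numbers to
unordered categories would fabricate an ordering.

## Selection criteria

* **Sample-related cut-off** (objective): select |MoR| ≥ w·Z₀/√(n₁+n₂),
  per-feature counts.  Z₀ = 3.28 is reconstructed as the sum of the two
  one-sided 5% standard-normal tail quantiles (2 × 1.6449); O behaves like
  a Z statistic for large samples, which motivates the scale.  w (default
  1) weights the desired effect magnitude and acts as a brake: the
  threshold falls as 1/√N, so with large samples more null features clear
  it — the screen's known specificity cost (measured directly by the
  validity study; specificity ≈ 0.81 at n₁+n₂ ≈ 22 under the default
  generator).  When not even the chain peak clears the bar the result
  carries an explicit `none_informative` status.
* **Entropy** (subjective, small samples): for chain prefix k with weights
  qᵢ = |MoR₍ᵢ₎|/Σ_{j≤k}|MoR₍ⱼ₎|, H_k = −Σ qᵢ ln qᵢ.  The prefix stops at
  the smallest k ≥ 2 where the adjusted change D_k = (H_{k+1} − H_k)/H_k
  first drops below δ (default 0.01); an absolute-change mode
  (D_k = H_{k+1} − H_k) is available, and is the variant that stops
  immediately after a single dominant score.  For an equal-value chain
  H_k = ln k exactly and D_k decreases monotonically with near-equal
  decrements — the behaviour that motivates the rule.
* **Permutation**: group labels reshuffled at fixed n₁, n₂ (independent)
  or members swapped within pairs (dependent); exhaustive enumeration
  whenever the number of distinct assignments is at most K, otherwise K
  random draws.  A feature is selected when its permutation p-value
  #{|MoR*| ≥ |MoR|}/K is ≤ α.  Because |MoR| is invariant under
  complementing the labels, exhaustive values come in mirror pairs and the
  smallest attainable p is 2/#assignments (e.g. 0.10 at n = 3 + 3) — the
  rule stays valid (null selection rate ≤ α) at the cost of that
  granularity.  `top_m` restricts testing to the head of the chain to
  save computation.
* **Fraction / top-proportion** (subjective): shortest prefix carrying a
  share d of the total |MoR| mass; or the ⌈ε·p⌉ largest.  Both are
  prefixes of the chain by construction.

The recommended workflow (`screen`) applies the objective cut-off first —
reporting "no informative variables" when nothing passes — and optionally
intersects with one subjective criterion when the pass list is too long
for practical follow-up.  No criterion is enforced as "the" rule; the
choice is documented guidance, not code.

## Synthetic-data generator

`SimulationConfig`/`generate` emulate the screening studies used to
evaluate the method: p features (default 1000), the first
`n_informative` (default 10) carrying a standardized mean shift NBD
(normalized biological difference, in pooled-sd units; class defaults
high = 2.0, semi = 1.0, none = 0.0), the rest exchangeable noise.  All
features share one distribution family:

* normal: N(0,1) vs N(NBD,1);
* uniform: width √12 (unit variance), second group's interval shifted;
* bimodal: equal mixture of unit-sd normals at ±a (a = 2 before rescaling
  to unit variance) — wide, poorly mean-estimated in small samples;
* bernoulli: (p₁,p₂) = (0.5 + NBD/4, 0.5 − NBD/4), the symmetric solution
  of |p₁−p₂|/√(p̄(1−p̄)) = NBD; NBD > 2 is unattainable and raises.

Dependent designs draw a shared per-pair component giving within-pair
correlation ρ (default 0.5); the informative shift is then specified in sd
units of the *pair difference* (raw shift NBD·√(2(1−ρ))), the scale a
paired analysis sees.  `dichotomize_at_median` converts a metric study to
a binary one at the pooled per-feature median (strictly-greater → 1), so
metric and binary versions carry comparable information.

What the generator does **not** emulate: correlation between features
(every feature is drawn independently — real expression panels are not),
heavy tails/outliers beyond the bimodal family, batch or stratification
structure, and informative missingness (the scorer tolerates missing
values; the generator never produces them).  Passing the simulation
studies therefore certifies the statistic's behaviour under clean
exchangeable noise, not robustness to correlated or contaminated panels.

## Evaluation harness

`run_study` loops generate → score → select → evaluate over condition
grids mirroring the published objectivity/reliability/validity designs,
with 100 replicate datasets per condition by default (the original studies
used 1000; 100 keeps a full grid in minutes on one CPU and leaves the
averages stable to ~0.01).  Sensitivity is the fraction of the designated
features selected; specificity the fraction of the other p − k features
not selected.  Note the designated features *are* the truth mask even at
NBD = 0 — sensitivity over designated-but-null features then reads as a
false-positive rate, which is how the non-informative study rows are to be
read.  An empty truth class yields NaN, never 0.  The random-forest
baseline (scikit-learn classifier + permutation importance at a positive
quantile) is qualitative only: no canonical selection rule exists for it,
so it never enters numeric comparisons.

## Numerical choices and edge cases

* Midranks for ties (rank scale); strictly-greater comparisons at
  quantile thresholds; numpy linear-interpolation quantiles.
* Chain ties broken by input order (stable sort), making reports
  deterministic.
* All randomness flows through one `numpy` Generator per run; fixed seeds
  give bitwise-identical simulations, permutations and bootstrap draws.
* Bootstrap: percentile intervals, resampling within groups; dependent
  designs resample whole pairs (the paired formulas need the pairing
  intact).  With few pairs, low-diversity resamples can degenerate
  (S = 0 → MoR 0), which widens intervals toward 0 rather than failing.
* Per-feature thresholds use per-feature non-missing counts, so features
  with missing values face a correspondingly stricter cut-off.

## Known limitations

* The sample-related cut-off's specificity falls as N grows at fixed w;
  w exists precisely to brake this, and the validity study quantifies it.
* At NBD = 2 and n = 15 + 15 the chain does *not* reliably place all 10
  informative features in the top 10 positions (≈30% of runs; the weakest
  of 10 sample effects regularly falls below the strongest of 990 null
  scores) — recovery is the selection rule's job, and the cut-off does
  reach sensitivity 1.00 there.
* Permutation granularity: two-sided p-values cannot go below
  2/#assignments; at n ≤ 3 + 3 no feature can pass α = 0.05.
* No modelling of feature interactions or covariate adjustment; factors
  with more than two levels are handled by pairwise screens only.
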