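# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the known limitations of `odornet`.

## Variables and data layout

Seven variables describe odor-evoked affect: per-rating valence V and
arousal A on a [-4, 4] grid; intensity I and familiarity F on a [0, 100]
slider; and three participant-level quantities — baseline valence BV and
arousal BA ([-4, 4]) measured once before the ratings, and the odor
detection threshold T ([1, 16]) from an adaptive forced-choice staircase.
Every matrix in the package uses the fixed node order
(V, A, I, F, BV, BA, T). Analysis is run separately per odor valence set
(unpleasant = negative mean valence, pleasant = positive; a mean of exactly
zero is rejected rather than arbitrarily assigned). Rows are pooled over
participants × odors; the participant-level columns repeat within
participant.

## Preprocessing

Outlier screening standardizes each rating variable per odor across
participants (n−1 SD throughout the package) and flags any participant
with |z| above the threshold (default 2). Flagging reports its evidence
— the offending (participant, odor, variable, z) triples — and never drops
data; exclusion is a separate explicit call. A literal "any |z| > 2" rule
flags a large share of any realistic sample (under normality ≈ 4.6% of
cells), so an automatic rule cannot reproduce a small fixed number of
exclusions; the package therefore leaves the exclusion decision to the
analyst, logged.

Within-individual standardization z-scores V, A, I, F per participant
across that participant's odors in the set, removing between-individual
level differences while keeping the within-individual ordering. Zero
variance standardizes to zeros; participants with fewer than two rows in a
set are excluded with a warning. BV, BA, T pass through raw — they carry
only between-individual variance and are Gaussianized by the nonparanormal
transform downstream.

Two descriptive checks accompany preprocessing: an ordinary least-squares
quadratic fit of per-odor mean arousal on mean valence (reported with
R² = 1 − SSres/SStot; R² is invariant to affine rescaling of the
predictor), and the largest relative deviation of a per-odor mean intensity
from the grand mean (the stimulus-set homogeneity criterion).

## Network estimation

* **Nonparanormal dialect.** Ranks with ties averaged, u = rank/(n+1),
  value = Φ⁻¹(u), column rescaled to unit sample SD. The shrunken
  denominator n+1 keeps quantiles finite; the transform is monotone per
  column. Constant columns are rejected by name.
* **Graphical lasso.** Block coordinate descent (one lasso regression per
  column of the working covariance W, W_ii = S_ii fixed — the diagonal is
  unpenalized, the convention for partial-correlation networks). The
  solver is jitted with numba; this is what makes the permutation and
  bootstrap Monte-Carlo loops (10⁵–10⁶ re-estimations) run in minutes.
  Convergence is declared when the largest off-diagonal change in W over a
  full sweep falls below `tol` (default 1e-5 on the path, 1e-7 for single
  fits); non-convergence raises, carrying the residual. Correctness is
  pinned by three independent oracles in the tests: the λ=0 solution equals
  the matrix inverse to 1e-6; the bivariate solution equals the
  soft-threshold closed form (implied partial correlation s₁₂ − λ); and
  solutions match scikit-learn's graphical lasso to ~1e-3 at its own
  convergence tolerance. KKT residuals are asserted directly on random
  instances.
* **Penalty path and selection.** 1000 log-spaced λ from
  λ_max = max|s_ij| (smallest penalty with an empty graph) down to
  0.01·λ_max, swept descending with warm starts. Each fit is scored with
  EBIC = −2ℓ + E·log n + 4γE·log p, ℓ = (n/2)(log det Θ − tr(SΘ)),
  γ = 0.5, E = nonzero upper-triangle entries at tolerance 1e-8 (lasso
  zeros are exact up to solver tolerance, so the tolerance only guards
  rounding). Ties on the path resolve to the first (sparsest) minimum.

## Network analysis

Edge length is 1/|ρ| — the standard weighted-graph convention in this
literature. Strength is Σ|ρ| over incident edges; closeness is the inverse
of summed shortest distances (default `within_component`: only finite
distances count, isolates get 0; a strict mode returns 0 for any node with
an unreachable peer, taking the infinite between-component distance
literally — published closeness values are ambiguous on this point, so
both modes are exposed and closeness is not used as a headline
reproduction). Betweenness uses Brandes counting over unordered pairs with
fractional tie credit (no ties occur at the packaged weights). Centralities
are z-scored across **all** nodes of the network, including isolates; this
choice reproduces the published standardized betweenness values exactly
and is therefore fixed. Note that summing the printed two-decimal weights
gives an unpleasant-network global strength of 1.84 against a published
1.85, and a standardized strength for I of 1.26 against a published 1.27 —
rounding of the printed weights, within the package's stated tolerances.

The edge-weight similarity between two networks is the Pearson correlation
of the vectorized upper triangles over all 21 node pairs, shared structural
zeros included (restricting to nonzero unions does not reproduce the
published r = .81).

## Robustness

Bootstrap edge CIs resample rows with replacement (same n), re-estimate
with identical settings, and report empirical 2.5/97.5 percentiles.
Case-dropping stability subsamples without replacement on a drop grid
(default 0.05–0.75 in steps of 0.05), re-estimates, and correlates each
centrality vector with the full-data vector across nodes. The
CS-coefficient is the largest drop proportion at which ≥95% of replicates
correlate ≥ 0.7, required to hold at every smaller proportion too (prefix
rule — a non-monotone curve cannot inflate CS); the grid cap makes 0.75
the maximum reportable value. Degenerate replicates (failed estimation or
zero-variance centralities) are recorded as missing and count as failures
in the CS criterion. The resampling unit is the row; a participant-level
pairing is available in the comparison test but not in the bootstrap,
where the appropriate unit for pooled rows is the row itself.

A caveat the tests quantify: percentile CIs around an L1-regularized
estimator inherit its shrinkage bias, so per-edge coverage of strong true
edges runs below nominal (~86–94% at weight 0.4) while structural zeros
are covered near 1; averaged over a 4-variable chain's six pairs the
coverage is ≈95%.

## Network comparison

The permutation test pools rows (canonically sorted, making the unpaired
test exactly symmetric in its arguments for equal group sizes), permutes
group labels preserving group sizes, re-estimates both networks per
permutation, and compares the observed M (largest absolute edge
difference) and S (absolute global-strength difference) to their
permutation distributions with the add-one rule p = (count+1)/(iter+1).
The study design is paired — the same observers rate both odor sets — but
the canonical test is an independent-groups test; unpaired is therefore
the default and a participant-swap paired mode is provided. Desk-scale
runs use 100–1000 iterations; 10,000 is the faithful setting. Calibration:
under a same-generator null the S rejection rate at α = .05 is 0.04
(500 runs × 200 permutations; the +1 correction makes the test very
slightly conservative on a discrete p grid).

Estimated networks are classified against the signed hypothesis model
(relations R1–R14; R3 is hypothesized for pleasant odors only, R14 has a
set-dependent sign) into: present-sign-match, present-sign-flip,
absent-though-hypothesized, novel-edge, correctly-absent — exhaustively
over the 21 pairs. An "R15" is mentioned in passing in the source
literature but never defined, so the model encodes the 14 defined
relations; the rule-of-thumb minimum sample size is 3 per hypothesized
edge = 42.

## Synthetic-data generator

The generator emulates the study: n participants (default 52) × the 40
packaged odor profiles, with one target partial-correlation network per
valence set (default: the two published networks). The implied precision
matrix (unit diagonal, off-diagonal −ρ) is checked positive definite and
inverted to a covariance Σ. The participant block (BV, BA, T) is drawn
once per participant from its marginal; rating rows are drawn from the
conditional Gaussian given the participant's values (`hierarchical=False`
draws them from the marginal instead, severing the cross-block
dependence). Latent scores are standardized to unit marginal SD, mapped
affinely to each odor's mean/SD, and clipped to the scale ranges; clipping
distorts the tails mildly at the packaged SDs and is covered by the
recovery tolerances. Participant variables map with population scales
BV ~ (0.8, 1.2), BA ~ (0.0, 1.2) — a mildly positive, calm baseline
typical of volunteer samples — and T ~ (8.5, 2.5), mid-range for
normosmic young adults; the source study reports no population values, so
these were chosen once as realistic and are configurable. Output is
bit-identical given the seed.

**What the generator does and does not emulate.** It reproduces the
marginal 7-variable dependence structure, the repeated-measures layout,
the per-odor rating levels and the scale bounds. It does not model
odor-specific network deviations, habituation across trials, or response
granularity. Two features of the faithful design actively confound the
estimation pipeline, and the tests make this visible rather than hiding
it:

1. *Participant-constant columns.* BV, BA, T repeat across each
   participant's ~40 rows, so their pooled correlations carry an effective
   sample size of n_participants while the EBIC believes n_rows. Spurious
   BA–BV and BA–T edges appear in most runs at any n. This is a property
   of the published pooled-rows pipeline, not of this implementation.
2. *Between-odor mean structure.* The per-odor means are shared by all
   participants and survive per-individual z-scoring, biasing pooled
   correlations (visibly as a spurious A–F edge in the unpleasant set at
   large n).

For estimator calibration the generator therefore offers
`uniform_profiles()` (homogeneous within-set profiles) and
`exact_participant_covariance=True` (the `mvrnorm(empirical=TRUE)` idiom:
the realized participant latents are whitened and re-colored so their
sample covariance equals the target block exactly). Under those
conditions the pipeline recovers the target supports with 0.35 false
edges per run (20 seeds, 500 participants); under the fully faithful
defaults it still recovers every true edge in 20/20 seeds but averages ~3
spurious edges per run, almost all in the participant block, for the
reasons above. Passing recovery tests therefore validate the estimation
chain; they do not certify that the pooled design is free of
repeated-measures artifacts on real data — it is not.

The staircase simulation implements the triple-forced-choice threshold
test: 16 dilution levels (1 strongest, 16 weakest), step toward weaker
after two successive correct responses, toward stronger after a miss,
stop at 7 reversals, threshold = mean of the last 4 reversal levels. The
responder detects with probability 1 − lapse at levels at or below the
true level and otherwise guesses at 1/3. The source procedure leaves the
start level and step unstated; defaults are start 16, step 1,
configurable. If the trial cap (400) is reached first, the result is
flagged incomplete and the threshold falls back to the mean of observed
reversals, or the current level when none occurred (this makes the
never-detecting floor case report 1 and the always-correct ceiling case
16). The estimator tracks the true level monotonically with a mild upward
bias (~+0.9 levels at mid-range) from the asymmetric up/down rule.

## Pipeline and determinism

`run_pipeline` derives one child seed per stochastic stage from the run
seed via a seed sequence, so a config fully determines the report.
Validation errors and numerical failures exit the CLI with codes 2 and 3
respectively. Problem sizes in the shipped tests are chosen to keep the
full suite around six minutes: recovery runs use 500 participants × 20
seeds, permutation calibration 500 runs × 200 iterations × 120 rows per
group, bootstrap coverage 100 repetitions × 250 replicates × 1000 rows.

## Limitations

* The published partial-correlation values, CS coefficients and the
  comparison-test p-value for the real sample require the deposited raw
  data and are not reproduced here; the package reproduces everything
  derivable from the printed tables and validates the machinery by
  simulation.
* Closeness across disconnected components is convention-dependent; both
  conventions are provided, neither is asserted against published values.
* The GGM assumes monotone-transformable linear dependence; the
  valence-arousal U-shape across odor means (R² ≈ 0.59 quadratic) is
  precisely the kind of relation the per-set analysis is meant to
  linearize, and the split into valence sets is part of the model, not a
  detail.
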