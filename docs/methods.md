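# Methods

## Task model

Trials run on a common clock: fixation [0, 0.5) s, first numerosity
[0.5, 1.0) s, delay 1 [1.0, 2.0) s, second numerosity [2.0, 2.5) s, delay 2
[2.5, 3.5) s, rule cue at 3.5 s; analyses end 0.2 s after the rule. The
factors are first number and second number (1, 3, 9 dots), stimulus protocol
(standard/control — a label controlling low-level visual confounds, with no
geometric content here), rule cue (red/blue), the derived decision
(same ⇔ first = second), and the motor act (red: release if different, hold
if same; blue: the reverse). Ordered number pairs are crossed with protocol
and rule, and the three same-pairs are duplicated so same and different
decisions contribute equally many slots: 12 pair slots × 2 × 2 = 48
conditions, 24 same / 24 different. (The duplication factor is fixed at 2;
exact decision balance therefore holds for the standard three-numerosity
design, which is the design all defaults assume.)

Unless stated otherwise every analysis uses **correct trials only**: decision
labels on error trials are ambiguous (the monkey's internal decision is not
observed), so the conservative choice is exclusion; `include_errors=True`
overrides this everywhere.

## ω² explained variance

For one neuron, one factor and one time window, firing rates grouped by
factor level enter a one-way ANOVA and

ω² = 100 · (SS_effect − df_effect · MS_error) / (MS_error + SS_total).

ω² is approximately unbiased under the null (unlike η²) and can therefore be
negative; negative values are retained, since averages and permutation
thresholds operate on the raw statistic. ω² is defined as 0 when SS_total = 0
(a silent window).

Time courses use a boxcar window of 200 ms stepped by 20 ms (176 windows on
[0, 3.7] s). Windows are half-open [left, right): a spike on a boundary
belongs to the later window, so contiguous grids count each spike once. Each
window is *labeled by its right edge*, matching the latency convention below.

Because level occupancies are unbalanced after error exclusion, each window's
PEV is the mean over balanced random subsamples (default 100): per subsample,
`min level count` trials are drawn without replacement within each level.
The permutation null recomputes the *same* statistic under label shuffles
(trials' time structure intact), so observed and null values are exchangeable
under no effect; the threshold is the per-window 99th percentile of 1,000
permutations (defaults). A neuron is selective for a factor when PEV exceeds
threshold for **10 consecutive windows** (5 on the secondary 100 ms / 25 ms
validation grid). The latency is the end of the first window of the first
qualifying run — isolated supra-threshold blips do not define latency, which
otherwise produces artifacts such as decision latencies before the second
number exists. The preferred level is the mode, over the longest significant
run, of the level with the highest mean rate; ties break toward the smaller
level and are logged.

Population summaries report per-window across-neuron mean ± SE PEV (raw or
normalized to each neuron's factor-wise maximum), per-window rank-sum
comparisons between factors at α = 0.01, cumulative counts of neurons with
latency ≤ t, and the pure/mixed selectivity overlap. The split-half tiling
control recomputes PEV on random stratified half-splits and correlates
(Spearman) train- and test-half peak times. Effect-size correlations are
Spearman correlations of per-neuron peak PEV between factor pairs within the
standard subgroups (first-only, second-only, both-numbers, non-number,
decision-pure, decision-mixed); subgroups smaller than 3 or with constant
values are omitted with a log entry.

## Tuning curves

Mean rate per numerosity in 0.5 s windows offset 100 ms from stimulus onset
for visual latency: [0.6, 1.1) s and [2.1, 2.6) s. Cross-period consistency
is the Pearson correlation between a neuron's two three-point curves (with
one value per numerosity a zero-lag correlation is the only meaningful
"cross-correlation"). The shuffle predictor permutes each neuron's
rate–numerosity assignment independently (neurons are independent
recordings) and is reported as mean + 3 SD of the *group-mean* correlation
across 1,000 shuffle repetitions. The SD of individual shuffled three-point
correlations is ~0.7, so a per-neuron band would exceed 1 and no group could
ever pass it; the group-level band is the well-posed reading.

## Pseudo-population decoding

Neurons recorded in separate sessions form a pseudo-population: per decoding
run, trials are drawn without replacement per neuron within each level
(train and test draws disjoint per neuron) and concatenated in a fixed neuron
order into pseudo-trials. No trial-to-trial noise correlation across neurons
is assumed — none exists across sessions. Inclusion requires ≥ 20 trials per
level (≥ 5 per ordered pair for the 9-class sequence factor).

Rates are 50 ms bin counts smoothed with a Gaussian of σ = 1 *bin*
(truncated at ±4σ, renormalized at edges so constants are preserved; σ in
bins is the only reading that keeps the kernel non-trivial at 50 ms
resolution). The classifier is a linear SVM with C = 1, one-vs-one for more
than two classes (the documented default multiclass arrangement of the ECOC
wrapper these analyses are conventionally run with); features are
standardized per window using training trials only. Defaults: 10 train and
10 test trials per level, 20 runs. The optional 5-fold cross-validation on
the training set is a diagnostic (`DecoderSpec.record_cv`) and never the
reported accuracy, which is always held-out. Significance: the mean accuracy
must exceed the 99th percentile of accuracies from decoders trained on
label-shuffled training trials (test labels intact), 1,000 permutations by
default. "Classification probabilities" are row-normalized confusion counts
accumulated over runs within selected (by default significant) windows.

Variants:

- **Cross-temporal**: train at each window, test at every window; per-cell
  permutation thresholds; temporal stability is assessed by a Wilcoxon
  sign-rank of diagonal accuracy against the row-mean off-diagonal accuracy,
  paired over train windows.
- **Cross-order**: numerosity decoders trained/tested across the two
  presentation epochs using epoch-averaged features ([0.6, 1.1) and
  [2.1, 2.6) s); cross cells exclude each neuron's training trials from the
  test draw.
- **Sequence vs decision**: both decoders run on the sequence-qualified
  population (≥ 5 trials per ordered pair); sequence chance is 100/9. The
  decision preset uses 10 training trials per level (the alternative
  3-trials-per-decision variant reported alongside it elsewhere is a preset,
  not hard-coded).
- **Decision generalization**: decision decoders trained on trials whose
  numbers exclude a held-out numerosity in both positions (5 train/level)
  and tested only on trials containing it, per held-out numerosity.

The label-shuffled *data* null used for chance calibration shuffles labels
**per neuron** (session-local). A single global shuffle of the shared
synthetic trial table leaves a common pool-composition bias in train and test
draws and measurably inflates shuffled accuracy; per-session shuffling is
also what a pseudo-population of independent sessions implies.

## Subspace geometry

At each window, trials are sorted into 6 cells (numerosity of the chosen
period × decision). Because the counterbalanced design makes cell occupancy
unequal (a numerosity has twice as many "different" as "same" trials), each
resample subsamples every cell to the minimum cell count and splits it
half/half. Training-half cell means, centered by their unweighted grand mean
r̄, form X (6 × n_neurons); PCA of X via SVD gives the K = 3 basis (an error
is raised if K exceeds the rank of X; degenerate resamples are dropped and
counted). Held-out cell means, centered by the *training* r̄, are projected
into the basis. For each decision, v₁ = z(3) − z(1) and v₂ = z(9) − z(1)
span the numerosity plane; the triangle area is ½‖v₁ × v₂‖ and

cos θ = (v_S1 × v_S2) · (v_D1 × v_D2) / (‖v_S1 × v_S2‖ ‖v_D1 × v_D2‖),

the normalized scalar product of the plane normals. (A chained cross product
of the two normals would be a vector, not a cosine; the scalar product is the
quantity implemented.) Zero-area planes make cos θ undefined for that
resample; such resamples are dropped with a logged count. Both area and
cos θ are invariant to condition-independent rate offsets, and the variance
spectrum is invariant to orthogonal rotations of neuron space (tested).

Time courses bootstrap the half-split 1,000 times (default). The baseline
band for cos θ is mean ± 3 SD of the per-window bootstrap-mean cosine over
windows ending before second-number onset. Windows before *first*-number
onset carry no condition information at all — plane orientation there is
undefined noise — so geometry analyses are conventionally evaluated on
windows from 0.5 s onward; the recovery tests do exactly that. Snapshot
windows for static plots default to 2.25 s and 3.0 s.

## Synthetic generator

Each neuron's instantaneous rate is baseline plus (i) an epoch gain times a
Gaussian tuning curve in log₂ numerosity (width 1 octave by default — the
standard numerosity-tuning model, which also reproduces numerical-distance
confusion effects), active inside a latency window per presentation period;
(ii) a decision term ramping up from an onset in late number-2/delay-2 and
sustained to the trial end. Second-period tuning is order-consistent
(shared preferred numerosity, 61% of two-period neurons by default),
re-preferring, or — for dissociation tests — fully order-specific via an
arbitrary per-numerosity drive map. The decision term is abstract
(pair-invariant sign) or conjunctive (independent random sign per number
pair), the two hypotheses the generalization analysis is designed to
distinguish. Rates are clipped at zero and spikes drawn as an inhomogeneous
Poisson process at 1 ms resolution by inverting the cumulative rate.

Default population composition mirrors a mixed-selectivity prefrontal
population: 5.6% pure first-number, 4.1% pure second-number, 7.4%
both-number, 9.8% pure decision, 7.1% mixed number+decision neurons, the
remainder untuned; baseline rates ~Gamma (mean 5 Hz), gains ~Gamma (mean
12 Hz, scaled by a global `effect_scale`), decision modulations mean 9 Hz
with random sign. Behavior is 90% correct, independently per trial, with
log-normal release reaction times (median ≈ 0.25 s). Number-response
latencies are stratified ("tiled") across the relevant span.

What the generator does **not** emulate: dot-display geometry (protocol is a
label with no rate effect by default), eye movements or aborted trials,
cross-neuron noise correlations within a session, non-Poisson spiking
statistics, firing-rate drift, or error-trial dynamics. Passing tests
therefore demonstrate that the analyses recover planted structure under
Poisson variability and realistic task statistics — not that any particular
biological dataset contains such structure.

## Problem sizes and runtime choices

Defaults follow the conventions above (100 subsamples, 1,000 permutations,
20 runs, 1,000 bootstraps). The test suite and acceptance checks run reduced
but statistically adequate sizes, chosen as the package's own desk-scale
conditions: 100–200 neuron populations, 96–384 trials, 200 permutations for
selectivity nulls and 100–200 for decoder nulls, 20 subsamples, 200
bootstraps, and cross-temporal decoding on the 50 ms grid over a 1 s span.
The statistic definitions are identical at every size.

## Known limitations

- The sliding PEV windows overlap 90%, so supra-threshold windows are
  strongly correlated; the 10-consecutive-window rule is calibrated
  empirically (false-positive control test) rather than analytically.
- With very strong planted signals and few training trials, permutation
  nulls built from shuffled training labels saturate near ceiling (partially
  aligned shuffles still separate), making strict threshold exceedance
  unattainable; this is a property of the test, visible only far from
  realistic effect sizes.
- Rule and action analyses use the standard grid ending 0.2 s after rule
  onset; post-rule dynamics beyond 3.7 s are out of scope.
- `pandas`/NPZ/CSV I/O assumes the documented dataset layout; proprietary
  acquisition formats and NWB are not supported.
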