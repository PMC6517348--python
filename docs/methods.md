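# Methods

## The model

`fmrecall` implements a feature model of immediate serial recall.  An item
is a vector of binary features split into two segments: *modality-dependent*
features tied to the physical presentation (voice quality, screen location)
and *modality-independent* features produced by internal categorisation and
identification.  Every presented item lays down two traces: a *primary
memory* (PM) trace that degrades, and an intact *secondary memory* (SM)
trace.  All features are drawn independently as +1 or −1 with equal
probability at encoding.

Forgetting is retroactive, similarity-based interference, not decay:

- **Adjacent overwriting.** Each PM trace is degraded by the immediately
  following item: any feature whose value equals the corresponding feature
  of the follower is overwritten to 0.  Only the immediate follower
  overwrites, and it does so with its own undegraded (post-adoption)
  values; no cascade.
- **End-of-list interference.** The final item is followed by internally
  generated activity, modelled as one random ±1 pseudo-item applied through
  the same match-and-zero rule to the modality-independent segment only.
  In expectation half of those features are zeroed.  Because
  modality-dependent features survive this pass, a representation rich in
  them (auditory presentation) keeps a sharper cue for the final position —
  the model's recency/modality mechanism.

Retrieval walks the output positions in an order given by a positional
random walk (below).  At each output position the cued PM trace samples one
SM trace by the Luce choice rule

    P(SM_j | PM_i) = s(i,j) / Σ_k s(i,k),      s(i,j) = exp(−d_ij),
    d_ij = (a/N) Σ_k b_k M_k,

where `M_k` is 1 when feature k of the PM cue differs from feature k of the
SM candidate (an overwritten 0 counts as a mismatch against either sign),
`N` is the number of compared features, `a` a distance-scaling constant and
`b_k` an attention bias fixed at 1.  A sampled item is *recovered* with
probability `exp(−c·r)`, where `r` counts that item's previous samplings in
the trial (output interference).  A recovered item is emitted and removed
from the search set; a recovery failure is an omission at that output
position (the participant says "pass"), and the item stays in the search
set — its `r` still increments.  An item can be emitted at most once.
A position is scored correct only if the item presented there was emitted
there (correct-in-position scoring).

**Order memory.** Positional codes random-walk along the position axis:
over `pi` opportunities, a code at an interior position moves to either
neighbour with probability θ/2 each; at the two list ends the code stays
with probability 1 − θ/2 and moves inward with θ/2, so no mass leaves the
list.  Iterating the one-step kernel from the identity yields the
positional-uncertainty matrix (row i = distribution of item i's current
positional code).  At retrieval each item samples a position from its row;
items are cued in order of sampled position, ties broken uniformly at
random.  We implement the retrieval rule at trial level (sample, then
sort) rather than as a greedy argmax over the expected distributions: a
deterministic greedy rule on expectations would never produce an order
error, which would make the perturbation machinery inert.

**Dual tasks and feature adoption.** A concurrent task's repeated output
generates features that are incorporated into every list item's PM trace:
`F` of the modality-independent features are set to +1 ("feature
adoption"), raising inter-item similarity, hence overwriting, hence errors.
The adoption count is `F_tapping` for spatial tapping, `F_suppression` for
articulatory suppression, plus `F_dissociation` when the dual task's domain
matches the primary task's (tapping↔spatial, suppression↔verbal); the sum
is clamped to the number of modality-independent features.  The symmetric
matched-pair rule is the only rule that can produce a double dissociation
across the two dual-task groups, and with `F_dissociation = 0` the two dual
tasks are exactly interchangeable within a domain (a property the test
suite checks).  A fractional `F` is realised per trial as ⌊F⌋ features plus
one more with probability F − ⌊F⌋, so the per-trial expectation equals `F`.
Adopted features are the leading modality-independent features in a fixed
canonical order; only the count is identifiable, their position in the
vector is immaterial by exchangeability.

## Parameters

| parameter | meaning | default | fitted? |
|---|---|---|---|
| `a_spatial`, `a_verbal` | distance scaling per task domain (dimensionless, >0); absorbs overall task difficulty | 20 | yes |
| `F_tapping`, `F_suppression` | adoption counts (features) per dual task | 0 | yes |
| `F_dissociation` | extra adoption when dual and primary task domains match | 0 | yes |
| `c` | recovery scaling (output interference) | 2.0 | no, fixed |
| `theta` | per-opportunity perturbation probability | 0.05 | no, fixed |
| `pi` | perturbation opportunities per trial | 10 | no, fixed |
| `b` | attention bias per feature | 1.0 | no, fixed |

`c` has no established value in the sources for this design; 2.0 makes a
second sampling of the same item rarely recoverable (e^−2 ≈ 0.14), a strong
but not absolute output-interference penalty.  It is exposed, logged in
every artifact, and held fixed across all fits so the five-parameter scheme
is unchanged.  `pi = 10` keeps positional gradients local (most mass within
±1 position at θ = 0.05) and is deliberately not fitted: both shipped
designs fit exactly five parameters.  Feature counts are 20/20
(modality-dependent/independent) for the auditory design and 2/20 for the
visual one, the model's customary settings for those modalities.

## Experiment presets

- `exp1_brooks`: two between-subjects groups (spatial task, 7 items;
  verbal task, 5 items), each under no dual task, articulatory suppression,
  and spatial tapping — six curves fitted simultaneously with five free
  parameters (`a` varies by domain; the three `F`s are shared).
- `gt_exp2`: two groups of order-reconstruction tasks (7 items, visual,
  2/20 features): one group does verbal and spatial tasks alone and under
  suppression, the other alone and under tapping — eight curves, same five
  free parameters.  The reconstruction search set is the 7 presented items;
  the 2 unpresented pool items are not modelled.

## Synthetic data

`generate_group_data` emulates the group structure of the designs: by
default 24 participants per group and 13 scored trials per condition per
participant (three 14-trial blocks whose first trial is practice).  The
group curve is the mean over participant means, so its noise is
participant-averaged binomial — exactly the structure the group-level fits
assume.  The generator does *not* emulate participant heterogeneity
(everyone shares one parameter vector), serial dependencies between trials,
strategy shifts, or response-format differences between spoken recall and
reconstruction-by-clicking.  Passing tests therefore demonstrate that the
pipeline is self-consistent (the fitter recovers the generator's
parameters; the comparison detects the generator's dissociation), not that
the model is correct for any particular empirical dataset.

## Fitting: ABC-PRC

The model has no tractable likelihood, so fitting is by approximate
Bayesian computation with sequential Monte Carlo and partial rejection
control:

- **Summary distance**: root-mean-square difference of proportion correct
  over every (condition, position) cell, all cells weighted equally.
- **Priors**: `a` ~ Normal(20, 10) truncated at 0 and renormalised (the
  scaling must be positive); adoption rates ~ 20·Beta(2, 2) (adoption
  affects some but not all of the 20 modality-independent features);
  `F_dissociation` ~ Uniform(0, 20), agnostic about dissociation.  The
  dissociation prior is read on the feature-count scale: a unit-interval
  specification is interpreted as a fraction of the 20 modality-independent
  features, the only reading consistent with posterior mass near 11
  features.
- **Schedule**: the first tolerance is the 20th percentile of 500 pilot
  prior-predictive distances (pilot size configurable); each later
  generation's tolerance is the median of the previous generation's
  accepted distances.  Generation 1 is plain rejection sampling; later
  generations resample a particle by weight, perturb with an independent
  Gaussian kernel (componentwise scale = kernel factor × the previous
  generation's weighted SD; out-of-support proposals are redrawn;
  zero-spread components are proposed unperturbed), simulate, and accept
  when the distance beats the tolerance.  Accepted particles get the PRC
  importance weight prior(proposal)/prior(source); weights are normalised
  each generation and the population is resampled to equal weights when the
  effective sample size falls below half the particle count.
- **Summaries**: weighted posterior means and 95% highest-density
  intervals, the latter as the shortest contiguous window over the sorted
  weighted sample (ties to the shortest then lowest window); checked
  against an exhaustive window search in the tests.

Full-scale defaults are 500 particles, 6 generations, 1000 simulated
trials per condition per distance evaluation.  The shipped tests and the
acceptance script run desk-scale studies at 200 particles / 4 generations /
300 trials (fits, recovery) and 100 / 3 / 200 (model choice), sizes chosen
so a complete recovery-plus-model-choice study runs on one core at coffee-
break scale; at 300 simulated trials the distance has a noise floor near
0.035, which is why tolerances plateau there.  Desk-scale runs use kernel
factor 1.0 (full-scale default 2.0): with tolerances already at the noise
floor, the narrower kernel roughly triples late-generation acceptance
without changing the stationary target, and the PRC weights correct for
the proposal either way.

**Bayes factor.** Evidence for the full model over the null
(`F_dissociation ≡ 0`, four free parameters) is computed by model-choice
ABC: each particle carries a model indicator drawn uniformly over
{full, null}; the joint population runs through the same PRC machinery
with within-model kernels (a nearly extinct model falls back to a
prior-scale kernel), and the BF is the ratio of final weighted indicator
frequencies.  When the disfavoured model retains no particles only a bound
is reportable: the result is flagged `capped` and reported as
> n_particles − 1 (or its reciprocal).  An acceptance-ratio alternative at
a common tolerance was considered and rejected: the indicator run uses
literally the same ABC settings as the estimation fits, which is the
cleanest reading of "same sampler, same settings".

## Numerical and design choices

- The simulator is batch-vectorised over trials (mismatch counts via one
  batched matrix product, using
  mismatches = (N − ⟨pm, sm⟩ + #zeros)/2 for features in {−1, 0, +1});
  batches are chunked at 16384 trials to bound memory.  All draws of a
  batch come from one seeded `numpy` Generator, so curves, fits and
  comparisons are bit-reproducible given (seed, n_trials); per-trial
  stream isolation was traded away for roughly two orders of magnitude of
  throughput, which the ABC loops require.
- Similarities that underflow to zero for every available item degenerate
  the Luce rule to a uniform choice among available items (only reachable
  at extreme `a`).
- Inverse-CDF categorical sampling uses a strict inequality and scales the
  uniform draw by the total mass, so zero-probability cells can never be
  selected and rounding at the top of the CDF is harmless.
- Positional sampling ties are broken by adding a uniform jitter before the
  argsort — equivalent to a uniformly random order among tied items.
- The 10-second retention interval of the auditory design has no dedicated
  mechanism; the model is applied unchanged.

## Known limitations

- ABC posteriors are conditional on the summary distance and tolerance;
  with desk-scale simulation sizes the tolerances sit at the Monte-Carlo
  noise floor and posteriors are over-dispersed relative to an exact-
  likelihood ideal.  HDI coverage in the recovery studies is accordingly
  conservative (at or above nominal).
- Group-level fitting only; no participant-level heterogeneity or
  hierarchical structure.
- The adoption rates and the dissociation boost are weakly identified from
  six curves (their posteriors stay broad); the distance scalings are well
  identified.
- Qualitative benchmark phenomena (suffix, phonemic-similarity, modality
  effects) are expressible with the primitives here but are not fitted or
  tested quantitatively.
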