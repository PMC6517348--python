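# fmrecall

Feature-model simulation of immediate serial recall, with likelihood-free
Bayesian fitting and model comparison.

## The problem

In dual-task experiments, a concurrent verbal task (articulatory
suppression) hurts verbal short-term memory more than a concurrent spatial
task (tapping a square of blocks), and vice versa.  Such single and double
dissociations are classically read as evidence for separate verbal and
visuo-spatial memory systems.  `fmrecall` implements the alternative: a
single feature-based memory in which items are ±1 feature vectors, and a
concurrent task interferes exactly to the extent that it generates features
similar to the memoranda.  The package lets you simulate that model,
fit it to group serial-position curves, and quantify the evidence for a
dissociation — without positing separate stores.

## The model in brief

Each item leaves an intact secondary-memory trace and a degradable
primary-memory trace over `N` binary features.  Interference zeroes any
primary-memory feature matched by the next item, plus (after the final
item) the modality-independent features of the last trace.  At recall, the
cue `PM_i` samples a target by the Luce choice rule over Shepard
similarities,

    P(SM_j | PM_i) = e^{−d_ij} / Σ_k e^{−d_ik},   d_ij = (a/N) Σ_k b_k M_k,

recovery of a sampled item succeeds with probability `e^{−cr}` (`r` = times
already sampled), and output order comes from positional codes that
random-walk with rate θ over π opportunities.  A dual task writes `F` shared
"+1" features into every trace (`F_tapping` or `F_suppression`, plus
`F_dissociation` when the dual task's domain matches the primary task's).
The free parameters in the shipped designs are `a_spatial`, `a_verbal`,
`F_tapping`, `F_suppression`, `F_dissociation`; fitting is by sequential
Monte Carlo ABC with partial rejection control (ABC-PRC), and a Bayes
factor compares the full model against a null with `F_dissociation = 0`.
See `docs/methods.md` for the complete account.

## Worked example

Generate a synthetic group experiment at a known parameter point, fit it,
and test for a dissociation:

```python
import numpy as np
from fmrecall import (ABCConfig, ModelParams, SerialRecallModel,
                      generate_group_data, preset_experiment)

design = preset_experiment("exp1_brooks")       # 6 curves, 2 groups of 24
truth = ModelParams(a_spatial=30.62, a_verbal=25.51, F_tapping=9.14,
                    F_suppression=10.59, F_dissociation=10.90)
data = generate_group_data(design, truth, seed=42)

model = SerialRecallModel(data, design)
config = ABCConfig(n_particles=200, n_generations=4, n_sim_trials=300,
                   pilot_samples=150, kernel_factor=1.0)
result = model.fit(config, seed=7)
print(result.summary())
```

```
Feature model of immediate serial recall — ABC-PRC fit
design: exp1_brooks   model: full
particles: 200   generations: 4   sim trials/condition: 300   seed: 7
final tolerance: 0.0376   final acceptance: 0.128

parameter            mean       sd               95% HDI
a_spatial           28.94     2.72        [24.07, 33.79]
a_verbal            28.37     3.79        [19.90, 35.14]
F_tapping            9.54     3.37         [2.76, 15.29]
F_suppression        9.41     3.27         [3.23, 14.39]
F_dissociation      13.30     3.44         [7.45, 20.00]
```

Each row is one free parameter: the weighted posterior mean, posterior SD,
and the 95% highest-density interval of the ABC posterior.  Here every
generating value (30.62, 25.51, 9.14, 10.59, 10.90) falls inside its HDI;
the adoption parameters are genuinely broad — six group curves carry
limited information about them — while the distance scalings are tight.
The dissociation question itself is answered by the Bayes factor:

```python
comparison = model.compare_null(ABCConfig(n_particles=100, n_generations=3,
                                          n_sim_trials=200, pilot_samples=100,
                                          kernel_factor=1.0), seed=8)
print(comparison)
```

```
BF(full/null) = 13.36  [freq full 0.930, null 0.070]
```

A BF(full/null) above ~3 favours a genuine dissociation; on data simulated
with `F_dissociation = 0` the same computation hovers at or below 1.

The same workflow is available from the shell:

```sh
fmrecall simulate --experiment exp1_brooks --seed 42 --out curves.csv
fmrecall fit curves.csv --seed 7 --out fit.json
fmrecall compare curves.csv --seed 8 --out bf.json
fmrecall recover --n-replicates 10 --seed 9 --out coverage.csv
```

## Layout

- `fmrecall.core` — traces, interference, retrieval, trial simulator
- `fmrecall.designs` — condition/experiment specs, feature adoption, presets
- `fmrecall.abc` — priors, summary distance, ABC-PRC, HDIs, posterior predictive
- `fmrecall.compare` — model-choice ABC Bayes factor
- `fmrecall.data` — synthetic group data, CSV exchange format, recovery studies
- `fmrecall.model` — `SerialRecallModel` / `SerialRecallResults` front end
- `fmrecall.cli` — the `fmrecall` command
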