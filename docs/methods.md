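# Methods

`aoanet` simulates the age-of-acquisition (AoA) effect in single-word
reading with a slot-coded connectionist model: items entered into training
earlier end up read more accurately, resist later interference, and survive
damage better than items entered later, even when total exposure is
equalised. This note documents the model, the synthetic materials, the
protocols, the measurements, and the numerical choices.

## The model

A feedforward network maps orthography to phonology:

- **Input**: 4 positional slots × 33 letters = 132 localist units. Slots
  1–2 hold onset letters, slot 3 the vowel/body, slot 4 the coda; slots 3–4
  together form the rime. A word activates exactly one unit per occupied
  slot block; empty (BLANK) slots are all-zero blocks. There is no
  dedicated blank unit: 33×4 and 28×4 exhaust the layer sizes.
- **Hidden**: 100 logistic units.
- **Output**: 4 slots × 28 phonemes = 112 localist units.

Activations are logistic, `σ(z) = 1/(1+e^(−z))`. Weights and biases are
initialised uniformly in [−0.5, +0.5]. Training minimises the halved
summed squared error `E = ½ Σ (o − t)²` with 0/1 targets — the classic
delta rule `δ = (o − t)·o(1−o)`. The protocols' learning rates assume this
convention; the factor-2 variant doubles the effective rate and drives the
high-rate protocol (learning rate 0.05 with momentum 0.9) into saturated,
pinned outputs.

Two optimizers:

- **Online backprop with momentum** (default): per-pattern updates
  `Δw = −lr·∂E/∂w + m·Δw_prev`, presentation order reshuffled every epoch.
- **Quickprop**: one batch update per epoch. Per weight, the secant step
  `Δw = Δw_prev · g/(g_prev − g)` jumps toward the vertex of the locally
  fitted parabola; `|Δw|` is capped at `μ·|Δw_prev|` (μ = 1.75) and the
  update falls back to a plain gradient step `−lr·g` when there is no
  previous step, the denominator vanishes, or the secant step points
  uphill (implied negative curvature). Quickprop gradients include the
  standard flat-spot elimination: a constant 0.1 added to the logistic
  derivative, so units pinned at the sigmoid's extremes keep a usable
  error signal. This is the feature that restores plasticity to saturated
  connections and underlies the optimizer contrast below. The batch
  gradient is the *mean* over the presentation list, so the fallback step
  does not scale with list length. Quickprop's learning rate is only this
  bootstrap/fallback epsilon; it is set to 0.5 in the Quickprop protocol —
  the algorithm conventionally runs with much larger epsilon than online
  backprop, and 0.05 leaves it grossly under-converged at protocol epoch
  counts.

## Synthetic materials

The original 327-word lexicon (five grade groups of 82/62/56/49/78
monosyllables) is not published, so a generator produces artificial slot
words with the statistics the analyses need:

- **Shape**: C(C)V(C) — slot 1 and the vowel always occupied; 40% of words
  carry a second onset letter, 60% a coda. Occupancy counts are exact per
  grade group, so groups are matched on word length.
- **Mapping**: in `quasi_regular` mode a random deterministic per-slot rule
  table maps letters to phonemes; a fixed fraction of items (default
  `inconsistency_rate = 0.2`) instead takes a deviant body→rime mapping
  that disagrees with the rule for every letter. The deviating count is
  exact per grade group (stratified), mirroring materials matched on
  consistency across groups; with independent draws, group-difficulty
  differences swamp the AoA effect at these sample sizes. In `arbitrary`
  mode pronunciations are drawn independently of spellings, emulating the
  unstructured random-pattern sets of earlier modelling work.
- **Frequency**: geometric draws (p = 0.5), identical across grades, so
  frequency and grade are unconfounded by construction.
- **Consistency**: each item's count of other items whose spelling differs
  in exactly one slot (a slot-granular Coltheart-N analogue), computed
  within the lexicon.

What the generator does *not* emulate: real Farsi orthography/phonology,
context-dependent many-to-many spelling–sound correspondences, semantic or
morphological structure, and realistic neighbourhood topology. Passing
tests therefore show that the *training dynamics* produce the effects on
materials with the right manipulable statistics — not that the model reads
Farsi.

## Protocols

All staged protocols train an **early** set alone, then a mixed set in
which **late** words appear twice per epoch, equalising total exposure
(150 + 150×1 = 150×2 = 300 presentations each at full scale). Simulation
runs (`curriculum.simulate`) use the protocol description's group sizes: 82
early (grade 1) and 87 late (grade 2) words. (The behavioural materials'
grade-2 group holds 62 words; the simulation protocol's own description
gives 87, and the generator accepts either.)

| id | stages (epochs) | lr | momentum | optimizer |
|----|-----------------|------|-----|-----------|
| sim1 | 150; 150 | 0.01 | 0.9 | backprop |
| sim2 | 150; 300 (doubled interleaving) | 0.01 | 0.9 | backprop |
| sim3 | sim1, group roles swapped | 0.01 | 0.9 | backprop |
| sim4 | 300; 300 | 0.05 | 0.9 | backprop |
| sim5 | 1500; 1500 | 0.05 | 0 | backprop |
| sim6 | sim1, then lesioning | 0.01 | 0.9 | backprop |
| sim7 | sim1 stages | 0.5 (ε) | 0.9 | quickprop |

Two cross-protocol comparisons use documented epoch overrides:

- momentum-free runs (sim5) are evaluated at 300+300 epochs, which reaches
  the same partial-mastery error regime as sim1 (the full 1500-epoch stages
  merely take ~5× longer to get to the same place);
- optimizer contrasts run Quickprop for 400+400 epochs
  (`QUICKPROP_EPOCHS`), because one batch update per epoch versus one
  update per presentation makes equal epoch counts wildly unequal compute.

## Measurements

- Per-item error is `sse = Σ (o − t)²` over the 112 output units from a
  clean forward pass; decoded whole-word correctness (0.5 readout
  threshold per slot block, argmax, lowest-index tie-break) is the
  alternative 0/1 metric.
- **End-of-training error** averages the last five recorded evaluations
  (≈ the final 50 epochs under the default every-10-epochs schedule). A
  single end-point read carries within-epoch presentation-order noise
  comparable to the AoA gap itself.
- The **AoA gap** is mean late-group error minus mean early-group error
  (positive = early advantage). Directional claims are asserted over fixed
  seed panels, one full pipeline run (fresh lexicon, fresh weights, fresh
  shuffling streams) per seed.
- **Lesioning** removes `round(severity·H)` hidden units per sample
  (round-half-up), either silencing them (all incoming/outgoing weights
  and the bias zeroed) or adding zero-mean Gaussian noise (sd 0.5) to
  their incoming/outgoing weights, over 20 independent samples per grid
  cell. The differential-vulnerability test uses the unit-removal method;
  weight noise at sd 0.5 produces milder graded damage whose differential
  component is weaker and noisier, so the two methods are compared only
  descriptively. Noise on activations (rather than weights) is not
  implemented: a lesioned network is a state object and its evaluation a
  deterministic forward pass.
- The **covariance analysis** regresses per-item error on intercept +
  frequency + consistency + grade dummies, with sequential (Type-I) sums
  of squares in that order, F-tests against the residual mean square, and
  a 1-df linear-trend contrast for grade entered after the covariates.
  With 327 items this gives factor df 4 and error df 320.
- **Saturation** is summarised as the mean |net input| and mean logistic
  slope `o(1−o)` of the output units on trained items; first-stage
  training raises the former and lowers the latter — the plasticity-loss
  signature that entrenches early items.

## Numerical choices and degenerate inputs

- Gradient zero-tolerance and Quickprop memory tolerance: 1e−12.
- Decoding threshold 0.5 matches the 0/1 logistic targets; ties break to
  the lowest phoneme index.
- Seed policy: one master seed spawns independent child streams (numpy
  `SeedSequence`) for lexicon generation, weight initialisation, shuffling
  and lesion sampling; every derived seed is recorded in run manifests,
  and no code path reads the clock or unseeded randomness.
- Singleton lexica get consistency 0; empty lexica, empty groups,
  out-of-range severities and rank-deficient analysis designs are
  rejected with named errors.

## Known limitations

- The behavioural results (group error means, the reported F values) are
  not reproducible because the per-word human data are unpublished; only
  the design arithmetic is checked.
- Directional effects are small relative to seed noise below roughly half
  the standard materials scale; the package runs at the protocols' own
  scale for assertions and leaves smaller presets (`DESK_SCALE`) for
  interactive exploration only.
- Even at the standard scale, the core staged-training advantage (sim1,
  sim3) is reliable across seeds, but the smaller effects — persistence
  under doubled interleaving, the momentum-free variant, and the
  per-seed optimizer contrast — carry substantial seed-to-seed noise at
  feasible run counts: different seed panels can return noticeably
  different majority fractions for them. The acceptance script reports
  the fractions for whatever panel its seed induces.
- The sim2/sim4 epoch totals follow one reading of an ambiguous protocol
  description (the alternative readings are runnable via overrides), and
  whether the original analysis used sequential or marginal sums of
  squares is unknown; sequential is the default here.
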