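# Methods

## The model

`bilatnet` implements a bilateral simple recurrent network (SRN) of spoken
word repetition.  A shared 25-unit phonological input layer feeds two
parallel processing pathways ("left" and "right" hemisphere), each with two
logistic hidden layers (H1 → H2), converging on a shared 25-unit
phonological output layer.  Each H1 layer has an Elman context: a copy of
its own activations from the previous time tick, fed back through trainable
weights.  Feedforward connections never cross between pathways; optional
sparse homotopic cross-connections (LH1↔RH1, LH2↔RH2) can link them.

A repetition trial spans six ticks.  The three phonemes of a
consonant–vowel–consonant (CVC) word are presented at the input on ticks
1–3; the model must reproduce them at the output on ticks 4–6, during which
the input is the zero vector and the Elman context alone carries the
memory.  Hidden units compute `a = σ(g·net)` with a per-layer gain
`g ∈ [0, 1]`; `g = 1` is the normal state, and lowering `g` compresses both
the unit's responses and (because the error derivative carries a factor
`g·a(1−a)`) its ability to learn — the model's implementation of
"inefficient" processing.

Training is online: after every word presentation the cross-entropy error
of the three production ticks is backpropagated and all weights are updated
once by plain gradient descent (no momentum, minibatching, or weight
decay).  Words are sampled i.i.d. with probability proportional to
`log(1 + token frequency)`.

### Gradient computation

Gradients flow backward through the full six-tick unrolled computation,
including the Elman context copies (backpropagation through time, the
`backprop="bptt"` default).  A per-tick truncated scheme that treats the
context as a constant input (`backprop="truncated"`) is also implemented,
but under this task's timing — error signals exist only on ticks 4–6, when
the input is zero — truncation gives the input→H1 weights an identically
zero gradient, leaving the input encoding untrained; empirically such a
model plateaus far below the repetition criterion.  The BPTT default is
therefore the configuration under which all reported behaviour is obtained.

### Cross-connections

Homotopic cross-connections are recurrent like the context: at tick `t`
they deliver the contralateral layer's activation from tick `t − 1`.
(Same-tick bidirectional links would make the within-tick computation
cyclic; the one-tick delay keeps the network a simple recurrent network.)
Their sparsity mask is drawn once at initialization, each direction
independently, at the configured density.  Under the `negative_only`
constraint the cross weights are clipped at zero after every update.

## The synthetic training environment

The task environment is 100 high-frequency (HF) and 100
low-frequency (LF) CVC words over a phoneme inventory in which each phoneme
is a 25-dimensional binary phonetic feature vector, plus 25 nonword probes
formed by changing exactly one phoneme of a word.  The concrete feature
table and word list are generated synthetically:

- **Inventory** — 18 consonants as distinct (place × manner × voicing)
  triples from a 6 × 3 × 2 articulatory grid, and 6 vowels as distinct
  (height × backness) pairs with rounding tied to backness; one feature is
  a consonant/vowel class indicator, and 7 trailing "acoustic" features are
  sparse random bits (`P(on) = 0.15`).  This mimics a distinctive-feature
  phonetic code: minimal pairs (e.g. a voicing contrast) differ in 1–3
  features, and the mean pairwise Hamming distance is ≈ 6 of 25.  An
  earlier uniform-random code (mean distance ≈ 12) made the task so
  linearly separable that lesioned models always recovered fully, which is
  inconsistent with the capacity behaviour the model is meant to exhibit
  (see *Calibration*).
- **Frequencies** — HF token frequencies uniform on [200, 2000], LF on
  [1, 20]: two disjoint bands whose log-compressed presentation
  probabilities give roughly a 3:1 HF:LF sampling ratio.
- **Scoring** — each production tick's output is decoded to the nearest
  inventory phoneme (Euclidean distance over all 25 features, ties broken
  by inventory order); an item is correct only if all three decoded
  phonemes match.

What the generator does *not* emulate: real phonotactics (any CVC triple is
a candidate word), stress, articulatory co-variation between slots, or a
natural word-frequency distribution.  Passing tests therefore show that the
network/lesion/recovery machinery produces the documented phenomena in a
statistically faithful environment, not that any specific natural-language
inventory would produce identical numbers.

## Calibration of the study conditions

Free hyperparameters were fixed once against the behavioural anchors the
study design specifies, before any acceptance measurement:

1. the intact 60/30 model must exceed 98% word and 96% nonword accuracy
   after 300,000 presentations, with the criterion reached late in
   development rather than in the first tenth of it;
2. ~30 hidden units is the minimum capacity for a *unilateral* model to
   support the task (a 30-unit single pathway just reaches criterion-level
   words with imperfect generalization; a 15-unit pathway fails);
3. a moderately lesioned left pathway retrains to an asymptote below the
   intact level within the 100,000-presentation recovery window (chronic
   deficit), while a right lesion leaves only a transient disruption.

`learning_rate = 5e-4` and `init_range = 0.5` satisfy all three; the
defaults are deliberately *not* faster settings (e.g. `1e-2`) that also
reach anchor 1 but saturate development ~6× early and erase anchors 2–3
by letting any lesion retrain to ceiling.

## Lesioning and recovery

A lesion marks a uniformly random subset of a hidden layer's live units
dead — activation clamped to 0 and, because both their activations and
error terms vanish, all their weights frozen — and adds one-time Gaussian
noise to every structurally present weight into and out of the layer
(input, context, cross, and H1→H2 blocks; biases excluded), surviving
units included.  Units are masked rather than removed so the lesioned and
perilesional populations remain addressable for measurement.  The lesion
RNG is separate from the training RNG.  The severity scheme pairs damage
proportions 0.1…1.0 with noise levels 0.1…1.0; the printed noise value is
used as the standard deviation by default, with a `variance` reading
available as a switch (the two readings differ by a square root and do not
change the qualitative orderings).

Recovery re-exposes the lesioned model to the unchanged training
environment for 100,000 presentations.  The lesioned layer's gain follows
a step ramp — `g = 0` for presentations [0, 1000), then 0.1, 0.2, …
reaching 1.0 at 10,000 — modelling initially inefficient perilesional
learning; all other layers keep `g = 1`.  The first trajectory checkpoint
is taken at 0 presentations with the ramp's initial gain applied, i.e. it
reflects the immediately-post-stroke silent lesion site.  Disabling the
ramp (`ramp=False`) reproduces the ablation control: the endpoint accuracy
is within seed noise of the ramped run.

Noise application is one-time at lesioning (not continuous during
recovery), and recovery phases are binned as acute = first 1,000
presentations, subacute = next 4,000, chronic = 5,000–40,000, configurable
via `PhaseBins`.

## Measures

All measures are pure (verified by weight checksums in the tests):

- **Pathway isolation** — a pathway's unique contribution is measured by
  zeroing the *opposite* pathway's input→H1 drive for the measurement run
  only.  Context, cross-connections, and biases remain active, so a
  silenced-side H1 layer still passes its bias-driven activity downstream;
  this is the intended reading of input-silencing and means the two
  "pathway contributions" are not strictly independent.
- **Functional contribution** — Pearson correlation between the
  pathway-isolated output patterns (words × production ticks × units) and
  the full model's patterns; a proxy for effective connectivity.
- **Output unit activation** — mean of the pathway-isolated output
  activations; a proxy for BOLD amplitude.
- **Laterality index** — `(L − R)/(L + R)` of any paired signal; also used
  for the capacity asymmetry index `(nL − nR)/(nL + nR)`.
- **RSA** — representational dissimilarity matrices (RDMs) are
  `1 − Pearson` over per-word pattern vectors; hidden patterns concatenate
  a layer's live-unit activations over the three production ticks; the
  target RDM is computed from the ground-truth phonological feature
  sequences (3 × 25 per word) by default, with a switch to use the model's
  produced outputs — ground truth keeps the reference defined during
  severe impairment.  The RSA score is the Pearson correlation of the two
  RDMs' lower triangles.  Degenerate cases (a silenced layer with constant
  patterns) yield NaN rather than a fabricated zero.
- **Weight statistics** — mean |w| and mean |Δw| versus a pre-lesion
  snapshot, over live, structurally present entries only.

## Numerical and design choices

- Contexts reset to zero between trials; trials are independent.
- Biases on all hidden and output units; never lesioned or noised.
- The two pathways are stored as single concatenated arrays with
  block-structure masks (re-imposed after every update); this is an
  implementation detail invisible at the API, chosen for speed.
- The hot training loop has a numba-compiled kernel mirroring the numpy
  reference implementation (`train_step`); the two agree to machine
  precision over hundreds of presentations (tested), and the package falls
  back to the reference loop if numba is absent.
- Cross-entropy outputs are clipped at 1e-12 for the loss computation
  only; gradients use the exact `a − τ` form.
- Whole-item scoring decodes by nearest neighbour rather than 0.5
  thresholding; ties break toward the earliest inventory phoneme.
- Statistical helpers: two-sided Pearson and paired t tests (scipy),
  Bonferroni correction (the most conservative choice, as the correction
  method is otherwise unconstrained), and a repeated-measures ANOVA
  (statsmodels `AnovaRM`) for the word-type × model-type analysis.
- Paired t on identical samples returns t = 0, p = 1 rather than NaN.

## Known limitations

- Mean hidden activation runs *against* capacity in this calibration: the
  smaller pathway's units work harder (their weights grow larger and
  saturate), so its mean activation is slightly higher, not lower.  The
  laterality results do not depend on this measure.
- In the left-mild recovery time-course, the acute→subacute rise of the
  *left* (lesioned-side) output activation — its rebound out of the gain
  ramp — is numerically larger than the right-side rise; the four sign
  contrasts (both sides rise early; only the right falls later) are the
  robust pattern.
- With the articulatory feature code, intact models typically reach 100%
  on words and nonwords at 300K presentations, so frequency and lexicality
  effects are visible during development (HF learned earliest, nonwords
  last) but not as asymptotic differences.
- Per-seed variability in the severe-lesion condition is substantial;
  severity orderings and RSA contrasts are stated as seed-averaged or
  checkpoint-pooled quantities.

## Problem sizes

Reported experiments use 300,000 developmental presentations, 100,000
recovery presentations (40,000 for the phase-binned time-course), 3 seeds
per condition in the default runners (20 in the full published-style
protocol, configurable), and checkpoint cadences of 10,000 (development)
and 500–2,000 (recovery) presentations.
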