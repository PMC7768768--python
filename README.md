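# bilatnet

A neurocomputational model of spoken word repetition in a bilateral
language network, and of aphasia and recovery after unilateral damage.

Clinical and imaging observations pull in different directions: language
looks strongly left-lateralized in chronic stroke aphasia, yet healthy
functional imaging shows bilateral (if asymmetric) activation, and reports
disagree on whether right-hemisphere activation after a left stroke is
compensatory or maladaptive.  `bilatnet` implements the modelling account
that reconciles these: a single functional network with two parallel
pathways of *unequal capacity*.  The package is for computational
neuroscientists and cognitive scientists who want to rerun, test, or
extend the simulations behind that account — lateralization from capacity
asymmetry, chronic aphasia after left but not right damage, dynamic
activation shifts during recovery, and the relation between behavioural
performance and "neuroimaging" proxies.

## The model

A simple recurrent network (SRN) with a shared 25-unit phonological input
and output layer and two hidden pathways (left/right), each two logistic
layers deep (H1 → H2), with an Elman context on H1.  A trial spans six
time ticks: the three phonemes of a CVC word are presented sequentially at
ticks 1–3 and must be reproduced at ticks 4–6.  Hidden units compute
`a = σ(g·net)` with per-layer gain `g`; training is online backpropagation
of cross-entropy error through the six ticks, one weight update per word
presentation, with words sampled by log-compressed frequency.

Key quantities (all implemented in `bilatnet.measures`):

- laterality index `(L − R)/(L + R)` over any paired left/right signal —
  applied to *functional contribution* (correlation of pathway-silenced
  output patterns with the full model's; an effective-connectivity proxy)
  and *output unit activation* (mean pathway-isolated output activation; a
  BOLD proxy);
- RSA: representational dissimilarity matrices `1 − r` over per-word
  activation patterns, compared with the target phonological RDM;
- lesioning: kill a random fraction of a hidden layer's units and add
  one-time Gaussian noise to its afferent/efferent weights, then retrain
  with an "inefficient learning" gain ramp over the first 10K recovery
  presentations.

The training environment (200 CVC words, 100 high- + 100 low-frequency,
25 single-phoneme-substitution nonwords, 25-dimensional binary phonetic
feature vectors) is generated synthetically by `bilatnet.lexicon`; see
`docs/methods.md` for what the generator does and does not emulate.

## Worked example

Train the standard 60/30 model (left pathway twice the capacity of the
right) and measure it:

```python
import numpy as np
import bilatnet as bn

inv = bn.build_inventory(seed=0)
lex = bn.generate_lexicon(inv, seed=0)

state = bn.init_network(bn.NetworkConfig(n_left=60, n_right=30, seed=1))
state, log = bn.train(state, lex, 300_000, eval_every=50_000,
                      rng=np.random.default_rng([1, 1]))
final = log.checkpoints[-1]
print(f"words {final['accuracy_words']:.1f}%  nonwords {final['accuracy_nw']:.1f}%")

fc = {s: bn.functional_contribution(state, lex, s) for s in ("left", "right")}
oa = {s: bn.mean_output_activation(state, lex, s) for s in ("left", "right")}
print(f"functional contribution L/R: {fc['left']:.3f}/{fc['right']:.3f} "
      f"-> LI {bn.laterality_index(fc['left'], fc['right']):+.3f}")
print(f"output activation      L/R: {oa['left']:.3f}/{oa['right']:.3f} "
      f"-> LI {bn.laterality_index(oa['left'], oa['right']):+.3f}")
print("RSA by layer:", {k: round(v, 3)
                        for k, v in bn.layer_rsa_scores(state, lex).items()})
```

Output of this exact script:

```
words 100.0%  nonwords 100.0%
functional contribution L/R: 0.962/0.428 -> LI +0.384
output activation      L/R: 0.152/0.078 -> LI +0.320
RSA by layer: {'LH1': 0.789, 'RH1': 0.297, 'LH2': 0.78, 'RH2': 0.275}
```

The model reaches the repetition criterion (>98% words, >96% nonwords) and
is left-lateralized on both measures — positive laterality indices — with
richer word representations (higher RSA) along the higher-capacity left
pathway.  Lesion it and watch it recover:

```python
lesioned = state.copy()
bn.apply_lesion(lesioned, bn.LesionSpec("LH1", proportion=0.5, noise_sd=0.5, seed=7))
lesioned, traj = bn.retrain(lesioned, lex, 100_000, eval_every=10_000,
                            rng=np.random.default_rng(2), condition="left_moderate")
df = traj.to_frame()
print(df[["presentations", "accuracy_words", "out_act_left", "out_act_right",
          "rsa_LH1", "rsa_RH1"]].round(3).tail(3).to_string(index=False))
```

```
 presentations  accuracy_words  out_act_left  out_act_right  rsa_LH1  rsa_RH1
         80000            98.5         0.147          0.111    0.742    0.351
         90000            99.0         0.147          0.109    0.746    0.352
        100000            99.0         0.147          0.110    0.749    0.351
```

The moderate (50% + noise 0.5) left lesion drops performance to floor
immediately (the first checkpoints of `df`), and 100K presentations of
retraining bring it back to just below the intact ceiling, with the
surviving left pathway reclaiming its dominant output contribution and
RSA.  Severe lesions (e.g. proportion 0.8) leave a substantial chronic
deficit, and the seed-averaged severity orderings are what the test suite
checks; single runs vary.

The same workflows are scriptable from the shell (`bilatnet make-lexicon`,
`train`, `lesion`, `retrain`, `measure`, and `experiment {capacity-sweep,
lesion-sweep, recovery-timecourse, interconnectivity}`); see
`bilatnet --help`.

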