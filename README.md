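# culsel

Drift versus cultural selection in the evolution of communication systems:
model fitting, Bayes-factor model comparison and micro-society simulation.

## The problem

When small groups of people invent a communication system from scratch —
for example by repeatedly drawing a fixed set of concepts for one another —
each group rapidly converges on a shared inventory of signs, and different
groups converge on different inventories. Is that convergence explained by
*neutral drift* (random copying of encountered variants, the null model of
cultural evolution), or does it require *selection*: a **coordination
bias** toward one's own or one's partner's variants, and/or a **content
bias** toward an intrinsically preferred variant?

`culsel` implements a mixed probabilistic model of variant choice that nests
all of these accounts, fits it to coded game records by exhaustive maximum
likelihood, quantifies the evidence for each bias with best-account Bayes
factors, and forward-simulates micro-societies under known parameters so
the whole inference pipeline can be validated by parameter recovery. It is
aimed at cultural-evolution and language-evolution researchers analysing
dyadic transmission experiments.

## The model

The unit of analysis is a **data structure**: an `8 participants x 7
generations` grid of coded variant labels for one concept in one
micro-society, with the round-robin pairing schedule and the within-pair
draw order. A participant's **history** h splits into ego-produced entries
(h|E) and witnessed partner entries (h|A). The probability of producing
variant x is

```
P(x | h) = (1-mu) * [ (1-beta) * ( (1-gamma) f(h|E,m)(x) + gamma f(h|A,m)(x) )
                      + beta * delta_tau(x) ]
           + mu * phi(x)
```

where `f` maps a list onto its relative frequencies, `h|E,m` / `h|A,m` keep
the last `m/2` entries of each kind, `gamma = (c+1)/2` reparameterizes the
coordination bias `c` in [-1, 1] (-1 fully egocentric, +1 fully
allocentric), `beta` equals the content-bias level `b` when the target
variant `tau` is in memory and 0 otherwise, `phi` is the flat distribution
over the variant universe, and `mu` is the mutation rate (default 0.02).
Drift is the sub-model `b = 0, c = 0`.

The likelihood of a data structure is the product of these probabilities
over every choice from generation 2 on (generation-1 choices have no
history). Fitting is an exhaustive search over the 484-point grid
`m in {2,4,6,8} x c in {-1,...,1 step 0.2} x b in {0,...,1 step 0.1}`, with
`tau` profiled out over the 8 most frequent attested variants. Evidence for
a bias is a **best-account Bayes factor** — the maximum likelihood of any
model with the bias over the maximum likelihood of any model without it —
with significance threshold 19, and each structure is classified as
`content_only`, `coordination_only`, `both`, `indeterminate_bias`
or `drift_consistent`.

## Worked example

```python
from culsel import *

cfg = SimulationConfig(
    true_params=ParameterSetting(m=2, c=-0.8, b=0.6, tau=None),
    tau_rule="random_g1",   # each structure prefers one of its own G1 variants
    seed=7,
)
corpus = simulate_corpus(cfg)
fits = [grid_search(d) for d in corpus]
bfs = [bayes_factors(f) for f in fits]

from culsel.selection import summary_to_text
print(summary_to_text(summarize_corpus(
    fits, bfs, [diversity_trajectory(d) for d in corpus])))
```

```
Corpus summary (64 data structures)
  evidence threshold: 19.0
  best-fit memory size m: 2: 61, 4: 2, 8: 1
  best-fit coordination bias c: -1.0: 19, -0.8: 30, -0.6: 8, -0.4: 3, -0.2: 1, 0.0: 2, 1.0: 1
  best-fit content-bias level b: 0.1: 3, 0.2: 1, 0.3: 3, 0.4: 6, 0.5: 16, 0.6: 11, 0.7: 11, 0.8: 5, 0.9: 6, 1.0: 2
  bias categories:
    content_only: 10 (15.6%)
    coordination_only: 9 (14.1%)
    both: 42 (65.6%)
    indeterminate_bias: 1 (1.6%)
    drift_consistent: 2 (3.1%)
  median Bayes factors: content 151.95, coordination 413.44, any 9650.20
  variant types per generation:
              G1      G2      G3      G4      G5      G6      G7
    mean  4.9688  4.3438  3.7812  3.1719  2.7344  2.2188  1.8750
    ...
```

The simulated truth (egocentric coordination bias c = -0.8, content bias
b = 0.6, memory m = 2) is recovered: the modal best-fit parameters sit on
or next to the true grid point, most structures show significant evidence
for both biases, and variant diversity decays from about 5 types at
generation 1 toward fixation by generation 7.

The same pipeline runs from the shell:

```sh
culsel simulate --config sim.json --seed 7 --out corpus.json
culsel fit corpus.json --out fits.json
culsel classify fits.json --threshold 19 --out classes.json
culsel report classes.json --plot panels.png
```

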