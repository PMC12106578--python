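# cegcn — evolving-weight GCN link prediction for multimorbidity networks

Multimorbidity — the coexistence of two or more chronic diseases in one
person — develops along age: disease pairs that share many comorbid partners
today tend to become comorbid themselves later.  `cegcn` models this as
**dynamic link prediction on an age-indexed comorbidity network**: diseases
are nodes, an edge at age *t* means at least one patient carries both
diseases by that age, and the task is to rank disease pairs by their
probability of being linked at age *t + 1*.

The core model is a graph convolutional network whose layer weights are not
static but are **evolved over the age axis by a matrix-valued GRU**:

* Per snapshot, features propagate through the symmetric-normalized
  adjacency: `H_{t,l+1} = σ(D̃^{-1/2} (A_t + I) D̃^{-1/2} H_{t,l} W_{t,l})`.
* Node features are one-hot encodings of the common-neighbor structural
  score `f_t(i) = (A_t² · 1)_i` — each node's degree plus its total
  common-neighbor count with every other node.
* Across ages, `W_{t,l} = GRU(summarize(H_{t,l}), W_{t-1,l})`: the n×d
  embedding matrix is pooled to the weight's shape by learned top-k scoring,
  and the GRU's update/reset gates decide how much of last year's weights to
  keep (`W_t = (1 − Z) ∘ W_{t-1} + Z ∘ W̃`).
* A symmetrized two-layer MLP scores node pairs; training minimizes
  class-weighted cross-entropy on next-age edges, with ranking quality
  measured by MAP (mean average precision over per-node queries) and MRR
  (mean reciprocal rank of the first true partner).

The reference cohort (CHARLS 2018, 3,333 multimorbid patients, 14 chronic
diseases, ages 45–90) is available on request only, so the package ships a
synthetic generator that emulates its structure with shared latent risk
factors and can *plant* the common-neighbor rule with known ground truth,
making every stage of the pipeline testable.

## Worked example

```python
from cegcn import CEGCNLinkPredictor, StaticGCNLinkPredictor
from cegcn.simulate import experiment_config, simulated_sequence

config = experiment_config(seed=101)                   # 250 patients, 14 diseases
sequence, cohort, truth = simulated_sequence(config, rule_strength=0.2)

model = CEGCNLinkPredictor(seed=1).fit(sequence)       # temporal 70/15/15 split
report = model.evaluate()                              # held-out test ages
print(f"test MAP={report.map:.3f} MRR={report.mrr:.3f} "
      f"({report.n_queries} queries)")

baseline = StaticGCNLinkPredictor(seed=1).fit(sequence)
print(f"static baseline MAP={baseline.evaluate().map:.3f}")

print(model.top_pairs(age=70, k=5))
```

Output from this exact snippet:

```
test MAP=0.944 MRR=0.944 (9 queries)
static baseline MAP=1.000
   disease_i  disease_j     score  already_linked
0         12         13  0.941239            True
1          0         12  0.919336            True
2          0         13  0.919336            True
3          8         12  0.899663            True
4          8         13  0.899663            True
```

On this particular cohort seed both models recover the planted rule almost
perfectly (the static ablation even edges out the recurrent model — the
planted rule is stationary across age, so a time-constant GCN is
well-specified for it; the seeded experiments in
`cegcn.experiments.planted_experiment` quantify the paired comparison
properly over five seeds).

`test MAP` is the mean, over held-out (age, disease) queries, of the average
precision of the predicted partner ranking; `MRR` averages the reciprocal
rank at which each disease's first true future partner appears.  The
`top_pairs` table ranks pairs by predicted link score at age 85;
`already_linked` flags pairs that are existing comorbidities rather than
predicted new ones.

The same pipeline is scriptable from the shell:

```bash
cegcn simulate --n-patients 250 --seed 7 --out cohort.csv --catalog-out catalog.csv
cegcn build-network --cohort cohort.csv --catalog catalog.csv --out snaps/
cegcn train --snapshots snaps/ --out run/
cegcn predict --run run/ --snapshots snaps/ --age 85 --top 10
```

## Layout

| module | contents |
|---|---|
| `cegcn.cohort` | catalog/cohort readers, yearly snapshot construction, prevalence |
| `cegcn.features` | squared-adjacency structural scores, one-hot vocabulary |
| `cegcn.model` | normalized convolution, top-k pooling, matrix GRU, scorer, loss |
| `cegcn.estimators` | `CEGCNLinkPredictor`, `StaticGCNLinkPredictor`, leakage audit |
| `cegcn.train` | temporal splits, targets, MAP/MRR, ranking reports |
| `cegcn.simulate` | latent-factor cohort generator, planted temporal rule |
| `cegcn.experiments` | seeded recovery and calibration studies |
| `cegcn.datasets` | published CHARLS 2018 reference counts and benchmark table |

See `docs/methods.md` for the modeling assumptions, parameter choices and
known limitations.
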