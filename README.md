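# polynest

Dynamic nest-network analysis for polydomous ant colonies.

Many wood ant species (e.g. the red wood ant *Formica lugubris*) are
polydomous: one colony inhabits several spatially separated nests connected
by worker trails that redistribute food — mainly honeydew collected from
trees — through the colony.  A nest's access to resources then depends not
only on its own surroundings but on its *position in the nest network*.
`polynest` is a library for asking whether that position has ecological
consequences: does the flow of resources through a nest predict whether the
nest survives, and whether it founds (buds) new nests?

It is written for behavioural ecologists working with repeated field maps
of colonies (nests, trees, trails with measured traffic), and for
methodologists interested in survival analysis on dynamic networks.

## The model

Each colony map is a weighted, spatially embedded graph.  Trail traffic is
measured as the trail length needed to find 10 workers, giving
`ants_per_cm = 10 / sample_gap` and `total_ants = ants_per_cm × length`;
trail **weight** divides the total by the mean population of the connected
nests (or the foraging nest's population for nest–tree trails).  Resource
flow through nest *i* is its **weighted betweenness centrality** — the
number of shortest paths between node pairs (trees included) passing
through *i*, with edge cost `1/weight` — normalized to the largest nest
value in the map, so every map's flow lies in [0, 1].

Nest survival is modelled with an **extended Cox proportional-hazards
model** on counting-process records (one row per nest per mapping
interval, covariates measured at the interval start, right censoring at
the last map):

    h(t, X) = h0(t) · exp(β₁X₁ + … + β_p X_p)

Because nests in one network are not independent, significance comes from
a **quadratic assignment procedure (QAP)**: the covariate of interest is
permuted among the nests of each colony×timepoint map (10,000 permutations
by default), the model refitted each time, and the observed Wald *z*
compared with the permutation null using the add-one rule
`p = (1 + #extreme) / (1 + B)`.

Budding is analysed with **binomial-logit mixed models**: founder status
(did this nest bud a new nest this interval?) on the attribute of
interest, with random intercepts for colony, nest identity and season,
tested by chi-squared **analysis of deviance** (2·Δ log-likelihood)
against the null model without the fixed effect.

A synthetic colony generator (`polynest.simulate`) emulates the field
structure — 13 colonies, 2–21 nests, five seasonal maps, lognormal
populations from tens of workers to over a million — with abandonment and
budding probabilities planted on the logit scale, and ledgers every event
it plants so each analysis stage can be tested against known truth.

## Worked example

```bash
python examples/03_qap_survival.py
```

```
494 nest survival records, 76 abandonments
betweenness: z = -5.33, n = 494, B = 999, p = 0.0010 (two_sided)
predicted S(t) for flow 0.1: 1.00, 0.92, 0.82, 0.73, 0.65
predicted S(t) for flow 0.5: 1.00, 0.97, 0.93, 0.89, 0.85
predicted S(t) for flow 0.9: 1.00, 0.99, 0.97, 0.96, 0.94
```

The generator plants a protective flow effect (log-hazard slope −2 per
unit normalized betweenness).  The negative *z* says higher resource flow
lowers the abandonment hazard; the permutation *p* is at its floor
1/(B+1).  The three curves are the model's predicted survival for nests
held at low (0.1), medium (0.5) and high (0.9) resource flow: a
high-flow nest retains ≈0.94 survival probability over four intervals,
a low-flow nest ≈0.65.

The other examples cover per-map metrics (`01`), event extraction and
founder classification (`02`), the budding GLMM with its
possible-founder policy harness (`04`), and the full pipeline with its
plain-text report (`05`).  A thin CLI wraps the same stages:

```bash
polynest simulate --out fixture --seed 1
polynest run --input fixture --out results --seed 1 --qap-b 999
```

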