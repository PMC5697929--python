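# partmig

Seasonal survival analysis for partially migratory populations: multi-event
(hidden-Markov) Cormack–Jolly–Seber models, QAICc model selection with
Akaike weights, migratory-strategy classification from dated detection
records, and the geometric-series break-even comparison of migrant versus
resident fitness. A synthetic-cohort generator stands in for field data, so
the whole pipeline is testable end to end.

**Who it is for:** quantitative ecologists analysing capture–mark–recapture
data from populations in which some individuals migrate for the winter and
others remain resident, and who want seasonal survival (Φ) and detection
(P) estimates, a ranked candidate-model table, and the breeding-success
excess residents would need to offset a migrant survival advantage.

## The model

Each bird's encounter history (0/1 per seasonal occasion: summer from
2 March, winter from 3 November) is modelled with two hidden states
{alive, dead}, conditioning on first capture: alive birds survive the
interval leaving occasion *t* with probability Φ(t) and are detected at an
occasion with probability P(t); dead birds are never detected. Φ and P are
logit-linear in additive two-level factors (season type, migratory
strategy, sex, age at capture), written in the compact formula notation

    Phi[season + migr].P[migr]

Models are ranked by QAICc = deviance/ĉ + 2K + 2K(K+1)/(n_eff − K − 1) and
weighted by w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2). The fitness comparison uses
the expected lifetime number of breeding seasons under seasonal survival,

    E(s1, s2) = s1 + s1·s2/(1 − s1·s2)

(s1 winter, s2 summer survival): the first breeding requires surviving one
winter, each later one a further summer + winter.

## Worked example

```python
from partmig import MultiEventCJS, SimulationConfig, simulate_population

cfg = SimulationConfig(n_residents=5000, n_migrants=5000, seed=42)
eh, cov, truth = simulate_population(cfg)

est = MultiEventCJS(model="Phi[season + migr].P[migr]", random_state=1)
est.fit(eh, covariates=cov)
r = est.predict_rate({"submodel": "phi", "season": "winter", "migr": "migrant"})
print(round(r["rate"], 3), round(r["ci_low"], 3), round(r["ci_high"], 3))
```

prints `0.725 0.711 0.739`: the fitted migrant winter survival recovers the
generating value 0.73 and the Wald interval (asymmetric on the probability
scale) covers it. The same cohort fitted with the full candidate set and
the default 262-bird study-scale configuration runs from the shell:

```bash
partmig run --seed 1 --out runs/demo
```

```
best model: Phi[season + migr].P[migr]
break-even excess: 61.25% (e_migrant=2.58, e_resident=1.60)
```

and `runs/demo/table.tsv` starts

```
model                               K  QAICc      delta   weight  deviance
Phi[season + migr].P[migr]          5  1020.7838  0.0000  0.6564  1010.4883
Phi[season + migr + sex].P[migr]    6  1022.1698  1.3860  0.3283  1009.7539
Phi[season].P[migr]                 4  1029.1100  8.3261  0.0102  1020.9139
```

i.e. the season + strategy survival model with strategy-dependent detection
is recovered as the best-supported structure, and the break-even line says
residents would need 61.25% higher breeding success than migrants
(expected reproductive seasons 2.58 vs 1.60) for the two strategies to be
equally fit. The interactive formula calculator:

```bash
partmig ess --s1-migrant 0.73 --s1-resident 0.57 --s2 0.89 --published-rounding
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the package's own break-even machinery, the expected
lifetime number of reproductive seasons for a migrant (winter survival
0.73, summer 0.89) and a resident (winter survival 0.57) and writes them as
JSON keyed `t1` / `t2`.

## Layout

```
src/partmig/
  simulate.py    synthetic cohort + dated detection records
  seasons.py     seasonal occasion calendar
  prep.py        strategy classification, exclusion filters, matrix build
  formula.py     model-formula mini-language
  design.py      logit design matrices
  engine.py      forward-algorithm likelihood, CJS oracle, MultiEventCJS
  selection.py   QAICc ranking and Akaike weights
  fitness.py     geometric-series break-even calculation
  pipeline.py    simulate -> prep -> fit -> rank -> break-even
  cli.py         partmig command-line interface
docs/methods.md  model, assumptions, numerical choices, limitations
```
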