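# necsuff

Degrees of necessity and sufficiency, attributable risk and explained
variation for dichotomous and right-censored survival outcomes.

## The problem

Prognostic-factor studies usually summarise a factor's effect with an
odds or hazard ratio and a p-value.  Neither answers two questions that
sit at the heart of causal thinking:

* **Necessity** — without the harmful level of the factor, can the
  outcome still develop?
* **Sufficiency** — with the harmful level, is the outcome unavoidable?

`necsuff` implements two paired measures, *DN* (degree of necessity) and
*DS* (degree of sufficiency), that quantify exactly this on a 0-to-1
scale, for any kind of prognostic factor (dichotomous, polytomous,
continuous) and any probability model (logistic regression, Cox
regression, or plain conditional probabilities from any source).

With p(x) = P(D | X = x) the conditional event probability and
p = P(D) the unconditional one, levels with p(x) < p are *protective*
and levels with p(x) > p *harmful*, and

```
DN1 = sqrt( E[ ((p − p(X)) / p)²        | p(X) < p ] )
DS1 = sqrt( E[ ((p(X) − p) / (1 − p))²  | p(X) > p ] )
```

with DN2/DS2 the un-squared variants.  For a single dichotomous factor
DN equals the classical attributable risk AR, DS the reverse
attributable risk AR\*, and Schemper's explained variation factorises
exactly: EV = DN · DS.  In general EV decomposes as

```
EV = (1 − α) · p/(1−p) · DN1² + α · (1−p)/p · DS1²
```

where α = P(harmful level).  For survival outcomes the same comparison
runs between conditional and unconditional cumulative incidences
F(t | x) and F(t) at every event time, averaged over the event-time
distribution with inverse-probability-of-censoring (reverse
Kaplan-Meier) weights, which makes the estimates robust to
administrative censoring before the horizon τ.

The package contains:

* `necsuff.binary` — estimation from probability vectors, closed 2x2
  forms, AR/AR\*, relative risk, the EV decomposition and partial
  (nested-model) measures;
* `necsuff.survival` — Kaplan-Meier and reverse-KM building blocks,
  per-time kernels, weighted overall DN/DS and the Schemper-Henderson
  explained variation, with conditional curves from stratified KM, Cox
  regression (via lifelines) or any user-supplied incidence matrix;
* `necsuff.population` — exact/quadrature population values for three
  scenario families (2x2, logistic-normal, two-group exponential
  survival with type I or administrative censoring);
* `necsuff.bootstrap` — percentile and BCa intervals with the
  direction-consistency truncation rule;
* `necsuff.simulate` — scenario-faithful data generators and a
  bias/coverage/width simulation harness;
* a `necsuff` command-line interface over all of the above.

## Worked example

A classical cohort: 12 664 Swedish males followed 33 years, smoking
status against death from lung cancer.  Cell counts in the 2x2 layout
(a, b = never/ever smoked among survivors; c, d = never/ever smoked
among lung-cancer deaths):

```
$ necsuff twobytwo --counts 8120,4331,36,177
{
  "dn1": 0.7375681257727829,
  "ds1": 0.02282815540200639,
  "ev": 0.01683731979470768,
  "alpha": 0.3559696778269109,
  "protective_level": 0,
  "relative_risk": 8.895371191955045,
  ...
}
```

Smoking raises the risk of lung-cancer death almost nine-fold
(RR = 8.90) and is quite *necessary* for it (DN = 0.74: most deaths
happened among smokers), yet utterly *insufficient* (DS = 0.02: almost
no smoker died of lung cancer).  Because the disease is rare
(P(D) ≈ 1.7%), the low DS dominates the explained variation,
EV = DN · DS ≈ 0.017 — the factor explains under 2% of the outcome
variability despite the large relative risk.

Population calculators answer design-style questions, e.g. the
two-group exponential survival model with hazard ratio 10 analysed at
τ = 4.90 (type I censoring):

```
$ necsuff population survival --hr 10 --alpha 0.5 --tau 4.90 --censoring type1
{
  "dn": 0.7113488378665193,
  "ds": 0.4383954690815832,
  "ev": 0.3404574462523584,
  "pct_censored": 31.00364886276702
}
```

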