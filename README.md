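# trawlcontact

Infer length-dependent fish escape behaviour in towed fishing gear from
catch data alone.

## The problem

When a trawl is modified with a selective device — here, a large-mesh escape
panel in the upper side of the aft section — the device only works on fish
that actually touch it. Direct observation of that contact (cameras, sonar)
routinely fails on deep, turbid fishing grounds. This package implements an
indirect route: fish a twin rig in which one trawl carries the panel and the
other is standard, compare the catches length class by length class, and
convert the comparison into a length-dependent *contact likelihood* — the
probability that a fish entering the panel section touches the panel and
escapes through it.

It is written for fisheries and gear-selectivity scientists working with
paired-gear (catch comparison) experiments.

## The model

For fish of length *l* caught in either codend, the catch comparison rate is
modelled by a logistic polynomial

    rate(l) = exp(f(l)) / (1 + exp(f(l))),    f(l) = Σᵢ qᵢ lⁱ,  i ≤ 4.

Every subset of {q₀…q₄} — including the empty set, which pins the curve at
the no-effect value 0.5 — is fitted by maximising the binomial log-likelihood
of codend membership pooled over hauls, and the best of the 32 candidates is
chosen by AIC. Efron percentile confidence bands come from a double bootstrap
(hauls, then fish within hauls; 2000 replicates by default) that re-runs the
full model selection inside every replicate.

With entry split *sp* between the trawls, and restricting to lengths that the
standard trawl retains completely while the panel releases every contacting
fish, the rate determines the contact likelihood *c(l)*:

    rate(l) = sp (1 − c(l)) / (1 − sp c(l)).

*c(l)* is modelled by the selectivity-style logistic

    c(l) = c₁ + (c₂ − c₁) / (1 + exp(−(ln 9 / SRc)(l − L50c)))

(model M1), with nested simplifications M2 (knife edge, SRc = 0), M3 (knife
edge to zero contact) and M4 (constant contact), again compared by AIC.

A generative simulator of the whole experiment (population → split → panel
contact → per-panel logit mesh retention → codend counts) doubles as the
package's synthetic-data source and demonstrates how selectivity in the
*standard* trawl confounds the comparison: it produces a cup-shaped rate
curve that is easily misread as size-dependent behaviour.

## Worked example

`examples/` contains one short script per capability. Inferring contact from
a simulated field-style experiment (`examples/contact_inference.py`, truth:
constant 55% contact):

```
selected contact model : M3
  M1 AIC  31262.94
  M2 AIC  31258.88
  M3 AIC  31257.08
  M4 AIC  31257.90
contact parameters     : c1=0.551 c2=0.000 L50c=77.0 SRc=0.0
plateau contact        : 0.551 (truth 0.55)
fit                    : deviance 41.10 on 48 dof (p = 0.7493)
```

The plateau estimate says 55.1% of entering fish touched the panel and
escaped — within noise of the generating truth; the goodness-of-fit p-value
(chi-square upper tail of the deviance) shows the model describes the data
adequately. The confounding mechanism
(`examples/selectivity_confounding.py`):

```
with a selective standard trawl:
  minimum rate 0.340 at 39.5 cm (interior dip = cup shape)
  rate at 20 cm 0.497, at 80 cm 0.487
with a non-selective standard trawl:
  rate rises monotonically: 0.334 at 20 cm -> 0.487 at 80 cm
  monotone: True
```

Same escape behaviour in both panels of output; only the control trawl's
mesh selection differs.

A thin CLI wraps the same functions for shell use:

```sh
trawlcontact simulate --out sim.csv --n-fish 20000 --n-hauls 10 --seed 7
trawlcontact pipeline --input sim.csv --species cod --reps 500 --seed 7 --out results/
```

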