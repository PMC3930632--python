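# Methods

## The experiment being modelled

A twin-rig trawler tows two otherwise identical trawls; one ("experimental")
carries a very-large-mesh panel in the upper side of its aft tapered section,
the other ("standard") does not. Each fish entering the rig is assumed to
enter the experimental trawl with a fixed, length-independent probability
*sp* (the split). Inside the panel section it touches the top panel with a
length-dependent probability *c(l)* — the same length dependency in both
trawls, since the sections are geometrically identical — and a touching fish
escapes through that panel unless the mesh retains it. Per-panel retention of
contacting fish is the standard selectivity logit with parameters L50p
(length at 50% retention) and SRp = L75 − L25. The codend probabilities are

    p_exp(l) = sp (1 − c(l)(1 − r_exp(l)))
    p_std(l) = (1 − sp)(1 − c(l)(1 − r_std(l)))
    p_escape(l) = 1 − p_exp(l) − p_std(l),

which conserve probability identically. The observable is, per length class,
the pair of codend counts; the catch comparison rate is
p_exp / (p_exp + p_std).

Two retention sentinels avoid degenerate parameter values: `release_all`
(every contacting fish escapes; used for the ~800 mm panel, whose L50p lies
far above any fish length) and `retain_all` (no escape; an ideal
non-selective control).

## Catch comparison stage

rate(l) is modelled as a logistic polynomial of order ≤ 4. All 2⁵ = 32
coefficient subsets, including the empty model rate ≡ 0.5 (the no-effect
null), are fitted by maximising the binomial log-likelihood of codend
membership, summed over length classes and pooled over hauls; classes with
zero total count are skipped and excluded from degrees of freedom. The lowest
AIC (2k − 2ℓ) wins; ties break toward fewer parameters, then lower
polynomial order. The likelihood is the binomial kernel without the
combinatorial constant, which cancels from AIC differences and deviances.

Numerics: lengths are divided by 100 before polynomial evaluation (l⁴ at
l ≈ 112 spans ten orders of magnitude otherwise); reported coefficients are
back-transformed. Because the binomial-logit log-likelihood is concave in
the coefficients, the fit uses Fisher scoring (IRLS) with step-halving — the
stationary point is the global maximum, so no multistart is needed; the
optimum is cross-checked against an independent GLM implementation and
against exhaustive grid search in the test suite. Fits whose linear
predictor exceeds |15| anywhere are flagged as separated/degenerate and
excluded from model selection. Counts may be non-integer after subsampling
correction; they enter the likelihood linearly.

Goodness of fit: deviance = 2(ℓ_saturated − ℓ_model), dof = informative
classes − free parameters, p-value = chi-square upper tail. dof counts
*informative* classes (positive total), the reading most consistent with
skipping empty classes in the likelihood.

## Contact stage

Within a restricted length window — above the largest length that can pass
the standard trawl's netting, and below any length at which the big panel
could itself restrict escape (no upper bound by default, since the panel
releases all sizes) — the standard trawl retains every contacting fish and
the panel releases every contacting fish, so the general model collapses to

    rate(l) = sp (1 − c(l)) / (1 − sp c(l)),

invertible as c = (sp − rate) / (sp (1 − rate)) for rate ∈ [0, sp]. An
observed rate above sp has no contact likelihood in [0, 1]; it is reported
as out-of-model and clamped only on request.

The window rule is configurable: `strict` keeps measured lengths strictly
above the cutoff (the gadoid convention — a 33 cm cutoff yields a window
starting at 34 cm), `inclusive` keeps the boundary class (the flatfish
convention). Species whose every size can pass the control netting (e.g.
Norway lobster) are rejected with an explanatory error: windowing cannot
remove the control's selectivity for them. Hauls with fewer than 10
individuals of the species inside the window are excluded (boundary: exactly
10 is retained) and their ids reported.

c(l) uses the same ln 9 / SR logistic convention as retention, blending from
plateau c₁ (small fish) to plateau c₂ (large fish) around L50c, both
plateaus box-constrained to [0, 1]; SRc = L75 − L25 of the transition, and
SRc = 0 is a knife edge taking the exact mean (c₁+c₂)/2 at L50c. Four nested
shapes are fitted (free parameters in braces):

| model | shape | free parameters |
|-------|-------|-----------------|
| M1 | full logistic | {c₁, c₂, L50c, SRc} |
| M2 | knife edge between plateaus | {c₁, c₂, L50c} |
| M3 | knife edge to zero contact | {c₁, L50c} |
| M4 | constant contact | {c} |

M1 is maximised by multistart L-BFGS-B (deterministic seeded starts around
an inversion-based heuristic; SRc floored at 0.01 cm). M2/M3 likelihoods are
piecewise constant in L50c, so they are profiled exactly over every boundary
between adjacent observed classes, with the plateau levels solved in closed
form (pooled-proportion inversion) when the sentinel retentions apply and by
bounded scalar search otherwise. M4 likewise. Estimates on a box bound carry
a `boundary` flag. AIC selects among M1–M4 with ties toward fewer
parameters.

A deliberate consequence of exact knife-edge profiling: when the true
contact curve is flat, the profiled breakpoint harvests noise worth ~2–4
log-likelihood units regardless of sample size, so AIC splits roughly evenly
between M2 (with two nearly equal plateaus) and M4 rather than selecting M4
outright. A local optimiser would hide this by under-exploring breakpoints;
we prefer the exact maximiser and document the behaviour. The selected curve
is flat-ish either way, and on genuinely knife-edged data M2 wins clearly.

The same fitting machinery accepts explicit per-panel retention curves, in
which case the full factorisation above replaces the restricted-window
relation. This is how the simulation-recovery analyses fit M1 across *all*
length classes with split and retention fixed at their generating values.

The split sp is a fixed input, default 0.5 (equal entry), not estimated:
with the window in place the likelihood cannot separate sp from a constant
shift in c, so sp must come from design knowledge or sensitivity analysis.

## Bootstrap

Uncertainty uses a double bootstrap: resample hauls with replacement to the
original haul count (between-haul variation), then within each selected haul
resample individual fish records — multinomial over the haul's observed
(length class, codend) cells, with size equal to the haul's (rounded) total.
The entire fitting procedure, model selection included, is re-run per
replicate, so the bands carry model-selection uncertainty. Bands are Efron
percentile intervals: empirical ((1−level)/2, (1+level)/2) quantiles with
linear interpolation between order statistics. Replicates whose fit fails
are redrawn (capped at 20 + 10·reps attempts) and counted. A single
bootstrap (fish only, hauls pooled) serves datasets too weak at the haul
level; default replicates 2000, reduced in tests and the acceptance script
(200) to keep runtimes in seconds.

When hauls are exchangeable (as in the simulator's uniform allocation), the
outer level adds haul-to-haul variation that the generative model does not
contain, so intervals are conservative; measured empirical coverage of the
95% band for rate(45 cm) is ~100% at 10 hauls × 500 fish. This is the
intended trade-off of the design, which prioritises never *under*-stating
uncertainty when averaging over hauls.

## Simulator and synthetic data

The simulator draws continuous lengths from a truncated-normal population,
allocates fish to hauls (uniformly, or by Dirichlet-style weights for
heterogeneous effort), and assigns each fish to {experimental codend,
standard codend, escaped} by the factorised probabilities at its continuous
length; caught fish are tallied into 1-cm measured classes (floor), and
model evaluation adds the half-class offset (midpoint = measured + 0.5).
Caught + escaped = entering, exactly.

Defaults are the diagnostic configuration used throughout: c₁ = 0.5,
c₂ = 0, L50c = 65 cm, SRc = 15 cm, sp = 0.5, standard-panel retention
L50p = 30 cm / SRp = 5 cm, experimental panel `release_all`. The cod-like
population stand-in is truncated normal, mean 45 cm, **sd 10 cm**, support
15–115 cm: the sd was set so that ≥ 99% of mass lies in 20–80 cm
("almost no fish" outside that range), which a sd of 12 would not satisfy.
With this population the region above 80 cm holds ~0.02% of fish, so the
large-length plateau c₂ is weakly identified in any single experiment; the
single-experiment M1 maximum-likelihood estimates scatter with sd ≈ 0.011
(c₁), ≈ 3 cm (L50c) and ≈ 4 cm (SRc) at 50 000 entering fish, with a small
downward bias on L50c/SRc induced by the c₂ ≥ 0 boundary. This is intrinsic
estimator variance (verified against truth-started refits), not an
optimisation artefact.

What the synthetic data do *not* emulate: real between-haul variation in
availability and size structure (hauls are exchangeable draws), measurement
error in length, species mixtures, and any length dependence in the split.
Passing tests therefore demonstrate correctness of the estimators under the
stated generative model, not field realism; on real data the double
bootstrap exists precisely because hauls are *not* exchangeable.

## Subsampling

When only a fraction of a codend's catch is length-measured, counts are
raised to haul totals (count / fraction) before fitting — fractional counts
are legal in the likelihood — with the original counts preserved alongside.
Whether raising should precede the comparison fit is an open question in the
source literature; raising is this package's documented choice.

## Problem sizes

Unit and property tests run on datasets of 10²–5·10⁴ fish and bootstrap
replicate counts of 30–400; the end-to-end checks use one 50 000-fish
experiment for parameter recovery and 60 experiments × 200 bootstrap
replicates (reduced 8-candidate family, subsets of {q₀, q₁, q₂}) for
interval coverage. These sizes were chosen so the full suite completes in a
few minutes on one core while leaving every statistical conclusion
comfortably resolved; the bootstrap default of 2000 replicates remains the
production setting.

## Known limitations

- sp is assumed known and length-independent; a wrong sp shifts c(l).
- The contact stage assumes every panel contact ends in escape; partial
  panel retention would downward-bias c(l) toward the panel's retention.
- Knife-edge models (M2/M3) report the breakpoint as the mid-edge between
  the two adjacent observed classes; its bootstrap distribution is discrete.
- AIC across M1–M4 treats the knife-edge breakpoint as one regular
  parameter, which is generous to M2/M3 under flat truth (see above).
- The chi-square calibration of the deviance relies on per-class totals
  being moderately large; with many near-empty classes the p-value is only
  indicative.
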