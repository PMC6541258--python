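# Methods

This note documents the statistical models, the numerical choices, and the
design decisions behind `lurefx`, and what the synthetic-data experiments do
and do not establish.

## Event processing

A *trap-day* is a calendar date on which a station was active; occasions are
calendar days with the boundary at local midnight. Timestamps are naive
local time throughout — the diel analysis presumes a single local clock, and
a single-site survey has one.

The independence filter anchors its window on the previous **retained**
capture of the same species at the same station (the sliding independent-
event convention). The alternative — anchoring on the previous raw photo —
can retain events closer together than the window and makes the filter
non-idempotent; with the retained anchor, retained events are provably
pairwise ≥ 1 h apart and re-filtering is the identity, which the property
tests verify. The window (default 1 h) is configurable.

Attractant age for the daily detection model is evaluated at the occasion's
start of day as whole days since the most recent refresh *date* (0 on the
refresh date itself); the model is daily, so sub-daily ages would be
spurious precision. Occasions on a refresh date are not split. For the
visitation analysis, elapsed time is instead exact (capture timestamp minus
the most recent refresh timestamp), binned half-open: day d covers
[24(d−1), 24d) hours, and events at ≥ 168 h are excluded from the binned
response but kept in the proportions' denominator (total independent
captures of the species).

## Occupancy-detection model

The likelihood is the standard single-season form with a latent occupancy
state per station, constant ψ, and occasion-level detection p_ij on the
logit scale; missing occasions (inactive camera days) contribute nothing.
Numerical details:

- Parameters live on the logit scale; the site log-likelihood uses
  `logaddexp` so all-zero histories are stable at extreme ψ or p.
- Covariates are z-scored over observed cells before optimisation;
  estimates and the covariance matrix are mapped back to the natural scale
  through the (linear) reparameterisation Jacobian.
- Optimiser: L-BFGS-B from a data-driven start (naive occupancy/detection)
  plus random restarts (5 by default; the likelihood is rarely multimodal
  but restarts are cheap). Convergence tolerance 1e-8 on the projected
  gradient.
- Standard errors come from the inverse of a central-finite-difference
  Hessian at the optimum (relative step 1e-4). The `converged` flag is
  cleared for saturated (all-ones) data, no-detection data, optimizer
  failure, or a non-positive-definite Hessian — boundary estimates are
  reported but flagged rather than trusted.
- AICc uses the number of stations as the effective sample size, the usual
  convention for occupancy model selection; it errors when n ≤ K + 1
  rather than returning a signed surprise.
- Detection-curve CIs are delta-method on the logit scale, then
  transformed, so endpoints stay inside (0, 1) and bracket the estimate. A
  parametric-bootstrap oracle in the tests agrees within 0.02 on a
  desk-scale fit.

The model set pairs attractant age with each effort measure additively and
never interacts terms; occupancy stays constant in all models so that AICc
differences isolate the detection structure.

## Diel activity density and randomization null

Activity is a von Mises kernel density on the 24-h circle. The kernel
concentration defaults to the Taylor (2008) rule of thumb,
κ_RT = [3n k̂² I₂(2k̂) / (4√π I₁(k̂)²)]^(2/5), where k̂ is the ML von Mises
concentration of the data (Best–Fisher approximation). The rule smooths
maximally for near-uniform data and sharpens for concentrated data; the
bandwidth is a keyword argument because no single rule is canonical. κ is
floored at 0.01 (an effectively uniform kernel) and capped at 500 so that
degenerate all-identical inputs stay finite. The 512-point grid is
renormalised so its periodic trapezoid integral is exactly 1; sampling is
inverse-CDF on that grid with linear interpolation (resolution ≈ 2.8 min),
deterministic given a seed.

Random capture histories draw, per capture: a station uniformly from the
stations at which the species was captured, a date uniformly from that
station's *active* dates, and a time of day from the fitted density; elapsed
time since refresh is then computed by the same code path as for observed
captures. Draws landing before a station's first logged refresh (possible
only on the first morning if baiting happened mid-day) are resampled.
Random histories are *not* passed through the independence filter — the
observed filtering is part of the data reduction, not of the null's
definition — and are not de-duplicated.

The p-value is the rank form (#{null < obs} + ½·#ties + 1)/(N + 1). Ties
are common because proportions are multiples of 1/n; counting them half
avoids the discreteness bias of either one-sided convention. One scale
serves both tails: p < α/2 ⇒ decreased visitation, p > 1 − α/2 ⇒ increased,
matching a two-tailed α = 0.05.

## Synthetic surveys

The generator emulates: 45 stations (configurable), deployments of 60–90
days with staggered starts, ~2% independently inactive camera-days,
installation baiting at the start of the first deployment day, and refresh
intervals of 3 + Gamma(shape 2) days rounded and clipped to [3, 27] with
mean ≈ 8 d at service hours (09:00–16:00). Species are parameterised by
(ψ, β₀, β_attract, diel mixture, within-day revisit rate); occupancy is
drawn once per station-species, detection is conditionally independent
across days given occupancy — deliberately matching the occupancy model's
own assumption so recovery experiments are well-posed — and detected days
emit 1 + Poisson(0.3) capture times from the diel mixture. The default
guild spans the behaviours of interest: bait-attracted nocturnal viverrids,
a weakly attracted diurnal mongoose, a bait-avoiding crepuscular duiker
(bimodal diel), and an indifferent cat.

What the generator does **not** emulate: behavioural autocorrelation across
days (trap-happiness), heterogeneity in ψ or p across stations beyond the
attractant effect, imperfect species identification, and clock drift.
Passing tests therefore establish internal correctness and calibration
under the model's assumptions, not robustness to their violation. One known
consequence: within-day revisits make observed bin proportions slightly
over-dispersed relative to the independent-draw null, so the type-I rate of
the randomization test runs marginally above nominal (≈ 0.06 rather than
0.05 in the calibration study) — the same structure is present in real
capture data, and the effect is within the tolerance the validation
experiments assert.

## Validation experiments (src/lurefx/experiments.py)

Problem sizes were chosen to give tight Monte-Carlo error at desk scale:

- *Likelihood oracle*: all 64 histories of 2 sites × 3 occasions against an
  independently written latent-state enumeration; agreement to < 1e-10.
- *Recovery*: 200 replicates of 200 stations × 70 occasions at ψ = 0.6,
  p₀ = 0.25, β_attract = −0.15/day; estimates essentially unbiased, ≥ 97%
  of replicates within 3 SE, 95% Wald coverage within binomial error.
- *Calibration*: one null survey layout, 500 replicate species
  (ψ = 0.6, p₀ = 0.10, β_attract = 0), N = 1000 randomizations; per-bin
  significant-classification rates near α and KS-uniform p-values.
- *Power*: 50 replicates at 200 stations with β_attract = −0.3/day; the
  attractant model ranks first by AICc and day 1 classifies "increased" in
  effectively all replicates.
- *Density*: flatness under a uniform diel pattern (equally spaced times,
  the deterministic realisation of that limit), normalization to 1e-6, and
  fit → sample(10⁴) → refit sup-norm stability.

## Open choices and limitations

- Whether the original field convention anchored independence on raw or
  retained captures is unknowable from the protocol description; the
  retained anchor was chosen for its invariants and the window is
  configurable.
- The AICc sample size for occupancy models is debated (sites vs. total
  observations); stations are used here.
- Surveys are pooled into one site set per species; per-survey fitting is a
  matter of passing each survey's logs separately.
- The permutation null conditions on the set of captured stations, so it
  tests *when* visits happen, not *where*; species captured at very few
  stations yield wide nulls and conservative classifications.
- Constant-ψ models mean detection covariates absorb any occupancy
  structure correlated with them; this mirrors the intended analysis but is
  a real limitation for heterogeneous landscapes.
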