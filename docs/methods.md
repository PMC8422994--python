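# Methods

## Temperature response model

The package models endpoint growth (OD600 at 24 h) as a function of
incubation temperature with the modified Briere curve

g(T) = c (T − Tmin)^a (Tmax − T)^b,  a, b ≥ 0, a + b > 0,

defined to be exactly zero at and outside [Tmin, Tmax]. Compared with the
classic Briere form c·T·(T − Tmin)·√(Tmax − T), the free exponents let the
curve take any skew, which is needed because antibiotics deform the
response asymmetrically. The curve is unimodal for a, b > 0 with the
closed-form optimum Topt = α·Tmax + (1 − α)·Tmin, α = a/(a+b).

The canonical parametrization used for fitting is (g_max, α, s, Tmin,
Tmax) with s = a + b:

g(T) = g_max · [ ((T − Tmin)/α)^α · ((Tmax − T)/(1 − α))^(1−α) · (Tmax − Tmin)^(−1) ]^s.

The bracketed factor equals 1 at Topt, so g(Topt) = g_max by
construction. Both directions of the conversion are implemented and are
exact inverses (round trips hold to ~1e-10 relative in tests). One-sided
shapes (a = 0 or b = 0) are allowed in the natural form but have no
interior optimum, so the canonical form rejects them; a = b = 0 is
rejected everywhere.

The thermal niche is [t_half_low, t_half_high], the two solutions of
g(T) = g_max/2, found by bracketed bisection on (Tmin, Topt] and
[Topt, Tmax) with absolute tolerance 1e-6 °C; breadth is their
difference. For extremely flat curves (s → 0) the crossing lies within
floating-point resolution of a growth limit and the limit is returned.
All temperatures are °C throughout; nothing converts to Kelvin.

## Likelihood and priors

For one condition with observations y_i at plated temperatures T_i:

- y_i | g(T_i), σ_{T_i} ~ Gamma with mean g(T_i) and sd σ_{T_i}
  (shape = μ²/σ², rate = μ/σ²),
- one σ per distinct plated temperature, σ_T | β ~ halfCauchy(β),
- β ~ halfCauchy(0.3).

The Gamma keeps growth positive and accommodates the strong
heteroskedasticity of plate data; the half-Cauchy hierarchy regularizes
the per-temperature scales, which are each informed by only a handful of
replicates. The Gamma mean is floored at 1e-6 growth units so
observations at temperatures where the curve is zero stay in-support;
observed values are floored at 1e-9 (the Gamma has no mass at exactly 0).

Default priors (all overridable via `PriorSpec`):

- Tmin ~ Normal(10, 10) truncated above at the coldest plated temperature;
- Tmax ~ Normal(50, 10) truncated below at the hottest temperature whose
  mean growth exceeds 5% of the condition's maximum mean growth. The 5%
  qualifier matters: with strictly positive Gamma noise every temperature
  shows "positive" growth, and anchoring the truncation at the hottest
  plated temperature would exclude true hot limits that sit just below it.
- α ~ Uniform(0, 1). An informative Beta prior here is tempting but
  measurably harmful: at the study's replication level (4 replicates per
  temperature) a Beta(2,2) prior pulls the fitted optimum toward the
  midpoint of the growth range by ~0.25 °C and costs credible-interval
  coverage, so the default is flat.
- s ~ halfNormal(5); g_max ~ halfNormal(2 × max observed growth).

## Posterior approximation

Inference works on a fixed unconstrained reparametrization (log/logit
transforms with their Jacobians). The default backend:

1. finds the joint mode by multi-start L-BFGS (data-driven start plus two
   seeded jitters),
2. builds a full-rank Gaussian from the mode and the inverse of a
   finite-difference Hessian (eigenvalues clipped at 1e-6 to handle flat
   directions),
3. draws from a mildly overdispersed multivariate-t proposal (df 7, scale
   1.3) built on that Gaussian, and importance-resamples against the exact
   log posterior using Pareto-smoothed weights (PSIS),
4. if the PSIS shape diagnostic k̂ exceeds 0.7 — the Gaussian geometry is
   inadequate, which happens mainly for strongly suppressed, low-growth
   conditions — the condition is automatically refit with the seeded
   affine-invariant ensemble sampler (emcee; 32+ walkers, 600 burn-in +
   1200 kept steps by default), which is also selectable directly as
   `method="mcmc"`.

Point estimates are posterior means; intervals are equal-tailed 95%
credible intervals. Derived quantities (Topt, half-max temperatures,
breadth) are computed per posterior draw (the half-max roots by a
vectorized bisection across draws) and then summarized — never by
transforming point estimates. Everything is deterministic given the
`FitConfig` seed, including the MCMC fallback.

Cross-checks in the test suite compare the default backend with long
MCMC runs; the two agree on Topt to well under the posterior scale.
Known limitation: frequentist coverage of the nominal 95% Topt interval
at study scale (7 temperatures × 4 replicates) is ~90%, slightly below
nominal, mostly because the weakly identified cold limit Tmin leans on
its prior and drags Topt's posterior slightly left of truth. This is a
property of the exact posterior, not of the approximation — MCMC shows
the same behavior — and it shrinks as replication grows.

## Shift classification

A condition's optimum (or breadth, or peak growth) is compared with the
no-drug control by credible-interval overlap: intervals that intersect
(closed intervals; touching endpoints count) give "overlap"; otherwise
the call is "higher"/"lower" by point estimate. Conditions whose fitted
peak growth is below 10% of the control's are dropped from downstream
combination analysis as too suppressed to yield reliable curve
parameters; the threshold is relative so it is scale-free.

## Combination-optimum models

For a pair XY with fitted single-drug optima Topt,X and Topt,Y and fitted
pair optimum Topt,XY, five candidate models are scored:

- min: Topt,XY = min(Topt,X, Topt,Y); max: the maximum; mean: the average;
- attenuated / elevated: the pair optimum lies beyond both singles.

The best of min/mean/max is the one with the smallest |observed −
predicted|; if that smallest error exceeds the cutoff (default 2.20 °C,
configurable; `derive_cutoff` can recompute a data-driven percentile of
the pooled error distribution instead) the pair is classed attenuated or
elevated by direction. Errors tied within 1e-9 °C report "multiple" with
the tied set. One edge case is possible under the rule but belongs to no
category: smallest error above the cutoff with the observed optimum
*between* the singles; it keeps the smallest-error category and carries
an "ambiguous" flag. For single-driver categories the driver is the drug
whose solo optimum is closer to the pair optimum; exact equidistance
yields no driver plus a tie flag. All outputs are invariant to swapping
the two drugs.

## Driver-dominance permutation tests

Restricted to pairs under single-driver categories, with M_d the number
of pairs drug d drives and n_d the number of single-driver pairs
containing d:

- global statistic D = Σ_d (M_d − n_d/2)², zero exactly when every drug
  drives half of its pairs;
- per-drug statistic M_d, tested one-sided for excess.

The null reassigns each pair's driver by an independent fair coin
(the literal form of "either drug equally likely to drive"); p-values use
the add-one convention (1 + #{null ≥ obs})/(1 + n_perm), so they are
never zero, with n_perm = 10,000 by default. Per-drug p-values are
Benjamini–Hochberg adjusted (Bonferroni available). Calibration is
verified by simulation: the global test's type-I error at α = 0.05 sits
inside the binomial noise band over hundreds of null repetitions, and a
single drug driving all 12 of its pairs in a 40-pair table is detected at
p < 0.01.

## Bliss independence profiles

Temperature and drug are treated as two stressors whose effects multiply
on relative growth under independence. The drug's own effect is its
growth ratio at a reference temperature, r_a = g_a(Tref)/g_0(Tref), with
Tref defaulting to the unstressed optimum — the natural normalization
point, where g_0 is maximal and best estimated (configurable). The null
curve is g̃_a(T) = g_0(T)·r_a and the score ε(T) = g_a(T) − g̃_a(T):
synergy below −tol, antagonism above +tol, independent otherwise, with
tol defaulting to 5% of g_0(Tref). Profiles are computed on fitted
posterior-mean curves over the overlap of the two supports. A drug that
scales the control curve uniformly gives ε ≡ 0 identically — the
identity the implementation is tested against.

## Synthetic data generator

The generator emulates the study design: temperatures (22, 25, 30, 37,
41, 44, 46 °C), 4 replicates, a no-drug control, 12 single drugs and
configurable pairs, with noise drawn from exactly the fitting likelihood
(Gamma, per-temperature sd), so recovery tests are well posed.

Chosen defaults, fixed once:

- Control truth: Topt 37.7 °C, breadth 15 °C, g_max 0.5 OD units over
  support [10, 47] °C — magnitudes matching drug-free *E. coli*.
- Per-temperature noise sd from 0.015 (46 °C, where growth has collapsed)
  to 0.06 (mid-range), the replicate scatter scale of 96-well OD reads.
- Single-drug effects: aminoglycoside-like drugs (GEN, TOB, STR) shift
  the optimum 4–5 °C left; other heat-similar drugs (TMP, NTR, FOX, AMP)
  1–2.5 °C left; cold-similar drugs (CLI, TET, ERY, LVX, CPR) 0–1 °C
  right — the left-heavy asymmetry of the real panel. All narrow the
  niche (factors 0.80–0.95) and suppress the peak to 55–80% of control
  (sublethal dosing).
- Pair curves realize a requested category exactly: the optimum is placed
  at the min/mean/max of the singles or displaced 3 °C beyond
  (attenuated/elevated), the breadth is 95% of the narrower single's, and
  the peak is the product of the singles' relative peaks. Requests that
  would push the optimum within 1 °C of a growth limit are rejected (the
  study generator falls back to "mean" and records the truth it actually
  used).

What the generator does not emulate: plate-position and batch effects,
concentration dependence, growth dynamics before 24 h, and
model-misspecification (data are generated from the fitted family).
Passing recovery tests therefore demonstrates the pipeline's correctness
and calibration under its own assumptions, not robustness to curve-shape
misspecification on real plates.

## Problem sizes and numerical choices

The test suite and the acceptance script use 50 simulated studies for
recovery/coverage, 500 repetitions for permutation calibration (n_perm
400–500 within each), a 33-condition study (12 drugs, 20 pairs) for the
end-to-end run, and 2000 posterior draws per fit — sizes at which each
stage's sampling noise is small relative to the effects it measures.
Posterior summaries are written with %.10g formatting so identical seeds
give byte-identical files; the run manifest records the seed and a hash
of the analysis-relevant configuration.
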