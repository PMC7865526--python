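# Methods

This note documents the models implemented in `ivivsim`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reasonable
option existed.

## Dissolution models and fitting

Per-vessel profiles (percent of dose dissolved vs. minutes) are fitted by
unweighted least squares on the percent scale with `scipy.optimize.curve_fit`
(trust-region reflective, bounds keeping parameters in their physical
domains, tolerances 1e-14 so noiseless data are recovered essentially to
machine precision). The candidate equations are

| model | y(t), % of dose | parameters |
|---|---|---|
| first-order | 100·m0·(1 − e^(−kd·t)) | m0, kd |
| zero-order | k0·t | k0 |
| Weibull | 100·m0·(1 − exp(−(t/td)^b)) | m0, td, b |
| logistic | 100·m0 / (1 + e^(−k(t−t50))) | m0, k, t50 |
| Higuchi | kh·√t | kh |
| Korsmeyer–Peppas | kp·t^n | kp, n |

These are descriptive, not mechanistic: their only job is to carry the in
vitro information into the in vivo model. Model choice uses the Gaussian
least-squares information criteria AIC = n·ln(SSR/n) + 2p and
BIC = n·ln(SSR/n) + p·ln(n), ranked by AIC with ties broken toward fewer
parameters, then lower BIC; when parameter counts are equal this reduces to
ranking by SSR. Power-law models (Weibull, Peppas) drop the t = 0 point,
where their derivative form is undefined; it carries no information (y = 0
identically). An all-zero response raises an explicit fit failure (the rate
is unidentifiable) rather than returning arbitrary numbers.

Initial guesses are derived from the data: m0 from the observed plateau,
kd = ln2 / (first time the response exceeds half its plateau), log-log
regression for the Peppas exponent. Asymptotic standard errors per fit come
from the Jacobian-based covariance. The across-vessel summary reports the
arithmetic mean of each parameter and its relative standard error of the
mean, RSE% = 100·(SD/√n)/mean — per-fit asymptotic SEs are kept for
diagnostics, but the summary uses vessel-to-vessel scatter, which is the
relevant uncertainty for a 12-vessel run. `m0` is allowed up to 1.2 to
tolerate assay noise, and values above 1.05 are flagged as supersaturated
readings.

## Absorption-rate calculations

`Kel = Cl/V1` throughout. The one-compartment peak time
`Tmax = ln(Ka/Kel)/(Ka − Kel)` (limit 1/Kel at Ka = Kel) cannot be solved
for Ka in closed form; `ka_from_tmax` exploits that the map is strictly
decreasing in Ka and uses Brent's method inside an automatically expanded
bracket (xtol 1e-15). The residual check on the recovered Tmax uses the
default tolerance 1e-10, applied relative to Tmax when Tmax exceeds one
minute so the criterion is attainable at double precision for very slow
kinetics. The flip-flop branch (Ka < Kel, arising when Tmax > 1/Kel) is
returned, not rejected — it is the unique mathematical solution.

Because dissolution and permeation are consecutive first-order steps, mean
times add: 1/Ka = 1/Kd + 1/Kat. The permeation-only constant is therefore
Kat = 1/(1/Ka − 1/Kd), defined only for Kd > Ka and always larger than Ka;
it is *decreasing* in Kd (instant dissolution leaves Kat → Ka; dissolution
as slow as the composite process forces Kat → ∞). Kat is computed per
product with that product's pH 6.8 Kd (the medium of the absorbing
segment) and the Test/Reference average is used in simulation for both
products, since permeation is substance-specific.

The built-in registry carries the literature values for the
amlodipine/irbesartan/hydrochlorothiazide 10/300/12.5 mg combination in
their published units (mL, min). Two caveats are flagged rather than
corrected: amlodipine's published V1/F of 1300 mL with Cl/F = 370 mL/min
implies a ~2.4-min elimination half-life, pharmacologically implausible but
carried as printed; and the Reference product's dissolution was published
only as its pH 6.8 Kd, so the Reference reuses the Test m0 at every pH and
the Test Kd at pH 1.2 and 4.5. With gastric absorption off and the small
intestine reached within tens of minutes, the pH 6.8 parameters dominate
the absorbed fraction, so this fallback affects mainly the (small) carried-
over dissolved mass at gastric emptying.

## GI transit and segment conditions

Transit is deterministic: the dose occupies stomach, small intestine and
large intestine for the scenario's mean residence times (five built-in
scenarios, stomach 10–60 min, total fixed at 2160 min = 36 h). Segment
boundaries are half-open, so the mapping from time to segment is
right-continuous and partitions the time axis. Per segment the dissolution
parameters switch by the pH mapping (fasted stomach 1.2, fed stomach 4.5,
intestine 6.8); the large intestine reuses the pH 6.8 set, the nearest
physiological medium among the three tested, and colonic absorption is on
by default (both are configuration knobs). Gastric absorption defaults to
zero. When a segment switch lowers the plateau below the amount already
dissolved, dissolution clamps to zero — no re-precipitation — and beyond
the total transit time dissolution halts. Per-subject stochastic transit
is deliberately out of scope: residence times are varied across scenarios,
not across subjects.

## The coupled ODE system and its solver

States per subject-period: cumulative dissolved D, dissolved-in-lumen L,
central amount A_c, peripheral amount A_p (two-compartment only):

    dD/dt  = Kd_seg · max(m0_seg·Dose − D, 0)
    dL/dt  = dD/dt − s_seg · 1[t ≥ Tlag] · Kat · L
    dA_c/dt = s_seg·1[t ≥ Tlag]·Kat·L − (Cl/V1)A_c − (Q/V1)A_c + (Q/V2)A_p
    dA_p/dt = (Q/V1)A_c − (Q/V2)A_p
    C(t) = A_c / V1

with s_seg the segment's absorption availability. Between event times
(segment boundaries, Tlag, end of transit) every coefficient is constant
and the clamp cannot activate mid-interval (D approaches its plateau
asymptotically), so the system is linear time-invariant. The default
backend therefore substitutes u = D − plateau, which removes the constant
input, and propagates the homogeneous system exactly through an
eigendecomposition of the (3 or 4)-state matrix, evaluated vectorized at
all requested times. This is exact to round-off and roughly 20× faster
than adaptive integration, which matters when a grid run solves ~10⁵
profiles. An adaptive RK45 backend (`method="rk45"`, rtol 1e-8/atol 1e-10,
mandatory restarts at every event time) remains available; it is the
automatic fallback whenever the eigenvector matrix is ill-conditioned
(condition number > 1e10, e.g. coincident rate constants), and the two
backends are cross-checked against each other and against the closed-form
three-exponential chain solution in the tests.

## Virtual subjects, observation and the BE decision

Each PK parameter (Cl/F, V1/F, Q/F, V2/F, Kat, Tlag) receives an
independent lognormal between-subject factor exp(η), η ~ N(0, σ²) with
σ = √ln(1 + (CV/100)²), shared across periods, and an independent
within-subject factor per period of the same form — the within-subject
mechanism acts on parameters, with residual error kept separate.
Formulation properties (m0, Kd) are not perturbed by default: they
distinguish T from R and are treated as batch constants. Sequences are
balanced by random permutation (half TR, half RT); odd N is rejected.
Sampled concentrations get multiplicative proportional error
C_obs = C·exp(ε), which keeps observations positive; the residual CV
defaults to 5% and is configurable, as no published magnitude exists for
it. Sampling schemes are named constants (sparse 10, typical 14, dense 17
points, all ending at 1440 min).

NCA uses the linear trapezoid to the last sample, maximum concentration,
and first time of maximum. AUC extrapolation to infinity is omitted: the
decision statistic is a within-subject ratio on a common sampling scheme,
where the truncation largely cancels. The 2×2 crossover analysis is the
closed-form period-difference estimator, algebraically identical to the
sequence/subject/period/treatment fixed-effects ANOVA (verified against a
statsmodels OLS fit in the tests): Δ̂ is the half-sum of per-sequence mean
log differences, SE² = MSE·(1/n1 + 1/n2)/2, df = n1 + n2 − 2, and the 90%
CI is exp(Δ̂ ± t₀.₀₅,df·SE). Acceptance limits 80–125% are inclusive, per
regulatory convention; a numerically zero residual variance (SE ≤ 1e-12)
collapses the CI to the point estimate, which then passes iff the GMR is
within limits. Overall bioequivalence requires every assessed metric (AUC
and Cmax by default) to pass.

## Monte Carlo layer

One virtual study = population draw → two simulated periods per subject →
observation → NCA → crossover analysis. For speed the profile is evaluated
directly at the scheme's sampling times (exact under the analytic
propagator). Replicates use independent `SeedSequence` spawns of the master
seed, so results are bit-reproducible, order-independent, and any single
replicate can be regenerated in isolation. The full factor grid is the
Cartesian product sample size {12,18,24,30,36} × scheme {typical, sparse,
dense} × transit {1–5} × BSV {5,10,20}% × WSV {5,10,20}% (675 scenarios);
the reduced factorial restricts to {12,18,24} × 3 schemes × transit {1,2}
× BSV {5,10} × WSV {10,20} (72), with hand-picked extra scenarios
appendable from configuration. The default replicate count is 10,000 per
scenario; tests and examples use hundreds, which estimate the same
probability within binomial error. Batches of a combination product are
ranked by the mean over scenarios of the minimum acceptance across drugs —
conservative, because a combination tablet passes only if every compound
does — with per-drug tables retained.

## Synthetic data

`generate_synthetic_dissolution` emulates a 12-vessel dissolution run:
first-order release with multiplicative lognormal noise (default CV 3%,
the scale of routine assay variability). It reproduces what the fitting
stage consumes — monotone saturating curves with vessel-to-vessel scatter —
but not features of real dissolution data such as heteroscedastic early
time points, coning or sticking artefacts, inter-run drift, or media
degradation; passing the recovery tests therefore demonstrates correctness
of the fitting machinery, not robustness to those artefacts. Likewise the
trial simulator's own output is self-consistent by construction; the BE
statistical tests use an independent direct lognormal crossover generator
so the decision layer is validated against textbook operating
characteristics (90% CI coverage, ≤5% consumer risk at a true ratio of
0.80, power monotone in N and in within-subject CV) rather than against
its own machinery.

## Problem sizes and determinism

Test and example runs use deliberately modest sizes — 2,000 replicates for
the statistical operating characteristics, 8 scenarios × 200 replicates
for the end-to-end grid, 100 parameter pairs for the solver round-trip —
chosen so the whole suite runs in well under a minute per component on a
single core while keeping Monte Carlo standard errors small relative to
the margins tested. Every stochastic path takes an explicit seed; re-runs
are bit-identical.

## Known limitations

- No per-subject stochastic gastric emptying or multi-segment intestinal
  absorption (ACAT-style models); transit varies only across scenarios.
- No enterohepatic recirculation, metabolite kinetics, or BLQ censoring.
- Dissolution variability is not propagated into subjects by default
  (formulation parameters are batch constants; a flag could enable it).
- AUC is truncated at the last sample; absolute bioavailability is folded
  into the /F parameterization.
- The irbesartan pH 4.5 plateau (m0 = 0.0234) is carried as published even
  though a 2.3% plateau is striking; under fed-stomach scenarios it makes
  irbesartan release during gastric residence nearly nil, which is exactly
  the discriminating behaviour the transit scenarios are meant to expose.
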