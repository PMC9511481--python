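# Methods

## Response metric and processing chain

The assay readout is one luminescence trace per well: an equilibration
phase, agonist injection, and 2 h of monitoring.  The response metric is
the area under the post-injection curve.  Processing is a fixed chain —
interwell correction → AUC → solvent subtraction → normalization — and the
code enforces the order (each stage records its completion; a later stage
called early raises `PipelineOrderError`).  Choices the convention leaves
open, and what this package does:

- **Interwell correction** divides each trace by the mean of its
  pre-injection readings (window configurable; default the full
  equilibration phase).  Wells with a non-positive pre-injection mean are
  excluded with a logged reason rather than failing the run.
- **AUC** is the trapezoid rule on the observed time points, exact for
  piecewise-linear signals; the default window is injection → injection
  + 2 h.  No quadrature beyond trapezoid is warranted for ~60 s sampling
  (verified against the closed-form integral of the trace model to < 0.1%).
- **Solvent subtraction** removes the mean AUC of the control wells matched
  on (experiment, pathway, receptor variant, compound); controls are
  consumed, not reported.
- **Normalization**: the reference maximal response is the mean corrected
  AUC of the reference agonist at its top plateau concentration (the
  highest tested concentration unless the config designates one), computed
  per experiment and per pathway, and set to 100%.  Per-experiment
  normalization is chosen because the reference is included in every
  experiment; if plateau wells are missing the maximum per-concentration
  mean is used with a warning.  Negative corrected AUCs are retained —
  clipping would bias the fitted bottom upward.

## Concentration–response model

Three-parameter logistic with Hill slope fixed at 1 (the standard
three-parameter agonist model):

    y(c) = bottom + (top − bottom) / (1 + EC50/c),

fitted by least squares in (bottom, top, log10 EC50).  For fixed log10 EC50
the model is linear in (bottom, top), so the fit is performed by variable
projection: a deterministic 0.5-log grid over log10 EC50 spanning the
tested concentration range ± 2 decades, with the linear pair solved exactly
at each node, then bounded 1-D refinement (tolerance 1e-10 log units)
around the best node.  This is a multi-start scheme whose inner starts are
solved to optimality, so it cannot be beaten by any explicit start grid
over (bottom, top); tests hold it against a dense three-dimensional grid
search.

**Confidence intervals** are 95% profile-likelihood intervals: endpoints
where the profiled RSS crosses `RSS_min · (1 + F(1, n−3; 0.95)/(n−3))`.
This F-inversion is exact for linear models and near-exact here, and —
unlike Wald intervals — produces the strongly asymmetric EC50 intervals
this assay yields.  Profiling log10 EC50 costs only 2×2 linear solves; the
Emax profile nests a 1-D inner search over log10 EC50.  If an endpoint is
not bracketed within ±12 decades (EC50) or 400 outward steps (Emax), the
interval is reported "n.d.".  Empirical coverage, measured over 1000 seeded
fits at the pooled three-experiment design (54 points, Gaussian response
noise of 8 percentage points — the error model the fit assumes), is 95.6%.
The trace-level generator's multiplicative noise is instead assessed by the
parameter-recovery study (below); CI calibration is a property of the
interval machinery and is measured under its own error model.

**"n.d." rule.**  A fit is *not determined* when (a) the optimizer fails,
(b) the fitted span is not distinguishable from zero — the 95% profile
interval of (top − bottom) includes 0, tested by comparing the flat-model
RSS against the profile threshold — or (c) the fitted EC50 lies above the
highest tested concentration.  This reproduces the behaviour expected for
weak partial agonists whose plateau is never reached.  n.d. propagates:
every quantity derived from an n.d. fit (RAi, β, variant comparisons) is
n.d., never a silent number.

## Bias quantification

Per pathway, intrinsic relative activity against the reference agonist:

    RAi = (Emax · EC50_ref) / (Emax_ref · EC50)

and the bias factor

    β = log10(RAi_βarr2 / RAi_miniGαq).

Base-10 logarithm is fixed by validation against the published worked
example: the combined β of compound 4a computes to 1.236 against the
printed 1.240, whereas a natural log would give 2.85.  The reported β is
the arithmetic mean of per-experiment β values, each experiment's compound
fits paired with the *same experiment's* reference fits — this pairing is
what makes the averaged β differ from the "combined" β computed from pooled
fits, and both are reported.  A compound needs ≥ 3 experiments with
determinable β in both pathways, else its bias is n.d.

Identities the implementation preserves exactly (and tests assert):
β ≡ 0 for the reference in every experiment; antisymmetry under pathway
swap; invariance under any common rescaling of the normalized response
axis; and switching the reference agonist shifts every compound's β by one
common constant (difference-of-logs identity).

**Significance.**  Kruskal–Wallis across all compounds' per-experiment β
sets (midranks, tie correction; the fully tied configuration is reported as
p = 1), then Dunn's post-hoc z-comparison of each compound against the
reference group, two-sided, with tie-corrected pooled-rank variance.  The
multiplicity adjustment over the compound-vs-reference family is Holm
(configurable); the convention names no adjustment, and Holm controls FWER
without the excess conservatism of Bonferroni.  Dunn's test is implemented
here directly (no suitable dependency provides it) and is verified against
exact permutation enumeration of rank configurations at n = 3 + 3: the
asymptotic p is not numerically equal to the exact permutation p at such
tiny n (the exact p has floor 2/C(6,3) = 0.1), so the tests check ordering
concordance and the exact enumeration values themselves.  Measured type-I
error of the adjusted bias call on simulated unbiased compounds (n = 3 per
group, 1000 studies) is ≈ 0.1% — conservative, far below nominal 5%.
Stars follow the usual tiers (* p < 0.05, ** p < 0.01).

**Variant comparisons** report EC50_mutant/EC50_WT (potency fold change)
and Emax_WT − Emax_mutant in percentage points, recomputed from fits or
from published values.

## Bias plots

For each compound, per-concentration mean responses (over wells and
experiments, with SEM) in the two assays are paired at equimolar
concentrations (≥ 3 shared concentrations required) and fitted with a
centered quadratic `y = a + b(x − x̄) + c(x − x̄)²` by OLS.  Centering makes
the intercept interpretable at the data centroid and decorrelates the
coefficients; translation of x changes only x̄.  Rendering is a thin
matplotlib layer; all analyses and tests target the numeric series.

## Synthetic plate generator

The generator emulates the study design: nine in-well concentrations
(1 pM, 10 pM, 100 pM, 1 nM, 10 nM, 100 nM, 1 µM, 10 µM, 25 µM), duplicate
wells, three independent experiments by default, solvent controls matched
per condition, both pathways per experiment, reference agonist always
present, 2 h post-injection monitoring.  Equilibration length (600 s) and
read interval (60 s) are not dictated by the emulated protocol and are
configurable assumptions.

Trace model (B baseline counts, kd decay, kr rise, t_inj injection time):

    f(t) = B·e^(−kd·t) + [t ≥ t_inj] · B·E·occ(c)·(1 − e^(−kr(t−t_inj)))·e^(−kd(t−t_inj))

with occupancy `occ(c) = c^h/(c^h + EC50^h)` (h = 1 by default) and E the
compound's efficacy as a fraction of the reference's.  The form reproduces
the rise-then-decay shape of live-cell luciferase signals while keeping the
AUC in closed form, so the processed, normalized response of a noiseless
plate lies exactly on the generating logistic (up to the reference-plateau
occupancy factor the normalization convention introduces — the oracle in
the tests includes it).  No mechanistic receptor/G-protein kinetics and no
substrate chemistry are modelled; the generator's purpose is the
statistical structure the analysis assumes, not biophysics.

Noise has four components with defaults chosen once to mirror the data's
character: per-well lognormal scale on the whole trace (σ = 0.1) and
per-experiment lognormal scale (σ = 0.2) — both deliberately *removed* by
interwell correction and per-experiment normalization, exercising exactly
what those steps exist to remove; additive Gaussian read noise (σ = 50
counts on a 10⁴-count baseline); and a per-well lognormal scale on the
agonist term only (σ = 0.15, variable effector expression), the component
that survives correction and produces realistic spread — with these
defaults the simulated pooled EC50 CIs (e.g. 12.5 [8.96–17.6] nM) match
the width of the published ones (12.9 [8.45–19.7] nM), and per-experiment β
values scatter by about ±0.15.  Kinetic defaults: baseline 10⁴ counts,
rise over ~5 min (kr = 1/300 s⁻¹), decay over ~1 h (kd = 1/3600 s⁻¹).

Randomness: one `numpy` generator per well, seeded by
`SeedSequence(master_seed, spawn_key=(experiment, pathway, compound,
concentration index, replicate))`; extending the design never perturbs
existing wells, and identical spec + seed reproduces plates bitwise.

**What passing on synthetic data does and does not show.**  The generator
reproduces the design, the noise structure the corrections target, and
response-level variability — so the tests demonstrate correctness of the
processing arithmetic, fitter, intervals and bias statistics under
realistic spread.  It does not emulate systematic artifacts of real plates
(edge effects, drift, substrate depletion coupling across wells,
receptor-reserve effects), so passing tests do not certify those are
handled; on real data they surface via the interwell correction and the
per-experiment design, as in the emulated protocol.

## Problem sizes used in the checks

Monte-Carlo checks run at fixed seeds: 200 seeded studies (3 experiments,
duplicate wells) for EC50/Emax recovery — median |log10 EC50 error| ≈ 0.04
against the < 0.1 requirement; 1000 fits for CI coverage; 1000 null studies
for the type-I rate; 200 seeded experiments for the zero-effect null.  The
whole suite completes in well under a minute on one core.

## Known limitations

- The logistic has Hill slope fixed at 1; steep or shallow curves will fit
  with biased EC50 (the generator can produce h ≠ 1 data to study this).
- RAi-based bias factors are reference- and system-dependent (as the
  reference-switch identity makes explicit); they are not transducer
  coupling constants, and cross-study comparison requires the same
  reference and assay.
- Pooled fits weight all experiments' points equally; no between-experiment
  variance component is modelled.
- The Dunn comparison at n = 3 experiments has very low power, and the
  normal approximation is coarse at such n (the implementation is
  conservative in aggregate, as the type-I study shows).
- Instrument exports must be converted to the long-format CSV; no vendor
  formats are parsed.
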