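# Methods

This note records the model as implemented, the defaults and why they were
chosen, the numerical choices, and what the synthetic scenarios do and do
not emulate.

## Trait scale and survival maps

Resistance to each insecticide is a quantitative trait (PRS) on an
arbitrary scale anchored by the Hill map to bioassay survival:
`K_B(z) = kmax * z^n / (z50 + z^n)` for z > 0 and 0 for z ≤ 0 (fully
susceptible individuals).  Defaults `z50 = 900, kmax = 1, n = 1` place 10%
bioassay survival — the conventional confirmed-resistance and withdrawal
criterion — at z = 100.  The algebraic inverse (`bioassay_to_prs`) exists
for k < kmax only; initialising a scenario "at 75% bioassay survival" goes
through it.

Field survival is `K_F = (phi1*K_B + phi2)^omega`, with `phi1 = 0.48,
phi2 = 0.15` from the published bioassay-versus-experimental-hut
regression.  The efficacy ω enters as an **exponent**: at ω = 0 (fully
decayed product) survival is 1 for every genotype, and survival decreases
monotonically in ω, including over-spray values ω > 1.  A product form
would violate both limits.  Proportions are clamped to [0, 1] after every
map (clamps are logged at debug level).

Efficacy decays in two phases: `omega0 * exp(-tau^p * delta_b)` until the
longevity threshold `tau_b`, then an additional `exp(-(tau-tau_b)^p *
delta_r)`.  The two phases agree exactly at `tau_b`.  The exponent `p`
defaults to 2 (a decay law quadratic in time-since-deployment) but is a
configuration field, because the printed form of the law flattens the
superscript and the quadratic reading, while the most consistent one, is
not certain.  With `p = 1` equal rates collapse the profile to a single
exponential exactly; with `p = 2` equal rates still give a single *rate
regime* but not a single closed form — the tests pin continuity and
monotonicity rather than a spurious collapse identity.

The PRS standard deviation is either fixed (default σ = 30, appropriate
while means stay near the withdrawal threshold) or linear in the mean
(`sigma = phi3*mean + phi4`, evaluated per site).  The shipped phi3/phi4
defaults are placeholders: no published values exist for them, and the
configuration marks them unvalidated.

## Selection within a generation

Newborns are Normal(mean, σ); the "polysmooth" representation discretises
the density onto a grid of bin centres spanning mean ± 6σ (2001 bins by
default), renormalised so each sex holds half the cohort (1:1 sex ratio at
hatching).  Males and females share the newborn mean; they differ only in
exposure (x for females, m·x for males) and, optionally, fitness-cost
magnitude.

* **Truncation branch**: the surviving fraction of exposed mosquitoes is
  the population mean field survival K̄, and the survivor mean is
  `mean + sigma * phi(q)/K̄` with q the standard-Normal upper-K̄ point.
  K̄ is evaluated **at the mean PRS** (the truncation threshold is defined
  by the survival expected of the mean genotype); a configuration flag
  (`mean_survival_integrated`) switches to the expectation of survival over
  the distribution for sensitivity analysis.  The same convention applies
  to the mixture partner's K̄ in both branches.
* **Probabilistic branch**: each bin survives with its own field survival;
  a co-deployed mixture partner contributes its population-mean survival as
  a constant factor (traits are tracked as separate distributions, so there
  is no individual-level correlation for the partner to act on; it thins
  the cohort without moving this trait's survivor mean).

Exposed survivors are pooled with the unexposed fraction; the parental mean
minus the newborn mean is the insecticide selection differential per sex.
Fitness costs are a separate differential, stored as positive magnitudes
and applied negatively — either fixed (PRS units; used with fixed σ) or as
a fraction of σ (used when σ tracks the mean).  The response is
`R = h2 * (S_female + S_male)/2 * beta`; β multiplies the whole bracket,
fitness-cost differentials included, so a fitness-cost-only response is
also β-scaled.

If every exposed mosquito dies (possible at ω > 1 with a fully susceptible
cohort), the low-level operations raise; the simulation loop catches the
condition, logs a warning, and proceeds with unexposed parents only
(zero insecticide differential), which is the biologically sensible limit.

## Multiple gonotrophic cycles

The probabilistic branch iterates over up to `gmax` feeding cycles per
generation (default 5).  Houses are treated with insecticide i only, j
only, or both (`c_i + c_j + c_ij = 1`); within a dual-treated house a
mosquito contacts i, j or both according to sex-specific splits Λ summing
to 1.  Encounters happen with per-cycle probability x; natural survival
between cycles is ρ = d^g (defaults d = 0.8, g = 3 days).  The first cycle
carries no ρ factor; every later cycle is multiplied through by it, so ρ
scales counts but never within-cycle means.

Per cycle, the four groups (i-survivors, j-survivors, both-survivors,
unexposed) are tracked as counts *and* as a frequency vector over the
trait grid.  Counts are computed as the sums of the corresponding per-bin
frequency components, which makes the bookkeeping identity
`N_P = N_iE + N_jE + N_ijE + N_u` exact (to rounding) and makes the
one-cycle limit equal the single-cycle probabilistic branch to ~1e-15 —
the test suite asserts both.  The partner's mean survival K̄_jF is frozen
at the partner trait's hatching mean for the whole generation, the same
within-generation freezing convention applied to insecticide decay (decay
advances between generations, not between cycles).

Females mate once, in their first cycle, so the male differential comes
from a single round of selection (encounter probability m·x with the male
Λ split) and is held constant across cycles.  The fitness-cost
differential likewise enters once and is carried to all cycles.  Each
cycle's female differential is the cycle's parental mean minus the
hatching mean; per-cycle responses are combined with oviposition weights
`N_P(G)/N_o`.  Cross resistance adds the partner's per-cycle response
times α inside the weighted sum (using the focal trait's weights); a trait
with nothing deployed against it receives its fitness-cost response plus
each deployed trait's own weighted total times α.  Mosquito age does not
affect susceptibility, and egg output per female is constant across
cycles — both deliberate simplifications.

The same machinery yields single-generation **age-profile snapshots**
(no evolution, full coverage): per-cycle female counts scaled so that
100,000 females complete cycle 1 in the absence of intervention, against
the geometric no-intervention profile ρ^(G−1).  Females completing ≥ 4
cycles (~the extrinsic incubation period of falciparum malaria) are
reported as the transmission-relevant tail.

## Landscape and generation loop

Two patches: intervention site and refugia.  Order of events per
generation: selection, mating, dispersal, egg laying.  Deployed traits
update by their full response; co-deployed and undeployed traits add
α-weighted correlated responses; the refugia updates by fitness costs
only.  Site means are floored at 0 — costs cannot drive the mean PRS
negative.  Dispersal mixes post-response means with rates
`r_Ref = (1−C)·θ` and `r_Int = θ·C`, applied literally even though the
mixing weights only sum to 1 at C = 0.5 (this matches the lineage of
prior two-patch IRM models); a normalised-mixing mode exists and is off
by default.

Deployment decisions are taken at interval boundaries (default every 10
generations) from the intervention-site female mean: an insecticide fails
at ≥ 10% bioassay survival and becomes redeployable only below 8%
(hysteresis, so no thrashing between the thresholds).  Sequences keep the
current product until it fails, then take the first available in arsenal
order; rotations advance cyclically every interval, skipping failed
products; mixtures, micro-mosaics and combinations deploy their pair until
*every* arsenal member has failed.  Products are refreshed (τ reset) at
each of their own interval boundaries, giving the sawtooth efficacy
profile of periodically redistributed nets; combinations carry independent
per-product intervals (e.g. nets every 3 years, spray yearly).  A
mid-interval threshold crossing leaves the product deployed until the next
decision point; an immediate-withdrawal mode exists and is off by default.
Runs end when no product is deployable or at the 500-generation cap
(50 years at the default 10 generations per year); duration in years is
the strategy's operational lifespan.  The truncation branch is restricted
to single-cycle monotherapies and mixtures — the truncation point is
undefined once the within-generation distribution is non-Normal, and
mosaics/combinations need the per-encounter machinery.

## Calibration of β

The exposure scaling factor β absorbs uncertainty in exposure and
heritability and pins simulations to a realistic timescale: a novel
insecticide should last ~10 years (100 generations) of continuous
deployment before reaching 10% bioassay survival.  `calibrate_beta`
bisects (geometrically, over β ∈ [1e−4, 1e4]) on the first-crossing
generation, which is monotone non-increasing in β.  Two modes:

* **single-set** (default): continuous monotherapy, fixed σ = 30, full
  coverage, no dispersal, no decay, no fitness costs, x = 0.7, m = 0.7,
  h² = 0.2, starting mean 0.  Deterministic and fast; this is the mode the
  acceptance script exercises.
* **averaged**: the crossing time is averaged over a Latin-hypercube
  sample of {x, m, h², C, θ} (30 sets by default; runs that never cross
  contribute the cap), matching the *average*-lifespan reading of the
  target.  The strategy-evaluation experiments default to this mode
  (`default_experiment_beta`), because under the single-set β the
  comparison sweeps — whose scenarios include partial coverage, dispersal
  and fitness costs — essentially never reach the withdrawal threshold
  within the 50-year cap, and every comparison degenerates to a censored
  draw.

The two branches calibrate to very different β (≈11 vs ≈0.5 single-set):
truncating the least-resistant 85% of exposed mosquitoes is a far stronger
per-generation selection event than probabilistic survival along a shallow
survival gradient, and β absorbs exactly this kind of mechanism-scale
uncertainty.

## Experiments and their desk scales

The experiment layer reruns the standard study designs at workstation
scale; sizes below are the package's defaults and the ones the test suite
uses.

* **Strategy comparisons** (sequences / rotations / full-dose mixtures,
  two identical insecticides, no decay, 10-generation interval, 500-
  generation cap): 200 Latin-hypercube sets over coverage (0.1–0.9),
  dispersal (0.1–0.9), per-sex fitness costs (0.04–0.58), female exposure
  (0.4–0.9), male exposure (0–1), heritability (0.05–0.3), replicated at
  cross-resistance α ∈ {−0.3, 0, +0.3} (the full design uses the 7-value α
  grid and 5000 sets; the package computes 35,000-run sweeps only on
  request).  Winners are decided on operational lifespan; equal lifespans
  are draws, flagged censored when both runs cap — censored draws may not
  be truly equivalent.  Runs whose sampled fitness costs exceed the
  insecticide differential never evolve resistance; these are genuine
  draws (where resistance cannot establish, IRM choice is moot).
* **Branch agreement**: identical parameter sets and seeds across
  branches; outcomes classified as full agreement (same non-draw winner),
  agreement (draws in both), partial disagreement (draw in exactly one),
  full disagreement (opposite winners).
* **Feature showcase**: five strategies (sequence, rotation, micro-mosaic,
  full- and half-dose mixture) under all 2³ on/off permutations of decay,
  cross resistance and multiple cycles, at h²={0.2, 0.25}, x = m = 0.7,
  fixed costs 0.2/sex, C = 0.7, θ = 0.3, starting mean 50, two
  30-generation deployment intervals; ranked by mean intervention-site
  bioassay survival across generations and traits.
* **Rotation vs micro-mosaic**: same LHS axes, 10-generation interval, no
  withdrawal threshold, 200-generation horizon, with a single cycle, five
  cycles without natural mortality, and five cycles with d = 0.8, g = 3.
  The reported metric is the mean bioassay survival over *both* traits
  (micro-mosaic minus rotation): a single-trait metric is contaminated by
  which insecticide the rotation deploys first, so the symmetric version
  is used.
* **σ sweep**: σ from 5 to 100 in steps of 5, full coverage, no costs, no
  decay, time to 10% bioassay survival (capped at 500), replicated over
  LHS sets of {x, m, h²}, both branches.

Experiment runs use 1001 grid bins (the package default is 2001); the
branch-equivalence tests show grid effects at this resolution are orders
of magnitude below every assertion tolerance.

## What the synthetic scenarios do and do not emulate

Scenario generators produce parameter configurations, not data: the model
is deterministic given a configuration, and all randomness lives in
parameter sampling (Latin hypercube, seeded).  The scenarios emulate the
*operational* structure of vector control — dosing, decay, redeployment
clocks, coverage splits, withdrawal rules — under idealised biology:
discrete non-overlapping generations, a perfectly Normal newborn trait
each generation, no linkage disequilibrium or individual-level genetic
correlation, no sub-lethal effects, no explicit population dynamics or
density dependence, no age-dependent susceptibility, and a single
amalgamated refugia.  Passing tests therefore demonstrate internal
consistency and direction-of-effect behaviour of the model, not predictive
accuracy for any specific field setting.

## Numerical choices and degenerate inputs

Grid: mean ± 6σ, 2001 bins (≥ 100 enforced); the newborn distribution is
re-Normalised every generation — the warped, selected distribution
persists only within a generation (across its cycles).  Survival maps are
clamped to [0, 1].  Bisection for β stops within 1 generation of target
(2 in averaged mode) or errors with its bracket.  p_survive = 0 in the
truncation intensity, an empty exposed cohort, an extinct cycle cohort,
and non-positive σ all raise typed errors; the generation loop converts
the first two into the unexposed-parents-only limit with a warning.
Conservation identities hold to 1e−12 relative; the one-cycle limit of
the multi-cycle machinery matches the single-cycle branch to 1e−10.

## Known limitations

The truncation branch cannot represent multi-cycle selection, mosaics or
combinations (above).  The two-patch mixing weights do not sum to one away
from C = 0.5 unless normalised mixing is enabled.  σ-vs-mean coefficients
(phi3/phi4) ship as unvalidated placeholders.  The per-cycle-dispersal
variant of the multi-cycle model (females migrating between sites within a
generation) is not implemented; dispersal acts between generations only.
Strategy comparisons at high fitness costs produce many structural draws
in the probabilistic branch (resistance cannot establish against the
cost), which compresses differences between strategies there; the
truncation branch, with its much larger differentials, is insensitive to
costs in the sampled range.
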