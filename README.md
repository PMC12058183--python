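# irmsim

A dynamic, polygenic simulator of insecticide-resistance evolution in
mosquito populations, built for evaluating insecticide-resistance-management
(IRM) strategies: sequences, rotations, full- and reduced-dose mixtures,
micro-mosaics, and ITN + IRS combinations.

Insecticide-treated nets (ITNs) and indoor residual spraying (IRS) drive
strong selection for resistance in malaria vectors.  Most IRM models assume
resistance is monogenic; genome-wide evidence suggests it is substantially
polygenic.  `irmsim` treats resistance as a quantitative trait — the
*polygenic resistance score* (PRS) — and recomputes the strength of
selection every generation from the current resistance level, the deployed
dose, and the decaying efficacy of the product.  It is aimed at vector-control
modellers and IRM analysts who want to compare deployment policies under
explicitly polygenic assumptions.

## The model

Resistance to each insecticide *i* is a Normally distributed trait
z<sub>I</sub> with mean z̄<sub>I</sub> and standard deviation σ<sub>I</sub>.
The PRS maps to the proportion surviving a discriminating-dose bioassay
through a Hill curve,

&nbsp;&nbsp;K<sub>iB</sub> = K<sub>max</sub> z<sup>n</sup> / (z<sub>50</sub> + z<sup>n</sup>),&nbsp;&nbsp;&nbsp; z<sub>50</sub> = 900, K<sub>max</sub> = n = 1,

so z = 100 corresponds to 10% bioassay survival, the conventional
"confirmed resistance" withdrawal criterion.  Field survival of an encounter
with a product at efficacy ω is (φ₁K<sub>iB</sub> + φ₂)<sup>ω</sup> with
φ₁ = 0.48, φ₂ = 0.15; efficacy itself decays post-deployment in two phases
(a slow basal rate δ<sub>b</sub>, then a rapid rate δ<sub>r</sub> once the
product's intended longevity τ<sub>b</sub> is exceeded).

Within a generation, exposure removes part of the cohort; the
between-generation change in the mean follows the sex-specific Breeder's
equation

&nbsp;&nbsp;R = h² (S<sub>♀</sub> + S<sub>♂</sub>) / 2 · β,

where the selection differentials S are computed dynamically by either

* **truncation selection** (`polytruncate` branch): only the top
  K̄<sub>iF</sub> fraction of exposed mosquitoes survive, so
  S comes from the classical selection-intensity formula for a truncated
  Normal; or
* **probabilistic selection** (`polysmooth` branch): each individual
  survives with its own field-survival probability, evaluated over a binned
  trait distribution.

The probabilistic branch extends to multiple gonotrophic cycles — each
feeding cycle brings a fresh encounter (and natural mortality ρ = d<sup>g</sup>
between cycles), with per-cycle responses weighted by oviposition counts —
which is what makes micro-mosaics and ITN + IRS combinations, and female
age profiles, simulable.  A two-patch landscape (intervention site +
untreated refugia, coverage C, dispersal θ) supplies gene flow; genetic
correlations α between traits supply cross resistance; fitness costs enter
as a negative selection differential.  β is an exposure scaling factor
calibrated so a novel insecticide lasts ~10 years of continuous deployment
before reaching the 10% withdrawal threshold.

## Worked example

```python
import irmsim as im
from irmsim import experiments as ex

im.bioassay_survival(100.0)     # 0.1   -- PRS 100 = 10% bioassay survival
im.bioassay_to_prs(0.10)        # 100.0

beta = ex.default_experiment_beta("polysmooth")   # averaged calibration: 56.234

params = {"x": 0.7, "m": 0.7, "h2": 0.2, "coverage": 0.7, "theta": 0.3,
          "fitness_female": 0.0, "fitness_male": 0.0}
for kind in ("sequence", "rotation", "mixture"):
    cfg = ex.comparison_scenario(params, kind, beta=beta)
    traj = im.run_simulation(cfg, branch="polysmooth")
    print(f"{kind:9s} {traj.termination:10s} {traj.n_generations:3d} "
          f"generations = {traj.duration_years:4.1f} years")
```

prints

```
sequence  exhausted  120 generations = 12.0 years
rotation  exhausted  120 generations = 12.0 years
mixture   exhausted  300 generations = 30.0 years
```

Two identical insecticides deployed one-after-the-other (sequence) or
swapped every year (rotation) both run out after 12 years — every product
has crossed the 10% bioassay-survival withdrawal threshold — while the
full-dose mixture of the same two products lasts 30 years.  That mixtures
outlast monotherapy policies, increasingly so under positive cross
resistance, is the headline result the test suite checks at scale.

The same machinery is exposed on the command line:

```bash
irmsim calibrate --branch polysmooth --out beta.json
irmsim simulate --config examples/sequence_two_insecticides.yaml --out run/
irmsim age-profile --config examples/sequence_two_insecticides.yaml --mean-prs 100 --out ages/
irmsim compare --strategy-a mixture --strategy-b sequence --n-sets 200 --seed 1 --out cmp/
irmsim sigma-sweep --branch polytruncate --out sigma.csv
irmsim showcase --out showcase.csv
```

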