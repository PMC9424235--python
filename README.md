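# allokin

Steady-state kinetics of **nonessential enzyme activation**, built for the
question of how small molecules stimulate the AP-lyase (β-elimination)
activity of the DNA-repair glycosylase OGG1: does the free nucleobase
product act as a catalytic base inside the active site
(product-assisted catalysis), or does it bind an allosteric site and
accelerate the chemical step (allosteric activation)?  The two hypotheses
imply different binding orders for substrate S and activator A, and the
binding order is testable from initial rates measured on an S × A grid.

The package is aimed at enzymologists and screening scientists who need
to (i) simulate and analyze molecular-beacon fluorescence assays,
(ii) fit and discriminate activation mechanisms, and (iii) normalize
activator screens and characterize hits with dose-response curves.

## The model

Three rapid-equilibrium binding schemes are implemented, with V = k꜀ₐₜ·E꜀,
Michaelis constant K_m, activation constant K_a, interaction coefficient α
and k꜀ₐₜ amplification β:

* **random binding** (general modifier): A binds E and ES,

  v = V·S·(1 + βA/(αK_a)) / ( K_m·(1 + A/K_a) + S·(1 + A/(αK_a)) )

* **ordered, substrate first**: A binds only ES,

  v = V·S·(1 + βA/K_a) / ( K_m + S·(1 + A/K_a) )

* **ordered, activator first**: S binds only EA,

  v = βV·x / (1 + A/K_a + x),  x = S·A/(αK_m·K_a)

The activator-first scheme predicts zero rate at A = 0, so an enzyme with
basal activity rules it out; the remaining two are discriminated by
global least-squares fitting of an S × A rate grid and AICc ranking (the
substrate-first scheme is the K_a → ∞ limit of the random one, so an
extra-sum-of-squares F-test is reported for that nested pair).  Screening
uses percent activation normalized between the basal (0 %) and
positive-control (100 %) plate aggregates with a strict > 20 % hit
threshold, and hits are characterized with the Hill model
ν = (E_max − B)/(1 + (EC₅₀/[A])ⁿ) + B.

Reference parameter presets for the two nucleobase activators
(8-bromoguanine: K_m 15 nM, k꜀ₐₜ 0.009 s⁻¹, K_a 12 μM, α 1.2, β 36;
9-deazaguanine: K_m 12 nM, k꜀ₐₜ 0.006 s⁻¹, K_a 333 μM, β 18; both at
10 nM enzyme) ship in `allokin.fixtures()`, together with the activator
dose lists and a two-fold substrate series these values were estimated
on.  A synthetic-data module generates rate grids, beacon progress
curves, FAM calibration standards and 1536-well screening plates with
seeded noise, so the whole pipeline runs without any external data.

## Worked example

Simulate a duplicate 5 %-noise initial-rate grid for the 8-bromoguanine
design and ask which mechanism the data support:

```python
import numpy as np
from allokin import NoiseModel, compare_mechanisms, fixtures, generate_rate_grid

fx = fixtures()
table = generate_rate_grid(
    fx.bromoguanine, fx.substrate_series, fx.bromoguanine_doses,
    noise=NoiseModel("proportional", sd=0.05, seed=7), replicates=2,
)
result = compare_mechanisms(table, random_state=0)
best = result.fits[result.selected]
e, se = best.estimates, best.standard_errors
print(f"selected mechanism : {result.selected} "
      f"(delta AICc vs substrate-first = "
      f"{result.delta_aicc['ordered_substrate_first']:.1f})")
print(f"Km    = {e.Km*1e9:6.2f} +/- {se['Km']*1e9:.2f} nM")
print(f"kcat  = {e.kcat:8.4f} +/- {se['kcat']:.4f} 1/s")
print(f"Ka    = {e.Ka*1e6:6.2f} +/- {se['Ka']*1e6:.2f} uM")
print(f"alpha = {e.alpha:6.2f} +/- {se['alpha']:.2f}")
print(f"beta  = {e.beta:6.1f} +/- {se['beta']:.1f}")
print(f"F-test (substrate-first vs random): p = {result.f_test['p_value']:.2e}")
```

Output:

```
selected mechanism : random (delta AICc vs substrate-first = 104.0)
Km    =  14.36 +/- 1.23 nM
kcat  =   0.0089 +/- 0.0008 1/s
Ka    =  11.96 +/- 1.61 uM
alpha =   1.32 +/- 0.22
beta  =   38.3 +/- 3.4
F-test (substrate-first vs random): p = 2.08e-23
```

The random mechanism wins decisively, and the fit recovers the
generating constants within their standard errors: the activator binds
free enzyme and the ES complex with similar affinity (α ≈ 1) and works
almost entirely by amplifying k꜀ₐₜ (β ≫ 1) — the allosteric-activation
signature.  The same operations are available from the shell via the
`allokin` command (`make-synthetic`, `simulate-curves`, `extract-rates`,
`fit-mechanism`, `compare`, `make-plate`, `screen`, `dose-response`).

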