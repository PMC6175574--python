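# gltkin

Kinetic analysis of coupled Na⁺/L-aspartate binding to a sodium-coupled
aspartate transporter (an archaeal glutamate-transporter homologue)
locked in its inward-facing state — for biophysicists studying how
secondary transporters achieve thermodynamically coupled, intermediates-free
loading and unloading of substrate and ions.

## The model

Substrate (A) and three Na⁺ ions bind through a six-reaction mass-action
network:

```
1: T    + Na ⇌ TNa       2: TNa  + Na ⇌ TNa2      3: TNa   + A  ⇌ TANa
4: TNa2 + A  ⇌ TANa2     5: TANa + Na ⇌ TANa2     6: TANa2 + Na ⇌ TANa3
```

The first ion binds slowly and weakly (k_on,1 = 36 M⁻¹s⁻¹, K_D1 = 0.5 M)
and rate-limits assembly; the last ion binds fast and tightly
(K_D6 = 10 µM) and its release gates substrate dissociation. Reactions
2+4 and 3+5 form the network's single cycle, constrained by detailed
balance (K_D2·K_D4 = K_D3·K_D5). Alongside the network the package
implements the standard closed forms used to read relaxation data:

* k_obs = k_off + k_on[Na⁺]³[A] — the rejected fully concerted law;
* k_obs,d = k_off,asp·K_D,Naⁿ/([Na⁺]ⁿ + K_D,Naⁿ) — Na⁺-gated release;
* k_obs = k_r + k₋ᵣ·K_D/(K_D + [L]) and its full two-step generalisation
  (the slow eigenvalue of T* ⇌ T ⇌ TL) — Na⁺-driven conformational
  selection, with plateau k_r = k_on,1·[Na⁺];
* branch-flux ratios η/ρ = ([Na⁺]/K_D)·(k₄/k₃), giving equal flux
  through the "second Na⁺ binds first" and "substrate binds first"
  assembly paths at 3.6 mM Na⁺.

Everything runs on synthetic relaxation traces generated by the package
itself (`gltkin.synthetic`), shaped like the published experiments:
cuvette binding reactions, 100-fold-dilution dissociation reactions, a
blocker (DL-TBOA) variant without the final locking step, and a
fast-mutant variant. Model fitting follows a statsmodels-like pattern:
build a Model from data, call `.fit()`, read estimates, standard errors
and `summary()` off the Results object
(`HillDissociationModel`, `ConformationalSelectionModel`,
`NetworkGlobalModel` — the last fits the free rate constants
{on₃, off₃, on₄} by full ODE simulation under the cycle constraint).

## Worked example

```python
import numpy as np
import gltkin as g

scheme = g.build_scheme("P11W_ASP")
rates = g.canonical_rate_set("P11W_ASP")

print("apparent K_D(L-asp) at 1 mM Na+: %.1f uM"
      % (g.apparent_kd_ligand(scheme, rates, 1e-3) * 1e6))

# dissociation gate: simulate the dilution series and fit the Hill law
diss = g.kobs_surface(scheme, rates, np.geomspace(50e-6, 1e-3, 10),
                      None, direction="dissociation")
print(g.fit_hill_dissociation(diss, n_fixed=2).summary())

# branch fluxes at the crossover
from gltkin.relaxation import make_binding_experiment
from gltkin.flux import integrated_branch_probability
exp = make_binding_experiment(1e-6, 3.6e-3, 1e-4, scheme, rates)
p3, p4 = integrated_branch_probability(scheme, rates, exp)
print(f"branch shares at 3.6 mM Na+: substrate-first {p3:.3f}, ion-first {p4:.3f}")
```

prints

```
apparent K_D(L-asp) at 1 mM Na+: 100.0 uM
Na+-gated dissociation fit (k_obs,d = k_off,asp K^n/([Na]^n + K^n))
  Hill n (fixed)   : 2
  k_off,asp (s^-1) : 0.1832 +/- 0.0017
  K_D,Na (M)       : 7.347e-05 +/- 7.3e-07
  RSS              : 2.453e-06
branch shares at 3.6 mM Na+: substrate-first 0.500, ion-first 0.500
```

Reading: at 1 mM Na⁺ half-saturation of substrate binding needs 100 µM
L-asp; the dilution series recovers an intrinsic release rate of
~0.18 s⁻¹ (the substrate leaves in a few seconds once the locking ions
are off, versus hours when Na⁺ is high); and at 3.6 mM Na⁺ complex
assembly is a coin flip between the two reaction paths — binding order
is probabilistic, not a fixed mechanism.

A command-line interface mirrors the library:

```sh
gltkin make-synthetic --variant P11W_ASP --seed 1 --out dataset/
gltkin report --dataset dataset/
gltkin fit-global --traces dataset/ --max-traces 12 --out fit.json
gltkin flux --na 3.6e-3
```

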