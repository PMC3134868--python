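# lipokin

Simulation and fitting of the transfer kinetics of poorly water-soluble drug
molecules between liposomal nanocarriers.

Poorly water-soluble drugs (temoporfin, cyclosporine A, amphotericin B,
paclitaxel, ...) are delivered in liposomes and partition into the
hydrophobic bilayer. In a donor/acceptor assay the drug migrates from
initially loaded donor liposomes to empty acceptors until the two populations
equilibrate, and the observed kinetics is typically a single exponential —
remarkable, given that transfer happens through two different microscopic
mechanisms at once:

* **collisions** between liposomes (rate ∝ product of carrier
  concentrations), and
* **diffusion** of drug monomers through the aqueous phase (release, then
  uptake).

`lipokin` implements this model at three levels and the estimation tools
around it. It targets pharmaceutics and biophysics groups who run
donor/acceptor separation assays and want to extract mechanistic rate
constants from release curves.

## The model

The microscopic state is the pair of occupancy distributions `d_j`, `a_j` —
the number of donor/acceptor carriers holding exactly `j` drug molecules
(0 ≤ j ≤ m, with m the per-carrier capacity). Collisions transfer one
molecule between two carriers with weight `g(i, j) = i − j` (ideal mixing) or
`g(i, j) = (i − j)(1 − i/m)(1 − j/m)` (attractive drug–drug interactions,
which suppress transfer out of nearly full carriers). Chemical mismatch
between the carrier types enters through the integer offset `k`, the
difference in per-carrier drug count at thermal equilibrium, with
`−M/N_a ≤ k ≤ M/N_d` and a free-energy interpretation
`Δg⁰/k_BT = ln((M/N_a + k)/(M/N_d − k))`.

With the ideal kernel the first moments `M_d = Σ j d_j`, `M_a = Σ j a_j`
close exactly onto

    dM_d/dt = (K/N) (M_a N_d − M_d N_a + k N_a N_d),
    M_a(t) = (1 − e^{−Kt}) (N_a/N) (M − k N_d),

with `K = K_coll N/V + K_diff` — so the apparent rate is linear in the total
carrier concentration `N/V`, and a dilution series separates the collision
(slope) and diffusion (intercept) contributions.

Beyond the first-order regime the package covers:

* **high loading** — uptake saturates with the filled fraction `M/(mN)`,
  accelerating transfer by `1/(1 − M/(mN))` for similar carriers and shifting
  the equilibrium toward a uniform distribution for dissimilar ones;
* **crowding** — the interacting kernel makes release from nearly full
  donors sigmoidal (interior inflection point);
* **leaflet two-state kinetics** — drug must flip-flop (rate `G`) from the
  inner to the outer leaflet before it can transfer, giving biexponential
  release with eigenrates `ω₁ + ω₂ = 2G + K`, `(ω₁ − ω₂)² = 4G² + K²`.

## Worked example

Simulate a noisy two-state release assay (K = 1, G = 0.1, symmetric
carriers) and recover both rate constants from the biexponential fit:

```python
import numpy as np
from lipokin import (CarrierEnsemble, generate_noisy_timecourse,
                     fit_biexponential, effective_rates)

ensemble = CarrierEnsemble(n_donor=100, n_acceptor=100, volume=1.0, capacity=100)
print("eigenrates at G/K = 1/10:", effective_rates(K=1.0, G=0.1))

course = generate_noisy_timecourse(
    "two_state",
    dict(ensemble=ensemble, total_drug=200.0, K=1.0, G=0.1),
    np.linspace(0.0, 40.0, 120),
    noise_sd=0.005,
    seed=42,
)
fit = fit_biexponential(course)
print(f"omega1 = {fit.estimates['omega1']:.4f}  omega2 = {fit.estimates['omega2']:.4f}")
print(f"K = {fit.estimates['K']:.4f}  G = {fit.estimates['G']:.4f}")
print(f"residual rms = {fit.residual_rms:.4f}")
```

prints

```
eigenrates at G/K = 1/10: (1.1099019513592785, 0.09009804864072146)
omega1 = 1.0731  omega2 = 0.0916
K = 0.9599  G = 0.1024
residual rms = 0.0038
```

The exact eigenrates are 1.11 K and 0.09 K; from a single noisy curve
(Gaussian noise, sd 0.005 on the transferred fraction) the fit recovers the
transfer rate K within ~4% and the flip-flop rate G within ~3%, with the
residual scatter matching the injected noise level.

A command-line interface wraps the same functionality
(`lipokin simulate | analyze | fit | decompose`); see
`lipokin simulate --show-config` and the commented template in
`examples/config_template.yaml`.

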