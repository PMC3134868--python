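# Methods

## Model

`lipokin` models the exchange of poorly water-soluble drug molecules between
two fixed populations of mobile nanocarriers — `N_d` donors and `N_a`
acceptors in an aqueous volume `V` — under the assumptions that carriers
neither fuse nor divide, that the aqueous solution is spatially uniform (slow
transfer, no reaction–diffusion coupling), and that the fraction of drug
dissolved in water is negligible except as an explicit intermediate pool in
the diffusion mechanism. Populations are mean-field: the occupancy
distributions `d_j`, `a_j` (number of carriers holding `j` of at most `m`
drug molecules) are continuous-valued expected counts, not stochastic
samples.

Two transfer mechanisms are implemented.

**Collision.** A second-order process between carrier pairs: a collision
between carriers holding `i` and `j` molecules moves one molecule with
weight `g(i, j)`, either `i − j` (ideal mixing) or
`(i − j)(1 − i/m)(1 − j/m)` (crowding from attractive drug–drug
interactions). Chemical mismatch between the populations is a per-carrier
equilibrium offset `k` (integer at the distribution level), which shifts the
occupancy index in the donor–acceptor cross terms. Occupancies referenced
outside `[0, m]` contribute zero; the boundary term shared by the split
lower/upper sums is transcribed literally, and the implementation is
certified against an independent nested-loop transcription of the same sums
rather than by re-deriving the combinatorics.

**Diffusion.** First-order release (`K^rel · j · d_j`) into an aqueous pool
`M_w`, second-order uptake (`K^upt · (m − j) · d_j · M_w/V`) out of it, each
population with its own rates. The pool balance is computed from the state's
own moments, so total drug `M_d + M_a + M_w` is conserved identically.

With the ideal kernel the first moments close exactly onto the
two-compartment law `dM_d/dt = (K/N)(M_a N_d − M_d N_a + k N_a N_d)`; both
mechanisms reduce to it (diffusion under a quasi-steady pool, equal uptake
rates and weak loading), with the combined apparent rate
`K = K_coll N/V + K_diff`. On top of this sit the nonlinear high-loading
system, whose stationary point is the physical root of a quadratic in
`M_d/M`, and the four-compartment leaflet (two-state) system with flip-flop
rates between the inner and outer leaflets.

## Validity regime of the index-shifted cross terms

For `k ≠ 0` the shifted cross sums reference transfer weights at effective
occupancies outside `[0, m]` whenever a populated boundary class meets a
partner near the opposite boundary (for example, at `k = −2` an empty donor
meeting an empty acceptor carries weight `g(0, −2) = 2` with no molecule to
move). The zero-outside-range convention then clips one side of such fluxes,
so exact carrier conservation and exact moment closure hold only while the
occupancy distributions carry no weight within `|k|` of the index
boundaries. This is the regime the offset describes — a *small* equilibrium
imbalance between comparably loaded carriers — and in it the closure is
exact to integrator tolerance (verified at donor load 20 of capacity 100,
`k ∈ {−2, 0, 3}`: deviation < 1e−11; at load 5 with `k = −2`, where the
donor distribution reaches occupancy 0, the deviation grows to ~4e−4).
Relatedly, the crowded kernel is only paired with `k = 0` (chemically
similar carriers): the occupancy factors break the antisymmetric pairing of
donor- and acceptor-side cross fluxes, so crowded transfer with `k ≠ 0`
does not conserve drug and the collision operator logs a warning if asked
for it. The crowding correction is applied to the collision mechanism only,
not to diffusion uptake/release.

## Parameters

| Parameter | Units | Default | Meaning |
| --- | --- | --- | --- |
| `n_donor`, `n_acceptor` | count | 100, 100 | carrier populations, constant in time |
| `volume` | volume | 1.0 | aqueous volume; sets concentration units |
| `capacity` (m) | count/carrier | 100 | maximum drug load of one carrier |
| `k_offset` (k) | count/carrier | 0 | equilibrium donor–acceptor load difference; bounded by `[−M/N_a, M/N_d]` |
| `k_coll` | volume/time | 0 | unit collision transfer rate |
| `k_diff` | 1/time | 0 | diffusion transfer rate (apparent) |
| `k_rel_*`, `k_upt_*` | 1/time, volume/time | 0 | release and uptake rates per population |
| flip rates / `G` | 1/time | 0 | leaflet flip-flop; `flip_*_out` is inner→outer |

Times are arbitrary but must be consistent with the rates; no absolute
temperature enters (`Δg⁰` is reported in units of `k_B T`). The offset `k`
is treated as constant — its temperature dependence is not modeled.

## Numerical choices

* Master-equation integration uses LSODA (adaptive, automatic stiffness
  switching — crowded-kernel runs near full loading are stiff) at
  `rtol = 1e−8`, `atol = 1e−10 · N`, evaluated on the caller's grid; the
  `t = 0` snapshot is the supplied state verbatim. The collision right-hand
  side is assembled from precomputed kernel matrices and cumulative sums
  (a few O(m²) array operations per call).
* Compartment ODEs use DOP853 at `rtol = 1e−11`; the high-loading system is
  integrated in fractions `(M_d/M, M_a/M)` to keep tolerances scale-free.
* The high-loading stationary quadratic selects the root inside `[0, M]`;
  when both roots qualify, the one continuous with the weak-loading limit
  `M_d/M → K_a f_d / (K_d f_a + K_a f_d)` wins.
* The two-state closed form's degenerate spectrum `ω₁ = ω₂` is unreachable
  for `K > 0` (the gap is `√(4G² + K²) ≥ K`) but is still evaluated by its
  analytic `t·e^{−ωt}` limit when `|ω₁ − ω₂| < 1e−10·ω₁`.
* The spectral map `(K, G) → (ω₁, ω₂)` is exactly two-to-one: `(K, G)` and
  `(2G, K/2)` have identical spectra. `rates_from_effective` returns the
  `K ≥ 2G` representative — fast inter-carrier transfer with slow flip-flop,
  the regime in which the two decay scales are experimentally resolvable —
  and validates by forward substitution. Admissible spectra require
  `√2·(ω₁ − ω₂) ≥ ω₁ + ω₂`; anything else raises.
* Inflection detection smooths with a 3-point moving average, requires the
  sign change of the discrete second derivative to persist for two
  consecutive intervals, ignores the endpoints, and only searches where the
  slope still exceeds 1e−3 of its peak — without the slope guard, integrator
  ripple on the flat tail of a monoexponential produces spurious
  inflections.

## Synthetic data

`generate_noisy_timecourse` emulates a donor/acceptor separation assay: a
named forward model (`mono`, `high_loading`, `two_state`) produces the true
fraction transferred `M_a(t)/M`, and additive homoscedastic Gaussian noise
(default scenarios use sd 0.01 for single-exponential fits, 0.005 for
biexponential ones, on a 0..1 fraction scale) is drawn from one explicitly
seeded generator per call, making every curve reproducible bit-for-bit. Real
assays differ in ways the generator does not emulate: heteroscedastic and
possibly correlated instrument noise, baseline drift, imperfect
donor/acceptor separation, and normalization error when the plateau is not
known a priori. Passing recovery tests therefore demonstrate estimator
correctness and calibration under the stated noise model, not robustness to
instrument systematics. Fits minimize unweighted least squares (inverse
variance weights when per-point errors are supplied); the
rate-vs-concentration mechanism split is a weighted line fit whose negative
estimates are truncated at zero and flagged.

## Problem sizes

The shipped checks run the full distribution model at capacity `m = 100`
with 100 + 100 carriers (ideal-kernel closure at donor load 20 for
`k ∈ {−2, 0, 3}`; crowded-kernel runs at loads 2, 10 and 98 out to 200
transfer times), recovery calibrations with 100 seeds of 50–120-point
curves, and a five-concentration mechanism-decomposition pipeline. All are
chosen as the smallest systems that exhibit each regime cleanly.

## Known limitations

* No stochastic (event-driven) simulation; fluctuations around the
  mean-field populations are not represented.
* No fusion/fission of carriers, no microscopic estimation of `k`, `K_coll`
  or `K_diff` from lipid/drug chemistry, and no curvature-dependent
  asymmetry of the leaflet flip-flop rates.
* The crowded kernel with `k ≠ 0` is outside the model (see above); the
  general dissimilar-carrier two-state system is integrated numerically
  only, with `k` biasing the inter-carrier exchange but not the flip
  equilibrium.
* Weak-loading curves under the crowded kernel retain an O(l/m) dependence
  on the initial load: loads 2 and 10 of capacity 100 produce transfer
  curves that agree to ~1.5e−2 in `M_a/M` (visually overlapping, not
  identical).
* Plateau-to-`k` conversion of fitted release curves is left to the user:
  the fit treats the plateau as free because assay normalization conventions
  vary.
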