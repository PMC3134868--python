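"""System definition and equilibrium thermodynamics for inter-carrier drug transfer.

A fixed ensemble of ``N_d`` donor and ``N_a`` acceptor liposomes (or any small
mobile nanocarrier: micelles, colloids, nanoparticles) shares a total of ``M``
poorly water-soluble drug molecules in an aqueous volume ``V``.  Each carrier
holds at most ``capacity`` (m) drug molecules.  Chemical mismatch between the
two carrier types is encoded by the equilibrium offset ``k``: the difference in
per-carrier drug count between a donor and an acceptor at thermal equilibrium
(k = 0 for chemically identical carriers).  The admissible range is
``-M/N_a <= k <= M/N_d``; at the upper bound all drug stays in the donors, at
the lower bound all of it ends up in the acceptors.

Transfer proceeds by two mechanisms acting in parallel:

* **collision**: drug hops between two carriers that come into contact, with
  unit rate ``k_coll`` (volume/time);
* **diffusion**: drug is released into the aqueous phase (rates ``K^rel``,
  1/time) and taken up again by a carrier (rates ``K^upt``, volume/time).

Under weak loading both mechanisms produce the same apparent first-order
kinetics with rate constant ``K = k_coll * N/V + k_diff`` — the quantity a
donor/acceptor separation assay measures.  Its linear dependence on the total
carrier concentration ``N/V`` is what allows the two mechanisms to be told
apart experimentally (see :func:`lipokin.fitting.mechanism_decomposition`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

logger = logging.getLogger("lipokin.system")

__all__ = [
    "CarrierEnsemble",
    "RateSet",
    "DerivedRates",
    "transfer_weight",
    "k_bounds",
    "equilibrium_partition",
    "equilibrium_thermodynamics",
    "apparent_rate",
    "forward_backward_rates",
]


@dataclass(frozen=True)
class CarrierEnsemble:
    """The fixed carrier system: counts, volume, capacity and equilibrium offset.

    Parameters
    ----------
    n_donor, n_acceptor
        Number of donor / acceptor carriers (``N_d``, ``N_a``); both at least 1
        and constant in time (no fusion or fission).
    volume
        Volume ``V`` of the aqueous solution, in arbitrary but consistent
        volume units (the same units used for ``k_coll`` and ``K^upt``).
    capacity
        Maximum number ``m`` of drug molecules a single carrier can hold.
    k_offset
        Equilibrium offset ``k`` (drug molecules per carrier).  Stored as a
        real number; the distribution-level collision kinetics additionally
        requires it to be an integer and validates that at its own call site.
    """

    n_donor: int
    n_acceptor: int
    volume: float = 1.0
    capacity: int = 100
    k_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.n_donor < 1 or self.n_acceptor < 1:
            raise ValueError("n_donor and n_acceptor must each be >= 1")
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")

    @property
    def n_total(self) -> int:
        """Total number of carriers ``N = N_d + N_a`` (derived, never stored)."""
        return self.n_donor + self.n_acceptor

    @property
    def concentration(self) -> float:
        """Total carrier concentration ``N/V``."""
        return self.n_total / self.volume


@dataclass(frozen=True)
class RateSet:
    """All kinetic constants of the model, with explicit unit conventions.

    Unset rates default to 0, meaning the corresponding mechanism is absent.
    Flip-flop rates are named by physical direction: ``flip_*_out`` moves drug
    from the inner to the outer leaflet (K_1 of the two-state scheme),
    ``flip_*_in`` from the outer to the inner leaflet (K_2).  When
    ``flip_symmetric`` is set it overrides all four individual flip rates
    (symmetric bilayer, chemically similar carriers).
    """

    k_coll: float = 0.0           # volume/time
    k_diff: float = 0.0           # 1/time
    k_rel_donor: float = 0.0      # 1/time
    k_rel_acceptor: float = 0.0   # 1/time
    k_upt_donor: float = 0.0      # volume/time
    k_upt_acceptor: float = 0.0   # volume/time
    flip_donor_out: float = 0.0   # 1/time, inner -> outer (K_1^d)
    flip_donor_in: float = 0.0    # 1/time, outer -> inner (K_2^d)
    flip_acceptor_out: float = 0.0  # 1/time, inner -> outer (K_1^a)
    flip_acceptor_in: float = 0.0   # 1/time, outer -> inner (K_2^a)
    flip_symmetric: Optional[float] = None  # 1/time, overrides the four above

    def __post_init__(self) -> None:
        for name in (
            "k_coll", "k_diff", "k_rel_donor", "k_rel_acceptor",
            "k_upt_donor", "k_upt_acceptor", "flip_donor_out", "flip_donor_in",
            "flip_acceptor_out", "flip_acceptor_in",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be non-negative")
        if self.flip_symmetric is not None and self.flip_symmetric < 0:
            raise ValueError("flip_symmetric must be non-negative")

    # Effective flip rates after applying the symmetric override.
    @property
    def eff_flip_donor_out(self) -> float:
        return self.flip_donor_out if self.flip_symmetric is None else self.flip_symmetric

    @property
    def eff_flip_donor_in(self) -> float:
        return self.flip_donor_in if self.flip_symmetric is None else self.flip_symmetric

    @property
    def eff_flip_acceptor_out(self) -> float:
        return self.flip_acceptor_out if self.flip_symmetric is None else self.flip_symmetric

    @property
    def eff_flip_acceptor_in(self) -> float:
        return self.flip_acceptor_in if self.flip_symmetric is None else self.flip_symmetric


@dataclass(frozen=True)
class DerivedRates:
    """Rates and thermodynamic quantities derived from the system definition.

    ``delta_g0`` is the standard Gibbs free-energy change for moving one drug
    molecule from a donor to an acceptor carrier, in units of ``k_B T``
    (dimensionless); no absolute temperature enters the model.  Whenever both
    ``k_forward`` and ``k_backward`` are finite and nonzero,
    ``k_eq = k_forward / k_backward`` and ``k_eq = exp(-delta_g0)``.
    """

    k_apparent: Optional[float] = None   # 1/time
    k_forward: Optional[float] = None    # 1/time (K_1)
    k_backward: Optional[float] = None   # 1/time (K_2)
    k_eq: Optional[float] = None         # dimensionless
    delta_g0: Optional[float] = None     # units of k_B T
    omega1: Optional[float] = None       # 1/time
    omega2: Optional[float] = None       # 1/time


def _kernel_value(i, j, capacity: int, mode: str):
    """Transfer kernel g(i, j), evaluated arithmetically (no range checks).

    ``ideal`` is the non-interacting form g = i - j; ``crowded`` multiplies in
    the occupancy factors (1 - i/m)(1 - j/m) that model attractive drug-drug
    interactions suppressing transfer out of (and into) nearly full carriers.
    """
    if mode == "ideal":
        return i - j
    if mode == "crowded":
        return (i - j) * (1.0 - i / capacity) * (1.0 - j / capacity)
    raise ValueError(f"unknown kernel mode {mode!r}; choose 'ideal' or 'crowded'")


def transfer_weight(i: int, j: int, capacity: int, mode: str = "ideal") -> float:
    """Per-collision transfer weight between a carrier with ``i`` and one with ``j`` drugs.

    Callers order the arguments donor-richer first (``i >= j``), matching the
    split sums of the distribution-level kinetics, so the result is always
    non-negative.

    Raises
    ------
    ValueError
        If an index lies outside ``[0, capacity]`` or ``i < j``.
    """
    if not (0 <= i <= capacity) or not (0 <= j <= capacity):
        raise ValueError(
            f"indices must lie in [0, {capacity}]; got i={i}, j={j}"
        )
    if i < j:
        raise ValueError(f"transfer_weight requires i >= j; got i={i} < j={j}")
    return float(_kernel_value(i, j, capacity, mode))


def k_bounds(ensemble: CarrierEnsemble, total_drug: float) -> tuple[float, float]:
    """Admissible range ``(-M/N_a, M/N_d)`` of the equilibrium offset ``k``.

    ``total_drug = 0`` is allowed and returns ``(0, 0)`` (no drug, no offset);
    negative drug amounts raise.
    """
    if total_drug < 0:
        raise ValueError("total_drug must be non-negative")
    return (-total_drug / ensemble.n_acceptor, total_drug / ensemble.n_donor)


def _check_k(ensemble: CarrierEnsemble, total_drug: float) -> None:
    lo, hi = k_bounds(ensemble, total_drug)
    k = ensemble.k_offset
    if k < lo:
        raise ValueError(
            f"k_offset={k} violates the lower bound -M/N_a = {lo} for M={total_drug}"
        )
    if k > hi:
        raise ValueError(
            f"k_offset={k} violates the upper bound M/N_d = {hi} for M={total_drug}"
        )


def equilibrium_partition(
    ensemble: CarrierEnsemble, total_drug: float
) -> tuple[float, float]:
    """Long-time partition ``(M_d^eq, M_a^eq)`` of the drug between the two populations.

    ``M_d^eq = (N_d/N) (M + k N_a)`` and ``M_a^eq = (N_a/N) (M - k N_d)``; the
    two always sum to ``M`` and satisfy ``M_d^eq/N_d - M_a^eq/N_a = k``.
    """
    _check_k(ensemble, total_drug)
    n = ensemble.n_total
    k = ensemble.k_offset
    m_d = ensemble.n_donor / n * (total_drug + k * ensemble.n_acceptor)
    m_a = ensemble.n_acceptor / n * (total_drug - k * ensemble.n_donor)
    return (m_d, m_a)


def equilibrium_thermodynamics(
    ensemble: CarrierEnsemble, total_drug: float
) -> DerivedRates:
    """Equilibrium constant and standard free-energy change of donor-to-acceptor transfer.

    ``K_eq = (N_a/N_d) (M - k N_d) / (M + k N_a)`` and
    ``delta_g0 = ln((M/N_a + k) / (M/N_d - k))`` in units of ``k_B T``, so that
    ``K_eq = exp(-delta_g0)``.  For chemically identical carriers (k = 0) the
    free energy ``ln(N_d/N_a)`` is purely entropic.  At the closed bounds of
    ``k`` the transfer is one-sided: ``K_eq`` is 0 or infinite and ``delta_g0``
    diverges to +/- infinity; these values are returned rather than raised.
    """
    _check_k(ensemble, total_drug)
    m = total_drug
    k = ensemble.k_offset
    n_d, n_a = ensemble.n_donor, ensemble.n_acceptor
    num = m - k * n_d   # vanishes at the upper bound k = M/N_d
    den = m + k * n_a   # vanishes at the lower bound k = -M/N_a
    if num <= 0:
        return DerivedRates(k_eq=0.0, delta_g0=math.inf)
    if den <= 0:
        return DerivedRates(k_eq=math.inf, delta_g0=-math.inf)
    k_eq = (n_a / n_d) * num / den
    delta_g0 = math.log((m / n_a + k) / (m / n_d - k))
    return DerivedRates(k_eq=k_eq, delta_g0=delta_g0)


def apparent_rate(rates: RateSet, ensemble: CarrierEnsemble) -> float:
    """Apparent first-order rate constant ``K = k_coll * N/V + k_diff``.

    Linear in the total carrier concentration ``N/V``: the slope isolates the
    collision contribution and the intercept the diffusion contribution.
    """
    return rates.k_coll * ensemble.concentration + rates.k_diff


def forward_backward_rates(
    K: float, ensemble: CarrierEnsemble, total_drug: float
) -> tuple[float, float]:
    """Forward/backward rates ``(K_1, K_2)`` of the equivalent reaction D <-> A.

    ``K_1 = (1 - k N_d / M) K N_a / N`` and ``K_2 = (1 + k N_a / M) K N_d / N``,
    obtained by matching the exponential solution of the population kinetics to
    the two-state reaction scheme; their ratio reproduces the equilibrium
    constant ``K_eq``.
    """
    k = ensemble.k_offset
    if total_drug == 0:
        if k != 0:
            raise ValueError("total_drug=0 with k_offset != 0 is undefined")
        frac_d = frac_a = 0.0
    else:
        _check_k(ensemble, total_drug)
        frac_d = k * ensemble.n_donor / total_drug
        frac_a = k * ensemble.n_acceptor / total_drug
    n = ensemble.n_total
    k1 = (1.0 - frac_d) * K * ensemble.n_acceptor / n
    k2 = (1.0 + frac_a) * K * ensemble.n_donor / n
    return (k1, k2)
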