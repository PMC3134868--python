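"""Compartment-level rate equations for donor/acceptor drug transfer.

Three tiers of reduced kinetics, each integrating totals rather than full
occupancy distributions:

* first-order transfer ``dM_d/dt = (K/N)(M_a N_d - M_d N_a + k N_a N_d)`` —
  the exact moment closure of the ideal-kernel collision kinetics and, under
  weak loading, of the diffusion kinetics;
* the nonlinear high-loading system, in which uptake saturates with the
  filled fraction of each population and the equilibrium shifts toward a
  uniform drug distribution as the global load ``M/(mN)`` grows;
* the four-compartment two-state (leaflet) system, where drug must flip-flop
  from the inner to the outer leaflet before it can transfer, producing
  biexponential kinetics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .system import CarrierEnsemble, _kernel_value  # noqa: F401  (shared helpers)
from .system import k_bounds

logger = logging.getLogger("lipokin.compartments")

__all__ = [
    "CompartmentState",
    "TimeCourse",
    "integrate_first_order",
    "integrate_high_loading",
    "high_loading_equilibrium",
    "integrate_two_state",
]


@dataclass
class CompartmentState:
    """Drug totals per compartment; leaflet-resolved fields for the two-state model.

    In single-state use only ``m_donor`` and ``m_acceptor`` are populated and
    their sum is the conserved total ``M``.  In two-state use all four leaflet
    counts are non-negative, sum to ``M``, and aggregate as
    ``m_donor = m_donor_inner + m_donor_outer`` (likewise for acceptors).
    """

    m_donor: float = 0.0
    m_acceptor: float = 0.0
    m_donor_inner: float | None = None
    m_donor_outer: float | None = None
    m_acceptor_inner: float | None = None
    m_acceptor_outer: float | None = None


@dataclass
class TimeCourse:
    """Named compartment series on a strictly increasing time grid."""

    times: np.ndarray
    columns: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, col in self.columns.items():
            self.columns[name] = np.asarray(col, dtype=float)
            if self.columns[name].size != self.times.size:
                raise ValueError(f"column {name!r} length does not match times")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.columns[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, **self.columns})

    def to_csv(self, path) -> None:
        """CSV export: columns time, M_d, M_a [, leaflet columns]; '.' decimal."""
        self.to_frame().to_csv(path, index=False)


def _check_grid(t_grid) -> np.ndarray:
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2:
        raise ValueError("t_grid must contain at least two points")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    return t_grid


def _solve(rhs, y0, t_grid, rtol=1e-11, atol=1e-13):
    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), y0, method="DOP853", t_eval=t_grid,
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol


def integrate_first_order(
    ensemble: CarrierEnsemble,
    K: float,
    total_drug: float,
    t_grid,
    initial: tuple[float, float] | None = None,
) -> TimeCourse:
    """Integrate the linear two-compartment transfer equations.

    Defaults to all drug initially in the donors; the result reproduces the
    monoexponential closed form ``M_a(t) = (1 - e^{-Kt})(N_a/N)(M - k N_d)``
    to integrator accuracy.
    """
    t_grid = _check_grid(t_grid)
    lo, hi = k_bounds(ensemble, total_drug)
    k = ensemble.k_offset
    if not (lo <= k <= hi):
        raise ValueError(f"k_offset={k} outside [{lo}, {hi}] for M={total_drug}")
    if initial is None:
        initial = (total_drug, 0.0)
    n = ensemble.n_total
    n_d, n_a = ensemble.n_donor, ensemble.n_acceptor

    def rhs(t, y):
        m_d, m_a = y
        flux = (K / n) * (m_a * n_d - m_d * n_a + k * n_a * n_d)
        return [flux, -flux]

    scale = max(abs(total_drug), 1.0)
    sol = _solve(rhs, list(initial), t_grid, atol=1e-13 * scale)
    logger.info("integrate_first_order K=%g M=%g k=%g n_t=%d", K, total_drug, k, t_grid.size)
    return TimeCourse(
        sol.t, {"M_d": sol.y[0], "M_a": sol.y[1]},
        meta={"model": "first_order", "K": K, "k_offset": k, "total_drug": total_drug},
    )


def _load_fraction(ensemble: CarrierEnsemble, total_drug: float) -> float:
    return total_drug / (ensemble.capacity * ensemble.n_total)


def integrate_high_loading(
    ensemble: CarrierEnsemble,
    k_rel_donor: float,
    k_rel_acceptor: float,
    total_drug: float,
    t_grid,
    initial: tuple[float, float] | None = None,
) -> TimeCourse:
    """Integrate the nonlinear high-loading transfer system.

    Uptake by each population saturates with its filled fraction, so the
    kinetics is nonlinear in ``(M_d, M_a)`` unless the release rates are
    equal.  Integration is performed on the fractions ``(M_d/M, M_a/M)`` to
    keep tolerances scale-free; the trajectory approaches the stationary
    point returned by :func:`high_loading_equilibrium`.
    """
    t_grid = _check_grid(t_grid)
    if k_rel_donor < 0 or k_rel_acceptor < 0:
        raise ValueError("release rates must be non-negative")
    mn = ensemble.capacity * ensemble.n_total
    if total_drug > mn:
        raise ValueError(
            f"total_drug={total_drug} exceeds the ensemble capacity m*N={mn}"
        )
    if total_drug <= 0:
        raise ValueError("total_drug must be positive")
    mu = _load_fraction(ensemble, total_drug)
    if mu >= 1.0:
        raise ValueError("M = mN: every carrier is full and no transfer can occur")
    if initial is None:
        initial = (total_drug, 0.0)
    if initial[0] > ensemble.capacity * ensemble.n_donor:
        raise ValueError("initial donor content exceeds donor capacity m*N_d")
    f_d = ensemble.n_donor / ensemble.n_total
    f_a = ensemble.n_acceptor / ensemble.n_total
    denom = 1.0 - mu

    def rhs(t, y):
        x_d, x_a = y  # fractions M_d/M, M_a/M
        flux = (
            -k_rel_donor * (f_a - x_a * mu) / denom * x_d
            + k_rel_acceptor * (f_d - x_d * mu) / denom * x_a
        )
        return [flux, -flux]

    y0 = [initial[0] / total_drug, initial[1] / total_drug]
    sol = _solve(rhs, y0, t_grid)
    logger.info(
        "integrate_high_loading ratio=%g load=%g n_t=%d",
        np.divide(k_rel_donor, k_rel_acceptor) if k_rel_acceptor else np.inf,
        mu, t_grid.size,
    )
    return TimeCourse(
        sol.t,
        {"M_d": sol.y[0] * total_drug, "M_a": sol.y[1] * total_drug},
        meta={
            "model": "high_loading",
            "k_rel_donor": k_rel_donor,
            "k_rel_acceptor": k_rel_acceptor,
            "load_fraction": mu,
            "total_drug": total_drug,
        },
    )


def high_loading_equilibrium(
    ensemble: CarrierEnsemble,
    k_rel_donor: float,
    k_rel_acceptor: float,
    total_drug: float,
) -> tuple[float, float]:
    """Stationary partition ``(M_d^eq, M_a^eq)`` of the high-loading system.

    Solves the stationary balance — release from donors equals release from
    acceptors, each weighted by the partner's free capacity — which is a
    quadratic in the donor fraction ``x = M_d/M``:

        (K_d - K_a) mu x^2 + [K_d f_a + K_a f_d + mu (K_a - K_d)] x - K_a f_d = 0

    with ``mu = M/(mN)``, ``f_d = N_d/N``, ``f_a = N_a/N``.  The physical root
    lies in ``[0, 1]``; if both roots do, the one continuous with the
    weak-loading limit ``x -> K_a f_d / (K_d f_a + K_a f_d)`` is selected.
    """
    if total_drug <= 0:
        raise ValueError("total_drug must be positive")
    mn = ensemble.capacity * ensemble.n_total
    if total_drug > mn:
        raise ValueError(f"total_drug={total_drug} exceeds capacity m*N={mn}")
    mu = _load_fraction(ensemble, total_drug)
    f_d = ensemble.n_donor / ensemble.n_total
    f_a = ensemble.n_acceptor / ensemble.n_total
    kd, ka = k_rel_donor, k_rel_acceptor
    if kd < 0 or ka < 0 or (kd == 0 and ka == 0):
        raise ValueError("release rates must be non-negative and not both zero")

    a = (kd - ka) * mu
    b = kd * f_a + ka * f_d + mu * (ka - kd)
    c = -ka * f_d
    x_weak = ka * f_d / (kd * f_a + ka * f_d)
    if a == 0.0:
        x = -c / b
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise RuntimeError("no real stationary point (inconsistent inputs)")
        sq = np.sqrt(disc)
        roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
        inside = [r for r in roots if -1e-12 <= r <= 1.0 + 1e-12]
        if not inside:
            raise RuntimeError("no admissible stationary point in [0, M]")
        # continuity with the weak-loading limit breaks ties
        x = min(inside, key=lambda r: abs(r - x_weak))
    x = min(max(x, 0.0), 1.0)
    return (x * total_drug, (1.0 - x) * total_drug)


def integrate_two_state(
    ensemble: CarrierEnsemble,
    K: float,
    total_drug: float,
    t_grid,
    *,
    flip_symmetric: float | None = None,
    flip_donor_out: float = 0.0,
    flip_donor_in: float = 0.0,
    flip_acceptor_out: float = 0.0,
    flip_acceptor_in: float = 0.0,
    initial_split: float = 0.5,
) -> TimeCourse:
    """Integrate the four-compartment (leaflet-resolved) transfer system.

    Inter-carrier exchange acts only on the outer-leaflet contents, while
    flip-flop couples the inner and outer leaflets of each population.  The
    default initial condition puts all drug in the donors, split equally
    between their leaflets.  ``flip_symmetric`` sets all four flip rates to a
    common value ``G`` (symmetric bilayer, chemically similar carriers) and
    requires ``k_offset = 0``; in that case the trajectory matches the
    biexponential closed form with effective rates ``omega_1, omega_2``.
    """
    t_grid = _check_grid(t_grid)
    if flip_symmetric is not None:
        if flip_symmetric < 0:
            raise ValueError("flip rates must be non-negative")
        if ensemble.k_offset != 0:
            raise ValueError("the symmetric flip-flop variant assumes k_offset = 0")
        k1d = k2d = k1a = k2a = flip_symmetric
    else:
        k1d, k2d = flip_donor_out, flip_donor_in
        k1a, k2a = flip_acceptor_out, flip_acceptor_in
        if min(k1d, k2d, k1a, k2a) < 0:
            raise ValueError("flip rates must be non-negative")
    lo, hi = k_bounds(ensemble, total_drug)
    k = ensemble.k_offset
    if not (lo <= k <= hi):
        raise ValueError(f"k_offset={k} outside [{lo}, {hi}] for M={total_drug}")
    if not (0.0 <= initial_split <= 1.0):
        raise ValueError("initial_split must lie in [0, 1]")

    n = ensemble.n_total
    n_d, n_a = ensemble.n_donor, ensemble.n_acceptor
    m = total_drug
    # state order: M_d^O, M_d^I, M_a^O, M_a^I
    y0 = [m * (1.0 - initial_split), m * initial_split, 0.0, 0.0]

    def rhs(t, y):
        mdo, mdi, mao, mai = y
        xfer_d = (K / n) * (mao * n_d - mdo * n_a + k * n_a * n_d)
        xfer_a = (K / n) * (mdo * n_a - mao * n_d - k * n_a * n_d)
        flip_d = k1d * mdi - k2d * mdo   # net inner -> outer, donors
        flip_a = k1a * mai - k2a * mao
        return [xfer_d + flip_d, -flip_d, xfer_a + flip_a, -flip_a]

    sol = _solve(rhs, y0, t_grid, atol=1e-14 * max(m, 1.0))
    logger.info(
        "integrate_two_state K=%g G=%s k=%g n_t=%d",
        K, flip_symmetric, k, t_grid.size,
    )
    return TimeCourse(
        sol.t,
        {
            "M_d_O": sol.y[0],
            "M_d_I": sol.y[1],
            "M_a_O": sol.y[2],
            "M_a_I": sol.y[3],
            "M_d": sol.y[0] + sol.y[1],
            "M_a": sol.y[2] + sol.y[3],
        },
        meta={
            "model": "two_state",
            "K": K,
            "flip_symmetric": flip_symmetric,
            "total_drug": total_drug,
        },
    )
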