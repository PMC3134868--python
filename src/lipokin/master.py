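"""Distribution-level (master-equation) kinetics of inter-carrier drug transfer.

The microscopic state is the pair of occupancy distributions ``d_j`` and
``a_j`` — the number of donor / acceptor carriers holding exactly ``j`` drug
molecules (0 <= j <= m) — plus the aqueous drug count ``M_w``.  Carrier counts
``N_d = sum_j d_j`` and ``N_a = sum_j a_j`` are the zeroth moments, and the
compartment drug contents ``M_d = sum_j j d_j``, ``M_a = sum_j j a_j`` the
first moments.

Two mechanisms drive the distributions:

* **collision** — a second-order process between pairs of carriers.  A
  collision between carriers holding ``i`` and ``j`` molecules transfers one
  molecule with weight ``g(i, j)`` (ideal ``i - j``, or the crowded kernel
  ``(i - j)(1 - i/m)(1 - j/m)``).  Donor-acceptor cross terms are shifted by
  the integer equilibrium offset ``k``, and any occupancy referenced outside
  ``[0, m]`` is treated as zero.  With the ideal kernel the first moments
  close exactly onto the two-compartment rate equations, so the observed
  kinetics is a pure exponential; the crowded kernel breaks closure and can
  produce sigmoidal transfer at high initial loading.
* **diffusion** — first-order release (flux ``K^rel * j * d_j``) into the
  aqueous pool and second-order uptake (flux ``K^upt * (m - j) * d_j * M_w/V``)
  out of it, for each population with its own rates.

Both right-hand sides conserve carrier counts exactly and total drug
``M_d + M_a + M_w`` exactly; the integrator preserves them to its tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .system import CarrierEnsemble, RateSet, _kernel_value

logger = logging.getLogger("lipokin.master")

__all__ = [
    "DistributionState",
    "DistributionTrajectory",
    "make_initial_state",
    "moments",
    "collision_rhs",
    "diffusion_rhs",
    "integrate_master",
    "detect_inflection",
]


@dataclass
class DistributionState:
    """Occupancy distributions ``d_0..d_m``, ``a_0..a_m`` and aqueous drug ``M_w``.

    Populations are continuous-valued expected counts (mean-field); indices
    outside ``[0, m]`` are treated as zero by every consumer.
    """

    donors: np.ndarray
    acceptors: np.ndarray
    aqueous: float = 0.0

    def __post_init__(self) -> None:
        self.donors = np.asarray(self.donors, dtype=float)
        self.acceptors = np.asarray(self.acceptors, dtype=float)
        if self.donors.ndim != 1 or self.acceptors.ndim != 1:
            raise ValueError("donors and acceptors must be 1-D sequences")
        if self.donors.shape != self.acceptors.shape:
            raise ValueError("donors and acceptors must have the same length")

    @property
    def capacity(self) -> int:
        return self.donors.size - 1

    def copy(self) -> "DistributionState":
        return DistributionState(self.donors.copy(), self.acceptors.copy(), self.aqueous)


@dataclass
class DistributionTrajectory:
    """Time-ordered sequence of :class:`DistributionState` snapshots."""

    times: np.ndarray
    states: list = field(default_factory=list)

    def moments_frame(self) -> pd.DataFrame:
        """Moments along the trajectory as a data frame (time, M_d, M_a, M_w, N_d, N_a)."""
        rows = []
        for t, s in zip(self.times, self.states):
            n_d, n_a, m_d, m_a = moments(s)
            rows.append((t, m_d, m_a, s.aqueous, n_d, n_a))
        return pd.DataFrame(rows, columns=["time", "M_d", "M_a", "M_w", "N_d", "N_a"])

    def to_frame(self) -> pd.DataFrame:
        """Full trajectory: columns time, d_0..d_m, a_0..a_m, M_w, M_d, M_a."""
        m = self.states[0].capacity
        cols = (
            ["time"]
            + [f"d_{j}" for j in range(m + 1)]
            + [f"a_{j}" for j in range(m + 1)]
            + ["M_w", "M_d", "M_a"]
        )
        rows = []
        for t, s in zip(self.times, self.states):
            _, _, m_d, m_a = moments(s)
            rows.append(
                np.concatenate(([t], s.donors, s.acceptors, [s.aqueous, m_d, m_a]))
            )
        return pd.DataFrame(rows, columns=cols)

    def to_csv(self, path) -> None:
        """Export as CSV (comma-separated, '.' decimal point)."""
        self.to_frame().to_csv(path, index=False)


def make_initial_state(
    ensemble: CarrierEnsemble, donor_load: int, acceptor_load: int = 0
) -> DistributionState:
    """Delta-loaded initial state: every donor holds ``donor_load`` molecules.

    All ``N_d`` donors sit at occupancy ``donor_load`` and all ``N_a``
    acceptors at ``acceptor_load`` (default empty); the aqueous pool starts
    empty.
    """
    m = ensemble.capacity
    for name, load in (("donor_load", donor_load), ("acceptor_load", acceptor_load)):
        if not (0 <= load <= m):
            raise ValueError(f"{name}={load} outside [0, capacity={m}]")
    d = np.zeros(m + 1)
    a = np.zeros(m + 1)
    d[int(donor_load)] = ensemble.n_donor
    a[int(acceptor_load)] = ensemble.n_acceptor
    return DistributionState(d, a, 0.0)


def moments(state: DistributionState) -> tuple[float, float, float, float]:
    """Zeroth and first moments ``(N_d, N_a, M_d, M_a)`` of the distributions."""
    j = np.arange(state.donors.size)
    return (
        float(state.donors.sum()),
        float(state.acceptors.sum()),
        float(j @ state.donors),
        float(j @ state.acceptors),
    )


class _CollisionOperator:
    """Vectorized evaluation of the collision master equation right-hand side.

    The four sum groups (same-population collisions from below/above, and the
    k-shifted cross-population collisions from below/above) are assembled from
    cumulative sums of kernel-weighted populations; the kernel matrices depend
    only on (m, k, mode) and are precomputed once, so a single call costs a
    handful of O(m^2) array operations.  Out-of-range occupancies contribute
    zero by index clipping with validity masks.
    """

    def __init__(self, capacity: int, k_offset: int, mode: str) -> None:
        m = int(capacity)
        k = int(k_offset)
        self.m, self.k, self.mode = m, k, mode
        if mode == "crowded" and k != 0:
            # the index-shifted cross terms pair donor- and acceptor-side
            # fluxes only for the ideal kernel; with crowding the occupancy
            # factors break that pairing and drug conservation with it
            logger.warning(
                "crowded kernel with k_offset=%d: the crowding model assumes "
                "chemically similar carriers (k=0); drug conservation is not "
                "guaranteed", k,
            )
        xs = np.arange(m + 2, dtype=float)[:, None]   # first kernel argument 0..m+1
        iv = np.arange(m + 1, dtype=float)[None, :]   # population index 0..m
        # same-population kernels: g(x, i) and g(i, y)
        self.G_low = _kernel_value(xs, iv, m, mode)           # (m+2, m+1)
        self.G_up = _kernel_value(iv.T, iv, m, mode)          # (m+1, m+1), rows i, cols y
        # cross-population kernels, donor side (partner index shifted by +k)
        self.Gx_low_d = _kernel_value(xs, iv + k, m, mode)    # g(x, i'+k)
        self.Gx_up_d = _kernel_value(iv.T + k, iv, m, mode)   # g(i'+k, y)
        # acceptor side: same structure with k -> -k
        self.Gx_low_a = _kernel_value(xs, iv - k, m, mode)
        self.Gx_up_a = _kernel_value(iv.T - k, iv, m, mode)

    @staticmethod
    def _revcumsum(arr: np.ndarray) -> np.ndarray:
        return np.cumsum(arr[::-1], axis=0)[::-1]

    def _one_side(self, p, q, Gx_low, Gx_up, k):
        """d/dt of population ``p`` given partner population ``q`` (offset k)."""
        m = self.m
        j = np.arange(m + 1)
        p_up = np.append(p[1:], 0.0)             # p_{j+1}
        p_dn = np.concatenate(([0.0], p[:-1]))   # p_{j-1}

        # same-population sums: L(x, j) = sum_{i<=j} p_i g(x, i),
        #                       U(y, j) = sum_{i>=j} p_i g(i, y)
        P = np.cumsum(self.G_low * p[None, :], axis=1)
        R = self._revcumsum(p[:, None] * self.G_up)
        t1 = p_up * P[j + 1, j] - p * P[j, j]
        u_m1 = np.zeros(m + 1)
        u_m1[1:] = R[j[1:], j[1:] - 1]
        t2 = p_dn * u_m1 - p * R[j, j]

        # cross-population sums with partner occupancies shifted by k:
        #   Lc(x, j) = sum_{i'=0}^{j-k} q_{i'} g(x, i'+k)   (empty if j-k < 0)
        #   Uc(y, j) = sum_{i'=j-k}^{m} q_{i'} g(i'+k, y)   (empty if j-k > m)
        Pc = np.cumsum(Gx_low * q[None, :], axis=1)
        Rc = self._revcumsum(q[:, None] * Gx_up)
        jk = j - k
        cl = np.clip(jk, 0, m)
        lo_ok = jk >= 0
        hi_ok = jk <= m
        t3 = p_up * np.where(lo_ok, Pc[j + 1, cl], 0.0) - p * np.where(
            lo_ok, Pc[j, cl], 0.0
        )
        uc_m1 = np.zeros(m + 1)
        uc_m1[1:] = np.where(hi_ok[1:], Rc[cl[1:], j[1:] - 1], 0.0)
        t4 = p_dn * uc_m1 - p * np.where(hi_ok, Rc[cl, j], 0.0)
        return t1 + t2 + t3 + t4

    def __call__(self, d: np.ndarray, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ddot = self._one_side(d, a, self.Gx_low_d, self.Gx_up_d, self.k)
        adot = self._one_side(a, d, self.Gx_low_a, self.Gx_up_a, -self.k)
        return ddot, adot


def _integer_offset(ensemble: CarrierEnsemble) -> int:
    k = ensemble.k_offset
    if k != round(k):
        raise ValueError(
            "the collision master equation shifts occupancy indices by k and "
            f"therefore requires an integer k_offset; got {k}"
        )
    return int(round(k))


def collision_rhs(
    state: DistributionState,
    ensemble: CarrierEnsemble,
    k_coll: float,
    mode: str = "ideal",
) -> DistributionState:
    """Time derivative of the distributions under the collision mechanism.

    Returns a :class:`DistributionState` holding ``d(d_j)/dt``, ``d(a_j)/dt``
    and ``dM_w/dt = 0`` (collisions never touch the aqueous pool).  Requires
    an integer ``k_offset``.
    """
    k = _integer_offset(ensemble)
    op = _CollisionOperator(state.capacity, k, mode)
    ddot, adot = op(state.donors, state.acceptors)
    scale = k_coll / ensemble.volume
    return DistributionState(scale * ddot, scale * adot, 0.0)


def diffusion_rhs(
    state: DistributionState, ensemble: CarrierEnsemble, rates: RateSet
) -> DistributionState:
    """Time derivative under the diffusion (release/uptake) mechanism.

    Release flux out of occupancy class j is ``K^rel * j * p_j``; uptake into
    class j is ``K^upt * (m - (j-1)) * p_{j-1} * M_w/V``.  The aqueous pool
    balances all release and uptake so that total drug is conserved exactly.
    """
    m = state.capacity
    j = np.arange(m + 1, dtype=float)
    c_w = state.aqueous / ensemble.volume

    def one(p, k_rel, k_upt):
        p_up = np.append(p[1:], 0.0)
        p_dn = np.concatenate(([0.0], p[:-1]))
        rel = k_rel * ((j + 1) * p_up - j * p)
        upt = k_upt * c_w * ((m - (j - 1)) * p_dn - (m - j) * p)
        return rel + upt

    ddot = one(state.donors, rates.k_rel_donor, rates.k_upt_donor)
    adot = one(state.acceptors, rates.k_rel_acceptor, rates.k_upt_acceptor)
    # balance against the state's own moments so conservation is exact even
    # for states whose carrier counts differ from the nominal ensemble
    n_d, n_a, m_d, m_a = moments(state)
    wdot = (
        rates.k_rel_donor * m_d
        - rates.k_upt_donor * c_w * (m * n_d - m_d)
        + rates.k_rel_acceptor * m_a
        - rates.k_upt_acceptor * c_w * (m * n_a - m_a)
    )
    return DistributionState(ddot, adot, wdot)


def integrate_master(
    initial: DistributionState,
    ensemble: CarrierEnsemble,
    rates: RateSet,
    mechanism: str = "collision",
    mode: str = "ideal",
    t_grid=None,
    rtol: float = 1e-8,
    atol: float | None = None,
    method: str = "LSODA",
) -> DistributionTrajectory:
    """Integrate the master equation on ``t_grid`` and return the trajectory.

    ``mechanism`` is ``'collision'``, ``'diffusion'`` or ``'both'`` (the two
    right-hand sides simply add).  The default integrator is LSODA — adaptive
    with automatic stiffness switching, which matters for crowded-kernel runs
    near full loading — at relative tolerance 1e-8 and absolute tolerance
    ``1e-10 * N``; output is evaluated on the requested grid.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1:
        raise ValueError("t_grid must be a non-empty 1-D sequence")
    if t_grid[0] != 0.0:
        raise ValueError("t_grid must start at 0")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if mechanism not in ("collision", "diffusion", "both"):
        raise ValueError("mechanism must be 'collision', 'diffusion' or 'both'")

    m = initial.capacity
    if m != ensemble.capacity:
        raise ValueError("state capacity does not match ensemble capacity")
    n = m + 1
    if atol is None:
        atol = 1e-10 * ensemble.n_total

    op = None
    if mechanism in ("collision", "both"):
        op = _CollisionOperator(m, _integer_offset(ensemble), mode)
    coll_scale = rates.k_coll / ensemble.volume

    use_diff = mechanism in ("diffusion", "both")
    jv = np.arange(n, dtype=float)
    inv_v = 1.0 / ensemble.volume

    def rhs(t, y):
        d = y[:n]
        a = y[n:2 * n]
        dy = np.zeros_like(y)
        if op is not None:
            cd, ca = op(d, a)
            dy[:n] += coll_scale * cd
            dy[n:2 * n] += coll_scale * ca
        if use_diff:
            c_w = y[-1] * inv_v
            for sl, p, k_rel, k_upt in (
                (slice(0, n), d, rates.k_rel_donor, rates.k_upt_donor),
                (slice(n, 2 * n), a, rates.k_rel_acceptor, rates.k_upt_acceptor),
            ):
                p_up = np.append(p[1:], 0.0)
                p_dn = np.concatenate(([0.0], p[:-1]))
                dy[sl] += k_rel * ((jv + 1) * p_up - jv * p)
                dy[sl] += k_upt * c_w * ((m - (jv - 1)) * p_dn - (m - jv) * p)
                dy[-1] += k_rel * float(jv @ p) - k_upt * c_w * (
                    m * float(p.sum()) - float(jv @ p)
                )
        return dy

    y0 = np.concatenate((initial.donors, initial.acceptors, [initial.aqueous]))
    logger.info(
        "integrate_master mechanism=%s mode=%s m=%d k=%s rtol=%g atol=%g t_end=%g",
        mechanism, mode, m, ensemble.k_offset, rtol, atol, t_grid[-1],
    )
    if t_grid.size == 1:  # only t=0 requested: no integration needed
        return DistributionTrajectory(t_grid, [initial.copy()])
    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), y0, method=method, t_eval=t_grid,
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else t_grid[0]
        raise RuntimeError(
            f"master-equation integration failed at t={last_t}: {sol.message}"
        )
    states = [
        DistributionState(sol.y[:n, i].copy(), sol.y[n:2 * n, i].copy(), float(sol.y[-1, i]))
        for i in range(sol.t.size)
    ]
    states[0] = initial.copy()  # t = 0 is the supplied state, exactly
    return DistributionTrajectory(sol.t.copy(), states)


def detect_inflection(times, values):
    """Interior inflection time of a rising curve, or ``None`` if there is none.

    Applies a 3-point moving average before differencing (to suppress
    floating-point ripple on near-exponential curves) and requires the sign of
    the discrete second derivative to change from + to - and persist for at
    least two consecutive intervals; sign changes at the endpoints are
    ignored.  Pure exponential approaches (concave throughout) return
    ``None``; sigmoidal curves return the crossing time, linearly
    interpolated.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 5:
        raise ValueError("detect_inflection requires at least 5 points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    smooth = values.copy()
    smooth[1:-1] = (values[:-2] + values[1:-1] + values[2:]) / 3.0
    d1 = np.gradient(smooth, times)
    d2 = np.gradient(d1, times)

    # Only the region where the curve still rises appreciably is searched:
    # once the slope has decayed to a tiny fraction of its peak, the second
    # derivative is pure integrator/rounding ripple around zero.
    significant = np.abs(d1) >= 1e-3 * np.max(np.abs(d1))

    n = times.size
    # interior scan: need two positive points before and two negative after
    for i in range(1, n - 3):
        if not (significant[i] and significant[i + 1]):
            continue
        if d2[i - 1] > 0 and d2[i] > 0 and d2[i + 1] < 0 and d2[i + 2] < 0:
            # linear interpolation of the zero crossing between i and i+1
            t0, t1 = times[i], times[i + 1]
            y0, y1 = d2[i], d2[i + 1]
            return float(t0 - y0 * (t1 - t0) / (y1 - y0))
    return None
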