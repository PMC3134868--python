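"""Closed-form solutions and spectral relations of the transfer kinetics.

The monoexponential law of first-order transfer, the accelerated exponential
of the high-loading system with chemically similar carriers, the
biexponential four-compartment (leaflet) solution, and the algebraic maps
between the physical rates ``(K, G)`` and the observed decay eigenrates
``(omega_1, omega_2)``:

    omega_1 + omega_2 = 2 G + K,
    (omega_1 - omega_2)^2 = 4 G^2 + K^2.

Note the forward map is exactly two-to-one: ``(K, G)`` and ``(2G, K/2)``
produce identical spectra.  :func:`rates_from_effective` returns the
``K >= 2G`` representative (fast inter-carrier transfer, slow flip-flop — the
regime in which the two decay scales are experimentally resolvable).
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .system import CarrierEnsemble, equilibrium_partition, k_bounds

logger = logging.getLogger("lipokin.closedforms")

__all__ = [
    "monoexponential_solution",
    "high_loading_symmetric_solution",
    "two_state_solution",
    "effective_rates",
    "rates_from_effective",
]

#: relative spectral gap below which the confluent (equal-rate) limit is used
_CONFLUENT_TOL = 1e-10


def _check_time(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


def monoexponential_solution(t, K: float, ensemble: CarrierEnsemble, total_drug: float):
    """First-order transfer: ``M_a(t) = (1 - e^{-Kt}) (N_a/N) (M - k N_d)``.

    Returns ``(M_d, M_a)`` with ``M_d = M - M_a``; scalar or array ``t``.
    ``K`` is the inverse characteristic time of the transfer.
    """
    t = _check_time(t)
    lo, hi = k_bounds(ensemble, total_drug)
    k = ensemble.k_offset
    if not (lo <= k <= hi):
        raise ValueError(f"k_offset={k} outside [{lo}, {hi}] for M={total_drug}")
    plateau = ensemble.n_acceptor / ensemble.n_total * (total_drug - k * ensemble.n_donor)
    m_a = (1.0 - np.exp(-K * t)) * plateau
    return (total_drug - m_a, m_a)


def high_loading_symmetric_solution(
    t, k_diff: float, ensemble: CarrierEnsemble, total_drug: float
):
    """High-loading transfer between chemically similar carriers.

    A single release rate gives a pure exponential with the rate constant
    boosted by crowding: ``rate = k_diff / (1 - M/(mN))``, approaching the
    weak-loading law as ``M/(mN) -> 0``.  Returns ``(M_d, M_a)``.
    """
    t = _check_time(t)
    mu = total_drug / (ensemble.capacity * ensemble.n_total)
    if mu >= 1.0:
        raise ValueError(
            "M = mN: the effective rate k_diff/(1 - M/(mN)) diverges; "
            "every carrier is full and the kinetics is undefined"
        )
    rate = k_diff / (1.0 - mu)
    f_a = ensemble.n_acceptor / ensemble.n_total
    m_a = (1.0 - np.exp(-rate * t)) * f_a * total_drug
    return (total_drug - m_a, m_a)


def effective_rates(K: float, G: float) -> tuple[float, float]:
    """Decay eigenrates ``(omega_1, omega_2)`` of the symmetric two-state model.

    ``omega_{1,2} = (2G + K +/- sqrt(4G^2 + K^2)) / 2``, ordered
    ``omega_1 >= omega_2 >= 0`` (omega_1 is the fast mode).
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if G < 0:
        raise ValueError("G must be non-negative")
    s = 2.0 * G + K
    r = math.sqrt(4.0 * G * G + K * K)
    return ((s + r) / 2.0, (s - r) / 2.0)


def rates_from_effective(omega1: float, omega2: float) -> tuple[float, float]:
    """Invert the spectral relations: recover ``(K, G)`` from ``(omega_1, omega_2)``.

    Solves ``omega_1 + omega_2 = 2G + K`` together with
    ``(omega_1 - omega_2)^2 = 4G^2 + K^2`` exactly; of the two algebraic
    solutions (which swap ``K <-> 2G``) the ``K >= 2G`` representative is
    returned.  The result is validated by forward substitution.  Spectra with
    ``2 (omega_1 - omega_2)^2 < (omega_1 + omega_2)^2`` are not produced by
    any ``(K >= 0, G >= 0)`` and raise.
    """
    if not (omega1 >= omega2 >= 0.0):
        raise ValueError("require omega1 >= omega2 >= 0")
    if omega1 == 0.0:
        raise ValueError("omega1 and omega2 cannot both be zero")
    s = omega1 + omega2
    disc = 2.0 * (omega1 - omega2) ** 2 - s * s
    if disc < 0.0:
        if disc > -1e-12 * s * s:  # allow rounding at the K = 2G boundary
            disc = 0.0
        else:
            raise ValueError(
                "no (K >= 0, G >= 0) reproduces these rates: requires "
                "sqrt(2) * (omega1 - omega2) >= omega1 + omega2"
            )
    G = (s - math.sqrt(disc)) / 4.0
    K = s - 2.0 * G
    w1, w2 = effective_rates(K, G)
    if not (
        math.isclose(w1, omega1, rel_tol=1e-9, abs_tol=1e-12 * s)
        and math.isclose(w2, omega2, rel_tol=1e-9, abs_tol=1e-12 * s)
    ):
        raise ValueError("forward substitution failed to reproduce the input rates")
    return (K, G)


def two_state_solution(
    t, K: float, G: float, ensemble: CarrierEnsemble, total_drug: float
):
    """Biexponential solution of the symmetric two-state (leaflet) model.

    Assumes chemically similar carriers (k = 0), symmetric flip-flop rate
    ``G``, and all drug initially in the donors split equally between their
    leaflets.  Returns ``(M_d_O, M_d_I, M_a_O, M_a_I)``; the aggregates
    ``M_d = M_d_O + M_d_I`` and ``M_a`` are biexponential in ``omega_1`` and
    ``omega_2``.  The confluent case ``omega_1 = omega_2`` (reachable only in
    a degenerate limit, since the spectral gap is ``sqrt(4G^2 + K^2) >= K``)
    is evaluated by its analytic ``t e^{-omega t}`` limit rather than 0/0.
    """
    t = _check_time(t)
    if ensemble.k_offset != 0:
        raise ValueError("the two-state closed form assumes k_offset = 0")
    w1, w2 = effective_rates(K, G)
    m = total_drug
    f_d = ensemble.n_donor / ensemble.n_total
    f_a = ensemble.n_acceptor / ensemble.n_total

    if abs(w1 - w2) < _CONFLUENT_TOL * w1:
        w = 0.5 * (w1 + w2)
        ew = np.exp(-w * t)
        E = (1.0 + w * t) * ew       # lim (w2 e^{-w1 t} - w1 e^{-w2 t}) / (w2 - w1)
        D = -t * ew                  # lim (e^{-w2 t} - e^{-w1 t}) / (w2 - w1)
    else:
        e1 = np.exp(-w1 * t)
        e2 = np.exp(-w2 * t)
        E = (w2 * e1 - w1 * e2) / (w2 - w1)
        D = (e2 - e1) / (w2 - w1)

    m_d_i = 0.5 * m * (f_d + f_a * E)
    m_d_o = m_d_i + 0.5 * m * K * f_a * D
    m_a_i = 0.5 * m * f_a * (1.0 - E)
    m_a_o = m_a_i - 0.5 * m * K * f_a * D
    return (m_d_o, m_d_i, m_a_o, m_a_i)
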