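"""Distribution-level kinetics: literal-transcription oracle, conservation, closure."""

import numpy as np
import pytest

from lipokin import (
    CarrierEnsemble,
    DistributionState,
    RateSet,
    collision_rhs,
    detect_inflection,
    diffusion_rhs,
    integrate_master,
    make_initial_state,
    moments,
    monoexponential_solution,
)


# ------------------------------------------------------------------ oracle
# Independent nested-loop transcription of the collision master equation,
# used to certify the vectorized operator.

def _g(i, j, m, mode):
    if mode == "ideal":
        return i - j
    return (i - j) * (1 - i / m) * (1 - j / m)


def _get(arr, idx, m):
    return arr[idx] if 0 <= idx <= m else 0.0


def _collision_rhs_literal(d, a, m, k, mode):
    out = []
    for p, q, kk in ((d, a, k), (a, d, -k)):
        deriv = np.zeros(m + 1)
        for j in range(m + 1):
            s = 0.0
            for i in range(0, j + 1):
                s += _get(p, i, m) * (
                    _get(p, j + 1, m) * _g(j + 1, i, m, mode)
                    - _get(p, j, m) * _g(j, i, m, mode)
                )
            for i in range(j, m + 1):
                s += _get(p, i, m) * (
                    _get(p, j - 1, m) * _g(i, j - 1, m, mode)
                    - _get(p, j, m) * _g(i, j, m, mode)
                )
            for i in range(kk, j + 1):
                s += _get(q, i - kk, m) * (
                    _get(p, j + 1, m) * _g(j + 1, i, m, mode)
                    - _get(p, j, m) * _g(j, i, m, mode)
                )
            for i in range(j, m + kk + 1):
                s += _get(q, i - kk, m) * (
                    _get(p, j - 1, m) * _g(i, j - 1, m, mode)
                    - _get(p, j, m) * _g(i, j, m, mode)
                )
            deriv[j] = s
        out.append(deriv)
    return out[0], out[1]


@pytest.mark.parametrize("k", [-2, 0, 3])
@pytest.mark.parametrize("mode", ["ideal", "crowded"])
def test_collision_rhs_matches_literal_transcription(k, mode, rng):
    m = 11
    ens = CarrierEnsemble(10, 10, 1.0, m, float(k))
    for _ in range(5):
        d = rng.random(m + 1) * 3.0
        a = rng.random(m + 1) * 3.0
        vec = collision_rhs(DistributionState(d, a), ens, 1.0, mode)
        bd, ba = _collision_rhs_literal(d, a, m, k, mode)
        np.testing.assert_allclose(vec.donors, bd, atol=1e-11)
        np.testing.assert_allclose(vec.acceptors, ba, atol=1e-11)


@pytest.mark.parametrize(
    "mode, k",
    [("ideal", -3), ("ideal", 0), ("ideal", 2), ("crowded", 0)],
)
def test_collision_rhs_conserves_carriers_and_drug(k, mode, rng):
    """Zeroth moments of the derivative vanish; joint first moment vanishes.

    Random states keep their support |k| classes away from the index
    boundaries, the regime in which the index-shifted cross sums clip
    nothing and conservation is exact.  The crowded kernel is checked at
    k = 0, its defining regime (chemically similar carriers).
    """
    m = 30
    pad = abs(k)
    ens = CarrierEnsemble(10, 10, 1.0, m, float(k))
    for _ in range(5):
        d = np.zeros(m + 1)
        a = np.zeros(m + 1)
        d[pad:m + 1 - pad] = rng.random(m + 1 - 2 * pad) * 2.0
        a[pad:m + 1 - pad] = rng.random(m + 1 - 2 * pad) * 2.0
        deriv = collision_rhs(DistributionState(d, a), ens, 1.0, mode)
        j = np.arange(m + 1)
        assert abs(deriv.donors.sum()) < 1e-9
        assert abs(deriv.acceptors.sum()) < 1e-9
        assert abs(j @ deriv.donors + j @ deriv.acceptors) < 1e-9


@pytest.mark.parametrize("k", [-2, 0, 3])
def test_collision_ideal_first_moments_close_exactly(k, rng):
    """With the ideal kernel the first moments follow the two-compartment law."""
    m = 30
    pad = abs(k)
    ens = CarrierEnsemble(10, 10, 1.0, m, float(k))
    for _ in range(5):
        d = np.zeros(m + 1)
        a = np.zeros(m + 1)
        d[pad:m + 1 - pad] = rng.random(m + 1 - 2 * pad) * 2.0
        a[pad:m + 1 - pad] = rng.random(m + 1 - 2 * pad) * 2.0
        state = DistributionState(d, a)
        n_d, n_a, m_d, m_a = moments(state)
        deriv = collision_rhs(state, ens, 1.0, "ideal")
        j = np.arange(m + 1)
        # scale K_coll/V = 1: dM_d/dt = M_a N_d - M_d N_a + k N_a N_d
        expected = m_a * n_d - m_d * n_a + k * n_a * n_d
        assert j @ deriv.donors == pytest.approx(expected, rel=1e-10, abs=1e-9)


def test_collision_requires_integer_offset():
    ens = CarrierEnsemble(10, 10, 1.0, 5, 0.5)
    state = make_initial_state(CarrierEnsemble(10, 10, 1.0, 5, 0.0), 2)
    with pytest.raises(ValueError, match="integer"):
        collision_rhs(state, ens, 1.0)


# ------------------------------------------------------------------ diffusion

def test_diffusion_rhs_conservation_and_closure(rng):
    m = 20
    ens = CarrierEnsemble(10, 15, 2.0, m)
    rates = RateSet(k_rel_donor=1.3, k_rel_acceptor=0.4,
                    k_upt_donor=0.8, k_upt_acceptor=1.1)
    for _ in range(5):
        state = DistributionState(rng.random(m + 1), rng.random(m + 1),
                                  aqueous=float(rng.random() * 5))
        n_d, n_a, m_d, m_a = moments(state)
        deriv = diffusion_rhs(state, ens, rates)
        j = np.arange(m + 1)
        assert abs(deriv.donors.sum()) < 1e-12
        assert abs(deriv.acceptors.sum()) < 1e-12
        # total drug including the aqueous pool is conserved
        total_dot = j @ deriv.donors + j @ deriv.acceptors + deriv.aqueous
        assert abs(total_dot) < 1e-9
        # first moment of the donor derivative: release + saturable uptake
        c_w = state.aqueous / ens.volume
        expected = -rates.k_rel_donor * m_d + rates.k_upt_donor * c_w * (m * n_d - m_d)
        assert j @ deriv.donors == pytest.approx(expected, rel=1e-10, abs=1e-10)


# ------------------------------------------------------------------ states & moments

def test_make_initial_state_delta_loading(symmetric_ensemble):
    s = make_initial_state(symmetric_ensemble, 98)
    assert s.donors[98] == 100 and s.donors.sum() == 100
    assert s.acceptors[0] == 100 and s.acceptors.sum() == 100
    assert s.aqueous == 0.0
    ens = CarrierEnsemble(6, 9, capacity=3)
    s = make_initial_state(ens, 2, 1)
    assert s.donors.sum() == 6 and s.acceptors.sum() == 9
    with pytest.raises(ValueError):
        make_initial_state(ens, 4)


def test_moments_worked_snapshot():
    """6 donors d=(1,2,2,1) and 9 acceptors a=(5,3,1,0) at capacity 3."""
    state = DistributionState([1, 2, 2, 1], [5, 3, 1, 0])
    assert moments(state) == (6.0, 9.0, 9.0, 5.0)
    empty = DistributionState(np.zeros(4), np.zeros(4))
    assert moments(empty) == (0.0, 0.0, 0.0, 0.0)


# ------------------------------------------------------------------ integration

def test_integrate_master_matches_closed_form(symmetric_ensemble):
    """Ideal-kernel transfer is exactly monoexponential (moment closure)."""
    rates = RateSet(k_coll=1.0 / 200.0)  # K = k_coll N/V = 1
    s0 = make_initial_state(symmetric_ensemble, 2)
    t = np.linspace(0.0, 5.0, 26)
    traj = integrate_master(s0, symmetric_ensemble, rates, "collision", "ideal", t)
    mf = traj.moments_frame()
    _, m_a = monoexponential_solution(t, 1.0, symmetric_ensemble, 200.0)
    assert np.max(np.abs(mf["M_a"].to_numpy() - m_a)) / 200.0 < 1e-6
    # the first snapshot is the initial state, exactly
    np.testing.assert_array_equal(traj.states[0].donors, s0.donors)
    np.testing.assert_array_equal(traj.states[0].acceptors, s0.acceptors)


def test_integrate_master_conservation_and_monotonicity(symmetric_ensemble):
    rates = RateSet(k_coll=1.0 / 200.0)
    s0 = make_initial_state(symmetric_ensemble, 50)
    t = np.linspace(0.0, 30.0, 61)
    traj = integrate_master(s0, symmetric_ensemble, rates, "collision", "crowded", t)
    mf = traj.moments_frame()
    M = 50 * 100.0
    assert np.max(np.abs(mf["N_d"] - 100.0)) < 1e-6 * M
    assert np.max(np.abs(mf["N_a"] - 100.0)) < 1e-6 * M
    assert np.max(np.abs(mf["M_d"] + mf["M_a"] + mf["M_w"] - M)) < 1e-6 * M
    # all drug starts in the donors and k = 0: uptake is monotone
    assert np.all(np.diff(mf["M_a"].to_numpy()) > -1e-9 * M)


def test_crowded_kernel_reaches_equipartition():
    """Near-full donors still equilibrate to equal per-carrier loading at k=0."""
    ens = CarrierEnsemble(50, 50, 1.0, 40)
    rates = RateSet(k_coll=1.0 / 100.0)
    s0 = make_initial_state(ens, 38)
    t = np.linspace(0.0, 300.0, 121)
    traj = integrate_master(s0, ens, rates, "collision", "crowded", t)
    mf = traj.moments_frame()
    M = 38 * 50.0
    assert mf["M_a"].iloc[-1] / M == pytest.approx(0.5, abs=1e-4)


def test_diffusion_quasi_steady_matches_first_order(symmetric_ensemble):
    """Fast uptake + weak loading reduce diffusion to first-order transfer."""
    rates = RateSet(k_rel_donor=1.0, k_rel_acceptor=1.0,
                    k_upt_donor=1.0, k_upt_acceptor=1.0)
    s0 = make_initial_state(symmetric_ensemble, 2)  # l = m/50
    t = np.linspace(0.0, 5.0, 26)
    traj = integrate_master(s0, symmetric_ensemble, rates, "diffusion", t_grid=t)
    got = traj.moments_frame()["M_a"].to_numpy()
    _, want = monoexponential_solution(t, 1.0, symmetric_ensemble, 200.0)
    rel = np.abs(got[1:] - want[1:]) / want[1:]
    assert np.max(rel) < 0.01


def test_integrate_master_both_mechanisms(symmetric_ensemble):
    rates = RateSet(k_coll=0.5 / 200.0, k_rel_donor=0.5, k_rel_acceptor=0.5,
                    k_upt_donor=1.0, k_upt_acceptor=1.0)
    s0 = make_initial_state(symmetric_ensemble, 2)
    t = np.linspace(0.0, 5.0, 21)
    traj = integrate_master(s0, symmetric_ensemble, rates, "both", t_grid=t)
    mf = traj.moments_frame()
    # combined apparent rate K = 0.5 (collision) + 0.5 (diffusion) = 1
    _, want = monoexponential_solution(t, 1.0, symmetric_ensemble, 200.0)
    assert np.max(np.abs(mf["M_a"].to_numpy() - want)) / 200.0 < 0.01
    assert np.max(np.abs(mf["M_d"] + mf["M_a"] + mf["M_w"] - 200.0)) < 1e-6 * 200


def test_integrate_master_grid_validation(symmetric_ensemble):
    s0 = make_initial_state(symmetric_ensemble, 2)
    rates = RateSet(k_coll=1.0)
    with pytest.raises(ValueError):
        integrate_master(s0, symmetric_ensemble, rates, t_grid=[1.0, 2.0])
    with pytest.raises(ValueError):
        integrate_master(s0, symmetric_ensemble, rates, t_grid=[0.0, 2.0, 1.0])
    with pytest.raises(ValueError):
        integrate_master(s0, symmetric_ensemble, rates, mechanism="teleport",
                         t_grid=[0.0, 1.0])


# ------------------------------------------------------------------ diagnostics

def test_detect_inflection_exponential_absent():
    t = np.linspace(0.0, 10.0, 200)
    assert detect_inflection(t, 1.0 - np.exp(-t)) is None


def test_detect_inflection_logistic_center():
    t = np.linspace(0.0, 10.0, 200)
    y = 1.0 / (1.0 + np.exp(-(t - 5.0)))
    found = detect_inflection(t, y)
    assert found == pytest.approx(5.0, abs=0.1)


def test_detect_inflection_needs_points():
    with pytest.raises(ValueError):
        detect_inflection([0, 1, 2, 3], [0, 1, 2, 3])


# ------------------------------------------------------------------ export

def test_trajectory_csv_export(tmp_path, symmetric_ensemble):
    ens = CarrierEnsemble(6, 9, capacity=3)
    rates = RateSet(k_coll=0.1)
    s0 = make_initial_state(ens, 2)
    t = np.linspace(0.0, 1.0, 5)
    traj = integrate_master(s0, ens, rates, t_grid=t)
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    import pandas as pd

    df = pd.read_csv(path)
    assert list(df.columns) == (
        ["time"] + [f"d_{j}" for j in range(4)] + [f"a_{j}" for j in range(4)]
        + ["M_w", "M_d", "M_a"]
    )
    assert df["time"].tolist() == pytest.approx(t.tolist())
    assert df["M_d"].iloc[0] == pytest.approx(12.0)  # 6 donors * 2 drugs
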