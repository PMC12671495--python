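import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from psiikin import (
    ConnectivityParams,
    PqPoolParams,
    closed_from_vf,
    cross_section_rescale,
    fit_dcmu_induction,
    make_preset,
    simulate_dcmu_induction,
    simulate_pq_pool_rise,
    slowdown_and_pq_ratio,
    two_thirds_antenna_size,
    vf_from_closed,
)
from psiikin.connectivity import closure_time, invert_closure


# ---------------------------------------------------------------- V(C) map

@pytest.mark.parametrize("J", [0.0, 0.6, 1.0, 2.05, 8.0])
def test_vf_boundaries(J):
    assert vf_from_closed(0.0, J) == 0.0
    assert vf_from_closed(1.0, J) == pytest.approx(1.0)


def test_vf_hand_value():
    # J=1 => p=1/2; V(0.5) = 0.5*0.5/(1-0.25) = 1/3
    assert vf_from_closed(0.5, 1.0) == pytest.approx(1.0 / 3.0)


def test_vf_linear_when_unconnected():
    C = np.linspace(0, 1, 11)
    assert np.allclose(vf_from_closed(C, 0.0), C)


@settings(deadline=None, derandomize=True)
@given(
    C=st.floats(min_value=0.0, max_value=1.0),
    J=st.floats(min_value=0.0, max_value=10.0),
)
def test_inverse_forward_roundtrip(C, J):
    assert closed_from_vf(vf_from_closed(C, J), J) == pytest.approx(C, abs=1e-12)


@pytest.mark.parametrize("J", [0.5, 2.05])
def test_vf_strictly_increasing_in_c(J):
    C = np.linspace(0, 1, 201)
    assert np.all(np.diff(vf_from_closed(C, J)) > 0)


# ------------------------------------------------------- DCMU induction

def test_unconnected_limit_is_exponential(t_grid):
    params = ConnectivityParams(J=0.0, k_ph=3.0, F0=0.2, Fv=0.8)
    trace = simulate_dcmu_induction(params, t_grid)
    expected = 0.2 + 0.8 * (1.0 - np.exp(-3.0 * t_grid))
    assert np.max(np.abs(trace.value - expected)) < 1e-12


def test_connected_curve_is_sigmoidal(t_grid):
    params = ConnectivityParams(J=2.05, k_ph=7.0, F0=0.18, Fv=0.82)
    trace = simulate_dcmu_induction(params, t_grid)
    V = (trace.value - 0.18) / 0.82
    d2 = np.diff(V, 2)[:20]
    assert np.all(d2 > 0)  # positive initial curvature


@pytest.mark.parametrize("genotype", ["WT", "NoM", "koLhcb", "koLHCII"])
def test_implicit_solution_matches_ode_integration(genotype, t_grid):
    """Closed-form inversion vs brute-force high-order ODE integration."""
    pre = make_preset(genotype)
    params = ConnectivityParams(J=pre.J, k_ph=pre.k_ph, F0=pre.F0, Fv=pre.Fv)
    trace = simulate_dcmu_induction(params, t_grid)
    p = params.p

    def rhs(_t, y):
        return [params.k_ph * (1 - min(y[0], 1 - 1e-12)) / (1 - p * min(y[0], 1 - 1e-12))]

    sol = solve_ivp(rhs, (0, t_grid[-1]), [0.0], t_eval=t_grid, method="DOP853",
                    rtol=1e-10, atol=1e-12)
    V_impl = (trace.value - params.F0) / params.Fv
    V_ode = vf_from_closed(np.clip(sol.y[0], 0, 1), params.J)
    assert np.max(np.abs(V_impl - V_ode)) < 1e-6


def test_two_thirds_time_exponential_closed_form():
    # grid long enough that the trace maximum is the true Fm plateau
    t = np.arange(0.0, 14.0, 1e-3)
    trace = simulate_dcmu_induction(ConnectivityParams(J=0.0, k_ph=1.0), t)
    t23, inv = two_thirds_antenna_size(trace)
    assert t23 == pytest.approx(np.log(3.0), rel=1e-3)
    assert inv == pytest.approx(1.0 / np.log(3.0), rel=1e-3)


def test_two_thirds_time_connected_against_root_finder():
    # independent oracle: root-find the implicit form at V = 2/3
    J, k = 2.05, 1.0
    t_star = brentq(
        lambda tt: vf_from_closed(invert_closure(tt, J, k), J) - 2.0 / 3.0, 0.1, 5.0
    )
    assert t_star == pytest.approx(1.220, abs=2e-3)
    t = np.arange(0.0, 8.0, 1e-3)
    trace = simulate_dcmu_induction(ConnectivityParams(J=J, k_ph=k), t)
    t23, _ = two_thirds_antenna_size(trace)
    assert t23 == pytest.approx(t_star, rel=1e-3)


def test_fit_recovers_noiseless_parameters(t_grid):
    truth = ConnectivityParams(J=0.79, k_ph=5.0, F0=0.3, Fv=0.9)
    fit = fit_dcmu_induction(simulate_dcmu_induction(truth, t_grid))
    assert fit.params.J == pytest.approx(truth.J, rel=1e-3)
    assert fit.params.k_ph == pytest.approx(truth.k_ph, rel=1e-3)
    assert fit.params.F0 == pytest.approx(truth.F0, rel=1e-3)
    assert fit.params.Fv == pytest.approx(truth.Fv, rel=1e-3)


def test_fit_warns_on_truncated_induction():
    t = np.arange(0.0, 0.12, 1e-3)  # stops well before the Fm plateau
    trace = simulate_dcmu_induction(ConnectivityParams(J=1.0, k_ph=5.0, F0=0.2, Fv=0.8), t)
    with pytest.warns(UserWarning, match="truncated"):
        fit = fit_dcmu_induction(trace)
    assert any("truncated" in w for w in fit.warnings)


# --------------------------------------------------- cross-section rescale

def test_rescale_identity(t_grid):
    trace = simulate_dcmu_induction(ConnectivityParams(J=2.0, k_ph=7.0), t_grid)
    res = cross_section_rescale(trace, trace)
    assert res.factor == pytest.approx(1.0, rel=1e-9)
    assert res.v06_time_ratio == pytest.approx(1.0, rel=1e-9)
    assert not res.shape_mismatch


@pytest.mark.parametrize("s", [0.4, 2.5])
def test_rescale_timescale_invariance(s):
    """The model depends on k_ph·t only, so scaling k_ph by s is an exact
    time rescaling and the equal-area factor equals s."""
    t = np.arange(0.0, 10.0, 2e-3)
    ref = simulate_dcmu_induction(ConnectivityParams(J=1.5, k_ph=4.0), t)
    scaled = simulate_dcmu_induction(ConnectivityParams(J=1.5, k_ph=4.0 * s), t)
    res = cross_section_rescale(scaled, ref)
    assert res.factor == pytest.approx(s, rel=5e-3)
    assert not res.shape_mismatch


def test_rescale_flags_shape_mismatch_on_different_j():
    t = np.arange(0.0, 10.0, 2e-3)
    ref = simulate_dcmu_induction(ConnectivityParams(J=2.05, k_ph=7.0), t)
    other = simulate_dcmu_induction(ConnectivityParams(J=0.0, k_ph=7.0), t)
    res = cross_section_rescale(other, ref)
    assert res.shape_mismatch
    assert res.factor > 0  # factor still returned


# ------------------------------------------------------------ PQ-pool rise

def test_tiny_pool_approaches_dcmu_curve(t_grid):
    params = ConnectivityParams(J=1.0, k_ph=5.0, F0=0.2, Fv=0.8)
    dcmu = simulate_dcmu_induction(params, t_grid)
    pooled = simulate_pq_pool_rise(params, PqPoolParams(n_pq=1e-4, k_ox=100.0), t_grid)
    assert np.max(np.abs(pooled.value - dcmu.value)) < 5e-3


def test_rise_slows_monotonically_with_pool_size():
    params = ConnectivityParams(J=2.0, k_ph=7.0, F0=0.2, Fv=0.8)
    t = np.arange(0.0, 40.0, 5e-3)
    t23s = []
    for n_pq in [2.0, 6.0, 12.0, 24.0]:
        trace = simulate_pq_pool_rise(params, PqPoolParams(n_pq=n_pq, k_ox=150.0), t)
        t23s.append(two_thirds_antenna_size(trace)[0])
    assert np.all(np.diff(t23s) > 0)


def test_slowdown_identity():
    t = np.arange(0.0, 10.0, 2e-3)
    params = ConnectivityParams(J=2.0, k_ph=7.0, F0=0.2, Fv=0.8)
    trace = simulate_pq_pool_rise(params, PqPoolParams(n_pq=12.0, k_ox=150.0), t)
    res = slowdown_and_pq_ratio(trace, trace, sigma_ratio=1.0)
    assert res.slowdown == pytest.approx(1.0)
    assert res.pq_per_rc_ratio == pytest.approx(1.0)


def test_pq_ratio_recovered_from_known_pool_sizes():
    """Generator round-trip: pair built with a known n_pq ratio R returns
    sigma_ratio x slowdown within 15% of R."""
    t = np.arange(0.0, 60.0, 5e-3)
    base = ConnectivityParams(J=2.0, k_ph=7.0, F0=0.2, Fv=0.8)
    bigger = ConnectivityParams(J=2.0, k_ph=7.0 * 1.5, F0=0.2, Fv=0.8)  # sigma x1.5
    R = 4.0
    ref = simulate_pq_pool_rise(base, PqPoolParams(n_pq=12.0, k_ox=150.0), t)
    test = simulate_pq_pool_rise(bigger, PqPoolParams(n_pq=12.0 * R, k_ox=150.0), t)
    res = slowdown_and_pq_ratio(test, ref, sigma_ratio=1.5)
    assert abs(res.pq_per_rc_ratio - R) / R < 0.15
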