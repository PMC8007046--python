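"""Closed-form detectability model: exact identities, shapes, and the
well-mixed simulation cross-check."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metdiv import (NeutralParams, TypeStructure, bmd_pmf,
                    bmd_pmf_from_detectability, detectability,
                    expected_bmd_multitype, expected_bmd_neutral, expected_bp,
                    order_map, population_size, seeding_weights, size_to_k)
from metdiv.analytic import analytic_curves, origination_variance


@pytest.fixture
def params():
    return NeutralParams(u=0.15, rho=0.72, f=0.02)


# ---------------------------------------------------------------------------
# population size and order map
# ---------------------------------------------------------------------------

def test_population_size_basics(params):
    assert population_size(0.0, params) == pytest.approx(1.0)
    # growth exponent r = lambda0 * (1 - rho); at large t, N ~ e^{rt}/rho
    r = params.lambda0 * (1 - params.rho)
    t = 300.0
    assert population_size(t, params) == pytest.approx(
        np.exp(r * t) / params.rho, rel=1e-6)
    p5 = NeutralParams(u=0.15, rho=0.5, f=0.02, lambda0=1.0)
    t1 = 1.0 / (p5.lambda0 * (1 - p5.rho))  # r*t = 1
    assert population_size(t1, p5) == pytest.approx(2 * np.e - np.exp(-1))


def test_order_map_matches_population_size(params):
    """Two code paths: g(j) closed form vs u * N(t_j) with
    t_j = j/(u*lambda0)."""
    js = np.arange(0, 12)
    t_j = js / (params.u * params.lambda0)
    expected = params.u * population_size(t_j, params)
    assert np.allclose(order_map(js, params), expected, rtol=1e-12)
    assert order_map(0, params) == pytest.approx(params.u)
    g = order_map(js, params)
    assert (np.diff(g) > 0).all()


def test_detectability_high_precision(params):
    """Eq values recomputed with sympy arbitrary precision."""
    import sympy

    u, rho, f = map(sympy.Rational, ("15/100", "72/100", "2/100"))
    base = u / (u - sympy.log(1 + (rho - 1) * f))
    for j in (1, 2, 3):
        x = (1 - rho) * j / u
        g = u * (sympy.exp(-x) + 2 * sympy.sinh(x) / rho)
        expect = float((base ** g).evalf(30))
        assert detectability(j, params) == pytest.approx(expect, rel=1e-12)


def test_detectability_sequence_shape(params):
    d = detectability(np.arange(0, 30), params)
    assert d[0] == 1.0
    assert (np.diff(d[:8]) < 0).all()     # strictly decreasing early
    assert d[-1] < 1e-12                  # -> 0
    # rho -> 1: base -> 1, detectability -> 1 for fixed j
    near1 = NeutralParams(u=0.15, rho=0.999999, f=0.02)
    assert detectability(3, near1) > 0.999


def test_detectability_domain_error():
    with pytest.raises(ValueError):
        NeutralParams(u=0.15, rho=0.5, f=1.2)
    # f >= 1/(1-rho) is impossible for f < 1, so the in-range guard
    # triggers through the multitype rescaling instead (below)


# ---------------------------------------------------------------------------
# pmf and expectation
# ---------------------------------------------------------------------------

def test_pmf_hand_set_detectabilities():
    dist = bmd_pmf_from_detectability(np.array([1.0, 0.9, 0.5, 0.1]))
    assert np.allclose(dist.pmf, [0.1, 0.4, 0.4, 0.1])
    assert dist.mean == pytest.approx(0.1 * 0 + 0.4 * 1 + 0.4 * 2 + 0.1 * 3)


def test_pmf_point_mass_at_zero(params):
    dist = bmd_pmf(0, params)
    assert dist.pmf.tolist() == [1.0]
    assert dist.mean == 0.0 and dist.std == 0.0


@given(k=st.integers(0, 1000))
@settings(deadline=None, max_examples=30)
def test_pmf_telescoping_normalization(k):
    params = NeutralParams(u=0.15, rho=0.9, f=0.02)
    dist = bmd_pmf(k, params)
    assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-12)
    assert (dist.pmf >= -1e-15).all()
    assert dist.pmf.size == k + 1


@given(
    u=st.floats(0.05, 0.5), rho=st.floats(0.1, 0.97),
    f=st.floats(0.005, 0.2), k=st.integers(1, 200),
)
@settings(deadline=None, max_examples=60)
def test_eq12_equals_pmf_mean(u, rho, f, k):
    """The direct expectation sum and the pmf mean are independent code
    paths; they must agree to 1e-9."""
    params = NeutralParams(u=u, rho=rho, f=f)
    assert expected_bmd_neutral(k, f, rho, u) == pytest.approx(
        bmd_pmf(k, params).mean, abs=1e-9)


def test_neutral_monotonicity_and_two_phases():
    for rho in (0.5, 0.72, 0.9):
        E = [expected_bmd_neutral(k, 0.02, rho, 0.15) for k in range(120)]
        assert (np.diff(E) >= -1e-12).all()
    # flat-phase length (first k with E > 0.5) increases with rho
    def flat_len(rho):
        for k in range(500):
            if expected_bmd_neutral(k, 0.02, rho, 0.15) > 0.5:
                return k
        return 500
    lens = [flat_len(r) for r in (0.5, 0.8, 0.95)]
    assert lens[0] < lens[1] < lens[2]
    # late phase: steady increase at slope ~1 per variant
    E = [expected_bmd_neutral(k, 0.02, 0.72, 0.15) for k in range(30, 60)]
    slopes = np.diff(E)
    assert np.allclose(slopes, 1.0, atol=0.05)


# ---------------------------------------------------------------------------
# multi-type mixture
# ---------------------------------------------------------------------------

def fig7_structure(scenario):
    rho = [0.95, 0.93, 0.83]
    T = [0.0, size_to_k(600, 0.95, 0.15), size_to_k(4.6e5, 0.95, 0.15)]
    return TypeStructure(rho=rho, T=T, f=[1.0, 0.873, 0.771],
                         scenario=scenario, u=0.15)


def test_seeding_weights_basics():
    st_a = fig7_structure("most_advanced")
    T1 = st_a.T[1]
    assert seeding_weights(T1 - 1, st_a).tolist() == [1.0, 0.0, 0.0]
    assert seeding_weights(T1 + 1, st_a).tolist() == [0.0, 1.0, 0.0]
    st_b = TypeStructure(rho=[0.95, 0.93], T=[0, 10], f=[1.0, 0.5],
                         scenario="fitness_proportional", u=0.15,
                         birth_rates=[1.0, 1.0])
    w = seeding_weights(12, st_b)
    assert w == pytest.approx([0.5, 0.5])  # equal birth rates
    st_c = TypeStructure(rho=[0.95, 0.93], T=[0, 10], f=[1.0, 0.5],
                         scenario="uniform", u=0.15)
    for k in (5, 15, 40):
        w = seeding_weights(k, st_c)
        assert w.sum() == pytest.approx(1.0)
        if k < 10:
            assert w[1] == 0.0
    # the late type eventually dominates the uniform weights
    assert seeding_weights(60, st_c)[1] > 0.9


def test_uniform_weights_half_when_sizes_cross():
    """Scenario (c): phi_1 = N_1/(N_0+N_1) = 1/2 where the expected type
    sizes cross."""
    from scipy.optimize import brentq

    from metdiv.analytic import _expected_type_size

    st_c = TypeStructure(rho=[0.95, 0.80], T=[0, 5], f=[1.0, 0.5],
                         scenario="uniform", u=0.15)

    def gap(k):
        n1 = _expected_type_size(k, 5.0, 0.80, 0.15)
        n0 = _expected_type_size(k, 0.0, 0.95, 0.15) - n1
        return n1 - n0

    k_star = brentq(gap, 5.01, 60)
    w = seeding_weights(k_star, st_c)
    assert w[1] == pytest.approx(0.5, abs=1e-6)


def test_mixture_collapse_to_neutral():
    st2 = TypeStructure(rho=[0.95, 0.90], T=[0, 8], f=[1.0, 1.0 - 1e-12],
                        scenario="most_advanced", u=0.15)
    k = 30
    e, _ = expected_bmd_multitype(k, st2, alpha=0.01)
    assert e == pytest.approx(
        expected_bmd_neutral(k - 8, 0.02, 0.90, 0.15), rel=1e-6)


def test_mixture_drops_at_type_introductions():
    for scenario in ("most_advanced", "fitness_proportional"):
        stx = fig7_structure(scenario)
        ks = np.arange(0, 63)
        E = np.array([expected_bmd_multitype(k, stx)[0] for k in ks])
        d = np.diff(E)
        t1, t2 = int(stx.T[1]), int(stx.T[2])
        assert d[t1 - 1 : t1 + 2].min() < 0, scenario
        assert d[t2 - 1 : t2 + 2].min() < 0, scenario
    # scenario (c): a gradual change in monotonicity after T1
    stc = fig7_structure("uniform")
    E = np.array([expected_bmd_multitype(k, stc)[0] for k in np.arange(63)])
    assert np.diff(E)[int(stc.T[1]):].min() < 0


def test_origination_variance_by_scenario():
    sta = fig7_structure("most_advanced")
    stb = fig7_structure("fitness_proportional")
    k_after = sta.T[1] + 4
    assert origination_variance(k_after, sta) == 0.0
    assert origination_variance(k_after, stb) > 0.0
    # mixture std rises after a detectable type appears under (b)
    _, s_before = expected_bmd_multitype(sta.T[1] - 2, stb)
    _, s_after = expected_bmd_multitype(sta.T[1] + 6, stb)
    assert s_after > s_before


def test_mixture_degenerate_rescaled_threshold():
    """A rescaled threshold >= 1 (the subpopulation cannot host a variant
    at the overall threshold) degenerates that branch to B_md = K."""
    stx = TypeStructure(rho=[0.95, 0.90], T=[0, 5], f=[1.0, 0.01],
                        scenario="most_advanced", u=0.15)
    with pytest.warns(UserWarning, match="rescaled threshold"):
        e, s = expected_bmd_multitype(10, stx, alpha=0.3)  # 2*.3/.01 = 60
    assert e == pytest.approx(10 - 5)  # every post-T1 variant undetectable
    assert s == pytest.approx(0.0)


def test_type_structure_validation():
    with pytest.raises(ValueError):
        TypeStructure(rho=[0.9, 0.95], T=[0, 5], f=[1, 0.5])  # rho up
    with pytest.raises(ValueError):
        TypeStructure(rho=[0.9, 0.8], T=[5, 10], f=[1, 0.5])  # T0 != 0
    with pytest.raises(ValueError):
        TypeStructure(rho=[0.9, 0.8], T=[0, 5], f=[1, 1.5])   # f out


# ---------------------------------------------------------------------------
# B_p
# ---------------------------------------------------------------------------

def test_expected_bp_arithmetic_and_clamp():
    assert expected_bp(20, 50, 5) == 35.0
    with pytest.warns(UserWarning, match="clamped"):
        assert expected_bp(100, 50, 5) == 0.0


def test_bp_flat_where_bmd_linear():
    """Where E[B_md] increases ~1 per variant, B_p stays constant; drops
    in B_md at type introductions appear as drops in B_p."""
    params_f = 0.4  # gamma-level threshold
    E = {k: expected_bmd_neutral(k, params_f, 0.72, 0.15)
         for k in range(25, 40)}
    bp = [expected_bp(k, 60, E[k]) for k in range(25, 40)]
    assert np.ptp(np.diff(bp)) < 0.05  # flat
    import warnings

    stx = fig7_structure("most_advanced")
    t1 = int(stx.T[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bmd_g = {k: expected_bmd_multitype(k, stx, alpha=0.2)[0]
                 for k in (t1 - 1, t1 + 1)}
    bp_pair = [expected_bp(k, 60, bmd_g[k]) for k in (t1 - 1, t1 + 1)]
    assert bp_pair[1] < bp_pair[0]


def test_analytic_curves_frame():
    stx = fig7_structure("fitness_proportional")
    df = analytic_curves(np.arange(0, 20), stx, alpha=0.01, gamma=0.2,
                         M_count=50)
    assert list(df.columns) == ["k", "scenario", "E_bmd", "Std_bmd", "E_bp"]
    assert len(df) == 20
    assert (df["E_bmd"] >= 0).all()


# ---------------------------------------------------------------------------
# simulation cross-check (well-mixed)
# ---------------------------------------------------------------------------

def test_wellmixed_simulation_tracks_model():
    """Empirical B_md from non-spatial birth-death runs follows the
    closed-form expectation in rank and overall magnitude. The analytic
    model is an asymptotic approximation (deterministic order map,
    infinite-population detectability), so agreement at N=4000 is
    structural, not exact."""
    from scipy.stats import spearmanr

    from metdiv.branching import empirical_bmd

    pairs = empirical_bmd(4000, f=0.02, u=0.15, rho=0.72, n_replicates=80,
                          rng=np.random.default_rng(5))
    emp = np.array([b for _, b in pairs], dtype=float)
    ana = np.array([expected_bmd_neutral(int(k), 0.02, 0.72, 0.15)
                    for k, _ in pairs])
    assert 0.4 < emp.mean() / ana.mean() < 1.3
    assert spearmanr(emp, ana).statistic > 0.3
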