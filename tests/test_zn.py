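import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from znsh import (
    FrustratedHop,
    LinearCrossingModel,
    ZNInputs,
    diabatize_crossing,
    hop_adjust_momentum,
    lz_probability,
    mass_scaled_difference_sq,
    mass_scaled_product,
    zn_parameters,
    zn_probability,
    zn_single_passage_probability,
)


# ---------------------------------------------------------------------------
# mass-scaled force reductions
# ---------------------------------------------------------------------------

def brute_force_product(F1, F2, masses):
    total = 0.0
    for i, m in enumerate(masses):
        for a in range(F1.shape[1]):
            total += F2[i, a] * F1[i, a] / m
    return total


def brute_force_difference_sq(F1, F2, masses):
    total = 0.0
    for i, m in enumerate(masses):
        for a in range(F1.shape[1]):
            total += (F2[i, a] - F1[i, a]) ** 2 / m
    return total


def test_mass_scaled_reductions_simple_cases():
    assert mass_scaled_product([1, 0, 0], [1, 0, 0], [2.0]) == pytest.approx(0.5)
    assert mass_scaled_product([1, 0, 0], [0, 1, 0], [2.0]) == pytest.approx(0.0)
    assert mass_scaled_difference_sq([1.0], [1.0], [3.0]) == 0.0
    assert mass_scaled_difference_sq([0.0], [2.0], [4.0]) == pytest.approx(1.0)


@settings(max_examples=30, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_mass_scaled_reductions_match_double_loop(seed):
    rng = np.random.default_rng(seed)
    F1 = rng.normal(size=(2, 3))
    F2 = rng.normal(size=(2, 3))
    masses = np.array([12.0, 1.0]) * 1822.888
    assert mass_scaled_product(F1, F2, masses) == pytest.approx(
        brute_force_product(F1, F2, masses), rel=1e-12
    )
    d2 = mass_scaled_difference_sq(F1, F2, masses)
    assert d2 == pytest.approx(brute_force_difference_sq(F1, F2, masses), rel=1e-12)
    assert d2 >= 0


def test_dimension_mismatch_rejected():
    with pytest.raises(ValueError):
        mass_scaled_product([1, 2, 3], [1, 2], [1.0])


# ---------------------------------------------------------------------------
# a^2, b^2 and the probability
# ---------------------------------------------------------------------------

def test_parameters_closed_form_on_linear_crossing():
    """a^2 and b^2 match an independent symbolic substitution for a
    linear crossing with same-sign diabatic slopes."""
    s1, s2, V, mu, E = -0.004, -0.011, 0.002, 1800.0, 0.01
    res = zn_single_passage_probability(s1, s2, V, mu, E)
    F1, F2 = abs(s1), abs(s2)
    dF = abs(s2 - s1)
    a_sq_expected = math.sqrt(F1 * F2) * dF / (2.0 * mu * (2 * V) ** 3)
    b_sq_expected = E * dF / (math.sqrt(F1 * F2) * 2 * V)
    assert res.a_sq == pytest.approx(a_sq_expected, rel=1e-12)
    assert res.b_sq == pytest.approx(b_sq_expected, rel=1e-12)
    assert res.branch == +1


def test_degenerate_parallel_forces_give_zero_probability():
    inputs = ZNInputs(F1=0.01, F2=0.01, V12=0.002, Ex=0.0, Et=0.01)
    res = zn_parameters(inputs, G=1e-4, D_sq=0.0)
    assert res.a_sq == 0.0 and res.b_sq == 0.0 and res.probability == 0.0


def test_power_counting_in_coupling():
    """Doubling V12 scales a^2 by 1/8 and |b^2| by 1/2."""
    G, D_sq = 3.2e-8, 5.0e-8
    r1 = zn_parameters(ZNInputs(F1=1, F2=1, V12=0.002, Ex=0.0, Et=0.02), G, D_sq)
    r2 = zn_parameters(ZNInputs(F1=1, F2=1, V12=0.004, Ex=0.0, Et=0.02), G, D_sq)
    assert r2.a_sq == pytest.approx(r1.a_sq / 8.0, rel=1e-12)
    assert abs(r2.b_sq) == pytest.approx(abs(r1.b_sq) / 2.0, rel=1e-12)


def test_nonlz_topology_uses_magnitude_of_force_product():
    """Opposite-sign diabatic forces (intersection topology) are flagged
    but still produce a valid probability via |G|."""
    inputs = ZNInputs(F1=0.01, F2=0.01, V12=0.002, Ex=0.0, Et=0.01)
    pos = zn_parameters(inputs, G=2.0e-8, D_sq=5.0e-8)
    neg = zn_parameters(inputs, G=-2.0e-8, D_sq=5.0e-8)
    assert neg.a_sq == pytest.approx(pos.a_sq)
    assert neg.probability == pytest.approx(pos.probability)


def test_probability_reference_value():
    # direct high-precision evaluation of the closed form at a^2 = b^2 = 1
    expected = math.exp(-(math.pi / 4.0) * math.sqrt(2.0 / (1.0 + math.sqrt(2.0))))
    assert expected == pytest.approx(0.4893, abs=1e-4)
    assert zn_probability(1.0, 1.0, +1) == pytest.approx(expected, rel=1e-12)


def test_probability_limits():
    # adiabatic (strong-coupling) limit
    assert zn_probability(1e-10, 1.0, +1) < 1e-12
    # high collision energy -> diabatic limit
    assert zn_probability(1.0, 1e8, +1) == pytest.approx(1.0, abs=1e-3)
    with pytest.raises(ValueError):
        zn_probability(0.0, 1.0)


def test_probability_continuous_and_monotone_in_collision_energy():
    """p(Et) is continuous across Et = Ex and non-decreasing for an
    LZ-type crossing."""
    G, D_sq, V12, Ex = 3.0e-8, 6.0e-8, 0.0015, 0.05
    ets = np.linspace(Ex - 0.02, Ex + 0.05, 1401)
    ps = [
        zn_parameters(ZNInputs(F1=1, F2=1, V12=V12, Ex=Ex, Et=et), G, D_sq).probability
        for et in ets
    ]
    ps = np.array(ps)
    assert np.all(np.diff(ps) >= -1e-14)
    assert np.max(np.abs(np.diff(ps))) < 0.01  # no jump at the branch point
    below = zn_parameters(ZNInputs(F1=1, F2=1, V12=V12, Ex=Ex, Et=Ex - 1e-9), G, D_sq)
    above = zn_parameters(ZNInputs(F1=1, F2=1, V12=V12, Ex=Ex, Et=Ex + 1e-9), G, D_sq)
    assert below.branch == -1 and above.branch == +1
    assert below.probability == pytest.approx(above.probability, abs=1e-6)


def test_tunneling_branch_clamps_to_zero():
    # deep below the crossing the - branch yields p = 0
    assert zn_probability(0.5, -3.0, -1) == 0.0


# ---------------------------------------------------------------------------
# diabatization at a gap minimum
# ---------------------------------------------------------------------------

def test_diabatize_recovers_linear_model():
    model = LinearCrossingModel(-0.006, 0.02, 0.002, 2000.0)
    width = 2 * model.coupling / abs(model.slope_2 - model.slope_1)
    for h in (0.3 * width, 10.0 * width):
        F1, F2, V12, Ex = diabatize_crossing(
            model.evaluate([-h]), model.evaluate([0.0]), model.evaluate([h])
        )
        assert V12 == pytest.approx(model.coupling, rel=0.02)
        assert Ex == pytest.approx(0.0, abs=1e-12)  # symmetric crossing energy
        dF = np.linalg.norm(F2 - F1)
        assert dF == pytest.approx(abs(model.slope_2 - model.slope_1), rel=0.05)
        slopes = sorted([-float(F1[0]), -float(F2[0])])
        assert slopes == pytest.approx([model.slope_1, model.slope_2], rel=0.05)


def test_diabatize_requires_bracketing_minimum():
    model = LinearCrossingModel(-0.006, 0.02, 0.002, 2000.0)
    with pytest.raises(ValueError, match="bracket"):
        diabatize_crossing(
            model.evaluate([0.1]), model.evaluate([0.2]), model.evaluate([0.3])
        )


# ---------------------------------------------------------------------------
# momentum adjustment at hops
# ---------------------------------------------------------------------------

def kinetic(v, m):
    return 0.5 * float(np.sum(np.asarray(m) * np.asarray(v) ** 2))


def test_hop_adjust_identity_for_zero_gap():
    v = np.array([0.003, -0.001, 0.002])
    out = hop_adjust_momentum(v, np.full(3, 1836.0), np.array([1.0, 0, 0]), 0.0)
    assert np.array_equal(out, v)


@pytest.mark.parametrize("deltaE", [2e-3, -1e-4])
def test_hop_adjust_conserves_energy_exactly(deltaE):
    rng = np.random.default_rng(4)
    v = rng.normal(scale=1e-3, size=4)
    m = np.array([1836.0, 1836.0, 4000.0, 4000.0])
    d = rng.normal(size=4)
    d /= np.linalg.norm(d)
    out = hop_adjust_momentum(v, m, d, deltaE)
    assert kinetic(out, m) - kinetic(v, m) == pytest.approx(deltaE, abs=1e-10)
    # only the component along d changed
    perp = v - np.dot(v, d) * d
    perp_out = out - np.dot(out, d) * d
    assert np.allclose(perp, perp_out, atol=1e-14)


def test_frustrated_hop_raises_and_preserves_velocities():
    v = np.array([1e-5])
    m = np.array([1836.0])
    with pytest.raises(FrustratedHop):
        hop_adjust_momentum(v, m, np.array([1.0]), -0.1)
    assert v[0] == 1e-5  # untouched


def test_zero_direction_rejected():
    with pytest.raises(ValueError):
        hop_adjust_momentum([1e-3], [1836.0], [0.0], 1e-3)


# ---------------------------------------------------------------------------
# Landau-Zener limit
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("energy", [0.03, 0.045, 0.06])
def test_weak_coupling_high_energy_reduces_to_landau_zener(energy):
    s1, s2, V, mu = -0.001, -0.010, 0.0008, 1000.0
    p_zn = zn_single_passage_probability(s1, s2, V, mu, energy).probability
    v = math.sqrt(2.0 * energy / mu)
    p_lz = lz_probability(v, s2 - s1, V)
    assert p_zn == pytest.approx(p_lz, rel=0.05)
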