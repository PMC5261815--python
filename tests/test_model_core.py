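"""Flux laws, the assembled right-hand side, and its conservation structure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ferroflux as ff
from ferroflux.model import rhs, state_index


# ----------------------------------------------------------------------
# elementary flux laws
# ----------------------------------------------------------------------

@pytest.mark.parametrize("rate, pool, expected", [
    (0.0, 123.0, 0.0),
    (0.2, 100.0, 20.0),
])
def test_flux_linear_values(rate, pool, expected):
    assert ff.flux_linear(rate, pool) == pytest.approx(expected)


def test_flux_linear_is_linear_in_pool():
    v = 0.37
    assert ff.flux_linear(v, 3.0 + 11.0) == pytest.approx(
        ff.flux_linear(v, 3.0) + ff.flux_linear(v, 11.0))


@pytest.mark.parametrize("u, pool, fpn, expected", [
    (0.5, 10.0, 0.0, 0.0),     # no ferroportin, no export
    (1.0, 10.0, 2.0, 20.0),
])
def test_flux_export_values(u, pool, fpn, expected):
    assert ff.flux_export(u, pool, fpn) == pytest.approx(expected)


def test_flux_export_bilinear_in_fpn():
    assert ff.flux_export(0.3, 7.0, 4.0) == pytest.approx(
        2 * ff.flux_export(0.3, 7.0, 2.0))


def test_duodenal_uptake_half_saturation_and_limit():
    assert ff.duodenal_uptake(5.0, 36.0, 5.0) == pytest.approx(18.0)
    assert ff.duodenal_uptake(1e9, 36.0, 5.0) == pytest.approx(36.0, rel=1e-6)


def test_duodenal_uptake_high_diet_with_kduo_five_times_normal():
    # K_duo = 5 x normal diet: uptake at 100 x normal is V * 100/105,
    # cross-checked against a numeric sweep approaching saturation
    V, K = 36.0, 5.0
    assert ff.duodenal_uptake(100.0, V, K) == pytest.approx(V * 100 / 105)
    sweep = [ff.duodenal_uptake(f, V, K) for f in (10, 100, 1000, 10000)]
    assert all(np.diff(sweep) > 0) and sweep[-1] < V


def test_liver_export_cap():
    u, fpn, cap = 0.01, 1.3, 200.0
    below = ff.liver_export(u, fpn, 150.0, cap)
    assert below == pytest.approx(ff.flux_export(u, 150.0, fpn))
    assert ff.liver_export(u, fpn, 2 * cap, cap) == pytest.approx(
        ff.liver_export(u, fpn, cap, cap))


def test_liver_export_monotone_continuous_in_liver_iron():
    grid = np.linspace(0.0, 600.0, 2001)
    flux = np.array([ff.liver_export(0.01, 1.0, fe, 200.0) for fe in grid])
    assert np.all(np.diff(flux) >= 0)
    assert np.max(np.abs(np.diff(flux))) < 0.01 * 1.0 * (grid[1] - grid[0]) * 1.01


def test_liver_import_limits():
    v, vN, K = 0.18, 1.0, 6.0
    assert ff.liver_import(3.0, v, 0.0, K) == pytest.approx(v * 3.0)
    tiny = 1e-6 * K
    assert ff.liver_import(tiny, v, vN, K) / tiny == pytest.approx(v, rel=1e-4)
    big = 1e3 * K
    assert ff.liver_import(big, v, vN, K) == pytest.approx((v + vN) * big, rel=2e-3)


def test_fpn_mrna_rate_balance_and_inhibition():
    a, K, d = 0.35, 0.02, 0.35
    assert ff.fpn_mrna_rate(a, 0.0, K, d, a / d) == pytest.approx(0.0)
    # LPS at the inhibition constant halves synthesis
    assert ff.fpn_mrna_rate(a, K, K, d, 0.0) == pytest.approx(a / 2)
    # saturating LPS: pure exponential decay at d_mRNA
    assert ff.fpn_mrna_rate(a, 1e9, K, d, 2.0) == pytest.approx(-d * 2.0, rel=1e-6)


def test_fpn_protein_rate_hepcidin_action():
    kw = dict(b_o=0.1, Fe_organ=65.0, K_IRE=2.0, mRNA=1.0, k1=0.02, Fpn=1.0)
    base = ff.fpn_protein_rate(k2_o=0.075, Hep=0.0, **kw)
    assert base == pytest.approx(0.1 * 65 / 67 - 0.02)
    # C326S: dynamics independent of hepcidin
    assert ff.fpn_protein_rate(k2_o=0.0, Hep=50.0, **kw) == pytest.approx(base)
    # doubling hepcidin adds exactly k2 * Hep to the degradation rate
    r1 = ff.fpn_protein_rate(k2_o=0.075, Hep=1.0, **kw)
    r2 = ff.fpn_protein_rate(k2_o=0.075, Hep=2.0, **kw)
    assert r1 - r2 == pytest.approx(0.075 * 1.0 * kw["Fpn"])


@pytest.mark.parametrize("func, args", [
    (ff.flux_linear, (-1.0, 1.0)),
    (ff.flux_export, (1.0, -1.0, 1.0)),
    (ff.duodenal_uptake, (1.0, 1.0, 0.0)),
    (ff.liver_import, (1.0, 1.0, 1.0, -2.0)),
    (ff.fpn_mrna_rate, (0.1, -0.5, 0.02, 0.3, 1.0)),
])
def test_domain_errors(func, args):
    with pytest.raises(ValueError):
        func(*args)


# ----------------------------------------------------------------------
# structure
# ----------------------------------------------------------------------

def test_structural_counts():
    assert len(ff.STATE_NAMES) == 20
    assert len(ff.KINETIC_PARAM_NAMES) == 48
    assert len(set(ff.STATE_NAMES)) == 20
    with pytest.raises(KeyError):
        state_index("Fe_brain")


def test_all_rates_zero_gives_zero_derivative(ref_params):
    zeros = {n: 0.0 for n in ff.KINETIC_PARAM_NAMES
             if not n.startswith("K")}
    p = ref_params.replace(**zeros)
    y = np.abs(np.random.default_rng(0).normal(size=20))
    assert np.allclose(rhs(0.0, y, p), 0.0)


def test_bone_marrow_balance_is_mass_action(ref_params, rng):
    """d(Fe_bm)/dt = v_bm*Fe_serum - v_RBC*Fe_bm - v_splBM*Fe_bm."""
    p = ref_params
    i_bm = state_index("Fe_bm")
    for _ in range(25):
        y = rng.uniform(0.0, 50.0, size=20)
        expected = p.v_bm * y[0] - (p.v_RBC + p.v_splBM) * y[i_bm]
        assert rhs(0.0, y, p)[i_bm] == pytest.approx(expected, rel=1e-12)


def test_total_iron_mass_balance_on_random_states(ref_params, rng):
    """Summed iron derivatives = dietary uptake - shedding - skin loss."""
    p = ref_params
    for _ in range(100):
        y = rng.uniform(0.0, 200.0, size=20)
        dy = rhs(0.0, y, p)
        uptake = ff.duodenal_uptake(p.Fe_food, p.V_duo, p.K_duo)
        losses = p.l_duo * y[3] + p.l_other * y[6]
        assert dy[:7].sum() == pytest.approx(uptake - losses, rel=1e-9, abs=1e-12)


def test_rhs_rejects_nan(ref_params):
    y = np.ones(20)
    y[5] = np.nan
    with pytest.raises(FloatingPointError):
        rhs(0.0, y, ref_params)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10**6))
def test_trajectories_stay_nonnegative(seed):
    """Random non-negative starts: all species stay >= -1e-9 along the run."""
    p = ff.reference_parameters()
    gen = np.random.default_rng(seed)
    y0 = ff.steady_state(p) * gen.uniform(0.2, 5.0, size=20)
    traj = ff.integrate(p, y0, np.linspace(0.0, 500.0, 26))
    assert traj.states.min() >= -1e-9
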