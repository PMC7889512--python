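"""Flux laws, residual assembly, and conservation identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import veinflow as vf
from veinflow.toynets import chain_layout, grid2x2_layout, random_toy_layout
from veinflow.transport import (
    assemble_residual,
    assemble_system,
    cross_flux,
    phloem_edge_flux,
    sucrose_edge_flux,
    sucrose_loading,
    transpiration_flux,
    xylem_edge_flux,
)

finite = st.floats(-10, 10, allow_nan=False)


def test_xylem_flux_examples():
    # efflux toward a lower-pressure neighbor
    assert xylem_edge_flux(5.0, 0.0, -0.1) == pytest.approx(-0.5)
    assert xylem_edge_flux(3.0, 0.2, 0.2) == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(K=st.floats(0, 100), p1=finite, p2=finite)
def test_water_flux_antisymmetry(K, p1, p2):
    assert xylem_edge_flux(K, p1, p2) == pytest.approx(-xylem_edge_flux(K, p2, p1))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(K=st.floats(0, 10), p1=finite, p2=finite,
       c1=st.floats(0, 500), c2=st.floats(0, 500))
def test_phloem_flux_reduces_to_darcy_without_reflection(K, p1, p2, c1, c2):
    params = vf.ModelParams()  # sigma_lateral = 0
    assert phloem_edge_flux(K, p1, p2, c1, c2, params) == pytest.approx(
        xylem_edge_flux(K, p1, p2)
    )


def test_phloem_flux_osmotic_term():
    params = vf.ModelParams(sigma_lateral=1.0)
    # equal pressures, dC = 100 at 293 K: F = -K * RT * 100 = -K * 0.2435
    f = phloem_edge_flux(0.15, 0.1, 0.1, 100.0, 200.0, params)
    assert f == pytest.approx(-0.15 * 8.31e-6 * 293.0 * 100.0)
    assert f == pytest.approx(-0.15 * 0.2435, rel=1e-3)
    # plain pressure drive
    assert phloem_edge_flux(0.15, 0.0, 0.01, 0, 0, params) == pytest.approx(1.5e-3)


def test_cross_flux_muench_drive():
    params = vf.ModelParams()
    # equal hydraulic pressures: the dissolved sucrose pulls water from
    # the xylem into the phloem
    f = cross_flux(0.5, 0.1, 170.0, 0.1, params)
    assert f == pytest.approx(-0.5 * 8.31e-6 * 293.0 * 170.0)
    assert f == pytest.approx(-2.07e-1, rel=1e-2)
    assert cross_flux(0.5, 0.1, 0.0, 0.1, params) == 0.0
    assert cross_flux(0.0, 5.0, 300.0, -1.0, params) == 0.0


def test_sucrose_flux_schemes():
    lit = vf.ModelParams(sucrose_scheme="literal")
    upw = vf.ModelParams(sucrose_scheme="upwind")
    assert sucrose_edge_flux(0.0, 170.0, 170.0, 1e-15, lit) == 0.0
    # convection-dominated arithmetic: v_mu * F * C
    s = sucrose_edge_flux(1e-3, 170.0, 170.0, 0.0, lit)
    assert s == pytest.approx(18e-9 * 1e-3 * 170.0)
    assert s == pytest.approx(3.06e-9, rel=1e-3)
    # schemes differ only for inflow (F > 0) with unequal concentrations
    assert sucrose_edge_flux(1e-3, 100.0, 200.0, 0.0, lit) != pytest.approx(
        sucrose_edge_flux(1e-3, 100.0, 200.0, 0.0, upw)
    )
    assert sucrose_edge_flux(-1e-3, 100.0, 200.0, 0.0, lit) == pytest.approx(
        sucrose_edge_flux(-1e-3, 100.0, 200.0, 0.0, upw)
    )
    # both reduce to diffusion at zero flow
    assert sucrose_edge_flux(0.0, 100.0, 200.0, 1e-12, upw) == pytest.approx(1e-10)


def test_transpiration_and_loading_fluxes():
    assert transpiration_flux(-2.0, 4e-6) == pytest.approx(-8e-6)
    assert transpiration_flux(0.0, 4e-6) == 0.0
    assert sucrose_loading(2.78e-7, 4e-6) == pytest.approx(1.112e-12)


def test_leaf_totals_match_area_times_rate(ref_shape):
    params = vf.ModelParams()
    layout = vf.build_vein_layout(ref_shape, 45.0, spacing=0.002)
    E = params.transpiration_field(layout)[: layout.n]
    total = float((E * layout.area).sum())
    assert total == pytest.approx(-2.0 * 73.35e-4, rel=1e-3)
    lam = params.loading_field(layout)[: layout.n]
    assert float((lam * layout.area).sum()) == pytest.approx(2.039e-9, rel=1e-3)


def test_loading_gradient_preserves_mean(ref_shape):
    layout = vf.build_vein_layout(ref_shape, 45.0, spacing=0.002)
    uni = vf.ModelParams(loading_gradient=False)
    grad = vf.ModelParams(loading_gradient=True)
    a = layout.area
    lam_u = uni.loading_field(layout)[: layout.n]
    lam_g = grad.loading_field(layout)[: layout.n]
    assert float(lam_g @ a) == pytest.approx(float(lam_u @ a), rel=1e-12)
    # ~50% higher at the base, ~50% lower at the tip
    z = layout.xz[:, 1]
    base = lam_g[np.argmin(z)] / lam_u[0]
    tip = lam_g[np.argmax(z)] / lam_u[0]
    assert base == pytest.approx(1.5, abs=0.05)
    assert tip == pytest.approx(0.5, abs=0.05)


def test_residual_zero_at_two_node_solution():
    """Hand-solvable petiole + one node system has zero residual."""
    lay = chain_layout(1, K_edge=5.0, area=4e-6)
    params = vf.ModelParams(K_c=0.0, Lambda=0.0)
    # single Darcy equation: p1 = p0 + E a / K
    state = vf.NetworkState(
        p_xyl=np.array([-8e-6 / 5.0, 0.0]),
        p_ph=np.array([0.2, 0.2]),
        C=np.array([70.0, 70.0]),
    )
    r = assemble_residual(lay, params, state).vector()
    assert np.max(np.abs(r)) < 1e-18


def test_residual_at_zero_state_is_pure_forcing():
    lay = grid2x2_layout()
    params = vf.ModelParams()
    n = lay.n
    zero = vf.NetworkState(np.zeros(n + 1), np.zeros(n + 1), np.zeros(n + 1))
    res = assemble_residual(lay, params, zero)
    np.testing.assert_allclose(res.water_xyl[:n], params.E * lay.area)
    np.testing.assert_allclose(res.water_ph[:n], 0.0)
    np.testing.assert_allclose(res.sucrose[:n], params.Lambda * lay.area)


def test_interior_residual_sum_telescopes_to_petiole_flux():
    """Summing the xylem rows over interior nodes cancels every interior
    edge, leaving petiole influx + transpiration + cross transfer."""
    rng = np.random.default_rng(7)
    lay = random_toy_layout(rng)
    params = vf.ModelParams()
    n = lay.n
    state = vf.NetworkState(
        rng.normal(0, 0.1, n + 1), rng.normal(0.2, 0.1, n + 1), rng.uniform(10, 300, n + 1)
    )
    res = assemble_residual(lay, params, state)
    pet, first = lay.petiole, lay.first
    e = int(np.flatnonzero((lay.edges_u == pet) | (lay.edges_v == pet))[0])
    pet_influx = lay.K_xyl[e] * (state.p_xyl[pet] - state.p_xyl[first])
    Fc = params.K_c * ((state.p_ph[:n] - params.RT * state.C[:n]) - state.p_xyl[:n])
    total = pet_influx + float((params.E * lay.area).sum()) + float(Fc.sum())
    assert res.water_xyl[:n].sum() == pytest.approx(total, abs=1e-15)


@pytest.mark.parametrize("scheme", ["literal", "upwind"])
def test_jacobian_matches_finite_differences(scheme):
    lay = grid2x2_layout()
    params = vf.ModelParams(sucrose_scheme=scheme)
    N = lay.n + 1
    rng = np.random.default_rng(3)
    x = np.concatenate(
        [rng.normal(0, 0.1, N), rng.normal(0.2, 0.1, N), rng.uniform(50, 150, N)]
    )
    r, J = assemble_system(lay, params, x)
    J = J.toarray()
    Jfd = np.zeros_like(J)
    for k in range(3 * N):
        eps = 1e-6 * max(1.0, abs(x[k]))
        xp, xm = x.copy(), x.copy()
        xp[k] += eps
        xm[k] -= eps
        Jfd[:, k] = (assemble_system(lay, params, xp)[0]
                     - assemble_system(lay, params, xm)[0]) / (2 * eps)
    assert np.abs(J - Jfd).max() < 1e-6 * np.abs(Jfd).max()


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        vf.ModelParams(T=-1.0)
    with pytest.raises(ValueError):
        vf.ModelParams(K_c=-0.1)
    with pytest.raises(ValueError):
        vf.ModelParams(sucrose_scheme="quickest")
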