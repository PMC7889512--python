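"""Physical parameters, network state, flux laws, and residual assembly.

The steady state of the coupled xylem-phloem network is the root of a
nonlinear system with three unknowns per node: xylem hydraulic pressure
p_xyl (MPa), phloem total pressure p_ph (MPa), and phloem sucrose
concentration C (mol m^-3).  Per interior node the residuals are

* xylem water balance:   sum_d F_xyl + E a + F_c = 0
* phloem water balance:  sum_d F_ph  - F_c       = 0
* sucrose balance:       sum_d S     + Lambda a  = 0

with Darcy edge fluxes F = K dp, an osmotically driven cross-conduit
flux F_c = K_c ((p_ph - sigma_c R T C) - p_xyl) into the xylem node
(Muench coupling), and sucrose carried by convection plus diffusion,
S = (1 - sigma) v_mu F_ph C + G dC.  At the petiole the pressures are
Dirichlet and the sucrose condition is zero-Neumann (petiole
concentration pinned to its neighbor; convective export remains).

Sign convention: every node-centric flux is positive INTO the node, so a
transpiring leaf has E < 0.  Units are MPa, m, s, mmol (water), mol
(sucrose) throughout; with R = 8.31e-6 MPa m^3 mol^-1 K^-1 the product
R*T*C is an osmotic pressure in MPa directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
from scipy import sparse

from .leafgeom import VEIN_DIAMETER, XYLEM_CONDUCTIVITY

__all__ = [
    "ModelParams",
    "NetworkState",
    "ResidualVector",
    "xylem_edge_flux",
    "phloem_edge_flux",
    "cross_flux",
    "sucrose_edge_flux",
    "transpiration_flux",
    "sucrose_loading",
    "assemble_residual",
    "assemble_system",
    "balance_report",
]


@dataclass
class ModelParams:
    """All physical constants, rates, and boundary values.

    Defaults are the core model values; the commonly exercised
    alternatives are E in {-1, 0}, the linear loading gradient, K_c =
    5e-4 (network isolation), petiole pressures (-2.0, -1.8), and
    per-order conductivity overrides (e.g. 5x / 0.2x on order 2).
    """

    R: float = 8.31e-6            # gas constant, MPa m^3 mol^-1 K^-1
    T: float = 293.0              # leaf temperature, K
    D_su: float = 5.22e-10        # sucrose diffusivity, m^2 s^-1
    v_mu: float = 18.00e-9        # molal volume of water, m^3 mmol^-1
    K_c: float = 0.50             # xylem-phloem conduit conductance, mmol s^-1 MPa^-1
    sigma_lateral: float = 0.0    # reflection coefficient along phloem conduits
    sigma_cross: float = 1.0      # reflection coefficient of the cross conduit
    E: Union[float, np.ndarray] = -2.00      # transpiration rate, mmol s^-1 m^-2
    Lambda: Union[float, np.ndarray] = 2.78e-7  # sucrose loading, mol s^-1 m^-2
    loading_gradient: bool = False  # linear +50% base to -50% tip, same mean
    p_petiole_xyl: float = 0.00   # MPa
    p_petiole_ph: float = 0.20    # MPa
    sucrose_scheme: str = "literal"   # 'literal' | 'upwind'
    phloem_factor: float = 0.03   # K_ph / K_xyl
    conductivity: dict = field(default_factory=lambda: dict(XYLEM_CONDUCTIVITY))
    diameters: dict = field(default_factory=lambda: dict(VEIN_DIAMETER))

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.K_c < 0:
            raise ValueError("cross-conduit conductance must be non-negative")
        if self.sucrose_scheme not in ("literal", "upwind"):
            raise ValueError(f"unknown sucrose scheme {self.sucrose_scheme!r}")
        if any(v < 0 for v in self.conductivity.values()):
            raise ValueError("conductivities must be non-negative")

    @property
    def RT(self) -> float:
        return self.R * self.T

    def with_conductivity(self, order: int, value: float) -> "ModelParams":
        """Copy of the parameters with one vein order's conductivity replaced."""
        table = dict(self.conductivity)
        table[order] = value
        return replace(self, conductivity=table)

    def transpiration_field(self, layout) -> np.ndarray:
        """Per-node transpiration rate (length n+1, petiole entry 0)."""
        n = layout.n
        out = np.zeros(n + 1)
        out[:n] = self.E
        return out

    def loading_field(self, layout) -> np.ndarray:
        """Per-node sucrose loading rate (length n+1, petiole entry 0).

        With ``loading_gradient`` the rate varies linearly from 1.5x the
        mean at the leaf base to 0.5x at the tip and is renormalized so
        the leaf-area-weighted mean matches the uniform field exactly.
        """
        n = layout.n
        out = np.zeros(n + 1)
        if not self.loading_gradient:
            out[:n] = self.Lambda
            return out
        if layout.shape is None:
            raise ValueError("loading gradient requires a leaf layout with an outline")
        z = layout.xz[:, 1]
        lam = self.Lambda * (1.5 - z / layout.shape.length)
        a = layout.area
        lam *= self.Lambda * a.sum() / float(lam @ a)
        out[:n] = lam
        return out


@dataclass
class NetworkState:
    """Unknown fields on every interior node plus the petiole (id n)."""

    p_xyl: np.ndarray
    p_ph: np.ndarray
    C: np.ndarray

    def vector(self) -> np.ndarray:
        return np.concatenate([self.p_xyl, self.p_ph, self.C])

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "NetworkState":
        N = len(x) // 3
        return cls(x[:N].copy(), x[N:2 * N].copy(), x[2 * N:].copy())

    @property
    def n_nodes(self) -> int:
        return len(self.p_xyl)


@dataclass
class ResidualVector:
    """Per-node conservation residuals plus the petiole boundary rows."""

    water_xyl: np.ndarray   # mmol s^-1 (petiole row: Dirichlet, MPa)
    water_ph: np.ndarray    # mmol s^-1 (petiole row: Dirichlet, MPa)
    sucrose: np.ndarray     # mol s^-1  (petiole row: Neumann, mol m^-3)

    def vector(self) -> np.ndarray:
        return np.concatenate([self.water_xyl, self.water_ph, self.sucrose])


# ---------------------------------------------------------------------------
# Edge and node flux laws
# ---------------------------------------------------------------------------


def xylem_edge_flux(K, p_ij, p_d):
    """Darcy flux (mmol s^-1) into node ij from its neighbor d."""
    return K * (p_d - p_ij)


def phloem_edge_flux(K, p_ij, p_d, C_ij, C_d, params: ModelParams):
    """Phloem water flux into node ij, with the osmotic term scaled by
    the lateral reflection coefficient (0 by default: free solute
    passage reduces this to pure Darcy flow)."""
    return K * ((p_d - p_ij) - params.sigma_lateral * params.RT * (C_d - C_ij))


def cross_flux(K_c, p_ph, C_ph, p_xyl, params: ModelParams):
    """Water flux (mmol s^-1) from the phloem into the xylem node.

    Negative values mean water is drawn from the xylem into the phloem,
    which the dissolved sucrose does whenever the hydraulic pressures
    are equal (Muench mechanism).
    """
    return K_c * ((p_ph - params.sigma_cross * params.RT * C_ph) - p_xyl)


def sucrose_edge_flux(F_ph, C_ij, C_d, G, params: ModelParams):
    """Sucrose flux (mol s^-1) into node ij from neighbor d.

    ``literal`` uses the from-node concentration C_ij in the convective
    term for both flow directions; ``upwind`` uses the donor-cell
    concentration (the node water flows from), which makes pairwise
    fluxes antisymmetric and hence exactly mass-conserving.
    """
    alpha = (1.0 - params.sigma_lateral) * params.v_mu
    if params.sucrose_scheme == "upwind":
        C_conv = np.where(np.asarray(F_ph) > 0, C_d, C_ij)
    else:
        C_conv = C_ij
    return alpha * F_ph * C_conv + G * (C_d - C_ij)


def transpiration_flux(E, a_ij):
    """Transpiration flux E * a (mmol s^-1); negative for a transpiring leaf."""
    return E * a_ij


def sucrose_loading(lam, a_ij):
    """Sucrose loading flux Lambda * a (mol s^-1)."""
    return lam * a_ij


# ---------------------------------------------------------------------------
# Residual and Jacobian assembly
# ---------------------------------------------------------------------------


def _require_conductances(layout):
    if layout.K_xyl is None:
        raise ValueError("layout has no conductances; call assign_conductances first")


def _edge_fluxes(layout, params, px, pp, C):
    u, v = layout.edges_u, layout.edges_v
    fx = layout.K_xyl * (px[v] - px[u])
    fp = layout.K_ph * ((pp[v] - pp[u]) - params.sigma_lateral * params.RT * (C[v] - C[u]))
    return fx, fp


def assemble_residual(layout, params: ModelParams, state: NetworkState) -> ResidualVector:
    """Evaluate the steady-state residuals for a given state.

    Identically zero exactly at a steady-state solution.  Petiole rows
    hold the two Dirichlet pressure residuals and the zero-Neumann
    sucrose residual C_petiole - C_first.
    """
    _require_conductances(layout)
    n = layout.n
    N = n + 1
    px, pp, C = state.p_xyl, state.p_ph, state.C
    if len(px) != N:
        raise ValueError(f"state has {len(px)} nodes, layout needs {N}")
    u, v = layout.edges_u, layout.edges_v
    fx, fp = _edge_fluxes(layout, params, px, pp, C)

    r1 = np.zeros(N)
    np.add.at(r1, u, fx)
    np.add.at(r1, v, -fx)
    kc = np.zeros(N)
    kc[:n] = params.K_c
    Fc = kc * ((pp - params.sigma_cross * params.RT * C) - px)
    r1 += params.transpiration_field(layout) * np.append(layout.area, 0.0) + Fc

    r2 = np.zeros(N)
    np.add.at(r2, u, fp)
    np.add.at(r2, v, -fp)
    r2 -= Fc

    alpha = (1.0 - params.sigma_lateral) * params.v_mu
    G = layout.G_ph
    if params.sucrose_scheme == "upwind":
        C_don = np.where(fp > 0, C[v], C[u])
        Su = alpha * fp * C_don + G * (C[v] - C[u])
        Sv = -alpha * fp * C_don + G * (C[u] - C[v])
    else:
        Su = alpha * fp * C[u] + G * (C[v] - C[u])
        Sv = -alpha * fp * C[v] + G * (C[u] - C[v])
    r3 = np.zeros(N)
    np.add.at(r3, u, Su)
    np.add.at(r3, v, Sv)
    r3 += params.loading_field(layout) * np.append(layout.area, 0.0)

    pet = layout.petiole
    r1[pet] = px[pet] - params.p_petiole_xyl
    r2[pet] = pp[pet] - params.p_petiole_ph
    r3[pet] = C[pet] - C[layout.first]
    return ResidualVector(r1, r2, r3)


def assemble_system(layout, params: ModelParams, x: np.ndarray):
    """Residual vector and analytic sparse Jacobian at unknown vector x.

    Unknown ordering is [p_xyl; p_ph; C], each block of length n+1 with
    the petiole last.  The system is polynomial of degree 2 (through the
    F_ph * C convective term), so the Jacobian is exact and cheap.
    """
    _require_conductances(layout)
    n = layout.n
    N = n + 1
    state = NetworkState.from_vector(x)
    res = assemble_residual(layout, params, state)

    px, pp, C = state.p_xyl, state.p_ph, state.C
    u, v = layout.edges_u, layout.edges_v
    Kx, Kp, G = layout.K_xyl, layout.K_ph, layout.G_ph
    RT = params.RT
    sl, sc = params.sigma_lateral, params.sigma_cross
    alpha = (1.0 - sl) * params.v_mu
    fp = Kp * ((pp[v] - pp[u]) - sl * RT * (C[v] - C[u]))

    rows, cols, vals = [], [], []

    def add(r, c, val):
        rows.append(r)
        cols.append(c)
        vals.append(val)

    # --- xylem water rows (block offset 0), columns px:0, pp:N, C:2N
    add(u, u, -Kx)
    add(u, v, Kx)
    add(v, v, -Kx)
    add(v, u, Kx)
    ii = np.arange(n)
    kc = params.K_c
    add(ii, ii, np.full(n, -kc))
    add(ii, N + ii, np.full(n, kc))
    add(ii, 2 * N + ii, np.full(n, -kc * sc * RT))

    # --- phloem water rows (offset N)
    add(N + u, N + u, -Kp)
    add(N + u, N + v, Kp)
    add(N + v, N + v, -Kp)
    add(N + v, N + u, Kp)
    if sl != 0.0:
        add(N + u, 2 * N + u, Kp * sl * RT)
        add(N + u, 2 * N + v, -Kp * sl * RT)
        add(N + v, 2 * N + v, Kp * sl * RT)
        add(N + v, 2 * N + u, -Kp * sl * RT)
    add(N + ii, N + ii, np.full(n, -kc))
    add(N + ii, ii, np.full(n, kc))
    add(N + ii, 2 * N + ii, np.full(n, kc * sc * RT))

    # --- sucrose rows (offset 2N)
    if params.sucrose_scheme == "upwind":
        donor_is_v = fp > 0
        C_don = np.where(donor_is_v, C[v], C[u])
        # d(fp)/d(pp_v) = Kp, d(fp)/d(pp_u) = -Kp (sl-terms handled below)
        add(2 * N + u, N + v, alpha * Kp * C_don)
        add(2 * N + u, N + u, -alpha * Kp * C_don)
        add(2 * N + v, N + v, -alpha * Kp * C_don)
        add(2 * N + v, N + u, alpha * Kp * C_don)
        dSu_dCu = np.where(donor_is_v, 0.0, alpha * fp) - G
        dSu_dCv = np.where(donor_is_v, alpha * fp, 0.0) + G
        if sl != 0.0:
            dSu_dCu = dSu_dCu + alpha * C_don * Kp * sl * RT
            dSu_dCv = dSu_dCv - alpha * C_don * Kp * sl * RT
        add(2 * N + u, 2 * N + u, dSu_dCu)
        add(2 * N + u, 2 * N + v, dSu_dCv)
        dSv_dCv = np.where(donor_is_v, -alpha * fp, 0.0) - G
        dSv_dCu = np.where(donor_is_v, 0.0, -alpha * fp) + G
        if sl != 0.0:
            dSv_dCv = dSv_dCv - alpha * C_don * Kp * sl * RT
            dSv_dCu = dSv_dCu + alpha * C_don * Kp * sl * RT
        add(2 * N + v, 2 * N + v, dSv_dCv)
        add(2 * N + v, 2 * N + u, dSv_dCu)
    else:
        add(2 * N + u, N + v, alpha * Kp * C[u])
        add(2 * N + u, N + u, -alpha * Kp * C[u])
        add(2 * N + v, N + v, -alpha * Kp * C[v])
        add(2 * N + v, N + u, alpha * Kp * C[v])
        dSu_dCu = alpha * fp - G
        dSu_dCv = G * np.ones_like(fp)
        dSv_dCv = -alpha * fp - G
        dSv_dCu = G * np.ones_like(fp)
        if sl != 0.0:
            dSu_dCu = dSu_dCu + alpha * C[u] * Kp * sl * RT
            dSu_dCv = dSu_dCv - alpha * C[u] * Kp * sl * RT
            dSv_dCv = dSv_dCv - alpha * C[v] * Kp * sl * RT
            dSv_dCu = dSv_dCu + alpha * C[v] * Kp * sl * RT
        add(2 * N + u, 2 * N + u, dSu_dCu)
        add(2 * N + u, 2 * N + v, dSu_dCv)
        add(2 * N + v, 2 * N + v, dSv_dCv)
        add(2 * N + v, 2 * N + u, dSv_dCu)

    def _flat(seq):
        return np.concatenate(
            [np.ravel(np.broadcast_to(s, np.broadcast_shapes(np.shape(s), np.shape(val))))
             for s, val in zip(seq, vals)]
        )

    rows = _flat(rows)
    cols_arr = _flat(cols)
    vals_arr = _flat(vals)

    # drop any accumulation into the three petiole rows, then add the
    # boundary-condition rows
    pet = layout.petiole
    bc_rows = {pet, N + pet, 2 * N + pet}
    keep = ~np.isin(rows, list(bc_rows))
    rows, cols_arr, vals_arr = rows[keep], cols_arr[keep], vals_arr[keep]

    bc_r = np.array([pet, N + pet, 2 * N + pet, 2 * N + pet])
    bc_c = np.array([pet, N + pet, 2 * N + pet, 2 * N + layout.first])
    bc_v = np.array([1.0, 1.0, 1.0, -1.0])
    rows = np.concatenate([rows, bc_r])
    cols_arr = np.concatenate([cols_arr, bc_c])
    vals_arr = np.concatenate([vals_arr, bc_v])

    J = sparse.coo_matrix((vals_arr, (rows, cols_arr)), shape=(3 * N, 3 * N)).tocsr()
    return res.vector(), J


# ---------------------------------------------------------------------------
# Balance diagnostics
# ---------------------------------------------------------------------------


def _petiole_edge(layout):
    pet = layout.petiole
    mask = (layout.edges_u == pet) | (layout.edges_v == pet)
    idx = np.flatnonzero(mask)
    if len(idx) != 1:
        raise ValueError(f"expected exactly one petiole conduit, found {len(idx)}")
    return int(idx[0])


def balance_report(layout, params: ModelParams, state: NetworkState) -> dict:
    """Whole-leaf conservation closures at a (converged) state.

    Checks that xylem water entering at the petiole equals transpiration
    plus net xylem-to-phloem transfer, that the phloem petiole outflow
    equals the net cross-conduit transfer, and compares sucrose export
    at the petiole with total loading.  Under the upwind scheme the
    sucrose gap is zero to solver precision; under the literal scheme
    the pairwise convective term is not antisymmetric and the resulting
    conservation gap is reported, not hidden.
    """
    n = layout.n
    px, pp, C = state.p_xyl, state.p_ph, state.C
    e = _petiole_edge(layout)
    pet, first = layout.petiole, layout.first
    # K (p_pet - p_first) is the influx into the interior regardless of
    # the stored edge orientation
    xylem_inflow = layout.K_xyl[e] * (px[pet] - px[first])
    phloem_inflow = layout.K_ph[e] * (pp[pet] - pp[first])
    F_ph_first_pet = layout.K_ph[e] * (pp[pet] - pp[first])

    kc = params.K_c
    Fc = kc * ((pp[:n] - params.sigma_cross * params.RT * C[:n]) - px[:n])
    total_cross_into_xylem = float(Fc.sum())
    total_transpiration = float((params.transpiration_field(layout)[:n] * layout.area).sum())
    total_loading = float((params.loading_field(layout)[:n] * layout.area).sum())

    # sucrose flux on the petiole edge, from the first node's viewpoint
    alpha = (1.0 - params.sigma_lateral) * params.v_mu
    G = layout.G_ph[e]
    # influx into first node from petiole (negative = export)
    if params.sucrose_scheme == "upwind":
        C_conv = C[pet] if F_ph_first_pet > 0 else C[first]
    else:
        C_conv = C[first]
    S_in = alpha * F_ph_first_pet * C_conv + G * (C[pet] - C[first])
    sucrose_export = -float(S_in)

    return {
        "xylem_petiole_inflow": float(xylem_inflow),
        "total_transpiration": total_transpiration,
        "total_cross_into_xylem": total_cross_into_xylem,
        "xylem_closure_gap": float(xylem_inflow + total_transpiration + total_cross_into_xylem),
        "phloem_petiole_outflow": float(-phloem_inflow),
        "phloem_closure_gap": float(-phloem_inflow + total_cross_into_xylem),
        "sucrose_export": sucrose_export,
        "total_loading": total_loading,
        "sucrose_conservation_gap": sucrose_export - total_loading,
        "min_concentration": float(C[:n].min()) if n else float("nan"),
    }
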