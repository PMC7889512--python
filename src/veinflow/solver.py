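"""Steady-state solution of the coupled network system.

The main path is a damped Newton iteration with the analytic sparse
Jacobian (the system is polynomial of degree 2 in the unknowns, so the
Jacobian is exact).  On failure the solver falls back to homotopy
continuation, ramping the two coupling sources (K_c and the sucrose
loading) from the always-solvable linear xylem/phloem problem up to the
target, and finally to seeded perturbed restarts.  A dense,
independently coded brute-force oracle and a closed-form chain solution
are provided for verification on small instances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.optimize import fsolve
from scipy.sparse.linalg import spsolve

from .transport import ModelParams, NetworkState, assemble_residual, assemble_system

__all__ = [
    "SolverSettings",
    "SolverError",
    "solve_steady",
    "brute_force_oracle",
    "xylem_chain_closed_form",
]


class SolverError(RuntimeError):
    """Raised when the steady-state solve does not converge."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class SolverSettings:
    """Convergence controls for :func:`solve_steady`.

    The residual tolerance is relative: water residuals are compared to
    the typical nodal forcing magnitude (|E| a, or the cross-flux scale
    when transpiration is off) and sucrose residuals to the typical
    loading flux.  ``initial_concentration`` of 100 mol m^-3 sits inside
    the physically expected 150-190 mol m^-3 steady-state range.
    """

    tol: float = 1e-10
    max_iter: int = 60
    max_damping: int = 12
    n_continuation: int = 5
    n_restarts: int = 3
    initial_concentration: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


def _residual_scales(layout, params, x):
    """Per-equation-class scales for the relative convergence test."""
    n = layout.n
    N = n + 1
    px, pp, C = x[:N], x[N:2 * N], x[2 * N:]
    a = layout.area
    w_forcing = np.median(np.abs(params.transpiration_field(layout)[:n] * a))
    Fc = params.K_c * np.abs((pp[:n] - params.sigma_cross * params.RT * C[:n]) - px[:n])
    w_scale = max(w_forcing, np.max(Fc, initial=0.0), 1e-15)
    s_forcing = np.median(np.abs(params.loading_field(layout)[:n] * a))
    conv = params.v_mu * np.max(np.abs(layout.K_ph)) * 0.01 * np.max(np.abs(C), initial=0.0)
    s_scale = max(s_forcing, 1e-3 * conv, 1e-22)
    return w_scale, s_scale


def _scaled_norm(layout, r, w_scale, s_scale):
    N = layout.n + 1
    return max(
        np.max(np.abs(r[:N])) / w_scale,
        np.max(np.abs(r[N:2 * N])) / w_scale,
        np.max(np.abs(r[2 * N:])) / s_scale,
    )


def _initial_vector(layout, params, settings):
    N = layout.n + 1
    x = np.empty(3 * N)
    x[:N] = params.p_petiole_xyl
    x[N:2 * N] = params.p_petiole_ph
    x[2 * N:] = settings.initial_concentration
    return x


def _linear_water_solution(layout, params, settings):
    """Exact solution of the decoupled (K_c = 0, Lambda = 0) system.

    Both water blocks are linear; the sucrose field is then indeterminate
    up to a constant and is returned uniform at the initial guess.
    """
    n = layout.n
    N = n + 1
    u, v = layout.edges_u, layout.edges_v

    def solve_block(K, forcing, p_bc):
        rows = np.concatenate([u, u, v, v])
        cols = np.concatenate([u, v, v, u])
        vals = np.concatenate([-K, K, -K, K])
        pet = layout.petiole
        keep = rows != pet
        rows, cols, vals = rows[keep], cols[keep], vals[keep]
        rows = np.append(rows, pet)
        cols = np.append(cols, pet)
        vals = np.append(vals, 1.0)
        A = sparse.coo_matrix((vals, (rows, cols)), shape=(N, N)).tocsr()
        b = -forcing
        b[pet] = p_bc
        return spsolve(A, b)

    forcing = params.transpiration_field(layout) * np.append(layout.area, 0.0)
    px = solve_block(layout.K_xyl, forcing.copy(), params.p_petiole_xyl)
    pp = solve_block(layout.K_ph, np.zeros(N), params.p_petiole_ph)
    C = np.full(N, settings.initial_concentration)
    return np.concatenate([px, pp, C])


def _newton(layout, params, settings, x0):
    x = x0.copy()
    for it in range(settings.max_iter):
        r, J = assemble_system(layout, params, x)
        w_scale, s_scale = _residual_scales(layout, params, x)
        norm = _scaled_norm(layout, r, w_scale, s_scale)
        if norm < settings.tol:
            return x, {"iterations": it, "residual": norm}
        dx = spsolve(J.tocsc(), -r)
        if not np.all(np.isfinite(dx)):
            raise SolverError("singular Jacobian in Newton step", {"iteration": it})
        lam = 1.0
        for _ in range(settings.max_damping):
            r_new, _ = assemble_system(layout, params, x + lam * dx)
            if _scaled_norm(layout, r_new, w_scale, s_scale) < norm or lam < 1e-6:
                break
            lam *= 0.5
        x = x + lam * dx
    r, _ = assemble_system(layout, params, x)
    w_scale, s_scale = _residual_scales(layout, params, x)
    norm = _scaled_norm(layout, r, w_scale, s_scale)
    if norm < settings.tol:
        return x, {"iterations": settings.max_iter, "residual": norm}
    raise SolverError(
        f"Newton did not converge in {settings.max_iter} iterations "
        f"(scaled residual {norm:.3e})",
        {"residual": norm},
    )


def solve_steady(layout, params: ModelParams = None, settings: SolverSettings = None):
    """Solve the coupled network to steady state.

    Returns ``(state, diagnostics)``.  Diagnostics report the iteration
    count, the final scaled residual, and the whole-leaf balance
    closures.  The result is deterministic given (layout, params,
    settings) including the seed, which only enters the perturbed-restart
    fallback.  Negative concentrations at the solution are flagged with
    a warning (a model-regime signal), never clamped.
    """
    from .transport import balance_report

    params = params or ModelParams()
    settings = settings or SolverSettings()
    if layout.K_xyl is None:
        from .leafgeom import assign_conductances

        assign_conductances(layout, params)

    lam_field = params.loading_field(layout)
    degenerate = params.K_c == 0.0 and not np.any(lam_field)
    x0 = _initial_vector(layout, params, settings)
    strategy = "newton"
    if degenerate:
        x = _linear_water_solution(layout, params, settings)
        info = {"iterations": 0, "residual": 0.0}
        strategy = "linear-decoupled"
    else:
        try:
            x, info = _newton(layout, params, settings, x0)
        except SolverError:
            strategy = "continuation"
            x, info = _continuation(layout, params, settings, x0)

    state = NetworkState.from_vector(x)
    if state.C[:layout.n].min() < 0:
        warnings.warn(
            "negative sucrose concentration at the steady state; the "
            "parameter regime is outside the model's physical range",
            RuntimeWarning,
            stacklevel=2,
        )
    diagnostics = {
        "strategy": strategy,
        "iterations": info["iterations"],
        "residual": info["residual"],
        "balance": balance_report(layout, params, state),
    }
    return state, diagnostics


def _continuation(layout, params, settings, x0):
    rng = np.random.default_rng(settings.seed)
    last_err = None
    for attempt in range(settings.n_restarts):
        x = x0 + (0.0 if attempt == 0 else rng.normal(0.0, 1e-3, size=x0.shape))
        try:
            total_it = 0
            for t in np.linspace(1.0 / settings.n_continuation, 1.0, settings.n_continuation):
                params_t = replace(
                    params,
                    K_c=t * params.K_c,
                    Lambda=params.Lambda * t if np.isscalar(params.Lambda) else np.asarray(params.Lambda) * t,
                )
                x, info = _newton(layout, params_t, settings, x)
                total_it += info["iterations"]
            info["iterations"] = total_it
            return x, info
        except SolverError as err:
            last_err = err
    raise SolverError(
        f"continuation failed after {settings.n_restarts} restarts: {last_err}",
        getattr(last_err, "diagnostics", {}),
    )


# ---------------------------------------------------------------------------
# Independent verification paths
# ---------------------------------------------------------------------------


def _residual_loops(layout, params, px, pp, C):
    """Loop-based residual evaluation, independent of the vectorized
    assembly (used only by the brute-force oracle)."""
    n = layout.n
    N = n + 1
    pet, first = layout.petiole, layout.first
    RT = params.R * params.T
    alpha = (1.0 - params.sigma_lateral) * params.v_mu
    E = params.transpiration_field(layout)
    lam = params.loading_field(layout)
    area = list(layout.area) + [0.0]

    r = [0.0] * (3 * N)
    for e in range(len(layout.edges_u)):
        a, b = int(layout.edges_u[e]), int(layout.edges_v[e])
        Kx, Kp, G = layout.K_xyl[e], layout.K_ph[e], layout.G_ph[e]
        fx = Kx * (px[b] - px[a])
        r[a] += fx
        r[b] -= fx
        fp = Kp * ((pp[b] - pp[a]) - params.sigma_lateral * RT * (C[b] - C[a]))
        r[N + a] += fp
        r[N + b] -= fp
        if params.sucrose_scheme == "upwind":
            cdon = C[b] if fp > 0 else C[a]
            r[2 * N + a] += alpha * fp * cdon + G * (C[b] - C[a])
            r[2 * N + b] += -alpha * fp * cdon + G * (C[a] - C[b])
        else:
            r[2 * N + a] += alpha * fp * C[a] + G * (C[b] - C[a])
            r[2 * N + b] += -alpha * fp * C[b] + G * (C[a] - C[b])
    for i in range(n):
        Fc = params.K_c * ((pp[i] - params.sigma_cross * RT * C[i]) - px[i])
        r[i] += E[i] * area[i] + Fc
        r[N + i] -= Fc
        r[2 * N + i] += lam[i] * area[i]
    r[pet] = px[pet] - params.p_petiole_xyl
    r[N + pet] = pp[pet] - params.p_petiole_ph
    r[2 * N + pet] = C[pet] - C[first]
    return np.array(r)


def brute_force_oracle(layout, params: ModelParams = None, settings: SolverSettings = None):
    """Solve a small instance by an independent dense method.

    Uses MINPACK's hybrid solver with finite-difference Jacobians on a
    loop-coded residual, warm-started by homotopy continuation in
    (K_c, Lambda) from the exact linear xylem-only solution.  Intended
    for networks of a few tens of nodes; agrees with
    :func:`solve_steady` to ~1e-8 relative.
    """
    params = params or ModelParams()
    settings = settings or SolverSettings()
    if layout.K_xyl is None:
        from .leafgeom import assign_conductances

        assign_conductances(layout, params)
    if layout.n > 60:
        raise ValueError("brute-force oracle is for small instances only")

    x = _linear_water_solution(layout, params, settings)
    lam_field = params.loading_field(layout)
    if params.K_c == 0.0 and not np.any(lam_field):
        return NetworkState.from_vector(x)

    N = layout.n + 1
    # column scales (pressures ~0.1 MPa, concentrations ~100 mol m^-3)
    # and per-class row scales condition MINPACK's uniform tolerance
    col = np.concatenate([np.full(2 * N, 0.1), np.full(N, 100.0)])

    for t in np.linspace(0.2, 1.0, 5):
        params_t = replace(
            params,
            K_c=t * params.K_c,
            Lambda=params.Lambda * t if np.isscalar(params.Lambda) else np.asarray(params.Lambda) * t,
        )
        w_scale, s_scale = _residual_scales(layout, params_t, x)
        row = np.concatenate([np.full(2 * N, w_scale), np.full(N, s_scale)])
        row[layout.petiole] = 0.1
        row[N + layout.petiole] = 0.1
        row[2 * N + layout.petiole] = 100.0

        def fun_scaled(yv, p=params_t, rw=row):
            xv = yv * col
            r = _residual_loops(layout, p, xv[:N], xv[N:2 * N], xv[2 * N:])
            return r / rw

        y, infodict, ier, msg = fsolve(fun_scaled, x / col, full_output=True, xtol=1e-13)
        x = y * col
        # MINPACK may report "no progress" once it sits at the roundoff
        # floor; judge convergence by the scaled residual itself
        if ier != 1 and np.max(np.abs(fun_scaled(y))) > 1e-8:
            raise SolverError(f"oracle fsolve failed at homotopy step {t}: {msg}")
    return NetworkState.from_vector(x)


def xylem_chain_closed_form(n: int, K_edge: float, E: float, a: float, p0: float) -> np.ndarray:
    """Telescoping Darcy solution for a uniform xylem-only chain.

    Node m (1-based, petiole at pressure p0 upstream) satisfies
    ``p_m = p0 + (E a / K) * sum_{k=1..m} (n - k + 1)``: edge k carries
    the transpiration of all n-k+1 downstream nodes.  Monotone
    decreasing for E < 0.
    """
    m = np.arange(1, n + 1)
    downstream = n - np.arange(1, n + 1) + 1
    return p0 + (E * a / K_edge) * np.cumsum(downstream)
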