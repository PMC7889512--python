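"""Whole-leaf transport indices, angle sweeps, and field maps.

The headline index is the leaf area-average of a solved field — the
arithmetic mean over interior nodes — used as a whole-leaf efficiency
measure: with transpiration fixed, a less negative average xylem
pressure means a more conductive venation layout.  Sweeps regenerate
the layout per second-order vein angle (constant total vein length by
default, so the hydrodynamic resistance budget of the second-order
system is held fixed) and tabulate the averages against angle.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .leafgeom import (
    PAPER_ANGLES,
    LeafShape,
    assign_conductances,
    build_grid,
    build_vein_layout,
    make_leaf_shape,
)
from .solver import SolverError, SolverSettings, solve_steady
from .transport import ModelParams, NetworkState

__all__ = [
    "area_average",
    "solve_leaf",
    "sweep_vein_angle",
    "find_peak_angle",
    "variation_metric",
    "pressure_difference_map",
    "state_to_frame",
    "export_maps",
]

SWEEP_COLUMNS = [
    "theta_deg",
    "avg_p_xyl_MPa",
    "avg_p_ph_MPa",
    "avg_C_mol_m3",
    "converged",
    "iterations",
    "n_nodes",
    "order2_total_m",
    "n_order2_veins",
]


def area_average(values, layout) -> float:
    """Arithmetic mean of a nodal field over interior nodes.

    The petiole (a boundary reservoir, not part of the lamina) is
    excluded; ``values`` may have length n or n+1.
    """
    values = np.asarray(values, dtype=float)
    n = layout.n
    if n == 0:
        raise ValueError("layout has no interior nodes")
    if len(values) not in (n, n + 1):
        raise ValueError(f"field of length {len(values)} does not fit {n} nodes")
    return float(values[:n].mean())


def solve_leaf(
    shape,
    theta_deg: float,
    params: ModelParams = None,
    spacing: float = 0.002,
    mode: str = "constant_total_length",
    Lv=(0.010, 0.010),
    settings: SolverSettings = None,
    grid=None,
):
    """Build one (shape, angle) layout and solve it to steady state.

    Returns ``(layout, state, diagnostics)``.  Passing a prebuilt grid
    avoids recomputing the lattice across a sweep.
    """
    params = params or ModelParams()
    layout = build_vein_layout(shape, theta_deg, spacing=spacing, mode=mode, Lv=Lv, grid=grid)
    assign_conductances(layout, params)
    state, diag = solve_steady(layout, params, settings)
    return layout, state, diag


def sweep_vein_angle(
    shape,
    angles=PAPER_ANGLES,
    params: ModelParams = None,
    spacing: float = 0.002,
    mode: str = "constant_total_length",
    Lv=(0.010, 0.010),
    settings: SolverSettings = None,
) -> pd.DataFrame:
    """Area-average indices versus second-order vein angle.

    One steady-state solve per angle with a regenerated vein layout on a
    shared node lattice.  Raises :class:`SolverError` identifying the
    offending angle if any solve fails.
    """
    params = params or ModelParams()
    if isinstance(shape, str):
        shape = make_leaf_shape(shape)
    grid = build_grid(shape, spacing)
    rows = []
    for theta in sorted(angles):
        try:
            layout, state, diag = solve_leaf(
                shape, theta, params, spacing=spacing, mode=mode, Lv=Lv,
                settings=settings, grid=grid,
            )
        except SolverError as err:
            raise SolverError(
                f"sweep failed at theta={theta} deg for {shape.variant}: {err}"
            ) from err
        rows.append(
            {
                "theta_deg": theta,
                "avg_p_xyl_MPa": area_average(state.p_xyl, layout),
                "avg_p_ph_MPa": area_average(state.p_ph, layout),
                "avg_C_mol_m3": area_average(state.C, layout),
                "converged": True,
                "iterations": diag["iterations"],
                "n_nodes": layout.n,
                "order2_total_m": layout.meta.get("order2_total_m", np.nan),
                "n_order2_veins": layout.meta.get("n_order2_veins", 0),
            }
        )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def find_peak_angle(table: pd.DataFrame, field: str = "avg_p_xyl_MPa") -> float:
    """Angle of the sampled-grid maximum of a sweep column.

    No interpolation: peaks are reported on the sampled angles, with
    ties broken toward the smaller angle.
    """
    if len(table) < 1:
        raise ValueError("empty sweep table")
    if "converged" in table and not table["converged"].all():
        raise ValueError("sweep table contains unconverged rows")
    t = table.sort_values("theta_deg").reset_index(drop=True)
    return float(t["theta_deg"].iloc[int(np.argmax(t[field].to_numpy()))])


def variation_metric(
    table: pd.DataFrame, field: str = "avg_p_xyl_MPa", strategy: str = "range_over_mean"
) -> float:
    """Percent variation of an index across a sweep.

    The published degrees of variation do not come with a printed
    definition, so the metric is pluggable: ``range_over_mean`` (default)
    is 100 (max - min) / |mean|; ``range_over_max`` and
    ``range_over_min`` divide by |max| and |min| instead.
    """
    if len(table) < 2:
        raise ValueError("need at least two sweep rows")
    vals = table[field].to_numpy(dtype=float)
    rng = vals.max() - vals.min()
    denom = {
        "range_over_mean": abs(vals.mean()),
        "range_over_max": abs(vals.max()),
        "range_over_min": abs(vals.min()),
    }[strategy]
    if denom == 0:
        raise ZeroDivisionError("variation metric undefined for zero denominator")
    return 100.0 * rng / denom


def pressure_difference_map(state: NetworkState, params: ModelParams) -> np.ndarray:
    """Per-node xylem pressure minus phloem total (osmotically reduced)
    pressure: p_xyl - (p_ph - R T C).

    Positive values mark where the cross-conduit drive pushes water from
    the xylem into the phloem; the map is the circulation diagnostic
    (each node's value is -F_c / K_c).
    """
    return state.p_xyl - (state.p_ph - params.RT * state.C)


def state_to_frame(layout, state: NetworkState, params: ModelParams = None) -> pd.DataFrame:
    """Node table of positions, areas, and solved fields."""
    g = layout.grid
    n = layout.n
    df = pd.DataFrame(
        {
            "i": g.ij[:, 0] if g is not None else np.arange(n),
            "j": g.ij[:, 1] if g is not None else np.zeros(n, dtype=int),
            "x": layout.xz[:, 0],
            "z": layout.xz[:, 1],
            "a_ij": layout.area,
            "p_xyl": state.p_xyl[:n],
            "p_ph": state.p_ph[:n],
            "C": state.C[:n],
        }
    )
    if params is not None:
        df["p_diff"] = pressure_difference_map(state, params)[:n]
    return df


def edge_flux_frame(layout, state: NetworkState, params: ModelParams) -> pd.DataFrame:
    """Edge table of water and sucrose fluxes (into the ``u`` node)."""
    from .transport import sucrose_edge_flux

    u, v = layout.edges_u, layout.edges_v
    px, pp, C = state.p_xyl, state.p_ph, state.C
    fx = layout.K_xyl * (px[v] - px[u])
    fp = layout.K_ph * ((pp[v] - pp[u]) - params.sigma_lateral * params.RT * (C[v] - C[u]))
    S = sucrose_edge_flux(fp, C[u], C[v], layout.G_ph, params)
    return pd.DataFrame(
        {"u": u, "v": v, "order": layout.edge_order, "F_xyl": fx, "F_ph": fp, "S": S}
    )


def export_maps(state, layout, outdir, params: ModelParams = None, image: bool = False):
    """Write the node-field CSV (full precision) and optional heatmaps.

    Returns the written paths.  Heatmap rendering is optional because
    the CSV is the canonical, bit-round-trippable artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = state_to_frame(layout, state, params)
    paths = {"nodes": outdir / "state_nodes.csv"}
    # 17 significant digits: bit-exact float64 round-trip
    df.to_csv(paths["nodes"], index=False, float_format="%.17g")
    if params is not None:
        paths["edges"] = outdir / "state_edges.csv"
        edge_flux_frame(layout, state, params).to_csv(
            paths["edges"], index=False, float_format="%.17g"
        )
    if image:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fields = ["p_xyl", "p_ph", "C"] + (["p_diff"] if "p_diff" in df else [])
        for name in fields:
            fig, ax = plt.subplots(figsize=(4, 6))
            sc = ax.scatter(df["x"] * 100, df["z"] * 100, c=df[name], s=4, cmap="viridis")
            fig.colorbar(sc, ax=ax, label=name)
            ax.set_xlabel("x (cm)")
            ax.set_ylabel("z (cm)")
            ax.set_aspect("equal")
            p = outdir / f"map_{name}.png"
            fig.savefig(p, dpi=120, bbox_inches="tight")
            plt.close(fig)
            paths[f"map_{name}"] = p
    return paths
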