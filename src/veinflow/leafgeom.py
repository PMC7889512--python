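"""Leaf outlines, node lattices, and hierarchical vein layouts.

The model leaf is a lanceolate outline, mirror-symmetric about the main
vein, discretized on a rectangular lattice of nodes.  Veins of five orders
live on lattice lines and staircases:

* order 1 — the main vein along the symmetry axis, petiole to apex;
* order 2 — straight veins leaving the main vein at an angle theta,
  rasterized as staircases of axial and diagonal lattice steps;
* order 3 — every 6th lattice row and column;
* orders 4/5 — the remaining lattice lines, alternating by parity, so
  every lattice edge between adjacent interior nodes carries some order.

Where several orders share an edge, the lowest order (the widest, most
conductive vein) wins.  Coordinates: ``z`` runs petiole (0) to apex (L)
along the symmetry axis, ``x`` is lateral with the main vein at x = 0.
Lattice indices are ``(i, j)`` with i longitudinal (row 0 at z = 5 mm,
the first interior node) and j lateral (signed, j = 0 on the main vein).
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.special import gammaln

__all__ = [
    "LeafShape",
    "Grid",
    "VeinSegment",
    "VeinLayout",
    "LayoutError",
    "make_leaf_shape",
    "build_grid",
    "angle_to_ratio",
    "rasterize_vein",
    "layout_second_order_veins",
    "layout_higher_order_veins",
    "assign_conductances",
    "build_vein_layout",
    "layout_to_csv",
    "layout_from_csv",
    "PAPER_ANGLES",
    "SHAPE_DIMENSIONS",
    "TARGET_AREA",
    "XYLEM_CONDUCTIVITY",
    "VEIN_DIAMETER",
]

#: target lamina area shared by all three leaf shapes (m^2)
TARGET_AREA = 73.35e-4

#: (length, max width) in metres for the three studied leaf proportions
SHAPE_DIMENSIONS = {
    "reference": (0.16, 0.0647),
    "wide": (0.128, 0.0809),
    "narrow": (0.192, 0.0539),
}

#: distance from the petiole to the first interior main-vein node (m)
PETIOLE_OFFSET = 0.005

#: per-order xylem conductivity (m mmol s^-1 MPa^-1); edge conductance
#: is conductivity / edge length.  Phloem conductances are 3/100 of these.
XYLEM_CONDUCTIVITY = {1: 1.00e-2, 2: 5.00e-4, 3: 6.00e-5, 4: 4.00e-5, 5: 4.00e-6}

#: per-order vein (sieve tube) diameter (m), used for the diffusive
#: sucrose conductance G = D_su * (pi d^2 / 4) / length.
VEIN_DIAMETER = {1: 15.50e-6, 2: 11.30e-6, 3: 7.50e-6, 4: 7.20e-6, 5: 4.34e-6}

#: grid-compatible tangent ratios (rise p along z per run q along x) of
#: the 13 second-order vein angles of the angle sweep.  Keys are the
#: published angle labels in degrees.
ANGLE_RATIOS = {
    0.00: (0, 1),
    7.13: (1, 8),
    14.03: (1, 4),
    21.80: (2, 5),
    30.96: (3, 5),
    36.87: (3, 4),
    40.60: (6, 7),
    45.00: (1, 1),
    49.40: (7, 6),
    53.13: (4, 3),
    59.06: (5, 3),
    68.20: (5, 2),
    75.96: (4, 1),
}

PAPER_ANGLES = tuple(sorted(ANGLE_RATIOS))

#: total second-order vein length target and tolerance (m) in
#: constant_total_length mode
ORDER2_TOTAL_LENGTH = 0.74
ORDER2_LENGTH_TOL = 0.01

#: default axial interval between second-order vein stations (m)
ORDER2_SPACING = 0.010

# Compass step codes on the lattice: 1..8 = N, NE, E, SE, S, SW, W, NW.
# N is +z (toward the apex), E is +x.
DIRECTION_STEPS = {
    1: (1, 0),
    2: (1, 1),
    3: (0, 1),
    4: (-1, 1),
    5: (-1, 0),
    6: (-1, -1),
    7: (0, -1),
    8: (1, -1),
}


class LayoutError(RuntimeError):
    """A vein-layout constraint could not be satisfied on the lattice."""


# ---------------------------------------------------------------------------
# Leaf outline
# ---------------------------------------------------------------------------


def _sine_power_mean(q: float) -> float:
    # (1/pi) * int_0^pi sin(u)^q du = Gamma((q+1)/2) / (sqrt(pi) Gamma(q/2+1))
    return math.exp(
        0.5 * math.log(math.pi) + gammaln((q + 1.0) / 2.0) - gammaln(q / 2.0 + 1.0)
    ) / math.pi


@dataclass(frozen=True)
class LeafShape:
    """Outline of one leaf variant.

    The half-width profile is ``w(z) = (W/2) sin(pi z / L)^q`` with the
    exponent ``q`` fitted so that the outline area equals ``target_area``.
    The profile vanishes at the petiole (z=0) and apex (z=L) and peaks at
    W/2 mid-leaf.
    """

    variant: str
    length: float
    width: float
    target_area: float
    exponent: float

    def half_width(self, z):
        z = np.asarray(z, dtype=float)
        s = np.sin(np.pi * np.clip(z / self.length, 0.0, 1.0))
        w = 0.5 * self.width * np.power(np.clip(s, 0.0, None), self.exponent)
        w = np.where((z <= 0.0) | (z >= self.length), 0.0, w)
        return w if w.ndim else float(w)

    @property
    def area_ratio(self) -> float:
        """Outline area divided by the bounding-box area L*W."""
        return self.target_area / (self.length * self.width)


def make_leaf_shape(variant: str) -> LeafShape:
    """Construct one of the three studied leaf shapes.

    All three share the 73.35 cm^2 lamina area; the shape exponent of the
    half-width profile is solved by a 1-D root find so the integrated
    outline area matches exactly.
    """
    try:
        length, width = SHAPE_DIMENSIONS[variant]
    except KeyError:
        raise ValueError(
            f"unknown leaf variant {variant!r}; choose from {sorted(SHAPE_DIMENSIONS)}"
        ) from None
    ratio = TARGET_AREA / (length * width)
    q = brentq(lambda t: _sine_power_mean(t) - ratio, 1e-3, 20.0, xtol=1e-14)
    return LeafShape(variant, length, width, TARGET_AREA, q)


# ---------------------------------------------------------------------------
# Node lattice
# ---------------------------------------------------------------------------


@dataclass
class Grid:
    """Rectangular node lattice clipped to a leaf outline.

    Interior nodes are numbered 0..n-1 (row-major); the external petiole
    node carries id ``n``.  ``n_inside_raw`` counts nodes strictly inside
    the outline before pruning lattice-disconnected margin nodes.
    """

    shape: LeafShape
    spacing: float
    ij: np.ndarray          # (n, 2) int lattice indices (i, j)
    xz: np.ndarray          # (n, 2) float positions (x, z)
    area: np.ndarray        # (n,) nodal areas a_ij (m^2)
    index: dict             # (i, j) -> node id
    i_max: int
    n_inside_raw: int

    @property
    def n(self) -> int:
        return len(self.ij)

    @property
    def petiole(self) -> int:
        return self.n

    @property
    def first(self) -> int:
        """Interior main-vein node wired to the petiole (i=0, j=0)."""
        return self.index[(0, 0)]


def build_grid(shape: LeafShape, spacing: float) -> Grid:
    """Lay a node lattice over the outline and compute nodal areas.

    Nodes sit at x = j*spacing, z = 5 mm + i*spacing and are kept when
    strictly inside the outline and lattice-connected to the petiole.
    Each node's area is its lattice cell clipped to the outline; cells of
    excluded nodes are folded into the nearest kept node so the nodal
    areas sum to the outline area, and areas are mirror-symmetrized.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing >= shape.width / 4.0:
        raise ValueError(
            f"spacing {spacing} too coarse for leaf width {shape.width}"
            " (must be < width/4 to resolve the main-vein column)"
        )
    h = spacing
    L = shape.length
    i_max = int(math.floor((L - PETIOLE_OFFSET) / h - 1e-9))
    J = int(math.floor(shape.width / 2.0 / h + 1e-9))

    ii = np.arange(i_max + 1)
    jj = np.arange(-J, J + 1)
    zz = PETIOLE_OFFSET + ii * h
    xx = jj * h
    w = shape.half_width(zz)                       # (n_rows,)
    inside = np.abs(xx)[None, :] < w[:, None]      # (n_rows, n_cols)
    n_inside_raw = int(inside.sum())
    if not inside[0, J]:
        raise ValueError("first main-vein node at 5 mm lies outside the outline")

    # prune to the lattice component (axial 4-neighbors) reaching the petiole
    kept = np.zeros_like(inside)
    queue = deque([(0, J)])
    kept[0, J] = True
    while queue:
        a, b = queue.popleft()
        for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            na, nb = a + da, b + db
            if 0 <= na <= i_max and 0 <= nb <= 2 * J:
                if inside[na, nb] and not kept[na, nb]:
                    kept[na, nb] = True
                    queue.append((na, nb))

    ids = -np.ones(inside.shape, dtype=int)
    ij_list, xz_list = [], []
    nid = 0
    for a in range(i_max + 1):
        for b in range(2 * J + 1):
            if kept[a, b]:
                ids[a, b] = nid
                ij_list.append((a, b - J))
                xz_list.append((xx[b], zz[a]))
                nid += 1
    ij = np.array(ij_list, dtype=int)
    xz = np.array(xz_list, dtype=float)
    index = {tuple(p): k for k, p in enumerate(ij_list)}

    area = _nodal_areas(shape, h, i_max, J, kept, ids, xz)

    grid = Grid(shape, h, ij, xz, area, index, i_max, n_inside_raw)
    _symmetrize_areas(grid)
    return grid


def _nodal_areas(shape, h, i_max, J, kept, ids, kept_xz) -> np.ndarray:
    """Clip each lattice cell to the outline and fold orphan slivers.

    The overlap of a cell column [x1, x2] with the leaf cross-section
    [-w(z), w(z)] is integrated in z by composite Simpson per cell row;
    summed over all columns this telescopes to the exact width integral,
    so total area is limited only by the z-quadrature of the smooth
    outline.
    """
    L = shape.length
    n = int(kept.sum())
    area = np.zeros(n)
    orphan_centers, orphan_areas = [], []

    i_lo = int(math.floor((0.0 - (PETIOLE_OFFSET - h / 2.0)) / h)) - 1
    i_hi = int(math.ceil((L - (PETIOLE_OFFSET - h / 2.0)) / h)) + 1
    J_ext = J + 2
    cols = np.arange(-J_ext, J_ext + 1)
    x1 = cols * h - h / 2.0
    x2 = cols * h + h / 2.0

    npts = 21
    for i in range(i_lo, i_hi + 1):
        zc = PETIOLE_OFFSET + i * h
        zlo = max(zc - h / 2.0, 0.0)
        zhi = min(zc + h / 2.0, L)
        if zhi <= zlo:
            continue
        zs = np.linspace(zlo, zhi, npts)
        ws = shape.half_width(zs)                        # (npts,)
        lo = np.maximum(x1[:, None], -ws[None, :])
        hi = np.minimum(x2[:, None], ws[None, :])
        overlap = np.clip(hi - lo, 0.0, None)            # (n_cols, npts)
        # composite Simpson weights
        wts = np.ones(npts)
        wts[1:-1:2] = 4.0
        wts[2:-1:2] = 2.0
        wts *= (zhi - zlo) / (npts - 1) / 3.0
        cell_area = overlap @ wts                        # (n_cols,)
        for b, ca in zip(range(len(cols)), cell_area):
            if ca <= 0.0:
                continue
            jcol = cols[b]
            if 0 <= i <= i_max and -J <= jcol <= J and kept[i, jcol + J]:
                area[ids[i, jcol + J]] += ca
            else:
                orphan_centers.append((jcol * h, zc))
                orphan_areas.append(ca)

    if orphan_centers:
        tree = cKDTree(kept_xz)
        _, nearest = tree.query(np.array(orphan_centers))
        np.add.at(area, nearest, np.array(orphan_areas))
    return area


def _symmetrize_areas(grid: Grid) -> None:
    # exact mirror symmetry of a_ij; KDTree sliver assignment can break
    # ties asymmetrically at float precision
    for (i, j), nid in grid.index.items():
        if j > 0:
            mid = grid.index.get((i, -j))
            if mid is not None:
                m = 0.5 * (grid.area[nid] + grid.area[mid])
                grid.area[nid] = grid.area[mid] = m


# ---------------------------------------------------------------------------
# Vein segments
# ---------------------------------------------------------------------------


@dataclass
class VeinSegment:
    """A single vein: ordered node chain with its order and length."""

    order: int
    nodes: list                    # list of (i, j) lattice indices
    steps: list = field(default_factory=list)   # direction codes 1..8
    length: float = 0.0


def angle_to_ratio(theta_deg: float) -> tuple:
    """Resolve a vein angle to its lattice tangent ratio (p, q).

    p is the longitudinal rise and q the lateral run per staircase
    period, so tan(theta) = p/q with theta measured from the lateral
    (perpendicular-to-main-vein) direction.  Angles must land on a
    small-integer ratio within 0.05 degrees; the 13 published sweep
    angles are matched by their printed labels.
    """
    if not (0.0 <= theta_deg < 90.0):
        raise ValueError(f"vein angle {theta_deg} outside [0, 90)")
    for label, ratio in ANGLE_RATIOS.items():
        if abs(theta_deg - label) < 5e-3:
            return ratio
    frac = Fraction(math.tan(math.radians(theta_deg))).limit_denominator(16)
    realized = math.degrees(math.atan2(frac.numerator, frac.denominator))
    if abs(realized - theta_deg) > 0.05:
        raise ValueError(
            f"vein angle {theta_deg} deg is not grid-compatible "
            f"(closest lattice ratio {frac.numerator}/{frac.denominator} "
            f"realizes {realized:.3f} deg)"
        )
    return frac.numerator, frac.denominator


def rasterize_vein(grid: Grid, start: tuple, theta_deg: float, side: int = 1) -> VeinSegment:
    """Walk a second-order vein staircase from a main-vein node.

    The staircase interleaves axial and diagonal lattice steps (Bresenham
    error accumulation) so the net displacement per period is exactly q
    lateral by p longitudinal units; it truncates at the last interior
    node before the margin.  ``side`` +1 walks toward +x, -1 toward -x.
    """
    if start not in grid.index:
        raise ValueError(f"start node {start} is not an interior node")
    p, q = angle_to_ratio(theta_deg)
    h = grid.spacing
    i, j = start
    nodes = [(i, j)]
    steps = []
    length = 0.0
    err = 0
    while True:
        if p <= q:
            err += p
            if 2 * err >= q and p > 0:
                di, dj, err = 1, side, err - q
            else:
                di, dj = 0, side
        else:
            err += q
            if 2 * err >= p and q > 0:
                di, dj, err = 1, side, err - p
            else:
                di, dj = 1, 0
        ni, nj = i + di, j + dj
        if (ni, nj) not in grid.index:
            break
        code = {(1, 0): 1, (1, 1): 2, (0, 1): 3, (1, -1): 8, (0, -1): 7}[(di, dj)]
        nodes.append((ni, nj))
        steps.append(code)
        length += h * math.sqrt(2.0) if (di and dj) else h
        i, j = ni, nj
    return VeinSegment(order=2, nodes=nodes, steps=steps, length=length)


def layout_second_order_veins(
    grid: Grid,
    theta_deg: float,
    mode: str = "constant_total_length",
    Lv: tuple = (ORDER2_SPACING, ORDER2_SPACING),
    target_total: float = ORDER2_TOTAL_LENGTH,
    tol: float = ORDER2_LENGTH_TOL,
):
    """Place mirrored second-order vein pairs along the main vein.

    Stations start at the first interior node (5 mm from the petiole) and
    are spaced by alternating intervals L_v1/L_v2 snapped to the lattice.
    In ``constant_total_length`` mode the intervals are found by integer
    search so the summed staircase length approaches the 0.74 m budget
    (ties broken toward equal intervals), then individual stations are
    shifted/added/removed greedily by single lattice rows to land within
    the tolerance — the per-station "different extents" adjustment the
    rigid two-interval family cannot deliver on a coarse lattice.  In
    ``constant_spacing`` mode the intervals are fixed and the total
    floats.

    Returns ``(segments, meta)`` with meta carrying the chosen intervals
    and total length.
    """
    if mode not in ("constant_total_length", "constant_spacing"):
        raise ValueError(f"unknown second-order layout mode {mode!r}")
    h = grid.spacing
    rows = [i for i in range(grid.i_max + 1) if (i, 0) in grid.index]
    row_set = set(rows)
    pair_cache = {}
    for i in rows:
        segs = []
        for side in (1, -1):
            seg = rasterize_vein(grid, (i, 0), theta_deg, side)
            if len(seg.nodes) > 1:
                segs.append(seg)
        pair_cache[i] = segs
    pair_len = {i: sum(s.length for s in pair_cache[i]) for i in rows}

    def stations(s1: int, s2: int):
        out = [0]
        k = 0
        while True:
            nxt = out[-1] + (s1 if k % 2 == 0 else s2)
            if nxt in row_set:
                out.append(nxt)
                k += 1
            else:
                break
        return out

    if mode == "constant_spacing":
        s1 = max(1, round(Lv[0] / h))
        s2 = max(1, round(Lv[1] / h))
        chosen = (s1, s2)
        final = stations(s1, s2)
        best_total = sum(pair_len[i] for i in final)
    else:
        smax = max(2, round(0.030 / h))
        best_key, chosen, best_total = None, None, None
        for s1 in range(1, smax + 1):
            for s2 in range(1, smax + 1):
                total = sum(pair_len[i] for i in stations(s1, s2))
                key = (abs(total - target_total), abs(s1 - s2), s1 + s2, s1)
                if best_key is None or key < best_key:
                    best_key, chosen, best_total = key, (s1, s2), total
        final, best_total = _refine_stations(
            pair_len, stations(*chosen), target_total, tol
        )
        if abs(best_total - target_total) > tol:
            raise LayoutError(
                f"cannot reach total second-order length {target_total} m "
                f"within {tol} m on this lattice (best achievable "
                f"{best_total:.4f} m from base intervals {chosen[0] * h * 1e3:.0f}/"
                f"{chosen[1] * h * 1e3:.0f} mm)"
            )

    segments = [seg for i in final for seg in pair_cache[i]]
    meta = {
        "Lv1_m": chosen[0] * h,
        "Lv2_m": chosen[1] * h,
        "order2_total_m": best_total,
        "n_order2_veins": len(segments),
        "n_stations": len(final),
    }
    return segments, meta


def _refine_stations(pair_len, base, target, tol):
    """Greedy per-station adjustment of the connection-point set.

    Moves (single-row shift, insertion, removal; the 5 mm base station
    is pinned) are applied while they reduce the total-length deviation,
    stopping inside the tolerance.  Deterministic: candidates are
    scanned in sorted order and the best move wins.
    """
    sts = set(base)
    total = sum(pair_len[i] for i in sts)
    rows = set(pair_len)
    for _ in range(500):
        if abs(total - target) <= tol:
            break
        best = None

        def consider(move):
            nonlocal best
            if best is None or abs(move[3] - target) < abs(best[3] - target):
                best = move

        for cand in sorted(rows):
            if cand == 0:
                continue
            if cand in sts:
                if len(sts) > 2:
                    consider(("rm", cand, None, total - pair_len[cand]))
            else:
                consider(("add", cand, None, total + pair_len[cand]))
        for st in sorted(sts):
            if st == 0:
                continue
            for d in (-1, 1):
                c = st + d
                if c in rows and c not in sts:
                    consider(("shift", st, c, total - pair_len[st] + pair_len[c]))
        if best is None or abs(best[3] - target) >= abs(total - target) - 1e-12:
            break
        op, a, b, total = best
        if op == "rm":
            sts.remove(a)
        elif op == "add":
            sts.add(a)
        else:
            sts.remove(a)
            sts.add(b)
    return sorted(sts), total


def layout_higher_order_veins(grid: Grid, order45_parity: str = "even4"):
    """Build the main vein and the order-3/4/5 background lattice veins.

    The main vein (order 1) runs the symmetry axis from the first
    interior node to the apex.  Every 6th lattice row and column carries
    an order-3 vein; remaining lines alternate orders 4 and 5 by index
    parity (``even4``: even lines are order 4; ``odd4`` mirrors the
    convention).  Line indices are taken as absolute values so the
    pattern is mirror-symmetric.  Each maximal run of adjacent interior
    nodes on a line becomes one segment, so every interior lattice edge
    carries an order.
    """
    if order45_parity not in ("even4", "odd4"):
        raise ValueError(f"unknown parity convention {order45_parity!r}")

    def line_order(idx: int) -> int:
        a = abs(idx)
        if a % 6 == 0:
            return 3
        even = a % 2 == 0
        if order45_parity == "even4":
            return 4 if even else 5
        return 5 if even else 4

    h = grid.spacing
    segments = []

    # order 1: main vein along j = 0
    main_rows = [i for i in range(grid.i_max + 1) if (i, 0) in grid.index]
    runs = _runs(main_rows)
    for run in runs:
        nodes = [(i, 0) for i in run]
        if len(nodes) > 1 or run[0] == 0:
            segments.append(
                VeinSegment(1, nodes, [1] * (len(nodes) - 1), h * (len(nodes) - 1))
            )

    by_row = {}
    by_col = {}
    for (i, j) in grid.index:
        by_row.setdefault(i, []).append(j)
        by_col.setdefault(j, []).append(i)

    for i, js in by_row.items():
        order = line_order(i)
        for run in _runs(sorted(js)):
            if len(run) > 1:
                nodes = [(i, j) for j in run]
                segments.append(
                    VeinSegment(order, nodes, [3] * (len(nodes) - 1), h * (len(nodes) - 1))
                )
    for j, is_ in by_col.items():
        if j == 0:
            continue  # main vein
        order = line_order(j)
        for run in _runs(sorted(is_)):
            if len(run) > 1:
                nodes = [(i, j) for i in run]
                segments.append(
                    VeinSegment(order, nodes, [1] * (len(nodes) - 1), h * (len(nodes) - 1))
                )
    return segments


def _runs(sorted_vals):
    runs, cur = [], []
    for v in sorted_vals:
        if cur and v != cur[-1] + 1:
            runs.append(cur)
            cur = []
        cur.append(v)
    if cur:
        runs.append(cur)
    return runs


# ---------------------------------------------------------------------------
# Assembled layout
# ---------------------------------------------------------------------------


@dataclass
class VeinLayout:
    """One (shape, angle) venation instance as an edge-listed network.

    Interior nodes 0..n-1; petiole node id n.  Edge arrays are parallel;
    conductances are filled by :func:`assign_conductances`.
    """

    shape: LeafShape
    spacing: float
    theta_deg: float
    mode: str
    grid: Grid
    segments: list
    edges_u: np.ndarray
    edges_v: np.ndarray
    edge_order: np.ndarray
    edge_length: np.ndarray
    meta: dict
    K_xyl: np.ndarray = None
    K_ph: np.ndarray = None
    G_ph: np.ndarray = None

    @property
    def n(self) -> int:
        """Number of interior (unknown-bearing, transpiring) nodes."""
        return self.grid.n if self.grid is not None else self.meta["n"]

    @property
    def petiole(self) -> int:
        return self.n

    @property
    def first(self) -> int:
        return self.grid.first if self.grid is not None else self.meta["first"]

    @property
    def area(self) -> np.ndarray:
        return self.grid.area if self.grid is not None else self.meta["area"]

    @property
    def xz(self) -> np.ndarray:
        return self.grid.xz if self.grid is not None else self.meta["xz"]

    def total_length_by_order(self) -> dict:
        out = {}
        for o in np.unique(self.edge_order):
            out[int(o)] = float(self.edge_length[self.edge_order == o].sum())
        return out


def build_vein_layout(
    shape,
    theta_deg: float = 0.0,
    spacing: float = 0.002,
    mode: str = "constant_total_length",
    Lv: tuple = (ORDER2_SPACING, ORDER2_SPACING),
    order45_parity: str = "even4",
    grid: Grid = None,
) -> VeinLayout:
    """Generate the full vein layout for one leaf shape and vein angle.

    ``shape`` may be a variant name or a :class:`LeafShape`.  The edge
    set is the union of all segments plus the 5 mm petiole conduit; on
    shared edges the lowest order wins.
    """
    if isinstance(shape, str):
        shape = make_leaf_shape(shape)
    if grid is None:
        grid = build_grid(shape, spacing)
    second, meta2 = layout_second_order_veins(grid, theta_deg, mode=mode, Lv=Lv)
    higher = layout_higher_order_veins(grid, order45_parity)
    segments = higher + second

    h = grid.spacing
    edge_map = {}
    for seg in segments:
        for (a, b) in zip(seg.nodes[:-1], seg.nodes[1:]):
            ua, ub = grid.index[a], grid.index[b]
            key = (ua, ub) if ua < ub else (ub, ua)
            diag = (a[0] != b[0]) and (a[1] != b[1])
            length = h * math.sqrt(2.0) if diag else h
            prev = edge_map.get(key)
            if prev is None or seg.order < prev[0]:
                edge_map[key] = (seg.order, length)
            else:
                edge_map[key] = (prev[0], length)
    # petiole conduit: order 1, 5 mm, petiole node to first interior node
    edge_map[(grid.first, grid.petiole)] = (1, PETIOLE_OFFSET)

    keys = sorted(edge_map)
    edges_u = np.array([k[0] for k in keys], dtype=int)
    edges_v = np.array([k[1] for k in keys], dtype=int)
    edge_order = np.array([edge_map[k][0] for k in keys], dtype=int)
    edge_length = np.array([edge_map[k][1] for k in keys], dtype=float)

    meta = dict(meta2)
    meta["order45_parity"] = order45_parity
    layout = VeinLayout(
        shape, spacing, theta_deg, mode, grid, segments,
        edges_u, edges_v, edge_order, edge_length, meta,
    )
    return layout


def assign_conductances(layout: VeinLayout, params) -> VeinLayout:
    """Fill per-edge xylem/phloem conductances and diffusive conductances.

    K_xyl = conductivity[order] / length, K_ph = phloem_factor * K_xyl,
    G_ph = D_su * (pi d^2 / 4) / length with the per-order diameters.
    """
    conductivity = params.conductivity
    diameters = params.diameters
    orders = layout.edge_order
    missing = set(np.unique(orders)) - set(conductivity)
    if missing:
        raise ValueError(f"no conductivity for vein order(s) {sorted(missing)}")
    cond = np.array([conductivity[int(o)] for o in orders])
    diam = np.array([diameters[int(o)] for o in orders])
    layout.K_xyl = cond / layout.edge_length
    layout.K_ph = params.phloem_factor * layout.K_xyl
    layout.G_ph = params.D_su * (math.pi * diam**2 / 4.0) / layout.edge_length
    return layout


# ---------------------------------------------------------------------------
# Plain-text interchange
# ---------------------------------------------------------------------------


def layout_to_csv(layout: VeinLayout, outdir) -> dict:
    """Write node/edge tables (CSV) and a JSON metadata header.

    Returns the paths written.  Conductance columns are included when
    assigned.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = layout.grid
    nodes = pd.DataFrame(
        {
            "i": g.ij[:, 0],
            "j": g.ij[:, 1],
            "x": g.xz[:, 0],
            "z": g.xz[:, 1],
            "inside": 1,
            "a_ij": g.area,
        }
    )
    pet = pd.DataFrame(
        {"i": [-1], "j": [0], "x": [0.0], "z": [0.0], "inside": [0], "a_ij": [0.0]}
    )
    nodes = pd.concat([nodes, pet], ignore_index=True)
    edges = pd.DataFrame(
        {
            "u": layout.edges_u,
            "v": layout.edges_v,
            "order": layout.edge_order,
            "length": layout.edge_length,
        }
    )
    if layout.K_xyl is not None:
        edges["K_xyl"] = layout.K_xyl
        edges["K_ph"] = layout.K_ph
        edges["G_ph"] = layout.G_ph
    header = {
        "variant": layout.shape.variant,
        "length_m": layout.shape.length,
        "width_m": layout.shape.width,
        "spacing_m": layout.spacing,
        "theta_deg": layout.theta_deg,
        "mode": layout.mode,
        "n_nodes": layout.n,
        "meta": {k: v for k, v in layout.meta.items()},
        "total_length_by_order_m": layout.total_length_by_order(),
    }
    paths = {
        "nodes": outdir / "nodes.csv",
        "edges": outdir / "edges.csv",
        "header": outdir / "layout.json",
    }
    # 17 significant digits guarantee bit-exact float64 round-trips
    nodes.to_csv(paths["nodes"], index=False, float_format="%.17g")
    edges.to_csv(paths["edges"], index=False, float_format="%.17g")
    paths["header"].write_text(json.dumps(header, indent=2))
    return paths


def layout_from_csv(outdir) -> VeinLayout:
    """Rebuild a layout written by :func:`layout_to_csv`.

    The grid is regenerated from the header metadata (deterministic), and
    the stored edge table replaces the regenerated one bit-exactly.
    """
    import pandas as pd

    outdir = Path(outdir)
    header = json.loads((outdir / "layout.json").read_text())
    shape = make_leaf_shape(header["variant"])
    grid = build_grid(shape, header["spacing_m"])
    edges = pd.read_csv(outdir / "edges.csv", float_precision="round_trip")
    layout = VeinLayout(
        shape,
        header["spacing_m"],
        header["theta_deg"],
        header["mode"],
        grid,
        [],
        edges["u"].to_numpy(),
        edges["v"].to_numpy(),
        edges["order"].to_numpy(),
        edges["length"].to_numpy(),
        header.get("meta", {}),
    )
    if "K_xyl" in edges:
        layout.K_xyl = edges["K_xyl"].to_numpy()
        layout.K_ph = edges["K_ph"].to_numpy()
        layout.G_ph = edges["G_ph"].to_numpy()
    return layout
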