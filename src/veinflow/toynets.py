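"""Tiny hand-buildable networks for testing and verification.

These construct :class:`~veinflow.leafgeom.VeinLayout` objects directly
from explicit edge lists with prescribed conductances, bypassing the
leaf-geometry pipeline, so solver behavior can be checked against
closed forms and dense oracles.
"""

from __future__ import annotations

import math

import numpy as np

from .leafgeom import VeinLayout

__all__ = ["toy_layout", "chain_layout", "grid2x2_layout", "random_toy_layout"]


def toy_layout(n, edges, K_xyl, area, first=0, K_ph=None, G_ph=None,
               phloem_factor=0.03, G_scale=1e-12):
    """Build a toy network with n interior nodes plus a petiole (id n).

    ``edges`` is a list of (u, v) pairs over ids 0..n (the petiole edge
    must be included and must be the only edge touching node n).
    ``K_xyl`` may be a scalar or per-edge sequence; phloem and diffusive
    conductances default to proportional values.
    """
    edges = [tuple(e) for e in edges]
    m = len(edges)
    K_xyl = np.broadcast_to(np.asarray(K_xyl, dtype=float), (m,)).copy()
    K_ph = (phloem_factor * K_xyl if K_ph is None
            else np.broadcast_to(np.asarray(K_ph, dtype=float), (m,)).copy())
    G_ph = (G_scale * np.ones(m) if G_ph is None
            else np.broadcast_to(np.asarray(G_ph, dtype=float), (m,)).copy())
    area = np.broadcast_to(np.asarray(area, dtype=float), (n,)).copy()

    layout = VeinLayout(
        shape=None,
        spacing=float("nan"),
        theta_deg=0.0,
        mode="toy",
        grid=None,
        segments=[],
        edges_u=np.array([e[0] for e in edges], dtype=int),
        edges_v=np.array([e[1] for e in edges], dtype=int),
        edge_order=np.ones(m, dtype=int),
        edge_length=np.ones(m),
        meta={
            "n": n,
            "first": first,
            "area": area,
            "xz": np.column_stack([np.zeros(n), np.arange(n, dtype=float)]),
        },
        K_xyl=K_xyl,
        K_ph=K_ph,
        G_ph=G_ph,
    )
    return layout


def chain_layout(n, K_edge=5.0, area=4e-6, **kw):
    """Petiole -> node 0 -> ... -> node n-1 chain with uniform edges."""
    edges = [(0, n)] + [(i, i + 1) for i in range(n - 1)]
    return toy_layout(n, edges, K_edge, area, first=0, **kw)


def grid2x2_layout(K_edge=1.0, area=4e-6, **kw):
    """2x2 node square wired to the petiole through node 0."""
    edges = [(0, 4), (0, 1), (0, 2), (1, 3), (2, 3)]
    return toy_layout(4, edges, K_edge, area, first=0, **kw)


def random_toy_layout(rng, n_max=30):
    """Random connected toy network (spanning tree plus chords).

    Conductances span a few orders of magnitude; nodal areas are of
    leaf-cell size.  Node 0 is the petiole-adjacent node.
    """
    n = int(rng.integers(3, n_max + 1))
    edges = [(0, n)]
    for v in range(1, n):
        u = int(rng.integers(0, v))
        edges.append((u, v))
    n_extra = int(rng.integers(0, n // 2 + 1))
    for _ in range(n_extra):
        u, v = rng.choice(n, size=2, replace=False)
        if (min(u, v), max(u, v)) not in {(min(a, b), max(a, b)) for a, b in edges}:
            edges.append((int(u), int(v)))
    m = len(edges)
    K = 10.0 ** rng.uniform(-2, 1, size=m)
    area = 10.0 ** rng.uniform(-6.5, -5.5, size=n)
    G = 10.0 ** rng.uniform(-14, -11, size=m)
    return toy_layout(n, edges, K, area, first=0, G_ph=G)
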