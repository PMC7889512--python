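"""Shared fixtures: leaf solves and sweep tables reused across tests.

Expensive steady-state sweeps are session-scoped so the full suite pays
for each simulation campaign once.
"""

import numpy as np
import pytest

import veinflow as vf

VARIANTS = ("wide", "reference", "narrow")


@pytest.fixture(scope="session")
def ref_shape():
    return vf.make_leaf_shape("reference")


@pytest.fixture(scope="session")
def coarse_solve():
    """Reference leaf, 45 deg veins, 4 mm lattice: fast property probe."""
    params = vf.ModelParams()
    layout, state, diag = vf.solve_leaf("reference", 45.0, params, spacing=0.004)
    return layout, state, diag, params


@pytest.fixture(scope="session")
def solves45():
    """Core-parameter solves at 45 deg on the default 2 mm lattice."""
    params = vf.ModelParams()
    out = {}
    for v in VARIANTS:
        out[v] = vf.solve_leaf(v, 45.0, params)
    return out, params


@pytest.fixture(scope="session")
def core_sweeps():
    """Thirteen-angle sweeps, three shapes, core parameters."""
    return {v: vf.sweep_vein_angle(v) for v in VARIANTS}


@pytest.fixture(scope="session")
def k2x5_sweeps():
    """Sweeps with second-order conductance five-fold the core value."""
    params = vf.ModelParams().with_conductivity(2, 2.50e-3)
    return {v: vf.sweep_vein_angle(v, params=params) for v in VARIANTS}


@pytest.fixture(scope="session")
def k2fifth_sweeps():
    """Sweeps with second-order conductance one-fifth the core value."""
    params = vf.ModelParams().with_conductivity(2, 1.00e-4)
    return {v: vf.sweep_vein_angle(v, params=params) for v in VARIANTS}


def mirror_asymmetry(layout, field):
    """Largest |field(i,j) - field(i,-j)| over mirrored node pairs."""
    g = layout.grid
    worst = 0.0
    for (i, j), nid in g.index.items():
        if j > 0:
            mid = g.index.get((i, -j))
            if mid is not None:
                worst = max(worst, abs(field[nid] - field[mid]))
    return worst


def main_vein_profile(layout, field):
    """Field values along the main vein, petiole side to apex."""
    g = layout.grid
    ids = [g.index[(i, 0)] for i in range(g.i_max + 1) if (i, 0) in g.index]
    return np.asarray(field)[ids]
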