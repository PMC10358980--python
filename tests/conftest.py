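"""Shared fixtures.  Expensive simulations are session-scoped and reused."""

from __future__ import annotations

import numpy as np
import pytest

from mapeval.cells.twovar import TwoVariableModel
from mapeval.fixtures import build_standard_library
from mapeval.geometry import TissueGeometry, build_sheet_geometry
from mapeval.simulator import TissueParams, protocol_paced, run_monodomain

REENTRY_TS = 6.0  # time scale used by the standard library fixture


def make_cable(n: int = 81, spacing: float = 0.025) -> TissueGeometry:
    """1-D cable fixture: line elements along x."""
    nodes = np.column_stack([np.arange(n) * spacing, np.zeros(n), np.zeros(n)])
    elements = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    normals = np.tile([0.0, 0.0, 1.0], (n, 1))
    return TissueGeometry(nodes, elements, np.arange(n), normals,
                          np.empty((0, 3), dtype=np.int64))


@pytest.fixture(scope="session")
def nygren_strip_record():
    """Plane wave on a narrow sheet with the human atrial model (CV target)."""
    geom = build_sheet_geometry(81, 3, 0.025)
    params = TissueParams(duration=120.0)
    protocol = protocol_paced(geom, [0.0, 0.025, 0.0], radius=0.08, onset=1.0)
    return run_monodomain(geom, params, protocol, "nygren")


@pytest.fixture(scope="session")
def nygren_sheet_record():
    """Single paced beat on a 2 cm x 2 cm sheet (AcT-agreement target)."""
    geom = build_sheet_geometry(81, 81, 0.025)
    params = TissueParams(duration=90.0)
    protocol = protocol_paced(geom, [0.0, 1.0, 0.0], radius=0.15, onset=2.0)
    return run_monodomain(geom, params, protocol, "nygren")


@pytest.fixture(scope="session")
def twovar_sheet_record():
    """Centred paced beat on a symmetric sheet with the fast model."""
    geom = build_sheet_geometry(41, 41, 0.05)
    params = TissueParams(sigma=0.8, duration=300.0)
    protocol = protocol_paced(geom, [1.0, 1.0, 0.0], radius=0.12, onset=2.0)
    model = TwoVariableModel(time_scale=REENTRY_TS)
    return run_monodomain(geom, params, protocol, model)


@pytest.fixture(scope="session")
def std_library(tmp_path_factory):
    """The standard two-entry library (figure-of-eight + focal replication)."""
    out = tmp_path_factory.mktemp("stdlib")
    return build_standard_library(out_dir=out), out
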