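"""Virtual unipolar electrograms from the transmembrane-potential movie.

The extracellular potential at a point electrode x' is the volume-conductor
integral

    phi_e(x') = integral over the myocardium of  -sigma_e grad(Vm) . grad(1/r)

with r the distance from the source point to the electrode.  On P1 elements
grad(Vm) is constant per element, so the integral reduces to a fixed linear
map (the lead field) from nodal Vm values to electrode potentials, assembled
once with Gaussian quadrature and applied to every saved frame.  The
electrode is treated as a point; sheet geometries are given a nominal
uniform thickness so the integral remains a volume integral.

Uniform measurement noise is added per electrode: i.i.d. samples drawn
uniformly from [-level*dt, +level*dt] mV, with the level declared in mV/ms
(so at the standard 1 kHz sampling the bound is numerically equal to the
declared level).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem import element_gradients
from .geometry import ElectrodeArray, TissueGeometry
from .simulator import VmRecord

__all__ = ["ElectrogramParams", "ElectrogramSet", "lead_field", "compute_electrograms", "add_noise"]


@dataclass
class ElectrogramParams:
    """sigma_e: extracellular conductivity (mS/cm); quadrature_order: Gauss
    accuracy per element (1, 2, or >2 for the refined rule used as an
    accuracy oracle); sheet_thickness: nominal tissue thickness (cm) applied
    to surface-only (triangle) meshes."""

    sigma_e: float = 7.0
    quadrature_order: int = 2
    sheet_thickness: float = 0.03

    def __post_init__(self):
        if self.sigma_e <= 0:
            raise ValueError("sigma_e must be positive")
        if self.quadrature_order < 1:
            raise ValueError("quadrature order must be >= 1")


@dataclass
class ElectrogramSet:
    """Per-electrode extracellular time series sharing the Vm time base."""

    labels: list[str]
    times: np.ndarray
    phi_e: np.ndarray            # (n_electrodes, n_times) mV
    noise_levels: np.ndarray | None = None   # mV/ms per electrode
    noise_seed: int | None = None
    array: ElectrodeArray | None = field(default=None, repr=False)

    @property
    def sample_interval(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def trace(self, label: str) -> np.ndarray:
        return self.phi_e[self.labels.index(label)]


def _subdivide(verts: np.ndarray) -> list[np.ndarray]:
    """Uniform subdivision of a simplex given as (k, m) barycentric rows."""
    k = len(verts)
    if k == 3:
        a, b, c = verts
        ab, bc, ca = (a + b) / 2, (b + c) / 2, (c + a) / 2
        return [
            np.array([a, ab, ca]), np.array([ab, b, bc]),
            np.array([ca, bc, c]), np.array([ab, bc, ca]),
        ]
    if k == 4:
        a, b, c, d = verts
        ab, ac, ad = (a + b) / 2, (a + c) / 2, (a + d) / 2
        bc, bd, cd = (b + c) / 2, (b + d) / 2, (c + d) / 2
        # 4 corner tets + 4 tets of the inner octahedron split along ac-bd
        return [
            np.array([a, ab, ac, ad]), np.array([ab, b, bc, bd]),
            np.array([ac, bc, c, cd]), np.array([ad, bd, cd, d]),
            np.array([ab, ac, ad, bd]), np.array([ab, ac, bc, bd]),
            np.array([ac, ad, bd, cd]), np.array([ac, bc, bd, cd]),
        ]
    if k == 2:
        a, b = verts
        m = (a + b) / 2
        return [np.array([a, m]), np.array([m, b])]
    raise ValueError(f"unsupported simplex arity {k}")


def _base_rule(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Degree-2 rule on the reference simplex, barycentric points + weights."""
    if k == 2:
        g = 0.5 / np.sqrt(3.0)
        pts = np.array([[0.5 + g, 0.5 - g], [0.5 - g, 0.5 + g]])
        w = np.array([0.5, 0.5])
    elif k == 3:
        pts = np.array([
            [2 / 3, 1 / 6, 1 / 6], [1 / 6, 2 / 3, 1 / 6], [1 / 6, 1 / 6, 2 / 3],
        ])
        w = np.full(3, 1 / 3)
    elif k == 4:
        a, b = 0.5854101966249685, 0.1381966011250105
        pts = np.array([
            [a, b, b, b], [b, a, b, b], [b, b, a, b], [b, b, b, a],
        ])
        w = np.full(4, 0.25)
    else:
        raise ValueError(f"unsupported simplex arity {k}")
    return pts, w


def reference_quadrature(k: int, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric quadrature points and weights (summing to 1).

    order 1: centroid; order 2: the degree-2 simplex rule; order > 2: the
    degree-2 rule applied on uniformly subdivided child simplices (one
    level for orders 3-4, two levels above), which serves as the refined
    accuracy oracle for the smooth 1/r kernels integrated here.
    """
    if order == 1:
        return np.full((1, k), 1.0 / k), np.array([1.0])
    base_pts, base_w = _base_rule(k)
    if order == 2:
        return base_pts, base_w
    levels = 1 if order <= 4 else 2
    simplices = [np.eye(k)]
    for _ in range(levels):
        simplices = [child for s in simplices for child in _subdivide(s)]
    pts, ws = [], []
    frac = 1.0 / len(simplices)
    for s in simplices:
        # base points expressed in the child simplex: barycentric composition
        pts.append(base_pts @ s)
        ws.append(base_w * frac)
    return np.vstack(pts), np.concatenate(ws)


def lead_field(
    geom: TissueGeometry,
    array: ElectrodeArray,
    params: ElectrogramParams | None = None,
) -> np.ndarray:
    """Assemble the (n_electrodes, n_nodes) linear map from Vm to phi_e."""
    params = params or ElectrogramParams()
    elements = geom.elements
    k = elements.shape[1]
    if k == 2:
        raise ValueError("electrograms need triangle or tetrahedral elements")
    grads, measures = element_gradients(geom.nodes, elements)
    vol = measures * (params.sheet_thickness if k == 3 else 1.0)
    qpts_b, qw = reference_quadrature(k, params.quadrature_order)
    # quadrature points in space: (E, Q, 3)
    P = geom.nodes[elements]                      # (E, k, 3)
    X = np.einsum("qk,ekd->eqd", qpts_b, P)

    L = np.zeros((array.n_electrodes, geom.n_nodes))
    sig = params.sigma_e
    for ie in range(array.n_electrodes):
        xe = array.positions[ie]
        dvec = X - xe                              # (E, Q, 3)
        r = np.linalg.norm(dvec, axis=2)
        if np.min(r) < 1e-9:
            raise ValueError(
                f"electrode {array.labels[ie]!r} coincides with a quadrature point"
            )
        # -sigma_e * g_i . grad_x(1/r) = -sigma_e * g_i . (-(x-x')/r^3)
        kern = dvec / r[:, :, None] ** 3           # (E, Q, 3)
        wk = np.einsum("q,eqd->ed", qw, kern)      # weighted kernel per element
        contrib = sig * np.einsum("ekd,ed->ek", grads, wk) * vol[:, None]
        np.add.at(L[ie], elements.ravel(), contrib.ravel())
    return L


def compute_electrograms(
    record: VmRecord,
    array: ElectrodeArray,
    params: ElectrogramParams | None = None,
) -> ElectrogramSet:
    """Evaluate the unipolar electrogram at every electrode and saved frame."""
    params = params or ElectrogramParams()
    L = lead_field(record.geometry, array, params)
    phi = L @ np.asarray(record.vm, dtype=float)
    return ElectrogramSet(
        labels=list(array.labels),
        times=np.asarray(record.times, dtype=float),
        phi_e=phi,
        array=array,
    )


def add_noise(egms: ElectrogramSet, level_per_electrode, seed: int) -> ElectrogramSet:
    """Add uniform measurement noise, level declared in mV/ms per electrode.

    Samples are i.i.d. uniform on [-level*dt, +level*dt] mV per time sample
    (dt = sampling interval, 1 ms at 1 kHz).  Deterministic given the seed;
    level 0 leaves traces untouched.
    """
    levels = np.broadcast_to(
        np.asarray(level_per_electrode, dtype=float), (len(egms.labels),)
    ).copy()
    if np.any(levels < 0):
        raise ValueError("noise levels must be non-negative")
    dt = egms.sample_interval or 1.0
    rng = np.random.default_rng(seed)
    noise = rng.uniform(-1.0, 1.0, size=egms.phi_e.shape) * (levels[:, None] * dt)
    return ElectrogramSet(
        labels=list(egms.labels),
        times=egms.times.copy(),
        phi_e=egms.phi_e + noise,
        noise_levels=levels,
        noise_seed=int(seed),
        array=egms.array,
    )
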