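"""P1 finite-element operators on cable, triangle and tetrahedral meshes.

Provides the lumped mass matrix, the stiffness matrix for a unit isotropic
conductivity, and per-element shape-function gradients (3-D vectors), which
the simulator uses for diffusion and the electrogram module reuses to
evaluate the piecewise-constant spatial gradient of the potential.
Element measures are lengths (cm), areas (cm^2) or volumes (cm^3).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def element_gradients(nodes: np.ndarray, elements: np.ndarray):
    """Shape-function gradients and measures for P1 simplices.

    Returns ``grads`` of shape (E, k, 3) — the 3-D gradient of each of the
    k local basis functions (in-plane for surface triangles embedded in
    3-D) — and ``measures`` of shape (E,).
    """
    k = elements.shape[1]
    E = len(elements)
    grads = np.zeros((E, k, 3))
    measures = np.zeros(E)
    P = nodes[elements]  # (E, k, 3)
    if k == 2:
        d = P[:, 1] - P[:, 0]
        L = np.linalg.norm(d, axis=1)
        t = d / L[:, None]
        grads[:, 1] = t / L[:, None]
        grads[:, 0] = -grads[:, 1]
        measures = L
    elif k == 3:
        e1 = P[:, 1] - P[:, 0]
        e2 = P[:, 2] - P[:, 0]
        n = np.cross(e1, e2)
        twoA = np.linalg.norm(n, axis=1)
        measures = 0.5 * twoA
        nhat = n / twoA[:, None]
        # gradient of basis i is the 90-deg in-plane rotation of the opposite
        # edge, divided by twice the area
        opp = np.stack([P[:, 2] - P[:, 1], P[:, 0] - P[:, 2], P[:, 1] - P[:, 0]], axis=1)
        for i in range(3):
            grads[:, i] = np.cross(nhat, opp[:, i]) / twoA[:, None]
    elif k == 4:
        # rows of the inverse Jacobian give gradients of barycentric coords
        J = np.stack([P[:, 1] - P[:, 0], P[:, 2] - P[:, 0], P[:, 3] - P[:, 0]], axis=1)
        detJ = np.linalg.det(J)
        measures = np.abs(detJ) / 6.0
        Jinv = np.linalg.inv(J)
        # with x - P0 = lambda @ J, grad(lambda_i) is column i of J^-1
        grads[:, 1:] = np.transpose(Jinv, (0, 2, 1))
        grads[:, 0] = -grads[:, 1] - grads[:, 2] - grads[:, 3]
    else:
        raise ValueError(f"unsupported element arity {k}")
    return grads, measures


def assemble_operators(nodes: np.ndarray, elements: np.ndarray):
    """Lumped mass vector M (per node) and stiffness matrix K (unit sigma)."""
    n = len(nodes)
    k = elements.shape[1]
    grads, measures = element_gradients(nodes, elements)
    # local stiffness: measure * (g_i . g_j)
    local = np.einsum("eid,ejd->eij", grads, grads) * measures[:, None, None]
    rows = np.repeat(elements, k, axis=1).ravel()
    cols = np.tile(elements, (1, k)).ravel()
    K = sp.coo_matrix((local.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    M = np.zeros(n)
    np.add.at(M, elements.ravel(), np.repeat(measures / k, k))
    return M, K, grads, measures
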