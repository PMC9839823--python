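"""P1 finite elements on the current Eulerian configuration.

Because the reference->current map is affine per element, assembling the
Laplace-Beltrami operator in the Lagrangian frame with the discrete metric
is identical to assembling the plain Laplacian on the current node
positions; we do the latter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from rdgrow.sim2d.mesh import PlanarMesh, _signed_areas

__all__ = [
    "PotentialField",
    "assemble_p1",
    "solve_potential",
    "node_velocities",
]


@dataclass
class PotentialField:
    """Flow potential and derived velocities.

    phi: nodal potential (zero on the boundary).
    a: recovered nodal velocity grad(phi), (n, 2).
    boundary_flux: consistent normal flux int(dphi/dn psi_b ds) per boundary
    node; sums exactly to the discrete int(S dA).
    """

    phi: np.ndarray
    a: np.ndarray
    boundary_flux: np.ndarray
    total_source: float


def assemble_p1(coords: np.ndarray, tris: np.ndarray):
    """Stiffness K, consistent mass M, lumped mass diagonal, element data.

    Returns (K, M, lumped, grads, areas) where grads[(nt, 3, 2)] holds the
    barycentric-basis gradients used for gradient recovery.
    """
    nt = tris.shape[0]
    n = coords.shape[0]
    p = coords[tris]
    areas = _signed_areas(coords, tris)
    if np.any(areas <= 0):
        raise ValueError("mesh contains inverted or degenerate elements")
    # gradients of the three barycentric functions
    b = np.empty((nt, 3))
    c = np.empty((nt, 3))
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        b[:, i] = p[:, j, 1] - p[:, k, 1]
        c[:, i] = p[:, k, 0] - p[:, j, 0]
    grads = np.stack([b, c], axis=-1) / (2.0 * areas[:, None, None])

    Ke = np.einsum("tid,tjd->tij", grads, grads) * areas[:, None, None]
    Me = (np.ones((3, 3)) + np.eye(3))[None, :, :] * (areas[:, None, None] / 12.0)

    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    K = sparse.coo_array((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    M = sparse.coo_array((Me.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    lumped = np.zeros(n)
    np.add.at(lumped, tris.ravel(), np.repeat(areas / 3.0, 3))
    return K, M, lumped, grads, areas


def _recover_gradient(
    nodal: np.ndarray, tris: np.ndarray, grads: np.ndarray, areas: np.ndarray, n: int
) -> np.ndarray:
    """Area-weighted average of per-element P1 gradients at the nodes."""
    ge = np.einsum("ti,tid->td", nodal[tris], grads)  # (nt, 2)
    out = np.zeros((n, 2))
    wsum = np.zeros(n)
    w = np.repeat(areas, 3)
    np.add.at(out, tris.ravel(), np.repeat(ge, 3, axis=0) * w[:, None])
    np.add.at(wsum, tris.ravel(), w)
    return out / wsum[:, None]


def solve_potential(mesh: PlanarMesh, S_nodes: np.ndarray) -> PotentialField:
    """Solve lap(phi) = S on the current geometry with phi = 0 on the boundary."""
    S_nodes = np.asarray(S_nodes, dtype=float)
    n = mesh.n_nodes
    K, M, _, grads, areas = assemble_p1(mesh.x, mesh.triangles)
    load = -(M @ S_nodes)
    bnodes = mesh.boundary_loop
    interior = np.setdiff1d(np.arange(n), bnodes)
    phi = np.zeros(n)
    if interior.size:
        Kii = K[interior][:, interior]
        phi[interior] = spsolve(Kii.tocsc(), load[interior])
    if not np.all(np.isfinite(phi)):
        raise RuntimeError("singular Poisson system (degenerate mesh?)")
    a = _recover_gradient(phi, mesh.triangles, grads, areas, n)
    # consistent flux: int dphi/dn psi_b ds = (K phi)_b + (M S)_b
    resid = K @ phi + M @ S_nodes
    flux = resid[bnodes]
    return PotentialField(
        phi=phi, a=a, boundary_flux=flux, total_source=float(M @ S_nodes @ np.ones(n))
    )


def node_velocities(mesh: PlanarMesh, pot: PotentialField) -> np.ndarray:
    """Mesh velocity: recovered grad(phi) in the interior; on the boundary the
    consistent flux divided by the control length, directed along the outward
    area-gradient normal (so the discrete rate of area change equals the
    discrete total source exactly)."""
    v = pot.a.copy()
    loop = mesh.boundary_loop
    ring = mesh.x[loop]
    nxt = np.roll(ring, -1, axis=0)
    prv = np.roll(ring, 1, axis=0)
    g = 0.5 * np.column_stack([nxt[:, 1] - prv[:, 1], prv[:, 0] - nxt[:, 0]])
    glen = np.linalg.norm(g, axis=1)
    v[loop] = (pot.boundary_flux / glen**2)[:, None] * g
    return v
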