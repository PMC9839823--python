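"""Moving-mesh time stepping for the planar potential-flow model.

Each step is a first-order splitting: (i) solve the Poisson problem for the
flow potential from the current concentrations, (ii) advect the mesh nodes
with the flow (boundary nodes along the outward normal), (iii) take an
implicit backward-Euler step of reaction-diffusion-dilution on the moved
mesh. Because the mesh velocity is the material velocity, no convective
term appears.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import factorized

from rdgrow.kinetics import (
    GrowthLaw,
    KineticsSpec,
    evaluate_growth,
    evaluate_kinetics,
    find_equilibria,
    kinetics_jacobian_field,
)
from rdgrow.sim2d.fem import assemble_p1, node_velocities, solve_potential
from rdgrow.sim2d.mesh import (
    DomainSpec2D,
    PlanarMesh,
    _signed_areas,
    generate_domain,
    heal_ring,
    mesh_polygon,
    ring_bunching,
    triangle_quality,
)

__all__ = [
    "Sim2DConfig",
    "SimResult2D",
    "advance_2d",
    "remesh_2d",
    "run_simulation_2d",
    "initial_fields_2d",
]


@dataclass
class Sim2DConfig:
    domain: DomainSpec2D
    kinetics: KineticsSpec
    growth: GrowthLaw
    D: Sequence[float]
    t_final: float
    ic_mode: str = "noisy_equilibrium"  # or "custom"
    ic_profile: Optional[Callable] = None  # (x, y) -> (m, n) or (n,)
    noise_variance: float = 1e-2
    seed: int = 0
    dt_init: float = 0.1
    dt_max: float = 1.0
    cfl: float = 0.2
    newton_tol: float = 1e-9
    quality_threshold: float = 0.3
    n_snapshots: int = 6
    snapshot_times: Optional[Sequence[float]] = None
    store_fields: bool = True
    dilution: str = "geometric"  # or "nominal"
    max_boundary_edge_factor: float = 1.5


@dataclass
class SimResult2D:
    snapshot_times: list
    snapshots: list  # dicts: t, coords, triangles, u, boundary
    series: dict  # t, area, total_S, u_max, u_min
    config_hash: str = ""
    seed: Optional[int] = None


class _StepFailure(RuntimeError):
    pass


# ----------------------------------------------------------------------------


def _newton_rd_step(
    coords, tris, u_old, dt, spec, law, t_new, D, S_eff, tol, max_iter=12
):
    """Backward-Euler solve of u' = D lap u - u S + f(u) on fixed coords.

    ``S_eff`` (per node) is the dilution rate; pass None to evaluate the
    growth law at the implicit state instead (nominal dilution).
    """
    K, _, lumped, _, _ = assemble_p1(coords, tris)
    m, n = u_old.shape
    L = lumped
    u = u_old.copy()
    nominal = S_eff is None
    for _ in range(max_iter):
        S = evaluate_growth(law, t_new, u) if nominal else S_eff
        S = np.broadcast_to(S, (n,))
        f = evaluate_kinetics(spec, u)
        Jf = kinetics_jacobian_field(spec, u)
        Jf = np.broadcast_to(Jf, (m, m, n))
        blocks = []
        res = np.empty((m, n))
        for s in range(m):
            res[s] = L * (u[s] - u_old[s]) / dt + D[s] * (K @ u[s]) + L * (
                u[s] * S - f[s]
            )
        if nominal:
            from rdgrow.kinetics import growth_gradient_field

            gS = growth_gradient_field(law, t_new, u)
        for s in range(m):
            row = []
            for s2 in range(m):
                diag = -Jf[s, s2]
                if s == s2:
                    diag = diag + S
                if nominal:
                    diag = diag + u[s] * gS[s2]
                A = sparse.diags_array(L * diag)
                if s == s2:
                    A = A + sparse.diags_array(L / dt) + D[s] * K
                row.append(A)
            blocks.append(row)
        A = sparse.bmat(blocks, format="csc") if m > 1 else blocks[0][0].tocsc()
        try:
            delta = factorized(A)(res.ravel())
        except RuntimeError as exc:
            raise _StepFailure(f"linear solve failed: {exc}") from exc
        u = u - delta.reshape(m, n)
        scale = max(1.0, float(np.max(np.abs(u))))
        if np.max(np.abs(delta)) < tol * scale:
            if not np.all(np.isfinite(u)):
                raise _StepFailure("non-finite state after Newton step")
            return u
    raise _StepFailure("Newton did not converge")


def advance_2d(
    mesh: PlanarMesh,
    u: np.ndarray,
    t: float,
    spec: KineticsSpec,
    law: GrowthLaw,
    D: Sequence[float],
    dt: float,
    cfl: float = 0.2,
    newton_tol: float = 1e-9,
    max_halvings: int = 10,
    dilution: str = "geometric",
):
    """One splitting step; returns (mesh, u, t_new, info).

    ``dt`` is a request: it is capped by the CFL-like constraint
    max|v| dt < cfl * h and halved (up to ``max_halvings``) on element
    inversion or Newton failure.
    """
    u = np.atleast_2d(np.asarray(u, dtype=float))
    D = np.asarray(D, dtype=float)
    n = mesh.n_nodes
    S0 = np.broadcast_to(evaluate_growth(law, t, u), (n,))
    pot = solve_potential(mesh, S0)
    v = node_velocities(mesh, pot)
    vmax = float(np.max(np.linalg.norm(v, axis=1)))
    areas = mesh.element_areas()
    h_ref = float(np.sqrt(4.0 * np.percentile(areas, 5) / np.sqrt(3.0)))
    if vmax > 0:
        dt = min(dt, cfl * h_ref / vmax)

    _, _, lumped_old, _, _ = assemble_p1(mesh.x, mesh.triangles)
    for attempt in range(max_halvings + 1):
        x_new = mesh.x + dt * v
        if np.any(_signed_areas(x_new, mesh.triangles) <= 0):
            dt *= 0.5
            continue
        _, _, lumped_new, _, _ = assemble_p1(x_new, mesh.triangles)
        if dilution == "geometric":
            S_eff = (lumped_new - lumped_old) / (dt * lumped_new)
        else:
            S_eff = None
        try:
            u_new = _newton_rd_step(
                x_new, mesh.triangles, u, dt, spec, law, t + dt, D, S_eff, newton_tol
            )
        except _StepFailure:
            dt *= 0.5
            continue
        new_mesh = PlanarMesh(mesh.X, mesh.triangles, x_new, mesh.boundary_loop)
        info = {
            "dt": dt,
            "vmax": vmax,
            "total_source": pot.total_source,
            "halvings": attempt,
        }
        return new_mesh, u_new, t + dt, info
    raise RuntimeError(
        f"step failed at t={t:.6g}: element inversion/Newton failure after "
        f"{max_halvings} halvings (dt={dt:.3g})"
    )


# ----------------------------------------------------------------------------


def _interpolate_fields(
    old_coords: np.ndarray, old_tris: np.ndarray, old_u: np.ndarray, pts: np.ndarray
) -> np.ndarray:
    """Barycentric P1 interpolation with nearest-node fallback off-mesh.

    Candidate elements are found through a KD-tree over element centroids,
    which stays robust on meshes that are no longer Delaunay (or contain
    slivers) after advection.
    """
    from scipy.spatial import cKDTree

    corners = old_coords[old_tris]  # (nt, 3, 2)
    centroids = corners.mean(axis=1)
    tree = cKDTree(centroids)
    k = min(12, centroids.shape[0])
    _, cand = tree.query(pts, k=k)
    cand = np.atleast_2d(cand)

    a = corners[:, 0]
    e1 = corners[:, 1] - a
    e2 = corners[:, 2] - a
    det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    det = np.where(np.abs(det) < 1e-300, np.nan, det)

    n_pts = pts.shape[0]
    m = old_u.shape[0]
    out = np.empty((m, n_pts))
    found = np.zeros(n_pts, dtype=bool)
    lam = np.empty((n_pts, 3))
    tri_of = np.zeros(n_pts, dtype=np.int64)
    tol = -1e-9
    for col in range(cand.shape[1]):
        idx = cand[:, col]
        rel = pts - a[idx]
        l1 = (rel[:, 0] * e2[idx, 1] - rel[:, 1] * e2[idx, 0]) / det[idx]
        l2 = (e1[idx, 0] * rel[:, 1] - e1[idx, 1] * rel[:, 0]) / det[idx]
        l0 = 1.0 - l1 - l2
        inside = (l0 >= tol) & (l1 >= tol) & (l2 >= tol) & ~found
        lam[inside] = np.column_stack([l0, l1, l2])[inside]
        tri_of[inside] = idx[inside]
        found |= inside
        if found.all():
            break
    if np.any(found):
        vals = old_u[:, old_tris[tri_of]]  # (m, n_pts, 3)
        out[:, :] = np.einsum("mpc,pc->mp", vals, lam)
    if not found.all():
        node_tree = cKDTree(old_coords)
        _, nn = node_tree.query(pts[~found])
        out[:, ~found] = old_u[:, nn]
    return out


def remesh_2d(
    mesh: PlanarMesh, u: np.ndarray, h: float, max_edge_factor: float = 1.5
):
    """Re-triangulate the current Eulerian boundary; fields carried over by
    barycentric interpolation. The current geometry becomes the new
    reference (mu resets to one)."""
    u = np.atleast_2d(np.asarray(u, dtype=float))
    ring = mesh.boundary_polyline
    nxt = np.roll(ring, -1, axis=0)
    lens = np.linalg.norm(nxt - ring, axis=1)
    if np.any(lens > max_edge_factor * h):
        # insert chord midpoints on over-long edges (area-exact refinement)
        parts = []
        for i in range(len(ring)):
            parts.append(ring[i])
            if lens[i] > max_edge_factor * h:
                parts.append(0.5 * (ring[i] + nxt[i]))
        ring = np.asarray(parts)
    ring = heal_ring(ring)
    new_mesh = mesh_polygon(ring, h, resample_boundary=False)
    u_new = _interpolate_fields(mesh.x, mesh.triangles, u, new_mesh.X)
    return new_mesh, u_new


# ----------------------------------------------------------------------------


def initial_fields_2d(config: Sim2DConfig, mesh: PlanarMesh) -> np.ndarray:
    m = config.kinetics.n_species
    if config.ic_mode == "custom":
        vals = np.asarray(
            config.ic_profile(mesh.X[:, 0], mesh.X[:, 1]), dtype=float
        )
        return np.atleast_2d(vals)
    eqs = find_equilibria(config.kinetics)
    pos = [e for e in eqs if np.all(e.u_star > 0)]
    u_star = (pos or eqs)[-1].u_star
    rng = np.random.Generator(np.random.Philox(config.seed))
    eta = rng.normal(0.0, np.sqrt(config.noise_variance), size=(m, mesh.n_nodes))
    return u_star[:, None] * (1.0 + eta)


def run_simulation_2d(config: Sim2DConfig) -> SimResult2D:
    """Epoch loop of advance/remesh with snapshots and series records."""
    mesh = generate_domain(config.domain)
    u = initial_fields_2d(config, mesh)
    t = 0.0
    if config.snapshot_times is not None:
        snap_times = sorted(
            s for s in config.snapshot_times if 0.0 <= s <= config.t_final
        )
    else:
        snap_times = list(np.linspace(0.0, config.t_final, config.n_snapshots))

    snapshots = []
    snap_recorded = []

    def take_snapshot():
        snap = {
            "t": t,
            "boundary": mesh.boundary_polyline.copy(),
            "area": mesh.area(),
        }
        if config.store_fields:
            snap.update(
                coords=mesh.x.copy(), triangles=mesh.triangles.copy(), u=u.copy()
            )
        snapshots.append(snap)
        snap_recorded.append(t)

    series = {"t": [], "area": [], "total_S": [], "u_max": [], "u_min": []}

    def record(total_source):
        series["t"].append(t)
        series["area"].append(mesh.area())
        series["total_S"].append(total_source)
        series["u_max"].append(float(np.max(u[0])))
        series["u_min"].append(float(np.min(u[0])))

    n_bnodes = np.broadcast_to(
        evaluate_growth(config.growth, 0.0, u), (mesh.n_nodes,)
    )
    record(float(np.sum(assemble_p1(mesh.x, mesh.triangles)[2] * n_bnodes)))
    if snap_times and snap_times[0] <= 0.0:
        take_snapshot()
        snap_times = [s for s in snap_times if s > 0.0]

    dt = config.dt_init
    # slender geometries (e.g. the dumbbell channel) start below the absolute
    # quality threshold; trigger on degradation relative to the last remesh
    q_ref = float(np.min(triangle_quality(mesh.x, mesh.triangles)))
    while t < config.t_final - 1e-9:
        pending = [s for s in snap_times if s > t + 1e-9]
        cap = min(pending[0] - t if pending else np.inf, config.t_final - t)
        mesh, u, t, info = advance_2d(
            mesh,
            u,
            t,
            config.kinetics,
            config.growth,
            config.D,
            min(dt, cap),
            cfl=config.cfl,
            newton_tol=config.newton_tol,
            dilution=config.dilution,
        )
        record(info["total_source"])
        dt = min(info["dt"] * 1.2, config.dt_max)
        if pending and abs(t - pending[0]) < 1e-9:
            take_snapshot()
        q_min = float(np.min(triangle_quality(mesh.x, mesh.triangles)))
        ring = mesh.x[mesh.boundary_loop]
        blens = np.linalg.norm(np.roll(ring, -1, axis=0) - ring, axis=1)
        if (
            q_min < min(config.quality_threshold, 0.6 * q_ref)
            or float(np.max(blens)) > config.max_boundary_edge_factor * config.domain.h
            or ring_bunching(ring) < 0.25
        ):
            mesh, u = remesh_2d(
                mesh, u, config.domain.h, config.max_boundary_edge_factor
            )
            q_ref = float(np.min(triangle_quality(mesh.x, mesh.triangles)))

    if not snapshots or abs(snap_recorded[-1] - t) > 1e-9:
        take_snapshot()
    return SimResult2D(
        snapshot_times=snap_recorded,
        snapshots=snapshots,
        series={k: np.asarray(v) for k, v in series.items()},
        config_hash=hashlib.sha256(repr(config).encode()).hexdigest()[:16],
        seed=config.seed,
    )
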