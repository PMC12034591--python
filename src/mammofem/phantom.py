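"""Synthetic prone breast phantoms and forward-simulated supine observations.

No patient meshes or CT clouds are available, so every downstream stage is
exercised on phantoms: a hemispherical breast of configurable radius seated
on a cylindrically curved chest-wall patch. The hemisphere is meshed by
Delaunay triangulation of a seeded point lattice (the domain is convex, so
the triangulation fills it exactly), then sheared in z so its base lies on
the curved chest surface z = -curvature * x^2 — a volume-preserving map
that keeps the analytic hemisphere volume available as a meshing check and
makes the chest base an exact quadric height field.

Tissue layout (labels assigned by element centroid, in priority order):
tumor sphere, skin shell on the outer surface, deep adipose within the
configurable layer against the chest wall, a glandular ball, and
superficial adipose elsewhere. The chest midline strip (medial edge of the
base) is the fixed boundary; the inframammary-fold endpoint chain is the
inferior half of the base rim, ordered mid-chest to axilla.

Supine observations are produced by running the forward model (gravity +
contact + anchoring, no observation forces) and sampling the deformed
surface and the chest wall as point clouds with configurable Gaussian
noise, paired with exact ground truth for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import Delaunay

from . import anchoring as anch_mod
from . import contact as contact_mod
from . import fem
from .mesh import LabeledTetMesh, TissueLabel, extract_surface, orient_tets, \
    tet_volumes, find_containing_tets, interpolate_displacement


class PhantomError(ValueError):
    pass


@dataclass
class PhantomParams:
    """Geometry and discretization of one synthetic breast phantom."""

    breast_radius: float = 50.0  # mm
    chest_curvature: float = 0.002  # 1/mm, chest height = -c * x^2
    deep_layer_thickness: float = 15.0  # mm
    skin_thickness: float = 3.0  # mm
    tumor_center: tuple = (10.0, -8.0, 22.0)  # mm, unsheared frame
    tumor_radius: float = 7.5  # mm
    target_node_count: int = 1500
    seed: int = 0
    fixed_halfwidth: float = 5.0  # mm, width of the medial fixed strip
    gland_center_frac: float = 0.35  # gland center height, fraction of R
    gland_radius_frac: float = 0.50  # gland radius, fraction of R

    def validate(self) -> None:
        if self.breast_radius <= 0:
            raise PhantomError("degenerate parameter breast_radius: must be > 0")
        if not 0 <= self.deep_layer_thickness < self.breast_radius:
            raise PhantomError("degenerate parameter deep_layer_thickness: "
                               "must satisfy 0 <= t < breast_radius")
        if self.skin_thickness < 0:
            raise PhantomError("degenerate parameter skin_thickness: must be >= 0")
        if self.target_node_count < 50:
            raise PhantomError("degenerate parameter target_node_count: too small "
                               "to mesh (need >= 50)")
        c = np.asarray(self.tumor_center, dtype=float)
        if np.linalg.norm(c) + self.tumor_radius >= self.breast_radius \
                or c[2] - self.tumor_radius <= 0:
            raise PhantomError("tumor sphere is not strictly inside the breast volume")


@dataclass
class GroundTruth:
    """Exact supine state paired with an observation set.

    ``supine_tumor_points`` equals ``prone_tumor_points`` advected by
    ``true_displacement`` (barycentric interpolation); fiducials are the
    noise-free supine fiducial positions in the model frame.
    """

    true_displacement: np.ndarray  # (N, 3) mm
    supine_tumor_points: np.ndarray
    supine_fiducials: np.ndarray
    prone_tumor_points: np.ndarray
    meta: dict = field(default_factory=dict)


class ObservationError(RuntimeError):
    def __init__(self, msg, residual_history=None):
        super().__init__(msg)
        self.residual_history = residual_history or []


# -- meshing -------------------------------------------------------------

def _estimate_node_count(h: float, R: float) -> float:
    ri = max(R - 0.6 * h, 0.0)
    v_int = max((2.0 / 3.0) * np.pi * ri**3 - np.pi * ri**2 * 0.6 * h, 0.0)
    n_int = v_int / h**3
    n_cap = 2 * np.pi * R**2 / h**2
    n_base = np.pi * R**2 / h**2
    n_rim = 2 * np.pi * R / h
    return n_int + n_cap + n_base + n_rim


def _lattice_spacing(R: float, target: int) -> float:
    f = lambda h: _estimate_node_count(h, R) - target
    lo, hi = R / 50.0, R
    if f(lo) < 0:
        return lo
    return brentq(f, lo, hi, xtol=1e-6)


def _hemisphere_points(params: PhantomParams, h: float, rng: np.random.Generator):
    R = params.breast_radius
    pts = []

    # interior lattice, lightly jittered to avoid degenerate Delaunay slivers
    margin = 0.6 * h
    ax = np.arange(-R + margin, R - margin + 1e-9, h)
    az = np.arange(margin, R - margin + 1e-9, h)
    X, Y, Z = np.meshgrid(ax, ax, az, indexing="ij")
    lat = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    lat = lat + rng.uniform(-0.08 * h, 0.08 * h, size=lat.shape)
    keep = (np.linalg.norm(lat, axis=1) <= R - margin) & (lat[:, 2] >= margin)
    pts.append(lat[keep])

    # spherical cap (Fibonacci spiral, uniform in area)
    n_cap = max(int(round(2 * np.pi * R**2 / h**2)), 8)
    k = np.arange(n_cap)
    z = R * (k + 0.5) / n_cap
    r = np.sqrt(np.maximum(R**2 - z**2, 0.0))
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    cap = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pts.append(cap[cap[:, 2] >= 0.5 * h])

    # base rim ring (exactly radius R, z = 0)
    n_rim = max(int(round(2 * np.pi * R / h)), 8)
    th = 2 * np.pi * np.arange(n_rim) / n_rim
    rim = np.column_stack([R * np.cos(th), R * np.sin(th), np.zeros(n_rim)])
    pts.append(rim)

    # base disk (Vogel spiral, z = 0)
    n_base = max(int(round(np.pi * R**2 / h**2)), 8)
    k = np.arange(n_base)
    rr = (R - 0.7 * h) * np.sqrt((k + 0.5) / n_base)
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    base = np.column_stack([rr * np.cos(phi), rr * np.sin(phi), np.zeros(n_base)])
    pts.append(base)

    return np.vstack(pts), rim, n_rim


def generate_breast_phantom(params: PhantomParams) -> LabeledTetMesh:
    """Generate a labeled tetrahedral breast phantom.

    Deterministic: the same parameters (including the seed) reproduce the
    phantom byte-for-byte.
    """
    params.validate()
    R = params.breast_radius
    rng = np.random.default_rng(params.seed)
    h = _lattice_spacing(R, params.target_node_count)

    points, _, _ = _hemisphere_points(params, h, rng)
    try:
        tri = Delaunay(points)
    except Exception as exc:  # pragma: no cover - qhull failure
        raise PhantomError(f"meshing failure for breast_radius={R}, "
                           f"target_node_count={params.target_node_count}: {exc}")
    tets = orient_tets(points, tri.simplices)
    vol = tet_volumes(points, tets)
    tets = tets[vol > 1e-4 * h**3]  # drop boundary slivers
    if len(tets) == 0:
        raise PhantomError(f"meshing failure: all elements degenerate at "
                           f"target_node_count={params.target_node_count}")

    # drop unreferenced nodes and reindex
    used = np.unique(tets)
    remap = -np.ones(len(points), dtype=np.int64)
    remap[used] = np.arange(len(used))
    nodes_u = points[used]  # unsheared coordinates
    tets = remap[tets]

    # labels from unsheared centroids (priority: tumor > skin > deep > gland)
    cent = nodes_u[tets].mean(axis=1)
    labels = np.full(len(tets), int(TissueLabel.SUPERFICIAL_ADIPOSE), dtype=np.int64)
    gland_c = np.array([0.0, 0.0, params.gland_center_frac * R])
    in_gland = np.linalg.norm(cent - gland_c, axis=1) < params.gland_radius_frac * R
    labels[in_gland] = int(TissueLabel.GLAND)
    labels[cent[:, 2] < params.deep_layer_thickness] = int(TissueLabel.DEEP_ADIPOSE)
    labels[np.linalg.norm(cent, axis=1) > R - params.skin_thickness] = int(TissueLabel.SKIN)
    tum_c = np.asarray(params.tumor_center, dtype=float)
    labels[np.linalg.norm(cent - tum_c, axis=1) < params.tumor_radius] = int(TissueLabel.TUMOR)

    # shear onto the curved chest patch: z -> z - c * x^2 (volume-preserving)
    chest_height = -params.chest_curvature * nodes_u[:, 0] ** 2
    nodes = nodes_u.copy()
    nodes[:, 2] = nodes_u[:, 2] + chest_height

    surface = extract_surface(nodes, tets)
    surf_nodes = np.unique(surface)
    zu = nodes_u[:, 2]  # distance to chest wall along the anterior axis
    on_base = np.zeros(len(nodes), dtype=bool)
    on_base[surf_nodes] = zu[surf_nodes] < 1e-9
    chest_nodes = np.nonzero(on_base)[0]

    fixed = chest_nodes[nodes_u[chest_nodes, 0] <= -R + params.fixed_halfwidth]
    if fixed.size == 0:
        raise PhantomError("degenerate parameter fixed_halfwidth: fixed midline "
                           "strip is empty")

    # inframammary-fold chain: inferior base rim, mid-chest -> axilla
    rim_mask = on_base & (np.hypot(nodes_u[:, 0], nodes_u[:, 1]) > R - 1e-6)
    chain = np.nonzero(rim_mask & (nodes_u[:, 1] < -1e-9) & ~np.isin(
        np.arange(len(nodes)), fixed))[0]
    ang = np.arctan2(nodes_u[chain, 1], nodes_u[chain, 0])  # in (-pi, 0)
    chain = chain[np.argsort(ang)]

    nipple = surf_nodes[int(np.argmin(np.linalg.norm(
        nodes_u[surf_nodes] - np.array([0.0, 0.0, R]), axis=1)))]
    root = np.array([nodes[nipple, 0], nodes[nipple, 1],
                     -params.chest_curvature * nodes[nipple, 0] ** 2])

    fid = np.array([(0.30 * R, -0.16 * R, 0.50 * R),
                    (-0.24 * R, 0.20 * R, 0.44 * R)])
    fid[:, 2] += -params.chest_curvature * fid[:, 0] ** 2
    fiducials = np.vstack([nodes[nipple], fid])

    lm_xy = np.array([(-1.2 * R, 1.5 * R), (1.2 * R, 1.5 * R), (0.0, -1.6 * R)])
    landmarks = np.column_stack([lm_xy, -params.chest_curvature * lm_xy[:, 0] ** 2])

    mesh = LabeledTetMesh(
        nodes=nodes, tets=tets, labels=labels, surface_tris=surface,
        fixed_nodes=fixed, chest_nodes=chest_nodes, endpoint_chain=chain,
        chest_distance=zu.copy(), landmarks=landmarks, fiducials=fiducials,
        meta={
            "phantom_params": params, "lattice_spacing": h,
            "anchoring_root": root, "nipple_node": int(nipple),
            "frame": "right-handed, +z anterior (away from chest), prone "
                     "gravity along +z, supine along -z; mm",
        })
    mesh.validate()
    return mesh


def chest_wall_cloud(params: PhantomParams, n_points: int, rng: np.random.Generator,
                     extent: float = 1.25) -> np.ndarray:
    """Sample the analytic chest-wall surface as a point cloud (CT stand-in)."""
    R = params.breast_radius * extent
    r = R * np.sqrt(rng.uniform(0, 1, n_points))
    th = rng.uniform(0, 2 * np.pi, n_points)
    x, y = r * np.cos(th), r * np.sin(th)
    return np.column_stack([x, y, -params.chest_curvature * x**2])


def sample_tumor_points(params: PhantomParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample inside the (sheared) prone tumor sphere."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = params.tumor_radius * np.cbrt(rng.uniform(0, 1, n))
    pts = np.asarray(params.tumor_center, dtype=float) + r[:, None] * v
    pts[:, 2] += -params.chest_curvature * pts[:, 0] ** 2
    return pts


def _sample_surface(nodes, tris, n, rng):
    """Area-weighted uniform sample of points on a triangulated surface."""
    v = nodes[tris]
    areas = 0.5 * np.linalg.norm(np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)
    idx = rng.choice(len(tris), size=n, p=areas / areas.sum())
    r1, r2 = rng.uniform(size=n), rng.uniform(size=n)
    s = np.sqrt(r1)
    w = np.column_stack([1 - s, s * (1 - r2), s * r2])
    return np.einsum("pk,pkd->pd", w, v[idx])


def _random_rigid(rng, max_angle_deg=5.0, max_shift=12.0):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(rng.uniform(2.0, max_angle_deg))
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    Rm = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    t = rng.uniform(-max_shift, max_shift, size=3)
    return Rm, t


def generate_supine_observation(mesh: LabeledTetMesh, materials, sim,
                                noise_sd: float = 0.0, seed: int = 0,
                                n_surface: int = 2000, n_chest: int = 800,
                                n_tumor: int = 150,
                                rigid_perturbation: bool = True):
    """Forward-simulate the supine state and sample it as an observation.

    Runs the forward deformation (gravity + contact + anchoring, no
    observation forces), samples the deformed breast surface and the chest
    wall as point clouds with isotropic Gaussian noise of sd ``noise_sd``,
    interpolates the fiducial and tumor positions barycentrically, and
    returns the paired exact ground truth (always in the model frame,
    noise-free). If ``rigid_perturbation`` is set, a small seeded rigid
    transform moves the observation into a simulated CT frame; the
    landmark triplet carries it so registration can undo it.

    Returns ``(ObservationSet, GroundTruth)``.
    """
    from .registration import ObservationSet

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    params: PhantomParams = mesh.meta["phantom_params"]
    rng = np.random.default_rng(seed)

    wall = contact_mod.fit_quadric_surface(
        chest_wall_cloud(params, 600, np.random.default_rng(params.seed + 7)))
    anchor = anch_mod.build_anchoring(mesh, sim.w_a) if sim.w_a > 0 else None
    fwd = fem.forward_simulate(mesh, materials, sim,
                               wall=wall if sim.w_p > 0 else None, anchor=anchor)
    if not fwd.converged:
        raise ObservationError(
            f"forward solve did not converge in {fwd.iterations} iterations "
            f"(last update {fwd.residual_history[-1]:.3g} mm)",
            residual_history=fwd.residual_history)
    u = fwd.u
    deformed = mesh.nodes + u

    # anterior (skin-side) triangles: any vertex off the chest base
    on_chest = np.zeros(mesh.n_nodes, dtype=bool)
    on_chest[mesh.chest_nodes] = True
    anterior = mesh.surface_tris[~on_chest[mesh.surface_tris].all(axis=1)]
    skin_cloud = _sample_surface(deformed, anterior, n_surface, rng)
    chest_cloud = chest_wall_cloud(params, n_chest, rng)

    loc = find_containing_tets(mesh, mesh.fiducials)
    supine_fid = mesh.fiducials + interpolate_displacement(mesh, u, mesh.fiducials, loc)
    prone_tumor = sample_tumor_points(params, n_tumor, rng)
    loc_t = find_containing_tets(mesh, prone_tumor)
    supine_tumor = prone_tumor + interpolate_displacement(mesh, u, prone_tumor, loc_t)

    obs_skin, obs_chest = skin_cloud, chest_cloud
    obs_fid, obs_lm = supine_fid.copy(), mesh.landmarks.copy()
    meta = {"noise_sd": noise_sd, "seed": seed}
    if rigid_perturbation:
        Rm, t = _random_rigid(rng)
        obs_skin = obs_skin @ Rm.T + t
        obs_chest = obs_chest @ Rm.T + t
        obs_fid = obs_fid @ Rm.T + t
        obs_lm = obs_lm @ Rm.T + t
        meta["true_rigid"] = (Rm, t)
    if noise_sd > 0:
        obs_skin = obs_skin + rng.normal(0, noise_sd, obs_skin.shape)
        obs_chest = obs_chest + rng.normal(0, noise_sd, obs_chest.shape)
        obs_fid = obs_fid + rng.normal(0, noise_sd, obs_fid.shape)

    obs = ObservationSet(skin_points=obs_skin, chest_points=obs_chest,
                         fiducials=obs_fid, landmarks=obs_lm, meta=meta)
    truth = GroundTruth(true_displacement=u, supine_tumor_points=supine_tumor,
                        supine_fiducials=supine_fid, prone_tumor_points=prone_tumor,
                        meta={"iterations": fwd.iterations,
                              "residual_history": fwd.residual_history})
    return obs, truth
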