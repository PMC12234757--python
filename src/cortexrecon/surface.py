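"""Cortical-surface machinery: depth surfaces, mesh upsampling, vertex
sampling from sections, sphere inflation, spherical linear interpolation
and surface-to-volume projection.

Missing intensities between sparsely acquired sections are estimated on
the cortical manifold rather than in the volume: a family of
shared-topology meshes spans the ribbon from the WM border (depth 0) to
the pial border (depth 1); acquired section pixels are projected onto the
nearest surfaces; each surface is inflated to a sphere where piecewise
linear (spherical-barycentric) interpolation fills the gaps; and the
completed per-vertex fields are averaged back into voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError, cKDTree

from .core import Volume3D


@dataclass
class SurfaceMesh:
    """Triangle mesh; ``space_tag`` records the coordinate frame."""

    vertices: np.ndarray
    triangles: np.ndarray
    space_tag: str = "reference"   # reference | slab | sphere
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle indices out of range")
        if self.space_tag == "sphere":
            norms = np.linalg.norm(self.vertices, axis=1)
            if np.abs(norms - 1).max() > 1e-6:
                raise ValueError("sphere-space vertices must be unit-norm")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) index array."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
        return np.unique(np.sort(e, axis=1), axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def vertex_neighbors(self) -> list[np.ndarray]:
        e = self.edges()
        nbr: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for a, b in e:
            nbr[a].append(b)
            nbr[b].append(a)
        return [np.array(sorted(x), dtype=int) for x in nbr]


@dataclass
class VertexField:
    """Per-vertex values with an explicit missing mask."""

    values: np.ndarray
    known_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.known_mask = np.asarray(self.known_mask, dtype=bool)
        if self.values.shape != self.known_mask.shape:
            raise ValueError("values and known_mask must have equal shape")
        if not np.all(np.isfinite(self.values[self.known_mask])):
            raise ValueError("known values must be finite")


@dataclass
class DepthSurfaceSet:
    """Shared-topology meshes at evenly spaced cortical depths (0 = WM, 1 = pial)."""

    meshes: list[SurfaceMesh]
    depths: np.ndarray

    def __len__(self) -> int:
        return len(self.meshes)


def generate_depth_surfaces(wm: SurfaceMesh, pial: SurfaceMesh,
                            n_intermediate: int) -> DepthSurfaceSet:
    """Evenly subdivide the ribbon: vertex_i(d) = (1-d) wm_i + d pial_i."""
    if wm.triangles.shape != pial.triangles.shape or not np.array_equal(
            wm.triangles, pial.triangles):
        raise ValueError("WM and pial meshes must share triangulation")
    depths = np.linspace(0.0, 1.0, n_intermediate + 2)
    meshes = [
        SurfaceMesh((1 - d) * wm.vertices + d * pial.vertices,
                    wm.triangles.copy(), space_tag=wm.space_tag)
        for d in depths
    ]
    return DepthSurfaceSet(meshes=meshes, depths=depths)


# ---------------------------------------------------------------------------
# Mesh upsampling: P = A + alpha*AB + beta*AC on a regular barycentric grid
# ---------------------------------------------------------------------------

@dataclass
class UpsamplePattern:
    """Index-level subdivision pattern, reusable across shared-topology meshes.

    Each new vertex is defined by a source triangle and integer barycentric
    coordinates (i, j, n): position = A + (i/n) AB + (j/n) AC. Applying one
    pattern to every mesh of a depth-surface family (and to the inflated
    spheres) keeps vertex correspondence exact by construction.
    """

    n_per_tri: np.ndarray
    vertex_defs: list[tuple]
    faces: np.ndarray
    n_original: int


def upsample_pattern(meshes: list[SurfaceMesh], r: float) -> UpsamplePattern:
    """Compute the subdivision pattern guaranteeing max neighbor distance <= r
    on every mesh in the family (per-triangle count from the longest edge
    across the family; increments of alpha/beta are 0.5 r per edge length)."""
    if r <= 0:
        raise ValueError("target resolution r must be positive")
    tris = meshes[0].triangles
    max_edge = np.zeros(len(tris))
    for m in meshes:
        if not np.array_equal(m.triangles, tris):
            raise ValueError("meshes must share triangulation")
        v = m.vertices
        for a, b in ((0, 1), (1, 2), (0, 2)):
            e = np.linalg.norm(v[tris[:, a]] - v[tris[:, b]], axis=1)
            max_edge = np.maximum(max_edge, e)
    n_per_tri = np.maximum(1, np.ceil(max_edge / (0.5 * r) - 1e-12).astype(int))

    n_orig = meshes[0].n_vertices
    vertex_defs: list[tuple] = [("orig", i) for i in range(n_orig)]
    index: dict[tuple, int] = {("orig", i): i for i in range(n_orig)}
    faces: list[tuple[int, int, int]] = []

    def key_for(t: int, i: int, j: int, n: int, corners) -> tuple:
        a, b, c = corners
        if i == 0 and j == 0:
            return ("orig", a)
        if i == n and j == 0:
            return ("orig", b)
        if i == 0 and j == n:
            return ("orig", c)
        if j == 0:      # on edge AB
            return _edge_key(a, b, Fraction(i, n))
        if i == 0:      # on edge AC
            return _edge_key(a, c, Fraction(j, n))
        if i + j == n:  # on edge BC
            return _edge_key(b, c, Fraction(j, n))
        return ("int", t, i, j, n)

    def _edge_key(p: int, q: int, frac: Fraction) -> tuple:
        if p <= q:
            return ("edge", p, q, frac)
        return ("edge", q, p, 1 - frac)

    for t, (n, corners) in enumerate(zip(n_per_tri, tris)):
        n = int(n)
        grid = {}
        for i in range(n + 1):
            for j in range(n + 1 - i):
                k = key_for(t, i, j, n, corners)
                if k not in index:
                    index[k] = len(vertex_defs)
                    vertex_defs.append(k if k[0] != "orig" else ("orig", k[1]))
                    if k[0] == "edge":
                        # remember one concrete (t, i, j, n) realisation
                        vertex_defs[-1] = ("pt", t, i, j, n)
                grid[(i, j)] = index[k]
        for i in range(n):
            for j in range(n - i):
                faces.append((grid[(i, j)], grid[(i + 1, j)], grid[(i, j + 1)]))
                if i + j <= n - 2:
                    faces.append((grid[(i + 1, j)], grid[(i + 1, j + 1)], grid[(i, j + 1)]))

    return UpsamplePattern(
        n_per_tri=n_per_tri,
        vertex_defs=vertex_defs,
        faces=np.array(faces, dtype=int),
        n_original=n_orig,
    )


def apply_upsample(mesh: SurfaceMesh, pattern: UpsamplePattern) -> SurfaceMesh:
    """Instantiate a subdivision pattern on one mesh of the family.

    Original vertices are preserved (same indices). Sphere-space meshes are
    re-normalised to the unit sphere after point insertion.
    """
    tris = mesh.triangles
    v = mesh.vertices
    out = np.empty((len(pattern.vertex_defs), 3))
    for idx, d in enumerate(pattern.vertex_defs):
        if d[0] == "orig":
            out[idx] = v[d[1]]
        else:
            _, t, i, j, n = d
            a, b, c = tris[t]
            out[idx] = v[a] + (i / n) * (v[b] - v[a]) + (j / n) * (v[c] - v[a])
    if mesh.space_tag == "sphere":
        out = out / np.linalg.norm(out, axis=1, keepdims=True)
    return SurfaceMesh(out, pattern.faces.copy(), space_tag=mesh.space_tag)


def upsample_mesh(mesh: SurfaceMesh, r: float) -> SurfaceMesh:
    """Upsample one mesh so the max distance between neighbors is <= r."""
    return apply_upsample(mesh, upsample_pattern([mesh], r))


# ---------------------------------------------------------------------------
# Sphere inflation
# ---------------------------------------------------------------------------

def inflate_to_sphere(mesh: SurfaceMesh, center: np.ndarray | None = None) -> SurfaceMesh:
    """Radially project a star-shaped mesh onto the unit sphere.

    Exact for the phantom's radially convex geometry; real cortical meshes
    should supply externally inflated spheres instead. Orientation flips
    (a triangle whose spherical image is inverted) indicate the mesh is not
    star-shaped about ``center`` and raise an error. The relative edge-length
    distortion of the projection is reported in ``meta['distortion']``.
    """
    if center is None:
        center = mesh.vertices.mean(axis=0)
    p = mesh.vertices - np.asarray(center)
    r = np.linalg.norm(p, axis=1)
    if r.min() <= 0:
        raise ValueError("center coincides with a vertex; cannot inflate")
    u = p / r[:, None]
    tri = mesh.triangles
    det = np.einsum("ij,ij->i", u[tri[:, 0]],
                    np.cross(u[tri[:, 1]], u[tri[:, 2]]))
    if det.max() <= 0:
        det = -det  # consistent inward orientation is fine too
    if det.min() <= 0:
        raise ValueError(
            "mesh is not star-shaped about the given center; supply externally "
            "inflated sphere meshes instead"
        )
    sphere = SurfaceMesh(u, tri.copy(), space_tag="sphere")
    e = mesh.edges()
    orig = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    infl = np.linalg.norm(u[e[:, 0]] - u[e[:, 1]], axis=1)
    scale = np.median(orig / np.maximum(infl, 1e-30))
    rel = np.abs(infl * scale - orig) / np.maximum(orig, 1e-30)
    sphere.meta["distortion"] = {
        "median_rel_edge_error": float(np.median(rel)),
        "max_rel_edge_error": float(rel.max()),
    }
    return sphere


def validate_external_sphere(mesh: SurfaceMesh, sphere: SurfaceMesh) -> SurfaceMesh:
    """Accept an externally supplied sphere after topology validation."""
    if sphere.n_vertices != mesh.n_vertices:
        raise ValueError("sphere vertex count does not match the cortical mesh")
    v = sphere.vertices / np.linalg.norm(sphere.vertices, axis=1, keepdims=True)
    return SurfaceMesh(v, sphere.triangles.copy(), space_tag="sphere")


# ---------------------------------------------------------------------------
# Spherical piecewise-linear interpolation
# ---------------------------------------------------------------------------

def _patch_interp(pk: np.ndarray, vk: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation of a localized spherical patch:
    gnomonic projection about the patch centroid, 2D Delaunay, barycentric
    weights; queries outside the triangulation take the nearest known value
    (still within the known range)."""
    c = pk.mean(axis=0)
    c /= np.linalg.norm(c)
    b1 = np.cross(c, [0.0, 0.0, 1.0])
    if np.linalg.norm(b1) < 1e-8:
        b1 = np.cross(c, [0.0, 1.0, 0.0])
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(c, b1)

    def project(p):
        d = np.clip(p @ c, 1e-6, None)
        pp = p / d[:, None]
        return np.stack([pp @ b1, pp @ b2], axis=1)

    p2 = project(pk)
    q2 = project(np.atleast_2d(q))
    est = np.empty(len(q2))
    filled = np.zeros(len(q2), dtype=bool)
    try:
        tri = Delaunay(p2)
        simp = tri.find_simplex(q2)
    except QhullError:
        tri, simp = None, np.full(len(q2), -1)
    inside = simp >= 0
    if tri is not None and inside.any():
        trans = tri.transform[simp[inside]]
        bary2 = np.einsum("ijk,ik->ij", trans[:, :2], q2[inside] - trans[:, 2])
        w = np.concatenate([bary2, 1 - bary2.sum(axis=1, keepdims=True)], axis=1)
        w = np.clip(w, 0, None)
        w /= w.sum(axis=1, keepdims=True)
        est[inside] = np.einsum("ij,ij->i", w, vk[tri.simplices[simp[inside]]])
        filled[inside] = True
    if not filled.all():
        tree_k = cKDTree(pk)
        _, nn = tree_k.query(np.atleast_2d(q)[~filled])
        est[~filled] = vk[nn]
    return np.clip(est, vk.min(), vk.max())


def interpolate_sphere(sphere_mesh: SurfaceMesh, field: VertexField) -> VertexField:
    """Fill missing vertex values by piecewise-linear interpolation on the sphere.

    Known vertices form a spherical triangulation (convex hull for global
    coverage; gnomonic Delaunay for a localized patch); each missing vertex
    takes the barycentric combination of its containing triangle's values.
    Known vertices are returned unchanged; estimates are bounded by the
    min/max of the known values.
    """
    known = field.known_mask
    if known.sum() < 3:
        raise ValueError("need at least 3 known vertices for spherical interpolation")
    verts = sphere_mesh.vertices
    pk = verts[known]
    vk = field.values[known]
    if np.linalg.matrix_rank(pk - pk.mean(axis=0), tol=1e-9) < 2:
        raise ValueError("known vertices are collinear")
    out = field.values.copy()
    miss_idx = np.where(~known)[0]
    if miss_idx.size == 0:
        return VertexField(out, np.ones_like(known))
    q = verts[miss_idx]

    est = np.empty(len(miss_idx))
    filled = np.zeros(len(miss_idx), dtype=bool)
    global_ok = False
    if known.sum() >= 4:
        try:
            hull = ConvexHull(pk)
            # origin strictly inside => the hull triangulates the whole sphere
            global_ok = bool(np.all(hull.equations[:, -1] < -1e-9))
        except QhullError:
            global_ok = False
    if global_ok:
        simplices = hull.simplices
        cent = pk[simplices].mean(axis=1)
        cent /= np.linalg.norm(cent, axis=1, keepdims=True)
        tree = cKDTree(cent)
        k = min(24, len(simplices))
        _, cand = tree.query(q, k=k)
        cand = np.atleast_2d(cand)
        for j in range(cand.shape[1]):
            rows = np.where(~filled)[0]
            if rows.size == 0:
                break
            tri = simplices[cand[rows, j]]
            m = np.transpose(pk[tri], (0, 2, 1))       # columns = vertices
            try:
                w = np.linalg.solve(m, q[rows][..., None])[..., 0]
            except np.linalg.LinAlgError:
                continue
            s = w.sum(axis=1)
            ok = (np.abs(s) > 1e-12)
            wn = np.where(ok[:, None], w / np.where(s[:, None] == 0, 1, s[:, None]), -1)
            ok &= wn.min(axis=1) >= -1e-9
            if ok.any():
                wn = np.clip(wn[ok], 0, None)
                wn /= wn.sum(axis=1, keepdims=True)
                hit = rows[ok]
                est[hit] = np.einsum("ij,ij->i", wn, vk[tri[ok]])
                filled[hit] = True
        # numerical leftovers: nearest known value (still bounded)
        if not filled.all():
            tree_k = cKDTree(pk)
            _, nn = tree_k.query(q[~filled])
            est[~filled] = vk[nn]
    else:
        est = _patch_interp(pk, vk, q)

    out[miss_idx] = np.clip(est, vk.min(), vk.max())
    return VertexField(out, np.ones_like(known))


# ---------------------------------------------------------------------------
# Sampling acquired sections onto vertices
# ---------------------------------------------------------------------------

def sample_sections_to_vertices(
    stack,
    chains: dict,
    depth_surfaces: DepthSurfaceSet,
    acquisition: str,
    images: dict,
    spacing_mm: float,
    cut_axis: int = 1,
    masks: dict | None = None,
    snap_radius_px: float = 2.0,
) -> list[VertexField]:
    """Project acquired section pixels of one acquisition onto each depth mesh.

    Surfaces must already be in the slab (reconstruction) frame. A vertex is
    sampled when it lies within half a section thickness of an acquired
    plane of this acquisition; the value is the nearest-neighbor pixel of
    that section, read through the section's full inverse transform chain.

    Pixels at the tissue boundary are partial-volume contaminated (a
    digitized pixel mixing GM with WM or background is dimmed), so when GM
    ``masks`` are available, sampling snaps to the nearest pixel of the
    eroded GM mask within ``snap_radius_px``; vertices farther than that
    from clean GM, on background, or outside the image stay missing.
    """
    recs = [r for r in stack.records if r.acquisition == acquisition and r.qc_pass]
    fields: list[VertexField] = []
    if not recs:
        for m in depth_surfaces.meshes:
            fields.append(VertexField(np.zeros(m.n_vertices),
                                      np.zeros(m.n_vertices, dtype=bool)))
        return fields
    plane_w = np.array([r.sample_index * r.section_thickness_um / 1000.0 for r in recs])
    half = recs[0].section_thickness_um / 2000.0

    from scipy import ndimage as _ndi
    supports: dict = {}
    for r in recs:
        key = (r.slab_id, r.sample_index)
        if masks is not None and key in masks:
            mv = masks[key].values if hasattr(masks[key], "values") else masks[key]
            sup = _ndi.binary_erosion(mv > 0.5)
            if not sup.any():
                sup = mv > 0.5
            dist, (ir, ic) = _ndi.distance_transform_edt(~sup, return_indices=True)
            supports[key] = (dist, ir, ic)

    inplane = [a for a in range(3) if a != cut_axis]
    for mesh in depth_surfaces.meshes:
        v = mesh.vertices
        vals = np.zeros(mesh.n_vertices)
        knm = np.zeros(mesh.n_vertices, dtype=bool)
        d = np.abs(v[:, cut_axis][:, None] - plane_w[None, :])
        nearest = np.argmin(d, axis=1)
        ok = d[np.arange(len(v)), nearest] <= half + 1e-9
        for si in np.unique(nearest[ok]):
            sel = np.where(ok & (nearest == si))[0]
            r = recs[si]
            key = (r.slab_id, r.sample_index)
            img = images[key]
            pts = np.stack([v[sel, inplane[0]] / spacing_mm,
                            v[sel, inplane[1]] / spacing_mm], axis=1)
            chain = chains.get(key)
            if chain is not None:
                pts = chain.map_points(pts, (spacing_mm, spacing_mm))
            rr = np.round(pts[:, 0]).astype(int)
            cc = np.round(pts[:, 1]).astype(int)
            inb = (rr >= 0) & (rr < img.shape[0]) & (cc >= 0) & (cc < img.shape[1])
            got = np.zeros(len(sel))
            if key in supports:
                dist, ir, ic = supports[key]
                near = inb & (dist[rr.clip(0, img.shape[0] - 1),
                                   cc.clip(0, img.shape[1] - 1)] <= snap_radius_px)
                rs = ir[rr[near], cc[near]]
                cs = ic[rr[near], cc[near]]
                got[near] = img[rs, cs]
                good = near & (got > 0)
            else:
                got[inb] = img[rr[inb], cc[inb]]
                good = inb & (got > 0)
            vals[sel[good]] = got[good]
            knm[sel[good]] = True
        fields.append(VertexField(vals, knm))
    return fields


# ---------------------------------------------------------------------------
# Surface -> volume projection
# ---------------------------------------------------------------------------

def project_to_volume(
    depth_fields: list[VertexField],
    depth_surfaces: DepthSurfaceSet,
    out_grid: Volume3D,
    cortex_mask: np.ndarray,
    max_fill_iter: int = 200,
) -> Volume3D:
    """Average per-vertex values into the voxels containing them, then fill
    remaining empty cortical voxels by iterative neighborhood averaging
    (Laplacian fill, the discrete analogue of linear interpolation)."""
    cortex = np.asarray(cortex_mask, dtype=bool)
    shape = out_grid.shape
    acc = np.zeros(shape)
    cnt = np.zeros(shape)
    origin = np.asarray(out_grid.origin)
    sp = np.asarray(out_grid.spacing_mm)
    for mesh, fld in zip(depth_surfaces.meshes, depth_fields):
        if not fld.known_mask.all():
            raise ValueError("depth fields must be complete before projection")
        idx = np.round((mesh.vertices - origin) / sp).astype(int)
        inb = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
        idx = idx[inb]
        np.add.at(acc, (idx[:, 0], idx[:, 1], idx[:, 2]), fld.values[inb])
        np.add.at(cnt, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    hit = cnt > 0
    if not (hit & cortex).any():
        raise ValueError("no surface vertices fall inside the cortex mask")
    vol = np.zeros(shape)
    vol[hit] = acc[hit] / cnt[hit]
    vol[~cortex] = 0.0
    filled = hit & cortex

    todo = cortex & ~filled
    for _ in range(max_fill_iter):
        if not todo.any():
            break
        known = np.zeros(shape)
        known[filled] = vol[filled]
        nsum = np.zeros(shape)
        ncnt = np.zeros(shape)
        for ax in range(3):
            for s in (1, -1):
                nsum += np.roll(known, s, axis=ax)
                ncnt += np.roll(filled.astype(float), s, axis=ax)
        newly = todo & (ncnt > 0)
        if not newly.any():
            break
        vol[newly] = nsum[newly] / ncnt[newly]
        filled |= newly
        todo = cortex & ~filled
    return Volume3D(vol, spacing_mm=tuple(out_grid.spacing_mm),
                    origin=tuple(out_grid.origin), axis_map=out_grid.axis_map)


def vertex_voxel_coverage(depth_surfaces: DepthSurfaceSet, out_grid: Volume3D,
                          cortex_mask: np.ndarray) -> float:
    """Fraction of cortical voxels containing at least one surface vertex."""
    cortex = np.asarray(cortex_mask, dtype=bool)
    hit = np.zeros(out_grid.shape, dtype=bool)
    origin = np.asarray(out_grid.origin)
    sp = np.asarray(out_grid.spacing_mm)
    for mesh in depth_surfaces.meshes:
        idx = np.round((mesh.vertices - origin) / sp).astype(int)
        inb = np.all((idx >= 0) & (idx < np.array(out_grid.shape)), axis=1)
        idx = idx[inb]
        hit[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    n = int(cortex.sum())
    return float((hit & cortex).sum() / n) if n else 0.0


__all__ = [
    "SurfaceMesh", "VertexField", "DepthSurfaceSet", "UpsamplePattern",
    "generate_depth_surfaces", "upsample_pattern", "apply_upsample",
    "upsample_mesh", "inflate_to_sphere", "validate_external_sphere",
    "interpolate_sphere", "sample_sections_to_vertices",
    "project_to_volume", "vertex_voxel_coverage",
]
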