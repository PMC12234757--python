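"""Synthetic ground-truth "brain" generator.

The phantom is a star-shaped (radially convex) folded cortical ribbon: an
inner white-matter core whose outer boundary is a smoothly folded radial
function of direction, wrapped by a gray-matter shell of fixed thickness.
Because it is star-shaped, every surface in the family can be inflated to
a sphere by exact radial projection, and tissue labels and density fields
are analytic functions of position — sections, vertex samples and volumes
are all evaluated from the same closed form, so there is a known forward
model for every downstream test.

Sections are cut perpendicular to the cutting axis with the sparse,
interleaved, perturbed sampling pattern of real serial multi-modal
acquisitions: acquisitions cycle along the axis, most planes are never
acquired, slabs are separated by lost planes, each slab carries its own
small 3D affine deformation, and each kept section is perturbed by a
random in-plane rigid motion plus an optional smooth warp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage

from .core import (
    Deformation2D, Image2D, Rigid2D, SectionRecord, SectionStack,
    SlabBounds, TransformChain, Volume3D, save_manifest, save_section_image,
    save_volume,
)
from .surface import SurfaceMesh, VertexField

LABEL_BG, LABEL_WM, LABEL_GM = 0, 1, 2


@dataclass
class PhantomShape:
    """Geometry of the folded-ribbon phantom (all lengths in mm)."""

    base_radius_mm: float = 22.0
    fold_count: int = 6
    fold_amplitude_mm: float = 3.0
    thickness_mm: float = 6.0
    axis_scales: tuple[float, float, float] = (1.0, 1.0, 0.82)
    volume_shape: tuple[int, int, int] = (64, 256, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 0.25, 1.0)
    mesh_subdivisions: int = 4

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("ribbon thickness must be positive")
        if min(self.axis_scales) <= 0:
            raise ValueError("axis scales must be positive")
        if (self.base_radius_mm * min(self.axis_scales) - self.fold_amplitude_mm
                <= 2 * max(self.spacing_mm)):
            raise ValueError("fold amplitude too large: inner surface would self-intersect")
        margin = (self.base_radius_mm * max(self.axis_scales)
                  + self.fold_amplitude_mm + self.thickness_mm)
        half = min(n * s for n, s in zip(self.volume_shape, self.spacing_mm)) / 2
        if margin >= half:
            raise ValueError("phantom does not fit inside the volume")


@dataclass
class FieldSpec:
    """Band-limited random density field over the sphere of directions.

    The field is a weighted sum of modes ``(d_j . u) ** k_j`` with weights
    ``exp(-k_j * smoothness)``; higher smoothness suppresses high orders,
    and in the limit the field is the constant mid-range value. Values are
    affinely bounded into ``value_range`` via the analytic amplitude bound,
    so the declared range holds for every draw.
    """

    directions: np.ndarray      # (M, 3) unit vectors
    orders: np.ndarray          # (M,) integer mode orders >= 1
    amplitudes: np.ndarray      # (M,) raw coefficients
    smoothness: float
    value_range: tuple[float, float]
    norm: float | None = None   # realized amplitude (set once at synthesis)

    def _raw(self, u: np.ndarray) -> np.ndarray:
        w = self.amplitudes * np.exp(-self.orders * self.smoothness)
        if np.abs(w).sum() == 0:
            return np.zeros(u.shape[0])
        return ((u @ self.directions.T) ** self.orders) @ w

    def __call__(self, u: np.ndarray) -> np.ndarray:
        """Evaluate at an (N, 3) array of unit directions."""
        u = np.atleast_2d(u)
        lo, hi = self.value_range
        mid, half = (lo + hi) / 2, (hi - lo) / 2
        raw = self._raw(u)
        amp = self.norm
        if amp is None:
            w = self.amplitudes * np.exp(-self.orders * self.smoothness)
            amp = np.abs(w).sum()
        if amp == 0:
            return np.full(u.shape[0], mid)
        return np.clip(mid + half * raw / amp, lo, hi)


@dataclass
class SamplingScheme:
    """How sections are cut from the phantom (the study's acquisition design)."""

    coverage_fraction: float = 0.3
    acquisitions: tuple[str, ...] = ("acq0", "acq1", "acq2", "acq3")
    dropout_prob: float = 0.0
    n_slabs: int = 2
    slab_gap_sections: int = 3
    rigid_jitter: tuple[float, float] = (5.0, 3.0)   # max |rot deg|, max |trans px|
    warp_amplitude_px: float = 1.0
    slab_affine_jitter: tuple[float, float] = (2.0, 2.0)  # max |rot deg|, max |trans mm|
    noise_sd: float = 4.0
    polarity_flip: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.coverage_fraction <= 1:
            raise ValueError("coverage_fraction must be in (0, 1]")
        if self.n_slabs < 1:
            raise ValueError("n_slabs must be >= 1")


@dataclass
class Phantom:
    """Ground truth: labeled volume, surfaces, fields and applied transforms."""

    shape: PhantomShape
    truth_volume: Volume3D
    wm_mesh: SurfaceMesh
    pial_mesh: SurfaceMesh
    seed: int
    center_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    truth_fields: dict[str, FieldSpec] = field(default_factory=dict)
    intensity_params: dict[str, dict] = field(default_factory=dict)
    truth_transforms: dict[tuple[int, int], TransformChain] = field(default_factory=dict)
    slab_transforms: dict[int, np.ndarray] = field(default_factory=dict)  # 4x4 world affines
    slab_bounds: dict[int, SlabBounds] = field(default_factory=dict)
    sections: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    truth_masks: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    # -- analytic geometry -------------------------------------------------
    def _fold(self, u: np.ndarray) -> np.ndarray:
        """Radial fold term: Re[(ux + i*uz)^n], smooth, n-fold symmetric."""
        n = self.shape.fold_count
        z = u[:, 0] + 1j * u[:, 2]
        return np.real(z ** n)

    def inner_radius(self, u: np.ndarray) -> np.ndarray:
        """Inner (WM) surface radius: ellipsoidal base (so every coronal
        cross-section is elliptical, keeping in-plane rotation observable)
        plus the angular fold term."""
        s = np.asarray(self.shape.axis_scales)
        q = np.sqrt(((u / s) ** 2).sum(axis=1))
        base = self.shape.base_radius_mm / np.maximum(q, 1e-12)
        return base + self.shape.fold_amplitude_mm * self._fold(u)

    def labels_at(self, pts_mm: np.ndarray) -> np.ndarray:
        """Tissue label at world points (analytic; no resampling)."""
        p = np.atleast_2d(pts_mm) - self.center_mm
        r = np.linalg.norm(p, axis=1)
        u = np.divide(p, r[:, None], out=np.zeros_like(p), where=r[:, None] > 0)
        rin = self.inner_radius(u)
        out = np.full(p.shape[0], LABEL_BG, dtype=int)
        out[r < rin] = LABEL_WM
        out[(r >= rin) & (r <= rin + self.shape.thickness_mm)] = LABEL_GM
        return out

    def density_at(self, acquisition: str, pts_mm: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(pts_mm) - self.center_mm
        r = np.linalg.norm(p, axis=1)
        u = np.divide(p, r[:, None], out=np.zeros_like(p), where=r[:, None] > 0)
        return self.truth_fields[acquisition](u)

    def gm_mask(self) -> np.ndarray:
        return (self.truth_volume.values == LABEL_GM).astype(float)

    def truth_intensity_at(self, acquisition: str, pts_mm: np.ndarray) -> np.ndarray:
        """Noise-free forward-model intensity of GM at world points."""
        par = self.intensity_params[acquisition]
        dens = self.density_at(acquisition, pts_mm)
        val = par["gain"] * dens + par["offset"]
        if par["flip"]:
            val = 255.0 - val
        return np.clip(val, 1.0, 255.0)


def make_phantom(shape_params: PhantomShape | None = None, seed: int = 0) -> Phantom:
    """Build the labeled truth volume and shared-topology WM/pial meshes.

    Deterministic for a fixed seed. The two meshes are radial offsets of a
    single icosphere, so they share triangulation exactly.
    """
    shape = shape_params or PhantomShape()
    n = shape.volume_shape
    sp = tuple(shape.spacing_mm)
    center = np.array([(d - 1) * s / 2 for d, s in zip(n, sp)])

    ix = [np.arange(d) * s for d, s in zip(n, sp)]
    xx, yy, zz = np.meshgrid(*ix, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)

    base = trimesh.creation.icosphere(subdivisions=shape.mesh_subdivisions, radius=1.0)
    u = np.asarray(base.vertices)
    tris = np.asarray(base.faces)

    ph = Phantom(
        shape=shape,
        truth_volume=Volume3D(np.zeros(n), spacing_mm=sp),
        wm_mesh=SurfaceMesh(u.copy(), tris.copy(), space_tag="reference"),
        pial_mesh=SurfaceMesh(u.copy(), tris.copy(), space_tag="reference"),
        seed=seed,
        center_mm=center,
    )
    labels = ph.labels_at(pts).reshape(n).astype(float)
    ph.truth_volume = Volume3D(labels, spacing_mm=sp)

    rin = ph.inner_radius(u)
    ph.wm_mesh = SurfaceMesh(center + u * rin[:, None], tris.copy(), space_tag="reference")
    ph.pial_mesh = SurfaceMesh(center + u * (rin + shape.thickness_mm)[:, None],
                               tris.copy(), space_tag="reference")
    return ph


def synthesize_truth_fields(
    phantom: Phantom,
    acquisitions: tuple[str, ...],
    smoothness: float = 1.0,
    seed: int = 0,
    value_range: tuple[float, float] = (0.5, 2.0),
    n_modes: int = 6,
) -> dict[str, VertexField]:
    """Draw one smooth density field per acquisition and per-acquisition
    intensity mappings (gain/offset/polarity), storing both on the phantom.

    Returns the fields evaluated at the mid-depth mesh vertices as
    :class:`VertexField` objects (fully known).
    """
    if not acquisitions:
        raise ValueError("need at least one acquisition")
    rng = np.random.default_rng(seed)
    out: dict[str, VertexField] = {}
    mid_vertices = 0.5 * (phantom.wm_mesh.vertices + phantom.pial_mesh.vertices)
    p = mid_vertices - phantom.center_mm
    u = p / np.linalg.norm(p, axis=1, keepdims=True)
    for i, acq in enumerate(acquisitions):
        d = rng.normal(size=(n_modes, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        spec = FieldSpec(
            directions=d,
            orders=rng.integers(1, 4, size=n_modes),
            amplitudes=rng.normal(size=n_modes),
            smoothness=smoothness,
            value_range=value_range,
        )
        # normalize by the realized amplitude over a dense direction sample,
        # so the field actually spans its declared range (real multi-modal
        # sections show strong regional heterogeneity); a 5% margin plus the
        # final clip keeps every value inside the range
        probe = trimesh.creation.icosphere(subdivisions=4, radius=1.0).vertices
        realized = np.abs(spec._raw(np.asarray(probe))).max()
        spec.norm = float(realized) * 1.05 if realized > 0 else None
        phantom.truth_fields[acq] = spec
        lo, hi = value_range
        # distinct gain/offset per acquisition: GM intensities span most of
        # the 8-bit range (multi-modal sections are strongly heterogeneous),
        # well separated from the dark WM level
        gain = float(rng.uniform(115, 150)) / (hi - lo)
        offset = 100.0 - gain * lo + float(rng.uniform(0, 5))
        phantom.intensity_params[acq] = {
            "gain": gain, "offset": offset,
            "wm_level": float(rng.uniform(25, 45)),
            "flip": False,
        }
        vals = spec(u)
        out[acq] = VertexField(values=vals, known_mask=np.ones(len(vals), dtype=bool))
    return out


def _slab_affine(rng: np.random.Generator, center: np.ndarray,
                 max_rot_deg: float, max_trans_mm: float) -> np.ndarray:
    """Small random rigid 3D world affine about the phantom center."""
    ang = np.deg2rad(rng.uniform(-max_rot_deg, max_rot_deg, size=3))
    rx, ry, rz = ang
    Rx = np.array([[1, 0, 0], [0, np.cos(rx), -np.sin(rx)], [0, np.sin(rx), np.cos(rx)]])
    Ry = np.array([[np.cos(ry), 0, np.sin(ry)], [0, 1, 0], [-np.sin(ry), 0, np.cos(ry)]])
    Rz = np.array([[np.cos(rz), -np.sin(rz), 0], [np.sin(rz), np.cos(rz), 0], [0, 0, 1]])
    R = Rz @ Ry @ Rx
    t = rng.uniform(-max_trans_mm, max_trans_mm, size=3)
    m = np.eye(4)
    m[:3, :3] = R
    m[:3, 3] = center - R @ center + t
    return m


def _smooth_warp(rng: np.random.Generator, shape: tuple[int, int],
                 amplitude_px: float) -> Deformation2D:
    """Low-frequency random displacement field with max magnitude <= amplitude."""
    coarse = rng.normal(size=(2, 5, 5))
    disp = np.stack([
        ndimage.zoom(coarse[i], (shape[0] / 5, shape[1] / 5), order=3)
        for i in range(2)
    ])
    m = np.abs(disp).max()
    if m > 0:
        disp *= amplitude_px / m
    return Deformation2D(disp)


def _invert_map(chain: TransformChain, pts: np.ndarray) -> np.ndarray:
    """Numeric inverse of the chain map at (N, 2) pixel points -> source coords."""
    pts = np.asarray(pts, dtype=float)
    inv_r = chain.rigid.inverse()
    y = inv_r.map_points(pts)
    if chain.deforms:
        d = chain.deforms[0]
        z = y.copy()
        for _ in range(15):  # fixed-point inversion of x + d(x) = y
            dr = ndimage.map_coordinates(d.disp[0], z.T, order=1, mode="nearest")
            dc = ndimage.map_coordinates(d.disp[1], z.T, order=1, mode="nearest")
            z = y - np.stack([dr, dc], axis=1)
        y = z
    return y


def slice_sections(
    phantom: Phantom,
    scheme: SamplingScheme | None = None,
    seed: int = 0,
) -> tuple[SectionStack, dict[tuple[int, int], TransformChain]]:
    """Cut the phantom into a sparse, perturbed multi-modal section stack.

    Returns the stack and the ground-truth per-section transform chains
    (in the resampling convention: reconstruction pixel -> section pixel,
    so applying a truth chain to its section recovers the clean plane).
    Section images are kept on ``phantom.sections``.
    """
    scheme = scheme or SamplingScheme()
    missing = tuple(a for a in scheme.acquisitions if a not in phantom.truth_fields)
    if missing:
        synthesize_truth_fields(phantom, missing, seed=phantom.seed)
    rng = np.random.default_rng(seed)
    vol = phantom.truth_volume
    axis = vol.axis_map
    sp = vol.spacing_mm[0]          # in-plane pixel size (rows; axis 0)
    sp_c = vol.spacing_mm[2]        # in-plane pixel size (cols; axis 2)
    thick = vol.spacing_mm[axis]    # section thickness / cutting pitch

    gm = phantom.gm_mask()
    has_tissue = np.where(gm.sum(axis=(0, 2)) > 0)[0]
    lo, hi = int(has_tissue.min()), int(has_tissue.max())
    planes = np.arange(lo, hi + 1)

    # contiguous slab ranges separated by lost planes
    n_usable = len(planes)
    per = (n_usable - (scheme.n_slabs - 1) * scheme.slab_gap_sections) // scheme.n_slabs
    if per < 2:
        raise ValueError("too few planes for the requested slab layout")
    slab_of: dict[int, int] = {}
    start = lo
    for s in range(1, scheme.n_slabs + 1):
        stop = start + per if s < scheme.n_slabs else hi + 1
        for j in range(start, stop):
            slab_of[j] = s
        phantom.slab_bounds[s] = SlabBounds(
            slab_id=s,
            anterior_mm=vol.plane_world(stop - 1) + thick / 2,
            posterior_mm=vol.plane_world(start) - thick / 2,
        )
        start = stop + scheme.slab_gap_sections
    for s in range(1, scheme.n_slabs + 1):
        mr, mt = scheme.slab_affine_jitter
        phantom.slab_transforms[s] = (
            _slab_affine(rng, phantom.center_mm, mr, mt)
            if (mr > 0 or mt > 0) else np.eye(4)
        )

    records: list[SectionRecord] = []
    chains: dict[tuple[int, int], TransformChain] = {}
    shape2d = (vol.shape[0], vol.shape[2])
    maxrot, maxtr = scheme.rigid_jitter

    for j in planes:
        if j not in slab_of:
            continue
        acq = scheme.acquisitions[int(j) % len(scheme.acquisitions)]
        if rng.random() >= scheme.coverage_fraction:
            continue
        if scheme.dropout_prob > 0 and rng.random() < scheme.dropout_prob:
            continue
        s = slab_of[j]
        A = phantom.slab_transforms[s]

        # per-section perturbation, stored as its recovering chain
        rot = rng.uniform(-maxrot, maxrot)
        tr = rng.uniform(-maxtr, maxtr, size=2)
        ctr = ((shape2d[0] - 1) / 2, (shape2d[1] - 1) / 2)
        rigid = Rigid2D(rotation_deg=rot, translation=tuple(tr), center=ctr)
        deforms = []
        if scheme.warp_amplitude_px > 0:
            deforms.append(_smooth_warp(rng, shape2d, scheme.warp_amplitude_px))
        chain = TransformChain(rigid=rigid, deforms=deforms)

        # render the perturbed section analytically: push each section pixel
        # through the inverse of its recovering chain into the clean plane,
        # through the slab deformation into truth space, and evaluate the
        # forward model there. Pixels integrate a 3x3 subsample grid, the
        # area-average a digitizing camera performs (anti-aliased edges).
        rr, cc = np.meshgrid(np.arange(shape2d[0]), np.arange(shape2d[1]),
                             indexing="ij")
        base = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
        offs = (np.arange(3) - 1) / 3.0
        par = phantom.intensity_params[acq]
        acc = np.zeros(base.shape[0])
        gm_acc = np.zeros(base.shape[0])
        wm_acc = np.zeros(base.shape[0])
        for orow in offs:
            for ocol in offs:
                src = _invert_map(chain, base + [orow, ocol])
                w = np.empty((src.shape[0], 3))
                w[:, 0] = src[:, 0] * sp
                w[:, axis] = vol.plane_world(int(j))
                w[:, 2] = src[:, 1] * sp_c
                w_src = (A[:3, :3] @ w.T).T + A[:3, 3]
                lab = phantom.labels_at(w_src)
                dens = phantom.density_at(acq, w_src)
                gm = lab == LABEL_GM
                acc[gm] += par["gain"] * dens[gm] + par["offset"]
                acc[lab == LABEL_WM] += par["wm_level"]
                gm_acc += gm
                wm_acc += lab == LABEL_WM
        section = (acc / 9.0).reshape(shape2d)
        frac = ((gm_acc + wm_acc) / 9.0).reshape(shape2d)
        gm_px = (gm_acc.reshape(shape2d) / 9.0) > 0.5
        if gm_px.sum() == 0:
            continue
        tissue = frac > 0.5
        section[~tissue] = 0.0
        section[tissue] += rng.normal(0, scheme.noise_sd, size=int(tissue.sum()))
        if scheme.polarity_flip or par["flip"]:
            section[tissue] = 255.0 - section[tissue]
        section[tissue] = np.clip(section[tissue], 1, 255)
        section = np.round(section)  # 8-bit gray levels

        key = (s, int(j))
        phantom.sections[key] = section
        phantom.truth_masks[key] = gm_px.astype(float)
        chains[key] = chain
        records.append(SectionRecord(
            slab_id=s, sample_index=int(j), acquisition=acq,
            image_ref=f"slab{s}_sample{j}_{acq}.png",
            pixel_size_um=sp * 1000, section_thickness_um=thick * 1000,
        ))

    if not records:
        raise ValueError("sampling scheme kept no sections (coverage/dropout too severe)")
    stack = SectionStack(records)
    counts = {a: sum(1 for r in records if r.acquisition == a) for a in scheme.acquisitions}
    for a, c in counts.items():
        if c < 2:
            stack.warnings.append(f"acquisition '{a}' has only {c} section(s)")
    phantom.truth_transforms = chains
    return stack, chains


def write_phantom_dataset(phantom: Phantom, stack: SectionStack, out_dir: str | Path) -> Path:
    """Write a complete on-disk dataset in the same layout as real input:
    CSV manifest + PNG sections + NIfTI truth volume + OBJ meshes."""
    out = Path(out_dir)
    (out / "sections").mkdir(parents=True, exist_ok=True)
    for r in stack.records:
        img = phantom.sections[(r.slab_id, r.sample_index)]
        save_section_image(img, out / "sections" / r.image_ref)
        r.image_ref = str(Path("sections") / r.image_ref)
    save_manifest(stack, out / "manifest.csv")
    save_volume(phantom.truth_volume, out / "truth_labels.nii")
    for name, mesh in (("wm", phantom.wm_mesh), ("pial", phantom.pial_mesh)):
        trimesh.Trimesh(mesh.vertices, mesh.triangles, process=False).export(
            out / f"{name}.obj")
    return out


__all__ = [
    "LABEL_BG", "LABEL_WM", "LABEL_GM",
    "PhantomShape", "FieldSpec", "SamplingScheme", "Phantom",
    "make_phantom", "synthesize_truth_fields", "slice_sections",
    "write_phantom_dataset",
]
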