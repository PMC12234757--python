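"""Stage 2: iterative multi-resolution alignment to the reference volume.

At each resolution of a strictly decreasing schedule (e.g. 4, 2, 1 mm):

1. the 2D GM masks are transformed by their best available chains (stage-1
   rigids at the coarsest level, plus the accumulated 2D refinements after
   that) and assembled into a continuous fuzzy 3D GM volume, with
   unacquired planes filled by linear interpolation along the cutting axis;
2. the matching slab of the reference GM volume is registered in 3D
   (affine + deformable) onto the reconstructed GM volume;
3. every section is refined in 2D against its corresponding plane of the
   aligned reference, and the new deformation is appended to its chain.

Registration inputs stay fuzzy (interpolated gap planes are inherently
fractional); binarization at 0.5 is used only for Dice reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import backend
from .backend import Transform3D, resample_volume_through
from .core import (
    CUT_AXIS, Deformation2D, ResolutionSchedule, SectionStack, SlabBounds,
    TransformChain, Volume3D, apply_transform_2d, dice, resample_volume,
)
from .surface import SurfaceMesh, apply_upsample, upsample_pattern


def rasterize_surfaces_to_gm(wm_mesh: SurfaceMesh, pial_mesh: SurfaceMesh,
                             res_mm: float,
                             like: Volume3D | None = None) -> Volume3D:
    """Rasterize the cortical ribbon between two shared-topology meshes.

    A dense depth sweep of surfaces (vertex spacing and depth step both
    <= res/2 after upsampling) marks every voxel it passes through.
    """
    if not np.array_equal(wm_mesh.triangles, pial_mesh.triangles):
        raise ValueError("WM and pial meshes must share triangulation")
    pat = upsample_pattern([wm_mesh, pial_mesh], res_mm)
    wu = apply_upsample(wm_mesh, pat).vertices
    pu = apply_upsample(pial_mesh, pat).vertices
    thick = np.linalg.norm(pu - wu, axis=1).max()
    n_depth = max(2, int(np.ceil(thick / (res_mm / 2))) + 1)
    # inset the sweep half a voxel from each border: "contains a sample"
    # voxelization then estimates the ribbon volume without dilation bias
    inset = min(0.5 * res_mm / max(thick, 1e-9), 0.49)
    if like is None:
        allv = np.vstack([wu, pu])
        lo = allv.min(axis=0) - 2 * res_mm
        hi = allv.max(axis=0) + 2 * res_mm
        shape = tuple(int(np.ceil((h - l) / res_mm)) + 1 for l, h in zip(lo, hi))
        like = Volume3D(np.zeros(shape), spacing_mm=(res_mm,) * 3,
                        origin=tuple(lo))
    mask = np.zeros(like.shape, dtype=bool)
    origin = np.asarray(like.origin)
    sp = np.asarray(like.spacing_mm)
    for d in np.linspace(inset, 1 - inset, n_depth):
        v = (1 - d) * wu + d * pu
        idx = np.round((v - origin) / sp).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(like.shape)), axis=1)
        idx = idx[ok]
        mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return Volume3D(mask.astype(float), spacing_mm=tuple(like.spacing_mm),
                    origin=tuple(like.origin), axis_map=like.axis_map)


def _resample_plane(arr: np.ndarray, pixel_mm: float, res_mm: float) -> np.ndarray:
    """In-plane downsampling matching the volume resampler (block mean for
    integer factors, bilinear otherwise)."""
    f = res_mm / pixel_mm
    if abs(f - round(f)) < 1e-9 and round(f) >= 1:
        k = int(round(f))
        if k == 1:
            return arr.copy()
        h, w = (arr.shape[0] // k) * k, (arr.shape[1] // k) * k
        return arr[:h, :w].reshape(h // k, k, w // k, k).mean(axis=(1, 3))
    out_shape = (max(1, int(np.floor(arr.shape[0] / f))),
                 max(1, int(np.floor(arr.shape[1] / f))))
    rr, cc = np.meshgrid(*[((np.arange(n) + 0.5) * f - 0.5) for n in out_shape],
                         indexing="ij")
    return ndimage.map_coordinates(arr, [rr, cc], order=1, mode="constant",
                                   cval=0.0)


def assemble_gm_volume(masks2d: dict, chains: dict, stack: SectionStack,
                       res_mm: float, pixel_size_mm: float,
                       clip01: bool = True) -> Volume3D:
    """Assemble aligned 2D GM masks into a continuous fuzzy 3D volume.

    Acquired planes hold their transformed masks; gap planes are filled by
    linear interpolation between the two nearest acquired planes (weights
    proportional to inverse distance along the cutting axis). Planes
    outside the acquired range stay background.
    """
    recs = [r for r in stack.passing() if (r.slab_id, r.sample_index) in masks2d]
    if len(recs) < 2:
        raise ValueError("need at least 2 acquired planes to assemble a volume")
    thick = recs[0].section_thickness_um / 1000.0
    samples = sorted(r.sample_index for r in recs)
    smin, smax = samples[0], samples[-1]
    native = {}
    for r in recs:
        key = (r.slab_id, r.sample_index)
        arr = masks2d[key].values if hasattr(masks2d[key], "values") else masks2d[key]
        aligned = apply_transform_2d(
            arr, chains.get(key, TransformChain()), mode="linear",
            spacing_mm=(pixel_size_mm, pixel_size_mm))
        native[r.sample_index] = np.clip(aligned, 0, 1) if clip01 else aligned
    shp = next(iter(native.values())).shape
    n_planes = smax - smin + 1
    vol = np.zeros((shp[0], n_planes, shp[1]))
    acq = np.array(samples)
    for j in range(smin, smax + 1):
        if j in native:
            vol[:, j - smin, :] = native[j]
            continue
        lo = acq[acq < j].max()
        hi = acq[acq > j].min()
        w = (j - lo) / (hi - lo)
        vol[:, j - smin, :] = (1 - w) * native[lo] + w * native[hi]
    v = Volume3D(vol, spacing_mm=(pixel_size_mm, thick, pixel_size_mm),
                 origin=(0.0, smin * thick, 0.0))
    return resample_volume(v, res_mm, mode="linear")


def extract_reference_slab(ref_gm: Volume3D, bounds: SlabBounds) -> Volume3D:
    """Crop the reference GM volume to one slab's interval along the cutting axis."""
    a = ref_gm.axis_map
    n = ref_gm.shape[a]
    j0 = int(np.ceil(ref_gm.world_to_index(bounds.posterior_mm) - 1e-9))
    j1 = int(np.floor(ref_gm.world_to_index(bounds.anterior_mm) + 1e-9))
    j0c, j1c = max(j0, 0), min(j1, n - 1)
    if j0 > n - 1 or j1 < 0:
        raise ValueError("slab bounds fall outside the reference volume")
    if j1c < j0c:
        raise ValueError("slab bounds select no reference planes")
    sl = [slice(None)] * 3
    sl[a] = slice(j0c, j1c + 1)
    origin = list(ref_gm.origin)
    origin[a] = ref_gm.plane_world(j0c)
    return Volume3D(ref_gm.values[tuple(sl)].copy(),
                    spacing_mm=tuple(ref_gm.spacing_mm),
                    origin=tuple(origin), axis_map=a)


def register_3d(moving_ref_gm: Volume3D, fixed_recon_gm: Volume3D,
                res_mm: float, seed: int = 0,
                deform_iterations: int = 40) -> Transform3D:
    """Affine + deformable registration of the reference GM onto the
    reconstructed GM (both fuzzy, same world frame).

    The returned transform maps reconstruction-space points to reference-
    space points. The Dice (at threshold 0.5) of the warped reference never
    decreases relative to the unregistered overlap; stages that do not help
    are dropped (divergence policy: affine-only, or identity).
    """
    del seed  # registration is deterministic (dense sampling); kept for interface
    fixed = fixed_recon_gm if abs(fixed_recon_gm.spacing_mm[0] - res_mm) < 1e-9 \
        else resample_volume(fixed_recon_gm, res_mm)
    moving = moving_ref_gm

    def dice_of(t: Transform3D) -> float:
        w = resample_volume_through(moving, t, fixed)
        return dice(w.values > 0.5, fixed.values > 0.5)

    t_id = Transform3D(np.eye(4))
    d0 = dice_of(t_id)
    aff = backend.register_affine_3d(moving, fixed)
    t_aff = Transform3D(aff)
    d1 = dice_of(t_aff)
    if d1 < d0:
        t_aff, d1 = t_id, d0
    warped = resample_volume_through(moving, t_aff, fixed)
    fld, fld_inv = backend.register_deformable_3d(warped, fixed,
                                                  iterations=deform_iterations)
    t_full = Transform3D(t_aff.affine, deform=fld, deform_inv=fld_inv)
    d2 = dice_of(t_full)
    return t_full if d2 >= d1 else t_aff


def refine_2d(mask2d: np.ndarray, ref_plane: np.ndarray,
              res_mm: float) -> Deformation2D:
    """2D deformable refinement of a section's GM mask against the aligned
    reference plane (both on the ``res_mm`` grid). An empty reference plane
    yields an identity field flagged for QC."""
    ref = np.asarray(ref_plane, dtype=float)
    mov = np.asarray(mask2d, dtype=float)
    if (ref > 0.5).sum() == 0:
        d = Deformation2D(np.zeros((2,) + mov.shape), spacing_mm=(res_mm, res_mm))
        d.flagged = "empty reference plane"
        return d
    d = backend.register_deformable_2d(mov, ref, spacing_mm=(res_mm, res_mm))
    d.flagged = None
    return d


@dataclass
class MultiresState:
    """Evolving state of the multi-resolution loop for one slab."""

    slab_id: int
    chains: dict = field(default_factory=dict)
    slab_transform: Transform3D | None = None
    recon_gm: Volume3D | None = None
    aligned_ref: Volume3D | None = None
    dice_log: list = field(default_factory=list)   # [{"res":r, "dice":{sample: d}}]
    flags: list = field(default_factory=list)

    @property
    def median_dice_per_resolution(self) -> list[float]:
        return [float(np.median(list(e["dice"].values()))) for e in self.dice_log]


def run_multires(
    stack_slab: SectionStack,
    masks: dict,
    rigids: dict,
    ref_gm: Volume3D,
    bounds: SlabBounds | None,
    schedule: ResolutionSchedule,
    pixel_size_mm: float,
    seed: int = 0,
) -> MultiresState:
    """Run the full multi-resolution loop for one slab.

    ``rigids`` are the stage-1 transforms (the best available transforms at
    the first resolution); each resolution appends one 2D refinement per
    section. Returns the final chains, the slab's 3D transform, the
    reconstructed and aligned-reference GM volumes at the final resolution,
    and the per-resolution Dice log.
    """
    recs = [r for r in stack_slab.passing()
            if (r.slab_id, r.sample_index) in masks]
    if not recs:
        raise ValueError("no usable sections in slab")
    slab_id = recs[0].slab_id
    thick = recs[0].section_thickness_um / 1000.0
    state = MultiresState(slab_id=slab_id)
    state.chains = {
        (slab_id, r.sample_index): TransformChain(
            rigid=rigids.get((slab_id, r.sample_index), rigids.get(r.sample_index)))
        for r in recs
    }
    ref_slab = extract_reference_slab(ref_gm, bounds) if bounds is not None else ref_gm

    for res in schedule:
        recon = assemble_gm_volume(masks, state.chains, stack_slab, res,
                                   pixel_size_mm)
        ref_r = resample_volume(ref_slab, res, mode="linear")
        t3d = register_3d(ref_r, recon, res, seed=seed)
        aligned_ref = resample_volume_through(ref_r, t3d, recon)
        entry = {"res": res, "dice": {}}
        for r in recs:
            key = (slab_id, r.sample_index)
            arr = masks[key].values if hasattr(masks[key], "values") else masks[key]
            cur = apply_transform_2d(arr, state.chains[key], mode="linear",
                                     spacing_mm=(pixel_size_mm, pixel_size_mm))
            cur_r = _resample_plane(np.clip(cur, 0, 1), pixel_size_mm, res)
            # corresponding reference plane: nearest along the cutting axis,
            # ties toward posterior
            w = r.sample_index * thick
            jf = aligned_ref.world_to_index(w)
            j = int(np.clip(np.floor(jf + 0.5 - 1e-9), 0,
                            aligned_ref.shape[CUT_AXIS] - 1))
            refp = aligned_ref.plane(j)
            shp = (min(cur_r.shape[0], refp.shape[0]),
                   min(cur_r.shape[1], refp.shape[1]))
            cur_c, ref_c = cur_r[:shp[0], :shp[1]], refp[:shp[0], :shp[1]]
            d = refine_2d(cur_c, ref_c, res)
            if getattr(d, "flagged", None):
                state.flags.append((key, res, d.flagged))
            if np.abs(d.disp).max() > 0:
                state.chains[key].deforms.append(d)
                cur_c = apply_transform_2d(
                    arr, state.chains[key], out_shape=None, mode="linear",
                    spacing_mm=(pixel_size_mm, pixel_size_mm))
                cur_c = _resample_plane(np.clip(cur_c, 0, 1), pixel_size_mm,
                                        res)[:shp[0], :shp[1]]
            entry["dice"][r.sample_index] = dice(cur_c > 0.5, ref_c > 0.5)
        state.dice_log.append(entry)
        state.slab_transform = t3d
        state.recon_gm = recon
        state.aligned_ref = aligned_ref
    return state


__all__ = [
    "rasterize_surfaces_to_gm", "assemble_gm_volume", "extract_reference_slab",
    "register_3d", "refine_2d", "MultiresState", "run_multires",
]
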