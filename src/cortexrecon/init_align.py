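"""Stage 1: contrast-ranked, center-outward rigid chaining within each slab.

Low-contrast sections are hard to align, so acquisitions are ranked by the
Michelson contrast of their sections and aligned in descending order. In
the highest-contrast group the central section of the slab is fixed and
sections are chained outward, each aligning to its nearest already-fixed
same-group neighbor toward the center and then becoming fixed itself.
Every subsequent (lower-contrast) group aligns each of its sections to the
nearest fixed section of any higher-contrast group. Alignment is computed
on Gaussian-blurred GM masks by default, which makes the metric
acquisition-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import backend
from .core import GMMask, Image2D, Rigid2D, SectionStack, Volume3D, apply_transform_2d


@dataclass
class ContrastRanking:
    """Per-acquisition contrast scores and the descending alignment order."""

    scores: dict[str, float]
    order: list[str]

    def __post_init__(self) -> None:
        for a, s in self.scores.items():
            if not 0 <= s <= 1:
                raise ValueError(f"contrast score for {a!r} outside [0, 1]")


def michelson_contrast(img: Image2D | np.ndarray, tissue_mask) -> float:
    """(Imax - Imin) / (Imax + Imin) over tissue pixels; 0 for an all-dark image."""
    arr = img.values if isinstance(img, Image2D) else np.asarray(img, dtype=float)
    mv = tissue_mask.values if isinstance(tissue_mask, GMMask) else np.asarray(tissue_mask)
    sel = mv.astype(bool)
    if not sel.any():
        raise ValueError("tissue mask is empty")
    vals = arr[sel]
    imax, imin = float(vals.max()), float(vals.min())
    if imax + imin == 0:
        return 0.0
    return (imax - imin) / (imax + imin)


def rank_acquisitions(stack: SectionStack, masks: dict, images: dict,
                      statistic=np.median) -> ContrastRanking:
    """Aggregate per-section Michelson contrasts per acquisition (median by
    default) and order acquisitions by descending contrast, ties broken
    alphabetically."""
    per_acq: dict[str, list[float]] = {}
    for r in stack.passing():
        key = (r.slab_id, r.sample_index)
        if key not in masks:
            continue
        c = michelson_contrast(images[key], masks[key])
        per_acq.setdefault(r.acquisition, []).append(c)
    scores = {a: float(statistic(v)) for a, v in per_acq.items()}
    order = sorted(scores, key=lambda a: (-scores[a], a))
    return ContrastRanking(scores=scores, order=order)


def register_rigid_2d(moving, fixed, spacing_mm: tuple[float, float] = (1.0, 1.0),
                      blur_px: float = 1.0, metric: str = "mattes") -> Rigid2D:
    """Rigid registration of two section masks (or images).

    Inputs are blurred with a small Gaussian (sigma ``blur_px``) so binary
    masks present usable gradients. Returns the transform mapping fixed
    pixels to moving pixels; identity with a warning on divergence.
    """
    mv = np.asarray(moving.values if hasattr(moving, "values") else moving, float)
    fx = np.asarray(fixed.values if hasattr(fixed, "values") else fixed, float)
    if blur_px > 0:
        mv = ndimage.gaussian_filter(mv, blur_px)
        fx = ndimage.gaussian_filter(fx, blur_px)
    return backend.register_rigid_2d(mv, fx, spacing_mm, metric=metric)


def chain_align_slab(stack_slab: SectionStack, masks: dict,
                     ranking: ContrastRanking,
                     images: dict | None = None) -> dict[int, Rigid2D]:
    """Center-outward rigid chaining of one slab; returns per-sample rigids
    (mapping reconstruction pixels to section pixels).

    Registration runs on the blurred GM masks (default): pure shape
    alignment is immune to the smooth within-tissue intensity gradients
    that bias area matching between neighboring planes. Passing ``images``
    switches to raw-intensity registration under a correlation metric.
    """
    recs = [r for r in stack_slab.passing()
            if (r.slab_id, r.sample_index) in masks]
    if not recs:
        raise ValueError("slab has no usable sections")
    slab_id = recs[0].slab_id
    by_acq: dict[str, list] = {}
    for r in recs:
        by_acq.setdefault(r.acquisition, []).append(r)

    transforms: dict[int, Rigid2D] = {}
    aligned: dict[int, np.ndarray] = {}   # sample -> image resampled into recon frame
    fixed_samples: list[int] = []

    def mask_of(r):
        if images is not None:
            return np.asarray(images[(slab_id, r.sample_index)], dtype=float)
        return masks[(slab_id, r.sample_index)].values

    center_sample = None
    for gi, acq in enumerate(ranking.order):
        group = sorted(by_acq.get(acq, []), key=lambda r: r.sample_index)
        if not group:
            continue
        if gi == 0 or not fixed_samples:
            # central section of an even-count group: lower middle index
            mid = group[(len(group) - 1) // 2]
            center_sample = mid.sample_index
            transforms[mid.sample_index] = Rigid2D()
            aligned[mid.sample_index] = mask_of(mid)
            fixed_samples.append(mid.sample_index)
            rest = [r for r in group if r.sample_index != mid.sample_index]
            # outward sweep in both directions from the center
            rest.sort(key=lambda r: (abs(r.sample_index - center_sample),
                                     r.sample_index))
            todo = rest
            same_group_only = True
        else:
            todo = group
            same_group_only = False
        for r in todo:
            pool = fixed_samples
            if same_group_only:
                grp_samples = {x.sample_index for x in group} | {center_sample}
                pool = [s for s in fixed_samples if s in grp_samples]
            # nearest fixed neighbor; ties broken toward the slab center
            ref_sample = min(
                pool,
                key=lambda s: (abs(s - r.sample_index),
                               abs(s - center_sample)),
            )
            rigid = register_rigid_2d(
                mask_of(r), aligned[ref_sample],
                blur_px=0.0 if images is not None else 1.0,
                metric="correlation" if images is not None else "mattes")
            transforms[r.sample_index] = rigid
            aligned[r.sample_index] = apply_transform_2d(mask_of(r), rigid,
                                                         mode="linear")
            fixed_samples.append(r.sample_index)
    return transforms


def build_initial_volume(stack: SectionStack, rigids: dict, images: dict,
                         res_mm: float, pixel_size_mm: float) -> Volume3D:
    """Stack rigidly aligned sections into the initial volume.

    Sections are resampled through their rigid transforms into a common
    in-plane grid at ``res_mm`` and placed at world position
    sample_index x section thickness along the cutting axis; planes with no
    acquired section stay at the background value 0.
    """
    recs = stack.passing()
    if not recs:
        raise ValueError("no sections to stack")
    thick = recs[0].section_thickness_um / 1000.0
    samples = [r.sample_index for r in recs]
    smin, smax = min(samples), max(samples)
    shp = next(iter(images.values())).shape
    scale = res_mm / pixel_size_mm
    out_rc = (max(1, int(np.floor(shp[0] / scale))), max(1, int(np.floor(shp[1] / scale))))
    n_planes = max(1, int(np.floor((smax - smin + 1) * thick / res_mm)))
    vol = np.zeros((out_rc[0], n_planes, out_rc[1]))
    for r in recs:
        key = (r.slab_id, r.sample_index)
        if key not in rigids:
            continue
        j = int(np.floor((r.sample_index - smin) * thick / res_mm))
        if not 0 <= j < n_planes:
            continue
        img = np.asarray(images[key], dtype=float)
        rr, cc = np.meshgrid(np.arange(out_rc[0]), np.arange(out_rc[1]), indexing="ij")
        # output px -> native px (edge-aligned grids) -> rigid -> sample
        pts = np.stack([(rr.ravel() + 0.5) * scale - 0.5,
                        (cc.ravel() + 0.5) * scale - 0.5], axis=1)
        src = rigids[key].map_points(pts)
        plane = ndimage.map_coordinates(img, src.T, order=1, mode="constant",
                                        cval=0.0).reshape(out_rc)
        vol[:, j, :] = np.maximum(vol[:, j, :], plane)
    origin = (0.0, smin * thick, 0.0)
    return Volume3D(vol, spacing_mm=(res_mm, res_mm, res_mm), origin=origin)


__all__ = [
    "ContrastRanking", "michelson_contrast", "rank_acquisitions",
    "register_rigid_2d", "chain_align_slab", "build_initial_volume",
]
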