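"""Reusable validation statistics for reconstruction quality.

Five families: (1) windowed and inter-section Dice for alignment accuracy,
robust to damaged sections; (2) patch-based validation of the surface
interpolation inside acquired sections; (3) ROI-based interpolation
accuracy after 2D and after 3D resampling; (4) regional regression of
paired region means; (5) SUVR normalization and a permutation test
comparing within- vs between-group correlation lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage, stats
from skimage.segmentation import slic

from .core import CUT_AXIS, GMMask, Image2D, TransformChain, Volume3D, dice, \
    apply_transform_2d
from .surface import SurfaceMesh, VertexField, _patch_interp


def windowed_dice(pred, ref, window: int = 5) -> float:
    """Mean local Dice over a dense sliding window.

    Local scores are only computed where the prediction window contains
    tissue, so missing/damaged tissue in an otherwise well-aligned section
    does not drag the score down. Raises if the prediction has no tissue.
    """
    pv = (pred.values if isinstance(pred, GMMask) else np.asarray(pred)).astype(bool)
    rv = (ref.values if isinstance(ref, GMMask) else np.asarray(ref)).astype(bool)
    if pv.shape != rv.shape:
        raise ValueError("masks must share a grid")
    if not pv.any():
        raise ValueError("prediction contains no tissue")
    a = sliding_window_view(pv, (window, window)).sum(axis=(2, 3))
    b = sliding_window_view(rv, (window, window)).sum(axis=(2, 3))
    ab = sliding_window_view(pv & rv, (window, window)).sum(axis=(2, 3))
    use = a > 0
    if not use.any():
        raise ValueError("no window contains prediction tissue")
    scores = 2.0 * ab[use] / (a[use] + b[use])
    return float(scores.mean())


def intersection_dice(masks_by_sample: dict[int, np.ndarray]) -> dict[int, float]:
    """Per-section mean Dice with the nearest acquired anterior and
    posterior neighbors (single-sided at slab ends)."""
    if len(masks_by_sample) < 2:
        raise ValueError("need at least 2 sections")
    samples = sorted(masks_by_sample)
    out: dict[int, float] = {}
    for i, s in enumerate(samples):
        scores = []
        if i > 0:
            scores.append(dice(masks_by_sample[s], masks_by_sample[samples[i - 1]]))
        if i < len(samples) - 1:
            scores.append(dice(masks_by_sample[s], masks_by_sample[samples[i + 1]]))
        out[s] = float(np.mean(scores))
    return out


# ---------------------------------------------------------------------------
# Patch-based surface-interpolation validation
# ---------------------------------------------------------------------------

@dataclass
class PatchSpec:
    """Random-patch protocol: ring radius n ~ U{2..6}, core radius
    m ~ U{1..5} with m < n, estimation distances restricted to a
    physical window by rejection."""

    n_seeds: int = 10000
    ring_range: tuple[int, int] = (2, 6)
    core_range: tuple[int, int] = (1, 5)
    distance_window_mm: tuple[float, float] = (0.05, 1.2)
    seed: int = 0
    max_attempts_per_seed: int = 80


def _hop_rings(neighbors: list[np.ndarray], seed_vertex: int, n: int,
               allowed: np.ndarray) -> list[np.ndarray]:
    """Rings of graph distance 0..n from a seed, restricted to allowed vertices."""
    rings = [np.array([seed_vertex])]
    visited = {seed_vertex}
    frontier = [seed_vertex]
    for _ in range(n):
        nxt = []
        for v in frontier:
            for w in neighbors[v]:
                if w not in visited and allowed[w]:
                    visited.add(w)
                    nxt.append(w)
        rings.append(np.array(sorted(nxt), dtype=int))
        frontier = nxt
        if not nxt:
            break
    return rings


def patch_interpolation_validation(
    mesh_native: SurfaceMesh,
    mesh_sphere: SurfaceMesh,
    field: VertexField,
    spec: PatchSpec,
    plane_coord: np.ndarray | None = None,
    plane_tol_mm: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Hold-out validation of spherical interpolation within acquired data.

    Per accepted seed: grow hop rings 0..n (n ~ U{2..6}) around a random
    known vertex, restricted to known vertices in the same section plane
    when ``plane_coord``/``plane_tol_mm`` are given; treat rings 0..n-1 as
    missing; interpolate them from the ring-n vertices; compare the mean of
    the estimated core patch (rings 0..m, m ~ U{1..5}, m < n) with the true
    mean. Seeds whose estimation distances fall outside the physical window
    are rejected and redrawn. Returns (true_means, est_means, r2); r2 is
    None when the true means have zero variance (constant field: the
    agreement is then exact by construction and checked by the caller).
    """
    known = field.known_mask
    if known.sum() < 10:
        raise ValueError("insufficient known vertices for patch validation")
    rng = np.random.default_rng(spec.seed)
    neighbors = mesh_native.vertex_neighbors()
    kn_idx = np.where(known)[0]
    verts = mesh_native.vertices
    sph = mesh_sphere.vertices
    true_means, est_means = [], []
    lo, hi = spec.distance_window_mm
    accepted = 0
    attempts_left = spec.n_seeds * spec.max_attempts_per_seed
    while accepted < spec.n_seeds and attempts_left > 0:
        attempts_left -= 1
        s = int(rng.choice(kn_idx))
        n = int(rng.integers(spec.ring_range[0], spec.ring_range[1] + 1))
        m = int(rng.integers(spec.core_range[0], min(spec.core_range[1], n - 1) + 1))
        allowed = known.copy()
        if plane_coord is not None and plane_tol_mm is not None:
            allowed &= np.abs(plane_coord - plane_coord[s]) <= plane_tol_mm
        rings = _hop_rings(neighbors, s, n, allowed)
        if len(rings) < n + 1 or rings[n].size < 3:
            continue
        inner = np.concatenate(rings[:n])
        ring_n = rings[n]
        est_targets = np.concatenate(rings[: m + 1])
        # physical estimation distances: estimated vertices to known ring
        d = np.linalg.norm(verts[inner][:, None, :] - verts[ring_n][None, :, :],
                           axis=2).min(axis=1)
        if d.min() < lo or d.max() > hi:
            continue
        est = _patch_interp(sph[ring_n], field.values[ring_n], sph[est_targets])
        true_means.append(field.values[est_targets].mean())
        est_means.append(est.mean())
        accepted += 1
    t = np.asarray(true_means)
    e = np.asarray(est_means)
    if t.size == 0:
        raise ValueError("no patch satisfied the distance window")
    if np.ptp(t) == 0:
        return t, e, None
    r = np.corrcoef(t, e)[0, 1]
    return t, e, float(r ** 2)


# ---------------------------------------------------------------------------
# ROI-based interpolation accuracy
# ---------------------------------------------------------------------------

@dataclass
class RoiParcellation:
    """Per-pixel ROI labels on a section (0 = background)."""

    labels: np.ndarray
    target_mean_area_mm2: float

    @property
    def n_rois(self) -> int:
        return int(self.labels.max())


def make_roi_parcellation(section, mask, target_mean_area_mm2: float,
                          pixel_size_mm: float = 1.0) -> RoiParcellation:
    """SLIC superpixel parcellation of the tissue into contiguous ROIs of
    roughly the target mean area (spatial+intensity k-means clustering)."""
    arr = section.values if isinstance(section, Image2D) else np.asarray(section, float)
    mv = (mask.values if isinstance(mask, GMMask) else np.asarray(mask)).astype(bool)
    if not mv.any():
        raise ValueError("mask is empty")
    area_mm2 = mv.sum() * pixel_size_mm ** 2
    n = max(1, int(round(area_mm2 / target_mean_area_mm2)))
    if mv.sum() <= 4 or n == 1:
        return RoiParcellation(mv.astype(int), target_mean_area_mm2)
    labels = slic(arr, n_segments=n, mask=mv, compactness=0.05,
                  channel_axis=None, enforce_connectivity=True, start_label=1)
    labels = labels.astype(int)
    labels[~mv] = 0
    # relabel densely 1..K
    uniq = np.unique(labels)
    uniq = uniq[uniq > 0]
    remap = np.zeros(labels.max() + 1, dtype=int)
    remap[uniq] = np.arange(1, len(uniq) + 1)
    return RoiParcellation(remap[labels], target_mean_area_mm2)


def interpolation_accuracy(
    raw_sections: dict,
    parcellations: dict,
    chains: dict,
    recon_volume: Volume3D,
    pixel_size_mm: float = 1.0,
    thickness_mm: float = 1.0,
    mode: str = "linear",
) -> dict:
    """Per-ROI accuracy of pixel intensities after 2D alignment and after
    full 3D reconstruction.

    True region means come from the raw sections; the 2D estimate applies
    the same transform chain to section and parcellation (nearest for
    labels); the 3D estimate reads the reconstructed volume under the
    transformed parcellation at the section's plane. Accuracy per ROI is
    1 - |true - est| / true; ROIs with a zero true mean are excluded.
    """
    res_2d, res_3d, excluded = [], [], []
    for key, raw in raw_sections.items():
        arr = raw.values if isinstance(raw, Image2D) else np.asarray(raw, float)
        parc = parcellations[key].labels
        chain = chains.get(key, TransformChain())
        sp = (pixel_size_mm, pixel_size_mm)
        moved = apply_transform_2d(arr, chain, mode=mode, spacing_mm=sp)
        moved_lab = apply_transform_2d(parc.astype(float), chain, mode="nearest",
                                       spacing_mm=sp).astype(int)
        sample = key[1]
        j = int(np.clip(round(recon_volume.world_to_index(sample * thickness_mm)),
                        0, recon_volume.shape[CUT_AXIS] - 1))
        plane = recon_volume.plane(j)
        scale = recon_volume.spacing_mm[0] / pixel_size_mm
        if abs(scale - 1) > 1e-9:
            rr, cc = np.meshgrid(*[(np.arange(n) + 0.5) * scale - 0.5
                                   for n in moved_lab.shape], indexing="ij")
            plane = ndimage.map_coordinates(plane, [rr, cc], order=1,
                                            mode="constant", cval=0.0)
        else:
            plane = plane[:moved_lab.shape[0], :moved_lab.shape[1]]
        for roi in range(1, int(parc.max()) + 1):
            sel_raw = parc == roi
            true = arr[sel_raw].mean() if sel_raw.any() else 0.0
            if true == 0:
                excluded.append((key, roi))
                continue
            sel_mv = moved_lab == roi
            if not sel_mv.any():
                excluded.append((key, roi))
                continue
            est2 = moved[sel_mv].mean()
            est3 = plane[sel_mv].mean()
            res_2d.append(1.0 - abs(true - est2) / true)
            res_3d.append(1.0 - abs(true - est3) / true)
    a2, a3 = np.asarray(res_2d), np.asarray(res_3d)
    return {
        "per_roi_2d": a2, "per_roi_3d": a3,
        "mean_2d": float(a2.mean()) if a2.size else np.nan,
        "sd_2d": float(a2.std()) if a2.size else np.nan,
        "mean_3d": float(a3.mean()) if a3.size else np.nan,
        "sd_3d": float(a3.std()) if a3.size else np.nan,
        "excluded": excluded,
    }


# ---------------------------------------------------------------------------
# Regression, SUVR, permutation test
# ---------------------------------------------------------------------------

def regional_regression(means_a, means_b) -> tuple[float, float, float]:
    """OLS of b on a over paired region means; returns (slope, intercept, r2)."""
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need >= 3 paired region means")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in region means")
    res = stats.linregress(a, b)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def suvr(pet: Volume3D, wm_mask) -> Volume3D:
    """Standardized uptake value ratio: voxelwise division by the mean
    activity inside the WM mask."""
    mv = (wm_mask.values if isinstance(wm_mask, GMMask) else
          np.asarray(wm_mask)).astype(bool)
    if mv.shape != pet.shape:
        raise ValueError("WM mask grid does not match the PET volume")
    if not mv.any():
        raise ValueError("WM mask is empty")
    m = float(pet.values[mv].mean())
    if m == 0:
        raise ValueError("WM mean activity is zero")
    return Volume3D(pet.values / m, spacing_mm=tuple(pet.spacing_mm),
                    origin=tuple(pet.origin), axis_map=pet.axis_map)


def permutation_corr_test(within_group_corrs, between_group_corrs,
                          n_perm: int = 10000, seed: int = 0) -> float:
    """Permutation p-value for the absolute difference in mean correlation
    between two groups of correlation coefficients.

    Group labels are permuted over the pooled values; the p-value uses
    add-one smoothing: (1 + #{perm >= observed}) / (n_perm + 1).
    """
    w = np.asarray(within_group_corrs, dtype=float)
    b = np.asarray(between_group_corrs, dtype=float)
    if w.size == 0 or b.size == 0:
        raise ValueError("both correlation lists must be non-empty")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value", stacklevel=2)
    obs = abs(w.mean() - b.mean())
    pooled = np.concatenate([w, b])
    rng = np.random.default_rng(seed)
    count = 0
    nw = w.size
    for _ in range(int(n_perm)):
        perm = rng.permutation(pooled)
        stat = abs(perm[:nw].mean() - perm[nw:].mean())
        if stat >= obs - 1e-15:
            count += 1
    return (1 + count) / (n_perm + 1)


__all__ = [
    "windowed_dice", "intersection_dice", "PatchSpec",
    "patch_interpolation_validation", "RoiParcellation",
    "make_roi_parcellation", "interpolation_accuracy",
    "regional_regression", "suvr", "permutation_corr_test",
]
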