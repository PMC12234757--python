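"""Contrast-agnostic gray-matter segmentation of 2D sections.

Multi-modal section stacks (different ligands, stains) have wildly
different intensity distributions, so alignment runs on GM masks rather
than raw intensities. The segmenter is pluggable: any object with a
``predict(Image2D) -> GMMask`` method. The package ships

* a synthetic-training-image generator that renders random-contrast 2D
  sections from any labeled volume (random affine, random cortical
  layering, random per-class intensities, optional skull, augmentations)
  for training an external network, and
* a classical fallback/default segmenter based on Otsu thresholding with
  automatic polarity detection and largest-component cleanup.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .core import GMMask, Image2D, SectionStack, dice, save_section_image


class DegenerateInputError(ValueError):
    """The input has no usable structure (e.g., a constant image)."""


@dataclass
class SynthRecipe:
    """Recipe for the synthetic training set.

    Defaults follow the synthesis protocol this generator implements:
    10,000 images, 500 sections per randomly transformed volume, per-axis
    scaling ~ U(0.9, 1.1), rotations ~ U(0, 15) degrees, a random number of
    cortical layers ~ U{0..11} with Dirichlet(1,...,1) proportional
    thicknesses, and a skull ring retained in 50% of examples. Per-class
    intensities and augmentation strengths are configuration (no canonical
    values exist); the defaults below give strongly heterogeneous but
    plausible 8-bit contrasts.
    """

    n_images: int = 10000
    sections_per_volume: int = 500
    scale_range: tuple[float, float] = (0.9, 1.1)
    rotation_range_deg: tuple[float, float] = (0.0, 15.0)
    layer_count_range: tuple[int, int] = (0, 11)
    skull_prob: float = 0.5
    tissue_classes: tuple[str, ...] = (
        "WM", "subcortical_GM", "cortical_GM", "cerebellar_GM",
        "inside_background", "outside_background", "skull",
    )
    class_value_range: tuple[float, float] = (10.0, 245.0)
    noise_sd_range: tuple[float, float] = (0.0, 8.0)
    smoothing_sigma_range: tuple[float, float] = (0.0, 1.5)
    intensity_scale_range: tuple[float, float] = (0.8, 1.2)
    crop_fraction_range: tuple[float, float] = (0.85, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.skull_prob <= 1:
            raise ValueError("skull_prob must be in [0, 1]")
        for lo, hi in (self.scale_range, self.rotation_range_deg,
                       self.noise_sd_range, self.smoothing_sigma_range):
            if hi < lo:
                raise ValueError("invalid range in recipe")


#: label codes in generated training targets
TRAIN_BG, TRAIN_CORTEX, TRAIN_WM = 0, 1, 2


@dataclass
class TrainingPair:
    image: Image2D
    labels: Image2D          # 0 background, 1 cortex, 2 WM
    boundary: Image2D        # 1 at pixels bordering a different class
    n_layers: int = 0        # cortical layers drawn for this example


@runtime_checkable
class Segmenter(Protocol):
    """Anything that maps a section image to a binary GM mask on the same grid."""

    name: str

    def predict(self, img: Image2D) -> GMMask: ...


def _random_affine_labels(vol: np.ndarray, recipe: SynthRecipe,
                          rng: np.random.Generator) -> np.ndarray:
    """One random scaling+rotation of a 3D label volume (nearest neighbor)."""
    sc = rng.uniform(*recipe.scale_range, size=3)
    ang = np.deg2rad(rng.uniform(*recipe.rotation_range_deg, size=3))
    rx, ry, rz = ang
    Rx = np.array([[1, 0, 0], [0, np.cos(rx), -np.sin(rx)], [0, np.sin(rx), np.cos(rx)]])
    Ry = np.array([[np.cos(ry), 0, np.sin(ry)], [0, 1, 0], [-np.sin(ry), 0, np.cos(ry)]])
    Rz = np.array([[np.cos(rz), -np.sin(rz), 0], [np.sin(rz), np.cos(rz), 0], [0, 0, 1]])
    m = (Rz @ Ry @ Rx) * sc
    center = (np.array(vol.shape) - 1) / 2
    offset = center - m @ center
    return ndimage.affine_transform(vol, m, offset=offset, order=0, mode="constant",
                                    cval=0)


def _cortical_depth(cortex: np.ndarray, wm: np.ndarray) -> np.ndarray:
    """Approximate normalized depth (0 at the outer, 1 at the WM border) in 2D."""
    outside = ~(cortex | wm)
    d_out = ndimage.distance_transform_edt(~outside)
    d_wm = ndimage.distance_transform_edt(~wm) if wm.any() else np.ones_like(d_out)
    tot = d_out + d_wm
    depth = np.zeros(cortex.shape)
    depth[cortex] = d_out[cortex] / np.maximum(tot[cortex], 1e-9)
    return depth


def synthesize_training_pair(label_volume, recipe: SynthRecipe,
                             draw_seed: int) -> TrainingPair:
    """Render one synthetic section/label pair from a labeled volume.

    Label codes in the input volume: 0 background, 1 WM, 2 cortical GM
    (extra positive labels are treated as further tissue classes). One
    random affine is applied to the volume, one plane is extracted, the
    cortex is split into k ~ U{0..11} layers of Dirichlet-proportional
    thickness, every class receives a random intensity, a skull ring is
    added with probability ``skull_prob``, and smoothing/noise/scale/crop
    augmentations are applied. Deterministic in ``draw_seed``.
    """
    vol = np.asarray(label_volume.values if hasattr(label_volume, "values")
                     else label_volume)
    if not (vol == 2).any():
        raise ValueError("label volume contains no cortex class (label 2)")
    rng = np.random.default_rng(draw_seed)
    warped = _random_affine_labels(vol, recipe, rng)
    # pick a plane with cortex present
    counts = (warped == 2).sum(axis=(0, 2))
    good = np.where(counts > 0)[0]
    if good.size == 0:
        warped, good = vol, np.where((vol == 2).sum(axis=(0, 2)) > 0)[0]
    plane = warped[:, rng.choice(good), :]
    return _render_section(plane, recipe, rng)


def _render_section(plane: np.ndarray, recipe: SynthRecipe,
                    rng: np.random.Generator) -> TrainingPair:
    cortex = plane == 2
    wm = plane == 1
    lo, hi = recipe.layer_count_range
    k = int(rng.integers(lo, hi + 1))
    img = np.zeros(plane.shape)

    # random value per non-cortex class
    for lab in np.unique(plane):
        if lab in (0, 2):
            continue
        img[plane == lab] = rng.uniform(*recipe.class_value_range)
    if k == 0:
        img[cortex] = rng.uniform(*recipe.class_value_range)
    else:
        depth = _cortical_depth(cortex, wm)
        props = rng.dirichlet(np.ones(k))
        edges = np.concatenate([[0.0], np.cumsum(props)])
        vals = rng.uniform(*recipe.class_value_range, size=k)
        for i in range(k):
            sel = cortex & (depth >= edges[i]) & (depth <= edges[i + 1] + 1e-12)
            img[sel] = vals[i]

    if rng.random() < recipe.skull_prob:
        tissue = plane > 0
        ring = ndimage.binary_dilation(tissue, iterations=4) & \
            ~ndimage.binary_dilation(tissue, iterations=2)
        img[ring] = rng.uniform(*recipe.class_value_range)

    sig = rng.uniform(*recipe.smoothing_sigma_range)
    if sig > 0:
        img = ndimage.gaussian_filter(img, sig)
    img = img * rng.uniform(*recipe.intensity_scale_range)
    sd = rng.uniform(*recipe.noise_sd_range)
    if sd > 0:
        img = img + rng.normal(0, sd, size=img.shape)
    frac = rng.uniform(*recipe.crop_fraction_range)
    if frac < 1.0:
        h, w = img.shape
        ch, cw = int(h * frac), int(w * frac)
        r0 = int(rng.integers(0, h - ch + 1))
        c0 = int(rng.integers(0, w - cw + 1))
        zoom = (h / ch, w / cw)
        img = ndimage.zoom(img[r0:r0 + ch, c0:c0 + cw], zoom, order=1)[:h, :w]
        plane = ndimage.zoom(plane[r0:r0 + ch, c0:c0 + cw], zoom, order=0)[:h, :w]
        cortex, wm = plane == 2, plane == 1
    img = np.clip(img, 0, 255)

    labels = np.zeros(plane.shape, dtype=float)
    labels[cortex] = TRAIN_CORTEX
    labels[wm] = TRAIN_WM
    grad = ndimage.maximum_filter(labels, 3) != ndimage.minimum_filter(labels, 3)
    return TrainingPair(
        image=Image2D(img),
        labels=Image2D(labels),
        boundary=Image2D(grad.astype(float)),
        n_layers=k,
    )


def generate_training_set(label_volume, recipe: SynthRecipe,
                          out_dir: str | Path) -> pd.DataFrame:
    """Write ``recipe.n_images`` training pairs to disk.

    Sections are grouped: each block of ``sections_per_volume`` consecutive
    images shares one random volume transform (drawn from one seed), as in
    training-set generation from a transformed whole volume. Returns (and
    writes) the index CSV. Re-running with the same recipe reproduces the
    files bit for bit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vol = np.asarray(label_volume.values if hasattr(label_volume, "values")
                     else label_volume)
    rows = []
    n_groups = int(np.ceil(recipe.n_images / recipe.sections_per_volume))
    idx = 0
    for g in range(n_groups):
        rng = np.random.default_rng((recipe.seed, g))
        warped = _random_affine_labels(vol, recipe, rng)
        counts = (warped == 2).sum(axis=(0, 2))
        good = np.where(counts > 0)[0]
        if good.size == 0:
            warped, good = vol, np.where((vol == 2).sum(axis=(0, 2)) > 0)[0]
        for _ in range(min(recipe.sections_per_volume, recipe.n_images - idx)):
            plane = warped[:, rng.choice(good), :]
            pair = _render_section(plane, recipe, rng)
            img_p = out / f"img_{idx:05d}.png"
            lab_p = out / f"lab_{idx:05d}.png"
            bnd_p = out / f"bnd_{idx:05d}.png"
            save_section_image(pair.image, img_p)
            save_section_image(pair.labels.values * 100, lab_p)  # 0/100/200
            save_section_image(pair.boundary.values * 255, bnd_p)
            (out / f"meta_{idx:05d}.json").write_text(json.dumps(
                {"group": g, "index": idx, "classes": [0, 1, 2]}))
            rows.append({"index": idx, "group": g, "image": img_p.name,
                         "labels": lab_p.name, "boundary": bnd_p.name})
            idx += 1
    df = pd.DataFrame(rows)
    df.to_csv(out / "index.csv", index=False)
    return df


# ---------------------------------------------------------------------------
# Otsu fallback segmenter
# ---------------------------------------------------------------------------

def _otsu_threshold_256(values: np.ndarray) -> float:
    """Otsu threshold over a 256-bin histogram on [0, 256)."""
    counts, edges = np.histogram(values, bins=256, range=(0, 256))
    centers = (edges[:-1] + edges[1:]) / 2
    return float(threshold_otsu(hist=(counts, centers)))


def _ribbon_score(mask: np.ndarray) -> float:
    """How ribbon-like a candidate mask is: a dominant connected component
    with low solidity scores high (cortex is a thin folded band)."""
    if mask.sum() == 0:
        return -1.0
    lab = cc_label(mask)
    props = regionprops(lab)
    biggest = max(props, key=lambda p: p.area)
    frac = biggest.area / mask.sum()
    return frac * (1.0 - biggest.solidity)


def otsu_segment(img: Image2D | np.ndarray, tissue_side: str = "auto") -> GMMask:
    """Threshold-based GM segmentation of a section.

    The threshold maximizes between-class variance over a 256-bin histogram
    of the tissue (nonzero) pixels. ``tissue_side`` selects which side of
    the threshold is gray matter: ``bright``, ``dark``, or ``auto`` (the
    side whose largest connected component looks more like a cortical
    ribbon, i.e., is less solid). Constant images are rejected.
    """
    arr = img.values if isinstance(img, Image2D) else np.asarray(img, dtype=float)
    tissue = arr > 0
    vals = arr[tissue]
    if vals.size == 0 or np.unique(arr).size < 2:
        raise DegenerateInputError("image has fewer than 2 distinct values")
    if np.unique(vals).size < 2:
        raise DegenerateInputError("tissue is constant; cannot threshold")
    thr = _otsu_threshold_256(vals)
    bright = tissue & (arr > thr)
    dark = tissue & (arr <= thr)
    if tissue_side == "bright":
        keep = bright
    elif tissue_side == "dark":
        keep = dark
    elif tissue_side == "auto":
        keep = bright if _ribbon_score(bright) >= _ribbon_score(dark) else dark
    else:
        raise ValueError(f"unknown tissue_side {tissue_side!r}")
    return GMMask(keep.astype(float), is_binary=True)


@dataclass
class OtsuSegmenter:
    """Classical segmenter: Otsu threshold + largest-component cleanup."""

    tissue_side: str = "auto"
    keep_components: int = 1
    min_component_frac: float = 0.05
    name: str = "otsu"

    def predict(self, img: Image2D) -> GMMask:
        try:
            m = otsu_segment(img, self.tissue_side)
        except DegenerateInputError:
            arr = img.values if isinstance(img, Image2D) else np.asarray(img)
            return GMMask(np.zeros(arr.shape), is_binary=True)
        lab = cc_label(m.values > 0)
        if lab.max() == 0:
            return m
        sizes = np.bincount(lab.ravel())[1:]
        order = np.argsort(sizes)[::-1]
        keep = np.zeros_like(lab, dtype=bool)
        total = sizes.sum()
        for rank, ci in enumerate(order):
            if rank < self.keep_components or sizes[ci] >= self.min_component_frac * total:
                keep |= lab == ci + 1
        return GMMask(keep.astype(float), is_binary=True)


def segment_stack(
    stack: SectionStack,
    images: dict,
    segmenter: Segmenter,
    fallback: Segmenter | None = None,
    log: list | None = None,
) -> dict:
    """Segment every QC-passing section; fall back when the primary
    segmenter returns an empty mask; flag sections where both are empty."""
    fallback = fallback if fallback is not None else OtsuSegmenter()
    out: dict = {}
    for r in stack.records:
        if not r.qc_pass:
            continue
        key = (r.slab_id, r.sample_index)
        img = images[key]
        img2d = img if isinstance(img, Image2D) else Image2D(np.asarray(img, float))
        mask = segmenter.predict(img2d)
        if mask.values.sum() == 0 and fallback is not segmenter:
            mask = fallback.predict(img2d)
            if log is not None:
                log.append(f"section {key}: primary '{segmenter.name}' empty; "
                           f"used fallback '{fallback.name}'")
        if mask.values.sum() == 0:
            r.qc_pass = False
            r.exclude_reason = "empty_segmentation"
            if log is not None:
                log.append(f"section {key}: empty segmentation from both "
                           f"segmenters; excluded")
            continue
        out[key] = mask
    return out


def evaluate_segmentation(preds: list, manuals: list,
                          common_size: tuple[int, int] | None = None
                          ) -> tuple[np.ndarray, float, float]:
    """Per-pair Dice against manual labels plus mean and sd.

    If shapes differ (or ``common_size`` is forced) both masks are
    nearest-resized to a common evaluation size, default 415 x 558.
    """
    if len(preds) != len(manuals):
        raise ValueError("preds and manuals must pair up")
    scores = []
    for p, m in zip(preds, manuals):
        pv = p.values if isinstance(p, GMMask) else np.asarray(p)
        mv = m.values if isinstance(m, GMMask) else np.asarray(m)
        size = common_size
        if size is None and pv.shape != mv.shape:
            size = (415, 558)
        if size is not None:
            pv = _nearest_resize(pv, size)
            mv = _nearest_resize(mv, size)
        scores.append(dice(pv > 0, mv > 0))
    arr = np.asarray(scores)
    return arr, float(arr.mean()), float(arr.std())


def _nearest_resize(arr: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    return ndimage.zoom(arr.astype(float),
                        (size[0] / arr.shape[0], size[1] / arr.shape[1]),
                        order=0)


__all__ = [
    "DegenerateInputError", "SynthRecipe", "TrainingPair", "Segmenter",
    "TRAIN_BG", "TRAIN_CORTEX", "TRAIN_WM",
    "synthesize_training_pair", "generate_training_set",
    "otsu_segment", "OtsuSegmenter", "segment_stack", "evaluate_segmentation",
]
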