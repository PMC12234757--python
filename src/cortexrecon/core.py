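"""Domain types, I/O and shared primitives for serial-section 3D reconstruction.

Conventions used throughout the package
---------------------------------------
* Pixel / voxel indices are 0-based, pixel-center. World units are mm
  (section pixel sizes are carried in micrometres, as digitised sections
  are specified that way, and converted at use sites).
* Volumes are right-handed arrays indexed ``(x, y, z)``; the cutting
  (coronal) axis maps to array axis 1 by default, so a section at sample
  position ``j`` is the plane ``values[:, j, :]`` with rows = x and
  columns = z.
* Background is 0 everywhere; tissue is strictly positive after
  preprocessing, so masks and intensity images share one fill value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

#: Array axis that holds the cutting (coronal) direction.
CUT_AXIS = 1

#: Fill value for out-of-domain pixels after any resampling.
BACKGROUND = 0.0

MANIFEST_COLUMNS = ("slab", "sample", "acquisition", "image", "pixel_size_um")


class SchemaError(ValueError):
    """A tabular input is missing required structure."""


class IntegrityError(ValueError):
    """An input violates a uniqueness or consistency invariant."""


class GridMismatchError(ValueError):
    """Two gridded objects that must share a grid do not."""


# ---------------------------------------------------------------------------
# Section bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class SectionRecord:
    """One physical 2D section: where it was cut and how it was imaged."""

    slab_id: int
    sample_index: int
    acquisition: str
    image_ref: str
    pixel_size_um: float
    section_thickness_um: float = 1000.0
    qc_pass: bool = True
    exclude_reason: str | None = None

    def __post_init__(self) -> None:
        if self.slab_id < 1:
            raise IntegrityError(f"slab_id must be >= 1, got {self.slab_id}")
        if self.sample_index < 0:
            raise IntegrityError(f"sample_index must be >= 0, got {self.sample_index}")
        if self.pixel_size_um <= 0:
            raise IntegrityError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        if self.section_thickness_um <= 0:
            raise IntegrityError("section_thickness_um must be positive")


@dataclass
class SectionStack:
    """Ordered collection of sections from one hemisphere."""

    records: list[SectionRecord]
    axis: str = "coronal"
    species_tag: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise IntegrityError("a section stack must contain at least one record")
        seen: set[tuple[int, int]] = set()
        for r in self.records:
            key = (r.slab_id, r.sample_index)
            if key in seen:
                raise IntegrityError(f"duplicate (slab, sample) pair {key} in stack")
            seen.add(key)
        by_slab: dict[int, float] = {}
        for r in self.records:
            t = by_slab.setdefault(r.slab_id, r.section_thickness_um)
            if t != r.section_thickness_um:
                raise IntegrityError(
                    f"slab {r.slab_id} mixes section thicknesses ({t} vs {r.section_thickness_um})"
                )
        self.records.sort(key=lambda r: (r.slab_id, r.sample_index))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def slab_ids(self) -> list[int]:
        return sorted({r.slab_id for r in self.records})

    @property
    def acquisitions(self) -> list[str]:
        return sorted({r.acquisition for r in self.records})

    def for_slab(self, slab_id: int) -> "SectionStack":
        recs = [r for r in self.records if r.slab_id == slab_id]
        if not recs:
            raise IntegrityError(f"no records for slab {slab_id}")
        return SectionStack(list(recs), axis=self.axis, species_tag=self.species_tag)

    def passing(self) -> list[SectionRecord]:
        return [r for r in self.records if r.qc_pass]


def load_manifest(path: str | Path) -> SectionStack:
    """Read a CSV manifest of sections into a :class:`SectionStack`.

    Required columns: ``slab, sample, acquisition, image, pixel_size_um``;
    ``section_thickness_um`` is optional (default 1000 µm). Records are
    returned sorted by ``(slab, sample)`` with ``qc_pass`` defaulting true.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"manifest {path} is missing required column '{col}'")
    records = []
    for _, row in df.iterrows():
        records.append(
            SectionRecord(
                slab_id=int(row["slab"]),
                sample_index=int(row["sample"]),
                acquisition=str(row["acquisition"]),
                image_ref=str(row["image"]),
                pixel_size_um=float(row["pixel_size_um"]),
                section_thickness_um=float(row.get("section_thickness_um", 1000.0))
                if "section_thickness_um" in df.columns
                else 1000.0,
            )
        )
    return SectionStack(records)


def save_manifest(stack: SectionStack, path: str | Path) -> None:
    """Write a stack back to CSV in the manifest schema."""
    rows = [
        {
            "slab": r.slab_id,
            "sample": r.sample_index,
            "acquisition": r.acquisition,
            "image": r.image_ref,
            "pixel_size_um": r.pixel_size_um,
            "section_thickness_um": r.section_thickness_um,
        }
        for r in stack.records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gridded images, volumes, masks
# ---------------------------------------------------------------------------

@dataclass
class Image2D:
    """A 2D section image with grid metadata (row/col spacing in µm)."""

    values: np.ndarray
    spacing_um: tuple[float, float] = (1000.0, 1000.0)
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Image2D requires a 2D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Image2D values must be finite")
        if min(self.spacing_um) <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class Volume3D:
    """A 3D volume; world coordinates are ``origin + index * spacing_mm``."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_map: int = CUT_AXIS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("Volume3D requires a 3D array")
        if min(self.spacing_mm) <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def plane(self, j: int) -> np.ndarray:
        """The section plane at index ``j`` along the cutting axis."""
        return np.take(self.values, j, axis=self.axis_map)

    def plane_world(self, j: int) -> float:
        return self.origin[self.axis_map] + j * self.spacing_mm[self.axis_map]

    def world_to_index(self, w: float) -> float:
        """Continuous plane index along the cutting axis for world coord ``w``."""
        a = self.axis_map
        return (w - self.origin[a]) / self.spacing_mm[a]


@dataclass
class GMMask:
    """Gray-matter mask on a 2D or 3D grid; values in [0, 1]."""

    values: np.ndarray
    spacing: tuple = (1.0, 1.0)
    origin: tuple = (0.0, 0.0)
    is_binary: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("mask values must lie in [0, 1]")
        if self.is_binary and not np.isin(np.unique(self.values), (0.0, 1.0)).all():
            raise ValueError("binary mask contains non-{0,1} values")

    @property
    def shape(self):
        return self.values.shape


def dice(a: np.ndarray | GMMask, b: np.ndarray | GMMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two binary masks on one grid.

    Two empty masks count as perfect agreement (1.0), so windowed variants
    over tissue-free regions never produce NaN.
    """
    av = a.values if isinstance(a, GMMask) else np.asarray(a)
    bv = b.values if isinstance(b, GMMask) else np.asarray(b)
    if av.shape != bv.shape:
        raise GridMismatchError(f"mask shapes differ: {av.shape} vs {bv.shape}")
    ab = av.astype(bool)
    bb = bv.astype(bool)
    denom = int(ab.sum()) + int(bb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((ab & bb).sum()) / denom


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

@dataclass
class Rigid2D:
    """A 2D rigid transform: rotation (deg, CCW in array coords) about
    ``center`` followed by a ``(dr, dc)`` translation.

    ``map_points`` sends *output* pixel coordinates to *input* pixel
    coordinates (resampling convention), i.e. it encodes where each output
    pixel reads from.
    """

    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    center: tuple[float, float] = (0.0, 0.0)
    unit: str = "px"
    warning: str | None = None

    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix in (row, col) coordinates."""
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        rot = np.array([[c, -s], [s, c]])
        cen = np.asarray(self.center)
        t = np.asarray(self.translation)
        m = np.eye(3)
        m[:2, :2] = rot
        m[:2, 2] = cen - rot @ cen + t
        return m

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        """Apply to an (N, 2) array of (row, col) points."""
        m = self.matrix()
        pts = np.asarray(pts, dtype=float)
        return pts @ m[:2, :2].T + m[:2, 2]

    def compose(self, other: "Rigid2D") -> "Rigid2D":
        """Transform equal to applying ``self`` after ``other`` to points."""
        m = self.matrix() @ other.matrix()
        ang = np.rad2deg(np.arctan2(m[1, 0], m[0, 0]))
        return Rigid2D(rotation_deg=ang, translation=(m[0, 2], m[1, 2]), center=(0.0, 0.0))

    def inverse(self) -> "Rigid2D":
        m = np.linalg.inv(self.matrix())
        ang = np.rad2deg(np.arctan2(m[1, 0], m[0, 0]))
        return Rigid2D(rotation_deg=ang, translation=(m[0, 2], m[1, 2]), center=(0.0, 0.0))


@dataclass
class Deformation2D:
    """Dense 2D displacement field (in pixels of its own grid).

    ``disp`` has shape (2, H, W); the warp maps output point ``x`` to
    ``x + disp(x)`` (again the resampling convention). ``spacing_mm`` states
    the grid the field was estimated on so it can be re-used at other
    resolutions.
    """

    disp: np.ndarray
    spacing_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.disp = np.asarray(self.disp, dtype=float)
        if self.disp.ndim != 3 or self.disp.shape[0] != 2:
            raise ValueError("Deformation2D.disp must have shape (2, H, W)")
        if not np.all(np.isfinite(self.disp)):
            raise ValueError("displacement field must be finite")

    def map_points(self, pts: np.ndarray, pts_spacing_mm: tuple[float, float]) -> np.ndarray:
        """Warp (N, 2) points given in pixels of a grid with ``pts_spacing_mm``."""
        pts = np.asarray(pts, dtype=float)
        scale = np.array([pts_spacing_mm[0] / self.spacing_mm[0],
                          pts_spacing_mm[1] / self.spacing_mm[1]])
        own = pts * scale  # same world frame, different pixel size
        dr = ndimage.map_coordinates(self.disp[0], own.T, order=1, mode="nearest")
        dc = ndimage.map_coordinates(self.disp[1], own.T, order=1, mode="nearest")
        d_own = np.stack([dr, dc], axis=1)
        return pts + d_own / scale


@dataclass
class Deformation3D:
    """Dense 3D displacement field in voxels of its own grid (shape (3, X, Y, Z))."""

    disp: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.disp = np.asarray(self.disp, dtype=float)
        if self.disp.ndim != 4 or self.disp.shape[0] != 3:
            raise ValueError("Deformation3D.disp must have shape (3, X, Y, Z)")
        if not np.all(np.isfinite(self.disp)):
            raise ValueError("displacement field must be finite")


@dataclass
class TransformChain:
    """Best available transform for one section.

    Application order (fixed): rigid first, then each 2D refinement in
    schedule order. ``map_points`` composes them in the resampling
    direction: reconstruction-space pixel -> section pixel.
    """

    rigid: Rigid2D = field(default_factory=Rigid2D)
    deforms: list[Deformation2D] = field(default_factory=list)

    def map_points(self, pts: np.ndarray, pts_spacing_mm: tuple[float, float]) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        # refinements were estimated last-first in the output frame
        for d in reversed(self.deforms):
            pts = d.map_points(pts, pts_spacing_mm)
        return self.rigid.map_points(pts)


@dataclass
class ResolutionSchedule:
    """Strictly decreasing multi-resolution hierarchy; last entry = output."""

    resolutions_mm: list[float]

    def __post_init__(self) -> None:
        r = self.resolutions_mm
        if not r or any(x <= 0 for x in r):
            raise ValueError("resolutions must be positive")
        if any(b >= a for a, b in zip(r, r[1:])):
            raise ValueError("resolution schedule must be strictly decreasing")

    def __iter__(self):
        return iter(self.resolutions_mm)

    @property
    def final(self) -> float:
        return self.resolutions_mm[-1]


@dataclass
class SlabBounds:
    """Anterior/posterior world extent of one slab along the cutting axis."""

    slab_id: int
    anterior_mm: float
    posterior_mm: float

    def __post_init__(self) -> None:
        if not self.anterior_mm > self.posterior_mm:
            raise ValueError("anterior_mm must exceed posterior_mm (non-empty interval)")


# ---------------------------------------------------------------------------
# Transform application and resampling
# ---------------------------------------------------------------------------

def apply_transform_2d(
    img: Image2D | np.ndarray,
    transform: Rigid2D | TransformChain | Deformation2D,
    out_shape: tuple[int, int] | None = None,
    mode: str = "linear",
    spacing_mm: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Resample a 2D image through a transform onto an output grid.

    The transform maps output pixels to input pixels; out-of-domain pixels
    receive the background value 0.
    """
    arr = img.values if isinstance(img, Image2D) else np.asarray(img, dtype=float)
    if out_shape is None:
        out_shape = arr.shape
    rr, cc = np.meshgrid(np.arange(out_shape[0]), np.arange(out_shape[1]), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    if isinstance(transform, Rigid2D):
        src = transform.map_points(pts)
    elif isinstance(transform, TransformChain):
        src = transform.map_points(pts, spacing_mm)
    elif isinstance(transform, Deformation2D):
        src = transform.map_points(pts, spacing_mm)
    else:
        raise TypeError(f"unsupported transform type {type(transform)!r}")
    order = 0 if mode == "nearest" else 1
    out = ndimage.map_coordinates(arr, src.T, order=order, mode="constant", cval=BACKGROUND)
    return out.reshape(out_shape)


def _block_reduce_mean(arr: np.ndarray, factors: tuple[int, ...]) -> np.ndarray:
    sl = tuple(slice(0, (s // f) * f) for s, f in zip(arr.shape, factors))
    arr = arr[sl]
    shape = []
    for s, f in zip(arr.shape, factors):
        shape.extend([s // f, f])
    return arr.reshape(shape).mean(axis=tuple(range(1, 2 * arr.ndim, 2)))


def resample_volume(v: Volume3D, res_mm: float, mode: str = "linear") -> Volume3D:
    """Resample a volume to an isotropic grid of spacing ``res_mm``.

    Integer downsampling factors use exact block averaging (alias-free and
    mean-preserving); other ratios use tri-linear (or nearest) sampling at
    the new voxel centers, which are placed edge-aligned with the input.
    """
    if res_mm <= 0:
        raise ValueError("res_mm must be positive")
    sp = v.spacing_mm
    factors = [res_mm / s for s in sp]
    if mode == "linear" and all(abs(f - round(f)) < 1e-9 and round(f) >= 1 for f in factors):
        ifac = tuple(int(round(f)) for f in factors)
        if ifac == (1, 1, 1):
            return Volume3D(v.values.copy(), spacing_mm=(res_mm,) * 3, origin=v.origin,
                            axis_map=v.axis_map)
        out = _block_reduce_mean(v.values, ifac)
        origin = tuple(o + (res_mm - s) / 2 for o, s in zip(v.origin, sp))
        return Volume3D(out, spacing_mm=(res_mm,) * 3, origin=origin, axis_map=v.axis_map)
    new_shape = tuple(max(1, int(np.floor(s * spc / res_mm))) for s, spc in zip(v.shape, sp))
    # centers of output voxels in input index coordinates (edge-aligned grids)
    coords = np.meshgrid(
        *[((np.arange(n) + 0.5) * res_mm - 0.5 * spc) / spc for n, spc in zip(new_shape, sp)],
        indexing="ij",
    )
    order = 0 if mode == "nearest" else 1
    # clamp at the physical boundary: output centers stay inside the input
    # extent, so edge handling is clamping, not background fill
    out = ndimage.map_coordinates(
        v.values, np.stack([c.ravel() for c in coords]), order=order,
        mode="nearest",
    ).reshape(new_shape)
    origin = tuple(o + (res_mm - s) / 2 for o, s in zip(v.origin, sp))
    return Volume3D(out, spacing_mm=(res_mm,) * 3, origin=origin, axis_map=v.axis_map)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def load_section_image(path: str | Path, pixel_size_um: float = 1000.0) -> Image2D:
    """Load a section image (8/16-bit PNG/TIFF, or 2D NIfTI) as float values."""
    path = Path(path)
    if path.suffix in (".nii", ".gz") or str(path).endswith(".nii.gz"):
        im = nib.load(str(path))
        arr = np.squeeze(np.asarray(im.dataobj, dtype=float))
        zooms = im.header.get_zooms()[:2]
        return Image2D(arr, spacing_um=(zooms[0] * 1000, zooms[1] * 1000))
    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:  # RGB(A) -> luminance
        arr = arr[..., :3].mean(axis=-1)
    return Image2D(arr, spacing_um=(pixel_size_um, pixel_size_um))


def save_section_image(img: Image2D | np.ndarray, path: str | Path) -> None:
    arr = img.values if isinstance(img, Image2D) else np.asarray(img)
    iio.imwrite(Path(path), np.clip(arr, 0, 255).astype(np.uint8))


def volume_to_nifti(v: Volume3D) -> nib.Nifti1Image:
    aff = np.diag(list(v.spacing_mm) + [1.0])
    aff[:3, 3] = v.origin
    return nib.Nifti1Image(v.values.astype(np.float32), aff)


def save_volume(v: Volume3D, path: str | Path) -> None:
    nib.save(volume_to_nifti(v), str(path))


def load_volume(path: str | Path) -> Volume3D:
    im = nib.load(str(path))
    aff = im.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
    return Volume3D(np.asarray(im.dataobj, dtype=float), spacing_mm=spacing,
                    origin=tuple(float(x) for x in aff[:3, 3]))


def save_rigid(rigid: Rigid2D, path: str | Path) -> None:
    """Persist a rigid transform as an inspectable JSON sidecar."""
    Path(path).write_text(json.dumps({
        "rotation_deg": rigid.rotation_deg,
        "translation": list(rigid.translation),
        "center": list(rigid.center),
        "unit": rigid.unit,
    }, indent=2))


def load_rigid(path: str | Path) -> Rigid2D:
    d = json.loads(Path(path).read_text())
    return Rigid2D(rotation_deg=d["rotation_deg"], translation=tuple(d["translation"]),
                   center=tuple(d["center"]), unit=d.get("unit", "px"))


def save_deformation(d: Deformation2D | Deformation3D, path: str | Path) -> None:
    """Displacement fields go to NIfTI vector images (components on last axis)."""
    arr = np.moveaxis(d.disp, 0, -1).astype(np.float32)
    sp = list(d.spacing_mm) + [1.0] * (4 - len(d.spacing_mm))
    nib.save(nib.Nifti1Image(arr, np.diag(sp[:3] + [1.0])), str(path))


__all__ = [
    "BACKGROUND", "CUT_AXIS", "MANIFEST_COLUMNS",
    "SchemaError", "IntegrityError", "GridMismatchError",
    "SectionRecord", "SectionStack", "Image2D", "Volume3D", "GMMask",
    "Rigid2D", "Deformation2D", "Deformation3D", "TransformChain",
    "ResolutionSchedule", "SlabBounds",
    "dice", "apply_transform_2d", "resample_volume",
    "load_manifest", "save_manifest", "load_section_image", "save_section_image",
    "save_volume", "load_volume", "volume_to_nifti",
    "save_rigid", "load_rigid", "save_deformation",
]
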