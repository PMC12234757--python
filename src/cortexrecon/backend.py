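"""Registration backend: rigid/deformable 2D and affine/deformable 3D.

The rest of the package talks to registration through the small functions
here (image pairs in, transform objects out), so the backend is swappable.
This implementation uses SimpleITK: multi-resolution Mattes mutual
information with gradient-descent refinement for the rigid stage, and
symmetric-forces demons for the deformable stages. All metrics use dense
sampling, so results are deterministic for fixed inputs.

Conventions: 2D physical coordinates are (row*spacing, col*spacing); 3D
physical coordinates equal the package's world mm frame. All returned
transforms are in the resampling direction (fixed/output -> moving/input).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .core import Deformation2D, Deformation3D, Rigid2D, Volume3D, dice


def _sitk2d(arr: np.ndarray, spacing_mm: tuple[float, float]) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.T, dtype=np.float64))
    img.SetSpacing((float(spacing_mm[0]), float(spacing_mm[1])))
    return img


def _sitk3d(v: Volume3D) -> sitk.Image:
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(v.values.transpose(2, 1, 0), dtype=np.float64))
    img.SetSpacing(tuple(float(s) for s in v.spacing_mm))
    img.SetOrigin(tuple(float(o) for o in v.origin))
    return img


def _rigid_from_sitk_2d(t: sitk.Transform, spacing_mm: tuple[float, float]) -> Rigid2D:
    """Convert a physical-space 2D transform to pixel (row, col) form by probing."""
    sr, sc = spacing_mm

    def px(p_rc):
        q = t.TransformPoint((p_rc[0] * sr, p_rc[1] * sc))
        return np.array([q[0] / sr, q[1] / sc])

    o = px((0.0, 0.0))
    er = px((1.0, 0.0)) - o
    ec = px((0.0, 1.0)) - o
    m = np.stack([er, ec], axis=1)
    ang = np.rad2deg(np.arctan2(m[1, 0], m[0, 0]))
    return Rigid2D(rotation_deg=float(ang), translation=(float(o[0]), float(o[1])),
                   center=(0.0, 0.0))


def _similarity_after(moving: np.ndarray, fixed: np.ndarray, rigid: Rigid2D) -> float:
    """Negative mean-squared error of moving resampled through rigid vs fixed."""
    rr, cc = np.meshgrid(np.arange(fixed.shape[0]), np.arange(fixed.shape[1]),
                         indexing="ij")
    pts = rigid.map_points(np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float))
    res = ndimage.map_coordinates(moving, pts.T, order=1, mode="constant",
                                  cval=0.0).reshape(fixed.shape)
    return -float(np.mean((res - fixed) ** 2))


def register_rigid_2d(
    moving: np.ndarray,
    fixed: np.ndarray,
    spacing_mm: tuple[float, float] = (1.0, 1.0),
    metric: str = "mattes",
) -> Rigid2D:
    """Recover the rigid transform aligning ``moving`` onto ``fixed``.

    Multi-resolution (shrink 4/2/1) with a moments initializer and a final
    full-resolution gradient refinement. On optimizer failure, or if the
    result fits worse than the identity, the identity is returned with a
    warning flag set.
    """
    f = _sitk2d(np.asarray(fixed, dtype=float), spacing_mm)
    m = _sitk2d(np.asarray(moving, dtype=float), spacing_mm)
    try:
        init = sitk.CenteredTransformInitializer(
            f, m, sitk.Euler2DTransform(),
            sitk.CenteredTransformInitializerFilter.MOMENTS)
        reg = sitk.ImageRegistrationMethod()
        if metric == "mattes":
            reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
        elif metric == "correlation":
            reg.SetMetricAsCorrelation()
        else:
            reg.SetMetricAsMeanSquares()
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=1.0, minStep=1e-5, numberOfIterations=300,
            gradientMagnitudeTolerance=1e-7)
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel([4, 2, 1])
        reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
        reg.SetSmoothingSigmasAreSpecifiedInPhysicalUnits(False)
        reg.SetInitialTransform(init, inPlace=False)
        out = reg.Execute(f, m)
        # final refinement at full resolution with a finer step
        reg2 = sitk.ImageRegistrationMethod()
        reg2.SetMetricAsMeanSquares()
        reg2.SetInterpolator(sitk.sitkLinear)
        reg2.SetOptimizerAsRegularStepGradientDescent(
            learningRate=0.2, minStep=1e-6, numberOfIterations=100,
            gradientMagnitudeTolerance=1e-8)
        reg2.SetOptimizerScalesFromPhysicalShift()
        reg2.SetInitialTransform(out, inPlace=False)
        out = reg2.Execute(f, m)
        rigid = _rigid_from_sitk_2d(out, spacing_mm)
    except RuntimeError:
        r = Rigid2D()
        r.warning = "optimizer failure; identity returned"
        return r
    mov = np.asarray(moving, dtype=float)
    fix = np.asarray(fixed, dtype=float)
    if _similarity_after(mov, fix, rigid) < _similarity_after(mov, fix, Rigid2D()):
        r = Rigid2D()
        r.warning = "registration fit worse than identity; identity returned"
        return r
    return rigid


def register_deformable_2d(
    moving: np.ndarray,
    fixed: np.ndarray,
    spacing_mm: tuple[float, float] = (1.0, 1.0),
    iterations: int = 60,
    smoothing_sigma_px: float = 1.5,
    presmooth_px: float = 1.0,
) -> Deformation2D:
    """Demons deformable registration of ``moving`` onto ``fixed``.

    Inputs are lightly Gaussian-blurred first (binary masks have no usable
    gradients otherwise). If the warp does not improve the binary overlap,
    a zero field is returned.
    """
    mov = np.asarray(moving, dtype=float)
    fix = np.asarray(fixed, dtype=float)
    fb = ndimage.gaussian_filter(fix, presmooth_px)
    mb = ndimage.gaussian_filter(mov, presmooth_px)
    f = _sitk2d(fb, spacing_mm)
    m = _sitk2d(mb, spacing_mm)
    dem = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    dem.SetNumberOfIterations(int(iterations))
    dem.SetStandardDeviations(smoothing_sigma_px * float(np.mean(spacing_mm)))
    field = dem.Execute(f, m)
    arr = sitk.GetArrayFromImage(field)  # (cols, rows, 2), components (vr*sp, vc*sp)
    dr = arr[..., 0].T / spacing_mm[0]
    dc = arr[..., 1].T / spacing_mm[1]
    deform = Deformation2D(np.stack([dr, dc]), spacing_mm=spacing_mm)

    before = dice(mov > 0.5, fix > 0.5)
    rr, cc = np.meshgrid(np.arange(fix.shape[0]), np.arange(fix.shape[1]), indexing="ij")
    pts = deform.map_points(np.stack([rr.ravel(), cc.ravel()], 1).astype(float), spacing_mm)
    warped = ndimage.map_coordinates(mov, pts.T, order=1, mode="constant",
                                     cval=0.0).reshape(fix.shape)
    after = dice(warped > 0.5, fix > 0.5)
    if after < before:
        return Deformation2D(np.zeros_like(deform.disp), spacing_mm=spacing_mm)
    return deform


@dataclass
class Transform3D:
    """3D map reconstruction-space -> reference-space (world mm): x -> A(x + d(x)).

    ``deform``/``deform_inv`` live on the reconstruction grid; the inverse
    map (reference -> reconstruction, used to carry surface vertices into
    slab space) is x -> phi_inv(A^-1 x) with phi_inv(y) = y + d_inv(y).
    """

    affine: np.ndarray
    deform: Deformation3D | None = None
    deform_inv: Deformation3D | None = None

    def _interp_disp(self, d: Deformation3D, pts: np.ndarray) -> np.ndarray:
        idx = (pts - np.asarray(d.origin)) / np.asarray(d.spacing_mm)
        out = np.empty_like(pts)
        for i in range(3):
            out[:, i] = ndimage.map_coordinates(d.disp[i], idx.T, order=1,
                                                mode="nearest")
        return out

    def map_points(self, pts_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        if self.deform is not None:
            pts = pts + self._interp_disp(self.deform, pts)
        return pts @ self.affine[:3, :3].T + self.affine[:3, 3]

    def inverse_map_points(self, pts_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        ainv = np.linalg.inv(self.affine)
        pts = pts @ ainv[:3, :3].T + ainv[:3, 3]
        if self.deform_inv is not None:
            pts = pts + self._interp_disp(self.deform_inv, pts)
        return pts


def resample_volume_through(moving: Volume3D, t: Transform3D, like: Volume3D,
                            mode: str = "linear") -> Volume3D:
    """Resample ``moving`` through ``t`` onto the grid of ``like``."""
    grids = np.meshgrid(*[np.arange(n) for n in like.shape], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    pts = pts * np.asarray(like.spacing_mm) + np.asarray(like.origin)
    src = t.map_points(pts)
    idx = (src - np.asarray(moving.origin)) / np.asarray(moving.spacing_mm)
    order = 0 if mode == "nearest" else 1
    out = ndimage.map_coordinates(moving.values, idx.T, order=order,
                                  mode="constant", cval=0.0).reshape(like.shape)
    return Volume3D(out, spacing_mm=tuple(like.spacing_mm), origin=tuple(like.origin),
                    axis_map=like.axis_map)


def _affine_from_sitk_3d(t: sitk.Transform) -> np.ndarray:
    o = np.array(t.TransformPoint((0.0, 0.0, 0.0)))
    m = np.eye(4)
    for i in range(3):
        e = [0.0, 0.0, 0.0]
        e[i] = 1.0
        m[:3, i] = np.array(t.TransformPoint(tuple(e))) - o
    m[:3, 3] = o
    return m


def register_affine_3d(moving: Volume3D, fixed: Volume3D,
                       rigid_only: bool = False) -> np.ndarray:
    """Affine (rigid-initialized) world-space registration; returns a 4x4
    matrix mapping fixed world coords to moving world coords."""
    f = _sitk3d(fixed)
    m = _sitk3d(moving)

    def run(init, levels=(4, 2, 1), lr=1.0):
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsCorrelation()
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=lr, minStep=1e-5, numberOfIterations=200,
            gradientMagnitudeTolerance=1e-7)
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel(list(levels))
        reg.SetSmoothingSigmasPerLevel([lv / 2 for lv in levels])
        reg.SetSmoothingSigmasAreSpecifiedInPhysicalUnits(False)
        reg.SetInitialTransform(init, inPlace=False)
        return reg.Execute(f, m)

    try:
        init = sitk.CenteredTransformInitializer(
            f, m, sitk.Euler3DTransform(),
            sitk.CenteredTransformInitializerFilter.MOMENTS)
        rigid = run(init)
        arig = _affine_from_sitk_3d(rigid)
        if rigid_only:
            return arig
        aff = sitk.AffineTransform(3)
        aff.SetMatrix(tuple(arig[:3, :3].ravel()))
        aff.SetTranslation(tuple(arig[:3, 3]))
        final = run(aff, levels=(2, 1), lr=0.3)
        return _affine_from_sitk_3d(final)
    except RuntimeError:
        return np.eye(4)


def register_deformable_3d(moving: Volume3D, fixed: Volume3D,
                           iterations: int = 40,
                           smoothing_sigma_mm: float | None = None
                           ) -> tuple[Deformation3D, Deformation3D]:
    """Demons registration of ``moving`` onto ``fixed`` (shared world frame).

    Returns the displacement field (mm, on the fixed grid) and its numeric
    inverse.
    """
    if smoothing_sigma_mm is None:
        smoothing_sigma_mm = 1.5 * float(np.mean(fixed.spacing_mm))
    f = _sitk3d(fixed)
    m = _sitk3d(moving)
    dem = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    dem.SetNumberOfIterations(int(iterations))
    dem.SetStandardDeviations(float(smoothing_sigma_mm))
    field = dem.Execute(f, m)
    inv = sitk.InvertDisplacementField(
        field, maximumNumberOfIterations=30,
        meanErrorToleranceThreshold=0.001, maxErrorToleranceThreshold=0.1,
        enforceBoundaryCondition=True)

    def to_def(img) -> Deformation3D:
        arr = sitk.GetArrayFromImage(img)          # (nz, ny, nx, 3), comps (x,y,z)
        arr = arr.transpose(2, 1, 0, 3)            # (nx, ny, nz, 3)
        return Deformation3D(np.moveaxis(arr, -1, 0),
                             spacing_mm=tuple(fixed.spacing_mm),
                             origin=tuple(fixed.origin))

    return to_def(field), to_def(inv)


__all__ = [
    "register_rigid_2d", "register_deformable_2d",
    "register_affine_3d", "register_deformable_3d",
    "Transform3D", "resample_volume_through",
]
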