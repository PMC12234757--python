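"""Shared fixtures: small phantoms for unit tests and the full-size
reconstruction runs shared by the acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from cortexrecon import phantom as ph
from cortexrecon.core import Volume3D, resample_volume
from cortexrecon.pipeline import PipelineConfig, ReconInput, run_reconstruction


def reference_from(p: ph.Phantom, res_mm: float = 1.0) -> Volume3D:
    """Binary reference GM volume derived from the phantom truth labels."""
    gm = Volume3D(p.gm_mask(), spacing_mm=p.truth_volume.spacing_mm,
                  origin=p.truth_volume.origin)
    r = resample_volume(gm, res_mm)
    return Volume3D((r.values > 0.5).astype(float), spacing_mm=r.spacing_mm,
                    origin=r.origin, axis_map=r.axis_map)


SMALL_SHAPE = dict(base_radius_mm=10.0, fold_amplitude_mm=1.5, thickness_mm=4.0,
                   volume_shape=(32, 64, 32), spacing_mm=(1.0, 0.5, 1.0),
                   mesh_subdivisions=3)


@pytest.fixture(scope="session")
def small_phantom():
    p = ph.make_phantom(ph.PhantomShape(**SMALL_SHAPE), seed=7)
    ph.synthesize_truth_fields(p, ("acq0", "acq1"), seed=7)
    return p


@pytest.fixture(scope="session")
def small_stack(small_phantom):
    scheme = ph.SamplingScheme(coverage_fraction=0.5, acquisitions=("acq0", "acq1"),
                               n_slabs=1, slab_affine_jitter=(0.0, 0.0))
    stack, chains = ph.slice_sections(small_phantom, scheme, seed=11)
    return stack, chains


def _default_phantom_run(seed: int):
    """The study's standard end-to-end conditions: 64^3 1 mm reference,
    4 interleaved acquisitions, 30% coverage, 2 slabs, default jitter,
    schedule 4 -> 2 -> 1 mm."""
    p = ph.make_phantom(seed=seed)
    ph.synthesize_truth_fields(p, ("acq0", "acq1", "acq2", "acq3"), seed=seed)
    stack, truth_chains = ph.slice_sections(p, ph.SamplingScheme(), seed=seed)
    inp = ReconInput(stack=stack, images=p.sections, ref_gm=reference_from(p),
                     wm_mesh=p.wm_mesh, pial_mesh=p.pial_mesh,
                     bounds=p.slab_bounds)
    cfg = PipelineConfig(schedule=[4.0, 2.0, 1.0], seed=seed)
    result = run_reconstruction(inp, cfg)
    return p, stack, truth_chains, result


@pytest.fixture(scope="session")
def phantom_run():
    """Full phantom reconstruction under the default study conditions."""
    return _default_phantom_run(seed=0)


@pytest.fixture(scope="session")
def identity_run():
    """Zero-perturbation, full-coverage phantom with ground-truth masks:
    the reconstruction should be the identity up to rasterization."""
    shape = ph.PhantomShape(volume_shape=(64, 64, 64), spacing_mm=(1.0, 1.0, 1.0))
    p = ph.make_phantom(shape, seed=0)
    ph.synthesize_truth_fields(p, ("acq0", "acq1", "acq2", "acq3"), seed=0)
    scheme = ph.SamplingScheme(coverage_fraction=1.0, n_slabs=1,
                               rigid_jitter=(0.0, 0.0), warp_amplitude_px=0.0,
                               slab_affine_jitter=(0.0, 0.0))
    stack, _ = ph.slice_sections(p, scheme, seed=1)
    inp = ReconInput(stack=stack, images=p.sections, ref_gm=reference_from(p),
                     wm_mesh=p.wm_mesh, pial_mesh=p.pial_mesh,
                     bounds=p.slab_bounds)
    cfg = PipelineConfig(schedule=[4.0, 2.0, 1.0], seed=0)
    result = run_reconstruction(inp, cfg, precomputed_masks=p.truth_masks)
    return p, stack, result
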