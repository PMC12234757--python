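"""Depth surfaces, mesh upsampling, sphere inflation, spherical
interpolation, vertex sampling and surface-to-volume projection."""

import numpy as np
import pytest
import trimesh

from cortexrecon import phantom as ph
from cortexrecon.core import Volume3D
from cortexrecon.surface import (
    DepthSurfaceSet, SurfaceMesh, VertexField, apply_upsample,
    generate_depth_surfaces, inflate_to_sphere, interpolate_sphere,
    project_to_volume, sample_sections_to_vertices, upsample_mesh,
    upsample_pattern, validate_external_sphere, vertex_voxel_coverage,
)


def icomesh(subdiv=2, radius=1.0):
    m = trimesh.creation.icosphere(subdivisions=subdiv, radius=radius)
    return SurfaceMesh(np.array(m.vertices), np.array(m.faces))


class TestDepthSurfaces:
    def test_endpoints_equal_wm_and_pial(self, small_phantom):
        d = generate_depth_surfaces(small_phantom.wm_mesh,
                                    small_phantom.pial_mesh, 3)
        assert np.allclose(d.meshes[0].vertices, small_phantom.wm_mesh.vertices)
        assert np.allclose(d.meshes[-1].vertices, small_phantom.pial_mesh.vertices)

    def test_single_intermediate_is_midpoint(self, small_phantom):
        d = generate_depth_surfaces(small_phantom.wm_mesh,
                                    small_phantom.pial_mesh, 1)
        mid = 0.5 * (small_phantom.wm_mesh.vertices
                     + small_phantom.pial_mesh.vertices)
        assert np.allclose(d.meshes[1].vertices, mid)

    def test_eighteen_intermediates_give_twenty_meshes(self, small_phantom):
        d = generate_depth_surfaces(small_phantom.wm_mesh,
                                    small_phantom.pial_mesh, 18)
        assert len(d) == 20

    def test_topology_mismatch_rejected(self):
        a = icomesh(1)
        b = icomesh(2)
        with pytest.raises(ValueError):
            generate_depth_surfaces(a, b, 1)


class TestUpsampleMesh:
    def test_small_triangle_unchanged(self):
        r = 1.0
        tri = SurfaceMesh(0.4 * r * np.array([[0, 0, 0], [1, 0, 0],
                                              [0.5, np.sqrt(3) / 2, 0]]),
                          np.array([[0, 1, 2]]))
        up = upsample_mesh(tri, r)
        assert up.n_vertices == 3 and len(up.triangles) == 1

    def test_unit_edge_triangle_gives_six_points_four_triangles(self):
        r = 1.0
        tri = SurfaceMesh(r * np.array([[0, 0, 0], [1, 0, 0],
                                        [0.5, np.sqrt(3) / 2, 0]]),
                          np.array([[0, 1, 2]]))
        up = upsample_mesh(tri, r)
        assert up.n_vertices == 6
        assert len(up.triangles) == 4
        # alpha, beta in {0, 0.5, 1}: 3 corners + 3 edge midpoints
        mids = {(0.5, 0, 0), (0.25, np.sqrt(3) / 4, 0), (0.75, np.sqrt(3) / 4, 0)}
        got = {tuple(np.round(v, 6)) for v in up.vertices}
        for m in mids:
            assert tuple(np.round(m, 6)) in got

    @pytest.mark.parametrize("seed", range(10))
    def test_random_mesh_properties(self, seed):
        """Max neighbor distance <= r, originals preserved, and every
        inserted point lies inside its source triangle (barycentric oracle)."""
        rng = np.random.default_rng(seed)
        mesh = icomesh(1, radius=rng.uniform(2, 8))
        jitter = rng.normal(0, 0.1, size=mesh.vertices.shape)
        mesh = SurfaceMesh(mesh.vertices + jitter, mesh.triangles)
        r = rng.uniform(0.5, 2.0)
        pat = upsample_pattern([mesh], r)
        up = apply_upsample(mesh, pat)
        assert up.edge_lengths().max() <= r + 1e-9
        assert np.allclose(up.vertices[:mesh.n_vertices], mesh.vertices)
        for idx, d in enumerate(pat.vertex_defs):
            if d[0] != "pt":
                continue
            _, t, i, j, n = d
            a, b, c = mesh.triangles[t]
            p = up.vertices[idx]
            # barycentric coordinates wrt the source triangle
            m = np.stack([mesh.vertices[b] - mesh.vertices[a],
                          mesh.vertices[c] - mesh.vertices[a]], axis=1)
            coef, *_ = np.linalg.lstsq(m, p - mesh.vertices[a], rcond=None)
            al, be = coef
            assert -1e-9 <= al <= 1 + 1e-9
            assert -1e-9 <= be <= 1 + 1e-9
            assert al + be <= 1 + 1e-9

    def test_shared_pattern_gives_identical_topology(self, small_phantom):
        pat = upsample_pattern([small_phantom.wm_mesh, small_phantom.pial_mesh],
                               1.0)
        a = apply_upsample(small_phantom.wm_mesh, pat)
        b = apply_upsample(small_phantom.pial_mesh, pat)
        assert a.n_vertices == b.n_vertices
        assert np.array_equal(a.triangles, b.triangles)

    def test_nonpositive_resolution_rejected(self):
        with pytest.raises(ValueError):
            upsample_mesh(icomesh(1), 0.0)


class TestInflate:
    def test_spherical_mesh_is_identity_up_to_normalization(self):
        m = icomesh(2, radius=7.0)
        s = inflate_to_sphere(m, center=np.zeros(3))
        assert np.allclose(s.vertices, m.vertices / 7.0, atol=1e-12)

    def test_phantom_mid_surface_inflates_without_flips(self, small_phantom):
        d = generate_depth_surfaces(small_phantom.wm_mesh,
                                    small_phantom.pial_mesh, 1)
        s = inflate_to_sphere(d.meshes[1], center=small_phantom.center_mm)
        u = s.vertices
        tri = s.triangles
        det = np.einsum("ij,ij->i", u[tri[:, 0]],
                        np.cross(u[tri[:, 1]], u[tri[:, 2]]))
        assert (det > 0).all() or (det < 0).all()
        assert "distortion" in s.meta

    def test_external_sphere_validated_and_normalized(self):
        m = icomesh(1, radius=3.0)
        sphere = SurfaceMesh(m.vertices * 2, m.triangles)
        out = validate_external_sphere(m, sphere)
        assert np.allclose(np.linalg.norm(out.vertices, axis=1), 1.0)
        with pytest.raises(ValueError):
            validate_external_sphere(icomesh(2), sphere)

    def test_non_star_shaped_rejected(self):
        m = icomesh(2, radius=1.0)
        v = m.vertices.copy()
        v[0] *= -0.5  # pull one vertex through the center
        with pytest.raises(ValueError, match="star-shaped"):
            inflate_to_sphere(SurfaceMesh(v, m.triangles), center=np.zeros(3))


class TestInterpolateSphere:
    @pytest.fixture(scope="class")
    def sphere(self):
        m = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        return SurfaceMesh(np.array(m.vertices), np.array(m.faces),
                           space_tag="sphere")

    def test_constant_known_field_fills_constant(self, sphere):
        rng = np.random.default_rng(0)
        known = rng.random(sphere.n_vertices) < 0.1
        fld = VertexField(np.where(known, 4.2, 0.0), known)
        out = interpolate_sphere(sphere, fld)
        assert np.allclose(out.values, 4.2)

    def test_known_vertices_unchanged(self, sphere):
        rng = np.random.default_rng(1)
        known = rng.random(sphere.n_vertices) < 0.2
        vals = np.where(known, rng.random(sphere.n_vertices), 0.0)
        out = interpolate_sphere(sphere, VertexField(vals, known))
        assert np.array_equal(out.values[known], vals[known])

    def test_linear_ambient_field_recovered(self, sphere):
        rng = np.random.default_rng(2)
        a = np.array([0.3, -0.7, 0.5])
        f = sphere.vertices @ a
        known = np.zeros(sphere.n_vertices, bool)
        known[rng.choice(sphere.n_vertices, 200, replace=False)] = True
        out = interpolate_sphere(sphere, VertexField(np.where(known, f, 0), known))
        miss = ~known
        r2 = np.corrcoef(out.values[miss], f[miss])[0, 1] ** 2
        assert r2 >= 0.99
        assert out.values.min() >= f[known].min() - 1e-12
        assert out.values.max() <= f[known].max() + 1e-12

    def test_too_few_known_rejected(self, sphere):
        known = np.zeros(sphere.n_vertices, bool)
        known[:2] = True
        with pytest.raises(ValueError):
            interpolate_sphere(sphere, VertexField(np.zeros(sphere.n_vertices),
                                                   known))


class TestSampling:
    @pytest.fixture(scope="class")
    def setup(self, small_phantom):
        scheme = ph.SamplingScheme(coverage_fraction=0.5,
                                   acquisitions=("acq0",), n_slabs=1,
                                   rigid_jitter=(0.0, 0.0),
                                   warp_amplitude_px=0.0,
                                   slab_affine_jitter=(0.0, 0.0), noise_sd=0.0)
        stack, chains = ph.slice_sections(small_phantom, scheme, seed=21)
        depth = generate_depth_surfaces(small_phantom.wm_mesh,
                                        small_phantom.pial_mesh, 4)
        pat = upsample_pattern([small_phantom.wm_mesh,
                                small_phantom.pial_mesh], 1.0)
        up = DepthSurfaceSet([apply_upsample(m, pat) for m in depth.meshes],
                             depth.depths)
        return stack, chains, up

    def test_sampling_is_idempotent(self, small_phantom, setup):
        stack, chains, up = setup
        a = sample_sections_to_vertices(stack, chains, up, "acq0",
                                        small_phantom.sections, 1.0)
        b = sample_sections_to_vertices(stack, chains, up, "acq0",
                                        small_phantom.sections, 1.0)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.values, fb.values)
            assert np.array_equal(fa.known_mask, fb.known_mask)

    def test_vertex_on_constant_plane_reads_constant(self, small_phantom, setup):
        stack, chains, up = setup
        key = (1, stack.records[0].sample_index)
        const_img = np.where(np.asarray(small_phantom.sections[key]) > 0,
                             123.0, 0.0)
        images = dict(small_phantom.sections)
        images[key] = const_img
        fields = sample_sections_to_vertices(stack, chains, up, "acq0",
                                             images, 1.0)
        plane_y = key[1] * 0.5
        hit = False
        for mesh, fld in zip(up.meshes, fields):
            sel = (np.abs(mesh.vertices[:, 1] - plane_y) <= 0.25) & fld.known_mask
            if sel.any():
                assert np.all(fld.values[sel] == 123.0)
                hit = True
        assert hit

    def test_vertices_far_from_planes_stay_missing(self, small_phantom, setup):
        stack, chains, up = setup
        fields = sample_sections_to_vertices(stack, chains, up, "acq0",
                                             small_phantom.sections, 1.0)
        planes = np.array([r.sample_index * 0.5 for r in stack.records
                           if r.acquisition == "acq0"])
        for mesh, fld in zip(up.meshes, fields):
            d = np.abs(mesh.vertices[:, 1][:, None] - planes[None, :]).min(axis=1)
            far = d > 0.25 + 1e-9
            assert not fld.known_mask[far].any()

    def test_sampled_values_match_truth_field(self, small_phantom, setup):
        """Forward-model check: noiseless sampled vertex values equal the
        analytic truth intensity at the vertex (within partial-volume slack)."""
        stack, chains, up = setup
        fields = sample_sections_to_vertices(stack, chains, up, "acq0",
                                             small_phantom.sections, 1.0)
        errs = []
        for mesh, fld in zip(up.meshes[1:-1], fields[1:-1]):
            sel = fld.known_mask
            if not sel.any():
                continue
            tv = small_phantom.truth_intensity_at("acq0", mesh.vertices[sel])
            errs.append(np.abs(fld.values[sel] - tv).mean())
        # nearest-pixel reads within a couple of gray levels of the truth
        assert np.mean(errs) <= 8.0

    def test_absent_acquisition_yields_all_missing(self, small_phantom, setup):
        stack, chains, up = setup
        fields = sample_sections_to_vertices(stack, chains, up, "ghost",
                                             small_phantom.sections, 1.0)
        assert all(not f.known_mask.any() for f in fields)


class TestProjection:
    @pytest.fixture(scope="class")
    def grid(self, small_phantom):
        from cortexrecon.multires import rasterize_surfaces_to_gm
        cortex = rasterize_surfaces_to_gm(small_phantom.wm_mesh,
                                          small_phantom.pial_mesh, 1.0)
        return cortex

    def _upsampled(self, small_phantom, n_int=6):
        depth = generate_depth_surfaces(small_phantom.wm_mesh,
                                        small_phantom.pial_mesh, n_int)
        pat = upsample_pattern([small_phantom.wm_mesh,
                                small_phantom.pial_mesh], 1.0)
        return DepthSurfaceSet([apply_upsample(m, pat) for m in depth.meshes],
                               depth.depths)

    def test_constant_field_projects_exactly(self, small_phantom, grid):
        up = self._upsampled(small_phantom)
        fields = [VertexField(np.full(m.n_vertices, 7.5),
                              np.ones(m.n_vertices, bool)) for m in up.meshes]
        vol = project_to_volume(fields, up, grid, grid.values > 0.5)
        cortex = grid.values > 0.5
        assert np.allclose(vol.values[cortex], 7.5)
        assert np.all(vol.values[~cortex] == 0)

    def test_voxel_mean_of_two_vertices(self):
        mesh = SurfaceMesh(np.array([[1.1, 1.2, 1.3], [0.9, 0.8, 1.2],
                                     [5.0, 5.0, 5.0]]),
                           np.array([[0, 1, 2]]))
        dss = DepthSurfaceSet([mesh], np.array([0.5]))
        grid = Volume3D(np.zeros((8, 8, 8)))
        cortex = np.ones((8, 8, 8), bool)
        fld = VertexField(np.array([10.0, 20.0, 99.0]), np.ones(3, bool))
        vol = project_to_volume([fld], dss, grid, cortex, max_fill_iter=0)
        assert vol.values[1, 1, 1] == 15.0
        assert vol.values[5, 5, 5] == 99.0

    def test_incomplete_field_rejected(self, small_phantom, grid):
        up = self._upsampled(small_phantom, 2)
        fields = [VertexField(np.zeros(m.n_vertices),
                              np.zeros(m.n_vertices, bool)) for m in up.meshes]
        with pytest.raises(ValueError):
            project_to_volume(fields, up, grid, grid.values > 0.5)

    def test_vertex_coverage_near_complete(self, small_phantom, grid):
        up = self._upsampled(small_phantom, 8)
        cov = vertex_voxel_coverage(up, grid, grid.values > 0.5)
        assert cov >= 0.99
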