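import numpy as np
import pytest

from kidneymorph import (
    TriangleMesh,
    affine_align,
    build_template,
    generate_template_shape,
    nonrigid_propagate,
    patch_effect,
    rigid_align,
    vertex_geometry,
)


def rot_z(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


class TestRigid:
    def test_recovers_rotation_translation(self, small_template):
        moved = TriangleMesh(
            small_template.vertices @ rot_z(np.pi / 2).T + [5.0, 0, 0],
            small_template.faces,
        )
        _, aligned = rigid_align(moved, small_template)
        rmsd = np.sqrt(np.mean(np.sum((aligned.vertices - small_template.vertices) ** 2, 1)))
        assert rmsd < 1e-6

    def test_identity(self, small_template):
        tf, _ = rigid_align(small_template, small_template)
        np.testing.assert_allclose(tf.matrix, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(tf.translation, 0.0, atol=1e-9)

    def test_scale_not_removed(self, small_template):
        scaled = TriangleMesh(small_template.vertices * 1.2, small_template.faces)
        tf, aligned = rigid_align(scaled, small_template)
        # rotation stays orthonormal, residual stays large
        np.testing.assert_allclose(tf.matrix @ tf.matrix.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(tf.matrix) == pytest.approx(1.0, abs=1e-8)
        rmsd = np.sqrt(np.mean(np.sum((aligned.vertices - small_template.vertices) ** 2, 1)))
        assert rmsd > 1.0

    def test_preserves_intervertex_distances(self, small_template):
        moved = TriangleMesh(
            small_template.vertices @ rot_z(0.7).T + [3.0, -2.0, 1.0],
            small_template.faces,
        )
        _, aligned = rigid_align(moved, small_template)
        d_before = np.linalg.norm(moved.vertices[1:] - moved.vertices[:-1], axis=1)
        d_after = np.linalg.norm(aligned.vertices[1:] - aligned.vertices[:-1], axis=1)
        np.testing.assert_allclose(d_after, d_before, rtol=1e-9)

    def test_icp_unmatched_topology(self, small_template):
        other = generate_template_shape(200, bend=0.4, seed=0)
        moved = TriangleMesh(other.vertices @ rot_z(0.3).T + [8.0, 3.0, 0.0], other.faces)
        _, aligned = rigid_align(moved, other)
        assert np.abs(aligned.vertices - other.vertices).max() < 1e-3

    def test_degenerate_collinear_raises(self):
        line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        m = TriangleMesh(line, np.array([[0, 1, 2]]))
        with pytest.raises(ValueError, match="degenerate|collinear"):
            rigid_align(m, m)


class TestAffine:
    def test_shear_recovered(self, small_template):
        S = np.array([[1.0, 0.3, 0], [0, 1.0, 0], [0, 0, 1.0]])
        moved = TriangleMesh(small_template.vertices @ S.T, small_template.faces)
        tf, aligned = affine_align(moved, small_template)
        np.testing.assert_allclose(tf.matrix, np.linalg.inv(S), atol=1e-8)
        assert np.abs(aligned.vertices - small_template.vertices).max() < 1e-8

    def test_identity(self, small_template):
        tf, _ = affine_align(small_template, small_template)
        np.testing.assert_allclose(tf.matrix, np.eye(3), atol=1e-8)

    def test_anisotropic_scale_recovered(self, small_template):
        S = np.diag([1.1, 0.9, 1.0])
        moved = TriangleMesh(small_template.vertices @ S, small_template.faces)
        tf, _ = affine_align(moved, small_template)
        np.testing.assert_allclose(tf.matrix, np.linalg.inv(S), atol=1e-8)

    def test_rank_deficient_raises(self):
        flat = np.zeros((6, 3))
        flat[:, 0] = np.arange(6)
        m = TriangleMesh(flat, np.array([[0, 1, 2]]))
        with pytest.raises(ValueError, match="rank"):
            affine_align(m, m, corresponded=True)


class TestNonrigidPropagate:
    def test_identity(self, small_template):
        out = nonrigid_propagate(small_template, small_template)
        assert np.abs(out - small_template.vertices).max() < 1e-6

    def test_inflation_along_normals(self, small_template, small_geometry):
        subj = TriangleMesh(
            small_template.vertices + 2.0 * small_geometry.normals,
            small_template.faces,
        )
        out = nonrigid_propagate(small_template, subj)
        err = np.linalg.norm(out - subj.vertices, axis=1)
        assert err.max() < 0.2

    def test_localised_bump_within_epsilon(self, small_template, small_geometry):
        from kidneymorph.registration import closest_point_on_surface

        bump = patch_effect(small_template, small_geometry, 10, 20.0, 4.0)
        subj = TriangleMesh(
            small_template.vertices + bump[:, None] * small_geometry.normals,
            small_template.faces,
        )
        out = nonrigid_propagate(small_template, subj, epsilon=0.5)
        _, resid = closest_point_on_surface(subj, out)
        assert resid.max() < 0.5


class TestBuildTemplate:
    def sphere(self, r, sub=2):
        import trimesh

        s = trimesh.creation.icosphere(subdivisions=sub, radius=r)
        return TriangleMesh.from_trimesh(s)

    def test_two_concentric_spheres_mean_radius(self):
        tmpl = build_template([self.sphere(1.0), self.sphere(3.0)])
        radii = np.linalg.norm(tmpl.vertices, axis=1)
        np.testing.assert_allclose(radii, 2.0, atol=1e-6)

    def test_single_input_unchanged(self, small_template):
        out = build_template([small_template])
        np.testing.assert_array_equal(out.vertices, small_template.vertices)

    def test_noise_cohort_recovers_template(self, small_template, small_geometry, rng):
        n = 20
        meshes = [
            TriangleMesh(
                small_template.vertices
                + rng.normal(0, 1.0, small_template.n_vertices)[:, None]
                * small_geometry.normals,
                small_template.faces,
            )
            for _ in range(n)
        ]
        tmpl = build_template([small_template] + meshes, reference_index=0)
        err = np.linalg.norm(tmpl.vertices - small_template.vertices, axis=1)
        # mean of n+1 shapes with unit-SD normal noise: error ~ 1/sqrt(n)
        assert err.mean() < 3.0 / np.sqrt(n)

    def test_order_insensitive_given_reference(self, small_template, small_geometry, rng):
        meshes = [
            TriangleMesh(
                small_template.vertices
                + rng.normal(0, 0.5, small_template.n_vertices)[:, None]
                * small_geometry.normals,
                small_template.faces,
            )
            for _ in range(6)
        ]
        t1 = build_template(meshes, reference_index=0)
        shuffled = [meshes[0]] + meshes[:0:-1]
        t2 = build_template(shuffled, reference_index=0)
        assert np.abs(t1.vertices - t2.vertices).max() < 1e-3
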