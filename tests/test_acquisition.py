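"""Thick-slice stack sampling, session simulation, repetition averaging."""

import numpy as np
import pytest

import mdtmap as m
from mdtmap.acquisition import build_sampling_operator, build_stack_grid
from mdtmap.grids import centered_grid

from conftest import central_crop


def dense_operator_oracle(source, stack, geometry):
    """Naive scalar-loop construction of the D*B*R matrix.

    Independent of the vectorized sparse builder: per stack voxel, walk the
    slice-profile taps along the slice normal and accumulate tri-linear
    interpolation weights one corner at a time.
    """
    if geometry.slice_profile == "boxcar":
        w = geometry.slice_thickness_mm
        n = max(1, int(round(w / source.spacing.min())))
        offsets = [(i - (n - 1) / 2) * (w / n) for i in range(n)]
        weights = [1.0 / n] * n
    else:
        sigma = geometry.slice_thickness_mm / np.sqrt(8 * np.log(2))
        step = min(source.spacing.min(), sigma)
        k = int(np.ceil(2.5 * sigma / step))
        offsets = [i * step for i in range(-k, k + 1)]
        weights = [np.exp(-0.5 * (o / sigma) ** 2) for o in offsets]
        total = sum(weights)
        weights = [w / total for w in weights]

    slice_dir = stack.affine[:3, 2] / np.linalg.norm(stack.affine[:3, 2])
    inv = np.linalg.inv(source.affine)
    a = np.zeros((stack.n_voxels, source.n_voxels))
    row = 0
    for i in range(stack.shape[0]):
        for j in range(stack.shape[1]):
            for k_ in range(stack.shape[2]):
                world = stack.affine @ np.array([i, j, k_, 1.0])
                for off, wgt in zip(offsets, weights):
                    pt = world[:3] + off * slice_dir
                    vox = (inv @ np.append(pt, 1.0))[:3]
                    base = np.floor(vox).astype(int)
                    frac = vox - base
                    for cx in (0, 1):
                        for cy in (0, 1):
                            for cz in (0, 1):
                                idx = base + [cx, cy, cz]
                                if np.any(idx < 0) or np.any(idx >= source.shape):
                                    continue
                                wt = (
                                    (frac[0] if cx else 1 - frac[0])
                                    * (frac[1] if cy else 1 - frac[1])
                                    * (frac[2] if cz else 1 - frac[2])
                                )
                                col = (
                                    idx[0] * source.shape[1] + idx[1]
                                ) * source.shape[2] + idx[2]
                                a[row, col] += wgt * wt
                row += 1
    return a


class TestSampleStack:
    def test_identity_geometry(self, small_phantom, identity_geometry):
        """Matched spacing, 0 degrees, boxcar: stack reproduces the volume."""
        sig = small_phantom.shell_signal(1500.0)
        stack, grid = m.sample_stack(sig, small_phantom.grid, identity_geometry, 0.0)
        np.testing.assert_allclose(
            central_crop(stack, sig.shape), sig, atol=1e-6
        )

    @pytest.mark.parametrize("profile", ["gaussian", "boxcar"])
    def test_unit_dc_gain(self, profile):
        """A uniform unit volume maps to unit stack values wherever the
        profile support lies inside the source (unit-gain normalization)."""
        grid = centered_grid(24, 1.0)
        geom = m.StackGeometry(in_plane_mm=(1.5, 1.5), slice_thickness_mm=4.0,
                               slice_profile=profile)
        stack, sgrid = m.sample_stack(np.ones(grid.shape), grid, geom, 30.0)
        centers = sgrid.voxel_centers().reshape(*sgrid.shape, 3)
        inside = np.abs(centers).max(axis=-1) <= 12 - 1.5 * 4.0
        assert inside.sum() > 100
        np.testing.assert_allclose(stack[inside], 1.0, atol=1e-6)

    @pytest.mark.parametrize("angle,profile", [(0.0, "boxcar"), (40.0, "gaussian")])
    def test_matches_dense_matrix_oracle(self, angle, profile):
        """The fused sparse operator equals a naive dense D*B*R build."""
        src = centered_grid(8, 1.0)
        geom = m.StackGeometry(in_plane_mm=(1.5, 1.5), slice_thickness_mm=3.0,
                               slice_profile=profile)
        stack = build_stack_grid(src, geom, angle)
        op = build_sampling_operator(src, stack, geom)
        dense = dense_operator_oracle(src, stack, geom)
        assert np.abs(op.toarray() - dense).max() < 1e-10

    def test_adjoint_identity(self):
        """<A x, y> == <x, A^T y> for the implemented operator pair."""
        rng = np.random.default_rng(0)
        src = centered_grid(10, 1.0)
        geom = m.StackGeometry(in_plane_mm=(1.3, 1.3), slice_thickness_mm=3.5)
        for angle in (0.0, 62.0, 110.0):
            stack = build_stack_grid(src, geom, angle)
            op = build_sampling_operator(src, stack, geom)
            x = rng.standard_normal(src.n_voxels)
            y = rng.standard_normal(stack.n_voxels)
            lhs = (op @ x) @ y
            rhs = x @ (op.T @ y)
            assert abs(lhs - rhs) <= 1e-8 * np.linalg.norm(x) * np.linalg.norm(y)

    def test_invalid_inputs(self, small_phantom):
        sig = small_phantom.shell_signal(0.0)
        geom = m.StackGeometry()
        with pytest.raises(ValueError):
            m.sample_stack(sig, small_phantom.grid, geom, 190.0)
        bad = sig.copy()
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            m.sample_stack(bad, small_phantom.grid, geom, 0.0)
        with pytest.raises(ValueError):
            m.StackGeometry(in_plane_mm=(2.0, 2.0), slice_thickness_mm=1.0)


class TestSimulateSession:
    def test_volume_count_for_default_protocol(self, small_phantom):
        """1 + 16 + 24 repetitions across 6 rotations -> 246 volumes."""
        sess = m.simulate_session(
            small_phantom, m.default_protocol(), m.StackGeometry(), 0.02, seed=1
        )
        assert sess.n_volumes == 246

    def test_noiseless_b0_is_sampled_total_fraction(self, small_phantom):
        geom = m.StackGeometry(rotation_angles_deg=(0.0, 90.0))
        sess = m.simulate_session(
            small_phantom, m.default_protocol(repetitions=(1, 1, 1)), geom, 0.0
        )
        expected, _ = m.sample_stack(
            small_phantom.total_fraction(), small_phantom.grid, geom, 0.0
        )
        np.testing.assert_allclose(sess.volumes[0][0][0], expected, atol=1e-12)

    def test_deterministic_under_seed(self, small_phantom):
        geom = m.StackGeometry(rotation_angles_deg=(0.0, 60.0))
        prot = m.default_protocol(repetitions=(1, 2, 2))
        a = m.simulate_session(small_phantom, prot, geom, 0.05, seed=9)
        b = m.simulate_session(small_phantom, prot, geom, 0.05, seed=9)
        for va, vb in zip(a.volumes, b.volumes):
            for sa, sb in zip(va, vb):
                np.testing.assert_array_equal(sa, sb)

    def test_roundtrip_save_load(self, small_phantom, tmp_path):
        geom = m.StackGeometry(rotation_angles_deg=(0.0, 45.0))
        sess = m.simulate_session(
            small_phantom, m.default_protocol(repetitions=(1, 2, 2)), geom, 0.01,
            seed=3,
        )
        sess.save(tmp_path / "stacks")
        back = m.LowResStackSet.load(tmp_path / "stacks")
        assert back.n_volumes == sess.n_volumes
        assert back.noise_sigma == sess.noise_sigma
        for va, vb in zip(sess.volumes, back.volumes):
            for sa, sb in zip(va, vb):
                np.testing.assert_array_equal(sa, sb)


class TestAverageRepetitions:
    def _session(self, phantom, sigma, seed=None, reps=(1, 4, 4)):
        return m.simulate_session(
            phantom,
            m.default_protocol(repetitions=reps),
            m.StackGeometry(rotation_angles_deg=(0.0,)),
            sigma,
            seed=seed,
        )

    def test_noiseless_mean_equals_member(self, small_phantom):
        sess = self._session(small_phantom, 0.0)
        avg = m.average_repetitions(sess)
        np.testing.assert_array_equal(avg.volumes[0][1][0], sess.volumes[0][1][0])
        assert avg.repetitions == (1, 1, 1)
        assert avg.meta["averaging_method"] == "mean"

    def test_plain_mean_arithmetic(self, small_phantom):
        sess = self._session(small_phantom, 0.0, reps=(1, 2, 2))
        sess.volumes[0][1][0][:] = 0.2
        sess.volumes[0][1][1][:] = 0.4
        avg = m.average_repetitions(sess, method="mean")
        np.testing.assert_allclose(avg.volumes[0][1][0], 0.3)

    def test_mean_noise_scaling(self, small_phantom):
        """With 16 repetitions the voxelwise std of the mean is sigma/4."""
        sigma = 0.02
        sess = self._session(small_phantom, sigma, seed=11, reps=(1, 16, 1))
        avg = m.average_repetitions(sess, method="mean")
        clean = m.average_repetitions(self._session(small_phantom, 0.0,
                                                    reps=(1, 1, 1)))
        sel = clean.volumes[0][0][0] > 0.9  # interior head, high SNR
        resid = (avg.volumes[0][1][0] - clean.volumes[0][1][0])[sel]
        assert resid.std() == pytest.approx(sigma / 4, rel=0.20)

    def test_rician_corrected_removes_noise_floor(self, small_phantom):
        """At low SNR the plain mean inflates weak signals (rectified noise
        floor); the second-moment correction removes the inflation."""
        sigma = 0.05
        sess = self._session(small_phantom, sigma, seed=5, reps=(1, 1, 64))
        clean = m.average_repetitions(self._session(small_phantom, 0.0,
                                                    reps=(1, 1, 1)))
        truth = clean.volumes[0][2][0]
        sel = (truth > 0.05) & (truth < 0.15)  # weak but nonzero signal
        plain = m.average_repetitions(sess, method="mean").volumes[0][2][0]
        corrected = m.average_repetitions(sess).volumes[0][2][0]
        bias_plain = (plain - truth)[sel].mean()
        bias_corr = (corrected - truth)[sel].mean()
        assert bias_plain > 3 * abs(bias_corr)
        assert abs(bias_corr) < 0.005

    def test_corrected_requires_sigma(self, small_phantom):
        sess = self._session(small_phantom, 0.0)
        with pytest.raises(ValueError):
            m.average_repetitions(sess, method="rician_corrected")
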