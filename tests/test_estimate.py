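"""Two-shell tissue diffusivity (MDT), ADC baseline, masking, windowing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mdtmap as m


def mixture_two_shell(mds, fractions, b1=1500.0, b2=2500.0):
    mix = m.CompartmentMixture(
        tuple(m.DiffusionCompartment(md, f) for md, f in zip(mds, fractions))
    )
    return m.mixture_signal(mix, b1), m.mixture_signal(mix, b2)


class TestComputeMdt:
    def test_mono_exponential_identity(self):
        s1, s2 = np.exp(-1.05), np.exp(-1.75)
        assert m.compute_mdt(s1, s2, 1500, 2500) == pytest.approx(0.7, rel=1e-12)

    def test_equal_signals_give_zero(self):
        assert m.compute_mdt(0.3, 0.3, 1500, 2500) == 0.0

    def test_partial_volume_voxel_bias(self, tissue_csf_mixture):
        """30% CSF biases the two-shell estimate by only ~+1.7%."""
        s1 = m.mixture_signal(tissue_csf_mixture, 1500.0)
        s2 = m.mixture_signal(tissue_csf_mixture, 2500.0)
        assert m.compute_mdt(s1, s2) == pytest.approx(0.7122, abs=5e-4)

    @given(
        mds=st.lists(st.floats(0.05, 3.5), min_size=1, max_size=5),
        data=st.data(),
    )
    @settings(max_examples=1000, deadline=None)
    def test_bounded_by_compartment_range(self, mds, data):
        """MDT of any noiseless mixture lies in [min md, max md], and a
        single compartment is recovered to 1e-12 relative error."""
        fr = data.draw(
            st.lists(st.floats(0.01, 1.0), min_size=len(mds), max_size=len(mds))
        )
        fr = np.asarray(fr) / max(sum(fr), 1.0)
        s1, s2 = mixture_two_shell(mds, fr)
        est = m.compute_mdt(s1, s2)
        lo, hi = min(mds), max(mds)
        assert lo - 1e-9 <= est <= hi + 1e-9
        if len(mds) == 1:
            assert est == pytest.approx(mds[0], rel=1e-12)

    def test_floor_and_b_order_errors(self):
        with pytest.raises(ValueError):
            m.compute_mdt(0.3, 0.2, 2500, 1500)
        with pytest.raises(ValueError):
            m.compute_mdt(1e-9, 0.2, 1500, 2500)

    def test_map_flags_floored_voxels_invalid(self):
        s1 = np.array([[[0.35, 1e-9]]])
        s2 = np.array([[[0.17, 0.17]]])
        mp = m.mdt_map(s1, s2, np.eye(4))
        assert mp.valid[0, 0, 0] and not mp.valid[0, 0, 1]
        assert np.isnan(mp.values[0, 0, 1])


class TestComputeAdc:
    def test_mono_exponential(self):
        assert m.compute_adc(1.0, np.exp(-0.7), 1000) == pytest.approx(0.7, rel=1e-12)
        assert m.compute_adc(0.4, 0.4, 1000) == 0.0

    def test_partial_volume_voxel_bias(self, tissue_csf_mixture):
        """Same 30% CSF voxel: conventional b=0-1000 ADC is biased +45%."""
        sb = m.mixture_signal(tissue_csf_mixture, 1000.0)
        assert sb == pytest.approx(0.362546, abs=1e-6)
        assert m.compute_adc(1.0, sb, 1000) == pytest.approx(1.0146, abs=5e-4)


class TestCsfSuppressionDominance:
    def test_mdt_dominates_adc_across_csf_fractions(self):
        """For every CSF fraction in (0, 0.5], the two-shell estimate is
        closer to the tissue truth than the conventional ADC — the entire
        point of estimating in the high-b range."""
        for f_csf in np.linspace(0.01, 0.5, 50):
            mds = (0.7, m.FREE_WATER_DIFFUSIVITY)
            fr = (1 - f_csf, f_csf)
            s1, s2 = mixture_two_shell(mds, fr)
            mdt_bias = m.compute_mdt(s1, s2) - 0.7
            s0 = sum(fr)
            sb = mixture_two_shell(mds, fr, 0.0, 1000.0)[1]
            adc_bias = m.compute_adc(s0, sb, 1000.0) - 0.7
            assert abs(mdt_bias) < abs(adc_bias)


class TestMaskAndWindow:
    def _map(self):
        vals = np.linspace(0.4, 1.0, 27).reshape(3, 3, 3)
        return m.MDTMap(vals, np.ones((3, 3, 3), bool), np.eye(4))

    def test_all_ones_mask_is_identity(self):
        mp = self._map()
        mask = m.CorticalMask(np.ones((3, 3, 3), bool), np.eye(4))
        out = m.apply_cortical_mask(mp, mask)
        np.testing.assert_array_equal(out.values, mp.values)
        np.testing.assert_array_equal(out.valid, mp.valid)

    def test_all_zeros_mask_invalidates_with_warning(self):
        mp = self._map()
        mask = m.CorticalMask(np.zeros((3, 3, 3), bool), np.eye(4))
        with pytest.warns(UserWarning, match="empty"):
            out = m.apply_cortical_mask(mp, mask)
        assert not out.valid.any()

    def test_half_mask_popcount(self):
        mp = self._map()
        mask_arr = np.zeros((3, 3, 3), bool)
        mask_arr[:, :, :2] = True
        out = m.apply_cortical_mask(mp, m.CorticalMask(mask_arr, np.eye(4)))
        assert out.valid.sum() == (mask_arr & mp.valid).sum()

    def test_mask_resampled_nearest_neighbor(self):
        """A mask on a 2x coarser grid is resampled with binary semantics."""
        vals = np.full((4, 4, 4), 0.7)
        affine = np.eye(4)
        mp = m.MDTMap(vals, np.ones((4, 4, 4), bool), affine)
        coarse_aff = np.diag([2.0, 2.0, 2.0, 1.0])
        coarse_aff[:3, 3] = 0.5  # coarse voxel centers between fine ones
        mask_arr = np.zeros((2, 2, 2), bool)
        mask_arr[0] = True
        out = m.apply_cortical_mask(mp, m.CorticalMask(mask_arr, coarse_aff))
        assert set(np.unique(out.valid[:2])) == {True}
        assert set(np.unique(out.valid[2:])) == {False}

    def test_window_endpoints_and_midpoint(self):
        mp = self._map()
        disp = m.render_window(mp, 0.5, 0.9)
        np.testing.assert_allclose(disp.min(), 0.0)
        np.testing.assert_allclose(disp.max(), 1.0)
        idx = np.unravel_index(np.argmin(np.abs(mp.values - 0.7)), (3, 3, 3))
        assert disp[idx] == pytest.approx((mp.values[idx] - 0.5) / 0.4)

    def test_invalid_voxels_render_dark(self):
        """A CSF voxel whose high-b signal fell below the floor renders 0."""
        vals = np.array([[[3.0, 0.7]]])
        valid = np.array([[[False, True]]])
        disp = m.render_window(m.MDTMap(vals, valid, np.eye(4)))
        assert disp[0, 0, 0] == 0.0
        assert disp[0, 0, 1] == pytest.approx(0.5)

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            m.render_window(self._map(), 0.9, 0.5)


class TestPvBiasReport:
    def _closed_form_maps(self):
        """Small grid of noiseless voxels at fixed CSF fractions."""
        csf = np.array([0.0, 0.25, 0.3, 0.45]).reshape(4, 1, 1)
        s1 = (1 - csf) * np.exp(-1.5 * 0.7) + csf * np.exp(-1.5 * 3.0)
        s2 = (1 - csf) * np.exp(-2.5 * 0.7) + csf * np.exp(-2.5 * 3.0)
        s0 = np.ones_like(csf)
        sb = (1 - csf) * np.exp(-1.0 * 0.7) + csf * np.exp(-1.0 * 3.0)
        mdt = m.mdt_map(s1, s2, np.eye(4))
        adc = m.adc_map(s0, sb, np.eye(4), b=1000.0)
        truth = np.full(csf.shape, 0.7)
        return csf, mdt, adc, truth

    def test_closed_form_bin_biases(self):
        csf, mdt, adc, truth = self._closed_form_maps()
        rep = m.pv_bias_report(csf, mdt, adc, truth, np.ones(csf.shape, bool))
        row = rep[(rep.csf_lo == 0.2) & (rep.csf_hi == 0.3)].iloc[0]
        # voxels at CSF fractions 0.25 and 0.30 fall in this bin
        expected_mdt = np.mean(
            [m.compute_mdt(*mixture_two_shell((0.7, 3.0), (1 - f, f))) - 0.7
             for f in (0.25, 0.30)]
        )
        assert row.mdt_bias == pytest.approx(expected_mdt, abs=1e-9)
        assert row.adc_bias > 10 * row.mdt_bias

    def test_zero_csf_bin_unbiased(self):
        csf, mdt, adc, truth = self._closed_form_maps()
        rep = m.pv_bias_report(csf, mdt, adc, truth, np.ones(csf.shape, bool))
        row = rep.iloc[0]
        assert abs(row.mdt_bias) < 1e-9
        assert abs(row.adc_bias) < 1e-9

    def test_row_count_and_empty_bins(self):
        csf, mdt, adc, truth = self._closed_form_maps()
        rep = m.pv_bias_report(csf, mdt, adc, truth, np.ones(csf.shape, bool),
                               bins=(0.0, 0.25, 0.5, 0.75))
        assert len(rep) == 3
        assert rep.iloc[2].n_voxels == 0
        assert np.isnan(rep.iloc[2].mdt_bias)

    def test_phantom_input(self, small_phantom):
        s1 = small_phantom.shell_signal(1500.0)
        s2 = small_phantom.shell_signal(2500.0)
        s0 = small_phantom.shell_signal(0.0)
        mdt = m.mdt_map(s1, s2, small_phantom.grid.affine)
        adc = m.adc_map(s0, s1, small_phantom.grid.affine, b=1500.0)
        rep = m.pv_bias_report(small_phantom, mdt, adc)
        assert (rep.n_voxels > 0).any()
        filled = rep.dropna()
        assert (filled.adc_bias.abs() >= filled.mdt_bias.abs() - 1e-12).all()
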