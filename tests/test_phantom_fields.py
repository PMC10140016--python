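"""Phantom construction, array layouts, surrogate fields and container I/O."""

import numpy as np
import pytest
from scipy import ndimage

from ptxbench.arrays import CHANNEL_COUNTS, make_array_spec
from ptxbench.constants import F_7T_HZ, F_14T_HZ
from ptxbench.errors import (ConfigurationError, FieldFormatError,
                             FieldModelError, SarUnavailableError)
from ptxbench.fields import (ChannelFieldSet, element_fields, io_fieldset,
                             read_fieldset, simulate_fields, skin_depth,
                             strip_e_field, write_fieldset)
from ptxbench.phantom import (PhantomConfig, build_phantom, load_tissue_table)
from ptxbench.superposition import power_correlation
from ptxbench.sar import build_q_matrices

from conftest import custom_array, tiny_config


class TestPhantom:
    def test_roi_volume_matches_analytic_ellipsoid(self, demo_phantom):
        cfg = demo_phantom.config
        a, b, c = cfg.heart_semiaxes
        analytic = 4.0 / 3.0 * np.pi * a * b * c  # mm^3
        vox = cfg.voxel_size**3
        measured = demo_phantom.roi_mask.sum() * vox
        shell = demo_phantom.roi_mask & ~ndimage.binary_erosion(
            demo_phantom.roi_mask)
        assert abs(measured - analytic) <= shell.sum() * vox

    def test_degenerate_heart_is_a_configuration_error(self):
        cfg = tiny_config()
        with pytest.raises(ConfigurationError):
            build_phantom(
                PhantomConfig(**{**cfg.__dict__, "heart_semiaxes": (0.0, 0.0, 0.0)})
            )

    def test_heart_outside_torso_is_rejected(self):
        cfg = tiny_config()
        with pytest.raises(ConfigurationError):
            build_phantom(
                PhantomConfig(**{**cfg.__dict__, "heart_center": (35.0, 0.0, 0.0)})
            )

    def test_deterministic_for_fixed_config(self):
        p1 = build_phantom(tiny_config())
        p2 = build_phantom(tiny_config())
        assert np.array_equal(p1.tissue_label, p2.tissue_label)
        assert np.array_equal(p1.roi_mask, p2.roi_mask)

    def test_roi_lies_inside_tissue(self, demo_phantom):
        assert demo_phantom.roi_mask.any()
        assert demo_phantom.body_mask[demo_phantom.roi_mask].all()

    def test_tissue_tables_exist_for_both_frequencies(self):
        for f in (F_7T_HZ, F_14T_HZ):
            table = load_tissue_table(f)
            for prop in table.values():
                assert prop.sigma >= 0 and prop.eps_r >= 1 and prop.rho > 0
        with pytest.raises(ConfigurationError):
            load_tissue_table(128e6)


class TestArraySpec:
    @pytest.mark.parametrize(("bb", "setup"), sorted(CHANNEL_COUNTS))
    def test_channel_counts_match_the_design_table(self, bb, setup,
                                                   demo_phantom):
        spec = make_array_spec(bb, setup, demo_phantom)
        assert spec.n_channels == CHANNEL_COUNTS[(bb, setup)]
        # equal anterior / posterior split
        anterior = spec.element_centers[:, 0] > 0
        assert anterior.sum() == spec.n_channels // 2

    def test_same_channel_count_setup_reuses_baseline_centers(self,
                                                              demo_phantom):
        bl = make_array_spec("BT", "BL-7T", demo_phantom)
        scc = make_array_spec("BT", "SCC-14T", demo_phantom)
        assert np.allclose(bl.element_centers, scc.element_centers)
        assert bl.frequency == F_7T_HZ and scc.frequency == F_14T_HZ

    def test_unknown_pair_is_rejected(self, demo_phantom):
        with pytest.raises(ConfigurationError):
            make_array_spec("LOOP", "BL-7T", demo_phantom)


class TestSurrogateFields:
    def test_peak_b1_lies_on_the_element_axis(self, tiny_phantom):
        b1p, _, _ = element_fields(tiny_phantom, (58.0, 0.0, 0.0),
                                   (0, 0, 1), 120.0, F_7T_HZ)
        i, j, k = np.unravel_index(np.argmax(np.abs(b1p)), b1p.shape)
        ax = tiny_phantom.axes_mm()
        # straight line from the element into the torso is the -x ray at y=z=0
        assert abs(ax[1][j]) <= tiny_phantom.voxel_size
        assert abs(ax[2][k]) <= tiny_phantom.voxel_size

    def test_mirrored_elements_give_mirrored_magnitudes(self, tiny_phantom):
        kw = dict(orientation=(0, 0, 1), length_mm=120.0, frequency=F_7T_HZ,
                  normalize=False)
        bp_a, _, _ = element_fields(tiny_phantom, (58.0, 20.0, 0.0), **kw)
        bp_b, _, _ = element_fields(tiny_phantom, (58.0, -20.0, 0.0), **kw)
        assert np.allclose(np.abs(bp_a), np.abs(bp_b)[:, ::-1, :], rtol=1e-9)

    def test_receive_field_convention_mirrors_transmit(self, tiny_phantom):
        """For a dipole on the y = 0 plane, |B1-(x,y,z)| = |B1+(x,-y,z)|."""
        bp, bm, _ = element_fields(tiny_phantom, (58.0, 0.0, 0.0),
                                   (0, 0, 1), 120.0, F_7T_HZ, normalize=False)
        assert np.allclose(np.abs(bm), np.abs(bp)[:, ::-1, :], rtol=1e-9)

    def test_frequency_attenuation_follows_the_skin_depth_closed_form(
            self, tiny_phantom):
        """|B1+| ratio between 600 and 297.2 MHz at the heart center equals
        the closed-form exponential attenuation along the entry path."""
        center = np.array([58.0, 0.0, 0.0])
        kw = dict(orientation=(0, 0, 1), length_mm=120.0, normalize=False)
        b_lo, _, _ = element_fields(tiny_phantom, center, frequency=F_7T_HZ, **kw)
        b_hi, _, _ = element_fields(tiny_phantom, center, frequency=F_14T_HZ, **kw)
        idx = tiny_phantom.heart_center_index()
        ratio = np.abs(b_hi[idx]) / np.abs(b_lo[idx])

        # independent arithmetic: ellipse-entry point and skin depths
        ax = tiny_phantom.axes_mm()
        voxel = np.array([ax[0][idx[0]], ax[1][idx[1]], ax[2][idx[2]]])
        a, b = tiny_phantom.config.torso_semiaxes
        d = voxel - center
        qa = (d[0] / a) ** 2 + (d[1] / b) ** 2
        qb = 2 * (center[0] * d[0] / a**2 + center[1] * d[1] / b**2)
        qc = (center[0] / a) ** 2 + (center[1] / b) ** 2 - 1
        t_in = (-qb - np.sqrt(qb**2 - 4 * qa * qc)) / (2 * qa)
        depth_m = (1.0 - t_in) * np.linalg.norm(d) * 1e-3
        mu0 = 4e-7 * np.pi
        deltas = {
            f: np.sqrt(2.0 / (2 * np.pi * f * mu0 *
                              load_tissue_table(f)[3].sigma))
            for f in (F_7T_HZ, F_14T_HZ)
        }
        expected = np.exp(-depth_m * (1 / deltas[F_14T_HZ] - 1 / deltas[F_7T_HZ]))
        assert ratio == pytest.approx(expected, rel=1e-6)

    def test_heart_b1_decreases_with_frequency_after_normalization(
            self, tiny_phantom):
        centers = [(60.0, -25.0, 0.0), (60.0, 25.0, 0.0), (-60.0, 0.0, 0.0)]
        lo = simulate_fields(tiny_phantom, custom_array(centers, F_7T_HZ),
                             seed=7, jitter_mm=0.0)
        hi = simulate_fields(tiny_phantom, custom_array(centers, F_14T_HZ),
                             seed=7, jitter_mm=0.0)
        roi = tiny_phantom.roi_mask
        for ch in range(3):
            assert (np.abs(hi.b1_plus[ch, roi]).mean()
                    <= np.abs(lo.b1_plus[ch, roi]).mean())

    def test_field_linearity_in_the_excitation(self, fieldset3):
        rng = np.random.default_rng(0)
        w = rng.standard_normal(3) + 1j * rng.standard_normal(3)
        s1 = fieldset3.superpose(w)
        manual = sum(w[c] * fieldset3.b1_plus[c] for c in range(3))
        np.testing.assert_allclose(s1, manual, rtol=1e-12)
        np.testing.assert_allclose(fieldset3.superpose(2 * w), 2 * s1,
                                   rtol=1e-12)

    def test_element_inside_tissue_is_rejected(self, tiny_phantom):
        with pytest.raises(FieldModelError):
            element_fields(tiny_phantom, (0.0, 0.0, 0.0), (0, 0, 1), 120.0,
                           F_7T_HZ)

    def test_sample_loss_never_exceeds_accepted_power(self, fieldset3):
        sigma, _, _ = fieldset3.phantom.property_maps(fieldset3.frequency)
        for ch in range(3):
            p = 0.5 * np.sum(
                sigma * np.sum(np.abs(fieldset3.e_field[ch]) ** 2, axis=0)
            ) * fieldset3.phantom.voxel_volume_m3
            assert p <= fieldset3.per_channel_power * (1 + 1e-9)

    def test_skin_depth_shrinks_with_frequency(self):
        assert skin_depth(F_14T_HZ, 0.86) < skin_depth(F_7T_HZ, 0.77)


class TestContainerIO:
    def _random_fieldset(self, phantom, nch=2, with_e=True, seed=0):
        rng = np.random.default_rng(seed)
        shp = (nch, *phantom.shape)
        mk = lambda s: rng.standard_normal(s) + 1j * rng.standard_normal(s)
        return ChannelFieldSet(
            b1_plus=mk(shp), b1_minus=mk(shp),
            e_field=mk((nch, 3, *phantom.shape)) if with_e else None,
            phantom=phantom, frequency=F_7T_HZ,
        )

    def test_round_trip_is_bit_identical(self, tiny_phantom, tmp_path):
        fs = self._random_fieldset(tiny_phantom)
        path = tmp_path / "fields.h5"
        io_fieldset(path, "write", fs)
        back = io_fieldset(path, "read")
        assert np.array_equal(back.b1_plus, fs.b1_plus)
        assert np.array_equal(back.b1_minus, fs.b1_minus)
        assert np.array_equal(back.e_field, fs.e_field)
        assert np.array_equal(back.phantom.tissue_label,
                              tiny_phantom.tissue_label)
        assert back.frequency == fs.frequency
        assert back.per_channel_power == fs.per_channel_power

    def test_missing_e_field_flags_sar_unavailable(self, tiny_phantom,
                                                   tmp_path):
        fs = strip_e_field(self._random_fieldset(tiny_phantom))
        path = tmp_path / "no_e.h5"
        write_fieldset(path, fs)
        back = read_fieldset(path)
        assert back.e_field is None and not back.has_sar_inputs
        with pytest.raises(SarUnavailableError, match="sample term"):
            power_correlation(back)
        with pytest.raises(SarUnavailableError):
            build_q_matrices(back)

    def test_channels_keep_stored_order(self, tiny_phantom, tmp_path):
        fs = self._random_fieldset(tiny_phantom, nch=5)
        for ch in range(5):
            fs.b1_plus[ch] = ch + 1.0
        path = tmp_path / "ordered.h5"
        write_fieldset(path, fs)
        back = read_fieldset(path)
        for ch in range(5):
            assert np.all(back.b1_plus[ch].real == ch + 1.0)

    def test_invalid_mode_is_rejected(self, tmp_path):
        with pytest.raises(FieldFormatError):
            io_fieldset(tmp_path / "x.h5", "append")

    def test_shape_mismatch_is_a_format_error(self, tiny_phantom):
        fs = self._random_fieldset(tiny_phantom)
        with pytest.raises(FieldFormatError):
            ChannelFieldSet(
                b1_plus=fs.b1_plus, b1_minus=fs.b1_minus[:1],
                e_field=None, phantom=tiny_phantom, frequency=F_7T_HZ,
            )
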