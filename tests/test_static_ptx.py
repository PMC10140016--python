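"""Static shimming: power bookkeeping, objectives, oracle equivalence, MOO."""

import dataclasses

import numpy as np
import pytest

from ptxbench.constants import F_7T_HZ, R_REF_OHM, U_REF_V
from ptxbench.errors import ConfigurationError
from ptxbench.fields import ChannelFieldSet
from ptxbench.optimize import GAConfig
from ptxbench.sar import average_10g, build_q_matrices, compress_vop
from ptxbench.static_ptx import (ExcitationVector, equal_phase_baseline,
                                 forward_power, roi_metrics, shim, shim_moo,
                                 superpose_scaled)

FAST_GA = GAConfig(population=60, generations=30)


class TestForwardPower:
    def test_64_channels_at_full_amplitude_book_128_kw(self):
        exc = ExcitationVector(np.ones(64, dtype=complex))
        assert forward_power(exc) == pytest.approx(128.0, rel=1e-12)

    def test_32_channels_book_64_kw(self):
        exc = ExcitationVector(np.exp(1j * np.linspace(0, 3, 32)))
        assert forward_power(exc) == pytest.approx(64.0, rel=1e-12)

    def test_single_channel_books_2_kw_and_the_port_voltage(self):
        exc = ExcitationVector(np.ones(1, dtype=complex))
        assert forward_power(exc) == pytest.approx(316.22776601683796**2 / 50 / 1e3)
        assert U_REF_V == pytest.approx(316.23, abs=0.01)
        assert R_REF_OHM == 50.0

    def test_zero_weights_book_zero(self):
        exc = ExcitationVector(np.zeros(8), mode="phase-amplitude")
        assert forward_power(exc) == 0.0

    def test_phase_only_mode_normalizes_amplitudes(self):
        exc = ExcitationVector(np.array([2.0, 1.0 + 1.0j]))
        np.testing.assert_allclose(np.abs(exc.weights), 1.0)


class TestSuperposeScaled:
    def test_single_channel_drive_is_proportional_to_its_map(self, fieldset3):
        e1 = np.array([1.0, 0.0, 0.0], dtype=complex)
        m = superpose_scaled(fieldset3, e1)
        expected = np.abs(fieldset3.b1_plus[0]) * np.sqrt(
            1e3 / fieldset3.per_channel_power)
        np.testing.assert_allclose(m, expected, rtol=1e-12)

    def test_global_phase_invariance(self, fieldset3):
        rng = np.random.default_rng(0)
        w = rng.standard_normal(3) + 1j * rng.standard_normal(3)
        m1 = superpose_scaled(fieldset3, w)
        m2 = superpose_scaled(fieldset3, w * np.exp(1j * 1.234))
        np.testing.assert_allclose(m1, m2, rtol=1e-12)

    def test_opposite_phases_cancel_identical_channels(self, tiny_phantom):
        b = np.ones((2, *tiny_phantom.shape), dtype=complex)
        fs = ChannelFieldSet(b1_plus=b, b1_minus=b.copy(), e_field=None,
                             phantom=tiny_phantom, frequency=F_7T_HZ)
        m = superpose_scaled(fs, np.array([1.0, -1.0], dtype=complex))
        np.testing.assert_allclose(m, 0.0, atol=1e-12)


class TestRoiMetrics:
    def test_constant_map_has_zero_cov(self, tiny_phantom):
        b = np.full((1, *tiny_phantom.shape), 2.0 + 0j)
        fs = ChannelFieldSet(b1_plus=b, b1_minus=b.copy(), e_field=None,
                             phantom=tiny_phantom, frequency=F_7T_HZ)
        res = roi_metrics(fs, tiny_phantom.roi_mask, np.array([1.0 + 0j]))
        assert res.mean_b1_roi == pytest.approx(res.min_b1_roi)
        assert res.cov_roi == pytest.approx(0.0, abs=1e-9)

    def test_zero_voxel_in_roi_drives_the_minimum_to_zero(self, tiny_phantom):
        b = np.full((1, *tiny_phantom.shape), 1.0 + 0j)
        idx = tuple(np.argwhere(tiny_phantom.roi_mask)[0])
        b[(0, *idx)] = 0.0
        fs = ChannelFieldSet(b1_plus=b, b1_minus=b.copy(), e_field=None,
                             phantom=tiny_phantom, frequency=F_7T_HZ)
        res = roi_metrics(fs, tiny_phantom.roi_mask, np.array([1.0 + 0j]))
        assert res.min_b1_roi == 0.0

    def test_cov_equals_direct_recomputation(self, fieldset3):
        rng = np.random.default_rng(5)
        w = rng.standard_normal(3) + 1j * rng.standard_normal(3)
        roi = fieldset3.phantom.roi_mask
        res = roi_metrics(fieldset3, roi, ExcitationVector(w, "phase-amplitude"))
        vals = superpose_scaled(fieldset3, w)[roi]
        assert res.cov_roi == pytest.approx(100 * vals.std() / vals.mean(),
                                            rel=1e-12)

    def test_reported_p_fwd_matches_the_quadratic_form(self, fieldset3):
        rng = np.random.default_rng(6)
        w = rng.standard_normal(3) + 1j * rng.standard_normal(3)
        exc = ExcitationVector(w, "phase-amplitude")
        res = roi_metrics(fieldset3, fieldset3.phantom.roi_mask, exc)
        expected = U_REF_V**2 / R_REF_OHM * np.sum(np.abs(w) ** 2) / 1e3
        assert res.p_fwd_kw == pytest.approx(expected, rel=1e-12)


class TestShim:
    def test_single_channel_has_no_freedom(self, fieldset3):
        fs1 = dataclasses.replace(
            fieldset3,
            b1_plus=fieldset3.b1_plus[:1], b1_minus=fieldset3.b1_minus[:1],
            e_field=None,
        )
        roi = fieldset3.phantom.roi_mask
        res = shim(fs1, roi, "MINB1", "phase-only", FAST_GA, seed=0)
        expected = superpose_scaled(fs1, np.array([1.0 + 0j]))[roi].min()
        assert res.min_b1_roi == pytest.approx(expected, rel=1e-9)

    def test_uniform_fields_give_zero_cov_for_any_drive(self, tiny_phantom):
        b = np.ones((3, *tiny_phantom.shape), dtype=complex)
        fs = ChannelFieldSet(b1_plus=b, b1_minus=b.copy(), e_field=None,
                             phantom=tiny_phantom, frequency=F_7T_HZ)
        res = shim(fs, tiny_phantom.roi_mask, "COV", "phase-only",
                   GAConfig(population=20, generations=5), seed=0)
        assert res.cov_roi == pytest.approx(0.0, abs=1e-9)

    def test_empty_roi_is_rejected(self, fieldset3):
        with pytest.raises(ConfigurationError):
            shim(fieldset3, np.zeros(fieldset3.phantom.shape, bool))

    def test_beats_the_equal_phase_baseline(self, fieldset3):
        roi = fieldset3.phantom.roi_mask
        base = equal_phase_baseline(fieldset3, roi)
        res = shim(fieldset3, roi, "MINB1", "phase-only", FAST_GA, seed=1)
        assert res.min_b1_roi >= base.min_b1_roi - 1e-12

    def test_deterministic_for_a_fixed_seed(self, fieldset3):
        roi = fieldset3.phantom.roi_mask
        r1 = shim(fieldset3, roi, "MINB1", "phase-only", FAST_GA, seed=3)
        r2 = shim(fieldset3, roi, "MINB1", "phase-only", FAST_GA, seed=3)
        np.testing.assert_array_equal(r1.exc.weights, r2.exc.weights)

    @pytest.mark.parametrize("objective", ["MINB1", "COV"])
    def test_matches_exhaustive_phase_grid_oracle(self, fieldset3, objective):
        """GA + local refinement vs a 2-degree exhaustive phase grid (channel
        1 fixed by global-phase invariance), within 1% of objective value."""
        roi = fieldset3.phantom.roi_mask
        assert roi.sum() <= 30
        res = shim(fieldset3, roi, objective, "phase-only", FAST_GA, seed=0)

        b = fieldset3.b1_plus[:, roi]  # (3, nvox)
        step = np.deg2rad(2.0)
        phases = np.arange(0.0, 2 * np.pi, step)
        p1, p2 = np.meshgrid(phases, phases, indexing="ij")
        w = np.stack([np.ones_like(p1).ravel(),
                      np.exp(1j * p1).ravel(),
                      np.exp(1j * p2).ravel()])
        maps = np.abs(w.T @ b) * np.sqrt(1e3 / (3 * fieldset3.per_channel_power))
        if objective == "MINB1":
            oracle = maps.min(axis=1).max()
            achieved = res.min_b1_roi
            assert achieved >= oracle * (1 - 0.01)
        else:
            oracle = (maps.std(axis=1) / maps.mean(axis=1)).min()
            achieved = res.cov_roi / 100.0
            assert achieved <= oracle * (1 + 0.01) + 1e-12

    def test_amplitude_freedom_never_hurts_min_b1(self, fieldset3):
        roi = fieldset3.phantom.roi_mask
        for seed in range(5):
            po = shim(fieldset3, roi, "MINB1", "phase-only", FAST_GA, seed=seed)
            pa = shim(fieldset3, roi, "MINB1", "phase-amplitude", FAST_GA,
                      seed=seed)
            assert pa.min_b1_roi >= po.min_b1_roi * (1 - 0.02)


@pytest.fixture(scope="module")
def sar_sets(fieldset4, tiny_phantom):
    q10 = average_10g(build_q_matrices(fieldset4), tiny_phantom,
                      frequency=fieldset4.frequency)
    vops = compress_vop(q10, 15.0, seed=0)
    return q10, vops


class TestMoo:
    def test_front_is_mutually_non_dominated(self, fieldset4, sar_sets):
        q10, vops = sar_sets
        front = shim_moo(fieldset4, fieldset4.phantom.roi_mask, vops, q10,
                         ga_config=FAST_GA, seed=0)
        f = np.column_stack([-front.min_b1, front.max_sar_vop])
        for i in range(len(f)):
            for j in range(len(f)):
                if i != j:
                    dominated = np.all(f[j] <= f[i]) and np.any(f[j] < f[i])
                    assert not dominated

    def test_front_sorted_by_sar_has_nondecreasing_min_b1(self, fieldset4,
                                                          sar_sets):
        q10, vops = sar_sets
        front = shim_moo(fieldset4, fieldset4.phantom.roi_mask, vops, q10,
                         ga_config=FAST_GA, seed=1)
        order = np.argsort(front.max_sar_vop)
        assert np.all(np.diff(front.min_b1[order]) >= -1e-9)

    def test_selected_point_maximizes_the_sar_normalized_min_b1(
            self, fieldset4, sar_sets):
        q10, vops = sar_sets
        front = shim_moo(fieldset4, fieldset4.phantom.roi_mask, vops, q10,
                         ga_config=FAST_GA, seed=2)
        score = front.min_b1 / np.sqrt(front.max_sar_full)
        assert front.selected == int(np.argmax(score))
        # VOP bound dominates the uncompressed re-evaluation
        assert np.all(front.max_sar_vop >= front.max_sar_full * (1 - 1e-9))

    def test_single_channel_front_collapses(self, fieldset3, tiny_phantom):
        fs1 = dataclasses.replace(
            fieldset3,
            b1_plus=fieldset3.b1_plus[:1], b1_minus=fieldset3.b1_minus[:1],
            e_field=fieldset3.e_field[:1],
        )
        q10 = average_10g(build_q_matrices(fs1), tiny_phantom,
                          frequency=fs1.frequency)
        vops = compress_vop(q10, 15.0, seed=0)
        front = shim_moo(fs1, tiny_phantom.roi_mask, vops, q10,
                         mode="phase-only",
                         ga_config=GAConfig(population=20, generations=10),
                         seed=0)
        assert len(front.min_b1) == 1
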