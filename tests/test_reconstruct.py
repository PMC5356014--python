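"""Reconstruction core: rational approximation, lattice segmentation,
reference restoration, background suppression, HR resampling, baselines."""

import math
from dataclasses import replace
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pixelsr as px
from pixelsr.register import _estimate_from_ratio
from pixelsr.reconstruct import (InsufficientDataError, ReconParams,
                                 baseline_align, baseline_ets, pixel_sr,
                                 rational_approx, resample_hr,
                                 restore_reference, rmse_vs_truth,
                                 segment_lines, suppress_background,
                                 WarpedPointCloud, matched_filter_sigmas)


def exhaustive_best_rational(alpha: float, max_den: int):
    best = None
    for r in range(1, max_den + 1):
        p = round(alpha * r)
        err = abs(alpha - p / r)
        if best is None or err < best[0] - 1e-15:
            best = (err, p, r)
    return best[1], best[2]


class TestRationalApprox:
    @pytest.mark.parametrize("alpha, max_den, expected", [
        (0.25, 10, (1, 4)),
        (0.5075, 100, (34, 67)),     # frozen from the exhaustive oracle
        (0.3, 1, (0, 1)),
        (0.7, 1, (1, 1)),
        (1.0, 5, (1, 1)),
    ])
    def test_documented_examples(self, alpha, max_den, expected):
        assert rational_approx(alpha, max_den) == expected

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(alpha=st.floats(1e-6, 1.0), max_den=st.integers(1, 150))
    def test_matches_exhaustive_search(self, alpha, max_den):
        p, r = rational_approx(alpha, max_den)
        pe, re_ = exhaustive_best_rational(alpha, max_den)
        assert r <= max_den
        assert abs(alpha - p / r) <= abs(alpha - pe / re_) + 1e-15

    def test_exact_rationals_recovered(self):
        for frac in (Fraction(3, 7), Fraction(5, 8), Fraction(13, 64)):
            p, r = rational_approx(float(frac), 64)
            assert Fraction(p, r) == frac


class TestSegmentLines:
    def test_point_count_equals_sample_count(self, scene_record, registered):
        cloud = segment_lines(scene_record, registered)
        assert cloud.value.size == scene_record.samples.size
        assert np.array_equal(cloud.value, scene_record.samples)

    def test_integer_ratio_gives_rectangular_lattice(self, cfg_small):
        cfg_locked = replace(cfg_small, f=cfg_small.F * 430)
        rec = px.synth_record(None, cfg_locked, noise_sd=0.0, seed=1)
        cloud = segment_lines(rec, _estimate_from_ratio(rec, 430.0))
        xs = np.unique(np.round(cloud.x[:430 * 4] % cloud.geometry.dx, 9))
        assert xs.size <= 430

    def test_positions_match_simulator_bookkeeping(self, scene_record):
        """With the true ratio, x positions equal the simulator's own."""
        gt = scene_record.ground_truth
        cloud = segment_lines(scene_record,
                              _estimate_from_ratio(scene_record, gt.ratio))
        geom = cloud.geometry
        k = np.arange(scene_record.samples.size)
        m = np.floor(k / gt.ratio).astype(np.int64)
        x_true = (k - m * gt.ratio) * geom.dx
        assert np.allclose(cloud.x, x_true, atol=1e-9)

    def test_short_record_rejected(self, cfg_small):
        rec = px.RawRecord(samples=np.ones(100), config=cfg_small)
        with pytest.raises(InsufficientDataError):
            segment_lines(rec, _estimate_from_ratio(rec, cfg_small.ratio))


class TestRestoreReference:
    def test_q1_reference_matches_average_line(self, background_record):
        est = px.register(background_record)
        ref = restore_reference(background_record, est, 1)
        gt = background_record.ground_truth
        truth = np.interp(ref.x, gt.envelope_x, gt.envelope,
                          period=ref.line_length)
        assert np.sqrt(np.mean((ref.values - truth) ** 2)) < 0.02

    @pytest.mark.parametrize("q", [2, 3, 4, 5])
    def test_sinusoid_beyond_single_line_nyquist(self, q):
        """Noise-free equivalent-time sampling recovers a sinusoid at 0.8 of
        the fine-grid Nyquist with < 1% relative RMSE (closed-form oracle)."""
        from pixelsr.experiments import ets_oracle
        assert ets_oracle(qs=(q,), seed=0)[q] < 0.01

    def test_locked_clock_degrades_to_upsampled_line(self, cfg_small):
        cfg_locked = replace(cfg_small, f=cfg_small.F * 430)
        rec = px.synth_record(None, cfg_locked, noise_sd=0.0, seed=1)
        est = _estimate_from_ratio(rec, 430.0)
        ref = restore_reference(rec, est, 4, robust=False)
        assert ref.n_phases == 1
        assert not ref.coverage_ok
        assert np.all(np.isfinite(ref.values))

    def test_too_many_reference_lines_rejected(self, background_record):
        est = px.register(background_record)
        with pytest.raises(InsufficientDataError):
            restore_reference(background_record, est, 4, n_ref_lines=10_000)


class TestSuppressBackground:
    def test_background_only_residual_near_zero(self, background_record):
        est = px.register(background_record)
        cloud = segment_lines(background_record, est)
        ref = restore_reference(background_record, est, 4)
        out = suppress_background(cloud, ref, mode="subtract")
        assert abs(out.value.mean()) < 3 * 0.01 / math.sqrt(out.value.size) + 2e-3

    def test_divide_recovers_transmittance(self, scene_record, registered):
        cloud = segment_lines(scene_record, registered)
        ref = restore_reference(scene_record, registered, 4)
        out = suppress_background(cloud, ref, mode="divide")
        gt = scene_record.ground_truth
        # samples inside the object should sit near the blurred transmittance
        inside = (np.abs(cloud.x - (gt.x_offset + 32)) < 2) \
            & (np.abs(cloud.y - gt.scene.objects[0].center[1]) < 1)
        assert 0.2 < out.value[inside].mean() < 0.8

    def test_zero_reference_subtract_is_identity(self, scene_record, registered):
        cloud = segment_lines(scene_record, registered)
        ref = restore_reference(scene_record, registered, 1)
        zero = replace_values(ref, np.zeros_like(ref.values))
        out = suppress_background(cloud, zero, mode="subtract")
        assert np.array_equal(out.value, cloud.value)

    def test_divide_by_near_zero_reference_rejected(self, scene_record,
                                                    registered):
        cloud = segment_lines(scene_record, registered)
        ref = restore_reference(scene_record, registered, 1)
        bad = replace_values(ref, np.zeros_like(ref.values))
        with pytest.raises(ValueError):
            suppress_background(cloud, bad, mode="divide")


def replace_values(ref, values):
    from dataclasses import replace as dc_replace
    return dc_replace(ref, values=values)


class TestResampleHR:
    def test_uniform_cloud_reproduces_constant(self, cfg):
        geom = px.geometry(cfg)
        rng = np.random.default_rng(0)
        n = 4000
        cloud = WarpedPointCloud(
            x=rng.uniform(0, 50, n), y=rng.uniform(0, 20, n),
            value=np.full(n, 3.14), geometry=geom, line_length=50.0)
        img = resample_hr(cloud, ReconParams(q=4), cfg)
        assert np.allclose(img.grid, 3.14, atol=1e-9)

    def test_single_point_blob_centered_on_value(self, cfg):
        geom = px.geometry(cfg)
        cloud = WarpedPointCloud(
            x=np.array([10.0]), y=np.array([5.0]), value=np.array([2.0]),
            geometry=geom, line_length=20.0)
        img = resample_hr(cloud, ReconParams(q=4), cfg)
        row = int((5.0 - img.origin[1]) / img.pitch_y)
        col = int(10.0 / img.pitch_x)
        assert img.grid[row, col] == pytest.approx(2.0, rel=1e-6)

    def test_weighted_average_bounded_by_input_range(self, scene_record,
                                                     registered):
        cloud = segment_lines(scene_record, registered)
        img = resample_hr(cloud, ReconParams(q=4), scene_record.config)
        assert img.grid.min() >= cloud.value.min() - 1e-9
        assert img.grid.max() <= cloud.value.max() + 1e-9

    def test_empty_cloud_rejected(self, cfg):
        geom = px.geometry(cfg)
        cloud = WarpedPointCloud(x=np.empty(0), y=np.empty(0),
                                 value=np.empty(0), geometry=geom)
        with pytest.raises(ValueError):
            resample_hr(cloud, ReconParams(q=4), cfg)

    def test_matched_filter_widths(self, cfg):
        sx, sy = matched_filter_sigmas(cfg)
        # d_opt = 2 μm dominates the 10 GHz bandwidth limit (0.89 μm)
        assert sx == pytest.approx(2.0 / 2.355, rel=1e-6)
        assert sy == pytest.approx(2.0 / 2.355, rel=1e-6)


class TestPipelines:
    def test_pixel_sr_attaches_provenance(self, scene_record, registered):
        img = pixel_sr(scene_record, ReconParams(bg_mode="divide"),
                       estimate=registered)
        assert img.provenance["method"] == "pixel_sr"
        assert img.provenance["q"] == 4
        assert img.pitch_x == pytest.approx(3.55 / 4, rel=1e-6)

    def test_align_keeps_one_row_per_line(self, scene_record, registered):
        img = baseline_align(scene_record, registered,
                             ReconParams(bg_mode="divide"))
        geom = px.geometry(scene_record.config)
        assert img.grid.shape[0] == scene_record.n_lines - 1 \
            or img.grid.shape[0] == scene_record.n_lines
        assert img.pitch_y == pytest.approx(geom.dy)

    def test_ets_collapses_rows_q_fold(self, scene_record, registered):
        img = baseline_ets(scene_record, registered, 4,
                           ReconParams(bg_mode="divide"))
        n_lines = int(scene_record.samples.size // registered.ratio)
        assert img.grid.shape[0] == n_lines // 4
        geom = px.geometry(scene_record.config)
        assert img.pitch_y == pytest.approx(4 * geom.dy)
        with pytest.raises(ValueError):
            baseline_ets(scene_record, registered, 1)

    def test_locked_clock_sr_reduces_to_align(self, cfg_small):
        """No drift → no sub-pixel information → SR ≈ naive alignment."""
        cfg_locked = replace(cfg_small, f=cfg_small.F * 430)
        geom = px.geometry(cfg_locked)
        h = cfg_locked.n_lines * geom.dy
        obj = px.SceneObject("disk", (16.0, h / 2), (3.5, 3.5), 0, 0.5)
        scene = px.SceneSpec(32.0, h, (obj,))
        rec = px.synth_record(scene, cfg_locked, noise_sd=0.0, seed=2)
        est = _estimate_from_ratio(rec, 430.0)
        params = ReconParams(bg_mode="divide", q=4)
        sr = pixel_sr(rec, params, estimate=est)
        al = baseline_align(rec, est, params)
        # compare on the SR grid within the field; the align rows first get
        # the same matched filter the SR resampler applies
        from scipy import ndimage
        sx, sy = matched_filter_sigmas(cfg_locked)
        al_s = ndimage.gaussian_filter(
            al.grid, (sy / al.pitch_y, sx / al.pitch_x), mode="nearest")
        gt = rec.ground_truth
        sel = (sr.x >= gt.x_offset) & (sr.x <= gt.x_offset + 32)
        rows = np.clip((sr.y / al.pitch_y).astype(int), 0, al.grid.shape[0] - 1)
        diff = sr.grid[:, sel] - al_s[rows][:, sel]
        # the two pipelines interpolate the empty columns differently
        # (kernel normalization vs linear prefill), so equality is approximate
        assert np.sqrt((diff ** 2).mean()) < 0.03

    def test_sr_beats_align_on_super_nyquist_scene(self, scene_record,
                                                   registered):
        params = ReconParams(bg_mode="divide")
        sig = matched_filter_sigmas(scene_record.config)
        sr = pixel_sr(scene_record, params, estimate=registered)
        al = baseline_align(scene_record, registered, params)
        r_sr = rmse_vs_truth(scene_record, sr, target_sigmas=sig)
        r_al = rmse_vs_truth(scene_record, al, target_sigmas=sig)
        assert r_sr < r_al
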