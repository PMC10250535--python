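"""Optical pipeline stages on analytic fixtures and small phantoms."""

import numpy as np
import pytest

from epicard.optical import (APDMap, VoltageMovie, activation_map, apd_map,
                             detrend, ensemble_average, process_movie,
                             segment_rois, spatial_filter,
                             transmural_gradient)
from epicard.phantom import ap_kernel, male_like_config, generate_movie
from epicard.traces import APTrace


def _cycle_movie(n_beats=4, L=100, size=8, noise_sd=0.0, seed=0):
    """Tiny movie of identical repeated kernel cycles (+ optional noise)."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_beats * L, dtype=float)
    sig = ap_kernel((t - 10.0) % L, 40.0)
    frames = np.tile(sig[:, None, None], (1, size, size)).astype(np.float32)
    if noise_sd > 0:
        frames = frames + noise_sd * rng.standard_normal(frames.shape).astype(
            np.float32)
    mask = np.ones((size, size), dtype=bool)
    return VoltageMovie(frames, mask, frame_interval=1.0, pixel_size=0.05,
                        pacing_cycle=float(L))


# ---------------------------------------------------------------------------
# ensemble averaging
# ---------------------------------------------------------------------------
def test_ensemble_average_of_identical_cycles_is_one_cycle():
    movie = _cycle_movie()
    out = ensemble_average(movie, 4)
    assert out.n_frames == 100
    # exactly periodic movie: the average equals one cycle (some rotation)
    matched = any(
        np.allclose(out.frames,
                    np.roll(movie.frames[:100], -s, axis=0), atol=1e-5)
        for s in range(100)
    )
    assert matched


def test_ensemble_average_single_beat_idempotent():
    movie = _cycle_movie(n_beats=1)
    out = ensemble_average(movie, 1)
    np.testing.assert_allclose(out.frames, movie.frames, atol=1e-6)


def test_ensemble_average_rejects_short_movies():
    movie = _cycle_movie(n_beats=2)
    with pytest.raises(ValueError):
        ensemble_average(movie, 3)


def test_ensemble_average_detects_misaligned_pacing():
    movie = _cycle_movie(n_beats=4)
    frames = movie.frames.copy()
    # replace the last cycle by an uncorrelated signal
    rng = np.random.default_rng(1)
    frames[300:] = rng.standard_normal(frames[300:].shape).astype(np.float32)
    bad = VoltageMovie(frames, movie.mask, pacing_cycle=100.0)
    with pytest.raises(ValueError, match="misaligned|cycle"):
        ensemble_average(bad, 4)


def test_ensemble_average_noise_reduction_scales_as_sqrt_n():
    """Averaging 16 beats reduces white noise about four-fold."""
    ratios = []
    for seed in range(5):
        clean = _cycle_movie(n_beats=16, noise_sd=0.0)
        noisy = _cycle_movie(n_beats=16, noise_sd=0.1, seed=seed)
        avg = ensemble_average(noisy, 16)
        resid = avg.frames - clean.frames[:100]
        ratios.append(resid.std() / 0.1)
    assert np.mean(ratios) == pytest.approx(0.25, rel=0.10)


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------
def _single_ap_trace(apd90=60.0, L=200, delay=30.0):
    t = np.arange(L, dtype=float)
    return ap_kernel(t - delay, apd90)


def test_detrend_removes_injected_linear_ramp():
    v = _single_ap_trace()
    ramp = 0.4 * np.arange(v.size) / v.size
    out = detrend(APTrace(1.0, v + ramp), poly_order=1)
    assert np.max(np.abs(out.values - v)) < 0.01  # 1% of unit amplitude


def test_detrend_leaves_driftless_trace_unchanged():
    v = _single_ap_trace()
    out = detrend(APTrace(1.0, v), poly_order=3)
    assert np.max(np.abs(out.values - v)) < 0.01


def test_detrend_order0_removes_constant_offset():
    v = _single_ap_trace() + 7.5
    out = detrend(APTrace(1.0, v), poly_order=0)
    assert np.max(np.abs(out.values - _single_ap_trace())) < 0.01


def test_detrend_short_trace_raises():
    with pytest.raises(ValueError):
        detrend(APTrace(1.0, np.array([0.0, 1.0, 0.0])), poly_order=3)


# ---------------------------------------------------------------------------
# spatial filtering
# ---------------------------------------------------------------------------
def test_spatial_filter_uniform_frame_unchanged():
    frames = np.full((3, 6, 6), 2.5, dtype=np.float32)
    mask = np.ones((6, 6), dtype=bool)
    out = spatial_filter(VoltageMovie(frames, mask, pacing_cycle=3.0))
    np.testing.assert_allclose(out.frames, frames, atol=1e-6)


def test_spatial_filter_impulse_kernel_arithmetic():
    frames = np.zeros((1, 7, 7), dtype=np.float32)
    frames[0, 3, 3] = 9.0
    mask = np.ones((7, 7), dtype=bool)
    out = spatial_filter(VoltageMovie(frames, mask, pacing_cycle=1.0))
    assert out.frames[0, 3, 3] == pytest.approx(1.0, abs=1e-6)
    assert out.frames[0, 2, 3] == pytest.approx(1.0, abs=1e-6)


def test_spatial_filter_does_not_bleed_across_mask():
    frames = np.zeros((1, 7, 7), dtype=np.float32)
    frames[0, 3, 3] = 9.0
    mask = np.zeros((7, 7), dtype=bool)
    mask[3, :] = True  # single-row tissue
    out = spatial_filter(VoltageMovie(frames, mask, pacing_cycle=1.0))
    # out-of-mask pixels untouched; in-mask average uses 3 in-mask neighbors
    assert out.frames[0, 2, 3] == 0.0
    assert out.frames[0, 3, 3] == pytest.approx(3.0, abs=1e-6)


def test_spatial_filter_reduces_checkerboard_variance():
    rng = np.random.default_rng(0)
    frames = rng.standard_normal((2, 32, 32)).astype(np.float32)
    mask = np.ones((32, 32), dtype=bool)
    out = spatial_filter(VoltageMovie(frames, mask, pacing_cycle=2.0))
    interior = out.frames[:, 8:24, 8:24]
    ratio = interior.var() / frames[:, 8:24, 8:24].var()
    assert ratio == pytest.approx(1.0 / 9.0, rel=0.25)


# ---------------------------------------------------------------------------
# maps
# ---------------------------------------------------------------------------
def test_uniform_phantom_apd_map_recovers_69ms():
    """Zero-noise phantom with uniform APD90 of 69 ms maps to 69 +- 0.5.

    Evaluated on interior pixels (full 3x3 filter neighbourhoods); mask
    boundary pixels see one-sided neighbourhoods of time-shifted
    waveforms and are excluded from quantitative regions throughout the
    pipeline (cf. the transmural ray margins).
    """
    from scipy import ndimage
    cfg = male_like_config(seed=0, apd_slope_ms_per_mm=0.0,
                           apd_jitter_ms=0.0, noise_sd=0.0, n_beats=2,
                           image_size=96, outer_radius_mm=2.0,
                           inner_radius_mm=1.2)
    movie, truth = generate_movie(cfg)
    result = process_movie(movie)
    interior = ndimage.binary_erosion(movie.mask, np.ones((3, 3)))
    vals = result["apd_map"].masked_values(interior)
    assert vals.size > 1000
    assert np.all(np.abs(vals - 69.0) <= 0.5)


def test_apd_map_defined_only_inside_mask():
    cfg = male_like_config(seed=1, n_beats=2, image_size=96,
                           outer_radius_mm=2.0, inner_radius_mm=1.2)
    movie, _ = generate_movie(cfg)
    result = process_movie(movie)
    outside = ~movie.mask
    assert np.all(np.isnan(result["apd_map"].values[outside]))
    assert np.all(np.isnan(result["activation_map"].values[outside]))


def test_activation_map_increases_away_from_stimulus():
    cfg = male_like_config(seed=2, n_beats=2, image_size=96,
                           outer_radius_mm=2.0, inner_radius_mm=1.2,
                           noise_sd=0.02)
    movie, truth = generate_movie(cfg)
    result = process_movie(movie)
    act = result["activation_map"]
    sel = act.qc_pass & np.isfinite(truth["activation"])
    err = act.values[sel] - truth["activation"][sel]
    err -= err.mean()  # window offset is arbitrary
    assert np.sqrt((err ** 2).mean()) < 1.0


# ---------------------------------------------------------------------------
# segmentation and gradient
# ---------------------------------------------------------------------------
def _annulus_mask(size=128, r_out=50, r_in=28):
    c = (size - 1) / 2
    rr, cc = np.indices((size, size))
    r = np.hypot(rr - c, cc - c)
    return (r >= r_in) & (r <= r_out)


def test_epicardial_third_area_fraction_of_sector():
    mask = _annulus_mask()
    rois = segment_rois(mask, sector=(0.0, 90.0), pixel_size=0.05)
    r_out, r_in = 50.0, 28.0
    r23 = r_in + 2.0 / 3.0 * (r_out - r_in)
    expected = (r_out ** 2 - r23 ** 2) / (r_out ** 2 - r_in ** 2)
    got = rois.epicardial_third.sum() / rois.lv_free_wall.sum()
    assert got == pytest.approx(expected, rel=0.05)
    assert np.all(rois.lv_free_wall[rois.epicardial_third])


def test_rays_ordered_endo_to_epi():
    rois = segment_rois(_annulus_mask(), pixel_size=0.05)
    assert len(rois.rays) >= 10
    for ray in rois.rays:
        depths = [d for _, _, d in ray]
        assert all(b >= a for a, b in zip(depths, depths[1:]))
        assert depths[0] >= 0.0


def test_papillary_bump_excluded_from_free_wall():
    cfg = male_like_config(seed=0, papillary_bumps=((45.0, 0.35),),
                           noise_sd=0.0, n_beats=2)
    movie, truth = generate_movie(cfg)
    rois = segment_rois(movie.mask, pixel_size=cfg.pixel_size_mm)
    bump = truth["papillary"]
    assert bump.sum() > 0
    overlap = (rois.lv_free_wall & bump).sum() / bump.sum()
    assert overlap < 0.25


def test_segmentation_requires_cavity():
    mask = np.zeros((64, 64), dtype=bool)
    mask[10:50, 10:50] = True  # solid block, no cavity
    with pytest.raises(ValueError, match="cavity"):
        segment_rois(mask)


def test_uniform_apd_map_has_zero_gradient():
    mask = _annulus_mask()
    rois = segment_rois(mask, pixel_size=0.05)
    amap = APDMap(values=np.where(mask, 70.0, np.nan), level_percent=90,
                  qc_pass=mask)
    grad, slopes = transmural_gradient(amap, rois)
    assert grad == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(slopes, 0.0)


def test_gradient_requires_enough_rays():
    mask = _annulus_mask()
    rois = segment_rois(mask, pixel_size=0.05, n_rays=12)
    amap = APDMap(values=np.where(mask, np.nan, np.nan), level_percent=90,
                  qc_pass=np.zeros_like(mask))
    with pytest.raises(ValueError, match="rays"):
        transmural_gradient(amap, rois)
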