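"""Phantom generator: determinism, ground-truth fidelity, cohorts."""

import numpy as np
import pytest

from epicard.phantom import (PhantomConfig, ap_kernel, female_like_config,
                             generate_cohort, generate_movie, kernel_apd,
                             male_like_config)
from epicard.traces import APTrace, apd


def test_same_seed_gives_bit_identical_movies():
    cfg = male_like_config(seed=11, n_beats=2, image_size=64,
                           outer_radius_mm=1.3, inner_radius_mm=0.7)
    a, _ = generate_movie(cfg)
    b, _ = generate_movie(cfg)
    np.testing.assert_array_equal(a.frames, b.frames)
    c, _ = generate_movie(cfg.replace(seed=12))
    assert not np.array_equal(a.frames, c.frames)


def test_kernel_apd90_is_exact_by_construction():
    for target in (40.0, 69.0, 85.0):
        t = np.arange(0.0, 200.0, 0.01)
        v = ap_kernel(t - 20.0, target)
        assert apd(APTrace(0.01, v), 90) == pytest.approx(target, abs=0.02)
        # other levels agree with the closed-form kernel widths
        assert apd(APTrace(0.01, v), 50) == pytest.approx(
            kernel_apd(target, 50), abs=0.02)


def test_kernel_varies_only_repolarization_phase():
    """Upstroke is shared; only the falling phase stretches with APD."""
    t = np.arange(0.0, 5.0, 0.01)
    short = ap_kernel(t, 40.0)
    long_ = ap_kernel(t, 80.0)
    np.testing.assert_allclose(short[t <= 2.0], long_[t <= 2.0], atol=1e-12)


def test_invalid_geometry_rejected():
    with pytest.raises(ValueError):
        PhantomConfig(inner_radius_mm=2.0, outer_radius_mm=1.5)
    with pytest.raises(ValueError):
        PhantomConfig(outer_radius_mm=4.0, image_size=64)  # does not fit
    with pytest.raises(ValueError):
        PhantomConfig(noise_sd=-0.1)


def test_truth_maps_follow_configured_gradient():
    cfg = male_like_config(seed=0, apd_jitter_ms=0.0)
    _, truth = generate_movie(cfg)
    apd90 = truth["apd90"]
    depth = truth["depth_mm"]
    sel = np.isfinite(apd90) & np.isfinite(depth)
    slope = np.polynomial.polynomial.polyfit(depth[sel], apd90[sel], 1)[1]
    assert slope == pytest.approx(cfg.apd_slope_ms_per_mm, rel=1e-6)
    wall = cfg.outer_radius_mm - cfg.inner_radius_mm
    at_epi = apd90[sel][np.argmax(depth[sel])]
    assert at_epi == pytest.approx(
        cfg.apd_epi_ms + cfg.apd_slope_ms_per_mm * (depth[sel].max() - wall),
        abs=1e-6)


def test_female_like_defaults_longer_and_flatter():
    m, f = male_like_config(), female_like_config()
    assert f.apd_epi_ms > m.apd_epi_ms
    assert abs(f.apd_slope_ms_per_mm) < abs(m.apd_slope_ms_per_mm)


def test_group_truth_ordering_male_vs_female():
    """Group-level phantom maps preserve the configured ordering."""
    mm, mt = generate_movie(male_like_config(seed=5))
    fm, ft = generate_movie(female_like_config(seed=5))
    epi_sel_m = mt["depth_mm"] > 0.8
    epi_sel_f = ft["depth_mm"] > 0.8
    assert (np.nanmean(ft["apd90"][epi_sel_f])
            > np.nanmean(mt["apd90"][epi_sel_m]))


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------
def test_cohort_zero_variance_collapses_to_group_means():
    df = generate_cohort({"a": 60.0, "b": 75.0}, n_animals=3,
                         slices_per_animal=2, between_sd=0.0, within_sd=0.0,
                         seed=0)
    assert np.allclose(df[df.group == "a"]["value"], 60.0)
    assert np.allclose(df[df.group == "b"]["value"], 75.0)
    assert len(df) == 12


def test_cohort_seeded_determinism():
    a = generate_cohort({"g": 70.0}, 4, seed=9)
    b = generate_cohort({"g": 70.0}, 4, seed=9)
    assert a.equals(b)


def test_cohort_requires_two_animals():
    with pytest.raises(ValueError):
        generate_cohort({"g": 70.0}, 1)


def test_cohort_grand_mean_is_unbiased():
    """Monte Carlo: the sample grand mean matches the group mean within
    3 standard errors."""
    means = []
    for seed in range(300):
        df = generate_cohort({"g": 69.0}, n_animals=6, slices_per_animal=2,
                             between_sd=3.0, within_sd=1.5, seed=seed)
        means.append(df.groupby("animal")["value"].mean().mean())
    se = np.std(means) / np.sqrt(len(means))
    assert np.mean(means) == pytest.approx(69.0, abs=3 * se + 1e-9)


def test_between_animal_sd_increases_group_cov():
    """Larger between-animal SD raises the expected animal-level CV."""
    def mean_cv(between_sd):
        cvs = []
        for seed in range(200):
            df = generate_cohort({"g": 69.0}, n_animals=6,
                                 slices_per_animal=2,
                                 between_sd=between_sd, within_sd=1.0,
                                 seed=seed)
            vals = df.groupby("animal")["value"].mean()
            cvs.append(vals.std(ddof=1) / vals.mean())
        return np.mean(cvs)

    cv1, cv2, cv3 = (mean_cv(b) for b in (1.0, 3.0, 8.0))
    assert cv1 < cv2 < cv3
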