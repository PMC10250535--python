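"""AP feature extraction: closed forms, invariances, dense-grid oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epicard.traces import (APTrace, UnrepolarizedError, activation_time,
                            ap_features, apd, normalize_polarity,
                            percent_change)


def triangle_trace(dt=0.1, rise=10.0, fall=10.0, base=0.0, peak=1.0,
                   pad=40.0):
    """Symmetric triangular pulse with closed-form widths."""
    t = np.arange(0.0, rise + fall + 2 * pad + dt / 2, dt)
    v = np.full_like(t, base)
    up = (t >= pad) & (t < pad + rise)
    v[up] = base + (peak - base) * (t[up] - pad) / rise
    dn = (t >= pad + rise) & (t <= pad + rise + fall)
    v[dn] = peak - (peak - base) * (t[dn] - pad - rise) / fall
    return APTrace(dt=dt, values=v)


@pytest.mark.parametrize("level,expected", [(90, 18.0), (50, 10.0)])
def test_triangle_widths_closed_form(level, expected):
    tr = triangle_trace()
    assert apd(tr, level) == pytest.approx(expected, abs=1e-6)


def test_apd_monotone_in_level():
    tr = triangle_trace()
    levels = [10, 30, 50, 80, 90, 95]
    widths = [apd(tr, lv) for lv in levels]
    assert all(w1 <= w2 + 1e-12 for w1, w2 in zip(widths, widths[1:]))


def test_apd_features_ordering(baseline_last_ap):
    f = ap_features(baseline_last_ap)
    assert f.APD30 <= f.APD50 <= f.APD80 <= f.APD90
    assert f.amplitude > 60.0


@settings(derandomize=True, max_examples=25, deadline=None)
@given(gain=st.floats(0.01, 50.0), offset=st.floats(-100.0, 100.0))
def test_apd_invariant_under_affine_transform(gain, offset):
    """Gain/offset invariance: mV traces and normalized fluorescence
    measure identically."""
    tr = triangle_trace()
    scaled = APTrace(dt=tr.dt, values=gain * tr.values + offset)
    assert apd(scaled, 80) == pytest.approx(apd(tr, 80), abs=1e-9)


def test_apd_unrepolarized_raises():
    tr = triangle_trace()
    cut = APTrace(dt=tr.dt, values=tr.values[: int(45 / tr.dt)])
    with pytest.raises(UnrepolarizedError):
        apd(cut, 90)


def test_apd_level_validation():
    tr = triangle_trace()
    for bad in (0, 100, -5, 150):
        with pytest.raises(ValueError):
            apd(tr, bad)


def test_activation_time_of_step():
    dt = 0.5
    t37 = 37.0
    t = np.arange(0.0, 80.0, dt)
    v = np.where(t >= t37, 1.0, 0.0)
    assert activation_time(APTrace(dt=dt, values=v)) == pytest.approx(
        t37 - dt / 2, abs=dt / 2 + 1e-9)


def test_activation_time_shift_equivariance():
    tr = triangle_trace()
    a0 = activation_time(tr)
    assert activation_time(tr.shifted(13.25)) == pytest.approx(a0 + 13.25)


def test_activation_time_flat_trace_raises():
    with pytest.raises(ValueError):
        activation_time(APTrace(dt=1.0, values=np.zeros(50)))


def test_activation_time_matches_native_resolution(baseline_train):
    """Max-dV/dt time at 1 ms agrees with the native solver sampling
    within 1 ms."""
    from epicard.simulate import last_ap

    native = APTrace(dt=baseline_train.dt,
                     values=baseline_train.values[-2000:])
    optical = last_ap(baseline_train, 5.0)
    assert activation_time(optical) == pytest.approx(
        activation_time(native), abs=1.0)


def test_apd_agrees_with_dense_grid_crossing_oracle(baseline_last_ap):
    """APD against a brute-force threshold-crossing scan at 0.01 ms."""
    tr = baseline_last_ap
    dense = tr.resample(0.01)
    for level in (30, 50, 80, 90):
        v = dense.values
        peak = int(np.argmax(v))
        base = v[: max(peak - 1, 1)].min()
        thr = base + (1 - level / 100.0) * (v[peak] - base)
        above = v >= thr
        i_up = np.argmax(above)
        i_dn = peak + np.argmax(~above[peak:])
        width = (i_dn - i_up) * dense.dt
        assert apd(tr, level) == pytest.approx(width, abs=0.5)


@pytest.mark.parametrize("p,c,expected", [(128, 100, 28.0), (7, 7, 0.0),
                                          (50, 100, -50.0)])
def test_percent_change_values(p, c, expected):
    assert percent_change(p, c) == pytest.approx(expected)


def test_percent_change_zero_control():
    with pytest.raises(ValueError):
        percent_change(1.0, 0.0)


def test_normalize_polarity_flips_inverted_deflection():
    tr = triangle_trace()
    inverted = 2.0 * np.median(tr.values) - tr.values
    restored = normalize_polarity(inverted)
    assert np.argmax(restored) == np.argmax(tr.values)
    # positive-going traces are untouched
    np.testing.assert_array_equal(normalize_polarity(tr.values), tr.values)


def test_aptrace_validation():
    with pytest.raises(ValueError):
        APTrace(dt=0.0, values=np.ones(10))
    with pytest.raises(ValueError):
        APTrace(dt=1.0, values=np.array([1.0, np.nan]))
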