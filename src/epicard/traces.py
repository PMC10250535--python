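"""Action-potential feature extraction.

Works identically on simulated membrane-potential traces (mV) and on
normalized fluorescence traces, because every measurement is affine
invariant: the AP amplitude is peak minus diastolic baseline, and APD at
X% repolarization is the width of the AP at the threshold
``baseline + (1 - X/100) * amplitude``, with sub-sample linear
interpolation at both crossings.

The diastolic baseline is the minimum over the 30 ms window preceding the
upstroke; if the trace starts essentially at the upstroke (as a window cut
at the stimulus does) the global trace minimum is used instead. APD is
measured from the upward threshold crossing, not from the activation time,
so simulated and optically recorded APs are compared like-for-like.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASELINE_WINDOW_MS = 30.0


class UnrepolarizedError(ValueError):
    """The trace never re-crosses the repolarization threshold."""


@dataclass
class APTrace:
    """Uniformly sampled single- or multi-beat trace.

    Attributes
    ----------
    dt : float
        Sample interval (ms).
    values : ndarray
        Membrane potential (mV) or normalized fluorescence.
    t0 : float
        Time offset of the first sample (ms).
    """

    dt: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace must be a 1-D array with >= 2 samples")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.dt * (self.values.size - 1)

    def resample(self, dt: float) -> "APTrace":
        """Resample by linear interpolation onto a uniform ``dt`` grid."""
        if not dt > 0:
            raise ValueError(f"dt must be positive, got {dt}")
        n = int(np.floor(self.duration / dt)) + 1
        t_new = self.t0 + dt * np.arange(n)
        return APTrace(dt=dt, values=np.interp(t_new, self.t, self.values),
                       t0=self.t0)

    def shifted(self, delta: float) -> "APTrace":
        return APTrace(dt=self.dt, values=self.values.copy(),
                       t0=self.t0 + delta)


@dataclass
class APFeatures:
    """Scalar AP descriptors; APD30 <= APD50 <= APD80 <= APD90 by design."""

    APD30: float
    APD50: float
    APD80: float
    APD90: float
    activation_time: float
    amplitude: float
    baseline: float
    peak_time: float


def _peak_index(values: np.ndarray) -> int:
    i = int(np.argmax(values))
    if values[i] - values.min() <= 0:
        raise ValueError("flat trace: no AP peak found")
    return i


def _upstroke_index(values: np.ndarray, peak: int) -> int:
    """Sample index of the maximum forward difference up to the peak."""
    if peak == 0:
        return 0
    dv = np.diff(values[: peak + 1])
    return int(np.argmax(dv))


def _baseline(trace: APTrace, upstroke: int) -> float:
    n_pre = upstroke
    if n_pre >= 3:
        n_win = max(3, int(round(BASELINE_WINDOW_MS / trace.dt)))
        return float(np.min(trace.values[max(0, n_pre - n_win): n_pre]))
    return float(np.min(trace.values))


def _cross_up(t: np.ndarray, v: np.ndarray, thr: float, peak: int) -> float:
    """Time of the last upward threshold crossing at or before the peak."""
    below = np.flatnonzero(v[:peak] < thr)
    if below.size == 0:
        # trace starts above threshold: treat the first sample as the crossing
        return float(t[0])
    i = below[-1]
    f = (thr - v[i]) / (v[i + 1] - v[i])
    return float(t[i] + f * (t[i + 1] - t[i]))


def _cross_down(t: np.ndarray, v: np.ndarray, thr: float, peak: int) -> float:
    """Time of the first downward threshold crossing after the peak."""
    after = v[peak:]
    below = np.flatnonzero(after < thr)
    if below.size == 0:
        raise UnrepolarizedError(
            f"unrepolarized: trace never re-crosses threshold {thr:.4g}"
        )
    j = peak + below[0]
    f = (v[j - 1] - thr) / (v[j - 1] - v[j])
    return float(t[j - 1] + f * (t[j] - t[j - 1]))


def apd(trace: APTrace, level_percent: float) -> float:
    """AP duration (ms) at ``level_percent``% repolarization.

    The trace must contain exactly one AP (one dominant local maximum).
    Raises :class:`UnrepolarizedError` if repolarization to the level is
    never reached.
    """
    if not 0 < level_percent < 100:
        raise ValueError(f"level must be in (0, 100), got {level_percent}")
    v = trace.values
    t = trace.t
    peak = _peak_index(v)
    upstroke = _upstroke_index(v, peak)
    base = _baseline(trace, upstroke)
    amplitude = v[peak] - base
    if amplitude <= 0:
        raise ValueError("non-positive AP amplitude")
    thr = base + (1.0 - level_percent / 100.0) * amplitude
    return _cross_down(t, v, thr, peak) - _cross_up(t, v, thr, peak)


def activation_time(trace: APTrace) -> float:
    """Time (ms) of the maximum first temporal derivative of the upstroke.

    The discrete derivative maximum is refined by a parabolic fit through
    the three central-difference values around it.
    """
    v = trace.values
    peak = _peak_index(v)
    if peak == 0:
        raise ValueError("upstroke not contained in trace")
    dv = np.diff(v[: peak + 1]) / trace.dt
    i = int(np.argmax(dv))
    # mid-sample times of the forward differences
    t_mid = trace.t0 + trace.dt * (np.arange(dv.size) + 0.5)
    if 0 < i < dv.size - 1:
        denom = dv[i - 1] - 2.0 * dv[i] + dv[i + 1]
        if denom < 0:
            delta = 0.5 * (dv[i - 1] - dv[i + 1]) / denom
            return float(t_mid[i] + np.clip(delta, -0.5, 0.5) * trace.dt)
    return float(t_mid[i])


def ap_features(trace: APTrace) -> APFeatures:
    """All standard AP descriptors of a single-AP trace."""
    v = trace.values
    t = trace.t
    peak = _peak_index(v)
    upstroke = _upstroke_index(v, peak)
    base = _baseline(trace, upstroke)
    amplitude = float(v[peak] - base)
    if amplitude <= 0:
        raise ValueError("non-positive AP amplitude")
    apds = {}
    for level in (30, 50, 80, 90):
        thr = base + (1.0 - level / 100.0) * amplitude
        apds[level] = _cross_down(t, v, thr, peak) - _cross_up(t, v, thr, peak)
    return APFeatures(
        APD30=apds[30], APD50=apds[50], APD80=apds[80], APD90=apds[90],
        activation_time=activation_time(trace),
        amplitude=amplitude, baseline=base, peak_time=float(t[peak]),
    )


def percent_change(measure_perturbed: float, measure_control: float) -> float:
    """100 * (perturbed - control) / control."""
    if measure_control == 0:
        raise ValueError("control measure is zero; percent change undefined")
    return 100.0 * (measure_perturbed - measure_control) / measure_control


def normalize_polarity(values: np.ndarray) -> np.ndarray:
    """Flip a fluorescence trace so depolarization is a positive deflection.

    Voltage-sensitive dyes report depolarization as a *decrease* in
    fluorescence; the deflection direction is judged against the median.
    """
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    if med - values.min() > values.max() - med:
        return 2.0 * med - values
    return values
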