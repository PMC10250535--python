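"""Pacing protocols and in-silico perturbation experiments.

All protocols pace the single cell with a rectangular 1 ms inward current
pulse at 1.5x the baseline excitation threshold, the same relative
stimulus strength used for tissue pacing, and read AP features off the
last AP of a 5 s, 5 Hz train (25 beats), resampled to 1 ms -- the optical
mapping temporal resolution.

Integration uses the adaptive stiff LSODA solver (rtol 1e-6, atol 1e-8)
over stimulus-on / stimulus-off segments, so the discontinuous pulse never
falls inside a solver step. The solver settings are module constants and
fixed for reproducibility; repeated runs are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .model import INITIAL_STATE, IDX, pack_params, rhs
from .params import ModelParameters
from .traces import APTrace, UnrepolarizedError, ap_features, percent_change

logger = logging.getLogger(__name__)

RTOL = 1e-6
ATOL = 1e-8
DT_OUT = 0.1            # native output sampling, ms
DT_OPTICAL = 1.0        # measurement sampling, ms
MIN_AP_AMPLITUDE = 60.0  # mV; every stimulus must elicit at least this
STEADY_STATE_TOL_PCT = 1.0  # beat-to-beat APD80 agreement criterion
DEFAULT_FACTORS = tuple(np.round(np.arange(0.50, 1.5001, 0.05), 10))
DEFAULT_SHIFTS = (0.0, -5.0, -10.0, -15.0)

#: modifier ids accepted by the calibration and shift protocols
MODIFIER_IDS = ("Ktof", "Kur", "NaL")


class SubThresholdError(RuntimeError):
    """A pacing stimulus failed to elicit an action potential."""


def _apply_modifier(
    params: ModelParameters, modifier_id: str, factor: float
) -> ModelParameters:
    if modifier_id == "NaL":
        return params.with_k_reopen(factor)
    if modifier_id in ("Ktof", "Kur"):
        return params.with_scale(modifier_id, factor)
    raise ValueError(
        f"unknown modifier id {modifier_id!r}; expected one of {MODIFIER_IDS}"
    )


# ---------------------------------------------------------------------------
# core integration
# ---------------------------------------------------------------------------
def _segment_grid(t0: float, t1: float, dt: float) -> np.ndarray:
    n = max(1, int(round((t1 - t0) / dt)))
    return np.linspace(t0, t1, n + 1)


def integrate_beats(
    params: ModelParameters,
    n_beats: int,
    y0: np.ndarray | None = None,
    dt_out: float = DT_OUT,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate ``n_beats`` paced cycles; returns (t, states).

    The state is carried continuously across beats. Output samples lie on
    a uniform ``dt_out`` grid starting at the first stimulus onset.
    """
    if n_beats < 1:
        raise ValueError("need at least one beat")
    cl = params.cycle_length
    sd = params.stim_duration
    p_on = pack_params(params, params.stim_amplitude)
    p_off = pack_params(params, 0.0)
    y = INITIAL_STATE.copy() if y0 is None else np.asarray(y0, float).copy()

    t_all: list[np.ndarray] = []
    y_all: list[np.ndarray] = []
    for beat in range(n_beats):
        t_offset = beat * cl
        t1 = _segment_grid(0.0, sd, dt_out)
        sol1 = odeint(rhs, y, t1, args=(p_on,), rtol=RTOL, atol=ATOL,
                      tfirst=True, mxstep=200000)
        y = sol1[-1]
        t2 = _segment_grid(sd, cl, dt_out)
        sol2 = odeint(rhs, y, t2, args=(p_off,), rtol=RTOL, atol=ATOL,
                      tfirst=True, mxstep=200000)
        y = sol2[-1]
        t_all.append(t_offset + t1)
        y_all.append(sol1)
        t_all.append(t_offset + t2[1:])
        y_all.append(sol2[1:])
    t = np.concatenate(t_all)
    Y = np.concatenate(y_all, axis=0)
    # drop the duplicated stimulus-end sample of each beat
    keep = np.concatenate(([True], np.diff(t) > 1e-12))
    return t[keep], Y[keep]


def run_paced(
    params: ModelParameters,
    rate_Hz: float,
    duration_s: float,
    dt_out: float = DT_OUT,
    y0: np.ndarray | None = None,
    return_states: bool = False,
):
    """Pace the cell at ``rate_Hz`` for ``duration_s`` seconds.

    Every stimulus must elicit an AP (beat peak at least 60 mV above the
    pre-beat diastolic potential), otherwise :class:`SubThresholdError`
    is raised. Returns the voltage trace; with ``return_states=True``
    additionally the full (t, states) arrays.
    """
    n_beats = int(round(rate_Hz * duration_s))
    if n_beats < 2:
        raise ValueError("protocol requires at least 2 beats")
    cl = 1000.0 / rate_Hz
    params = ModelParameters.from_dict({**params.to_dict(), "cycle_length": cl})
    t, Y = integrate_beats(params, n_beats, y0=y0, dt_out=dt_out)
    V = Y[:, IDX["V"]]
    per_beat = int(round(cl / dt_out))
    for beat in range(n_beats):
        seg = V[beat * per_beat: (beat + 1) * per_beat + 1]
        if seg.max() - seg[0] <= MIN_AP_AMPLITUDE:
            raise SubThresholdError(
                f"sub-threshold stimulus: beat {beat + 1} amplitude "
                f"{seg.max() - seg[0]:.1f} mV"
            )
    trace = APTrace(dt=dt_out, values=V, t0=0.0)
    if return_states:
        return trace, t, Y
    return trace


def last_ap(trace: APTrace, rate_Hz: float) -> APTrace:
    """Final cycle of a paced trace, resampled to 1 ms.

    The window starts at the last stimulus onset and spans one cycle
    length; resampling is by linear interpolation, matching the temporal
    resolution of the optical recordings.
    """
    cl = 1000.0 / rate_Hz
    n_beats = int(round((trace.duration + trace.dt) / cl))
    if n_beats < 1:
        raise ValueError("trace shorter than one pacing cycle")
    return beat_window(trace, rate_Hz, n_beats - 1)


def beat_window(trace: APTrace, rate_Hz: float, beat_index: int) -> APTrace:
    """One cycle-length window of beat ``beat_index`` (0-based), at 1 ms."""
    cl = 1000.0 / rate_Hz
    start = beat_index * cl
    if start + cl > trace.duration + trace.dt + 1e-9:
        raise ValueError(f"beat {beat_index} not contained in trace")
    n = int(round(cl / DT_OPTICAL))
    t_new = start + DT_OPTICAL * np.arange(n)
    values = np.interp(t_new, trace.t, trace.values)
    return APTrace(dt=DT_OPTICAL, values=values, t0=0.0)


# ---------------------------------------------------------------------------
# stimulus threshold
# ---------------------------------------------------------------------------
def _excites(params: ModelParameters, amplitude: float) -> bool:
    p = ModelParameters.from_dict(
        {**params.to_dict(), "stim_amplitude": amplitude, "cycle_length": 50.0}
    )
    _, Y = integrate_beats(p, 1, dt_out=0.5)
    return Y[:, IDX["V"]].max() > 0.0


def find_threshold(
    params: ModelParameters | None = None,
    bracket: tuple[float, float] = (1.0, 100.0),
    rel_tol: float = 0.005,
) -> float:
    """Excitation threshold (pA/pF) of a 1 ms pulse, by bisection.

    Excitation means the AP overshoots 0 mV within 50 ms of the pulse.
    """
    params = params or ModelParameters()
    lo, hi = bracket
    if _excites(params, lo):
        raise ValueError(f"lower bracket {lo} already excites")
    if not _excites(params, hi):
        raise ValueError(f"upper bracket {hi} does not excite")
    while (hi - lo) / hi > rel_tol:
        mid = 0.5 * (lo + hi)
        if _excites(params, mid):
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# steady-state last AP
# ---------------------------------------------------------------------------
_BASELINE_STATE_CACHE: dict = {}


def baseline_paced_state(
    params: ModelParameters,
    rate_Hz: float = 5.0,
    duration_s: float = 5.0,
) -> np.ndarray:
    """State of the *baseline* cell after a 5 Hz adaptation train.

    All perturbation protocols start from this rate-adapted state rather
    than from the quiescent published initial conditions, mirroring the
    experiment in which slices are paced continuously and interventions
    are applied during pacing. (From the quiescent state the first beat
    carries a fully-loaded-SR Ca2+ transient that can trap strongly
    K+-reduced variants in a depolarized metastable state.)

    Only stimulus and pacing fields of ``params`` matter here; the cell
    itself is the unperturbed baseline. Results are cached.
    """
    base = ModelParameters(
        stim_amplitude=params.stim_amplitude,
        stim_duration=params.stim_duration,
        cycle_length=1000.0 / rate_Hz,
    )
    key = (round(base.stim_amplitude, 6), round(base.stim_duration, 6),
           round(rate_Hz, 6), round(duration_s, 6))
    if key not in _BASELINE_STATE_CACHE:
        n_beats = int(round(rate_Hz * duration_s))
        _, Y = integrate_beats(base, n_beats)
        _BASELINE_STATE_CACHE[key] = Y[-1].copy()
    return _BASELINE_STATE_CACHE[key].copy()


def paced_last_ap(
    params: ModelParameters,
    rate_Hz: float = 5.0,
    duration_s: float = 5.0,
    max_duration_s: float = 20.0,
    from_paced_baseline: bool = True,
) -> APTrace:
    """Steady-state last AP of a paced train at 1 ms resolution.

    The cell is first adapted to the pacing rate at baseline parameters
    (see :func:`baseline_paced_state`), then paced for ``duration_s``
    with ``params``. The last AP is accepted when its APD80 agrees
    within 1% with the same-parity preceding beat (same parity because
    the model shows small APD alternans at 5 Hz); otherwise the train is
    extended (logged) up to ``max_duration_s``. An unrepolarized last
    beat is returned as-is -- downstream feature extraction decides how
    to flag it.
    """
    y0 = baseline_paced_state(params, rate_Hz) if from_paced_baseline else None
    duration = duration_s
    while True:
        trace = run_paced(params, rate_Hz, duration, y0=y0)
        n_beats = int(round(rate_Hz * duration))
        final = last_ap(trace, rate_Hz)
        try:
            apd_last = ap_features(final).APD80
            apd_prev = ap_features(beat_window(trace, rate_Hz, n_beats - 3)).APD80
        except UnrepolarizedError:
            return final
        if abs(percent_change(apd_last, apd_prev)) < STEADY_STATE_TOL_PCT:
            return final
        if duration >= max_duration_s:
            logger.warning(
                "steady state not reached within %.0f s (same-parity beats "
                "differ by %.2f%%); using final beat",
                duration, percent_change(apd_last, apd_prev),
            )
            return final
        duration = min(2 * duration, max_duration_s)
        logger.info("extending pacing to %.0f s to reach steady state", duration)


# ---------------------------------------------------------------------------
# scan protocols
# ---------------------------------------------------------------------------
@dataclass
class ScanResult:
    """APD grid of a one-parameter perturbation scan.

    ``table`` has one row per grid point with the absolute APDs (ms), the
    percent changes relative to the control point (factor 1 / shift 0,
    exactly 0 there by construction), and a repolarization-failure flag.
    """

    modifier_id: str
    grid_name: str
    table: pd.DataFrame

    def row(self, value: float) -> pd.Series:
        tab = self.table
        match = tab[np.isclose(tab[self.grid_name], value)]
        if match.empty:
            raise KeyError(f"{self.grid_name}={value} not in scan grid")
        return match.iloc[0]


_APD_LEVELS = (30, 50, 80, 90)


def _features_row(trace: APTrace) -> tuple[dict, bool]:
    """APDs of a last-AP window; NaNs plus a flag if unrepolarized."""
    try:
        f = ap_features(trace)
        return ({"APD30": f.APD30, "APD50": f.APD50, "APD80": f.APD80,
                 "APD90": f.APD90}, False)
    except UnrepolarizedError:
        out = {}
        for level in _APD_LEVELS:
            try:
                from .traces import apd
                out[f"APD{level}"] = apd(trace, level)
            except UnrepolarizedError:
                out[f"APD{level}"] = np.nan
        return out, True


def _scan_table(
    grid_name: str,
    grid: np.ndarray,
    control_value: float,
    apd_rows: list[dict],
    flags: list[bool],
) -> pd.DataFrame:
    table = pd.DataFrame(apd_rows)
    table.insert(0, grid_name, grid)
    table["repolarization_failure"] = flags
    control = table[np.isclose(table[grid_name], control_value)]
    if control.empty:
        raise ValueError(f"scan grid must contain the control point "
                         f"{grid_name}={control_value}")
    ctrl = control.iloc[0]
    for level in _APD_LEVELS:
        col = f"APD{level}"
        table[f"pct_{col}"] = [
            percent_change(v, ctrl[col]) if np.isfinite(v) else np.nan
            for v in table[col]
        ]
    return table


def conductance_scan(
    current_id: str,
    factors: tuple | np.ndarray = DEFAULT_FACTORS,
    params: ModelParameters | None = None,
    rate_Hz: float = 5.0,
    duration_s: float = 5.0,
) -> ScanResult:
    """Scan a K+ conductance multiplier over ``factors`` (control = 1.0).

    Only the three conductances the perturbation study varies are
    accepted: Ktof, Kur, Kss.
    """
    if current_id not in ("Ktof", "Kur", "Kss"):
        raise ValueError(
            f"conductance scans cover Ktof, Kur, Kss; got {current_id!r}"
        )
    params = params or ModelParameters()
    grid = np.asarray(factors, dtype=float)
    rows, flags = [], []
    for f in grid:
        try:
            trace = paced_last_ap(params.with_scale(current_id, f),
                                  rate_Hz, duration_s)
        except SubThresholdError as exc:
            raise SubThresholdError(
                f"{current_id} scan failed at factor {f}: {exc}"
            ) from exc
        row, flag = _features_row(trace)
        rows.append(row)
        flags.append(flag)
    return ScanResult(current_id, "factor",
                      _scan_table("factor", grid, 1.0, rows, flags))


def nal_scan(
    k_factors: tuple | np.ndarray = DEFAULT_FACTORS,
    params: ModelParameters | None = None,
    rate_Hz: float = 5.0,
    duration_s: float = 5.0,
) -> ScanResult:
    """Scan the Na_v re-opening rate multiplier (late Na+ current)."""
    params = params or ModelParameters()
    grid = np.asarray(k_factors, dtype=float)
    rows, flags = [], []
    for f in grid:
        try:
            trace = paced_last_ap(params.with_k_reopen(f), rate_Hz, duration_s)
        except SubThresholdError as exc:
            raise SubThresholdError(
                f"re-opening-rate scan failed at factor {f}: {exc}"
            ) from exc
        row, flag = _features_row(trace)
        rows.append(row)
        flags.append(flag)
    return ScanResult("NaL", "factor",
                      _scan_table("factor", grid, 1.0, rows, flags))


def cal_shift_scan(
    shifts_mV: tuple | np.ndarray = DEFAULT_SHIFTS,
    modifier_id: str = "none",
    modifier_factor: float | None = None,
    params: ModelParameters | None = None,
    rate_Hz: float = 5.0,
    duration_s: float = 5.0,
    control_trace: APTrace | None = None,
) -> ScanResult:
    """Scan the I_CaL activation shift, optionally on top of a modifier.

    Percent changes are relative to (shift 0, no modifier): the scan
    quantifies AP prolongation caused by Ca2+-channel over-activation
    under a given repolarization-reserve condition. Grid points where the
    AP fails to repolarize before the next stimulus are flagged, not
    fatal.
    """
    params = params or ModelParameters()
    shifts = np.asarray(shifts_mV, dtype=float)
    if np.any(shifts > 0):
        raise ValueError("activation shifts must be <= 0 mV")
    base = params
    if modifier_id != "none":
        if modifier_factor is None:
            raise ValueError("modifier_factor required when modifier_id given")
        base = _apply_modifier(params, modifier_id, modifier_factor)

    if control_trace is None:
        control_trace = paced_last_ap(params, rate_Hz, duration_s)
    ctrl_row, _ = _features_row(control_trace)

    rows, flags = [], []
    for dv in shifts:
        if dv == 0.0 and modifier_id == "none":
            rows.append(dict(ctrl_row))
            flags.append(False)
            continue
        try:
            trace = paced_last_ap(base.with_caL_shift(dv), rate_Hz,
                                  duration_s)
            row, flag = _features_row(trace)
        except SubThresholdError:
            row = {f"APD{lv}": np.nan for lv in _APD_LEVELS}
            flag = True
        rows.append(row)
        flags.append(flag)

    table = pd.DataFrame(rows)
    table.insert(0, "shift_mV", shifts)
    table["repolarization_failure"] = flags
    for level in _APD_LEVELS:
        col = f"APD{level}"
        table[f"pct_{col}"] = [
            percent_change(v, ctrl_row[col]) if np.isfinite(v) else np.nan
            for v in table[col]
        ]
    label = modifier_id if modifier_id == "none" else (
        f"{modifier_id}x{modifier_factor:.4g}")
    return ScanResult(label, "shift_mV", table)


# ---------------------------------------------------------------------------
# modifier calibration
# ---------------------------------------------------------------------------
def calibrate_modifier_for_apd80(
    target_percent: float,
    modifier_id: str,
    params: ModelParameters | None = None,
    bounds: tuple[float, float] = (0.3, 3.0),
    tol_pp: float = 0.25,
    rate_Hz: float = 5.0,
    duration_s: float = 5.0,
    control_apd80: float | None = None,
) -> float:
    """Modifier factor producing a ``target_percent`` change in APD80.

    Bisection on the factor until the steady-state APD80 change is within
    ``tol_pp`` percentage points of the target. K+ conductance reductions
    and re-opening-rate increases both prolong the AP, so the search
    brackets are oriented by the sign of the response at the bounds.
    """
    if modifier_id not in MODIFIER_IDS:
        raise ValueError(
            f"unknown modifier id {modifier_id!r}; expected one of {MODIFIER_IDS}"
        )
    params = params or ModelParameters()
    if target_percent == 0.0:
        return 1.0
    if control_apd80 is None:
        control_apd80 = ap_features(paced_last_ap(params, rate_Hz,
                                                  duration_s)).APD80

    def response(factor: float) -> float:
        # loss of 1:1 capture / repolarization failure = unbounded
        # prolongation; steers the bisection back into the valid range
        try:
            trace = paced_last_ap(_apply_modifier(params, modifier_id, factor),
                                  rate_Hz, duration_s)
            return percent_change(ap_features(trace).APD80, control_apd80)
        except (SubThresholdError, UnrepolarizedError):
            return float("inf")

    lo, hi = bounds
    r_lo, r_hi = response(lo), response(hi)
    if not (min(r_lo, r_hi) <= target_percent <= max(r_lo, r_hi)):
        raise ValueError(
            f"target {target_percent:+.2f}% APD80 unreachable for "
            f"{modifier_id} in factor bounds {bounds}: responses "
            f"[{r_lo:+.2f}%, {r_hi:+.2f}%]"
        )
    increasing = r_hi > r_lo
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        r_mid = response(mid)
        if abs(r_mid - target_percent) <= tol_pp:
            return mid
        if (r_mid < target_percent) == increasing:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            return 0.5 * (lo + hi)
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# unpaced relaxation (resting state)
# ---------------------------------------------------------------------------
def resting_state(
    params: ModelParameters | None = None,
    duration_s: float = 10.0,
    y0: np.ndarray | None = None,
) -> np.ndarray:
    """State after a long unpaced relaxation from the initial conditions."""
    params = params or ModelParameters()
    p_off = pack_params(params, 0.0)
    y = INITIAL_STATE.copy() if y0 is None else np.asarray(y0, float).copy()
    t = np.linspace(0.0, duration_s * 1000.0, 101)
    sol = odeint(rhs, y, t, args=(p_off,), rtol=RTOL, atol=ATOL,
                 tfirst=True, mxstep=500000)
    return sol[-1]
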