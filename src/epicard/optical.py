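"""Voltage-movie processing: movies to APD/activation maps and gradients.

The processing chain follows standard optical-mapping practice for paced
preparations: ensemble averaging of aligned pacing cycles, polynomial
drift correction fitted on diastolic samples, a mask-aware 3x3 spatial
mean filter, then per-pixel AP feature extraction. Regions of interest
(LV free wall sector, epicardial third, transmural rays) are derived from
the tissue mask geometry; the transmural APD gradient is quantified as a
per-ray regression slope in ms/mm (negative = APD shortens toward the
epicardium).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .traces import (APTrace, UnrepolarizedError, activation_time, apd,
                     normalize_polarity)

QC_AMPLITUDE_FLOOR = 0.20   # fraction of the in-mask median beat amplitude
DEFAULT_POLY_ORDER = 3
DIASTOLIC_FRACTION = 0.10   # of beat amplitude; first-pass diastole criterion


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class VoltageMovie:
    """Time-major fluorescence stack with a tissue mask.

    Attributes
    ----------
    frames : ndarray, shape (T, H, W)
        Fluorescence values (arbitrary units, any polarity).
    frame_interval : float
        ms per frame (1.0 for a 1 kHz camera).
    pixel_size : float
        mm per pixel (0.05 for the 50 um effective resolution).
    mask : ndarray of bool, shape (H, W)
        Tissue pixels.
    pacing_cycle : float
        Pacing cycle length in ms.
    """

    frames: np.ndarray
    mask: np.ndarray
    frame_interval: float = 1.0
    pixel_size: float = 0.05
    pacing_cycle: float = 200.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if self.mask.shape != self.frames.shape[1:]:
            raise ValueError("mask shape must match frame shape")
        if not self.mask.any():
            raise ValueError("tissue mask is empty")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def frames_per_cycle(self) -> int:
        return int(round(self.pacing_cycle / self.frame_interval))

    def mean_trace(self) -> np.ndarray:
        return self.frames[:, self.mask].mean(axis=1)

    def pixel_trace(self, row: int, col: int) -> APTrace:
        return APTrace(dt=self.frame_interval,
                       values=self.frames[:, row, col].astype(float))

    # -- IO -----------------------------------------------------------------
    def to_tiff(self, movie_path: str | Path, mask_path: str | Path | None = None):
        tifffile.imwrite(str(movie_path), self.frames,
                         metadata={"axes": "TYX"})
        if mask_path is not None:
            tifffile.imwrite(str(mask_path), self.mask.astype(np.uint8))

    @classmethod
    def from_tiff(cls, movie_path, mask_path, frame_interval=1.0,
                  pixel_size=0.05, pacing_cycle=200.0) -> "VoltageMovie":
        frames = tifffile.imread(str(movie_path)).astype(np.float32)
        mask = tifffile.imread(str(mask_path)).astype(bool)
        return cls(frames=frames, mask=mask, frame_interval=frame_interval,
                   pixel_size=pixel_size, pacing_cycle=pacing_cycle)


@dataclass
class APDMap:
    """Per-pixel APD (ms); NaN outside the mask or where QC failed."""

    values: np.ndarray
    level_percent: float
    qc_pass: np.ndarray

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.values.astype(np.float32))

    def masked_values(self, region: np.ndarray | None = None) -> np.ndarray:
        sel = np.isfinite(self.values)
        if region is not None:
            sel &= region
        return self.values[sel]


@dataclass
class ROISet:
    """LV free-wall segmentation: masks plus ordered transmural rays.

    ``rays`` is a list of record arrays with fields row, col, depth_mm
    (transmural depth from the endocardial boundary, increasing toward
    the epicardium).
    """

    lv_free_wall: np.ndarray
    epicardial_third: np.ndarray
    rays: list
    cavity_center: tuple

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cavity_center": list(self.cavity_center),
            "lv_free_wall": np.argwhere(self.lv_free_wall).tolist(),
            "epicardial_third": np.argwhere(self.epicardial_third).tolist(),
            "rays": [
                [[int(r), int(c), float(d)] for r, c, d in ray]
                for ray in self.rays
            ],
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# processing stages
# ---------------------------------------------------------------------------
def ensure_positive_polarity(movie: VoltageMovie) -> VoltageMovie:
    """Flip the movie if depolarization is a negative deflection.

    Voltage-sensitive dyes report depolarization as decreased
    fluorescence; the decision is made once per movie on the mask-mean
    trace, so pixel noise cannot flip individual traces.
    """
    mean = movie.mean_trace()
    flipped = normalize_polarity(mean)
    if flipped is not mean and not np.array_equal(flipped, mean):
        frames = movie.frames.copy()
        med = np.median(movie.frames[:, movie.mask])
        frames[:, movie.mask] = 2.0 * med - movie.frames[:, movie.mask]
        return VoltageMovie(frames, movie.mask, movie.frame_interval,
                            movie.pixel_size, movie.pacing_cycle)
    return movie


def _detect_first_activation(mean: np.ndarray) -> int:
    lo, hi = mean.min(), mean.max()
    thr = lo + 0.5 * (hi - lo)
    above = np.flatnonzero(mean >= thr)
    if above.size == 0:
        raise ValueError("cycle detection failure: no activation in movie")
    return int(above[0])


def ensemble_average(movie: VoltageMovie, n_beats: int) -> VoltageMovie:
    """Average ``n_beats`` aligned pacing cycles into a single cycle.

    Alignment uses the first mask-mean activation; each subsequent cycle
    window must correlate with the first (r > 0.8 on the mask-mean
    trace), otherwise pacing is considered misaligned and an error is
    raised.
    """
    L = movie.frames_per_cycle
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if movie.n_frames < n_beats * L:
        raise ValueError(
            f"movie too short for {n_beats} cycles of {L} frames"
        )
    mean = movie.mean_trace()
    start = _detect_first_activation(mean)
    # start windows one quarter-cycle before activation when possible
    start = max(0, start - L // 4)
    if start + n_beats * L > movie.n_frames:
        start = movie.n_frames - n_beats * L
    ref = mean[start: start + L]
    acc = np.zeros((L,) + movie.frames.shape[1:], dtype=np.float64)
    for b in range(n_beats):
        seg = slice(start + b * L, start + (b + 1) * L)
        cyc = mean[seg]
        if n_beats > 1:
            r = np.corrcoef(ref - ref.mean(), cyc - cyc.mean())[0, 1]
            if not np.isfinite(r) or r < 0.8:
                raise ValueError(
                    f"cycle detection failure: beat {b + 1} misaligned "
                    f"(r = {r:.2f})"
                )
        acc += movie.frames[seg]
    acc /= n_beats
    return VoltageMovie(acc.astype(np.float32), movie.mask,
                        movie.frame_interval, movie.pixel_size,
                        movie.pacing_cycle)


def detrend(trace: APTrace, poly_order: int = DEFAULT_POLY_ORDER) -> APTrace:
    """Remove slow baseline drift by polynomial fitting.

    Diastolic samples are first taken as everything below 10% of the
    beat amplitude -- a criterion that always keeps anchors across the
    whole window -- and the polynomial fitted to them and subtracted. A
    refinement pass then re-selects diastole on the corrected trace as
    samples within twice the residual noise of zero, which excludes the
    sub-threshold repolarization foot of the AP, and refits; the final
    diastolic mean is restored to 0.
    """
    v = trace.values.astype(float)
    if v.size <= poly_order + 1:
        raise ValueError("trace shorter than polynomial order + 2")
    corrected = _detrend_columns(trace.t, v[:, None], poly_order)[:, 0]
    return APTrace(dt=trace.dt, values=corrected, t0=trace.t0)


def _fit_baseline(X: np.ndarray, v: np.ndarray, dia: np.ndarray) -> np.ndarray:
    """Weighted per-column polynomial baselines (einsum-batched solves)."""
    w = dia.astype(float)
    A = np.einsum("tk,ti,tj->kij", w, X, X)
    b = np.einsum("tk,ti,tk->ki", w, X, v)
    coef = np.linalg.solve(A, b[..., None])[..., 0]
    return np.einsum("ti,ki->tk", X, coef)


def _detrend_columns(t: np.ndarray, values: np.ndarray,
                     poly_order: int) -> np.ndarray:
    """Per-column polynomial drift removal on diastolic samples.

    ``values`` is (n_samples, n_columns); all columns are handled with
    batched small normal-equation solves, no Python loops.
    """
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    if n <= poly_order + 1:
        raise ValueError("trace shorter than polynomial order + 2")
    lo = v.min(axis=0)
    amp = v.max(axis=0) - lo
    amp = np.where(amp > 0, amp, 1.0)
    dia = v <= lo + DIASTOLIC_FRACTION * amp
    if (dia.sum(axis=0) <= poly_order + 1).any():
        raise ValueError("degenerate drift fit: too few diastolic samples")
    ts = (t - t.mean()) / max(np.ptp(t), 1.0)
    X = np.vander(ts, poly_order + 1, increasing=True)
    base = _fit_baseline(X, v, dia)
    resid = v - base
    # refinement: exclude the AP's sub-threshold foot from the anchors
    for _ in range(2):
        neg = np.where(resid <= 0, resid, 0.0)
        n_neg = np.maximum((resid <= 0).sum(axis=0), 1)
        sigma = np.sqrt((neg ** 2).sum(axis=0) / n_neg)
        dia_new = resid <= np.maximum(2.0 * sigma, 0.02 * amp)
        # accept only if the refined set still anchors both window ends
        q = max(n // 4, poly_order + 2)
        enough = ((dia_new.sum(axis=0) > max(poly_order + 2, 8))
                  & (dia_new[:q].sum(axis=0) >= 2)
                  & (dia_new[-q:].sum(axis=0) >= 2))
        dia = np.where(enough[None, :], dia_new, dia)
        base = _fit_baseline(X, v, dia)
        resid = v - base
    if not np.all(np.isfinite(base)):
        raise ValueError("degenerate drift fit")
    dia_mean = (np.where(dia, resid, 0.0).sum(axis=0)
                / np.maximum(dia.sum(axis=0), 1))
    return resid - dia_mean


def detrend_movie(movie: VoltageMovie,
                  poly_order: int = DEFAULT_POLY_ORDER) -> VoltageMovie:
    """Apply :func:`detrend` to every in-mask pixel trace (vectorized)."""
    frames = movie.frames.astype(np.float64).copy()
    rows, cols = np.nonzero(movie.mask)
    t = movie.frame_interval * np.arange(movie.n_frames)
    frames[:, rows, cols] = _detrend_columns(
        t, frames[:, rows, cols], poly_order)
    return VoltageMovie(frames.astype(np.float32), movie.mask,
                        movie.frame_interval, movie.pixel_size,
                        movie.pacing_cycle)


def spatial_filter(movie: VoltageMovie) -> VoltageMovie:
    """Mask-aware 3x3 spatial mean filter, per frame.

    The kernel is renormalized over in-mask neighbours so tissue values
    never mix with background; out-of-mask pixels are untouched.
    """
    maskf = movie.mask.astype(np.float64)
    norm = ndimage.uniform_filter(maskf, size=3, mode="constant")
    frames = movie.frames.astype(np.float64)
    acc = ndimage.uniform_filter(frames * maskf[None, :, :],
                                 size=(1, 3, 3), mode="constant")
    out = movie.frames.astype(np.float64).copy()
    valid = movie.mask & (norm > 0)
    out[:, valid] = acc[:, valid] / norm[valid]
    return VoltageMovie(out.astype(np.float32), movie.mask,
                        movie.frame_interval, movie.pixel_size,
                        movie.pacing_cycle)


def _beat_amplitudes(movie: VoltageMovie) -> np.ndarray:
    amp = np.full(movie.mask.shape, np.nan)
    px = movie.frames[:, movie.mask]
    amp[movie.mask] = px.max(axis=0) - px.min(axis=0)
    return amp


def apd_map(movie: VoltageMovie, level_percent: float = 90.0) -> APDMap:
    """Per-pixel APD map of an averaged, detrended, filtered cycle.

    Pixels whose beat amplitude is below 20% of the in-mask median, or
    whose trace never repolarizes to the level, are flagged and excluded
    (NaN). If more than half of the mask fails QC an error is raised.
    """
    values = np.full(movie.mask.shape, np.nan)
    qc = np.zeros(movie.mask.shape, dtype=bool)
    amp = _beat_amplitudes(movie)
    floor = QC_AMPLITUDE_FLOOR * np.nanmedian(amp[movie.mask])
    rows, cols = np.nonzero(movie.mask)
    for r, c in zip(rows, cols):
        if amp[r, c] < floor:
            continue
        try:
            values[r, c] = apd(movie.pixel_trace(r, c), level_percent)
            qc[r, c] = True
        except (UnrepolarizedError, ValueError):
            continue
    n_mask = movie.mask.sum()
    if qc.sum() < 0.5 * n_mask:
        raise ValueError(
            f"APD map failed QC on {n_mask - qc.sum()} of {n_mask} pixels"
        )
    return APDMap(values=values, level_percent=level_percent, qc_pass=qc)


def activation_map(movie: VoltageMovie) -> APDMap:
    """Per-pixel activation-time map (maximum upstroke derivative)."""
    values = np.full(movie.mask.shape, np.nan)
    qc = np.zeros(movie.mask.shape, dtype=bool)
    amp = _beat_amplitudes(movie)
    floor = QC_AMPLITUDE_FLOOR * np.nanmedian(amp[movie.mask])
    rows, cols = np.nonzero(movie.mask)
    for r, c in zip(rows, cols):
        if amp[r, c] < floor:
            continue
        try:
            values[r, c] = activation_time(movie.pixel_trace(r, c))
            qc[r, c] = True
        except ValueError:
            continue
    return APDMap(values=values, level_percent=np.nan, qc_pass=qc)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------
def _find_cavity(mask: np.ndarray) -> np.ndarray:
    """Largest background component not touching the image border."""
    bg = ~mask
    labels, n = ndimage.label(bg)
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_labels = set(np.unique(labels[border & bg]))
    best, best_size = 0, 0
    for lab in range(1, n + 1):
        if lab in border_labels:
            continue
        size = int((labels == lab).sum())
        if size > best_size:
            best, best_size = lab, size
    if best == 0:
        raise ValueError("no cavity found inside the tissue mask")
    return labels == best


def segment_rois(
    mask: np.ndarray,
    sector: tuple[float, float] = (0.0, 360.0),
    cavity_center: tuple[float, float] | None = None,
    pixel_size: float = 0.05,
    exclusion_mask: np.ndarray | None = None,
    n_rays: int = 60,
    boundary_margin_px: float = 2.0,
) -> ROISet:
    """Segment the LV free wall of a short-axis slice mask.

    ``sector`` is the angular range (degrees, image convention: angle of
    (dx, dy) = (col - cx, row - cy)) of the free wall to analyze.
    Papillary protrusions into the cavity are removed automatically as
    tissue inside the convex hull of the cavity (or supplied explicitly
    via ``exclusion_mask``). The epicardial third is the outer third of the
    transmural depth; rays run endocardium -> epicardium, with
    ``boundary_margin_px`` trimmed off both ends because boundary pixels
    are biased by the one-sided spatial filter at the tissue edge (their
    transmural depth is still measured from the true endocardial
    boundary).
    """
    mask = np.asarray(mask, dtype=bool)
    cavity = _find_cavity(mask)
    if cavity_center is None:
        r, c = np.nonzero(cavity)
        cavity_center = (float(r.mean()), float(c.mean()))
    cy, cx = cavity_center

    if exclusion_mask is None:
        # papillary muscles protrude from the endocardium into the cavity;
        # the short-axis cavity itself is convex to good approximation, so
        # tissue inside the cavity's convex hull is papillary
        from skimage.morphology import convex_hull_image
        papillary = convex_hull_image(cavity) & mask
    else:
        papillary = np.asarray(exclusion_mask, dtype=bool)
    wall = mask & ~papillary

    # angular sector selection
    rows, cols = np.indices(mask.shape)
    theta = np.degrees(np.arctan2(rows - cy, cols - cx)) % 360.0
    th0, th1 = sector[0] % 360.0, sector[1] % 360.0
    if (sector[1] - sector[0]) % 360.0 == 0.0:
        in_sector = np.ones_like(mask)
    elif th0 <= th1:
        in_sector = (theta >= th0) & (theta <= th1)
    else:
        in_sector = (theta >= th0) | (theta <= th1)
    wall_sector = wall & in_sector

    # normalized transmural depth from distance transforms
    d_endo = ndimage.distance_transform_edt(~(cavity | papillary))
    outside = ~mask & ~cavity
    d_epi = ndimage.distance_transform_edt(~outside)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = d_endo / (d_endo + d_epi)
    epicardial_third = wall_sector & (frac >= 2.0 / 3.0)

    # transmural rays
    span = (sector[1] - sector[0]) % 360.0 or 360.0
    angles = sector[0] + span * (np.arange(n_rays) + 0.5) / n_rays
    r_max = float(np.hypot(mask.shape[0], mask.shape[1]))
    rays = []
    for ang in angles:
        ca, sa = np.cos(np.radians(ang)), np.sin(np.radians(ang))
        radii = np.arange(0.0, r_max, 0.5)
        rr = np.round(cy + radii * sa).astype(int)
        cc = np.round(cx + radii * ca).astype(int)
        ok = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
        rr, cc, radii = rr[ok], cc[ok], radii[ok]
        inw = wall_sector[rr, cc]
        if not inw.any():
            continue
        i_endo = np.argmax(inw)                   # first wall pixel
        i_epi = len(inw) - 1 - np.argmax(inw[::-1])  # last wall pixel
        margin = int(round(boundary_margin_px / 0.5))  # radii step is 0.5 px
        seen = set()
        ray = []
        for i in range(i_endo + margin, i_epi + 1 - margin):
            if not inw[i]:
                continue
            key = (rr[i], cc[i])
            if key in seen:
                continue
            seen.add(key)
            depth_mm = (radii[i] - radii[i_endo]) * pixel_size
            ray.append((rr[i], cc[i], depth_mm))
        if len(ray) >= 3:
            rays.append(ray)
    if not rays:
        raise ValueError("no transmural rays found in sector")
    return ROISet(lv_free_wall=wall_sector, epicardial_third=epicardial_third,
                  rays=rays, cavity_center=(cy, cx))


# ---------------------------------------------------------------------------
# transmural gradient
# ---------------------------------------------------------------------------
def transmural_gradient(
    apd_map_: APDMap,
    rois: ROISet,
    min_valid_per_ray: int = 5,
) -> tuple[float, np.ndarray]:
    """Mean transmural APD gradient (ms/mm) and the per-ray slopes.

    Each ray's slope comes from a least-squares regression of APD on
    transmural depth (endocardium = 0 mm); rays with too few valid
    pixels are dropped. Negative slope = APD shortens toward the
    epicardium. Requires at least 10 valid rays.
    """
    slopes = []
    for ray in rois.rays:
        depths, vals = [], []
        for r, c, d in ray:
            v = apd_map_.values[r, c]
            if np.isfinite(v):
                depths.append(d)
                vals.append(v)
        if len(vals) < min_valid_per_ray or np.ptp(depths) <= 0:
            continue
        slope = np.polynomial.polynomial.polyfit(depths, vals, 1)[1]
        slopes.append(slope)
    slopes = np.asarray(slopes)
    if slopes.size < 10:
        raise ValueError(
            f"only {slopes.size} valid transmural rays (need >= 10)"
        )
    return float(slopes.mean()), slopes


def radial_gradient_map(apd_map_: APDMap, rois: ROISet,
                        pixel_size: float = 0.05) -> float:
    """Secondary estimate: mean radial component of the local 2-D gradient.

    Finite-difference gradients are noisier at 50 um pixels than the
    per-ray regression, which is the primary definition.
    """
    vals = apd_map_.values
    gy, gx = np.gradient(vals)
    cy, cx = rois.cavity_center
    rows, cols = np.indices(vals.shape)
    dy, dx = rows - cy, cols - cx
    norm = np.hypot(dy, dx)
    norm[norm == 0] = 1.0
    radial = (gy * dy + gx * dx) / norm / pixel_size
    sel = rois.lv_free_wall & np.isfinite(radial)
    if not sel.any():
        raise ValueError("no valid pixels for radial gradient")
    return float(np.nanmean(radial[sel]))


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------
def process_movie(
    movie: VoltageMovie,
    level_percent: float = 90.0,
    n_beats: int | None = None,
    poly_order: int = DEFAULT_POLY_ORDER,
) -> dict:
    """Movie -> maps, with the recorded stage order.

    Stages: polarity normalization -> ensemble averaging -> per-pixel
    polynomial drift correction -> mask-aware 3x3 spatial mean filter ->
    per-pixel APD and activation maps. Returns a dict with the averaged
    cycle, the APD map, the activation map, and the configuration used.
    """
    if n_beats is None:
        n_beats = movie.n_frames // movie.frames_per_cycle
    config = {
        "level_percent": level_percent,
        "n_beats": n_beats,
        "poly_order": poly_order,
        "frame_interval_ms": movie.frame_interval,
        "pixel_size_mm": movie.pixel_size,
        "pacing_cycle_ms": movie.pacing_cycle,
        "stage_order": ["polarity", "ensemble_average", "detrend",
                        "spatial_filter", "measure"],
    }
    m = ensure_positive_polarity(movie)
    m = ensemble_average(m, n_beats)
    m = detrend_movie(m, poly_order)
    m = spatial_filter(m)
    return {
        "cycle": m,
        "apd_map": apd_map(m, level_percent),
        "activation_map": activation_map(m),
        "config": config,
    }
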