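"""Seeded synthetic voltage-movie phantoms with ground truth.

The phantom emulates a paced short-axis left-ventricular slice as seen by
a voltage-dye camera: an annular wall (optionally with papillary bumps
protruding into the cavity), a transmural APD90 field, activation
spreading from an epicardial stimulus site at a fixed conduction
velocity, a stereotyped AP waveform per pixel, and the principal camera
artifacts (additive Gaussian noise, shared polynomial baseline drift with
per-pixel jitter, exponential photobleaching, inverted dye polarity, and
per-pixel gain variation).

Defaults are the study conditions of the imaged preparations: 200 ms
pacing cycle (5 Hz), 1 kHz frame rate, 0.05 mm pixels, male-like
epicardial APD90 of 69 ms with a strong negative transmural gradient; the
female-like configuration is longer, leveled and more variable between
animals (no absolute printed values exist for females, so those defaults
are explicitly synthetic choices).

Every output is a deterministic function of the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .optical import VoltageMovie

# analytic AP kernel shape constants
T_RISE_MS = 2.0
FALL_EXPONENT = 2.0


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass
class PhantomConfig:
    """Full specification of one synthetic movie.

    Geometry is an annulus (outer/inner radius in mm) centred in a square
    field; ``papillary_bumps`` is a list of (angle_deg, bump_radius_mm)
    disks attached to the endocardial boundary. The APD90 field is
    ``apd_epi_ms`` at the epicardial boundary plus ``apd_slope_ms_per_mm``
    times (depth - wall thickness) along the transmural depth (so a
    negative slope makes the endocardium longer), plus smooth spatial
    jitter with SD ``apd_jitter_ms``.
    """

    image_size: int = 128
    pixel_size_mm: float = 0.05
    outer_radius_mm: float = 2.6
    inner_radius_mm: float = 1.5
    sector_deg: tuple = (0.0, 360.0)
    papillary_bumps: tuple = ()
    apd_epi_ms: float = 69.0
    apd_slope_ms_per_mm: float = -10.0
    apd_jitter_ms: float = 1.0
    velocity_m_per_s: float = 0.35
    stim_angle_deg: float = 0.0
    noise_sd: float = 0.05          # fraction of beat amplitude
    drift_coeffs: tuple = (0.0, 0.15, -0.10, 0.05)  # fraction of amplitude
    drift_jitter: float = 0.1       # per-pixel relative coefficient jitter
    bleach_tau_s: float = 20.0
    gain_jitter: float = 0.1
    invert_polarity: bool = True
    n_beats: int = 4
    cycle_ms: float = 200.0
    frame_interval_ms: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inner_radius_mm >= self.outer_radius_mm:
            raise ValueError("inner radius must be smaller than outer radius")
        if 2 * self.outer_radius_mm >= self.image_size * self.pixel_size_mm:
            raise ValueError("annulus does not fit in the field of view")
        for sd in (self.apd_jitter_ms, self.noise_sd, self.drift_jitter,
                   self.gain_jitter):
            if sd < 0:
                raise ValueError("all SDs must be >= 0")

    def replace(self, **kw) -> "PhantomConfig":
        return dataclasses.replace(self, **kw)


def male_like_config(**kw) -> PhantomConfig:
    """Male-like slice: epicardial APD90 69 ms, strong negative gradient."""
    return PhantomConfig(**kw)


def female_like_config(**kw) -> PhantomConfig:
    """Female-like slice: longer epicardial APD90, near-leveled gradient.

    Absolute female values are synthetic choices (longer and more
    variable than male, gradient close to zero).
    """
    defaults = dict(apd_epi_ms=80.0, apd_slope_ms_per_mm=-3.0,
                    apd_jitter_ms=1.5)
    defaults.update(kw)
    return PhantomConfig(**defaults)


# ---------------------------------------------------------------------------
# analytic AP kernel
# ---------------------------------------------------------------------------
def _fall_fraction(level: float) -> float:
    """Scaled repolarization time at which the kernel crosses ``level``."""
    return (np.arccos(2.0 * level - 1.0) / np.pi) ** (1.0 / FALL_EXPONENT)


def _rise_crossing(level: float) -> float:
    """Time within the upstroke at which the kernel crosses ``level``."""
    return T_RISE_MS * np.arccos(1.0 - 2.0 * level) / np.pi


def fall_duration_for_apd90(apd90: np.ndarray | float) -> np.ndarray | float:
    """Repolarization-phase duration giving an exact APD90.

    APD90 is the width at 10% of amplitude: from the upstroke crossing at
    ``_rise_crossing(0.1)`` to the repolarization crossing at
    ``T_RISE_MS + _fall_fraction(0.1) * D``.
    """
    up = _rise_crossing(0.1)
    return (np.asarray(apd90, dtype=float) - (T_RISE_MS - up)) / _fall_fraction(0.1)


def kernel_apd(apd90: float, level_percent: float) -> float:
    """Ground-truth APD of the kernel at any repolarization level."""
    lv = 1.0 - level_percent / 100.0
    D = fall_duration_for_apd90(apd90)
    return float(T_RISE_MS - _rise_crossing(lv) + _fall_fraction(lv) * D)


def ap_kernel(t: np.ndarray, apd90: np.ndarray) -> np.ndarray:
    """Normalized AP waveform: sine-squared upstroke, raised-cosine
    repolarization whose duration is scaled so APD90 is exact; the
    upstroke is fixed so spatial APD variation only stretches the
    repolarization phase.

    ``t`` (ms since local activation onset) and ``apd90`` broadcast.
    """
    t = np.asarray(t, dtype=float)
    D = fall_duration_for_apd90(apd90)
    out = np.zeros(np.broadcast(t, D).shape)
    rising = (t >= 0) & (t < T_RISE_MS)
    tt = np.broadcast_to(t, out.shape)
    np.copyto(out, 0.5 * (1.0 - np.cos(np.pi * tt / T_RISE_MS)), where=rising)
    u = (tt - T_RISE_MS) / np.broadcast_to(D, out.shape)
    falling = (u >= 0) & (u < 1.0)
    np.copyto(out, 0.5 * (1.0 + np.cos(np.pi * u ** FALL_EXPONENT)),
              where=falling)
    return out


def activation_onset_truth(config: PhantomConfig) -> float:
    """Ground-truth activation time offset within the kernel (ms).

    The maximum temporal derivative of the sine-squared upstroke is at
    half the rise time.
    """
    return T_RISE_MS / 2.0


# ---------------------------------------------------------------------------
# movie generation
# ---------------------------------------------------------------------------
def _geometry(config: PhantomConfig):
    n = config.image_size
    px = config.pixel_size_mm
    c = (n - 1) / 2.0
    rows, cols = np.indices((n, n))
    x_mm = (cols - c) * px
    y_mm = (rows - c) * px
    r_mm = np.hypot(x_mm, y_mm)
    theta = np.degrees(np.arctan2(y_mm, x_mm)) % 360.0

    annulus = (r_mm >= config.inner_radius_mm) & (r_mm <= config.outer_radius_mm)
    th0, th1 = config.sector_deg[0] % 360.0, config.sector_deg[1] % 360.0
    if (config.sector_deg[1] - config.sector_deg[0]) % 360.0 == 0.0:
        in_sector = np.ones((n, n), dtype=bool)
    elif th0 <= th1:
        in_sector = (theta >= th0) & (theta <= th1)
    else:
        in_sector = (theta >= th0) | (theta <= th1)
    wall = annulus & in_sector

    papillary = np.zeros((n, n), dtype=bool)
    for ang, rad in config.papillary_bumps:
        bx = (config.inner_radius_mm - 0.3 * rad) * np.cos(np.radians(ang))
        by = (config.inner_radius_mm - 0.3 * rad) * np.sin(np.radians(ang))
        papillary |= np.hypot(x_mm - bx, y_mm - by) <= rad
    papillary &= r_mm < config.inner_radius_mm  # only the cavity protrusion
    mask = wall | papillary

    depth_mm = np.clip(r_mm - config.inner_radius_mm, 0.0, None)
    return mask, wall, papillary, depth_mm, x_mm, y_mm


def generate_movie(config: PhantomConfig) -> tuple[VoltageMovie, dict]:
    """Generate a phantom movie and its ground truth.

    Returns ``(movie, truth)`` where ``truth`` holds the exact per-pixel
    APD90 map (``apd90``), activation-time map (``activation``), the
    tissue/wall/papillary masks, and the config. The mapping from seed to
    output is deterministic.
    """
    rng = np.random.default_rng(config.seed)
    mask, wall, papillary, depth_mm, x_mm, y_mm = _geometry(config)
    wall_thickness = config.outer_radius_mm - config.inner_radius_mm

    # ground-truth APD90 field: epicardial value + slope * (depth - wall)
    apd90 = (config.apd_epi_ms
             + config.apd_slope_ms_per_mm * (depth_mm - wall_thickness))
    if config.apd_jitter_ms > 0:
        from scipy import ndimage
        raw = rng.standard_normal(mask.shape)
        smooth = ndimage.gaussian_filter(raw, sigma=3.0)
        smooth /= smooth[mask].std() or 1.0
        apd90 = apd90 + config.apd_jitter_ms * smooth
    apd90 = np.clip(apd90, 5.0, 0.9 * config.cycle_ms)

    # activation delay from epicardial stimulus site
    sx = config.outer_radius_mm * np.cos(np.radians(config.stim_angle_deg))
    sy = config.outer_radius_mm * np.sin(np.radians(config.stim_angle_deg))
    dist_mm = np.hypot(x_mm - sx, y_mm - sy)
    delay_ms = dist_mm / config.velocity_m_per_s  # mm / (mm/ms)

    n_frames = int(round(config.n_beats * config.cycle_ms
                         / config.frame_interval_ms))
    t = config.frame_interval_ms * np.arange(n_frames)

    rows, cols = np.nonzero(mask)
    npx = rows.size
    apd_px = apd90[rows, cols]
    delay_px = delay_ms[rows, cols]

    # waveform: periodic in the pacing cycle
    phase = (t[:, None] - delay_px[None, :]) % config.cycle_ms
    signal = ap_kernel(phase, apd_px[None, :])

    amp = 1.0
    gain = 1.0 + config.gain_jitter * rng.standard_normal(npx)
    offset = 10.0 + 0.5 * rng.standard_normal(npx)
    total_t = max(t[-1], 1.0)
    drift_shared = np.asarray(config.drift_coeffs, dtype=float)
    drift_px_coeffs = drift_shared[None, :] * (
        1.0 + config.drift_jitter * rng.standard_normal((npx,
                                                         drift_shared.size)))
    tn = (t / total_t)[:, None]
    drift = np.zeros((n_frames, npx))
    for k in range(drift_shared.size):
        drift += drift_px_coeffs[None, :, k][0] * tn ** k

    bleach = np.exp(-t / (config.bleach_tau_s * 1000.0))[:, None]
    fluor = (offset[None, :] + amp * gain[None, :] * signal) * bleach
    fluor = fluor + amp * drift
    if config.noise_sd > 0:
        fluor = fluor + amp * config.noise_sd * rng.standard_normal(
            (n_frames, npx))
    if config.invert_polarity:
        fluor = 2.0 * np.median(fluor) - fluor

    frames = np.zeros((n_frames,) + mask.shape, dtype=np.float32)
    frames[:, rows, cols] = fluor.astype(np.float32)

    movie = VoltageMovie(frames=frames, mask=mask,
                         frame_interval=config.frame_interval_ms,
                         pixel_size=config.pixel_size_mm,
                         pacing_cycle=config.cycle_ms)
    apd90_truth = np.where(mask, apd90, np.nan)
    activation_truth = np.where(mask, delay_ms + activation_onset_truth(config),
                                np.nan)
    truth = {
        "apd90": apd90_truth,
        "activation": activation_truth,
        "mask": mask,
        "wall": wall,
        "papillary": papillary,
        "depth_mm": np.where(mask, depth_mm, np.nan),
        "config": config,
    }
    return movie, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------
def generate_cohort(
    group_means: dict[str, float],
    n_animals: dict[str, int] | int,
    slices_per_animal: int = 2,
    between_sd: float | dict[str, float] = 3.0,
    within_sd: float | dict[str, float] = 1.5,
    seed: int = 0,
    value_name: str = "value",
) -> pd.DataFrame:
    """Hierarchical scalar draws: group -> animal -> slice.

    Animal means are Normal(group mean, between-animal SD); slice values
    are Normal(animal mean, within-animal SD). Returns a tidy frame with
    columns (group, animal, slice, value). Fully determined by ``seed``.
    """
    rng = np.random.default_rng(seed)
    records = []
    for g, mu in group_means.items():
        n_a = n_animals[g] if isinstance(n_animals, dict) else n_animals
        if n_a < 2:
            raise ValueError("need at least 2 animals per group")
        b_sd = between_sd[g] if isinstance(between_sd, dict) else between_sd
        w_sd = within_sd[g] if isinstance(within_sd, dict) else within_sd
        for a in range(n_a):
            animal_mean = mu + b_sd * rng.standard_normal()
            for s in range(slices_per_animal):
                value = animal_mean + w_sd * rng.standard_normal()
                records.append({"group": g, "animal": f"{g}{a + 1}",
                                "slice": s + 1, value_name: value})
    return pd.DataFrame.from_records(records)


def cohort_phantom_configs(
    n_animals: int,
    slices_per_animal: int,
    base_config: PhantomConfig,
    between_apd_sd: float,
    within_apd_sd: float,
    between_slope_sd: float,
    within_slope_sd: float,
    seed: int = 0,
) -> list[tuple[str, int, PhantomConfig]]:
    """Per-slice phantom configs with hierarchically drawn parameters.

    Draws each animal's epicardial APD90 and transmural slope around the
    group (base config) values, then each slice around the animal; every
    slice gets its own derived seed. Returns (animal, slice, config)
    triples.
    """
    rng = np.random.default_rng(seed)
    out = []
    for a in range(n_animals):
        a_apd = base_config.apd_epi_ms + between_apd_sd * rng.standard_normal()
        a_slope = (base_config.apd_slope_ms_per_mm
                   + between_slope_sd * rng.standard_normal())
        for s in range(slices_per_animal):
            s_apd = a_apd + within_apd_sd * rng.standard_normal()
            s_slope = a_slope + within_slope_sd * rng.standard_normal()
            cfg = base_config.replace(
                apd_epi_ms=float(s_apd),
                apd_slope_ms_per_mm=float(s_slope),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            out.append((f"A{a + 1}", s + 1, cfg))
    return out
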