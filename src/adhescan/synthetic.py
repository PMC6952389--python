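"""Synthetic biosensor stacks, brightfield masks and FD curves with ground truth.

No public dataset of combined RWG-biosensor / FluidFM single-cell
recordings exists, so every downstream stage of the package is exercised
on synthetic data with full ground truth. The generator emulates:

* a wavelength-shift image stack — each cell is a radially decaying bump
  (Gaussian profile truncated at the cell's footprint radius) whose
  amplitude follows a logistic time course, on a coarse sensor grid
  (25 µm pixels, 3 s frames by default) with i.i.d. Gaussian pixel noise;
* brightfield-style binary masks — the footprint where the noiseless
  final-frame bump exceeds the cell's adequate threshold, rendered on a
  fine optical pixel grid;
* force-distance curves — a baseline with a triangular or smooth adhesive
  dip of prescribed depth (adhesion force) and enclosed area (adhesion
  energy);
* IWS/force/energy calibration tables with controlled relative noise.

The ground truth (per-cell areas, IWS, force and energy versus time) is
computed in closed form from the bump parameters, so pipeline output can
be compared against it exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .fluidfm import FDCurve
from .io import CellMask, WSStack
from .thresholds import SaturationThresholdModel

__all__ = [
    "PopulationConfig",
    "GroundTruth",
    "PlacementError",
    "generate_ws_stack",
    "generate_fd_curve",
    "generate_calibration_set",
    "generate_sigmoid_track",
]


class PlacementError(RuntimeError):
    """Cell centres could not be placed at the required minimum separation."""


@dataclass
class PopulationConfig:
    """Parameters of a synthetic cell population on one sensor.

    Defaults emulate a confluent adhesion assay on a 2×2 mm sensor read at
    25 µm pitch every 3 s for 90 min: log-normal final peak WS centred so
    a median cell saturates near 15 pJ of adhesion energy, spreading rate
    constants around 0.005 1/s, and spreading midpoints dispersed across
    the population. ``noise_sd`` is the per-pixel per-frame sensor noise
    in pm (an explicit setting, not derived from any instrument).
    """

    n_cells: int = 300
    grid_shape: tuple[int, int] = (80, 80)
    pixel_pitch: float = 25.0  # µm
    frame_interval: float = 3.0  # s
    duration: float = 5400.0  # s
    amplitude_mu_log: float = math.log(2600.0)  # ln pm of final peak WS
    amplitude_sigma_log: float = 0.35
    footprint_mean_um: float = 45.0  # support radius of the bump
    footprint_sd_um: float = 6.0
    footprint_range_um: tuple[float, float] = (25.0, 70.0)
    rate_mean: float = 0.005  # 1/s, logistic spreading rate
    rate_sd: float = 0.0015
    rate_range: tuple[float, float] = (0.002, 0.012)
    midpoint_mean_s: float = 1200.0
    midpoint_sd_s: float = 400.0
    midpoint_range_s: tuple[float, float] = (300.0, 3000.0)
    noise_sd: float = 30.0  # pm
    min_separation_um: float = 55.0
    at_a_pm: float = 3128.0  # saturation-threshold law used as ground truth
    at_b_pm: float = 2935.0
    slope_force: float = 4.9e-4  # nN/(pm·µm²)
    slope_energy: float = 6.4e-6  # pJ/(pm·µm²)
    profile_sigma_fraction: float = 0.4  # Gaussian σ as fraction of footprint radius
    mask_pixel_um: float = 2.0  # brightfield mask pixel size
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.amplitude_sigma_log < 0:
            raise ValueError("amplitude_sigma_log must be >= 0")
        for name in (
            "pixel_pitch", "frame_interval", "duration",
            "footprint_mean_um", "rate_mean", "min_separation_um",
            "at_a_pm", "at_b_pm", "slope_force", "slope_energy",
            "profile_sigma_fraction", "mask_pixel_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval)) + 1

    @property
    def at_model(self) -> SaturationThresholdModel:
        return SaturationThresholdModel(self.at_a_pm, self.at_b_pm)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Closed-form truth for a generated population.

    ``cells`` has one row per cell (centre, final peak, footprint, kinetic
    parameters and final area/IWS/force/energy); the array attributes hold
    the noiseless per-frame series, shape (n_frames, n_cells).
    """

    cells: pd.DataFrame
    times: np.ndarray
    peak: np.ndarray  # pm
    threshold: np.ndarray  # pm (adequate threshold for the current peak)
    area: np.ndarray  # µm²
    iws: np.ndarray  # pm·µm²
    force: np.ndarray  # nN
    energy: np.ndarray  # pJ

    def series_table(self) -> pd.DataFrame:
        """Long-format (cell_id, frame, t_s, ...) view of the truth series."""
        n_frames, n_cells = self.peak.shape
        frames = np.repeat(np.arange(n_frames), n_cells)
        ids = np.tile(np.arange(n_cells), n_frames)
        return pd.DataFrame(
            {
                "cell_id": ids,
                "frame": frames,
                "t_s": np.repeat(self.times, n_cells),
                "peak_pm": self.peak.ravel(),
                "threshold_pm": self.threshold.ravel(),
                "area_um2": self.area.ravel(),
                "iws_pm_um2": self.iws.ravel(),
                "force_nN": self.force.ravel(),
                "energy_pJ": self.energy.ravel(),
            }
        )


def _place_centers(config: PopulationConfig, radii: np.ndarray, rng: np.random.Generator):
    """Rejection-sample cell centres, snapped to sensor pixel centres.

    Centres keep each cell's full footprint inside the sensor and respect
    the configured minimum separation; bounded retries guard against
    infeasible densities.
    """
    h, w = config.grid_shape
    pitch = config.pixel_pitch
    rows = np.empty(config.n_cells, dtype=int)
    cols = np.empty(config.n_cells, dtype=int)
    max_attempts = 2000 * max(config.n_cells, 1)
    attempts = 0
    placed = 0
    while placed < config.n_cells:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed only {placed}/{config.n_cells} cells after {attempts} attempts; "
                f"reduce density or min_separation_um"
            )
        attempts += 1
        margin = radii[placed]
        lo_r, hi_r = int(np.ceil(margin / pitch)), int(np.floor((h - 1) - margin / pitch))
        lo_c, hi_c = int(np.ceil(margin / pitch)), int(np.floor((w - 1) - margin / pitch))
        if lo_r > hi_r or lo_c > hi_c:
            raise PlacementError("footprint larger than the sensor grid")
        r = int(rng.integers(lo_r, hi_r + 1))
        c = int(rng.integers(lo_c, hi_c + 1))
        if placed:
            d2 = (rows[:placed] - r) ** 2 + (cols[:placed] - c) ** 2
            if np.min(d2) * pitch**2 < config.min_separation_um**2:
                continue
        rows[placed], cols[placed] = r, c
        placed += 1
    return rows, cols


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    return np.clip(out, lo, hi)


def _truth_series(config: PopulationConfig, amp_final, sigma, support, times):
    """Closed-form per-frame truth for truncated-Gaussian logistic bumps."""
    a, b = config.at_a_pm, config.at_b_pm
    # per-cell logistic, normalised so the final frame reaches amp_final exactly
    rates = sigma["rate"][None, :]
    mids = sigma["midpoint"][None, :]
    t = times[:, None]
    logistic = 1.0 / (1.0 + np.exp(-rates * (t - mids)))
    logistic = logistic / logistic[-1:, :]
    peak = amp_final[None, :] * logistic
    threshold = a * peak / (b + peak)
    sig = sigma["sigma"][None, :]
    sup = support[None, :]
    active = peak > threshold  # equivalent to peak > a - b
    with np.errstate(divide="ignore", invalid="ignore"):
        r_th = np.sqrt(2.0 * sig**2 * np.log(np.where(active, peak / threshold, 1.0)))
    r_th = np.minimum(np.where(active, r_th, 0.0), sup)
    area = np.pi * r_th**2
    # integral of the Gaussian bump above the threshold radius
    edge = peak * np.exp(-(r_th**2) / (2.0 * sig**2))
    iws = 2.0 * np.pi * sig**2 * (peak - edge)
    iws[~active] = 0.0
    force = config.slope_force * iws
    energy = config.slope_energy * iws
    return peak, threshold, area, iws, force, energy


def generate_ws_stack(config: PopulationConfig):
    """Generate a WS stack, its ground truth and per-cell brightfield masks.

    Returns ``(stack, truth, masks)``. Masks are crops around each cell of
    the footprint where the noiseless final-frame bump exceeds the cell's
    adequate threshold, rendered at ``config.mask_pixel_um`` resolution —
    the synthetic stand-in for a segmented brightfield image.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.grid_shape
    n_frames = config.n_frames
    times = np.arange(n_frames) * config.frame_interval
    n = config.n_cells

    amp_final = rng.lognormal(config.amplitude_mu_log, config.amplitude_sigma_log, n)
    support = _truncated_normal(
        rng, config.footprint_mean_um, config.footprint_sd_um, *config.footprint_range_um, size=n
    )
    rate = _truncated_normal(rng, config.rate_mean, config.rate_sd, *config.rate_range, size=n)
    midpoint = _truncated_normal(
        rng, config.midpoint_mean_s, config.midpoint_sd_s, *config.midpoint_range_s, size=n
    )
    sigma = config.profile_sigma_fraction * support
    rows, cols = _place_centers(config, support, rng) if n else (np.array([], int), np.array([], int))

    stack = np.zeros((n_frames, h, w))
    pitch = config.pixel_pitch
    for i in range(n):
        half = int(np.ceil(support[i] / pitch))
        r0, r1 = max(rows[i] - half, 0), min(rows[i] + half, h - 1)
        c0, c1 = max(cols[i] - half, 0), min(cols[i] + half, w - 1)
        rr = (np.arange(r0, r1 + 1) - rows[i]) * pitch
        cc = (np.arange(c0, c1 + 1) - cols[i]) * pitch
        d2 = rr[:, None] ** 2 + cc[None, :] ** 2
        profile = np.exp(-d2 / (2.0 * sigma[i] ** 2))
        profile[d2 > support[i] ** 2] = 0.0
        logistic = 1.0 / (1.0 + np.exp(-rate[i] * (times - midpoint[i])))
        amp = amp_final[i] * logistic / logistic[-1]
        stack[:, r0 : r1 + 1, c0 : c1 + 1] += amp[:, None, None] * profile[None, :, :]

    if config.noise_sd > 0:
        stack += rng.normal(0.0, config.noise_sd, stack.shape)

    params = {"rate": rate, "midpoint": midpoint, "sigma": sigma}
    if n:
        peak, threshold, area, iws, force, energy = _truth_series(
            config, amp_final, params, support, times
        )
    else:
        peak = threshold = area = iws = force = energy = np.zeros((n_frames, 0))

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "row": rows,
            "col": cols,
            "y_um": rows * pitch,
            "x_um": cols * pitch,
            "final_peak_pm": amp_final,
            "footprint_um": support,
            "sigma_um": sigma,
            "rate_1_per_s": rate,
            "midpoint_s": midpoint,
            "final_threshold_pm": threshold[-1] if n else np.array([]),
            "final_area_um2": area[-1] if n else np.array([]),
            "final_iws_pm_um2": iws[-1] if n else np.array([]),
            "final_force_nN": force[-1] if n else np.array([]),
            "final_energy_pJ": energy[-1] if n else np.array([]),
        }
    )
    truth = GroundTruth(cells, times, peak, threshold, area, iws, force, energy)

    masks = []
    if n:
        r_th_final = np.sqrt(np.maximum(area[-1], 0.0) / np.pi)
        for i in range(n):
            masks.append(_disk_mask(r_th_final[i], config.mask_pixel_um))
    ws_stack = WSStack(
        stack,
        config.pixel_pitch,
        config.frame_interval,
        {"seed": config.seed, "generator": "adhescan.synthetic", "config": config.to_dict()},
    )
    return ws_stack, truth, masks


def _disk_mask(radius_um: float, pixel_um: float) -> CellMask:
    """Binary disk of the given radius on a fine optical pixel grid."""
    half = max(int(np.ceil(radius_um / pixel_um)) + 2, 2)
    coords = (np.arange(-half, half + 1) + 0.0) * pixel_um
    d2 = coords[:, None] ** 2 + coords[None, :] ** 2
    return CellMask(d2 <= radius_um**2, pixel_um**2)


def generate_fd_curve(
    f_adh: float,
    e_adh: float,
    z_range: float = 70.0,
    n_points: int = 1000,
    noise_sd: float = 0.0,
    seed: int | None = None,
    shape: str = "triangle",
) -> FDCurve:
    """Synthetic retraction force-distance curve with a known adhesive dip.

    The curve is zero except for a dip of depth ``f_adh`` (nN) whose
    enclosed area equals ``e_adh`` (pJ); the dip width follows as
    w = 2·E/F (with 1 pJ = 1000 nN·µm). ``shape`` is ``"triangle"`` (the
    dip's breakpoints are inserted into the sample grid, so trapezoidal
    evaluation recovers force and energy exactly in the noiseless case)
    or ``"smooth"`` (a sin² dip of the same depth and area).
    """
    if f_adh < 0 or e_adh < 0:
        raise ValueError("f_adh and e_adh must be non-negative")
    if (f_adh == 0) != (e_adh == 0):
        raise ValueError("a dip needs both f_adh > 0 and e_adh > 0 (or both zero)")
    z = np.linspace(0.0, z_range, n_points)
    if f_adh == 0:
        force = np.zeros_like(z)
    else:
        width = 2.0 * (e_adh * 1e3) / f_adh  # µm; e in pJ -> nN·µm
        z_start = 0.05 * z_range
        if z_start + width > 0.9 * z_range:
            raise ValueError(
                f"dip of width {width:.1f} µm does not fit into z_range {z_range:.1f} µm"
            )
        if shape == "triangle":
            breakpoints = np.array([z_start, z_start + width / 2, z_start + width])
            z = np.unique(np.concatenate([z, breakpoints]))
            force = np.zeros_like(z)
            apex = z_start + width / 2
            rising = (z >= z_start) & (z <= apex)
            falling = (z > apex) & (z <= z_start + width)
            force[rising] = -f_adh * (z[rising] - z_start) / (width / 2)
            force[falling] = -f_adh * (z_start + width - z[falling]) / (width / 2)
        elif shape == "smooth":
            force = np.zeros_like(z)
            inside = (z >= z_start) & (z <= z_start + width)
            u = (z[inside] - z_start) / width
            force[inside] = -f_adh * np.sin(np.pi * u) ** 2
        else:
            raise ValueError(f"unknown dip shape {shape!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        force = force + rng.normal(0.0, noise_sd, force.shape)
    return FDCurve(z, force=force)


def generate_calibration_set(
    n: int,
    slope_force: float = 4.9e-4,
    slope_energy: float = 6.4e-6,
    rel_noise: float = 0.25,
    seed: int | None = None,
    iws_range: tuple[float, float] = (2.0e5, 4.0e6),
    iws_values=None,
) -> pd.DataFrame:
    """Paired (IWS, force, energy) table emulating a combined experiment.

    IWS values are drawn uniformly over ``iws_range`` (covering the
    instrument's usable force range) unless given explicitly; force and
    energy are proportional with independent multiplicative Gaussian noise
    of relative SD ``rel_noise``.
    """
    if n < 2:
        raise ValueError("need n >= 2 cells for a calibration set")
    if slope_force <= 0 or slope_energy <= 0:
        raise ValueError("slopes must be positive")
    rng = np.random.default_rng(seed)
    if iws_values is None:
        iws = rng.uniform(*iws_range, n)
    else:
        iws = np.asarray(iws_values, dtype=float)
        if iws.size != n:
            raise ValueError("iws_values length must equal n")
    force = slope_force * iws * (1.0 + rng.normal(0.0, rel_noise, n))
    energy = slope_energy * iws * (1.0 + rng.normal(0.0, rel_noise, n))
    return pd.DataFrame({"iws_pm_um2": iws, "force_nN": force, "energy_pJ": energy})


def generate_sigmoid_track(
    saturation: float = 15.0,
    rate: float = 0.005,
    midpoint: float = 1200.0,
    frame_interval: float = 3.0,
    duration: float = 5400.0,
    noise_sd: float = 0.5,
    seed: int | None = None,
):
    """Single-cell adhesion-energy time course E(t) = E_sat/(1+e^{−r(t−t₀)}).

    Returns ``(times, energy)`` sampled every ``frame_interval`` seconds
    with additive Gaussian noise — the canonical single-cell kinetic test
    signal (defaults: 15 pJ saturation, 0.005 1/s rate, 90 min span).
    """
    times = np.arange(0.0, duration + frame_interval / 2, frame_interval)
    energy = saturation / (1.0 + np.exp(-rate * (times - midpoint)))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        energy = energy + rng.normal(0.0, noise_sd, times.shape)
    return times, energy
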