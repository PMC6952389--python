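"""Single-cell segmentation of wavelength-shift images and IWS extraction.

The per-cell adhesion proxy is the *integrated wavelength shift*

    IWS = A_pix · Σ_i WS_i   over pixels with WS_i > threshold,

in pm·µm². A frame is processed in four steps: (1) bilinear refinement of
the coarse 25 µm sensor grid, (2) detection of local maxima, taken as cell
centres, (3) Voronoi tessellation of the frame with those maxima as
generators, so each cell owns the region of pixels closer to its centre
than to any other, and (4) application of a cell-specific threshold —
predicted from the segment's maximal pixel value by the saturation law in
:mod:`adhescan.thresholds` — followed by integration over the
above-threshold pixels of the segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import WSStack
from .thresholds import SaturationThresholdModel

__all__ = [
    "CellSegment",
    "CellTrack",
    "interpolate_frame",
    "interpolated_pitch",
    "find_cell_centers",
    "voronoi_partition",
    "segment_frame",
    "compute_iws",
    "extract_tracks",
    "tracks_to_table",
]

log = logging.getLogger(__name__)

#: Minimum WS_m (pm) for a segment to count as a cell rather than noise,
#: unless a higher multiple of the background SD applies.
MIN_NOISE_FLOOR_PM = 100.0


@dataclass
class CellSegment:
    """One Voronoi segment of a frame with its thresholded statistics.

    ``segment_pixels`` and ``above_pixels`` are flat indices into the
    (interpolated) frame; ``above_pixels`` is the subset whose WS exceeds
    the segment's threshold.
    """

    generator: tuple[int, int]  # (row, col) in interpolated pixel indices
    segment_pixels: np.ndarray
    above_pixels: np.ndarray
    ws_max: float  # pm, the segment's maximal pixel value WS_m
    threshold: float  # pm
    area: float  # µm²
    iws: float  # pm·µm²
    pixel_area: float  # µm² of one interpolated pixel


@dataclass
class CellTrack:
    """Per-frame IWS/area series of one cell over the whole stack."""

    cell_id: int
    generator: tuple[int, int]  # interpolated pixel indices on the final frame
    center_um: tuple[float, float]  # (y, x) µm of the generator pixel centre
    times: np.ndarray  # s
    area: np.ndarray  # µm²
    iws: np.ndarray  # pm·µm²
    ws_max: np.ndarray = field(default=None)  # pm, per frame

    @property
    def mean_ws(self) -> np.ndarray:
        """Cell-averaged WS in pm (IWS / area; 0 where the area is 0)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(self.area > 0, self.iws / np.where(self.area > 0, self.area, 1.0), 0.0)
        return out


def interpolated_pitch(pixel_pitch: float, k: int) -> float:
    """Pixel pitch after ``k`` dyadic refinements: pitch / 2**k (µm)."""
    return pixel_pitch / 2**k


def interpolate_frame(frame: np.ndarray, k: int) -> np.ndarray:
    """Bilinearly refine a frame, halving the pixel pitch ``k`` times.

    Each original grid interval is subdivided into 2**k sub-intervals, so
    an H×W frame becomes ((H-1)·2**k + 1) × ((W-1)·2**k + 1) and values at
    the original node positions are preserved exactly. ``k = 0`` is the
    identity.
    """
    if not (isinstance(k, (int, np.integer)) and k >= 0):
        raise ValueError(f"interpolation degree k must be a non-negative integer, got {k!r}")
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if k == 0:
        return frame.copy()
    f = 2**k
    h, w = frame.shape
    rows = np.arange((h - 1) * f + 1) / f
    cols = np.arange((w - 1) * f + 1) / f
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(frame, [rr, cc], order=1, mode="nearest")


def _strict_local_maxima(frame: np.ndarray) -> np.ndarray:
    """Boolean mask of pixels strictly greater than all 8 neighbours."""
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neighbour_max = ndimage.maximum_filter(frame, footprint=footprint, mode="constant", cval=-np.inf)
    return frame > neighbour_max


def find_cell_centers(
    frame: np.ndarray,
    min_prominence: float,
    min_separation: float,
    pixel_pitch: float = 1.0,
) -> list[tuple[int, int]]:
    """Detect cell centres as pruned strict local maxima of a frame.

    A pixel qualifies if it is strictly greater than its 8 neighbours and
    rises at least ``min_prominence`` (pm) above the frame's background
    level (its median). Candidates are then greedily pruned in descending
    value order (ties broken row-major) so that no two returned centres are
    closer than ``min_separation`` (in the units of ``pixel_pitch``,
    i.e. µm when a pitch in µm is given); the higher peak wins.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame must be finite")
    baseline = float(np.median(frame))
    mask = _strict_local_maxima(frame) & (frame - baseline >= min_prominence)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return []
    values = frame[rows, cols]
    # descending value, then row-major position
    order = np.lexsort((cols, rows, -values))
    rows, cols = rows[order], cols[order]
    min_sep_px2 = (min_separation / pixel_pitch) ** 2
    kept_r: list[int] = []
    kept_c: list[int] = []
    for r, c in zip(rows, cols):
        if kept_r:
            d2 = (np.array(kept_r) - r) ** 2 + (np.array(kept_c) - c) ** 2
            if np.any(d2 < min_sep_px2):
                continue
        kept_r.append(int(r))
        kept_c.append(int(c))
    return list(zip(kept_r, kept_c))


def voronoi_partition(
    generators: list[tuple[int, int]] | np.ndarray,
    grid_shape: tuple[int, int],
    chunk: int = 200_000,
) -> np.ndarray:
    """Label every pixel with the index of its nearest generator.

    Distances are Euclidean between pixel centres; equidistant pixels go to
    the lowest generator index, making the partition deterministic. The
    assignment is computed exactly (integer arithmetic), chunked to bound
    memory on finely interpolated grids.
    """
    gen = np.asarray(generators, dtype=np.int64)
    if gen.size == 0:
        raise ValueError("voronoi_partition requires at least one generator; "
                         "return an empty segmentation instead")
    if gen.ndim != 2 or gen.shape[1] != 2:
        raise ValueError("generators must be (n, 2) (row, col) coordinates")
    h, w = grid_shape
    labels = np.empty(h * w, dtype=np.int32)
    rr, cc = np.divmod(np.arange(h * w, dtype=np.int64), w)
    for start in range(0, h * w, chunk):
        sl = slice(start, min(start + chunk, h * w))
        d2 = (rr[sl, None] - gen[None, :, 0]) ** 2 + (cc[sl, None] - gen[None, :, 1]) ** 2
        labels[sl] = np.argmin(d2, axis=1)  # first minimum -> lowest index
    return labels.reshape(h, w)


def compute_iws(ws_values: np.ndarray, pixel_area: float) -> float:
    """Integrated wavelength shift: pixel area × sum of WS values (pm·µm²)."""
    if pixel_area <= 0:
        raise ValueError("pixel_area must be > 0")
    values = np.asarray(ws_values, dtype=float)
    return float(pixel_area * values.sum())


def estimate_background_sd(frame: np.ndarray) -> float:
    """Robust background noise SD (pm) via the median absolute deviation."""
    frame = np.asarray(frame, dtype=float)
    med = np.median(frame)
    return float(1.4826 * np.median(np.abs(frame - med)))


def _noise_floor(raw_frame: np.ndarray, noise_floor: float | None) -> float:
    if noise_floor is not None:
        return noise_floor
    return max(5.0 * estimate_background_sd(raw_frame), MIN_NOISE_FLOOR_PM)


def segment_frame(
    frame: np.ndarray,
    at_model: SaturationThresholdModel,
    pixel_pitch: float,
    k: int = 4,
    min_prominence: float | None = None,
    min_separation: float = 50.0,
    noise_floor: float | None = None,
) -> list[CellSegment]:
    """Segment a single frame into per-cell thresholded Voronoi segments.

    Parameters
    ----------
    frame:
        Raw H×W WS frame in pm (not yet interpolated).
    at_model:
        Saturation law used to predict each segment's threshold from its
        maximal pixel value.
    pixel_pitch:
        Raw pixel pitch in µm.
    k:
        Bilinear interpolation degree (pitch divided by 2**k).
    min_prominence:
        Peak prominence for centre detection, pm; default 3× the estimated
        background SD (at least 1 pm).
    min_separation:
        Minimum centre separation in µm.
    noise_floor:
        Segments whose WS_m falls below this (pm) are discarded as noise;
        default max(5× background SD, 100 pm).
    """
    frame = np.asarray(frame, dtype=float)
    floor = _noise_floor(frame, noise_floor)
    if min_prominence is None:
        min_prominence = max(3.0 * estimate_background_sd(frame), 1.0)
    fine = interpolate_frame(frame, k)
    pitch = interpolated_pitch(pixel_pitch, k)
    pixel_area = pitch**2
    centers = find_cell_centers(fine, min_prominence, min_separation, pitch)
    centers = [c for c in centers if fine[c] >= floor]
    if not centers:
        return []
    labels = voronoi_partition(centers, fine.shape)
    flat_labels = labels.ravel()
    flat_vals = fine.ravel()
    segments: list[CellSegment] = []
    for idx, center in enumerate(centers):
        seg_pixels = np.nonzero(flat_labels == idx)[0]
        ws_m = float(flat_vals[seg_pixels].max())
        threshold = at_model.predict(max(ws_m, 0.0))
        above = seg_pixels[flat_vals[seg_pixels] > threshold]
        area = above.size * pixel_area
        iws = compute_iws(flat_vals[above], pixel_area)
        segments.append(
            CellSegment(center, seg_pixels, above, ws_m, threshold, area, iws, pixel_area)
        )
    return segments


def _frame_stats(
    fine_flat: np.ndarray,
    labels_flat: np.ndarray,
    n_labels: int,
    pixel_area: float,
    at_model: SaturationThresholdModel,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-label (WS_m, area, IWS) of one interpolated frame."""
    ws_m = np.full(n_labels, -np.inf)
    np.maximum.at(ws_m, labels_flat, fine_flat)
    thresholds = at_model.predict(np.maximum(ws_m, 0.0))
    above = fine_flat > thresholds[labels_flat]
    counts = np.bincount(labels_flat[above], minlength=n_labels)
    sums = np.bincount(labels_flat[above], weights=fine_flat[above], minlength=n_labels)
    return ws_m, counts * pixel_area, sums * pixel_area


def extract_tracks(
    stack: WSStack,
    at_model: SaturationThresholdModel,
    k: int = 4,
    min_prominence: float | None = None,
    min_separation: float = 50.0,
    noise_floor: float | None = None,
) -> list[CellTrack]:
    """Per-cell IWS/area time series for a whole stack.

    Cell centres are detected on the final frame — where cells are fully
    spread and brightest — and held fixed for all frames (cells are assumed
    non-migrating over the experiment), so each cell keeps one identity.
    The Voronoi partition is computed once; every frame is interpolated and
    reduced to per-segment WS_m, threshold, area and IWS.
    """
    final = stack.frame(stack.n_frames - 1)
    floor = _noise_floor(final, noise_floor)
    if min_prominence is None:
        min_prominence = max(3.0 * estimate_background_sd(final), 1.0)
    fine_final = interpolate_frame(final, k)
    pitch = interpolated_pitch(stack.pixel_pitch, k)
    pixel_area = pitch**2
    centers = find_cell_centers(fine_final, min_prominence, min_separation, pitch)
    centers = [c for c in centers if fine_final[c] >= floor]
    if not centers:
        log.warning("no cells detected on the final frame; returning empty track list")
        return []
    labels = voronoi_partition(centers, fine_final.shape).ravel()
    n = len(centers)
    times = stack.times
    area = np.zeros((stack.n_frames, n))
    iws = np.zeros((stack.n_frames, n))
    ws_m = np.zeros((stack.n_frames, n))
    for t in range(stack.n_frames):
        fine = interpolate_frame(stack.frame(t), k).ravel()
        ws_m[t], area[t], iws[t] = _frame_stats(fine, labels, n, pixel_area, at_model)
    tracks = []
    for i, (r, c) in enumerate(centers):
        tracks.append(
            CellTrack(
                cell_id=i,
                generator=(r, c),
                center_um=(r * pitch, c * pitch),
                times=times,
                area=area[:, i],
                iws=iws[:, i],
                ws_max=ws_m[:, i],
            )
        )
    return tracks


def tracks_to_table(tracks: list[CellTrack]) -> pd.DataFrame:
    """Long-format table (cell_id, frame, t_s, area_um2, iws_pm_um2, mean_ws_pm)."""
    records = []
    for tr in tracks:
        mean_ws = tr.mean_ws
        for f in range(len(tr.times)):
            records.append(
                (tr.cell_id, f, tr.times[f], tr.area[f], tr.iws[f], mean_ws[f])
            )
    return pd.DataFrame(
        records, columns=["cell_id", "frame", "t_s", "area_um2", "iws_pm_um2", "mean_ws_pm"]
    )
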