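"""End-to-end pipeline: simulate → segment → threshold-fit → FD-evaluate →
calibrate → population statistics.

Each stage reads and writes plain on-disk artifacts (CSV tables, JSON
models, HDF5/TIFF stacks) in a run directory, so stages can be re-run or
swapped for real instrument data. A run is fully described by a
:class:`RunConfig`; identical config and seed reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import fluidfm, kinetics, segmentation, synthetic
from .io import read_ws_stack, write_ws_stack
from .thresholds import SaturationThresholdModel, find_adequate_threshold, fit_at_model

__all__ = ["RunConfig", "StageError", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "segment", "fit_threshold", "eval_fd", "calibrate", "kinetics")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    ``population`` holds overrides for the synthetic generator
    (:class:`~adhescan.synthetic.PopulationConfig` fields); unknown keys
    anywhere in the config are rejected before any stage runs.
    """

    out_dir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # simulate
    population: dict = field(default_factory=dict)
    stack_format: str = "h5"  # or "tiff"
    n_calibration_cells: int = 30
    fd_noise_sd_nn: float = 5.0
    write_truth_series: bool = False
    # segmentation
    k: int = 4
    min_prominence: float | None = None
    min_separation: float = 50.0
    noise_floor: float | None = None
    frame_stride: int = 1
    # inputs for runs on real data (optional when simulating)
    stack_path: str | None = None
    fd_dir: str | None = None
    # threshold fit
    at_tol_um2: float | None = None
    # kinetics
    n_time_bins: int = 30
    n_value_bins: int = 40
    plot: bool = False

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {ALL_STAGES}")
        if not (isinstance(self.k, int) and self.k >= 0):
            raise ValueError(f"interpolation degree k must be a non-negative integer, got {self.k!r}")
        if self.frame_stride < 1:
            raise ValueError("frame_stride must be >= 1")
        if self.n_calibration_cells < 3:
            raise ValueError("n_calibration_cells must be >= 3")
        if self.stack_format not in ("h5", "tiff"):
            raise ValueError("stack_format must be 'h5' or 'tiff'")
        pop_fields = {f.name for f in dataclasses.fields(synthetic.PopulationConfig)}
        unknown_pop = set(self.population) - pop_fields
        if unknown_pop:
            raise ValueError(f"unknown population keys {sorted(unknown_pop)}")
        # materialise once so invalid values fail before any stage runs
        synthetic.PopulationConfig(**{"seed": self.seed, **self.population})

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "stages" in d:
            d = {**d, "stages": tuple(d["stages"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def population_config(self) -> synthetic.PopulationConfig:
        return synthetic.PopulationConfig(**{"seed": self.seed, **self.population})


def _stage_simulate(config: RunConfig, out: Path) -> None:
    pop = config.population_config()
    stack, truth, masks = synthetic.generate_ws_stack(pop)
    suffix = ".h5" if config.stack_format == "h5" else ".tiff"
    write_ws_stack(stack, out / f"stack{suffix}")
    truth.cells.to_csv(out / "truth_cells.csv", index=False)
    if config.write_truth_series:
        truth.series_table().to_csv(out / "truth_series.csv", index=False)

    # calibration subset: brightfield-style footprint areas + FD curves
    n_cal = min(config.n_calibration_cells, len(truth.cells))
    cal_rows = truth.cells.iloc[:n_cal]
    pd.DataFrame(
        {
            "cell_id": cal_rows.cell_id,
            "y_um": cal_rows.y_um,
            "x_um": cal_rows.x_um,
            "target_area_um2": [m.area for m in masks[:n_cal]],
        }
    ).to_csv(out / "calibration_cells.csv", index=False)
    fd_dir = out / "fd_curves"
    fd_dir.mkdir(exist_ok=True)
    rng_seed = np.random.default_rng(pop.seed + 1)
    for _, row in cal_rows.iterrows():
        curve = synthetic.generate_fd_curve(
            max(row.final_force_nN, 1.0),
            max(row.final_energy_pJ, 1e-3),
            noise_sd=config.fd_noise_sd_nn,
            seed=int(rng_seed.integers(2**31)),
            shape="smooth",
        )
        pd.DataFrame({"z_um": curve.z, "force_nN": curve.force}).to_csv(
            fd_dir / f"cell_{int(row.cell_id):04d}.csv", index=False
        )


def _load_stack(config: RunConfig, out: Path):
    path = Path(config.stack_path) if config.stack_path else None
    if path is None:
        for cand in (out / "stack.h5", out / "stack.tiff"):
            if cand.exists():
                path = cand
                break
    if path is None or not path.exists():
        raise FileNotFoundError("no stack found; run simulate or pass stack_path")
    return read_ws_stack(path)


def _segment_geometry(stack, config: RunConfig):
    """Interpolated final frame, detected centres and Voronoi labels."""
    final = stack.frame(stack.n_frames - 1)
    fine = segmentation.interpolate_frame(final, config.k)
    pitch = segmentation.interpolated_pitch(stack.pixel_pitch, config.k)
    floor = segmentation._noise_floor(final, config.noise_floor)
    prom = config.min_prominence
    if prom is None:
        prom = max(3.0 * segmentation.estimate_background_sd(final), 1.0)
    centers = segmentation.find_cell_centers(fine, prom, config.min_separation, pitch)
    centers = [c for c in centers if fine[c] >= floor]
    return fine, pitch, centers


def _stage_fit_threshold(config: RunConfig, out: Path) -> None:
    cal_path = out / "calibration_cells.csv"
    if not cal_path.exists():
        raise FileNotFoundError(f"{cal_path} (produced by simulate, or supply your own)")
    cal_cells = pd.read_csv(cal_path)
    stack = _load_stack(config, out)
    fine, pitch, centers = _segment_geometry(stack, config)
    if not centers:
        raise RuntimeError("no cells detected on the final frame")
    labels = segmentation.voronoi_partition(centers, fine.shape)
    flat_vals = fine.ravel()
    flat_labels = labels.ravel()
    centers_um = np.asarray(centers, dtype=float) * pitch
    pairs = []
    for _, row in cal_cells.iterrows():
        d2 = (centers_um[:, 0] - row.y_um) ** 2 + (centers_um[:, 1] - row.x_um) ** 2
        idx = int(np.argmin(d2))
        seg_vals = flat_vals[flat_labels == idx]
        ws_m = float(seg_vals.max())
        at = find_adequate_threshold(seg_vals, pitch**2, row.target_area_um2, config.at_tol_um2)
        pairs.append((int(row.cell_id), ws_m, at, row.target_area_um2))
    pairs_df = pd.DataFrame(pairs, columns=["cell_id", "ws_max_pm", "at_pm", "target_area_um2"])
    pairs_df.to_csv(out / "at_pairs.csv", index=False)
    model = fit_at_model(pairs_df.ws_max_pm, pairs_df.at_pm)
    (out / "at_model.json").write_text(json.dumps(model.to_dict(), indent=1))
    log.info("fitted threshold model: %s", model.summary())


def _load_at_model(out: Path) -> SaturationThresholdModel:
    path = out / "at_model.json"
    if path.exists():
        return SaturationThresholdModel.from_dict(json.loads(path.read_text()))
    log.warning("no fitted threshold model found; using reference parameters")
    return SaturationThresholdModel(3128.0, 2935.0)


def _stage_segment(config: RunConfig, out: Path) -> None:
    stack = _load_stack(config, out)
    if config.frame_stride > 1:
        stack = stack.downsample(config.frame_stride)
    at_model = _load_at_model(out)
    tracks = segmentation.extract_tracks(
        stack,
        at_model,
        k=config.k,
        min_prominence=config.min_prominence,
        min_separation=config.min_separation,
        noise_floor=config.noise_floor,
    )
    table = segmentation.tracks_to_table(tracks)
    table.to_csv(out / "tracks.csv", index=False)
    centers = pd.DataFrame(
        {
            "cell_id": [t.cell_id for t in tracks],
            "y_um": [t.center_um[0] for t in tracks],
            "x_um": [t.center_um[1] for t in tracks],
        }
    )
    centers.to_csv(out / "track_centers.csv", index=False)
    log.info("extracted %d tracks over %d frames", len(tracks), stack.n_frames)


def _stage_eval_fd(config: RunConfig, out: Path) -> None:
    fd_dir = Path(config.fd_dir) if config.fd_dir else out / "fd_curves"
    if not fd_dir.exists():
        raise FileNotFoundError(f"FD curve directory {fd_dir}")
    rows = []
    for path in sorted(fd_dir.glob("*.csv")):
        df = pd.read_csv(path)
        if not {"z_um", "force_nN"} <= set(df.columns):
            raise ValueError(f"{path} must have columns z_um, force_nN")
        curve = fluidfm.FDCurve(df.z_um.to_numpy(), force=df.force_nN.to_numpy())
        meas = fluidfm.evaluate_fd(curve)
        rows.append((path.stem, meas.adhesion_force, meas.adhesion_energy, ";".join(meas.qc_flags)))
    pd.DataFrame(
        rows, columns=["curve_id", "adhesion_force_nN", "adhesion_energy_pJ", "qc_flags"]
    ).to_csv(out / "adhesion.csv", index=False)


def _stage_calibrate(config: RunConfig, out: Path) -> None:
    for name in ("tracks.csv", "track_centers.csv", "adhesion.csv", "calibration_cells.csv"):
        if not (out / name).exists():
            raise FileNotFoundError(out / name)
    tracks = pd.read_csv(out / "tracks.csv")
    centers = pd.read_csv(out / "track_centers.csv")
    adhesion = pd.read_csv(out / "adhesion.csv")
    cal_cells = pd.read_csv(out / "calibration_cells.csv")
    final_frame = tracks.frame.max()
    final_iws = tracks[tracks.frame == final_frame].set_index("cell_id").iws_pm_um2
    triples = []
    for _, row in cal_cells.iterrows():
        d2 = (centers.y_um - row.y_um) ** 2 + (centers.x_um - row.x_um) ** 2
        track_id = int(centers.cell_id.iloc[int(np.argmin(d2))])
        curve_id = f"cell_{int(row.cell_id):04d}"
        match = adhesion[adhesion.curve_id == curve_id]
        if match.empty:
            continue
        triples.append(
            (final_iws.loc[track_id], float(match.adhesion_force_nN.iloc[0]),
             float(match.adhesion_energy_pJ.iloc[0]))
        )
    arr = np.array(triples)
    model = cal.fit_calibration(arr[:, 0], arr[:, 1], arr[:, 2])
    (out / "calibration.json").write_text(json.dumps(model.to_dict(), indent=1))
    log.info("fitted calibration: %s", model.summary())


def _stage_kinetics(config: RunConfig, out: Path) -> None:
    for name in ("tracks.csv", "calibration.json"):
        if not (out / name).exists():
            raise FileNotFoundError(out / name)
    tracks = pd.read_csv(out / "tracks.csv")
    model = cal.CalibrationModel.from_dict(json.loads((out / "calibration.json").read_text()))
    wide = tracks.pivot(index="frame", columns="cell_id", values="iws_pm_um2")
    times = tracks.groupby("frame").t_s.first().to_numpy()
    iws = np.clip(wide.to_numpy(), 0.0, None)
    force = model.slope_force * iws
    energy = model.slope_energy * iws
    # detection floor: the calibrated force of a one-raw-pixel segment at
    # the segmentation noise floor
    floor_iws = segmentation.MIN_NOISE_FLOOR_PM * 625.0
    floor_force = model.slope_force * floor_iws
    tc = kinetics.population_timecourse(times, force, detection_floor=floor_force)
    tc.to_csv(out / "force_timecourse.csv", index=False)
    t_edges = np.linspace(times[0], times[-1] + 1e-9, config.n_time_bins + 1)
    v_max = float(np.nanmax(force)) if np.isfinite(force).any() else 1.0
    v_edges = np.linspace(0.0, max(v_max, 1e-9), config.n_value_bins + 1)
    spec = kinetics.compute_spectrogram(times, force, t_edges, v_edges, "force")
    pd.DataFrame(spec.frequencies).to_csv(out / "spectrogram_force.csv", index=False)
    (out / "spectrogram_bins.json").write_text(
        json.dumps(
            {
                "quantity": "force",
                "time_edges_s": spec.time_edges.tolist(),
                "value_edges_nN": spec.value_edges.tolist(),
            },
            indent=1,
        )
    )
    # per-cell sigmoid fits of calibrated energy
    fits = []
    for j, cell_id in enumerate(wide.columns):
        try:
            fit = kinetics.fit_sigmoid(times, energy[:, j])
        except (RuntimeError, ValueError):
            continue
        fits.append((cell_id, fit.saturation, fit.rate, fit.midpoint, fit.rmse, fit.degenerate))
    pd.DataFrame(
        fits, columns=["cell_id", "saturation_pJ", "rate_1_per_s", "midpoint_s", "rmse", "degenerate"]
    ).to_csv(out / "sigmoid_fits.csv", index=False)
    if config.plot:
        _plot_kinetics(out, times, tc, spec)


def _plot_kinetics(out: Path, times, timecourse, spec) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].plot(timecourse.t_s / 60, timecourse["mean"], label="mean")
    axes[0].plot(timecourse.t_s / 60, timecourse["mode"], label="mode")
    axes[0].set_xlabel("time (min)")
    axes[0].set_ylabel("adhesion force (nN)")
    axes[0].legend()
    freq = np.where(spec.frequencies > 0, spec.frequencies, np.nan)
    axes[1].pcolormesh(
        spec.time_edges / 60, spec.value_edges, freq, norm=LogNorm(), cmap="viridis"
    )
    axes[1].set_xlabel("time (min)")
    axes[1].set_ylabel("adhesion force (nN)")
    fig.tight_layout()
    fig.savefig(out / "kinetics.png", dpi=120)
    plt.close(fig)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "fit_threshold": _stage_fit_threshold,
    "eval_fd": _stage_eval_fd,
    "calibrate": _stage_calibrate,
    "kinetics": _stage_kinetics,
}

# fit_threshold precedes segment: the whole-stack segmentation needs the
# fitted saturation-threshold model
_STAGE_ORDER = ("simulate", "fit_threshold", "segment", "eval_fd", "calibrate", "kinetics")


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages in order; returns the run directory.

    Every artifact is written under ``config.out_dir`` together with a
    config echo (``run_config.yaml``); any stage failure aborts the run
    with the stage name in the raised :class:`StageError`.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    echo = dataclasses.asdict(config)
    echo["stages"] = list(config.stages)
    (out / "run_config.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))
    for stage in _STAGE_ORDER:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, out)
        except Exception as err:
            raise StageError(stage, str(err)) from err
        log.info("stage %-13s done in %.1f s", stage, time.perf_counter() - t0)
    return out
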