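"""Population-level adhesion kinetics statistics.

Once tracks are calibrated to force/energy, three summaries describe the
population: (1) per-cell sigmoid fits of the adhesion build-up, E(t) =
E_sat / (1 + exp(−r(t − t₀))), whose saturation value and rate constant
characterise the extent and speed of spreading; (2) per-timepoint
log-normal fits of the across-cell force distribution, whose derived mean,
mode and variance trace the population's heterogeneity over time; and
(3) adhesion spectrograms — time-resolved normalised histograms of the
per-cell values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SigmoidFit",
    "LogNormalFit",
    "Spectrogram",
    "fit_sigmoid",
    "fit_lognormal",
    "population_timecourse",
    "compute_spectrogram",
]


@dataclass(frozen=True)
class SigmoidFit:
    """Logistic fit E(t) = saturation / (1 + exp(-rate (t - midpoint)))."""

    saturation: float  # pJ (or nN, per the fitted quantity)
    rate: float  # 1/s
    midpoint: float  # s
    rmse: float
    degenerate: bool = False

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.saturation / (1.0 + np.exp(-self.rate * (t - self.midpoint)))

    def summary(self) -> str:
        tag = "  [degenerate]" if self.degenerate else ""
        return (
            f"Sigmoid fit: saturation = {self.saturation:.4g}, rate = {self.rate:.4g} 1/s, "
            f"midpoint = {self.midpoint:.4g} s, RMSE = {self.rmse:.3g}{tag}"
        )


@dataclass(frozen=True)
class LogNormalFit:
    """Log-normal MLE on the natural-log scale, with closed-form moments."""

    mu_log: float
    sigma_log: float
    n: int
    degenerate: bool = False

    @property
    def mean(self) -> float:
        return float(np.exp(self.mu_log + self.sigma_log**2 / 2))

    @property
    def median(self) -> float:
        return float(np.exp(self.mu_log))

    @property
    def mode(self) -> float:
        return float(np.exp(self.mu_log - self.sigma_log**2))

    @property
    def variance(self) -> float:
        s2 = self.sigma_log**2
        return float((np.exp(s2) - 1.0) * np.exp(2 * self.mu_log + s2))

    def summary(self) -> str:
        return (
            f"Log-normal fit (n={self.n}): mu={self.mu_log:.4g}, sigma={self.sigma_log:.4g}; "
            f"mode={self.mode:.4g} <= median={self.median:.4g} <= mean={self.mean:.4g}"
        )


@dataclass
class Spectrogram:
    """Time-resolved relative-frequency histogram of a per-cell quantity."""

    time_edges: np.ndarray  # s
    value_edges: np.ndarray  # quantity units
    frequencies: np.ndarray  # (n_value_bins, n_time_bins), columns sum to 1
    quantity: str = "force"
    empty_columns: np.ndarray = field(default=None)  # boolean per time bin


def _logistic(t, sat, rate, t0):
    return sat / (1.0 + np.exp(-rate * (t - t0)))


def fit_sigmoid(times, values) -> SigmoidFit:
    """Least-squares 3-parameter logistic fit of an adhesion time series.

    Initial guesses come from the data: saturation from the late plateau,
    midpoint from the half-maximum crossing, rate from the central slope.
    A series with no rise (constant, or monotone decreasing) is returned
    with ``degenerate=True`` — the rate is unidentifiable there.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be matching 1-D arrays")
    if t.size < 10:
        raise ValueError("need at least 10 samples spanning rise and plateau")

    y_max = float(y.max())
    rise = y_max - float(y.min())
    if y_max <= 0 or rise <= 1e-12 * max(abs(y_max), 1.0):
        return SigmoidFit(max(y_max, 0.0), 0.0, float(t[t.size // 2]), float(np.std(y)), True)

    sat0 = y_max
    half = y.min() + 0.5 * rise
    t0_0 = float(t[np.argmin(np.abs(y - half))])
    span = float(t[-1] - t[0])
    r0 = 4.0 / max(span / 4.0, np.finfo(float).tiny)
    try:
        popt, _ = curve_fit(
            _logistic,
            t,
            y,
            p0=(sat0, r0, t0_0),
            bounds=([1e-12, 1e-9, t[0] - 10 * span], [np.inf, np.inf, t[-1] + 10 * span]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"sigmoid fit did not converge: {err}") from err
    resid = y - _logistic(t, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return SigmoidFit(float(popt[0]), float(popt[1]), float(popt[2]), rmse)


def fit_lognormal(samples) -> LogNormalFit:
    """Log-moment MLE of a log-normal distribution.

    mu = mean(ln x), sigma = population SD of ln x. All samples must be
    strictly positive; an all-equal sample yields sigma = 0 and is flagged
    degenerate.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D sample of at least 3 values")
    if np.any(x <= 0):
        raise ValueError("log-normal fit requires strictly positive samples")
    logs = np.log(x)
    mu = float(np.mean(logs))
    sigma = 0.0 if np.ptp(logs) == 0 else float(np.std(logs))  # population (MLE) form
    return LogNormalFit(mu, sigma, int(x.size), degenerate=sigma == 0.0)


def population_timecourse(
    times: np.ndarray,
    values: np.ndarray,
    detection_floor: float = 0.0,
    min_cells: int = 3,
) -> "pd.DataFrame":
    """Per-timepoint log-normal fits of the across-cell distribution.

    Parameters
    ----------
    times:
        (T,) frame times in s.
    values:
        (T, n_cells) calibrated per-cell values (force nN or energy pJ).
    detection_floor:
        Cells at or below this value at a timepoint are excluded from that
        timepoint's fit (noise below the segmentation floor).
    min_cells:
        Timepoints with fewer included cells are emitted as missing (NaN),
        not zero.

    Returns a DataFrame with columns t_s, n, mu_log, sigma_log, mean,
    mode, variance.
    """
    import pandas as pd

    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != times.size:
        raise ValueError("values must be (n_times, n_cells)")
    rows = []
    for i, t in enumerate(times):
        sample = values[i]
        sample = sample[np.isfinite(sample) & (sample > detection_floor)]
        if sample.size < min_cells:
            rows.append((t, sample.size, *([np.nan] * 5)))
            continue
        fit = fit_lognormal(sample)
        rows.append((t, fit.n, fit.mu_log, fit.sigma_log, fit.mean, fit.mode, fit.variance))
    return pd.DataFrame(
        rows, columns=["t_s", "n", "mu_log", "sigma_log", "mean", "mode", "variance"]
    )


def compute_spectrogram(
    times: np.ndarray,
    values: np.ndarray,
    time_edges: np.ndarray,
    value_edges: np.ndarray,
    quantity: str = "force",
) -> Spectrogram:
    """Adhesion spectrogram: per-time-bin normalised histograms.

    For each time bin, the per-cell values of all frames falling in the bin
    are histogrammed over ``value_edges`` and normalised to relative
    frequency (columns sum to 1 wherever any value fell inside the range).
    Stored frequencies are linear; any log scaling is presentation-only.
    Empty time bins yield all-zero columns, flagged in ``empty_columns``.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    time_edges = np.asarray(time_edges, dtype=float)
    value_edges = np.asarray(value_edges, dtype=float)
    for name, edges in (("time_edges", time_edges), ("value_edges", value_edges)):
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError(f"{name} must be strictly increasing with >= 2 edges")
    if values.ndim != 2 or values.shape[0] != times.size:
        raise ValueError("values must be (n_times, n_cells)")
    n_tb = time_edges.size - 1
    n_vb = value_edges.size - 1
    freqs = np.zeros((n_vb, n_tb))
    empty = np.zeros(n_tb, dtype=bool)
    t_idx = np.digitize(times, time_edges) - 1
    for b in range(n_tb):
        sel = values[(t_idx == b)].ravel()
        sel = sel[np.isfinite(sel)]
        counts, _ = np.histogram(sel, bins=value_edges)
        total = counts.sum()
        if total == 0:
            empty[b] = True
            continue
        freqs[:, b] = counts / total
    if empty.any():
        warnings.warn(f"{int(empty.sum())} empty time bin(s) in spectrogram", stacklevel=2)
    return Spectrogram(time_edges, value_edges, freqs, quantity, empty)
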