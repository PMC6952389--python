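"""Adaptive per-cell thresholding of biosensor images.

A single global WS cutoff cannot separate every cell from the background:
strongly adhering cells need a high cutoff while faint ones disappear under
it. Instead, each cell gets its own *adequate threshold* (AT) — the cutoff
at which the cell's above-threshold biosensor area equals its footprint
area measured independently on a brightfield image. Across cells the AT
follows a saturation law in the cell's maximal pixel value WS_m,

    AT(WS_m) = a · WS_m / (b + WS_m),

so once (a, b) are fitted on a calibration set of cells with brightfield
masks, thresholds for all further cells can be predicted from the
biosensor image alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SaturationThresholdModel",
    "find_adequate_threshold",
    "fit_at_model",
    "predict_threshold",
]


@dataclass(frozen=True)
class SaturationThresholdModel:
    """Fitted saturation law AT = a·WS_m/(b + WS_m).

    Attributes
    ----------
    a:
        Asymptotic threshold in pm (AT for an infinitely bright cell).
    b:
        Half-saturation maximal pixel value in pm: AT(b) = a/2.
    r_squared:
        Coefficient of determination of the fit (1 for noiseless data).
    n_cells:
        Number of (WS_m, AT) pairs used in the fit.
    """

    a: float
    b: float
    r_squared: float = float("nan")
    n_cells: int = 0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"saturation parameters must be positive, got a={self.a}, b={self.b}")

    def predict(self, ws_m):
        return predict_threshold(self, ws_m)

    def summary(self) -> str:
        lines = [
            "Saturation threshold model  AT = a*WS_m/(b + WS_m)",
            f"  a (asymptotic threshold) : {self.a:10.1f} pm",
            f"  b (half-saturation WS_m) : {self.b:10.1f} pm",
            f"  R^2                      : {self.r_squared:10.4f}",
            f"  n cells                  : {self.n_cells:10d}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "a_pm": self.a,
            "b_pm": self.b,
            "r_squared": self.r_squared,
            "n_cells": self.n_cells,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SaturationThresholdModel":
        return cls(d["a_pm"], d["b_pm"], d.get("r_squared", float("nan")), d.get("n_cells", 0))


def predict_threshold(model: SaturationThresholdModel, ws_m):
    """Adequate threshold (pm) for a cell with maximal pixel value ``ws_m``.

    Strictly increasing in ``ws_m`` and bounded above by ``model.a``.
    """
    ws_m = np.asarray(ws_m, dtype=float)
    if np.any(ws_m < 0):
        raise ValueError("ws_m must be non-negative")
    out = model.a * ws_m / (model.b + ws_m)
    return float(out) if out.ndim == 0 else out


def find_adequate_threshold(
    frame: np.ndarray,
    pixel_area: float,
    target_area: float,
    tol: float | None = None,
    max_iter: int = 60,
) -> float:
    """Threshold at which the above-threshold area matches ``target_area``.

    Bisects the monotone non-increasing map threshold ↦ area(WS > threshold)
    over the cell's segment ``frame`` (typically an interpolated Voronoi
    segment, so the area function is quasi-continuous). Returns the first
    bisection iterate whose area is within ``tol`` of the target; if the
    discrete area function jumps over the target the midpoint of the final
    bracketing step is returned.

    Parameters
    ----------
    frame:
        WS values (pm) of the pixels belonging to the cell's segment.
    pixel_area:
        Area of one (interpolated) pixel in µm².
    target_area:
        Footprint area to match, µm² (e.g. from a brightfield mask).
    tol:
        Acceptable |area - target_area| in µm²; default one pixel area,
        the finest resolvable step.
    """
    values = np.asarray(frame, dtype=float).ravel()
    if pixel_area <= 0:
        raise ValueError("pixel_area must be > 0")
    if target_area <= 0:
        raise ValueError("target_area must be > 0")
    if tol is None:
        tol = pixel_area

    def area(th: float) -> float:
        return float(np.count_nonzero(values > th)) * pixel_area

    lo = 0.0
    if area(lo) + tol < target_area:
        raise ValueError(
            f"target_area {target_area:.1f} µm² exceeds the zero-threshold area "
            f"{area(lo):.1f} µm²; unreachable"
        )
    hi = float(values.max())
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        a_mid = area(mid)
        if abs(a_mid - target_area) <= tol:
            return mid
        if a_mid > target_area:
            lo = mid  # too many pixels survive -> raise threshold
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _saturation(ws_m, a, b):
    return a * ws_m / (b + ws_m)


def fit_at_model(ws_m, at) -> SaturationThresholdModel:
    """Nonlinear least-squares fit of the saturation law to (WS_m, AT) pairs.

    Initial guess a₀ = max(AT), b₀ = median(WS_m); both parameters
    constrained positive. Raises on degenerate designs (fewer than 3 pairs,
    all WS_m equal, or all AT ≈ 0).
    """
    ws_m = np.asarray(ws_m, dtype=float)
    at = np.asarray(at, dtype=float)
    if ws_m.shape != at.shape or ws_m.ndim != 1:
        raise ValueError("ws_m and at must be 1-D arrays of equal length")
    if ws_m.size < 3:
        raise ValueError("need at least 3 (WS_m, AT) pairs")
    if np.ptp(ws_m) == 0:
        raise ValueError("degenerate design: all WS_m values equal")
    if np.max(np.abs(at)) == 0:
        raise ValueError("degenerate data: all adequate thresholds are zero")

    p0 = (float(at.max()), float(np.median(ws_m)))
    try:
        popt, pcov = curve_fit(
            _saturation, ws_m, at, p0=p0, bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=10000
        )
    except RuntimeError as err:  # pragma: no cover - pathological data
        raise RuntimeError(f"saturation fit did not converge: {err}") from err
    residuals = at - _saturation(ws_m, *popt)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((at - at.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return SaturationThresholdModel(float(popt[0]), float(popt[1]), r2, int(ws_m.size))
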