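"""Linear calibration of the biosensor IWS signal to adhesion force/energy.

Combined experiments measure, on the same single cells, the integrated
wavelength shift (IWS, pm·µm²) from the biosensor and the adhesion force
(nN) and energy (pJ) from FluidFM detachment. Both mechanical quantities
are proportional to IWS, so the calibration is a zero-intercept linear
fit

    F = s_F · IWS,      E = s_E · IWS,

with Pearson correlation coefficients as the diagnostic of linearity.
Zero IWS (no cell) must map to zero force, hence the intercept is not
estimated; a free-intercept fit is reported alongside as a diagnostic
only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CalibrationModel", "fit_calibration", "apply_calibration"]


def _zero_intercept_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope through the origin and its standard error."""
    sxx = float(np.sum(x * x))
    slope = float(np.sum(x * y)) / sxx
    resid = y - slope * x
    dof = max(x.size - 1, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    return slope, se


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted IWS→force and IWS→energy proportionality.

    Attributes
    ----------
    slope_force:
        nN per pm·µm².
    slope_energy:
        pJ per pm·µm².
    corr_force, corr_energy:
        Pearson correlation of the raw (IWS, force) and (IWS, energy) pairs.
    se_force, se_energy:
        Standard errors of the two slopes.
    intercept_force, intercept_energy:
        Diagnostic free-intercept fits (not used by :func:`apply_calibration`).
    """

    slope_force: float
    slope_energy: float
    corr_force: float = float("nan")
    corr_energy: float = float("nan")
    se_force: float = float("nan")
    se_energy: float = float("nan")
    n_cells: int = 0
    intercept_force: float = float("nan")
    intercept_energy: float = float("nan")

    def summary(self) -> str:
        return "\n".join(
            [
                "IWS calibration (zero-intercept least squares)",
                f"  force slope  : {self.slope_force:.4e} ± {self.se_force:.1e} nN/(pm·µm²)"
                f"   C = {self.corr_force:.4f}",
                f"  energy slope : {self.slope_energy:.4e} ± {self.se_energy:.1e} pJ/(pm·µm²)"
                f"   C = {self.corr_energy:.4f}",
                f"  n cells      : {self.n_cells}",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "slope_force_nN_per_pm_um2": self.slope_force,
            "slope_energy_pJ_per_pm_um2": self.slope_energy,
            "corr_force": self.corr_force,
            "corr_energy": self.corr_energy,
            "se_force": self.se_force,
            "se_energy": self.se_energy,
            "n_cells": self.n_cells,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            d["slope_force_nN_per_pm_um2"],
            d["slope_energy_pJ_per_pm_um2"],
            d.get("corr_force", float("nan")),
            d.get("corr_energy", float("nan")),
            d.get("se_force", float("nan")),
            d.get("se_energy", float("nan")),
            d.get("n_cells", 0),
        )


def fit_calibration(iws, force, energy) -> CalibrationModel:
    """Fit the IWS→(force, energy) calibration on per-cell triples.

    Requires at least 3 cells and a non-degenerate IWS design. Negative
    slopes are admitted (the correlation then diagnoses the problem) but
    the data are expected to be positively proportional.
    """
    iws = np.asarray(iws, dtype=float)
    force = np.asarray(force, dtype=float)
    energy = np.asarray(energy, dtype=float)
    if not (iws.shape == force.shape == energy.shape) or iws.ndim != 1:
        raise ValueError("iws, force, energy must be 1-D arrays of equal length")
    if iws.size < 3:
        raise ValueError("need at least 3 cells to calibrate")
    if np.ptp(iws) == 0:
        raise ValueError("rank-deficient design: all IWS values equal")

    slope_f, se_f = _zero_intercept_fit(iws, force)
    slope_e, se_e = _zero_intercept_fit(iws, energy)
    corr_f = float(stats.pearsonr(iws, force).statistic)
    corr_e = float(stats.pearsonr(iws, energy).statistic)
    lin_f = stats.linregress(iws, force)
    lin_e = stats.linregress(iws, energy)
    return CalibrationModel(
        slope_f, slope_e, corr_f, corr_e, se_f, se_e, int(iws.size),
        float(lin_f.intercept), float(lin_e.intercept),
    )


def apply_calibration(iws, model: CalibrationModel, clip_negative: bool = True):
    """Convert IWS series to (force nN, energy pJ) with the fitted slopes.

    Negative IWS values — possible for noise below threshold — are clamped
    to 0 before scaling. Returns ``(force, energy)`` arrays (scalars in,
    scalars out).
    """
    arr = np.asarray(iws, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if clip_negative and np.any(arr < 0):
        import warnings

        warnings.warn("negative IWS values clamped to 0", stacklevel=2)
        arr = np.clip(arr, 0.0, None)
    force = model.slope_force * arr
    energy = model.slope_energy * arr
    if scalar:
        return float(force[0]), float(energy[0])
    return force, energy
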