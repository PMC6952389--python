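"""Fluidic force microscopy (FluidFM) curve evaluation.

A hollow cantilever with a circular aperture is pressed onto an adhered
cell, negative pressure fixes the cell to the aperture, and the cantilever
is retracted while its deflection is recorded. The force-distance curve is
evaluated into two scalars: the adhesion force (magnitude of the deepest
point after rebasing the curve so its final sample reads 0 nN) and the
adhesion energy (integral of |force| over the retraction distance between
the zero crossings bracketing the adhesive dip).

Raw photodetector voltages are converted to force with two calibration
factors: the inverse optical lever sensitivity (m/V, from hard-contact
approach curves) and the cantilever spring constant (N/m, an input —
measured on the instrument, e.g. by the Sader method).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProbeCalibration",
    "FDCurve",
    "AdhesionMeasurement",
    "fit_sensitivity",
    "deflection_to_force",
    "evaluate_fd",
    "compute_probe_limits",
]

MBAR_TO_PA = 100.0


@dataclass(frozen=True)
class ProbeCalibration:
    """FluidFM probe parameters.

    spring_constant in N/m; sensitivity in m/V; aperture_diameter in µm;
    max_negative_pressure in mbar (magnitude); retraction_speed in µm/s.
    """

    spring_constant: float = 2.0
    sensitivity: float | None = None
    aperture_diameter: float = 8.0
    max_negative_pressure: float = 700.0
    retraction_speed: float = 1.0

    def __post_init__(self) -> None:
        for name in ("spring_constant", "aperture_diameter", "max_negative_pressure", "retraction_speed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sensitivity is not None and self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive when set")


@dataclass
class FDCurve:
    """Force-distance record of one retraction.

    ``z`` is the strictly monotone retraction position in µm; ``force`` the
    calibrated force in nN, or ``psd`` the raw detector signal in mV when
    the curve is not yet calibrated.
    """

    z: np.ndarray
    force: np.ndarray | None = None
    psd: np.ndarray | None = None
    calibration: ProbeCalibration | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.size < 2:
            raise ValueError("an FD curve needs at least 2 samples")
        dz = np.diff(self.z)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z must be strictly monotone")
        for name in ("force", "psd"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if val.shape != self.z.shape:
                    raise ValueError(f"{name} must match z in length")
                setattr(self, name, val)
        if self.force is None and self.psd is None:
            raise ValueError("curve must carry force or raw psd data")

    def calibrated(self) -> "FDCurve":
        """Return a copy whose force channel is populated (nN)."""
        if self.force is not None:
            return self
        if self.calibration is None:
            raise ValueError("raw curve without calibration metadata")
        force = deflection_to_force(self.psd, self.calibration)
        return FDCurve(self.z, force=force, psd=self.psd, calibration=self.calibration)


@dataclass
class AdhesionMeasurement:
    """Evaluated adhesion parameters of one detachment."""

    adhesion_force: float  # nN
    adhesion_energy: float  # pJ
    qc_flags: list[str] = field(default_factory=list)


def fit_sensitivity(approach_curves, contact_slices=None) -> float:
    """Inverse optical lever sensitivity (m/V) from hard-contact approaches.

    Each record is a (displacement_m, deflection_V) pair of arrays; a first
    order polynomial is fitted to the contact region of each (the whole
    record unless ``contact_slices`` gives per-curve index slices) and the
    arithmetic mean of the fitted slopes is returned.
    """
    if len(approach_curves) < 1:
        raise ValueError("need at least one approach curve")
    slopes = []
    for i, (disp, defl) in enumerate(approach_curves):
        disp = np.asarray(disp, dtype=float)
        defl = np.asarray(defl, dtype=float)
        if contact_slices is not None:
            sl = contact_slices[i]
            disp, defl = disp[sl], defl[sl]
        if disp.size < 3:
            raise ValueError("contact region must contain at least 3 points")
        slope = np.polynomial.polynomial.polyfit(defl, disp, 1)[1]
        slopes.append(slope)
    sens = float(np.mean(slopes))
    if sens <= 0:
        raise ValueError(f"non-positive fitted sensitivity ({sens:g} m/V); "
                         "flat or inverted contact region")
    return sens


def deflection_to_force(psd_mv, calib: ProbeCalibration) -> np.ndarray:
    """Convert raw PSD signal (mV) to force (nN).

    force = psd × sensitivity × spring_constant; the unit chain
    mV · (m/V) · (N/m) gives 10⁻³ N per (mV·m/V·N/m), i.e. 10⁶ nN.
    """
    if calib.sensitivity is None:
        raise ValueError("probe calibration lacks the optical lever sensitivity")
    psd = np.asarray(psd_mv, dtype=float)
    newton = psd * 1e-3 * calib.sensitivity * calib.spring_constant
    return newton * 1e9


def _zero_crossing(z0, f0, z1, f1):
    """z of the linearly interpolated zero between two samples."""
    if f0 == f1:
        return z0
    return z0 + (z1 - z0) * (0.0 - f0) / (f1 - f0)


def evaluate_fd(curve: FDCurve, f_max_nn: float | None = None) -> AdhesionMeasurement:
    """Evaluate a retraction curve into adhesion force and energy.

    The final sample is taken as the free cantilever (force 0 nN) and the
    whole curve is shifted accordingly. The adhesion force is the magnitude
    of the rebased curve's absolute minimum. The adhesion energy is the
    integral (trapezoidal) of |force| over z between the last zero crossing
    before the minimum — or the start of the curve if the force never
    crosses zero before it — and the first zero crossing after it, with
    crossings located by linear interpolation; 1 nN·µm = 1 fJ = 10⁻³ pJ.

    ``f_max_nn`` is the probe's holding-force limit; a minimum within 5% of
    it is flagged, since the cell-cantilever contact, not the cell-surface
    adhesion, may have ruptured.
    """
    curve = curve.calibrated()
    z = curve.z
    force = curve.force.copy()
    if z[0] > z[-1]:  # store retraction in increasing z
        z = z[::-1].copy()
        force = force[::-1].copy()
    force = force - force[-1]  # rebase: free cantilever at the end reads 0
    flags: list[str] = []
    imin = int(np.argmin(force))
    fmin = force[imin]
    if fmin >= 0:
        if np.allclose(force, 0):
            flags.append("all-zero")
        return AdhesionMeasurement(0.0, 0.0, flags)
    adhesion_force = float(-fmin)

    # bracket the adhesive dip with interpolated zero crossings
    left_i = imin
    while left_i > 0 and force[left_i - 1] < 0:
        left_i -= 1
    if left_i == 0:
        z_left = z[0]
        if force[0] < 0:
            flags.append("no-baseline-return")
    else:
        z_left = _zero_crossing(z[left_i - 1], force[left_i - 1], z[left_i], force[left_i])
    right_i = imin
    while right_i < len(force) - 1 and force[right_i + 1] < 0:
        right_i += 1
    if right_i == len(force) - 1:
        z_right = z[-1]
    else:
        z_right = _zero_crossing(z[right_i], force[right_i], z[right_i + 1], force[right_i + 1])

    zz = np.concatenate(([z_left], z[left_i : right_i + 1], [z_right]))
    ff = np.concatenate(([0.0], force[left_i : right_i + 1], [0.0]))
    energy_nn_um = float(np.trapezoid(np.abs(ff), zz))
    adhesion_energy = energy_nn_um * 1e-3  # nN·µm = fJ -> pJ

    if f_max_nn is not None and adhesion_force >= 0.95 * f_max_nn:
        flags.append("near-f-max")
    return AdhesionMeasurement(adhesion_force, adhesion_energy, flags)


def compute_probe_limits(calib: ProbeCalibration) -> tuple[float, float]:
    """Probe operating limits: (holding force µN, loading rate µN/s).

    The suction through the aperture sets the maximal measurable force,
    f_max = |P| · π (d/2)²; the loading rate during retraction is
    spring_constant × retraction_speed.
    """
    radius_m = calib.aperture_diameter / 2 * 1e-6
    f_max_n = abs(calib.max_negative_pressure) * MBAR_TO_PA * np.pi * radius_m**2
    f_max_un = f_max_n * 1e6
    loading_rate = calib.spring_constant * calib.retraction_speed  # (N/m)(µm/s) = µN/s
    return float(f_max_un), float(loading_rate)
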