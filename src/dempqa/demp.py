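"""The dynamical effective-measurement-plane (DEMP) model.

A 2D ion-chamber array measures as if on a single plane — the effective
measurement plane (EMP) — whose depth below the detector surface depends
on the beam's gantry angle.  At gantry 0 the EMP coincides with the
manufacturer-marked reference plane 3.5 mm below the surface (the OEMP);
at other angles it is displaced by an offset ``delta_d(theta)``, positive
toward the detector bottom.  The model is left-right symmetric: theta and
360 - theta share the same EMP, so offsets are stored on the half-grid
0..180 deg in 10 deg steps.  A second parameter, the effective density
``rho`` of the 0.75 mm anode layer beneath the chambers, captures the
extra attenuation seen by beams entering from below (PA directions).

Offsets between grid angles are linearly interpolated, except strictly
inside the intervals (80, 100) and (260, 280) deg, where the angular
response may fluctuate erratically and interpolation is refused by
default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import Beam, DensityVolume
from .dose_engine import EngineParams, point_dose

__all__ = [
    "DEMPModel",
    "CFCurve",
    "ExcludedAngleError",
    "canonical_angle",
    "cf_curve",
    "DEFAULT_GRID_ANGLES",
    "DEFAULT_EXCLUDED_INTERVALS",
]

DEFAULT_GRID_ANGLES: tuple[float, ...] = tuple(10.0 * k for k in range(19))
DEFAULT_EXCLUDED_INTERVALS: tuple[tuple[float, float], ...] = ((80.0, 100.0), (260.0, 280.0))

_ANGLE_RESOLUTION = 0.1  # linac gantry scale


class ExcludedAngleError(ValueError):
    """Raised when an offset is requested strictly inside an excluded interval."""

    def __init__(self, theta_deg: float, interval: tuple[float, float]):
        self.theta_deg = theta_deg
        self.interval = interval
        super().__init__(
            f"gantry angle {theta_deg:g} deg lies strictly inside the excluded "
            f"interval ({interval[0]:g}, {interval[1]:g}) deg where interpolated "
            "offsets are unreliable"
        )


def canonical_angle(theta_deg: float) -> float:
    """Fold an angle onto [0, 180] using the left-right symmetry."""
    t = float(theta_deg) % 360.0
    return t if t <= 180.0 else 360.0 - t


@dataclass
class DEMPModel:
    """Angle grid of EMP depth offsets plus the effective anode density."""

    delta_d_mm: np.ndarray = field(default_factory=lambda: np.zeros(19))
    rho_g_cm3: float = 2.0
    angles_deg: np.ndarray = field(
        default_factory=lambda: np.asarray(DEFAULT_GRID_ANGLES)
    )
    excluded_intervals: tuple[tuple[float, float], ...] = DEFAULT_EXCLUDED_INTERVALS
    oemp_depth_mm: float = 3.5
    policy_on_excluded: str = "error"  # or "warn"

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.delta_d_mm = np.asarray(self.delta_d_mm, dtype=float)
        if len(self.delta_d_mm) != len(self.angles_deg):
            raise ValueError("one offset per grid angle is required")
        if not np.all(np.isfinite(self.delta_d_mm)):
            raise ValueError("offsets must be finite")
        if self.rho_g_cm3 <= 0:
            raise ValueError("effective anode density must be positive")
        if self.policy_on_excluded not in ("error", "warn"):
            raise ValueError("policy_on_excluded must be 'error' or 'warn'")

    # -- evaluation --------------------------------------------------------

    def _check_excluded(self, theta_norm: float) -> None:
        snapped = round(theta_norm / _ANGLE_RESOLUTION) * _ANGLE_RESOLUTION
        for lo, hi in self.excluded_intervals:
            if lo < snapped < hi:
                # served exactly if it is a grid angle (grid hits are trusted)
                folded = canonical_angle(snapped)
                if np.any(np.isclose(self.angles_deg, folded, atol=_ANGLE_RESOLUTION / 2)):
                    return
                if self.policy_on_excluded == "error":
                    raise ExcludedAngleError(theta_norm, (lo, hi))
                import warnings

                warnings.warn(str(ExcludedAngleError(theta_norm, (lo, hi))))
                return

    def delta_d(self, theta_deg: float) -> float:
        """Offset at any gantry angle: symmetry fold, then linear interpolation."""
        t = float(theta_deg) % 360.0
        self._check_excluded(t)
        folded = canonical_angle(t)
        return float(np.interp(folded, self.angles_deg, self.delta_d_mm))

    def emp_depth(self, theta_deg: float) -> float:
        """EMP depth below the detector surface, mm (OEMP depth + offset)."""
        return self.oemp_depth_mm + self.delta_d(theta_deg)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "oemp_depth_mm": self.oemp_depth_mm,
            "angles_deg": self.angles_deg.tolist(),
            "delta_d_mm": self.delta_d_mm.tolist(),
            "rho_g_cm3": self.rho_g_cm3,
            "excluded_intervals": [list(iv) for iv in self.excluded_intervals],
            "policy": self.policy_on_excluded,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "DEMPModel":
        return cls(
            delta_d_mm=np.asarray(doc["delta_d_mm"], dtype=float),
            rho_g_cm3=float(doc["rho_g_cm3"]),
            angles_deg=np.asarray(doc["angles_deg"], dtype=float),
            excluded_intervals=tuple(tuple(iv) for iv in doc.get("excluded_intervals", DEFAULT_EXCLUDED_INTERVALS)),
            oemp_depth_mm=float(doc.get("oemp_depth_mm", 3.5)),
            policy_on_excluded=str(doc.get("policy", "error")),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "DEMPModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class CFCurve:
    """Angular correction-factor curve for the central pixel chamber."""

    angles_deg: np.ndarray
    cf_values: np.ndarray

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.cf_values = np.asarray(self.cf_values, dtype=float)

    def derivative(self) -> tuple[np.ndarray, np.ndarray]:
        """Finite-difference dCF/dtheta at interval midpoints."""
        mid = 0.5 * (self.angles_deg[1:] + self.angles_deg[:-1])
        d = np.diff(self.cf_values) / np.diff(self.angles_deg)
        return mid, d


def cf_curve(
    model: DEMPModel,
    engine: EngineParams,
    phantom: DensityVolume,
    angles_deg=None,
    aperture_mm=(-20.0, 20.0, -50.0, 50.0),
    mu: float = 100.0,
    setup_offset_mm: float = 0.0,
) -> CFCurve:
    """Reproduce the correction-factor curve of the central chamber.

    For each angle the calibration beam (4 cm x 10 cm) is evaluated at
    the center of the EMP and at the center of the iso-plane (the OEMP);
    CF is the ratio EMP dose / OEMP dose.  ``setup_offset_mm`` shifts
    both sampling points vertically, emulating an AP-PA setup error.
    """
    phantom = phantom.with_anode_density(model.rho_g_cm3)
    surface_z = phantom.meta.get("detector_surface_z_mm", model.oemp_depth_mm)
    if angles_deg is None:
        angles_deg = [
            a
            for a in model.angles_deg
            if not any(lo < a < hi for lo, hi in model.excluded_intervals)
        ]
    angles = np.asarray(angles_deg, dtype=float)
    cfs = np.empty_like(angles)
    for i, a in enumerate(angles):
        beam = Beam(float(a % 360.0), aperture_mm, mu)
        z_emp = surface_z - model.emp_depth(a) + setup_offset_mm
        z_oemp = surface_z - model.oemp_depth_mm + setup_offset_mm
        d = point_dose(beam, phantom, engine, [[0.0, 0.0, z_emp], [0.0, 0.0, z_oemp]])
        if d[1] <= 0:
            raise ZeroDivisionError(
                f"OEMP dose is zero at gantry {a:g} deg; CF undefined"
            )
        cfs[i] = d[0] / d[1]
    return CFCurve(angles_deg=angles, cf_values=cfs)
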