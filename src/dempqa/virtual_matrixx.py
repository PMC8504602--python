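"""Virtual chamber-array: forward simulation of measurements.

Applies a ground-truth DEMP configuration forward — per-beam 3D dose
with the anode at the truth density, planar extraction at the truth EMP
depth, Gaussian volume averaging, chamber sampling — and adds seeded
Gaussian noise, producing the chamber grids a physical array would
deliver.  This makes the calibration (which inverts exactly this
mechanism) and the verification workflow testable without a linac.

Also provides the fixture plan suite: eight open single-beam plans, one
conformal-like seven-beam plan, and four multi-segment pseudo-IMRT
plans standing in for the TG-119 tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .demp import DEMPModel
from .dose_engine import EngineParams, compute_beam_dose, dose_grid_for_depths
from .geometry import Beam, ChamberLayout, DensityVolume, Plan, build_chamber_layout
from .planar import ChamberGrid, convolve_response, extract_planar, sample_at_chambers

__all__ = [
    "NoiseSpec",
    "simulate_measurement",
    "make_test_suite",
    "example_truth_model",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise, sigma as a percentage of the max dose."""

    sigma_pct_of_max: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_pct_of_max < 0:
            raise ValueError("noise sigma must be non-negative")


# Monotone offset table qualitatively matching a calibrated detector:
# zero at normal incidence, growing toward PA irradiation, up to ~1 cm.
_TRUTH_DELTA_D = np.array(
    [0.0, 0.0, 0.1, 0.3, 0.5, 0.8, 1.1, 1.5, 2.0, 2.5,
     3.1, 3.7, 4.4, 5.0, 5.9, 6.9, 8.0, 9.0, 10.0]
)


def example_truth_model(rho_g_cm3: float = 3.5) -> DEMPModel:
    """A plausible ground-truth model used as the injected test fixture."""
    return DEMPModel(delta_d_mm=_TRUTH_DELTA_D.copy(), rho_g_cm3=rho_g_cm3)


def simulate_measurement(
    plan: Plan,
    truth: DEMPModel,
    engine: EngineParams,
    phantom: DensityVolume,
    noise: NoiseSpec | None = None,
    sigma_avg_mm: float = 2.0,
    layout: ChamberLayout | None = None,
    spacing_mm: float = 1.0,
) -> ChamberGrid:
    """Forward-model a chamber-grid measurement of a plan.

    Per beam: 3D dose with the anode ROI at the truth density, planar
    extraction at the truth EMP depth, Gaussian volume averaging of
    width ``sigma_avg_mm``, bilinear sampling at the chamber centers;
    beams are summed and seeded noise of sigma = pct x max dose is
    added.  Negative post-noise values are clipped to zero.
    """
    layout = layout or build_chamber_layout()
    phantom = phantom.with_anode_density(truth.rho_g_cm3)
    surface_z = phantom.meta.get("detector_surface_z_mm", truth.oemp_depth_mm)
    total = None
    for beam in plan.beams:
        depth = truth.emp_depth(beam.gantry_deg)
        grid = dose_grid_for_depths(phantom, [depth], spacing_mm=spacing_mm)
        dose = compute_beam_dose(beam, phantom, engine, grid=grid)
        planar = extract_planar(dose, depth, surface_z_mm=surface_z)
        if sigma_avg_mm > 0:
            planar = convolve_response(planar, sigma_avg_mm)
        sampled = sample_at_chambers(planar, layout)
        total = sampled.values if total is None else total + sampled.values
    if noise is not None and noise.sigma_pct_of_max > 0:
        rng = np.random.default_rng(noise.seed)
        sigma = noise.sigma_pct_of_max / 100.0 * np.nanmax(total)
        total = total + rng.normal(0.0, sigma, size=total.shape)
        neg = np.nansum(total < 0)
        if neg:
            logger.info("clipping %d negative post-noise chamber values to 0", int(neg))
        total = np.clip(total, 0.0, None)
        total = np.where(layout.populated_mask, total, np.nan)
    return ChamberGrid(layout=layout, values=total)


def _imrt_plan(label: str, beam_specs) -> Plan:
    beams = []
    for gantry, segments in beam_specs:
        for (x1, x2, y1, y2), mu in segments:
            beams.append(Beam(gantry, (x1, x2, y1, y2), mu))
    return Plan(label=label, beams=beams)


def make_test_suite(phantom: DensityVolume | None = None) -> list[Plan]:
    """The thirteen-plan verification suite.

    Eight jaw-collimated single-beam plans (4 cm x 4 cm and 5 cm x 3 cm
    at gantry 0, 50, 130, 180 deg), one seven-beam conformal-like plan
    with near-equispaced angles, and four multi-segment pseudo-IMRT
    plans (5-9 beams, 2-5 weighted rectangular segments per beam).  All
    generated angles avoid the excluded intervals (80, 100) and
    (260, 280) deg.
    """
    plans: list[Plan] = []
    for sx, sy, tag in ((40.0, 40.0, "4x4"), (50.0, 30.0, "5x3")):
        for ang in (0.0, 50.0, 130.0, 180.0):
            plans.append(
                Plan(
                    label=f"single_{tag}_{int(ang):03d}",
                    beams=[Beam(ang, (-sx / 2, sx / 2, -sy / 2, sy / 2), 100.0)],
                )
            )
    conf_angles = (0.0, 51.4, 102.9, 154.3, 205.7, 257.1, 308.6)
    plans.append(
        Plan(
            label="conformal_7f",
            beams=[Beam(a, (-30.0, 30.0, -30.0, 30.0), 30.0) for a in conf_angles],
        )
    )
    plans.append(_imrt_plan("imrt_multitarget", [
        (0.0, [((-40, 40, -40, 40), 40.0), ((-15, 15, -15, 15), 25.0)]),
        (51.4, [((-35, 35, -30, 30), 30.0), ((-10, 20, -20, 10), 20.0)]),
        (154.3, [((-30, 30, -35, 35), 30.0), ((-20, 5, -5, 25), 15.0)]),
        (205.7, [((-35, 30, -30, 30), 30.0), ((-5, 25, -25, 5), 20.0)]),
        (308.6, [((-40, 35, -35, 30), 30.0), ((-15, 10, -10, 20), 15.0)]),
    ]))
    plans.append(_imrt_plan("imrt_prostate", [
        (0.0, [((-35, 35, -30, 30), 35.0), ((-12, 12, -18, 6), 20.0)]),
        (75.0, [((-30, 30, -30, 30), 30.0), ((-20, 10, -10, 20), 15.0), ((-5, 15, -15, 5), 10.0)]),
        (135.0, [((-30, 35, -25, 30), 30.0), ((-10, 18, -14, 10), 15.0)]),
        (225.0, [((-35, 30, -30, 25), 30.0), ((-18, 10, -10, 14), 15.0)]),
        (285.0, [((-30, 30, -30, 30), 30.0), ((-10, 20, -20, 10), 15.0), ((-15, 5, -5, 15), 10.0)]),
    ]))
    plans.append(_imrt_plan("imrt_head_neck", [
        (0.0, [((-45, 45, -40, 40), 30.0), ((-25, 25, -30, 10), 18.0), ((-10, 30, -5, 30), 12.0)]),
        (40.0, [((-40, 40, -40, 35), 25.0), ((-20, 25, -25, 15), 15.0)]),
        (105.0, [((-35, 40, -35, 40), 25.0), ((-15, 25, -20, 20), 12.0)]),
        (180.0, [((-40, 40, -40, 40), 25.0), ((-25, 20, -15, 25), 15.0), ((-5, 20, -25, 0), 8.0)]),
        (255.0, [((-40, 35, -40, 35), 25.0), ((-25, 15, -20, 20), 12.0)]),
        (320.0, [((-40, 40, -35, 40), 25.0), ((-25, 20, -15, 25), 15.0)]),
    ]))
    plans.append(_imrt_plan("imrt_c_shape", [
        (0.0, [((-40, 40, -40, 40), 30.0), ((-30, 30, 10, 35), 18.0), ((-30, -10, -35, 10), 12.0)]),
        (51.4, [((-35, 35, -35, 35), 25.0), ((-25, 25, 5, 30), 15.0)]),
        (102.9, [((-35, 35, -35, 35), 25.0), ((10, 30, -30, 30), 12.0)]),
        (154.3, [((-35, 35, -35, 35), 25.0), ((-30, 30, -35, -5), 15.0)]),
        (180.0, [((-40, 40, -40, 40), 20.0), ((-30, -5, -30, 30), 12.0)]),
        (205.7, [((-35, 35, -35, 35), 25.0), ((-30, 30, -35, -5), 15.0)]),
        (257.1, [((-35, 35, -35, 35), 25.0), ((-30, -10, -30, 30), 12.0)]),
        (308.6, [((-35, 35, -35, 35), 25.0), ((-25, 25, 5, 30), 15.0)]),
        (340.0, [((-40, 40, -40, 40), 20.0), ((5, 30, -30, 30), 12.0)]),
    ]))
    return plans
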