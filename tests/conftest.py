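import numpy as np
import pytest
from hypothesis import settings

import dempqa as d

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

# Resolution used for the heavier calibration studies: coarse enough to keep
# the suite fast, fine enough that the forward and inverse models stay
# consistent (both run on the same grid).
CAL_SPACING_MM = 2.5


@pytest.fixture(scope="session")
def engine():
    return d.EngineParams()


@pytest.fixture(scope="session")
def phantom():
    return d.build_slab_phantom()


@pytest.fixture(scope="session")
def truth():
    return d.example_truth_model()


@pytest.fixture(scope="session")
def layout():
    return d.build_chamber_layout()


@pytest.fixture(scope="session")
def calibration_recovery(phantom, engine, truth):
    """Joint (delta_d, rho) fit on noiseless synthetic calibration data."""
    plans = d.make_calibration_plans()
    meas = [
        d.simulate_measurement(
            p, truth, engine, phantom, noise=None, sigma_avg_mm=0.0,
            spacing_mm=CAL_SPACING_MM,
        )
        for p in plans
    ]
    cal_set = d.CalibrationSet(plans=plans, measurements=meas, phantom=phantom, engine=engine)
    cal = d.DEMPCalibration(cal_set, dose_grid_spacing_mm=CAL_SPACING_MM)
    result = cal.fit()
    return {"truth": truth, "result": result, "cal": cal, "cal_set": cal_set}


@pytest.fixture(scope="session")
def oblique_verification(phantom, engine, truth):
    """Corrected and uncorrected verification of a noisy oblique 4x4 beam."""
    plan = d.Plan("single_4x4_130", [d.Beam(130.0, (-20.0, 20.0, -20.0, 20.0), 100.0)])
    meas = d.simulate_measurement(
        plan, truth, engine, phantom, noise=d.NoiseSpec(0.5, seed=123), sigma_avg_mm=2.0
    )
    corrected = d.run_verification(
        plan, truth, meas, response_sigma_mm=2.0, engine=engine, phantom=phantom
    )
    uncorrected = d.run_verification(
        plan, truth, meas, response_sigma_mm=2.0, engine=engine, phantom=phantom,
        corrected=False,
    )
    return {"plan": plan, "measurement": meas, "corrected": corrected, "uncorrected": uncorrected}


@pytest.fixture(scope="session")
def grid_resolution_errors(phantom, engine, truth, layout):
    """Average chamber-wise % difference between 1 mm and 0.8 mm dose grids."""
    from dempqa.dose_engine import dose_grid_for_depths

    ph = phantom.with_anode_density(truth.rho_g_cm3)
    errors = {}
    for angle in truth.angles_deg:
        if any(lo < angle < hi for lo, hi in truth.excluded_intervals):
            continue
        depth = truth.emp_depth(angle)
        beam = d.Beam(float(angle), (-20.0, 20.0, -50.0, 50.0), 100.0)
        grids = []
        for sp in (1.0, 0.8):
            g = dose_grid_for_depths(ph, [depth], spacing_mm=sp)
            dose = d.compute_beam_dose(beam, ph, engine, grid=g)
            planar = d.extract_planar(dose, depth)
            grids.append(d.sample_at_chambers(planar, layout))
        _, avg = d.percent_error_map(grids[0], grids[1])
        errors[float(angle)] = avg
    return errors


@pytest.fixture
def rng():
    return np.random.default_rng(7)
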