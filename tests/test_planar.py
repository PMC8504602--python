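import numpy as np
import pytest
from hypothesis import given, strategies as st

import dempqa as d
from dempqa.dose_engine import Dose3D
from dempqa.geometry import Grid3D
from dempqa.planar import PlanarDose, read_chamber_grid, read_planar, write_chamber_grid, write_planar


def brute_trilinear(grid: Grid3D, values: np.ndarray, point) -> float:
    """Independent textbook trilinear interpolation at one point."""
    out = 0.0
    idx = []
    for i in range(3):
        t = (point[i] - grid.origin_mm[i]) / grid.spacing_mm[i]
        k = int(np.floor(t))
        k = min(max(k, 0), grid.shape[i] - 2)
        idx.append((k, t - k))
    (i, fx), (j, fy), (k, fz) = idx
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                w = ((1 - fx, fx)[di]) * ((1 - fy, fy)[dj]) * ((1 - fz, fz)[dk])
                out += w * values[i + di, j + dj, k + dk]
    return out


def brute_bilinear(planar: PlanarDose, x: float, y: float) -> float:
    xs, ys = planar.x_mm, planar.y_mm
    i = min(max(int(np.floor((x - xs[0]) / planar.spacing_mm[0])), 0), len(xs) - 2)
    j = min(max(int(np.floor((y - ys[0]) / planar.spacing_mm[1])), 0), len(ys) - 2)
    fx = (x - xs[i]) / planar.spacing_mm[0]
    fy = (y - ys[j]) / planar.spacing_mm[1]
    v = planar.values
    return (
        v[i, j] * (1 - fx) * (1 - fy)
        + v[i + 1, j] * fx * (1 - fy)
        + v[i, j + 1] * (1 - fx) * fy
        + v[i + 1, j + 1] * fx * fy
    )


@pytest.fixture
def random_dose(rng):
    grid = Grid3D((-2.0, -2.0, 1.5), (1.0, 1.0, 1.0), (5, 5, 5))
    return Dose3D(grid=grid, dose=rng.uniform(0.0, 2.0, size=grid.shape))


class TestExtractPlanar:
    def test_grid_plane_is_exact_copy(self, random_dose):
        # depth mapping: z = 3.5 - depth; z=2.5 is grid plane index 1
        planar = d.extract_planar(random_dose, 1.0)
        np.testing.assert_array_equal(planar.values, random_dose.dose[:, :, 1])

    def test_midway_plane_is_slice_mean(self, random_dose):
        planar = d.extract_planar(random_dose, 0.5)  # z=3.0
        np.testing.assert_allclose(
            planar.values, 0.5 * (random_dose.dose[:, :, 1] + random_dose.dose[:, :, 2]),
            atol=1e-15,
        )

    def test_matches_brute_force_trilinear(self, random_dose, rng):
        for depth in rng.uniform(-1.9, 1.9, size=5):
            planar = d.extract_planar(random_dose, depth)
            z = 3.5 - depth
            for i in (0, 2, 4):
                for j in (1, 3):
                    x, y = planar.x_mm[i], planar.y_mm[j]
                    expect = brute_trilinear(random_dose.grid, random_dose.dose, (x, y, z))
                    assert planar.values[i, j] == pytest.approx(expect, abs=1e-12)

    def test_depth_outside_grid_rejected(self, random_dose):
        with pytest.raises(ValueError, match="outside"):
            d.extract_planar(random_dose, -5.0)


class TestSampleAtChambers:
    def test_uniform_and_linear_fields(self, layout):
        xs = np.arange(-130.0, 131.0)
        planar = PlanarDose((-130.0, -130.0), (1.0, 1.0), np.full((261, 261), 1.7), 3.5)
        grid = d.sample_at_chambers(planar, layout)
        assert np.allclose(grid.populated_values, 1.7)
        vals = np.clip(2.0 + 0.01 * xs[:, None] + 0.0 * xs[None, :], 0, None)
        planar = PlanarDose((-130.0, -130.0), (1.0, 1.0), vals, 3.5)
        grid = d.sample_at_chambers(planar, layout)
        expect = 2.0 + 0.01 * layout.positions[:, 0]
        got = grid.values[layout.populated_mask]
        # bilinear is exact for fields linear in x
        order = np.argsort(layout.positions[:, 0], kind="stable")
        np.testing.assert_allclose(np.sort(got), np.sort(expect), atol=1e-12)

    def test_matches_brute_force_bilinear(self, rng):
        lay = d.build_chamber_layout(pitch_mm=3.0, n_rows=4, n_cols=4, unpopulated=())
        vals = rng.uniform(0, 1, size=(25, 25))
        planar = PlanarDose((-12.0, -12.0), (1.0, 1.0), vals, 3.5)
        grid = d.sample_at_chambers(planar, lay)
        for r in range(4):
            for c in range(4):
                x, y = lay.col_x_mm()[c], lay.row_y_mm()[r]
                assert grid.values[r, c] == pytest.approx(brute_bilinear(planar, x, y), abs=1e-12)

    def test_chambers_outside_extent_rejected(self, layout):
        planar = PlanarDose((-50.0, -50.0), (1.0, 1.0), np.ones((101, 101)), 3.5)
        with pytest.raises(ValueError, match="beyond"):
            d.sample_at_chambers(planar, layout)


class TestResampleChambers:
    @given(st.floats(-0.02, 0.02), st.floats(-0.02, 0.02), st.floats(1.0, 3.0))
    def test_linear_fields_exact_and_round_trip(self, ax, ay, c):
        lay = d.build_chamber_layout()
        X = lay.col_x_mm()[None, :]
        Y = lay.row_y_mm()[:, None]
        vals = c + ax * X + ay * Y + 0.0 * (X + Y)
        vals = vals - vals.min() + 0.1  # keep doses positive
        vals = np.where(lay.populated_mask, vals, np.nan)
        grid = d.ChamberGrid(layout=lay, values=vals)
        planar = d.resample_chambers_to_grid(grid, 1.0)
        # exact linear reproduction at arbitrary interior pixels
        i, j = 40, 110
        x, y = planar.x_mm[i], planar.y_mm[j]
        expect = (c + ax * x + ay * y) - (c + ax * X + ay * Y).min() + 0.1
        assert planar.values[i, j] == pytest.approx(expect, abs=1e-9)
        # round trip back to the chambers
        back = d.sample_at_chambers(planar, lay)
        np.testing.assert_allclose(
            back.populated_values, grid.populated_values, atol=1e-9
        )

    def test_constant_field(self, layout):
        vals = np.where(layout.populated_mask, 0.8, np.nan)
        planar = d.resample_chambers_to_grid(d.ChamberGrid(layout=layout, values=vals))
        assert np.allclose(planar.values, 0.8)

    def test_invalid_spacing(self, layout):
        vals = np.where(layout.populated_mask, 1.0, np.nan)
        grid = d.ChamberGrid(layout=layout, values=vals)
        with pytest.raises(ValueError):
            d.resample_chambers_to_grid(grid, 0.0)

    def test_no_extrapolation_beyond_outer_chambers(self, layout):
        vals = np.where(layout.populated_mask, 1.0, np.nan)
        planar = d.resample_chambers_to_grid(d.ChamberGrid(layout=layout, values=vals))
        assert planar.x_mm[0] >= layout.col_x_mm()[0]
        assert planar.x_mm[-1] <= layout.col_x_mm()[-1]


class TestConvolveResponse:
    def test_sigma_zero_is_identity(self, rng):
        planar = PlanarDose((0, 0), (1, 1), rng.uniform(0, 1, (20, 20)), 3.5)
        out = d.convolve_response(planar, 0.0)
        np.testing.assert_array_equal(out.values, planar.values)

    def test_impulse_becomes_gaussian_of_stated_sigma(self):
        vals = np.zeros((81, 81))
        vals[40, 40] = 1.0
        planar = PlanarDose((-40, -40), (1, 1), vals, 3.5)
        out = d.convolve_response(planar, 2.0)
        x = planar.x_mm
        profile = out.values[:, 40]
        sigma_est = np.sqrt(np.sum(profile * x**2) / np.sum(profile))
        assert sigma_est == pytest.approx(2.0, rel=0.02)
        # mass conserved
        assert out.values.sum() == pytest.approx(1.0, rel=1e-3)

    def test_uniform_interior_unchanged_and_shift_invariance(self, rng):
        planar = PlanarDose((0, 0), (1, 1), np.full((40, 40), 2.5), 3.5)
        out = d.convolve_response(planar, 2.0)
        np.testing.assert_allclose(out.values[8:-8, 8:-8], 2.5, atol=1e-6)
        # translation commutes on interior pixels
        f = np.zeros((60, 60))
        f[20:30, 25:35] = rng.uniform(1, 2, (10, 10))
        a = d.convolve_response(PlanarDose((0, 0), (1, 1), f, 3.5), 1.5).values
        b = d.convolve_response(PlanarDose((0, 0), (1, 1), np.roll(f, 4, axis=0), 3.5), 1.5).values
        np.testing.assert_allclose(np.roll(a, 4, axis=0)[10:-10, 10:-10], b[10:-10, 10:-10], atol=1e-9)


class TestPercentError:
    def test_identical_and_uniform_offsets(self):
        a = PlanarDose((0, 0), (1, 1), np.ones((5, 5)), 3.5)
        b = PlanarDose((0, 0), (1, 1), np.full((5, 5), 1.01), 3.5)
        err, avg = d.percent_error_map(a, a)
        assert avg == 0.0 and np.all(err == 0.0)
        err, avg = d.percent_error_map(a, b)
        assert avg == pytest.approx(1.0)

    def test_two_pixel_toy(self):
        a = PlanarDose((0, 0), (1, 1), np.array([[1.0, 2.0]]), 3.5)
        b = PlanarDose((0, 0), (1, 1), np.array([[1.0, 1.9]]), 3.5)
        err, avg = d.percent_error_map(a, b)
        np.testing.assert_allclose(err, [[0.0, 5.0]])
        assert avg == pytest.approx(2.5)

    def test_zero_reference_rejected(self):
        z = PlanarDose((0, 0), (1, 1), np.zeros((3, 3)), 3.5)
        with pytest.raises(ValueError, match="zero"):
            d.percent_error_map(z, z)


class TestProfiles:
    def test_symmetric_constant_and_out_of_extent(self, rng):
        xs = np.linspace(-20, 20, 41)
        vals = np.exp(-0.5 * (xs[:, None] / 7.0) ** 2) * np.exp(-0.5 * (xs[None, :] / 7.0) ** 2)
        planar = PlanarDose((-20, -20), (1, 1), vals, 3.5)
        x, prof = d.extract_profile(planar, "x", 0.0)
        np.testing.assert_allclose(prof, prof[::-1], atol=1e-9)
        flat = PlanarDose((-20, -20), (1, 1), np.full((41, 41), 0.3), 3.5)
        _, prof = d.extract_profile(flat, "y", 5.0)
        assert np.allclose(prof, 0.3)
        with pytest.raises(ValueError, match="outside"):
            d.extract_profile(planar, "x", 100.0)

    def test_penumbra_width_matches_closed_form(self, phantom, engine):
        from dempqa.dose_engine import dose_grid_for_depths
        from scipy.stats import norm

        grid = dose_grid_for_depths(phantom, [3.5], spacing_mm=1.0, lateral_halfspan_mm=60.0)
        beam = d.Beam(0.0, (-20.0, 20.0, -50.0, 50.0), 100.0)
        dose = d.compute_beam_dose(beam, phantom, engine, grid=grid)
        planar = d.extract_planar(dose, 3.5)
        x, prof = d.extract_profile(planar, "x", 0.0)
        prof = prof / prof[np.argmin(np.abs(x))]
        # 80-20 width of one edge of an erf profile
        def crossing(level):
            idx = np.where((prof[:-1] - level) * (prof[1:] - level) < 0)[0][0]
            f = (level - prof[idx]) / (prof[idx + 1] - prof[idx])
            return x[idx] + f * (x[idx + 1] - x[idx])

        width = abs(crossing(0.2) - crossing(0.8))
        expect = (norm.ppf(0.8) - norm.ppf(0.2)) * engine.penumbra_sigma_mm
        assert width == pytest.approx(expect, rel=0.05)


class TestTextIO:
    def test_chamber_grid_round_trip_with_na_corners(self, layout, tmp_path, rng):
        vals = np.where(
            layout.populated_mask,
            rng.uniform(0.1, 1.0, (layout.n_rows, layout.n_cols)),
            np.nan,
        )
        grid = d.ChamberGrid(layout=layout, values=vals)
        path = tmp_path / "m.tsv"
        write_chamber_grid(grid, path)
        text = path.read_text()
        assert "NA" in text.splitlines()[1]  # corner row carries NA
        back = read_chamber_grid(path)
        assert back.layout.n_populated == 1020
        np.testing.assert_allclose(
            back.populated_values, grid.populated_values, rtol=1e-5
        )

    def test_planar_round_trip(self, tmp_path, rng):
        planar = PlanarDose((-5.0, -3.0), (1.0, 1.0), rng.uniform(0, 1, (11, 7)), 8.5)
        path = tmp_path / "p.tsv"
        write_planar(planar, path)
        back = read_planar(path)
        assert back.plane_depth_mm == 8.5
        np.testing.assert_allclose(back.values, planar.values, rtol=1e-5)
        np.testing.assert_allclose(back.x_mm, planar.x_mm, atol=1e-9)
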