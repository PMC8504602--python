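"""Planar dose extraction, chamber sampling, resampling, and error maps.

Planar doses are fine-grid 2D fields at a stated depth below the
detector surface; chamber grids hold one value per populated chamber of
a :class:`~dempqa.geometry.ChamberLayout` (NaN at unpopulated sites).
All coordinates are physical mm at pixel/chamber centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter

from .dose_engine import Dose3D
from .geometry import ChamberLayout

__all__ = [
    "PlanarDose",
    "ChamberGrid",
    "extract_planar",
    "sample_at_chambers",
    "resample_chambers_to_grid",
    "convolve_response",
    "percent_error_map",
    "extract_profile",
    "read_chamber_grid",
    "write_chamber_grid",
    "write_planar",
    "read_planar",
]


@dataclass
class PlanarDose:
    """2D dose field: ``values[i, j]`` at (x_i, y_j), in Gy."""

    origin_mm: tuple[float, float]
    spacing_mm: tuple[float, float]
    values: np.ndarray
    plane_depth_mm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if np.any(self.values < -1e-12):
            raise ValueError("dose values must be non-negative")

    @property
    def x_mm(self) -> np.ndarray:
        return self.origin_mm[0] + self.spacing_mm[0] * np.arange(self.values.shape[0])

    @property
    def y_mm(self) -> np.ndarray:
        return self.origin_mm[1] + self.spacing_mm[1] * np.arange(self.values.shape[1])

    def interpolator(self, bounds_error: bool = True, fill_value=np.nan) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            (self.x_mm, self.y_mm), self.values,
            method="linear", bounds_error=bounds_error, fill_value=fill_value,
        )


@dataclass
class ChamberGrid:
    """Per-chamber doses on the detector lattice (NaN where unpopulated)."""

    layout: ChamberLayout
    values: np.ndarray  # (n_rows, n_cols), Gy

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.layout.n_rows, self.layout.n_cols):
            raise ValueError("chamber value array must match the lattice shape")
        pop = self.layout.populated_mask
        if np.any(~np.isfinite(self.values[pop])):
            raise ValueError("populated chambers must carry finite values")

    @property
    def populated_values(self) -> np.ndarray:
        return self.values[self.layout.populated_mask]

    def max(self) -> float:
        return float(np.nanmax(self.values))


def extract_planar(dose: Dose3D, depth_mm: float, surface_z_mm: float = 3.5) -> PlanarDose:
    """Horizontal plane at a stated depth below the detector surface.

    Trilinear interpolation on the 3D grid degenerates to a linear blend
    of the two bracketing z-slices (the in-plane lattice is shared), so
    a depth coinciding with a grid plane returns that slice exactly.
    """
    z = surface_z_mm - depth_mm
    zs = dose.grid.axis(2)
    if not (zs[0] <= z <= zs[-1]):
        raise ValueError(
            f"plane z={z:g} mm (depth {depth_mm:g} mm) outside dose grid z-extent "
            f"[{zs[0]:g}, {zs[-1]:g}]"
        )
    k = int(np.clip(np.searchsorted(zs, z) - 1, 0, len(zs) - 2))
    w = (z - zs[k]) / (zs[k + 1] - zs[k])
    plane = (1.0 - w) * dose.dose[:, :, k] + w * dose.dose[:, :, k + 1]
    return PlanarDose(
        origin_mm=(dose.grid.origin_mm[0], dose.grid.origin_mm[1]),
        spacing_mm=(dose.grid.spacing_mm[0], dose.grid.spacing_mm[1]),
        values=plane,
        plane_depth_mm=depth_mm,
    )


def sample_at_chambers(planar: PlanarDose, layout: ChamberLayout) -> ChamberGrid:
    """Bilinear samples of a planar dose at the chamber centers."""
    xs = layout.col_x_mm()
    ys = layout.row_y_mm()
    if xs[0] < planar.x_mm[0] or xs[-1] > planar.x_mm[-1] or ys[0] < planar.y_mm[0] or ys[-1] > planar.y_mm[-1]:
        raise ValueError(
            "chamber lattice extends beyond the planar dose extent: "
            f"chambers x [{xs[0]:g}, {xs[-1]:g}], y [{ys[0]:g}, {ys[-1]:g}] vs "
            f"planar x [{planar.x_mm[0]:g}, {planar.x_mm[-1]:g}], "
            f"y [{planar.y_mm[0]:g}, {planar.y_mm[-1]:g}]"
        )
    interp = planar.interpolator()
    X, Y = np.meshgrid(xs, ys, indexing="xy")  # rows vary with y
    vals = interp(np.column_stack([X.ravel(), Y.ravel()])).reshape(layout.n_rows, layout.n_cols)
    vals = np.where(layout.populated_mask, vals, np.nan)
    return ChamberGrid(layout=layout, values=vals)


def _fill_corner_nans(layout: ChamberLayout, vals: np.ndarray) -> np.ndarray:
    """Fill unpopulated sites by parallelogram extrapolation from neighbours.

    ``f[r,c] = f[r,c'] + f[r',c] - f[r',c']`` with (r', c') the adjacent
    interior site — exact for fields linear in x and y, which keeps the
    resampling operator linear-exact over the full lattice square.
    """
    out = vals.copy()
    n_r, n_c = out.shape
    for r, c in sorted(layout.unpopulated):
        r2 = r + 1 if r < n_r - 1 else r - 1
        c2 = c + 1 if c < n_c - 1 else c - 1
        out[r, c] = out[r, c2] + out[r2, c] - out[r2, c2]
    return out


def resample_chambers_to_grid(meas: ChamberGrid, target_spacing_mm: float = 1.0) -> PlanarDose:
    """Bilinear interpolation of chamber values onto a fine grid.

    The grid covers the chamber lattice square symmetrically at the
    target pitch with no extrapolation beyond the outer chambers; the
    few unpopulated corner sites are filled by local linear
    extrapolation before interpolating.
    """
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    layout = meas.layout
    xs = layout.col_x_mm()
    ys = layout.row_y_mm()
    filled = _fill_corner_nans(layout, meas.values)
    interp = RegularGridInterpolator((ys, xs), filled, method="linear", bounds_error=True)

    def fine_axis(lo: float, hi: float) -> tuple[np.ndarray, float]:
        # endpoint-inclusive so the outer chambers are covered without
        # extrapolation; the realized pitch is the nearest exact divisor
        # of the span (1.0009 mm for the default lattice at 1 mm target)
        n_int = max(1, int(round((hi - lo) / target_spacing_mm)))
        return np.linspace(lo, hi, n_int + 1), (hi - lo) / n_int

    fx, sx = fine_axis(xs[0], xs[-1])
    fy, sy = fine_axis(ys[0], ys[-1])
    X, Y = np.meshgrid(fx, fy, indexing="ij")
    vals = interp(np.column_stack([Y.ravel(), X.ravel()])).reshape(len(fx), len(fy))
    return PlanarDose(
        origin_mm=(fx[0], fy[0]),
        spacing_mm=(sx, sy),
        values=np.clip(vals, 0.0, None),
        plane_depth_mm=layout.oemp_depth_mm,
    )


def convolve_response(planar: PlanarDose, sigma_mm: float) -> PlanarDose:
    """Isotropic Gaussian smoothing modelling chamber volume averaging."""
    if sigma_mm < 0:
        raise ValueError("sigma must be non-negative")
    if sigma_mm == 0:
        return PlanarDose(planar.origin_mm, planar.spacing_mm, planar.values.copy(),
                          planar.plane_depth_mm)
    sig = (sigma_mm / planar.spacing_mm[0], sigma_mm / planar.spacing_mm[1])
    vals = gaussian_filter(planar.values, sigma=sig, mode="nearest")
    return PlanarDose(planar.origin_mm, planar.spacing_mm, vals, planar.plane_depth_mm)


def percent_error_map(ref, test, threshold_pct: float | None = None):
    """Pixel-wise |ref - test| / max(ref) x 100 and its average.

    Both arguments must share a sampling domain (two PlanarDose on the
    same lattice or two ChamberGrid on the same layout).  If
    ``threshold_pct`` is given, the average is restricted to pixels
    where the reference exceeds that percentage of its maximum.
    """
    rv, tv = _paired_values(ref, test)
    finite = np.isfinite(rv) & np.isfinite(tv)
    norm = np.nanmax(rv)
    if not norm > 0:
        raise ValueError("reference maximum is zero; percent errors undefined")
    err = np.where(finite, np.abs(rv - tv) / norm * 100.0, np.nan)
    sel = finite
    if threshold_pct is not None:
        sel = sel & (rv >= threshold_pct / 100.0 * norm)
    return err, float(np.mean(err[sel]))


def _paired_values(ref, test) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(ref, PlanarDose) and isinstance(test, PlanarDose):
        if ref.values.shape != test.values.shape or not np.allclose(
            [*ref.origin_mm, *ref.spacing_mm], [*test.origin_mm, *test.spacing_mm]
        ):
            raise ValueError("planar doses are not on the same sampling domain")
        return ref.values, test.values
    if isinstance(ref, ChamberGrid) and isinstance(test, ChamberGrid):
        if ref.values.shape != test.values.shape:
            raise ValueError("chamber grids are not on the same layout")
        return ref.values, test.values
    raise TypeError("ref and test must both be PlanarDose or both ChamberGrid")


def extract_profile(planar: PlanarDose, axis: str, through_mm: float = 0.0):
    """1D dose profile along x (at y=through) or along y (at x=through)."""
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    interp = planar.interpolator()
    if axis == "x":
        if not (planar.y_mm[0] <= through_mm <= planar.y_mm[-1]):
            raise ValueError("profile line outside the planar extent")
        coords = planar.x_mm
        pts = np.column_stack([coords, np.full_like(coords, through_mm)])
    else:
        if not (planar.x_mm[0] <= through_mm <= planar.x_mm[-1]):
            raise ValueError("profile line outside the planar extent")
        coords = planar.y_mm
        pts = np.column_stack([np.full_like(coords, through_mm), coords])
    return coords, interp(pts)


# --------------------------------------------------------------------------- #
# text I/O — tab-separated grids with coordinate headers


def write_chamber_grid(meas: ChamberGrid, path) -> None:
    """Write the chamber grid dialect: x header row, y header column, NA corners."""
    xs = meas.layout.col_x_mm()
    ys = meas.layout.row_y_mm()
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(f"{x:.6g}" for x in xs) + "\n")
        for r in range(meas.layout.n_rows):
            cells = [
                "NA" if not np.isfinite(meas.values[r, c]) else f"{meas.values[r, c]:.6g}"
                for c in range(meas.layout.n_cols)
            ]
            fh.write(f"{ys[r]:.6g}\t" + "\t".join(cells) + "\n")


def read_chamber_grid(path, layout: ChamberLayout | None = None) -> ChamberGrid:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        xs = np.array([float(v) for v in header])
        rows, ys = [], []
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            if not cells or cells[0] == "":
                continue
            ys.append(float(cells[0]))
            rows.append([np.nan if v == "NA" else float(v) for v in cells[1:]])
    vals = np.asarray(rows)
    if layout is None:
        pitch = float(np.diff(xs).mean())
        unpop = [(r, c) for r, c in zip(*np.nonzero(~np.isfinite(vals)))]
        from .geometry import build_chamber_layout

        layout = build_chamber_layout(
            pitch_mm=pitch, n_rows=vals.shape[0], n_cols=vals.shape[1], unpopulated=unpop
        )
    return ChamberGrid(layout=layout, values=vals)


def write_planar(planar: PlanarDose, path) -> None:
    """Planar dose in the same text dialect, at its native pitch."""
    with open(path, "w") as fh:
        fh.write(f"# depth_mm\t{planar.plane_depth_mm:.6g}\n")
        fh.write("\t" + "\t".join(f"{x:.6g}" for x in planar.x_mm) + "\n")
        for j, y in enumerate(planar.y_mm):
            fh.write(f"{y:.6g}\t" + "\t".join(f"{v:.6g}" for v in planar.values[:, j]) + "\n")


def read_planar(path) -> PlanarDose:
    with open(path) as fh:
        first = fh.readline()
        depth = 3.5
        if first.startswith("#"):
            depth = float(first.split("\t")[1])
            first = fh.readline()
        xs = np.array([float(v) for v in first.rstrip("\n").split("\t")[1:]])
        ys, rows = [], []
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            if not cells or cells[0] == "":
                continue
            ys.append(float(cells[0]))
            rows.append([float(v) for v in cells[1:]])
    vals = np.asarray(rows).T  # rows were y
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    return PlanarDose(
        origin_mm=(xs[0], ys[0]),
        spacing_mm=(float(np.diff(xs).mean()), float(np.diff(ys).mean())),
        values=vals,
        plane_depth_mm=depth,
    )
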