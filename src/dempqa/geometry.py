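"""Detector, phantom, and plan geometry.

Coordinate conventions (IEC 61217, fixed room frame):

* x — crossplane, parallel to the MLC leaf-motion direction;
* y — inplane, the gantry rotation axis (chamber columns run along y);
* z — vertical, positive up; the isocenter is the origin.

The 2D chamber array lies horizontally with its reference measurement
plane (the OEMP, 3.5 mm below the detector surface) aligned with the
isocenter plane z = 0, so the detector surface sits at z = +3.5 mm.
Depths quoted "below the detector surface" therefore map to world
coordinates as ``z = surface_z - depth``; the positive depth direction
points toward the detector bottom.

The gantry angle theta places the source at ``iso + SAD * (sin t, 0,
cos t)``: 0 deg is vertically above the isocenter (an AP beam) and the
angle increases clockwise when viewed from the couch foot, so 180 deg
irradiates the array from below (PA) through its backscatter and anode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "Grid3D",
    "Box",
    "ChamberLayout",
    "DetectorStack",
    "DensityVolume",
    "Beam",
    "Plan",
    "build_chamber_layout",
    "build_slab_phantom",
    "make_calibration_plans",
    "load_plan",
    "save_plan",
    "load_phantom_spec",
]


# --------------------------------------------------------------------------- #
# voxel grid


@dataclass(frozen=True)
class Grid3D:
    """Regular voxel lattice: ``origin_mm`` is the center of voxel (0,0,0)."""

    origin_mm: tuple[float, float, float]
    spacing_mm: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("grid spacing must be positive")
        if any(n <= 0 for n in self.shape):
            raise ValueError("grid shape must be positive")

    def axis(self, i: int) -> np.ndarray:
        return self.origin_mm[i] + self.spacing_mm[i] * np.arange(self.shape[i])

    @property
    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.axis(0), self.axis(1), self.axis(2)

    @property
    def lower_mm(self) -> np.ndarray:
        """Outer lower corner of the voxelized volume (voxel faces)."""
        return np.asarray(self.origin_mm) - 0.5 * np.asarray(self.spacing_mm)

    @property
    def upper_mm(self) -> np.ndarray:
        return self.lower_mm + np.asarray(self.spacing_mm) * np.asarray(self.shape)


@dataclass(frozen=True)
class Box:
    """Axis-aligned homogeneous box with a density override."""

    lower_mm: tuple[float, float, float]
    upper_mm: tuple[float, float, float]
    density: float

    def __post_init__(self) -> None:
        if any(l >= u for l, u in zip(self.lower_mm, self.upper_mm)):
            raise ValueError("box lower bound must be below upper bound")
        if self.density < 0:
            raise ValueError("density must be non-negative")


def _axis_overlap_fraction(centers: np.ndarray, spacing: float,
                           lo: float, hi: float) -> np.ndarray:
    """Fraction of each voxel (along one axis) covered by [lo, hi]."""
    left = centers - spacing / 2.0
    right = centers + spacing / 2.0
    return np.clip((np.minimum(right, hi) - np.maximum(left, lo)) / spacing, 0.0, 1.0)


def _box_fractions(grid: Grid3D, lower, upper) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return tuple(
        _axis_overlap_fraction(grid.axis(i), grid.spacing_mm[i], lower[i], upper[i])
        for i in range(3)
    )


# --------------------------------------------------------------------------- #
# detector array


@dataclass(frozen=True)
class ChamberLayout:
    """Square lattice of pixel ionization chambers.

    The default layout is the 32 x 32 grid at 7.62 mm pitch with the four
    extreme corner positions unpopulated, i.e. 1020 chambers over a
    nominally 24.4 cm x 24.4 cm active square.  Row index increases with
    +y, column index with +x; the lattice is centered on the beam axis.
    """

    pitch_mm: float = 7.62
    n_rows: int = 32
    n_cols: int = 32
    unpopulated: frozenset[tuple[int, int]] = frozenset(
        {(0, 0), (0, 31), (31, 0), (31, 31)}
    )
    oemp_depth_mm: float = 3.5
    chamber_diameter_mm: float = 4.5
    chamber_height_mm: float = 5.0

    @property
    def active_side_mm(self) -> float:
        return self.n_cols * self.pitch_mm

    @property
    def n_populated(self) -> int:
        return self.n_rows * self.n_cols - len(self.unpopulated)

    def col_x_mm(self) -> np.ndarray:
        return (np.arange(self.n_cols) - (self.n_cols - 1) / 2.0) * self.pitch_mm

    def row_y_mm(self) -> np.ndarray:
        return (np.arange(self.n_rows) - (self.n_rows - 1) / 2.0) * self.pitch_mm

    @property
    def populated_mask(self) -> np.ndarray:
        """Boolean (n_rows, n_cols) mask of populated lattice sites."""
        mask = np.ones((self.n_rows, self.n_cols), dtype=bool)
        for r, c in self.unpopulated:
            mask[r, c] = False
        return mask

    @property
    def positions(self) -> np.ndarray:
        """(n_populated, 2) array of (x, y) chamber centers in mm."""
        xs = self.col_x_mm()
        ys = self.row_y_mm()
        rr, cc = np.nonzero(self.populated_mask)
        return np.column_stack([xs[cc], ys[rr]])


def build_chamber_layout(
    pitch_mm: float = 7.62,
    n_rows: int = 32,
    n_cols: int = 32,
    unpopulated: Iterable[tuple[int, int]] | None = None,
    **overrides,
) -> ChamberLayout:
    """Construct a chamber layout, defaulting to the 1020-chamber array.

    ``unpopulated=None`` removes the four extreme corners (manufacturer
    layout); pass an explicit iterable (possibly empty) to override.
    """
    if pitch_mm <= 0:
        raise ValueError("pitch must be positive")
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("row/column counts must be positive")
    if unpopulated is None:
        unpop = frozenset(
            {(0, 0), (0, n_cols - 1), (n_rows - 1, 0), (n_rows - 1, n_cols - 1)}
        )
    else:
        unpop = frozenset((int(r), int(c)) for r, c in unpopulated)
        for r, c in unpop:
            if not (0 <= r < n_rows and 0 <= c < n_cols):
                raise ValueError(f"unpopulated position {(r, c)} outside lattice")
    if len(unpop) > n_rows * n_cols:
        raise ValueError("more unpopulated positions than lattice sites")
    return ChamberLayout(
        pitch_mm=pitch_mm, n_rows=n_rows, n_cols=n_cols, unpopulated=unpop, **overrides
    )


# --------------------------------------------------------------------------- #
# detector stack & phantom


@dataclass(frozen=True)
class DetectorStack:
    """Depth structure of the detector, in mm below its top surface.

    The absorber occupies [0, 3], the chamber layer [3, 8] (the OEMP at
    3.5 mm lies inside it), the 0.75 mm anode layer starts at
    ``anode_top_mm``, and 35 mm of backscatter material sits below the
    anode.  Everything is treated as water-equivalent (``body_density``)
    except the anode region, whose effective density is a free model
    parameter set later by calibration.
    """

    absorber_thickness_mm: float = 3.0
    chamber_layer_mm: tuple[float, float] = (3.0, 8.0)
    anode_top_mm: float = 8.0
    anode_thickness_mm: float = 0.75
    backscatter_thickness_mm: float = 35.0
    body_density: float = 1.0
    oemp_depth_mm: float = 3.5

    def __post_init__(self) -> None:
        if not (self.chamber_layer_mm[0] <= self.oemp_depth_mm <= self.chamber_layer_mm[1]):
            raise ValueError("OEMP depth must lie inside the chamber layer")
        if self.anode_thickness_mm <= 0:
            raise ValueError("anode thickness must be positive")

    @property
    def anode_span_mm(self) -> tuple[float, float]:
        return (self.anode_top_mm, self.anode_top_mm + self.anode_thickness_mm)

    @property
    def total_thickness_mm(self) -> float:
        return self.anode_span_mm[1] + self.backscatter_thickness_mm


@dataclass
class DensityVolume:
    """3D voxel density map with named ROIs and an analytic box description.

    ``regions`` lists axis-aligned homogeneous boxes painted (in order)
    over the uniform ``body_density`` background; the voxel array is the
    partial-volume rasterization of that description, so ray integrals
    through the boxes and through the voxels agree for axis-aligned rays
    and to sub-voxel accuracy otherwise.  Volumes imported from arrays
    have ``regions=None`` and are treated as purely voxelized.
    """

    grid: Grid3D
    density: np.ndarray
    body_density: float = 1.0
    regions: list[Box] | None = None
    roi_boxes: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = field(
        default_factory=dict
    )
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density)
        if self.density.shape != tuple(self.grid.shape):
            raise ValueError("density array shape does not match grid")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")

    @classmethod
    def uniform(cls, grid: Grid3D, density: float = 1.0, **kw) -> "DensityVolume":
        arr = np.full(grid.shape, density, dtype=np.float32)
        return cls(grid=grid, density=arr, body_density=density, regions=[], **kw)

    def roi_mask(self, name: str) -> np.ndarray:
        """Boolean mask of voxels overlapping the named ROI box."""
        lo, hi = self.roi_boxes[name]
        fx, fy, fz = _box_fractions(self.grid, lo, hi)
        return (fx[:, None, None] * fy[None, :, None] * fz[None, None, :]) > 0

    def override_roi(self, name: str, density: float) -> "DensityVolume":
        """Return a copy with the named ROI's density overwritten.

        The override is partial-volume weighted at the ROI boundary and
        touches only voxels that intersect the ROI box.
        """
        lo, hi = self.roi_boxes[name]
        new = DensityVolume(
            grid=self.grid,
            density=self.density.copy(),
            body_density=self.body_density,
            regions=None if self.regions is None else list(self.regions),
            roi_boxes=dict(self.roi_boxes),
            meta=dict(self.meta),
        )
        fx, fy, fz = _box_fractions(self.grid, lo, hi)
        frac = fx[:, None, None] * fy[None, :, None] * fz[None, None, :]
        sel = frac > 0
        base = np.full(self.density.shape, self.body_density, dtype=self.density.dtype)
        new.density[sel] = (
            base[sel] * (1.0 - frac[sel]) + density * frac[sel]
        ).astype(self.density.dtype)
        if new.regions is not None:
            new.regions = [
                b for b in new.regions if (tuple(b.lower_mm), tuple(b.upper_mm)) != (tuple(lo), tuple(hi))
            ]
            if density != self.body_density:
                new.regions.append(Box(tuple(lo), tuple(hi), float(density)))
        return new

    def with_anode_density(self, rho_g_cm3: float) -> "DensityVolume":
        """Convenience: override the registered ``"anode"`` ROI."""
        return self.override_roi("anode", rho_g_cm3)


def build_slab_phantom(
    buildup_cm: float = 7.0,
    backscatter_cm: float = 8.0,
    stack: DetectorStack | None = None,
    spacing_mm: float = 1.0,
    lateral_halfspan_mm: float = 150.0,
) -> DensityVolume:
    """Water-slab phantom with the detector embedded, OEMP on the isocenter.

    ``buildup_cm`` of solid water sits on the detector surface and
    ``backscatter_cm`` below its housing.  The detector body (absorber,
    chamber layer, internal backscatter) is modelled water-equivalent;
    the 0.75 mm anode layer is registered as the ``"anode"`` ROI at body
    density, to be overridden with an effective density.

    The grid is isotropic with voxel centers on multiples of
    ``spacing_mm`` so the isocenter plane z = 0 is grid-aligned.
    """
    if buildup_cm <= 0 or backscatter_cm <= 0:
        raise ValueError("slab thicknesses must be positive")
    stack = stack or DetectorStack()
    if spacing_mm > 4.0 * stack.anode_thickness_mm:
        raise ValueError(
            "grid spacing coarser than 4x the anode thickness cannot resolve the anode ROI"
        )
    surface_z = stack.oemp_depth_mm  # OEMP at z=0
    z_hi = surface_z + 10.0 * buildup_cm
    z_lo = surface_z - stack.total_thickness_mm - 10.0 * backscatter_cm

    def centered_axis(lo: float, hi: float) -> np.ndarray:
        kmin = math.floor(lo / spacing_mm + 0.5)
        kmax = math.ceil(hi / spacing_mm - 0.5)
        return spacing_mm * np.arange(kmin, kmax + 1)

    zax = centered_axis(z_lo, z_hi)
    nlat = 2 * math.floor(lateral_halfspan_mm / spacing_mm) + 1
    lat0 = -spacing_mm * (nlat - 1) / 2.0
    grid = Grid3D(
        origin_mm=(lat0, lat0, float(zax[0])),
        spacing_mm=(spacing_mm, spacing_mm, spacing_mm),
        shape=(nlat, nlat, len(zax)),
    )
    vol = DensityVolume.uniform(grid, stack.body_density)
    a_lo, a_hi = stack.anode_span_mm
    anode_half = 0.5 * 243.84  # lateral extent of the active area
    anode_box = (
        (-anode_half, -anode_half, surface_z - a_hi),
        (anode_half, anode_half, surface_z - a_lo),
    )
    vol.roi_boxes["anode"] = anode_box
    vol.meta.update(
        detector_surface_z_mm=surface_z,
        oemp_depth_mm=stack.oemp_depth_mm,
        buildup_mm=10.0 * buildup_cm,
        backscatter_mm=10.0 * backscatter_cm,
        stack_total_mm=stack.total_thickness_mm,
    )
    return vol


# --------------------------------------------------------------------------- #
# beams and plans


@dataclass(frozen=True)
class Beam:
    """Single rectangular segment: gantry angle, aperture at iso, MU weight.

    ``aperture_mm`` is (x1, x2, y1, y2) at the isocenter plane in the
    beam's collimator frame; x is the MLC leaf-motion direction.
    """

    gantry_deg: float
    aperture_mm: tuple[float, float, float, float]
    mu: float
    sad_mm: float = 1000.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gantry_deg < 360.0):
            raise ValueError("gantry angle must lie in [0, 360)")
        x1, x2, y1, y2 = self.aperture_mm
        if not (x1 < x2 and y1 < y2):
            raise ValueError("aperture must satisfy x1<x2 and y1<y2")
        if self.mu <= 0:
            raise ValueError("beam weight (MU) must be positive")
        if self.sad_mm <= 0:
            raise ValueError("SAD must be positive")

    @property
    def source_mm(self) -> np.ndarray:
        t = math.radians(self.gantry_deg)
        return self.sad_mm * np.array([math.sin(t), 0.0, math.cos(t)])

    @property
    def axis_unit(self) -> np.ndarray:
        """Unit vector from source toward the isocenter."""
        return -self.source_mm / self.sad_mm

    @property
    def crossplane_unit(self) -> np.ndarray:
        t = math.radians(self.gantry_deg)
        return np.array([math.cos(t), 0.0, -math.sin(t)])


@dataclass
class Plan:
    label: str
    beams: list[Beam]

    def __post_init__(self) -> None:
        if not self.beams:
            raise ValueError("a plan must contain at least one beam")

    @property
    def angles_deg(self) -> list[float]:
        return [b.gantry_deg for b in self.beams]


def make_calibration_plans(
    phantom: DensityVolume | None = None,
    angles_deg: Sequence[float] | None = None,
    aperture_mm: tuple[float, float, float, float] = (-20.0, 20.0, -50.0, 50.0),
    mu: float = 100.0,
) -> list[Plan]:
    """One single-beam plan per calibration angle (0..180 deg in 10 deg steps).

    Each beam carries the 4 cm x 10 cm jaw-collimated aperture used for
    model calibration; x (4 cm) is the MLC-motion direction, chosen
    narrow enough that the penumbra falls on the sensitive area even for
    near-90 deg incidence.
    """
    if angles_deg is None:
        angles_deg = [10.0 * k for k in range(19)]
    return [
        Plan(label=f"cal_{int(round(a)):03d}", beams=[Beam(a, aperture_mm, mu)])
        for a in angles_deg
    ]


# --------------------------------------------------------------------------- #
# plan / phantom file I/O


def save_plan(plan: Plan, path) -> None:
    doc = {
        "label": plan.label,
        "beams": [
            {
                "gantry_deg": float(b.gantry_deg),
                "aperture_mm": [float(v) for v in b.aperture_mm],
                "mu": float(b.mu),
                "sad_mm": float(b.sad_mm),
            }
            for b in plan.beams
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_plan(path) -> Plan:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    beams = [
        Beam(
            gantry_deg=float(b["gantry_deg"]),
            aperture_mm=tuple(float(v) for v in b["aperture_mm"]),
            mu=float(b["mu"]),
            sad_mm=float(b.get("sad_mm", 1000.0)),
        )
        for b in doc["beams"]
    ]
    return Plan(label=str(doc.get("label", "plan")), beams=beams)


def load_phantom_spec(path) -> DensityVolume:
    """Build a slab phantom from a YAML spec (thicknesses, spacing, overrides)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    stack_kw = doc.get("stack", {})
    stack = DetectorStack(**stack_kw) if stack_kw else None
    return build_slab_phantom(
        buildup_cm=float(doc.get("buildup_cm", 7.0)),
        backscatter_cm=float(doc.get("backscatter_cm", 8.0)),
        stack=stack,
        spacing_mm=float(doc.get("spacing_mm", 1.0)),
        lateral_halfspan_mm=float(doc.get("lateral_halfspan_mm", 150.0)),
    )
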