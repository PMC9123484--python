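"""Wide-field perimetry testing grid: geometry, subfields, hemifields.

The grid is a 185-point radial stimulus layout spanning 55.5 degrees nasally
and superiorly, 67 degrees inferiorly and 80 degrees temporally, partitioned
into a central 30-degree disc (108 points, including two blind-spot locations)
and four peripheral quadrants (inferotemporal 22, inferonasal 17,
superotemporal 22, superonasal 16).

Coordinates are chart coordinates in visual-field degrees: x positive toward
chart-right, y positive superior.  Anatomic temporal direction is chart-right
for a right eye (OD) and chart-left for a left eye (OS); the OS grid is the
mirror image of the OD grid about the vertical meridian.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "Eye",
    "Subfield",
    "GridPoint",
    "TestingGrid",
    "build_grid",
    "subfield_mask",
    "hemifield_masks",
    "classify_subfield",
    "CENTRAL_RADIUS_DEG",
    "SUBFIELD_COUNTS",
]


class Eye(str, Enum):
    """Laterality: OD = right eye, OS = left eye."""

    OD = "OD"
    OS = "OS"


class Subfield(str, Enum):
    """Visual-field subfields: central 30-degree disc plus four peripheral quadrants."""

    CENTRAL30 = "central30"
    INFEROTEMPORAL = "inferotemporal"
    INFERONASAL = "inferonasal"
    SUPEROTEMPORAL = "superotemporal"
    SUPERONASAL = "superonasal"


CENTRAL_RADIUS_DEG = 30.0

#: Expected number of grid points per subfield.
SUBFIELD_COUNTS = {
    Subfield.CENTRAL30: 108,
    Subfield.INFEROTEMPORAL: 22,
    Subfield.INFERONASAL: 17,
    Subfield.SUPEROTEMPORAL: 22,
    Subfield.SUPERONASAL: 16,
}

N_POINTS = 185

# --- constructive recipe -----------------------------------------------------
# Central rings: (eccentricity deg, number of evenly spaced meridians starting
# at 90 deg).  Each ring contains the vertical meridian (90/270) => 10 central
# vertical-meridian points across the five rings.
_CENTRAL_RINGS = ((6.0, 12), (12.0, 16), (18.0, 20), (24.0, 24), (30.0, 32))

# Two dedicated blind-spot stimulus locations at the OD blind spot
# (~15 deg temporal, slightly inferior); their nasal mirror images are ordinary
# grid points so that each central hemifield keeps 47 points after exclusions.
_BLIND_SPOT_OD = ((15.0, -1.5), (15.0, -4.5))

# Peripheral fans per quadrant (OD chart angles, counter-clockwise from
# chart-right): (ring eccentricities, meridians strictly inside the quadrant).
_PERIPHERAL_FANS = (
    ((36.0, 45.75, 55.5), (11.25, 22.5, 33.75, 45.0, 56.25, 67.5, 78.75)),   # ST, 21
    ((36.0, 42.5, 49.0, 55.5), (101.25, 123.75, 146.25, 168.75)),            # SN, 16
    ((36.0, 42.0, 48.0, 54.0), (195.0, 217.5, 240.0, 262.5)),                # IN, 16
    ((36.0, 46.0, 56.5, 67.0), (285.0, 300.0, 315.0, 330.0, 345.0)),         # IT, 20
)

# Axis points realising the grid extents (OD chart coordinates).
_AXIS_POINTS = ((80.0, 0.0), (0.0, 55.5), (-55.5, 0.0), (0.0, -67.0))

_TOL = 1e-9


@dataclass(frozen=True)
class GridPoint:
    """One stimulus location of the testing grid."""

    point_id: int
    x_deg: float
    y_deg: float
    eccentricity_deg: float
    meridian_deg: float
    subfield: Subfield
    is_blind_spot: bool
    on_vertical_meridian: bool


def _pol2cart(ecc: float, meridian_deg: float) -> tuple[float, float]:
    """Polar chart coordinates to cartesian, snapping ~0 values exactly to 0."""
    x = ecc * np.cos(np.deg2rad(meridian_deg))
    y = ecc * np.sin(np.deg2rad(meridian_deg))
    if abs(x) < _TOL * max(1.0, ecc):
        x = 0.0
    if abs(y) < _TOL * max(1.0, ecc):
        y = 0.0
    return float(x), float(y)


def classify_subfield(temporal_x: float, y: float, eccentricity: float) -> Subfield:
    """Assign a location to its subfield.

    ``temporal_x`` is the anatomic-temporal coordinate (positive toward the
    temporal field).  Tie-breaks for peripheral boundary points: exactly on the
    horizontal meridian -> inferior quadrant of that side; exactly on the
    vertical meridian -> temporal quadrant of that vertical side.
    """
    if eccentricity <= CENTRAL_RADIUS_DEG + _TOL:
        return Subfield.CENTRAL30
    if abs(y) < _TOL:
        return Subfield.INFEROTEMPORAL if temporal_x > 0 else Subfield.INFERONASAL
    if abs(temporal_x) < _TOL:
        return Subfield.SUPEROTEMPORAL if y > 0 else Subfield.INFEROTEMPORAL
    if temporal_x > 0:
        return Subfield.SUPEROTEMPORAL if y > 0 else Subfield.INFEROTEMPORAL
    return Subfield.SUPERONASAL if y > 0 else Subfield.INFERONASAL


#: Fixed subfield order for integer-coded classification.
SUBFIELD_ORDER: tuple[Subfield, ...] = (
    Subfield.CENTRAL30,
    Subfield.INFEROTEMPORAL,
    Subfield.INFERONASAL,
    Subfield.SUPEROTEMPORAL,
    Subfield.SUPERONASAL,
)


def classify_subfield_codes(
    temporal_x: np.ndarray, y: np.ndarray, eccentricity: np.ndarray
) -> np.ndarray:
    """Vectorised subfield classification as indices into :data:`SUBFIELD_ORDER`."""
    temporal_x = np.asarray(temporal_x, dtype=float)
    y = np.asarray(y, dtype=float)
    eccentricity = np.asarray(eccentricity, dtype=float)
    c, it, inn, st, sn = range(5)
    out = np.empty(temporal_x.shape, dtype=np.uint8)
    central = eccentricity <= CENTRAL_RADIUS_DEG + _TOL
    on_h = np.abs(y) < _TOL
    on_v = np.abs(temporal_x) < _TOL
    out[central] = c
    p = ~central
    out[p & on_h & (temporal_x > 0)] = it
    out[p & on_h & (temporal_x <= 0)] = inn
    out[p & ~on_h & on_v & (y > 0)] = st
    out[p & ~on_h & on_v & (y < 0)] = it
    q = p & ~on_h & ~on_v
    out[q & (temporal_x > 0) & (y > 0)] = st
    out[q & (temporal_x > 0) & (y < 0)] = it
    out[q & (temporal_x < 0) & (y > 0)] = sn
    out[q & (temporal_x < 0) & (y < 0)] = inn
    return out


def classify_subfield_arrays(
    temporal_x: np.ndarray, y: np.ndarray, eccentricity: np.ndarray
) -> np.ndarray:
    """Vectorised :func:`classify_subfield`; returns an object array of Subfield."""
    codes = classify_subfield_codes(temporal_x, y, eccentricity)
    lookup = np.array(SUBFIELD_ORDER, dtype=object)
    return lookup[codes]


@dataclass(frozen=True)
class TestingGrid:
    """The 185-point testing grid for one laterality.

    Backed by parallel numpy arrays ordered by ``point_id``; :attr:`points`
    exposes the same data as :class:`GridPoint` records.
    """

    laterality: Eye
    x: np.ndarray
    y: np.ndarray
    subfields: np.ndarray  # object array of Subfield
    is_blind_spot: np.ndarray
    on_vertical_meridian: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.x)
        if not (len(self.y) == len(self.subfields) == len(self.is_blind_spot)
                == len(self.on_vertical_meridian) == n):
            raise ValueError("grid arrays must have equal length")
        coords = {(round(xi, 6), round(yi, 6)) for xi, yi in zip(self.x, self.y)}
        if len(coords) != n:
            raise ValueError("grid contains duplicate (x, y) coordinates")

    # -- derived geometry -----------------------------------------------------
    @property
    def n_points(self) -> int:
        return len(self.x)

    @property
    def eccentricity(self) -> np.ndarray:
        return np.hypot(self.x, self.y)

    @property
    def meridian(self) -> np.ndarray:
        return np.degrees(np.arctan2(self.y, self.x)) % 360.0

    @property
    def temporal_x(self) -> np.ndarray:
        """Anatomic-temporal coordinate (positive toward the temporal field)."""
        return self.x if self.laterality is Eye.OD else -self.x

    @property
    def extents(self) -> dict[str, float]:
        """Maximal reach (deg) in the four anatomic directions."""
        tx = self.temporal_x
        return {
            "nasal": float(np.max(-tx)),
            "superior": float(np.max(self.y)),
            "inferior": float(np.max(-self.y)),
            "temporal": float(np.max(tx)),
        }

    @property
    def points(self) -> list[GridPoint]:
        ecc = self.eccentricity
        mer = self.meridian
        return [
            GridPoint(i, float(self.x[i]), float(self.y[i]), float(ecc[i]),
                      float(mer[i]), self.subfields[i],
                      bool(self.is_blind_spot[i]), bool(self.on_vertical_meridian[i]))
            for i in range(self.n_points)
        ]

    def __iter__(self) -> Iterator[GridPoint]:
        return iter(self.points)

    # -- masks ----------------------------------------------------------------
    def subfield_mask(self, subfield: Subfield | str) -> np.ndarray:
        return subfield_mask(self, subfield)

    def hemifield_masks(self) -> tuple[np.ndarray, np.ndarray]:
        return hemifield_masks(self)

    def mirror(self) -> "TestingGrid":
        """Grid of the fellow eye (mirror about the vertical meridian)."""
        other = Eye.OS if self.laterality is Eye.OD else Eye.OD
        return TestingGrid(
            laterality=other,
            x=-self.x,
            y=self.y.copy(),
            subfields=self.subfields.copy(),
            is_blind_spot=self.is_blind_spot.copy(),
            on_vertical_meridian=self.on_vertical_meridian.copy(),
        )

    # -- serialisation --------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "point_id": np.arange(self.n_points),
                "x_deg": self.x,
                "y_deg": self.y,
                "subfield": [s.value for s in self.subfields],
                "is_blind_spot": self.is_blind_spot.astype(int),
                "on_vertical_meridian": self.on_vertical_meridian.astype(int),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, laterality: Eye | str) -> "TestingGrid":
        required = {"point_id", "x_deg", "y_deg", "subfield", "is_blind_spot",
                    "on_vertical_meridian"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"grid table missing columns: {sorted(missing)}")
        df = df.sort_values("point_id")
        return cls(
            laterality=Eye(laterality),
            x=df["x_deg"].to_numpy(float),
            y=df["y_deg"].to_numpy(float),
            subfields=np.array([Subfield(s) for s in df["subfield"]], dtype=object),
            is_blind_spot=df["is_blind_spot"].to_numpy(bool),
            on_vertical_meridian=df["on_vertical_meridian"].to_numpy(bool),
        )

    @classmethod
    def from_csv(cls, path: str | Path, laterality: Eye | str = Eye.OD) -> "TestingGrid":
        return cls.from_dataframe(pd.read_csv(path), laterality)


def _build_od_table() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Construct the canonical OD point set: (x, y, is_blind_spot, on_vertical)."""
    xs: list[float] = []
    ys: list[float] = []
    blind: list[bool] = []

    # central rings
    for ecc, m in _CENTRAL_RINGS:
        angles = (90.0 + 360.0 * np.arange(m) / m) % 360.0
        for a in np.sort(angles):
            x, y = _pol2cart(ecc, a)
            xs.append(x)
            ys.append(y)
            blind.append(False)
    # blind-spot points and their nasal mirrors
    for bx, by in _BLIND_SPOT_OD:
        xs.append(bx)
        ys.append(by)
        blind.append(True)
    for bx, by in _BLIND_SPOT_OD:
        xs.append(-bx)
        ys.append(by)
        blind.append(False)
    # axis extent points
    for ax, ay in _AXIS_POINTS:
        xs.append(ax)
        ys.append(ay)
        blind.append(False)
    # peripheral fans
    for rings, meridians in _PERIPHERAL_FANS:
        for ecc in rings:
            for a in meridians:
                x, y = _pol2cart(ecc, a)
                xs.append(x)
                ys.append(y)
                blind.append(False)

    x = np.array(xs)
    y = np.array(ys)
    is_blind = np.array(blind)
    on_vertical = np.abs(x) < _TOL
    return x, y, is_blind, on_vertical


def build_grid(laterality: Eye | str = Eye.OD) -> TestingGrid:
    """Construct the 185-point testing grid for the given eye.

    Deterministic and parameter-free.  The OS grid is the mirror image of the
    OD grid about the vertical meridian; anatomic subfield labels (nasal vs
    temporal) are preserved under mirroring.
    """
    laterality = Eye(laterality)
    x, y, is_blind, on_vertical = _build_od_table()
    ecc = np.hypot(x, y)
    subfields = classify_subfield_arrays(x, y, ecc)  # OD: temporal_x == x
    od = TestingGrid(
        laterality=Eye.OD,
        x=x,
        y=y,
        subfields=subfields,
        is_blind_spot=is_blind,
        on_vertical_meridian=on_vertical,
    )
    return od if laterality is Eye.OD else od.mirror()


def subfield_mask(grid: TestingGrid, subfield: Subfield | str) -> np.ndarray:
    """Boolean mask over grid points belonging to ``subfield``."""
    subfield = Subfield(subfield)
    return np.array([s is subfield for s in grid.subfields])


def hemifield_masks(grid: TestingGrid) -> tuple[np.ndarray, np.ndarray]:
    """(nasal, temporal) masks over the central 30-degree disc.

    Points on the vertical meridian are excluded from both hemifields;
    blind-spot points and their mirror images across the vertical meridian are
    excluded so that the two hemifields stay comparable (47 points each).

    Raises
    ------
    ValueError
        If the grid violates the central exclusion constraint
        ``n_vertical + 2 * n_blind_spot == 14``.
    """
    central = subfield_mask(grid, Subfield.CENTRAL30)
    vertical = grid.on_vertical_meridian & central
    blind = grid.is_blind_spot & central
    n_v, n_b = int(vertical.sum()), int(blind.sum())
    if n_v + 2 * n_b != 14:
        raise ValueError(
            f"central exclusion constraint violated: {n_v} vertical-meridian "
            f"+ 2*{n_b} blind-spot points != 14"
        )
    # mirror images (about the vertical meridian) of the blind-spot points
    mirror = np.zeros(grid.n_points, dtype=bool)
    coords = {(round(float(x), 6), round(float(y), 6)): i
              for i, (x, y) in enumerate(zip(grid.x, grid.y))}
    for i in np.flatnonzero(blind):
        j = coords.get((round(float(-grid.x[i]), 6), round(float(grid.y[i]), 6)))
        if j is None:
            raise ValueError("blind-spot point lacks a mirror image in the grid")
        mirror[j] = True
    keep = central & ~vertical & ~blind & ~mirror
    tx = grid.temporal_x
    temporal = keep & (tx > 0)
    nasal = keep & (tx < 0)
    return nasal, temporal


def packaged_grid_path() -> Path:
    """Path to the canonical OD grid CSV shipped with the package."""
    return Path(str(importlib.resources.files("perifield").joinpath("data/grid_od.csv")))
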