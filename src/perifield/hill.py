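"""Hill-of-vision interpolation and volumetric integration in decibel-steradians.

Scattered pointwise sensitivities are interpolated piecewise-linearly on a
Delaunay triangulation and rasterised onto a regular lattice of chart degrees.
Chart position is read as a polar azimuthal-equidistant projection of the
viewing sphere (theta = eccentricity in radians, phi = meridian), so each
lattice cell carries a solid-angle weight

    d_omega = sin(theta) / theta * (pi/180)^2 * dx * dy     [steradians],

and a region's volume is the sum of interpolated dB values times cell solid
angles: the "volume under the hill of vision" in dB-sr.  No extrapolation is
performed outside the convex hull of the sampled points.

Region masks (subfields, caps) are evaluated with per-cell sub-sampling so a
cell crossing a region boundary contributes fractionally; the five subfield
fractions partition every defined cell exactly, making regional volumes sum
to the total volume to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

from .grid import (
    CENTRAL_RADIUS_DEG,
    SUBFIELD_ORDER,
    Eye,
    Subfield,
    TestingGrid,
    classify_subfield_codes,
)
from .io import ExamRecord

__all__ = [
    "Raster",
    "HillOfVision",
    "InterpolationError",
    "interpolate_points",
    "interpolate_field",
    "solid_angle_weights",
    "cap_solid_angle",
    "volume",
    "subfield_fractions",
    "cap_fraction",
    "composite_map",
    "hill_of_vision",
    "plot_heatmap",
]

DEFAULT_RESOLUTION_DEG = 0.5
DEFAULT_SUBSAMPLE = 4

DEG2 = (np.pi / 180.0) ** 2


class InterpolationError(ValueError):
    """Raised for degenerate (e.g. collinear) scattered point sets."""


@dataclass(frozen=True)
class Raster:
    """Interpolated sensitivity lattice.

    ``values[j, i]`` is the interpolated dB value at cell centre
    ``(xs[i], ys[j])``; NaN outside the convex hull of the sampled points.
    """

    xs: np.ndarray           # cell-centre x (deg), ascending
    ys: np.ndarray           # cell-centre y (deg), ascending
    values: np.ndarray       # shape (len(ys), len(xs)), NaN outside hull
    resolution_deg: float
    points_x: np.ndarray
    points_y: np.ndarray
    node_values: np.ndarray
    interpolator: LinearNDInterpolator
    mirror_x: bool = False   # interpolator triangulated on mirrored x

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of lattice cells inside the convex hull."""
        return np.isfinite(self.values)

    @property
    def grid_xy(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.xs, self.ys)

    @property
    def eccentricity(self) -> np.ndarray:
        gx, gy = self.grid_xy
        return np.hypot(gx, gy)

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Interpolated value at arbitrary chart coordinates (NaN outside hull)."""
        x = np.asarray(x, float)
        return self.interpolator(-x if self.mirror_x else x, np.asarray(y, float))

    def mirrored(self) -> "Raster":
        """The raster reflected about the vertical meridian (x -> -x)."""
        return Raster(
            xs=-self.xs[::-1], ys=self.ys, values=self.values[:, ::-1],
            resolution_deg=self.resolution_deg,
            points_x=-self.points_x, points_y=self.points_y,
            node_values=self.node_values, interpolator=self.interpolator,
            mirror_x=not self.mirror_x,
        )


def interpolate_points(
    x: np.ndarray,
    y: np.ndarray,
    values: np.ndarray,
    resolution_deg: float = DEFAULT_RESOLUTION_DEG,
) -> Raster:
    """Piecewise-linear (Delaunay barycentric) interpolation of scattered data.

    Exactly reproduces node values and any globally affine surface inside the
    convex hull; never extrapolates.
    """
    if resolution_deg <= 0:
        raise ValueError("resolution_deg must be positive")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    values = np.asarray(values, float)
    if not (len(x) == len(y) == len(values)):
        raise ValueError("x, y and values must have equal length")
    try:
        interp = LinearNDInterpolator(np.column_stack([x, y]), values)
    except (QhullError, ValueError) as exc:
        raise InterpolationError(f"degenerate point set: {exc}") from exc
    h = resolution_deg
    xs = np.arange(np.floor(x.min() / h) * h + h / 2, x.max(), h)
    ys = np.arange(np.floor(y.min() / h) * h + h / 2, y.max(), h)
    gx, gy = np.meshgrid(xs, ys)
    vals = interp(gx, gy)
    return Raster(
        xs=xs, ys=ys, values=vals, resolution_deg=h,
        points_x=x, points_y=y, node_values=values, interpolator=interp,
    )


def interpolate_field(
    exam: ExamRecord | np.ndarray,
    grid: TestingGrid,
    resolution_deg: float = DEFAULT_RESOLUTION_DEG,
) -> Raster:
    """Interpolate one exam's sensitivities over its testing grid."""
    v = exam.sensitivities if isinstance(exam, ExamRecord) else np.asarray(exam, float)
    if len(v) != grid.n_points:
        raise ValueError("exam/grid size mismatch")
    # triangulate in anatomic coordinates (temporal x positive): the ring
    # layout has co-circular points whose Delaunay triangulation is otherwise
    # ambiguous, and a canonical frame makes fellow-eye mirroring exact
    anat = interpolate_points(grid.temporal_x, grid.y, v, resolution_deg)
    return anat if grid.laterality is Eye.OD else anat.mirrored()


def solid_angle_weights(raster: Raster) -> np.ndarray:
    """Solid angle (sr) of each lattice cell under the polar projection.

    theta is the eccentricity in radians; the azimuthal-equidistant Jacobian
    sin(theta)/theta is evaluated at the cell centre.  Summed over a region,
    the weights converge to the region's true solid angle.
    """
    theta = np.deg2rad(raster.eccentricity)
    jac = np.where(theta > 0, np.sin(theta) / np.where(theta > 0, theta, 1.0), 1.0)
    return jac * raster.resolution_deg**2 * DEG2


def cap_solid_angle(radius_deg: float) -> float:
    """Closed-form solid angle of a spherical cap of the given angular radius."""
    return 2.0 * np.pi * (1.0 - np.cos(np.deg2rad(radius_deg)))


def _subsample_offsets(resolution: float, subsample: int) -> tuple[np.ndarray, np.ndarray]:
    step = resolution / subsample
    off = -resolution / 2 + step * (np.arange(subsample) + 0.5)
    return np.meshgrid(off, off)


def cap_fraction(
    raster: Raster, radius_deg: float, subsample: int = DEFAULT_SUBSAMPLE
) -> np.ndarray:
    """Per-cell fraction lying inside the disc of the given eccentricity radius."""
    gx, gy = raster.grid_xy
    ox, oy = _subsample_offsets(raster.resolution_deg, subsample)
    frac = np.zeros_like(gx)
    for dx, dy in zip(ox.ravel(), oy.ravel()):
        frac += np.hypot(gx + dx, gy + dy) <= radius_deg
    return frac / subsample**2


def subfield_fractions(
    raster: Raster,
    laterality: Eye | str,
    subsample: int = DEFAULT_SUBSAMPLE,
) -> dict[Subfield, np.ndarray]:
    """Per-cell membership fractions for the five subfields.

    The fractions of the five subfields sum to 1 in every cell (each
    sub-sample point is assigned to exactly one subfield), so regional
    volumes are exactly additive.
    """
    laterality = Eye(laterality)
    gx, gy = raster.grid_xy
    ox, oy = _subsample_offsets(raster.resolution_deg, subsample)
    counts = {s: np.zeros_like(gx) for s in SUBFIELD_ORDER}
    for dx, dy in zip(ox.ravel(), oy.ravel()):
        px, py = gx + dx, gy + dy
        tx = px if laterality is Eye.OD else -px
        codes = classify_subfield_codes(tx, py, np.hypot(px, py))
        for i, s in enumerate(SUBFIELD_ORDER):
            counts[s] += codes == i
    return {s: c / subsample**2 for s, c in counts.items()}


def volume(
    raster: Raster,
    region: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> float:
    """Integrated sensitivity over a region, in dB-sr.

    ``region`` is a per-cell membership fraction (or boolean mask); ``None``
    integrates over the whole defined raster.  Linear in sensitivity and
    additive over disjoint regions.
    """
    if weights is None:
        weights = solid_angle_weights(raster)
    defined = raster.defined
    if region is None:
        frac = np.ones_like(weights)
    else:
        frac = np.asarray(region, dtype=float)
        if frac.shape != raster.values.shape:
            raise ValueError("region mask shape does not match the raster")
    eff = frac * defined
    if not np.any(eff > 0):
        raise ValueError("empty region: no defined raster cells selected")
    vals = np.where(defined, raster.values, 0.0)
    return float(np.sum(vals * weights * eff))


def composite_map(
    exams: Sequence[ExamRecord] | Mapping[str, np.ndarray],
    grid: TestingGrid,
    resolution_deg: float = DEFAULT_RESOLUTION_DEG,
) -> Raster:
    """Cohort composite: pointwise mean sensitivity per node, then interpolation.

    All exams must share the grid's laterality.
    """
    if isinstance(exams, Mapping):
        fields = [np.asarray(v, float) for v in exams.values()]
    else:
        if len({e.eye for e in exams}) > 1:
            raise ValueError("composite map requires a single laterality")
        if exams and isinstance(exams[0], ExamRecord):
            if exams[0].eye is not grid.laterality:
                raise ValueError("exam laterality does not match the grid")
        fields = [e.sensitivities for e in exams]
    if len(fields) == 0:
        raise ValueError("no exams supplied")
    mean_field = np.mean(np.stack(fields), axis=0)
    return interpolate_field(mean_field, grid, resolution_deg)


@dataclass(frozen=True)
class HillOfVision:
    """Interpolated hill of vision with solid-angle weights and volumes.

    ``v_tot`` integrates over the whole convex hull; ``v_30`` over the central
    30-degree disc; ``v_subfield`` maps each subfield to its volume.  The
    subfield volumes sum to ``v_tot`` (same partition, same hull).
    """

    raster: Raster
    cell_solid_angle: np.ndarray
    laterality: Eye
    v_tot: float
    v_30: float
    v_subfield: dict[Subfield, float]

    def volume(self, region: np.ndarray | None = None) -> float:
        return volume(self.raster, region, self.cell_solid_angle)


def hill_of_vision(
    exam: ExamRecord | np.ndarray,
    grid: TestingGrid,
    resolution_deg: float = DEFAULT_RESOLUTION_DEG,
    subsample: int = DEFAULT_SUBSAMPLE,
    fractions: dict[Subfield, np.ndarray] | None = None,
) -> HillOfVision:
    """Build the hill of vision for one exam and integrate its volumes.

    ``fractions`` may carry precomputed :func:`subfield_fractions` for the
    same grid/resolution (the subfield geometry is exam-independent).
    """
    raster = interpolate_field(exam, grid, resolution_deg)
    w = solid_angle_weights(raster)
    if fractions is None:
        fractions = subfield_fractions(raster, grid.laterality, subsample)
    v_sub = {s: volume(raster, f, w) for s, f in fractions.items()}
    return HillOfVision(
        raster=raster,
        cell_solid_angle=w,
        laterality=grid.laterality,
        v_tot=volume(raster, None, w),
        v_30=v_sub[Subfield.CENTRAL30],
        v_subfield=v_sub,
    )


def plot_heatmap(raster: Raster, ax=None, title: str | None = None,
                 cmap: str = "inferno", show_points: bool = False):
    """Render a sensitivity heatmap of an interpolated raster (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    extent = (
        raster.xs[0] - raster.resolution_deg / 2, raster.xs[-1] + raster.resolution_deg / 2,
        raster.ys[0] - raster.resolution_deg / 2, raster.ys[-1] + raster.resolution_deg / 2,
    )
    im = ax.imshow(raster.values, origin="lower", extent=extent, cmap=cmap)
    if show_points:
        ax.plot(raster.points_x, raster.points_y, "k.", ms=2)
    circ = plt.Circle((0, 0), CENTRAL_RADIUS_DEG, fill=False, ls="--", lw=0.8, color="w")
    ax.add_patch(circ)
    ax.set_xlabel("x (deg)")
    ax.set_ylabel("y (deg)")
    if title:
        ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, label="sensitivity (dB)")
    return ax
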