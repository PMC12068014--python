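"""Ray tracing from a virtual point source through the tube onto the SLM.

A fan of rays is launched from the desired focus inside the lumen, refracted
at the inner and outer cylinder surfaces while accumulating optical
pathlength (OPL = geometric length x local refractive index), then mapped by
the ideal Abbe-sine objective onto the virtual SLM/pupil plane.  The ideal
objective is realised by OPL bookkeeping: each exit ray's OPL is referenced
against the ray an unaberrated point source at the nominal focus would
produce at the same exit angle, so the design geometry yields an identically
flat wavefront.  Scattered per-ray OPL samples are finally rasterised onto
the SLM pixel grid by piecewise-linear interpolation on a Delaunay
triangulation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

from .optics_model import (
    ObjectiveModel,
    OpticalConfig,
    TubeModel,
    abbe_map,
    cylinder_intersect,
    vector_refract,
)

__all__ = [
    "RayBundle",
    "PupilSamples",
    "OplMap",
    "Rasterizer",
    "emit_fan",
    "trace_tube",
    "to_pupil",
    "rasterize",
    "propagate",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class RayBundle:
    """A fan of rays: positions, unit directions, accumulated OPL, alive mask."""

    positions: np.ndarray  # (N, 3) µm
    directions: np.ndarray  # (N, 3) unit
    opl: np.ndarray  # (N,) µm, index-weighted
    alive: np.ndarray  # (N,) bool

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (len(self.directions) == len(self.opl) == len(self.alive) == n):
            raise ValueError("RayBundle fields must share their first dimension")

    @property
    def n_rays(self) -> int:
        return len(self.positions)

    def copy(self) -> "RayBundle":
        return RayBundle(
            self.positions.copy(),
            self.directions.copy(),
            self.opl.copy(),
            self.alive.copy(),
        )


@dataclass
class PupilSamples:
    """Scattered OPL samples on the pupil plane (one per surviving ray)."""

    xy: np.ndarray  # (M, 2) pupil coordinates, units of pupil_radius
    opl: np.ndarray  # (M,) optical-pathlength difference vs. design (µm)


@dataclass
class OplMap:
    """OPL(x, y) rasterised on the SLM pixel grid.

    ``pupil_x``/``pupil_y`` hold the pupil coordinate of each pixel centre
    (pupil radius inscribed in the shorter grid dimension).
    """

    values: np.ndarray  # (ny, nx) µm; NaN outside valid_mask
    valid_mask: np.ndarray  # (ny, nx) bool
    pupil_x: np.ndarray  # (ny, nx)
    pupil_y: np.ndarray  # (ny, nx)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("OplMap values must be finite on valid pixels")


def pupil_pixel_grid(slm_shape, pupil_radius: float = 1.0):
    """Pupil coordinates of SLM pixel centres; radius inscribed in the grid."""
    ny, nx = slm_shape
    half = min(nx, ny) / 2.0
    x = (np.arange(nx) + 0.5 - nx / 2.0) / half * pupil_radius
    y = (np.arange(ny) + 0.5 - ny / 2.0) / half * pupil_radius
    return np.meshgrid(x, y)


def propagate(bundle: RayBundle, distance, n_medium: float) -> RayBundle:
    """Advance alive rays by ``distance`` in a homogeneous medium of index n."""
    t = np.broadcast_to(np.asarray(distance, dtype=float), (bundle.n_rays,))
    out = bundle.copy()
    a = out.alive
    out.positions[a] = bundle.positions[a] + t[a, None] * bundle.directions[a]
    out.opl[a] += n_medium * t[a]
    return out


def emit_fan(
    source,
    objective: ObjectiveModel,
    config: OpticalConfig,
    tube: TubeModel | None = None,
    cone_margin: float = 1.0,
    n_rays: int | None = None,
) -> RayBundle:
    """Launch a deterministic fan of rays from a point source at the focus.

    Directions sample the objective's acceptance cone uniformly in pupil
    area using a Fibonacci (golden-angle) spiral, which keeps the downstream
    scattered-data triangulation well conditioned at the pupil rim.  The
    maximum polar angle satisfies
    ``n_focus_medium * sin(theta_max) = NA * cone_margin``.

    The fan is fully deterministic; the config seed is not consumed.
    ``n_rays`` overrides the config's ray budget (e.g. a degenerate single
    axial ray for diagnostics).
    """
    source = np.asarray(source, dtype=float)
    if tube is not None and not tube.contains(source):
        raise ValueError(f"source {source.tolist()} is not inside the tube lumen")

    n = config.n_rays if n_rays is None else n_rays
    sin_max = objective.numerical_aperture * cone_margin / config.n_focus_medium
    if sin_max > 1.0:
        raise ValueError("acceptance cone exceeds 90 degrees in the focus medium")

    if n == 1:
        sin_theta = np.zeros(1)
        phi = np.zeros(1)
    else:
        i = np.arange(n)
        sin_theta = sin_max * np.sqrt((i + 0.5) / n)
        phi = i * _GOLDEN_ANGLE
    cos_theta = np.sqrt(1.0 - sin_theta**2)
    directions = np.column_stack(
        [
            sin_theta * np.cos(phi),
            sin_theta * np.sin(phi),
            -cos_theta,  # toward the objective
        ]
    )
    return RayBundle(
        positions=np.tile(source, (n, 1)),
        directions=directions,
        opl=np.zeros(n),
        alive=np.ones(n, dtype=bool),
    )


def _refract_at_cylinder(
    bundle: RayBundle, tube: TubeModel, radius: float, n_in: float, n_out: float
) -> RayBundle:
    """Intersect alive rays with one cylinder surface and refract across it."""
    out = bundle.copy()
    a = out.alive
    if not np.any(a):
        return out
    point, normal, dist, hit = cylinder_intersect(
        out.positions[a],
        out.directions[a],
        np.asarray(tube.axis_offset, dtype=float),
        tube.axis_direction,
        radius,
    )
    new_dir, tir = vector_refract(
        np.where(hit[:, None], out.directions[a], [0.0, 0.0, 1.0]),
        np.where(hit[:, None], normal, [0.0, 0.0, 1.0]),
        n_in,
        n_out,
    )
    ok = hit & ~tir
    idx = np.flatnonzero(a)
    out.positions[idx[ok]] = point[ok]
    out.directions[idx[ok]] = new_dir[ok]
    out.opl[idx[ok]] += n_in * dist[ok]
    out.alive[idx[~ok]] = False
    return out


def trace_tube(
    bundle: RayBundle, tube: TubeModel | None, config: OpticalConfig
) -> RayBundle:
    """Trace rays from inside the lumen through both cylinder surfaces.

    Rays refract at the inner surface (lumen -> shell) and then at the outer
    surface (shell -> outside); OPL grows by segment length times the local
    index.  TIR or geometric misses mask the ray dead and never raise.
    With ``tube=None`` the bundle passes unchanged (homogeneous scene).
    """
    if tube is None:
        return bundle.copy()
    out = _refract_at_cylinder(
        bundle, tube, tube.inner_radius, tube.n_lumen, tube.n_shell
    )
    out = _refract_at_cylinder(
        out, tube, tube.outer_radius, tube.n_shell, tube.n_outside
    )
    return out


def to_pupil(
    bundle: RayBundle, objective: ObjectiveModel, n_outside: float
) -> PupilSamples:
    """Map exit rays through the ideal objective to pupil OPL samples.

    The objective's contribution is the far-field reference: for a ray at
    position P with direction d in the exit medium, the pathlength difference
    against the design ray of equal angle from the nominal focus F is

        OPD = OPL_accumulated - n_outside * ((P - F) . d),

    which is exactly zero for every ray of an unaberrated point source at F.
    Rays outside the acceptance cone (or travelling away from the objective)
    are dropped.
    """
    a = bundle.alive
    pos = bundle.positions[a]
    d = bundle.directions[a]
    xy, inside = abbe_map(d, objective)
    f = np.asarray(objective.nominal_focus, dtype=float)
    opd = bundle.opl[a] - n_outside * np.sum((pos - f) * d, axis=-1)
    return PupilSamples(xy=xy[inside], opl=opd[inside])


class Rasterizer:
    """Piecewise-linear scattered-data rasteriser with a cached triangulation.

    Triangulates the pupil sample positions once; subsequent calls with new
    per-sample values are a sparse weighted sum, which makes re-evaluating
    the pattern during defocus optimisation cheap (sample positions do not
    move when the virtual objective translates axially).
    """

    def __init__(self, xy: np.ndarray, slm_shape, pupil_radius: float = 1.0):
        xy = np.asarray(xy, dtype=float)
        if len(xy) < 3:
            raise ValueError("need at least 3 pupil samples to triangulate")
        self.slm_shape = tuple(slm_shape)
        self.pupil_x, self.pupil_y = pupil_pixel_grid(slm_shape, pupil_radius)
        try:
            self.tri = Delaunay(xy)
        except Exception as exc:  # collinear / degenerate sample sets
            raise ValueError(f"degenerate pupil sample set: {exc}") from exc
        pixels = np.column_stack([self.pupil_x.ravel(), self.pupil_y.ravel()])
        simplex = self.tri.find_simplex(pixels)
        self.valid = simplex >= 0
        s = simplex[self.valid]
        transform = self.tri.transform[s]
        delta = pixels[self.valid] - transform[:, 2]
        bary = np.einsum("nij,nj->ni", transform[:, :2], delta)
        self._weights = np.column_stack([bary, 1.0 - bary.sum(axis=1)])
        self._vertices = self.tri.simplices[s]

    def __call__(self, values: np.ndarray) -> OplMap:
        values = np.asarray(values, dtype=float)
        if len(values) != self.tri.npoints:
            raise ValueError("value count does not match triangulated samples")
        flat = np.full(self.pupil_x.size, np.nan)
        flat[self.valid] = np.sum(values[self._vertices] * self._weights, axis=1)
        valid = self.valid.reshape(self.slm_shape)
        return OplMap(
            values=flat.reshape(self.slm_shape),
            valid_mask=valid,
            pupil_x=self.pupil_x,
            pupil_y=self.pupil_y,
        )


def rasterize(samples: PupilSamples, slm_shape, pupil_radius: float = 1.0) -> OplMap:
    """Rasterise scattered pupil OPL samples onto the SLM pixel grid.

    Linear interpolation on the Delaunay triangulation of the sample
    positions; pixels outside the convex hull carry ``valid_mask=False``.
    """
    return Rasterizer(samples.xy, slm_shape, pupil_radius)(samples.opl)
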