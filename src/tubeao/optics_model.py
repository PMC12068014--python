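"""Optical scene definition and elementary geometric-optics operators.

The scene is a glass capillary tube modelled as two infinite coaxial
cylindrical refracting surfaces, observed by an idealised Abbe-sine-corrected
objective.  Coordinate convention (fixed for the whole package): right-handed,
optical axis = +z pointing from the objective into the sample, tube axis in
the x-y plane at ``axis_angle`` from +x.  All lengths are in micrometres,
angles in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TubeModel",
    "ObjectiveModel",
    "OpticalConfig",
    "vector_refract",
    "cylinder_intersect",
    "abbe_map",
    "abbe_unmap",
]

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class TubeModel:
    """Two coaxial cylindrical interfaces with refractive media.

    Parameters
    ----------
    outer_radius : float
        Outer radius of the tube (µm).
    shell_thickness : float
        Thickness of the glass shell (µm); inner radius is
        ``outer_radius - shell_thickness``.
    n_shell : float
        Refractive index of the glass shell.
    n_lumen : float
        Index of the medium filling the lumen.
    n_outside : float
        Index of the medium between tube and objective.
    axis_angle : float
        Rotation of the tube axis about the optical axis, from +x (rad).
    axis_offset : tuple of float
        Position of a point on the tube axis in sample coordinates (µm).
    """

    outer_radius: float
    shell_thickness: float
    n_shell: float
    n_lumen: float
    n_outside: float
    axis_angle: float = 0.0
    axis_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.outer_radius > self.shell_thickness > 0:
            raise ValueError(
                "require outer_radius > shell_thickness > 0 "
                f"(got {self.outer_radius} and {self.shell_thickness})"
            )
        for name in ("n_shell", "n_lumen", "n_outside"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1 (got {getattr(self, name)})")

    @property
    def inner_radius(self) -> float:
        return self.outer_radius - self.shell_thickness

    @property
    def axis_direction(self) -> np.ndarray:
        """Unit vector along the tube axis (lies in the x-y plane)."""
        return np.array(
            [np.cos(self.axis_angle), np.sin(self.axis_angle), 0.0]
        )

    def rotated(self, delta_angle: float) -> "TubeModel":
        """Tube rotated about the optical axis by ``delta_angle``."""
        return replace(self, axis_angle=self.axis_angle + delta_angle)

    def contains(self, point) -> bool:
        """True if ``point`` lies strictly inside the lumen."""
        p = np.asarray(point, dtype=float) - np.asarray(self.axis_offset)
        u = self.axis_direction
        perp = p - np.dot(p, u) * u
        return float(np.linalg.norm(perp)) < self.inner_radius


@dataclass(frozen=True)
class ObjectiveModel:
    """Idealised Abbe-sine-corrected objective.

    ``pupil_radius`` fixes the unit of the pupil/SLM coordinate system; the
    default 1.0 means pupil coordinates are the normalised radius r/R.
    """

    numerical_aperture: float
    n_immersion: float
    nominal_focus: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pupil_radius: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.numerical_aperture <= self.n_immersion:
            raise ValueError(
                "require 0 < NA <= n_immersion "
                f"(got NA={self.numerical_aperture}, n={self.n_immersion})"
            )
        if self.pupil_radius <= 0:
            raise ValueError("pupil_radius must be > 0")

    @property
    def sin_theta_max(self) -> float:
        """Sine of the acceptance-cone half angle in the immersion medium."""
        return self.numerical_aperture / self.n_immersion

    def translated(self, dz: float) -> "ObjectiveModel":
        """Objective translated along the optical axis by ``dz`` (µm)."""
        f = self.nominal_focus
        return replace(self, nominal_focus=(f[0], f[1], f[2] + dz))


@dataclass(frozen=True)
class OpticalConfig:
    """Wavelength, ray budget and SLM raster for one computation."""

    wavelength: float
    n_focus_medium: float
    n_rays: int = 250_000
    slm_shape: tuple[int, int] = (512, 512)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")
        if self.n_rays < 3:
            raise ValueError("n_rays must be >= 3 for a non-degenerate triangulation")

    @property
    def k0(self) -> float:
        """Vacuum wavenumber 2π/λ (rad/µm)."""
        return 2.0 * np.pi / self.wavelength


def _check_unit(v: np.ndarray, name: str) -> None:
    norm = np.linalg.norm(v, axis=-1)
    if not np.allclose(norm, 1.0, atol=1e-6):
        raise ValueError(f"{name} must be unit length (|{name}| = {norm})")


def vector_refract(direction, normal, n1: float, n2: float):
    """Refract unit ray direction(s) at an interface via vectorial Snell's law.

    The surface normal may point to either side; it is internally oriented
    against the incoming ray.  Works on single vectors or (N, 3) arrays.

    Returns
    -------
    refracted : ndarray, same shape as ``direction``
        Unit direction of the transmitted ray; rows undergoing total internal
        reflection are NaN.
    tir : ndarray of bool
        Total-internal-reflection flag per ray.
    """
    d = np.atleast_2d(np.asarray(direction, dtype=float))
    n = np.atleast_2d(np.asarray(normal, dtype=float))
    _check_unit(d, "direction")
    _check_unit(n, "normal")
    # orient normal against the ray so cos(theta_i) >= 0
    cos_i = -np.sum(d * n, axis=-1)
    n_oriented = np.where(cos_i[:, None] < 0, -n, n)
    cos_i = np.abs(cos_i)

    mu = n1 / n2
    sin2_t = mu**2 * (1.0 - cos_i**2)
    tir = sin2_t > 1.0
    cos_t = np.sqrt(np.clip(1.0 - sin2_t, 0.0, None))
    t = mu * d + (mu * cos_i - cos_t)[:, None] * n_oriented
    t = t / np.linalg.norm(t, axis=-1, keepdims=True)
    t[tir] = np.nan
    if np.asarray(direction).ndim == 1:
        return t[0], bool(tir[0])
    return t, tir


def cylinder_intersect(origin, direction, axis_point, axis_direction, radius: float):
    """Nearest forward intersection of ray(s) with an infinite cylinder.

    Solves |w_perp + t d_perp|^2 = rho^2 with the axis component projected
    out, using the numerically stable quadratic form (important for the
    huge-radius slab limit).

    Returns
    -------
    point : (N, 3) ndarray
        Intersection points (NaN where the ray misses).
    normal : (N, 3) ndarray
        Outward unit surface normal at the hit point.
    distance : (N,) ndarray
        Travel distance t >= 0 (inf where the ray misses).
    hit : (N,) ndarray of bool
    """
    o = np.atleast_2d(np.asarray(origin, dtype=float))
    d = np.atleast_2d(np.asarray(direction, dtype=float))
    _check_unit(d, "direction")
    c = np.asarray(axis_point, dtype=float)
    u = np.asarray(axis_direction, dtype=float)
    u = u / np.linalg.norm(u)

    w = o - c
    w_par = (w @ u)[:, None] * u
    w_perp = w - w_par
    d_perp = d - (d @ u)[:, None] * u

    a = np.sum(d_perp * d_perp, axis=-1)
    b = 2.0 * np.sum(w_perp * d_perp, axis=-1)
    cc = np.sum(w_perp * w_perp, axis=-1) - radius**2

    eps = 1e-14
    disc = b * b - 4.0 * a * cc
    hit = (a > eps) & (disc >= 0.0)

    t = np.full(len(o), np.inf)
    with np.errstate(invalid="ignore", divide="ignore"):
        sqrt_disc = np.sqrt(np.where(disc >= 0, disc, np.nan))
        # stable: q = -(b + sign(b) sqrt(disc)) / 2; roots q/a and cc/q
        q = -0.5 * (b + np.copysign(sqrt_disc, np.where(b == 0, 1.0, b)))
        t1 = np.where(np.abs(a) > eps, q / a, np.inf)
        t2 = np.where(np.abs(q) > eps, cc / q, np.inf)
    t_lo = np.minimum(t1, t2)
    t_hi = np.maximum(t1, t2)
    fwd_tol = 1e-9
    t_sel = np.where(t_lo > fwd_tol, t_lo, np.where(t_hi > fwd_tol, t_hi, np.inf))
    t = np.where(hit, t_sel, np.inf)
    hit = hit & np.isfinite(t)

    with np.errstate(invalid="ignore"):
        point = o + t[:, None] * d
        rel = point - c
        normal = rel - (rel @ u)[:, None] * u
        normal = normal / np.linalg.norm(normal, axis=-1, keepdims=True)
    point[~hit] = np.nan
    normal[~hit] = np.nan

    if np.asarray(origin).ndim == 1:
        return point[0], normal[0], float(t[0]), bool(hit[0])
    return point, normal, t, hit


def abbe_map(direction, objective: ObjectiveModel):
    """Map exit-ray directions to pupil coordinates via the Abbe sine rule.

    A ray travelling toward the objective (d_z < 0) at polar angle theta to
    the optical axis lands at normalised pupil radius
    r/R = n_immersion sin(theta) / NA, with azimuth preserved.

    Returns
    -------
    xy : (N, 2) ndarray
        Pupil coordinates in units of ``objective.pupil_radius``.
    inside : (N,) bool
        False for rays outside the acceptance cone (or travelling away from
        the objective); these are to be masked dead, never clipped.
    """
    d = np.atleast_2d(np.asarray(direction, dtype=float))
    sin_theta_xy = d[:, :2] * (objective.n_immersion / objective.numerical_aperture)
    xy = sin_theta_xy * objective.pupil_radius
    r = np.linalg.norm(xy, axis=-1)
    inside = (d[:, 2] < 0) & (r <= objective.pupil_radius * (1 + 1e-12))
    if np.asarray(direction).ndim == 1:
        return xy[0], bool(inside[0])
    return xy, inside


def abbe_unmap(xy, objective: ObjectiveModel) -> np.ndarray:
    """Inverse of :func:`abbe_map`: pupil coordinates to unit exit direction."""
    single = np.asarray(xy).ndim == 1
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    s = xy / objective.pupil_radius * objective.sin_theta_max
    sin2 = np.sum(s * s, axis=-1)
    if np.any(sin2 > 1 + 1e-12):
        raise ValueError("pupil coordinate outside the unit pupil")
    dz = -np.sqrt(np.clip(1.0 - sin2, 0.0, None))
    d = np.column_stack([s, dz])
    return d[0] if single else d
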