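"""Zernike basis, pattern decomposition, and a simulated sensorless-AO baseline.

Zernike modes are indexed ANSI-style by (radial order n, signed azimuthal
order m) and stored unit-RMS orthonormal over the unit disk (coefficient =
RMS contribution in radians).  Because published mode amplitudes differ
between normalisation conventions, coefficients can be rescaled to the
unit-peak convention (coefficient of R_n^|m|(rho) cos/sin(|m| phi), radial
part 1 at the rim) via :meth:`ZernikeCoefficients.scaled`.

The sensorless-AO baseline mirrors an exhaustive experimental search: a
brute-force Cartesian grid over the amplitudes of two dominant modes, with
the feedback signal supplied by a digital twin (overlap of the candidate
against the ground-truth pattern), and bicubic interpolation to locate the
optimum between grid nodes.  A rotation-alignment calibration scans rigid
rotations of a pattern against the same feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .metrics import DefocusModel, PupilField, overlap
from .pattern import PhasePattern, rotate_pattern
from .raytracer import pupil_pixel_grid

__all__ = [
    "ZernikeCoefficients",
    "GridSearchResult",
    "zernike_mode",
    "zernike_modes_upto",
    "decompose",
    "reconstruct",
    "twin_feedback",
    "grid_search",
    "align_rotation",
]

_PEAK_FROM_RMS = "unit-peak"
_RMS = "unit-rms"


def _radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Zernike radial polynomial R_n^m (m = |m|)."""
    out = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        c = (
            (-1) ** k
            * factorial(n - k)
            / (factorial(k) * factorial((n + m) // 2 - k) * factorial((n - m) // 2 - k))
        )
        out += c * rho ** (n - 2 * k)
    return out


def _norm_factor(n: int, m: int) -> float:
    """Unit-RMS normalisation: sqrt(n+1) for m = 0, sqrt(2(n+1)) otherwise."""
    return np.sqrt((2.0 - (m == 0)) * (n + 1.0))


def zernike_mode(n: int, m: int, pupil_x, pupil_y, convention: str = _RMS):
    """Evaluate Zernike mode (n, m) on the given pupil coordinates.

    Zero outside the unit disk.  ``m >= 0`` selects the cosine (vertical)
    mode, ``m < 0`` the sine (oblique) mode.
    """
    if n < 0 or abs(m) > n or (n - abs(m)) % 2 != 0:
        raise ValueError(f"invalid Zernike indices (n={n}, m={m})")
    x = np.asarray(pupil_x, dtype=float)
    y = np.asarray(pupil_y, dtype=float)
    rho = np.hypot(x, y)
    phi = np.arctan2(y, x)
    inside = rho <= 1.0 + 1e-12
    r = _radial(n, abs(m), np.where(inside, rho, 0.0))
    ang = np.cos(abs(m) * phi) if m >= 0 else np.sin(abs(m) * phi)
    z = r * ang
    if convention == _RMS:
        z = z * _norm_factor(n, abs(m))
    elif convention != _PEAK_FROM_RMS:
        raise ValueError(f"unknown convention {convention!r}")
    return np.where(inside, z, 0.0)


def zernike_modes_upto(max_order: int) -> list[tuple[int, int]]:
    """All (n, m) index pairs with n <= max_order, ANSI ordering."""
    return [
        (n, m)
        for n in range(max_order + 1)
        for m in range(-n, n + 1, 2)
    ]


@dataclass
class ZernikeCoefficients:
    """Mode-indexed amplitudes (radians) of a decomposed pattern."""

    coefficients: dict[tuple[int, int], float]
    convention: str = _RMS
    residual_rms: float = np.nan

    def __getitem__(self, nm: tuple[int, int]) -> float:
        return self.coefficients.get(nm, 0.0)

    def scaled(self, convention: str) -> "ZernikeCoefficients":
        """Coefficients converted to another normalisation convention."""
        if convention == self.convention:
            return self
        if {self.convention, convention} != {_RMS, _PEAK_FROM_RMS}:
            raise ValueError(f"cannot convert {self.convention} -> {convention}")
        to_peak = convention == _PEAK_FROM_RMS
        coeffs = {
            (n, m): c * (_norm_factor(n, abs(m)) if to_peak else 1.0 / _norm_factor(n, abs(m)))
            for (n, m), c in self.coefficients.items()
        }
        return ZernikeCoefficients(coeffs, convention, self.residual_rms)

    def largest(self, exclude_gauge: bool = True) -> list[tuple[tuple[int, int], float]]:
        """Modes sorted by |amplitude|.

        By default the gauge modes — piston, tilt and defocus (2, 0) — are
        excluded: they do not degrade the focus (piston) or are removed by
        translating the objective/stage, so they carry no aberration content.
        """
        gauge = {(0, 0), (1, -1), (1, 1), (2, 0)}
        items = [
            (nm, c)
            for nm, c in self.coefficients.items()
            if not (exclude_gauge and nm in gauge)
        ]
        return sorted(items, key=lambda kv: -abs(kv[1]))


def decompose(
    pattern: PhasePattern, max_order: int = 8, convention: str = _RMS
) -> ZernikeCoefficients:
    """Least-squares Zernike decomposition of a pattern over its valid pixels."""
    mask = pattern.valid_mask
    if not np.any(mask):
        raise ValueError("pattern has no valid pixels")
    modes = zernike_modes_upto(max_order)
    design = np.column_stack(
        [zernike_mode(n, m, pattern.pupil_x, pattern.pupil_y)[mask] for n, m in modes]
    )
    rhs = pattern.phase[mask]
    coeffs, _, rank, _ = np.linalg.lstsq(design, rhs, rcond=None)
    if rank < len(modes):
        raise ValueError(
            "ill-conditioned Zernike fit: the valid-pixel mask is too sparse"
        )
    residual = rhs - design @ coeffs
    result = ZernikeCoefficients(
        coefficients={nm: float(c) for nm, c in zip(modes, coeffs)},
        convention=_RMS,
        residual_rms=float(np.sqrt(np.mean(residual**2))),
    )
    return result.scaled(convention)


def reconstruct(
    coeffs: ZernikeCoefficients, pupil_x, pupil_y, valid_mask=None
) -> PhasePattern:
    """Phase pattern synthesised from Zernike coefficients."""
    rms = coeffs.scaled(_RMS)
    phase = np.zeros_like(np.asarray(pupil_x, dtype=float))
    for (n, m), c in rms.coefficients.items():
        if c != 0.0:
            phase = phase + c * zernike_mode(n, m, pupil_x, pupil_y)
    if valid_mask is None:
        valid_mask = np.hypot(pupil_x, pupil_y) <= 1.0
    phase = np.where(valid_mask, phase, np.nan)
    return PhasePattern(
        phase=phase,
        valid_mask=np.asarray(valid_mask, dtype=bool),
        pupil_x=np.asarray(pupil_x, dtype=float),
        pupil_y=np.asarray(pupil_y, dtype=float),
        meta={"zernike": {f"{n},{m}": c for (n, m), c in rms.coefficients.items()}},
    )


def twin_feedback(
    candidate: PhasePattern,
    truth: PhasePattern,
    amplitude: PupilField,
    defocus: DefocusModel,
    zd_scan=None,
) -> float:
    """Digital-twin feedback signal: defocus-optimised |gamma|^2 vs. the truth.

    Stands in for the experimental fluorescence feedback: it is maximal iff
    the candidate corrects the true aberration up to piston and defocus, and
    it decreases monotonically with growing residual wavefront error in the
    small-aberration regime.  The default defocus scan is narrower than the
    metric default (+/-5 µm, 51 steps) because candidate and truth patterns
    are both defocus-free by construction.
    """
    if zd_scan is None:
        zd_scan = np.linspace(-5.0, 5.0, 51)
    g2, _ = overlap(truth, candidate, amplitude, defocus, zd_scan=zd_scan)
    return g2


@dataclass
class GridSearchResult:
    """Brute-force two-mode search: feedback surface and interpolated optimum."""

    grid: np.ndarray  # (len(axis_a), len(axis_b)) feedback values
    axis_a: np.ndarray
    axis_b: np.ndarray
    optimum: tuple[float, float]
    optimum_feedback: float
    on_boundary: bool


def grid_search(
    mode_a: tuple[int, int],
    mode_b: tuple[int, int],
    range_a,
    range_b,
    feedback,
    pupil_x,
    pupil_y,
    valid_mask=None,
    convention: str = _RMS,
) -> GridSearchResult:
    """Exhaustive feedback search over amplitudes of two Zernike modes.

    Every grid node is one feedback evaluation of the candidate pattern
    a * Z_a + b * Z_b; the continuous optimum is found by bicubic
    interpolation of the feedback surface around the best node.  An optimum
    on the scanned boundary is flagged (the range was too small).
    """
    axis_a = np.asarray(range_a, dtype=float)
    axis_b = np.asarray(range_b, dtype=float)
    if len(axis_a) < 4 or len(axis_b) < 4:
        raise ValueError("need at least 4 nodes per axis for bicubic interpolation")
    za = zernike_mode(*mode_a, pupil_x, pupil_y, convention=convention)
    zb = zernike_mode(*mode_b, pupil_x, pupil_y, convention=convention)
    if valid_mask is None:
        valid_mask = np.hypot(pupil_x, pupil_y) <= 1.0
    valid_mask = np.asarray(valid_mask, dtype=bool)

    def candidate(a: float, b: float) -> PhasePattern:
        phase = np.where(valid_mask, a * za + b * zb, np.nan)
        return PhasePattern(
            phase=phase,
            valid_mask=valid_mask,
            pupil_x=np.asarray(pupil_x, dtype=float),
            pupil_y=np.asarray(pupil_y, dtype=float),
            meta={"grid_search": (mode_a, mode_b, float(a), float(b))},
        )

    grid = np.array([[feedback(candidate(a, b)) for b in axis_b] for a in axis_a])

    spline = RectBivariateSpline(axis_a, axis_b, grid, kx=3, ky=3)
    ia, ib = np.unravel_index(np.argmax(grid), grid.shape)
    # refine inside the cell neighbourhood of the best node
    lo_a, hi_a = axis_a[max(ia - 1, 0)], axis_a[min(ia + 1, len(axis_a) - 1)]
    lo_b, hi_b = axis_b[max(ib - 1, 0)], axis_b[min(ib + 1, len(axis_b) - 1)]
    from scipy.optimize import minimize

    res = minimize(
        lambda p: -float(spline(p[0], p[1])[0, 0]),
        x0=[axis_a[ia], axis_b[ib]],
        bounds=[(lo_a, hi_a), (lo_b, hi_b)],
        method="L-BFGS-B",
    )
    opt_a, opt_b = float(res.x[0]), float(res.x[1])
    opt_val = float(-res.fun)
    # the bicubic surface can overshoot near a sharp peak; trust the spline
    # optimum only if the actual feedback there beats the best node
    actual = feedback(candidate(opt_a, opt_b))
    if actual < grid[ia, ib]:
        opt_a, opt_b = float(axis_a[ia]), float(axis_b[ib])
        opt_val = float(grid[ia, ib])
    else:
        opt_val = actual
    on_boundary = (
        ia in (0, len(axis_a) - 1)
        or ib in (0, len(axis_b) - 1)
    )
    return GridSearchResult(
        grid=grid,
        axis_a=axis_a,
        axis_b=axis_b,
        optimum=(opt_a, opt_b),
        optimum_feedback=opt_val,
        on_boundary=on_boundary,
    )


def align_rotation(
    pattern: PhasePattern,
    feedback,
    angle_range: float = np.deg2rad(2.0),
    n_angles: int = 81,
):
    """Rotation-alignment calibration: scan rigid rotations, maximise feedback.

    Scans ``n_angles`` rotations over [-angle_range, +angle_range] and
    refines the best sample with one parabolic fit.  Returns
    ``(best_angle, on_boundary)``; a boundary optimum signals that the
    scanned range was too small.
    """
    angles = np.linspace(-angle_range, angle_range, n_angles)
    vals = np.array([feedback(rotate_pattern(pattern, a)) for a in angles])
    i = int(np.argmax(vals))
    best = angles[i]
    on_boundary = i in (0, len(angles) - 1)
    if not on_boundary:
        f0, f1, f2 = vals[i - 1 : i + 2]
        denom = f0 - 2 * f1 + f2
        if denom < 0:
            h = angles[1] - angles[0]
            cand = best + 0.5 * h * (f0 - f2) / denom
            if feedback(rotate_pattern(pattern, cand)) >= f1:
                best = cand
    return float(best), on_boundary
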