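"""Focus-quality and image-contrast metrics.

The central quantity is the overlap coefficient gamma between two pupil
fields E1 = A exp(i phi1) and E2 = A exp(i (phi2 + phi_d)),

    gamma = sum_xy E1* E2,        |gamma|^2 in [0, 1],

with A the (real, unit-power) beam amplitude and phi_d a free defocus phase
scanned to maximise |gamma|^2.  |gamma|^2 is the fraction of the incident
energy in the perfectly corrected mode and equals the Strehl ratio of the
resulting focus, which makes it a natural sensitivity measure for the
computed correction patterns.

Image contrast enhancement is quantified by correlation disattenuation:
noise variance from a background measurement is subtracted from the
corrected/uncorrected stack variances before taking the ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .optics_model import ObjectiveModel, OpticalConfig, TubeModel
from .pattern import PhasePattern, compute_correction
from .raytracer import pupil_pixel_grid

__all__ = [
    "PupilField",
    "DefocusModel",
    "ContrastResult",
    "SweepPoint",
    "gaussian_amplitude",
    "defocus_phase",
    "overlap",
    "sensitivity_sweep",
    "contrast_enhancement",
    "percentile_projection",
]


@dataclass
class PupilField:
    """Real amplitude A(x, y) on the pupil, normalised so sum(A^2) = 1."""

    amplitude: np.ndarray  # (ny, nx), >= 0
    pupil_mask: np.ndarray  # (ny, nx) bool, pixels inside the pupil

    def __post_init__(self) -> None:
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be non-negative")
        power = float(np.sum(self.amplitude**2))
        if not np.isclose(power, 1.0, atol=1e-9):
            raise ValueError(f"amplitude must satisfy sum(A^2) = 1 (got {power})")


@dataclass(frozen=True)
class DefocusModel:
    """Parameters of the pupil defocus phase phi_d = z_d k0 sqrt(n^2 - (r NA / R)^2)."""

    n: float  # refractive index of the focus medium
    numerical_aperture: float
    k0: float  # vacuum wavenumber (rad/µm)
    pupil_radius: float = 1.0

    def __post_init__(self) -> None:
        if self.numerical_aperture > self.n:
            raise ValueError("NA must not exceed the focus-medium index")


@dataclass
class ContrastResult:
    """Contrast enhancement eta_sigma with its constituent variances."""

    eta_sigma: float  # NaN when undefined (non-positive variance difference)
    var_corrected: float
    var_uncorrected: float
    var_background: float
    defined: bool


def gaussian_amplitude(
    slm_shape, waist_factor: float = 1.18, pupil_radius: float = 1.0
) -> PupilField:
    """Gaussian beam amplitude A(r) ~ exp(-r^2 / w^2), w = waist_factor * R.

    Normalised to unit power over the pupil disk; zero outside.  The default
    waist of 1.18 pupil radii matches a measured illumination profile at the
    SLM surface.
    """
    if waist_factor <= 0:
        raise ValueError("waist_factor must be > 0")
    px, py = pupil_pixel_grid(slm_shape, pupil_radius)
    r2 = px**2 + py**2
    mask = r2 <= pupil_radius**2
    w = waist_factor * pupil_radius
    a = np.where(mask, np.exp(-r2 / w**2), 0.0)
    a /= np.sqrt(np.sum(a**2))
    return PupilField(amplitude=a, pupil_mask=mask)


def defocus_phase(model: DefocusModel, pupil_x, pupil_y, z_d: float) -> np.ndarray:
    """Defocus phase map phi_d = z_d k0 sqrt(n^2 - (r NA / R)^2); NaN beyond R."""
    r = np.hypot(np.asarray(pupil_x), np.asarray(pupil_y))
    s = r * model.numerical_aperture / model.pupil_radius
    arg = model.n**2 - s**2
    kz = np.sqrt(np.where(arg >= 0, arg, np.nan))
    return z_d * model.k0 * kz


def _shared_support(phi1: PhasePattern, phi2: PhasePattern, amplitude: PupilField):
    if phi1.shape != phi2.shape or phi1.shape != amplitude.amplitude.shape:
        raise ValueError("patterns and amplitude must share the SLM grid")
    mask = phi1.valid_mask & phi2.valid_mask & amplitude.pupil_mask
    if not np.any(mask):
        raise ValueError("patterns share no valid pixels")
    return mask


def overlap(
    phi1: PhasePattern,
    phi2: PhasePattern,
    amplitude: PupilField,
    defocus: DefocusModel,
    zd_scan=None,
    refine: bool = True,
):
    """Maximum |gamma|^2 between two patterns over a defocus scan.

    |gamma|^2 = |sum A^2 exp(i (phi2 + phi_d - phi1))|^2 with A^2
    renormalised over the contributing pixels (the intersection of both
    validity masks and the pupil).  The defocus distance z_d is scanned over
    ``zd_scan`` (default +/-20 µm in 401 steps) and the best sample is
    refined with one parabolic fit.

    Returns (gamma_squared, best_zd).
    """
    if zd_scan is None:
        zd_scan = np.linspace(-20.0, 20.0, 401)
    zd_scan = np.asarray(zd_scan, dtype=float)
    mask = _shared_support(phi1, phi2, amplitude)
    w = amplitude.amplitude[mask] ** 2
    w = w / np.sum(w)
    dphi = phi2.phase[mask] - phi1.phase[mask]
    kz = defocus_phase(
        _dc_replace(defocus, k0=1.0), phi1.pupil_x, phi1.pupil_y, 1.0
    )[mask] * defocus.k0  # kz(r): phase per µm of defocus

    base = w * np.exp(1j * dphi)

    def gamma2(zd: float) -> float:
        return float(np.abs(np.sum(base * np.exp(1j * zd * kz))) ** 2)

    vals = np.array([gamma2(z) for z in zd_scan])
    i = int(np.argmax(vals))
    best_zd, best_val = zd_scan[i], vals[i]
    if refine and 0 < i < len(zd_scan) - 1:
        # one parabolic refinement through the best sample and its neighbours
        z0, z1, _ = zd_scan[i - 1 : i + 2]
        f0, f1, f2 = vals[i - 1 : i + 2]
        denom = f0 - 2 * f1 + f2
        if denom < 0:  # curvature of a genuine peak
            zr = z1 + 0.5 * (z1 - z0) * (f0 - f2) / denom
            fr = gamma2(zr)
            if fr > best_val:
                best_zd, best_val = zr, fr
    return float(np.clip(best_val, 0.0, 1.0)), float(best_zd)


@dataclass
class SweepPoint:
    """One entry of a sensitivity curve."""

    value: float
    gamma_squared: float
    best_zd: float
    valid: bool


def sensitivity_sweep(
    parameter: str,
    values,
    tube: TubeModel,
    objective: ObjectiveModel,
    config: OpticalConfig,
    focus,
    reference: PhasePattern,
    amplitude: PupilField,
    zd_scan=None,
) -> list[SweepPoint]:
    """Overlap of the reference pattern against single-parameter perturbations.

    For each value the pattern is recomputed with only ``parameter``
    (one of outer_radius, shell_thickness, n_shell, axis_angle) changed and
    compared with the reference via :func:`overlap`.  Non-physical values
    are skipped with a warning entry (``valid=False``).
    """
    allowed = {"outer_radius", "shell_thickness", "n_shell", "axis_angle"}
    if parameter not in allowed:
        raise ValueError(f"parameter must be one of {sorted(allowed)}")
    defocus = DefocusModel(
        n=config.n_focus_medium,
        numerical_aperture=objective.numerical_aperture,
        k0=config.k0,
        pupil_radius=objective.pupil_radius,
    )
    out: list[SweepPoint] = []
    for v in values:
        try:
            perturbed = _dc_replace(tube, **{parameter: float(v)})
            if not perturbed.contains(np.asarray(focus, dtype=float)):
                raise ValueError("focus falls outside the perturbed lumen")
        except ValueError as exc:
            warnings.warn(f"skipping non-physical {parameter}={v}: {exc}")
            out.append(SweepPoint(float(v), np.nan, np.nan, False))
            continue
        pat = compute_correction(perturbed, objective, config, focus)
        g2, zd = overlap(reference, pat, amplitude, defocus, zd_scan=zd_scan)
        out.append(SweepPoint(float(v), g2, zd, True))
    return out


def contrast_enhancement(corrected, uncorrected, background) -> ContrastResult:
    """Noise-corrected contrast enhancement between two image stacks.

    eta_sigma = sqrt((var_corrected - var_background) /
                     (var_uncorrected - var_background)).

    The background stack (no signal present) estimates the additive,
    signal-independent noise variance; subtracting it disattenuates the
    ratio.  A non-positive variance difference in the denominator makes the
    result undefined (``defined=False``, eta NaN), never silently clipped.
    """
    vc = float(np.var(np.asarray(corrected, dtype=float)))
    vu = float(np.var(np.asarray(uncorrected, dtype=float)))
    vb = float(np.var(np.asarray(background, dtype=float)))
    num = vc - vb
    den = vu - vb
    if den <= 0 or num < 0:
        return ContrastResult(np.nan, vc, vu, vb, defined=False)
    return ContrastResult(float(np.sqrt(num / den)), vc, vu, vb, defined=True)


def percentile_projection(stack, q: float, axis: int = 0) -> np.ndarray:
    """Per-pixel q-th percentile along ``axis``; q = 100 is a max projection."""
    stack = np.asarray(stack)
    if not 0 <= q <= 100:
        raise ValueError("q must be in [0, 100]")
    if stack.shape[axis] == 0:
        raise ValueError("cannot project along an empty axis")
    return np.percentile(stack, q, axis=axis)
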