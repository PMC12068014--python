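"""SLM phase-correction patterns from optical-pathlength maps.

The raw correction is the phase conjugate of the aberrated wavefront,
phi(x, y) = -k0 * OPL(x, y).  Two non-aberrating components are removed
before display: defocus, by axially translating the virtual objective until
the mean-square phase gradient is minimal (AMSGrad optimiser), and tilt, by
subtracting the average transverse phase gradient.  Phase is stored
unwrapped; wrapping to [0, 2pi) is a view applied only at export.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .optics_model import ObjectiveModel, OpticalConfig, TubeModel
from .raytracer import (
    OplMap,
    PupilSamples,
    Rasterizer,
    RayBundle,
    emit_fan,
    to_pupil,
    trace_tube,
)

__all__ = [
    "PhasePattern",
    "opl_to_phase",
    "remove_tilt",
    "remove_defocus",
    "rotate_pattern",
    "compute_correction",
    "amsgrad_minimize",
]


@dataclass
class PhasePattern:
    """Unwrapped phase phi(x, y) on the SLM grid, with pupil mapping.

    ``meta`` records the generating parameters (focus, tube, objective,
    wavelength, objective translation) for provenance.
    """

    phase: np.ndarray  # (ny, nx) radians, unwrapped; NaN outside valid_mask
    valid_mask: np.ndarray  # (ny, nx) bool
    pupil_x: np.ndarray
    pupil_y: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.phase[self.valid_mask])):
            raise ValueError("phase must be finite on valid pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape

    def wrapped(self) -> np.ndarray:
        """Phase wrapped to [0, 2pi) for display; the unwrapped phase is kept."""
        return np.mod(self.phase, 2.0 * np.pi)

    def with_phase(self, phase: np.ndarray, **meta_updates) -> "PhasePattern":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return PhasePattern(
            phase=phase,
            valid_mask=self.valid_mask.copy(),
            pupil_x=self.pupil_x,
            pupil_y=self.pupil_y,
            meta=meta,
        )


def opl_to_phase(opl: OplMap, config: OpticalConfig, **meta) -> PhasePattern:
    """Phase-conjugate an OPL map: phi = -k0 * OPL, pixelwise."""
    return PhasePattern(
        phase=-config.k0 * opl.values,
        valid_mask=opl.valid_mask.copy(),
        pupil_x=opl.pupil_x,
        pupil_y=opl.pupil_y,
        meta={"wavelength": config.wavelength, **meta},
    )


def _mean_gradient(phase: np.ndarray, mask: np.ndarray, dx: float, dy: float):
    """Average transverse finite-difference gradient over valid pixels."""
    work = np.where(mask, phase, np.nan)
    gy, gx = np.gradient(work, dy, dx)
    return np.nanmean(gx), np.nanmean(gy)


def _mean_square_gradient(phase: np.ndarray, mask: np.ndarray, dx: float, dy: float):
    work = np.where(mask, phase, np.nan)
    gy, gx = np.gradient(work, dy, dx)
    return float(np.nanmean(gx**2 + gy**2))


def remove_tilt(pattern: PhasePattern, bundle: RayBundle | None = None) -> PhasePattern:
    """Subtract the average tilt (linear phase) from a pattern.

    The tilt coefficients are the mean finite-difference phase gradient over
    valid pixels — the rays' average tilt component for a fan sampled
    uniformly in pupil area.  The result has zero mean transverse gradient.
    The generating bundle is accepted for interface symmetry but not needed
    by this estimator.
    """
    dx = float(pattern.pupil_x[0, 1] - pattern.pupil_x[0, 0])
    dy = float(pattern.pupil_y[1, 0] - pattern.pupil_y[0, 0])
    a, b = _mean_gradient(pattern.phase, pattern.valid_mask, dx, dy)
    ramp = a * pattern.pupil_x + b * pattern.pupil_y
    return pattern.with_phase(pattern.phase - ramp, tilt_removed=(float(a), float(b)))


def amsgrad_minimize(
    objective,
    x0: float = 0.0,
    lr: float = 0.5,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
    fd_step: float = 0.01,
    max_iter: int = 500,
    xtol: float = 1e-3,
):
    """1-D AMSGrad descent with central finite-difference gradients.

    Returns (x_best, converged).  ``xtol`` is the |Delta x| stopping
    threshold (µm); non-convergence returns the best-so-far iterate with
    ``converged=False``.
    """
    x = float(x0)
    m = 0.0
    v = 0.0
    v_hat = 0.0
    converged = False
    for it in range(1, max_iter + 1):
        g = (objective(x + fd_step) - objective(x - fd_step)) / (2.0 * fd_step)
        m = beta1 * m + (1.0 - beta1) * g
        v = beta2 * v + (1.0 - beta2) * g * g
        v_hat = max(v_hat, v)
        step = lr * m / (np.sqrt(v_hat) + eps)
        x -= step
        if abs(step) < xtol:
            converged = True
            break
    return x, converged


@dataclass
class _TracedScene:
    """A tube-traced bundle with cached rasteriser; re-evaluable per defocus.

    Translating the virtual objective along the optical axis changes only the
    ideal-objective OPL reference, not the trajectory through the tube nor
    the pupil landing position of any ray, so the trace and triangulation are
    computed once and each translation is a cheap re-projection.
    """

    bundle: RayBundle
    objective: ObjectiveModel
    config: OpticalConfig
    n_outside: float

    def __post_init__(self) -> None:
        samples = to_pupil(self.bundle, self.objective, self.n_outside)
        self.samples0 = samples
        self.rasterizer = Rasterizer(samples.xy, self.config.slm_shape)
        # d_z of the surviving rays, in sample order, for the defocus shift
        a = self.bundle.alive
        d = self.bundle.directions[a]
        xy, inside = _pupil_inside(d, self.objective)
        self._dz = d[inside, 2]

    def samples_at(self, translation: float) -> PupilSamples:
        """Pupil samples with the objective translated by ``translation`` µm."""
        # OPD(delta) = OPD(0) + n_outside * delta * d_z  (F -> F + delta z_hat)
        opl = self.samples0.opl + self.n_outside * translation * self._dz
        return PupilSamples(xy=self.samples0.xy, opl=opl)

    def pattern_at(self, translation: float) -> PhasePattern:
        opl_map = self.rasterizer(self.samples_at(translation).opl)
        return opl_to_phase(opl_map, self.config, objective_translation=translation)


def _pupil_inside(directions, objective):
    from .optics_model import abbe_map

    return abbe_map(directions, objective)


def _make_traced_scene(tube, objective, config, focus, cone_margin=1.0):
    bundle = emit_fan(focus, objective, config, tube=tube, cone_margin=cone_margin)
    traced = trace_tube(bundle, tube, config)
    n_outside = tube.n_outside if tube is not None else config.n_focus_medium
    return _TracedScene(traced, objective, config, n_outside)


def remove_defocus(
    tube: TubeModel | None,
    objective: ObjectiveModel,
    config: OpticalConfig,
    focus,
    cone_margin: float = 1.0,
    max_iter: int = 500,
    xtol: float = 1e-3,
):
    """Find the objective translation that minimises the mean-square phase gradient.

    Re-traces the scene with the virtual objective translated axially and
    minimises the mean squared finite-difference phase gradient over valid
    pixels with AMSGrad, as in the pattern-computation procedure.  The
    translation is measured from ``objective.nominal_focus`` (which need not
    coincide with the source).  Returns ``(pattern, translation, converged)``
    with the pattern evaluated at the optimal translation.
    """
    scene = _make_traced_scene(tube, objective, config, focus, cone_margin)
    dx = float(scene.rasterizer.pupil_x[0, 1] - scene.rasterizer.pupil_x[0, 0])
    dy = dx

    def msg(translation: float) -> float:
        p = scene.pattern_at(translation)
        return _mean_square_gradient(p.phase, p.valid_mask, dx, dy)

    best, converged = amsgrad_minimize(msg, x0=0.0, max_iter=max_iter, xtol=xtol)
    # the objective is locally quadratic in the translation: polish the
    # AMSGrad iterate with a few exact parabolic-vertex steps
    h = 0.1
    for _ in range(12 if max_iter > 0 else 0):
        f0, f1, f2 = msg(best - h), msg(best), msg(best + h)
        denom = f0 - 2 * f1 + f2
        if denom <= 0:  # no local curvature at this scale
            h *= 0.5
            continue
        step = 0.5 * h * (f0 - f2) / denom
        if msg(best + step) <= f1:
            best += step
            if abs(step) < 1e-6:
                break
        else:
            h *= 0.5
    # flat-valley tie-break: prefer the smallest |translation|
    if msg(0.0) <= msg(best) * (1.0 + 1e-12):
        best = 0.0
        converged = True
    pattern = scene.pattern_at(best)
    pattern.meta.update(
        focus=tuple(np.asarray(focus, dtype=float)),
        defocus_translation=float(best),
        defocus_converged=bool(converged),
    )
    return pattern, float(best), converged


def rotate_pattern(pattern: PhasePattern, angle: float) -> PhasePattern:
    """Resample the pattern on a grid rotated about the pupil centre.

    Bilinear resampling; a pixel of the output is valid only if all the
    input pixels it draws from are valid.  ``angle=0`` is the identity.
    """
    if angle == 0.0:
        return pattern.with_phase(pattern.phase.copy(), rotation=0.0)
    ny, nx = pattern.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    c, s = np.cos(angle), np.sin(angle)
    # sample the input at the back-rotated coordinates
    xs = c * (xx - cx) + s * (yy - cy) + cx
    ys = -s * (xx - cx) + c * (yy - cy) + cy
    coords = np.array([ys.ravel(), xs.ravel()])
    filled = np.where(pattern.valid_mask, pattern.phase, 0.0)
    phase = ndimage.map_coordinates(filled, coords, order=1, mode="constant", cval=0.0)
    weight = ndimage.map_coordinates(
        pattern.valid_mask.astype(float), coords, order=1, mode="constant", cval=0.0
    )
    phase = phase.reshape(ny, nx)
    valid = (weight.reshape(ny, nx) > 1.0 - 1e-9)
    out = np.where(valid, phase, np.nan)
    meta = dict(pattern.meta)
    meta["rotation"] = meta.get("rotation", 0.0) + float(angle)
    return PhasePattern(
        phase=out,
        valid_mask=valid,
        pupil_x=pattern.pupil_x,
        pupil_y=pattern.pupil_y,
        meta=meta,
    )


def compute_correction(
    tube: TubeModel | None,
    objective: ObjectiveModel,
    config: OpticalConfig,
    focus,
    cone_margin: float = 1.0,
) -> PhasePattern:
    """End-to-end correction pattern for a focus inside the lumen.

    Pipeline: emit fan -> trace tube -> ideal objective -> rasterise ->
    phase conjugate, with defocus removed by objective translation and tilt
    subtracted.  Deterministic for a given configuration.
    """
    if tube is not None and not tube.contains(np.asarray(focus, dtype=float)):
        raise ValueError("focus must lie inside the tube lumen")
    # focus the virtual objective on the target before removing residual defocus
    recentred = dataclasses.replace(
        objective, nominal_focus=tuple(np.asarray(focus, dtype=float))
    )
    pattern, translation, converged = remove_defocus(
        tube, recentred, config, focus, cone_margin=cone_margin
    )
    pattern = remove_tilt(pattern)
    pattern.meta.update(
        tube=None if tube is None else dataclass_to_dict(tube),
        objective=dataclass_to_dict(objective),
        n_rays=config.n_rays,
        seed=config.seed,
    )
    return pattern


def dataclass_to_dict(obj) -> dict:
    import dataclasses as _dc

    return {
        f.name: getattr(obj, f.name)
        for f in _dc.fields(obj)
    }
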