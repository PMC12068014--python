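"""Synthetic scenes and image stacks for testing without external data.

Three generators cover the package's test surface:

* :func:`capillary_scene` — the nominal borosilicate capillary (outer radius
  286.5 µm, shell 215.5 µm, n = 1.5106) with named focus presets.
* :func:`slab_scene` — the plane-parallel-plate limit of the tube (a huge
  outer radius at fixed shell thickness) together with a closed-form
  optical-pathlength-difference oracle derived independently of the ray
  tracer, using only 2-D trigonometry.
* :func:`synth_stack` — bead-like image stacks with planted signal and noise
  variances for the contrast-enhancement metric.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics_model import ObjectiveModel, OpticalConfig, TubeModel

__all__ = [
    "SyntheticScene",
    "capillary_scene",
    "slab_scene",
    "synth_stack",
    "NOMINAL_OUTER_RADIUS",
    "NOMINAL_SHELL_THICKNESS",
    "NOMINAL_N_SHELL",
]

# nominal capillary geometry (bright-field measurement of the reference tube)
NOMINAL_OUTER_RADIUS = 286.5  # µm (± 1.5)
NOMINAL_SHELL_THICKNESS = 215.5  # µm (± 1.6)
NOMINAL_N_SHELL = 1.5106  # BK7 borosilicate (± 0.0005)


@dataclass
class SyntheticScene:
    """A complete, traceable optical scene plus optional known-truth metadata."""

    tube: TubeModel | None
    objective: ObjectiveModel
    config: OpticalConfig
    truth: dict | None = None
    focus_presets: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def capillary_scene(
    na: float | None = None,
    wavelength: float | None = None,
    n_immersion: float | None = None,
    n_lumen: float = 1.33,
    n_outside: float | None = None,
    outer_radius: float = NOMINAL_OUTER_RADIUS,
    shell_thickness: float = NOMINAL_SHELL_THICKNESS,
    n_shell: float = NOMINAL_N_SHELL,
    axis_angle: float = 0.0,
    n_rays: int = 250_000,
    slm_shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    preset_inset: float = 5.0,
) -> SyntheticScene:
    """The nominal glass capillary with Top/Centre/Bottom/Side focus presets.

    The objective's numerical aperture and the vacuum wavelength describe the
    instrument rather than the sample and have no meaningful default; they
    must be supplied explicitly.  ``n_immersion``/``n_outside`` default to
    the lumen index (a water-dipping arrangement).

    Presets (tube axis along +x at ``axis_angle=0``, +z pointing away from
    the objective): Top = just inside the inner wall nearest the objective,
    Bottom = farthest wall, Centre = on the tube axis, Side = just inside
    the wall on the horizontal midplane.  ``preset_inset`` is the distance
    (µm) the Top/Bottom/Side presets sit inside the inner wall.
    """
    if na is None or wavelength is None:
        missing = [k for k, v in {"na": na, "wavelength": wavelength}.items() if v is None]
        raise ValueError(
            f"instrument parameters {missing} are required and have no default"
        )
    if n_immersion is None:
        n_immersion = n_lumen
    if n_outside is None:
        n_outside = n_immersion
    tube = TubeModel(
        outer_radius=outer_radius,
        shell_thickness=shell_thickness,
        n_shell=n_shell,
        n_lumen=n_lumen,
        n_outside=n_outside,
        axis_angle=axis_angle,
    )
    objective = ObjectiveModel(numerical_aperture=na, n_immersion=n_immersion)
    config = OpticalConfig(
        wavelength=wavelength,
        n_focus_medium=n_lumen,
        n_rays=n_rays,
        slm_shape=slm_shape,
        seed=seed,
    )
    r = tube.inner_radius - preset_inset
    presets = {
        "top": (0.0, 0.0, -r),
        "centre": (0.0, 0.0, 0.0),
        "bottom": (0.0, 0.0, r),
        "side": (0.0, r, 0.0),
    }
    return SyntheticScene(
        tube=tube, objective=objective, config=config, focus_presets=presets
    )


def slab_scene(
    thickness: float,
    n_slab: float,
    n_before: float,
    n_after: float,
    na: float = 0.3,
    wavelength: float = 0.8,
    source_depth: float = 10.0,
    outer_radius: float = 2.0e8,
    n_rays: int = 10_000,
    slm_shape: tuple[int, int] = (128, 128),
):
    """Plane-parallel-plate limit scene with an independent analytic OPD oracle.

    The slab is realised as a tube of enormous outer radius at fixed shell
    thickness, positioned so the inner surface sits ``source_depth`` µm
    above the source (toward the objective) and is locally flat over the ray
    footprint.  The returned oracle ``opd(theta)`` gives the pupil
    optical-pathlength difference for an emission polar angle ``theta``,
    computed purely from scalar Snell refraction and plane geometry:

        opd(t1) = n1 d/cos(t1) + n2 T/cos(t2) - n3 (x_exit sin(t3)
                  + (d + T) cos(t3)),

    with sines related by Snell's law and x_exit the transverse exit
    coordinate.  This reproduces the exact wavefront error of a point source
    under a plate referenced to an ideal objective focused at the source.

    Returns ``(scene, opd)``.
    """
    if thickness <= 0:
        raise ValueError("thickness must be > 0")
    tube = TubeModel(
        outer_radius=outer_radius,
        shell_thickness=thickness,
        n_shell=max(n_slab, 1.0),
        n_lumen=max(n_before, 1.0),
        n_outside=max(n_after, 1.0),
        axis_angle=0.0,
        # inner surface (nearest the objective) at z = -source_depth
        axis_offset=(0.0, 0.0, (outer_radius - thickness) - source_depth),
    )
    # the objective sits in the exit medium
    objective = ObjectiveModel(numerical_aperture=na, n_immersion=max(n_after, 1.0))
    config = OpticalConfig(
        wavelength=wavelength,
        n_focus_medium=n_before,
        n_rays=n_rays,
        slm_shape=slm_shape,
    )
    d, t = source_depth, thickness
    n1, n2, n3 = n_before, n_slab, n_after

    def opd(theta):
        """Analytic pathlength difference for emission angle theta (rad)."""
        theta = np.asarray(theta, dtype=float)
        s1 = np.sin(theta)
        s2 = n1 * s1 / n2
        s3 = n1 * s1 / n3
        if np.any(np.abs(s3) > 1) or np.any(np.abs(s2) > 1):
            raise ValueError("angle beyond total internal reflection")
        c1, c2, c3 = (np.sqrt(1 - s * s) for s in (s1, s2, s3))
        x_exit = d * s1 / c1 + t * s2 / c2
        return n1 * d / c1 + n2 * t / c2 - n3 * (x_exit * s3 + (d + t) * c3)

    scene = SyntheticScene(
        tube=tube,
        objective=objective,
        config=config,
        truth={"kind": "slab", "thickness": t, "source_depth": d},
        focus_presets={"source": (0.0, 0.0, 0.0)},
    )
    return scene, opd


def synth_stack(
    shape: tuple[int, int, int] = (74, 64, 64),
    signal_variance: tuple[float, float] = (4.0, 1.0),
    background_variance: float = 0.25,
    n_beads: int = 40,
    seed: int = 0,
):
    """Bead-like stacks with planted signal variances plus independent noise.

    Builds one random field of Gaussian blobs, scales two copies to the
    exact requested signal variances (corrected-like and uncorrected-like),
    and adds independent Gaussian noise of ``background_variance`` to each;
    the background stack is pure noise.  Deterministic under ``seed``.

    Returns ``(corrected, uncorrected, background, true_ratio)`` where
    ``true_ratio = sqrt(var_corrected_signal / var_uncorrected_signal)`` is
    the contrast enhancement an ideal estimator should recover.
    """
    s2_c, s2_u = signal_variance
    if s2_u < 0 or s2_c < 0 or background_variance < 0:
        raise ValueError("variances must be >= 0")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    fld = np.zeros(shape)
    sigma = 1.5  # bead radius in voxels
    for _ in range(n_beads):
        cz, cy, cx = rng.uniform([0, 0, 0], [nz, ny, nx])
        fld += np.exp(
            -((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
        )
    fld -= fld.mean()
    std = fld.std()
    if std > 0:
        fld /= std

    noise_sd = np.sqrt(background_variance)
    corrected = np.sqrt(s2_c) * fld + rng.normal(0.0, noise_sd, shape)
    uncorrected = np.sqrt(s2_u) * fld + rng.normal(0.0, noise_sd, shape)
    background = rng.normal(0.0, noise_sd, shape)
    true_ratio = np.sqrt(s2_c / s2_u) if s2_u > 0 else np.inf
    return corrected, uncorrected, background, float(true_ratio)
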