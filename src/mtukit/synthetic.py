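"""Synthetic inputs with known ground truth for every pipeline stage.

Emulates the study's raw data so the whole analysis is testable on a desk:
textured contraction videos with exact per-pixel displacement fields,
Hertz-model indentation curves, linear-elastic tensile curves with a
fracture point, and labeled morphometry scenes.  Every generator takes an
explicit seed and is bit-reproducible; all randomness flows through one
``numpy.random.Generator``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.draw import polygon

from .mechanics import IndentationCurve, TensileCurve, hertz_force
from .morphometry import MorphometryScene

__all__ = [
    "Translation",
    "UniaxialContraction",
    "RigidRotation",
    "SyntheticVideoSpec",
    "GroundTruth",
    "gen_video",
    "gen_indentation_curve",
    "gen_tensile_curve",
    "gen_morphometry_scene",
    "write_video_tiff",
    "write_morphometry_scene",
]


# ---------------------------------------------------------------------------
# video generation

@dataclass(frozen=True)
class Translation:
    """Uniform translation, px/frame (image coords: +y is down)."""

    vx: float
    vy: float


@dataclass(frozen=True)
class UniaxialContraction:
    """Per-frame strain toward a center along one image axis."""

    strain_per_frame: float
    axis: str = "x"  # "x" (columns) or "y" (rows)
    center: tuple[float, float] | None = None  # (x, y) px; default image center


@dataclass(frozen=True)
class RigidRotation:
    """Rigid rotation about a center, rad/frame (counter-clockwise in
    display orientation, i.e. clockwise in raw row/col indexing)."""

    omega: float
    center: tuple[float, float] | None = None


MotionModel = Translation | UniaxialContraction | RigidRotation


@dataclass(frozen=True)
class SyntheticVideoSpec:
    """Parameters of a synthetic contraction video.

    ``texture_scale`` is the spatial correlation length (px) of the random
    tissue texture; ``noise_sd`` the additive Gaussian intensity noise
    (intensity units on a [0, 1] scale).  The frame rate default matches
    the study's stimulation recordings (25 fps); pixel size and bit depth
    are not reported there, so the defaults here are package choices.
    """

    width_px: int = 192
    height_px: int = 192
    n_frames: int = 6
    pixel_size_um: float = 10.0
    frame_rate: float = 25.0
    texture_scale_px: float = 4.0
    noise_sd: float = 0.01
    motion_model: MotionModel = Translation(0.0, 0.0)
    void_rects: tuple[tuple[int, int, int, int], ...] = ()  # (x0, y0, w, h)
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.pixel_size_um <= 0 or self.frame_rate <= 0:
            raise ValueError("pixel size and frame rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.texture_scale_px <= 0:
            raise ValueError("texture_scale_px must be positive")


@dataclass
class GroundTruth:
    """Exact applied motion: one (u, v) field per consecutive frame pair.

    ``flows[k]`` has shape (2, H, W): displacement in px of the feature at
    each pixel of frame k as it moves into frame k+1 (u = x/col component,
    v = y/row component).  ``void_mask`` marks intentionally dark regions
    in frame 0.
    """

    flows: np.ndarray  # (n_frames-1, 2, H, W)
    void_mask: np.ndarray  # (H, W) bool


def _texture(spec: SyntheticVideoSpec, rng: np.random.Generator) -> np.ndarray:
    # pad so warps can sample outside the visible frame without repeating
    # edge values inside the field of view
    pad = int(np.ceil(0.25 * max(spec.height_px, spec.width_px))) + 8
    raw = rng.standard_normal(
        (spec.height_px + 2 * pad, spec.width_px + 2 * pad)
    )
    tex = gaussian_filter(raw, spec.texture_scale_px)
    tex = (tex - tex.mean()) / (tex.std() + 1e-12)
    tex = 0.55 + 0.15 * tex
    for x0, y0, w, h in spec.void_rects:
        tex[pad + y0 : pad + y0 + h, pad + x0 : pad + x0 + w] = 0.05
    return np.clip(tex, 0.0, 1.0), pad


def _cumulative_inverse_map(
    model: MotionModel, k: int, X: np.ndarray, Y: np.ndarray, shape: tuple
) -> tuple[np.ndarray, np.ndarray]:
    """Material (frame-0) coordinates of each pixel of frame k."""
    h, w = shape
    if isinstance(model, Translation):
        return X - k * model.vx, Y - k * model.vy
    if isinstance(model, UniaxialContraction):
        cx, cy = model.center or ((w - 1) / 2.0, (h - 1) / 2.0)
        a = (1.0 - model.strain_per_frame) ** k
        if model.axis == "x":
            return cx + (X - cx) / a, Y
        return X, cy + (Y - cy) / a
    if isinstance(model, RigidRotation):
        cx, cy = model.center or ((w - 1) / 2.0, (h - 1) / 2.0)
        th = -k * model.omega  # inverse rotation (display orientation)
        c, s = np.cos(th), np.sin(th)
        dx, dy = X - cx, Y - cy
        # display-orientation CCW rotation in row/col coords
        return cx + c * dx + s * dy, cy - s * dx + c * dy
    raise TypeError(f"unknown motion model {model!r}")


def _true_flow(
    model: MotionModel, X: np.ndarray, Y: np.ndarray, shape: tuple
) -> tuple[np.ndarray, np.ndarray]:
    """Exact displacement of the feature at pixel (X, Y) into the next frame."""
    h, w = shape
    if isinstance(model, Translation):
        return np.full_like(X, model.vx), np.full_like(Y, model.vy)
    if isinstance(model, UniaxialContraction):
        cx, cy = model.center or ((w - 1) / 2.0, (h - 1) / 2.0)
        s = model.strain_per_frame
        if model.axis == "x":
            return -s * (X - cx), np.zeros_like(Y)
        return np.zeros_like(X), -s * (Y - cy)
    if isinstance(model, RigidRotation):
        cx, cy = model.center or ((w - 1) / 2.0, (h - 1) / 2.0)
        c, s = np.cos(model.omega), np.sin(model.omega)
        dx, dy = X - cx, Y - cy
        return (c * dx + s * dy) - dx, (-s * dx + c * dy) - dy
    raise TypeError(f"unknown motion model {model!r}")


def gen_video(spec: SyntheticVideoSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a textured video under a known motion model.

    Returns float frames in [0, 1], shape (n_frames, H, W), and the exact
    ground truth.  Frames are the band-limited texture warped per the motion
    model (bilinear sampling) with additive Gaussian noise.  Warns when the
    per-frame displacement exceeds half the texture scale, where gradient-
    based flow estimation becomes ill-posed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tex, pad = _texture(spec, rng)
    h, w = spec.height_px, spec.width_px
    Y, X = np.mgrid[0:h, 0:w].astype(float)

    u0, v0 = _true_flow(spec.motion_model, X, Y, (h, w))
    max_disp = float(np.hypot(u0, v0).max())
    if max_disp > spec.texture_scale_px / 2.0:
        warnings.warn(
            f"per-frame displacement {max_disp:.2f} px exceeds half the "
            f"texture scale ({spec.texture_scale_px} px); flow estimation "
            "may be ill-posed",
            stacklevel=2,
        )

    frames = np.empty((spec.n_frames, h, w))
    flows = np.empty((spec.n_frames - 1, 2, h, w))
    for k in range(spec.n_frames):
        Xs, Ys = _cumulative_inverse_map(spec.motion_model, k, X, Y, (h, w))
        frame = map_coordinates(
            tex, [Ys + pad, Xs + pad], order=1, mode="nearest"
        )
        if spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, size=frame.shape)
        frames[k] = np.clip(frame, 0.0, 1.0)
        if k < spec.n_frames - 1:
            u, v = _true_flow(spec.motion_model, X, Y, (h, w))
            flows[k, 0], flows[k, 1] = u, v

    void = np.zeros((h, w), dtype=bool)
    for x0, y0, wr, hr in spec.void_rects:
        void[y0 : y0 + hr, x0 : x0 + wr] = True
    return frames, GroundTruth(flows=flows, void_mask=void)


def write_video_tiff(
    frames: np.ndarray, path: str | Path, spec: SyntheticVideoSpec,
    bit_depth: int = 16,
) -> None:
    """Write frames as multi-page grayscale TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    if bit_depth == 8:
        data = np.round(frames * 255).astype(np.uint8)
    elif bit_depth == 16:
        data = np.round(frames * 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    tifffile.imwrite(path, data)
    meta = {
        "pixel_size_um": spec.pixel_size_um,
        "frame_rate_fps": spec.frame_rate,
        "seed": spec.seed,
        "motion_model": repr(spec.motion_model),
        "bit_depth": bit_depth,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# mechanics curves

def gen_indentation_curve(
    E_kpa: float,
    nu: float = 0.4,
    R_um: float = 100.0,
    d_max_um: float = 10.0,
    n_points: int = 50,
    noise_sd_uN: float = 0.0,
    seed: int = 0,
    condition: str = "immersed",
) -> IndentationCurve:
    """Hertz-model force-depth curve with optional Gaussian force noise.

    Rejects ``d_max_um`` beyond 10% of the indenter radius — the validity
    bound the measurement protocol itself imposes.
    """
    if E_kpa <= 0:
        raise ValueError("E must be positive")
    if not 0 <= nu < 0.5:
        raise ValueError("nu must lie in [0, 0.5)")
    if not 0 < d_max_um <= 0.1 * R_um:
        raise ValueError(
            f"d_max must lie in (0, 0.1 R] = (0, {0.1 * R_um:.3g}] μm for "
            "Hertz validity"
        )
    depth = np.linspace(0.0, d_max_um, n_points)
    force = np.asarray(hertz_force(depth, E_kpa, nu, R_um))
    if noise_sd_uN > 0:
        rng = np.random.default_rng(seed)
        force = force + rng.normal(0.0, noise_sd_uN, size=force.shape)
    return IndentationCurve(depth, force, R_um, condition)


def gen_tensile_curve(
    E_kpa: float,
    cross_section_mm2: float,
    gauge_length_mm: float,
    fracture_strain: float,
    n_points: int = 200,
    noise_sd_mN: float = 0.0,
    seed: int = 0,
    overshoot: float = 0.2,
) -> TensileCurve:
    """Linear-elastic tensile curve with a sharp fracture.

    Force ramps as E * A * strain up to ``fracture_strain``, then drops to
    zero for a further ``overshoot`` fraction of the fracture displacement.
    Noise is added before fracture only.
    """
    if min(E_kpa, cross_section_mm2, gauge_length_mm, fracture_strain) <= 0:
        raise ValueError("all tensile parameters must be positive")
    if fracture_strain >= 1:
        raise ValueError("fracture_strain must be < 1")
    d_frac = fracture_strain * gauge_length_mm
    n_post = max(2, int(round(overshoot * n_points)))
    disp = np.concatenate(
        [
            np.linspace(0.0, d_frac, n_points),  # fracture point sampled exactly
            d_frac * (1 + np.linspace(0, overshoot, n_post + 1)[1:]),
        ]
    )
    strain = disp / gauge_length_mm
    force = E_kpa * cross_section_mm2 * strain  # kPa*mm^2 = mN
    broken = strain > fracture_strain * (1 + 1e-12)
    if noise_sd_mN > 0:
        rng = np.random.default_rng(seed)
        force = force + rng.normal(0.0, noise_sd_mN, size=force.shape)
    force[broken] = 0.0
    return TensileCurve(disp, force, cross_section_mm2, gauge_length_mm)


# ---------------------------------------------------------------------------
# morphometry scenes

def _stamp_tube(
    labels: np.ndarray, center: np.ndarray, axis: np.ndarray,
    length: float, width: float, lab: int,
) -> bool:
    """Draw a rotated rectangle if it does not collide; returns success."""
    n = np.array([-axis[1], axis[0]])
    c = center
    half_l, half_w = length / 2.0, width / 2.0
    corners = np.array(
        [
            c + half_l * axis + half_w * n,
            c + half_l * axis - half_w * n,
            c - half_l * axis - half_w * n,
            c - half_l * axis + half_w * n,
        ]
    )
    rr, cc = polygon(corners[:, 1], corners[:, 0], labels.shape)
    if rr.size == 0 or np.any(labels[rr, cc] != 0):
        return False
    labels[rr, cc] = lab
    return True


def gen_morphometry_scene(
    n_tubes: int = 8,
    mean_width_um: float = 25.0,
    angle_concentration: float = 8.0,
    fusion_fraction: float = 0.5,
    n_nuclei: int = 60,
    seed: int = 0,
    *,
    image_shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 2.0,
    marker_positive_fraction: float = 1.0,
    max_attempts: int = 200,
) -> MorphometryScene:
    """Labeled scene of elongated myotubes with planted nuclei.

    Tube axes are drawn about the reference (y) axis with a von-Mises-type
    angular concentration (0 = isotropic, large = parallel).  Exactly
    ``round(fusion_fraction * n_nuclei)`` nuclei are placed inside
    marker-positive tubes, the rest in the background.  Raises if tubes
    cannot be packed without overlap within the attempt bound.
    """
    if not 0 <= fusion_fraction <= 1:
        raise ValueError("fusion_fraction must lie in [0, 1]")
    if angle_concentration < 0:
        raise ValueError("angle_concentration must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    labels = np.zeros((h, w), dtype=np.int32)
    width_px = mean_width_um / pixel_size_um

    marker: dict[int, bool] = {}
    n_positive = max(1, round(marker_positive_fraction * n_tubes))
    for lab in range(1, n_tubes + 1):
        ok = False
        for _ in range(max_attempts):
            if angle_concentration == 0:
                theta = rng.uniform(-np.pi / 2, np.pi / 2)
            else:
                theta = rng.vonmises(0.0, angle_concentration) / 2.0
            # angle about the y (reference) axis: axis vector in (x, y)
            axis = np.array([np.sin(theta), np.cos(theta)])
            length = rng.uniform(0.45, 0.75) * min(h, w)
            width_i = max(4.0, rng.normal(width_px, 0.08 * width_px))
            center = np.array(
                [rng.uniform(0.15 * w, 0.85 * w), rng.uniform(0.15 * h, 0.85 * h)]
            )
            if _stamp_tube(labels, center, axis, length, width_i, lab):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place tube {lab} without overlap after "
                f"{max_attempts} attempts; reduce n_tubes or width"
            )
        marker[lab] = lab <= n_positive

    pos_labels = [l for l, p in marker.items() if p]
    pos_mask = np.isin(labels, pos_labels) & (labels > 0)
    bg_mask = labels == 0
    n_inside = round(fusion_fraction * n_nuclei)

    def _sample(mask: np.ndarray, n: int) -> np.ndarray:
        rows, cols = np.nonzero(mask)
        idx = rng.choice(rows.size, size=n, replace=True)
        jitter = rng.uniform(-0.4, 0.4, size=(n, 2))
        return np.column_stack([cols[idx], rows[idx]]) + jitter

    nuclei = np.vstack(
        [
            _sample(pos_mask, n_inside) if n_inside else np.empty((0, 2)),
            _sample(bg_mask, n_nuclei - n_inside)
            if n_nuclei - n_inside
            else np.empty((0, 2)),
        ]
    )
    return MorphometryScene(
        nuclei=nuclei,
        tube_labels=labels,
        marker_positive=marker,
        reference_axis=(0.0, 1.0),
        pixel_size_um=pixel_size_um,
    )


def write_morphometry_scene(scene: MorphometryScene, stem: str | Path) -> None:
    """Write a scene as label TIFF + marker CSV + nuclei CSV."""
    stem = Path(stem)
    tifffile.imwrite(stem.with_suffix(".labels.tif"), scene.tube_labels)
    pd.DataFrame(
        {
            "label": list(scene.marker_positive),
            "marker_positive": list(scene.marker_positive.values()),
        }
    ).to_csv(stem.with_suffix(".markers.csv"), index=False)
    pd.DataFrame(scene.nuclei, columns=["x_px", "y_px"]).to_csv(
        stem.with_suffix(".nuclei.csv"), index=False
    )
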