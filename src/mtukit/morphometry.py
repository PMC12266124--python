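"""Myotube morphometry: maturity statistics from labeled imaging scenes.

Scenes arrive already segmented (instance-labeled myotube masks, nucleus
centroids, per-tube MyHC-positivity); this module computes the standard
muscle-maturity readouts: fusion index, shift angle relative to the tension
axis, myotube width and texture variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import polygon2mask
from skimage.morphology import medial_axis

logger = logging.getLogger(__name__)

__all__ = [
    "MorphometryScene",
    "fusion_index",
    "shift_angles",
    "myotube_widths",
    "texture_variance",
    "tube_table",
]


@dataclass
class MorphometryScene:
    """Labeled morphometry scene.

    nuclei : (n, 2) float array of (x, y) centroid coordinates in px.
    tube_labels : 2-D int array; 0 = background, k > 0 = myotube instance k.
    marker_positive : dict mapping tube label -> MyHC-positivity.
    reference_axis : unit vector (x, y) of the construct tension axis.
    pixel_size_um : μm per pixel.
    """

    nuclei: np.ndarray
    tube_labels: np.ndarray
    marker_positive: dict[int, bool]
    reference_axis: tuple[float, float] = (0.0, 1.0)
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.nuclei = np.asarray(self.nuclei, dtype=float).reshape(-1, 2)
        self.tube_labels = np.asarray(self.tube_labels)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        labels = set(np.unique(self.tube_labels)) - {0}
        if any(l <= 0 for l in labels):
            raise ValueError("tube labels must be positive integers")
        missing = labels - set(self.marker_positive)
        if missing:
            raise ValueError(f"marker_positive missing labels {sorted(missing)}")

    def labels(self) -> list[int]:
        return sorted(set(np.unique(self.tube_labels)) - {0})


def _nucleus_tube(scene: MorphometryScene) -> np.ndarray:
    """Tube label under each nucleus centroid (0 = background)."""
    h, w = scene.tube_labels.shape
    cols = np.clip(np.rint(scene.nuclei[:, 0]).astype(int), 0, w - 1)
    rows = np.clip(np.rint(scene.nuclei[:, 1]).astype(int), 0, h - 1)
    return scene.tube_labels[rows, cols]


def fusion_index(scene: MorphometryScene) -> float:
    """Fraction of nuclei lying inside MyHC-positive myotubes.

    The nucleus centroid decides membership (nuclei are counted, not nuclear
    area); boundary pixels count as inside.
    """
    if scene.nuclei.shape[0] == 0:
        raise ValueError("scene has no nuclei")
    under = _nucleus_tube(scene)
    positive = np.array(
        [bool(l) and scene.marker_positive.get(int(l), False) for l in under]
    )
    return float(positive.sum() / under.size)


def _principal_axis(mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Unit major-axis vector (x, y) and axis ratio from second moments."""
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([cols, rows]).astype(float)
    pts -= pts.mean(axis=0)
    cov = pts.T @ pts / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    ratio = np.sqrt(evals[1] / max(evals[0], 1e-12))
    return evecs[:, 1], float(ratio)


def shift_angles(
    scene: MorphometryScene, *, min_axis_ratio: float = 1.2
) -> tuple[pd.Series, float]:
    """Per-tube acute angle (deg) between the tube's long axis and the
    reference axis, and their mean.

    Tubes too round for a well-defined major axis (major/minor axis ratio
    below ``min_axis_ratio``) are excluded with a log entry.
    """
    ref = np.asarray(scene.reference_axis, dtype=float)
    ref = ref / np.linalg.norm(ref)
    angles = {}
    for lab in scene.labels():
        mask = scene.tube_labels == lab
        axis, ratio = _principal_axis(mask)
        if ratio < min_axis_ratio:
            logger.info(
                "tube %d excluded from shift-angle: axis ratio %.2f "
                "below %.2f",
                lab,
                ratio,
                min_axis_ratio,
            )
            continue
        cosang = np.clip(abs(float(axis @ ref)), 0.0, 1.0)
        angles[lab] = float(np.degrees(np.arccos(cosang)))
    series = pd.Series(angles, name="shift_angle_deg", dtype=float)
    mean = float(series.mean()) if len(series) else float("nan")
    return series, mean


def myotube_widths(scene: MorphometryScene) -> pd.DataFrame:
    """Per-tube width: twice the median medial-axis distance, in μm.

    Tubes thinner than 2 px are flagged unreliable (width still reported).
    """
    rows = []
    for lab in scene.labels():
        mask = scene.tube_labels == lab
        skel, dist = medial_axis(mask, return_distance=True)
        on = skel & (dist > 0)
        if not on.any():
            rows.append((lab, np.nan, np.nan, False))
            continue
        # dist reaches the *center* of the nearest background pixel, half a
        # pixel beyond the tube border on each side; subtract that bias
        width_px = 2.0 * float(np.median(dist[on])) - 1.0
        rows.append(
            (lab, width_px, width_px * scene.pixel_size_um, width_px >= 2.0)
        )
    return pd.DataFrame(
        rows, columns=["label", "width_px", "width_um", "reliable"]
    ).set_index("label")


def texture_variance(
    image: np.ndarray, roi: np.ndarray | list[tuple[float, float]]
) -> float:
    """Variance of pixel intensities inside a region of interest.

    ``roi`` is either a boolean mask or a polygon given as (x, y) vertices.
    The matrix texture differs between muscle and tendon bioinks, so this
    variance separates construct regions under brightfield imaging.
    """
    image = np.asarray(image, dtype=float)
    roi = np.asarray(roi)
    if roi.dtype == bool:
        mask = roi
        if mask.shape != image.shape:
            raise ValueError("mask shape must match image shape")
    else:
        verts_rc = roi[:, ::-1]  # (x, y) -> (row, col)
        mask = polygon2mask(image.shape, verts_rc)
    if not mask.any():
        raise ValueError("ROI is empty or lies outside the image")
    return float(np.var(image[mask]))


def tube_table(scene: MorphometryScene) -> pd.DataFrame:
    """Per-tube summary: width (μm), shift angle (deg), marker positivity."""
    widths = myotube_widths(scene)
    angles, _ = shift_angles(scene)
    df = widths[["width_um", "reliable"]].copy()
    df["shift_angle_deg"] = angles
    df["marker_positive"] = [
        scene.marker_positive[int(l)] for l in df.index
    ]
    return df
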