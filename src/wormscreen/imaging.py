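"""Per-frame worm segmentation and shape metrics.

Worms are dark objects on a light agar background. Each frame is
thresholded (Otsu), connected components are labelled, size-filtered,
and each surviving component is summarised by its area A (pixel count),
perimeter P (Crofton multi-direction intercept length of the hole-filled
silhouette, i.e. the outer contour only) and the circularity shape
descriptor 4*pi*A/P**2: 1 for a circle, tending to 0 for elongated
shapes. A worm whose circularity exceeds 0.6 is coiling; values around
0.5 correspond to omega turns and around 0.2 to the normal sinusoidal
crawl.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label, perimeter_crofton, regionprops

logger = logging.getLogger(__name__)

COIL_THRESHOLD = 0.6
TURN_THRESHOLD = 0.4

POSTURES = ("sinusoidal", "turn", "coil")


@dataclass
class FrameStack:
    """Ordered image sequence with acquisition context."""

    frames: np.ndarray  # (n_frames, height, width), grayscale or bool
    fps: float
    px_scale: float | None = None  # px per mm, optional

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, height, width) array")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        self.frames = frames

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class Detection:
    """One segmented worm in one frame.

    Coordinates are 0-based pixel indices, x = column, y = row, origin
    at the top-left corner.
    """

    frame_index: int
    object_id: int
    area: float  # px^2
    perimeter: float  # px
    circularity: float
    centroid: tuple[float, float]  # (x, y)
    posture: str | None = None


@dataclass
class SegmentationConfig:
    """Knobs for per-frame segmentation.

    ``min_area``/``max_area`` default to 0.25x and 2.5x the nominal worm
    silhouette area (length x width); blobs above ``max_area`` are
    treated as worm-worm collisions and dropped for that frame.
    """

    worm_length: float = 60.0
    worm_width: float = 6.0
    min_area: float | None = None
    max_area: float | None = None
    dark_on_light: bool = True
    fill_holes_for_perimeter: bool = True  # outer contour only (coil annulus)

    nominal_area: float = field(init=False)

    def __post_init__(self) -> None:
        self.nominal_area = self.worm_length * self.worm_width
        if self.min_area is None:
            self.min_area = 0.25 * self.nominal_area
        if self.max_area is None:
            self.max_area = 2.5 * self.nominal_area


def circularity(area: float, perimeter: float) -> float:
    """4*pi*A/P**2, clipped at 1 (the continuous supremum).

    1 for a perfect circle; decreases toward 0 as the shape elongates.
    """
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return min(1.0, 4.0 * math.pi * area / perimeter**2)


def classify_posture(
    circ: float,
    coil_threshold: float = COIL_THRESHOLD,
    turn_threshold: float = TURN_THRESHOLD,
) -> str:
    """Posture class from circularity: coil iff circ > coil_threshold
    (strict), turn for (turn_threshold, coil_threshold], else sinusoidal."""
    if not 0.0 < circ <= 1.0:
        raise ValueError(f"circularity must be in (0, 1], got {circ}")
    if circ > coil_threshold:
        return "coil"
    if circ > turn_threshold:
        return "turn"
    return "sinusoidal"


def _binarize(image: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    if image.dtype == bool:
        return image
    lo, hi = float(image.min()), float(image.max())
    if lo == hi:  # uniform frame: no foreground
        return np.zeros(image.shape, dtype=bool)
    t = threshold_otsu(image)
    return image < t if config.dark_on_light else image > t


def segment_frame(
    image: np.ndarray,
    config: SegmentationConfig | None = None,
    *,
    frame_index: int = 0,
    classify: bool = True,
) -> list[Detection]:
    """Segment one frame into per-worm detections.

    Foreground is separated by Otsu thresholding (dark-on-light unless
    configured otherwise), connected components are labelled (8-connected)
    and filtered to [min_area, max_area]. Over-size blobs are logged as
    presumed collisions and dropped. Binary images are used as-is.
    """
    if config is None:
        config = SegmentationConfig()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("segment_frame expects a single 2-D image")
    mask = _binarize(image, config)
    labels = label(mask, connectivity=2)
    detections: list[Detection] = []
    object_id = 0
    for region in regionprops(labels):
        area = float(region.area)
        if area < config.min_area:
            continue
        if area > config.max_area:
            logger.info(
                "frame %d: blob of %.0f px^2 exceeds max_area=%.0f, "
                "dropped as a collision",
                frame_index, area, config.max_area,
            )
            continue
        region_mask = labels[region.slice] == region.label
        if config.fill_holes_for_perimeter:
            region_mask = ndi.binary_fill_holes(region_mask)
        perim = float(perimeter_crofton(region_mask, directions=4))
        if perim <= 0:
            continue
        circ = circularity(area, perim)
        cy, cx = region.centroid
        detections.append(
            Detection(
                frame_index=frame_index,
                object_id=object_id,
                area=area,
                perimeter=perim,
                circularity=circ,
                centroid=(float(cx), float(cy)),
                posture=classify_posture(circ) if classify else None,
            )
        )
        object_id += 1
    return detections


def segment_stack(
    stack: FrameStack, config: SegmentationConfig | None = None
) -> list[list[Detection]]:
    """Segment every frame of a stack; returns per-frame detection lists."""
    return [
        segment_frame(frame, config, frame_index=i)
        for i, frame in enumerate(stack.frames)
    ]
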