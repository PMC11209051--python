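"""Colour-Doppler vascularity scoring (modified Gumbsch scale, 0-4).

The ordinal grade summarises intratesticular colour-flow: 0 no detectable
flow; 1 one to three small colour signals; 2 up to three distinct vessels;
3 more than three distinct vessels; 4 the course of a vessel is visible.
"Distinct" is operationalised as a connected component at or above a pixel
size threshold, and "course visible" as a component elongated beyond a
major/minor-axis ratio (or with a long enough morphological skeleton) —
stated conventions for what the original scale defines visually.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops
from skimage.morphology import skeletonize

#: default thresholds at ~0.1-0.15 mm/pixel
DEFAULT_MIN_PIXELS = 4         # components below this are speckle noise
DEFAULT_DISTINCT_PIXELS = 10   # size at which a signal counts as a vessel
DEFAULT_COURSE_ELONGATION = 4.0
DEFAULT_COURSE_SKELETON = 30   # pixels of skeleton length

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class VesselComponent:
    """One connected colour-flow signal."""

    pixel_count: int
    bbox: tuple                 # (min_row, min_col, max_row, max_col)
    elongation: float           # major/minor axis of the best-fit ellipse
    skeleton_length: int


@dataclass(frozen=True)
class DopplerScore:
    score: int
    n_components: int
    n_distinct: int
    course_visible: bool


def detect_vessels(overlay: np.ndarray, parenchyma_mask: np.ndarray,
                   min_pixels: int = DEFAULT_MIN_PIXELS) -> list:
    """Extract 8-connected colour-flow components intersecting the parenchyma.

    Components smaller than ``min_pixels`` are discarded as noise; the rest
    are returned sorted by size, largest first.
    """
    overlay = np.asarray(overlay, dtype=bool)
    parenchyma_mask = np.asarray(parenchyma_mask, dtype=bool)
    if overlay.shape != parenchyma_mask.shape:
        raise ValueError("overlay and parenchyma mask shapes differ")
    labels, n = ndimage.label(overlay, structure=_EIGHT_CONNECTED)
    comps = []
    for prop in regionprops(labels):
        region = labels[prop.slice] == prop.label
        if not (parenchyma_mask[prop.slice] & region).any():
            continue
        if prop.area < min_pixels:
            continue
        minor = max(prop.axis_minor_length, 1.0)
        comps.append(VesselComponent(
            pixel_count=int(prop.area),
            bbox=tuple(prop.bbox),
            elongation=float(prop.axis_major_length / minor),
            skeleton_length=int(skeletonize(region).sum()),
        ))
    comps.sort(key=lambda c: -c.pixel_count)
    return comps


def score_doppler(components: Sequence[VesselComponent],
                  distinct_pixels: int = DEFAULT_DISTINCT_PIXELS,
                  course_elongation: float = DEFAULT_COURSE_ELONGATION,
                  course_skeleton: int = DEFAULT_COURSE_SKELETON) -> DopplerScore:
    """Assign the 0-4 vascularity grade from detected components.

    Course visibility dominates: a single sufficiently elongated vessel
    scores 4 regardless of how many other signals are present.
    """
    if distinct_pixels <= 0 or course_elongation <= 0:
        raise ValueError("thresholds must be positive")
    n = len(components)
    course = any(c.elongation >= course_elongation
                 or c.skeleton_length >= course_skeleton
                 for c in components)
    n_distinct = sum(c.pixel_count >= distinct_pixels for c in components)
    if n == 0:
        score = 0
    elif course:
        score = 4
    elif n_distinct > 3:
        score = 3
    elif n_distinct >= 1:
        score = 2
    else:
        score = 1
    return DopplerScore(score=score, n_components=n,
                        n_distinct=n_distinct, course_visible=course)


def score_cohort(scores: Sequence[int]) -> Dict[int, int]:
    """Percentage of testes per score at one exam week, rounded half-up.

    The five percentages sum to 100 +/- 1 (integer rounding).
    """
    scores = list(scores)
    if not scores:
        raise ValueError("at least one scored frame is required")
    n = len(scores)
    return {s: int(math.floor(scores.count(s) / n * 100 + 0.5))
            for s in range(5)}
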