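"""Grayscale echotexture quantification of B-mode testicular ultrasound.

Two region-of-interest conventions are implemented, mirroring standard
practice in veterinary andrology image analysis:

* **spot-meter technique** — nine square 2 mm² spots placed inside the
  parenchyma (avoiding the mediastinum testis); echogenicity is the mean of
  the nine spot means and heterogeneity the standard deviation of those
  means.
* **region-area technique** — per-pixel statistics over the whole outlined
  parenchyma with the mediastinum testis excluded; heterogeneity here is
  the pixel-level standard deviation, which samples texture over a much
  larger area and is the headline heterogeneity metric.

Echogenicity values are plain 8-bit grayscale intensities, 0 (anechoic)
to 255 (hyperechoic). Percent echogenicity standardizes parenchymal
brightness against a highly echogenic internal reference (capsule, or the
mediastinum in the modified variant): reference mean / parenchyma mean x 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

GRAYSCALE_MAX = 255

#: inclusive upper bounds of the low / moderate echogenicity bands
LOW_MAX = 85
MODERATE_MAX = 170

#: number and physical size of spot-meter ROIs
DEFAULT_N_SPOTS = 9
DEFAULT_SPOT_AREA_MM2 = 2.0


class SpotPlacementError(RuntimeError):
    """Raised when the requested spots cannot fit inside the parenchyma."""


@dataclass
class UltrasoundFrame:
    """A single B-mode frame with named binary region masks.

    Pixels are an 8-bit grayscale grid (row-major, origin top-left).  Masks
    are boolean arrays of identical shape; recognised names are
    ``parenchyma``, ``mediastinum``, ``capsule`` and ``doppler`` (colour-flow
    overlay).  ``flags`` carries frame-level annotations such as
    ``"spot-meter infeasible"`` for testes too small for the nine-spot grid.
    """

    pixels: np.ndarray
    mm_per_pixel: float
    masks: dict = field(default_factory=dict)
    week: Optional[float] = None
    dog_id: Optional[str] = None
    side: Optional[str] = None
    flags: tuple = ()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale grid")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > GRAYSCALE_MAX:
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")
        clean = {}
        for name, mask in self.masks.items():
            mask = np.asarray(mask).astype(bool)
            if mask.shape != self.pixels.shape:
                raise ValueError(f"mask {name!r} shape {mask.shape} does not "
                                 f"match pixels {self.pixels.shape}")
            clean[name] = mask
        self.masks = clean

    def mask(self, name: str) -> Optional[np.ndarray]:
        m = self.masks.get(name)
        if m is None or not m.any():
            return None
        return m


@dataclass
class EchotextureResult:
    """Per-frame echotexture summary (all intensities on the 0-255 scale)."""

    gi_parenchyma_spot: Optional[float]
    het_spot: Optional[float]
    gi_parenchyma_region: float
    het_region: float
    gi_mediastinum: Optional[float]
    gi_capsule: Optional[float]
    ratio_capsule_parenchyma: Optional[float]
    ratio_mediastinum_parenchyma: Optional[float]
    category: str
    spot_coordinates: tuple = ()


def spot_side_pixels(mm_per_pixel: float,
                     spot_area_mm2: float = DEFAULT_SPOT_AREA_MM2) -> int:
    """Side length in pixels of a square spot of the given physical area."""
    return int(round(math.sqrt(spot_area_mm2) / mm_per_pixel))


def _valid_positions(valid: np.ndarray, side: int) -> np.ndarray:
    """Boolean grid of top-left corners where a side x side square is fully valid."""
    h, w = valid.shape
    if side > h or side > w:
        return np.zeros((0, 0), dtype=bool)
    integ = np.zeros((h + 1, w + 1), dtype=np.int64)
    integ[1:, 1:] = np.cumsum(np.cumsum(valid, axis=0), axis=1)
    block = (integ[side:, side:] - integ[:-side, side:]
             - integ[side:, :-side] + integ[:-side, :-side])
    return block == side * side


def place_spots(frame: UltrasoundFrame,
                n_spots: int = DEFAULT_N_SPOTS,
                spot_area_mm2: float = DEFAULT_SPOT_AREA_MM2) -> list:
    """Place ``n_spots`` non-overlapping square spots inside the parenchyma.

    Placement is deterministic: the bounding box of the usable parenchyma
    (parenchyma minus mediastinum) is divided into a grid of cells, one spot
    per cell, each spot snapped to the valid position nearest its cell
    centre.  Spots never intersect the mediastinum mask.  Returns a list of
    ``(row, col, side)`` top-left footprints in row-major order.

    Raises :class:`SpotPlacementError` when the grid cannot fit — the
    young-testis case where fixed-area spots do not fit the small gonad.
    """
    par = frame.mask("parenchyma")
    if par is None:
        raise SpotPlacementError("spot-meter infeasible: empty parenchyma mask")
    side = spot_side_pixels(frame.mm_per_pixel, spot_area_mm2)
    if side < 1:
        raise ValueError("spot side smaller than one pixel")
    valid = par.copy()
    mt = frame.masks.get("mediastinum")
    if mt is not None:
        valid &= ~mt

    g = math.ceil(math.sqrt(n_spots))
    ok = _valid_positions(valid, side)
    if ok.size == 0 or not ok.any():
        raise SpotPlacementError("spot-meter infeasible")

    rows = np.any(valid, axis=1).nonzero()[0]
    cols = np.any(valid, axis=0).nonzero()[0]
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1

    for shrink in (0.0, 0.08, 0.16, 0.24):
        dr = int(round(shrink * (r1 - r0) / 2))
        dc = int(round(shrink * (c1 - c0) / 2))
        br0, br1, bc0, bc1 = r0 + dr, r1 - dr, c0 + dc, c1 - dc
        if (br1 - br0) < g * side or (bc1 - bc0) < g * side:
            break
        redges = np.linspace(br0, br1, g + 1).round().astype(int)
        cedges = np.linspace(bc0, bc1, g + 1).round().astype(int)
        spots: list = []
        feasible = True
        for gi in range(g):
            for gj in range(g):
                if len(spots) == n_spots:
                    break
                ra, rb = redges[gi], redges[gi + 1] - side
                ca, cb = cedges[gj], cedges[gj + 1] - side
                if rb < ra or cb < ca:
                    feasible = False
                    break
                sub = ok[ra:rb + 1, ca:cb + 1]
                cand = np.argwhere(sub)
                if cand.size == 0:
                    feasible = False
                    break
                centre = np.array([(rb - ra) / 2, (cb - ca) / 2])
                d2 = ((cand - centre) ** 2).sum(axis=1)
                best = cand[np.lexsort((cand[:, 1], cand[:, 0], d2))[0]]
                spots.append((int(ra + best[0]), int(ca + best[1]), side))
            if not feasible:
                break
        if feasible and len(spots) == n_spots:
            return spots
    raise SpotPlacementError("spot-meter infeasible")


def spot_meter_stats(frame: UltrasoundFrame, spots: Sequence) -> tuple:
    """Mean grayscale intensity and heterogeneity by the spot-meter convention.

    Returns ``(mean of spot means, SD of spot means)`` with the n-1
    denominator. Requires at least two spots.
    """
    if len(spots) < 2:
        raise ValueError("spot-meter statistics require at least two spots")
    means = []
    for r, c, side in spots:
        block = frame.pixels[r:r + side, c:c + side]
        if block.size == 0:
            raise ValueError("empty spot footprint")
        means.append(float(block.mean()))
    means = np.asarray(means)
    return float(means.mean()), float(means.std(ddof=1))


def region_area_stats(frame: UltrasoundFrame) -> tuple:
    """Mean grayscale intensity and pixel-SD over parenchyma minus mediastinum."""
    par = frame.mask("parenchyma")
    if par is None:
        raise ValueError("empty parenchyma mask")
    eff = par.copy()
    mt = frame.masks.get("mediastinum")
    if mt is not None:
        eff &= ~mt
    vals = frame.pixels[eff].astype(np.float64)
    if vals.size == 0:
        raise ValueError("parenchyma minus mediastinum is empty")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd


def structure_gi(frame: UltrasoundFrame, structure: str) -> Optional[float]:
    """Mean grayscale intensity of a named structure, or None if not imaged.

    Pre-onset mediastinum (empty mask) yields ``None`` — a distinguished
    "not imaged" result rather than zero.
    """
    if structure not in ("mediastinum", "capsule", "parenchyma"):
        raise ValueError(f"unknown structure {structure!r}")
    m = frame.mask(structure)
    if m is None:
        return None
    return float(frame.pixels[m].mean())


def percent_echogenicity(reference_gi: float, parenchyma_gi: float) -> float:
    """Reference-structure GI over parenchymal GI, times 100.

    Used with the capsule as reference and, in the modified variant, the
    mediastinum testis.
    """
    if parenchyma_gi <= 0:
        raise ZeroDivisionError("percent echogenicity undefined for "
                                "non-positive parenchymal intensity")
    return reference_gi / parenchyma_gi * 100.0


def categorize_echogenicity(mean_gi: float) -> str:
    """Classify a mean grayscale intensity into low / moderate / high.

    Bands are 0-85, 86-170 and 171-255; non-integer inputs are rounded
    half-up before classification.
    """
    if not 0 <= mean_gi <= GRAYSCALE_MAX:
        raise ValueError("grayscale intensity outside [0, 255]")
    g = math.floor(mean_gi + 0.5)
    if g <= LOW_MAX:
        return "low"
    if g <= MODERATE_MAX:
        return "moderate"
    return "high"


def measure_frame(frame: UltrasoundFrame,
                  n_spots: int = DEFAULT_N_SPOTS,
                  spot_area_mm2: float = DEFAULT_SPOT_AREA_MM2) -> EchotextureResult:
    """Full echotexture panel for one frame.

    Spot-meter values are None when the nine-spot grid does not fit (small
    testes); the region-area technique is always evaluated. Ratios are
    None when the reference structure is not imaged.
    """
    gi_region, het_region = region_area_stats(frame)
    try:
        spots = place_spots(frame, n_spots=n_spots, spot_area_mm2=spot_area_mm2)
        gi_spot, het_spot = spot_meter_stats(frame, spots)
    except SpotPlacementError:
        spots, gi_spot, het_spot = [], None, None

    gi_mt = structure_gi(frame, "mediastinum")
    gi_cap = structure_gi(frame, "capsule")
    ratio_cap = (percent_echogenicity(gi_cap, gi_region)
                 if gi_cap is not None else None)
    ratio_mt = (percent_echogenicity(gi_mt, gi_region)
                if gi_mt is not None else None)
    return EchotextureResult(
        gi_parenchyma_spot=gi_spot,
        het_spot=het_spot,
        gi_parenchyma_region=gi_region,
        het_region=het_region,
        gi_mediastinum=gi_mt,
        gi_capsule=gi_cap,
        ratio_capsule_parenchyma=ratio_cap,
        ratio_mediastinum_parenchyma=ratio_mt,
        category=categorize_echogenicity(gi_region),
        spot_coordinates=tuple(spots),
    )
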