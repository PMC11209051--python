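"""Volume formulas and semen arithmetic for the maturation work-up.

Calliper volumes (scrotal sac, testis) use the ellipsoid formula
V = 0.5236 x length x width x height; ultrasonographic testicular volume
uses the empirical canine constant V = 0.71 x l x w x h.  Haemocytometer
concentration is the averaged chamber count x 10^6 spermatozoa/mL (the
published convention folds the 1:100 dilution and chamber geometry into
the single factor; the dilution is carried as metadata).  A sample is
fertile when total sperm strictly exceeds 200 million.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

ELLIPSOID_C = 0.5236
US_VOLUME_C = 0.71

FERTILE_TOTAL_SPERM = 200e6
VIABILITY_TARGET_COUNT = 300
CHAMBER_FACTOR = 1e6   # spermatozoa per mL per averaged chamber count


@dataclass(frozen=True)
class TriaxialDims:
    """Length, width, height in cm."""

    length: float
    width: float
    height: float

    def __post_init__(self):
        if min(self.length, self.width, self.height) < 0:
            raise ValueError("dimensions must be non-negative")


@dataclass(frozen=True)
class SemenSample:
    """One ejaculate evaluation.

    ``mean_chamber_count`` is the averaged haemocytometer chamber count;
    ``live_count``/``dead_count`` come from an eosin-nigrosin smear with a
    300-spermatozoa target (fewer are tolerated but flagged).
    """

    volume: float                       # mL
    mean_chamber_count: float = 0.0
    dilution: float = 100.0             # 1:100 by default
    motile_fraction: Optional[float] = None   # percent
    live_count: int = 0
    dead_count: int = 0
    week: Optional[float] = None

    def __post_init__(self):
        if self.volume < 0 or self.mean_chamber_count < 0:
            raise ValueError("volume and counts must be non-negative")
        if self.live_count < 0 or self.dead_count < 0:
            raise ValueError("stained-smear counts must be non-negative")


def _volume(dims, c: float) -> float:
    if not isinstance(dims, TriaxialDims):
        dims = TriaxialDims(*dims)
    return c * dims.length * dims.width * dims.height


def volume_clinical(dims) -> float:
    """Ellipsoid volume (cm^3) from calliper length/width/height in cm."""
    return _volume(dims, ELLIPSOID_C)


def volume_us(dims) -> float:
    """Ultrasonographic testicular volume (cm^3): 0.71 x l x w x h."""
    return _volume(dims, US_VOLUME_C)


def concentration(sample: SemenSample) -> float:
    """Spermatozoa per mL: averaged chamber count x 10^6."""
    return sample.mean_chamber_count * CHAMBER_FACTOR


def total_sperm(sample: SemenSample) -> float:
    """Total spermatozoa in the ejaculate: concentration x volume."""
    return concentration(sample) * sample.volume


def is_fertile(total: float) -> bool:
    """Fertile iff total sperm count strictly exceeds 200 x 10^6."""
    return total > FERTILE_TOTAL_SPERM


def viability(sample: SemenSample) -> Tuple[float, bool]:
    """Percent live spermatozoa and a low-count flag.

    Returns ``(live/(live+dead) x 100, flagged)`` where the flag marks
    smears in which fewer than 300 spermatozoa could be counted.
    """
    counted = sample.live_count + sample.dead_count
    if counted == 0:
        raise ZeroDivisionError("no spermatozoa counted on the smear")
    pct = sample.live_count / counted * 100.0
    return pct, counted < VIABILITY_TARGET_COUNT


def percent_of_maturity(value: float, mature_value: float) -> float:
    """A measurement as a percentage of its adult (mature) value."""
    if mature_value <= 0:
        raise ZeroDivisionError("mature reference value must be positive")
    return value / mature_value * 100.0


def add_morphometry_columns(df):
    """Add scrotum/testis/US volume and fertility columns to a cohort table.

    Volumes are computed from the calliper and ultrasound triaxial columns;
    ``fertile`` applies the strict 200-million threshold to ``total_sperm``
    (missing semen stays missing).
    """
    out = df.copy()
    out["scrotum_volume"] = (ELLIPSOID_C * out["scrotal_l"]
                             * out["scrotal_w"] * out["scrotal_h"])
    out["testis_volume"] = (ELLIPSOID_C * out["testis_l"]
                            * out["testis_w"] * out["testis_h"])
    out["us_volume"] = (US_VOLUME_C * out["us_l"]
                        * out["us_w"] * out["us_h"])
    out["fertile"] = out["total_sperm"].map(
        lambda t: math.nan if (t != t) else float(is_fertile(t)))
    return out
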