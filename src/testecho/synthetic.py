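"""Synthetic longitudinal cohort and B-mode/Doppler frame generator.

Emulates a biweekly ultrasound follow-up of laboratory Beagle puppies from
week 4 to week 40 of age: 8 dogs x 2 testes per exam, with somatometrics,
calliper and ultrasonographic testis dimensions, semen parameters, a
colour-Doppler vascularity class per testis, and rendered speckle frames
whose region statistics follow the programmed maturation trajectories.

Trajectory shapes are piecewise linear-then-plateau for the grayscale
curves and logistic for body/testis growth; the rising-phase slopes default
to 2.525 grayscale units/week (parenchyma) and 4.251 (mediastinum testis).
Milestones default to first ejaculate at week 28, first spermatozoa at week
30, and fertile ejaculates (total sperm > 200 million) from week 36.

Speckle is modelled as gamma-distributed multiplicative texture whose shape
parameter is set from the target mean/SD of the region, quantized to 8-bit;
at the default operating points (mean 55-120, SD 8-22) the [0, 255] clip is
inactive to within floating error, so mask means and SDs track the
trajectories up to sampling error.

Randomness is hierarchical: a single master seed spawns fixed per-dog,
per-week and per-frame seed sequences, so cohorts are reproducible
bit-for-bit and extensible without perturbing existing records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Iterator, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .echotexture import UltrasoundFrame, place_spots, SpotPlacementError

# ---------------------------------------------------------------------------
# study-design constants

DEFAULT_WEEKS: Tuple[int, ...] = tuple(range(4, 41, 2))
SIDES = ("left", "right")

#: ellipsoid constant for calliper volumes and empirical US volume constant
ELLIPSOID_C = 0.5236
US_VOLUME_C = 0.71

#: printed proportion (percent) of testes per colour-Doppler score 0-4 at
#: each exam week; weeks 4-20 are uniformly score 0.
DOPPLER_SCORE_TABLE: Dict[int, Tuple[int, int, int, int, int]] = {
    **{w: (100, 0, 0, 0, 0) for w in range(4, 21, 2)},
    22: (69, 31, 0, 0, 0),
    24: (31, 19, 44, 6, 0),
    26: (69, 19, 12, 0, 0),
    28: (6, 13, 31, 37, 13),
    30: (0, 6, 25, 44, 25),
    32: (0, 0, 0, 25, 75),
    34: (0, 0, 0, 19, 81),
    36: (0, 0, 0, 19, 81),
    38: (0, 0, 0, 19, 81),
    40: (0, 0, 0, 12, 88),
}

#: median total-sperm anchors (spermatozoa per ejaculate) by week; the
#: week-40 value matches the adult Beagle mean of 363 million.
SPERM_MEDIANS = {28: 0.0, 30: 5e6, 32: 4e7, 34: 1.2e8, 36: 3.0e8,
                 38: 3.4e8, 40: 3.63e8}
MOTILITY_MEDIANS = {28: 0.0, 30: 0.0, 32: 65.0, 34: 75.0, 36: 82.0,
                    38: 86.0, 40: 88.0}
VIABILITY_MEDIANS = {30: 70.0, 32: 78.0, 34: 82.0, 36: 86.0,
                     38: 88.0, 40: 90.0}
EJACULATE_ML = {28: 0.3, 30: 0.5, 32: 0.8, 34: 1.1, 36: 1.4,
                38: 1.6, 40: 1.8}

#: onset weeks at which the mediastinum testis is first imaged, for an
#: 8-dog cohort (one dog at week 4, six dogs by week 6, all by week 8)
MT_ONSET_PATTERN_8 = (4, 6, 6, 6, 6, 6, 8, 8)

#: cohort-level milestones: first ejaculate, first spermatozoa, fertile
DEFAULT_MILESTONES = (28, 30, 36)

# logistic growth anchors (midpoint week, scale weeks, baseline fraction)
# solved from percent-of-maturity milestones of the longitudinal design
_WEIGHT_LOGISTIC = (20.3, 5.33, 0.12)
_HEIGHT_LOGISTIC = (19.3, 3.64, 0.25)
_TESTIS_VOL_LOGISTIC = (31.4, 4.2, 0.0)
_SCROTAL_VOL_LOGISTIC = (28.9, 2.4, 0.0)
_US_VOL_LOGISTIC = (23.3, 4.0, 0.0)

_CLINICAL_OVER_US = 1.55   # clinical calliper volume exceeds US volume
_SCROTAL_OVER_US = 2.4

COLUMNS = [
    "dog_id", "testis_side", "week", "weight", "height",
    "scrotal_l", "scrotal_w", "scrotal_h",
    "testis_l", "testis_w", "testis_h",
    "us_l", "us_w", "us_h",
    "ejaculate_volume", "motility", "viability",
    "concentration", "total_sperm", "doppler_score", "frame_path",
]


@dataclass(frozen=True)
class MaturationProfile:
    """Per-dog trajectory parameters driving the generator.

    Grayscale anchors: parenchyma starts at ``gi_start`` at week 6 (a small
    dip from week 4), rises at ``gi_slope``/week to a plateau at
    ``gi_plateau_week`` with a slow residual drift afterwards; the
    mediastinum band appears at ``mt_onset_week`` and rises at
    ``mt_slope``/week; the capsule climbs to ``capsule_plateau`` by week 32;
    region heterogeneity rises linearly from ``het_start`` to ``het_end``.
    """

    dog_id: str = "dog01"
    adult_weight: float = 12.0           # kg
    adult_height: float = 38.0           # cm at withers
    adult_testis_volume: float = 8.5     # cm^3, ultrasonographic
    gi_start: float = 55.0               # parenchyma GI at week 6
    gi_slope: float = 2.525              # GI units / week, rising phase
    gi_plateau_week: float = 30.0
    gi_plateau_drift: float = 0.4        # residual GI units / week past plateau
    gi_dip: float = 3.0                  # week 4 -> 6 decrease
    mt_onset_week: float = 8.0
    mt_start: float = 80.0               # mediastinum GI at week 8
    mt_slope: float = 4.251
    capsule_start: float = 150.0         # capsule GI at week 4
    capsule_plateau: float = 215.0
    capsule_plateau_week: float = 32.0
    het_start: float = 8.0               # region SD at week 4
    het_end: float = 22.0                # region SD from week 36
    het_end_week: float = 36.0
    milestone_weeks: Tuple[int, int, int] = DEFAULT_MILESTONES
    noise_sd: float = 1.5                # testis-level GI measurement noise
    seed: int = 0

    def __post_init__(self):
        for name in ("gi_start", "mt_start", "capsule_start",
                     "capsule_plateau", "het_start", "het_end"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name}={v} outside grayscale range")
        fe, fs, ft = self.milestone_weeks
        if not fe < fs < ft:
            raise ValueError("milestone weeks must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not DEFAULT_WEEKS[0] <= self.gi_plateau_week <= DEFAULT_WEEKS[-1]:
            raise ValueError("gi_plateau_week outside the study window")

    # -- grayscale trajectories ------------------------------------------

    def gi_parenchyma(self, week: float) -> float:
        if week < 6:
            frac = (6 - week) / 2.0
            v = self.gi_start + self.gi_dip * frac
        else:
            v = self.gi_start + self.gi_slope * (min(week, self.gi_plateau_week) - 6)
            if week > self.gi_plateau_week:
                v += self.gi_plateau_drift * (week - self.gi_plateau_week)
        return float(np.clip(v, 0, 255))

    def heterogeneity(self, week: float) -> float:
        w = np.clip(week, 4, self.het_end_week)
        frac = (w - 4) / (self.het_end_week - 4)
        return float(self.het_start + frac * (self.het_end - self.het_start))

    def gi_mediastinum(self, week: float) -> Optional[float]:
        if week < self.mt_onset_week:
            return None
        cap = self.mt_start + self.mt_slope * 28.0   # plateau by week 36
        v = self.mt_start + self.mt_slope * (week - 8.0)
        return float(np.clip(v, 55.0, min(cap, 255.0)))

    def gi_capsule(self, week: float) -> float:
        w = np.clip(week, 4, self.capsule_plateau_week)
        frac = (w - 4) / (self.capsule_plateau_week - 4)
        return float(self.capsule_start
                     + frac * (self.capsule_plateau - self.capsule_start))

    # -- growth trajectories ---------------------------------------------

    @staticmethod
    def _logistic(week: float, mid: float, scale: float, base: float) -> float:
        f = 1.0 / (1.0 + math.exp(-(week - mid) / scale))
        return base + (1.0 - base) * f

    def weight(self, week: float) -> float:
        return self.adult_weight * self._logistic(week, *_WEIGHT_LOGISTIC)

    def height(self, week: float) -> float:
        return self.adult_height * self._logistic(week, *_HEIGHT_LOGISTIC)

    def us_volume(self, week: float) -> float:
        v = self.adult_testis_volume * self._logistic(week, *_US_VOL_LOGISTIC)
        return max(v, 0.2)

    def clinical_volume(self, week: float) -> float:
        adult = self.adult_testis_volume * _CLINICAL_OVER_US
        return max(adult * self._logistic(week, *_TESTIS_VOL_LOGISTIC), 0.25)

    def scrotal_volume(self, week: float) -> float:
        adult = self.adult_testis_volume * _SCROTAL_OVER_US
        return max(adult * self._logistic(week, *_SCROTAL_VOL_LOGISTIC), 0.5)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout: who is examined, when, and frame geometry."""

    n_dogs: int = 8
    weeks: Tuple[int, ...] = DEFAULT_WEEKS
    testes_per_dog: int = 2
    master_seed: int = 0
    image_size: int = 256
    mm_per_pixel: float = 0.15

    def __post_init__(self):
        if self.n_dogs < 1:
            raise ValueError("n_dogs must be at least 1")
        if not self.weeks or list(self.weeks) != sorted(set(self.weeks)):
            raise ValueError("weeks must be a non-empty strictly "
                             "ascending grid")
        if self.testes_per_dog not in (1, 2):
            raise ValueError("testes_per_dog must be 1 or 2")
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")
        object.__setattr__(self, "weeks", tuple(int(w) for w in self.weeks))


# ---------------------------------------------------------------------------
# seeding helpers

def _rng(*entropy) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


#: per-exam (2-week) autocorrelation of the dog-level maturation latent
LATENT_AR = 0.6


def _dog_week_latent(config: CohortConfig, dog_idx: int, week: int) -> float:
    """Shared dog-week maturation latent coupling GI noise and sperm output.

    A stationary AR(1) series over the exam grid: a dog examined slightly
    "ahead" of its cohort stays ahead for a while, so same-day measurements
    co-vary most strongly and the coupling decays over successive exams.
    Innovations are sub-seeded per (dog, week), so extending the week grid
    never perturbs earlier exams.
    """
    z: Optional[float] = None
    for w in config.weeks:
        eps = float(_rng(config.master_seed, dog_idx, w, 11).standard_normal())
        z = eps if z is None else (LATENT_AR * z
                                   + math.sqrt(1 - LATENT_AR ** 2) * eps)
        if w >= week:
            break
    return float(z)


def _gi_deviation(config: CohortConfig, profile: MaturationProfile,
                  dog_idx: int, week: int, side_idx: int) -> float:
    z = _dog_week_latent(config, dog_idx, week)
    e = float(_rng(config.master_seed, dog_idx, week, side_idx, 12)
              .standard_normal())
    return profile.noise_sd * (0.9 * z + 0.436 * e)


# ---------------------------------------------------------------------------
# profiles and table generation

def build_profiles(config: CohortConfig,
                   overrides: Optional[dict] = None) -> Dict[str, MaturationProfile]:
    """Construct per-dog profiles with mild between-dog variation.

    For the canonical 8-dog cohort, mediastinum onset weeks follow the
    observed pattern (one dog at week 4, six by week 6, all by week 8);
    other cohort sizes use a deterministic week-8 onset.
    ``overrides`` maps dog_id -> dict of profile-field replacements.
    """
    overrides = overrides or {}
    if config.n_dogs == 8:
        onsets = list(MT_ONSET_PATTERN_8)
        _rng(config.master_seed, 55).shuffle(onsets)
    else:
        onsets = [8.0] * config.n_dogs

    profiles: Dict[str, MaturationProfile] = {}
    for i in range(config.n_dogs):
        dog_id = f"dog{i + 1:02d}"
        r = _rng(config.master_seed, i, 1)
        p = MaturationProfile(
            dog_id=dog_id,
            adult_weight=round(12.0 * (1 + 0.05 * r.standard_normal()), 2),
            adult_height=round(38.0 * (1 + 0.04 * r.standard_normal()), 1),
            adult_testis_volume=round(8.5 * (1 + 0.08 * r.standard_normal()), 2),
            gi_start=55.0 + 1.5 * r.standard_normal(),
            capsule_plateau=215.0 + 1.5 * r.standard_normal(),
            mt_onset_week=float(onsets[i]),
            seed=int(_rng(config.master_seed, i, 2).integers(2 ** 31)),
        )
        if dog_id in overrides:
            p = replace(p, **overrides[dog_id])
        profiles[dog_id] = p
    return profiles


def _allocate_counts(percentages: Sequence[float], n: int) -> list:
    """Largest-remainder integer allocation of n items to the given shares."""
    quotas = np.asarray(percentages, dtype=float) * n / 100.0
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    order = np.lexsort((np.arange(len(quotas)), -(quotas - counts)))
    for k in order[:short]:
        counts[k] += 1
    return counts.tolist()


def doppler_assignments(config: CohortConfig, week: int) -> list:
    """Stratified colour-Doppler class per testis at a week.

    Class counts follow the study's per-week score proportions via
    largest-remainder rounding (exactly the printed counts at n=16 testes)
    and are shuffled deterministically across the cohort's testes.
    """
    n = config.n_dogs * config.testes_per_dog
    wk = week if week in DOPPLER_SCORE_TABLE else min(
        DOPPLER_SCORE_TABLE, key=lambda k: abs(k - week))
    counts = _allocate_counts(DOPPLER_SCORE_TABLE[wk], n)
    classes = np.repeat(np.arange(5), counts)
    _rng(config.master_seed, week, 77).shuffle(classes)
    return classes.tolist()


def _dims_from_volume(volume: float, c: float,
                      rng: np.random.Generator) -> Tuple[float, float, float]:
    """Triaxial (l, w, h) in cm for a prolate ellipsoid of the given volume."""
    w = (volume / (1.5 * c)) ** (1.0 / 3.0)
    jit = 1.0 + 0.02 * rng.standard_normal(3)
    return (round(1.5 * w * jit[0], 2), round(w * jit[1], 2),
            round(w * jit[2], 2))


def _interp(anchors: dict, week: float) -> float:
    ws = sorted(anchors)
    return float(np.interp(week, ws, [anchors[w] for w in ws]))


def generate_cohort(config: CohortConfig,
                    profile_overrides: Optional[dict] = None) -> pd.DataFrame:
    """Generate the longitudinal exam table: one row per dog x testis x week.

    Semen fields are missing before each dog's first-ejaculate week; at the
    first-sperm week counts are very low with zero motility; from the
    fertile-milestone week the cohort median total sperm exceeds 200
    million.  ``total_sperm = concentration x ejaculate_volume`` holds
    exactly.  Doppler classes are stratified to the study's per-week score
    proportions.  Left and right testes are exchangeable draws around the
    same dog-level curve.
    """
    profiles = build_profiles(config, profile_overrides)
    # dogs whose very first ejaculate already contains a few spermatozoa
    n_early = min(2, config.n_dogs)
    early_sperm = set(_rng(config.master_seed, 66).choice(
        config.n_dogs, size=n_early, replace=False).tolist())

    rows = []
    for week in config.weeks:
        classes = doppler_assignments(config, week)
        t = 0
        for i, (dog_id, p) in enumerate(profiles.items()):
            fe, fs, ft = p.milestone_weeks
            z = _dog_week_latent(config, i, week)
            r_dog = _rng(config.master_seed, i, week, 21)

            weight = round(p.weight(week) * (1 + 0.015 * r_dog.standard_normal()), 2)
            height = round(p.height(week) * (1 + 0.01 * r_dog.standard_normal()), 1)

            if week < fe:
                vol = mot = via = conc = tot = math.nan
            else:
                vol = round(_interp(EJACULATE_ML, week)
                            * (1 + 0.08 * r_dog.standard_normal()), 2)
                vol = max(vol, 0.05)
                if week < fs:
                    tot = 2e5 if i in early_sperm else 0.0
                    mot, via = 0.0, math.nan
                else:
                    e_s = r_dog.standard_normal()
                    tot = _interp(SPERM_MEDIANS, week) * math.exp(
                        0.33 * z + 0.1 * e_s)
                    tot = float(round(tot))
                    mot_med = _interp(MOTILITY_MEDIANS, week)
                    mot = 0.0 if week <= fs else float(np.clip(
                        5 * round((mot_med + 4 * r_dog.standard_normal()) / 5),
                        0, 100))
                    via = float(np.clip(round(
                        _interp(VIABILITY_MEDIANS, week)
                        + 3 * r_dog.standard_normal(), 1), 0, 100))
                conc = tot / vol if vol > 0 else 0.0

            for s in range(config.testes_per_dog):
                side = SIDES[s]
                r = _rng(config.master_seed, i, week, s, 22)
                tl, tw, th = _dims_from_volume(p.clinical_volume(week),
                                               ELLIPSOID_C, r)
                sl, sw, sh = _dims_from_volume(p.scrotal_volume(week),
                                               ELLIPSOID_C, r)
                ul, uw, uh = _dims_from_volume(p.us_volume(week),
                                               US_VOLUME_C, r)
                rows.append({
                    "dog_id": dog_id, "testis_side": side, "week": week,
                    "weight": weight, "height": height,
                    "scrotal_l": sl, "scrotal_w": sw, "scrotal_h": sh,
                    "testis_l": tl, "testis_w": tw, "testis_h": th,
                    "us_l": ul, "us_w": uw, "us_h": uh,
                    "ejaculate_volume": vol, "motility": mot,
                    "viability": via, "concentration": conc,
                    "total_sperm": tot,
                    "doppler_score": classes[t],
                    "frame_path": "",
                })
                t += 1
    df = pd.DataFrame(rows, columns=COLUMNS)
    return df.sort_values(["dog_id", "week", "testis_side"],
                          ignore_index=True)


# ---------------------------------------------------------------------------
# frame rendering

def _ellipse_geometry(profile: MaturationProfile, week: float,
                      size: int, mm_per_pixel: float):
    v = profile.us_volume(week)
    w_cm = (v / (1.5 * US_VOLUME_C)) ** (1.0 / 3.0)
    a = (1.5 * w_cm / 2.0) * 10.0 / mm_per_pixel     # long semi-axis, px
    b = (w_cm / 2.0) * 10.0 / mm_per_pixel
    limit = size / 2.0 - 4
    if a > limit:
        b *= limit / a
        a = limit
    b = min(b, limit)
    return a, b


def render_bmode_frame(profile: MaturationProfile, week: float,
                       size: int = 256, mm_per_pixel: float = 0.15,
                       seed: Optional[int] = None,
                       gi_offset: float = 0.0,
                       rng: Optional[np.random.Generator] = None) -> UltrasoundFrame:
    """Render one synthetic B-mode frame with region masks.

    An elliptical testis on a dark background: gamma-speckled parenchyma at
    the profile's GI/heterogeneity operating point (plus ``gi_offset``, the
    testis-level deviation), a bright central mediastinum band from its
    onset week, and a 3-pixel hyperechoic capsule rim.  Frames whose testis
    is too small for the nine-spot grid carry the ``"spot-meter
    infeasible"`` flag.
    """
    if rng is None:
        rng = np.random.default_rng(profile.seed if seed is None else seed)
    a, b = _ellipse_geometry(profile, week, size, mm_per_pixel)
    cy = cx = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    dist = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
    interior = dist <= 1.0

    from scipy import ndimage
    inner = ndimage.binary_erosion(interior, iterations=3)
    capsule = interior & ~inner

    mt = np.zeros_like(interior)
    mt_gi = profile.gi_mediastinum(week)
    if mt_gi is not None:
        band = max(1, int(round(0.35 / mm_per_pixel / 2)))
        core = ndimage.binary_erosion(inner, iterations=2)
        mt = core & (np.abs(yy - cy) <= band)
    parenchyma = inner & ~mt

    img = np.clip(rng.normal(12.0, 4.0, (size, size)), 0, 40)

    mu = max(profile.gi_parenchyma(week) + gi_offset, 1.0)
    sigma = profile.heterogeneity(week)
    n_par = int(parenchyma.sum())
    if n_par:
        if sigma > 0:
            shape = (mu / sigma) ** 2
            img[parenchyma] = rng.gamma(shape, mu / shape, n_par)
        else:
            img[parenchyma] = mu
    if mt_gi is not None and mt.any():
        img[mt] = rng.normal(mt_gi, 6.0, int(mt.sum())) if sigma > 0 else mt_gi
    cap_gi = profile.gi_capsule(week)
    if capsule.any():
        img[capsule] = (rng.normal(cap_gi, 6.0, int(capsule.sum()))
                        if sigma > 0 else cap_gi)

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    frame = UltrasoundFrame(
        pixels=pixels, mm_per_pixel=mm_per_pixel,
        masks={"parenchyma": parenchyma, "mediastinum": mt, "capsule": capsule},
        week=week, dog_id=profile.dog_id, flags=(),
    )
    try:
        place_spots(frame)
    except SpotPlacementError:
        frame.flags = ("spot-meter infeasible",)
    return frame


def render_cohort_frame(config: CohortConfig, profiles: Dict[str, MaturationProfile],
                        dog_id: str, week: int, side: str) -> UltrasoundFrame:
    """Render the frame for one cohort record with its reproducible sub-seed."""
    dog_idx = list(profiles).index(dog_id)
    side_idx = SIDES.index(side)
    p = profiles[dog_id]
    dev = _gi_deviation(config, p, dog_idx, week, side_idx)
    frame = render_bmode_frame(
        p, week, size=config.image_size, mm_per_pixel=config.mm_per_pixel,
        rng=_rng(config.master_seed, dog_idx, week, side_idx, 101),
        gi_offset=dev)
    frame.side = side
    return frame


def iter_cohort_frames(config: CohortConfig,
                       profiles: Optional[Dict[str, MaturationProfile]] = None,
                       ) -> Iterator[Tuple[str, int, str, UltrasoundFrame]]:
    """Yield ``(dog_id, week, side, frame)`` for every cohort exam."""
    if profiles is None:
        profiles = build_profiles(config)
    for dog_id in profiles:
        for week in config.weeks:
            for side in SIDES[:config.testes_per_dog]:
                yield dog_id, week, side, render_cohort_frame(
                    config, profiles, dog_id, week, side)


# ---------------------------------------------------------------------------
# colour-Doppler overlay rendering

_CROSS = np.array([[0, 0], [0, 1], [0, -1], [1, 0], [-1, 0], [1, 1]])


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(math.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = yy ** 2 + xx ** 2 <= radius ** 2
    return np.stack([yy[keep], xx[keep]], axis=1)


def _place_blobs(rng, valid_coords, existing, n, offsets, overlay, min_sep):
    """Stamp n blobs at well-separated random centres; True on success."""
    placed = 0
    attempts = 0
    h, w = overlay.shape
    while placed < n and attempts < 4000:
        attempts += 1
        cy, cx = valid_coords[rng.integers(len(valid_coords))]
        if any((cy - ey) ** 2 + (cx - ex) ** 2 < min_sep ** 2
               for ey, ex in existing):
            continue
        pts = offsets + (cy, cx)
        ok = ((pts[:, 0] >= 0) & (pts[:, 0] < h)
              & (pts[:, 1] >= 0) & (pts[:, 1] < w))
        pts = pts[ok]
        overlay[pts[:, 0], pts[:, 1]] = True
        existing.append((cy, cx))
        placed += 1
    return placed == n


def render_doppler_overlay(score_class: int, seed: int,
                           parenchyma_mask: np.ndarray) -> np.ndarray:
    """Render a boolean colour-flow overlay of the requested vascularity class.

    Class 0: no flow.  Class 1: 1-3 small sub-threshold blobs.  Class 2: 1-3
    distinct (above-size-threshold) blobs.  Class 3: at least four distinct
    blobs.  Class 4: one elongated sinuous vessel course (plus up to two
    distinct blobs).  All coloured pixels lie inside the parenchyma mask.
    """
    if score_class not in range(5):
        raise ValueError(f"invalid Doppler score class {score_class!r}")
    parenchyma_mask = np.asarray(parenchyma_mask, dtype=bool)
    overlay = np.zeros_like(parenchyma_mask)
    if score_class == 0:
        return overlay

    from scipy import ndimage
    rng = np.random.default_rng(seed)
    valid = ndimage.binary_erosion(parenchyma_mask, iterations=4)
    coords = np.argwhere(valid)
    if coords.size == 0:
        raise ValueError("parenchyma too small for the requested flow class")
    existing: list = []

    if score_class == 4:
        rows = np.any(valid, axis=1).nonzero()[0]
        cols = np.any(valid, axis=0).nonzero()[0]
        cy = int(rows.mean())
        length = min(70, int(0.55 * (cols[-1] - cols[0])))
        length = max(length, 36)
        x0 = int((cols[0] + cols[-1]) / 2 - length / 2)
        # keep the course clear of the central mediastinum band so it is not
        # fragmented by the parenchyma-mask clip
        sign = 1 if rng.random() < 0.5 else -1
        y0 = cy + sign * int(10 + rng.integers(0, 4))
        amp = 3.5 + rng.random()
        lam = 36.0 + 6 * rng.random()
        for x in range(x0, x0 + length):
            y = int(round(y0 + amp * math.sin(2 * math.pi * (x - x0) / lam)))
            for dy in (-1, 0, 1):
                yy_ = y + dy
                if 0 <= yy_ < overlay.shape[0] and 0 <= x < overlay.shape[1] \
                        and parenchyma_mask[yy_, x]:
                    overlay[yy_, x] = True
        for x in range(x0, x0 + length, 8):
            existing.append((y0, x))

    if score_class == 1:
        n = int(rng.integers(1, 4))
        offs, sep = _CROSS, 12
    elif score_class == 2:
        n = int(rng.integers(1, 4))
        offs, sep = _disk_offsets(2.6), 16
    elif score_class == 3:
        n = int(rng.integers(4, 7))
        offs, sep = _disk_offsets(2.6), 14
    else:
        n = int(rng.integers(0, 3))
        offs, sep = _disk_offsets(2.6), 18

    if n and not _place_blobs(rng, coords, existing, n, offs, overlay, sep):
        raise ValueError("parenchyma too small for the requested flow class")
    return overlay & parenchyma_mask
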