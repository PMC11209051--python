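"""End-to-end glue: simulate, render, measure, and score a cohort in memory.

These helpers bind the generator to the measurement stages without touching
disk, so analyses and tests can run on a fully measured table in one call.
The CLI wraps the same functions around PNG/CSV files.
"""

from __future__ import annotations

from typing import Dict, Optional

import pandas as pd

from . import doppler as dop
from . import synthetic as syn
from .echotexture import measure_frame
from .morphometry import add_morphometry_columns

#: echotexture columns appended by measurement, in CSV order
ECHO_COLUMNS = ["gi_spot", "het_spot", "gi_region", "het_region",
                "gi_mt", "gi_capsule", "ratio_cap", "ratio_mt", "category"]


def measure_cohort(config: syn.CohortConfig,
                   cohort: Optional[pd.DataFrame] = None,
                   profile_overrides: Optional[dict] = None,
                   score_overlays: bool = True) -> pd.DataFrame:
    """Render every exam's frame, measure echotexture, and re-score Doppler.

    Returns the cohort table with the echotexture columns, morphometric
    volumes, and — when ``score_overlays`` — a ``doppler_score_measured``
    column obtained by rendering the assigned flow class and running the
    component detector and scorer on the overlay.
    """
    profiles = syn.build_profiles(config, profile_overrides)
    if cohort is None:
        cohort = syn.generate_cohort(config, profile_overrides)
    df = cohort.set_index(["dog_id", "week", "testis_side"], drop=False)

    records: Dict[tuple, dict] = {}
    for dog_id, week, side, frame in syn.iter_cohort_frames(config, profiles):
        res = measure_frame(frame)
        row = {
            "gi_spot": res.gi_parenchyma_spot,
            "het_spot": res.het_spot,
            "gi_region": res.gi_parenchyma_region,
            "het_region": res.het_region,
            "gi_mt": res.gi_mediastinum,
            "gi_capsule": res.gi_capsule,
            "ratio_cap": res.ratio_capsule_parenchyma,
            "ratio_mt": res.ratio_mediastinum_parenchyma,
            "category": res.category,
        }
        if score_overlays:
            key = (dog_id, week, side)
            assigned = int(df.loc[key, "doppler_score"])
            dog_idx = list(profiles).index(dog_id)
            side_idx = syn.SIDES.index(side)
            seed = int(syn._rng(config.master_seed, dog_idx, week,
                                side_idx, 202).integers(2 ** 31))
            overlay = syn.render_doppler_overlay(
                assigned, seed, frame.masks["parenchyma"])
            comps = dop.detect_vessels(overlay, frame.masks["parenchyma"])
            row["doppler_score_measured"] = dop.score_doppler(comps).score
        records[(dog_id, week, side)] = row

    extra = pd.DataFrame.from_dict(records, orient="index")
    extra.index.names = ["dog_id", "week", "testis_side"]
    merged = (cohort.set_index(["dog_id", "week", "testis_side"])
              .join(extra).reset_index())
    return add_morphometry_columns(merged)


def doppler_proportions(df: pd.DataFrame,
                        score_col: str = "doppler_score_measured"
                        ) -> pd.DataFrame:
    """Per-week percentage of testes at each Doppler score (0-4)."""
    col = score_col if score_col in df.columns else "doppler_score"
    rows = {}
    for week, grp in df.groupby("week"):
        scores = grp[col].dropna().astype(int).tolist()
        if scores:
            rows[int(week)] = dop.score_cohort(scores)
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "week"
    out.columns = [f"score_{c}" for c in out.columns]
    return out
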