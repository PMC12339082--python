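"""Reproduction of the study's cohort contrasts on synthetic cohorts.

Each target regenerates a synthetic cohort at the study's group sizes with
the shipped effect profile, runs the relevant measurement stage on every
animal's image, and reports the percent difference of the mutant group mean
relative to the wild-type group mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import histomorphometry as hm
from .calibration import apply_calibration, fit_calibration
from .pipeline import RunConfig
from .stats import percent_difference
from .synthetic import Cohort, SyntheticConfig, generate_cohort, load_effect_profiles

#: cohort contrasts reproduced from the study, keyed by target id
TARGETS: dict[str, dict] = {
    "t1": {"age": "8W", "measure": "gp_thickness_um", "seed_offset": 11},
    "t2": {"age": "15W", "measure": "gp_thickness_um", "seed_offset": 12},
    "t3": {"age": "8W", "measure": "bvtv_primary", "seed_offset": 13},
    "t4": {"age": "15W", "measure": "bvtv_primary", "seed_offset": 14},
    "t5": {"age": "8W", "measure": "bvtv_secondary", "seed_offset": 15},
    "t6": {"age": "8W", "measure": "tbth_secondary_um", "seed_offset": 16},
    "t7": {"age": "15W", "measure": "tbth_secondary_um", "seed_offset": 17},
}


def derive_seed(base_seed: int, offset: int) -> int:
    """Fold a per-target offset into the user seed (stays below 2^31)."""
    return (10007 * int(base_seed) + int(offset)) % (2**31)


def measure_animal(raw: np.ndarray, synth: SyntheticConfig, config: RunConfig,
                   measures: tuple[str, ...]) -> dict[str, float]:
    """Run only the measurement stages needed for ``measures`` on one image."""
    model = fit_calibration(synth.carbon_gl, synth.aluminum_gl, config.calibration)
    camap = apply_calibration(raw, model, pixel_size=synth.pixel_size)
    mask = hm.make_mineral_mask(camap, threshold=config.mineral_threshold)
    margin_px = int(round(config.trabecular_margin_um / synth.pixel_size))
    col_range = (margin_px, mask.shape[1] - margin_px)
    out: dict[str, float] = {}
    if "gp_thickness_um" in measures:
        gp = hm.growth_plate_thickness(
            mask, opening_radius=config.opening_radius, column_range=col_range
        )
        out["gp_thickness_um"] = gp.mean_thickness
    band_measures = {m for m in measures if m != "gp_thickness_um"}
    if band_measures:
        front = hm.detect_mineralization_front(mask, opening_radius=config.opening_radius)
        primary, secondary = hm.define_spongiosa_rois(
            front, mask.shape, synth.pixel_size,
            primary_um=config.primary_band_um, secondary_um=config.secondary_band_um,
            column_range=col_range,
        )
        rois = {"primary": primary, "secondary": secondary}
        for m in band_measures:
            kind, _, region = m.partition("_")
            region = region.removesuffix("_um")
            roi = rois[region]
            if kind == "bvtv":
                out[m] = hm.bv_tv(mask, roi).bv_tv
            elif kind == "tbth":
                out[m] = hm.trabecular_thickness(mask, roi)
            else:
                raise ValueError(f"unknown measure '{m}'")
    return out


def measure_cohort(cohort: Cohort, measures: tuple[str, ...],
                   config: RunConfig | None = None) -> pd.DataFrame:
    """Per-animal measurements for a rendered cohort."""
    config = config or RunConfig(pixel_size=cohort.config.pixel_size)
    rows = []
    for s in cohort.samples:
        rec = {"sample_id": s.sample_id, "genotype": s.genotype}
        rec.update(measure_animal(s.raw, cohort.config, config, measures))
        rows.append(rec)
    return pd.DataFrame(rows)


def run_target(target_id: str, base_seed: int = 1,
               profiles: dict | None = None) -> dict:
    """Regenerate the cohort for one target and measure its group contrast.

    Returns the percent difference (mutant vs wild-type group means), the
    number of animals used, and the per-group means.
    """
    spec = TARGETS[target_id]
    profiles = profiles or load_effect_profiles()
    entry = profiles[spec["age"]]
    cfg = SyntheticConfig(
        empty_fraction_pct=entry.get("empty_fraction_pct", 8.0),
        counted_lacunae_mean=entry.get("counted_lacunae_mean", 1400),
    )
    cohort = generate_cohort(
        cfg,
        n_wt=entry["n_wt"],
        n_mut=entry["n_mut"],
        seed=derive_seed(base_seed, spec["seed_offset"]),
        effects=entry["effects"],
        age_group=spec["age"],
    )
    df = measure_cohort(cohort, (spec["measure"],))
    mean_wt = float(df.loc[df["genotype"] == "WT", spec["measure"]].mean())
    mean_mut = float(df.loc[df["genotype"] == "MUT", spec["measure"]].mean())
    return {
        "value": percent_difference(mean_wt, mean_mut),
        "n": int(len(df)),
        "measure": spec["measure"],
        "age_group": spec["age"],
        "mean_wt": mean_wt,
        "mean_mut": mean_mut,
    }
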