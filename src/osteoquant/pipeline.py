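"""Per-sample and per-cohort orchestration.

``run_sample`` executes the full chain on one image — calibration → mineral
mask → growth-plate and spongiosa histomorphometry → site BMDDs → cortical
OLS — and returns a flat record.  ``run_cohort`` maps that over a manifest,
builds the wild-type metaphyseal reference BMDD per age, attaches
CaLow/CaHigh, and runs the group comparisons per measure.

Every output record carries a short hash of the configuration so results
remain attributable to the exact thresholds that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bmdd as _bmdd
from . import histomorphometry as hm
from . import ols as _ols
from . import stats as _stats
from .calibration import CalibrationConstants, apply_calibration, fit_calibration, load_image
from .errors import FrontNotFoundError, MetadataError, OsteoquantError, ReferenceError_

log = logging.getLogger("osteoquant")

SITES = ("Ct", "Es", "Ms")


@dataclass
class RunConfig:
    """All fixed constants of a pipeline run."""

    pixel_size: float = 0.88  # µm/px
    mineral_threshold: float = 5.2  # wt%Ca
    bmdd_bin_width: float = 0.17  # wt%Ca
    ols_min_area: float = 5.0  # µm²
    ols_max_area: float = 200.0  # µm²
    primary_band_um: float = 500.0
    secondary_band_um: float = 1000.0
    cortex_width_um: float = 60.0  # lateral cortical band evaluated for Ct/OLS
    trabecular_margin_um: float = 80.0  # lateral margin excluded from spongiosa ROIs
    opening_radius: int = 1
    alpha: float = 0.05
    tukey_family: str = "site"
    calibration: CalibrationConstants = field(default_factory=CalibrationConstants)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.mineral_threshold, self.bmdd_bin_width, self.ols_min_area,
               self.primary_band_um, self.secondary_band_um, self.pixel_size) <= 0:
            raise ValueError("all thresholds and band depths must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        cal = data.pop("calibration", None)
        cfg = cls(**data)
        if cal:
            cfg.calibration = CalibrationConstants(**cal)
        return cfg

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def measure_sample(raw: np.ndarray, metadata: dict, config: RunConfig) -> dict:
    """Run the measurement chain on an in-memory 8-bit raster.

    ``metadata`` must provide the measured standards gray levels
    (``carbon_gl``, ``aluminum_gl``); ``pixel_size`` overrides the config.
    Stages that cannot run (e.g. no growth-plate band) record an error
    string for their fields and the rest of the record completes.
    """
    for key in ("carbon_gl", "aluminum_gl"):
        if key not in metadata or metadata[key] is None:
            raise MetadataError(f"missing standards metadata '{key}'")
    ps = float(metadata.get("pixel_size", config.pixel_size))
    model = fit_calibration(metadata["carbon_gl"], metadata["aluminum_gl"], config.calibration)
    camap = apply_calibration(raw, model, pixel_size=ps)
    mask = hm.make_mineral_mask(camap, threshold=config.mineral_threshold)
    n_cols = mask.shape[1]
    margin_px = int(round(config.trabecular_margin_um / ps))
    col_range = (margin_px, n_cols - margin_px)
    cw = int(round(config.cortex_width_um / ps))

    record: dict = {
        "sample_id": metadata.get("sample_id", "sample"),
        "config_hash": config.hash(),
        "pixel_size": ps,
    }

    gp_rows = None
    try:
        gp = hm.growth_plate_thickness(
            mask, opening_radius=config.opening_radius, column_range=col_range
        )
        record["gp_thickness_um"] = gp.mean_thickness
        record["gp_n_valid_columns"] = gp.n_valid_columns
        front = hm.detect_mineralization_front(mask, opening_radius=config.opening_radius)
        gp_rows = front.band_rows
        primary, secondary = hm.define_spongiosa_rois(
            front,
            mask.shape,
            ps,
            primary_um=config.primary_band_um,
            secondary_um=config.secondary_band_um,
            column_range=col_range,
        )
        for roi in (primary, secondary):
            short = "primary" if roi.label.startswith("primary") else "secondary"
            res = hm.bv_tv(mask, roi)
            record[f"bvtv_{short}"] = res.bv_tv
            record[f"bone_area_{short}_um2"] = res.bone_area
            record[f"tissue_area_{short}_um2"] = res.tissue_area
            tbth = hm.trabecular_thickness(mask, roi)
            record[f"tbth_{short}_um"] = tbth
            record[f"tbn_{short}_per_mm"] = hm.trabecular_number(res.bv_tv, tbth)
    except FrontNotFoundError as exc:
        record["gp_error"] = str(exc)

    # site BMDDs: cortex = lateral bands; Es/Ms = interior above/below the band
    site_masks: dict[str, np.ndarray] = {}
    cols = np.zeros(n_cols, dtype=bool)
    cols[:cw] = True
    cols[n_cols - cw :] = True
    site_masks["Ct"] = np.broadcast_to(cols[None, :], mask.shape).copy()
    if gp_rows is not None:
        start, stop = gp_rows
        es = np.zeros(mask.shape, dtype=bool)
        es[:start, margin_px : n_cols - margin_px] = True
        ms = np.zeros(mask.shape, dtype=bool)
        ms[stop:, margin_px : n_cols - margin_px] = True
        site_masks["Es"] = es
        site_masks["Ms"] = ms
    for site, region in site_masks.items():
        try:
            curve = _bmdd.compute_bmdd(
                camap, region=region, threshold=config.mineral_threshold,
                bin_width=config.bmdd_bin_width,
            )
            params = _bmdd.bmdd_params(curve)
            record[f"ca_mean_{site}"] = params.ca_mean
            record[f"ca_peak_{site}"] = params.ca_peak
            record[f"ca_width_{site}"] = params.ca_width
            record[f"_curve_{site}"] = curve
        except OsteoquantError as exc:
            record[f"bmdd_error_{site}"] = str(exc)

    # cortical OLS
    try:
        roi_ct = hm.ROISpec(label="cortex", mask=site_masks["Ct"])
        records = _ols.extract_ols(
            mask, min_area=config.ols_min_area, max_area=config.ols_max_area, roi=roi_ct
        )
        summary = _ols.ols_summary(records, mask, roi=roi_ct)
        record["ols_porosity_pct"] = summary.ols_porosity
        record["ols_density_per_mm2"] = summary.ols_density
        record["ols_median_area_um2"] = summary.median_area
        record["ols_median_perimeter_um"] = summary.median_perimeter
        record["ols_n_lacunae"] = summary.n_lacunae
    except OsteoquantError as exc:
        record["ols_error"] = str(exc)

    return record


def run_sample(image_path, metadata: dict, config: RunConfig) -> dict:
    """Load one image from disk and measure it."""
    raw = load_image(image_path)
    meta = dict(metadata)
    meta.setdefault("sample_id", Path(image_path).stem)
    return measure_sample(raw, meta, config)


#: measures compared between genotypes in the cohort report
COHORT_MEASURES = (
    "gp_thickness_um",
    "bvtv_primary",
    "tbth_primary_um",
    "tbn_primary_per_mm",
    "bvtv_secondary",
    "tbth_secondary_um",
    "tbn_secondary_per_mm",
    "ca_mean_Ct",
    "ca_mean_Es",
    "ca_mean_Ms",
    "ols_porosity_pct",
    "ols_density_per_mm2",
    "ca_low_Ms",
    "ca_high_Ms",
)


@dataclass
class CohortReport:
    records: pd.DataFrame
    comparisons: pd.DataFrame
    reference_p5: float
    reference_p95: float
    config_hash: str
    excluded: list[str]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "per_sample.csv", index=False)
        self.comparisons.to_csv(outdir / "comparisons.csv", index=False)
        (outdir / "report.json").write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "reference_p5": self.reference_p5,
                    "reference_p95": self.reference_p95,
                    "excluded": self.excluded,
                },
                indent=1,
            )
        )


def run_cohort(manifest_path, config: RunConfig, image_dir=None) -> CohortReport:
    """Measure every sample in a manifest and compare the genotype groups.

    The reference BMDD is pooled from the wild-type metaphyseal curves of
    the cohort; CaLow/CaHigh of every sample are evaluated against it.
    Unreadable images are skipped with a warning and listed in the report.
    """
    manifest_path = Path(manifest_path)
    image_dir = Path(image_dir) if image_dir else manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    records: list[dict] = []
    excluded: list[str] = []
    for _, row in manifest.iterrows():
        meta = row.to_dict()
        try:
            rec = run_sample(image_dir / row["image"], meta, config)
        except (OSError, OsteoquantError) as exc:
            log.warning("skipping sample %s: %s", row.get("sample_id"), exc)
            excluded.append(str(row.get("sample_id")))
            continue
        rec["genotype"] = row.get("genotype")
        rec["sex"] = row.get("sex")
        rec["age_group"] = row.get("age_group")
        if {"n_empty_lacunae", "n_total_lacunae"} <= set(manifest.columns):
            counts = _ols.LacunaCounts(
                sample_id=rec["sample_id"],
                n_empty=int(row["n_empty_lacunae"]),
                n_total=int(row["n_total_lacunae"]),
            )
            rec["empty_lacunae_pct"] = _ols.empty_fraction(counts)
        records.append(rec)

    wt_ms = [r["_curve_Ms"] for r in records if r.get("genotype") == "WT" and "_curve_Ms" in r]
    if not wt_ms:
        raise ReferenceError_("no wild-type metaphyseal BMDD available for the reference")
    ref = _bmdd.reference_percentiles(wt_ms)
    for r in records:
        for site in SITES:
            curve = r.pop(f"_curve_{site}", None)
            if curve is not None:
                lo, hi = _bmdd.ca_low_high(curve, ref)
                r[f"ca_low_{site}"] = lo
                r[f"ca_high_{site}"] = hi

    df = pd.DataFrame(records)
    comparisons = []
    measures = [m for m in COHORT_MEASURES if m in df.columns] + (
        ["empty_lacunae_pct"] if "empty_lacunae_pct" in df.columns else []
    )
    for measure in measures:
        wt = df.loc[df["genotype"] == "WT", measure].dropna().to_numpy(float)
        mut = df.loc[df["genotype"] == "MUT", measure].dropna().to_numpy(float)
        if wt.size < 3 or mut.size < 3:
            continue
        cmp_ = _stats.compare_two_groups(wt, mut, alpha=config.alpha)
        comparisons.append(
            {
                "measure": measure,
                "test": cmp_.test_name,
                "statistic": cmp_.statistic,
                "p_value": cmp_.p_value,
                "n_wt": cmp_.n_a,
                "n_mut": cmp_.n_b,
                "mean_wt": cmp_.mean_a,
                "mean_mut": cmp_.mean_b,
                "percent_difference": cmp_.percent_difference,
                "significant": cmp_.p_value < config.alpha,
            }
        )
    return CohortReport(
        records=df,
        comparisons=pd.DataFrame(comparisons),
        reference_p5=ref.p5,
        reference_p95=ref.p95,
        config_hash=config.hash(),
        excluded=excluded,
    )
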