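"""Synthetic qBEI phantom generator with planted, recorded ground truth.

Emulates an 8-bit backscattered-electron image of a longitudinal long-bone
section: lateral cortical bands, an epiphyseal trabecular compartment ending
in a thin subchondral plate, the unmineralized growth-plate band (spanning
the full section width), and a metaphyseal compartment whose first 500 µm
carry primary-spongiosa texture and the rest secondary-spongiosa texture.
Calcium values are drawn per zone (mineralization decreasing from cortex to
epiphysis to metaphysis), mapped to gray through the inverse of the
two-point standards calibration, and degraded with additive Gaussian noise.
Elliptical osteocyte lacunae are stamped into the cortex as enclosed
unmineralized voids.

Trabecular texture is an axis-aligned lattice of rods with jittered spacing:
rod width plants Tb.Th and the width/spacing ratio plants BV/TV, so every
planted quantity is well defined and recorded from the *rasterized* image.

Cohorts draw per-animal multipliers around the configured targets; mutant
animals additionally carry the multiplicative effect profile.  By default
each group's multipliers are normalized to mean 1 ("group-mean anchoring"),
so planted cohort contrasts equal the configured effect scalings exactly;
set ``anchor_group_means=False`` for iid draws (e.g. null-calibration
studies).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .calibration import CalibrationConstants, fit_calibration
from .errors import ConfigError


@dataclass(frozen=True)
class ZoneCa:
    """Gaussian calcium distribution of one tissue zone (wt%Ca)."""

    mean: float
    sd: float


@dataclass(frozen=True)
class Texture:
    """Trabecular rod texture targets."""

    bvtv_pct: float  # target bone area fraction, %
    tbth_um: float  # target rod width (plants Tb.Th)
    jitter_frac: float = 0.12  # positional jitter as a fraction of spacing


@dataclass(frozen=True)
class LacunaField:
    density_per_mm2: float = 300.0  # lacunae per mm² of cortex
    median_area_um2: float = 15.0  # log-normal median sectional area
    log_sigma: float = 0.45
    area_range_um2: tuple[float, float] = (7.0, 180.0)  # kept inside the 5–200 gate
    aspect_range: tuple[float, float] = (1.4, 2.6)
    angle_sd_deg: float = 20.0  # orientation scatter around the bone axis


@dataclass
class SyntheticConfig:
    """Geometry, composition and imaging parameters of the phantom.

    Defaults describe a wild-type mouse section at the imaging protocol's
    0.88 µm/px resolution; zone calcium means decrease from cortex to
    epiphysis to metaphysis.
    """

    image_width_px: int = 1200
    pixel_size: float = 0.88  # µm/px
    margin_um: float = 35.0  # embedding background above/below the section
    cortex_width_um: float = 60.0
    epiphysis_um: float = 300.0  # includes the subchondral plate
    subchondral_plate_um: float = 30.0
    growth_plate_um: float = 150.0
    gp_wiggle_amp_um: float = 2.6
    gp_wiggle_period_um: float = 180.0
    metaphysis_um: float = 1600.0

    ca_cortex: ZoneCa = field(default_factory=lambda: ZoneCa(24.0, 1.5))
    ca_epiphysis: ZoneCa = field(default_factory=lambda: ZoneCa(23.0, 1.5))
    ca_metaphysis: ZoneCa = field(default_factory=lambda: ZoneCa(21.5, 2.0))

    texture_epiphysis: Texture = field(default_factory=lambda: Texture(35.0, 50.0))
    texture_primary: Texture = field(default_factory=lambda: Texture(40.0, 25.0))
    texture_secondary: Texture = field(default_factory=lambda: Texture(25.0, 45.0))

    lacunae: LacunaField = field(default_factory=LacunaField)

    noise_gl_sd: float = 2.0  # additive Gaussian noise, gray levels
    carbon_gl: float = 25.0  # measured standards (defaults: no drift)
    aluminum_gl: float = 225.0
    calibration: CalibrationConstants = field(default_factory=CalibrationConstants)

    between_animal_cv: float = 0.08
    ca_between_animal_cv: float = 0.02
    anchor_group_means: bool = True
    empty_fraction_pct: float = 8.0  # wild-type baseline of empty lacunae
    counted_lacunae_mean: float = 1400.0  # manual histology counts per animal

    enforce_zone_ordering: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.pixel_size <= 0 or self.image_width_px < 4 * self.cortex_px:
            raise ConfigError("image too narrow for the cortical bands")
        if min(self.margin_um, self.cortex_width_um, self.epiphysis_um,
               self.growth_plate_um, self.metaphysis_um) <= 0:
            raise ConfigError("all zone extents must be positive")
        if self.subchondral_plate_um >= self.epiphysis_um:
            raise ConfigError("subchondral plate thicker than the epiphysis")
        if self.enforce_zone_ordering and not (
            self.ca_cortex.mean >= self.ca_epiphysis.mean >= self.ca_metaphysis.mean
        ):
            raise ConfigError(
                "zone Ca means must decrease cortex -> epiphysis -> metaphysis "
                "(set enforce_zone_ordering=False to override)"
            )
        for t in (self.texture_epiphysis, self.texture_primary, self.texture_secondary):
            if not (0 < t.bvtv_pct < 100) or t.tbth_um <= 0:
                raise ConfigError("texture targets must satisfy 0 < BV/TV < 100, Tb.Th > 0")

    # -- pixel helpers -------------------------------------------------
    @property
    def cortex_px(self) -> int:
        return int(round(self.cortex_width_um / self.pixel_size))

    def px(self, um: float) -> int:
        return int(round(um / self.pixel_size))


@dataclass
class AnimalParams:
    """Per-animal realization of the phantom targets."""

    gp_um: float
    bvtv: dict[str, float]  # region -> %
    tbth: dict[str, float]  # region -> µm
    ca_means: dict[str, float]  # zone -> wt%Ca
    empty_fraction_pct: float

    @classmethod
    def from_config(cls, cfg: SyntheticConfig) -> "AnimalParams":
        return cls(
            gp_um=cfg.growth_plate_um,
            bvtv={
                "epiphysis": cfg.texture_epiphysis.bvtv_pct,
                "primary": cfg.texture_primary.bvtv_pct,
                "secondary": cfg.texture_secondary.bvtv_pct,
            },
            tbth={
                "epiphysis": cfg.texture_epiphysis.tbth_um,
                "primary": cfg.texture_primary.tbth_um,
                "secondary": cfg.texture_secondary.tbth_um,
            },
            ca_means={
                "cortex": cfg.ca_cortex.mean,
                "epiphysis": cfg.ca_epiphysis.mean,
                "metaphysis": cfg.ca_metaphysis.mean,
            },
            empty_fraction_pct=cfg.empty_fraction_pct,
        )


#: zone label codes in GroundTruth.zone_labels
ZONE_CODES = {
    "background": 0,
    "cortex": 1,
    "epiphysis": 2,
    "growth_plate": 3,
    "primary": 4,
    "secondary": 5,
}


@dataclass
class GroundTruth:
    """Planted truth recorded from the rasterized phantom."""

    zone_labels: np.ndarray  # uint8 raster of ZONE_CODES
    mineral_mask: np.ndarray  # pre-noise binary mineral raster
    gp_top_row: np.ndarray  # per-column first growth-plate row
    gp_bottom_row: np.ndarray  # per-column first metaphyseal row
    lacunae: list[dict]  # center, semi-axes, angle, rasterized area
    band_bvtv_pct: dict[str, float]  # rasterized mineral fraction per band
    band_tbth_um: dict[str, float]  # rasterized rod width per band
    params: AnimalParams
    pixel_size: float

    @property
    def gp_thickness_px(self) -> np.ndarray:
        return self.gp_bottom_row - self.gp_top_row

    @property
    def gp_mean_thickness_um(self) -> float:
        return float(self.gp_thickness_px.mean() * self.pixel_size)

    def summary_dict(self) -> dict:
        return {
            "gp_mean_thickness_um": self.gp_mean_thickness_um,
            "band_bvtv_pct": self.band_bvtv_pct,
            "band_tbth_um": self.band_tbth_um,
            "n_lacunae": len(self.lacunae),
            "lacunae": self.lacunae,
            "params": dataclasses.asdict(self.params),
        }


def _rod_pattern(
    c0: int, c1: int, width_px: float, spacing_px: float, jitter_frac: float,
    n_cols: int, rng: np.random.Generator,
) -> np.ndarray:
    """Boolean column pattern of jittered parallel rods inside [c0, c1)."""
    pattern = np.zeros(n_cols, dtype=bool)
    w = max(1, int(round(width_px)))
    phase = rng.uniform(0.0, spacing_px)
    jit_amp = jitter_frac * spacing_px / 2.0
    pos = c0 - spacing_px + phase
    while pos < c1:
        start = int(round(pos + rng.uniform(-jit_amp, jit_amp)))
        lo, hi = max(start, c0), min(start + w, c1)
        if hi > lo:
            pattern[lo:hi] = True
        pos += spacing_px
    return pattern


def _stamp_lacunae(
    mineral: np.ndarray,
    zone: np.ndarray,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """Stamp enclosed elliptical voids into the cortical bands."""
    from skimage.draw import ellipse as draw_ellipse

    ps = cfg.pixel_size
    lac = cfg.lacunae
    cortex = zone == ZONE_CODES["cortex"]
    area_mm2 = cortex.sum() * ps**2 / 1e6
    n_target = rng.poisson(lac.density_per_mm2 * area_mm2)
    mu = np.log(lac.median_area_um2)
    reserved = np.zeros_like(mineral)
    records: list[dict] = []
    rows_c, cols_c = np.nonzero(cortex)
    if rows_c.size == 0 or n_target == 0:
        return records
    h, wimg = mineral.shape
    attempts = 0
    while len(records) < n_target and attempts < 60 * n_target:
        attempts += 1
        area = float(np.exp(rng.normal(mu, lac.log_sigma)))
        if not (lac.area_range_um2[0] <= area <= lac.area_range_um2[1]):
            continue
        aspect = rng.uniform(*lac.aspect_range)
        angle = np.deg2rad(rng.normal(0.0, lac.angle_sd_deg))
        a_px = np.sqrt(area * aspect / np.pi) / ps  # semi-axis along the bone axis
        b_px = a_px / aspect
        k = rng.integers(rows_c.size)
        r0, c0 = int(rows_c[k]), int(cols_c[k])
        rr, cc = draw_ellipse(r0, c0, a_px, b_px, rotation=angle)
        # clearance footprint: 2 px larger, must stay inside cortex mineral
        rr2, cc2 = draw_ellipse(r0, c0, a_px + 2, b_px + 2, rotation=angle)
        if (rr2.min() < 0 or cc2.min() < 0 or rr2.max() >= h or cc2.max() >= wimg):
            continue
        foot = (rr2, cc2)
        if not (cortex[foot].all() and mineral[foot].all()) or reserved[foot].any():
            continue
        mineral[rr, cc] = False
        reserved[foot] = True
        records.append(
            {
                "center_rc": [r0, c0],
                "semi_axes_px": [float(a_px), float(b_px)],
                "angle_rad": float(angle),
                "target_area_um2": area,
                "raster_area_um2": float(rr.size * ps**2),
                "raster_area_px": int(rr.size),
            }
        )
    return records


def generate_bone_image(
    config: SyntheticConfig,
    seed: int | np.random.Generator,
    params: AnimalParams | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render one phantom section.

    Deterministic for a fixed (config, params, seed).  Returns the raw 8-bit
    image and the :class:`GroundTruth` recorded from the rasterization.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = config
    params = params or AnimalParams.from_config(cfg)
    ps = cfg.pixel_size
    W = cfg.image_width_px
    margin = cfg.px(cfg.margin_um)
    epi_px = cfg.px(cfg.epiphysis_um)
    plate_px = cfg.px(cfg.subchondral_plate_um)
    gp_px = max(1, int(round(params.gp_um / ps)))
    meta_px = cfg.px(cfg.metaphysis_um)
    H = margin + epi_px + gp_px + meta_px + margin
    cw = cfg.cortex_px
    e0, e1 = margin, margin + epi_px
    bone_end = H - margin

    # growth-plate band: parallel boundaries with a smooth lateral wiggle
    amp = cfg.gp_wiggle_amp_um / ps
    period = max(cfg.gp_wiggle_period_um / ps, 8.0)
    phase = rng.uniform(0, 2 * np.pi)
    cols = np.arange(W)
    wiggle = np.round(amp * np.sin(2 * np.pi * cols / period + phase)).astype(int)
    gp_top = e1 + wiggle
    gp_bottom = gp_top + gp_px

    rr = np.arange(H)[:, None]
    in_gp = (rr >= gp_top[None, :]) & (rr < gp_bottom[None, :])
    bone_rows = (rr >= e0) & (rr < bone_end)

    cortex_cols = np.zeros(W, dtype=bool)
    cortex_cols[:cw] = True
    cortex_cols[W - cw :] = True
    field_c0, field_c1 = cw, W - cw

    def rods(region: str, texture_jitter: float) -> np.ndarray:
        w_px = params.tbth[region] / ps
        spacing = w_px / (params.bvtv[region] / 100.0)
        return _rod_pattern(field_c0, field_c1, w_px, spacing, texture_jitter, W, rng)

    rods_epi = rods("epiphysis", cfg.texture_epiphysis.jitter_frac)
    rods_pri = rods("primary", cfg.texture_primary.jitter_frac)
    rods_sec = rods("secondary", cfg.texture_secondary.jitter_frac)

    d1 = cfg.px(500.0)
    plate = (rr >= gp_top[None, :] - plate_px) & (rr < gp_top[None, :]) & ~cortex_cols[None, :]
    epi_zone = (rr >= e0) & (rr < gp_top[None, :] - plate_px) & ~cortex_cols[None, :]
    pri_zone = (rr >= gp_bottom[None, :]) & (rr < gp_bottom[None, :] + d1) & ~cortex_cols[None, :]
    sec_zone = (rr >= gp_bottom[None, :] + d1) & (rr < bone_end) & ~cortex_cols[None, :]

    mineral = np.zeros((H, W), dtype=bool)
    mineral |= bone_rows & cortex_cols[None, :] & ~in_gp
    mineral |= plate
    mineral |= epi_zone & rods_epi[None, :]
    mineral |= pri_zone & rods_pri[None, :]
    mineral |= sec_zone & rods_sec[None, :]

    zone = np.zeros((H, W), dtype=np.uint8)
    zone[bone_rows & cortex_cols[None, :] & ~in_gp] = ZONE_CODES["cortex"]
    zone[(epi_zone | plate)] = ZONE_CODES["epiphysis"]
    zone[in_gp] = ZONE_CODES["growth_plate"]
    zone[pri_zone] = ZONE_CODES["primary"]
    zone[sec_zone] = ZONE_CODES["secondary"]

    lacunae = _stamp_lacunae(mineral, zone, cfg, rng)

    # calcium raster: per-zone Gaussian for mineral pixels, 0 elsewhere
    ca = np.zeros((H, W), dtype=float)
    zone_ca = {
        ZONE_CODES["cortex"]: ("cortex", cfg.ca_cortex.sd),
        ZONE_CODES["epiphysis"]: ("epiphysis", cfg.ca_epiphysis.sd),
        ZONE_CODES["primary"]: ("metaphysis", cfg.ca_metaphysis.sd),
        ZONE_CODES["secondary"]: ("metaphysis", cfg.ca_metaphysis.sd),
    }
    for code, (zone_name, sd) in zone_ca.items():
        sel = mineral & (zone == code)
        n = int(sel.sum())
        if n:
            ca[sel] = np.clip(rng.normal(params.ca_means[zone_name], sd, size=n), 6.0, 44.5)

    model = fit_calibration(cfg.carbon_gl, cfg.aluminum_gl, cfg.calibration)
    gray = model.gray_for_ca(ca)
    if cfg.noise_gl_sd > 0:
        gray = gray + rng.normal(0.0, cfg.noise_gl_sd, size=gray.shape)
    raw = np.clip(np.round(gray), 0, 255).astype(np.uint8)

    # rasterized band truths (trabecular field only, excluding cortex)
    fieldc = ~cortex_cols[None, :]
    band_bvtv = {}
    for name, zone_sel in (("primary", pri_zone), ("secondary", sec_zone), ("epiphysis", epi_zone)):
        sel = zone_sel & fieldc
        band_bvtv[name] = float(100.0 * (mineral & sel).sum() / max(sel.sum(), 1))
    band_tbth = {
        name: max(1, int(round(params.tbth[name] / ps))) * ps
        for name in ("primary", "secondary", "epiphysis")
    }

    gt = GroundTruth(
        zone_labels=zone,
        mineral_mask=mineral,
        gp_top_row=gp_top.copy(),
        gp_bottom_row=gp_bottom.copy(),
        lacunae=lacunae,
        band_bvtv_pct=band_bvtv,
        band_tbth_um=band_tbth,
        params=params,
        pixel_size=ps,
    )
    return raw, gt


# ---------------------------------------------------------------------------
# cohorts

MEASURE_KEYS = (
    "growth_plate_thickness",
    "bvtv_primary",
    "tbth_primary",
    "bvtv_secondary",
    "tbth_secondary",
    "bvtv_epiphysis",
    "tbth_epiphysis",
    "ca_mean",
    "empty_fraction",
)


@dataclass
class CohortSample:
    sample_id: str
    genotype: str  # WT / MUT
    sex: str  # M / F
    age_group: str
    params: AnimalParams
    empty_counts: tuple[int, int]  # (n_empty, n_total) from simulated histology
    raw: np.ndarray | None = None
    ground_truth: GroundTruth | None = None


@dataclass
class Cohort:
    samples: list[CohortSample]
    config: SyntheticConfig
    effects: dict[str, float]
    age_group: str

    def write(self, outdir) -> Path:
        """Write TIFF images, a manifest CSV and per-sample ground truth."""
        import pandas as pd
        import tifffile

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for s in self.samples:
            img_path = outdir / f"{s.sample_id}.tif"
            gt_path = outdir / f"{s.sample_id}.groundtruth.json"
            if s.raw is not None:
                tifffile.imwrite(str(img_path), s.raw)
            if s.ground_truth is not None:
                gt_path.write_text(json.dumps(s.ground_truth.summary_dict(), indent=1))
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "genotype": s.genotype,
                    "sex": s.sex,
                    "age_group": s.age_group,
                    "image": img_path.name,
                    "carbon_gl": self.config.carbon_gl,
                    "aluminum_gl": self.config.aluminum_gl,
                    "pixel_size": self.config.pixel_size,
                    "n_empty_lacunae": s.empty_counts[0],
                    "n_total_lacunae": s.empty_counts[1],
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
        return outdir / "manifest.csv"


def _multipliers(
    n: int, cv: float, anchor: bool, rng: np.random.Generator
) -> np.ndarray:
    """Log-normal per-animal multipliers, optionally normalized to mean 1."""
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    m = np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=n))
    if anchor:
        m = m / m.mean()
    return m


def generate_cohort(
    config: SyntheticConfig,
    n_wt: int,
    n_mut: int,
    seed: int,
    effects: dict[str, float] | None = None,
    age_group: str = "8W",
    render_images: bool = True,
) -> Cohort:
    """Generate a two-genotype cohort with planted group contrasts.

    ``effects`` maps measure names (:data:`MEASURE_KEYS`) to multiplicative
    mutant/wild-type scalings; missing keys default to 1 (no effect).  With
    ``render_images=False`` only per-animal parameters and histology counts
    are produced (fast path for calibration studies).
    """
    if n_wt < 1 or n_mut < 1:
        raise ConfigError("need at least one animal per genotype")
    effects = dict(effects or {})
    unknown = set(effects) - set(MEASURE_KEYS)
    if unknown:
        raise ConfigError(f"unknown effect keys: {sorted(unknown)}")
    for k, v in effects.items():
        if v <= 0:
            raise ConfigError(f"effect scaling for '{k}' must be positive")
    rng = np.random.default_rng(seed)
    cfg = config
    base = AnimalParams.from_config(cfg)
    samples: list[CohortSample] = []
    for genotype, n in (("WT", n_wt), ("MUT", n_mut)):
        mult = {
            k: _multipliers(n, cfg.between_animal_cv, cfg.anchor_group_means, rng)
            for k in MEASURE_KEYS
            if k not in ("ca_mean",)
        }
        mult["ca_mean"] = _multipliers(n, cfg.ca_between_animal_cv, cfg.anchor_group_means, rng)
        eff = {k: (effects.get(k, 1.0) if genotype == "MUT" else 1.0) for k in MEASURE_KEYS}
        for i in range(n):
            params = AnimalParams(
                gp_um=base.gp_um * mult["growth_plate_thickness"][i] * eff["growth_plate_thickness"],
                bvtv={
                    r: min(base.bvtv[r] * mult[f"bvtv_{r}"][i] * eff[f"bvtv_{r}"], 95.0)
                    for r in ("epiphysis", "primary", "secondary")
                },
                tbth={
                    r: base.tbth[r] * mult[f"tbth_{r}"][i] * eff[f"tbth_{r}"]
                    for r in ("epiphysis", "primary", "secondary")
                },
                ca_means={z: v * mult["ca_mean"][i] * eff["ca_mean"] for z, v in base.ca_means.items()},
                empty_fraction_pct=min(
                    base.empty_fraction_pct * mult["empty_fraction"][i] * eff["empty_fraction"], 100.0
                ),
            )
            n_total = int(rng.poisson(cfg.counted_lacunae_mean))
            n_empty = int(rng.binomial(max(n_total, 1), params.empty_fraction_pct / 100.0))
            sid = f"{age_group}_{genotype}_{i + 1:02d}"
            raw = gt = None
            if render_images:
                raw, gt = generate_bone_image(cfg, rng, params=params)
            samples.append(
                CohortSample(
                    sample_id=sid,
                    genotype=genotype,
                    sex="MF"[i % 2],
                    age_group=age_group,
                    params=params,
                    empty_counts=(n_empty, max(n_total, 1)),
                    raw=raw,
                    ground_truth=gt,
                )
            )
    return Cohort(samples=samples, config=cfg, effects=effects, age_group=age_group)


def load_effect_profiles(path=None) -> dict:
    """Load the shipped (or a user) effect-profile file.

    The shipped profiles encode the study's reported wild-type/mutant group
    differences per age group as multiplicative scalings, plus the cohort
    sizes used for each age.
    """
    import yaml

    if path is not None:
        text = Path(path).read_text()
    else:
        text = resources.files("osteoquant").joinpath("data/effect_profiles.yaml").read_text()
    return yaml.safe_load(text)
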