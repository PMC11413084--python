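"""Synthetic histology fields and cohorts with known ground truth.

Two generators live here. :func:`render_histology_field` paints a single
DAB/hematoxylin-like RGB field with an exact pixel-level truth mask, so the
percent-positive-area estimators can be tested against a known planted
fraction. :func:`generate_cohort` builds a cohort in which regional tau
burden, PET SUVR, and the ordinal staging labels (Braak, Thal, neuritic
plaque score, ADNC, TDP-43) share the statistical structure the downstream
analyses assume: SUVR is a noisy increasing function of regional burden in
cortical (on-target) regions, off-target regions carry PET signal unrelated
to local tau, Braak stage is a threshold function of regional burden, and a
configurable fraction of subjects follow a primary age-related tauopathy
(PART) profile (low amyloid, Braak I-IV).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from collections.abc import Iterator, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy import ndimage
from skimage.draw import ellipse, line

__all__ = [
    "StainModel",
    "ImageSpec",
    "CohortConfig",
    "HistoField",
    "Cohort",
    "SchemaError",
    "render_histology_field",
    "generate_cohort",
    "write_fixture_set",
    "load_fixture_set",
    "TEMPORAL_META_MEMBERS",
    "CORTICAL_META_MEMBERS",
    "OFF_TARGET_REGIONS",
    "REFERENCE_REGION",
]


class SchemaError(ValueError):
    """A loaded table does not match the expected schema."""


# Canonical region vocabulary used across the package. Meta-ROI membership
# mirrors the temporal and cortical flortaucipir composites; bilateral
# members are represented by a single (hemisphere-averaged) value.
TEMPORAL_META_MEMBERS = (
    "entorhinal",
    "superior_middle_temporal",
    "medial_temporal_ba37",
    "inferolateral_temporal",
)
CORTICAL_META_MEMBERS = (
    "middle_frontal",
    "superior_middle_temporal",
    "inferior_parietal",
    "occipital_ba17_18",
    "anterior_cingulate",
    "medial_temporal_ba37",
    "inferolateral_temporal",
    "parieto_occipital_ba39",
    "precuneus_ba7",
    "frontal_premotor_ba6",
    "frontal_anterior_ba9",
    "orbitofrontal_ba11",
    "primary_motor_ba4",
)
OFF_TARGET_REGIONS = ("midbrain", "basal_ganglia", "choroid_plexus")
REFERENCE_REGION = "cerebellar_grey"

DEFAULT_REGIONS = tuple(
    dict.fromkeys(
        TEMPORAL_META_MEMBERS + CORTICAL_META_MEMBERS + OFF_TARGET_REGIONS + (REFERENCE_REGION,)
    )
)

# Relative regional involvement, transentorhinal cortex highest, primary
# sensorimotor and off-target regions lowest. Burden = severity x value.
DEFAULT_SUSCEPTIBILITY = {
    "entorhinal": 1.00,
    "inferolateral_temporal": 0.60,
    "medial_temporal_ba37": 0.55,
    "superior_middle_temporal": 0.50,
    "precuneus_ba7": 0.35,
    "inferior_parietal": 0.35,
    "middle_frontal": 0.30,
    "anterior_cingulate": 0.30,
    "parieto_occipital_ba39": 0.30,
    "frontal_anterior_ba9": 0.25,
    "orbitofrontal_ba11": 0.25,
    "frontal_premotor_ba6": 0.20,
    "occipital_ba17_18": 0.15,
    "primary_motor_ba4": 0.10,
    "midbrain": 0.0,
    "basal_ganglia": 0.0,
    "choroid_plexus": 0.0,
    "cerebellar_grey": 0.0,
}

# Anchor region per Braak stage (transentorhinal -> neocortical spread) and
# the burden (% area) that region must reach for the stage to be assigned.
DEFAULT_BRAAK_ANCHORS = (
    "entorhinal",
    "entorhinal",
    "medial_temporal_ba37",
    "inferolateral_temporal",
    "superior_middle_temporal",
    "occipital_ba17_18",
)
DEFAULT_BRAAK_THRESHOLDS = (0.02, 0.08, 0.15, 0.30, 0.62, 0.63)


@dataclass(frozen=True)
class StainModel:
    """Color model for a DAB-stained, hematoxylin-counterstained field.

    ``per_subject_intensity_scale`` multiplies the darkness of the
    counterstain background (values above 1 darken it), emulating the
    between-subject staining-intensity variation that forces per-subject
    thresholding. DAB chromogen color is not scaled.
    """

    dab_rgb_mean: tuple[float, float, float] = (88.0, 34.0, 24.0)
    hema_rgb_mean: tuple[float, float, float] = (165.0, 150.0, 200.0)
    per_subject_intensity_scale: float = 1.0
    pixel_noise_sd: float = 2.5

    def __post_init__(self) -> None:
        r, g, b = self.dab_rgb_mean
        if not (r > g > b):
            raise ValueError("DAB mean must satisfy red > green > blue")
        hr, _, hb = self.hema_rgb_mean
        if hb < hr:
            raise ValueError("hematoxylin mean must satisfy blue >= red")
        if self.per_subject_intensity_scale <= 0:
            raise ValueError("intensity scale must be positive")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel noise sd must be non-negative")


@dataclass(frozen=True)
class ImageSpec:
    """Geometry and planted positive fraction for one synthetic field."""

    width: int = 512
    height: int = 512
    target_positive_fraction: float = 0.01
    tangle_vs_neurite_mix: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 16 or self.height < 16:
            raise ValueError("image dimensions must be at least 16 pixels")
        if not 0.0 <= self.target_positive_fraction <= 1.0:
            raise ValueError("target_positive_fraction must lie in [0, 1]")
        if not 0.0 <= self.tangle_vs_neurite_mix <= 1.0:
            raise ValueError("tangle_vs_neurite_mix must lie in [0, 1]")


@dataclass
class HistoField:
    """One RGB histology field with provenance tags and optional truth."""

    pixels: np.ndarray
    subject_id: str = "S000"
    region_name: str = "unspecified"
    field_index: int = 1
    magnification_tag: str = "5x"
    truth_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        if self.field_index not in (1, 2, 3):
            raise ValueError("field_index must be 1, 2 or 3")
        if self.truth_mask is not None and self.truth_mask.shape != self.pixels.shape[:2]:
            raise ValueError("truth_mask shape must match image")

    @property
    def truth_fraction(self) -> float | None:
        if self.truth_mask is None:
            return None
        return float(self.truth_mask.sum()) / self.truth_mask.size


def _draw_tangle(rng: np.random.Generator, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    r0 = rng.uniform(0, h)
    c0 = rng.uniform(0, w)
    a = rng.uniform(2.5, 9.0)
    b = a * rng.uniform(0.45, 1.0)
    rot = rng.uniform(0, np.pi)
    return ellipse(r0, c0, a, b, shape=(h, w), rotation=rot)


def _draw_neurite(rng: np.random.Generator, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    # curvilinear stroke: short line segments with drifting heading
    r = rng.uniform(0, h)
    c = rng.uniform(0, w)
    theta = rng.uniform(0, 2 * np.pi)
    n_seg = int(rng.integers(8, 30))
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for _ in range(n_seg):
        theta += rng.normal(0, 0.35)
        r2 = r + 2.5 * np.sin(theta)
        c2 = c + 2.5 * np.cos(theta)
        rr, cc = line(int(round(r)), int(round(c)), int(round(r2)), int(round(c2)))
        rows.append(rr)
        cols.append(cc)
        r, c = r2, c2
    rr = np.concatenate(rows)
    cc = np.concatenate(cols)
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    rr, cc = rr[keep], cc[keep]
    if rng.random() < 0.5 and rr.size:  # thicker neurite
        rr = np.concatenate([rr, np.clip(rr + 1, 0, h - 1)])
        cc = np.concatenate([cc, cc])
    return rr, cc


def _adjust_mask_to_count(mask: np.ndarray, target: int, rng: np.random.Generator) -> np.ndarray:
    """Trim or add boundary pixels until the mask holds exactly ``target``."""
    mask = mask.copy()
    while int(mask.sum()) > target:
        boundary = mask & ~ndimage.binary_erosion(mask)
        idx = np.flatnonzero(boundary)
        if idx.size == 0:  # isolated pixels only
            idx = np.flatnonzero(mask)
        excess = int(mask.sum()) - target
        drop = rng.choice(idx, size=min(excess, idx.size), replace=False)
        mask.flat[drop] = False
    while int(mask.sum()) < target:
        if mask.any():
            cand = np.flatnonzero(ndimage.binary_dilation(mask) & ~mask)
        else:
            cand = np.flatnonzero(~mask)
        deficit = target - int(mask.sum())
        add = rng.choice(cand, size=min(deficit, cand.size), replace=False)
        mask.flat[add] = True
    return mask


def render_histology_field(
    spec: ImageSpec,
    stain: StainModel | None = None,
    *,
    subject_id: str = "S000",
    region_name: str = "unspecified",
    field_index: int = 1,
) -> HistoField:
    """Render one synthetic AT8-like field with an exact truth mask.

    Tangle-like elliptical blobs and thread-like curvilinear neurites are
    placed at random until the positive area reaches the target; single
    boundary pixels are then trimmed or added so the realized fraction
    matches ``spec.target_positive_fraction`` exactly (to the nearest whole
    pixel). Deterministic given ``spec.seed``.
    """
    stain = stain or StainModel()
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)
    size = h * w
    target = int(round(spec.target_positive_fraction * size))

    mask = np.zeros((h, w), dtype=bool)
    if target == size:
        mask[:] = True
    elif target > 0:
        for _ in range(100_000):
            if int(mask.sum()) >= target:
                break
            if rng.random() < spec.tangle_vs_neurite_mix:
                rr, cc = _draw_tangle(rng, h, w)
            else:
                rr, cc = _draw_neurite(rng, h, w)
            mask[rr, cc] = True
        mask = _adjust_mask_to_count(mask, target, rng)

    scale = stain.per_subject_intensity_scale
    hema = 255.0 - scale * (255.0 - np.asarray(stain.hema_rgb_mean))
    dab = np.asarray(stain.dab_rgb_mean)
    img = np.where(mask[..., None], dab, hema)
    if stain.pixel_noise_sd > 0:
        img = img + rng.normal(0.0, stain.pixel_noise_sd, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return HistoField(
        pixels=pixels,
        subject_id=subject_id,
        region_name=region_name,
        field_index=field_index,
        truth_mask=mask,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    The SUVR mapping ``suvr = suvr_intercept + suvr_slope * burden_pct``
    (plus covariate effects, times multiplicative gamma noise with mean 1)
    places the temporal meta-ROI positivity cut-off of 1.36 at a composite
    burden of (1.36 - intercept) / slope = 0.85 %AT8 area under the
    defaults, which is the planted detection threshold the Youden analysis
    should recover.
    """

    n_subjects: int = 63
    region_list: tuple[str, ...] = DEFAULT_REGIONS
    susceptibility: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUSCEPTIBILITY)
    )
    # latent severity: mixture of a low mode (controls / PART) and a heavy
    # right tail (AD), in units of entorhinal % area
    severity_low_weight: float = 0.55
    severity_low_median: float = 0.06
    severity_low_sigma: float = 1.0
    severity_high_median: float = 2.5
    severity_high_sigma: float = 0.8
    severity_distribution: str = "mixture"  # or "uniform"
    severity_uniform_max: float = 5.0
    # SUVR model
    suvr_intercept: float = 1.02
    suvr_slope: float = 0.40
    suvr_noise_shape: float | None = 625.0  # gamma shape; None disables noise
    offtarget_suvr_mean: float = 1.30
    offtarget_suvr_sd: float = 0.15
    age_effect: float = -0.001  # SUVR units per year, centered at 80
    sex_effect: float = -0.02  # male offset
    interval_effect: float = 0.0  # per month PET-to-post-mortem
    # staging
    braak_anchor_regions: tuple[str, ...] = DEFAULT_BRAAK_ANCHORS
    braak_thresholds: tuple[float, ...] = DEFAULT_BRAAK_THRESHOLDS
    part_fraction: float = 0.20
    # histology rendering
    fields_per_region: int = 2
    image_size: int = 512
    intensity_scale_range: tuple[float, float] = (0.8, 1.3)
    stain_noise_sd: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not self.region_list:
            raise ValueError("region list must not be empty")
        if len(set(self.region_list)) != len(self.region_list):
            raise ValueError("region names must be unique")
        thr = np.asarray(self.braak_thresholds, dtype=float)
        if thr.size != 6 or not np.all(np.diff(thr) > 0):
            raise ValueError("braak_thresholds must be 6 strictly increasing values")
        if len(self.braak_anchor_regions) != 6:
            raise ValueError("six Braak anchor regions are required")
        for r in self.braak_anchor_regions:
            if r not in self.susceptibility or self.susceptibility[r] <= 0:
                raise ValueError(f"Braak anchor region {r!r} needs positive susceptibility")
        sev_cuts = thr / np.array([self.susceptibility[r] for r in self.braak_anchor_regions])
        if not np.all(np.diff(sev_cuts) > 0):
            raise ValueError("implied severity cutpoints must be strictly increasing")
        if self.suvr_slope < 0 or (
            self.suvr_noise_shape is not None and self.suvr_noise_shape <= 0
        ):
            raise ValueError("slope must be >= 0 and noise shape positive")
        if not 0.0 <= self.part_fraction <= 1.0:
            raise ValueError("part_fraction must lie in [0, 1]")
        if self.fields_per_region not in (1, 2, 3):
            raise ValueError("fields_per_region must be 1, 2 or 3")

    @property
    def severity_braak_cutpoints(self) -> np.ndarray:
        """Latent-severity values at which each Braak stage is reached."""
        thr = np.asarray(self.braak_thresholds, dtype=float)
        susc = np.array([self.susceptibility[r] for r in self.braak_anchor_regions])
        return thr / susc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["region_list"] = list(self.region_list)
        d["braak_anchor_regions"] = list(self.braak_anchor_regions)
        d["braak_thresholds"] = list(self.braak_thresholds)
        d["intensity_scale_range"] = list(self.intensity_scale_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("region_list", "braak_anchor_regions", "braak_thresholds",
                    "intensity_scale_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def linearity_demo(cls, n_subjects: int = 400, seed: int = 0) -> "CohortConfig":
        """Conditions for the stage-vs-sextile linearity comparison.

        Latent severity is uniform so that sextile means of burden are
        linear in sextile rank, while the geometric spacing of the Braak
        severity cutpoints makes burden (and hence SUVR) an exponential-like
        function of the stage code. Between-subject SUVR heterogeneity is
        larger here (CV about 20%, gamma shape 25), matching the substantial
        residual scatter around the burden trend in autopsy-PET cohorts, so
        that residual scatter rather than the burden sample's quantile
        wiggle dominates within sextiles.
        """
        return cls(
            n_subjects=n_subjects,
            severity_distribution="uniform",
            severity_uniform_max=5.0,
            suvr_noise_shape=25.0,
            part_fraction=0.0,
            age_effect=0.0,
            sex_effect=0.0,
            braak_anchor_regions=("entorhinal",) * 6,
            braak_thresholds=(0.05, 0.15, 0.4, 1.0, 2.2, 4.0),
            seed=seed,
        )


SUBJECT_COLUMNS = [
    "subject_id", "age", "sex_male", "pm_interval_months", "braak_stage",
    "thal_phase", "plaque_score", "adnc", "tdp_stage", "severity",
    "intensity_scale",
]
REGIONAL_COLUMNS = [
    "subject_id", "region", "region_class", "burden_pct", "roi_mean",
    "ref_mean", "suvr",
]


@dataclass
class Cohort:
    """Subject metadata plus long-format per subject x region table."""

    config: CohortConfig
    subjects: pd.DataFrame
    regional: pd.DataFrame

    def merged(self) -> pd.DataFrame:
        """Regional rows joined with subject-level covariates."""
        return self.regional.merge(self.subjects, on="subject_id", validate="m:1")

    def iter_histology_fields(
        self,
        subjects: Sequence[str] | None = None,
        regions: Sequence[str] | None = None,
        image_size: int | None = None,
    ) -> Iterator[HistoField]:
        """Lazily render histology fields whose planted fraction equals the
        generated regional burden. Rendering is deterministic per
        (seed, subject, region, field) so any subset reproduces exactly."""
        size = image_size or self.config.image_size
        subj_index = {s: i for i, s in enumerate(self.subjects["subject_id"])}
        reg_index = {r: i for i, r in enumerate(self.config.region_list)}
        scale = dict(zip(self.subjects["subject_id"], self.subjects["intensity_scale"]))
        rows = self.regional
        if subjects is not None:
            rows = rows[rows["subject_id"].isin(set(subjects))]
        if regions is not None:
            rows = rows[rows["region"].isin(set(regions))]
        for row in rows.itertuples(index=False):
            stain = StainModel(
                per_subject_intensity_scale=float(scale[row.subject_id]),
                pixel_noise_sd=self.config.stain_noise_sd,
            )
            for k in range(1, self.config.fields_per_region + 1):
                ss = np.random.SeedSequence(
                    self.config.seed,
                    spawn_key=(7, subj_index[row.subject_id], reg_index[row.region], k),
                )
                spec = ImageSpec(
                    width=size,
                    height=size,
                    target_positive_fraction=min(1.0, row.burden_pct / 100.0),
                    seed=int(ss.generate_state(1)[0]),
                )
                yield render_histology_field(
                    spec, stain,
                    subject_id=row.subject_id,
                    region_name=row.region,
                    field_index=k,
                )


def _draw_severity(cfg: CohortConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if cfg.severity_distribution == "uniform":
        return rng.uniform(0.0, cfg.severity_uniform_max, n)
    low = rng.random(n) < cfg.severity_low_weight
    sev = np.where(
        low,
        rng.lognormal(np.log(cfg.severity_low_median), cfg.severity_low_sigma, n),
        rng.lognormal(np.log(cfg.severity_high_median), cfg.severity_high_sigma, n),
    )
    return sev


def _braak_stage(cfg: CohortConfig, severity: np.ndarray) -> np.ndarray:
    cuts = cfg.severity_braak_cutpoints
    return np.searchsorted(cuts, severity, side="right").astype(int)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the synthetic cohort tables (images are rendered lazily).

    Per subject a latent severity is drawn; regional burden is severity
    times the region's susceptibility (off-target and cerebellar regions get
    a near-zero, severity-independent floor); Braak stage is assigned by
    thresholding anchor-region burdens; amyloid-linked labels (Thal phase,
    neuritic plaque score, ADNC) track severity except in forced-PART
    subjects; on-target SUVR is an affine function of burden with covariate
    effects and multiplicative gamma noise; off-target SUVR is drawn
    independently of local burden.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    n = cfg.n_subjects

    severity = _draw_severity(cfg, rng, n)
    cuts = cfg.severity_braak_cutpoints

    # PART subjects: tau present but capped at Braak IV, low amyloid
    is_part = rng.random(n) < cfg.part_fraction
    lo, hi = cuts[0], cuts[4]
    part_sev = np.exp(rng.uniform(np.log(lo * 1.05), np.log(hi * 0.95), n))
    severity = np.where(is_part, part_sev, severity)

    braak = _braak_stage(cfg, severity)

    age = np.clip(rng.normal(80.0, 8.0, n), 55.0, 100.0).round(1)
    sex_male = (rng.random(n) < 0.5).astype(int)
    interval = rng.uniform(1.0, 30.0, n).round(1)
    intensity_scale = rng.uniform(*cfg.intensity_scale_range, n).round(3)

    # amyloid latent tracks severity except in PART
    abeta = severity * rng.lognormal(0.0, 0.5, n)
    thal = np.searchsorted([0.05, 0.15, 0.4, 1.0, 2.5], abeta).astype(int)
    part_thal = rng.choice([0, 1, 2], size=n, p=[0.4, 0.3, 0.3])
    thal = np.where(is_part, part_thal, thal)
    plaque = np.searchsorted([0.1, 0.5, 1.5], abeta).astype(int)
    plaque = np.where(is_part, np.minimum(plaque, 1), plaque)

    thal_bin = np.select([thal == 0, thal < 3, thal < 5], [0, 1, 2], default=3)
    braak_bin = np.select([braak == 0, braak <= 2, braak <= 4], [0, 1, 2], default=3)
    adnc = np.rint((thal_bin + braak_bin + plaque) / 3.0).astype(int)

    p_tdp = np.clip((age - 65.0) / 60.0, 0.0, 0.6)
    has_tdp = rng.random(n) < p_tdp
    tdp = np.where(has_tdp, rng.integers(1, 7, n), 0)

    subject_ids = [f"S{i + 1:03d}" for i in range(n)]
    subjects = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age": age,
            "sex_male": sex_male,
            "pm_interval_months": interval,
            "braak_stage": braak,
            "thal_phase": thal,
            "plaque_score": plaque,
            "adnc": adnc,
            "tdp_stage": tdp,
            "severity": severity,
            "intensity_scale": intensity_scale,
        },
        columns=SUBJECT_COLUMNS,
    )

    records = []
    ref_mean = np.clip(rng.normal(1.0, 0.08, n), 0.5, None)
    for region in cfg.region_list:
        susc = cfg.susceptibility.get(region, 0.0)
        if region == REFERENCE_REGION:
            region_class = "reference"
            burden = np.zeros(n)
            suvr = np.clip(rng.normal(1.0, 0.02, n), 0.5, None)
        elif region in OFF_TARGET_REGIONS or susc == 0.0:
            region_class = "off_target"
            burden = rng.uniform(0.0, 0.02, n)
            suvr = np.clip(
                rng.normal(cfg.offtarget_suvr_mean, cfg.offtarget_suvr_sd, n), 0.3, None
            )
        else:
            region_class = "on_target"
            burden = np.minimum(severity * susc, 40.0)
            mu = (
                cfg.suvr_intercept
                + cfg.suvr_slope * burden
                + cfg.age_effect * (age - 80.0)
                + cfg.sex_effect * sex_male
                + cfg.interval_effect * interval
            )
            mu = np.clip(mu, 0.2, None)
            if cfg.suvr_noise_shape is not None:
                k = cfg.suvr_noise_shape
                suvr = mu * rng.gamma(k, 1.0 / k, n)
            else:
                suvr = mu
        records.append(
            pd.DataFrame(
                {
                    "subject_id": subject_ids,
                    "region": region,
                    "region_class": region_class,
                    "burden_pct": np.round(burden, 6),
                    "roi_mean": np.round(suvr * ref_mean, 6),
                    "ref_mean": np.round(ref_mean, 6),
                    "suvr": np.round(suvr, 6),
                }
            )
        )
    regional = pd.concat(records, ignore_index=True)[REGIONAL_COLUMNS]
    return Cohort(config=cfg, subjects=subjects, regional=regional)


def _write_mask_png(mask: np.ndarray, path: Path) -> None:
    Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(path)


def write_fixture_set(
    cohort: Cohort,
    directory: str | Path,
    *,
    images: bool = True,
    image_subjects: Sequence[str] | None = None,
    image_regions: Sequence[str] | None = None,
    image_size: int | None = None,
) -> dict:
    """Write tables, config, optional images/masks, and a JSON manifest.

    Returns the manifest. Tables round-trip byte-identically through
    :func:`load_fixture_set` followed by a second write.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    subjects_path = directory / "subjects.csv"
    regional_path = directory / "regional.csv"
    cohort.subjects.to_csv(subjects_path, index=False, lineterminator="\n")
    cohort.regional.to_csv(regional_path, index=False, lineterminator="\n")
    files += ["subjects.csv", "regional.csv"]

    config_path = directory / "config.yaml"
    config_path.write_text(yaml.safe_dump(cohort.config.to_dict(), sort_keys=True))
    files.append("config.yaml")

    image_entries = []
    if images:
        (directory / "images").mkdir(exist_ok=True)
        (directory / "masks").mkdir(exist_ok=True)
        for fld in cohort.iter_histology_fields(
            subjects=image_subjects, regions=image_regions, image_size=image_size
        ):
            stem = f"{fld.subject_id}_{fld.region_name}_f{fld.field_index}"
            img_rel = f"images/{stem}.png"
            msk_rel = f"masks/{stem}_mask.png"
            Image.fromarray(fld.pixels, mode="RGB").save(directory / img_rel)
            _write_mask_png(fld.truth_mask, directory / msk_rel)
            image_entries.append(
                {
                    "image": img_rel,
                    "mask": msk_rel,
                    "subject_id": fld.subject_id,
                    "region": fld.region_name,
                    "field_index": fld.field_index,
                    "truth_fraction": fld.truth_fraction,
                }
            )

    manifest = {
        "seed": cohort.config.seed,
        "config_hash": cohort.config.config_hash(),
        "tables": files,
        "images": image_entries,
        "n_subjects": int(len(cohort.subjects)),
        "n_regions": len(cohort.config.region_list),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _require_columns(df: pd.DataFrame, required: Sequence[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing required column(s): {', '.join(missing)}")


def load_fixture_set(directory: str | Path) -> Cohort:
    """Reload a fixture directory written by :func:`write_fixture_set`."""
    directory = Path(directory)
    config = CohortConfig.from_dict(yaml.safe_load((directory / "config.yaml").read_text()))
    subjects = pd.read_csv(directory / "subjects.csv")
    regional = pd.read_csv(directory / "regional.csv")
    _require_columns(subjects, SUBJECT_COLUMNS, "subjects.csv")
    _require_columns(regional, REGIONAL_COLUMNS, "regional.csv")
    return Cohort(config=config, subjects=subjects, regional=regional)
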