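"""Percent AT8-positive area from RGB histology fields.

Two quantification routes are provided, mirroring a manual-thresholding
workflow and its automated cross-check:

* **threshold** — a red-green counterstain-suppression score
  ``s = max(0, R - G)`` is computed per pixel (high for brown DAB
  chromogen, near zero for the blue-purple hematoxylin counterstain and
  white background), a single per-subject threshold is fitted from the
  pooled score distribution, and pixels at or above it are counted.
* **graphcut** — pixels with red channel above a cutoff are set to white,
  the image is converted to grayscale, and a binary Markov-random-field
  segmentation (two-class Gaussian likelihood unary term, contrast-weighted
  Potts smoothness term) is solved exactly by s-t minimum cut.

Regional percent positive area is the arithmetic mean over the 1-3 fields
sampled for that subject and region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.filters import threshold_otsu

from .graphcut import grid_edges, labeling_energy, solve_binary_mrf
from .synthetic import HistoField

__all__ = [
    "SegmentationResult",
    "GraphCutParams",
    "RegionalPathology",
    "suppress_counterstain",
    "fit_subject_threshold",
    "threshold_quant",
    "graphcut_quant",
    "regional_pct",
    "quantify_cohort_fields",
    "load_field_png",
]

DEFAULT_THRESHOLD_FLOOR = 25.0
DEFAULT_THRESHOLD_CEILING = 240.0


@dataclass
class SegmentationResult:
    """Binary pathology mask plus the derived percent positive area."""

    mask: np.ndarray
    positive_fraction_pct: float
    method: Literal["threshold", "graphcut"]
    threshold_value: float | None = None
    energy: float | None = None
    subject_id: str | None = None
    region_name: str | None = None
    field_index: int | None = None

    def __post_init__(self) -> None:
        expected = 100.0 * float(self.mask.sum()) / self.mask.size
        if self.positive_fraction_pct != expected:
            raise ValueError("positive_fraction_pct inconsistent with mask")


@dataclass(frozen=True)
class GraphCutParams:
    """Parameters of the MRF segmentation.

    ``red_cutoff`` follows the pre-processing rule that pixels with red
    intensity strictly above the cutoff are set to white before grayscale
    conversion. ``unary_model`` is either ``"auto"`` (two-class Gaussian
    initialized from an Otsu split of the grayscale image) or an explicit
    ``((mu_bg, sd_bg), (mu_fg, sd_fg))`` pair.
    """

    red_cutoff: int = 100
    lambda_smooth: float = 2.0
    sigma_contrast: float | None = None  # None: mean absolute neighbor difference
    connectivity: Literal[4, 8] = 4
    unary_model: str | tuple = "auto"

    def __post_init__(self) -> None:
        if not 0 <= self.red_cutoff <= 255:
            raise ValueError("red_cutoff must lie in [0, 255]")
        if self.lambda_smooth < 0:
            raise ValueError("lambda_smooth must be non-negative")
        if self.sigma_contrast is not None and self.sigma_contrast <= 0:
            raise ValueError("sigma_contrast must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class RegionalPathology:
    """Mean percent positive area over the fields of one subject-region."""

    subject_id: str
    region_name: str
    pct_at8: float
    n_fields: int
    method: str


def _as_rgb_array(image: HistoField | np.ndarray) -> np.ndarray:
    pixels = image.pixels if isinstance(image, HistoField) else np.asarray(image)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    return pixels


def suppress_counterstain(image: HistoField | np.ndarray) -> np.ndarray:
    """Per-pixel stain score s = max(0, R - G), in 8-bit units.

    The score is high for DAB brown (red well above green) and near zero for
    the hematoxylin counterstain (red close to green) and white background.
    """
    pixels = _as_rgb_array(image).astype(np.int16)
    score = np.clip(pixels[..., 0] - pixels[..., 1], 0, 255)
    return score.astype(np.uint8)


def fit_subject_threshold(
    score_maps: Sequence[np.ndarray],
    *,
    floor: float = DEFAULT_THRESHOLD_FLOOR,
    ceiling: float = DEFAULT_THRESHOLD_CEILING,
    k: float = 4.0,
    strategy: Literal["background_tail", "otsu"] = "background_tail",
) -> float:
    """One reproducible stain-score threshold per subject.

    The default ``background_tail`` strategy models the pooled score
    distribution's dominant (counterstain) mode robustly and places the
    threshold ``k`` robust standard deviations above it:
    ``median + k * 1.4826 * MAD``. This emulates choosing the level at which
    diffuse background disappears while tangles and neurites remain, and it
    tracks between-subject staining intensity. The ``otsu`` strategy applies
    Otsu's criterion to the pooled histogram instead. Either way the result
    is clamped to ``[floor, ceiling]``.
    """
    maps = [np.asarray(m).ravel() for m in score_maps]
    if not maps:
        raise ValueError("at least one score map is required")
    pooled = np.concatenate(maps).astype(float)
    if pooled.max() == pooled.min():
        return float(floor)
    if strategy == "background_tail":
        med = float(np.median(pooled))
        mad = float(np.median(np.abs(pooled - med)))
        # half-bin guard: scores are 8-bit quantized, so the raw MAD
        # underestimates the spread of a narrow background mode
        s0 = 1.4826 * mad + 0.5 if mad > 0 else float(pooled.std())
        trimmed = pooled[pooled <= med + 4.0 * s0]
        t = float(trimmed.mean()) + k * float(trimmed.std())
    elif strategy == "otsu":
        counts, bin_edges = np.histogram(pooled, bins=256, range=(0, 256))
        centers = (bin_edges[:-1] + bin_edges[1:]) / 2.0
        t = float(threshold_otsu(hist=(counts, centers)))
    else:
        raise ValueError(f"unknown threshold strategy {strategy!r}")
    return float(min(max(t, floor), ceiling))


def _result_tags(image: HistoField | np.ndarray) -> dict:
    if isinstance(image, HistoField):
        return {
            "subject_id": image.subject_id,
            "region_name": image.region_name,
            "field_index": image.field_index,
        }
    return {}


def threshold_quant(
    image: HistoField | np.ndarray, threshold_value: float
) -> SegmentationResult:
    """Counterstain-suppressed intensity thresholding.

    The mask keeps pixels whose stain score is at or above the threshold;
    the reported percentage is exactly 100 * (mask pixels) / (all pixels).
    """
    if not 0 <= threshold_value <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    score = suppress_counterstain(image)
    mask = score >= threshold_value
    pct = 100.0 * float(mask.sum()) / mask.size
    return SegmentationResult(
        mask=mask,
        positive_fraction_pct=pct,
        method="threshold",
        threshold_value=float(threshold_value),
        **_result_tags(image),
    )


def _preprocess_graphcut(pixels: np.ndarray, red_cutoff: int) -> np.ndarray:
    """White-out high-red pixels, then integer-luma grayscale."""
    img = pixels.astype(float).copy()
    high_red = pixels[..., 0] > red_cutoff  # strict: ties at the cutoff are kept
    img[high_red] = 255.0
    gray = np.rint(0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2])
    return gray.astype(np.int32)


def _two_class_gaussians(
    gray: np.ndarray, unary_model: str | tuple
) -> tuple[tuple[float, float], tuple[float, float]] | None:
    """((mu_bg, sd_bg), (mu_fg, sd_fg)); None if no foreground evidence.

    Foreground is the darker class (chromogen is dark; whitened background
    is bright). Standard deviations are floored at 0.5 gray levels.
    """
    if unary_model != "auto":
        (mu0, sd0), (mu1, sd1) = unary_model
        return (float(mu0), max(float(sd0), 0.5)), (float(mu1), max(float(sd1), 0.5))
    vals = gray.ravel().astype(float)
    if vals.max() == vals.min():
        return None
    t = threshold_otsu(vals)
    fg = vals[vals <= t]
    bg = vals[vals > t]
    if fg.size == 0 or bg.size == 0:
        return None
    return (
        (float(bg.mean()), max(float(bg.std()), 0.5)),
        (float(fg.mean()), max(float(fg.std()), 0.5)),
    )


_UNARY_CLAMP = 1.0e4


def _gaussian_unary(gray: np.ndarray, mu: float, sd: float) -> np.ndarray:
    u = 0.5 * ((gray.astype(float) - mu) / sd) ** 2 + np.log(sd)
    return np.minimum(u, _UNARY_CLAMP)


def graphcut_quant(
    image: HistoField | np.ndarray, params: GraphCutParams | None = None
) -> SegmentationResult:
    """MRF segmentation of pathology from background, solved exactly.

    Pre-processing sets pixels with red channel above ``params.red_cutoff``
    to white and converts to grayscale. The binary labeling then minimizes

        E(L) = sum_p U_p(L_p)
             + lambda * sum_{(p,q)} exp(-(I_p - I_q)^2 / (2 sigma^2)) [L_p != L_q]

    with U the negative log-likelihood of a two-class Gaussian intensity
    model. The global optimum is found by s-t minimum cut. A degenerate
    single-intensity image yields an all-background labeling with a warning.
    """
    params = params or GraphCutParams()
    pixels = _as_rgb_array(image)
    gray = _preprocess_graphcut(pixels, params.red_cutoff)
    h, w = gray.shape

    model = _two_class_gaussians(gray, params.unary_model)
    if model is None:
        warnings.warn(
            "degenerate single-intensity image: returning all-background labeling",
            stacklevel=2,
        )
        mask = np.zeros((h, w), dtype=bool)
        return SegmentationResult(
            mask=mask,
            positive_fraction_pct=0.0,
            method="graphcut",
            energy=None,
            **_result_tags(image),
        )
    (mu_bg, sd_bg), (mu_fg, sd_fg) = model
    unary_bg = _gaussian_unary(gray, mu_bg, sd_bg)
    unary_fg = _gaussian_unary(gray, mu_fg, sd_fg)

    p, q = grid_edges(h, w, params.connectivity)
    flat = gray.ravel().astype(float)
    diff = flat[p] - flat[q]
    sigma = params.sigma_contrast
    if sigma is None:
        sigma = float(np.abs(diff).mean())
        if sigma <= 0:
            sigma = 1.0
    weights = params.lambda_smooth * np.exp(-(diff**2) / (2.0 * sigma**2))

    labels, energy = solve_binary_mrf(
        unary_bg.ravel(), unary_fg.ravel(), (p, q), weights
    )
    mask = labels.reshape(h, w)
    pct = 100.0 * float(mask.sum()) / mask.size
    return SegmentationResult(
        mask=mask,
        positive_fraction_pct=pct,
        method="graphcut",
        energy=energy,
        **_result_tags(image),
    )


def graphcut_energy_of_mask(
    image: HistoField | np.ndarray, mask: np.ndarray, params: GraphCutParams | None = None
) -> float:
    """Energy of an arbitrary labeling under the graph-cut model of ``image``."""
    params = params or GraphCutParams()
    pixels = _as_rgb_array(image)
    gray = _preprocess_graphcut(pixels, params.red_cutoff)
    model = _two_class_gaussians(gray, params.unary_model)
    if model is None:
        raise ValueError("degenerate image has no two-class model")
    (mu_bg, sd_bg), (mu_fg, sd_fg) = model
    h, w = gray.shape
    p, q = grid_edges(h, w, params.connectivity)
    flat = gray.ravel().astype(float)
    diff = flat[p] - flat[q]
    sigma = params.sigma_contrast
    if sigma is None:
        sigma = float(np.abs(diff).mean()) or 1.0
    weights = params.lambda_smooth * np.exp(-(diff**2) / (2.0 * sigma**2))
    return labeling_energy(
        mask, _gaussian_unary(gray, mu_bg, sd_bg).ravel(),
        _gaussian_unary(gray, mu_fg, sd_fg).ravel(), (p, q), weights,
    )


def regional_pct(fields: Sequence[SegmentationResult]) -> RegionalPathology:
    """Mean percent positive area over the 1-3 fields of one subject-region."""
    if not 1 <= len(fields) <= 3:
        raise ValueError("a region is sampled at 1-3 fields")
    subjects = {f.subject_id for f in fields}
    regions = {f.region_name for f in fields}
    methods = {f.method for f in fields}
    if len(subjects) > 1:
        raise ValueError(f"mixed subjects in one region aggregate: {sorted(subjects)}")
    if len(regions) > 1:
        raise ValueError(f"mixed regions in one aggregate: {sorted(map(str, regions))}")
    if len(methods) > 1:
        raise ValueError(f"mixed methods in one aggregate: {sorted(methods)}")
    return RegionalPathology(
        subject_id=fields[0].subject_id or "unknown",
        region_name=fields[0].region_name or "unknown",
        pct_at8=float(np.mean([f.positive_fraction_pct for f in fields])),
        n_fields=len(fields),
        method=fields[0].method,
    )


def load_field_png(path: str | Path, **tags) -> HistoField:
    """Read an 8-bit RGB PNG/TIFF into a :class:`HistoField`."""
    arr = np.asarray(Image.open(path).convert("RGB"))
    return HistoField(pixels=arr, **tags)


def quantify_cohort_fields(
    fields: Iterable[HistoField],
    method: Literal["threshold", "graphcut"] = "threshold",
    *,
    graphcut_params: GraphCutParams | None = None,
    threshold_floor: float = DEFAULT_THRESHOLD_FLOOR,
    threshold_ceiling: float = DEFAULT_THRESHOLD_CEILING,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify a stream of fields; returns (per-image, per-region) tables.

    For the threshold method a single threshold per subject is fitted from
    the pooled stain scores of all of that subject's fields, then applied to
    each field.
    """
    field_list = list(fields)
    per_image_rows = []
    results: dict[tuple[str, str], list[SegmentationResult]] = {}

    if method == "threshold":
        by_subject: dict[str, list[HistoField]] = {}
        for f in field_list:
            by_subject.setdefault(f.subject_id, []).append(f)
        thresholds = {
            s: fit_subject_threshold(
                [suppress_counterstain(f) for f in flds],
                floor=threshold_floor,
                ceiling=threshold_ceiling,
            )
            for s, flds in by_subject.items()
        }
        for f in field_list:
            res = threshold_quant(f, thresholds[f.subject_id])
            results.setdefault((f.subject_id, f.region_name), []).append(res)
    elif method == "graphcut":
        for f in field_list:
            res = graphcut_quant(f, graphcut_params)
            results.setdefault((f.subject_id, f.region_name), []).append(res)
    else:
        raise ValueError(f"unknown method {method!r}")

    for (subject, region), res_list in results.items():
        for res in res_list:
            per_image_rows.append(
                {
                    "subject_id": subject,
                    "region": region,
                    "field_index": res.field_index,
                    "method": res.method,
                    "threshold": res.threshold_value,
                    "pct_positive": res.positive_fraction_pct,
                }
            )
    regional_rows = [
        vars(regional_pct(res_list)) for res_list in results.values()
    ]
    per_image = pd.DataFrame(per_image_rows)
    regional = pd.DataFrame(regional_rows).rename(
        columns={"region_name": "region", "pct_at8": "pct_at8"}
    )
    return per_image, regional
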