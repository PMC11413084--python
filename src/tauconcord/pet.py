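"""SUVR computation, meta-ROI composition, and PET positivity calls.

A standardized uptake value ratio (SUVR) is the regional PET activity
divided by the activity of a reference region unaffected by the pathology
(here the inferior cerebellar cortex). Composite meta-ROIs are unweighted
arithmetic means of member-region SUVRs; bilateral members enter as a single
hemisphere-averaged value. Positivity uses fixed SUVR cut-offs: 1.36 for the
temporal composite and 1.19 for the larger cortical composite, with the
inclusive convention suvr >= cutoff -> positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MetaROIDefinition",
    "PositivityCall",
    "ReferenceRegionError",
    "TEMPORAL_CUTOFF",
    "CORTICAL_CUTOFF",
    "compute_suvr",
    "compose_meta_roi",
    "classify_positivity",
    "load_meta_roi",
    "meta_roi_table",
]

TEMPORAL_CUTOFF = 1.36
CORTICAL_CUTOFF = 1.19


class ReferenceRegionError(ValueError):
    """The reference-region mean is non-positive."""


@dataclass(frozen=True)
class MetaROIDefinition:
    """A named composite ROI: unique member regions with laterality tags."""

    name: str
    members: tuple[str, ...]
    laterality: tuple[str, ...]
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("meta-ROI must have at least one member")
        if len(set(self.members)) != len(self.members):
            raise ValueError("meta-ROI members must be unique")
        if len(self.laterality) != len(self.members):
            raise ValueError("one laterality tag per member is required")


@dataclass(frozen=True)
class PositivityCall:
    subject_id: str
    meta_roi_name: str
    suvr: float
    cutoff: float
    positive: bool


def load_meta_roi(name: str) -> MetaROIDefinition:
    """Load a shipped composite definition (``"temporal"`` or ``"cortical"``)."""
    payload = json.loads(
        resources.files("tauconcord.data").joinpath("meta_rois.json").read_text()
    )
    if name not in payload:
        raise KeyError(f"unknown meta-ROI {name!r}; available: {sorted(payload)}")
    entry = payload[name]
    return MetaROIDefinition(
        name=entry["name"],
        members=tuple(m["region"] for m in entry["members"]),
        laterality=tuple(m["laterality"] for m in entry["members"]),
        cutoff=entry.get("cutoff"),
    )


def compute_suvr(roi_mean, ref_mean):
    """SUVR = regional mean activity / reference-region mean activity.

    Accepts scalars or arrays; raises :class:`ReferenceRegionError` if any
    reference mean is non-positive.
    """
    roi = np.asarray(roi_mean, dtype=float)
    ref = np.asarray(ref_mean, dtype=float)
    if np.any(ref <= 0):
        raise ReferenceRegionError("reference-region mean must be positive")
    out = roi / ref
    return float(out) if out.ndim == 0 else out


def compose_meta_roi(
    suvrs: Mapping[str, float] | pd.Series, definition: MetaROIDefinition
) -> float:
    """Unweighted arithmetic mean of the member-region SUVRs."""
    missing = [m for m in definition.members if m not in suvrs]
    if missing:
        raise KeyError(
            f"meta-ROI {definition.name!r} missing member region(s): {', '.join(missing)}"
        )
    return float(np.mean([float(suvrs[m]) for m in definition.members]))


def classify_positivity(
    suvr: float,
    cutoff: float,
    *,
    subject_id: str = "unknown",
    meta_roi_name: str = "custom",
    inclusive: bool = True,
) -> PositivityCall:
    """PET positivity at a fixed cut-off (inclusive: suvr >= cutoff)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    positive = suvr >= cutoff if inclusive else suvr > cutoff
    return PositivityCall(
        subject_id=subject_id,
        meta_roi_name=meta_roi_name,
        suvr=float(suvr),
        cutoff=float(cutoff),
        positive=bool(positive),
    )


def meta_roi_table(
    regional: pd.DataFrame,
    definitions: list[MetaROIDefinition] | None = None,
    *,
    suvr_col: str = "suvr",
) -> pd.DataFrame:
    """Per-subject composite SUVRs and positivity calls from a long table.

    ``regional`` needs columns subject_id, region and ``suvr_col``. Returns
    one row per subject with ``<name>_suvr`` and ``<name>_positive`` columns
    for each composite definition.
    """
    if definitions is None:
        definitions = [load_meta_roi("temporal"), load_meta_roi("cortical")]
    wide = regional.pivot_table(
        index="subject_id", columns="region", values=suvr_col, aggfunc="mean"
    )
    out = pd.DataFrame(index=wide.index)
    for d in definitions:
        missing = [m for m in d.members if m not in wide.columns]
        if missing:
            raise KeyError(
                f"meta-ROI {d.name!r} missing member region(s): {', '.join(missing)}"
            )
        out[f"{d.name}_suvr"] = wide[list(d.members)].mean(axis=1)
        if d.cutoff is not None:
            out[f"{d.name}_positive"] = out[f"{d.name}_suvr"] >= d.cutoff
    return out.reset_index()
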