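"""Cohort interchange format: read, write, validate, and filter.

A cohort is a JSON document holding one record per patient: distributed
findings as polygon drawings in normalized template coordinates, lateralized
findings as (finding, side) pairs, viscero-visceral symptoms as flags, and
the final single-organ diagnosis. The format is schema validated (pydantic
models below; a static JSON-schema export ships in ``docs/cohort.schema.json``)
and deliberately resolution independent: drawings only meet a pixel grid when
rasterized against an atlas.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Any, Literal, Optional

import numpy as np
import pydantic
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import CohortValidationError, ContractError

log = logging.getLogger(__name__)

# Enumerated tokens ---------------------------------------------------------

DISTRIBUTED_SIGNS: tuple[str, ...] = (
    "spontaneous_pain",
    "allodynia",
    "superficial_hyperalgesia",
    "deep_hyperalgesia",
    "superficial_skin_resistance",
    "muscle_resistance",
    "defense",
    "asymmetric_hyperhidrosis",
    "piloerection",
    "vasomotor_changes",
    "zoster",
    "passive_movement_resistance",
)

LATERALIZED_FINDINGS: tuple[str, ...] = (
    "mydriasis",
    "glossy_eye",
    "eyelid_separation",
    "tense_facial_muscles",
    "asymmetric_posture",
    "reduced_respiration",
)

SYMPTOMS: tuple[str, ...] = (
    "nausea",
    "vomiting",
    "constipation",
    "diarrhea",
    "meteorism",
    "urinary_retention",
)

ORGANS: tuple[str, ...] = (
    "heart",
    "lungs",
    "stomach",
    "liver_gallbladder",
    "kidneys_ureters",
    "other",
    "multi",
    "undiagnosed",
)

#: The five organ groups that enter organ-specific analyses.
ANALYZABLE_ORGANS: tuple[str, ...] = ORGANS[:5]

SignToken = Literal[DISTRIBUTED_SIGNS]  # type: ignore[valid-type]
LateralizedToken = Literal[LATERALIZED_FINDINGS]  # type: ignore[valid-type]
SymptomToken = Literal[SYMPTOMS]  # type: ignore[valid-type]
OrganToken = Literal[ORGANS]  # type: ignore[valid-type]


# Records -------------------------------------------------------------------


class DrawingRecord(BaseModel):
    """One distributed finding drawn on one template view.

    ``polygons`` is a list of closed polygons, each an ordered vertex list
    of (x, y) pairs in normalized [0, 1] x [0, 1] template coordinates.
    """

    sign: SignToken
    view: Literal["front", "back"]
    polygons: list[list[tuple[float, float]]]

    @field_validator("polygons")
    @classmethod
    def _check_polygons(cls, polys):
        for k, poly in enumerate(polys):
            if len(poly) < 3:
                raise ValueError(f"polygon {k} has {len(poly)} vertices; need >= 3")
            for xy in poly:
                if not (0.0 <= xy[0] <= 1.0 and 0.0 <= xy[1] <= 1.0):
                    raise ValueError(f"polygon {k} vertex {xy} outside [0,1]x[0,1]")
        return polys


class LateralizedFinding(BaseModel):
    finding: LateralizedToken
    side: Literal["left", "right"]


class PatientRecord(BaseModel):
    """One patient: drawings, lateralized findings, symptoms, diagnosis.

    Demographics are optional; the statistics only need ``id`` and
    ``organ``.
    """

    id: str
    organ: OrganToken
    drawings: list[DrawingRecord] = Field(default_factory=list)
    lateralized: list[LateralizedFinding] = Field(default_factory=list)
    symptoms: list[SymptomToken] = Field(default_factory=list)
    age: Optional[float] = None
    sex: Optional[Literal["female", "male"]] = None

    @field_validator("symptoms")
    @classmethod
    def _unique_symptoms(cls, v):
        if len(set(v)) != len(v):
            raise ValueError("duplicate symptom tokens")
        return v


class Cohort(BaseModel):
    """A list of patient records plus provenance metadata."""

    patients: list[PatientRecord]
    meta: dict[str, Any] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _unique_ids(self):
        ids = [p.id for p in self.patients]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids: {dup}")
        return self

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)


# IO ------------------------------------------------------------------------


def _validate_patients(raw_patients: list[dict]) -> list[PatientRecord]:
    patients = []
    for k, raw in enumerate(raw_patients):
        pid = raw.get("id", f"<record {k}>") if isinstance(raw, dict) else f"<record {k}>"
        try:
            patients.append(PatientRecord.model_validate(raw))
        except pydantic.ValidationError as err:
            first = err.errors()[0]
            loc = ".".join(str(p) for p in first["loc"]) or "<record>"
            raise CohortValidationError(
                f"patient {pid!r}, field {loc!r}: {first['msg']}"
            ) from err
    return patients


def read_cohort(path: str | Path) -> Cohort:
    """Read and validate a cohort JSON file.

    Raises :class:`CohortValidationError` naming the offending patient id
    and field on any schema violation.
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    if not isinstance(doc, dict) or "patients" not in doc:
        raise CohortValidationError(f"{path}: not a cohort document (no 'patients' key)")
    patients = _validate_patients(doc["patients"])
    cohort = Cohort(patients=patients, meta=doc.get("meta", {}))
    if not cohort.patients:
        warnings.warn(f"{path}: cohort is empty", stacklevel=2)
    cohort.meta.setdefault("source", str(path))
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort as JSON; writing then reading reproduces the cohort."""
    path = Path(path)
    meta = {k: v for k, v in cohort.meta.items() if k != "source"}
    doc = {"meta": meta, "patients": [p.model_dump(mode="json") for p in cohort.patients]}
    path.write_text(json.dumps(doc, indent=1))
    return path


def validate_cohort(cohort: Cohort) -> Cohort:
    """Re-run full schema validation on an in-memory cohort."""
    return Cohort(
        patients=_validate_patients([p.model_dump() for p in cohort.patients]),
        meta=dict(cohort.meta),
    )


# Cohort selection ----------------------------------------------------------


def select_single_organ(cohort: Cohort, min_per_organ: int = 4) -> Cohort:
    """Apply the single-organ selection filter.

    Retains patients whose diagnosis falls in one of the five analyzable
    organ groups (heart, lungs, stomach, liver/gallbladder, kidneys/ureters)
    and drops any organ group with fewer than ``min_per_organ`` patients.
    Retained/dropped counts are logged and recorded in ``meta['selection']``.
    An empty result is a warning, not an error.
    """
    if min_per_organ < 1:
        raise ContractError("min_per_organ must be >= 1")
    counts: dict[str, int] = {}
    for p in cohort.patients:
        counts[p.organ] = counts.get(p.organ, 0) + 1
    kept_organs = {
        o for o in ANALYZABLE_ORGANS if counts.get(o, 0) >= min_per_organ
    }
    kept = [p for p in cohort.patients if p.organ in kept_organs]
    dropped = len(cohort.patients) - len(kept)
    log.info(
        "single-organ selection: retained %d, dropped %d (organ groups kept: %s)",
        len(kept), dropped, sorted(kept_organs),
    )
    if not kept:
        warnings.warn("single-organ selection produced an empty cohort", stacklevel=2)
    meta = dict(cohort.meta)
    meta["selection"] = {
        "min_per_organ": min_per_organ,
        "retained": len(kept),
        "dropped": dropped,
        "organ_groups": sorted(kept_organs),
    }
    return Cohort(patients=kept, meta=meta)


# Mask serialization --------------------------------------------------------


def export_mask_nifti(mask, path: str | Path) -> Path:
    """Write a binary body map as an unsigned 8-bit NIfTI volume.

    ``mask`` is either an object with ``front``/``back`` 2-D arrays (a
    :class:`~segmaps.rasterize.BinaryBodyMap`) or a (rows, cols, 2) array.
    Front and back views are the two slices along the last axis; the affine
    is identity. Values must be binary.
    """
    import nibabel as nib

    if hasattr(mask, "front") and hasattr(mask, "back"):
        vol = np.stack([np.asarray(mask.front), np.asarray(mask.back)], axis=-1)
    else:
        vol = np.asarray(mask)
    if vol.ndim != 3 or vol.shape[-1] != 2:
        raise ContractError(f"expected (rows, cols, 2) mask volume, got {vol.shape}")
    if not np.isin(vol, (0, 1)).all():
        raise ContractError("mask is not binary")
    nib.save(nib.Nifti1Image(vol.astype(np.uint8), np.eye(4)), str(Path(path)))
    return Path(path)


def load_mask_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a mask written by :func:`export_mask_nifti` as (front, back)."""
    import nibabel as nib

    vol = np.asarray(nib.load(str(path)).dataobj).astype(np.uint8)
    if vol.ndim != 3 or vol.shape[-1] != 2:
        raise ContractError(f"{path}: expected (rows, cols, 2) volume, got {vol.shape}")
    return vol[..., 0], vol[..., 1]


def export_schema(path: str | Path) -> Path:
    """Write the cohort JSON schema document for external consumers."""
    path = Path(path)
    path.write_text(json.dumps(Cohort.model_json_schema(), indent=1))
    return path
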