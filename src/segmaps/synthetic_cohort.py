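"""Synthetic patient cohorts with known segmental ground truth.

No patient-level dataset accompanies the study this package models, so this
generator emulates its statistical structure: organ-specific segmental
spans, the Hansen–Schliack side rule (segmental signs ipsilateral to the
affected organ), cohort-wide sign/symptom prevalences, and spontaneous pain
distributed along the body midline. Every generated cohort carries its
ground truth (which segments, sides, and coverage fractions were drawn per
sign) so parameter-recovery tests can close the loop through the full
rasterization and statistics pipeline.

Generative model per patient:

* the organ group is assigned from the cohort mix (single-organ groups plus
  the undiagnosed / multi-organ / other strata of the recruitment flow;
  patients outside the five analyzable groups still present findings, drawn
  from a hidden profile sampled uniformly among the five organs);
* each distributed sign is present independently with its prevalence; a
  present sign is drawn as rectangles covering a sampled fraction of a
  contiguous run of half segments inside the organ's span, on the
  ipsilateral half with the side-rule probability (default 0.85), on both
  template views;
* spontaneous pain is a midline-straddling rectangle over the organ's pain
  segments, also on both views;
* lateralized findings (mydriasis etc.) are present with their prevalence
  and placed ipsilateral with a per-organ probability;
* paired organs (lungs, kidneys/ureters) sample an affected side, bilateral
  with a configurable probability, and signs follow the affected side.

All randomness flows from one seed; per-patient substreams are derived
deterministically, so identical specs give bit-identical cohorts.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .atlas import (
    SEGMENT_INDEX,
    segment_band,
    segment_half_width,
    segment_range,
    template_x_interval,
)
from .drawings_io import (
    DISTRIBUTED_SIGNS,
    LATERALIZED_FINDINGS,
    ORGANS,
    SYMPTOMS,
    Cohort,
    DrawingRecord,
    LateralizedFinding,
    PatientRecord,
)
from .errors import ContractError

# ---------------------------------------------------------------------------
# Study-level defaults
# ---------------------------------------------------------------------------

#: Cohort-wide prevalences (fractions of the 110-patient single-organ
#: sample). The study reports only these marginals, not per-organ rates, so
#: every organ profile reuses them — a documented modeling convenience.
SIGN_PREVALENCE: dict[str, float] = {
    "superficial_hyperalgesia": 46 / 110,
    "muscle_resistance": 39 / 110,
    "defense": 13 / 110,
    "deep_hyperalgesia": 13 / 110,
    "superficial_skin_resistance": 12 / 110,
    "vasomotor_changes": 10 / 110,
    "allodynia": 2 / 110,
    "piloerection": 1 / 110,
    "asymmetric_hyperhidrosis": 1 / 110,
    "zoster": 0.0,
    "passive_movement_resistance": 0.0,
}

LATERALIZED_PREVALENCE: dict[str, float] = {
    "mydriasis": 37 / 110,
    "tense_facial_muscles": 11 / 110,
    "glossy_eye": 8 / 110,
    "eyelid_separation": 0.0,
    "asymmetric_posture": 7 / 110,
    "reduced_respiration": 3 / 110,
}

SYMPTOM_PREVALENCE: dict[str, float] = {
    "nausea": 45 / 110,
    "vomiting": 18 / 110,
    "diarrhea": 10 / 110,
    "meteorism": 8 / 110,
    "constipation": 5 / 110,
    "urinary_retention": 0.0,
}

PAIN_PREVALENCE: float = 85 / 110

#: Recruitment-flow composition: 110 single-organ patients (heart and
#: liver/gallbladder group sizes recoverable from the printed mydriasis
#: counts and percentages; the remaining single-organ groups are plausible
#: splits summing to 110) plus undiagnosed, multi-organ, and
#: other-single-organ strata, totalling 208.
DEFAULT_ORGAN_COUNTS: dict[str, int] = {
    "heart": 62,
    "lungs": 18,
    "stomach": 10,
    "liver_gallbladder": 12,
    "kidneys_ureters": 8,
    "undiagnosed": 50,
    "multi": 39,
    "other": 9,
}
DEFAULT_N = sum(DEFAULT_ORGAN_COUNTS.values())  # 208


# ---------------------------------------------------------------------------
# Spec
# ---------------------------------------------------------------------------


class OrganProfile(BaseModel):
    """Generative parameters for one organ group."""

    organ: str
    span: list[str]
    span_max: list[str]
    ipsilateral: str  # "left", "right", or "both" for paired organs
    side_rule_p: float = 0.85
    bilateral_p: float = 0.0
    mydriasis_ipsi_p: float = 0.85
    sign_prevalence: dict[str, float] = Field(default_factory=lambda: dict(SIGN_PREVALENCE))
    lateralized_prevalence: dict[str, float] = Field(
        default_factory=lambda: dict(LATERALIZED_PREVALENCE)
    )
    symptom_prevalence: dict[str, float] = Field(
        default_factory=lambda: dict(SYMPTOM_PREVALENCE)
    )
    pain_prevalence: float = PAIN_PREVALENCE
    pain_span: list[str] = Field(default_factory=list)
    pain_midline: bool = True

    @field_validator("ipsilateral")
    @classmethod
    def _side_token(cls, v):
        if v not in ("left", "right", "both"):
            raise ValueError(f"ipsilateral must be left/right/both, got {v!r}")
        return v

    @model_validator(mode="after")
    def _check(self):
        for seg in self.span + self.span_max + self.pain_span:
            if seg not in SEGMENT_INDEX:
                raise ValueError(f"unknown segment {seg!r}")
        if not set(self.span_max) <= set(self.span):
            raise ValueError("span_max must be a subset of span")
        probs = (
            [self.side_rule_p, self.bilateral_p, self.mydriasis_ipsi_p, self.pain_prevalence]
            + list(self.sign_prevalence.values())
            + list(self.lateralized_prevalence.values())
            + list(self.symptom_prevalence.values())
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        self.span.sort(key=SEGMENT_INDEX.__getitem__)
        self.span_max.sort(key=SEGMENT_INDEX.__getitem__)
        self.pain_span.sort(key=SEGMENT_INDEX.__getitem__)
        return self


class SyntheticSpec(BaseModel):
    """Full generative specification for one synthetic cohort."""

    profiles: dict[str, OrganProfile]
    organ_mix: dict[str, float]
    n: int = DEFAULT_N
    #: Distribution of the fraction of a target half segment a drawing
    #: fills: normal(coverage_mean, coverage_sd) clipped to
    #: [coverage_min, coverage_max].
    coverage_mean: float = 0.6
    coverage_sd: float = 0.15
    coverage_min: float = 0.3
    coverage_max: float = 0.95
    jitter_px: float = 0.5  # vertex noise, in pixels of the reference grid
    atlas_rows: int = 132  # reference grid used only to scale the jitter
    atlas_cols: int = 40
    seed: int = 0
    exact_mix: bool = True  # apportion organ counts exactly vs multinomial
    age_mean: float = 57.3
    age_sd: float = 17.2
    female_p: float = 85 / 208

    @model_validator(mode="after")
    def _check(self):
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if abs(sum(self.organ_mix.values()) - 1.0) > 1e-9:
            raise ValueError("organ mix must sum to 1")
        for organ in self.organ_mix:
            if organ not in ORGANS:
                raise ValueError(f"unknown organ {organ!r} in mix")
        missing = [
            o for o in self.organ_mix
            if o in ("heart", "lungs", "stomach", "liver_gallbladder", "kidneys_ureters")
            and o not in self.profiles
        ]
        if missing:
            raise ValueError(f"organ mix references organs without profiles: {missing}")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be >= 0")
        if not (0.0 < self.coverage_min <= self.coverage_max <= 1.0):
            raise ValueError("coverage bounds must satisfy 0 < min <= max <= 1")
        return self


def default_profiles() -> dict[str, OrganProfile]:
    """The five organ profiles with the study's spans and side rule.

    Heart: signs concentrated in T3-T5, left-sided. Lungs: widespread
    V2-L2, paired (often bilateral). Stomach: thoracic T2-T12 with a T6-T9
    maximum, left-sided. Liver/gallbladder: shoulder segments C3-C5 plus a
    thoracic block, right-sided, mydriasis fully ipsilateral. Kidneys/
    ureters: narrow T6-L2, paired. Spontaneous pain sits in midline
    segments of each span (epigastric T5-T9 for lungs/stomach/liver).
    """
    return {
        "heart": OrganProfile(
            organ="heart",
            span=segment_range("T3", "T5"),
            span_max=segment_range("T3", "T5"),
            ipsilateral="left",
            mydriasis_ipsi_p=0.83,
            pain_span=segment_range("T3", "T5"),
        ),
        "lungs": OrganProfile(
            organ="lungs",
            span=segment_range("V2", "L2"),
            span_max=segment_range("V2", "L2"),
            ipsilateral="both",
            bilateral_p=0.3,
            pain_span=segment_range("T5", "T9"),
        ),
        "stomach": OrganProfile(
            organ="stomach",
            span=segment_range("T2", "T12"),
            span_max=segment_range("T6", "T9"),
            ipsilateral="left",
            pain_span=segment_range("T6", "T9"),
        ),
        "liver_gallbladder": OrganProfile(
            organ="liver_gallbladder",
            span=segment_range("C3", "C5") + segment_range("T5", "T10"),
            span_max=segment_range("T7", "T8"),
            ipsilateral="right",
            mydriasis_ipsi_p=1.0,
            pain_span=segment_range("T5", "T9"),
        ),
        "kidneys_ureters": OrganProfile(
            organ="kidneys_ureters",
            span=segment_range("T6", "L2"),
            span_max=segment_range("T6", "L2"),
            ipsilateral="both",
            bilateral_p=0.3,
            pain_span=segment_range("T10", "L2"),
        ),
    }


def default_spec(n: int = DEFAULT_N, seed: int = 0, **overrides) -> SyntheticSpec:
    """The default study-like spec; keyword overrides replace spec fields."""
    mix = overrides.pop(
        "organ_mix", {o: c / DEFAULT_N for o, c in DEFAULT_ORGAN_COUNTS.items()}
    )
    profiles = overrides.pop("profiles", default_profiles())
    return SyntheticSpec(profiles=profiles, organ_mix=mix, n=n, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _apportion(n: int, mix: dict[str, float]) -> list[str]:
    """Largest-remainder apportionment of n patients over the mix."""
    organs = sorted(mix)
    raw = {o: n * mix[o] for o in organs}
    counts = {o: int(np.floor(raw[o])) for o in organs}
    short = n - sum(counts.values())
    by_rem = sorted(organs, key=lambda o: (-(raw[o] - counts[o]), o))
    for o in by_rem[:short]:
        counts[o] += 1
    out: list[str] = []
    for o in organs:
        out.extend([o] * counts[o])
    return out


def _contiguous_blocks(span: list[str]) -> list[list[str]]:
    blocks: list[list[str]] = []
    for seg in span:
        if blocks and SEGMENT_INDEX[seg] == SEGMENT_INDEX[blocks[-1][-1]] + 1:
            blocks[-1].append(seg)
        else:
            blocks.append([seg])
    return blocks


def _sample_run(block: list[str], anchor: list[str], rng: np.random.Generator) -> list[str]:
    """Contiguous sub-run of a block that always contains its anchor."""
    a0 = block.index(anchor[0])
    a1 = block.index(anchor[-1])
    start = int(rng.integers(0, a0 + 1))
    end = int(rng.integers(a1, len(block)))
    return block[start : end + 1]


def _jitter(xy: list[tuple[float, float]], spec: SyntheticSpec,
            rng: np.random.Generator) -> list[tuple[float, float]]:
    if spec.jitter_px == 0.0:
        return xy
    sx = spec.jitter_px / spec.atlas_cols
    sy = spec.jitter_px / spec.atlas_rows
    out = []
    for x, y in xy:
        out.append(
            (
                float(np.clip(x + rng.normal(0.0, sx), 0.0, 1.0)),
                float(np.clip(y + rng.normal(0.0, sy), 0.0, 1.0)),
            )
        )
    return out


def _rects_for_run(
    run: list[str], view: str, side: str, fraction: float
) -> list[list[tuple[float, float]]]:
    """Axis-aligned rectangles covering ``fraction`` of each half segment.

    The run is grouped into cranio-caudally contiguous stretches of equal
    band half-width (head vs trunk column); each group becomes one rectangle
    anchored at the midline on the requested subject side, or straddling the
    midline symmetrically for ``side='both'``.
    """
    rects = []
    groups: list[list[str]] = []
    for seg in run:
        if (
            groups
            and segment_half_width(groups[-1][-1]) == segment_half_width(seg)
            and SEGMENT_INDEX[seg] == SEGMENT_INDEX[groups[-1][-1]] + 1
        ):
            groups[-1].append(seg)
        else:
            groups.append([seg])
    for group in groups:
        bands = [segment_band(seg, view) for seg in group]
        y0 = min(b[0] for b in bands if b is not None)
        y1 = max(b[1] for b in bands if b is not None)
        hw = segment_half_width(group[0])
        if side == "both":
            x0, x1 = 0.5 - fraction * hw, 0.5 + fraction * hw
        else:
            a, b = template_x_interval(view, side, hw)
            if a == 0.5:  # template-right half: grow outward from midline
                x0, x1 = 0.5, 0.5 + fraction * hw
            else:  # template-left half
                x0, x1 = 0.5 - fraction * hw, 0.5
        rects.append([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
    return rects


def _opposite(side: str) -> str:
    return "right" if side == "left" else "left"


def _sample_fraction(spec: SyntheticSpec, rng: np.random.Generator) -> float:
    f = rng.normal(spec.coverage_mean, spec.coverage_sd)
    return float(np.clip(f, spec.coverage_min, spec.coverage_max))


def generate(spec: SyntheticSpec) -> tuple[Cohort, dict]:
    """Generate a cohort and its ground truth from a spec.

    Returns ``(cohort, truth)`` where ``truth`` maps patient ids to the
    drawn sign runs (segments, side, coverage fraction), symptom sets,
    lateralized findings, and — for patients outside the five analyzable
    groups — the hidden organ profile that produced their findings.
    """
    if not isinstance(spec, SyntheticSpec):
        raise ContractError("generate() expects a SyntheticSpec")
    master = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    if spec.exact_mix:
        assignment = _apportion(spec.n, spec.organ_mix)
    else:
        organs = sorted(spec.organ_mix)
        probs = np.array([spec.organ_mix[o] for o in organs])
        assignment = [organs[i] for i in master.choice(len(organs), size=spec.n, p=probs)]
    master.shuffle(assignment)

    profile_names = sorted(spec.profiles)
    patients: list[PatientRecord] = []
    truth: dict[str, dict] = {}
    for i, organ in enumerate(assignment):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1, i]))
        pid = f"SYN{i:04d}"
        if organ in spec.profiles:
            profile = spec.profiles[organ]
        else:  # undiagnosed / multi / other: hidden single-organ physiology
            profile = spec.profiles[profile_names[int(rng.integers(len(profile_names)))]]

        # paired organs: affected side; unpaired: fixed ipsilateral side
        if profile.ipsilateral == "both":
            if rng.random() < profile.bilateral_p:
                affected = "both"
            else:
                affected = "left" if rng.random() < 0.5 else "right"
        else:
            affected = profile.ipsilateral

        blocks = _contiguous_blocks(profile.span)
        anchors = []
        for block in blocks:
            inter = [s for s in block if s in profile.span_max]
            anchors.append(inter if inter else block)

        drawings: list[DrawingRecord] = []
        truth_signs: dict[str, dict] = {}
        for sign in DISTRIBUTED_SIGNS:
            if sign == "spontaneous_pain":
                continue
            if rng.random() >= profile.sign_prevalence.get(sign, 0.0):
                continue
            if affected == "both":
                side = "both"
            else:
                side = affected if rng.random() < profile.side_rule_p else _opposite(affected)
            fraction = _sample_fraction(spec, rng)
            run: list[str] = []
            for block, anchor in zip(blocks, anchors):
                run.extend(_sample_run(block, anchor, rng))
            for view in ("front", "back"):
                polys = [
                    _jitter(rect, spec, rng)
                    for rect in _rects_for_run(run, view, side, fraction)
                ]
                drawings.append(DrawingRecord(sign=sign, view=view, polygons=polys))
            truth_signs[sign] = {"segments": run, "side": side, "fraction": fraction}

        pain = rng.random() < profile.pain_prevalence
        if pain and profile.pain_span:
            fraction = _sample_fraction(spec, rng)
            for view in ("front", "back"):
                polys = [
                    _jitter(rect, spec, rng)
                    for rect in _rects_for_run(profile.pain_span, view, "both", fraction)
                ]
                drawings.append(
                    DrawingRecord(sign="spontaneous_pain", view=view, polygons=polys)
                )

        lateralized: list[LateralizedFinding] = []
        for finding in LATERALIZED_FINDINGS:
            if rng.random() >= profile.lateralized_prevalence.get(finding, 0.0):
                continue
            ipsi_p = (
                profile.mydriasis_ipsi_p if finding == "mydriasis" else profile.side_rule_p
            )
            if affected == "both":
                side = "left" if rng.random() < 0.5 else "right"
            else:
                side = affected if rng.random() < ipsi_p else _opposite(affected)
            lateralized.append(LateralizedFinding(finding=finding, side=side))

        symptoms = [
            s for s in SYMPTOMS if rng.random() < profile.symptom_prevalence.get(s, 0.0)
        ]
        age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 18.0, 97.0))
        sex = "female" if rng.random() < spec.female_p else "male"
        patients.append(
            PatientRecord(
                id=pid, organ=organ, drawings=drawings, lateralized=lateralized,
                symptoms=symptoms, age=round(age, 1), sex=sex,
            )
        )
        truth[pid] = {
            "organ": organ,
            "profile": profile.organ,
            "affected_side": affected,
            "signs": truth_signs,
            "pain": pain,
            "lateralized": [f.model_dump() for f in lateralized],
            "symptoms": symptoms,
        }

    cohort = Cohort(
        patients=patients,
        meta={"generator": "segmaps.synthetic_cohort", "seed": spec.seed, "n": spec.n},
    )
    return cohort, {"seed": spec.seed, "n": spec.n, "patients": truth}
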