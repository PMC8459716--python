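"""Segmental statistics: coverage, lateralization, mean maps, frequencies.

These are the study's core quantities:

* **Segment coverage** — for a binarized body map, the percentage of each
  segment's pixels that the map covers, front and back pooled into one
  segment denominator. Segments under a 5% coverage threshold are excluded
  as marginal (drawing imperfections); surviving segments are then split at
  the midline into left/right halves whose coverages are reported
  separately (lateralization).
* **Mean body maps** — pixel-wise mean of per-patient binarized maps for
  one organ group, for all signs pooled or for spontaneous pain alone.
* **Lateralization summaries** — counts of lateralized findings by subject
  side per organ, with the percentage ipsilateral to the organ under the
  Hansen–Schliack side rule (heart and stomach are left-sided organs,
  liver/gallbladder right-sided; lungs and kidneys are paired, so
  ipsilaterality is undefined and reported as NA).
* **Frequency tables** — per finding/symptom, the number and percentage of
  patients presenting it at least once.

Percentages are reported to one decimal (ties round half away from zero);
ipsilateral percentages to the nearest integer; zero denominators give NA,
never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import SEGMENT_CODE, SEGMENTS, SIDE_CODE, VIEWS, SegmentAtlas
from .drawings_io import (
    ANALYZABLE_ORGANS,
    DISTRIBUTED_SIGNS,
    LATERALIZED_FINDINGS,
    SYMPTOMS,
    Cohort,
)
from .errors import ContractError, EmptyResultError
from .rasterize import BinaryBodyMap, patient_sign_map

#: Ipsilateral side per organ under the side rule; None for paired organs,
#: where lateralization is of descriptive value only.
IPSILATERAL_SIDE: dict[str, str | None] = {
    "heart": "left",
    "stomach": "left",
    "liver_gallbladder": "right",
    "lungs": None,
    "kidneys_ureters": None,
}


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (not banker's rounding)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


def segment_coverage(
    bmap, atlas: SegmentAtlas, threshold: float = 0.05
) -> pd.DataFrame:
    """Per-segment coverage of a body map, with the 5% inclusion rule.

    ``bmap`` is a :class:`~segmaps.rasterize.BinaryBodyMap` or any object
    with ``front``/``back`` grids (mean maps with fractional values are
    accepted; "set pixels" then generalizes to pixel mass). Front and back
    are pooled into one denominator per segment. Rows with ``side='both'``
    are emitted for every segment with its pass/fail flag; ``left``/``right``
    half rows are emitted only for segments passing the threshold.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ContractError(f"threshold {threshold} outside [0, 1]")
    front = np.asarray(bmap.front, dtype=float)
    back = np.asarray(bmap.back, dtype=float)
    values = {"front": front, "back": back}
    rows = []
    for seg in SEGMENTS:
        code = SEGMENT_CODE[seg]
        n_total = 0
        n_set = 0.0
        halves = {s: [0, 0.0] for s in ("left", "right")}  # [total, set]
        for view in VIEWS:
            in_seg = atlas.labels[view] == code
            n_total += int(in_seg.sum())
            n_set += float(values[view][in_seg].sum())
            for side_name, side_code in SIDE_CODE.items():
                half = in_seg & (atlas.side[view] == side_code)
                halves[side_name][0] += int(half.sum())
                halves[side_name][1] += float(values[view][half].sum())
        if n_total == 0:  # cannot happen for the schematic atlas
            continue
        fraction = n_set / n_total
        passed = fraction >= threshold
        rows.append(
            {
                "segment": seg,
                "side": "both",
                "n_set": n_set,
                "n_total": n_total,
                "coverage": 100.0 * n_set / n_total,
                "passed_threshold": passed,
            }
        )
        if passed:
            for side_name in ("left", "right"):
                h_total, h_set = halves[side_name]
                rows.append(
                    {
                        "segment": seg,
                        "side": side_name,
                        "n_set": h_set,
                        "n_total": h_total,
                        "coverage": (100.0 * h_set / h_total) if h_total else float("nan"),
                        "passed_threshold": passed,
                    }
                )
    return pd.DataFrame(rows)


def included_segments(coverage: pd.DataFrame) -> list[str]:
    """Segments passing the coverage threshold, cranio-caudal order."""
    passed = coverage[(coverage["side"] == "both") & coverage["passed_threshold"]]
    return sorted(passed["segment"], key=SEGMENTS.index)


# ---------------------------------------------------------------------------
# Mean maps
# ---------------------------------------------------------------------------


@dataclass
class MeanBodyMap:
    """Pixel-wise fraction of patients (0..1) with that pixel set."""

    front: np.ndarray
    back: np.ndarray
    n: int
    organ: str | None = None
    what: str | None = None


def _organ_patients(cohort: Cohort, organ: str):
    patients = [p for p in cohort.patients if p.organ == organ]
    if not patients:
        raise EmptyResultError(f"no patients with organ {organ!r}")
    return patients


def mean_map(
    cohort: Cohort, organ: str, what: str, atlas: SegmentAtlas
) -> MeanBodyMap:
    """Mean distribution of signs or pain over one organ group.

    ``what`` is ``"all_signs"`` (each patient contributes the superimposed,
    binarized union of all distributed signs), ``"pain"`` (only the
    spontaneous-pain drawing), or a single sign token. The denominator is
    the number of patients in the organ group, so pixel values are exact
    multiples of 1/n in [0, 1].
    """
    patients = _organ_patients(cohort, organ)
    acc_front = np.zeros((atlas.rows, atlas.cols), dtype=np.int64)
    acc_back = np.zeros((atlas.rows, atlas.cols), dtype=np.int64)
    for p in patients:
        m = patient_sign_map(p, atlas, include=what)
        acc_front += m.front
        acc_back += m.back
    n = len(patients)
    return MeanBodyMap(
        front=acc_front / n, back=acc_back / n, n=n, organ=organ, what=what
    )


def side_mass(mmap, atlas: SegmentAtlas) -> tuple[float, float]:
    """Total pixel mass of a map on the subject's left and right halves."""
    left = right = 0.0
    for view in VIEWS:
        values = np.asarray(getattr(mmap, "front" if view == "front" else "back"), float)
        left += float(values[atlas.side[view] == SIDE_CODE["left"]].sum())
        right += float(values[atlas.side[view] == SIDE_CODE["right"]].sum())
    return left, right


# ---------------------------------------------------------------------------
# Mean number of signs per half segment
# ---------------------------------------------------------------------------


def mean_signs_per_half_segment(
    cohort: Cohort, organ: str, atlas: SegmentAtlas, threshold: float = 0.05
) -> pd.DataFrame:
    """Mean number of distributed signs touching each half segment.

    For each patient and each distributed sign (spontaneous pain excluded),
    the sign contributes 1 to a half segment when the sign's own coverage of
    the full segment passes the threshold and the sign touches that half.
    The table reports the per-patient mean per (segment, side).
    """
    patients = _organ_patients(cohort, organ)
    acc: dict[tuple[str, str], int] = {
        (seg, side): 0 for seg in SEGMENTS for side in ("left", "right")
    }
    for p in patients:
        present = {d.sign for d in p.drawings if d.sign != "spontaneous_pain"}
        for sign in sorted(present):
            smap = patient_sign_map(p, atlas, include=sign)
            cov = segment_coverage(smap, atlas, threshold=threshold)
            half_rows = cov[cov["side"].isin(("left", "right"))]
            touched = half_rows[half_rows["n_set"] > 0]
            for _, row in touched.iterrows():
                acc[(row["segment"], row["side"])] += 1
    n = len(patients)
    records = [
        {"segment": seg, "side": side, "mean_count": acc[(seg, side)] / n}
        for seg in SEGMENTS
        for side in ("left", "right")
    ]
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Lateralization of (finding, side) pairs
# ---------------------------------------------------------------------------


def lateralization_summary(cohort: Cohort, organ: str) -> pd.DataFrame:
    """Counts of lateralized findings by side, with percent ipsilateral.

    Front and back are one surface for these findings (they carry only a
    side label). ``percent_ipsilateral`` is rounded to the nearest integer
    and is NA for the paired organs (lungs, kidneys/ureters) and whenever
    a finding has no lateralized occurrences.
    """
    if organ not in ANALYZABLE_ORGANS:
        raise ContractError(f"organ {organ!r} not in {ANALYZABLE_ORGANS}")
    patients = [p for p in cohort.patients if p.organ == organ]
    ipsi_side = IPSILATERAL_SIDE[organ]
    rows = []
    for finding in LATERALIZED_FINDINGS:
        n_left = sum(
            1 for p in patients for f in p.lateralized
            if f.finding == finding and f.side == "left"
        )
        n_right = sum(
            1 for p in patients for f in p.lateralized
            if f.finding == finding and f.side == "right"
        )
        total = n_left + n_right
        if ipsi_side is None or total == 0:
            pct = float("nan")
        else:
            n_ipsi = n_left if ipsi_side == "left" else n_right
            pct = round_half_away(100.0 * n_ipsi / total)
        rows.append(
            {
                "organ": organ,
                "finding": finding,
                "n_left": n_left,
                "n_right": n_right,
                "ipsilateral_side": ipsi_side if ipsi_side else "NA",
                "percent_ipsilateral": pct,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Frequency table
# ---------------------------------------------------------------------------


def frequency_table(cohort: Cohort) -> pd.DataFrame:
    """Number and percentage of patients with each finding or symptom.

    Includes every distributed sign (spontaneous pain listed as its own
    row), every lateralized finding, every symptom, and the aggregate rows
    "at least 1 segmental sign" (distributed signs other than pain, or any
    lateralized finding) and "at least 1 segmental symptom". Percentages
    are of the whole cohort, one decimal, ties away from zero.
    """
    if not cohort.patients:
        raise ContractError("frequency_table needs a non-empty cohort")
    n_cohort = len(cohort.patients)

    def pct(n: int) -> float:
        return round_half_away(100.0 * n / n_cohort, 1)

    rows = []
    for sign in DISTRIBUTED_SIGNS:
        if sign == "spontaneous_pain":
            continue
        n = sum(1 for p in cohort.patients if any(d.sign == sign for d in p.drawings))
        rows.append({"finding": sign, "kind": "sign", "n": n, "percent": pct(n)})
    for finding in LATERALIZED_FINDINGS:
        n = sum(
            1 for p in cohort.patients
            if any(f.finding == finding for f in p.lateralized)
        )
        rows.append({"finding": finding, "kind": "sign", "n": n, "percent": pct(n)})
    n_any_sign = sum(
        1 for p in cohort.patients
        if any(d.sign != "spontaneous_pain" for d in p.drawings) or p.lateralized
    )
    rows.append(
        {"finding": "at_least_1_segmental_sign", "kind": "aggregate",
         "n": n_any_sign, "percent": pct(n_any_sign)}
    )
    for symptom in SYMPTOMS:
        n = sum(1 for p in cohort.patients if symptom in p.symptoms)
        rows.append({"finding": symptom, "kind": "symptom", "n": n, "percent": pct(n)})
    n_any_symptom = sum(1 for p in cohort.patients if p.symptoms)
    rows.append(
        {"finding": "at_least_1_segmental_symptom", "kind": "aggregate",
         "n": n_any_symptom, "percent": pct(n_any_symptom)}
    )
    n_pain = sum(
        1 for p in cohort.patients
        if any(d.sign == "spontaneous_pain" for d in p.drawings)
    )
    rows.append(
        {"finding": "spontaneous_pain", "kind": "pain", "n": n_pain, "percent": pct(n_pain)}
    )
    return pd.DataFrame(rows)
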