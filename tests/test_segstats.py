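"""Coverage statistics, lateralization, mean maps, frequency tables."""

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    make_cohort,
    make_patient,
    oracle_coverage,
    oracle_segment_counts,
    random_mask,
    segment_rect,
)
from segmaps import (
    frequency_table,
    lateralization_summary,
    mean_map,
    mean_signs_per_half_segment,
    segment_coverage,
)
from segmaps.atlas import SEGMENT_CODE, SEGMENTS
from segmaps.drawings_io import DrawingRecord, LateralizedFinding
from segmaps.errors import ContractError, EmptyResultError
from segmaps.rasterize import BinaryBodyMap, empty_map, patient_sign_map
from segmaps.segstats import included_segments, round_half_away, side_mass


# ---------------------------------------------------------------------------
# segment coverage
# ---------------------------------------------------------------------------


def test_empty_map_no_segment_passes(atlas):
    cov = segment_coverage(empty_map(atlas), atlas)
    both = cov[cov["side"] == "both"]
    assert (both["coverage"] == 0).all()
    assert not both["passed_threshold"].any()
    assert len(cov[cov["side"] != "both"]) == 0  # no halves for excluded segments


def test_body_mask_full_coverage(atlas):
    full = BinaryBodyMap(
        front=atlas.body_mask("front").astype(np.uint8),
        back=atlas.body_mask("back").astype(np.uint8),
    )
    cov = segment_coverage(full, atlas)
    assert (cov["coverage"] == 100.0).all()
    both = cov[cov["side"] == "both"]
    assert both["passed_threshold"].all() and len(both) == 33
    assert len(cov[cov["side"] == "left"]) == 33


def test_five_percent_boundary(atlas195):
    """T5 has exactly 200 pixels on this grid: 10 set pass, 9 are excluded."""
    code = SEGMENT_CODE["T5"]
    n_total = sum(
        int((atlas195.labels[v] == code).sum()) for v in ("front", "back")
    )
    assert n_total == 200
    rr, cc = np.nonzero(atlas195.labels["front"] == code)
    for n_set, expect_pass in ((10, True), (9, False)):
        front = np.zeros((atlas195.rows, atlas195.cols), np.uint8)
        front[rr[:n_set], cc[:n_set]] = 1
        m = BinaryBodyMap(front=front, back=np.zeros_like(front))
        cov = segment_coverage(m, atlas195)
        row = cov[(cov.segment == "T5") & (cov.side == "both")].iloc[0]
        assert row["coverage"] == pytest.approx(100.0 * n_set / 200)
        assert bool(row["passed_threshold"]) is expect_pass


def test_coverage_matches_bruteforce_oracle(atlas):
    rng = np.random.default_rng(123)
    for _ in range(5):
        m = random_mask(atlas, rng)
        cov = segment_coverage(m, atlas, threshold=0.0)
        both = cov[cov["side"] == "both"].set_index("segment")
        for seg in ("V1", "C5", "T5", "L3", "S2", "Cog1"):
            assert both.loc[seg, "coverage"] == pytest.approx(
                oracle_coverage(atlas, m, seg)
            )
        # half-segment counts against the Counter oracle
        set_px, tot_px = oracle_segment_counts(atlas, m)
        halves = cov[cov["side"] == "left"].set_index("segment")
        for seg in halves.index:
            code = SEGMENT_CODE[seg]
            assert halves.loc[seg, "n_set"] == set_px[(code, 1)]
            assert halves.loc[seg, "n_total"] == tot_px[(code, 1)]


def test_threshold_monotonicity(atlas):
    rng = np.random.default_rng(321)
    m = random_mask(atlas, rng, p=0.12)
    previous = None
    for thr in (0.0, 0.05, 0.1, 0.2, 0.5, 1.0):
        inc = set(included_segments(segment_coverage(m, atlas, threshold=thr)))
        if previous is not None:
            assert inc <= previous
        previous = inc


def test_threshold_out_of_range(atlas):
    with pytest.raises(ContractError):
        segment_coverage(empty_map(atlas), atlas, threshold=1.5)


# ---------------------------------------------------------------------------
# mean maps
# ---------------------------------------------------------------------------


def test_mean_map_single_patient_is_own_map(atlas):
    p = make_patient("a", signs=("muscle_resistance",))
    cohort = make_cohort([p])
    mm = mean_map(cohort, "heart", "all_signs", atlas)
    own = patient_sign_map(p, atlas, "all_signs")
    assert np.array_equal(mm.front, own.front.astype(float))
    assert mm.n == 1


def test_mean_map_disjoint_patients(atlas):
    pa = make_patient("a", signs=("muscle_resistance",))
    pb = make_patient("b")
    pb.drawings = [
        DrawingRecord(sign="defense", view="front", polygons=[segment_rect("T8")])
    ]
    mm = mean_map(make_cohort([pa, pb]), "heart", "all_signs", atlas)
    vals = set(np.unique(mm.front))
    assert vals <= {0.0, 0.5}
    assert 0.5 in vals


def test_mean_map_matches_accumulate_oracle(atlas):
    from segmaps import default_spec, generate

    cohort, _ = generate(default_spec(n=10, seed=21, organ_mix={"heart": 1.0}))
    mm = mean_map(cohort, "heart", "all_signs", atlas)
    acc = np.zeros((atlas.rows, atlas.cols))
    for p in cohort.patients:
        acc += patient_sign_map(p, atlas, "all_signs").front
    assert np.allclose(mm.front, acc / 10)
    # conservation: n * mean has integer pixel values in [0, n]
    scaled = mm.front * mm.n
    assert np.allclose(scaled, np.round(scaled))
    assert scaled.max() <= mm.n


def test_mean_map_no_patients_raises(atlas):
    with pytest.raises(EmptyResultError):
        mean_map(make_cohort([make_patient("a", "heart")]), "stomach",
                 "all_signs", atlas)


# ---------------------------------------------------------------------------
# mean signs per half segment
# ---------------------------------------------------------------------------


def test_one_sign_full_segment(atlas):
    p = make_patient("a", signs=("muscle_resistance",))
    # front-only T5 rectangle covers 50% of the pooled T5 denominator
    table = mean_signs_per_half_segment(make_cohort([p]), "heart", atlas)
    t5 = table[table.segment == "T5"].set_index("side")["mean_count"]
    assert t5["left"] == 1.0 and t5["right"] == 1.0
    assert table[table.segment != "T5"]["mean_count"].sum() == 0.0


def test_no_signs_all_zero(atlas):
    table = mean_signs_per_half_segment(
        make_cohort([make_patient("a")]), "heart", atlas
    )
    assert (table["mean_count"] == 0).all()


def test_half_segment_counts_match_explicit_recount(atlas):
    from segmaps import default_spec, generate

    cohort, _ = generate(default_spec(n=8, seed=33, organ_mix={"stomach": 1.0}))
    table = mean_signs_per_half_segment(cohort, "stomach", atlas)
    acc = {(seg, side): 0 for seg in SEGMENTS for side in ("left", "right")}
    for p in cohort.patients:
        for sign in sorted({d.sign for d in p.drawings if d.sign != "spontaneous_pain"}):
            m = patient_sign_map(p, atlas, sign)
            set_px, tot_px = oracle_segment_counts(atlas, m)
            for seg in SEGMENTS:
                code = SEGMENT_CODE[seg]
                tot = tot_px[(code, 1)] + tot_px[(code, 2)]
                covered = set_px[(code, 1)] + set_px[(code, 2)]
                if tot and covered / tot >= 0.05:
                    for side, s in (("left", 1), ("right", 2)):
                        if set_px[(code, s)] > 0:
                            acc[(seg, side)] += 1
    n = len(cohort.patients)
    got = table.set_index(["segment", "side"])["mean_count"]
    for key, count in acc.items():
        assert got.loc[key] == pytest.approx(count / n)


# ---------------------------------------------------------------------------
# lateralization
# ---------------------------------------------------------------------------


def _lateralized_cohort(organ, finding, n_left, n_right):
    patients = []
    for i in range(n_left):
        patients.append(make_patient(
            f"l{i}", organ,
            lateralized=[LateralizedFinding(finding=finding, side="left")]))
    for i in range(n_right):
        patients.append(make_patient(
            f"r{i}", organ,
            lateralized=[LateralizedFinding(finding=finding, side="right")]))
    return make_cohort(patients)


def test_heart_mydriasis_83_percent():
    cohort = _lateralized_cohort("heart", "mydriasis", 15, 3)
    table = lateralization_summary(cohort, "heart")
    row = table[table.finding == "mydriasis"].iloc[0]
    assert (row.n_left, row.n_right) == (15, 3)
    assert row.ipsilateral_side == "left"
    assert row.percent_ipsilateral == 83


def test_liver_mydriasis_100_percent():
    cohort = _lateralized_cohort("liver_gallbladder", "mydriasis", 0, 5)
    row = lateralization_summary(cohort, "liver_gallbladder")
    row = row[row.finding == "mydriasis"].iloc[0]
    assert row.percent_ipsilateral == 100


def test_zero_findings_is_na_not_zero():
    cohort = make_cohort([make_patient("a", "heart")])
    table = lateralization_summary(cohort, "heart")
    assert table["percent_ipsilateral"].isna().all()
    assert (table["n_left"] + table["n_right"] == 0).all()


def test_paired_organ_is_na():
    cohort = _lateralized_cohort("lungs", "mydriasis", 9, 1)
    row = lateralization_summary(cohort, "lungs")
    row = row[row.finding == "mydriasis"].iloc[0]
    assert row.ipsilateral_side == "NA"
    assert pd.isna(row.percent_ipsilateral)
    assert row.n_left + row.n_right == 10  # consistency with raw findings


# ---------------------------------------------------------------------------
# frequency table and rounding
# ---------------------------------------------------------------------------


def test_frequency_percent_arithmetic():
    """46 of 110 patients with a sign -> 41.8%; absent finding -> 0 (0.0%)."""
    patients = [
        make_patient(i, signs=("superficial_hyperalgesia",)) for i in range(46)
    ] + [make_patient(46 + i) for i in range(64)]
    table = frequency_table(make_cohort(patients)).set_index("finding")
    assert table.loc["superficial_hyperalgesia", "n"] == 46
    assert table.loc["superficial_hyperalgesia", "percent"] == 41.8
    assert table.loc["allodynia", "n"] == 0
    assert table.loc["allodynia", "percent"] == 0.0


def test_frequency_rounding_half_away_from_zero():
    """1 of 16 is exactly 6.25%: printed as 6.3, not banker's 6.2."""
    patients = [make_patient(0, signs=("allodynia",))] + [
        make_patient(i + 1) for i in range(15)
    ]
    table = frequency_table(make_cohort(patients)).set_index("finding")
    assert table.loc["allodynia", "percent"] == 6.3


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.integers(0, 10_000), st.integers(1, 3))
def test_round_half_away_matches_decimal(n, ndigits):
    x = n / 16.0  # exact binary fractions: ties are real ties
    expected = float(
        Decimal(repr(x)).quantize(Decimal(f"1e-{ndigits}"), rounding=ROUND_HALF_UP)
    )
    assert round_half_away(x, ndigits) == expected


def test_side_mass_splits_total(atlas):
    rng = np.random.default_rng(77)
    m = random_mask(atlas, rng)
    left, right = side_mass(m, atlas)
    assert left + right == m.pixel_count()
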