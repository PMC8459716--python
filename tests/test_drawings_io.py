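"""Cohort interchange format: round trips, validation, selection filter."""

import json

import numpy as np
import pytest

from conftest import make_cohort, make_patient, random_mask
from segmaps import (
    Cohort,
    default_spec,
    export_mask_nifti,
    generate,
    load_mask_nifti,
    read_cohort,
    select_single_organ,
    write_cohort,
)
from segmaps.errors import CohortValidationError, ContractError


@pytest.fixture
def tiny_cohort():
    cohort, _ = generate(default_spec(n=3, seed=11))
    return cohort


def test_cohort_roundtrip(tiny_cohort, tmp_path):
    path = write_cohort(tiny_cohort, tmp_path / "cohort.json")
    back = read_cohort(path)
    assert back.patients == tiny_cohort.patients
    assert back.meta["seed"] == tiny_cohort.meta["seed"]


def _write_raw(tmp_path, patients):
    path = tmp_path / "bad.json"
    path.write_text(json.dumps({"patients": patients}))
    return path


def test_two_vertex_polygon_rejected(tmp_path):
    path = _write_raw(
        tmp_path,
        [{
            "id": "P1", "organ": "heart",
            "drawings": [{"sign": "allodynia", "view": "front",
                          "polygons": [[[0.1, 0.1], [0.2, 0.2]]]}],
        }],
    )
    with pytest.raises(CohortValidationError, match="P1"):
        read_cohort(path)


def test_unknown_sign_token_rejected(tmp_path):
    path = _write_raw(
        tmp_path,
        [{
            "id": "P2", "organ": "heart",
            "drawings": [{"sign": "tickling", "view": "front",
                          "polygons": [[[0.1, 0.1], [0.2, 0.1], [0.2, 0.2]]]}],
        }],
    )
    with pytest.raises(CohortValidationError, match="P2.*sign"):
        read_cohort(path)


def test_coordinates_outside_unit_square_rejected(tmp_path):
    path = _write_raw(
        tmp_path,
        [{
            "id": "P3", "organ": "lungs",
            "drawings": [{"sign": "zoster", "view": "back",
                          "polygons": [[[0.1, 0.1], [1.2, 0.1], [0.2, 0.2]]]}],
        }],
    )
    with pytest.raises(CohortValidationError, match="P3"):
        read_cohort(path)


def test_duplicate_patient_ids_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        make_cohort([make_patient("A"), make_patient("A")])


def test_select_single_organ_study_flow():
    """208 patients with 50 undiagnosed, 39 multi, 9 other -> 110 retained."""
    patients = (
        [make_patient(f"h{i}", "heart") for i in range(62)]
        + [make_patient(f"l{i}", "lungs") for i in range(18)]
        + [make_patient(f"s{i}", "stomach") for i in range(10)]
        + [make_patient(f"g{i}", "liver_gallbladder") for i in range(12)]
        + [make_patient(f"k{i}", "kidneys_ureters") for i in range(8)]
        + [make_patient(f"u{i}", "undiagnosed") for i in range(50)]
        + [make_patient(f"m{i}", "multi") for i in range(39)]
        + [make_patient(f"o{i}", "other") for i in range(9)]
    )
    cohort = make_cohort(patients)
    assert len(cohort.patients) == 208
    selected = select_single_organ(cohort)
    assert len(selected.patients) == 110
    assert selected.meta["selection"]["retained"] == 110
    assert selected.meta["selection"]["dropped"] == 98


def test_select_drops_small_organ_groups():
    cohort = make_cohort(
        [make_patient(f"s{i}", "stomach") for i in range(3)]
        + [make_patient(f"h{i}", "heart") for i in range(5)]
    )
    selected = select_single_organ(cohort, min_per_organ=4)
    assert {p.organ for p in selected.patients} == {"heart"}
    everyone = select_single_organ(cohort, min_per_organ=1)
    assert len(everyone.patients) == 8


def test_select_is_idempotent(tiny_cohort):
    once = select_single_organ(tiny_cohort, min_per_organ=1)
    twice = select_single_organ(once, min_per_organ=1)
    assert once.patients == twice.patients


def test_select_empty_result_warns():
    cohort = make_cohort([make_patient("u1", "undiagnosed")])
    with pytest.warns(UserWarning, match="empty"):
        selected = select_single_organ(cohort)
    assert selected.patients == []


def test_mask_nifti_roundtrip(atlas, tmp_path):
    rng = np.random.default_rng(42)
    mask = random_mask(atlas, rng)
    export_mask_nifti(mask, tmp_path / "mask.nii.gz")
    front, back = load_mask_nifti(tmp_path / "mask.nii.gz")
    assert np.array_equal(front, mask.front)
    assert np.array_equal(back, mask.back)


def test_mask_nifti_degenerate_cases(tmp_path):
    import nibabel as nib

    zero = np.zeros((66, 20, 2), dtype=np.uint8)
    export_mask_nifti(zero, tmp_path / "zero.nii.gz")
    assert np.asarray(nib.load(str(tmp_path / "zero.nii.gz")).dataobj).sum() == 0
    one = zero.copy()
    one[5, 7, 1] = 1
    export_mask_nifti(one, tmp_path / "one.nii.gz")
    vol = np.asarray(nib.load(str(tmp_path / "one.nii.gz")).dataobj)
    assert vol.sum() == 1 and vol[5, 7, 1] == 1


def test_mask_nifti_rejects_non_binary(tmp_path):
    bad = np.full((66, 20, 2), 3, dtype=np.uint8)
    with pytest.raises(ContractError, match="binary"):
        export_mask_nifti(bad, tmp_path / "bad.nii.gz")


def test_empty_cohort_file_warns(tmp_path):
    path = tmp_path / "empty.json"
    path.write_text(json.dumps({"patients": []}))
    with pytest.warns(UserWarning, match="empty"):
        cohort = read_cohort(path)
    assert isinstance(cohort, Cohort)
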