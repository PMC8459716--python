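"""Schematic front/back segmental body atlas.

The atlas assigns every pixel of a front and a back body-template view to
exactly one spinal (or trigeminal) segment and one anatomical body side.
The segmental scheme has 33 segments: trigeminal V1-V3, cervical C2-C8
(C1 has no dermatome), thoracic T1-T12, lumbar L1-L5, sacral S1-S5, and
coccygeal Cog1. All coverage statistics downstream depend only on these
label maps, so the atlas is a deliberately schematic arrangement of
axis-aligned bands rather than anatomical artwork:

* a head column (V1-V3 and C2-C3 as horizontal bands),
* a trunk column (C4-T12, L1-S5 as contiguous cranio-caudal bands; the
  lowest back-view band is Cog1, which is dorsal),
* arm rectangles flanking the trunk at the C5-T1 band rows, and
* leg rectangles below the trunk carrying the L2-S2 dermatomes.

Coordinates are 0-based, row-major, origin at the top-left of each view.
"Left" and "right" always mean the SUBJECT's anatomical side: on the front
view the subject's left half is the right half of the image, on the back
view it is the left half. Side labels are stored explicitly per pixel so no
view-mirroring convention can corrupt downstream statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AtlasSizeError, ContractError

# --------------------------------------------------------------------------
# Segment naming scheme
# --------------------------------------------------------------------------

SEGMENTS: tuple[str, ...] = (
    ("V1", "V2", "V3")
    + tuple(f"C{i}" for i in range(2, 9))
    + tuple(f"T{i}" for i in range(1, 13))
    + tuple(f"L{i}" for i in range(1, 6))
    + tuple(f"S{i}" for i in range(1, 6))
    + ("Cog1",)
)
assert len(SEGMENTS) == 33

#: 1-based integer code per segment; 0 is background.
SEGMENT_CODE: dict[str, int] = {name: i + 1 for i, name in enumerate(SEGMENTS)}
SEGMENT_INDEX: dict[str, int] = {name: i for i, name in enumerate(SEGMENTS)}

VIEWS: tuple[str, str] = ("front", "back")
SIDES: tuple[str, str] = ("left", "right")
SIDE_CODE: dict[str, int] = {"left": 1, "right": 2}

MIN_ROWS = 66
MIN_COLS = 20


def segment_range(first: str, last: str) -> list[str]:
    """Contiguous run of segments in cranio-caudal order, inclusive."""
    i, j = SEGMENT_INDEX[first], SEGMENT_INDEX[last]
    if i > j:
        raise ContractError(f"segment range {first}..{last} is not cranio-caudal")
    return list(SEGMENTS[i : j + 1])


# --------------------------------------------------------------------------
# Normalized layout geometry (resolution independent)
# --------------------------------------------------------------------------
# The vertical axis is divided into 39 equal units: 5 head bands (V1, V2,
# V3, C2, C3), 28 trunk slots (C4..C8, T1..T12, L1..L5, S1..S5 plus one
# extra caudal slot that holds Cog1 on the back view and extends S5 on the
# front), and 6 leg bands (L2..S2).

N_UNITS = 39
_HEAD_SEGS = ("V1", "V2", "V3", "C2", "C3")  # units 0..4
_TRUNK_SEGS = tuple(SEGMENTS[5:32])  # C4..S5, slots 0..26 (units 5..31)
_EXTRA_SLOT_UNIT = 32  # S5 on the front view, Cog1 on the back view
_LEG_SEGS = ("L2", "L3", "L4", "L5", "S1", "S2")  # units 33..38
_ARM_SEGS = ("C5", "C6", "C7", "C8", "T1")  # trunk slots 1..5, units 6..10

HEAD_HALF_WIDTH = 1.0 / 6.0  # head spans the central third
TRUNK_HALF_WIDTH = 0.25  # trunk and legs span the central half


def segment_band(segment: str, view: str) -> tuple[float, float] | None:
    """Normalized y-interval of a segment's primary (head/trunk) band.

    Returns None for Cog1 on the front view. Limb duplications of the
    C5-T1 and L2-S2 bands are not reported here; they share the trunk
    band rows (arms) or sit in the leg region (legs).
    """
    if view not in VIEWS:
        raise ContractError(f"unknown view {view!r}")
    if segment in _HEAD_SEGS:
        u = _HEAD_SEGS.index(segment)
        return (u / N_UNITS, (u + 1) / N_UNITS)
    if segment == "Cog1":
        if view == "front":
            return None
        return (_EXTRA_SLOT_UNIT / N_UNITS, (_EXTRA_SLOT_UNIT + 1) / N_UNITS)
    slot = _TRUNK_SEGS.index(segment)
    y0 = (5 + slot) / N_UNITS
    y1 = (6 + slot) / N_UNITS
    if segment == "S5" and view == "front":
        y1 = (_EXTRA_SLOT_UNIT + 1) / N_UNITS  # extra slot extends S5
    return (y0, y1)


def segment_half_width(segment: str) -> float:
    """Half-width (from the midline, normalized x) of a segment's band."""
    return HEAD_HALF_WIDTH if segment in _HEAD_SEGS else TRUNK_HALF_WIDTH


def template_x_interval(view: str, side: str, half_width: float) -> tuple[float, float]:
    """Template x-interval of one subject-side half of a central band.

    On the front view the subject's left is the template's right half and
    vice versa; on the back view template and subject sides coincide.
    """
    if side not in SIDES:
        raise ContractError(f"unknown side {side!r}")
    template_right = (view == "front") == (side == "left")
    if template_right:
        return (0.5, 0.5 + half_width)
    return (0.5 - half_width, 0.5)


# --------------------------------------------------------------------------
# Atlas container
# --------------------------------------------------------------------------


@dataclass
class SegmentAtlas:
    """Per-pixel segment and side labels for the front and back views.

    ``labels[view]`` holds integer segment codes (0 = background, else
    ``SEGMENT_CODE``); ``side[view]`` holds 0 (background), 1 (subject
    left) or 2 (subject right).
    """

    rows: int
    cols: int
    labels: dict[str, np.ndarray]
    side: dict[str, np.ndarray]
    sacral_on_front: bool = True
    names: tuple[str, ...] = field(default=SEGMENTS, repr=False)

    def body_mask(self, view: str) -> np.ndarray:
        return self.labels[view] > 0

    def segment_mask(self, segment: str, view: str) -> np.ndarray:
        return self.labels[view] == SEGMENT_CODE[segment]

    def equals(self, other: "SegmentAtlas") -> bool:
        return (
            self.rows == other.rows
            and self.cols == other.cols
            and all(np.array_equal(self.labels[v], other.labels[v]) for v in VIEWS)
            and all(np.array_equal(self.side[v], other.side[v]) for v in VIEWS)
        )


def build_schematic_atlas(
    rows: int, cols: int, *, sacral_on_front: bool = True
) -> SegmentAtlas:
    """Construct the deterministic schematic atlas at a given resolution.

    Pixels are labeled by their center point in normalized coordinates, so
    the construction is resolution consistent. Requires ``rows >= 66`` and
    ``cols >= 20`` so that every band is at least one pixel tall and every
    left/right half at least one pixel wide.

    Parameters
    ----------
    sacral_on_front
        Whether the S3-S5 bands appear on the front view as well as the
        back (perineal representation is ambiguous on a flat template).
    """
    if rows < MIN_ROWS or cols < MIN_COLS:
        raise AtlasSizeError(
            f"atlas grid {rows}x{cols} is below the minimum {MIN_ROWS}x{MIN_COLS}: "
            f"segment band {_smallest_failing_segment(rows, cols)!r} cannot be "
            "resolved into non-empty left/right halves"
        )

    y = (np.arange(rows) + 0.5) / rows
    x = (np.arange(cols) + 0.5) / cols
    units = np.floor(y * N_UNITS).astype(int)
    dist = np.abs(x - 0.5)
    inner_head = dist < HEAD_HALF_WIDTH
    inner_trunk = dist < TRUNK_HALF_WIDTH
    outer = ~inner_trunk
    on_midline = x == 0.5  # only possible for odd column counts

    labels: dict[str, np.ndarray] = {}
    side: dict[str, np.ndarray] = {}
    front_sacral_excluded = {"S3", "S4", "S5"} if not sacral_on_front else set()
    for view in VIEWS:
        lab = np.zeros((rows, cols), dtype=np.uint8)
        for r in range(rows):
            u = units[r]
            if u <= 4:
                lab[r, inner_head] = SEGMENT_CODE[_HEAD_SEGS[u]]
            elif u <= _EXTRA_SLOT_UNIT:
                if u == _EXTRA_SLOT_UNIT:
                    seg = "S5" if view == "front" else "Cog1"
                else:
                    seg = _TRUNK_SEGS[u - 5]
                if not (view == "front" and seg in front_sacral_excluded):
                    lab[r, inner_trunk] = SEGMENT_CODE[seg]
                if 6 <= u <= 10:  # arm rows share the C5..T1 slots
                    lab[r, outer] = SEGMENT_CODE[_TRUNK_SEGS[u - 5]]
            else:
                lab[r, inner_trunk] = SEGMENT_CODE[_LEG_SEGS[u - 33]]
        lab[:, on_midline] = 0  # odd grids: the exact midline column is no-man's land
        body = lab > 0
        # subject side: front view mirrors the template, back view does not
        template_left = x < 0.5
        if view == "front":
            side_row = np.where(template_left, SIDE_CODE["right"], SIDE_CODE["left"])
        else:
            side_row = np.where(template_left, SIDE_CODE["left"], SIDE_CODE["right"])
        sid = np.where(body, side_row[np.newaxis, :], 0).astype(np.uint8)
        labels[view] = lab
        side[view] = sid

    return SegmentAtlas(
        rows=rows, cols=cols, labels=labels, side=side, sacral_on_front=sacral_on_front
    )


def _smallest_failing_segment(rows: int, cols: int) -> str:
    """Name the first segment whose band degenerates at this grid size.

    Every band is one vertical unit tall, so when rows are short the first
    empty band in cranio-caudal order is reported; when only the width
    fails, the narrow head bands (V1 first) lose their halves first.
    """
    if rows >= MIN_ROWS:
        return "V1"
    y = (np.arange(max(rows, 1)) + 0.5) / max(rows, 1)
    units = set(np.floor(y * N_UNITS).astype(int))
    for u in range(N_UNITS):
        if u not in units:
            if u <= 4:
                return _HEAD_SEGS[u]
            if u < _EXTRA_SLOT_UNIT:
                return _TRUNK_SEGS[u - 5]
            if u == _EXTRA_SLOT_UNIT:
                return "Cog1"
            return _LEG_SEGS[u - 33]
    return "Cog1"  # all bands present but halves under-resolved


# --------------------------------------------------------------------------
# Pixel bookkeeping and serialization
# --------------------------------------------------------------------------


def segment_pixel_counts(atlas: SegmentAtlas) -> pd.DataFrame:
    """Pixel count per (segment, side, view), including zero rows.

    The counts over all (segment, side) pairs sum to the body-mask size of
    each view (partition property).
    """
    rows = []
    for view in VIEWS:
        lab = atlas.labels[view]
        sid = atlas.side[view]
        for side_name, side_code in SIDE_CODE.items():
            counts = np.bincount(lab[sid == side_code], minlength=34)
            for seg in SEGMENTS:
                rows.append(
                    {
                        "segment": seg,
                        "side": side_name,
                        "view": view,
                        "n_pixels": int(counts[SEGMENT_CODE[seg]]),
                    }
                )
    return pd.DataFrame(rows)


def save_atlas_nifti(atlas: SegmentAtlas, path: str | Path) -> Path:
    """Write the label maps as a NIfTI volume (front/back as two slices).

    A JSON sidecar (``<stem>.labels.json``) records the integer-code to
    segment-name table. The affine is identity; the grid is schematic.
    """
    import nibabel as nib

    path = Path(path)
    vol = np.stack([atlas.labels["front"], atlas.labels["back"]], axis=-1)
    nib.save(nib.Nifti1Image(vol.astype(np.uint8), np.eye(4)), str(path))
    stem = path.name[: -len("".join(path.suffixes))] if path.suffixes else path.name
    sidecar = path.with_name(stem + ".labels.json")
    sidecar.write_text(
        json.dumps({str(code): name for name, code in SEGMENT_CODE.items()}, indent=1)
    )
    return path


def save_atlas_png(atlas: SegmentAtlas, path: str | Path) -> Path:
    """Render a quick visual check image of both views."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(6, 8))
    for ax, view in zip(axes, VIEWS):
        ax.imshow(atlas.labels[view], cmap="nipy_spectral", interpolation="nearest")
        ax.set_title(view)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
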