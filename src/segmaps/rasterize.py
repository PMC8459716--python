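"""Rasterize drawings to binary body maps and superimpose them.

A drawing's polygons are filled with the even-odd rule sampled at pixel
centers (``skimage.draw.polygon``), clipped to the atlas body mask of the
drawing's view. Per-patient maps are the pixel-wise OR of the individual
sign maps followed by binarization: the number of coinciding signs at a
pixel is deliberately discarded; only bodily location is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from skimage.draw import polygon as _sk_polygon

from .atlas import VIEWS, SegmentAtlas
from .drawings_io import DrawingRecord, PatientRecord
from .errors import ContractError


@dataclass
class BinaryBodyMap:
    """A per-view bit grid on the atlas dimensions, zero outside the body."""

    front: np.ndarray
    back: np.ndarray
    patient_id: str | None = None
    signs: tuple[str, ...] = field(default=())

    def view(self, name: str) -> np.ndarray:
        if name not in VIEWS:
            raise ContractError(f"unknown view {name!r}")
        return self.front if name == "front" else self.back

    @property
    def shape(self) -> tuple[int, int]:
        return self.front.shape

    def pixel_count(self) -> int:
        return int(self.front.sum() + self.back.sum())

    def equals(self, other: "BinaryBodyMap") -> bool:
        return np.array_equal(self.front, other.front) and np.array_equal(
            self.back, other.back
        )


def empty_map(atlas: SegmentAtlas, **kw) -> BinaryBodyMap:
    z = np.zeros((atlas.rows, atlas.cols), dtype=np.uint8)
    return BinaryBodyMap(front=z, back=z.copy(), **kw)


def _polygon_area(verts: Sequence[tuple[float, float]]) -> float:
    """Shoelace area in normalized coordinates."""
    xy = np.asarray(verts, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def fill_polygon(
    verts: Sequence[tuple[float, float]], rows: int, cols: int
) -> np.ndarray:
    """Even-odd fill of one polygon, sampled at pixel centers.

    Vertices are (x, y) in normalized template coordinates; pixel (r, c)
    has its center at ((r + 0.5) / rows, (c + 0.5) / cols).
    """
    xy = np.asarray(verts, dtype=float)
    rr_f = xy[:, 1] * rows - 0.5
    cc_f = xy[:, 0] * cols - 0.5
    grid = np.zeros((rows, cols), dtype=np.uint8)
    rr, cc = _sk_polygon(rr_f, cc_f, shape=(rows, cols))
    grid[rr, cc] = 1
    return grid


def rasterize_drawing(d: DrawingRecord, atlas: SegmentAtlas) -> BinaryBodyMap:
    """Convert one drawing to a binary body map on the atlas grid.

    The polygon interiors (even-odd rule) are OR-combined, then intersected
    with the body mask of the drawing's view; the other view stays all-zero.
    Degenerate zero-area polygons contribute nothing and raise a warning.
    """
    grid = np.zeros((atlas.rows, atlas.cols), dtype=np.uint8)
    for k, poly in enumerate(d.polygons):
        if _polygon_area(poly) == 0.0:
            warnings.warn(
                f"degenerate zero-area polygon {k} in {d.sign!r} drawing; skipped",
                stacklevel=2,
            )
            continue
        grid |= fill_polygon(poly, atlas.rows, atlas.cols)
    grid &= atlas.body_mask(d.view).astype(np.uint8)
    other = np.zeros_like(grid)
    if d.view == "front":
        return BinaryBodyMap(front=grid, back=other, signs=(d.sign,))
    return BinaryBodyMap(front=other, back=grid, signs=(d.sign,))


def superimpose_binarize(maps: Iterable[BinaryBodyMap]) -> BinaryBodyMap:
    """Pixel-wise OR of binary maps (idempotent, order independent).

    Sign multiplicity at a pixel is not preserved: the result records only
    whether at least one sign was found at each body point.
    """
    maps = list(maps)
    if not maps:
        raise ContractError("superimpose_binarize needs at least one map")
    shape = maps[0].shape
    front = np.zeros(shape, dtype=np.uint8)
    back = np.zeros(shape, dtype=np.uint8)
    signs: list[str] = []
    ids = {m.patient_id for m in maps if m.patient_id is not None}
    for m in maps:
        if m.shape != shape:
            raise ContractError(f"grid mismatch: {m.shape} vs {shape}")
        front |= m.front.astype(np.uint8)
        back |= m.back.astype(np.uint8)
        signs.extend(m.signs)
    pid = ids.pop() if len(ids) == 1 else None
    return BinaryBodyMap(front=front, back=back, patient_id=pid,
                         signs=tuple(dict.fromkeys(signs)))


def patient_sign_map(
    patient: PatientRecord,
    atlas: SegmentAtlas,
    include: str | Sequence[str] = "all_signs",
) -> BinaryBodyMap:
    """Superimposed, binarized map of a patient's distributed findings.

    ``include`` selects drawings: ``"all_signs"`` (every distributed sign
    except spontaneous pain), ``"pain"`` (spontaneous pain only), or an
    explicit sign token / sequence of tokens.
    """
    if include == "all_signs":
        selected = [d for d in patient.drawings if d.sign != "spontaneous_pain"]
    elif include == "pain":
        selected = [d for d in patient.drawings if d.sign == "spontaneous_pain"]
    else:
        tokens = (include,) if isinstance(include, str) else tuple(include)
        selected = [d for d in patient.drawings if d.sign in tokens]
    if not selected:
        m = empty_map(atlas)
        m.patient_id = patient.id
        return m
    out = superimpose_binarize([rasterize_drawing(d, atlas) for d in selected])
    out.patient_id = patient.id
    return out
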