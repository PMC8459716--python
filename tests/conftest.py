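"""Shared fixtures and independent counting oracles.

The oracles deliberately avoid the package's vectorized code paths: pixel
bookkeeping is done with plain Python loops/Counters, point-in-polygon with
matplotlib's path machinery.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from segmaps import build_schematic_atlas
from segmaps.atlas import SEGMENT_CODE, VIEWS, segment_band
from segmaps.drawings_io import Cohort, DrawingRecord, PatientRecord
from segmaps.rasterize import BinaryBodyMap


@pytest.fixture(scope="session")
def atlas():
    """Default-resolution atlas (132 x 40)."""
    return build_schematic_atlas(132, 40)


@pytest.fixture(scope="session")
def atlas195():
    """Atlas where every plain trunk segment has exactly 200 pixels.

    195 rows give exactly 5 rows per vertical unit; 40 columns give a
    20-column trunk; 5 x 20 x 2 views = 200 pixels for T5.
    """
    return build_schematic_atlas(195, 40)


def segment_rect(segment: str, view: str = "front"):
    """Rectangle polygon exactly covering a trunk segment's band (both halves)."""
    y0, y1 = segment_band(segment, view)
    return [(0.25, y0), (0.75, y0), (0.75, y1), (0.25, y1)]


def make_patient(pid, organ="heart", signs=(), pain=False, lateralized=(),
                 symptoms=(), **kw) -> PatientRecord:
    """Patient whose distributed findings each cover T5 on the front view."""
    drawings = [
        DrawingRecord(sign=s, view="front", polygons=[segment_rect("T5")])
        for s in signs
    ]
    if pain:
        drawings.append(
            DrawingRecord(sign="spontaneous_pain", view="front",
                          polygons=[segment_rect("T5")])
        )
    return PatientRecord(id=str(pid), organ=organ, drawings=drawings,
                         lateralized=list(lateralized), symptoms=list(symptoms), **kw)


def make_cohort(patients) -> Cohort:
    return Cohort(patients=list(patients))


def random_mask(atlas, rng, p=0.2) -> BinaryBodyMap:
    """Random binary map restricted to the atlas body."""
    grids = {}
    for view in VIEWS:
        g = (rng.random((atlas.rows, atlas.cols)) < p).astype(np.uint8)
        grids[view] = g & atlas.body_mask(view).astype(np.uint8)
    return BinaryBodyMap(front=grids["front"], back=grids["back"])


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def oracle_segment_counts(atlas, mask) -> tuple[Counter, Counter]:
    """Counter-based per-(segment, side) set-pixel and total-pixel counts.

    Pools front and back views, like the coverage statistics do. Pure
    Python iteration; independent of numpy reductions.
    """
    set_px: Counter = Counter()
    tot_px: Counter = Counter()
    for view in VIEWS:
        lab = atlas.labels[view].ravel()
        sid = atlas.side[view].ravel()
        val = np.asarray(mask.front if view == "front" else mask.back).ravel()
        for L, s, v in zip(lab.tolist(), sid.tolist(), val.tolist()):
            if L == 0:
                continue
            tot_px[(L, s)] += 1
            if v:
                set_px[(L, s)] += v
    return set_px, tot_px


def oracle_point_in_polygon(verts, rows, cols) -> np.ndarray:
    """Fill a polygon by testing every pixel center with matplotlib."""
    from matplotlib.path import Path as MplPath

    path = MplPath([(x * cols - 0.5, y * rows - 0.5) for x, y in verts])
    cc, rr = np.meshgrid(np.arange(cols), np.arange(rows))
    pts = np.column_stack([cc.ravel(), rr.ravel()])
    return path.contains_points(pts).reshape(rows, cols).astype(np.uint8)


def oracle_coverage(atlas, mask, segment: str) -> float:
    """Brute-force pooled coverage percentage of one segment."""
    code = SEGMENT_CODE[segment]
    set_px, tot_px = oracle_segment_counts(atlas, mask)
    n_set = set_px[(code, 1)] + set_px[(code, 2)]
    n_tot = tot_px[(code, 1)] + tot_px[(code, 2)]
    return 100.0 * n_set / n_tot
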