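"""End-to-end orchestration: run the full analysis and emit result files.

`run_analysis` applies the single-organ cohort filter, builds the schematic
atlas, and writes the study's result surfaces: frequency table, per-organ
lateralization summaries, per-organ segment-coverage tables for the pooled
signs and for spontaneous pain, mean body maps (NIfTI and PNG), the mean
number of signs per half segment, a demographics table, and a machine-
readable run manifest. Everything is deterministic given (cohort, config).
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from . import __version__
from .atlas import SegmentAtlas, build_schematic_atlas, save_atlas_nifti, save_atlas_png
from .drawings_io import ANALYZABLE_ORGANS, Cohort, read_cohort, select_single_organ
from .errors import ContractError
from .segstats import (
    MeanBodyMap,
    frequency_table,
    lateralization_summary,
    mean_map,
    mean_signs_per_half_segment,
    round_half_away,
    segment_coverage,
    side_mass,
)

log = logging.getLogger(__name__)


class AnalysisConfig(BaseModel):
    """Tunable parameters of a full analysis run."""

    atlas_rows: int = 132
    atlas_cols: int = 40
    threshold: float = 0.05  # segment inclusion: minimum coverage fraction
    min_per_organ: int = 4
    percent_decimals: int = 1
    outdir: Optional[Path] = None
    maps_dir: Optional[Path] = None  # NIfTI/PNG output; defaults to outdir/maps
    save_maps: bool = True

    @model_validator(mode="after")
    def _check(self):
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")
        if self.min_per_organ < 1:
            raise ValueError("min_per_organ must be >= 1")
        return self


def demographics_summary(cohort: Cohort) -> pd.DataFrame:
    """Simple demographics: n, age mean/SD, sex counts, organ counts.

    Missing demographics are tolerated; the age row is NA when no patient
    carries an age. The SD is the population SD (ddof=0), so a
    single-patient cohort reports SD 0.
    """
    if not cohort.patients:
        raise ContractError("demographics_summary needs a non-empty cohort")
    rows = [{"characteristic": "n", "value": len(cohort.patients)}]
    ages = [p.age for p in cohort.patients if p.age is not None]
    if ages:
        rows.append({"characteristic": "age_mean", "value": float(np.mean(ages))})
        rows.append({"characteristic": "age_sd", "value": float(np.std(ages))})
    else:
        rows.append({"characteristic": "age_mean", "value": float("nan")})
        rows.append({"characteristic": "age_sd", "value": float("nan")})
    for sex in ("female", "male"):
        n = sum(1 for p in cohort.patients if p.sex == sex)
        rows.append({"characteristic": f"sex_{sex}", "value": n})
    organs = sorted({p.organ for p in cohort.patients})
    for organ in organs:
        n = sum(1 for p in cohort.patients if p.organ == organ)
        rows.append({"characteristic": f"organ_{organ}", "value": n})
    return pd.DataFrame(rows)


def run_analysis(
    cohort: Union[Cohort, str, Path], config: AnalysisConfig | None = None
) -> dict:
    """Run the full pipeline on a cohort (object or JSON path).

    Returns a result bundle (dict of DataFrames and mean maps); when
    ``config.outdir`` is set, all tables are written as CSV, mean maps as
    NIfTI+PNG under ``config.maps_dir``, and a manifest as JSON.
    """
    config = config or AnalysisConfig()
    if not isinstance(cohort, Cohort):
        cohort = read_cohort(cohort)
    source = cohort.meta.get("source", "<in-memory>")

    selected = select_single_organ(cohort, min_per_organ=config.min_per_organ)
    atlas = build_schematic_atlas(config.atlas_rows, config.atlas_cols)
    organs = [o for o in ANALYZABLE_ORGANS
              if o in {p.organ for p in selected.patients}]

    bundle: dict = {
        "cohort": selected,
        "atlas": atlas,
        "frequency_table": frequency_table(selected) if selected.patients else None,
        "demographics": demographics_summary(selected) if selected.patients else None,
    }

    lat_tables = [lateralization_summary(selected, organ) for organ in organs]
    bundle["lateralization"] = (
        pd.concat(lat_tables, ignore_index=True) if lat_tables else pd.DataFrame()
    )

    coverage_parts = []
    half_signs_parts = []
    bundle["mean_maps"] = {}
    for organ in organs:
        for what in ("all_signs", "pain"):
            mmap = mean_map(selected, organ, what, atlas)
            bundle["mean_maps"][(organ, what)] = mmap
            cov = segment_coverage(mmap, atlas, threshold=config.threshold)
            cov.insert(0, "organ", organ)
            cov.insert(1, "target", what)
            coverage_parts.append(cov)
        half = mean_signs_per_half_segment(
            selected, organ, atlas, threshold=config.threshold
        )
        half.insert(0, "organ", organ)
        half_signs_parts.append(half)
    bundle["coverage"] = (
        pd.concat(coverage_parts, ignore_index=True) if coverage_parts else pd.DataFrame()
    )
    bundle["mean_signs_per_half_segment"] = (
        pd.concat(half_signs_parts, ignore_index=True)
        if half_signs_parts else pd.DataFrame()
    )

    lat_mass = []
    for organ in organs:
        for what in ("all_signs", "pain"):
            left, right = side_mass(bundle["mean_maps"][(organ, what)], atlas)
            lat_mass.append(
                {
                    "organ": organ,
                    "target": what,
                    "mass_left": left,
                    "mass_right": right,
                    "left_right_ratio": left / right if right > 0 else float("nan"),
                }
            )
    bundle["side_mass"] = pd.DataFrame(lat_mass)

    if config.outdir is not None:
        _write_bundle(bundle, cohort, config, source)
    return bundle


def _write_bundle(bundle: dict, raw_cohort: Cohort, config: AnalysisConfig,
                  source: str) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in (
        "frequency_table",
        "demographics",
        "lateralization",
        "coverage",
        "mean_signs_per_half_segment",
        "side_mass",
    ):
        table = bundle.get(name)
        if isinstance(table, pd.DataFrame):
            table.to_csv(outdir / f"{name}.csv", index=False)
    if config.save_maps:
        maps_dir = Path(config.maps_dir) if config.maps_dir else outdir / "maps"
        maps_dir.mkdir(parents=True, exist_ok=True)
        atlas: SegmentAtlas = bundle["atlas"]
        save_atlas_nifti(atlas, maps_dir / "atlas.nii.gz")
        save_atlas_png(atlas, maps_dir / "atlas.png")
        for (organ, what), mmap in bundle["mean_maps"].items():
            _save_mean_map(mmap, maps_dir / f"mean_{organ}_{what}")
    manifest = {
        "package": "segmaps",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "source": source,
        "cohort_meta": {k: v for k, v in raw_cohort.meta.items() if k != "source"},
        "config": json.loads(config.model_dump_json(exclude={"outdir", "maps_dir"})),
        "n_input": len(raw_cohort.patients),
        "n_retained": len(bundle["cohort"].patients),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("analysis bundle written to %s", outdir)


def _save_mean_map(mmap: MeanBodyMap, stem: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import nibabel as nib

    vol = np.stack([mmap.front, mmap.back], axis=-1).astype(np.float32)
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(stem.with_suffix(".nii.gz")))
    fig, axes = plt.subplots(1, 2, figsize=(6, 8))
    for ax, (view, grid) in zip(axes, (("front", mmap.front), ("back", mmap.back))):
        im = ax.imshow(grid, cmap="hot", vmin=0, vmax=max(grid.max(), 1e-9),
                       interpolation="nearest")
        ax.set_title(f"{mmap.organ} {mmap.what} {view} (n={mmap.n})")
        ax.axis("off")
    fig.colorbar(im, ax=axes, shrink=0.6)
    fig.savefig(stem.with_suffix(".png"), dpi=120)
    plt.close(fig)
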