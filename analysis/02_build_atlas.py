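"""Build the schematic segmental body atlas and check its bookkeeping.

Constructs the 132x40 front/back atlas (33 segments: V1-V3, C2-C8, T1-T12,
L1-L5, S1-S5, Cog1), writes the per-(segment, side, view) pixel counts to
results/, and exports the label volume (NIfTI) plus a visual-check PNG to
scratch/ (binary artifacts).
"""

from pathlib import Path

from segmaps import build_schematic_atlas, segment_pixel_counts
from segmaps.atlas import save_atlas_nifti, save_atlas_png

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    atlas = build_schematic_atlas(132, 40)
    counts = segment_pixel_counts(atlas)
    counts.to_csv(RESULTS / "atlas_pixel_counts.csv", index=False)
    body = sum(int(atlas.body_mask(v).sum()) for v in ("front", "back"))
    assert counts["n_pixels"].sum() == body  # partition property
    print(f"atlas 132x40: {body} body pixels partitioned into 33 segments x 2 sides")
    print(f"per-segment pixel counts -> {RESULTS/'atlas_pixel_counts.csv'}")
    save_atlas_nifti(atlas, SCRATCH / "atlas.nii.gz")
    save_atlas_png(atlas, SCRATCH / "atlas_preview.png")
    print(f"label volume and preview image -> {SCRATCH}/")


if __name__ == "__main__":
    main()
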