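"""Run the full segmental analysis on the simulated cohort.

Applies the single-organ filter (>=4 patients per organ group), rasterizes
every drawing, and writes the study's result surfaces to results/: the
frequency table, per-organ lateralization summaries, per-organ segment
coverage (all signs pooled and spontaneous pain separately, 5% inclusion
rule), the mean number of signs per half segment, demographics, and a run
manifest. Mean body maps (NIfTI/PNG) go to scratch/.

Run analysis/01_simulate_cohort.py first.
"""

from pathlib import Path

from segmaps import AnalysisConfig, run_analysis

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    config = AnalysisConfig(outdir=RESULTS, maps_dir=SCRATCH / "maps")
    bundle = run_analysis(SCRATCH / "cohort.json", config)

    cohort = bundle["cohort"]
    print(f"retained {len(cohort.patients)} single-organ patients")
    ft = bundle["frequency_table"].set_index("finding")
    for key in ("spontaneous_pain", "at_least_1_segmental_sign",
                "superficial_hyperalgesia", "muscle_resistance", "mydriasis"):
        row = ft.loc[key]
        print(f"  {key:28s} {row['n']:3d} ({row['percent']:.1f}%)")

    lat = bundle["lateralization"]
    myd = lat[(lat.finding == "mydriasis")]
    print("mydriasis lateralization (percent ipsilateral; NA for paired organs):")
    for _, r in myd.iterrows():
        pct = "NA" if r.percent_ipsilateral != r.percent_ipsilateral else f"{r.percent_ipsilateral:.0f}%"
        print(f"  {r.organ:20s} left {r.n_left:3d} right {r.n_right:3d} -> {pct}")
    print(f"tables -> {RESULTS}/, mean maps -> {SCRATCH/'maps'}/")


if __name__ == "__main__":
    main()
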