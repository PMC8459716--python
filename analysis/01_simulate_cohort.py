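"""Generate the default synthetic study cohort.

Emulates the recruitment flow of the emergency-room study: 208 patients,
of whom 110 fall into the five analyzable single-organ groups (heart 62,
lungs 18, stomach 10, liver/gallbladder 12, kidneys/ureters 8), plus 50
undiagnosed, 39 multi-organ, and 9 other single-organ patients. Writes the
cohort and its generative ground truth under scratch/ (bulky regenerable
data); downstream drivers read them from there.
"""

from pathlib import Path
import json

from segmaps import default_spec, generate, write_cohort

SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
SEED = 2017  # study recruitment year


def main() -> None:
    SCRATCH.mkdir(exist_ok=True)
    spec = default_spec(n=208, seed=SEED)
    cohort, truth = generate(spec)
    write_cohort(cohort, SCRATCH / "cohort.json")
    (SCRATCH / "ground_truth.json").write_text(json.dumps(truth, indent=1))

    by_organ: dict[str, int] = {}
    for p in cohort.patients:
        by_organ[p.organ] = by_organ.get(p.organ, 0) + 1
    print(f"simulated {len(cohort.patients)} patients (seed {SEED})")
    for organ, n in sorted(by_organ.items(), key=lambda kv: -kv[1]):
        print(f"  {organ:20s} {n:4d}")
    print(f"wrote {SCRATCH/'cohort.json'} and ground_truth.json")


if __name__ == "__main__":
    main()
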