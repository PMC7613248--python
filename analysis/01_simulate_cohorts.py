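"""Simulate the two injury cohorts (two replicate hearts each).

Clone-independent: every clone converts endocardium to nppc-like
fibroblasts at 50%. Clone-dependent: rates alternate 30% / 80% across
clones. Writes reads, annotations and ground truth under results/sim/.
"""

from pathlib import Path

from scartree import io, scenarios
from scartree.simulate import simulate_dataset

SEED = 20260927 % 100_000
OUT = Path(__file__).resolve().parents[1] / "results" / "sim"

COHORTS = {
    "clone_independent": scenarios.clone_independent_config,
    "clone_dependent": scenarios.clone_dependent_config,
}


def main() -> None:
    for cohort, make in COHORTS.items():
        outdir = OUT / cohort
        outdir.mkdir(parents=True, exist_ok=True)
        for r in range(2):
            rep = f"R{r + 1}"
            cfg = make(seed=SEED + 1000 * r, replicate=rep)
            truth, reads, ann = simulate_dataset(cfg)
            io.write_reads(reads, outdir / f"reads_{rep}.tsv")
            io.write_annotation(ann, outdir / f"annotation_{rep}.csv")
            (outdir / f"truth_{rep}.json").write_text(truth.to_json())
            n_types = ann["cell_type"].value_counts().to_dict()
            print(f"{cohort}/{rep}: {len(reads)} reads, {len(ann)} cells, {n_types}")


if __name__ == "__main__":
    main()
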