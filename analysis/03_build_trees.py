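"""Reconstruct one scar lineage tree per replicate heart and place cells.

Writes tree JSON plus Newick exports and reports placement statistics.
"""

from pathlib import Path

from scartree import io
from scartree.tree import build_tree

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for cohort_dir in sorted((RESULTS / "sim").iterdir()):
        for profiles_path in sorted(cohort_dir.glob("profiles_*.json")):
            rep = profiles_path.stem.split("_")[1]
            profiles = io.read_profiles(profiles_path)
            tree, conflicts = build_tree(profiles, replicate=rep)
            io.write_tree(tree, cohort_dir / f"tree_{rep}.json")
            io.write_newick(tree, cohort_dir / f"tree_{rep}.nwk")
            print(
                f"{cohort_dir.name}/{rep}: {len(tree.nodes)} nodes, "
                f"{tree.n_cells()} cells placed, {len(conflicts)} conflicts"
            )


if __name__ == "__main__":
    main()
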