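"""Replicate-integrated weighted lineage correlations and cell-type clusters.

Contracts each tree to its lineage splits, pools node compositions across
the two replicate hearts, computes the size-weighted correlation matrix
and cuts the average-linkage dendrogram at distance 0.6.
"""

from pathlib import Path

import pandas as pd

from scartree import io
from scartree.lineage import (
    cluster_cell_types,
    contract_vertical_branches,
    node_composition,
    weighted_correlation,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def load_cohort(cohort_dir: Path):
    trees = [
        contract_vertical_branches(io.read_tree(p))
        for p in sorted(cohort_dir.glob("tree_*.json"))
    ]
    ann = pd.concat(
        [io.read_annotation(p) for p in sorted(cohort_dir.glob("annotation_*.csv"))],
        ignore_index=True,
    )
    return trees, ann


def main() -> None:
    for cohort_dir in sorted((RESULTS / "sim").iterdir()):
        trees, ann = load_cohort(cohort_dir)
        comp = node_composition(trees, ann)
        corr = weighted_correlation(comp)
        io.write_matrix_tsv(corr, cohort_dir / "correlation.tsv")
        labels = cluster_cell_types(corr, distance_threshold=0.6)
        labels.to_csv(cohort_dir / "clusters.tsv", sep="\t")
        print(f"== {cohort_dir.name}: {len(comp.counts)} nodes pooled")
        print(corr.round(2).to_string())
        print("clusters:", labels.to_dict())


if __name__ == "__main__":
    main()
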