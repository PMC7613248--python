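"""Leaf-level conditional co-occurrence probabilities per cohort.

The targeted statistic: among leaves containing the derived transient
type, how often is the putative source present? Asymmetry between
P(source | derived) and P(derived | source) diagnoses a clone-restricted
origin, as only a subset of source clones responds.
"""

from pathlib import Path

from scartree.lineage import conditional_probability
from scartree.scenarios import DERIVED_TYPE, SOURCE_TYPE

import importlib.util as _ilu

_spec = _ilu.spec_from_file_location(
    "corr_step", Path(__file__).with_name("04_lineage_correlation.py")
)
corr_step = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(corr_step)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for cohort_dir in sorted((RESULTS / "sim").iterdir()):
        trees, ann = corr_step.load_cohort(cohort_dir)
        prob, n_leaves = conditional_probability(trees, ann)
        prob.to_csv(cohort_dir / "conditional_probability.tsv", sep="\t")
        n_leaves.to_csv(cohort_dir / "leaf_counts.tsv", sep="\t")
        p_sd = prob.loc[SOURCE_TYPE, DERIVED_TYPE]
        p_ds = prob.loc[DERIVED_TYPE, SOURCE_TYPE]
        print(
            f"{cohort_dir.name}: P({SOURCE_TYPE}|{DERIVED_TYPE}) = {p_sd:.3f} "
            f"over {n_leaves[DERIVED_TYPE]} leaves; "
            f"P({DERIVED_TYPE}|{SOURCE_TYPE}) = {p_ds:.3f}"
        )


if __name__ == "__main__":
    main()
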