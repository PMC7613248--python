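"""Canonical simulation scenarios used throughout the analysis.

Two cohorts contrast the behaviours that motivate the two lineage
statistics. Both share the same developmental structure — six division
generations, scars on 60% of segments, four clones (clades at two
divisions), and an endocardium-like source type that is abundant in two
clones (60%) and scarcer (30%) in the other two, so node compositions vary
across clones far more than the binomial conversion noise within nodes,
while even source-poor leaves hold enough source cells that a responding
leaf essentially never converts them all:

* clone-independent: every clone converts source cells to the transient
  derived state at the same global rate (0.5) — correlation-based
  clustering is stable;
* clone-dependent: conversion rates alternate 0.3 / 0.8 across clones —
  the source/derived correlation collapses while the leaf-level
  conditional probability P(source | derived) stays near 1.

Readout is noiseless (full detection, exact reads, no doublets) so these
cohorts probe the statistics, not the error model. Two replicate "hearts"
of 2,000 cells each per cohort mirror replicate integration.
"""

from __future__ import annotations

from .simulate import CountDist, SimConfig, TransitionSpec

SOURCE_TYPE = "endocardium"
DERIVED_TYPE = "nppc_fibro"

_PROPENSITIES = {
    "c0": {"endocardium": 0.6, "fibro_a": 0.3, "epicardium": 0.1},
    "c1": {"endocardium": 0.6, "fibro_a": 0.3, "epicardium": 0.1},
    "c2": {"endocardium": 0.3, "fibro_b": 0.6, "epicardium": 0.1},
    "c3": {"endocardium": 0.3, "fibro_b": 0.6, "epicardium": 0.1},
}

CLONE_INDEPENDENT_RATE = 0.5
# The strongly responding clones are the source-poor ones (an injury hits a
# region, not the clones where the source type happens to be abundant), so
# derived abundance decouples from the overall clone composition axis.
CLONE_DEPENDENT_RATES = {"c0": 0.3, "c1": 0.3, "c2": 0.8, "c3": 0.8}


def _base_config(seed: int, replicate: str, transition: TransitionSpec) -> SimConfig:
    return SimConfig(
        n_generations=6,
        scar_rate=0.6,
        allele_alphabet_size=400,
        n_cells=4000,
        clone_depth=2,
        clone_type_propensities=_PROPENSITIES,
        transitions=(transition,),
        detection_prob=1.0,
        molecules_per_scar=CountDist("constant", 1),
        reads_per_molecule=CountDist("constant", 2),
        substitution_error_rate=0.0,
        doublet_rate=0.0,
        replicate=replicate,
        timepoint="7dpi",
        seed=seed,
    )


def clone_independent_config(seed: int, replicate: str = "R1") -> SimConfig:
    t = TransitionSpec(SOURCE_TYPE, DERIVED_TYPE, rate=CLONE_INDEPENDENT_RATE)
    return _base_config(seed, replicate, t)


def clone_dependent_config(seed: int, replicate: str = "R1") -> SimConfig:
    t = TransitionSpec(SOURCE_TYPE, DERIVED_TYPE, clone_rates=CLONE_DEPENDENT_RATES)
    return _base_config(seed, replicate, t)


def noiseless_recovery_config(seed: int, replicate: str = "R1") -> SimConfig:
    """Small noiseless experiment for exact tree-topology recovery:
    four generations (30 segments, scar rate 2/3 — an expected 20
    scar-creation events), 500 cells, full detection."""
    return SimConfig(
        n_generations=4,
        scar_rate=2.0 / 3.0,
        allele_alphabet_size=100,
        n_cells=500,
        clone_depth=2,
        clone_type_propensities={"default": {"typeA": 0.5, "typeB": 0.5}},
        transitions=(),
        detection_prob=1.0,
        molecules_per_scar=CountDist("constant", 1),
        reads_per_molecule=CountDist("constant", 2),
        substitution_error_rate=0.0,
        doublet_rate=0.0,
        replicate=replicate,
        timepoint="ctrl",
        seed=seed,
    )
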