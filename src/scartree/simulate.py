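"""Synthetic clonal-barcoding data with clone-dependent injury responses.

Emulates a zebrafish-style lineage-recording experiment: Cas9 creates
heritable genetic scars on a transgene during early development, cells
differentiate with clone-biased type propensities, an injury converts some
source-type cells into a transient derived state (at a rate that may differ
between clones), and the scars are finally read out by single-cell
sequencing with dropout, amplification noise, substitution errors and
doublets.

The ground truth (scar-event tree, clone membership, realized transitions)
is retained so that downstream reconstruction can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

BASES = np.array(list("ACGT"))
SCAR_LEN = 75
BARCODE_LEN = 16
UMI_LEN = 10

__all__ = [
    "SimConfig",
    "TransitionSpec",
    "CountDist",
    "Cell",
    "SimTruth",
    "simulate_development",
    "apply_injury_transitions",
    "simulate_scar_readout",
    "simulate_dataset",
    "profiles_from_population",
]


class AlleleExhaustionError(RuntimeError):
    """More scar-creation events than distinct alleles in the alphabet."""


@dataclass(frozen=True)
class CountDist:
    """Small distribution spec for per-molecule read counts and
    per-scar molecule counts.

    kind "constant": always round(mean); kind "poisson": 1 + Poisson(mean-1),
    so the support starts at 1 and the mean is the requested mean.
    """

    kind: str = "poisson"
    mean: float = 4.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "poisson"):
            raise ValueError(f"unknown count distribution kind {self.kind!r}")
        if self.mean < 1:
            raise ValueError("count distribution mean must be >= 1")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "constant":
            return np.full(size, int(round(self.mean)), dtype=int)
        return 1 + rng.poisson(self.mean - 1.0, size=size)


@dataclass(frozen=True)
class TransitionSpec:
    """An injury-induced conversion source -> derived transient state.

    Either ``rate`` (clone-independent, one global rate) or ``clone_rates``
    (map clone id -> rate, with optional "default" key) must be given.
    """

    source: str
    derived: str
    rate: float | None = None
    clone_rates: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if (self.rate is None) == (self.clone_rates is None):
            raise ValueError("give exactly one of rate / clone_rates")
        rates = [self.rate] if self.rate is not None else list(self.clone_rates.values())
        for r in rates:
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"transition rate {r} outside [0, 1]")

    def rate_for(self, clone: str) -> float:
        if self.rate is not None:
            return self.rate
        if clone in self.clone_rates:
            return self.clone_rates[clone]
        if "default" in self.clone_rates:
            return self.clone_rates["default"]
        raise KeyError(
            f"no transition rate for clone {clone!r} and no 'default' supplied"
        )


@dataclass
class SimConfig:
    """Parameters of one synthetic clonal-barcoding experiment.

    clone_type_propensities maps clone id ("c0", "c1", ... or "default")
    to a distribution over base cell types. Clones are the clades at
    ``clone_depth`` divisions, so there are 2**clone_depth of them.
    """

    n_generations: int = 5
    scar_rate: float = 0.6
    allele_alphabet_size: int = 1000
    n_cells: int = 2000
    clone_depth: int = 2
    clone_type_propensities: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"default": {"typeA": 0.5, "typeB": 0.5}}
    )
    transitions: Sequence[TransitionSpec] = field(default_factory=tuple)
    detection_prob: float = 1.0
    molecules_per_scar: CountDist = field(default_factory=lambda: CountDist("poisson", 2.0))
    reads_per_molecule: CountDist = field(default_factory=lambda: CountDist("poisson", 4.0))
    substitution_error_rate: float = 0.0
    doublet_rate: float = 0.0
    allele_reuse: bool = False
    replicate: str = "R1"
    timepoint: str = "7dpi"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not (0 <= self.clone_depth <= self.n_generations):
            raise ValueError("clone_depth must be in [0, n_generations]")
        for name, p in [
            ("scar_rate", self.scar_rate),
            ("detection_prob", self.detection_prob),
            ("substitution_error_rate", self.substitution_error_rate),
            ("doublet_rate", self.doublet_rate),
        ]:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1]")
        for clone, dist in self.clone_type_propensities.items():
            tot = float(sum(dist.values()))
            if not np.isclose(tot, 1.0):
                raise ValueError(f"type propensities for {clone!r} sum to {tot}, not 1")

    def propensities_for(self, clone: str) -> Mapping[str, float]:
        if clone in self.clone_type_propensities:
            return self.clone_type_propensities[clone]
        if "default" in self.clone_type_propensities:
            return self.clone_type_propensities["default"]
        raise KeyError(f"no type propensities for clone {clone!r} and no 'default'")


@dataclass
class Cell:
    cell_id: str
    leaf: int  # leaf index in the division tree, 0 .. 2**G - 1
    clone: str
    base_type: str
    realized_type: str
    scars: tuple[str, ...]  # alleles on the root path, root-to-leaf order


@dataclass
class SimTruth:
    """Ground truth of one simulation, for recovery scoring.

    scar_parent maps each created allele to the allele created on the
    nearest scarred ancestor segment (None for alleles directly below the
    unscarred zygote). scar_segment records (generation, node index within
    generation) of the segment that acquired the allele.
    """

    scar_parent: dict[str, str | None]
    scar_segment: dict[str, tuple[int, int]]
    clone_of_cell: dict[str, str]
    base_type_of_cell: dict[str, str]
    realized_type_of_cell: dict[str, str]
    rates_used: list[dict]
    barcode_of_cell: dict[str, str] = field(default_factory=dict)
    doublet_members: dict[str, tuple[str, str]] = field(default_factory=dict)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1, sort_keys=True)


def _random_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    idx = rng.integers(0, 4, size=(n, length))
    return ["".join(row) for row in BASES[idx]]


def _unique_random_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        for s in _random_seqs(rng, n - len(out), length):
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def simulate_development(config: SimConfig) -> tuple[SimTruth, list[Cell]]:
    """Run early development: binary divisions, scar creation, cell typing.

    Each lineage segment (edge of the division tree) independently acquires
    at most one new scar allele with probability ``scar_rate``; a cell
    inherits every scar on its root path. Clones are the clades at
    ``clone_depth`` divisions and set the base-type propensities.
    """
    rng = np.random.default_rng([config.seed, 1])
    G = config.n_generations

    # Segment (g, k): edge entering node k of generation g (1-based g).
    segments = [(g, k) for g in range(1, G + 1) for k in range(2**g)]
    scarred = rng.random(len(segments)) < config.scar_rate
    n_events = int(scarred.sum())
    if n_events > config.allele_alphabet_size and not config.allele_reuse:
        raise AlleleExhaustionError(
            f"{n_events} scar-creation events but only "
            f"{config.allele_alphabet_size} alleles in the alphabet; enlarge "
            "allele_alphabet_size or enable allele_reuse"
        )
    pool = _unique_random_seqs(rng, config.allele_alphabet_size, SCAR_LEN)
    if config.allele_reuse:
        # Skewed reuse: allele ranks drawn from a geometric-ish distribution,
        # so early ranks recur — a stress test for tree building.
        ranks = np.minimum(
            rng.geometric(p=3.0 / config.allele_alphabet_size, size=n_events) - 1,
            config.allele_alphabet_size - 1,
        )
        alleles = [pool[r] for r in ranks]
    else:
        alleles = pool[:n_events]

    scar_at: dict[tuple[int, int], str] = {}
    it = iter(alleles)
    for seg, has in zip(segments, scarred):
        if has:
            scar_at[seg] = next(it)

    def root_path(leaf: int) -> list[tuple[int, int]]:
        return [(g, leaf >> (G - g)) for g in range(1, G + 1)]

    scar_parent: dict[str, str | None] = {}
    scar_segment: dict[str, tuple[int, int]] = {}
    for (g, k), allele in scar_at.items():
        parent = None
        for ga in range(g - 1, 0, -1):
            anc = (ga, k >> (g - ga))
            if anc in scar_at:
                parent = scar_at[anc]
                break
        # With allele reuse the same allele can be created twice; the first
        # recorded event wins for the truth tree (recovery is then undefined).
        scar_parent.setdefault(allele, parent)
        scar_segment.setdefault(allele, (g, k))

    leaves = rng.integers(0, 2**G, size=config.n_cells)
    cells: list[Cell] = []
    clone_of: dict[str, str] = {}
    base_of: dict[str, str] = {}
    for i, leaf in enumerate(leaves):
        cid = f"cell{i:05d}"
        clone = f"c{leaf >> (G - config.clone_depth)}" if config.clone_depth else "c0"
        props = config.propensities_for(clone)
        types = list(props)
        btype = types[rng.choice(len(types), p=np.array([props[t] for t in types]))]
        scars = tuple(
            scar_at[seg] for seg in root_path(int(leaf)) if seg in scar_at
        )
        cells.append(Cell(cid, int(leaf), clone, btype, btype, scars))
        clone_of[cid] = clone
        base_of[cid] = btype

    truth = SimTruth(
        scar_parent=scar_parent,
        scar_segment=scar_segment,
        clone_of_cell=clone_of,
        base_type_of_cell=base_of,
        realized_type_of_cell=dict(base_of),
        rates_used=[dataclasses.asdict(t) for t in config.transitions],
    )
    return truth, cells


def apply_injury_transitions(
    cells: list[Cell],
    transitions: Sequence[TransitionSpec],
    seed: int | np.random.Generator,
    truth: SimTruth | None = None,
) -> list[Cell]:
    """Convert source-type cells to their derived transient state.

    Each source cell converts independently with its clone's rate
    (clone-independent specs use one global rate). Mutates nothing;
    returns a new population. If ``truth`` is given its realized-type map
    is updated in place.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng([seed, 2])
    present = {c.realized_type for c in cells}
    for t in transitions:
        if t.source not in present:
            raise ValueError(f"transition source type {t.source!r} not in population")
    out: list[Cell] = []
    for c in cells:
        new_type = c.realized_type
        for t in transitions:
            if new_type == t.source and rng.random() < t.rate_for(c.clone):
                new_type = t.derived
        out.append(dataclasses.replace(c, realized_type=new_type))
        if truth is not None:
            truth.realized_type_of_cell[c.cell_id] = new_type
    return out


def _mutate_reads(seqs: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    if rate == 0.0 or not seqs:
        return seqs
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1).copy()
    hit = rng.random(arr.shape) < rate
    n_hits = int(hit.sum())
    if n_hits:
        # substitute with a uniformly random different base
        cur = arr[hit]
        repl = BASES[rng.integers(0, 4, size=n_hits)].astype("S1")
        same = repl == cur
        while same.any():
            repl[same] = BASES[rng.integers(0, 4, size=int(same.sum()))].astype("S1")
            same = repl == cur
        arr[hit] = repl
    return [row.tobytes().decode() for row in arr]


def simulate_scar_readout(
    cells: list[Cell],
    config: SimConfig,
    truth: SimTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sequence the population: returns (read table, cell annotation).

    Per cell, each true scar is detected with ``detection_prob``; a detected
    scar yields molecules (distinct UMIs drawn uniformly from the 10-base
    UMI space, collisions allowed) with read counts from
    ``reads_per_molecule``; each read suffers independent per-base
    substitution errors. With probability ``doublet_rate`` a droplet fuses
    two cells under one barcode (the annotation then reports the first
    member's type; provenance goes to ``truth.doublet_members``).
    """
    rng = np.random.default_rng([config.seed, 3])
    barcodes = _unique_random_seqs(rng, len(cells), BARCODE_LEN)

    # group cells into droplets
    order = rng.permutation(len(cells))
    droplets: list[tuple[Cell, ...]] = []
    i = 0
    while i < len(order):
        if i + 1 < len(order) and rng.random() < config.doublet_rate:
            droplets.append((cells[order[i]], cells[order[i + 1]]))
            i += 2
        else:
            droplets.append((cells[order[i]],))
            i += 1

    bc_rows, umi_rows, seq_rows = [], [], []
    ann_rows = []
    for bc, members in zip(barcodes, droplets):
        for c in members:
            if truth is not None:
                truth.barcode_of_cell[c.cell_id] = bc
        if len(members) == 2 and truth is not None:
            truth.doublet_members[bc] = (members[0].cell_id, members[1].cell_id)
        ann_rows.append(
            (bc, members[0].realized_type, config.replicate, config.timepoint)
        )
        for c in members:
            if not c.scars:
                continue
            detected = rng.random(len(c.scars)) < config.detection_prob
            det_scars = [s for s, d in zip(c.scars, detected) if d]
            if not det_scars:
                continue
            n_mol = config.molecules_per_scar.sample(rng, len(det_scars))
            for scar, nm in zip(det_scars, n_mol):
                umi_idx = rng.integers(0, 4, size=(nm, UMI_LEN))
                umis = ["".join(row) for row in BASES[umi_idx]]
                n_reads = config.reads_per_molecule.sample(rng, nm)
                for umi, nr in zip(umis, n_reads):
                    bc_rows.extend([bc] * int(nr))
                    umi_rows.extend([umi] * int(nr))
                    seq_rows.extend([scar] * int(nr))

    seq_rows = _mutate_reads(seq_rows, config.substitution_error_rate, rng)
    reads = pd.DataFrame(
        {"cell_barcode": bc_rows, "umi": umi_rows, "scar_seq": seq_rows}
    )
    annotation = pd.DataFrame(
        ann_rows, columns=["cell_barcode", "cell_type", "replicate", "timepoint"]
    )
    return reads, annotation


def simulate_dataset(config: SimConfig) -> tuple[SimTruth, pd.DataFrame, pd.DataFrame]:
    """Development + injury transitions + readout in one call."""
    truth, cells = simulate_development(config)
    if config.transitions:
        cells = apply_injury_transitions(
            cells, config.transitions, np.random.default_rng([config.seed, 2]), truth
        )
    reads, annotation = simulate_scar_readout(cells, config, truth)
    return truth, reads, annotation


def profiles_from_population(cells: list[Cell]) -> dict[str, dict[str, int]]:
    """Noise-free scar profiles keyed by cell id (one molecule per scar)."""
    return {c.cell_id: {s: 1 for s in c.scars} for c in cells}
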