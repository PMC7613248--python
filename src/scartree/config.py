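"""Pipeline configuration: validated parameters with YAML round-tripping."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs.

    Either ``simulate_scenario`` (clone_independent | clone_dependent |
    noiseless, with ``n_replicates``) or ``reads_path``/``annotation_path``
    supplies the input. The single ``seed`` feeds every random stage
    through fixed substreams, so changing ``reps`` in one stage does not
    perturb another.
    """

    # inputs
    simulate_scenario: str | None = None
    n_replicates: int = 2
    reads_path: str | None = None
    annotation_path: str | None = None
    # filter parameters
    min_reads: int = 2
    max_hamming: int = 2
    # tree parameters
    min_cells: int = 1
    # analysis parameters
    subtree_inclusive: bool = True
    linkage: str = "average"
    n_clusters: int | None = None
    distance_threshold: float | None = 0.6
    stability_mode: str = "nodes"
    fraction: float = 0.5
    reps: int = 1000
    targets: list[str] = field(default_factory=list)
    # secretome parameters
    scale: float = 10000.0
    cap: float = 5.0
    min_z: float = 2.0
    min_mean: float = 10.0
    # run metadata
    seed: int = 0
    run_name: str = "run"

    def __post_init__(self) -> None:
        if self.simulate_scenario is None and self.reads_path is None:
            raise ValueError("config needs simulate_scenario or reads_path")
        if self.simulate_scenario is not None and self.simulate_scenario not in (
            "clone_independent", "clone_dependent", "noiseless"
        ):
            raise ValueError(f"unknown scenario {self.simulate_scenario!r}")
        if self.reads_path is not None and self.annotation_path is None:
            raise ValueError("reads_path requires annotation_path")
        if self.min_reads < 1 or self.max_hamming < 0 or self.min_cells < 1:
            raise ValueError("invalid filter/tree parameters")
        if not (0 < self.fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")
        if self.reps < 1 or self.n_replicates < 1:
            raise ValueError("reps and n_replicates must be >= 1")
        if self.stability_mode not in ("cells", "nodes"):
            raise ValueError("stability_mode must be 'cells' or 'nodes'")
        if (self.n_clusters is None) == (self.distance_threshold is None):
            raise ValueError("give exactly one of n_clusters / distance_threshold")
        for name in ("scale", "cap", "min_z", "min_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
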