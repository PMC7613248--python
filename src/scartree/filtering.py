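"""Molecule-level filtering of single-cell scar reads.

Raw amplicon reads carry sequencing and PCR artifacts: singleton reads,
chimeric barcode/UMI/scar combinations, near-identical scar variants, and
cell doublets. The cascade here turns a read table (cell_barcode, umi,
scar_seq — one row per read) into per-cell scar profiles:

1. truncate scar sequences to 75 nt, dropping shorter ones;
2. collapse reads to molecules, requiring >= 2 reads per molecule;
3. resolve ambiguous assignments: most prevalent scar per (barcode, UMI),
   then UMI per (barcode, scar), then barcode per (UMI, scar);
4. within each cell, merge scar alleles within Hamming distance 2 unless
   both are independently credible;
5. flag likely doublets by an excess distinct-scar count relative to the
   cell type's distribution.

All tie-breaks are deterministic: highest read support first, then the
lexicographically smallest sequence/identifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCAR_LEN = 75
MOLECULE_COLUMNS = ["cell_barcode", "umi", "scar_seq", "n_reads"]

__all__ = [
    "CellScarProfile",
    "FilterLog",
    "truncate_and_length_filter",
    "collapse_reads_to_molecules",
    "resolve_ambiguous_assignments",
    "merge_similar_scars",
    "remove_scar_doublets",
    "run_filter_pipeline",
    "hamming",
]


@dataclass
class CellScarProfile:
    cell_barcode: str
    scars: dict[str, int]  # allele -> molecule count
    doublet_flag: bool = False


@dataclass
class FilterLog:
    """Record-count audit trail of the cascade."""

    stages: list[tuple[str, int]] = field(default_factory=list)

    def record(self, stage: str, n: int) -> None:
        self.stages.append((stage, n))
        logger.info("%s: %d records", stage, n)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "records"])


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance undefined for unequal lengths")
    return sum(x != y for x, y in zip(a, b))


def truncate_and_length_filter(
    reads: pd.DataFrame, length: int = SCAR_LEN, primer_prefix: str | None = None
) -> pd.DataFrame:
    """Truncate scar sequences to ``length`` nt and drop shorter reads.

    ``primer_prefix`` optionally drops reads not starting with the exact
    amplicon primer (normally removed upstream during alignment).
    """
    out = reads
    if primer_prefix:
        keep = out["scar_seq"].str.startswith(primer_prefix)
        logger.info("primer check dropped %d reads", int((~keep).sum()))
        out = out[keep]
    lens = out["scar_seq"].str.len()
    short = int((lens < length).sum())
    out = out.loc[lens >= length].copy()
    out["scar_seq"] = out["scar_seq"].str[:length]
    logger.info("length filter dropped %d reads shorter than %d", short, length)
    if out.empty:
        logger.warning("no reads survive the length filter")
    return out.reset_index(drop=True)


def collapse_reads_to_molecules(reads: pd.DataFrame, min_reads: int = 2) -> pd.DataFrame:
    """Deduplicate reads to molecules and require read support.

    One molecule per (cell_barcode, umi, scar_seq) with its read count;
    molecules with fewer than ``min_reads`` reads are discarded as
    straightforward sequencing errors.
    """
    if reads.empty:
        return pd.DataFrame(columns=MOLECULE_COLUMNS)
    mol = (
        reads.groupby(["cell_barcode", "umi", "scar_seq"], sort=True)
        .size()
        .rename("n_reads")
        .reset_index()
    )
    return mol[mol["n_reads"] >= min_reads].reset_index(drop=True)


def _keep_most_prevalent(
    mol: pd.DataFrame, group: list[str], value: str
) -> pd.DataFrame:
    """Keep, per ``group``, the row with the highest read count; ties go to
    the lexicographically smallest ``value``."""
    srt = mol.sort_values(
        by=group + ["n_reads", value], ascending=[True] * len(group) + [False, True]
    )
    return srt.drop_duplicates(subset=group, keep="first")


def resolve_ambiguous_assignments(molecules: pd.DataFrame) -> pd.DataFrame:
    """Remove chimeric molecules by sequential most-prevalent selection.

    In order: one scar per (barcode, UMI); one UMI per (barcode, scar);
    one barcode per (UMI, scar). Later passes only drop rows, so earlier
    uniqueness is preserved and the operation is idempotent.
    """
    if molecules.empty:
        return molecules.copy()
    mol = _keep_most_prevalent(molecules, ["cell_barcode", "umi"], "scar_seq")
    mol = _keep_most_prevalent(mol, ["cell_barcode", "scar_seq"], "umi")
    mol = _keep_most_prevalent(mol, ["umi", "scar_seq"], "cell_barcode")
    return mol.sort_values(MOLECULE_COLUMNS[:3]).reset_index(drop=True)


def _keep_both(
    a: str,
    b: str,
    counts: dict[str, int],
    cells_with: dict[str, set[str]],
    barcode: str,
    min_molecules: int = 2,
    min_solo_cells: int = 2,
) -> bool:
    """Are two similar alleles both independently credible in this cell?

    Both are kept iff each has >= ``min_molecules`` molecules here AND each
    is seen without the other in >= ``min_solo_cells`` other cells. This is
    the cross-cell-evidence reading of "verifiably correct".
    """
    if counts[a] < min_molecules or counts[b] < min_molecules:
        return False
    solo_a = cells_with.get(a, set()) - cells_with.get(b, set()) - {barcode}
    solo_b = cells_with.get(b, set()) - cells_with.get(a, set()) - {barcode}
    return len(solo_a) >= min_solo_cells and len(solo_b) >= min_solo_cells


def merge_similar_scars(
    molecules: pd.DataFrame, max_hamming: int = 2
) -> dict[str, CellScarProfile]:
    """Collapse per-cell scar alleles within ``max_hamming`` substitutions.

    Within each cell, allele pairs at Hamming distance <= ``max_hamming``
    are kept separate only if both pass the keep-both criteria; otherwise
    the minor allele (fewer molecules, then fewer reads, then
    lexicographically larger) is absorbed into the major one with counts
    summed. Returns per-cell profiles keyed by barcode.
    """
    if molecules.empty:
        return {}
    per = molecules.groupby(["cell_barcode", "scar_seq"]).agg(
        n_mol=("scar_seq", "size"), n_reads=("n_reads", "sum")
    )
    cells_with: dict[str, set[str]] = {}
    for (bc, scar) in per.index:
        cells_with.setdefault(scar, set()).add(bc)

    profiles: dict[str, CellScarProfile] = {}
    for bc, sub in per.groupby(level=0, sort=True):
        counts = {scar: int(n) for (_, scar), n in sub["n_mol"].items()}
        reads = {scar: int(n) for (_, scar), n in sub["n_reads"].items()}
        # major-first processing order
        order = sorted(counts, key=lambda s: (-counts[s], -reads[s], s))
        changed = True
        while changed:
            changed = False
            order = sorted(counts, key=lambda s: (-counts[s], -reads[s], s))
            for i in range(len(order)):
                for j in range(i + 1, len(order)):
                    a, b = order[i], order[j]
                    if hamming(a, b) > max_hamming:
                        continue
                    if _keep_both(a, b, counts, cells_with, bc):
                        continue
                    counts[a] += counts.pop(b)
                    reads[a] += reads.pop(b)
                    changed = True
                    break
                if changed:
                    break
        profiles[bc] = CellScarProfile(bc, counts)
    return profiles


def remove_scar_doublets(
    profiles: dict[str, CellScarProfile],
    annotation: pd.DataFrame,
    mad_factor: float = 3.0,
    min_excess: int = 2,
    min_cells_per_type: int = 5,
) -> dict[str, CellScarProfile]:
    """Flag cells whose distinct-scar count is an outlier for their type.

    Doublets merge two cells' scar sets and therefore carry an excess of
    distinct scars. A cell is flagged when its count exceeds
    median + max(mad_factor * MAD, min_excess) of its cell type's
    distribution (raw median absolute deviation). Types with fewer than
    ``min_cells_per_type`` cells fall back to the global distribution.
    """
    type_of = dict(zip(annotation["cell_barcode"], annotation["cell_type"]))
    counts = pd.Series({bc: len(p.scars) for bc, p in profiles.items()}, dtype=float)
    if counts.empty:
        return profiles
    types = counts.index.map(lambda bc: type_of.get(bc, "__unannotated__"))
    frame = pd.DataFrame({"n_scars": counts, "cell_type": types})

    def threshold(values: pd.Series) -> float:
        med = float(values.median())
        mad = float((values - med).abs().median())
        return med + max(mad_factor * mad, float(min_excess))

    global_thr = threshold(frame["n_scars"])
    for ctype, grp in frame.groupby("cell_type"):
        if len(grp) < min_cells_per_type:
            logger.info(
                "cell type %r has %d cells; using global doublet threshold",
                ctype, len(grp),
            )
            thr = global_thr
        else:
            thr = threshold(grp["n_scars"])
        for bc in grp.index[grp["n_scars"] > thr]:
            profiles[bc].doublet_flag = True
    n_flagged = sum(p.doublet_flag for p in profiles.values())
    logger.info("doublet filter flagged %d of %d cells", n_flagged, len(profiles))
    return profiles


def run_filter_pipeline(
    reads: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    min_reads: int = 2,
    max_hamming: int = 2,
    length: int = SCAR_LEN,
    primer_prefix: str | None = None,
) -> tuple[dict[str, CellScarProfile], FilterLog]:
    """The whole cascade; returns profiles plus a record-count audit log."""
    log = FilterLog()
    log.record("input_reads", len(reads))
    reads = truncate_and_length_filter(reads, length=length, primer_prefix=primer_prefix)
    log.record("after_length_filter", len(reads))
    mol = collapse_reads_to_molecules(reads, min_reads=min_reads)
    log.record("molecules_min_reads", len(mol))
    mol = resolve_ambiguous_assignments(mol)
    log.record("molecules_resolved", len(mol))
    profiles = merge_similar_scars(mol, max_hamming=max_hamming)
    log.record("cells_with_scars", len(profiles))
    if annotation is not None:
        profiles = remove_scar_doublets(profiles, annotation)
        log.record(
            "cells_after_doublet_flag",
            sum(not p.doublet_flag for p in profiles.values()),
        )
    return profiles, log
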