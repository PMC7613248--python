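"""Readers and writers for the pipeline's plain-text artifacts.

Reads: TSV (cell_barcode, umi, scar_seq). Annotation: CSV (cell_barcode,
cell_type, replicate, timepoint). Profiles: JSON cell -> allele -> count.
Trees: JSON plus Newick export. Matrices: TSV or MatrixMarket triplets.
Readers validate schemas; writers are byte-stable for identical inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse

from .filtering import CellScarProfile
from .tree import LineageTree

READ_COLUMNS = ["cell_barcode", "umi", "scar_seq"]
ANNOTATION_COLUMNS = ["cell_barcode", "cell_type", "replicate", "timepoint"]

__all__ = [
    "read_reads", "write_reads",
    "read_annotation", "write_annotation",
    "read_profiles", "write_profiles",
    "read_tree", "write_tree", "write_newick",
    "read_matrix_tsv", "write_matrix_tsv", "read_mtx",
    "SchemaError",
]


class SchemaError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; found {list(df.columns)}")


def read_reads(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, READ_COLUMNS, path)
    bad = df[READ_COLUMNS].isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:10]  # +2: header + 1-based
        raise SchemaError(f"{path}: malformed rows at lines {lines}")
    return df[READ_COLUMNS]


def write_reads(reads: pd.DataFrame, path: str | Path) -> None:
    reads[READ_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ANNOTATION_COLUMNS, path)
    return df[ANNOTATION_COLUMNS]


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation[ANNOTATION_COLUMNS].to_csv(path, index=False)


def write_profiles(profiles: dict[str, CellScarProfile], path: str | Path) -> None:
    payload = {
        bc: {"scars": dict(sorted(p.scars.items())), "doublet": p.doublet_flag}
        for bc, p in sorted(profiles.items())
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_profiles(path: str | Path) -> dict[str, CellScarProfile]:
    payload = json.loads(Path(path).read_text())
    out: dict[str, CellScarProfile] = {}
    for bc, d in payload.items():
        if "scars" not in d:
            raise SchemaError(f"{path}: profile {bc!r} lacks 'scars'")
        out[bc] = CellScarProfile(bc, {k: int(v) for k, v in d["scars"].items()},
                                  bool(d.get("doublet", False)))
    return out


def write_tree(tree: LineageTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_json())


def read_tree(path: str | Path) -> LineageTree:
    return LineageTree.from_json(Path(path).read_text())


def write_newick(tree: LineageTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_mtx(
    mtx_path: str | Path, genes_path: str | Path, barcodes_path: str | Path
) -> pd.DataFrame:
    """Cells x genes dense DataFrame from a MatrixMarket triplet
    (matrix stored genes x cells, the common convention)."""
    m = scipy.io.mmread(str(mtx_path))
    genes = Path(genes_path).read_text().split()
    barcodes = Path(barcodes_path).read_text().split()
    m = scipy.sparse.csr_matrix(m)
    if m.shape != (len(genes), len(barcodes)):
        raise SchemaError(
            f"{mtx_path}: shape {m.shape} does not match "
            f"{len(genes)} genes x {len(barcodes)} barcodes"
        )
    return pd.DataFrame(m.toarray().T, index=barcodes, columns=genes)
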