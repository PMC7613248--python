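import numpy as np
import pandas as pd
import pytest

from scartree.filtering import CellScarProfile
from scartree.tree import LineageTree


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def profiles_from_sets(cells: dict[str, set[str] | dict[str, int]]):
    """Build CellScarProfiles from plain scar sets (count 1 each) or dicts."""
    out = {}
    for bc, scars in cells.items():
        if isinstance(scars, dict):
            out[bc] = CellScarProfile(bc, dict(scars))
        else:
            out[bc] = CellScarProfile(bc, {s: 1 for s in scars})
    return out


def annotation_frame(types: dict[str, str], replicate="R1", timepoint="7dpi"):
    return pd.DataFrame(
        {
            "cell_barcode": list(types),
            "cell_type": list(types.values()),
            "replicate": replicate,
            "timepoint": timepoint,
        }
    )


def manual_tree(spec: dict, replicate="R1") -> LineageTree:
    """Build a LineageTree from {node_name: (parent_name|None, scar|None,
    [cells])}; exactly one entry must have parent None (the root)."""
    tree = LineageTree(replicate=replicate)
    tree.nodes.clear()
    ids = {name: i for i, name in enumerate(spec)}
    for name, (parent, scar, cells) in spec.items():
        nid = ids[name]
        pid = ids[parent] if parent is not None else None
        from scartree.tree import TreeNode

        tree.nodes[nid] = TreeNode(nid, scar, pid, [], list(cells))
        if pid is None:
            tree.root = nid
    for name, (parent, _, _) in spec.items():
        if parent is not None:
            tree.nodes[ids[parent]].children.append(ids[name])
    tree._next_id = len(spec)
    return tree
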