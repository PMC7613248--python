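"""Filtering cascade: truncation, read support, chimera resolution,
near-identical scar merging and doublet flagging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import annotation_frame, profiles_from_sets
from scartree import fixtures
from scartree.filtering import (
    collapse_reads_to_molecules,
    hamming,
    merge_similar_scars,
    remove_scar_doublets,
    resolve_ambiguous_assignments,
    run_filter_pipeline,
    truncate_and_length_filter,
)

L = 75
A75, C75, G75 = "A" * L, "C" * L, "G" * L


def reads_frame(rows):
    return pd.DataFrame(rows, columns=["cell_barcode", "umi", "scar_seq"])


def mol_frame(rows):
    return pd.DataFrame(rows, columns=["cell_barcode", "umi", "scar_seq", "n_reads"])


class TestTruncation:
    def test_long_reads_truncated_short_removed_exact_kept(self):
        df = reads_frame(
            [("b", "u1", "A" * 80), ("b", "u2", "A" * 74), ("b", "u3", A75)]
        )
        out = truncate_and_length_filter(df)
        assert list(out["scar_seq"]) == [A75, A75]

    def test_full_length_input_preserves_row_count(self):
        df = reads_frame([("b", f"u{i}", A75) for i in range(5)])
        assert len(truncate_and_length_filter(df)) == 5

    def test_primer_prefix_flag(self):
        df = reads_frame([("b", "u1", "AC" + A75), ("b", "u2", "GG" + A75)])
        out = truncate_and_length_filter(df, primer_prefix="AC")
        assert len(out) == 1 and out["scar_seq"].iloc[0].startswith("AC")


class TestCollapse:
    def test_singleton_molecules_removed(self):
        df = reads_frame([("b", "u1", A75)] * 3 + [("b", "u2", A75)])
        out = collapse_reads_to_molecules(df)
        assert out.to_records(index=False).tolist() == [("b", "u1", A75, 3)]

    def test_two_reads_retained(self):
        out = collapse_reads_to_molecules(reads_frame([("b", "u1", A75)] * 2))
        assert out["n_reads"].tolist() == [2]

    def test_empty_input(self):
        assert collapse_reads_to_molecules(reads_frame([])).empty


class TestResolve:
    def test_most_prevalent_scar_kept(self):
        mol = mol_frame([("b", "u1", A75, 5), ("b", "u1", C75, 2)])
        out = resolve_ambiguous_assignments(mol)
        assert out["scar_seq"].tolist() == [A75]

    def test_read_tie_broken_lexicographically(self):
        mol = mol_frame([("b", "u1", C75, 3), ("b", "u1", A75, 3)])
        out = resolve_ambiguous_assignments(mol)
        assert out["scar_seq"].tolist() == [A75]

    def test_consistent_table_unchanged_and_idempotent(self):
        mol = mol_frame([("b1", "u1", A75, 3), ("b2", "u2", C75, 2)])
        once = resolve_ambiguous_assignments(mol)
        twice = resolve_ambiguous_assignments(once)
        pd.testing.assert_frame_equal(once, twice)
        assert set(map(tuple, once.to_records(index=False))) == set(
            map(tuple, mol.to_records(index=False))
        )

    def test_each_pairing_is_unique_after_resolution(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"b{rng.integers(3)}", f"u{rng.integers(3)}",
             [A75, C75, G75][rng.integers(3)], int(rng.integers(2, 9)))
            for _ in range(40)
        ]
        out = resolve_ambiguous_assignments(mol_frame(rows))
        for cols in (["cell_barcode", "umi"], ["cell_barcode", "scar_seq"],
                     ["umi", "scar_seq"]):
            assert not out.duplicated(subset=cols).any()


class TestMerge:
    def test_minor_variant_absorbed_into_major(self):
        variant = A75[:-1] + "C"
        rows = [("b", f"u{i}", A75, 2) for i in range(10)] + [("b", "ux", variant, 2)]
        profiles = merge_similar_scars(mol_frame(rows))
        assert profiles["b"].scars == {A75: 11}

    def test_distant_alleles_both_kept(self):
        rows = [("b", "u1", A75, 2), ("b", "u2", C75, 2)]  # distance 75
        profiles = merge_similar_scars(mol_frame(rows))
        assert profiles["b"].scars == {A75: 1, C75: 1}

    def test_keep_both_with_cross_cell_evidence(self):
        variant = A75[:-1] + "C"
        rows = [("b", "u1", A75, 2), ("b", "u2", A75, 2),
                ("b", "u3", variant, 2), ("b", "u4", variant, 2)]
        # each allele alone in >= 2 other cells
        for i, bc in enumerate(["s1", "s2", "s3", "s4"]):
            rows.append((bc, f"v{i}", A75 if i < 2 else variant, 2))
        profiles = merge_similar_scars(mol_frame(rows))
        assert profiles["b"].scars == {A75: 2, variant: 2}

    def test_without_cross_cell_evidence_pair_merges(self):
        variant = A75[:-1] + "C"
        rows = [("b", "u1", A75, 2), ("b", "u2", A75, 2),
                ("b", "u3", variant, 2), ("b", "u4", variant, 2)]
        profiles = merge_similar_scars(mol_frame(rows))
        assert profiles["b"].scars == {A75: 4}

    def test_unequal_lengths_fail(self):
        with pytest.raises(ValueError, match="Hamming"):
            hamming(A75, A75 + "A")


class TestDoubletFlag:
    def test_clear_outlier_flagged(self):
        cells = {f"b{i}": {f"s{i}a", f"s{i}b", f"s{i}c"} for i in range(6)}
        cells["odd"] = {f"x{j}" for j in range(9)}
        profiles = profiles_from_sets(cells)
        ann = annotation_frame({bc: "T" for bc in cells})
        remove_scar_doublets(profiles, ann)
        assert profiles["odd"].doublet_flag
        assert not any(profiles[f"b{i}"].doublet_flag for i in range(6))

    def test_uniform_counts_unflagged(self):
        profiles = profiles_from_sets({f"b{i}": {f"s{i}"} for i in range(8)})
        ann = annotation_frame({f"b{i}": "T" for i in range(8)})
        remove_scar_doublets(profiles, ann)
        assert not any(p.doublet_flag for p in profiles.values())

    def test_simulated_doublets_mostly_flagged(self):
        from scartree.simulate import CountDist, SimConfig, simulate_dataset

        # high scar rate -> tight per-cell scar-count distribution, so a
        # fused barcode's excess of distinct scars is a clear outlier
        cfg = SimConfig(
            n_generations=6, scar_rate=0.9, allele_alphabet_size=200,
            n_cells=800, detection_prob=1.0,
            molecules_per_scar=CountDist("constant", 1),
            reads_per_molecule=CountDist("constant", 2),
            doublet_rate=0.08, seed=21,
        )
        truth, reads, ann = simulate_dataset(cfg)
        profiles, _ = run_filter_pipeline(reads, ann)
        flagged = {bc for bc, p in profiles.items() if p.doublet_flag}
        true_doublets = {
            bc for bc in truth.doublet_members
            if bc in profiles and len(profiles[bc].scars) > 0
        }
        assert true_doublets
        assert len(flagged & true_doublets) / len(true_doublets) >= 0.8


def test_majority_sequence_survives_one_mutated_read():
    mutated = A75[:40] + "T" + A75[41:]
    df = reads_frame([("b", "u1", A75)] * 9 + [("b", "u1", mutated)])
    profiles, _ = run_filter_pipeline(df)
    assert profiles["b"].scars == {A75: 1}


def test_packaged_fixture_reproduces_expected_profiles():
    profiles, _ = run_filter_pipeline(
        fixtures.filter_fixture_reads(), fixtures.filter_fixture_annotation()
    )
    assert {bc: p.scars for bc, p in profiles.items()} == fixtures.EXPECTED_PROFILES
    assert {bc for bc, p in profiles.items() if p.doublet_flag} == fixtures.EXPECTED_DOUBLETS


@st.composite
def read_tables(draw):
    n = draw(st.integers(1, 30))
    seqs = [A75, C75, A75[:-1] + "G"]
    rows = [
        (
            f"b{draw(st.integers(0, 2))}",
            f"u{draw(st.integers(0, 2))}",
            seqs[draw(st.integers(0, 2))],
        )
        for _ in range(n)
    ]
    return reads_frame(rows)


@settings(max_examples=25, derandomize=True)
@given(read_tables())
def test_cascade_is_monotone_and_deterministic(reads):
    """Each stage only drops rows; rerunning yields identical output."""
    t = truncate_and_length_filter(reads)
    assert len(t) <= len(reads)
    m = collapse_reads_to_molecules(t)
    assert m["n_reads"].sum() <= len(t)
    r = resolve_ambiguous_assignments(m)
    assert len(r) <= len(m)
    p1 = merge_similar_scars(r)
    p2 = merge_similar_scars(resolve_ambiguous_assignments(m))
    assert {bc: p.scars for bc, p in p1.items()} == {bc: p.scars for bc, p in p2.items()}
    for p in p1.values():
        assert p.scars and all(v > 0 for v in p.scars.values())
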