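"""A small synthetic filtering fixture with a hand-derived expected outcome.

Forty reads over seven cells, constructed so that every rule of the
filtering cascade fires at least once: truncation of an over-length read,
removal of a short read, the two-read support requirement, most-prevalent
resolution of a chimeric (barcode, UMI) pair including a read-count tie,
most-prevalent barcode per (UMI, scar) across two cells, absorption of a
near-identical scar variant, and the distinct-scar doublet flag.

The expected profiles below were derived by hand from the filter rules;
they are the oracle the cascade is checked against.
"""

from __future__ import annotations

import pandas as pd

S1 = "A" * 75
S1V = "A" * 74 + "C"          # Hamming 1 from S1
S2 = "C" * 75
S3 = "G" * 75
S3V = "G" * 73 + "TT"         # Hamming 2 from S3
S4 = "T" * 75
S5 = "AC" * 37 + "A"          # far from everything
LONG80 = "C" * 80             # truncates to S2
SHORT74 = "A" * 74            # dropped by the length filter


def filter_fixture_reads() -> pd.DataFrame:
    """The 40-read table (cell_barcode, umi, scar_seq; one row per read)."""
    rows: list[tuple[str, str, str]] = []

    def add(bc: str, umi: str, seq: str, n: int) -> None:
        rows.extend([(bc, umi, seq)] * n)

    # BC1: two S1 molecules plus a 1-substitution variant; after resolution
    # one UMI per (cell, scar) remains and the variant is absorbed into S1.
    add("BC1", "u01", S1, 3)
    add("BC1", "u02", S1, 2)
    add("BC1", "u03", S1V, 2)
    # BC2: chimeric (barcode, UMI) pairs; u04 resolves by read count,
    # u05 by the lexicographic tie-break (S2 < S3); then one UMI per scar.
    add("BC2", "u04", S2, 3)
    add("BC2", "u04", S3, 2)
    add("BC2", "u05", S3, 2)
    add("BC2", "u05", S2, 2)
    # BC3: an 80-nt read truncating to S2 (but see uX below), a short read,
    # and a singleton molecule.
    add("BC3", "uX", LONG80, 2)
    add("BC3", "u06", SHORT74, 2)
    add("BC3", "u07", S3, 1)
    # BC4: two molecules at Hamming distance 2; neither passes the
    # keep-both criteria, so the minor is absorbed into S3.
    add("BC4", "u08", S3, 2)
    add("BC4", "u09", S3V, 2)
    # BC5: five unrelated scars — a doublet by scar count.
    for umi, seq in [("u10", S1), ("u11", S2), ("u12", S3), ("u13", S4), ("u14", S5)]:
        add("BC5", umi, seq, 2)
    # BC6: a single ordinary molecule.
    add("BC6", "u15", S1, 2)
    # BC7 shares (uX, S2) with BC3's truncated molecule and wins on reads,
    # emptying BC3 entirely.
    add("BC7", "uX", S2, 3)

    reads = pd.DataFrame(rows, columns=["cell_barcode", "umi", "scar_seq"])
    assert len(reads) == 40
    return reads


def filter_fixture_annotation() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_barcode": [f"BC{i}" for i in range(1, 8)],
            "cell_type": ["fibro"] * 7,
            "replicate": ["R1"] * 7,
            "timepoint": ["7dpi"] * 7,
        }
    )


# Hand-derived expected outcome: allele -> molecule count per retained cell,
# plus the doublet flag. BC3 loses its only molecule at the (UMI, scar)
# resolution step and is absent.
EXPECTED_PROFILES: dict[str, dict[str, int]] = {
    "BC1": {S1: 2},
    "BC2": {S2: 1},
    "BC4": {S3: 2},
    "BC5": {S1: 1, S2: 1, S3: 1, S4: 1, S5: 1},
    "BC6": {S1: 1},
    "BC7": {S2: 1},
}
EXPECTED_DOUBLETS: set[str] = {"BC5"}
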