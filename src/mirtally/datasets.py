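"""Small bundled reference tables.

Both tables come from a published deep-sequencing study of salt-stressed
wild eggplant (*Solanum linnaeanum*) roots comparing an NaCl-treated library
(TR) with an untreated control (CK).  They are used as worked examples and
as fixed inputs for exercising the reporting and calling rules on real
published numbers.
"""

from __future__ import annotations

import pandas as pd

from .preprocess import LibraryStats

#: Per-library read accounting of the two root small-RNA libraries.
_CATEGORY_COUNTS = {
    "CK": {
        "raw": 13_989_100,
        "mappable": 8_462_890,
        "miRNA": 466_136,
        "mRNA": 723_297,
        "RFam": 1_315_886,
        "Repbase": 5_674,
        "genome": 1_763_934,
        "no_hit": 4_187_963,
    },
    "TR": {
        "raw": 21_284_496,
        "mappable": 8_999_145,
        "miRNA": 437_144,
        "mRNA": 793_475,
        "RFam": 1_387_942,
        "Repbase": 4_745,
        "genome": 2_063_801,
        "no_hit": 4_312_038,
    },
}

#: Salt-responsive miRNAs: log2 fold change (TR/CK, normalized counts) and
#: the exact-test p-value reported for each.
_SALT_RESPONSE_ROWS = [
    ("sli-miR156b", -1.01, 2.46e-127),
    ("sli-miR156c", -1.18, 2.72e-52),
    ("sli-miR162b", -1.25, 8.35e-99),
    ("sli-miR164c", 1.03, 3.57e-16),
    ("sli-miR166d", 1.97, 1.02e-45),
    ("sli-miR167a", -1.45, 4.26e-166),
    ("sli-miR167b", -1.25, 5.57e-15),
    ("sli-miR171b", -1.18, 1.89e-47),
    ("sli-miR171e", -1.08, 1.24e-12),
    ("sli-miR172a", -1.66, 1.94e-44),
    ("sli-miR319a", -1.07, 2.28e-28),
    ("sli-miR397a", 1.91, 1.04e-43),
    ("sli-miR399b", -1.14, 9.82e-14),
    ("sli-miR5300", -1.92, 1.55e-155),
]


def load_library_stats() -> tuple[LibraryStats, LibraryStats]:
    """Published per-category read accounting as (CK, TR) LibraryStats."""
    out = []
    for lib in ("CK", "TR"):
        c = _CATEGORY_COUNTS[lib]
        out.append(
            LibraryStats(
                raw_reads=c["raw"],
                mappable_reads=c["mappable"],
                categories={
                    k: v for k, v in c.items() if k not in ("raw", "mappable")
                },
            )
        )
    return out[0], out[1]


def load_salt_response_table() -> pd.DataFrame:
    """Published salt-responsive miRNA table: name, log2fc, pvalue."""
    return pd.DataFrame(_SALT_RESPONSE_ROWS, columns=["name", "log2fc", "pvalue"])
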