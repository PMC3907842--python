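"""Summary tables, qPCR relative expression and sequencing/qPCR concordance.

Percentages are rounded half-up to two decimals; composite percentages are
formed by summing the already-rounded addends, which is how published
per-category read-accounting tables combine their rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import MirtallyError
from .preprocess import LibraryStats

#: category display order of the per-library accounting table
TABLE_CATEGORIES = ("miRNA", "mRNA", "RFam", "Repbase", "genome", "no_hit")
#: categories combined into the "repeats + mRNA + other RNAs" composite
COMPOSITE_CATEGORIES = ("mRNA", "RFam", "Repbase")


class EmptyLibraryError(MirtallyError):
    pass


def round_half_up(value: float, ndigits: int = 2) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, ndigits: int = 2) -> float:
    return round_half_up(count / total * 100.0, ndigits)


def table1_summary(ck: LibraryStats, tr: LibraryStats) -> pd.DataFrame:
    """Per-category read counts and percentages for the two libraries."""
    if ck.mappable_reads == 0 or tr.mappable_reads == 0:
        raise EmptyLibraryError("a library has zero mappable reads")
    rows = [
        {
            "category": "Raw reads",
            "ck_count": ck.raw_reads,
            "ck_percent": math.nan,
            "tr_count": tr.raw_reads,
            "tr_percent": math.nan,
        },
        {
            "category": "Mappable reads",
            "ck_count": ck.mappable_reads,
            "ck_percent": 100.0,
            "tr_count": tr.mappable_reads,
            "tr_percent": 100.0,
        },
    ]
    for cat in TABLE_CATEGORIES:
        rows.append(
            {
                "category": f"Mapped to {cat}" if cat != "no_hit" else "No hit",
                "ck_count": ck.categories.get(cat, 0),
                "ck_percent": percent(ck.categories.get(cat, 0), ck.mappable_reads),
                "tr_count": tr.categories.get(cat, 0),
                "tr_percent": percent(tr.categories.get(cat, 0), tr.mappable_reads),
            }
        )
    return pd.DataFrame(rows)


def composite_percent(stats: LibraryStats, categories=COMPOSITE_CATEGORIES) -> float:
    """Sum of the rounded per-category percentages (e.g. repeats+mRNA+other RNAs)."""
    if stats.mappable_reads == 0:
        raise EmptyLibraryError("zero mappable reads")
    total = sum(
        percent(stats.categories.get(c, 0), stats.mappable_reads) for c in categories
    )
    return round_half_up(total)


@dataclass
class RelativeExpression:
    """2^-ddCt fold change of a miRNA in TR relative to CK."""

    fold_change: float
    log2_fold: float
    sd_log2: float  # standard deviation of ddCt, propagated from replicates

    @property
    def interval(self) -> tuple[float, float]:
        return (
            2.0 ** (self.log2_fold - self.sd_log2),
            2.0 ** (self.log2_fold + self.sd_log2),
        )


def relative_expression(
    ct: pd.DataFrame, target: str, reference: str = "U6"
) -> RelativeExpression:
    """Reference-corrected relative expression from a Ct table.

    ``ct`` has columns sample (CK/TR), gene, replicate, ct.  The fold change
    is 2^-(dCt_TR - dCt_CK) with dCt_s = mean Ct(target, s) - mean
    Ct(reference, s); replicate scatter is propagated as the root sum of the
    standard errors of the four means.
    """
    required = {"sample", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise MirtallyError(f"Ct table must have columns {sorted(required)}")
    dct = {}
    var = 0.0
    for sample in ("CK", "TR"):
        sub = ct[ct["sample"] == sample]
        t = sub[sub["gene"] == target]["ct"]
        r = sub[sub["gene"] == reference]["ct"]
        if t.empty or r.empty:
            raise MirtallyError(f"missing {target!r} or {reference!r} Ct values in {sample}")
        dct[sample] = t.mean() - r.mean()
        for series in (t, r):
            if len(series) > 1:
                var += series.var(ddof=1) / len(series)
    ddct = dct["TR"] - dct["CK"]
    log2_fold = -ddct
    return RelativeExpression(2.0**log2_fold, log2_fold, math.sqrt(var))


def concordance(de: pd.DataFrame, qpcr_folds: dict[str, float]) -> pd.DataFrame:
    """Direction agreement between sequencing DE results and qPCR fold changes."""
    shared = [m for m in de["name"] if m in qpcr_folds]
    rows = []
    for name in shared:
        lfc = float(de.loc[de["name"] == name, "log2fc"].iloc[0])
        qfc = math.log2(qpcr_folds[name])
        rows.append(
            {
                "name": name,
                "seq_direction": "up" if lfc > 0 else "down" if lfc < 0 else "flat",
                "qpcr_direction": "up" if qfc > 0 else "down" if qfc < 0 else "flat",
                "agree": (lfc > 0) == (qfc > 0) and (lfc < 0) == (qfc < 0),
            }
        )
    if not rows:
        import warnings

        warnings.warn("no shared miRNAs between sequencing and qPCR results")
    return pd.DataFrame(rows, columns=["name", "seq_direction", "qpcr_direction", "agree"])


def write_run_report(
    path: str | Path,
    summary: pd.DataFrame,
    de: pd.DataFrame,
    profiles: pd.DataFrame | None = None,
    concord: pd.DataFrame | None = None,
) -> None:
    """Write a single plain-text run report combining the pipeline outputs."""
    with open(path, "w") as fh:
        fh.write("Read accounting\n")
        fh.write(summary.to_string(index=False))
        fh.write("\n\n")
        if profiles is not None:
            n_fam = profiles.loc[profiles["arm"] == "mature", "family"].nunique()
            n_mat = int((profiles["arm"] == "mature").sum())
            n_star = int((profiles["arm"] == "star").sum())
            fh.write(
                f"Conserved miRNA profiles: {n_mat} mature, {n_star} star, "
                f"{n_fam} families\n\n"
            )
        n_up = int((de["call"] == "up").sum())
        n_down = int((de["call"] == "down").sum())
        fh.write(f"Differential expression: {n_up} up, {n_down} down of {len(de)} tested\n")
        fh.write(de.to_string(index=False))
        fh.write("\n")
        if concord is not None and len(concord):
            fh.write("\nqPCR concordance\n")
            fh.write(concord.to_string(index=False))
            fh.write("\n")
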