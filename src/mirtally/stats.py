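"""Library normalization and exact tag-count differential expression.

Normalization is the median-of-ratios scheme: each tag's counts are divided
by a per-library size factor, defined as the median over tags of the ratio
between the tag's count in that library and its pseudo-reference count (the
geometric mean of the tag's counts across libraries; tags with a zero count
in any library are excluded from the median).

Significance of a count difference between two libraries is assessed with
the Audic-Claverie exact test for tag-count data.  Given ``x`` counts in a
library of ``N1`` reads, the probability of observing ``k`` counts in a
second library of ``N2`` reads is

    p(k | x) = (N2/N1)^k * (x+k)! / (x! k! (1 + N2/N1)^(x+k+1))

which is the negative-binomial pmf with ``x+1`` successes and success
probability ``N1/(N1+N2)``.  The two-sided p-value doubles the smaller of
the lower and upper tails at the observed ``y`` (capped at 1).  All sums are
carried out in log space via the log-gamma function; the open upper tail is
summed forward until terms fall below 1e-16 of the running total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from ._util import MirtallyError

_TAIL_EPS_LOG = math.log(1e-16)


class NormalizationError(MirtallyError):
    """No tag has nonzero counts in every library; fall back to total-count scaling."""


@dataclass
class SizeFactors:
    s_ck: float
    s_tr: float
    n_tags_used: int


def size_factors(counts: pd.DataFrame | np.ndarray) -> SizeFactors:
    """Median-of-ratios size factors for a two-library count table.

    ``counts`` is a DataFrame with ``count_ck``/``count_tr`` columns (or an
    (n, 2) array).  Tags with a zero in either library are excluded from the
    pseudo-reference.  The median of an even-length list is the mean of the
    two central values (numpy's convention).
    """
    if isinstance(counts, pd.DataFrame):
        mat = counts[["count_ck", "count_tr"]].to_numpy(dtype=float)
    else:
        mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise MirtallyError("counts must be an (n, 2) table")
    usable = np.all(mat > 0, axis=1)
    if not usable.any():
        raise NormalizationError(
            "no tag has nonzero counts in all libraries; use total-count scaling instead"
        )
    sub = mat[usable]
    log_g = np.mean(np.log(sub), axis=1)  # log geometric mean per tag
    ratios = np.log(sub) - log_g[:, None]
    s = np.exp(np.median(ratios, axis=0))
    return SizeFactors(float(s[0]), float(s[1]), int(usable.sum()))


def _log_pmf(k: np.ndarray, x: int, log_r: float, log_1pr: float) -> np.ndarray:
    return (
        k * log_r
        + gammaln(x + k + 1.0)
        - gammaln(x + 1.0)
        - gammaln(k + 1.0)
        - (x + k + 1.0) * log_1pr
    )


def _log_lower_tail(y: int, x: int, n1: float, n2: float) -> float:
    """log of the closed lower tail sum_{k<=y} p(k | x) with r = N2/N1."""
    r = n2 / n1
    log_r = math.log(r)
    log_1pr = math.log1p(r)
    ks = np.arange(0, y + 1, dtype=float)
    return float(logsumexp(_log_pmf(ks, x, log_r, log_1pr)))


def _log_upper_tail(y: int, x: int, n1: float, n2: float) -> float:
    """log of the open-ended upper tail sum_{k>=y} p(k | x), summed forward."""
    r = n2 / n1
    log_r = math.log(r)
    log_1pr = math.log1p(r)
    mean = (x + 1.0) * r
    sd = math.sqrt((x + 1.0) * r * (1.0 + r))
    hi = int(max(y, mean + 10.0 * sd)) + 64
    pieces: list[float] = []
    lo = y
    while True:
        ks = np.arange(lo, hi + 1, dtype=float)
        terms = _log_pmf(ks, x, log_r, log_1pr)
        pieces.append(float(logsumexp(terms)))
        total = float(logsumexp(pieces))
        if terms[-1] < total + _TAIL_EPS_LOG:
            return total
        lo, hi = hi + 1, hi + 1 + 2 * (hi - lo + 1)


def audic_claverie_p(
    x: int, y: int, n1: float, n2: float, sided: str = "two"
) -> float:
    """Audic-Claverie p-value for raw counts (x, y) in libraries (N1, N2).

    The default two-sided p doubles the smaller of the two conditional lower
    tails, P(K <= y | x; N2/N1) and P(J <= x | y; N1/N2), capped at 1.  The
    two directions are exchangeable by construction — swapping (x, N1) with
    (y, N2) returns the same p — and the two tails are complementary
    (their probabilities sum to one), so this equals doubling the smaller of
    P(K <= y | x) and the strict upper tail P(K > y | x).  ``sided`` may
    also be ``"lower"`` (P(K <= y | x)) or ``"upper"`` (P(K >= y | x)) for
    one-directional tests.
    """
    if x < 0 or y < 0:
        raise MirtallyError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise MirtallyError("library sizes must be positive")
    if sided == "lower":
        return min(1.0, math.exp(_log_lower_tail(y, x, n1, n2)))
    if sided == "upper":
        return min(1.0, math.exp(_log_upper_tail(y, x, n1, n2)))
    if sided != "two":
        raise MirtallyError(f"sided must be 'two', 'lower' or 'upper', not {sided!r}")
    log_fwd = _log_lower_tail(y, x, n1, n2)
    log_rev = _log_lower_tail(x, y, n2, n1)
    p = 2.0 * math.exp(min(log_fwd, log_rev))
    return min(1.0, p)


def classify_call(
    log2fc: float, pvalue: float, lfc_cut: float = 1.0, alpha: float = 0.05
) -> str:
    """Regulation call from a fold change and p-value (strict inequalities)."""
    if pvalue < alpha:
        if log2fc > lfc_cut:
            return "up"
        if log2fc < -lfc_cut:
            return "down"
    return "none"


def call_de(
    profiles: pd.DataFrame,
    factors: SizeFactors,
    n1: float,
    n2: float,
    min_len: int = 18,
    max_len: int = 24,
    min_norm: float = 10.0,
    lfc_cut: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential-expression calls for miRNA profiles.

    Profiles outside ``[min_len, max_len]`` nt or with normalized counts of
    at most ``min_norm`` in both libraries are excluded.  The log2 fold
    change is computed on normalized counts (a 0.5 pseudo-count replaces a
    zero side, for reporting only); the p-value is the two-sided
    Audic-Claverie test on the raw counts with the per-library mappable read
    totals as library sizes.  Calls use strict inequalities.
    """
    if factors is None:
        raise MirtallyError("size factors must be computed before calling DE")
    df = profiles.copy()
    if df.empty:
        return df.assign(norm_ck=[], norm_tr=[], log2fc=[], pvalue=[], call=[])
    df["len"] = df["sequence"].str.len()
    df = df[(df["len"] >= min_len) & (df["len"] <= max_len)].drop(columns="len")

    df["norm_ck"] = df["count_ck"] / factors.s_ck
    df["norm_tr"] = df["count_tr"] / factors.s_tr
    df = df[np.maximum(df["norm_ck"], df["norm_tr"]) > min_norm]

    num = df["norm_tr"].where(df["norm_tr"] > 0, 0.5)
    den = df["norm_ck"].where(df["norm_ck"] > 0, 0.5)
    df["log2fc"] = np.log2(num / den)
    df["pvalue"] = [
        audic_claverie_p(int(x), int(y), n1, n2)
        for x, y in zip(df["count_ck"], df["count_tr"])
    ]
    df["call"] = [
        classify_call(l, p, lfc_cut, alpha) for l, p in zip(df["log2fc"], df["pvalue"])
    ]
    return df.sort_values("name", ignore_index=True)


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
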