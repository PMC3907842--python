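"""Independent brute-force / exact-arithmetic oracles used by the tests.

Everything here is deliberately naive and separate from the package's
implementations: exact rational tail sums for the tag-count test, a plain
nested-loop homology scan, and direct arithmetic for normalization and
relative expression.
"""

from __future__ import annotations

import math
from fractions import Fraction


# --- exact rational Audic-Claverie -----------------------------------------

def ac_pmf_exact(k: int, x: int, n1: int, n2: int) -> Fraction:
    r = Fraction(n2, n1)
    return Fraction(math.comb(x + k, k)) * r**k / (1 + r) ** (x + k + 1)


def ac_lower_tail_exact(y: int, x: int, n1: int, n2: int) -> Fraction:
    r = Fraction(n2, n1)
    term = Fraction(1, 1) / (1 + r) ** (x + 1)  # k = 0
    total = term
    for k in range(y):
        term = term * r * (x + k + 1) / ((1 + r) * (k + 1))
        total += term
    return total


def ac_two_sided_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    fwd = ac_lower_tail_exact(y, x, n1, n2)
    rev = ac_lower_tail_exact(x, y, n2, n1)
    return min(Fraction(1), 2 * min(fwd, rev))


def ac_upper_tail_exact(y: int, x: int, n1: int, n2: int) -> Fraction:
    if y == 0:
        return Fraction(1)
    return 1 - ac_lower_tail_exact(y - 1, x, n1, n2)


# --- brute-force homology scan ---------------------------------------------

def _overlap_mismatches(ref: str, tag: str, start: int, max_mm: int) -> tuple[int, int]:
    """(overlap, mismatches) of `tag` placed at `start` on `ref`; early abort."""
    lo = max(0, start)
    hi = min(len(ref), start + len(tag))
    ov = hi - lo
    mm = 0
    for p in range(lo, hi):
        if ref[p] != tag[p - start]:
            mm += 1
            if mm > max_mm:
                return ov, mm
    return ov, mm


def brute_match(
    tag: str,
    matures: dict[str, str],
    precursors: dict[str, str],
    max_mm: int = 2,
    shift: int = 3,
    min_overlap: int = 16,
):
    """All-pairs shifted-ungapped scan; returns (name, mm, overlap, is_star) or None."""
    best = None
    for name in sorted(matures):
        ref = matures[name]
        for start in range(-shift, shift + 1):
            end_off = start + len(tag) - len(ref)
            if abs(end_off) > shift:
                continue
            ov, mm = _overlap_mismatches(ref, tag, start, max_mm)
            if ov < min_overlap or mm > max_mm:
                continue
            cand = (mm, -ov, name)
            if best is None or cand < best:
                best = cand
    if best is not None:
        return best[2], best[0], -best[1], False

    # star arm: scan each precursor outside its mature locus
    locus = {}
    for mname, mseq in sorted(matures.items()):
        for pname, pseq in sorted(precursors.items()):
            pos = pseq.find(mseq)
            if pos >= 0:
                locus[mname] = (pname, pos)
                break
    for mname in sorted(locus):
        pname, mpos = locus[mname]
        pseq = precursors[pname]
        mlen = len(matures[mname])
        for start in range(-shift, len(pseq) + shift - len(tag) + 1):
            end = start + len(tag)
            if end > len(pseq) + shift:
                continue
            if start < mpos + mlen and end > mpos:
                continue  # overlaps the mature locus
            ov, mm = _overlap_mismatches(pseq, tag, start, max_mm)
            if ov < min_overlap or mm > max_mm:
                continue
            cand = (mm, -ov, mname)
            if best is None or cand < best:
                best = cand
    if best is not None:
        return best[2], best[0], -best[1], True
    return None


def brute_category(tag: str, refs, order=("miRNA", "mRNA", "RFam", "Repbase", "genome")) -> str:
    """Naive precedence cascade using brute_match and plain substring tests."""
    from mirtally._util import revcomp

    for cat in order:
        if cat == "miRNA":
            if brute_match(tag, refs.mature, refs.precursor) is not None:
                return "miRNA"
        elif cat == "mRNA":
            if any(tag in s for s in refs.mrna.values()):
                return "mRNA"
        elif cat == "RFam":
            if any(tag in s for s in refs.rfam.values()):
                return "RFam"
        elif cat == "Repbase":
            if any(tag in s for s in refs.repeat.values()):
                return "Repbase"
        elif cat == "genome":
            if any(tag in s or tag in revcomp(s) for s in refs.genome.values()):
                return "genome"
    return "no_hit"


# --- direct-arithmetic helpers ---------------------------------------------

def median_of_ratios(counts: list[tuple[float, float]]) -> tuple[float, float]:
    """Hand-rolled median-of-ratios on a two-column count list."""
    import statistics

    usable = [(a, b) for a, b in counts if a > 0 and b > 0]
    gms = [math.sqrt(a * b) for a, b in usable]
    s1 = statistics.median(a / g for (a, _), g in zip(usable, gms))
    s2 = statistics.median(b / g for (_, b), g in zip(usable, gms))
    return s1, s2


def ddct_fold(ct_rows: list[tuple[str, str, float]], target: str, reference: str) -> float:
    """Spreadsheet-style 2^-ddCt from (sample, gene, ct) rows."""

    def mean(sample, gene):
        vals = [c for s, g, c in ct_rows if s == sample and g == gene]
        return sum(vals) / len(vals)

    d_ck = mean("CK", target) - mean("CK", reference)
    d_tr = mean("TR", target) - mean("TR", reference)
    return 2.0 ** -(d_tr - d_ck)
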