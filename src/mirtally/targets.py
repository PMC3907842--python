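"""Plant miRNA target prediction by complementarity penalty scoring.

Each candidate site on a transcript is scored against the reverse complement
of the miRNA: Watson-Crick pairs cost 0, G:U wobbles 0.5, mismatches 1.0 and
single-nucleotide bulges 2.0, with every penalty doubled when it falls at
miRNA positions 2-13 from the 5' end (the seed-proximal region plant
cleavage sites are most sensitive to).  A perfect site scores 0; sites with
a penalty expectation at or below the cutoff (default 3.0) are reported.
This is a transparent stand-in for the scoring used by common plant
target-prediction servers; the penalties and cutoff are configurable.

At most one single-nucleotide bulge per site is considered, on either
strand.  Only the sense strand of the transcripts is searched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import MirtallyError, encode, read_fasta

#: penalty for an unpaired (bulged) nucleotide, before position weighting
GAP_PENALTY = 2.0
MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
#: inclusive range of miRNA positions (1-based, from the 5' end) where
#: penalties are doubled
CORE_RANGE = (2, 13)

_PAIR = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # miRNA base vs target base


class AlignmentError(MirtallyError):
    pass


@dataclass
class TargetHit:
    mirna: str
    transcript: str
    position: int  # 1-based start of the site on the transcript
    score: float
    alignment: tuple[str, str, str]  # miRNA 3'->5', match line, target 5'->3'


def _weight(pos: int) -> float:
    return 2.0 if CORE_RANGE[0] <= pos <= CORE_RANGE[1] else 1.0


def _pair_penalty(m: str, t: str) -> float:
    if (m, t) in _PAIR:
        return 0.0
    if (m, t) in _WOBBLE:
        return WOBBLE_PENALTY
    return MISMATCH_PENALTY


def _match_char(m: str, t: str) -> str:
    if (m, t) in _PAIR:
        return "|"
    if (m, t) in _WOBBLE:
        return "o"
    return " "


def _candidates(mirna: str, site: str):
    """Yield (score, top, mid, bottom) for every allowed gap placement.

    ``top`` is the miRNA written 3'->5' so it pairs column-wise with the
    site written 5'->3'.
    """
    L, S = len(mirna), len(site)
    rm = mirna[::-1]  # rm[j] is miRNA position L-j (1-based)
    if S == L:
        score = sum(
            _weight(L - j) * _pair_penalty(rm[j], site[j]) for j in range(L)
        )
        mid = "".join(_match_char(rm[j], site[j]) for j in range(L))
        yield score, rm, mid, site
    elif S == L + 1:
        # one unpaired target base (bulge in the target, gap in the miRNA)
        for g in range(S):
            score = GAP_PENALTY * _weight(min(max(L - g, 1), L))
            cols = []
            for j in range(L):
                t = site[j + (j >= g)]
                score += _weight(L - j) * _pair_penalty(rm[j], t)
                cols.append(_match_char(rm[j], t))
            top = rm[:g] + "-" + rm[g:]
            mid = "".join(cols[:g]) + " " + "".join(cols[g:])
            yield score, top, mid, site
    elif S == L - 1:
        # one unpaired miRNA base (gap in the target)
        for m in range(L):
            score = GAP_PENALTY * _weight(L - m)
            cols = []
            for j in range(L):
                if j == m:
                    cols.append(" ")
                    continue
                t = site[j - (j > m)]
                score += _weight(L - j) * _pair_penalty(rm[j], t)
                cols.append(_match_char(rm[j], t))
            bottom = site[:m] + "-" + site[m:]
            yield score, rm, "".join(cols), bottom
    else:
        raise AlignmentError(
            f"site length {S} outside the single-bulge allowance for a {L} nt miRNA"
        )


def score_site(mirna: str, site: str) -> float:
    """Penalty score of a site against a miRNA (best gap placement)."""
    if not mirna or not site:
        raise AlignmentError("miRNA and site must be non-empty")
    return min(c[0] for c in _candidates(mirna, site))


def align_site(mirna: str, site: str) -> tuple[float, tuple[str, str, str]]:
    """Best-scoring alignment of a site, as (score, (miRNA 3'->5', match, site))."""
    best = min(_candidates(mirna, site), key=lambda c: c[0])
    return best[0], (best[1], best[2], best[3])


def _penalty_matrix(mirna: str) -> np.ndarray:
    """Q[j, code] = weighted penalty of pairing miRNA (3'->5' index j) with base code."""
    L = len(mirna)
    rm = mirna[::-1]
    q = np.empty((L, 5))
    for j in range(L):
        w = _weight(L - j)
        for code, base in enumerate("ACGT"):
            q[j, code] = w * _pair_penalty(rm[j], base)
        q[j, 4] = np.inf  # ambiguous base: never a hit
    return q


def _window_scores(mirna: str, enc: np.ndarray) -> list[tuple[int, int, np.ndarray]]:
    """Best penalty per window start for each allowed window length.

    Returns (window_length, n_windows, scores) triples covering the ungapped
    and single-bulge alignments, computed with prefix/suffix sums so the cost
    is O(L * transcript length) per variant.
    """
    L = len(mirna)
    n = enc.size
    q = _penalty_matrix(mirna)
    out = []

    # ungapped: site length L
    n0 = n - L + 1
    if n0 > 0:
        s0 = np.zeros(n0)
        for j in range(L):
            s0 += q[j, enc[j : j + n0]]
        out.append((L, n0, s0))

    # bulged target: site length L+1, bulge at site index g
    n1 = n - L
    if n1 > 0:
        a = np.zeros((L + 1, n1))  # prefix sums of A_j
        b = np.zeros((L + 1, n1))  # suffix sums of B_j
        for j in range(L):
            a[j + 1] = a[j] + q[j, enc[j : j + n1]]
        for j in range(L - 1, -1, -1):
            b[j] = b[j + 1] + q[j, enc[j + 1 : j + 1 + n1]]
        best = np.full(n1, np.inf)
        for g in range(L + 1):
            gap = GAP_PENALTY * _weight(min(max(L - g, 1), L))
            best = np.minimum(best, a[g] + b[g] + gap)
        out.append((L + 1, n1, best))

    # bulged miRNA: site length L-1, miRNA 3'->5' index m unpaired
    n2 = n - L + 2
    if L >= 2 and n2 > 0:
        a = np.zeros((L + 1, n2))
        b = np.zeros((L + 1, n2))
        for j in range(L - 1):  # A'_j uses site index j (only valid for j <= L-2)
            a[j + 1] = a[j] + q[j, enc[j : j + n2]]
        a[L] = a[L - 1]
        for j in range(L - 1, 0, -1):  # B'_j uses site index j-1
            b[j] = b[j + 1] + q[j, enc[j - 1 : j - 1 + n2]]
        best = np.full(n2, np.inf)
        for m in range(L):
            gap = GAP_PENALTY * _weight(L - m)
            best = np.minimum(best, a[m] + b[m + 1] + gap)
        out.append((L - 1, n2, best))

    return out


def predict_targets(
    mirnas: Mapping[str, str] | pd.DataFrame,
    transcripts: Mapping[str, str] | str | Path,
    cutoff: float = 3.0,
) -> pd.DataFrame:
    """Scan transcripts for miRNA complementarity sites scoring <= cutoff.

    Overlapping hits of the same miRNA on the same transcript are collapsed
    to the best-scoring site.  Output is sorted by (miRNA, score, transcript,
    position); positions are 1-based.
    """
    if isinstance(mirnas, pd.DataFrame):
        mirnas = dict(zip(mirnas["name"], mirnas["sequence"]))
    if isinstance(transcripts, (str, Path)):
        transcripts = read_fasta(transcripts)
    if not transcripts:
        raise MirtallyError("transcript set is empty")

    enc_cache = {t: encode(seq) for t, seq in transcripts.items()}
    rows = []
    for mname in sorted(mirnas):
        mseq = mirnas[mname]
        for tname, seq in transcripts.items():
            enc = enc_cache[tname]
            cands = []
            for wlen, nwin, scores in _window_scores(mseq, enc):
                for start in np.flatnonzero(scores <= cutoff):
                    cands.append((float(scores[start]), int(start), wlen))
            if not cands:
                continue
            # collapse overlapping candidate windows to the best site
            cands.sort(key=lambda c: (c[0], c[1], c[2]))
            kept: list[tuple[float, int, int]] = []
            for score, start, wlen in cands:
                if all(
                    start + wlen <= ks or start >= ks + kw for _, ks, kw in kept
                ):
                    kept.append((score, start, wlen))
            for score, start, wlen in kept:
                site = seq[start : start + wlen]
                _, aln = align_site(mseq, site)
                rows.append(
                    {
                        "mirna": mname,
                        "transcript": tname,
                        "position": start + 1,
                        "score": score,
                        "alignment": ";".join(aln),
                    }
                )
    hits = pd.DataFrame(rows, columns=["mirna", "transcript", "position", "score", "alignment"])
    return hits.sort_values(
        by=["mirna", "score", "transcript", "position"], ignore_index=True
    )


def write_hits(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", index=False)
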