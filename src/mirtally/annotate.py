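"""Hierarchical annotation of collapsed small-RNA tags.

Each tag receives exactly one category through a precedence cascade
(miRNA > mRNA > RFam > Repbase > genome > no_hit by default).  Conserved
miRNAs are identified by homology to known mature sequences: an ungapped
end-to-end alignment allowing at most ``max_shift`` nucleotides of slack at
each terminus, at most ``max_mm`` substitutions over the aligned overlap, and
an overlap of at least ``min_overlap`` nt.  Tags failing the mature test but
matching the precursor on the arm opposite the mature by the same rule are
flagged as star (passenger-strand) sequences.

mRNA / RFam / Repbase membership is exact-substring; genome membership is
exact-substring on either strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import ConfigError, SENTINEL, encode, read_fasta, revcomp
from .preprocess import LibraryStats

DEFAULT_ORDER = ("miRNA", "mRNA", "RFam", "Repbase", "genome")
CATEGORIES = DEFAULT_ORDER + ("no_hit",)


@dataclass
class MatchHit:
    """Best homology hit of a tag against the known-miRNA references."""

    name: str
    mismatches: int
    overlap: int
    is_star: bool


@dataclass
class ReferenceSet:
    mature: dict[str, str]
    precursor: dict[str, str]
    mrna: dict[str, str]
    rfam: dict[str, str]
    repeat: dict[str, str]
    genome: dict[str, str]

    @classmethod
    def from_paths(cls, mature, precursor, mrna, rfam, repeat, genome) -> "ReferenceSet":
        return cls(
            read_fasta(mature),
            read_fasta(precursor),
            read_fasta(mrna),
            read_fasta(rfam),
            read_fasta(repeat),
            read_fasta(genome),
        )

    @classmethod
    def from_bundle(cls, bundle) -> "ReferenceSet":
        return cls(
            dict(bundle.mature),
            dict(bundle.precursor),
            dict(bundle.mrna),
            dict(bundle.contaminant),
            dict(bundle.repeat),
            dict(bundle.genome),
        )


class MirnaIndex:
    """Homology matcher against mature miRNAs and their precursors.

    The matching rule is a shifted ungapped alignment: the tag may start or
    end up to ``max_shift`` nt away from the reference terminus, overhanging
    bases are unaligned, the aligned overlap must span at least
    ``min_overlap`` nt and contain at most ``max_mm`` substitutions.  The best
    hit has the fewest mismatches, ties broken by longest overlap, then
    lexicographically smallest reference name.  A tag that fails against
    every mature sequence but aligns to a precursor region disjoint from its
    mature locus is a star hit.
    """

    def __init__(
        self,
        mature: dict[str, str],
        precursor: dict[str, str] | None = None,
        max_mm: int = 2,
        max_shift: int = 3,
        min_overlap: int = 16,
    ):
        if not mature:
            raise ConfigError("empty mature reference set")
        if max_mm < 0:
            raise ConfigError("max_mm must be >= 0")
        self.max_mm = max_mm
        self.max_shift = max_shift
        self.min_overlap = min_overlap
        self.mature = dict(sorted(mature.items()))
        self.precursor = dict(sorted((precursor or {}).items()))
        # locate each mature on its precursor (exact substring; first
        # containing precursor in name order)
        self.locus: dict[str, tuple[str, int]] = {}
        for mname, mseq in self.mature.items():
            for pname, pseq in self.precursor.items():
                pos = pseq.find(mseq)
                if pos >= 0:
                    self.locus[mname] = (pname, pos)
                    break

    # -- vectorised core ---------------------------------------------------

    def _windows(self, ref: str):
        """Padded encoding of a reference for shifted window extraction."""
        pad = np.full(self.max_shift, SENTINEL, dtype=np.uint8)
        return np.concatenate([pad, encode(ref), pad])

    def match_many(self, tags: Sequence[str]) -> list[MatchHit | None]:
        n = len(tags)
        results: list[MatchHit | None] = [None] * n
        by_len: dict[int, list[int]] = {}
        for i, t in enumerate(tags):
            by_len.setdefault(len(t), []).append(i)

        for L, idxs in by_len.items():
            if L < self.min_overlap:
                continue
            arr = np.stack([encode(tags[i]) for i in idxs])  # (g, L)
            g = arr.shape[0]
            best_mm = np.full(g, 255, dtype=np.int16)
            best_ov = np.zeros(g, dtype=np.int16)
            best_ref = np.full(g, -1, dtype=np.int32)

            mat_names = list(self.mature)
            for ref_i, mname in enumerate(mat_names):
                mseq = self.mature[mname]
                Lm = len(mseq)
                padded = self._windows(mseq)
                s = self.max_shift
                for o in range(0, Lm + 2 * s - L + 1):
                    start_off = o - s  # tag start relative to mature start
                    end_off = start_off + L - Lm
                    if abs(start_off) > s or abs(end_off) > s:
                        continue
                    win = padded[o : o + L]
                    real = win != SENTINEL
                    ov = int(real.sum())
                    if ov < self.min_overlap:
                        continue
                    mm = ov - (arr[:, real] == win[real]).sum(axis=1)
                    upd = (mm <= self.max_mm) & (
                        (mm < best_mm) | ((mm == best_mm) & (ov > best_ov))
                    )
                    if upd.any():
                        best_mm[upd] = mm[upd]
                        best_ov[upd] = ov
                        best_ref[upd] = ref_i

            for gi, i in enumerate(idxs):
                if best_ref[gi] >= 0:
                    results[i] = MatchHit(
                        mat_names[best_ref[gi]], int(best_mm[gi]), int(best_ov[gi]), False
                    )

            # star pass for tags without a mature hit
            unhit = [gi for gi in range(g) if best_ref[gi] < 0]
            if not unhit or not self.locus:
                continue
            sub = arr[unhit]
            gs = sub.shape[0]
            s_mm = np.full(gs, 255, dtype=np.int16)
            s_ov = np.zeros(gs, dtype=np.int16)
            s_ref = np.full(gs, -1, dtype=np.int32)
            loci = sorted(self.locus.items())  # mature-name order
            for ref_i, (mname, (pname, mpos)) in enumerate(loci):
                pseq = self.precursor[pname]
                Lp = len(pseq)
                Lm = len(self.mature[mname])
                padded = self._windows(pseq)
                s = self.max_shift
                for o in range(0, Lp + 2 * s - L + 1):
                    start = o - s  # tag start on precursor coordinates
                    end = start + L
                    if start < -s or end > Lp + s:
                        continue
                    # must lie on the arm opposite the mature locus
                    if start < mpos + Lm and end > mpos:
                        continue
                    win = padded[o : o + L]
                    real = win != SENTINEL
                    ov = int(real.sum())
                    if ov < self.min_overlap:
                        continue
                    mm = ov - (sub[:, real] == win[real]).sum(axis=1)
                    upd = (mm <= self.max_mm) & (
                        (mm < s_mm) | ((mm == s_mm) & (ov > s_ov))
                    )
                    if upd.any():
                        s_mm[upd] = mm[upd]
                        s_ov[upd] = ov
                        s_ref[upd] = ref_i
            for gj, gi in enumerate(unhit):
                if s_ref[gj] >= 0:
                    results[idxs[gi]] = MatchHit(
                        loci[s_ref[gj]][0], int(s_mm[gj]), int(s_ov[gj]), True
                    )
        return results

    def match(self, tag: str) -> MatchHit | None:
        return self.match_many([tag])[0]


def classify_cascade(
    tag_table: pd.DataFrame,
    refs: ReferenceSet,
    order: Sequence[str] = DEFAULT_ORDER,
    max_mm: int = 2,
    max_shift: int = 3,
    min_overlap: int = 16,
    raw_reads: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, LibraryStats, LibraryStats]:
    """Assign one category per tag and tally per-library category reads.

    Returns the annotated tag table (tag columns plus ``category``,
    ``best_hit_name``, ``mismatches``, ``is_star``) and per-library
    :class:`LibraryStats` with category read counts summing to the mappable
    reads.
    """
    unknown = set(order) - set(DEFAULT_ORDER)
    if unknown:
        raise ConfigError(f"unknown cascade categories: {sorted(unknown)}")

    seqs = tag_table["sequence"].tolist()
    n = len(seqs)

    index = MirnaIndex(refs.mature, refs.precursor, max_mm, max_shift, min_overlap)
    hits = index.match_many(seqs)

    sep = "#"
    mrna_text = sep.join(refs.mrna.values())
    rfam_text = sep.join(refs.rfam.values())
    repeat_text = sep.join(refs.repeat.values())
    genome_fwd = sep.join(refs.genome.values())
    genome_text = genome_fwd + sep + revcomp(genome_fwd)

    def _hit_name(text: str, records: dict[str, str], seq: str) -> str:
        for name, rseq in records.items():
            if seq in rseq:
                return name
        return ""

    categories = [""] * n
    best = [""] * n
    mism: list[float] = [np.nan] * n
    star = [False] * n

    for i, seq in enumerate(seqs):
        for cat in order:
            if cat == "miRNA":
                if hits[i] is not None:
                    categories[i] = "miRNA"
                    best[i] = hits[i].name
                    mism[i] = hits[i].mismatches
                    star[i] = hits[i].is_star
                    break
            elif cat == "mRNA":
                if seq in mrna_text:
                    categories[i] = "mRNA"
                    best[i] = _hit_name(mrna_text, refs.mrna, seq)
                    break
            elif cat == "RFam":
                if seq in rfam_text:
                    categories[i] = "RFam"
                    best[i] = _hit_name(rfam_text, refs.rfam, seq)
                    break
            elif cat == "Repbase":
                if seq in repeat_text:
                    categories[i] = "Repbase"
                    best[i] = _hit_name(repeat_text, refs.repeat, seq)
                    break
            elif cat == "genome":
                if seq in genome_text:
                    categories[i] = "genome"
                    best[i] = next(iter(refs.genome), "")
                    break
        else:
            categories[i] = "no_hit"

    annot = tag_table.copy()
    annot["category"] = categories
    annot["best_hit_name"] = best
    annot["mismatches"] = mism
    annot["is_star"] = star

    stats = []
    for li, col in enumerate(("count_ck", "count_tr")):
        cat_counts = annot.groupby("category")[col].sum().to_dict()
        ls = LibraryStats(
            raw_reads=raw_reads[li] if raw_reads else int(annot[col].sum()),
            mappable_reads=int(annot[col].sum()),
            categories={c: int(cat_counts.get(c, 0)) for c in CATEGORIES},
        )
        stats.append(ls)
    return annot, stats[0], stats[1]


_FAMILY_RE = re.compile(r"(?:mir|miR|MIR)-?(\d+)")


def family_of(name: str) -> str:
    """Strip the species prefix and trailing variant letters: sli-miR166a -> miR166."""
    m = _FAMILY_RE.search(name)
    return f"miR{m.group(1)}" if m else name


def build_profiles(annot: pd.DataFrame, min_reads: int = 6) -> pd.DataFrame:
    """Aggregate miRNA-category tags into per-miRNA (mature/star) profiles.

    Tags assigned to the same reference miRNA and arm are summed; profiles
    are kept only when either library shows at least ``min_reads`` reads
    (the read-support filter against sequencing error).
    """
    mir = annot[annot["category"] == "miRNA"]
    rows = []
    for (name, is_star), grp in mir.groupby(["best_hit_name", "is_star"]):
        grp = grp.assign(total=grp.count_ck + grp.count_tr).sort_values(
            by=["total", "sequence"], ascending=[False, True]
        )
        rows.append(
            {
                "name": name + ("*" if is_star else ""),
                "family": family_of(name),
                "arm": "star" if is_star else "mature",
                "sequence": grp.iloc[0]["sequence"],
                "count_ck": int(grp.count_ck.sum()),
                "count_tr": int(grp.count_tr.sum()),
            }
        )
    profiles = pd.DataFrame(
        rows, columns=["name", "family", "arm", "sequence", "count_ck", "count_tr"]
    )
    if len(profiles):
        keep = (profiles.count_ck >= min_reads) | (profiles.count_tr >= min_reads)
        profiles = profiles[keep].sort_values("name", ignore_index=True)
    return profiles


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot.to_csv(path, sep="\t", index=False)
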