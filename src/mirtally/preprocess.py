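"""Raw FASTQ to unique small-RNA tags.

The "impurity" removal implemented here is deliberately minimal and concrete:
3' adapter trimming, exclusion of reads containing ambiguous bases, and
length gating to the sequenced insert range (15-32 nt by default).  Reads
surviving these filters are the *mappable* reads; collapsing them yields one
:class:`SmallRNATag` per distinct sequence with exact per-library counts.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._util import MirtallyError, clean_seq


class FastqParseError(MirtallyError):
    """Raised when a FASTQ record cannot be parsed; names the record index."""


class EmptyInputError(MirtallyError):
    pass


@dataclass
class SmallRNATag:
    """A unique collapsed read sequence with raw counts per library."""

    sequence: str
    count_ck: int
    count_tr: int

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class LibraryStats:
    """Per-library read accounting, filled in by preprocess and annotate."""

    raw_reads: int = 0
    mappable_reads: int = 0
    categories: dict[str, int] = field(default_factory=dict)


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(source) -> Iterable[tuple[str, str]]:
    """Yield (title, sequence) pairs, wrapping parse errors with an index."""
    idx = 0
    it = FastqGeneralIterator(source)
    while True:
        try:
            title, seq, _qual = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise FastqParseError(f"malformed FASTQ record at index {idx}: {exc}") from exc
        yield title, seq
        idx += 1


def find_adapter(read: str, adapter: str, min_prefix: int = 6) -> int:
    """Locate the 3' adapter in a read; return the insert length, or -1.

    The adapter is recognised at the leftmost position where either the full
    adapter matches with at most one substitution, or the read suffix
    (>= ``min_prefix`` nt) exactly equals a prefix of the adapter.
    """
    n, m = len(read), len(adapter)
    # leftmost exact-suffix candidate (covers the overwhelmingly common case)
    seed = adapter[:min_prefix]
    exact = -1
    j = read.find(seed)
    while j != -1:
        seg = read[j : j + m]
        if adapter.startswith(seg):
            exact = j
            break
        j = read.find(seed, j + 1)
    # a full-adapter hit with one mismatch may start before the exact hit
    limit = exact if exact != -1 else n
    for i in range(0, min(limit, n - m + 1)):
        mm = 0
        for a, b in zip(read[i : i + m], adapter):
            if a != b:
                mm += 1
                if mm > 1:
                    break
        if mm <= 1:
            return i
    return exact


def trim_and_filter(
    fastq: str | Path | Iterable[str],
    adapter: str,
    min_len: int = 15,
    max_len: int = 32,
) -> tuple[list[str], LibraryStats]:
    """Adapter-trim and length-gate one library.

    ``fastq`` may be a path (optionally gzipped) or an iterable of FASTQ
    lines.  Returns the clean insert sequences (uppercase DNA) and the
    per-library tally of raw vs mappable reads.
    """
    if not adapter:
        raise MirtallyError("adapter must be non-empty")
    if min_len > max_len:
        raise MirtallyError("min_len must be <= max_len")
    adapter = clean_seq(adapter)

    stats = LibraryStats()
    clean: list[str] = []

    if isinstance(fastq, (str, Path)):
        handle = _open_text(fastq)
        close = True
    else:
        # iterable of lines (e.g. in-memory records from the simulator)
        import io

        handle = io.StringIO("".join(fastq))
        close = False
    try:
        for _title, seq in _iter_fastq(handle):
            stats.raw_reads += 1
            seq = clean_seq(seq)
            pos = find_adapter(seq, adapter)
            insert = seq[:pos] if pos != -1 else seq
            if "N" in insert:
                continue
            if not (min_len <= len(insert) <= max_len):
                continue
            clean.append(insert)
            stats.mappable_reads += 1
    finally:
        if close:
            handle.close()
    return clean, stats


def collapse(reads_ck: Sequence[str], reads_tr: Sequence[str]) -> pd.DataFrame:
    """Collapse clean reads from both libraries into a unique-tag table.

    One row per distinct sequence with exact per-library multiplicities,
    sorted by total count (descending) then sequence (ascending) so repeated
    runs produce byte-identical tables.
    """
    if not reads_ck and not reads_tr:
        raise EmptyInputError("both libraries are empty after filtering")
    ck = Counter(reads_ck)
    tr = Counter(reads_tr)
    seqs = sorted(set(ck) | set(tr))
    df = pd.DataFrame(
        {
            "sequence": seqs,
            "length": [len(s) for s in seqs],
            "count_ck": [ck.get(s, 0) for s in seqs],
            "count_tr": [tr.get(s, 0) for s in seqs],
        }
    )
    df = (
        df.assign(total=df.count_ck + df.count_tr)
        .sort_values(by=["total", "sequence"], ascending=[False, True], ignore_index=True)
        .drop(columns="total")
    )
    return df


def tags_from_frame(df: pd.DataFrame) -> list[SmallRNATag]:
    return [
        SmallRNATag(row.sequence, int(row.count_ck), int(row.count_tr))
        for row in df.itertuples(index=False)
    ]


def write_tag_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tag_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
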