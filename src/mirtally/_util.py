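"""Shared low-level helpers: alphabet handling, sequence encoding, FASTA I/O."""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# uint8 codes: A=0 C=1 G=2 T=3, anything else (incl. padding sentinel) = 4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
SENTINEL = np.uint8(4)


class MirtallyError(Exception):
    """Base class for all package errors."""


class ConfigError(MirtallyError):
    """Invalid or impossible configuration."""


def clean_seq(seq: str) -> str:
    """Canonicalise a nucleotide string: uppercase, RNA U -> DNA T."""
    return seq.strip().upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def mask_kmers(seq: str, kmers: Iterable[str], rng: np.random.Generator) -> str:
    """Substitute bases until none of `kmers` occurs in `seq`.

    Used by the simulator so inserts never contain adapter seeds, which would
    make adapter detection ambiguous.
    """
    kmers = list(kmers)
    s = list(seq)
    changed = True
    while changed:
        changed = False
        text = "".join(s)
        for k in kmers:
            pos = text.find(k)
            if pos >= 0:
                j = pos + int(rng.integers(0, len(k)))
                alternatives = [b for b in BASES if b != s[j]]
                s[j] = alternatives[int(rng.integers(0, 3))]
                changed = True
                break
    return "".join(s)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA file into an ordered name -> cleaned-sequence mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = clean_seq(str(rec.seq))
    return records


def write_fasta(path: str | os.PathLike, records: Mapping[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n{seq}\n")
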