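"""Synthetic small-RNA-seq data with known ground truth.

Emulates a two-library (control "CK" vs treatment "TR") small-RNA sequencing
experiment: a set of conserved miRNA families with mature and star arms
embedded in precursors, contaminant (rRNA/tRNA-like), mRNA, repeat and genome
reference sequences, and two FASTQ libraries of 3'-adapter-ligated reads with
planted per-miRNA fold changes between the libraries.  Every emitted read
carries its provenance, so each downstream stage of the pipeline can be
checked against the generating truth.

Design notes
------------
* All sequences use the DNA alphabet (T, not U); ingest code normalises U->T.
* Reference sequences and filler inserts are masked so that no 6-mer of the
  3' adapter occurs inside an insert; adapter location is therefore
  unambiguous and the ground-truth read accounting is exact when
  ``error_rate`` is zero.
* Expected read counts are expressed directly in reads per library; a
  "random filler" source absorbs the remainder of the library depth, so the
  expected TR/CK ratio of a differentially expressed miRNA is exactly
  ``2**planted_log2fc`` while each library still totals ``depth_per_library``
  reads exactly.
* Star (passenger-strand) reads are emitted at a fixed small fraction of the
  mature arm's control abundance in both libraries and are not scaled by the
  planted fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import ConfigError, mask_kmers, random_seq, revcomp, write_fasta

#: miRBase-style family numbers used for naming synthetic families.
FAMILY_NUMBERS = [
    156, 159, 160, 162, 164, 166, 167, 168, 169, 171, 172, 319, 390, 393,
    396, 397, 398, 399, 403, 408, 482, 530, 827, 858, 1919, 2911, 5300, 6022,
    6024, 6026, 7122, 7696, 7981, 8007, 9471, 9478,
]

#: Illumina TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: library depth at which abundance_range is expressed (expected reads per
#: miRNA scale linearly with depth_per_library relative to this)
REFERENCE_DEPTH = 50000

_MEMBER_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass
class SyntheticConfig:
    """Parameters of the simulated experiment.

    Counts are per library; abundances are expected reads per library at the
    configured depth.
    """

    n_mirnas: int = 40
    n_families: int = 15
    mirna_length_range: tuple[int, int] = (20, 22)
    n_contaminants: int = 30
    n_mrnas: int = 20
    n_repeats: int = 8
    genome_length: int = 20000
    depth_per_library: int = 50000
    de_fraction: float = 0.2
    planted_log2fc: float = 2.0
    error_rate: float = 0.001
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 40
    seed: int = 0
    # expected reads per miRNA per library at a 50,000-read library, drawn
    # log-uniformly and scaled linearly with depth_per_library
    abundance_range: tuple[float, float] = (2.0, 1000.0)
    # DE miRNAs are only planted on miRNAs whose CK expectation is at least this
    de_min_expected: float = 50.0
    star_fraction: float = 0.05
    # expected fraction of the library drawn from each non-miRNA class;
    # the remainder (after miRNAs, stars and these classes) is random filler
    mrna_fraction: float = 0.09
    contaminant_fraction: float = 0.155
    repeat_fraction: float = 0.001
    genome_fraction: float = 0.21

    def __post_init__(self) -> None:
        counts = {
            "n_mirnas": self.n_mirnas,
            "n_families": self.n_families,
            "n_contaminants": self.n_contaminants,
            "n_mrnas": self.n_mrnas,
            "n_repeats": self.n_repeats,
            "genome_length": self.genome_length,
            "depth_per_library": self.depth_per_library,
            "read_length": self.read_length,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigError(f"{name} must be > 0, got {value}")
        if self.n_mirnas < self.n_families:
            raise ConfigError("n_mirnas must be >= n_families")
        if self.n_families > len(FAMILY_NUMBERS):
            raise ConfigError(f"at most {len(FAMILY_NUMBERS)} families supported")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError("de_fraction must be in [0, 1]")
        if not 0.0 <= self.error_rate < 0.1:
            raise ConfigError("error_rate must be in [0, 0.1)")
        lo, hi = self.mirna_length_range
        if not (18 <= lo <= hi <= 24):
            raise ConfigError("mirna_length_range must lie within 18-24 nt")
        if not self.adapter:
            raise ConfigError("adapter must be non-empty")
        if not 0 < self.abundance_range[0] <= self.abundance_range[1]:
            raise ConfigError("abundance_range must be positive and ordered")


@dataclass
class ReferenceBundle:
    """All reference sequences: known miRNAs plus the annotation background.

    ``star_arm`` records the passenger-strand sequence embedded in each
    precursor (keyed by mature name); it is generator bookkeeping used to emit
    star reads and is not written as a reference file — annotation must
    recover stars from the precursors alone.
    """

    mature: dict[str, str]
    precursor: dict[str, str]
    mrna: dict[str, str]
    contaminant: dict[str, str]
    repeat: dict[str, str]
    genome: dict[str, str]
    star_arm: dict[str, str] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for kind in ("mature", "precursor", "mrna", "contaminant", "repeat", "genome"):
            path = outdir / f"{kind}.fa"
            write_fasta(path, getattr(self, kind))
            paths[kind] = path
        return paths


@dataclass
class GroundTruth:
    """Generating truth: per-miRNA abundances/labels and per-read provenance."""

    mirna: pd.DataFrame  # name, family, cls, ck_expected, tr_expected, ck_reads, tr_reads, label
    provenance: dict[str, pd.DataFrame] = field(default_factory=dict)  # lib -> read_id, cls, source, insert_len

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / "ground_truth.tsv"
        out = self.mirna.rename(
            columns={"ck_expected": "ck_abundance", "tr_expected": "tr_abundance"}
        )
        out.to_csv(path, sep="\t", index=False)
        for lib, df in self.provenance.items():
            df.to_csv(outdir / f"provenance_{lib.lower()}.tsv", sep="\t", index=False)
        return path


def _adapter_kmers(adapter: str, k: int = 6) -> list[str]:
    if len(adapter) < k:
        return [adapter]
    return [adapter[i : i + k] for i in range(len(adapter) - k + 1)]


def _masked_random_seq(rng: np.random.Generator, length: int, kmers: list[str]) -> str:
    return mask_kmers(random_seq(rng, length), kmers, rng)


def generate_references(config: SyntheticConfig) -> ReferenceBundle:
    """Build the reference bundle (mature/precursor/mRNA/contaminant/repeat/genome).

    Each mature miRNA is an exact substring of exactly one precursor; the
    precursor carries a star arm (approximately the reverse complement of the
    mature) on the opposite side of a loop spacer.  Family naming follows the
    miRBase convention ``sli-miR<NNN><letter>``.
    """
    rng = np.random.default_rng([int(config.seed), 1])
    kmers = _adapter_kmers(config.adapter)
    lo, hi = config.mirna_length_range

    # distribute members over families: one each, remainder at random
    members = np.ones(config.n_families, dtype=int)
    extra = config.n_mirnas - config.n_families
    if extra:
        members += np.bincount(
            rng.integers(0, config.n_families, size=extra), minlength=config.n_families
        )

    mature: dict[str, str] = {}
    precursor: dict[str, str] = {}
    star_arm: dict[str, str] = {}
    used: set[str] = set()
    for fam_idx in range(config.n_families):
        fam_num = FAMILY_NUMBERS[fam_idx]
        core = _masked_random_seq(rng, hi, kmers)
        for j in range(members[fam_idx]):
            length = int(rng.integers(lo, hi + 1))
            seq = core[:length]

            def _clashes(s: str) -> bool:
                # members must be pairwise distinct and containment-free so
                # each mature occurs in exactly one precursor
                return (
                    any(s in u or u in s for u in used)
                    or any(k in s for k in kmers)
                )

            attempts = 0
            while _clashes(seq) or (j > 0 and attempts == 0):
                pos = int(rng.integers(0, length))
                alt = [b for b in "ACGT" if b != seq[pos]]
                seq = seq[:pos] + alt[int(rng.integers(0, 3))] + seq[pos + 1 :]
                attempts += 1
            used.add(seq)
            name = f"sli-miR{fam_num}{_MEMBER_LETTERS[j]}"
            mature[name] = seq

            star = mask_kmers(revcomp(seq), kmers, rng)
            star_arm[name] = star
            flank5 = _masked_random_seq(rng, int(rng.integers(10, 16)), kmers)
            loop = _masked_random_seq(rng, int(rng.integers(8, 16)), kmers)
            flank3 = _masked_random_seq(rng, int(rng.integers(10, 16)), kmers)
            if rng.random() < 0.5:
                arms = seq + loop + star
            else:
                arms = star + loop + seq
            precursor[f"sli-MIR{fam_num}{_MEMBER_LETTERS[j]}"] = flank5 + arms + flank3

    def _records(prefix: str, n: int, lo_len: int, hi_len: int) -> dict[str, str]:
        return {
            f"{prefix}{i + 1}": _masked_random_seq(rng, int(rng.integers(lo_len, hi_len + 1)), kmers)
            for i in range(n)
        }

    mrna = _records("mRNA_", config.n_mrnas, 300, 800)
    contaminant = _records("RFam_", config.n_contaminants, 60, 160)
    repeat = _records("Repbase_", config.n_repeats, 100, 200)
    genome = {"chr1": _masked_random_seq(rng, config.genome_length, kmers)}
    # the reverse complement of the genome is also searched downstream:
    # mask adapter seeds on that strand too
    genome["chr1"] = revcomp(mask_kmers(revcomp(genome["chr1"]), kmers, rng))

    return ReferenceBundle(mature, precursor, mrna, contaminant, repeat, genome, star_arm)


def _fragment(rng: np.random.Generator, seq: str, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, min(hi, len(seq)) + 1))
    start = int(rng.integers(0, len(seq) - length + 1))
    return seq[start : start + length]


def simulate_libraries(
    config: SyntheticConfig,
    refs: ReferenceBundle,
    outdir: str | Path | None = None,
) -> tuple[list[str], list[str], GroundTruth] | tuple[Path, Path, GroundTruth]:
    """Simulate the CK and TR FASTQ libraries.

    Returns the two libraries (as FASTQ file paths when ``outdir`` is given,
    otherwise as lists of FASTQ record strings) plus the :class:`GroundTruth`.
    """
    if config.depth_per_library <= 0:
        raise ConfigError("depth_per_library must be positive")
    rng = np.random.default_rng([int(config.seed), 2])
    depth = config.depth_per_library

    names = list(refs.mature)
    n = len(names)
    lo_ab, hi_ab = config.abundance_range
    lam = np.exp(rng.uniform(math.log(lo_ab), math.log(hi_ab), size=n))
    lam *= depth / REFERENCE_DEPTH

    n_de = int(round(config.de_fraction * n))
    eligible = np.flatnonzero(lam >= config.de_min_expected)
    if n_de > eligible.size:
        raise ConfigError(
            f"cannot plant {n_de} DE miRNAs: only {eligible.size} have expected "
            f"CK counts >= {config.de_min_expected}"
        )
    de_idx = rng.choice(eligible, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    signs = np.zeros(n)
    # alternate up/down among the planted miRNAs, order randomised
    planted = rng.permutation(de_idx)
    signs[planted[0::2]] = 1.0
    signs[planted[1::2]] = -1.0

    ck_expected = lam.copy()
    tr_expected = lam * np.power(2.0, signs * config.planted_log2fc)
    labels = np.where(signs > 0, "up", np.where(signs < 0, "down", "none"))

    # source table rows: (name, class, expected_ck, expected_tr, sampler key)
    sources: list[tuple[str, str, float, float]] = []
    for i, name in enumerate(names):
        sources.append((name, "miRNA", float(ck_expected[i]), float(tr_expected[i])))
    star_ab = config.star_fraction * lam
    for i, name in enumerate(names):
        sources.append((name + "*", "miRNA_star", float(star_ab[i]), float(star_ab[i])))

    def _class_rows(records: dict[str, str], cls: str, fraction: float) -> None:
        if not records or fraction <= 0:
            return
        w = np.exp(rng.uniform(math.log(1.0), math.log(100.0), size=len(records)))
        w = w / w.sum() * fraction * depth
        for (name, _), wi in zip(records.items(), w):
            sources.append((name, cls, float(wi), float(wi)))

    _class_rows(refs.contaminant, "RFam", config.contaminant_fraction)
    _class_rows(refs.mrna, "mRNA", config.mrna_fraction)
    _class_rows(refs.repeat, "Repbase", config.repeat_fraction)
    sources.append(("chr1", "genome", config.genome_fraction * depth, config.genome_fraction * depth))

    tot_ck = sum(s[2] for s in sources)
    tot_tr = sum(s[3] for s in sources)
    filler_ck, filler_tr = depth - tot_ck, depth - tot_tr
    if filler_ck <= 0 or filler_tr <= 0:
        raise ConfigError(
            "depth_per_library too small for the configured class fractions "
            f"(non-filler expectation CK={tot_ck:.0f}, TR={tot_tr:.0f})"
        )
    sources.append(("random", "filler", filler_ck, filler_tr))

    kmers = _adapter_kmers(config.adapter)
    star_seqs = {name + "*": seq for name, seq in refs.star_arm.items()}

    expected = {
        "CK": np.array([s[2] for s in sources]),
        "TR": np.array([s[3] for s in sources]),
    }

    mirna_reads = {"CK": np.zeros(n, dtype=int), "TR": np.zeros(n, dtype=int)}
    libraries: dict[str, list[str]] = {}
    provenance: dict[str, pd.DataFrame] = {}
    frag_lo, frag_hi = 16, 34

    for lib in ("CK", "TR"):
        p = expected[lib] / expected[lib].sum()
        counts = rng.multinomial(depth, p)
        records: list[tuple[str, str, str, int]] = []  # (cls, src, insert, insert_len)
        for (src_name, cls, _, _), c in zip(sources, counts):
            for _ in range(int(c)):
                if cls in ("miRNA", "miRNA_star"):
                    insert = refs.mature[src_name] if cls == "miRNA" else star_seqs[src_name]
                elif cls == "mRNA":
                    insert = _fragment(rng, refs.mrna[src_name], frag_lo, 28)
                elif cls == "RFam":
                    insert = _fragment(rng, refs.contaminant[src_name], frag_lo, 28)
                elif cls == "Repbase":
                    insert = _fragment(rng, refs.repeat[src_name], frag_lo, 28)
                elif cls == "genome":
                    frag = _fragment(rng, refs.genome["chr1"], frag_lo, frag_hi)
                    insert = frag if rng.random() < 0.5 else revcomp(frag)
                else:  # filler
                    insert = _masked_random_seq(rng, int(rng.integers(18, 29)), kmers)
                records.append((cls, src_name, insert, len(insert)))
        for i, c in enumerate(counts[:n]):
            mirna_reads[lib][i] = c

        order = rng.permutation(len(records))
        reads: list[str] = []
        rows = []
        for serial, idx in enumerate(order):
            cls, src_name, insert, ilen = records[idx]
            read = (insert + config.adapter)[: config.read_length]
            if config.error_rate > 0:
                mask = rng.random(len(read)) < config.error_rate
                if mask.any():
                    chars = list(read)
                    for j in np.flatnonzero(mask):
                        alt = [b for b in "ACGT" if b != chars[j]]
                        chars[j] = alt[int(rng.integers(0, 3))]
                    read = "".join(chars)
            rid = f"{lib}_{serial:06d}|{cls}|{src_name}|{ilen}"
            reads.append(f"@{rid}\n{read}\n+\n{'I' * len(read)}\n")
            rows.append((rid, cls, src_name, ilen))
        libraries[lib] = reads
        provenance[lib] = pd.DataFrame(rows, columns=["read_id", "cls", "source", "insert_len"])

    truth = GroundTruth(
        mirna=pd.DataFrame(
            {
                "name": names,
                "family": [_family_of(nm) for nm in names],
                "cls": "miRNA",
                "ck_expected": ck_expected,
                "tr_expected": tr_expected,
                "ck_reads": mirna_reads["CK"],
                "tr_reads": mirna_reads["TR"],
                "label": labels,
            }
        ),
        provenance=provenance,
    )

    if outdir is None:
        return libraries["CK"], libraries["TR"], truth
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for lib in ("CK", "TR"):
        path = outdir / f"{lib.lower()}.fastq"
        with open(path, "w") as fh:
            fh.writelines(libraries[lib])
        paths.append(path)
    truth.write(outdir)
    return paths[0], paths[1], truth


def _family_of(name: str) -> str:
    import re

    m = re.search(r"(?:mir|miR|MIR)-?(\d+)", name)
    return f"miR{m.group(1)}" if m else name


def simulate_ct_table(
    truth: GroundTruth,
    mirnas: list[str],
    replicates: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
    reference: str = "U6",
) -> pd.DataFrame:
    """Generate a qPCR cycle-threshold table consistent with the ground truth.

    Ct decreases by one cycle per doubling of abundance; the reference snRNA
    is constant across conditions.
    """
    rng = np.random.default_rng([int(seed), 3])
    rows = []
    table = truth.mirna.set_index("name")
    for sample, col in (("CK", "ck_expected"), ("TR", "tr_expected")):
        for rep in range(1, replicates + 1):
            rows.append((sample, reference, rep, 18.0 + rng.normal(0.0, noise_sd)))
            for name in mirnas:
                ct = 30.0 - math.log2(float(table.loc[name, col])) + rng.normal(0.0, noise_sd)
                rows.append((sample, name, rep, ct))
    return pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["mirna_length_range"] = list(d["mirna_length_range"])
    d["abundance_range"] = list(d["abundance_range"])
    return d
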