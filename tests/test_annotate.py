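"""Homology matching, the classification cascade and profile building."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirtally._util import ConfigError, revcomp
from mirtally.annotate import (
    MirnaIndex,
    ReferenceSet,
    build_profiles,
    classify_cascade,
    family_of,
)
from mirtally.preprocess import collapse, trim_and_filter

from oracles import brute_category, brute_match

MAT = {
    "sli-miR156a": "TGACAGAAGAGAGTGAGCACA",
    "sli-miR166a": "TCGGACCAGGCTTCATTCCCC",
}
PREC = {
    "sli-MIR156a": "GGATGCATGATC" + "TGACAGAAGAGAGTGAGCACA" + "ATCGGATCGA"
    + revcomp("TGACAGAAGAGAGTGAGCACA") + "CCGATCGGATTA",
    "sli-MIR166a": "ACCGATTAGGCA" + "TCGGACCAGGCTTCATTCCCC" + "TTACGGACCA"
    + revcomp("TCGGACCAGGCTTCATTCCCC") + "AGGATCCGGTAC",
}


def _mutate(seq: str, pos: int) -> str:
    alt = {"A": "C", "C": "A", "G": "T", "T": "G"}
    return seq[:pos] + alt[seq[pos]] + seq[pos + 1 :]


class TestMirnaIndex:
    def test_exact_mature_hit(self):
        idx = MirnaIndex(MAT, PREC)
        hit = idx.match(MAT["sli-miR156a"])
        assert hit.name == "sli-miR156a"
        assert hit.mismatches == 0 and not hit.is_star

    def test_two_mismatches_accepted_three_rejected(self):
        idx = MirnaIndex(MAT, PREC)
        tag2 = _mutate(_mutate(MAT["sli-miR156a"], 4), 10)
        assert idx.match(tag2).mismatches == 2
        tag3 = _mutate(tag2, 15)
        assert idx.match(tag3) is None

    def test_shifted_and_truncated_tags_match(self):
        idx = MirnaIndex(MAT, PREC)
        # drop 2 nt from the 5' end: still >= 16 nt of overlap, 0 mismatches
        hit = idx.match(MAT["sli-miR166a"][2:])
        assert hit.name == "sli-miR166a" and hit.mismatches == 0

    def test_star_arm_detected_from_precursor(self):
        idx = MirnaIndex(MAT, PREC)
        star = revcomp(MAT["sli-miR156a"])
        hit = idx.match(star)
        assert hit is not None and hit.is_star and hit.name == "sli-miR156a"

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ConfigError):
            MirnaIndex({})

    def test_matches_brute_force_scan_on_synthetic_tags(self, small_run):
        """Vectorised matcher agrees with the nested-loop all-pairs scan."""
        cfg, refs, ck, tr, _ = small_run
        reads_ck, _ = trim_and_filter(ck, cfg.adapter)
        reads_tr, _ = trim_and_filter(tr, cfg.adapter)
        table = collapse(reads_ck, reads_tr)
        idx = MirnaIndex(refs.mature, refs.precursor)
        hits = idx.match_many(table.sequence.tolist())
        for seq, hit in zip(table.sequence, hits):
            expected = brute_match(seq, refs.mature, refs.precursor)
            if expected is None:
                assert hit is None, seq
            else:
                assert hit is not None, seq
                assert (hit.name, hit.mismatches, hit.overlap, hit.is_star) == expected, seq


@pytest.fixture(scope="module")
def cascade(small_run):
    cfg, refs, ck, tr, _ = small_run
    reads_ck, stats_ck = trim_and_filter(ck, cfg.adapter)
    reads_tr, stats_tr = trim_and_filter(tr, cfg.adapter)
    table = collapse(reads_ck, reads_tr)
    rs = ReferenceSet.from_bundle(refs)
    annot, c1, c2 = classify_cascade(
        table, rs, raw_reads=(stats_ck.raw_reads, stats_tr.raw_reads)
    )
    return rs, annot, c1, c2


class TestCascade:
    def test_category_partition_sums_to_mappable(self, cascade):
        _, annot, c1, c2 = cascade
        assert sum(c1.categories.values()) == c1.mappable_reads == annot.count_ck.sum()
        assert sum(c2.categories.values()) == c2.mappable_reads == annot.count_tr.sum()
        assert (annot.category != "").all()

    def test_mirna_takes_precedence_over_mrna(self):
        mirna_seq = MAT["sli-miR156a"]
        rs = ReferenceSet(
            mature=MAT,
            precursor=PREC,
            mrna={"m1": "CCCC" + mirna_seq + "GGGG"},
            rfam={},
            repeat={},
            genome={"chr1": "ACGT" * 20},
        )
        table = pd.DataFrame(
            {"sequence": [mirna_seq], "length": [len(mirna_seq)], "count_ck": [5], "count_tr": [3]}
        )
        annot, _, _ = classify_cascade(table, rs)
        assert annot.category.iloc[0] == "miRNA"

    def test_genome_match_is_reverse_complement_aware(self):
        tag = "ATCGATCGATTAGCCGATTACG"
        genome = "G" * 12 + revcomp(tag) + "C" * 12
        rs = ReferenceSet(MAT, PREC, {}, {}, {}, {"chr1": genome})
        table = pd.DataFrame(
            {"sequence": [tag], "length": [len(tag)], "count_ck": [1], "count_tr": [0]}
        )
        annot, _, _ = classify_cascade(table, rs)
        assert annot.category.iloc[0] == "genome"

    def test_agrees_with_brute_force_cascade(self, cascade, small_run):
        _, refs, *_ = small_run
        rs, annot, _, _ = cascade
        for row in annot.itertuples():
            assert row.category == brute_category(row.sequence, rs), row.sequence


class TestProfiles:
    def test_read_support_filter_is_strictly_more_than_five(self):
        annot = pd.DataFrame(
            {
                "sequence": ["A" * 21, "C" * 21],
                "count_ck": [5, 6],
                "count_tr": [5, 0],
                "category": ["miRNA", "miRNA"],
                "best_hit_name": ["sli-miR156a", "sli-miR166a"],
                "is_star": [False, False],
            }
        )
        prof = build_profiles(annot, min_reads=6)
        assert list(prof.name) == ["sli-miR166a"]

    def test_member_tags_summed_per_reference_and_arm(self):
        annot = pd.DataFrame(
            {
                "sequence": ["A" * 21, "A" * 20 + "C", "G" * 21],
                "count_ck": [10, 5, 7],
                "count_tr": [2, 1, 0],
                "category": ["miRNA", "miRNA", "miRNA"],
                "best_hit_name": ["sli-miR156a", "sli-miR156a", "sli-miR156a"],
                "is_star": [False, False, True],
            }
        )
        prof = build_profiles(annot)
        mature = prof[prof.arm == "mature"].iloc[0]
        assert mature["count_ck"] == 15 and mature["count_tr"] == 3
        assert mature["sequence"] == "A" * 21  # highest-count member tag
        star = prof[prof.arm == "star"].iloc[0]
        assert star["name"] == "sli-miR156a*" and star["count_ck"] == 7

    def test_family_grouping_collapses_member_letters(self):
        names = [f"sli-miR166{letter}" for letter in "abcdefghijk"]
        fams = {family_of(n) for n in names}
        assert fams == {"miR166"}
        assert family_of("sli-miR5300") == "miR5300"
        assert family_of("ath-MIR396b") == "miR396"

    def test_recovered_profiles_match_ground_truth_filter(self, clean_run):
        cfg, refs, ck, tr, truth = clean_run
        reads_ck, _ = trim_and_filter(ck, cfg.adapter)
        reads_tr, _ = trim_and_filter(tr, cfg.adapter)
        table = collapse(reads_ck, reads_tr)
        rs = ReferenceSet.from_bundle(refs)
        annot, _, _ = classify_cascade(table, rs)
        prof = build_profiles(annot, min_reads=6)
        mature = prof[prof.arm == "mature"]
        gt = truth.mirna
        expected = set(gt[(gt.ck_reads >= 6) | (gt.tr_reads >= 6)].name)
        assert set(mature.name) == expected
        # error-free data: perfect recall with zero mismatches
        mm = annot.loc[annot.category == "miRNA", "mismatches"]
        assert (mm == 0).all()
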