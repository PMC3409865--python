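"""Artifact filtering, adapter trimming, unique-read collapsing and size
tables."""

import random
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnacascade.preprocess import (collapse_unique, filter_artifact_reads,
                                    merge_unique, preprocess_reads,
                                    size_distribution, trim_adapter,
                                    trim_with_rescue)
from srnacascade.sequtils import hamming, random_dna
from srnacascade.simulate import ADAPTER3

RNG = np.random.default_rng(11)


@pytest.mark.parametrize("read, removed_as", [
    ("A" * 36, "homopolymer"),
    ("ACGT" * 8 + "ACGN", "n_containing"),
    ("ACGT" * 9, None),
    ("A" * 20 + "CGT" * 5 + "A", None),  # internal poly-A run is legitimate
])
def test_artifact_filter(read, removed_as):
    kept, removals = filter_artifact_reads([read])
    if removed_as is None:
        assert kept == [read]
    else:
        assert kept == [] and removals[removed_as] == 1


def test_artifact_filter_empty_input():
    assert filter_artifact_reads([]) == ([], {"n_containing": 0, "homopolymer": 0})


def _make_read(insert, adapter=ADAPTER3, fill="G"):
    read = insert + adapter
    read = read + fill * max(0, 36 - len(read))
    return read[:36]


def test_trim_exact_adapter_position_21():
    insert = random_dna(RNG, 20)
    res = trim_adapter(_make_read(insert), ADAPTER3)
    assert res.status == "trimmed"
    assert res.insert == insert
    assert res.adapter_start == 21


def test_two_mismatches_in_first_ten_aligned_bases_blocks_trimming():
    insert = random_dna(RNG, 20)
    bad = list(ADAPTER3)
    bad[0] = "A" if bad[0] != "A" else "C"
    bad[5] = "A" if bad[5] != "A" else "C"
    res = trim_adapter(_make_read(insert, "".join(bad)), ADAPTER3)
    assert res.status == "untrimmed"


def test_one_mismatch_is_tolerated():
    insert = random_dna(RNG, 20)
    bad = list(ADAPTER3)
    bad[3] = "A" if bad[3] != "A" else "C"
    res = trim_adapter(_make_read(insert, "".join(bad)), ADAPTER3)
    assert res.status == "trimmed" and res.adapter_start == 21


def test_leftmost_hit_wins():
    # a periodic adapter puts valid alignments at read positions 19 and 25;
    # the scanner must report 19, in agreement with the exhaustive oracle
    adapter = "ACGTAC" * 4
    read = random_dna(RNG, 18) + adapter[:18]
    res = trim_adapter(read, adapter)
    oracle = _oracle_trim(read, adapter, 10, 1, 18)
    assert oracle[1] == 19 or oracle[1] is None  # sanity on the construction
    assert (res.status, res.adapter_start) == oracle
    assert res.adapter_start == 19


def test_adapter_shorter_than_min_match_is_config_error():
    with pytest.raises(ValueError):
        trim_adapter("A" * 36, "ACGTACG", min_match=10)


def _oracle_trim(read, adapter, min_match, max_mismatch, search_start):
    """Exhaustive enumeration of every (position, mismatch) pair."""
    hits = []
    for pos in range(search_start, len(read) + 1):
        aligned = min(len(adapter), len(read) - pos + 1)
        if aligned < min_match:
            continue
        mism = hamming(read[pos - 1:pos - 1 + aligned], adapter[:aligned])
        if mism <= max_mismatch:
            hits.append((pos, mism))
    if not hits:
        return ("untrimmed", None)
    pos = min(hits)[0]
    return (("adapter_only" if pos == 1 else "trimmed"), pos)


def test_trimmer_matches_exhaustive_enumeration_on_random_reads():
    rng = np.random.default_rng(7)
    for _ in range(2000):
        read = random_dna(rng, 36)
        if rng.random() < 0.6:  # plant an adapter at a random position
            pos = int(rng.integers(1, 37))
            read = (read[:pos - 1] + ADAPTER3)[:36]
            read = read + random_dna(rng, 36 - len(read))
        res = trim_adapter(read, ADAPTER3)
        assert (res.status, res.adapter_start) == _oracle_trim(
            read, ADAPTER3, 10, 1, 18)


def test_secondary_pass_rescues_short_inserts_and_adapter_only():
    short = random_dna(RNG, 10)
    res, which = trim_with_rescue(_make_read(short), ADAPTER3)
    assert res.status == "trimmed" and which == "secondary"
    assert res.insert == short
    res, which = trim_with_rescue(_make_read(""), ADAPTER3)
    assert res.status == "adapter_only" and which == "secondary"
    assert res.insert == ""


def test_collapse_counts_and_roundtrip():
    unique = collapse_unique(["X" * 20, "X" * 20, "Y" * 20], "g")
    table = {u.sequence: u.count("g") for u in unique}
    assert table == {"X" * 20: 2, "Y" * 20: 1}
    # expand back: multiset identity
    expanded = Counter({u.sequence: u.count("g") for u in unique})
    assert expanded == Counter(["X" * 20, "X" * 20, "Y" * 20])


def test_collapse_matches_sort_and_scan_oracle():
    rng = np.random.default_rng(5)
    pool = [random_dna(rng, 20) for _ in range(300)]
    inserts = [pool[int(rng.integers(0, 300))] for _ in range(100_000)]
    unique = collapse_unique(inserts, "g")
    ordered = sorted(inserts)
    oracle = {}
    i = 0
    while i < len(ordered):  # hash-free sort-and-scan
        j = i
        while j < len(ordered) and ordered[j] == ordered[i]:
            j += 1
        oracle[ordered[i]] = j - i
        i = j
    assert {u.sequence: u.count("g") for u in unique} == oracle
    assert sum(u.count("g") for u in unique) == len(inserts)


@settings(derandomize=True, max_examples=30)
@given(st.lists(st.text(alphabet="ACGT", min_size=1, max_size=8), max_size=60),
       st.randoms())
def test_collapse_is_order_invariant(inserts, rnd):
    a = collapse_unique(inserts, "g")
    shuffled = list(inserts)
    rnd.shuffle(shuffled)
    b = collapse_unique(shuffled, "g")
    assert [(u.sequence, u.counts) for u in a] == [(u.sequence, u.counts) for u in b]


def test_size_distribution_thresholds_and_totals():
    inserts = (["A" * 20 + "C"] * 12 + ["C" * 20] * 5 + ["G" * 18 + "T"] * 2
               + ["T" * 17] * 1)
    unique = collapse_unique(inserts, "g")
    tables = size_distribution(unique, "g")
    for t, df in tables.items():
        body = df[df["length"] != "total"]
        totals = df[df["length"] == "total"].iloc[0]
        assert body["unique_reads"].sum() == totals["unique_reads"]
        assert body["read_count"].sum() == totals["read_count"]
    # monotonicity: cells never grow as the threshold tightens
    for col in ("unique_reads", "read_count"):
        c1 = tables[1][col].to_numpy()
        c4 = tables[4][col].to_numpy()
        c10 = tables[10][col].to_numpy()
        assert (c10 <= c4).all() and (c4 <= c1).all()
    assert tables[10][tables[10]["length"] != "total"]["read_count"].sum() == 12


def test_uniform_count_five_makes_thresholds_1_and_4_identical():
    inserts = [random_dna(RNG, 21) for _ in range(8)] * 5
    unique = collapse_unique(inserts, "g")
    tables = size_distribution(unique, "g")
    assert tables[1].equals(tables[4])
    assert tables[10][tables[10]["length"] != "total"]["read_count"].sum() == 0


def test_preprocess_read_count_conservation():
    rng = np.random.default_rng(3)
    reads = [_make_read(random_dna(rng, int(rng.integers(17, 27))))
             for _ in range(500)]
    reads += ["A" * 36] * 5 + [_make_read(random_dna(rng, 20))[:35] + "N"] * 4
    reads += [random_dna(rng, 36) for _ in range(20)]  # mostly untrimmed
    unique, stats, _ = preprocess_reads(reads, ADAPTER3, "g")
    total_inserts = sum(u.count("g") for u in unique)
    assert (stats["raw_reads"] == stats["removed_n_containing"]
            + stats["removed_homopolymer"] + stats["untrimmed"] + total_inserts)


def test_merge_unique_combines_groups():
    a = collapse_unique(["ACGTACGTACGTACGTA"] * 3, "a")
    b = collapse_unique(["ACGTACGTACGTACGTA"] * 2 + ["TTTTACGTACGTACGTT"], "b")
    merged = merge_unique(a, b)
    by_seq = {u.sequence: u.counts for u in merged}
    assert by_seq["ACGTACGTACGTACGTA"] == {"a": 3, "b": 2}
    assert by_seq["TTTTACGTACGTACGTT"] == {"b": 1}
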