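"""Read matching, chloroplast partition, miRNA/isomiR/star detection,
inclusion clustering, transgene profiling and full cascade behaviour."""

import numpy as np
import pytest

from srnacascade.cascade import (CascadeConfig, CascadeStage, StarUndefinedError,
                                 cluster_by_inclusion, detect_isomirs,
                                 infer_star_sequence, match_reads,
                                 partition_chloroplast, profile_known_mirnas,
                                 profile_transgene, run_cascade)
from srnacascade.novel import fold_hairpin, parse_dot_bracket
from srnacascade.preprocess import UniqueRead
from srnacascade.sequtils import random_dna, revcomp

RNG = np.random.default_rng(23)


# --- matcher ---------------------------------------------------------------

def brute_force_hits(read, ref, budget):
    hits = []
    for start in range(len(ref) - len(read) + 1):
        mism = sum(a != b for a, b in zip(read, ref[start:start + len(read)]))
        if mism <= budget:
            hits.append((start + 1, mism))
    return hits


def test_exact_subsequence_maps_at_offset():
    ref = random_dna(RNG, 200)
    read = ref[50:71]
    recs = match_reads([read], {"f": ref}, 0, "+")
    assert any(r.position == 51 and r.mismatches == 0 for r in recs)


def test_single_substitution_needs_budget():
    ref = random_dna(RNG, 100)
    read = list(ref[20:41])
    read[5] = "A" if read[5] != "A" else "C"
    read = "".join(read)
    assert match_reads([read], {"f": ref}, 0, "+") == []
    recs = match_reads([read], {"f": ref}, 2, "+")
    assert any(r.position == 21 and r.mismatches == 1 for r in recs)


@pytest.mark.parametrize("budget", [0, 1, 2])
def test_matcher_agrees_with_bruteforce_hamming(budget):
    rng = np.random.default_rng(100 + budget)
    ref = random_dna(rng, 400)
    for _ in range(500):
        if rng.random() < 0.5:
            s = int(rng.integers(0, 380))
            read = list(ref[s:s + 20])
            for p in rng.choice(20, size=int(rng.integers(0, 4)), replace=False):
                read[p] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(read)
        else:
            read = random_dna(rng, 20)
        recs = match_reads([read], {"f": ref}, budget, "+")
        got = sorted((r.position, r.mismatches) for r in recs)
        assert got == sorted(brute_force_hits(read, ref, budget))


def test_strand_symmetry():
    ref = random_dna(RNG, 150)
    read = revcomp(ref[40:62])
    minus = match_reads([read], {"f": ref}, 0, "-")
    plus_of_rc = match_reads([revcomp(read)], {"f": ref}, 0, "+")
    assert {(r.position, len(r.sequence)) for r in minus} \
        == {(r.position, len(r.sequence)) for r in plus_of_rc}
    assert any(r.position == 41 and r.strand == "-" for r in minus)


def test_empty_read_never_maps():
    assert match_reads([""], {"f": "ACGTACGT"}, 2, "+-") == []


# --- chloroplast partition --------------------------------------------------

def test_partition_is_conservative_and_correct():
    genome = random_dna(RNG, 2000)
    cp_reads = [UniqueRead(genome[i:i + 21], {"g": 5}) for i in (10, 400, 900)]
    cp_anti = [UniqueRead(revcomp(genome[1200:1222]), {"g": 2})]
    other = [UniqueRead(random_dna(RNG, 21), {"g": 3}) for _ in range(5)]
    cp, non_cp, summary = partition_chloroplast(cp_reads + cp_anti + other, genome)
    assert {u.sequence for u in cp} == {u.sequence for u in cp_reads + cp_anti}
    assert len(cp) + len(non_cp) == 9
    assert summary["chloroplast"]["g"] == 17 and summary["non_chloroplast"]["g"] == 15


# --- known miRNA profiling --------------------------------------------------

def test_mature_equality_counts_and_length_gate():
    mature = random_dna(RNG, 21)
    reads = [UniqueRead(mature, {"a": 10, "b": 4}),
             UniqueRead(mature[:16], {"a": 7}),  # too short for the stage
             UniqueRead(random_dna(RNG, 21), {"a": 1})]
    table, matched, remaining = profile_known_mirnas(reads, {"mirX": mature})
    assert len(matched) == 1 and matched[0].sequence == mature
    row = table.iloc[0]
    assert row["mirna"] == "mirX" and row["a"] == 10 and row["b"] == 4
    assert {u.sequence for u in remaining} == {reads[1].sequence, reads[2].sequence}


# --- mature* inference ------------------------------------------------------

def perfect_hairpin(mature, arm_extra=6, loop=8, flank=10, rng=RNG):
    arm = mature + random_dna(rng, arm_extra)
    return (random_dna(rng, flank) + arm + random_dna(rng, loop)
            + revcomp(arm) + random_dna(rng, flank))


def perfect_pairs(precursor, flank, arm_len, loop):
    """Pair table of the ideal stem: arm position k pairs its mirror."""
    n = len(precursor)
    pairs = np.zeros(n + 1, dtype=int)
    for k in range(arm_len):
        i = flank + 1 + k
        j = n - flank - k
        pairs[i], pairs[j] = j, i
    return pairs


def test_star_on_perfect_stem_is_shifted_reverse_complement():
    mature = random_dna(RNG, 21)
    prec = perfect_hairpin(mature, arm_extra=6, loop=8, flank=10)
    pairs = perfect_pairs(prec, 10, 27, 8)
    star = infer_star_sequence(prec, mature, pairs)
    # the duplex partner of the mature, with a 2-nt 3' overhang on each strand
    i = 11
    j = i + 20
    n = len(prec)
    expect = prec[(n - j + 1 + 2) - 1:(n - i + 1 + 2)]
    assert star == expect
    assert len(star) == len(mature)
    # 10 flank + 27 arm: star lies on the 3' arm
    assert prec.find(star) > j


def test_star_of_star_is_involutive_on_perfect_stems():
    rng = np.random.default_rng(42)
    for _ in range(50):
        mature = random_dna(rng, int(rng.integers(20, 25)))
        flank, extra, loop = 10, 6, 9
        prec = perfect_hairpin(mature, extra, loop, flank, rng)
        pairs = perfect_pairs(prec, flank, len(mature) + extra, loop)
        star = infer_star_sequence(prec, mature, pairs)
        back = infer_star_sequence(prec, star, pairs)
        assert back == mature


def test_mature_spanning_loop_is_an_error():
    mature = random_dna(RNG, 21)
    prec = perfect_hairpin(mature, 6, 8, 10)
    pairs = perfect_pairs(prec, 10, 27, 8)
    loop_span = prec[30:54]  # crosses the loop
    with pytest.raises((StarUndefinedError, ValueError)):
        infer_star_sequence(prec, loop_span, pairs)


def test_unpaired_mature_reports_no_star():
    mature = random_dna(RNG, 21)
    prec = perfect_hairpin(mature, 6, 8, 10)
    pairs = np.zeros(len(prec) + 1, dtype=int)
    with pytest.raises(StarUndefinedError):
        infer_star_sequence(prec, mature, pairs)


def test_star_inference_composes_with_folding(bundle):
    # on the generator's planted stems, folding + inference puts the star on
    # the opposite arm without overlapping the mature
    name = sorted(bundle.mirna_set)[0]
    prec = bundle.mirna_set[name]["precursor"]
    mature = bundle.mirna_set[name]["mature"]
    star = infer_star_sequence(prec, mature, fold_hairpin(prec).pairs)
    m0, s0 = prec.find(mature), prec.find(star)
    assert s0 != -1
    assert s0 >= m0 + len(mature) or s0 + len(star) <= m0


# --- isomiRs ----------------------------------------------------------------

def _iso_fixture():
    rng = np.random.default_rng(9)
    mature = random_dna(rng, 21)
    prec = perfect_hairpin(mature, 6, 8, 10, rng)
    return prec, mature


def test_three_prime_extension_is_isomir():
    prec, mature = _iso_fixture()
    ext = prec[10:10 + 22]  # mature + one precursor base
    table, matched, remaining = detect_isomirs(
        [UniqueRead(ext, {"g": 3})], {"m1": (prec, mature)})
    assert len(matched) == 1 and table.iloc[0]["count_g"] == 3


def test_two_substitutions_is_not_isomir():
    prec, mature = _iso_fixture()
    variant = list(mature)
    variant[4] = "A" if variant[4] != "A" else "C"
    variant[9] = "A" if variant[9] != "A" else "C"
    table, matched, remaining = detect_isomirs(
        [UniqueRead("".join(variant), {"g": 1})], {"m1": (prec, mature)})
    assert matched == [] and len(remaining) == 1


def test_isomir_table_counts_designed_variants():
    prec, mature = _iso_fixture()
    variants = [prec[10:32], mature[1:], mature[:20]]
    reads = [UniqueRead(v, {"a": i + 1, "b": 2}) for i, v in enumerate(variants)]
    table, matched, _ = detect_isomirs(reads, {"m1": (prec, mature)})
    assert len(matched) == 3
    row = table.iloc[0]
    assert row["unique_reads"] == 3
    assert row["count_a"] == 6 and row["count_b"] == 6


# --- inclusion clustering ---------------------------------------------------

def test_substring_chain_forms_single_cluster():
    base = random_dna(RNG, 24)
    reads = [UniqueRead(s, {"g": 1}) for s in (base, base[1:22], base[3:20])]
    clusters = cluster_by_inclusion(reads)
    assert len(clusters) == 1
    assert clusters[0].representative == base
    assert clusters[0].counts == {"g": 3}


def test_disjoint_reads_form_two_clusters():
    reads = [UniqueRead("ACGTACGTACGTACGTACGT", {"g": 1}),
             UniqueRead("TTGGCCAATTGGCCAATTGG", {"g": 1})]
    assert len(cluster_by_inclusion(reads)) == 2


def test_clustering_is_shuffle_invariant():
    rng = np.random.default_rng(77)
    base1, base2 = random_dna(rng, 26), random_dna(rng, 24)
    reads = [UniqueRead(s, {"g": 1}) for s in
             (base1, base1[2:24], base1[4:21], base2, base2[1:20])]
    reference = cluster_by_inclusion(reads)
    ref_repr = [(c.representative, sorted(c.members)) for c in reference]
    for _ in range(20):
        shuffled = list(reads)
        rng.shuffle(shuffled)
        got = cluster_by_inclusion(shuffled)
        assert [(c.representative, sorted(c.members)) for c in got] == ref_repr


# --- transgene profiling ----------------------------------------------------

def test_transgene_profile_counts_strands_and_overlap():
    gene = random_dna(RNG, 300)
    sense = UniqueRead(gene[100:121], {"transgenic": 8})
    anti = UniqueRead(revcomp(gene[105:127]), {"transgenic": 3})
    table, coverage = profile_transgene([sense, anti], {"tg": gene})
    plus = table[(table["gene"] == "tg") & (table["strand"] == "+")].iloc[0]
    minus = table[(table["gene"] == "tg") & (table["strand"] == "-")].iloc[0]
    assert plus["transgenic"] == 8 and minus["transgenic"] == 3
    assert bool(plus["sense_antisense_overlap"])
    cov = coverage["tg"]
    assert cov["+"].max() <= 1.0 and cov["+"].sum() >= 1.0
    assert cov["+"][100] > 0 and cov["-"][110] > 0


def test_absent_transgene_has_zero_hits():
    gene = random_dna(RNG, 200)
    reads = [UniqueRead(random_dna(RNG, 21), {"control": 5})]
    table, _ = profile_transgene(reads, {"tg": gene})
    assert (table["control"].sum() if "control" in table else 0) == 0


# --- full cascade -----------------------------------------------------------

def _toy_config(mirna, repeat_seq):
    stages = [
        CascadeStage("mirna_mature", {"m1": mirna}, 0, "+"),
        CascadeStage("repeat", {"te1": repeat_seq}, 0, "+-", min_read_length=20),
    ]
    return CascadeConfig(stages)


def test_earlier_stage_wins_on_double_match():
    mirna = random_dna(RNG, 21)
    repeat_seq = random_dna(RNG, 100) + mirna + random_dna(RNG, 100)
    reads = [UniqueRead(mirna, {"g": 4})]
    result = run_cascade(reads, _toy_config(mirna, repeat_seq))
    assert result.assignments[mirna][0] == "mirna_mature"


def test_empty_input_gives_empty_summaries():
    result = run_cascade([], _toy_config(random_dna(RNG, 21), random_dna(RNG, 60)))
    assert result.summaries["unique_reads"].sum() == 0
    assert result.unassigned == []


def test_cascade_conserves_counts():
    rng = np.random.default_rng(15)
    mirna = random_dna(rng, 21)
    repeat_seq = random_dna(rng, 200)
    reads = [UniqueRead(mirna, {"a": 3, "b": 1}),
             UniqueRead(repeat_seq[10:31], {"a": 2}),
             UniqueRead(random_dna(rng, 22), {"b": 5}),
             UniqueRead(random_dna(rng, 15), {"a": 1})]  # length-filtered
    result = run_cascade(reads, _toy_config(mirna, repeat_seq))
    for g in ("a", "b"):
        assert result.summaries[g].sum() == sum(u.count(g) for u in reads)
    labels = dict((s, lab) for s, (lab, _) in result.assignments.items())
    assert labels[reads[3].sequence] == "length_filtered"


def test_misordered_config_rejected():
    with pytest.raises(ValueError):
        CascadeConfig([CascadeStage("repeat", {}, 0, "+"),
                       CascadeStage("mirna_mature", {}, 0, "+")])
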