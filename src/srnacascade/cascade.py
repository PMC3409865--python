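"""Hierarchical classification of unique reads against ordered reference
libraries with read removal.

Each unique read is assigned to the first library it maps to in a fixed order
(chloroplast -> species mature miRNA -> isomiR -> homolog miRNA -> ncRNA
families -> repeats -> antisense genes -> transgene set); mapped reads are
removed from the stream so later libraries never see them, which makes the
per-library counts an exact partition of the input. Alignment is
substitution-only (no indels): a read maps if the full read occurs inside a
library sequence with at most the library's mismatch budget, on the requested
strands. Antisense hits are reported with 1-based start positions on the
feature's + strand and strand "-".
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import UniqueRead
from .sequtils import revcomp, scan_hamming

CASCADE_ORDER = (
    "chloroplast",
    "mirna_mature",
    "mirna_isomir",
    "mirna_homolog",
    "ncrna",
    "repeat",
    "gene_antisense",
    "transgene",
)


@dataclass
class ClassificationRecord:
    sequence: str
    library: str
    feature: str
    strand: str
    position: int  # 1-based start on the feature's + strand
    mismatches: int


@dataclass
class CascadeStage:
    name: str
    library: dict  # feature name -> sequence
    max_mismatch: int = 0
    strands: str = "+"
    min_read_length: int = 1
    star_sequences: dict | None = None  # mirna_mature stage only


@dataclass
class CascadeConfig:
    stages: list[CascadeStage]
    min_length_after_chloroplast: int = 17

    def __post_init__(self):
        names = [s.name for s in self.stages]
        order = [n for n in CASCADE_ORDER if n in names]
        if names != order or len(set(names)) != len(names):
            raise ValueError(
                f"cascade stages must follow the fixed order {CASCADE_ORDER}, got {names}")


def match_reads(reads, library: dict, max_mismatch: int = 0,
                strands: str = "+-") -> list[ClassificationRecord]:
    """All alignments of each full read inside the library sequences.

    `reads` may be UniqueReads or plain sequences. Substitutions only; a read
    maps if at least one alignment exists. Minus-strand alignments are found by
    scanning the reverse complement of the reference and reported in + strand
    coordinates with strand "-".
    """
    records = []
    seqs = [r.sequence if isinstance(r, UniqueRead) else r for r in reads]
    for feature, ref in library.items():
        n = len(ref)
        for strand in strands:
            target = ref if strand == "+" else revcomp(ref)
            for seq in seqs:
                if not seq:
                    continue
                for start, mism in scan_hamming(seq, target, max_mismatch):
                    if strand == "+":
                        pos = start
                    else:
                        pos = n - (start + len(seq) - 1) + 1
                    records.append(ClassificationRecord(seq, "", feature,
                                                        strand, pos, mism))
    return records


def partition_chloroplast(reads, chloroplast_genome: str):
    """Split unique reads into chloroplast (0 mismatches, both strands) and
    non-chloroplast streams; returns (cp, non_cp, summary)."""
    lib = {"chloroplast": chloroplast_genome}
    mapped = {r.sequence for r in match_reads(reads, lib, 0, "+-")}
    cp = [u for u in reads if u.sequence in mapped]
    non_cp = [u for u in reads if u.sequence not in mapped]
    groups = sorted({g for u in reads for g in u.counts})
    summary = {
        "chloroplast": {"unique": len(cp),
                        **{g: sum(u.count(g) for u in cp) for g in groups}},
        "non_chloroplast": {"unique": len(non_cp),
                            **{g: sum(u.count(g) for u in non_cp) for g in groups}},
    }
    assert len(cp) + len(non_cp) == len(reads)
    return cp, non_cp, summary


def profile_known_mirnas(reads, mirna_mature: dict, min_length: int = 17,
                         star_sequences: dict | None = None):
    """Exact-equality counts per mature miRNA (and optional theoretical mature*
    sequences) per group. Reads shorter than `min_length` are the caller's
    responsibility to remove; they are ignored here.

    Returns (table, matched_reads, remaining_reads). Counting is by exact
    sequence identity with the mature; end-length variants belong to the isomiR
    stage, which keeps mature and isomiR accounting disjoint.
    """
    lookup = {}
    for name, seq in mirna_mature.items():
        lookup.setdefault(seq, []).append((name, "mature"))
    for name, seq in (star_sequences or {}).items():
        lookup.setdefault(seq, []).append((name, "star"))
    matched, remaining = [], []
    rows = defaultdict(lambda: defaultdict(int))
    for u in reads:
        if len(u.sequence) >= min_length and u.sequence in lookup:
            matched.append(u)
            for name, kind in lookup[u.sequence]:
                for g, c in u.counts.items():
                    rows[(name, kind)][g] += c
        else:
            remaining.append(u)
    table = pd.DataFrame(
        [{"mirna": name, "kind": kind, "sequence": seq,
          **{g: cnts.get(g, 0) for g in sorted({g for c in rows.values() for g in c})}}
         for (name, kind), cnts in rows.items()
         for seq in [next(s for s, nk in lookup.items() if (name, kind) in nk)]]
    )
    return table, matched, remaining


class StarUndefinedError(ValueError):
    """Raised when the mature has no paired bases in the hairpin, or the
    inferred star would overlap the mature (mature spans the loop)."""


def infer_star_sequence(precursor: str, mature: str, pairs) -> str:
    """Theoretical mature* from the precursor secondary structure, assuming a
    perfect 2-nt 3' overhang on each strand of the miRNA/miRNA* duplex.

    `pairs` is a 1-based pair table (pairs[i] = j if i pairs j, 0 if unpaired;
    index 0 unused). On a perfect stem this returns the reverse complement of
    the mature shifted by 2 at each 3' end; with imperfect pairing the
    outermost paired bases of the mature anchor the duplex and unpaired ends
    are extrapolated.
    """
    start = precursor.find(mature)
    if start == -1:
        raise ValueError("mature is not a substring of the precursor")
    i, j = start + 1, start + len(mature)  # 1-based inclusive
    paired = [p for p in range(i, j + 1) if pairs[p] != 0]
    if not paired:
        raise StarUndefinedError("mature is unpaired in the structure")
    i_p, j_p = paired[0], paired[-1]
    # star 5' end pairs mature position j-2; star 3' end overhangs partner of i-2
    star_a = pairs[j_p] - ((j - 2) - j_p)
    star_b = pairs[i_p] + (i_p - (i - 2))
    lo, hi = sorted((star_a, star_b))
    if lo < 1 or hi > len(precursor):
        raise StarUndefinedError("inferred star extends outside the precursor")
    if not (hi < i or lo > j):
        raise StarUndefinedError("mature spans the loop; no opposite arm exists")
    return precursor[lo - 1:hi]


def detect_isomirs(reads, precursors: dict):
    """isomiR assignment: a read is an isomiR of miRNA M if it aligns within
    M's precursor with at most one substitution, overlapping M's locus, and is
    not identical to the mature (5'/3' extension/truncation variants align
    exactly; the single-substitution case covers edited/variant reads).

    `precursors` maps name -> (precursor_seq, mature_seq). Reads matching more
    than one precursor are assigned to all and flagged ambiguous.
    Returns (per-precursor table, matched_reads, remaining_reads).
    """
    loci = {}
    for name, (prec, mature) in precursors.items():
        s = prec.find(mature)
        if s == -1:
            raise ValueError(f"mature of {name} not found in its precursor")
        loci[name] = (prec, s + 1, s + len(mature), mature)
    per = defaultdict(lambda: {"unique": 0, "counts": defaultdict(int), "reads": []})
    matched, remaining = [], []
    for u in reads:
        hits = []
        for name, (prec, lo, hi, mature) in loci.items():
            if u.sequence == mature:
                continue
            for start, mism in scan_hamming(u.sequence, prec, 1):
                end = start + len(u.sequence) - 1
                if start <= hi and end >= lo:  # overlaps the mature locus
                    hits.append(name)
                    break
        if hits:
            matched.append(u)
            for name in hits:
                per[name]["unique"] += 1
                per[name]["reads"].append(u.sequence)
                for g, c in u.counts.items():
                    per[name]["counts"][g] += c
        else:
            remaining.append(u)
    groups = sorted({g for d in per.values() for g in d["counts"]})
    table = pd.DataFrame(
        [{"mirna": name, "unique_reads": d["unique"],
          **{f"count_{g}": d["counts"].get(g, 0) for g in groups},
          "ambiguous": any(sum(seq in per[o]["reads"] for o in per) > 1
                           for seq in d["reads"])}
         for name, d in per.items()]
    )
    if not table.empty:
        table = table.sort_values("mirna", ignore_index=True)
    return table, matched, remaining


@dataclass
class ReadCluster:
    representative: str
    members: list[str] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)
    genes: set = field(default_factory=set)
    origins: set = field(default_factory=set)


def cluster_by_inclusion(reads, gene_hits: dict | None = None,
                         origin_libraries: dict | None = None) -> list[ReadCluster]:
    """Greedy perfect-inclusion clustering of (antisense) reads.

    Reads are sorted by descending length then lexicographically; each read
    joins the first cluster whose representative contains it as an exact
    substring, else founds a new cluster. Optional `gene_hits`
    (sequence -> gene ids) annotates clusters; optional `origin_libraries`
    (label -> {feature: seq}) re-maps each representative to forward strands of
    other libraries to annotate a likely origin.
    """
    ordered = sorted(reads, key=lambda u: (-len(u.sequence), u.sequence))
    clusters: list[ReadCluster] = []
    for u in ordered:
        for cl in clusters:
            if u.sequence in cl.representative:
                cl.members.append(u.sequence)
                for g, c in u.counts.items():
                    cl.counts[g] = cl.counts.get(g, 0) + c
                if gene_hits:
                    cl.genes |= set(gene_hits.get(u.sequence, ()))
                break
        else:
            cl = ReadCluster(u.sequence, [u.sequence], dict(u.counts))
            if gene_hits:
                cl.genes = set(gene_hits.get(u.sequence, ()))
            clusters.append(cl)
    if origin_libraries:
        for cl in clusters:
            for label, lib in origin_libraries.items():
                if match_reads([cl.representative], lib, 0, "+"):
                    cl.origins.add(label)
    return clusters


def profile_transgene(reads, genes: dict):
    """Exact-match hits per strand per gene per group plus per-position
    coverage profiles (fraction of unique reads covering each position,
    strand-resolved) and sense/antisense interval-overlap detection."""
    records = match_reads(reads, genes, 0, "+-")
    counts = {u.sequence: u.counts for u in reads if isinstance(u, UniqueRead)}
    rows = []
    coverage = {}
    for gene, seq in genes.items():
        n = len(seq)
        gene_recs = [r for r in records if r.feature == gene]
        n_unique = len({r.sequence for r in gene_recs})
        cov = {"+": np.zeros(n), "-": np.zeros(n)}
        intervals = {"+": [], "-": []}
        for r in gene_recs:
            cov[r.strand][r.position - 1:r.position - 1 + len(r.sequence)] += 1
            intervals[r.strand].append((r.position, r.position + len(r.sequence) - 1))
        if n_unique:
            for s in "+-":
                cov[s] /= n_unique
        overlap = any(a1 <= b2 and b1 <= a2
                      for a1, a2 in intervals["+"] for b1, b2 in intervals["-"])
        coverage[gene] = {"denominator": f"unique reads hitting {gene} ({n_unique})",
                          "+": cov["+"], "-": cov["-"]}
        groups = sorted({g for c in counts.values() for g in c})
        for strand in "+-":
            strand_seqs = {r.sequence for r in gene_recs if r.strand == strand}
            rows.append({"gene": gene, "strand": strand,
                         "unique_reads": len(strand_seqs),
                         **{g: sum(counts.get(s, {}).get(g, 0) for s in strand_seqs)
                            for g in groups},
                         "sense_antisense_overlap": overlap})
    return pd.DataFrame(rows), coverage


@dataclass
class CascadeResult:
    assignments: dict  # sequence -> (library label, [ClassificationRecord])
    summaries: pd.DataFrame
    unassigned: list
    length_filtered: list
    stage_tables: dict


def run_cascade(reads, config: CascadeConfig) -> CascadeResult:
    """Run the ordered mapping cascade with read removal.

    Every UniqueRead receives exactly one label (a stage name, "length_filtered"
    for non-chloroplast reads shorter than the miRNA-stage minimum, or
    "unassigned"). Per-library counts plus the remainder reconstruct the input
    exactly; this conservation is asserted on every run.
    """
    assignments: dict[str, tuple[str, list]] = {}
    stage_tables = {}
    stream = list(reads)
    length_filtered: list[UniqueRead] = []
    for stage in config.stages:
        if stage.name == "mirna_mature":
            # length gate applies from the miRNA stage onward
            short = [u for u in stream if len(u.sequence) < config.min_length_after_chloroplast]
            for u in short:
                assignments[u.sequence] = ("length_filtered", [])
            length_filtered = short
            stream = [u for u in stream
                      if len(u.sequence) >= config.min_length_after_chloroplast]
            table, matched, stream = profile_known_mirnas(
                stream, stage.library,
                min_length=config.min_length_after_chloroplast,
                star_sequences=stage.star_sequences)
            stage_tables[stage.name] = table
            for u in matched:
                assignments[u.sequence] = (stage.name, [])
            continue
        if stage.name == "mirna_isomir":
            table, matched, stream = detect_isomirs(stream, stage.library)
            stage_tables[stage.name] = table
            for u in matched:
                assignments[u.sequence] = (stage.name, [])
            continue
        if stage.name == "mirna_homolog":
            # exact sequence equality with homolog matures
            matures = set(stage.library.values())
            matched = [u for u in stream if u.sequence in matures]
            stream = [u for u in stream if u.sequence not in matures]
            for u in matched:
                assignments[u.sequence] = (stage.name, [])
            continue
        eligible = [u for u in stream if len(u.sequence) >= stage.min_read_length]
        recs = match_reads(eligible, stage.library, stage.max_mismatch, stage.strands)
        by_seq = defaultdict(list)
        for r in recs:
            r.library = stage.name
            by_seq[r.sequence].append(r)
        matched_seqs = set(by_seq)
        for u in stream:
            if u.sequence in matched_seqs:
                assignments[u.sequence] = (stage.name, by_seq[u.sequence])
        stream = [u for u in stream if u.sequence not in matched_seqs]
    unassigned = stream
    for u in unassigned:
        assignments[u.sequence] = ("unassigned", [])

    groups = sorted({g for u in reads for g in u.counts})
    labels = [s.name for s in config.stages] + ["length_filtered", "unassigned"]
    read_index = {u.sequence: u for u in reads}
    rows = []
    for label in labels:
        seqs = [s for s, (lab, _) in assignments.items() if lab == label]
        rows.append({"library": label, "unique_reads": len(seqs),
                     **{g: sum(read_index[s].count(g) for s in seqs) for g in groups}})
    summaries = pd.DataFrame(rows)
    assert summaries["unique_reads"].sum() == len(reads)
    for g in groups:
        assert summaries[g].sum() == sum(u.count(g) for u in reads), \
            "cascade count conservation violated"
    return CascadeResult(assignments, summaries, unassigned, length_filtered,
                         stage_tables)
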