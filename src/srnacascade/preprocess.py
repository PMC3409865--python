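"""Raw-read preprocessing: artifact filtering, 3' adapter trimming, unique-read
collapsing and thresholded size-distribution tables.

The trimming rules mirror a two-pass scheme used for 36-base single-end sRNA
reads: the primary adapter search begins at base 18 (inserts of 17-26 nt for a
22-nt adapter with a 10-nt minimum match), and reads unmatched there get a
permissive secondary scan from base 1, which yields the 0-16 nt insert lengths
seen in deep libraries (length 0 = adapter-only read). Untrimmed reads are kept
only for diagnostics (the length-36 row) and never enter classification.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .sequtils import hamming

READ_LENGTH = 36
DEFAULT_THRESHOLDS = (1, 4, 10)


@dataclass
class TrimResult:
    status: str  # "trimmed" | "untrimmed" | "adapter_only"
    insert: str
    adapter_start: int | None  # 1-based position of the adapter in the read

    def __post_init__(self):
        if self.status == "trimmed" and self.adapter_start is not None:
            assert len(self.insert) == self.adapter_start - 1


@dataclass
class UniqueRead:
    """A distinct trimmed sequence with per-group read counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    def count(self, group: str) -> int:
        return self.counts.get(group, 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def filter_artifact_reads(reads):
    """Remove N-containing reads and full-length single-nucleotide homopolymers.

    Returns (survivors, removals) where removals counts reads per reason.
    A read containing at least one N is removed; the homopolymer rule applies to
    the whole read (a poly-A/T/C/G run shorter than the read is legitimate).
    """
    kept = []
    removals = {"n_containing": 0, "homopolymer": 0}
    for read in reads:
        if "N" in read:
            removals["n_containing"] += 1
        elif len(set(read)) == 1 and len(read) > 0:
            removals["homopolymer"] += 1
        else:
            kept.append(read)
    return kept, removals


def trim_adapter(read: str, adapter3: str, min_match: int = 10,
                 max_mismatch: int = 1, search_start: int = 18) -> TrimResult:
    """Locate the 3' adapter in a read and split off the insert.

    Candidate 1-based adapter start positions run from `search_start` to
    len(read) - min_match + 1. A hit requires the aligned adapter prefix
    (truncated at the read end, length >= min_match) to match with at most
    `max_mismatch` substitutions; the leftmost hit wins (at a fixed position the
    mismatch count is unique, so no further tie-break is needed).
    """
    if len(adapter3) < min_match:
        raise ValueError("adapter shorter than the minimum match length")
    n = len(read)
    best = None
    for pos in range(search_start, n - min_match + 2):  # 1-based
        aligned = min(len(adapter3), n - pos + 1)
        mism = hamming(read[pos - 1:pos - 1 + aligned], adapter3[:aligned])
        if mism <= max_mismatch:
            best = (pos, mism)
            break
    if best is None:
        return TrimResult("untrimmed", read, None)
    pos = best[0]
    if pos == 1:
        return TrimResult("adapter_only", "", 1)
    return TrimResult("trimmed", read[:pos - 1], pos)


def trim_with_rescue(read: str, adapter3: str, min_match: int = 10,
                     max_mismatch: int = 1, search_start: int = 18):
    """Two-pass trimming: primary scan from `search_start`, then a permissive
    secondary scan from base 1 for reads left untrimmed by the primary pass.

    Returns (TrimResult, pass_label) with pass_label in
    {"primary", "secondary", "none"} so the two stages stay separately logged.
    """
    res = trim_adapter(read, adapter3, min_match, max_mismatch, search_start)
    if res.status != "untrimmed":
        return res, "primary"
    res = trim_adapter(read, adapter3, min_match, max_mismatch, search_start=1)
    if res.status != "untrimmed":
        return res, "secondary"
    return res, "none"


def remove_untrimmed(results):
    """Keep inserts of trimmed and adapter-only reads (the latter count as
    length-0 inserts); returns (inserts, n_discarded)."""
    inserts = []
    discarded = 0
    for res in results:
        if res.status == "untrimmed":
            discarded += 1
        else:
            inserts.append(res.insert)
    return inserts, discarded


def collapse_unique(inserts, group: str) -> list[UniqueRead]:
    """Group identical insert sequences into UniqueReads for one library.

    Deterministic order: descending count, then lexicographic sequence.
    """
    counts = Counter(inserts)
    out = [UniqueRead(seq, {group: c}) for seq, c in counts.items()]
    out.sort(key=lambda u: (-u.count(group), u.sequence))
    return out


def merge_unique(*collections) -> list[UniqueRead]:
    """Merge per-group UniqueRead collections into one table keyed by sequence."""
    merged: dict[str, UniqueRead] = {}
    for coll in collections:
        for u in coll:
            tgt = merged.setdefault(u.sequence, UniqueRead(u.sequence, {}))
            for g, c in u.counts.items():
                tgt.counts[g] = tgt.counts.get(g, 0) + c
    out = list(merged.values())
    out.sort(key=lambda u: (-u.total, u.sequence))
    return out


def size_distribution(unique, group: str,
                      thresholds=DEFAULT_THRESHOLDS,
                      max_length: int = READ_LENGTH) -> dict[int, pd.DataFrame]:
    """Per-length unique-read and read-count tables, one per read-count threshold.

    Threshold t keeps UniqueReads whose count in `group` is >= t (limit
    included). A totals row is appended; it equals the column sums.
    """
    tables = {}
    for t in thresholds:
        if t < 1:
            raise ValueError("threshold must be >= 1")
        uniq = Counter()
        cnt = Counter()
        for u in unique:
            c = u.count(group)
            if c >= t:
                uniq[len(u.sequence)] += 1
                cnt[len(u.sequence)] += c
        rows = [(ln, uniq.get(ln, 0), cnt.get(ln, 0)) for ln in range(max_length + 1)]
        df = pd.DataFrame(rows, columns=["length", "unique_reads", "read_count"])
        total = pd.DataFrame([{"length": "total",
                               "unique_reads": df["unique_reads"].sum(),
                               "read_count": df["read_count"].sum()}])
        tables[t] = pd.concat([df, total], ignore_index=True)
    return tables


def preprocess_reads(raw_reads, adapter3: str, group: str, *,
                     min_match: int = 10, max_mismatch: int = 1,
                     search_start: int = 18):
    """Full preprocessing of one raw library.

    Returns (unique_reads, stats) where stats carries the per-stage accounting
    needed for read-count conservation checks:
    raw = artifacts + untrimmed + sum of insert counts.
    """
    filtered, removals = filter_artifact_reads(raw_reads)
    inserts = []
    stats = {
        "raw_reads": len(raw_reads),
        "removed_n_containing": removals["n_containing"],
        "removed_homopolymer": removals["homopolymer"],
        "trimmed_primary": 0,
        "trimmed_secondary": 0,
        "adapter_only": 0,
        "untrimmed": 0,
    }
    untrimmed_counter = Counter()
    for read in filtered:
        res, which = trim_with_rescue(read, adapter3, min_match, max_mismatch,
                                      search_start)
        if res.status == "untrimmed":
            stats["untrimmed"] += 1
            untrimmed_counter[read] += 1
        else:
            if res.status == "adapter_only":
                stats["adapter_only"] += 1
            stats[f"trimmed_{which}"] += 1
            inserts.append(res.insert)
    unique = collapse_unique(inserts, group)
    stats["inserts"] = len(inserts)
    conserved = (stats["raw_reads"] == stats["removed_n_containing"]
                 + stats["removed_homopolymer"] + stats["untrimmed"]
                 + stats["inserts"])
    assert conserved, "read-count conservation violated in preprocessing"
    return unique, stats, untrimmed_counter
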