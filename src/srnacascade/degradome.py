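"""Degradome (PARE) cleavage-site calling.

A degradome tag marks the 5' end of the 3' fragment of a cleaved transcript.
For miRNA-guided cleavage between miRNA positions p and p+1 (canonically
10/11), the tag's 5' portion is the reverse complement of miRNA positions
p..1. Calls tolerate a small number of extra tag bases 5' of the complementary
block (flagged, never silent); when several (offset, p) alignments pass, the
smallest 5' offset wins first and then the smallest p, so canonical
offset-0 calls dominate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .sequtils import revcomp

DEFAULT_POSITIONS = range(10, 16)
DEFAULT_CALL_LENGTHS = (20, 21)
INGEST_LENGTH_RANGE = (13, 26)


@dataclass
class DegradomeTag:
    sequence: str
    count: int = 1

    def __post_init__(self):
        lo, hi = INGEST_LENGTH_RANGE
        if not lo <= len(self.sequence) <= hi:
            raise ValueError(f"tag length outside ingest range {INGEST_LENGTH_RANGE}")


@dataclass
class CleavageCall:
    mirna: str
    tag: str
    position: str  # "p/p+1"
    p: int
    offset: int  # extra tag bases 5' of the complementary block
    matched_span: int
    transcript_hits: list


def call_cleavage(tag: str, mirna: str, mirna_name: str = "",
                  positions=DEFAULT_POSITIONS, min_span: int = 10,
                  max_offset_slack: int = 1) -> CleavageCall | None:
    """Test a tag against a guiding miRNA at each candidate cleavage position.

    At position p the tag (after skipping up to `max_offset_slack` 5' bases)
    must begin with the exact reverse complement of miRNA positions p..1 — no
    mismatches and no G:U credit in the complementary span. Returns the call
    with minimal (offset, p), or None.
    """
    if len(tag) < min_span:
        return None
    for offset in range(0, max_offset_slack + 1):
        for p in positions:
            if p < min_span:
                continue
            block = revcomp(mirna[:p])
            if tag[offset:offset + p] == block and offset + p <= len(tag):
                return CleavageCall(mirna_name, tag, f"{p}/{p + 1}", p, offset,
                                    p, [])
    return None


def assign_tags(tags, transcript_set: dict):
    """Exact + strand substring search of each tag in the transcripts.

    Returns {tag: [transcript ids]}; multi-hit tags report every transcript.
    Antisense-only occurrences are not hits but are flagged separately under
    key (tag, "antisense").
    """
    hits = {}
    for tag in tags:
        seq = tag.sequence if isinstance(tag, DegradomeTag) else tag
        fwd = [name for name, t in sorted(transcript_set.items()) if seq in t]
        hits[seq] = fwd
        if not fwd:
            anti = [name for name, t in sorted(transcript_set.items())
                    if revcomp(seq) in t]
            if anti:
                hits[(seq, "antisense")] = anti
    return hits


def call_all(tags, mirnas: dict, transcript_set: dict | None = None,
             call_lengths=DEFAULT_CALL_LENGTHS, **kwargs) -> list[CleavageCall]:
    """Scan a tag library against a set of candidate miRNAs.

    Only tags whose length is in `call_lengths` (default 20-21 nt, the
    expected MmeI product size) enter bulk calling; `call_cleavage` itself has
    no length gate beyond the minimum complementary span.
    """
    calls = []
    tag_hits = assign_tags(tags, transcript_set) if transcript_set else {}
    for tag in tags:
        seq = tag.sequence if isinstance(tag, DegradomeTag) else tag
        if len(seq) not in call_lengths:
            continue
        for name, mirna in sorted(mirnas.items()):
            call = call_cleavage(seq, mirna, name, **kwargs)
            if call is not None:
                call.transcript_hits = tag_hits.get(seq, [])
                calls.append(call)
    return calls


def summarize_degradome(calls) -> pd.DataFrame:
    """Per-miRNA validation summary: distinct tags, positions observed,
    transcripts hit, and a validated flag (>= 1 call)."""
    per = {}
    for c in calls:
        d = per.setdefault(c.mirna, {"tags": set(), "positions": set(),
                                     "transcripts": set()})
        d["tags"].add(c.tag)
        d["positions"].add(c.position)
        d["transcripts"] |= set(c.transcript_hits)
    rows = [{"mirna": name, "n_tags": len(d["tags"]),
             "positions": ",".join(sorted(d["positions"],
                                          key=lambda s: int(s.split("/")[0]))),
             "transcripts": ",".join(sorted(d["transcripts"])),
             "validated": True}
            for name, d in sorted(per.items())]
    return pd.DataFrame(rows)
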