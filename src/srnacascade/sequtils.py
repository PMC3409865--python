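"""Shared sequence primitives: alphabet handling, reverse complement, Hamming scans.

All stored sequences use the DNA alphabet; RNA input (U) is converted at ingest.
Coordinates are 1-based and inclusive on a feature's + strand throughout the package.
"""

from __future__ import annotations

import numpy as np

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_BASE_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _BASE_CODE[ord(_b)] = _i


def to_dna(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T)."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as uint8 codes 0..4."""
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains characters outside {A,C,G,T,N}")
    return codes


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA), size=length))


def scan_hamming(read: str, reference: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All (1-based start, mismatches) alignments of the full read inside
    `reference` with <= max_mismatch substitutions (no indels).

    Vectorized sliding-window Hamming scan; N never matches anything.
    """
    n, m = len(reference), len(read)
    if m == 0 or m > n:
        return []
    if max_mismatch == 0:
        # exact: delegate to C-level substring search
        out = []
        start = reference.find(read)
        while start != -1:
            out.append((start + 1, 0))
            start = reference.find(read, start + 1)
        return out
    ref = encode(reference)
    q = encode(read)
    windows = np.lib.stride_tricks.sliding_window_view(ref, m)
    # differing codes count as mismatches; N==N (equal codes) must too
    mism = (windows != q).sum(axis=1) + ((windows == 4) & (q == 4)).sum(axis=1)
    hits = np.nonzero(mism <= max_mismatch)[0]
    return [(int(i) + 1, int(mism[i])) for i in hits]
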