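"""Novel-miRNA discovery: genome/EST mapping of unassigned reads, precursor
window extraction, hairpin folding and the minimum-free-energy filter.

The default folding backend is a non-crossing minimum-energy dynamic program
with a nearest-neighbor stacked-pair table and logarithmic loop penalties
(hairpin loop >= 3 nt, {AU, GC, GU} pairs only). It is an approximation
adequate for thresholding hairpins, not a full thermodynamic model; the
backend is pluggable, and externally supplied MFE values (e.g. published
tables) can be fed to the filter directly. A candidate passes when its hairpin
energy is strictly below the threshold (default -18 kcal/mol), the read lies
on a single, well-paired arm of the stem, and the read does not map into the
repeat set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .preprocess import UniqueRead
from .sequtils import encode, scan_hamming

MFE_THRESHOLD = -18.0
MIN_HAIRPIN_LOOP = 3
MAX_INTERNAL = 10  # max unpaired bases in a bulge/internal loop

# base codes A=0 C=1 G=2 T=3; pair indices AU=0 UA=1 GC=2 CG=3 GU=4 UG=5
_PAIR_INDEX = -np.ones((4, 4), dtype=np.int64)
_PAIR_INDEX[0, 3] = 0
_PAIR_INDEX[3, 0] = 1
_PAIR_INDEX[2, 1] = 2
_PAIR_INDEX[1, 2] = 3
_PAIR_INDEX[2, 3] = 4
_PAIR_INDEX[3, 2] = 5

# stacked-pair free energies (kcal/mol), rows = outer pair, cols = inner pair
_STACK = np.array([
    [-0.9, -1.1, -2.2, -2.1, -0.6, -1.4],
    [-1.3, -0.9, -2.4, -2.1, -1.0, -1.3],
    [-2.1, -2.1, -3.3, -2.4, -1.4, -2.1],
    [-2.4, -2.1, -3.4, -3.3, -1.5, -2.5],
    [-1.3, -1.4, -2.5, -2.1, -0.5, 1.3],
    [-1.0, -0.6, -1.5, -1.4, 0.3, -0.5],
])

_MULTI_PENALTY = 3.4
_INF = 1e9


@njit(cache=True)
def _hairpin_energy(size):
    return 5.6 + 1.3 * math.log(size / 3.0) if size > 3 else 5.6


@njit(cache=True)
def _loop_energy(size):
    return 3.2 + 1.1 * math.log(size)


@njit(cache=True)
def _fold_dp(codes, pair_index, stack):
    n = codes.shape[0]
    V = np.full((n, n), _INF)
    W = np.zeros((n, n))
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            pij = pair_index[codes[i], codes[j]]
            if pij >= 0:
                best = _hairpin_energy(j - i - 1)
                # stack / bulge / internal loop closing (k, l)
                for k in range(i + 1, min(i + 2 + MAX_INTERNAL, j)):
                    left = k - i - 1
                    if left > MAX_INTERNAL:
                        break
                    for l in range(max(k + 1, j - 1 - (MAX_INTERNAL - left)), j):
                        right = j - l - 1
                        if left + right > MAX_INTERNAL:
                            continue
                        pkl = pair_index[codes[k], codes[l]]
                        if pkl < 0 or V[k, l] >= _INF:
                            continue
                        if left == 0 and right == 0:
                            e = V[k, l] + stack[pij, pkl]
                        else:
                            e = V[k, l] + _loop_energy(left + right)
                        if e < best:
                            best = e
                # multibranch
                for m in range(i + 2, j - 2):
                    e = W[i + 1, m] + W[m + 1, j - 1] + _MULTI_PENALTY
                    if e < best:
                        best = e
                V[i, j] = best
            w = W[i + 1, j]
            if W[i, j - 1] < w:
                w = W[i, j - 1]
            if V[i, j] < w:
                w = V[i, j]
            for m in range(i + 1, j):
                e = W[i, m] + W[m + 1, j]
                if e < w:
                    w = e
            W[i, j] = min(w, 0.0)
    return V, W


@dataclass
class FoldResult:
    """Secondary structure as a 1-based pair table plus its energy.

    pairs[i] = j when base i pairs base j (0 = unpaired; index 0 unused)."""

    pairs: np.ndarray
    mfe: float

    def dot_bracket(self) -> str:
        n = len(self.pairs) - 1
        out = ["."] * n
        for i in range(1, n + 1):
            j = int(self.pairs[i])
            if j > i:
                out[i - 1] = "("
                out[j - 1] = ")"
        return "".join(out)


def parse_dot_bracket(s: str) -> np.ndarray:
    pairs = np.zeros(len(s) + 1, dtype=np.int64)
    stack = []
    for i, c in enumerate(s, start=1):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pairs[i], pairs[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pairs


def fold_hairpin(sequence: str) -> FoldResult:
    """Fold a candidate precursor with the built-in energy-minimization DP.

    Requires length >= 40 (shorter windows cannot hold a miRNA hairpin) and a
    pure ACGT sequence (RNA input must be converted upstream).
    """
    if len(sequence) < 40:
        raise ValueError("precursor candidates must be at least 40 nt")
    if any(c not in "ACGT" for c in sequence):
        raise ValueError("sequence contains non-ACGT symbols")
    codes = encode(sequence).astype(np.int64)
    V, W = _fold_dp(codes, _PAIR_INDEX, _STACK)
    pairs = np.zeros(len(sequence) + 1, dtype=np.int64)
    _traceback_w(codes, V, W, 0, len(sequence) - 1, pairs)
    return FoldResult(pairs, float(W[0, len(sequence) - 1]))


_EPS = 1e-7


def _traceback_w(codes, V, W, i, j, pairs):
    while j - i > MIN_HAIRPIN_LOOP:
        w = W[i, j]
        if w >= -_EPS:  # empty structure
            return
        if abs(W[i + 1, j] - w) < _EPS:
            i += 1
            continue
        if abs(W[i, j - 1] - w) < _EPS:
            j -= 1
            continue
        if abs(V[i, j] - w) < _EPS:
            _traceback_v(codes, V, W, i, j, pairs)
            return
        for m in range(i + 1, j):
            if abs(W[i, m] + W[m + 1, j] - w) < _EPS:
                _traceback_w(codes, V, W, i, m, pairs)
                _traceback_w(codes, V, W, m + 1, j, pairs)
                return
        return  # numerically unresolvable; leave unpaired


def _traceback_v(codes, V, W, i, j, pairs):
    while True:
        pairs[i + 1], pairs[j + 1] = j + 1, i + 1
        v = V[i, j]
        pij = _PAIR_INDEX[codes[i], codes[j]]
        if abs(_hairpin_energy(j - i - 1) - v) < _EPS:
            return
        found = False
        for k in range(i + 1, min(i + 2 + MAX_INTERNAL, j)):
            left = k - i - 1
            if left > MAX_INTERNAL or found:
                break
            for l in range(max(k + 1, j - 1 - (MAX_INTERNAL - left)), j):
                right = j - l - 1
                if left + right > MAX_INTERNAL:
                    continue
                pkl = _PAIR_INDEX[codes[k], codes[l]]
                if pkl < 0 or V[k, l] >= _INF:
                    continue
                e = V[k, l] + (_STACK[pij, pkl] if left == 0 and right == 0
                               else _loop_energy(left + right))
                if abs(e - v) < _EPS:
                    i, j = k, l
                    found = True
                    break
        if found:
            continue
        for m in range(i + 2, j - 2):
            if abs(W[i + 1, m] + W[m + 1, j - 1] + _MULTI_PENALTY - v) < _EPS:
                _traceback_w(codes, V, W, i + 1, m, pairs)
                _traceback_w(codes, V, W, m + 1, j - 1, pairs)
                return
        return


@dataclass
class MiRNACandidate:
    read: UniqueRead
    source_contig: str
    locus: tuple  # (1-based start, end, strand) on the contig
    precursor: str
    precursor_offset: int  # 1-based start of the window on the contig
    structure: FoldResult | None = None
    mfe: float | None = None
    verdict: str | None = None  # pass | fail_mfe | fail_hairpin | fail_repeat
    orf_flag: bool = False
    notes: list = field(default_factory=list)


def map_unassigned(reads, primary_contigs: dict, related_contigs: dict | None = None,
                   primary_mismatch: int = 1, related_mismatch: int = 2):
    """Loci per read against the primary-species contigs (1 mismatch), falling
    back to related-species contigs (2 mismatches) only for reads with no
    primary hit. Returns {sequence: [(contig, start, strand, mismatches, tier)]}."""
    loci = {}
    for u in reads:
        seq = u.sequence if isinstance(u, UniqueRead) else u
        hits = _scan_contigs(seq, primary_contigs, primary_mismatch, "primary")
        if not hits and related_contigs:
            hits = _scan_contigs(seq, related_contigs, related_mismatch, "related")
        if hits:
            loci[seq] = hits
    return loci


def _scan_contigs(seq, contigs, budget, tier):
    from .sequtils import revcomp

    hits = []
    for name in sorted(contigs):
        ref = contigs[name]
        for start, mism in scan_hamming(seq, ref, budget):
            hits.append((name, start, "+", mism, tier))
        for start, mism in scan_hamming(seq, revcomp(ref), budget):
            pos = len(ref) - (start + len(seq) - 1) + 1
            hits.append((name, pos, "-", mism, tier))
    return hits


def extract_precursor_window(contig: str, locus: tuple, flank: int = 150,
                             near: int = 20):
    """Two candidate precursor windows around a mapped read locus, one biased
    to leave room for a 3' arm (read near the window 5' end) and one for a 5'
    arm. Windows are clipped at contig ends and always contain the locus.

    Returns [(window_seq, 1-based window start on contig), ...].
    """
    start, end = locus[0], locus[1]
    if not (1 <= start <= end <= len(contig)):
        raise ValueError("locus outside contig")
    windows = []
    for lo, hi in ((start - near, end + flank), (start - flank, end + near)):
        lo = max(1, lo)
        hi = min(len(contig), hi)
        windows.append((contig[lo - 1:hi], lo))
    return windows


def read_arm_fraction(fold: FoldResult, read_start: int, read_end: int,
                      arm_purity: float = 0.9):
    """(fraction of read bases paired, single-arm flag) for a read occupying
    1-based positions read_start..read_end of the folded sequence.

    The read lies on a single arm when at least `arm_purity` of its paired
    bases have partners on one side of the read; this tolerates the odd stray
    pair from flanking sequence while still rejecting loop-spanning reads
    (partners inside the read span count against purity on both sides)."""
    partners = [int(fold.pairs[p]) for p in range(read_start, read_end + 1)]
    paired = [p for p in partners if p != 0]
    frac = len(paired) / (read_end - read_start + 1)
    left = sum(p < read_start for p in paired)
    right = sum(p > read_end for p in paired)
    one_arm = bool(paired) and max(left, right) >= arm_purity * len(paired)
    return frac, one_arm


def filter_candidates(candidates, mfe_threshold: float = MFE_THRESHOLD,
                      repeat_set: dict | None = None,
                      min_arm_paired: float = 0.6):
    """Assign a verdict to each candidate.

    fail_repeat when the read maps into the repeat set (0 mismatches, both
    strands); fail_mfe when mfe >= threshold ("lower than" is strict, so a
    hairpin at exactly the threshold fails); fail_hairpin when the read does
    not sit on a single arm with at least `min_arm_paired` of its bases paired.
    Externally computed MFE values already stored on a candidate are consumed
    as-is; folding is only consulted when present.
    """
    for cand in candidates:
        seq = cand.read.sequence if isinstance(cand.read, UniqueRead) else cand.read
        if repeat_set and any(
                scan_hamming(seq, ref, 0) or
                scan_hamming(seq, _rc(ref), 0) for ref in repeat_set.values()):
            cand.verdict = "fail_repeat"
            continue
        if cand.mfe is None and cand.structure is not None:
            cand.mfe = cand.structure.mfe
        if cand.mfe is None or cand.mfe >= mfe_threshold:
            cand.verdict = "fail_mfe"
            continue
        if cand.structure is not None:
            rs = cand.locus[0] - cand.precursor_offset + 1
            re_ = rs + (cand.locus[1] - cand.locus[0])
            frac, one_arm = read_arm_fraction(cand.structure, rs, re_)
            if not one_arm or frac < min_arm_paired:
                cand.verdict = "fail_hairpin"
                continue
        cand.verdict = "pass"
    return candidates


def _rc(seq):
    from .sequtils import revcomp

    return revcomp(seq)


def orf_flag(window: str, min_codons: int = 80) -> bool:
    """Crude protein-coding screen: an open reading frame of at least
    `min_codons` codons in any forward frame of the window raises the flag."""
    n = len(window)
    for frame in range(3):
        run = 0
        for p in range(frame, n - 2, 3):
            codon = window[p:p + 3]
            if codon in ("TAA", "TAG", "TGA"):
                run = 0
            else:
                run += 1
                if run >= min_codons:
                    return True
    return False


def discover(reads, primary_contigs: dict, related_contigs: dict | None = None,
             repeat_set: dict | None = None, flank: int = 150,
             mfe_threshold: float = MFE_THRESHOLD,
             fold_backend=fold_hairpin) -> list[MiRNACandidate]:
    """Full discovery pass over the cascade remainder.

    For each mapped read the two precursor windows are folded and the window
    whose structure places the read on one well-paired arm at the lower energy
    is kept; candidates then run through the verdict filter.
    """
    loci = map_unassigned(reads, primary_contigs, related_contigs)
    contigs = dict(primary_contigs)
    if related_contigs:
        contigs.update(related_contigs)
    candidates = []
    for u in reads:
        seq = u.sequence if isinstance(u, UniqueRead) else u
        if seq not in loci:
            continue
        contig, start, strand, mism, tier = loci[seq][0]
        end = start + len(seq) - 1
        ref = contigs[contig]
        if strand == "-":
            ref = _rc(ref)
            start, end = len(ref) - end + 1, len(ref) - start + 1
        best = None
        for window, off in extract_precursor_window(ref, (start, end), flank):
            fold = fold_backend(window)
            rs = start - off + 1
            frac, one_arm = read_arm_fraction(fold, rs, rs + len(seq) - 1)
            key = (not one_arm, fold.mfe)
            if best is None or key < best[0]:
                best = (key, window, off, fold)
        _, window, off, fold = best
        cand = MiRNACandidate(u if isinstance(u, UniqueRead) else UniqueRead(seq),
                              contig, (start, end, strand), window, off,
                              structure=fold, mfe=fold.mfe,
                              orf_flag=orf_flag(window))
        candidates.append(cand)
    return filter_candidates(candidates, mfe_threshold, repeat_set)


def candidate_table(candidates, group_a: str, group_b: str, factor) -> pd.DataFrame:
    """Per-candidate table: sequence, per-group counts, normalized count,
    log2 ratio, hairpin MFE, location, verdict."""
    from .diffexp import log2_ratio, normalize_count

    rows = []
    for c in candidates:
        a, b = c.read.count(group_a), c.read.count(group_b)
        norm = normalize_count(b, factor)
        rows.append({
            "sequence": c.read.sequence, "count_a": a, "count_b": b,
            "normalized_b": norm,
            "log2": log2_ratio(a, norm) if (a > 0 and norm > 0) else None,
            "mfe": c.mfe,
            "location": f"{c.source_contig}:{c.locus[0]}-{c.locus[1]}({c.locus[2]})",
            "verdict": c.verdict, "orf_flag": c.orf_flag,
        })
    return pd.DataFrame(rows)
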