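"""Two-library count normalization and |log2| >= 1 differential-expression
accounting.

The design has one pooled library per condition, so no replicate variance is
available; differential expression is a pure fold-change classifier. Counts of
the second group are scaled by the ratio of the two groups' total
(non-chloroplast) read counts so that scaled totals are identical, and a read
or feature is called differentially expressed when |log2(normalized_B /
count_A)| >= 1, i.e. at least a factor of two between groups. Zero counts give
an undefined log2 and are reported as group-specific instead (no pseudocount).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .preprocess import DEFAULT_THRESHOLDS


@dataclass
class NormalizationFactor:
    numerator_total: int
    denominator_total: int

    @property
    def value(self) -> float:
        return self.numerator_total / self.denominator_total


@dataclass
class DEEntry:
    feature: str
    count_a: int
    count_b: int
    normalized_b: float
    log2_ratio: float | None
    de_class: str  # A-specific | B-specific | common-DE-up | common-DE-down | common-flat


def normalization_factor(total_a: int, total_b: int) -> NormalizationFactor:
    """Ratio of group totals, kept at full precision (display layers may round)."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("group totals must be positive")
    return NormalizationFactor(total_a, total_b)


def normalize_count(count_b: int, factor: NormalizationFactor) -> float:
    if count_b < 0:
        raise ValueError("counts must be nonnegative")
    return count_b * factor.value


def log2_ratio(count_a: int, normalized_b: float) -> float | None:
    """log2(normalized_B / count_A); None (undefined) when either side is zero,
    in which case the feature is group-specific. Both zero is a caller error
    (such features are dropped with a warning upstream)."""
    if count_a < 0 or normalized_b < 0:
        raise ValueError("counts must be nonnegative")
    if count_a == 0 and normalized_b == 0:
        raise ValueError("feature absent from both groups")
    if count_a == 0 or normalized_b == 0:
        return None
    return math.log2(normalized_b / count_a)


def classify_feature(feature: str, count_a: int, count_b: int,
                     factor: NormalizationFactor,
                     log2_threshold: float = 1.0) -> DEEntry:
    norm_b = normalize_count(count_b, factor)
    ratio = log2_ratio(count_a, norm_b)
    if ratio is None:
        cls = "A-specific" if count_a > 0 else "B-specific"
    elif ratio >= log2_threshold:
        cls = "common-DE-up"
    elif ratio <= -log2_threshold:
        cls = "common-DE-down"
    else:
        cls = "common-flat"
    return DEEntry(feature, count_a, count_b, norm_b, ratio, cls)


def summarize_groups(unique_reads, group_a: str, group_b: str,
                     thresholds=DEFAULT_THRESHOLDS,
                     factor: NormalizationFactor | None = None,
                     log2_threshold: float = 1.0) -> pd.DataFrame:
    """Group-comparison accounting for one read stream, per threshold.

    At threshold t the universe is every read with count >= t in at least one
    group. A read is sample-specific when it clears the threshold in one group
    and is entirely absent (count 0) from the other; reads present in both
    groups are "common" and are classified by the |log2| rule on normalized
    counts. The factor defaults to the ratio of this stream's totals at
    threshold 1 but is normally supplied once from the non-chloroplast stream
    and reused everywhere.
    """
    if factor is None:
        ta = sum(u.count(group_a) for u in unique_reads)
        tb = sum(u.count(group_b) for u in unique_reads)
        factor = normalization_factor(ta, tb)
    rows = []
    for t in thresholds:
        if t < 1:
            raise ValueError("threshold must be >= 1")
        set_a = [u for u in unique_reads if u.count(group_a) >= t]
        set_b = [u for u in unique_reads if u.count(group_b) >= t]
        universe = {u.sequence: u for u in set_a + set_b}
        spec_a = [u for u in universe.values() if u.count(group_b) == 0]
        spec_b = [u for u in universe.values() if u.count(group_a) == 0]
        common = [u for u in universe.values()
                  if u.count(group_a) > 0 and u.count(group_b) > 0]
        assert len(spec_a) + len(spec_b) + len(common) == len(universe)
        de_a = de_b = 0
        for u in common:
            ratio = log2_ratio(u.count(group_a),
                               normalize_count(u.count(group_b), factor))
            if ratio is not None and ratio <= -log2_threshold:
                de_a += 1  # higher in group A
            elif ratio is not None and ratio >= log2_threshold:
                de_b += 1
        total_a = sum(u.count(group_a) for u in set_a)
        total_b = sum(u.count(group_b) for u in set_b)
        rows.append({
            "threshold": t,
            "unique_a": len(set_a), "unique_b": len(set_b),
            "unique_fraction": len(set_a) / len(set_b) if set_b else float("nan"),
            "total_a": total_a, "total_b": total_b,
            "total_fraction": total_a / total_b if total_b else float("nan"),
            "specific_a": len(spec_a), "specific_b": len(spec_b),
            "specific_fraction": len(spec_a) / len(spec_b) if spec_b else float("nan"),
            "common": len(common),
            "de_a": de_a, "de_b": de_b, "de_sum": de_a + de_b,
            "de_percent": 100.0 * (de_a + de_b) / len(common) if common else float("nan"),
        })
    return pd.DataFrame(rows)


def feature_table(counts_a: dict, counts_b: dict,
                  factor: NormalizationFactor,
                  log2_threshold: float = 1.0) -> pd.DataFrame:
    """Per-feature DE table (feature, raw counts, normalized count, log2,
    class), dropping features absent from both groups with a warning."""
    import warnings

    rows = []
    for feature in sorted(set(counts_a) | set(counts_b)):
        a, b = counts_a.get(feature, 0), counts_b.get(feature, 0)
        if a == 0 and b == 0:
            warnings.warn(f"feature {feature} absent from both groups; dropped")
            continue
        e = classify_feature(feature, a, b, factor, log2_threshold)
        rows.append({"feature": feature, "count_a": a, "count_b": b,
                     "normalized_b": e.normalized_b, "log2": e.log2_ratio,
                     "class": e.de_class})
    return pd.DataFrame(rows)
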