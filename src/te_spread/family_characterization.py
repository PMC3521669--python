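"""Family attribute summaries by spreading class: superfamily composition,
attribute comparisons, normalized chromosomal distributions, and small-RNA
coverage statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import ranksum

logger = logging.getLogger(__name__)

SUPERFAMILIES = ("RLC", "RLG", "RLX", "LINE")
ATTRIBUTE_COLUMNS = ("family_id", "superfamily", "copy_number", "genome_mb",
                     "mean_fragment_length", "mean_insertion_date")


@dataclass
class SmallRNAStats:
    family_id: str
    mean_read_count_per_copy: float
    mean_covered_fraction: float


def read_attributes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(ATTRIBUTE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"attribute table missing columns "
                         f"{sorted(missing)}")
    return df


def superfamily_composition(classes: dict,
                            attributes: pd.DataFrame) -> pd.DataFrame:
    """Proportion of each superfamily within each spreading class."""
    superfamily = {}
    for row in attributes.itertuples(index=False):
        code = str(row.superfamily)
        if code not in SUPERFAMILIES:
            logger.warning("unknown superfamily %r for family %s; grouped "
                           "as 'other'", code, row.family_id)
            code = "other"
        superfamily[str(row.family_id)] = code
    rows = []
    by_class = {}
    for family_id, cls in classes.items():
        if family_id not in superfamily:
            raise ValueError(f"family {family_id!r} has no superfamily "
                             "attribute")
        by_class.setdefault(cls, []).append(superfamily[family_id])
    for cls, codes in sorted(by_class.items()):
        total = len(codes)
        for code in SUPERFAMILIES + ("other",):
            n = codes.count(code)
            rows.append({"class": cls, "superfamily": code, "n_families": n,
                         "proportion": n / total})
    return pd.DataFrame(rows)


def compare_attribute(attributes: pd.DataFrame, classes: dict,
                      attribute_name: str, class_a: str, class_b: str):
    """Two-sided Wilcoxon rank-sum on family-level attribute values."""
    from .methylation_context import GroupComparison

    values = {class_a: [], class_b: []}
    for row in attributes.itertuples(index=False):
        cls = classes.get(str(row.family_id))
        if cls not in values:
            continue
        value = getattr(row, attribute_name)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        values[cls].append(float(value))
    a, b = values[class_a], values[class_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need >= 2 families per class, got {len(a)} vs {len(b)}")
    res = ranksum(a, b)
    return GroupComparison(group_a=class_a, group_b=class_b, values_a=a,
                           values_b=b, statistic=float(res.statistic),
                           p_value=float(res.pvalue))


def chromosomal_distribution(repeats, family_id: str, chrom_lengths: dict,
                             n_windows: int = 20) -> np.ndarray:
    """Histogram of copy midpoints over chromosome-relative windows,
    normalized to the family's total copy number (sums to 1)."""
    if n_windows < 2:
        raise ValueError("n_windows must be >= 2")
    copies = [r for r in repeats if r.family_id == family_id]
    if not copies:
        raise ValueError(f"family {family_id!r} has zero copies")
    hist = np.zeros(n_windows)
    for rep in copies:
        rel = rep.interval.midpoint / chrom_lengths[rep.interval.chrom]
        window = min(int(rel * n_windows), n_windows - 1)
        hist[window] += 1
    return hist / hist.sum()


def class_distribution(repeats, classes: dict, chrom_lengths: dict,
                       n_windows: int = 20) -> dict:
    """Per-class mean of member-family normalized histograms (families
    weigh equally regardless of copy number)."""
    per_class = {}
    families = sorted({r.family_id for r in repeats})
    for family_id in families:
        cls = classes.get(family_id)
        if cls is None:
            continue
        hist = chromosomal_distribution(repeats, family_id, chrom_lengths,
                                        n_windows)
        per_class.setdefault(cls, []).append(hist)
    return {cls: np.mean(hists, axis=0)
            for cls, hists in sorted(per_class.items())}


def union_coverage(intervals, lo: int, hi: int) -> int:
    """Covered bases of [lo, hi) under the union of intervals (already on
    the right chromosome)."""
    clipped = sorted((max(iv.start, lo), min(iv.end, hi))
                     for iv in intervals if iv.start < hi and iv.end > lo)
    covered = 0
    cur_start, cur_end = None, None
    for s, e in clipped:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered


def smallrna_stats(smallrna_intervals, repeats) -> dict:
    """Per family: mean small-RNA read count per copy and mean fraction of
    the copy covered by the union of overlapping reads."""
    by_chrom = {}
    for iv in smallrna_intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda iv: iv.start)

    per_family = {}
    for rep in repeats:
        chrom = rep.interval.chrom
        lo, hi = rep.interval.start, rep.interval.end
        overlapping = [iv for iv in by_chrom.get(chrom, [])
                       if iv.start < hi and iv.end > lo]
        covered = union_coverage(overlapping, lo, hi)
        per_family.setdefault(rep.family_id, []).append(
            (len(overlapping), covered / (hi - lo)))
    stats_out = {}
    for family_id, rows in sorted(per_family.items()):
        counts = [c for c, _ in rows]
        fractions = [f for _, f in rows]
        stats_out[family_id] = SmallRNAStats(
            family_id=family_id,
            mean_read_count_per_copy=float(np.mean(counts)),
            mean_covered_fraction=float(np.mean(fractions)))
    return stats_out
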