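"""Context-resolved bisulfite methylation summaries.

Percent methylation for a region is the weighted definition: summed
methylated read counts over summed total read counts across all covered
cytosines of a context (a per-site binary mode is available behind a flag).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from ._stats import ranksum

from . import CLASS_NONE
from .formats_io import GenomicInterval, VALID_CONTEXTS, context_at, \
    cytosine_frame

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 1000
DEFAULT_ALPHA = 0.001


@dataclass
class ContextMethylationSummary:
    region_label: str
    context: str
    meth_c: int
    total_c: int

    @property
    def pct(self) -> float:
        if self.total_c <= 0:
            return math.nan
        return 100.0 * self.meth_c / self.total_c


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    values_a: list
    values_b: list
    statistic: float
    p_value: float
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def call_context(genome: dict, chrom: str, position: int,
                 strand: str) -> str:
    """CG/CHG/CHH context of the cytosine at (chrom, position, strand)."""
    if chrom not in genome:
        raise KeyError(f"unknown chromosome {chrom!r}")
    return context_at(genome[chrom], position, strand)


def low_copy_flanks(repeats, flank_bp: int = DEFAULT_FLANK_BP,
                    chrom_lengths: dict | None = None) -> list:
    """The two flank_bp intervals adjacent to each repeat copy, kept only
    when they overlap no annotated repeat and are not clipped at a
    chromosome end (the 3' check needs ``chrom_lengths``).
    Returns [(copy_id, side, GenomicInterval), ...].
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be > 0")
    by_chrom = {}
    for rep in repeats:
        by_chrom.setdefault(rep.interval.chrom, []).append(rep)
    flanks = []
    for chrom, reps in by_chrom.items():
        intervals = sorted((r.interval.start, r.interval.end) for r in reps)
        starts = np.array([s for s, _ in intervals])
        ends = np.array([e for _, e in intervals])
        cummax_ends = np.maximum.accumulate(ends)

        def overlaps_any(lo, hi):
            i = np.searchsorted(starts, hi, side="left")
            return i > 0 and cummax_ends[i - 1] > lo

        for rep in reps:
            left = (rep.interval.start - flank_bp, rep.interval.start)
            right = (rep.interval.end, rep.interval.end + flank_bp)
            if left[0] >= 0 and not overlaps_any(*left):
                flanks.append((rep.copy_id, "5prime",
                               GenomicInterval(chrom, left[0], left[1])))
            clipped = (chrom_lengths is not None
                       and chrom in chrom_lengths
                       and right[1] > chrom_lengths[chrom])
            if not clipped and not overlaps_any(*right):
                flanks.append((rep.copy_id, "3prime",
                               GenomicInterval(chrom, right[0], right[1])))
    return flanks


def _region_counts(df, regions) -> dict:
    """Summed (meth, total) per context over a list of intervals."""
    out = {ctx: [0, 0] for ctx in VALID_CONTEXTS}
    for chrom, grp in df.groupby("chrom", sort=False):
        positions = grp["position"].to_numpy()
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        meth = grp["meth_count"].to_numpy()[order]
        total = grp["total_count"].to_numpy()[order]
        ctxs = grp["context"].to_numpy()[order]
        for region in regions:
            if region.chrom != chrom:
                continue
            lo = np.searchsorted(positions, region.start, side="left")
            hi = np.searchsorted(positions, region.end, side="left")
            for ctx in VALID_CONTEXTS:
                mask = ctxs[lo:hi] == ctx
                out[ctx][0] += int(meth[lo:hi][mask].sum())
                out[ctx][1] += int(total[lo:hi][mask].sum())
    return out


def region_methylation(records, regions, region_label: str = "region",
                       binary: bool = False, min_coverage: int = 3) -> dict:
    """Per-context methylation summary over regions.

    Default mode sums read counts; ``binary`` mode instead calls each site
    methylated when meth/total >= 0.5 at coverage >= min_coverage, and the
    summary counts sites.
    """
    df = cytosine_frame(records)
    if binary:
        covered = df[df["total_count"] >= min_coverage].copy()
        covered["meth_count"] = (
            covered["meth_count"] / covered["total_count"] >= 0.5
        ).astype(int)
        covered["total_count"] = 1
        df = covered
    counts = _region_counts(df, regions)
    return {ctx: ContextMethylationSummary(region_label, ctx, m, t)
            for ctx, (m, t) in counts.items()}


def family_flank_and_internal(records, repeats, family_id: str,
                              flank_bp: int = DEFAULT_FLANK_BP,
                              chrom_lengths: dict | None = None,
                              **kwargs):
    """(flank summary, internal summary) per context for one family.

    Flanks are the low-copy flank_bp intervals of the family's copies;
    internal regions are the annotated repeat intervals themselves.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be > 0")
    fam_copies = [r for r in repeats if r.family_id == family_id]
    if not fam_copies:
        raise ValueError(f"family {family_id!r} has no copies")
    fam_copy_ids = {r.copy_id for r in fam_copies}
    all_flanks = low_copy_flanks(repeats, flank_bp, chrom_lengths)
    fam_flanks = [iv for cid, _, iv in all_flanks if cid in fam_copy_ids]
    flank_summary = (
        region_methylation(records, fam_flanks,
                           region_label=f"{family_id}:flank", **kwargs)
        if fam_flanks else None)
    internal_summary = region_methylation(
        records, [r.interval for r in fam_copies],
        region_label=f"{family_id}:internal", **kwargs)
    return flank_summary, internal_summary


def random_region_baseline(records, chrom_lengths: dict,
                           n_regions: int = 10_000,
                           region_bp: int = DEFAULT_FLANK_BP,
                           seed: int = 0, **kwargs) -> dict:
    """Summary over n_regions uniform random intervals of region_bp."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)
    lengths = np.array([max(chrom_lengths[c] - region_bp, 1)
                        for c in chroms], dtype=float)
    draws = rng.choice(len(chroms), size=n_regions,
                       p=lengths / lengths.sum())
    regions = []
    for i in range(n_regions):
        chrom = chroms[int(draws[i])]
        start = int(rng.integers(0, max(chrom_lengths[chrom] - region_bp,
                                        1)))
        regions.append(GenomicInterval(chrom, start, start + region_bp))
    return region_methylation(records, regions, region_label="random",
                              **kwargs)


def compare_groups(values_by_class: dict, context: str = "",
                   reference_class: str = CLASS_NONE,
                   alpha: float = DEFAULT_ALPHA) -> dict:
    """Two-sided Wilcoxon rank-sum of each class's family-level values
    against the reference (non-spreading) class."""
    if reference_class not in values_by_class:
        raise ValueError(f"reference class {reference_class!r} missing")
    ref = [v for v in values_by_class[reference_class]
           if not math.isnan(v)]
    comparisons = {}
    for cls, values in sorted(values_by_class.items()):
        if cls == reference_class:
            continue
        vals = [v for v in values if not math.isnan(v)]
        if len(vals) < 2 or len(ref) < 2:
            logger.warning("group %s vs %s: fewer than 2 families; "
                           "comparison undefined", cls, reference_class)
            continue
        res = ranksum(vals, ref)
        comparisons[cls] = GroupComparison(
            group_a=cls, group_b=reference_class, values_a=vals,
            values_b=ref, statistic=float(res.statistic),
            p_value=float(res.pvalue), alpha=alpha)
    return comparisons


def positional_profile(records, repeats, classes: dict,
                       chrom_lengths: dict, context: str = "CG",
                       n_windows: int = 20,
                       flank_bp: int = DEFAULT_FLANK_BP) -> dict:
    """Mean flank percent methylation per class x chromosome-relative
    window (copies mapped by midpoint / chromosome length)."""
    flank_by_copy = {}
    for cid, _, iv in low_copy_flanks(repeats, flank_bp, chrom_lengths):
        flank_by_copy.setdefault(cid, []).append(iv)
    df = cytosine_frame(records)
    cells = {}
    for rep in repeats:
        cls = classes.get(rep.family_id)
        if cls is None:
            continue
        chrom_len = chrom_lengths[rep.interval.chrom]
        rel = rep.interval.midpoint / chrom_len
        window = min(int(rel * n_windows) + 1, n_windows)
        flanks = flank_by_copy.get(rep.copy_id)
        if not flanks:
            continue
        counts = _region_counts(df, flanks)
        meth, total = counts[context]
        if total == 0:
            continue
        cells.setdefault((cls, window), []).append(100.0 * meth / total)
    return {key: float(np.mean(vals)) for key, vals in sorted(cells.items())}


def summaries_to_frame(summaries):
    """Tidy table from an iterable of (label, region_type, summary-dict)."""
    import pandas as pd

    rows = []
    for label, region_type, per_context in summaries:
        if per_context is None:
            continue
        for ctx in VALID_CONTEXTS:
            s = per_context[ctx]
            rows.append({
                "family_id": label, "region_type": region_type,
                "context": ctx, "meth_c": s.meth_c, "total_c": s.total_c,
                "pct": s.pct,
            })
    return pd.DataFrame(rows)
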