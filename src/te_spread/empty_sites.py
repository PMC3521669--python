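"""Detection of TE insertions absent from a query haplotype, and the
cross-genotype differential methylation test at the nearest flanking probe.

A boundary of an annotated repeat is called empty when at least
``min_support`` unique query reads anchor in the low-copy flank with a long
unaligned overhang beginning at the insertion point, and no read aligns
across the flank/repeat junction.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

BOUNDARY_5P = "5prime"
BOUNDARY_3P = "3prime"

STATUS_EMPTY = "empty"
STATUS_OCCUPIED = "occupied"
STATUS_AMBIGUOUS = "ambiguous"

DIRECTION_WITH = "higher_with_insertion"
DIRECTION_WITHOUT = "higher_without"


@dataclass(frozen=True)
class EmptySiteParams:
    min_support: int = 3
    min_outside_bp: int = 50      # aligned bases outside the repeat, > this
    min_identity_pct: float = 94.0
    max_tail_bp: int = 20         # non-junction-side unaligned tail, <= this
    min_overhang_bp: int = 20     # junction-side overhang, > this
    boundary_tol_bp: int = 3      # anchor / junction-penetration tolerance


@dataclass
class EmptySiteCall:
    repeat_copy_id: str
    family_id: str
    boundary_tested: str
    n_supporting_reads: int
    n_junction_reads: int
    status: str
    criteria_trace: list = field(default_factory=list)


@dataclass
class DifferentialMethylationCall:
    probe_id: str
    repeat_copy_id: str
    mean_with_insertion: float
    mean_without: float
    p_value: float
    alpha: float = 0.01

    @property
    def differential(self) -> bool:
        return self.p_value < self.alpha

    @property
    def direction(self):
        if not self.differential:
            return None
        return (DIRECTION_WITH
                if self.mean_with_insertion > self.mean_without
                else DIRECTION_WITHOUT)


def supporting_read(aln, repeat, boundary: str,
                    params: EmptySiteParams = EmptySiteParams()):
    """Evaluate one alignment as supporting evidence for an empty boundary.

    Returns (verdict, trace) where trace lists each clause with its
    outcome.  All clauses must hold:

    * aligned span in the flank (outside the repeat) > min_outside_bp
    * identity >= min_identity_pct
    * junction-side unaligned overhang > min_overhang_bp, anchored within
      +/- boundary_tol_bp of the repeat boundary
    * non-junction-side unaligned tail <= max_tail_bp
    * the aligned span does not run into the repeat beyond the tolerance
    """
    trace = []

    def clause(name, ok):
        trace.append((name, bool(ok)))
        return bool(ok)

    iv = aln.interval
    rep = repeat.interval
    if iv.chrom != rep.chrom:
        clause("same_chromosome", False)
        return False, trace
    clause("same_chromosome", True)

    if boundary == BOUNDARY_5P:
        edge = rep.start
        # read anchors in the left flank; junction side is the right end
        outside = min(iv.end, edge) - iv.start
        overhang = aln.right_unaligned
        tail = aln.left_unaligned
        anchor_offset = abs(iv.end - edge)
        penetration = iv.end - edge
    elif boundary == BOUNDARY_3P:
        edge = rep.end
        outside = iv.end - max(iv.start, edge)
        overhang = aln.left_unaligned
        tail = aln.right_unaligned
        anchor_offset = abs(iv.start - edge)
        penetration = edge - iv.start
    else:
        raise ValueError(f"invalid boundary {boundary!r}")

    ok = clause("aligned_outside_gt_min", outside > params.min_outside_bp)
    ok &= clause("identity_ge_min",
                 aln.identity_pct >= params.min_identity_pct)
    ok &= clause("overhang_gt_min", overhang > params.min_overhang_bp)
    ok &= clause("anchor_within_tol",
                 anchor_offset <= params.boundary_tol_bp)
    ok &= clause("tail_le_max", tail <= params.max_tail_bp)
    ok &= clause("no_deep_penetration",
                 penetration <= params.boundary_tol_bp)
    return ok, trace


def junction_covered(aln, repeat, boundary: str,
                     tolerance_bp: int = 3) -> bool:
    """True iff the aligned span has > tolerance_bp aligned bases on both
    sides of the boundary."""
    iv = aln.interval
    rep = repeat.interval
    if iv.chrom != rep.chrom:
        return False
    edge = rep.start if boundary == BOUNDARY_5P else rep.end
    return (iv.start < edge - tolerance_bp) and (iv.end > edge + tolerance_bp)


def detect_empty_sites(alignments, repeats,
                       params: EmptySiteParams = EmptySiteParams(),
                       require_both_flanks: bool = False) -> list:
    """Classify every repeat boundary as empty / occupied / ambiguous.

    empty: >= min_support supporting reads and 0 junction reads;
    occupied: >= 1 junction read and 0 supporting reads;
    ambiguous otherwise (insufficient or conflicting evidence).

    With ``require_both_flanks`` a combined per-copy call is still emitted
    per boundary; consumers should intersect the two.
    """
    by_chrom = {}
    for aln in alignments:
        if not aln.unique:
            continue
        by_chrom.setdefault(aln.interval.chrom, []).append(aln)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda a: a.interval.start)
    chrom_starts = {chrom: [a.interval.start for a in alns]
                    for chrom, alns in by_chrom.items()}
    max_span = max((a.interval.end - a.interval.start + a.query_length
                    for a in alignments), default=1000)

    calls = []
    for rep in repeats:
        chrom = rep.interval.chrom
        alns = by_chrom.get(chrom, [])
        starts = chrom_starts.get(chrom, [])
        for boundary in (BOUNDARY_5P, BOUNDARY_3P):
            edge = (rep.interval.start if boundary == BOUNDARY_5P
                    else rep.interval.end)
            lo = bisect.bisect_left(starts, edge - max_span)
            hi = bisect.bisect_right(starts, edge + max_span)
            n_support = 0
            n_junction = 0
            traces = []
            for aln in alns[lo:hi]:
                ok, trace = supporting_read(aln, rep, boundary, params)
                if ok:
                    n_support += 1
                    traces.append((aln.read_id, trace))
                if junction_covered(aln, rep, boundary,
                                    params.boundary_tol_bp):
                    n_junction += 1
            if n_support >= params.min_support and n_junction == 0:
                status = STATUS_EMPTY
            elif n_junction >= 1 and n_support == 0:
                status = STATUS_OCCUPIED
            else:
                status = STATUS_AMBIGUOUS
            calls.append(EmptySiteCall(
                repeat_copy_id=rep.copy_id, family_id=rep.family_id,
                boundary_tested=boundary, n_supporting_reads=n_support,
                n_junction_reads=n_junction, status=status,
                criteria_trace=traces))
    return calls


def combine_boundary_calls(calls, params: EmptySiteParams =
                           EmptySiteParams(),
                           require_both_flanks: bool = False) -> dict:
    """Per-copy status from the boundary calls.

    Supporting evidence is counted at the site level (summed over the two
    boundaries, matching the "reads supporting the site" criterion); any
    junction read at either boundary vetoes an empty call.  With
    ``require_both_flanks`` each boundary must independently reach
    min_support.
    """
    by_copy = {}
    for call in calls:
        by_copy.setdefault(call.repeat_copy_id, []).append(call)
    combined = {}
    for copy_id, copy_calls in by_copy.items():
        total_support = sum(c.n_supporting_reads for c in copy_calls)
        total_junction = sum(c.n_junction_reads for c in copy_calls)
        if require_both_flanks:
            enough = all(c.n_supporting_reads >= params.min_support
                         for c in copy_calls)
        else:
            enough = total_support >= params.min_support
        if enough and total_junction == 0:
            combined[copy_id] = STATUS_EMPTY
        elif total_junction >= 1 and total_support == 0:
            combined[copy_id] = STATUS_OCCUPIED
        else:
            combined[copy_id] = STATUS_AMBIGUOUS
    return combined


def nearest_probe(boundary_pos: float, chrom: str, probes,
                  max_distance_bp: float = 5000.0):
    """Single-copy probe with midpoint closest to the boundary; ties broken
    by probe_id.  Returns None (and logs) when nothing is within the cap."""
    best = None
    for p in probes:
        if not p.single_copy or p.interval.chrom != chrom:
            continue
        d = abs(p.midpoint - boundary_pos)
        key = (d, p.probe_id)
        if best is None or key < best[0]:
            best = (key, p)
    if best is None or best[0][0] > max_distance_bp:
        logger.info("no probe within %.0f bp of %s:%.0f; site dropped",
                    max_distance_bp, chrom, boundary_pos)
        return None
    return best[1]


def test_differential(probe, genotype_with: str, genotype_without: str,
                      mark: str, tissue: str, alpha: float = 0.01,
                      repeat_copy_id: str = ""
                      ) -> DifferentialMethylationCall:
    """Welch two-sample t-test on replicate log-ratios, two-sided."""
    reps_with = probe.signals.get((mark, genotype_with, tissue), [])
    reps_without = probe.signals.get((mark, genotype_without, tissue), [])
    if len(reps_with) < 2 or len(reps_without) < 2:
        raise ValueError(
            f"probe {probe.probe_id}: need >= 2 replicates per genotype")
    if np.var(reps_with) == 0 and np.var(reps_without) == 0 \
            and np.mean(reps_with) == np.mean(reps_without):
        p_value = 1.0
    else:
        res = stats.ttest_ind(reps_with, reps_without, equal_var=False)
        p_value = float(res.pvalue)
        if math.isnan(p_value):
            p_value = 1.0
    return DifferentialMethylationCall(
        probe_id=probe.probe_id, repeat_copy_id=repeat_copy_id,
        mean_with_insertion=float(np.mean(reps_with)),
        mean_without=float(np.mean(reps_without)),
        p_value=p_value, alpha=alpha)


def summarize(calls_by_class: dict, background_calls=None) -> dict:
    """Fractions of differential calls per spreading class, the direction
    bias among differential calls, and the genome-wide background."""
    summary = {"per_class": {}, "frac_higher_with_insertion": math.nan,
               "genome_wide_frac_differential": math.nan}
    all_differential = []
    for cls, calls in sorted(calls_by_class.items()):
        if not calls:
            summary["per_class"][cls] = {"n": 0,
                                         "frac_differential": math.nan}
            continue
        diff = [c for c in calls if c.differential]
        summary["per_class"][cls] = {
            "n": len(calls),
            "n_differential": len(diff),
            "frac_differential": len(diff) / len(calls),
        }
        all_differential.extend(diff)
    if all_differential:
        n_with = sum(1 for c in all_differential
                     if c.direction == DIRECTION_WITH)
        summary["frac_higher_with_insertion"] = \
            n_with / len(all_differential)
    if background_calls:
        n_diff = sum(1 for c in background_calls if c.differential)
        summary["genome_wide_frac_differential"] = \
            n_diff / len(background_calls)
    return summary
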