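"""Assign single-copy probes to their closest repeat and build per-family
200 bp-binned mean enrichment profiles with both flanks collapsed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_BIN_BP = 200
DEFAULT_WINDOW_BP = 4000
DEFAULT_MAX_DISTANCE_BP = 5000
DEFAULT_MIN_PROBES = 1000

SIDE_5P = "5prime"
SIDE_3P = "3prime"
SIDE_INTERNAL = "internal"


@dataclass(frozen=True)
class ProbeAssignment:
    probe_id: str
    repeat_copy_id: str
    family_id: str
    distance_bp: float
    side: str


@dataclass
class FlankBinProfile:
    """Mean enrichment per 200 bp distance bin for one family x mark x
    sample; bin k aggregates probes with distance in [200(k-1), 200k),
    pooling both flanks.  Empty bins carry mean = NaN.
    """

    family_id: str
    mark: str
    genotype: str
    tissue: str
    bin_means: list  # [(bin_index, mean_log_ratio_or_nan, probe_count), ...]
    bin_width_bp: int = DEFAULT_BIN_BP
    max_distance_bp: int = DEFAULT_WINDOW_BP

    def mean_for_bin(self, bin_index: int) -> float:
        for k, mean, _ in self.bin_means:
            if k == bin_index:
                return mean
        return math.nan

    def count_for_bin(self, bin_index: int) -> int:
        for k, _, count in self.bin_means:
            if k == bin_index:
                return count
        return 0


def bin_index(distance_bp: float, bin_width_bp: int = DEFAULT_BIN_BP) -> int:
    """1-based bin for a flank distance; bins are half-open
    [w*(k-1), w*k)."""
    if distance_bp < 0:
        raise ValueError(f"negative distance {distance_bp}")
    return int(distance_bp // bin_width_bp) + 1


def assign_probes(probes, repeats, max_distance_bp: int =
                  DEFAULT_MAX_DISTANCE_BP) -> list:
    """Assign each single-copy probe to its unique closest repeat.

    Probes farther than ``max_distance_bp`` from every repeat are excluded;
    probes whose midpoint falls inside a repeat get side='internal'.
    Equidistant ties are broken by (chrom, start, copy_id) of the repeat.
    """
    if not repeats:
        raise ValueError("repeat list is empty")
    if max_distance_bp <= 0:
        raise ValueError("max_distance_bp must be > 0")

    by_chrom = {}
    for rep in sorted(repeats, key=lambda r: (r.interval.chrom,
                                              r.interval.start, r.copy_id)):
        by_chrom.setdefault(rep.interval.chrom, []).append(rep)

    # precompute per-chromosome arrays: starts (sorted) and a running
    # maximum of ends with the first repeat attaining it (for overlap-safe
    # left-neighbour queries).
    chrom_index = {}
    for chrom, reps in by_chrom.items():
        starts = np.array([r.interval.start for r in reps], dtype=float)
        ends = [r.interval.end for r in reps]
        cummax_end = []
        cummax_rep = []
        best = -1
        best_rep = None
        for r, e in zip(reps, ends):
            if e > best:
                best, best_rep = e, r
            cummax_end.append(best)
            cummax_rep.append(best_rep)
        chrom_index[chrom] = (reps, starts, np.array(cummax_end, dtype=float),
                              cummax_rep)

    assignments = []
    for probe in sorted(probes, key=lambda p: p.probe_id):
        if not probe.single_copy:
            continue
        chrom = probe.interval.chrom
        if chrom not in chrom_index:
            continue
        reps, starts, cummax_end, cummax_rep = chrom_index[chrom]
        mid = probe.midpoint
        idx = int(np.searchsorted(starts, mid, side="right"))

        left_rep = cummax_rep[idx - 1] if idx > 0 else None
        left_end = cummax_end[idx - 1] if idx > 0 else -math.inf
        right_rep = reps[idx] if idx < len(reps) else None

        if left_rep is not None and mid < left_end \
                and mid >= left_rep.interval.start:
            # midpoint inside a repeat; find the containing repeat with the
            # smallest (start, copy_id) among overlap candidates
            container = None
            for r in reps[:idx]:
                if r.interval.start <= mid < r.interval.end:
                    container = r
                    break
            if container is not None:
                assignments.append(ProbeAssignment(
                    probe.probe_id, container.copy_id, container.family_id,
                    0.0, SIDE_INTERNAL))
                continue

        left_dist = mid - left_end if left_rep is not None else math.inf
        right_dist = (right_rep.interval.start - mid
                      if right_rep is not None else math.inf)
        left_dist = max(left_dist, 0.0)
        right_dist = max(right_dist, 0.0)

        if left_dist <= right_dist:
            best_rep, dist, side = left_rep, left_dist, SIDE_3P
            if left_dist == right_dist and right_rep is not None:
                logger.debug("probe %s equidistant between %s and %s; "
                             "keeping %s", probe.probe_id, left_rep.copy_id,
                             right_rep.copy_id, left_rep.copy_id)
        else:
            best_rep, dist, side = right_rep, right_dist, SIDE_5P
        if best_rep is None or dist > max_distance_bp:
            continue
        assignments.append(ProbeAssignment(
            probe.probe_id, best_rep.copy_id, best_rep.family_id,
            float(dist), side))
    return assignments


def assign_probes_bruteforce(probes, repeats,
                             max_distance_bp: int) -> list:
    """O(n*m) reference implementation of assign_probes (oracle)."""
    if not repeats:
        raise ValueError("repeat list is empty")
    ordered = sorted(repeats, key=lambda r: (r.interval.chrom,
                                             r.interval.start, r.copy_id))
    assignments = []
    for probe in sorted(probes, key=lambda p: p.probe_id):
        if not probe.single_copy:
            continue
        mid = probe.midpoint
        best = None  # (distance, order_key, repeat, side)
        for order, rep in enumerate(ordered):
            if rep.interval.chrom != probe.interval.chrom:
                continue
            if rep.interval.start <= mid < rep.interval.end:
                dist, side = 0.0, SIDE_INTERNAL
                key = (dist, 0, order)
            elif mid >= rep.interval.end:
                dist, side = mid - rep.interval.end, SIDE_3P
                key = (dist, 1, order)
            else:
                dist, side = rep.interval.start - mid, SIDE_5P
                key = (dist, 1, order)
            if best is None or key < best[0]:
                best = (key, rep, dist, side)
        if best is None:
            continue
        _, rep, dist, side = best
        if side != SIDE_INTERNAL and dist > max_distance_bp:
            continue
        assignments.append(ProbeAssignment(
            probe.probe_id, rep.copy_id, rep.family_id, float(dist), side))
    return assignments


def _replicate_means(probes, mark, genotype, tissue) -> dict:
    means = {}
    for p in probes:
        key = (mark, genotype, tissue)
        if key in p.signals and p.signals[key]:
            means[p.probe_id] = float(np.mean(p.signals[key]))
    return means


def family_profile(assignments, probes, family_id: str, mark: str,
                   genotype: str, tissue: str,
                   profile_window_bp: int = DEFAULT_WINDOW_BP,
                   bin_width_bp: int = DEFAULT_BIN_BP) -> FlankBinProfile:
    """Binned mean profile for one family: arithmetic mean over
    replicate-averaged probe values per bin, 5' and 3' flanks pooled.
    """
    fam_assignments = [a for a in assignments if a.family_id == family_id]
    if not fam_assignments:
        raise ValueError(f"unknown family {family_id!r} (no assignments)")
    probe_means = _replicate_means(probes, mark, genotype, tissue)
    n_bins = profile_window_bp // bin_width_bp
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for a in fam_assignments:
        if a.side == SIDE_INTERNAL:
            continue
        if a.distance_bp >= profile_window_bp:
            continue
        if a.probe_id not in probe_means:
            continue
        k = bin_index(a.distance_bp, bin_width_bp)
        sums[k - 1] += probe_means[a.probe_id]
        counts[k - 1] += 1
    bin_means = []
    for k in range(1, n_bins + 1):
        mean = sums[k - 1] / counts[k - 1] if counts[k - 1] else math.nan
        bin_means.append((k, mean, int(counts[k - 1])))
    return FlankBinProfile(family_id=family_id, mark=mark, genotype=genotype,
                           tissue=tissue, bin_means=bin_means,
                           bin_width_bp=bin_width_bp,
                           max_distance_bp=profile_window_bp)


def assigned_probe_counts(assignments, profile_window_bp: int =
                          DEFAULT_WINDOW_BP) -> dict:
    """Number of non-internal assigned probes within the window, per
    family."""
    counts = {}
    for a in assignments:
        if a.side == SIDE_INTERNAL or a.distance_bp >= profile_window_bp:
            continue
        counts[a.family_id] = counts.get(a.family_id, 0) + 1
    return counts


def profile_matrix(assignments, probes, marks, samples,
                   min_probes: int = DEFAULT_MIN_PROBES,
                   profile_window_bp: int = DEFAULT_WINDOW_BP,
                   bin_width_bp: int = DEFAULT_BIN_BP) -> list:
    """Profiles for every family with >= min_probes assigned flank probes
    within the window, for each mark and (genotype, tissue) sample.
    """
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    counts = assigned_probe_counts(assignments, profile_window_bp)
    eligible = sorted(f for f, n in counts.items() if n >= min_probes)
    n_bins = profile_window_bp // bin_width_bp

    # group assignments once: family -> [(probe_id, bin)]
    per_family = {}
    for a in assignments:
        if a.side == SIDE_INTERNAL or a.distance_bp >= profile_window_bp:
            continue
        if a.family_id not in counts or counts[a.family_id] < min_probes:
            continue
        per_family.setdefault(a.family_id, []).append(
            (a.probe_id, bin_index(a.distance_bp, bin_width_bp)))

    profiles = []
    for mark in marks:
        for genotype, tissue in samples:
            probe_means = _replicate_means(probes, mark, genotype, tissue)
            for family_id in eligible:
                sums = np.zeros(n_bins)
                bin_counts = np.zeros(n_bins, dtype=int)
                for probe_id, k in per_family.get(family_id, ()):
                    if probe_id not in probe_means:
                        continue
                    sums[k - 1] += probe_means[probe_id]
                    bin_counts[k - 1] += 1
                bin_means = [
                    (k, sums[k - 1] / bin_counts[k - 1]
                     if bin_counts[k - 1] else math.nan,
                     int(bin_counts[k - 1]))
                    for k in range(1, n_bins + 1)
                ]
                profiles.append(FlankBinProfile(
                    family_id=family_id, mark=mark, genotype=genotype,
                    tissue=tissue, bin_means=bin_means,
                    bin_width_bp=bin_width_bp,
                    max_distance_bp=profile_window_bp))
    profiles.sort(key=lambda p: (p.family_id, p.mark, p.genotype, p.tissue))
    return profiles


def profiles_to_frame(profiles):
    """Tidy table of profiles for TSV export."""
    import pandas as pd

    rows = []
    for prof in profiles:
        for k, mean, count in prof.bin_means:
            rows.append({
                "family_id": prof.family_id,
                "mark": prof.mark,
                "genotype": prof.genotype,
                "tissue": prof.tissue,
                "bin_index": k,
                "bin_start_bp": (k - 1) * prof.bin_width_bp,
                "bin_end_bp": k * prof.bin_width_bp,
                "mean_log_ratio": mean,
                "probe_count": count,
            })
    return pd.DataFrame(rows)
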