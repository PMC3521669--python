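"""Per-gene RPKM, distance to the closest upstream TE, and expression
comparisons across spreading classes within distance strata.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import ranksum

from . import CLASS_NONE

DEFAULT_CUTOFFS = (500, 1000, 2500, 5000)
NO_TE = "no_te"


@dataclass
class GeneExpression:
    gene_id: str
    counts: dict    # sample -> count
    rpkm_values: dict  # sample -> rpkm

    def rpkm_for(self, sample: str) -> float:
        return self.rpkm_values[sample]

    def expressed(self, sample: str) -> bool:
        return self.rpkm_values[sample] > 0


@dataclass
class ProximityRecord:
    gene_id: str
    nearest_upstream_family: str | None
    distance_bp: float  # inf when no upstream TE on the chromosome
    nearest_copy_id: str | None = None

    def stratum(self, cutoffs=DEFAULT_CUTOFFS):
        for cutoff in sorted(cutoffs):
            if self.distance_bp <= cutoff:
                return cutoff
        return None


def rpkm(count: int, exon_length_bp: int, library_size: int) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if exon_length_bp <= 0:
        raise ValueError("exon_length_bp must be > 0")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return 1e9 * count / (exon_length_bp * library_size)


def gene_expression(genes, counts_df: pd.DataFrame,
                    library_sizes: dict) -> dict:
    """Per-gene RPKM for every sample; returns {gene_id: GeneExpression}."""
    exon_len = {g.gene_id: g.exon_length_bp for g in genes}
    out = {}
    for row in counts_df.itertuples(index=False):
        gene_id = str(row.gene_id)
        sample = str(row.sample)
        if gene_id not in exon_len:
            raise ValueError(f"count row references unknown gene "
                             f"{gene_id!r}")
        if sample not in library_sizes:
            raise ValueError(f"no library size for sample {sample!r}")
        expr = out.setdefault(gene_id,
                              GeneExpression(gene_id, {}, {}))
        expr.counts[sample] = int(row.count)
        expr.rpkm_values[sample] = rpkm(int(row.count), exon_len[gene_id],
                                        library_sizes[sample])
    return out


def nearest_upstream_te(gene, repeats_sorted=None, *, _index=None
                        ) -> ProximityRecord:
    """Closest repeat edge 5' of the TSS (gene-strand-relative).

    A TSS inside a repeat gets distance 0.  With no upstream repeat on the
    chromosome the distance is +inf.
    """
    if gene.interval.strand not in ("+", "-"):
        raise ValueError(f"gene {gene.gene_id} has no strand")
    index = _index if _index is not None else build_repeat_index(
        repeats_sorted)
    chrom = gene.interval.chrom
    tss = gene.tss
    entry = index.get(chrom)
    if entry is None:
        return ProximityRecord(gene.gene_id, None, math.inf)
    starts, ends, reps, cummax_ends, cummax_reps = entry

    # containment: any repeat spanning the TSS gives distance 0
    i = bisect.bisect_right(starts, tss)
    if i > 0 and cummax_ends[i - 1] > tss:
        for r in reps[:i]:
            if r.interval.start <= tss < r.interval.end:
                return ProximityRecord(gene.gene_id, r.family_id, 0.0,
                                       r.copy_id)

    if gene.interval.strand == "+":
        # upstream = left: nearest repeat end <= tss
        if i == 0:
            return ProximityRecord(gene.gene_id, None, math.inf)
        best = cummax_reps[i - 1]
        return ProximityRecord(gene.gene_id, best.family_id,
                               float(tss - cummax_ends[i - 1]),
                               best.copy_id)
    # upstream = right: nearest repeat start >= tss
    j = bisect.bisect_left(starts, tss)
    if j >= len(starts):
        return ProximityRecord(gene.gene_id, None, math.inf)
    best = reps[j]
    return ProximityRecord(gene.gene_id, best.family_id,
                           float(starts[j] - tss), best.copy_id)


def build_repeat_index(repeats) -> dict:
    """Per-chromosome sorted arrays used by nearest_upstream_te."""
    by_chrom = {}
    for rep in sorted(repeats, key=lambda r: (r.interval.chrom,
                                              r.interval.start, r.copy_id)):
        by_chrom.setdefault(rep.interval.chrom, []).append(rep)
    index = {}
    for chrom, reps in by_chrom.items():
        starts = [r.interval.start for r in reps]
        ends = [r.interval.end for r in reps]
        cummax_ends = []
        cummax_reps = []
        best_end = -1
        best_rep = None
        for r, e in zip(reps, ends):
            if e > best_end:
                best_end, best_rep = e, r
            cummax_ends.append(best_end)
            cummax_reps.append(best_rep)
        index[chrom] = (starts, ends, reps, cummax_ends, cummax_reps)
    return index


def proximity_records(genes, repeats) -> dict:
    index = build_repeat_index(repeats)
    return {g.gene_id: nearest_upstream_te(g, _index=index) for g in genes}


def _class_of(record: ProximityRecord, classes: dict):
    if record.nearest_upstream_family is None:
        return None
    return classes.get(record.nearest_upstream_family)


def stratified_comparison(proximity: dict, expression: dict, classes: dict,
                          sample: str, cutoffs=DEFAULT_CUTOFFS,
                          exclude_zeros: bool = False,
                          nested: bool = True) -> pd.DataFrame:
    """Mean RPKM and rank-sum tests per (cutoff stratum x class).

    Nested mode (default): a gene at 400 bp enters every cutoff analysis
    with cutoff >= its distance.  Disjoint mode restricts each cutoff to
    distances above the previous cutoff.  Within each stratum, each
    spreading class is tested two-sided against the non-spreading class
    and against genes with no TE within the cutoff.
    """
    cutoffs = sorted(cutoffs)
    rows = []
    for ci, cutoff in enumerate(cutoffs):
        lower = 0 if nested or ci == 0 else cutoffs[ci - 1]
        groups = {}
        no_te_values = []
        for gene_id, record in proximity.items():
            if gene_id not in expression:
                continue
            value = expression[gene_id].rpkm_for(sample)
            if exclude_zeros and value == 0:
                continue
            if record.distance_bp <= cutoff:
                if not nested and record.distance_bp <= lower and ci > 0:
                    continue
                cls = _class_of(record, classes)
                if cls is None:
                    continue
                groups.setdefault(cls, []).append(value)
            else:
                no_te_values.append(value)
        non_spreading = groups.get(CLASS_NONE, [])
        for cls, values in sorted(groups.items()):
            p_vs_non = _ranksum_or_nan(values, non_spreading,
                                       skip_self=(cls == CLASS_NONE))
            p_vs_no_te = _ranksum_or_nan(values, no_te_values)
            rows.append({
                "cutoff_bp": cutoff, "class": cls, "n_genes": len(values),
                "mean_rpkm": float(np.mean(values)) if values else math.nan,
                "p_vs_nonspreading": p_vs_non,
                "p_vs_no_te": p_vs_no_te,
            })
        rows.append({
            "cutoff_bp": cutoff, "class": NO_TE,
            "n_genes": len(no_te_values),
            "mean_rpkm": (float(np.mean(no_te_values))
                          if no_te_values else math.nan),
            "p_vs_nonspreading": math.nan, "p_vs_no_te": math.nan,
        })
    return pd.DataFrame(rows)


def _ranksum_or_nan(a, b, skip_self: bool = False) -> float:
    if skip_self or len(a) < 2 or len(b) < 2:
        return math.nan
    res = ranksum(a, b)
    return float(res.pvalue)


def proportion_expressed(proximity: dict, expression: dict, classes: dict,
                         sample: str,
                         cutoffs=DEFAULT_CUTOFFS) -> pd.DataFrame:
    """Fraction of genes with RPKM > 0 per (cutoff stratum x class)."""
    rows = []
    for cutoff in sorted(cutoffs):
        groups = {}
        no_te = []
        for gene_id, record in proximity.items():
            if gene_id not in expression:
                continue
            expressed = expression[gene_id].expressed(sample)
            if record.distance_bp <= cutoff:
                cls = _class_of(record, classes)
                if cls is None:
                    continue
                groups.setdefault(cls, []).append(expressed)
            else:
                no_te.append(expressed)
        for cls, flags in sorted(groups.items()) + [(NO_TE, no_te)]:
            rows.append({
                "cutoff_bp": cutoff, "class": cls, "n_genes": len(flags),
                "n_expressed": int(sum(flags)),
                "proportion_expressed": (sum(flags) / len(flags)
                                         if flags else math.nan),
            })
    return pd.DataFrame(rows)
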