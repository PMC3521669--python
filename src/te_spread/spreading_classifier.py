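"""Permutation-based classification of TE families as spreading or not.

A pool of randomly placed zero-length pseudo-insertions provides the null
distribution: probes around each pseudo-site are binned exactly like probes
around real repeats (both pseudo-flanks collapsed).  Per family and 200 bp
bin, the observed mean enrichment is compared against B resampled null means
of matched family size, giving an add-one empirical p-value.  Families with
p < alpha in every bin up through the required distance for both 5mC and
H3K9me2 are called spreading (both); H3K9me2 alone gives spreading (H3K9).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import CLASS_BOTH, CLASS_H3K9, CLASS_NONE, CLASS_UNCLASSIFIABLE, \
    MARK_5MC, MARK_H3K9
from .flank_profiler import DEFAULT_BIN_BP, DEFAULT_WINDOW_BP

DEFAULT_N_SITES = 10_000
DEFAULT_B = 10_000
DEFAULT_ALPHA = 0.001
DEFAULT_REQUIRED_BINS = 4  # 4 x 200 bp = 800 bp


@dataclass
class NullSiteSet:
    """Randomly assigned pseudo-insertions with pre-binned probe values.

    ``bin_means[key]`` and ``bin_counts[key]`` are (n_sites, n_bins) arrays
    for key = (mark, genotype, tissue); ``pooled_values[key][k]`` holds the
    probe-level values contributing to bin k+1 across all sites.
    """

    sites: list  # [(chrom, position), ...]
    n_sites: int
    seed: int
    bin_width_bp: int
    window_bp: int
    bin_means: dict = field(default_factory=dict)
    bin_counts: dict = field(default_factory=dict)
    pooled_values: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.window_bp // self.bin_width_bp


@dataclass
class BinTestResult:
    family_id: str
    mark: str
    bin_index: int
    observed_mean: float
    null_means: np.ndarray
    p_empirical: float


@dataclass
class SpreadingClassification:
    family_id: str
    class_label: str
    alpha: float
    required_bins: int
    p_values: dict  # mark -> list of p (bins 1..n), NaN where undefined


def generate_null_sites(probes, repeats, n_sites: int = DEFAULT_N_SITES,
                        seed: int = 0,
                        window_bp: int = DEFAULT_WINDOW_BP,
                        bin_width_bp: int = DEFAULT_BIN_BP,
                        sample_keys=None) -> NullSiteSet:
    """Draw ``n_sites`` pseudo-insertion points uniformly from the union of
    probe-bearing chromosome spans and bin surrounding probe values.

    ``sample_keys`` restricts binning to the given (mark, genotype, tissue)
    keys; by default every key present on any probe is binned.
    """
    if n_sites < 100:
        raise ValueError("n_sites must be >= 100")
    single = [p for p in probes if p.single_copy]
    if not single:
        raise ValueError("probe-bearing chromosome space is empty")

    by_chrom = {}
    for p in single:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    chroms = sorted(by_chrom)
    spans = {}
    for chrom in chroms:
        mids = np.array(sorted(pp.midpoint for pp in by_chrom[chrom]))
        spans[chrom] = (mids[0], mids[-1])

    if sample_keys is None:
        keys = set()
        for p in single:
            keys.update(p.signals.keys())
        sample_keys = sorted(keys)

    # per chromosome: sorted midpoints + replicate-mean value per key
    chrom_mids = {}
    chrom_vals = {}
    for chrom in chroms:
        plist = sorted(by_chrom[chrom], key=lambda p: p.midpoint)
        mids = np.array([p.midpoint for p in plist])
        chrom_mids[chrom] = mids
        vals = {}
        for key in sample_keys:
            vals[key] = np.array(
                [np.mean(p.signals[key]) if key in p.signals else np.nan
                 for p in plist])
        chrom_vals[chrom] = vals

    rng = np.random.default_rng(seed)
    lengths = np.array([spans[c][1] - spans[c][0] for c in chroms])
    if lengths.sum() <= 0:
        raise ValueError("probe-bearing chromosome space has zero length")
    chrom_draws = rng.choice(len(chroms), size=n_sites,
                             p=lengths / lengths.sum())
    offsets = rng.uniform(0.0, 1.0, size=n_sites)

    n_bins = window_bp // bin_width_bp
    bin_means = {key: np.zeros((n_sites, n_bins)) for key in sample_keys}
    bin_counts = {key: np.zeros((n_sites, n_bins), dtype=np.int64)
                  for key in sample_keys}
    pooled = {key: [[] for _ in range(n_bins)] for key in sample_keys}

    sites = []
    for i in range(n_sites):
        chrom = chroms[int(chrom_draws[i])]
        lo, hi = spans[chrom]
        pos = lo + offsets[i] * (hi - lo)
        sites.append((chrom, float(pos)))
        mids = chrom_mids[chrom]
        left = np.searchsorted(mids, pos - window_bp, side="right")
        right = np.searchsorted(mids, pos + window_bp, side="left")
        if right <= left:
            continue
        dist = np.abs(mids[left:right] - pos)
        in_window = dist < window_bp
        bins = (dist[in_window] // bin_width_bp).astype(np.int64)
        for key in sample_keys:
            vals = chrom_vals[chrom][key][left:right][in_window]
            ok = ~np.isnan(vals)
            if not ok.any():
                continue
            b = bins[ok]
            v = vals[ok]
            np.add.at(bin_means[key][i], b, v)
            np.add.at(bin_counts[key][i], b, 1)
            for bb, vv in zip(b, v):
                pooled[key][bb].append(vv)

    for key in sample_keys:
        counts = bin_counts[key]
        with np.errstate(invalid="ignore"):
            bin_means[key] = np.where(counts > 0,
                                      bin_means[key] / np.maximum(counts, 1),
                                      0.0)
    pooled_values = {key: [np.array(v) for v in pooled[key]]
                     for key in sample_keys}
    return NullSiteSet(sites=sites, n_sites=n_sites, seed=seed,
                       bin_width_bp=bin_width_bp, window_bp=window_bp,
                       bin_means=bin_means, bin_counts=bin_counts,
                       pooled_values=pooled_values)


def empirical_p(observed_mean: float, null_means) -> float:
    """Add-one one-sided empirical p-value:
    (1 + #{null >= observed}) / (B + 1)."""
    null_means = np.asarray(null_means, dtype=float)
    if null_means.size == 0:
        raise ValueError("null_means must be non-empty")
    return float((1 + np.sum(null_means >= observed_mean))
                 / (null_means.size + 1))


def family_bin_null(null: NullSiteSet, sample_key, family_size: int,
                    bin_index: int, B: int, seed) -> np.ndarray:
    """B replicate null means: probe-count-weighted means of bin values
    from ``family_size`` pseudo-sites sampled with replacement."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    if B < 1000:
        raise ValueError("B must be >= 1000")
    counts = null.bin_counts[sample_key][:, bin_index - 1].astype(float)
    means = null.bin_means[sample_key][:, bin_index - 1]
    if counts.sum() == 0:
        raise ValueError(
            f"bin {bin_index} has zero probes across all pseudo-sites")
    weighted = means * counts
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, null.n_sites, size=(B, family_size))
    den = counts[idx].sum(axis=1)
    num = weighted[idx].sum(axis=1)
    bad = den == 0
    while bad.any():
        idx2 = rng.integers(0, null.n_sites,
                            size=(int(bad.sum()), family_size))
        den[bad] = counts[idx2].sum(axis=1)
        num[bad] = weighted[idx2].sum(axis=1)
        bad = den == 0
    return num / den


def classify_family(p_meth, p_h3k9, alpha: float = DEFAULT_ALPHA,
                    required_bins: int = DEFAULT_REQUIRED_BINS,
                    family_id: str = "", p_values=None
                    ) -> SpreadingClassification:
    """Apply the spreading rule to per-bin p-values (strict p < alpha in
    every bin 1..required_bins).
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if len(p_meth) < required_bins or len(p_h3k9) < required_bins:
        raise ValueError(
            f"p-value lists must cover bins 1..{required_bins}")
    meth_head = list(p_meth[:required_bins])
    h3k9_head = list(p_h3k9[:required_bins])
    if any(p is None or (isinstance(p, float) and math.isnan(p))
           for p in meth_head + h3k9_head):
        label = CLASS_UNCLASSIFIABLE
    else:
        meth_pass = all(p < alpha for p in meth_head)
        h3k9_pass = all(p < alpha for p in h3k9_head)
        if meth_pass and h3k9_pass:
            label = CLASS_BOTH
        elif h3k9_pass:
            label = CLASS_H3K9
        else:
            label = CLASS_NONE
    if p_values is None:
        p_values = {MARK_5MC: list(p_meth), MARK_H3K9: list(p_h3k9)}
    return SpreadingClassification(family_id=family_id, class_label=label,
                                   alpha=alpha,
                                   required_bins=required_bins,
                                   p_values=p_values)


def _ranksum_p(observed_values, pooled_null_values) -> float:
    """One-sided (enrichment) Mann-Whitney of family probe values against
    the pooled null probe values for the same bin."""
    if len(observed_values) == 0 or len(pooled_null_values) == 0:
        return math.nan
    res = stats.mannwhitneyu(observed_values, pooled_null_values,
                             alternative="greater")
    return float(res.pvalue)


def classify_all(profiles, null: NullSiteSet, family_sizes: dict,
                 alpha: float = DEFAULT_ALPHA,
                 required_bins: int = DEFAULT_REQUIRED_BINS,
                 B: int = DEFAULT_B, seed: int = 0,
                 genotype: str | None = None, tissue: str | None = None,
                 method: str = "mean",
                 assignments=None, probes=None) -> list:
    """Classify every profiled family.

    ``profiles`` must include 5mC and H3K9me2 profiles for the
    classification sample; p-values for any further profiled marks (e.g.
    H3K27me3) are computed and reported but never drive the class.

    method="mean" (default) tests the family bin mean against resampled
    matched-size null means; method="ranksum" runs a probe-level
    Mann-Whitney against the pooled null probe values (requires
    ``assignments`` and ``probes``).
    """
    if method not in ("mean", "ranksum"):
        raise ValueError(f"unknown method {method!r}")
    by_family = {}
    for prof in profiles:
        if genotype is not None and prof.genotype != genotype:
            continue
        if tissue is not None and prof.tissue != tissue:
            continue
        by_family.setdefault(prof.family_id, {})[prof.mark] = prof

    if method == "ranksum":
        if assignments is None or probes is None:
            raise ValueError("ranksum method needs assignments and probes")
        fam_bin_values = _family_bin_values(assignments, probes, null)

    mark_order = {}

    def _mark_idx(mark):
        return mark_order.setdefault(mark, len(mark_order))

    results = []
    for fam_idx, family_id in enumerate(sorted(by_family)):
        fam_profiles = by_family[family_id]
        family_size = int(family_sizes.get(family_id, 0))
        p_values = {}
        for mark in sorted(fam_profiles):
            prof = fam_profiles[mark]
            key = (mark, prof.genotype, prof.tissue)
            n_bins = len(prof.bin_means)
            ps = []
            for k in range(1, n_bins + 1):
                observed = prof.mean_for_bin(k)
                if math.isnan(observed) or family_size < 1 \
                        or key not in null.bin_means:
                    ps.append(math.nan)
                    continue
                if method == "mean":
                    try:
                        nm = family_bin_null(
                            null, key, family_size, k, B,
                            seed=(seed, fam_idx, _mark_idx(mark), k))
                    except ValueError:
                        ps.append(math.nan)
                        continue
                    ps.append(empirical_p(observed, nm))
                else:
                    obs_vals = fam_bin_values.get(
                        (family_id, key, k), np.array([]))
                    ps.append(_ranksum_p(obs_vals,
                                         null.pooled_values[key][k - 1]))
            p_values[mark] = ps
        p_meth = p_values.get(MARK_5MC, [math.nan] * required_bins)
        p_h3k9 = p_values.get(MARK_H3K9, [math.nan] * required_bins)
        results.append(classify_family(p_meth, p_h3k9, alpha, required_bins,
                                       family_id=family_id,
                                       p_values=p_values))
    return results


def _family_bin_values(assignments, probes, null: NullSiteSet) -> dict:
    """Probe-level replicate-mean values per (family, sample key, bin)."""
    from .flank_profiler import SIDE_INTERNAL, bin_index as _bin

    probe_by_id = {p.probe_id: p for p in probes}
    out = {}
    for a in assignments:
        if a.side == SIDE_INTERNAL or a.distance_bp >= null.window_bp:
            continue
        probe = probe_by_id.get(a.probe_id)
        if probe is None:
            continue
        k = _bin(a.distance_bp, null.bin_width_bp)
        for key, values in probe.signals.items():
            out.setdefault((a.family_id, key, k), []).append(
                float(np.mean(values)))
    return {k: np.array(v) for k, v in out.items()}


def classifications_to_frame(classifications, required_bins: int =
                             DEFAULT_REQUIRED_BINS):
    import pandas as pd

    rows = []
    for c in classifications:
        row = {"family_id": c.family_id, "class": c.class_label}
        for mark, ps in sorted(c.p_values.items()):
            for k in range(1, required_bins + 1):
                p = ps[k - 1] if k - 1 < len(ps) else math.nan
                row[f"p_{mark}_bin{k}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
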