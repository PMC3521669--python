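"""Ground-truth synthetic dataset generator.

Emits a self-consistent toy bundle — genome, TE annotation with known
spreading classes, tiling probes with replicate log-ratio signals for two
haplotypes, a per-cytosine bisulfite report, query-haplotype reads spanning
empty junctions, gene models with expression counts, small RNAs and family
attributes — so that every pipeline stage can be tested offline against
truth.

Signal model: the replicate log-ratio of mark m at a probe at distance d
from the nearest TE of family f is  A_{f,m} * exp(-d / lambda_{f,m}) plus
Gaussian noise; flank cytosine methylation probabilities are raised by the
same decay through a logistic link; haplotype 2 lacks each polymorphic copy
and its reads therefore produce supporting overhangs at empty junctions and
contiguous junction-covering alignments at occupied ones.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import CLASS_BOTH, CLASS_H3K9, CLASS_NONE, MARK_5MC, MARK_H3K9, \
    MARK_H3K27
from .formats_io import (
    GenomicInterval, RepeatAnnotation, ProbeSignal, GeneModel,
    ReadAlignment, write_fasta, write_repeats_bed, write_probes_tsv,
    write_signals_tsv, write_alignments_tsv,
    write_genes_gff3, write_bed_intervals, CytosineRecord,
)

GENOTYPE_WITH = "hap1"     # carries every annotated insertion
GENOTYPE_WITHOUT = "hap2"  # lacks the polymorphic copies
TISSUE = "leaf"
MARKS = (MARK_5MC, MARK_H3K9, MARK_H3K27)

SPREADING_TRUE = (CLASS_BOTH, CLASS_H3K9)


@dataclass
class FamilyConfig:
    family_id: str
    superfamily: str = "RLG"
    copy_number: int = 12
    element_length_bp: int = 1000
    true_class: str = CLASS_NONE
    effect_a_meth: float = 0.0
    effect_a_h3k9: float = 0.0
    lambda_bp: float = 600.0
    lambda_meth_bp: float | None = None   # defaults to lambda_bp
    internal_meth: dict = field(default_factory=lambda: {
        "CG": 0.9, "CHG": 0.8, "CHH": 0.1})
    polymorphism_rate: float = 0.0

    @property
    def meth_lambda(self) -> float:
        return self.lambda_meth_bp if self.lambda_meth_bp is not None \
            else self.lambda_bp


@dataclass
class ProbeConfig:
    spacing_bp: int = 200
    length_bp: int = 50
    noise_sd: float = 0.25
    replicates: int = 3


@dataclass
class BisulfiteConfig:
    coverage_mean: float = 7.0
    baseline: dict = field(default_factory=lambda: {
        "CG": 0.75, "CHG": 0.55, "CHH": 0.05})
    logit_scale: float = 4.0
    site_fraction: float = 1.0


@dataclass
class ReadsConfig:
    length_bp: int = 400
    coverage: float = 5.0
    error_rate: float = 0.0


@dataclass
class GenesConfig:
    n_genes: int = 120
    frac_no_te: float = 0.2
    gene_length_bp: int = 600
    exon_length_bp: int = 200         # two exons of this length
    distance_buckets: tuple = ((30, 450), (600, 950), (1200, 2300),
                               (2700, 4500))
    bucket_weights: tuple = (0.4, 0.2, 0.2, 0.2)
    mean_rpkm: float = 10.0
    sigma_log: float = 0.6
    suppression_factor: float = 0.2
    suppress_within_bp: float = 500.0
    silencing_prob_near: float = 0.0
    silencing_prob_base: float = 0.0
    library_size: int = 2_000_000
    sample: str = "hap1_leaf"


@dataclass
class SyntheticConfig:
    chromosomes: dict = field(default_factory=lambda: {
        "chr1": 300_000, "chr2": 300_000})
    families: list = field(default_factory=list)
    probes: ProbeConfig = field(default_factory=ProbeConfig)
    bisulfite: BisulfiteConfig = field(default_factory=BisulfiteConfig)
    reads: ReadsConfig = field(default_factory=ReadsConfig)
    genes: GenesConfig = field(default_factory=GenesConfig)
    gap_bp: int = 3000        # minimum spacing between placed elements
    reserve_bp: int = 40_000  # TE-free tail per chromosome (far genes)
    insertion_date_by_class: dict = field(default_factory=lambda: {
        CLASS_BOTH: 0.5, CLASS_H3K9: 1.0, CLASS_NONE: 2.5})
    smallrna_mean_per_copy: float = 2.0
    smallrna_length_bp: int = 24
    seed: int = 0

    def validate(self):
        if not self.families:
            raise ValueError("config needs at least one family")
        for fam in self.families:
            if not (0 <= fam.polymorphism_rate <= 1):
                raise ValueError("polymorphism_rate must be in [0, 1]")
            if fam.lambda_bp <= 0:
                raise ValueError("lambda_bp must be > 0")
            for p in fam.internal_meth.values():
                if not (0 <= p <= 1):
                    raise ValueError("internal_meth must be in [0, 1]")
        if self.probes.spacing_bp <= 0:
            raise ValueError("probe spacing must be > 0")


def default_families() -> list:
    fams = []
    for i in range(2):
        fams.append(FamilyConfig(
            family_id=f"famB{i}", superfamily="RLG", copy_number=24,
            true_class=CLASS_BOTH, effect_a_meth=0.8, effect_a_h3k9=0.8,
            lambda_bp=600.0, polymorphism_rate=0.4))
    fams.append(FamilyConfig(
        family_id="famK0", superfamily="RLC", true_class=CLASS_H3K9,
        copy_number=24, effect_a_meth=0.8, effect_a_h3k9=0.8,
        lambda_bp=600.0, lambda_meth_bp=120.0, polymorphism_rate=0.4))
    for i in range(5):
        sf = ["RLG", "RLC", "RLX", "LINE", "RLG"][i]
        fams.append(FamilyConfig(
            family_id=f"famN{i}", superfamily=sf, copy_number=24,
            true_class=CLASS_NONE,
            internal_meth={"CG": 0.9, "CHG": 0.8, "CHH": 0.25},
            polymorphism_rate=0.2))
    return fams


def default_config(seed: int = 0) -> SyntheticConfig:
    return SyntheticConfig(
        chromosomes={"chr1": 700_000, "chr2": 700_000},
        families=default_families(), seed=seed)


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    genome: dict
    repeats: list
    probes: list
    cytosines: pd.DataFrame
    alignments: list
    genes: list
    counts: pd.DataFrame
    library_sizes: dict
    smallrna: list
    attributes: pd.DataFrame
    truth: dict

    def cytosine_records(self) -> list:
        return [CytosineRecord(r.chrom, int(r.position), r.strand,
                               r.context, int(r.meth_count),
                               int(r.total_count))
                for r in self.cytosines.itertuples(index=False)]


ALL_STAGES = ("genome", "repeats", "probes", "bisulfite", "reads", "genes",
              "smallrna", "attributes")


def simulate(config: SyntheticConfig, outdir=None,
             stages=ALL_STAGES) -> SyntheticBundle:
    """Generate the bundle; deterministic for a given config + seed.

    ``stages`` trims expensive parts (e.g. omit "bisulfite" when only
    probe signals are needed).  Files are written when ``outdir`` is given.
    """
    config.validate()
    stages = set(stages)
    root = np.random.SeedSequence(config.seed)
    seeds = {name: np.random.default_rng(child) for name, child in
             zip(("placement", "genome", "signals", "bisulfite", "reads",
                  "genes", "smallrna", "attributes"),
                 root.spawn(8))}

    repeats, truth_copies = _place_repeats(config, seeds["placement"])

    genome = {}
    if stages & {"genome", "bisulfite", "reads"}:
        genome = _random_genome(config, seeds["genome"])

    probes = []
    if "probes" in stages:
        probes = _make_probes(config, repeats, truth_copies,
                              seeds["signals"])

    cytosines = pd.DataFrame(
        columns=["chrom", "position", "strand", "context", "meth_count",
                 "total_count"])
    if "bisulfite" in stages:
        cytosines = _make_bisulfite(config, genome, repeats,
                                    seeds["bisulfite"])

    alignments = []
    if "reads" in stages:
        alignments = _make_reads(config, genome, repeats, truth_copies,
                                 seeds["reads"])

    genes, counts, library_sizes, truth_genes = [], pd.DataFrame(
        columns=["gene_id", "sample", "count"]), {}, {}
    if "genes" in stages:
        genes, counts, library_sizes, truth_genes = _make_genes(
            config, repeats, seeds["genes"])

    smallrna = []
    if "smallrna" in stages:
        smallrna = _make_smallrna(config, repeats, seeds["smallrna"])

    attributes = pd.DataFrame()
    if "attributes" in stages:
        attributes = _make_attributes(config, repeats, seeds["attributes"])

    truth = {
        "seed": config.seed,
        "families": {
            fam.family_id: {
                "true_class": fam.true_class,
                "effect_a_meth": fam.effect_a_meth,
                "effect_a_h3k9": fam.effect_a_h3k9,
                "lambda_bp": fam.lambda_bp,
                "lambda_meth_bp": fam.meth_lambda,
                "polymorphism_rate": fam.polymorphism_rate,
                "copy_number": fam.copy_number,
                "superfamily": fam.superfamily,
            } for fam in config.families
        },
        "copies": truth_copies,
        "genes": truth_genes,
    }
    bundle = SyntheticBundle(
        config=config, genome=genome, repeats=repeats, probes=probes,
        cytosines=cytosines, alignments=alignments, genes=genes,
        counts=counts, library_sizes=library_sizes, smallrna=smallrna,
        attributes=attributes, truth=truth)
    if outdir is not None:
        _write_bundle(bundle, Path(outdir), stages)
    return bundle


# ---------------------------------------------------------------------------
# placement and genome
# ---------------------------------------------------------------------------

def _place_repeats(config, rng):
    chroms = sorted(config.chromosomes)
    max_elem = max(f.element_length_bp for f in config.families)
    slot_bp = max_elem + config.gap_bp
    slots = []
    for chrom in chroms:
        usable = config.chromosomes[chrom] - config.reserve_bp
        if usable < slot_bp:
            raise ValueError(f"chromosome {chrom} too short for one slot")
        for k in range(usable // slot_bp):
            slots.append((chrom, k * slot_bp))
    total_copies = sum(f.copy_number for f in config.families)
    if total_copies > len(slots):
        raise ValueError(
            f"cannot place {total_copies} copies into {len(slots)} slots; "
            "enlarge the genome or reduce copy numbers")
    order = rng.permutation(len(slots))[:total_copies]

    repeats = []
    truth_copies = {}
    i = 0
    for fam in config.families:
        for c in range(fam.copy_number):
            chrom, slot_start = slots[order[i]]
            i += 1
            jitter_max = slot_bp - fam.element_length_bp - 200
            start = slot_start + int(rng.integers(100, max(jitter_max, 101)))
            end = start + fam.element_length_bp
            copy_id = f"{fam.family_id}_c{c}"
            repeats.append(RepeatAnnotation(
                GenomicInterval(chrom, start, end, "+"), fam.family_id,
                fam.superfamily, copy_id))
            present = bool(rng.uniform() >= fam.polymorphism_rate)
            truth_copies[copy_id] = {
                "family_id": fam.family_id, "chrom": chrom,
                "start": start, "end": end, "present_hap2": present,
            }
    repeats.sort(key=lambda r: (r.interval.chrom, r.interval.start,
                                r.copy_id))
    return repeats, truth_copies


def _random_genome(config, rng) -> dict:
    bases = np.frombuffer(b"ACGT", dtype="S1")
    genome = {}
    for chrom in sorted(config.chromosomes):
        length = config.chromosomes[chrom]
        idx = rng.integers(0, 4, size=length)
        genome[chrom] = bases[idx].tobytes().decode()
    return genome


def _chrom_edges(repeats, chrom, exclude_absent=None):
    """Sorted start/end arrays of TEs on one chromosome; optionally drop
    copies absent from haplotype 2."""
    rows = [(r.interval.start, r.interval.end, r.family_id, r.copy_id)
            for r in repeats if r.interval.chrom == chrom
            and (exclude_absent is None or r.copy_id not in exclude_absent)]
    rows.sort()
    starts = np.array([s for s, _, _, _ in rows], dtype=float)
    ends = np.array([e for _, e, _, _ in rows], dtype=float)
    fams = [f for _, _, f, _ in rows]
    return starts, ends, fams


def _nearest_te(positions, starts, ends, fams):
    """Vectorized distance to the nearest TE edge (0 inside) and the index
    of that TE; positions/starts non-overlapping sorted."""
    n = positions.size
    dist = np.full(n, np.inf)
    fam_idx = np.full(n, -1, dtype=int)
    if starts.size == 0:
        return dist, fam_idx
    idx = np.searchsorted(starts, positions, side="right") - 1
    has_left = idx >= 0
    left_end = np.where(has_left, ends[np.maximum(idx, 0)], -np.inf)
    inside = has_left & (positions < left_end)
    left_dist = np.where(has_left, positions - left_end, np.inf)
    right = idx + 1
    has_right = right < starts.size
    right_dist = np.where(has_right,
                          starts[np.minimum(right, starts.size - 1)]
                          - positions, np.inf)
    use_left = left_dist <= right_dist
    dist = np.where(use_left, left_dist, right_dist)
    fam_idx = np.where(use_left, np.maximum(idx, 0),
                       np.minimum(right, starts.size - 1))
    dist = np.where(inside, 0.0, dist)
    fam_idx = np.where(inside, np.maximum(idx, 0), fam_idx)
    return dist, fam_idx


# ---------------------------------------------------------------------------
# probes and signals
# ---------------------------------------------------------------------------

def _make_probes(config, repeats, truth_copies, rng) -> list:
    fam_by_id = {f.family_id: f for f in config.families}
    absent = {cid for cid, t in truth_copies.items()
              if not t["present_hap2"]}
    pc = config.probes
    probes = []
    for chrom in sorted(config.chromosomes):
        length = config.chromosomes[chrom]
        starts_grid = np.arange(0, length - pc.length_bp + 1, pc.spacing_bp)
        mids = starts_grid + pc.length_bp / 2.0

        te1 = _chrom_edges(repeats, chrom)
        te2 = _chrom_edges(repeats, chrom, exclude_absent=absent)
        d1, f1 = _nearest_te(mids, *te1)
        d2, f2 = _nearest_te(mids, *te2)

        # single copy iff the footprint overlaps no annotated repeat
        s1, e1, _ = te1
        if s1.size:
            j = np.searchsorted(s1, starts_grid + pc.length_bp,
                                side="left") - 1
            overlap = (j >= 0) & (e1[np.maximum(j, 0)] > starts_grid)
        else:
            overlap = np.zeros(mids.size, dtype=bool)

        per_geno = {GENOTYPE_WITH: (d1, f1, te1[2]),
                    GENOTYPE_WITHOUT: (d2, f2, te2[2])}
        effects = {}
        for geno, (dist, fidx, fam_names) in per_geno.items():
            a_meth = np.zeros(mids.size)
            a_h3k9 = np.zeros(mids.size)
            for k in range(mids.size):
                if fidx[k] < 0 or not np.isfinite(dist[k]):
                    continue
                fam = fam_by_id[fam_names[fidx[k]]]
                a_meth[k] = fam.effect_a_meth * math.exp(
                    -dist[k] / fam.meth_lambda)
                a_h3k9[k] = fam.effect_a_h3k9 * math.exp(
                    -dist[k] / fam.lambda_bp)
            effects[geno] = {MARK_5MC: a_meth, MARK_H3K9: a_h3k9,
                             MARK_H3K27: np.zeros(mids.size)}

        noise = {}
        for geno in per_geno:
            for mark in MARKS:
                noise[(geno, mark)] = rng.normal(
                    0.0, pc.noise_sd, size=(mids.size, pc.replicates))

        for k in range(mids.size):
            start = int(starts_grid[k])
            probe = ProbeSignal(
                probe_id=f"{chrom}_p{start}",
                interval=GenomicInterval(chrom, start,
                                         start + pc.length_bp),
                single_copy=not bool(overlap[k]))
            for geno in per_geno:
                for mark in MARKS:
                    values = (effects[geno][mark][k]
                              + noise[(geno, mark)][k, :])
                    probe.signals[(mark, geno, TISSUE)] = \
                        [float(v) for v in values]
            probes.append(probe)
    return probes


# ---------------------------------------------------------------------------
# bisulfite report
# ---------------------------------------------------------------------------

def _make_bisulfite(config, genome, repeats, rng) -> pd.DataFrame:
    bc = config.bisulfite
    fam_by_id = {f.family_id: f for f in config.families}
    frames = []
    for chrom in sorted(config.chromosomes):
        seq = np.frombuffer(genome[chrom].encode(), dtype="S1")
        length = seq.size
        for strand in ("+", "-"):
            if strand == "+":
                pos = np.nonzero(seq[: length - 2] == b"C")[0]
                nxt = seq[pos + 1]
                nxt2 = seq[pos + 2]
                is_cg = nxt == b"G"
                is_chg = (~is_cg) & (nxt2 == b"G")
            else:
                pos = np.nonzero(seq == b"G")[0]
                pos = pos[pos >= 2]
                nxt = seq[pos - 1]    # complement G-next base
                nxt2 = seq[pos - 2]
                is_cg = nxt == b"C"
                is_chg = (~is_cg) & (nxt2 == b"C")
            context = np.where(is_cg, "CG", np.where(is_chg, "CHG", "CHH"))

            if bc.site_fraction < 1.0:
                keep = rng.uniform(size=pos.size) < bc.site_fraction
                pos, context = pos[keep], context[keep]

            starts, ends, fams = _chrom_edges(repeats, chrom)
            dist, fidx = _nearest_te(pos.astype(float), starts, ends, fams)
            inside = dist == 0.0

            p = np.empty(pos.size)
            base = np.array([bc.baseline[c] for c in context])
            bump = np.zeros(pos.size)
            for k in np.nonzero(np.isfinite(dist) & ~inside)[0]:
                fam = fam_by_id[fams[fidx[k]]]
                bump[k] = bc.logit_scale * fam.effect_a_meth * math.exp(
                    -dist[k] / fam.meth_lambda)
            p = expit(logit(np.clip(base, 1e-9, 1 - 1e-9)) + bump)
            for k in np.nonzero(inside)[0]:
                fam = fam_by_id[fams[fidx[k]]]
                p[k] = fam.internal_meth[str(context[k])]

            cov = rng.poisson(bc.coverage_mean, size=pos.size)
            covered = cov > 0
            meth = rng.binomial(cov[covered], p[covered])
            frames.append(pd.DataFrame({
                "chrom": chrom, "position": pos[covered],
                "strand": strand, "context": context[covered],
                "meth_count": meth, "total_count": cov[covered],
            }))
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["chrom", "position", "strand"],
                          ignore_index=True)


# ---------------------------------------------------------------------------
# haplotype-2 reads
# ---------------------------------------------------------------------------

def _make_reads(config, genome, repeats, truth_copies, rng) -> list:
    rc = config.reads
    absent = {cid for cid, t in truth_copies.items()
              if not t["present_hap2"]}
    alignments = []
    for chrom in sorted(config.chromosomes):
        length = config.chromosomes[chrom]
        gaps = sorted((truth_copies[cid]["start"], truth_copies[cid]["end"])
                      for cid in absent
                      if truth_copies[cid]["chrom"] == chrom)
        segments = []
        cursor = 0
        for s, e in gaps:
            if s > cursor:
                segments.append((cursor, s))
            cursor = e
        if cursor < length:
            segments.append((cursor, length))
        seg_lens = np.array([e - s for s, e in segments])
        cum = np.concatenate([[0], np.cumsum(seg_lens)])
        hap2_len = int(cum[-1])
        if hap2_len <= rc.length_bp:
            continue
        n_reads = int(round(rc.coverage * hap2_len / rc.length_bp))
        # stratified start placement: one read per stride with uniform
        # jitter, so local depth stays near the configured coverage
        stride = (hap2_len - rc.length_bp) / n_reads
        starts = (np.arange(n_reads) * stride
                  + rng.uniform(0, stride, size=n_reads)).astype(np.int64)
        starts.sort()
        for ridx, s in enumerate(starts):
            pieces = []   # (hap2_offset_in_read, ref_start, piece_len)
            remaining = rc.length_bp
            qoff = 0
            pos = int(s)
            seg_i = int(np.searchsorted(cum, pos, side="right")) - 1
            while remaining > 0 and seg_i < len(segments):
                seg_start, seg_end = segments[seg_i]
                within = pos - int(cum[seg_i])
                take = min(remaining, (seg_end - seg_start) - within)
                pieces.append((qoff, seg_start + within, take))
                qoff += take
                pos += take
                remaining -= take
                seg_i += 1
            best = max(pieces, key=lambda piece: piece[2])
            b_off, b_ref, b_len = best
            left = b_off
            right = rc.length_bp - b_off - b_len
            nm = int(rng.binomial(b_len, rc.error_rate)) \
                if rc.error_rate > 0 else 0
            identity = 100.0 * (b_len - nm) / b_len
            alignments.append(ReadAlignment(
                read_id=f"{chrom}_r{ridx}",
                query_length=rc.length_bp,
                interval=GenomicInterval(chrom, b_ref, b_ref + b_len, "+"),
                identity_pct=identity,
                left_unaligned=left,
                right_unaligned=right,
                unique=True))
    return alignments


def write_sam(alignments, chrom_lengths: dict, genome: dict, path) -> None:
    """Plain-text SAM with soft-clip CIGARs and NM tags."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom in sorted(chrom_lengths):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{chrom_lengths[chrom]}\n")
        for a in alignments:
            iv = a.interval
            alen = len(iv)
            cigar = ""
            if a.left_unaligned:
                cigar += f"{a.left_unaligned}S"
            cigar += f"{alen}M"
            if a.right_unaligned:
                cigar += f"{a.right_unaligned}S"
            if genome and iv.chrom in genome:
                core = genome[iv.chrom][iv.start:iv.end]
                seq = ("N" * a.left_unaligned) + core \
                    + ("N" * a.right_unaligned)
            else:
                seq = "*"
            nm = int(round(alen * (1 - a.identity_pct / 100.0)))
            fh.write(f"{a.read_id}\t0\t{iv.chrom}\t{iv.start + 1}\t60\t"
                     f"{cigar}\t*\t0\t0\t{seq}\t*\tNM:i:{nm}\n")


# ---------------------------------------------------------------------------
# genes and expression
# ---------------------------------------------------------------------------

def _make_genes(config, repeats, rng):
    from .expression_proximity import proximity_records

    gc = config.genes
    chroms = sorted(config.chromosomes)
    n_no_te = int(round(gc.n_genes * gc.frac_no_te))
    n_near = gc.n_genes - n_no_te

    genes = []
    copy_pool = list(repeats)
    rng.shuffle(copy_pool)
    buckets = list(gc.distance_buckets)
    weights = np.array(gc.bucket_weights, dtype=float)
    weights /= weights.sum()
    gi = 0
    for k in range(n_near):
        rep = copy_pool[k % len(copy_pool)]
        chrom_len = config.chromosomes[rep.interval.chrom]
        b = buckets[int(rng.choice(len(buckets), p=weights))]
        d = int(rng.integers(b[0], b[1] + 1))
        strand = "+" if rng.uniform() < 0.5 else "-"
        if strand == "+":
            tss = rep.interval.end + d
            start, end = tss, tss + gc.gene_length_bp
        else:
            tss = rep.interval.start - d
            start, end = tss - gc.gene_length_bp, tss
        if start < 0 or end > chrom_len:
            continue
        gene_id = f"gene{gi:04d}"
        gi += 1
        genes.append(_gene_model(gene_id, rep.interval.chrom, start, end,
                                 strand, gc))
    for k in range(n_no_te):
        chrom = chroms[k % len(chroms)]
        chrom_len = config.chromosomes[chrom]
        base = chrom_len - config.reserve_bp + 6000
        start = base + k // len(chroms) * (gc.gene_length_bp + 400)
        end = start + gc.gene_length_bp
        if end > chrom_len:
            continue
        gene_id = f"gene{gi:04d}"
        gi += 1
        genes.append(_gene_model(gene_id, chrom, start, end, "+", gc))

    # ground truth proximity from the emitted annotation itself
    prox = proximity_records(genes, repeats)
    fam_class = {f.family_id: f.true_class for f in config.families}

    rows = []
    truth_genes = {}
    for gene in genes:
        record = prox[gene.gene_id]
        near_class = (fam_class.get(record.nearest_upstream_family)
                      if record.nearest_upstream_family else None)
        suppressed = (near_class in SPREADING_TRUE
                      and record.distance_bp <= gc.suppress_within_bp)
        silence_p = (gc.silencing_prob_near if suppressed
                     else gc.silencing_prob_base)
        silenced = bool(rng.uniform() < silence_p)
        true_rpkm = float(gc.mean_rpkm * rng.lognormal(
            -gc.sigma_log ** 2 / 2.0, gc.sigma_log))
        if suppressed:
            true_rpkm *= gc.suppression_factor
        if silenced:
            true_rpkm = 0.0
        lam = true_rpkm * gene.exon_length_bp * gc.library_size / 1e9
        count = int(rng.poisson(lam))
        rows.append({"gene_id": gene.gene_id, "sample": gc.sample,
                     "count": count})
        truth_genes[gene.gene_id] = {
            "chrom": gene.interval.chrom, "strand": gene.interval.strand,
            "tss": gene.tss,
            "nearest_family": record.nearest_upstream_family,
            "distance_bp": (record.distance_bp
                            if math.isfinite(record.distance_bp)
                            else None),
            "nearest_class": near_class,
            "suppressed": bool(suppressed),
            "silenced": silenced,
            "true_rpkm": true_rpkm,
        }
    counts = pd.DataFrame(rows)
    return genes, counts, {gc.sample: gc.library_size}, truth_genes


def _gene_model(gene_id, chrom, start, end, strand, gc) -> GeneModel:
    exon1 = GenomicInterval(chrom, start, start + gc.exon_length_bp, strand)
    exon2 = GenomicInterval(chrom, end - gc.exon_length_bp, end, strand)
    return GeneModel(gene_id=gene_id,
                     interval=GenomicInterval(chrom, start, end, strand),
                     exons=(exon1, exon2),
                     exon_length_bp=2 * gc.exon_length_bp)


# ---------------------------------------------------------------------------
# small RNA and attributes
# ---------------------------------------------------------------------------

def _make_smallrna(config, repeats, rng) -> list:
    intervals = []
    for rep in repeats:
        n = int(rng.poisson(config.smallrna_mean_per_copy))
        for _ in range(n):
            max_start = len(rep.interval) - config.smallrna_length_bp
            if max_start <= 0:
                continue
            s = rep.interval.start + int(rng.integers(0, max_start))
            intervals.append(GenomicInterval(
                rep.interval.chrom, s, s + config.smallrna_length_bp))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start))
    return intervals


def _make_attributes(config, repeats, rng) -> pd.DataFrame:
    rows = []
    for fam in config.families:
        n_copies = sum(1 for r in repeats if r.family_id == fam.family_id)
        date_mean = config.insertion_date_by_class.get(fam.true_class, 2.0)
        rows.append({
            "family_id": fam.family_id,
            "superfamily": fam.superfamily,
            "copy_number": n_copies,
            "genome_mb": n_copies * fam.element_length_bp / 1e6,
            "mean_fragment_length": fam.element_length_bp,
            "mean_insertion_date": float(max(
                rng.normal(date_mean, 0.2), 0.01)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# output and truth comparison
# ---------------------------------------------------------------------------

def _write_bundle(bundle: SyntheticBundle, outdir: Path, stages) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config = bundle.config
    if "genome" in stages and bundle.genome:
        write_fasta(bundle.genome, outdir / "genome.fa")
    if "repeats" in stages:
        write_repeats_bed(bundle.repeats, outdir / "repeats.bed")
    if "probes" in stages:
        write_probes_tsv(bundle.probes, outdir / "probes.tsv")
        write_signals_tsv(bundle.probes, outdir / "signals.tsv")
    if "bisulfite" in stages and len(bundle.cytosines):
        bundle.cytosines.to_csv(outdir / "cx_report.tsv", sep="\t",
                                index=False)
    if "reads" in stages:
        write_alignments_tsv(bundle.alignments, outdir / "aln.tsv")
        write_sam(bundle.alignments, config.chromosomes, bundle.genome,
                  outdir / "hap2.sam")
    if "genes" in stages:
        write_genes_gff3(bundle.genes, outdir / "genes.gff3")
        bundle.counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)
        pd.DataFrame([{"sample": s, "library_size": n}
                      for s, n in bundle.library_sizes.items()]).to_csv(
            outdir / "libsizes.tsv", sep="\t", index=False)
    if "smallrna" in stages:
        write_bed_intervals(bundle.smallrna, outdir / "smallrna.bed")
    if "attributes" in stages:
        bundle.attributes.to_csv(outdir / "attributes.tsv", sep="\t",
                                 index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(bundle.truth, fh, indent=1)


def truth_compare(truth: dict, classes: dict | None = None,
                  empty_copy_status: dict | None = None,
                  dm_calls=None, expression: dict | None = None,
                  sample: str | None = None) -> dict:
    """Score pipeline outputs against the generator manifest.

    Any subset of outputs may be supplied; only the matching metrics are
    computed.
    """
    from .empty_sites import DIRECTION_WITH, STATUS_EMPTY

    metrics = {}
    if classes is not None:
        true_classes = {fid: t["true_class"]
                        for fid, t in truth["families"].items()}
        unknown = set(classes) - set(true_classes)
        if unknown:
            raise ValueError(f"predicted classes reference unknown "
                             f"families: {sorted(unknown)}")
        labels = sorted(set(true_classes.values()) | set(classes.values()))
        confusion = {t: {p: 0 for p in labels} for t in labels}
        n_correct = 0
        n_scored = 0
        for fid, predicted in classes.items():
            actual = true_classes[fid]
            confusion.setdefault(actual, {}).setdefault(predicted, 0)
            confusion[actual][predicted] += 1
            n_scored += 1
            if predicted == actual:
                n_correct += 1
        metrics["class_accuracy"] = (n_correct / n_scored if n_scored
                                     else math.nan)
        metrics["class_confusion"] = confusion
    if empty_copy_status is not None:
        actual_absent = {cid for cid, t in truth["copies"].items()
                         if not t["present_hap2"]}
        predicted_empty = {cid for cid, status in empty_copy_status.items()
                           if status == STATUS_EMPTY}
        tp = len(predicted_empty & actual_absent)
        metrics["empty_site_precision"] = (
            tp / len(predicted_empty) if predicted_empty else math.nan)
        metrics["empty_site_recall"] = (
            tp / len(actual_absent) if actual_absent else math.nan)
    if dm_calls is not None:
        differential = [c for c in dm_calls if c.differential]
        if differential:
            n_with = sum(1 for c in differential
                         if c.direction == DIRECTION_WITH)
            metrics["direction_fraction"] = n_with / len(differential)
        else:
            metrics["direction_fraction"] = math.nan
    if expression is not None:
        near_spreading = []
        near_non = []
        for gid, t in truth["genes"].items():
            if gid not in expression or t["distance_bp"] is None:
                continue
            if t["distance_bp"] > 500:
                continue
            value = (expression[gid].rpkm_for(sample) if sample
                     else list(expression[gid].rpkm_values.values())[0])
            if t["nearest_class"] in SPREADING_TRUE:
                near_spreading.append(value)
            elif t["nearest_class"] == CLASS_NONE:
                near_non.append(value)
        if near_spreading and near_non:
            metrics["expression_ratio"] = (
                float(np.mean(near_spreading)) / float(np.mean(near_non)))
        else:
            metrics["expression_ratio"] = math.nan
    return metrics
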