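"""End-to-end orchestration: simulate (or load) inputs, profile flanks,
classify spreading, summarize bisulfite contexts, call empty sites, test
expression proximity, characterize families, and score against truth.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import CLASS_UNCLASSIFIABLE, MARK_5MC, MARK_H3K9, MARK_H3K27, \
    __version__
from . import empty_sites as es
from . import expression_proximity as ep
from . import family_characterization as fc
from . import flank_profiler as fp
from . import methylation_context as mc
from . import spreading_classifier as sc
from . import synthetic_data as sd

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    bin_width_bp: int = 200
    window_bp: int = 4000
    max_distance_bp: int = 5000
    min_probes: int = 1000
    n_null: int = 10_000
    B: int = 10_000
    alpha: float = 0.001
    required_bins: int = 4
    flank_bp: int = 1000
    dm_alpha: float = 0.01
    cutoffs: tuple = (500, 1000, 2500, 5000)
    n_random_regions: int = 10_000
    empty_site: es.EmptySiteParams = field(
        default_factory=es.EmptySiteParams)
    genotype: str = sd.GENOTYPE_WITH
    genotype_without: str = sd.GENOTYPE_WITHOUT
    tissue: str = sd.TISSUE
    expression_sample: str = "hap1_leaf"
    seed: int = 0

    def validate(self):
        if not (0 < self.alpha < 1) or not (0 < self.dm_alpha < 1):
            raise ValueError("alpha values must be in (0, 1)")
        for name in ("bin_width_bp", "window_bp", "max_distance_bp",
                     "min_probes", "n_null", "B", "required_bins",
                     "flank_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def params_from_dict(data: dict) -> PipelineParams:
    data = dict(data)
    es_data = data.pop("empty_site", None)
    params = PipelineParams(**data)
    if es_data:
        params.empty_site = es.EmptySiteParams(**es_data)
    params.validate()
    return params


def run(sim_config: sd.SyntheticConfig | None = None,
        bundle: sd.SyntheticBundle | None = None,
        params: PipelineParams | None = None,
        outdir=None) -> dict:
    """Run every stage on a simulated bundle and return report.json data.

    Either a simulation config or a pre-built bundle must be given.
    """
    params = params or PipelineParams()
    params.validate()
    if bundle is None:
        if sim_config is None:
            raise ValueError("need a simulation config or a bundle")
        bundle = sd.simulate(sim_config, outdir=outdir)

    out = Path(outdir) if outdir is not None else None
    report = {"version": __version__, "params": _params_echo(params),
              "seed": params.seed}

    # --- profile + classify -------------------------------------------------
    single = [p for p in bundle.probes if p.single_copy]
    assignments = fp.assign_probes(single, bundle.repeats,
                                   params.max_distance_bp)
    samples = [(params.genotype, params.tissue)]
    profiles = fp.profile_matrix(
        assignments, single, (MARK_5MC, MARK_H3K9, MARK_H3K27), samples,
        min_probes=params.min_probes, profile_window_bp=params.window_bp,
        bin_width_bp=params.bin_width_bp)
    if out is not None:
        fp.profiles_to_frame(profiles).to_csv(out / "profiles.tsv",
                                              sep="\t", index=False)
    sample_keys = [(m, params.genotype, params.tissue)
                   for m in (MARK_5MC, MARK_H3K9, MARK_H3K27)]
    null = sc.generate_null_sites(
        single, bundle.repeats, n_sites=params.n_null, seed=params.seed,
        window_bp=params.window_bp, bin_width_bp=params.bin_width_bp,
        sample_keys=sample_keys)
    family_sizes = {}
    for rep in bundle.repeats:
        family_sizes[rep.family_id] = family_sizes.get(rep.family_id, 0) + 1
    classifications = sc.classify_all(
        profiles, null, family_sizes, alpha=params.alpha,
        required_bins=params.required_bins, B=params.B, seed=params.seed,
        genotype=params.genotype, tissue=params.tissue)
    classes = {c.family_id: c.class_label for c in classifications}
    if out is not None:
        sc.classifications_to_frame(
            classifications, params.required_bins).to_csv(
            out / "classes.tsv", sep="\t", index=False)
    class_counts = {}
    for c in classifications:
        class_counts[c.class_label] = class_counts.get(c.class_label, 0) + 1
    report["class_counts"] = class_counts

    # --- bisulfite context summaries ---------------------------------------
    usable_classes = {f: c for f, c in classes.items()
                      if c != CLASS_UNCLASSIFIABLE}
    if len(bundle.cytosines):
        chrom_lengths = dict(bundle.config.chromosomes)
        summaries = []
        flank_pct_by_class = {}
        for family_id in sorted({r.family_id for r in bundle.repeats}):
            flank, internal = mc.family_flank_and_internal(
                bundle.cytosines, bundle.repeats, family_id,
                params.flank_bp, chrom_lengths)
            summaries.append((family_id, "flank", flank))
            summaries.append((family_id, "internal", internal))
            cls = usable_classes.get(family_id)
            if cls is not None and flank is not None:
                flank_pct_by_class.setdefault(cls, []).append(
                    flank["CG"].pct)
        baseline = mc.random_region_baseline(
            bundle.cytosines, chrom_lengths,
            n_regions=params.n_random_regions,
            region_bp=params.flank_bp, seed=params.seed)
        summaries.append(("RANDOM", "random", baseline))
        if out is not None:
            mc.summaries_to_frame(summaries).to_csv(
                out / "bsmeth.tsv", sep="\t", index=False)
        comparisons = {}
        if len(flank_pct_by_class.get(sd.CLASS_NONE, [])) >= 2:
            comparisons = {
                cls: {"p_value": comp.p_value,
                      "significant": comp.significant}
                for cls, comp in mc.compare_groups(
                    flank_pct_by_class, context="CG").items()}
        report["flank_cg_comparisons"] = comparisons

    # --- empty sites --------------------------------------------------------
    dm_calls = []
    empty_status = {}
    if bundle.alignments:
        calls = es.detect_empty_sites(bundle.alignments, bundle.repeats,
                                      params.empty_site)
        empty_status = es.combine_boundary_calls(calls, params.empty_site)
        rep_by_copy = {r.copy_id: r for r in bundle.repeats}
        rows = []
        for call in calls:
            rows.append({
                "repeat_copy_id": call.repeat_copy_id,
                "family_id": call.family_id,
                "class": classes.get(call.family_id, "NA"),
                "boundary": call.boundary_tested,
                "status": call.status,
                "n_support": call.n_supporting_reads,
                "n_junction": call.n_junction_reads,
            })
        for copy_id, status in sorted(empty_status.items()):
            if status != es.STATUS_EMPTY:
                continue
            rep = rep_by_copy[copy_id]
            boundary_pos = rep.interval.start
            probe = es.nearest_probe(boundary_pos, rep.interval.chrom,
                                     single)
            if probe is None:
                continue
            try:
                dm = es.test_differential(
                    probe, params.genotype, params.genotype_without,
                    MARK_5MC, params.tissue, alpha=params.dm_alpha,
                    repeat_copy_id=copy_id)
            except ValueError:
                continue
            dm_calls.append(dm)
        if out is not None:
            pd.DataFrame(rows).to_csv(out / "empty.tsv", sep="\t",
                                      index=False)
        n_empty = sum(1 for s in empty_status.values()
                      if s == es.STATUS_EMPTY)
        report["n_empty_sites"] = n_empty
        if dm_calls:
            diff = [c for c in dm_calls if c.differential]
            report["frac_differential"] = len(diff) / len(dm_calls)
            if diff:
                report["frac_higher_with_insertion"] = sum(
                    1 for c in diff
                    if c.direction == es.DIRECTION_WITH) / len(diff)

    # --- expression ---------------------------------------------------------
    if bundle.genes:
        expression = ep.gene_expression(bundle.genes, bundle.counts,
                                        bundle.library_sizes)
        proximity = ep.proximity_records(bundle.genes, bundle.repeats)
        strat = ep.stratified_comparison(
            proximity, expression, usable_classes,
            sample=params.expression_sample, cutoffs=params.cutoffs)
        prop = ep.proportion_expressed(
            proximity, expression, usable_classes,
            sample=params.expression_sample, cutoffs=params.cutoffs)
        if out is not None:
            strat.to_csv(out / "expression.tsv", sep="\t", index=False)
            prop.to_csv(out / "prop_expressed.tsv", sep="\t", index=False)
        report["expression"] = strat.to_dict(orient="records")

    # --- characterization ---------------------------------------------------
    if len(bundle.attributes):
        comp = fc.superfamily_composition(usable_classes,
                                          bundle.attributes)
        if out is not None:
            comp.to_csv(out / "superfamilies.tsv", sep="\t", index=False)
        report["superfamily_composition"] = comp.to_dict(orient="records")
    if bundle.smallrna:
        srna = fc.smallrna_stats(bundle.smallrna, bundle.repeats)
        if out is not None:
            pd.DataFrame([
                {"family_id": s.family_id,
                 "mean_read_count_per_copy": s.mean_read_count_per_copy,
                 "mean_covered_fraction": s.mean_covered_fraction}
                for s in srna.values()]).to_csv(
                out / "smallrna.tsv", sep="\t", index=False)

    # --- truth comparison ---------------------------------------------------
    if bundle.truth:
        expression_arg = None
        sample_arg = None
        if bundle.genes:
            expression_arg = expression
            sample_arg = params.expression_sample
        metrics = sd.truth_compare(
            bundle.truth, classes=usable_classes or None,
            empty_copy_status=empty_status or None,
            dm_calls=dm_calls or None,
            expression=expression_arg, sample=sample_arg)
        report["truth_metrics"] = _jsonable(metrics)

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=1)
    return report


def _params_echo(params: PipelineParams) -> dict:
    echo = {k: v for k, v in vars(params).items() if k != "empty_site"}
    echo["empty_site"] = vars(params.empty_site)
    echo["cutoffs"] = list(params.cutoffs)
    return echo


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    return obj
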