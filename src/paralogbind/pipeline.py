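"""End-to-end orchestration of the synthetic-to-report pipeline.

Stages: simulate -> normalise -> window-smooth -> FDR threshold -> call
intervals -> core set -> joint comparison -> event classification -> gene
assignment -> annotation summaries -> overlap statistics -> differential
expression -> direct targets -> report.  Every stage is deterministic given
the configuration seed; any stage failure aborts with the stage name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import annotation, binding, compare, expression, io as pio, overlaps, synthetic, targets

log = logging.getLogger("paralogbind")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.code = f"E_{stage.upper()}"


@dataclass
class PipelineConfig:
    seed: int = 0
    # genome
    chrom_lengths: tuple[int, ...] = (400_000, 400_000)
    n_genes: int = 80
    gc_background: float = 0.42
    # probes
    probe_spacing: int = 100
    probe_length: int = 50
    # planted truth
    n_per_event: int = 8
    amplitude: float = 3.0
    increase_delta: float = 2.0
    region_length: int = 600
    binding_noise_sd: float = 0.3
    n_binding_replicates: int = 3
    n_down: int = 10
    n_up: int = 10
    n_variable: int = 6
    expression_effect: float = 2.0
    expression_noise_sd: float = 0.25
    n_timepoints: int = 5
    n_expression_replicates: int = 4
    # binding calls
    fdr_levels: tuple[float, ...] = (0.01, 0.05, 0.10, 0.25)
    core_fdr_level: float = 0.01
    half_width: int = 250
    min_probes: int = 3
    max_gap: int = 200
    # comparison
    t_quantile: float = 0.95
    delta: float = 1.0
    min_run: int = 3
    # expression scoring
    alpha_overall: float = 0.05
    alpha_timepoint: float = 0.05
    # annotation / overlap
    assignment_window: int = 10_000
    overlap_iterations: int = 200

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                coerced[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**coerced)


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Run every stage into ``outdir`` and return the report dictionary.

    The report echoes the full configuration and contains the planted-vs-
    recovered event table, interval counts per FDR level, the trend-class
    partition and the direct-target set.
    """
    os.makedirs(outdir, exist_ok=True)
    report: dict = {"config": asdict(config), "stages": {}}
    state: dict = {}

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            log.info("stage %s", name)
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, exc) from exc
            report["stages"][name] = {"seconds": round(time.time() - t0, 3)}

        return wrap

    @stage("simulate")
    def _():
        spec = synthetic.SyntheticGenomeSpec(
            n_chromosomes=len(config.chrom_lengths),
            chrom_lengths=config.chrom_lengths,
            n_genes=config.n_genes,
            gc_background=config.gc_background,
            seed=config.seed,
        )
        genome, sequences = synthetic.generate_genome(spec)
        probes = synthetic.generate_probe_layout(
            genome, config.probe_spacing, config.probe_length
        )
        truth_bind = synthetic.plant_binding_events(
            genome,
            n_per_event=config.n_per_event,
            amplitude=config.amplitude,
            increase_delta=config.increase_delta,
            region_length=config.region_length,
            seed=config.seed + 1,
        )
        bind_a = truth_bind.planted_binding.query(
            "factor == 'A' and condition == 'wt'"
        )[["chrom", "start", "end"]].drop_duplicates()
        near_binding = set(
            annotation.assign_intervals(bind_a, genome.genes, config.assignment_window)[
                "gene_id"
            ].dropna()
        )
        truth_expr = synthetic.plant_expression_trends(
            genome,
            n_down=config.n_down,
            n_up=config.n_up,
            n_variable=config.n_variable,
            effect_size=config.expression_effect,
            preferred_genes=near_binding,
            seed=config.seed + 2,
        )
        truth = synthetic.TruthSet(
            planted_binding=truth_bind.planted_binding,
            planted_expression=truth_expr.planted_expression,
        )
        profiles = synthetic.simulate_binding_profiles(
            genome, probes, truth,
            noise_sd=config.binding_noise_sd,
            n_replicates=config.n_binding_replicates,
            seed=config.seed + 3,
        )
        chip = synthetic.simulate_binding_profiles(
            genome, probes, truth,
            noise_sd=config.binding_noise_sd,
            n_replicates=config.n_binding_replicates,
            seed=config.seed + 6,
            assay_class="ChIP",
        )
        expr = synthetic.simulate_expression_timecourse(
            genome, truth,
            n_timepoints=config.n_timepoints,
            n_replicates=config.n_expression_replicates,
            noise_sd=config.expression_noise_sd,
            seed=config.seed + 4,
        )
        synthetic.write_fixtures(
            os.path.join(outdir, "fixtures"),
            genome=genome, sequences=sequences, probes=probes,
            profiles=profiles, truth=truth, expression=expr,
        )
        state.update(
            genome=genome, sequences=sequences, probes=probes,
            truth=truth, profiles=profiles, chip=chip, expr=expr,
        )

    @stage("call_intervals")
    def _():
        calls_by_level: dict[str, dict[float, pd.DataFrame]] = {}
        datasets = dict(state["profiles"])
        datasets["A_wt_ChIP"] = state["chip"]["A_wt"]
        for key, prof in datasets.items():
            qn = binding.quantile_normalize(prof.values)
            prof_qn = binding.SignalProfile(prof.layout, qn, prof.assay_class, prof.label)
            window = binding.smooth_windows(prof_qn, config.half_width, config.min_probes)
            calls_by_level[key] = binding.call_at_fdr_levels(
                window, config.fdr_levels, config.min_probes, config.max_gap
            )
        state["calls"] = calls_by_level
        table = {
            key: {level: len(df) for level, df in levels.items()}
            for key, levels in calls_by_level.items()
        }
        report["interval_counts_by_fdr"] = table
        for key, levels in calls_by_level.items():
            pio.write_bed(
                levels[config.core_fdr_level], os.path.join(outdir, f"intervals_{key}.bed")
            )

    @stage("core_set")
    def _():
        level = config.core_fdr_level
        core = binding.core_intersect(
            {"A_wt": state["calls"]["A_wt"][level]},
            {"A_wt_ChIP": state["calls"]["A_wt_ChIP"][level]},
        )
        state["core"] = core
        report["n_core_intervals"] = len(core)
        pio.write_bed(core, os.path.join(outdir, "core_intervals.bed"))

    @stage("compare_events")
    def _():
        joint = compare.joint_normalize(
            state["profiles"],
            t_quantile=config.t_quantile,
            min_run=config.min_run,
            max_gap=config.max_gap,
            delta=config.delta,
        )
        events = compare.classify_events(joint, "A_wt", "B_wt", "A_in_Bmut")
        state["joint"] = joint
        state["events"] = events
        pio.write_bed(
            events.rename(columns={"event": "name"}), os.path.join(outdir, "events.bed")
        )

    @stage("assign_genes")
    def _():
        genes = state["genome"].genes
        assign = annotation.assign_intervals(
            state["core"], genes, config.assignment_window
        )
        state["core_assignments"] = assign
        event_assign = annotation.assign_intervals(
            state["events"], genes, config.assignment_window
        )
        state["event_assignments"] = event_assign
        summary = compare.summarize_events(state["events"], event_assign)
        planted = (
            state["truth"].regions()["event_label"].value_counts().to_dict()
        )
        summary["planted_regions"] = [
            planted.get(e, 0) for e in summary["event"]
        ]
        report["event_table"] = summary.to_dict(orient="list")
        summary.to_csv(os.path.join(outdir, "event_summary.tsv"), sep="\t", index=False)

    @stage("annotate")
    def _():
        genes = state["genome"].genes
        features = annotation.classify_features(state["core"], genes)
        report["feature_counts"] = features.value_counts().to_dict()
        stats = annotation.tss_position_stats(state["core_assignments"], genes)
        report["tss_stats"] = {
            "n": stats["n"],
            "upstream_fraction": stats["upstream_fraction"],
            "downstream_fraction": stats["downstream_fraction"],
        }

    @stage("overlap_stats")
    def _():
        truth_regions = state["truth"].regions()
        universe = pd.DataFrame(
            {
                "chrom": list(state["genome"].chrom_lengths),
                "start": 0,
                "end": list(state["genome"].chrom_lengths.values()),
            }
        )
        if len(state["core"]):
            res = overlaps.subsample_zscore(
                state["core"],
                truth_regions,
                universe,
                n_iterations=config.overlap_iterations,
                seed=config.seed + 5,
            )
            report["core_vs_truth_overlap"] = asdict(res)

    @stage("expression_de")
    def _():
        trends, stats_ = expression.run_de(
            state["expr"],
            alpha_overall=config.alpha_overall,
            alpha_timepoint=config.alpha_timepoint,
        )
        state["trends"] = trends
        report["trend_partition"] = trends["class"].value_counts().to_dict()
        trends.to_csv(os.path.join(outdir, "trend_scores.tsv"), sep="\t", index=False)

    @stage("direct_targets")
    def _():
        bound_genes = set(state["core_assignments"]["gene_id"].dropna())
        tset = targets.call_direct_targets(state["trends"], bound_genes)
        state["targets"] = tset
        report["direct_targets"] = tset.counts
        tset.members.to_csv(os.path.join(outdir, "direct_targets.tsv"), sep="\t", index=False)

    @stage("report")
    def _():
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default, sort_keys=True)
        lines = ["paralogbind synthetic run", "=" * 30]
        lines.append(f"core intervals: {report['n_core_intervals']}")
        lines.append(f"event table: {report['event_table']}")
        lines.append(f"trend partition: {report['trend_partition']}")
        lines.append(f"direct targets: {report['direct_targets']}")
        with open(os.path.join(outdir, "report.txt"), "w") as fh:
            fh.write("\n".join(lines) + "\n")

    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
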