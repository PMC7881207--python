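"""End-to-end orchestration: DE -> TS definition -> threshold -> S/N scores
-> networks -> accumulation curves, with deterministic TSV artifacts."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .accumulation_profiles import accumulate, largest_gap
from .correlation_scores import (
    correlation_matrix,
    correlation_threshold,
    score_table,
    write_score_table,
)
from .diff_expression import classify_regulation, de_test, write_de_table
from .expression_io import (
    ExpressionMatrix,
    GeneList,
    SampleTable,
    read_expression_matrix,
    read_gene_list,
    read_sample_table,
    subset_stage,
    write_expression_matrix,
    write_gene_list,
    write_sample_table,
)
from .network_scores import binarize, export_network, n_scores, write_edge_table
from .synthetic_data import SimulationConfig, simulate_cohort, write_truth_table
from .ts_selection import define_ts_genes, write_ts_table

logger = logging.getLogger(__name__)

ARTIFACTS = (
    "de_table.tsv",
    "ts_genes.tsv",
    "threshold.tsv",
    "score_table.tsv",
    "network_pos_edges.tsv",
    "network_neg_edges.tsv",
    "accumulation.tsv",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    # exactly one of (simulate) / (expression_path + samples_path + ts_list_paths)
    simulate: SimulationConfig | None = None
    expression_path: str | None = None
    samples_path: str | None = None
    ts_list_paths: list[str] = field(default_factory=list)
    denylist_path: str | None = None
    stage: str = "2"
    fdr: float = 0.01
    alpha: float = 0.05
    tails: str = "one"
    sample_scope: str = "all"
    direction_rule: str = "down_only"
    missing: str = "error"
    linear_scale: bool = False

    def __post_init__(self) -> None:
        file_mode = self.expression_path is not None
        if self.simulate is not None and file_mode:
            raise ValueError("give either a simulation config or input paths, not both")
        if self.simulate is None and not file_mode:
            raise ValueError("either a simulation config or input paths is required")
        if file_mode and (self.samples_path is None or not self.ts_list_paths):
            raise ValueError("file mode needs expression, samples and >=1 TS candidate list")


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage, write all artifacts into ``outdir`` and return the
    run report (also written as ``run_report.json``).

    Identical configs (including the simulation seed) produce byte-identical
    TSV outputs.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- inputs -----------------------------------------------------------
    if cfg.simulate is not None:
        expr, samples, truth = simulate_cohort(cfg.simulate)
        candidates = GeneList(
            "planted_ts",
            set(truth.genes_with("strong_ts")) | set(truth.genes_with("weak_ts")),
            provenance="simulation ground truth",
        )
        write_expression_matrix(expr, out / "expression.tsv")
        write_sample_table(samples, out / "samples.tsv")
        write_truth_table(truth, out / "truth.tsv")
        write_gene_list(candidates, out / "ts_candidates.tsv")
        ts_lists = [candidates]
    else:
        try:
            expr = read_expression_matrix(
                cfg.expression_path, missing=cfg.missing, linear_scale=cfg.linear_scale
            )
            samples = read_sample_table(cfg.samples_path)
            ts_lists = [read_gene_list(p) for p in cfg.ts_list_paths]
        except (OSError, ValueError) as exc:
            raise PipelineError("input", str(exc)) from exc
    denylist = None
    if cfg.denylist_path is not None:
        denylist = read_gene_list(cfg.denylist_path, name="denylist")

    # ---- stage scoping and DE --------------------------------------------
    try:
        stage_expr, stage_samples = subset_stage(expr, samples, cfg.stage, include_normals=True)
    except (ValueError, KeyError) as exc:
        raise PipelineError("subset_stage", str(exc)) from exc
    try:
        de = de_test(stage_expr, stage_samples, fdr=cfg.fdr)
    except ValueError as exc:
        raise PipelineError("de_test", str(exc)) from exc
    write_de_table(de, out / "de_table.tsv")
    down, up = classify_regulation(de)

    # ---- TS definition ----------------------------------------------------
    padded = (ts_lists + [GeneList(f"empty{i}", set()) for i in range(3)])[:3]
    ts_set = define_ts_genes(
        {cfg.stage: (down, up)}, *padded, denylist=denylist, direction_rule=cfg.direction_rule
    )
    write_ts_table(ts_set, out / "ts_genes.tsv")
    if not ts_set.members:
        raise PipelineError("ts_selection", "TS gene set is empty; nothing to score")

    # DE columns for scoring: the stage's significant set, both directions,
    # excluding the TS genes themselves (self-correlations of 1 would be
    # counted as network structure otherwise).
    de_cols = sorted((down.members | up.members) - set(ts_set.members))
    if not de_cols:
        raise PipelineError("de_test", "no significant DE genes outside the TS set")

    # ---- correlations, threshold, scores ---------------------------------
    # TS rows come from the full stage-scoped matrix: a TS gene is scored
    # even at stages where it is not itself DE.
    ts_expr = stage_expr.subset_probes(ts_set.members)
    de_expr = stage_expr.subset_probes(de_cols)
    try:
        R = correlation_matrix(ts_expr, de_expr, sample_scope=cfg.sample_scope, samples=stage_samples)
    except ValueError as exc:
        raise PipelineError("correlation", str(exc)) from exc
    spec = correlation_threshold(cfg.alpha, len(de_cols), R.n_samples, tails=cfg.tails)
    with open(out / "threshold.tsv", "w", encoding="utf-8") as fh:
        fh.write("alpha\tm_tests\tn_samples\ttails\tt\tT\n")
        fh.write(
            f"{format(spec.alpha, '.17g')}\t{spec.m_tests}\t{spec.n_samples}\t{spec.tails}\t"
            f"{format(spec.t, '.17g')}\t{format(spec.T, '.17g')}\n"
        )

    s_rows = score_table(R, spec.T)
    n_rows = n_scores(R, spec.T)
    write_score_table(
        s_rows,
        out / "score_table.tsv",
        spec=spec,
        extra={
            "n_plus": {r.gene: r.n_plus for r in n_rows},
            "n_minus": {r.gene: r.n_minus for r in n_rows},
        },
    )

    # ---- networks ---------------------------------------------------------
    pos = binarize(R, spec.T, "pos_sig")
    neg = binarize(R, spec.T, "neg_sig")
    write_edge_table(export_network(pos), out / "network_pos_edges.tsv")
    write_edge_table(export_network(neg), out / "network_neg_edges.tsv")

    # ---- accumulation profiles -------------------------------------------
    curves = {
        "s_plus": accumulate({r.gene: r.s_plus for r in s_rows}, "s_plus"),
        "s_minus": accumulate({r.gene: r.s_minus for r in s_rows}, "s_minus"),
        "n_plus": accumulate({r.gene: r.n_plus for r in n_rows}, "n_plus"),
        "n_minus": accumulate({r.gene: r.n_minus for r in n_rows}, "n_minus"),
    }
    with open(out / "accumulation.tsv", "w", encoding="utf-8") as fh:
        fh.write("kind\trank\tgene\tscore\tcumulative\n")
        for kind, curve in curves.items():
            for i, (g, s, c) in enumerate(
                zip(curve.gene_order, curve.scores, curve.cumulative), start=1
            ):
                fh.write(f"{kind}\t{i}\t{g}\t{format(s, '.17g')}\t{format(c, '.17g')}\n")

    # ---- run report -------------------------------------------------------
    report = {
        "version": __version__,
        "parameters": {
            "stage": cfg.stage,
            "fdr": cfg.fdr,
            "alpha": cfg.alpha,
            "tails": cfg.tails,
            "sample_scope": cfg.sample_scope,
            "direction_rule": cfg.direction_rule,
            "missing": cfg.missing,
            "linear_scale": cfg.linear_scale,
            "simulate": (
                {k: getattr(cfg.simulate, k) for k in cfg.simulate.__dataclass_fields__}
                if cfg.simulate is not None
                else None
            ),
            "expression_path": cfg.expression_path,
            "samples_path": cfg.samples_path,
            "ts_list_paths": list(cfg.ts_list_paths),
            "denylist_path": cfg.denylist_path,
        },
        "threshold": {
            "alpha": spec.alpha,
            "m_tests": spec.m_tests,
            "n_samples": spec.n_samples,
            "tails": spec.tails,
            "t": spec.t,
            "T": spec.T,
        },
        "counts": {
            "probes": len(expr.probe_ids),
            "scoped_samples": len(stage_expr.sample_ids),
            "de_significant": len(down.members) + len(up.members),
            "de_down": len(down.members),
            "de_up": len(up.members),
            "ts_genes": len(ts_set.members),
            "de_columns_scored": len(de_cols),
        },
        "gaps": {
            "s": largest_gap(curves["s_plus"], curves["s_minus"]),
            "n": largest_gap(curves["n_plus"], curves["n_minus"]),
        },
        "artifacts": [str(out / a) for a in ARTIFACTS],
    }
    with open(out / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
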