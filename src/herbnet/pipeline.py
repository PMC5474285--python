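"""End-to-end orchestration: screen -> map targets -> networks -> enrichment
-> organ localization -> differential expression -> intersection.

A single config (YAML or dict) names every input file plus thresholds,
rescue list, organ panel, top-N and enrichment cutoff; all randomness used
by any stage funnels through one seed field. The run report is a plain
JSON-able dict of per-stage counts so the narrative numbers are auditable,
and it is a pure function of the inputs (no timestamps), so identical
config + seed reproduces it byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import core_io, de_compare, enrichment, netanalysis, organ_expression
from .adme_filter import FilterThresholds, apply_adme_filter
from .errors import HerbnetError, StageError, ValidationError
from .target_map import average_targets_per_compound, merge_interactions


@dataclass
class PipelineConfig:
    compounds: str
    edges: list[str]
    targets: str
    gene_sets: str | None = None
    expression: str | None = None
    organ_panel: list[str] = field(default_factory=list)
    rescue_ids: list[str] = field(default_factory=list)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    de_lists: list[str] = field(default_factory=list)
    top_n: int = 250
    p_cutoff: float = 0.01
    seed: int = 0
    outdir: str = "herbnet_out"

    def __post_init__(self):
        if self.top_n < 1:
            raise ValidationError("top_n must be >= 1")
        if not 0.0 < self.p_cutoff < 1.0:
            raise ValidationError("p_cutoff must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = FilterThresholds(**thr)
        return cfg


def _check_inputs(config: PipelineConfig) -> None:
    paths = [config.compounds, config.targets, *config.edges,
             *config.de_lists]
    for opt in (config.gene_sets, config.expression):
        if opt:
            paths.append(opt)
    missing = [p for p in paths if not Path(p).exists()]
    if missing:
        raise ValidationError(f"missing input file(s): {missing}")


def _write_manifest(outdir: Path, complete: bool, stages_done: list[str]) -> None:
    with open(outdir / "MANIFEST.json", "w", encoding="utf-8") as fh:
        json.dump({"complete": complete, "stages_done": stages_done}, fh,
                  indent=2)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and return the JSON-able run report.

    Any stage failure raises StageError naming the stage; partial outputs
    already written stay on disk with a MANIFEST marking the run
    incomplete.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "outputs": []}
    done: list[str] = []

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        report["outputs"].append(str(path))

    try:
        # --- stage: filter -------------------------------------------------
        stage = "filter"
        _check_inputs(config)
        compounds = core_io.read_compound_table(config.compounds)
        fr = apply_adme_filter(compounds, config.thresholds, config.rescue_ids)
        report["filter"] = {"n_compounds": len(compounds),
                            "passed": len(fr.passed),
                            "rescued": len(fr.rescued),
                            "excluded": len(fr.excluded)}
        retained = set(fr.retained)
        emit("filter_report.json", lambda p: Path(p).write_text(json.dumps(
            {"passed": sorted(fr.passed), "rescued": sorted(fr.rescued),
             "excluded": {k: v for k, v in sorted(fr.excluded.items())}},
            indent=2)))
        done.append(stage)

        # --- stage: map-targets --------------------------------------------
        stage = "map-targets"
        target_table = core_io.read_target_table(config.targets)
        edge_tables = [core_io.read_edge_table(p) for p in config.edges]
        catalog = merge_interactions(edge_tables,
                                     [c.compound_id for c in compounds],
                                     target_table)
        catalog.edges = [e for e in catalog.edges
                         if e.compound_id in retained]
        kept_accs = {e.uniprot_id for e in catalog.edges}
        catalog.targets = [t for t in catalog.targets
                           if t.uniprot_id in kept_accs]
        report["targets"] = {
            "edges": len(catalog.edges),
            "unique_targets": len(kept_accs),
            "avg_targets_per_compound":
                average_targets_per_compound(catalog, len(retained))
                if catalog.edges else 0.0,
            "unresolved_uniprot_ids": len(catalog.unresolved_uniprot_ids)}
        emit("catalog_edges.tsv",
             lambda p: core_io.write_edge_table(catalog.edges, p))
        done.append(stage)

        # --- stage: network ------------------------------------------------
        stage = "network"
        if not catalog.edges:
            raise ValidationError("no edges left after filtering; cannot "
                                  "build the compound-target network")
        ct = netanalysis.build_bipartite(
            [(e.compound_id, e.uniprot_id) for e in catalog.edges],
            left_ids=sorted(retained), right_ids=sorted(kept_accs))
        ct_cent = netanalysis.centrality_table(ct)
        report["ct_network"] = {
            "nodes": ct.n_nodes(), "edges": ct.n_edges(),
            "top_compounds_by_degree":
                netanalysis.rank_nodes(ct_cent, "degree", "left")[:5],
            "top_targets_by_degree":
                netanalysis.rank_nodes(ct_cent, "degree", "right")[:5]}
        emit("ct_network.sif", lambda p: core_io.write_network(
            ct, p, "sif", attributes=ct_cent))
        done.append(stage)

        # --- stage: enrich -------------------------------------------------
        stage = "enrich"
        gene_symbols = sorted({t.gene_symbol for t in catalog.targets})
        if config.gene_sets:
            collection = core_io.read_gmt(config.gene_sets)
            results, n_dropped = enrichment.run_enrichment(
                gene_symbols, collection, p_cutoff=config.p_cutoff)
            report["enrichment"] = {
                "sets_passing_cutoff": len(results),
                "query_genes_outside_universe": n_dropped,
                "top_sets": [r.set_id for r in results[:5]]}
            emit("enrichment.tsv", lambda p: _write_enrichment(results, p))
            if results:
                tp_edges = [(g, r.set_id) for r in results
                            for g in r.overlap_genes]
                tp = netanalysis.build_bipartite(
                    tp_edges,
                    left_ids=sorted({g for g, _s in tp_edges}),
                    right_ids=sorted({s for _g, s in tp_edges}))
                tp_cent = netanalysis.centrality_table(tp)
                report["tp_network"] = {"nodes": tp.n_nodes(),
                                        "edges": tp.n_edges()}
                emit("tp_network.sif", lambda p: core_io.write_network(
                    tp, p, "sif", attributes=tp_cent))
        else:
            report["enrichment"] = None
        done.append(stage)

        # --- stage: organs -------------------------------------------------
        stage = "organs"
        if config.expression:
            matrix = core_io.read_expression_matrix(config.expression)
            panel = config.organ_panel or list(matrix.col_ids)
            calls = organ_expression.above_average_calls(matrix, panel)
            freq = organ_expression.organ_frequency(calls)
            multi = organ_expression.genes_in_at_least_k_organs(calls, 2)
            report["organs"] = {
                "genes_profiled": matrix.values.shape[0],
                "genes_with_panel_call": len(
                    organ_expression.genes_in_at_least_k_organs(calls, 1)),
                "genes_in_two_or_more": len(multi),
                "organ_frequency": freq}
            emit("organ_frequency.tsv", lambda p: _write_freq(freq, p))
            network = organ_expression.build_organ_network(calls)
            if network.n_edges():
                emit("organ_network.sif", lambda p: core_io.write_network(
                    network, p, "sif"))
        else:
            report["organs"] = None
        done.append(stage)

        # --- stage: de-intersect -------------------------------------------
        stage = "de-intersect"
        if config.de_lists:
            lists = [core_io.read_id_list(p) for p in config.de_lists]
            union = de_compare.union_dedupe(lists)
            common, rows = de_compare.intersect_targets(
                union, gene_symbols, target_table)
            report["de"] = {"union_size": len(union),
                            "intersection_size": len(common),
                            "intersection_genes": common}
            emit("common_genes.tsv", lambda p: _write_common(rows, p))
        else:
            report["de"] = None
        done.append(stage)

    except HerbnetError as exc:
        _write_manifest(outdir, complete=False, stages_done=done)
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    _write_manifest(outdir, complete=True, stages_done=done)
    with open(outdir / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _write_enrichment(results, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("set_id\tk\tK\tn\tN\tp_value\tp_adjusted\toverlap\n")
        for r in results:
            fh.write(f"{r.set_id}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                     f"{r.p_value:.6g}\t{r.p_adjusted:.6g}\t"
                     f"{','.join(r.overlap_genes)}\n")


def _write_freq(freq, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tissue\tn_genes\n")
        for tissue, count in freq:
            fh.write(f"{tissue}\t{count}\n")


def _write_common(rows, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_symbol\tuniprot_id\tprotein_name\n")
        for g, acc, name in rows:
            fh.write(f"{g}\t{acc}\t{name}\n")
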