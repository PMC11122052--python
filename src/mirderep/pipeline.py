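"""End-to-end orchestration: ortholog mapping -> target sets -> enrichment
-> DEG integration (aging, parabiosis, hypothalamus) -> networks.

Every stage is an ordinary library call; :func:`run_all` threads them
together, writes each result table (TSV with provenance comment lines),
the networks (GraphML + SIF) and a machine-readable ``report.json``.
Reruns with identical inputs produce byte-identical outputs: provenance
lines carry the config hash and package version but no timestamps, and
per-stage wall-clock goes to the log only.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, deg_integration, io_formats, mirna_orthology
from . import network_builder, pathway_enrichment, target_sets
from .config import RunConfig

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunReport:
    """Machine-readable per-stage counts, consistent with the emitted files."""

    config: dict = field(default_factory=dict)
    version: str = __version__
    schema_version: int = 1
    mirnas_input: int = 0
    mirnas_mapped: int = 0
    mirnas_conserved: int = 0
    mirnas_unmatched: list[str] = field(default_factory=list)
    mirnas_excluded: list[str] = field(default_factory=list)
    targets_per_mirna: dict[str, int] = field(default_factory=dict)
    pathways_tested: int = 0
    pathways_significant_per_mirna: dict[str, int] = field(default_factory=dict)
    shared_pathways: int = 0
    universe_size: int = 0
    hits_aging: int = 0
    recurrent_genes: list[str] = field(default_factory=list)
    reversal_genes: list[str] = field(default_factory=list)
    widespread_genes: list[str] = field(default_factory=list)
    hits_hypothalamus: int = 0
    network_nodes: int = 0
    network_edges: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _provenance(config: RunConfig) -> list[str]:
    return [f"mirderep {__version__}", f"config_hash {config.config_hash()}"]


def build_universe(
    collection: io_formats.PathwayCollection,
    interactions: io_formats.InteractionTable,
    policy: str,
) -> set[str]:
    """Background gene universe for over-representation tests.

    ``pathway-union``: every gene annotated to >= 1 pathway (default);
    ``interaction-genes``: every target gene in the interaction table.
    """
    if policy == "pathway-union":
        return collection.all_genes()
    if policy == "interaction-genes":
        return set(interactions.genes())
    raise ValueError(f"unknown universe policy {policy!r}")


def run_all(config: RunConfig) -> RunReport:
    """Execute the whole pipeline under one config; returns the run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / ".incomplete"
    marker.write_text("run in progress\n", encoding="utf-8")
    prov = _provenance(config)
    report = RunReport(config={k: v for k, v in asdict(config).items() if k != "outdir"})
    stage = "load-inputs"
    try:
        t0 = time.perf_counter()
        all_mirnas = io_formats.read_mirna_table(config.mirnas)
        mouse = [m for m in all_mirnas if m.species == "mouse"]
        human = [m for m in all_mirnas if m.species == "human"]
        interactions = io_formats.read_interactions(config.interactions)
        collection = io_formats.read_gmt(config.pathways)
        ortho_table = io_formats.read_orthologs(config.orthologs)
        log.info("stage %s: %.2fs", stage, time.perf_counter() - t0)

        # --- miRNA orthology and seed conservation ---------------------------
        stage = "map-orthologs"
        t0 = time.perf_counter()
        mapping = mirna_orthology.map_mirna_orthologs(mouse, human)
        conserved, excluded = mirna_orthology.filter_conserved(mapping.pairs)
        report.mirnas_input = len(mouse)
        report.mirnas_mapped = len(mapping.pairs)
        report.mirnas_conserved = len(conserved)
        report.mirnas_unmatched = mapping.unmatched_mouse
        report.mirnas_excluded = [e.mirna_id for e in excluded]
        pairs_df = pd.DataFrame(
            [
                {"mouse_id": p.mouse_id, "human_id": p.human_id,
                 "identity": f"{p.identity:.4f}",
                 "seed_conserved": str(p.seed_conserved).lower()}
                for p in mapping.pairs
            ],
            columns=["mouse_id", "human_id", "identity", "seed_conserved"],
        )
        io_formats.write_tsv(pairs_df, outdir / "mirna_orthologs.tsv", prov)
        excl_df = pd.DataFrame(
            [{"id": e.mirna_id, "reason": e.reason} for e in excluded]
            + [{"id": mid, "reason": "no human ortholog match"} for mid in mapping.unmatched_mouse],
            columns=["id", "reason"],
        )
        io_formats.write_tsv(excl_df, outdir / "mirna_exclusions.tsv", prov)
        log.info("stage %s: %.2fs", stage, time.perf_counter() - t0)

        # --- target sets ------------------------------------------------------
        stage = "targets"
        t0 = time.perf_counter()
        human_ids = [p.human_id for p in conserved]
        sets = target_sets.build_target_sets(interactions, human_ids, config.evidence_policy)
        gene_to_mirnas = target_sets.invert_index(sets)
        report.targets_per_mirna = {s.mirna_id: len(s.genes) for s in sets}
        targets_df = pd.DataFrame(
            [
                {"mirna": s.mirna_id, "gene_human": g}
                for s in sets for g in sorted(s.genes)
            ],
            columns=["mirna", "gene_human"],
        )
        io_formats.write_tsv(
            targets_df, outdir / "target_sets.tsv",
            prov + [f"evidence_policy {config.evidence_policy}"],
        )
        log.info("stage %s: %.2fs", stage, time.perf_counter() - t0)

        # --- pathway enrichment ----------------------------------------------
        stage = "enrich"
        t0 = time.perf_counter()
        universe = build_universe(collection, interactions, config.universe_policy)
        report.universe_size = len(universe)
        enrich_rows = []
        top_rows = []
        significant: dict[str, set[str]] = {}
        for s in sets:
            results = pathway_enrichment.enrich(s.genes, collection, universe, query_id=s.mirna_id)
            report.pathways_tested = max(report.pathways_tested, len(results))
            significant[s.mirna_id] = pathway_enrichment.significant_pathways(
                results, config.alpha_enrichment
            )
            report.pathways_significant_per_mirna[s.mirna_id] = len(significant[s.mirna_id])
            for r in results:
                enrich_rows.append(_enrichment_row(r))
            for r in pathway_enrichment.top_pathways(results, config.top_n):
                top_rows.append(_enrichment_row(r))
        enrich_prov = prov + [f"universe_policy {config.universe_policy}",
                              f"universe_size {len(universe)}"]
        io_formats.write_tsv(pd.DataFrame(enrich_rows, columns=_ENRICH_COLUMNS),
                             outdir / "enrichment.tsv", enrich_prov)
        io_formats.write_tsv(pd.DataFrame(top_rows, columns=_ENRICH_COLUMNS),
                             outdir / "enrichment_top.tsv", enrich_prov)
        shared = pathway_enrichment.shared_pathways(significant, config.min_shared)
        report.shared_pathways = len(shared)
        shared_df = pd.DataFrame(
            [
                {"pathway_id": r.pathway_id, "count": r.count, "mirnas": ",".join(r.mirnas)}
                for r in shared
            ],
            columns=["pathway_id", "count", "mirnas"],
        )
        io_formats.write_tsv(shared_df, outdir / "shared_pathways.tsv", enrich_prov)
        log.info("stage %s: %.2fs", stage, time.perf_counter() - t0)

        # --- gene ortholog bridge --------------------------------------------
        stage = "gene-orthologs"
        t0 = time.perf_counter()
        human_genes = sorted(gene_to_mirnas)
        h2m, unmapped = mirna_orthology.map_gene_orthologs(
            human_genes, ortho_table, config.ortholog_policy
        )
        mouse_to_human = {ms[0]: h for h, ms in h2m.items() if ms}
        log.info("stage %s: %.2fs (%d unmapped)", stage, time.perf_counter() - t0, len(unmapped))

        # --- aging integration ------------------------------------------------
        stage = "integrate-aging"
        t0 = time.perf_counter()
        aging_spec = deg_integration.DEGFilterSpec(
            direction="up", effect_scale=deg_integration.LINEAR_FC,
            threshold=config.fc_min, inclusive=True, alpha=config.alpha_deg,
        )
        aging_table = io_formats.read_deg_table(
            config.deg_aging, "aging", deg_integration.LINEAR_FC
        )
        aging_filtered = deg_integration.filter_degs(aging_table, aging_spec)
        aging_hits = deg_integration.intersect_targets(aging_filtered, gene_to_mirnas, mouse_to_human)
        report.hits_aging = len(aging_hits)
        recurrent = deg_integration.recurrent_genes(aging_hits, config.min_groups)
        report.recurrent_genes = sorted(recurrent)
        io_formats.write_tsv(_hits_df(aging_hits), outdir / "hits_aging.tsv", prov)
        io_formats.write_tsv(
            pd.DataFrame(
                [{"gene": g, "n_cell_types": len(cts), "cell_types": ",".join(cts)}
                 for g, cts in sorted(recurrent.items())],
                columns=["gene", "n_cell_types", "cell_types"],
            ),
            outdir / "recurrent_genes.tsv", prov + [f"min_groups {config.min_groups}"],
        )
        log.info("stage %s: %.2fs", stage, time.perf_counter() - t0)

        # --- parabiosis reversal ----------------------------------------------
        stage = "integrate-parabiosis"
        t0 = time.perf_counter()
        parabiosis_table = io_formats.read_deg_table(
            config.deg_parabiosis, "parabiosis", deg_integration.LOGFC_ANY_BASE
        )
        ct_map = io_formats.read_cell_type_map(config.cell_type_map)
        down_spec = deg_integration.DEGFilterSpec(
            direction="down", effect_scale=deg_integration.LOGFC_ANY_BASE,
            threshold=0.0, inclusive=False, alpha=config.alpha_deg,
        )
        reversal = deg_integration.detect_reversal(aging_hits, parabiosis_table, down_spec, ct_map)
        report.reversal_genes = sorted({h.gene for h in reversal.hits})
        rev_df = pd.DataFrame(
            [
                {"gene": h.gene, "cell_type": h.cell_type,
                 "aging_effect": repr(h.aging_effect),
                 "parabiosis_effect": repr(h.parabiosis_effect),
                 "parabiosis_p_adj": repr(h.parabiosis_p_adj),
                 "mirnas": ",".join(h.mirnas)}
                for h in sorted(reversal.hits, key=lambda h: (h.gene, h.cell_type))
            ],
            columns=["gene", "cell_type", "aging_effect", "parabiosis_effect",
                     "parabiosis_p_adj", "mirnas"],
        )
        io_formats.write_tsv(rev_df, outdir / "reversal_hits.tsv", prov)
        log.info("stage %s: %.2fs", stage, time.perf_counter() - t0)

        # --- hypothalamus integration ------------------------------------------
        stage = "integrate-hypothalamus"
        t0 = time.perf_counter()
        hypo_spec = deg_integration.DEGFilterSpec(
            direction="up", effect_scale=deg_integration.LOG2_FC,
            threshold=config.hypo_log2fc_min, inclusive=False, alpha=config.alpha_deg,
        )
        hypo_table = io_formats.read_deg_table(
            config.deg_hypothalamus, "hypothalamus", deg_integration.LOG2_FC
        )
        hypo_filtered = deg_integration.filter_degs(hypo_table, hypo_spec)
        hypo_hits = deg_integration.intersect_targets(hypo_filtered, gene_to_mirnas, mouse_to_human)
        report.hits_hypothalamus = len(hypo_hits)
        widespread = deg_integration.widespread_genes(hypo_hits, config.min_types)
        report.widespread_genes = sorted(widespread)
        io_formats.write_tsv(_hits_df(hypo_hits), outdir / "hits_hypothalamus.tsv", prov)
        io_formats.write_tsv(
            pd.DataFrame(
                [{"gene": g, "n_cell_types": len(cts), "cell_types": ",".join(cts)}
                 for g, cts in sorted(widespread.items())],
                columns=["gene", "n_cell_types", "cell_types"],
            ),
            outdir / "widespread_genes.tsv", prov + [f"min_types {config.min_types}"],
        )
        log.info("stage %s: %.2fs", stage, time.perf_counter() - t0)

        # --- regulatory network -------------------------------------------------
        stage = "network"
        t0 = time.perf_counter()
        net = network_builder.build_network(aging_hits, mouse)
        # miRNA nodes are human ids; attach the mouse CSF logFC through the pairing
        csf = {p.human_id: next((m.csf_logfc_aging for m in mouse if m.id == p.mouse_id), None)
               for p in conserved}
        net.mirna_nodes = {m: csf.get(m) for m in net.mirna_nodes}
        summary = network_builder.network_summary(net)
        report.network_nodes = summary.n_mirnas + summary.n_genes
        report.network_edges = summary.n_edges
        io_formats.write_network(net, outdir / "network_aging.graphml", "graphml")
        io_formats.write_network(net, outdir / "network_aging.sif", "sif")
        log.info("stage %s: %.2fs", stage, time.perf_counter() - t0)

    except Exception as exc:  # noqa: BLE001 — report the failing stage, then re-raise
        marker.write_text(f"failed at stage {stage}: {exc}\n", encoding="utf-8")
        (outdir / "report.json.incomplete").write_text(report.to_json() + "\n", encoding="utf-8")
        raise StageError(stage, exc) from exc

    (outdir / "report.json").write_text(report.to_json() + "\n", encoding="utf-8")
    marker.unlink(missing_ok=True)
    return report


_ENRICH_COLUMNS = ["query", "pathway_id", "pathway_name", "k", "K", "n", "N",
                   "p", "q", "overlap_genes"]


def _enrichment_row(r) -> dict:
    return {
        "query": r.query_id, "pathway_id": r.pathway_id, "pathway_name": r.pathway_name,
        "k": r.k, "K": r.K, "n": r.n, "N": r.N,
        "p": f"{r.p:.6g}", "q": f"{r.q:.6g}", "overlap_genes": ",".join(r.overlap),
    }


def _hits_df(hits) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"dataset": h.dataset_id, "cell_type": h.cell_type, "gene": h.gene,
             "effect": repr(h.effect), "effect_scale": h.effect_scale,
             "p_adj": repr(h.p_adj), "mirnas": ",".join(h.mirnas)}
            for h in sorted(hits, key=lambda h: (h.gene, h.cell_type))
        ],
        columns=["dataset", "cell_type", "gene", "effect", "effect_scale", "p_adj", "mirnas"],
    )
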