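"""Synthetic inputs with planted, serialized ground truth.

The generator emulates the five pipeline inputs — miRNA panel,
validated-interaction table, pathway collection, gene ortholog table and
three cell-type-resolved DEG tables — with the statistical structure the
analysis assumes:

* pathway membership sampled uniformly; for each planted (miRNA, pathway)
  pair with enrichment factor f > 1, the fraction of the miRNA's targets
  inside the pathway is min(1, f*K/N) in expectation and exceeds the
  background rate K/N deterministically;
* null per-gene-per-cell-type effects log2FC ~ Normal(0, sigma_null) with
  adjusted p ~ Uniform(0,1), independent of the effect;
* planted records drawn from shifted distributions and rejection-sampled
  until they pass the published filters, so every planted instance is
  re-derivable from the emitted tables by applying those filters.

Planted enrichment pairs are assigned to pathways of at least
``planted_min_pathway_size`` members and to target sets of at least
``planted_min_targets`` genes: at the default enrichment factor a planted
pair in a tiny pathway would have an expected overlap of ~1 gene and would
not constitute recoverable ground truth.

Identical scenario + seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .deg_integration import (
    AGING_UP,
    HYPOTHALAMUS_UP,
    LINEAR_FC,
    LOG2_FC,
    LOGFC_ANY_BASE,
    PARABIOSIS_DOWN,
)
from .io_formats import (
    DEGTable,
    InteractionTable,
    OrthologRecord,
    OrthologTable,
    Pathway,
    PathwayCollection,
    collapse_interactions,
    write_deg_table,
    write_gmt,
    write_interactions,
    write_mirna_table,
    write_orthologs,
    write_tsv,
)
from .deg_integration import DEGRecord
from .mirna_orthology import MatureMiRNA
from .target_sets import TargetInteraction, classify_evidence

RNA = np.array(list("ACGU"))

STRONG_EXPERIMENTS = (
    "Luciferase reporter assay",
    "Western blot//qRT-PCR",
    "Luciferase reporter assay//Western blot",
)
WEAK_EXPERIMENTS = ("HITS-CLIP", "PAR-CLIP", "CLASH")

AGING_DATASET = "aging_brain"
PARABIOSIS_DATASET = "parabiosis_brain"
HYPOTHALAMUS_DATASET = "aged_hypothalamus"


@dataclass
class SyntheticScenario:
    """Scenario parameters; defaults match the scale of the emulated studies.

    10 analyzed miRNAs (after one non-conserved decoy is dropped from the
    input panel), ~2,000-gene universe, 150 pathways of 10-200 members,
    25/31/11 cell types for the aging, parabiosis and hypothalamus tables.
    """

    seed: int = 0
    n_genes: int = 2000
    n_pathways: int = 150
    pathway_size: tuple[int, int] = (10, 200)
    n_mirnas: int = 10
    target_set_size: tuple[int, int] = (50, 400)

    # planted pathway enrichment
    n_planted_pairs: int = 5
    enrichment_factor: float = 4.0
    planted_min_pathway_size: int = 100
    planted_min_targets: int = 200

    # miRNA panel
    n_decoy_nonconserved: int = 1
    mirna_length: int = 22

    # DEG-table cell types
    n_cell_types_aging: int = 25
    n_cell_types_parabiosis: int = 31
    n_cell_types_hypothalamus: int = 11

    # effect / p-value model
    sigma_null: float = 0.5
    mu_up: float = 2.0
    sigma_up: float = 0.5
    mu_rev: float = 1.0
    sigma_rev: float = 0.5
    beta_a: float = 0.05

    # planted DEG structure
    n_planted_aging: int = 12
    aging_multiplicity: tuple[int, int] = (2, 4)
    n_planted_reversal: int = 5
    n_planted_widespread: int = 7
    widespread_multiplicity: tuple[int, int] = (5, 8)

    def __post_init__(self) -> None:
        if self.enrichment_factor < 1:
            raise ValueError("enrichment factor must be >= 1")
        if self.mu_up <= math.log2(1.5):
            raise ValueError("mu_up must exceed log2(1.5) so planted effects clear the filter")
        if not 0 < self.beta_a <= 0.2:
            raise ValueError("beta_a must lie in (0, 0.2]")
        for name in ("sigma_null", "sigma_up", "sigma_rev", "mu_rev"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.widespread_multiplicity[0] < 5:
            raise ValueError("widespread planting needs multiplicity >= 5 cell types")
        if self.widespread_multiplicity[1] > self.n_cell_types_hypothalamus:
            raise ValueError("widespread multiplicity exceeds hypothalamus cell-type count")
        if self.n_planted_reversal > self.n_planted_aging:
            raise ValueError("reversal genes are a subset of planted aging genes")
        if self.n_planted_pairs > self.n_mirnas - self.n_decoy_nonconserved:
            raise ValueError("cannot plant more pairs than conserved miRNAs")
        if self.n_cell_types_parabiosis < self.n_cell_types_aging:
            raise ValueError("every aging cell type needs a parabiosis correspondent")


def load_scenario(path: str | Path) -> SyntheticScenario:
    """Read a scenario config (JSON or YAML) into a :class:`SyntheticScenario`."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: scenario config must be a mapping")
    valid = set(SyntheticScenario.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"{path}: unknown scenario key(s) {sorted(unknown)}")
    for key, val in data.items():
        if isinstance(val, list):
            data[key] = tuple(val)
    return SyntheticScenario(**data)


@dataclass(frozen=True)
class PlantedPair:
    mirna_id: str  # human mature id
    pathway_id: str
    factor: float


@dataclass
class GroundTruth:
    """Everything that was planted, keyed the way the pipeline reports it."""

    planted_pairs: list[PlantedPair] = field(default_factory=list)
    aging_genes: dict[str, list[str]] = field(default_factory=dict)  # mouse gene -> aging cell types
    reversal_genes: dict[str, list[str]] = field(default_factory=dict)  # mouse gene -> aging cell types
    widespread_genes: dict[str, list[str]] = field(default_factory=dict)  # mouse gene -> hypothalamus cell types
    nonconserved_mirnas: list[str] = field(default_factory=list)  # mouse ids

    def to_json(self) -> str:
        payload = {
            "planted_pairs": [asdict(p) for p in self.planted_pairs],
            "aging_genes": self.aging_genes,
            "reversal_genes": self.reversal_genes,
            "widespread_genes": self.widespread_genes,
            "nonconserved_mirnas": self.nonconserved_mirnas,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            planted_pairs=[PlantedPair(**p) for p in d["planted_pairs"]],
            aging_genes=d["aging_genes"],
            reversal_genes=d["reversal_genes"],
            widespread_genes=d["widespread_genes"],
            nonconserved_mirnas=d["nonconserved_mirnas"],
        )


@dataclass
class Universe:
    pathways: PathwayCollection
    interactions: InteractionTable
    orthologs: OrthologTable
    mouse_mirnas: list[MatureMiRNA]
    human_mirnas: list[MatureMiRNA]
    planted_pairs: list[PlantedPair]
    nonconserved_mirnas: list[str]

    @property
    def human_genes(self) -> list[str]:
        return [r.human for r in self.orthologs.records]


def _human_gene(i: int) -> str:
    return f"GENE{i:04d}"


def _mouse_gene(i: int) -> str:
    return f"Gene{i:04d}"


def _rng(sc: SyntheticScenario, stream: int) -> np.random.Generator:
    # independent, order-insensitive streams per stage
    return np.random.default_rng([sc.seed % (2**31), stream])


def simulate_universe(sc: SyntheticScenario) -> Universe:
    """Pathways, interactions, orthologs and the miRNA panel, with planted enrichment."""
    rng = _rng(sc, 0)
    genes = [_human_gene(i) for i in range(1, sc.n_genes + 1)]
    N = sc.n_genes

    # --- pathway collection -------------------------------------------------
    sizes = rng.integers(sc.pathway_size[0], sc.pathway_size[1] + 1, size=sc.n_pathways)
    pathways: dict[str, Pathway] = {}
    for j, K in enumerate(sizes, start=1):
        pid = f"R-SYN-{1000 + j}"
        members = rng.choice(N, size=int(K), replace=False)
        pathways[pid] = Pathway(
            id=pid,
            name=f"Synthetic pathway {j}",
            members=frozenset(genes[i] for i in members),
        )
    collection = PathwayCollection(pathways=pathways)

    # --- miRNA panel --------------------------------------------------------
    mouse_mirnas: list[MatureMiRNA] = []
    human_mirnas: list[MatureMiRNA] = []
    nonconserved: list[str] = []
    for i in range(1, sc.n_mirnas + 1):
        stem = f"miR-9{i:02d}-5p"
        seq = "".join(rng.choice(RNA, size=sc.mirna_length))
        mouse_seq = seq
        if i > sc.n_mirnas - sc.n_decoy_nonconserved:
            # decoy: mutate one seed position so the 7-mer differs
            pos = 3
            alt = [b for b in "ACGU" if b != seq[pos]]
            mouse_seq = seq[:pos] + str(rng.choice(alt)) + seq[pos + 1:]
            nonconserved.append(f"mmu-{stem}")
        csf_logfc = -abs(rng.normal(1.5, 0.5))
        mouse_mirnas.append(
            MatureMiRNA(id=f"mmu-{stem}", species="mouse", sequence=mouse_seq,
                        csf_logfc_aging=round(float(csf_logfc), 4))
        )
        human_mirnas.append(MatureMiRNA(id=f"hsa-{stem}", species="human", sequence=seq))

    conserved_human = [
        h.id for h, m in zip(human_mirnas, mouse_mirnas)
        if m.id not in nonconserved
    ]

    # --- planted enrichment pairs -------------------------------------------
    eligible = sorted(
        pid for pid, p in pathways.items() if len(p.members) >= sc.planted_min_pathway_size
    )
    if sc.n_planted_pairs > 0 and sc.enrichment_factor > 1:
        if len(eligible) < sc.n_planted_pairs:
            raise ValueError(
                f"only {len(eligible)} pathways reach planted_min_pathway_size="
                f"{sc.planted_min_pathway_size}; cannot plant {sc.n_planted_pairs} pairs"
            )
        chosen = rng.choice(len(eligible), size=sc.n_planted_pairs, replace=False)
        planted = [
            PlantedPair(mirna_id=conserved_human[j], pathway_id=eligible[int(c)],
                        factor=sc.enrichment_factor)
            for j, c in enumerate(chosen)
        ]
    else:
        planted = []
    planted_by_mirna = {p.mirna_id: p for p in planted}

    # --- target sets / interaction table ------------------------------------
    gene_index = {g: i for i, g in enumerate(genes)}
    records: list[TargetInteraction] = []
    for hm in human_mirnas:
        pair = planted_by_mirna.get(hm.id)
        if pair is not None:
            n_t = int(rng.integers(sc.planted_min_targets, sc.target_set_size[1] + 1))
            members = sorted(pathways[pair.pathway_id].members)
            K = len(members)
            frac = min(1.0, pair.factor * K / N)
            n_in = int(round(n_t * frac))
            if n_in <= n_t * K / N:
                n_in = int(n_t * K / N) + 1
            if n_in > min(n_t, K):
                raise ValueError(
                    f"infeasible enrichment for {hm.id}/{pair.pathway_id}: "
                    f"need {n_in} in-pathway targets but min(n, K) = {min(n_t, K)}"
                )
            inside = [members[i] for i in rng.choice(K, size=n_in, replace=False)]
            outside_pool = sorted(set(genes) - set(members))
            outside = [outside_pool[i] for i in
                       rng.choice(len(outside_pool), size=n_t - n_in, replace=False)]
            target_genes = inside + outside
        else:
            n_t = int(rng.integers(sc.target_set_size[0], sc.target_set_size[1] + 1))
            target_genes = [genes[i] for i in rng.choice(N, size=n_t, replace=False)]
        for g in target_genes:
            experiments = (
                str(rng.choice(STRONG_EXPERIMENTS)) if rng.random() < 0.6
                else str(rng.choice(WEAK_EXPERIMENTS))
            )
            exp_tuple = tuple(experiments.split("//"))
            records.append(
                TargetInteraction(
                    mirna_id=hm.id,
                    gene_human=g,
                    evidence=classify_evidence(exp_tuple),
                    experiments=exp_tuple,
                    n_refs=int(rng.integers(1, 6)),
                    gene_mouse=_mouse_gene(gene_index[g] + 1),
                )
            )
    interactions = InteractionTable(records=collapse_interactions(records), source="synthetic")

    # --- ortholog table (one-to-one) ----------------------------------------
    supports = rng.integers(1, 13, size=N)
    orthologs = OrthologTable(
        records=[
            OrthologRecord(human=_human_gene(i), mouse=_mouse_gene(i), support=int(s))
            for i, s in zip(range(1, N + 1), supports)
        ]
    )

    return Universe(
        pathways=collection, interactions=interactions, orthologs=orthologs,
        mouse_mirnas=mouse_mirnas, human_mirnas=human_mirnas,
        planted_pairs=planted, nonconserved_mirnas=nonconserved,
    )


def _truncated(draw, accept, max_tries: int = 10_000) -> float:
    for _ in range(max_tries):
        x = float(draw())
        if accept(x):
            return x
    raise RuntimeError("rejection sampling failed; check scenario parameters")


def aging_cell_type(i: int) -> str:
    return f"aging_ct{i:02d}"


def parabiosis_cell_type(i: int) -> str:
    return f"para_ct{i:02d}"


def hypothalamus_cell_type(i: int) -> str:
    return f"hypo_ct{i:02d}"


def default_cell_type_map(sc: SyntheticScenario) -> dict[str, str]:
    """Aging -> parabiosis cell-type correspondence (index-aligned)."""
    return {
        aging_cell_type(i): parabiosis_cell_type(i)
        for i in range(1, sc.n_cell_types_aging + 1)
    }


@dataclass
class ScenarioBundle:
    scenario: SyntheticScenario
    universe: Universe
    aging: DEGTable
    parabiosis: DEGTable
    hypothalamus: DEGTable
    cell_type_map: dict[str, str]
    truth: GroundTruth


def _null_grid(
    rng: np.random.Generator,
    dataset_id: str,
    genes_mouse: Sequence[str],
    cell_types: Sequence[str],
    sigma_null: float,
) -> dict[tuple[str, str], tuple[float, float]]:
    """(cell type, gene) -> (null log2 effect, null p_adj), vectorized."""
    n = len(genes_mouse) * len(cell_types)
    effects = rng.normal(0.0, sigma_null, size=n)
    pvals = rng.uniform(0.0, 1.0, size=n)
    out: dict[tuple[str, str], tuple[float, float]] = {}
    i = 0
    for ct in cell_types:
        for g in genes_mouse:
            out[(ct, g)] = (float(effects[i]), float(pvals[i]))
            i += 1
    return out


def simulate_deg_tables(
    sc: SyntheticScenario, universe: Universe
) -> tuple[DEGTable, DEGTable, DEGTable, GroundTruth]:
    """The three DEG tables plus ground truth listing every planted instance.

    Aging is emitted on the linear-FC scale (FC = 2^log2FC), parabiosis on
    an unspecified-base logFC scale, hypothalamus on log2FC — matching the
    scales of the emulated source studies.
    """
    rng = _rng(sc, 1)
    genes_mouse = [_mouse_gene(i) for i in range(1, sc.n_genes + 1)]
    aging_cts = [aging_cell_type(i) for i in range(1, sc.n_cell_types_aging + 1)]
    para_cts = [parabiosis_cell_type(i) for i in range(1, sc.n_cell_types_parabiosis + 1)]
    hypo_cts = [hypothalamus_cell_type(i) for i in range(1, sc.n_cell_types_hypothalamus + 1)]
    ct_map = default_cell_type_map(sc)

    # targets of conserved miRNAs, as mouse symbols (ortholog map is one-to-one)
    conserved_human_ids = {
        h.id for h, m in zip(universe.human_mirnas, universe.mouse_mirnas)
        if m.id not in universe.nonconserved_mirnas
    }
    human_to_mouse = {r.human: r.mouse for r in universe.orthologs.records}
    target_mouse = sorted(
        {
            human_to_mouse[r.gene_human]
            for r in universe.interactions.records
            if r.mirna_id in conserved_human_ids
        }
    )

    # --- choose planted genes ----------------------------------------------
    aging_idx = rng.choice(len(target_mouse), size=sc.n_planted_aging, replace=False)
    planted_aging = [target_mouse[int(i)] for i in aging_idx]
    reversal_idx = rng.choice(sc.n_planted_aging, size=sc.n_planted_reversal, replace=False)
    planted_reversal = [planted_aging[int(i)] for i in reversal_idx]
    widespread_idx = rng.choice(len(target_mouse), size=sc.n_planted_widespread, replace=False)
    planted_widespread = [target_mouse[int(i)] for i in widespread_idx]

    truth = GroundTruth(
        planted_pairs=list(universe.planted_pairs),
        nonconserved_mirnas=list(universe.nonconserved_mirnas),
    )

    log2_fc_min = math.log2(1.5)

    def up_effect(threshold: float) -> float:
        return _truncated(lambda: rng.normal(sc.mu_up, sc.sigma_up), lambda x: x > threshold)

    def sig_p() -> float:
        return _truncated(lambda: rng.beta(sc.beta_a, 1.0), lambda x: x < 0.05)

    # --- aging table (linear FC) --------------------------------------------
    aging_cells = _null_grid(rng, AGING_DATASET, genes_mouse, aging_cts, sc.sigma_null)
    for g in planted_aging:
        k = int(rng.integers(sc.aging_multiplicity[0], sc.aging_multiplicity[1] + 1))
        cts = [aging_cts[int(i)] for i in rng.choice(len(aging_cts), size=k, replace=False)]
        for ct in cts:
            aging_cells[(ct, g)] = (up_effect(log2_fc_min), sig_p())
        truth.aging_genes[g] = sorted(cts)

    # --- parabiosis table (logFC, unspecified base) --------------------------
    para_cells = _null_grid(rng, PARABIOSIS_DATASET, genes_mouse, para_cts, sc.sigma_null)
    for g in planted_reversal:
        for aging_ct in truth.aging_genes[g]:
            para_ct = ct_map.get(aging_ct)
            if para_ct is None:
                raise ValueError(
                    f"no parabiosis correspondence for aging cell type {aging_ct}"
                )
            eff = -abs(_truncated(lambda: rng.normal(sc.mu_rev, sc.sigma_rev),
                                  lambda x: x != 0.0))
            para_cells[(para_ct, g)] = (eff, sig_p())
        truth.reversal_genes[g] = sorted(truth.aging_genes[g])

    # --- hypothalamus table (log2FC) -----------------------------------------
    hypo_cells = _null_grid(rng, HYPOTHALAMUS_DATASET, genes_mouse, hypo_cts, sc.sigma_null)
    for g in planted_widespread:
        k = int(rng.integers(sc.widespread_multiplicity[0], sc.widespread_multiplicity[1] + 1))
        cts = [hypo_cts[int(i)] for i in rng.choice(len(hypo_cts), size=k, replace=False)]
        for ct in cts:
            hypo_cells[(ct, g)] = (up_effect(0.1), sig_p())
        truth.widespread_genes[g] = sorted(cts)

    def to_table(cells, dataset_id, scale, transform) -> DEGTable:
        records = [
            DEGRecord(dataset_id=dataset_id, cell_type=ct, gene=g,
                      effect=transform(eff), effect_scale=scale, p_adj=p)
            for (ct, g), (eff, p) in cells.items()
        ]
        return DEGTable(dataset_id=dataset_id, effect_scale=scale, records=records)

    aging = to_table(aging_cells, AGING_DATASET, LINEAR_FC, lambda x: float(2.0 ** x))
    parabiosis = to_table(para_cells, PARABIOSIS_DATASET, LOGFC_ANY_BASE, float)
    hypothalamus = to_table(hypo_cells, HYPOTHALAMUS_DATASET, LOG2_FC, float)
    return aging, parabiosis, hypothalamus, truth


def simulate_scenario(sc: SyntheticScenario) -> ScenarioBundle:
    """Run both stages and return every object the pipeline consumes."""
    universe = simulate_universe(sc)
    aging, parabiosis, hypothalamus, truth = simulate_deg_tables(sc, universe)
    return ScenarioBundle(
        scenario=sc, universe=universe, aging=aging, parabiosis=parabiosis,
        hypothalamus=hypothalamus, cell_type_map=default_cell_type_map(sc), truth=truth,
    )


def write_scenario(bundle: ScenarioBundle, outdir: str | Path) -> dict[str, Path]:
    """Emit every input file plus ground_truth.json and the scenario config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    u = bundle.universe
    paths = {
        "mirnas": outdir / "mirnas.tsv",
        "interactions": outdir / "interactions.tsv",
        "pathways": outdir / "pathways.gmt",
        "orthologs": outdir / "orthologs.tsv",
        "deg_aging": outdir / "deg_aging.tsv",
        "deg_parabiosis": outdir / "deg_parabiosis.tsv",
        "deg_hypothalamus": outdir / "deg_hypothalamus.tsv",
        "cell_type_map": outdir / "cell_type_map.tsv",
        "ground_truth": outdir / "ground_truth.json",
        "scenario": outdir / "scenario.json",
    }
    write_mirna_table(u.mouse_mirnas + u.human_mirnas, paths["mirnas"])
    write_interactions(u.interactions, paths["interactions"])
    write_gmt(u.pathways, paths["pathways"])
    write_orthologs(u.orthologs, paths["orthologs"])
    write_deg_table(bundle.aging, paths["deg_aging"])
    write_deg_table(bundle.parabiosis, paths["deg_parabiosis"])
    write_deg_table(bundle.hypothalamus, paths["deg_hypothalamus"])
    import pandas as pd

    write_tsv(
        pd.DataFrame(
            sorted(bundle.cell_type_map.items()), columns=["aging_type", "parabiosis_type"]
        ),
        paths["cell_type_map"],
    )
    paths["ground_truth"].write_text(bundle.truth.to_json() + "\n", encoding="utf-8")
    paths["scenario"].write_text(
        json.dumps(asdict(bundle.scenario), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths
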