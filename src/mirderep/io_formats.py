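"""Readers and writers for every external table and graph format.

All tabular inputs and outputs are UTF-8 TSV with a header row; lines
starting with "#" are comments (output files use them for provenance).
Pathway collections travel as standard GMT; networks as GraphML (full
attributes, round-trip safe), SIF (interaction label "targets") or a plain
edge TSV.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from ._util import check_species, norm_symbol
from .deg_integration import DEGRecord, EFFECT_SCALES, LINEAR_FC
from .mirna_orthology import MatureMiRNA
from .network_builder import (
    GENE_PREFIX,
    MIRNA_PREFIX,
    GeneNode,
    RegulatoryNetwork,
)
from .target_sets import STRONG, TargetInteraction, classify_evidence


class FormatError(ValueError):
    """Malformed or invariant-violating input file."""


# ---------------------------------------------------------------------------
# generic TSV plumbing


def _read_tsv(path: str | Path, required: Sequence[str], dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a commented TSV, rename columns per ``dialect`` (ours -> theirs)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if dialect:
        rename = {theirs: ours for ours, theirs in dialect.items()}
        missing_src = [theirs for theirs in dialect.values() if theirs not in df.columns]
        if missing_src:
            raise FormatError(f"{path}: missing required column(s) {missing_src}")
        df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, provenance: Sequence[str] = ()) -> None:
    """Write a TSV with optional "#" provenance comment lines before the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    for line in provenance:
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# interactions


DEFAULT_INTERACTION_COLUMNS = {
    "mirna": "mirna",
    "gene": "gene",
    "species": "species",
    "experiments": "experiments",
}
EXPERIMENT_SEPARATOR = "//"


@dataclass
class InteractionTable:
    """Validated miRNA->gene interactions, duplicates collapsed to strongest evidence."""

    records: list[TargetInteraction]
    source: str = ""

    def mirnas(self) -> list[str]:
        return sorted({r.mirna_id for r in self.records})

    def genes(self) -> list[str]:
        return sorted({r.gene_human for r in self.records})


def collapse_interactions(records: Iterable[TargetInteraction]) -> list[TargetInteraction]:
    """Collapse duplicate (miRNA, gene) rows: strongest evidence wins, references pool."""
    merged: dict[tuple[str, str], TargetInteraction] = {}
    for rec in records:
        key = (rec.mirna_id, norm_symbol(rec.gene_human))
        prev = merged.get(key)
        if prev is None:
            merged[key] = rec
            continue
        experiments = prev.experiments + tuple(
            e for e in rec.experiments if e not in prev.experiments
        )
        merged[key] = TargetInteraction(
            mirna_id=prev.mirna_id,
            gene_human=prev.gene_human,
            evidence=STRONG if STRONG in (prev.evidence, rec.evidence) else prev.evidence,
            experiments=experiments,
            n_refs=prev.n_refs + rec.n_refs,
            gene_mouse=prev.gene_mouse or rec.gene_mouse,
        )
    return sorted(merged.values(), key=lambda r: (r.mirna_id, norm_symbol(r.gene_human)))


def read_interactions(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    strong_vocabulary: Iterable[str] | None = None,
) -> InteractionTable:
    """Load a validated-interaction TSV (miRTarBase-style).

    Requires miRNA id, target gene, species and an experiments/support-type
    column (labels separated by "//"); an optional ``references`` column
    counts supporting publications (default 1). Evidence class is assigned
    per :func:`mirderep.target_sets.classify_evidence`.
    """
    df = _read_tsv(path, list(DEFAULT_INTERACTION_COLUMNS), dialect)
    kwargs = {} if strong_vocabulary is None else {"strong_vocabulary": strong_vocabulary}
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        check_species(getattr(row, "species"), row=i)
        experiments = tuple(
            e.strip() for e in getattr(row, "experiments").split(EXPERIMENT_SEPARATOR) if e.strip()
        )
        if not experiments:
            raise FormatError(f"{path}: row {i}: empty experiments field")
        n_refs = int(getattr(row, "references", 1) or 1) if hasattr(row, "references") else 1
        records.append(
            TargetInteraction(
                mirna_id=getattr(row, "mirna"),
                gene_human=getattr(row, "gene"),
                evidence=classify_evidence(experiments, **kwargs),
                experiments=experiments,
                n_refs=n_refs,
            )
        )
    return InteractionTable(records=collapse_interactions(records), source=str(path))


def write_interactions(table: InteractionTable, path: str | Path,
                       provenance: Sequence[str] = ()) -> None:
    df = pd.DataFrame(
        [
            {
                "mirna": r.mirna_id,
                "gene": r.gene_human,
                "species": "human",
                "experiments": EXPERIMENT_SEPARATOR.join(r.experiments),
                "references": r.n_refs,
            }
            for r in table.records
        ],
        columns=["mirna", "gene", "species", "experiments", "references"],
    )
    write_tsv(df, path, provenance)


# ---------------------------------------------------------------------------
# pathways (GMT)


@dataclass(frozen=True)
class Pathway:
    id: str
    name: str
    members: frozenset[str]
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"pathway {self.id} has an empty member set")


@dataclass
class PathwayCollection:
    pathways: dict[str, Pathway]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for p in self.pathways.values():
            out |= p.members
        return out

    def __len__(self) -> int:
        return len(self.pathways)


def read_gmt(path: str | Path) -> PathwayCollection:
    """Load a GMT file: one pathway per line — id, description, tab-separated members."""
    pathways: dict[str, Pathway] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            pid, name, *members = fields
            members = [m for m in members if m]
            if pid in pathways:
                raise FormatError(f"{path}: line {lineno}: duplicate pathway id {pid!r}")
            pathways[pid] = Pathway(id=pid, name=name, members=frozenset(members))
    return PathwayCollection(pathways=pathways)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        "\t".join([p.id, p.name, *sorted(p.members)])
        for p in (collection.pathways[k] for k in sorted(collection.pathways))
    ]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# DEG tables


DEFAULT_DEG_COLUMNS = {"cell_type": "cell_type", "gene": "gene",
                       "effect": "effect", "p_adj": "p_adj"}


@dataclass
class DEGTable:
    """Long-format differential-expression table with a declared effect scale."""

    dataset_id: str
    effect_scale: str
    records: list[DEGRecord]

    def cell_types(self) -> list[str]:
        return sorted({r.cell_type for r in self.records})


def read_deg_table(
    path: str | Path,
    dataset_id: str,
    effect_scale: str,
    dialect: Mapping[str, str] | None = None,
) -> DEGTable:
    """Load a long-format DEG TSV (cell_type, gene, effect, p_adj).

    Effects are stored on their declared scale, untransformed. Records
    violating the invariants (p_adj outside [0,1]; non-positive linear fold
    change; duplicate (cell type, gene)) are rejected with row numbers.
    """
    if effect_scale not in EFFECT_SCALES:
        raise FormatError(f"unknown effect scale {effect_scale!r}")
    df = _read_tsv(path, list(DEFAULT_DEG_COLUMNS), dialect)
    records: list[DEGRecord] = []
    seen: set[tuple[str, str]] = set()
    bad_rows: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            effect = float(getattr(row, "effect"))
            p_adj = float(getattr(row, "p_adj"))
            if math.isnan(effect) or math.isnan(p_adj):
                raise ValueError("NaN value")
            rec = DEGRecord(
                dataset_id=dataset_id,
                cell_type=getattr(row, "cell_type"),
                gene=getattr(row, "gene"),
                effect=effect,
                effect_scale=effect_scale,
                p_adj=p_adj,
            )
            key = (rec.cell_type, norm_symbol(rec.gene))
            if key in seen:
                raise ValueError(f"duplicate (cell type, gene) entry {key}")
            seen.add(key)
        except ValueError as exc:
            bad_rows.append(f"row {i}: {exc}")
            continue
        records.append(rec)
    if bad_rows:
        raise FormatError(f"{path}: invalid records:\n  " + "\n  ".join(bad_rows))
    return DEGTable(dataset_id=dataset_id, effect_scale=effect_scale, records=records)


def write_deg_table(table: DEGTable, path: str | Path, provenance: Sequence[str] = ()) -> None:
    df = pd.DataFrame(
        [
            {"cell_type": r.cell_type, "gene": r.gene,
             "effect": repr(r.effect), "p_adj": repr(r.p_adj)}
            for r in table.records
        ],
        columns=["cell_type", "gene", "effect", "p_adj"],
    )
    write_tsv(df, path, provenance)


# ---------------------------------------------------------------------------
# gene orthologs


@dataclass(frozen=True)
class OrthologRecord:
    human: str
    mouse: str
    support: int

    def __post_init__(self) -> None:
        if not self.human or not self.mouse:
            raise FormatError("ortholog symbols must be non-empty")
        if self.support < 1:
            raise FormatError(f"support count must be >= 1, got {self.support}")


@dataclass
class OrthologTable:
    records: list[OrthologRecord]


def read_orthologs(path: str | Path, dialect: Mapping[str, str] | None = None) -> OrthologTable:
    """Load a human<->mouse ortholog TSV (human, mouse, support)."""
    df = _read_tsv(path, ["human", "mouse", "support"], dialect)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                OrthologRecord(
                    human=getattr(row, "human"),
                    mouse=getattr(row, "mouse"),
                    support=int(getattr(row, "support")),
                )
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from exc
    return OrthologTable(records=records)


def write_orthologs(table: OrthologTable, path: str | Path, provenance: Sequence[str] = ()) -> None:
    df = pd.DataFrame(
        [{"human": r.human, "mouse": r.mouse, "support": r.support} for r in table.records],
        columns=["human", "mouse", "support"],
    )
    write_tsv(df, path, provenance)


def read_cell_type_map(path: str | Path) -> dict[str, str]:
    """Load an aging -> parabiosis cell-type correspondence TSV."""
    df = _read_tsv(path, ["aging_type", "parabiosis_type"])
    return dict(zip(df["aging_type"], df["parabiosis_type"]))


# ---------------------------------------------------------------------------
# miRNA tables


def read_mirna_table(path: str | Path, dialect: Mapping[str, str] | None = None) -> list[MatureMiRNA]:
    """Load a mature-miRNA TSV (id, species, sequence, optional csf_logfc)."""
    df = _read_tsv(path, ["id", "species", "sequence"], dialect)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        species = check_species(getattr(row, "species"), row=i)
        raw = getattr(row, "csf_logfc", "") if hasattr(row, "csf_logfc") else ""
        logfc = float(raw) if raw not in ("", "NA") else None
        out.append(
            MatureMiRNA(
                id=getattr(row, "id"), species=species,
                sequence=getattr(row, "sequence").upper().replace("T", "U"),
                csf_logfc_aging=logfc,
            )
        )
    return out


def write_mirna_table(mirnas: Sequence[MatureMiRNA], path: str | Path,
                      provenance: Sequence[str] = ()) -> None:
    df = pd.DataFrame(
        [
            {"id": m.id, "species": m.species, "sequence": m.sequence,
             "csf_logfc": "" if m.csf_logfc_aging is None else repr(m.csf_logfc_aging)}
            for m in mirnas
        ],
        columns=["id", "species", "sequence", "csf_logfc"],
    )
    write_tsv(df, path, provenance)


# ---------------------------------------------------------------------------
# networks


NETWORK_FORMATS = ("graphml", "sif", "edge-tsv")


def write_network(net: RegulatoryNetwork, path: str | Path, format: str = "graphml") -> None:
    """Serialize a regulatory network.

    GraphML carries all node attributes and round-trips through
    :func:`read_network`; SIF writes one "mirna targets gene" line per
    edge; edge-tsv is a two-column header TSV.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "graphml":
        g = net.to_networkx()
        nx.write_graphml(g, path, named_key_ids=True, edge_id_from_attribute=None)
    elif format == "sif":
        lines = [f"{m}\ttargets\t{g}" for m, g in sorted(net.edges)]
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    elif format == "edge-tsv":
        df = pd.DataFrame(sorted(net.edges), columns=["mirna", "gene"])
        write_tsv(df, path)
    else:
        raise ValueError(f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}")


def read_network(path: str | Path) -> RegulatoryNetwork:
    """Read a GraphML file written by :func:`write_network` back into a network."""
    g = nx.read_graphml(path)
    mirna_nodes: dict[str, float | None] = {}
    gene_nodes: dict[str, GeneNode] = {}
    for node, attrs in g.nodes(data=True):
        if attrs.get("node_class") == "miRNA":
            mid = node[len(MIRNA_PREFIX):] if node.startswith(MIRNA_PREFIX) else node
            logfc = attrs.get("csf_logfc_aging")
            mirna_nodes[mid] = None if logfc is None else float(logfc)
        elif attrs.get("node_class") == "gene":
            sym = node[len(GENE_PREFIX):] if node.startswith(GENE_PREFIX) else node
            cts = attrs.get("cell_types", "")
            gene_nodes[sym] = GeneNode(
                symbol=sym,
                max_effect=float(attrs["max_effect"]),
                cell_types=tuple(cts.split("|")) if cts else (),
            )
        else:
            raise FormatError(f"{path}: node {node!r} lacks a miRNA/gene class attribute")
    edges = set()
    for u, v in g.edges():
        if not u.startswith(MIRNA_PREFIX):
            u, v = v, u
        edges.add((u[len(MIRNA_PREFIX):], v[len(GENE_PREFIX):]))
    return RegulatoryNetwork(
        mirna_nodes=mirna_nodes,
        gene_nodes=gene_nodes,
        edges=frozenset(edges),
        effect_scale=g.graph.get("effect_scale"),
    )
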