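"""Per-miRNA experimentally validated target gene sets.

Interaction databases tier their support into "strong" functional assays
(reporter assays, Western blot, qPCR) and "weak" high-throughput evidence
(CLIP-seq family, CLASH, degradome). A (miRNA, gene) pair is classified
strong as soon as any listed experiment matches the strong-assay
vocabulary; the vocabulary is configurable because database label
spellings vary between releases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ._util import norm_symbol

log = logging.getLogger(__name__)

STRONG = "strong"
WEAK = "weak"

#: Substrings (lower-case) marking a functional, single-gene validation assay.
DEFAULT_STRONG_ASSAYS: frozenset[str] = frozenset(
    {"reporter assay", "luciferase", "western blot", "qpcr", "qrt-pcr"}
)


def classify_evidence(
    experiments: Sequence[str],
    strong_vocabulary: Iterable[str] = DEFAULT_STRONG_ASSAYS,
) -> str:
    """Return ``"strong"`` iff any experiment matches the strong-assay vocabulary."""
    if not experiments:
        raise ValueError("classify_evidence requires at least one experiment label")
    vocab = [v.lower() for v in strong_vocabulary]
    for exp in experiments:
        token = exp.lower()
        if any(v in token for v in vocab):
            return STRONG
    return WEAK


@dataclass(frozen=True)
class TargetInteraction:
    """One validated miRNA -> gene record (human ids; optional mouse ortholog)."""

    mirna_id: str
    gene_human: str
    evidence: str  # "strong" | "weak"
    experiments: tuple[str, ...]
    n_refs: int = 1
    gene_mouse: str | None = None

    def __post_init__(self) -> None:
        if self.evidence not in (STRONG, WEAK):
            raise ValueError(f"evidence must be strong|weak, got {self.evidence!r}")
        if self.n_refs < 1:
            raise ValueError(f"reference count must be >= 1, got {self.n_refs}")


@dataclass(frozen=True)
class TargetSet:
    mirna_id: str
    genes: frozenset[str]
    policy: str  # "strong-only" | "all"


def build_target_sets(
    table: "io_formats.InteractionTable",  # noqa: F821 — forward ref
    mirnas: Sequence[str],
    policy: str = "all",
) -> list[TargetSet]:
    """One :class:`TargetSet` per requested human miRNA id (possibly empty).

    Under ``strong-only``, genes supported only by high-throughput evidence
    are excluded. Symbols are de-duplicated case-insensitively, keeping the
    first spelling seen.
    """
    if policy not in ("strong-only", "all"):
        raise ValueError(f"unknown evidence policy {policy!r}")
    by_mirna: dict[str, dict[str, str]] = {m: {} for m in mirnas}
    wanted = set(mirnas)
    for rec in table.records:
        if rec.mirna_id not in wanted:
            continue
        if policy == "strong-only" and rec.evidence != STRONG:
            continue
        by_mirna[rec.mirna_id].setdefault(norm_symbol(rec.gene_human), rec.gene_human)
    sets = []
    for m in mirnas:
        genes = frozenset(by_mirna[m].values())
        if not genes:
            log.warning("miRNA %s has no interactions under policy %s", m, policy)
        sets.append(TargetSet(mirna_id=m, genes=genes, policy=policy))
    return sets


def invert_index(sets: Iterable[TargetSet]) -> dict[str, list[str]]:
    """gene -> lexicographically sorted list of miRNAs whose sets contain it."""
    index: dict[str, set[str]] = {}
    for ts in sets:
        for g in ts.genes:
            index.setdefault(g, set()).add(ts.mirna_id)
    return {g: sorted(ms) for g, ms in index.items()}
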