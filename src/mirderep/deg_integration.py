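"""Dataset-specific DEG filters and their intersection with miRNA target sets.

Three published filter rules are applied literally, including their
boundary semantics:

* aging atlas (25 brain cell types): TPM-based fold change >= 1.5
  (inclusive) and adjusted p < 0.05 — upregulated with age;
* heterochronic parabiosis (31 cell types): logFC < 0 (strict) and
  adjusted p < 0.05 — reversed in the old heterochronic parabiont;
* aged hypothalamus (11 cell types): log2FC > 0.1 (strict) and adjusted
  p < 0.05 — upregulated with age.

Surviving genes are intersected with the miRNA target sets (through the
human<->mouse gene ortholog bridge) to give "derepression hits": genes
whose age-related rise is consistent with loss of their repressing miRNA.
Recurrence (>= 2 cell classes), widespread upregulation (>= 5 cell types
in one dataset) and parabiosis reversal are computed from the hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._util import norm_symbol

log = logging.getLogger(__name__)

LINEAR_FC = "linear-FC"
LOG2_FC = "log2FC"
LOGFC_ANY_BASE = "logFC-unspecified-base"
EFFECT_SCALES = frozenset({LINEAR_FC, LOG2_FC, LOGFC_ANY_BASE})


class ScaleMismatchError(ValueError):
    """A filter spec was applied to a table on a different effect scale."""


@dataclass(frozen=True)
class DEGRecord:
    """One gene x cell-type differential-expression entry."""

    dataset_id: str
    cell_type: str
    gene: str  # mouse symbol
    effect: float
    effect_scale: str
    p_adj: float

    def __post_init__(self) -> None:
        if self.effect_scale not in EFFECT_SCALES:
            raise ValueError(f"unknown effect scale {self.effect_scale!r}")
        if not 0.0 <= self.p_adj <= 1.0:
            raise ValueError(f"adjusted p must lie in [0,1], got {self.p_adj}")
        if self.effect_scale == LINEAR_FC and self.effect <= 0:
            raise ValueError(f"linear fold change must be > 0, got {self.effect}")


@dataclass(frozen=True)
class DEGFilterSpec:
    """A dataset-specific threshold rule with explicit boundary semantics."""

    direction: str  # "up" | "down"
    effect_scale: str
    threshold: float
    inclusive: bool  # True: >= / <= at the boundary; False: strict > / <
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up|down, got {self.direction!r}")
        if self.effect_scale not in EFFECT_SCALES:
            raise ValueError(f"unknown effect scale {self.effect_scale!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0,1), got {self.alpha}")

    def passes(self, record: DEGRecord) -> bool:
        if record.p_adj >= self.alpha:
            return False
        e, t = record.effect, self.threshold
        if self.direction == "up":
            return e >= t if self.inclusive else e > t
        return e <= t if self.inclusive else e < t


#: Aging brain atlas: TPM-based FC >= 1.5 (boundary kept), adjusted p < 0.05.
AGING_UP = DEGFilterSpec(direction="up", effect_scale=LINEAR_FC, threshold=1.5,
                         inclusive=True, alpha=0.05)
#: Heterochronic parabiosis: logFC < 0 (strict), adjusted p < 0.05.
PARABIOSIS_DOWN = DEGFilterSpec(direction="down", effect_scale=LOGFC_ANY_BASE,
                                threshold=0.0, inclusive=False, alpha=0.05)
#: Aged hypothalamus: log2FC > 0.1 (strict), adjusted p < 0.05.
HYPOTHALAMUS_UP = DEGFilterSpec(direction="up", effect_scale=LOG2_FC, threshold=0.1,
                                inclusive=False, alpha=0.05)


def filter_degs(table: "io_formats.DEGTable", spec: DEGFilterSpec) -> list[DEGRecord]:  # noqa: F821
    """Records meeting the spec's direction/threshold/alpha rule. Idempotent.

    The table's declared effect scale must match the spec's expected scale;
    no silent conversion is ever attempted.
    """
    if table.effect_scale != spec.effect_scale:
        raise ScaleMismatchError(
            f"table {table.dataset_id!r} is on scale {table.effect_scale!r} "
            f"but the filter expects {spec.effect_scale!r}"
        )
    return [r for r in table.records if spec.passes(r)]


@dataclass(frozen=True)
class DerepressionHit:
    """An age-upregulated gene that is a validated target of >= 1 seed miRNA."""

    gene: str  # mouse symbol as loaded
    cell_type: str
    effect: float
    effect_scale: str
    p_adj: float
    mirnas: tuple[str, ...]
    dataset_id: str

    def __post_init__(self) -> None:
        if not self.mirnas:
            raise ValueError("a derepression hit must be targeted by >= 1 miRNA")


def intersect_targets(
    filtered: Iterable[DEGRecord],
    gene_to_mirnas: Mapping[str, Sequence[str]],
    mouse_to_human: Mapping[str, str],
) -> list[DerepressionHit]:
    """Keep filtered records whose mouse symbol maps to a targeted human symbol.

    ``gene_to_mirnas`` is keyed by human symbols (the inverted target
    index); ``mouse_to_human`` bridges mouse DEG symbols to human target
    symbols. Unmapped genes are counted in the log, not raised.
    """
    index = {norm_symbol(g): tuple(sorted(ms)) for g, ms in gene_to_mirnas.items()}
    bridge = {norm_symbol(m): h for m, h in mouse_to_human.items()}
    hits: list[DerepressionHit] = []
    unmapped = 0
    for rec in filtered:
        human = bridge.get(norm_symbol(rec.gene))
        if human is None:
            unmapped += 1
            continue
        mirnas = index.get(norm_symbol(human))
        if not mirnas:
            continue
        hits.append(
            DerepressionHit(
                gene=rec.gene, cell_type=rec.cell_type, effect=rec.effect,
                effect_scale=rec.effect_scale, p_adj=rec.p_adj,
                mirnas=mirnas, dataset_id=rec.dataset_id,
            )
        )
    if unmapped:
        log.info("%d filtered DEG records had no human ortholog and were skipped", unmapped)
    return hits


def _group_cell_types(
    hits: Iterable[DerepressionHit],
    rollup: Mapping[str, str] | None = None,
) -> dict[str, set[str]]:
    groups: dict[str, set[str]] = {}
    for h in hits:
        group = rollup.get(h.cell_type, h.cell_type) if rollup else h.cell_type
        groups.setdefault(h.gene, set()).add(group)
    return groups


def recurrent_genes(
    hits: Iterable[DerepressionHit],
    min_groups: int = 2,
    rollup: Mapping[str, str] | None = None,
) -> dict[str, list[str]]:
    """Genes hit in >= ``min_groups`` distinct cell classes, with their lists.

    ``rollup`` optionally maps cell types onto coarser cell classes before
    counting; without it, types are the grouping.
    """
    if min_groups < 1:
        raise ValueError("min_groups must be >= 1")
    return {
        g: sorted(cts)
        for g, cts in _group_cell_types(hits, rollup).items()
        if len(cts) >= min_groups
    }


def widespread_genes(
    hits: Iterable[DerepressionHit],
    min_types: int = 5,
) -> dict[str, list[str]]:
    """Genes hit in >= ``min_types`` distinct cell types of one dataset."""
    if min_types < 1:
        raise ValueError("min_types must be >= 1")
    hits = list(hits)
    datasets = {h.dataset_id for h in hits}
    if len(datasets) > 1:
        raise ValueError(f"widespread_genes expects one dataset, got {sorted(datasets)}")
    return {
        g: sorted(cts)
        for g, cts in _group_cell_types(hits).items()
        if len(cts) >= min_types
    }


@dataclass(frozen=True)
class ReversalHit:
    """A target gene up with aging whose expression drops under heterochronic parabiosis."""

    gene: str
    cell_type: str  # aging-dataset vocabulary
    aging_effect: float
    parabiosis_effect: float
    parabiosis_p_adj: float
    mirnas: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.parabiosis_effect >= 0:
            raise ValueError("a reversal requires a negative parabiosis effect")


@dataclass
class ReversalReport:
    hits: list[ReversalHit]
    skipped_cell_types: list[str] = field(default_factory=list)


def detect_reversal(
    aging_hits: Sequence[DerepressionHit],
    parabiosis: "io_formats.DEGTable",  # noqa: F821
    spec_down: DEGFilterSpec = PARABIOSIS_DOWN,
    cell_type_map: Mapping[str, str] | None = None,
) -> ReversalReport:
    """Aging hits that also pass the parabiosis down-filter in the matching cell type.

    The aging and parabiosis atlases use different cell-type vocabularies
    (25 vs 31 types), reconciled by an explicit ``cell_type_map``
    (aging type -> parabiosis type); a hit cell type missing from the map
    is an error listing every unmapped type. A mapped type absent from the
    parabiosis table itself yields no hit and is recorded in the report.
    """
    cell_type_map = dict(cell_type_map or {})
    unmapped = sorted({h.cell_type for h in aging_hits} - set(cell_type_map))
    if unmapped:
        raise ValueError(
            "aging cell types missing from the correspondence map: " + ", ".join(unmapped)
        )
    down = filter_degs(parabiosis, spec_down)
    down_index = {(norm_symbol(r.gene), r.cell_type): r for r in down}
    parabiosis_types = {r.cell_type for r in parabiosis.records}

    hits: list[ReversalHit] = []
    skipped: set[str] = set()
    for h in aging_hits:
        target_type = cell_type_map[h.cell_type]
        if target_type not in parabiosis_types:
            skipped.add(h.cell_type)
            continue
        rec = down_index.get((norm_symbol(h.gene), target_type))
        if rec is None:
            continue
        hits.append(
            ReversalHit(
                gene=h.gene, cell_type=h.cell_type, aging_effect=h.effect,
                parabiosis_effect=rec.effect, parabiosis_p_adj=rec.p_adj,
                mirnas=h.mirnas,
            )
        )
    if skipped:
        log.info("aging cell types absent from the parabiosis table: %s",
                 ", ".join(sorted(skipped)))
    return ReversalReport(hits=hits, skipped_cell_types=sorted(skipped))
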