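"""Mouse -> human mature-miRNA ortholog mapping and seed conservation.

Mature miRNAs of one family are 5'-aligned; the 7-mer seed (nucleotides
2-8 of the mature sequence, 1-based) is the primary determinant of target
pairing. A mouse miRNA is analyzed through its human ortholog only when
the two seeds are strictly identical; non-conserved miRNAs are dropped
with a logged reason. Sequence identity is reported as a descriptive
statistic but never used for filtering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

SEED_START = 1  # 0-based offset of seed position 2
SEED_LENGTH = 7


class AmbiguousOrthologError(ValueError):
    """One mouse miRNA matches several human candidates by name stem."""


def extract_seed(sequence: str) -> str:
    """Return the 7-mer seed: positions 2-8 (1-based) of a mature sequence.

    DNA-alphabet input (T instead of U) is converted with a warning rather
    than rejected.
    """
    seq = sequence.strip().upper()
    if "T" in seq:
        warnings.warn(
            "DNA alphabet detected; converting T -> U", UserWarning, stacklevel=2
        )
        seq = seq.replace("T", "U")
    if len(seq) < SEED_START + SEED_LENGTH:
        raise ValueError(f"sequence too short for seed: {sequence!r} (length {len(seq)} < 8)")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid RNA characters {sorted(bad)} in {sequence!r}")
    return seq[SEED_START : SEED_START + SEED_LENGTH]


def pair_identity(a: str, b: str) -> float:
    """Left-anchored positionwise identity over the longer length.

    Returns 1.0 iff the strings are identical; symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("pair_identity requires two non-empty sequences")
    matches = sum(x == y for x, y in zip(a, b))
    return matches / max(len(a), len(b))


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA with its seed and (mouse only) CSF aging log-fold-change."""

    id: str
    species: str  # "human" | "mouse"
    sequence: str
    seed: str = ""
    csf_logfc_aging: float | None = None

    def __post_init__(self) -> None:
        if self.species not in ("human", "mouse"):
            raise ValueError(f"unknown species {self.species!r}")
        if not self.seed:
            object.__setattr__(self, "seed", extract_seed(self.sequence))
        if len(self.seed) != SEED_LENGTH:
            raise ValueError(f"seed must be a 7-mer, got {self.seed!r}")
        if self.seed != self.sequence.upper().replace("T", "U")[SEED_START : SEED_START + SEED_LENGTH]:
            raise ValueError(f"seed {self.seed!r} is not positions 2-8 of {self.sequence!r}")

    @property
    def name_stem(self) -> str:
        """Id without the species prefix: 'mmu-miR-17-5p' -> 'miR-17-5p'."""
        for prefix in ("mmu-", "hsa-"):
            if self.id.startswith(prefix):
                return self.id[len(prefix):]
        return self.id


@dataclass(frozen=True)
class MiRNAOrthologPair:
    mouse_id: str
    human_id: str
    identity: float
    seed_conserved: bool


@dataclass
class OrthologyReport:
    """Pairs plus the bookkeeping the pipeline report needs."""

    pairs: list[MiRNAOrthologPair]
    unmatched_mouse: list[str] = field(default_factory=list)


def map_mirna_orthologs(
    mouse: Sequence[MatureMiRNA],
    human: Sequence[MatureMiRNA],
    name_map: Mapping[str, str] | None = None,
) -> OrthologyReport:
    """Pair each mouse miRNA with its human ortholog.

    Pairing is by explicit ``name_map`` (mouse id -> human id) when given,
    otherwise by name stem (species prefix stripped). Mouse miRNAs with no
    human match are reported, not silently dropped; several human
    candidates for one stem without an explicit entry raise
    :class:`AmbiguousOrthologError`.
    """
    name_map = dict(name_map or {})
    human_by_id = {m.id: m for m in human}
    human_by_stem: dict[str, list[MatureMiRNA]] = {}
    for m in human:
        human_by_stem.setdefault(m.name_stem, []).append(m)

    for mouse_id, human_id in name_map.items():
        if mouse_id not in {m.id for m in mouse}:
            raise ValueError(f"name_map references unknown mouse miRNA {mouse_id!r}")
        if human_id not in human_by_id:
            raise ValueError(f"name_map references unknown human miRNA {human_id!r}")

    pairs: list[MiRNAOrthologPair] = []
    unmatched: list[str] = []
    for mm in mouse:
        if mm.id in name_map:
            hm = human_by_id[name_map[mm.id]]
        else:
            candidates = human_by_stem.get(mm.name_stem, [])
            if not candidates:
                unmatched.append(mm.id)
                continue
            if len(candidates) > 1:
                names = ", ".join(sorted(c.id for c in candidates))
                raise AmbiguousOrthologError(
                    f"{mm.id} matches several human miRNAs ({names}); "
                    f"disambiguate via name_map"
                )
            hm = candidates[0]
        pairs.append(
            MiRNAOrthologPair(
                mouse_id=mm.id,
                human_id=hm.id,
                identity=pair_identity(mm.sequence.upper().replace("T", "U"),
                                       hm.sequence.upper().replace("T", "U")),
                seed_conserved=mm.seed == hm.seed,
            )
        )
    if unmatched:
        log.info("%d mouse miRNAs had no human ortholog match: %s",
                 len(unmatched), ", ".join(unmatched))
    return OrthologyReport(pairs=pairs, unmatched_mouse=unmatched)


@dataclass(frozen=True)
class ExclusionRecord:
    mirna_id: str
    reason: str


def filter_conserved(
    pairs: Iterable[MiRNAOrthologPair],
) -> tuple[list[MiRNAOrthologPair], list[ExclusionRecord]]:
    """Keep exactly the seed-conserved pairs; log every exclusion by name."""
    kept: list[MiRNAOrthologPair] = []
    excluded: list[ExclusionRecord] = []
    for p in pairs:
        if p.seed_conserved:
            kept.append(p)
        else:
            rec = ExclusionRecord(p.mouse_id, "seed not conserved between mouse and human ortholog")
            excluded.append(rec)
            log.info("excluded %s: %s", rec.mirna_id, rec.reason)
    return kept, excluded


def map_gene_orthologs(
    genes: Iterable[str],
    table: "io_formats.OrthologTable",  # noqa: F821 — forward ref, avoids import cycle
    policy: str = "best-support",
) -> tuple[dict[str, list[str]], list[str]]:
    """Map human gene symbols to mouse orthologs via an orthology-prediction table.

    Under ``best-support`` each human gene maps to the single mouse symbol
    with the highest support count (ties broken lexicographically and
    logged); under ``keep-all`` every predicted ortholog is kept. Genes
    absent from the table map to an empty list and are returned in the
    unmapped report.
    """
    if policy not in ("keep-all", "best-support"):
        raise ValueError(f"unknown policy {policy!r}")
    from ._util import norm_symbol

    by_human: dict[str, list[tuple[str, int]]] = {}
    spelling: dict[str, str] = {}
    for rec in table.records:
        key = norm_symbol(rec.human)
        by_human.setdefault(key, []).append((rec.mouse, rec.support))
        spelling.setdefault(key, rec.human)

    mapping: dict[str, list[str]] = {}
    unmapped: list[str] = []
    for g in genes:
        key = norm_symbol(g)
        candidates = by_human.get(key)
        if not candidates:
            mapping[g] = []
            unmapped.append(g)
            continue
        if policy == "keep-all":
            mapping[g] = sorted({m for m, _ in candidates})
        else:
            best_support = max(s for _, s in candidates)
            best = sorted(m for m, s in candidates if s == best_support)
            if len(best) > 1:
                log.info("gene %s: support tie among %s; keeping %s", g, best, best[0])
            mapping[g] = [best[0]]
    if unmapped:
        log.info("%d human genes had no mouse ortholog entry", len(unmapped))
    return mapping, unmapped
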