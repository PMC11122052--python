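"""Shared helpers: symbol normalization and species vocabulary."""

from __future__ import annotations

SPECIES = frozenset({"human", "mouse"})


def norm_symbol(symbol: str) -> str:
    """Case-insensitive key for gene-symbol comparison.

    Output tables keep the species' conventional casing (mouse
    "Cdkn2a", human "CDKN2A"); all joins go through this key.
    Hyphens are part of the symbol (mitochondrial "mt-Co2").
    """
    return symbol.strip().upper()


def check_species(tag: str, *, row: int | None = None) -> str:
    tag = tag.strip().lower()
    if tag not in SPECIES:
        where = f" (row {row})" if row is not None else ""
        raise ValueError(
            f"unknown species tag {tag!r}{where}; expected one of {sorted(SPECIES)}"
        )
    return tag
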