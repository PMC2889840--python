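"""Protein pool: the roster of candidate proteins and their pathway catalogues.

The pool is the universe over which association networks are built.  Each
protein carries exactly one pathway catalogue out of five: the TNF pathway,
the IL-1 pathway, the MyD88-dependent and MyD88-independent arms of TLR-4
signalling, and the negative regulators.  A packaged fixture transcribes the
60-protein roster used for the TNFα-stimulated endothelium study.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

logger = logging.getLogger(__name__)

#: Canonical catalogue codes, in pathway-activation order (negative
#: regulators sit outside the activation cascade and come last).
CATALOGUES = ("TNF", "IL1", "TLR4_MYD88_DEP", "TLR4_MYD88_IND", "NEG_REG")

#: Accepted header spellings -> canonical catalogue code.
_HEADER_ALIASES = {
    "TNF": "TNF",
    "IL-1": "IL1",
    "IL1": "IL1",
    "MYD88-DEPENDENT TLR-4": "TLR4_MYD88_DEP",
    "TLR4_MYD88_DEP": "TLR4_MYD88_DEP",
    "MYD88-INDEPENDENT TLR-4": "TLR4_MYD88_IND",
    "TLR4_MYD88_IND": "TLR4_MYD88_IND",
    "NEGATIVE REGULATORS": "NEG_REG",
    "NEG_REG": "NEG_REG",
}

#: Greek-letter transliteration used to normalise symbols from plain-text
#: sources that cannot carry the glyphs (IL1α -> IL1A, IKKβ -> IKKB, ...).
GREEK_ALIASES = {"α": "A", "β": "B", "γ": "G", "ε": "E", "κ": "K"}


class CatalogueConflictError(ValueError):
    """A symbol appears under more than one pathway catalogue."""


def normalize_symbol(symbol: str) -> str:
    """Upper-case a gene symbol and transliterate Greek letters.

    Symbols are matched case-insensitively and reported in upper case;
    α/β/γ/ε map to A/B/G/E so that plain-text edge lists and the pool
    fixture agree on one spelling.
    """
    s = symbol.strip()
    for greek, latin in GREEK_ALIASES.items():
        s = s.replace(greek, latin).replace(greek.upper(), latin)
    return s.upper()


@dataclass(frozen=True)
class ProteinPool:
    """Roster of proteins, each assigned to exactly one pathway catalogue."""

    entries: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for symbol, catalogue in self.entries:
            if catalogue not in CATALOGUES:
                raise ValueError(f"unknown catalogue {catalogue!r} for {symbol!r}")
            if symbol in seen:
                raise CatalogueConflictError(
                    f"symbol {symbol!r} listed under both {seen[symbol]!r} "
                    f"and {catalogue!r}; the pool is a partition"
                )
            seen[symbol] = catalogue

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.entries)

    @property
    def catalogue_of(self) -> dict[str, str]:
        return dict(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.catalogue_of

    def count_by_catalogue(self) -> dict[str, int]:
        counts = {c: 0 for c in CATALOGUES}
        for _, cat in self.entries:
            counts[cat] += 1
        return counts


def parse_protein_pool(text: str) -> ProteinPool:
    """Parse a tab-delimited catalogue table into a :class:`ProteinPool`.

    The table has one column per pathway catalogue (header row names the
    catalogues) and one symbol per cell.  Every non-empty cell becomes an
    entry; a symbol appearing under two columns raises
    :class:`CatalogueConflictError` because the roster is a partition.
    An empty table yields an empty pool with a warning.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        warnings.warn("empty protein pool table", stacklevel=2)
        return ProteinPool()
    header = lines[0].split("\t")
    catalogues = []
    for col in header:
        key = col.strip().upper()
        if key not in _HEADER_ALIASES:
            raise ValueError(f"unrecognised catalogue header {col!r}")
        catalogues.append(_HEADER_ALIASES[key])
    entries: list[tuple[str, str]] = []
    for line in lines[1:]:
        cells = line.split("\t")
        for j, cell in enumerate(cells):
            if j >= len(catalogues) or not cell.strip():
                continue
            entries.append((normalize_symbol(cell), catalogues[j]))
    if not entries:
        warnings.warn("protein pool table has no symbols", stacklevel=2)
    logger.info("parsed protein pool: %d entries", len(entries))
    return ProteinPool(tuple(entries))


def read_protein_pool(path: str | Path) -> ProteinPool:
    """Read a pool table from a file path."""
    return parse_protein_pool(Path(path).read_text(encoding="utf-8"))


def load_default_pool() -> ProteinPool:
    """Load the packaged 60-protein roster for the TNFα inflammation study."""
    text = resources.files("ppanet.data").joinpath("protein_pool.tsv").read_text(
        encoding="utf-8"
    )
    return parse_protein_pool(text)


def load_receptor_list() -> frozenset[str]:
    """Packaged receptor symbols used for the bow-tie input side."""
    text = resources.files("ppanet.data").joinpath("receptors.txt").read_text(
        encoding="utf-8"
    )
    return frozenset(normalize_symbol(s) for s in text.split() if s.strip())
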