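"""Glycan/PTM composition algebra.

Compositions are integer count vectors over a small set of building blocks
(monosaccharides and sub-monosaccharide modifications). All masses are
*average* masses in daltons, matching how intact-protein native MS data are
annotated: at 20-30 kDa the isotope envelope is unresolved and the centroid
tracks the average mass.

The default residue table::

    Hex      162.1424   hexose (Man/Gal/Glc)
    HexNAc   203.1950   N-acetylhexosamine (GlcNAc/GalNAc)
    dHex     146.1430   deoxyhexose (Fuc)
    Neu5Ac   291.2579   N-acetylneuraminic acid (sialic acid)
    Neu5Gc   307.2573   N-glycolylneuraminic acid
    Pho       79.9799   phosphorylation
    Acetyl    42.0373   O-acetylation (typically on sialic acid)
    Hydroxyl  15.9994   -CH3 -> -CH2OH replacement (NeuAc -> NeuGc)

Note that Neu5Gc can equivalently be written Neu5Ac + Hydroxyl
(291.2579 + 15.9994 = 307.2573); both encodings are accepted and are
isobaric by construction.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping
from pathlib import Path

__all__ = [
    "DEFAULT_TABLE",
    "ALIASES",
    "CANONICAL_ORDER",
    "MonosaccharideTable",
    "GlycanComposition",
    "parse_composition",
    "format_composition",
    "composition_mass",
]


class CompositionError(ValueError):
    """Raised on unparseable composition text or unknown building blocks."""


#: Average residue masses in Da.
DEFAULT_MASSES: dict[str, float] = {
    "Hex": 162.1424,
    "HexNAc": 203.1950,
    "dHex": 146.1430,
    "Neu5Ac": 291.2579,
    "Neu5Gc": 307.2573,
    "Pho": 79.9799,
    "Acetyl": 42.0373,
    "Hydroxyl": 15.9994,
}

#: Accepted synonyms, resolved to canonical table names at parse time.
ALIASES: dict[str, str] = {
    "Fuc": "dHex",
    "Sia": "Neu5Ac",
    "NeuAc": "Neu5Ac",
    "NeuGc": "Neu5Gc",
    "Man": "Hex",
    "Gal": "Hex",
    "Glc": "Hex",
    "GlcNAc": "HexNAc",
    "GalNAc": "HexNAc",
    "Phospho": "Pho",
    "Ac": "Acetyl",
}

#: Stable formatting order (for diffable output).
CANONICAL_ORDER: tuple[str, ...] = (
    "Hex",
    "HexNAc",
    "dHex",
    "Neu5Ac",
    "Neu5Gc",
    "Hydroxyl",
    "Acetyl",
    "Pho",
)

#: Display names used when formatting (paper-style inline notation).
_DISPLAY = {"dHex": "Fuc", "Neu5Ac": "Sia", "Neu5Gc": "NeuGc"}


class MonosaccharideTable(Mapping):
    """Immutable name -> average residue mass (Da) lookup.

    Unknown-name lookups raise :class:`CompositionError` naming the token.
    """

    def __init__(self, entries: Mapping[str, float] | None = None):
        entries = dict(DEFAULT_MASSES if entries is None else entries)
        for name, m in entries.items():
            if not m > 0:
                raise CompositionError(f"residue mass for {name!r} must be > 0, got {m}")
        self._entries = entries

    def __getitem__(self, name: str) -> float:
        try:
            return self._entries[name]
        except KeyError:
            raise CompositionError(
                f"unknown building block {name!r}; known: {sorted(self._entries)}"
            ) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __repr__(self) -> str:  # pragma: no cover
        return f"MonosaccharideTable({self._entries!r})"

    @classmethod
    def from_file(cls, path: str | Path) -> "MonosaccharideTable":
        """Load a table from delimited text with two columns: name, mass_da.

        Comma, tab or whitespace delimited; lines starting with ``#`` are
        ignored. Allows substituting e.g. monoisotopic masses.
        """
        entries: dict[str, float] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[,\t\s]+", line)
            if len(parts) != 2:
                raise CompositionError(f"{path}:{lineno}: expected 'name mass', got {raw!r}")
            try:
                entries[parts[0]] = float(parts[1])
            except ValueError:
                raise CompositionError(f"{path}:{lineno}: non-numeric mass {parts[1]!r}") from None
        return cls(entries)


#: Module-level default table instance.
DEFAULT_TABLE = MonosaccharideTable()


def _canonical(name: str) -> str:
    return ALIASES.get(name, name)


class GlycanComposition(Mapping):
    """Integer count vector over glycan building blocks.

    Counts are non-negative; an absent key is equivalent to count 0, and
    equality is count-wise (zero entries are dropped on construction).
    Supports ``+`` for count-wise addition.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean: dict[str, int] = {}
        for name, c in (counts or {}).items():
            c = int(c)
            if c < 0:
                raise CompositionError(f"negative count for {name!r}: {c}")
            if c:
                key = _canonical(name)
                clean[key] = clean.get(key, 0) + c
        self._counts = clean

    def __getitem__(self, name: str) -> int:
        return self._counts.get(_canonical(name), 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, name: object) -> bool:
        return isinstance(name, str) and _canonical(name) in self._counts

    def __eq__(self, other: object) -> bool:
        if isinstance(other, GlycanComposition):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self == GlycanComposition(other)
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __add__(self, other: "GlycanComposition | Mapping[str, int]") -> "GlycanComposition":
        merged = dict(self._counts)
        for name, c in GlycanComposition(other).items():
            merged[name] = merged.get(name, 0) + c
        return GlycanComposition(merged)

    def __bool__(self) -> bool:
        return bool(self._counts)

    def __repr__(self) -> str:
        return f"GlycanComposition({self._counts!r})"

    def __str__(self) -> str:
        return format_composition(self)

    def mass(self, table: MonosaccharideTable = DEFAULT_TABLE) -> float:
        return composition_mass(self, table)

    def without(self, *names: str) -> "GlycanComposition":
        """Copy with the given building blocks removed (counts set to 0)."""
        drop = {_canonical(n) for n in names}
        return GlycanComposition({k: v for k, v in self._counts.items() if k not in drop})


# Longest-first alternation so HexNAc wins over Hex, Neu5Ac over Neu, etc.
_NAMES = sorted(set(DEFAULT_MASSES) | set(ALIASES), key=len, reverse=True)
_TOKEN = re.compile(
    r"(?P<name>" + "|".join(re.escape(n) for n in _NAMES) + r")"
    r"(?:\((?P<paren>\d+)\)|_?(?P<plain>\d+)_?)?"
)


def parse_composition(text: str) -> GlycanComposition:
    """Parse inline composition notation into a :class:`GlycanComposition`.

    Accepts concatenated ``Name``+count tokens (``Hex22HexNAc19Fuc3Sia13``),
    the ``Name(count)`` dialect (``HexNAc(2)Hex(5)``), and underscore-delimited
    counts (``Hex_22_HexNAc_19_``). A missing count means 1. The empty string
    is the empty composition.
    """
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            raise CompositionError(
                f"cannot parse composition at {text[pos:pos + 12]!r} (offset {pos} of {text!r})"
            )
        name = _canonical(m.group("name"))
        count = int(m.group("paren") or m.group("plain") or 1)
        counts[name] = counts.get(name, 0) + count
        pos = m.end()
    return GlycanComposition(counts)


def format_composition(comp: GlycanComposition) -> str:
    """Format in canonical block order using paper-style names (Fuc, Sia)."""
    parts = []
    for name in CANONICAL_ORDER:
        c = comp[name]
        if c:
            parts.append(f"{_DISPLAY.get(name, name)}{c}")
    extra = sorted(set(comp) - set(CANONICAL_ORDER))
    for name in extra:
        parts.append(f"{name}{comp[name]}")
    return "".join(parts)


def composition_mass(
    comp: GlycanComposition | Mapping[str, int],
    table: MonosaccharideTable = DEFAULT_TABLE,
) -> float:
    """Total average mass in Da: sum of count x residue mass."""
    if not isinstance(comp, GlycanComposition):
        comp = GlycanComposition(comp)
    return sum(count * table[name] for name, count in comp.items())
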