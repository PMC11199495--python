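"""Seven-rank taxonomy paths with de-novo placeholder names.

Reference databases for engineered ecosystems carry a complete seven-rank
taxonomy (kingdom to species) for every sequence.  Lineages without an
official name receive systematic placeholder names of the form
``midas_<r>_<n>`` where ``<r>`` is a one-letter rank code (k, p, c, o, f,
g, s) and ``<n>`` a numeric identifier, so that unclassified lineages can
be tracked alongside officially named taxa at every rank.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import InvalidInputError

#: Rank names in root-to-leaf order.
RANKS: tuple[str, ...] = (
    "kingdom", "phylum", "class", "order", "family", "genus", "species",
)

#: One-letter rank codes used in placeholder names and ``k__`` prefixes.
RANK_LETTERS: tuple[str, ...] = ("k", "p", "c", "o", "f", "g", "s")

_PLACEHOLDER_RE = re.compile(r"^([A-Za-z]+)_([kpcofgs])_(\d+)$")
_PREFIX_RE = re.compile(r"^([kpcofgs])__(.*)$")

#: Default prefix for placeholder names.
PLACEHOLDER_PREFIX = "midas"


def is_placeholder(name: str, rank_index: int | None = None,
                   prefix: str = PLACEHOLDER_PREFIX) -> bool:
    """True iff *name* is a placeholder name (optionally for a given rank).

    A placeholder name matches ``<prefix>_<r>_<integer>``; when
    *rank_index* is given the rank letter must match that position.
    """
    m = _PLACEHOLDER_RE.match(name)
    if m is None or m.group(1) != prefix:
        return False
    if rank_index is not None:
        return m.group(2) == RANK_LETTERS[rank_index]
    return True


@dataclass(frozen=True)
class TaxonomyPath:
    """An ordered seven-rank lineage; trailing ranks may be blank.

    Invariants enforced at construction: exactly seven names, blanks only
    as a suffix (no empty rank above a filled one), and any placeholder
    name carries the rank letter of its own position.
    """

    names: tuple[str, ...]
    prefix: str = field(default=PLACEHOLDER_PREFIX, compare=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise InvalidInputError(
                f"taxonomy must have exactly {len(RANKS)} ranks, "
                f"got {len(self.names)}: {self.names!r}")
        seen_blank = False
        for i, name in enumerate(self.names):
            if name == "":
                seen_blank = True
            elif seen_blank:
                raise InvalidInputError(
                    f"rank {RANKS[i]} is filled below a blank rank: "
                    f"{self.names!r}")
            m = _PLACEHOLDER_RE.match(name)
            if m is not None and m.group(1) == self.prefix \
                    and m.group(2) != RANK_LETTERS[i]:
                raise InvalidInputError(
                    f"placeholder {name!r} carries rank letter "
                    f"{m.group(2)!r} but sits at rank {RANKS[i]!r}")

    @property
    def placeholder_flags(self) -> tuple[bool, ...]:
        return tuple(is_placeholder(n, i, self.prefix)
                     for i, n in enumerate(self.names))

    def name_at(self, rank: str) -> str:
        return self.names[RANKS.index(rank)]

    def truncate(self, depth: int) -> "TaxonomyPath":
        """Blank all ranks below *depth* filled ranks."""
        return TaxonomyPath(
            tuple(self.names[:depth]) + ("",) * (len(RANKS) - depth),
            self.prefix)

    def prefix_names(self, depth: int) -> tuple[str, ...]:
        return self.names[:depth]

    @property
    def depth(self) -> int:
        """Number of filled ranks."""
        return sum(1 for n in self.names if n != "")


def parse_taxonomy(text: str, prefix: str = PLACEHOLDER_PREFIX) -> TaxonomyPath:
    """Parse a semicolon-delimited taxonomy string into a :class:`TaxonomyPath`.

    Both bare names (``Bacteria;Firmicutes;...``) and rank-prefixed names
    (``k__Bacteria;p__Firmicutes;...``) are accepted; missing trailing
    ranks become blank.  More than seven fields is an error, as is a
    placeholder whose rank letter disagrees with its position.
    """
    fields = [f.strip() for f in text.strip().split(";")]
    if len(fields) == 1 and fields[0] == "":
        fields = []
    if len(fields) > len(RANKS):
        raise InvalidInputError(
            f"taxonomy string has {len(fields)} fields, at most "
            f"{len(RANKS)} allowed: {text!r}")
    names = []
    for i, f in enumerate(fields):
        m = _PREFIX_RE.match(f)
        if m is not None:
            if m.group(1) != RANK_LETTERS[i]:
                raise InvalidInputError(
                    f"rank prefix {m.group(1)!r}__ at position {i} "
                    f"({RANKS[i]}) in {text!r}")
            f = m.group(2)
        names.append(f)
    names += [""] * (len(RANKS) - len(names))
    return TaxonomyPath(tuple(names), prefix)


def format_taxonomy(path: TaxonomyPath, prefixed: bool = False) -> str:
    """Format a path back to a semicolon-delimited string (lossless)."""
    if prefixed:
        return ";".join(f"{RANK_LETTERS[i]}__{n}"
                        for i, n in enumerate(path.names))
    return ";".join(path.names)
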