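"""Ranked lineages and taxonomic agreement.

A lineage is a gap-free path down the canonical seven-rank ladder
(domain, phylum, class, order, family, genus, species), possibly
truncated.  Decontamination decisions rest on two questions this module
answers: at which rank do two lineages agree, and does the declared
target taxonomy reach deep enough for homology-guided classification.

Name matching is exact case-insensitive string equality.  No taxid
resolution or synonym handling is attempted: reference databases supply
lineage strings, and fuzzy matching would need an external taxonomy dump.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "RANKS",
    "Lineage",
    "parse_lineage",
    "agreement_rank",
    "is_taxonomy_deep_enough",
    "read_lineage_table",
]

#: Canonical rank ladder, shallowest first.
RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

# Common single-letter rank prefixes (GTDB/Greengenes style), stripped on parse.
_PREFIXES = tuple(f"{r[0]}__" for r in RANKS)


def rank_index(rank: str) -> int:
    """Position of *rank* on the ladder (0 = domain). Unknown rank -> ValueError."""
    try:
        return _RANK_INDEX[rank]
    except KeyError:
        raise ValueError(
            f"unknown rank {rank!r}; expected one of {', '.join(RANKS)}"
        ) from None


@dataclass(frozen=True)
class Lineage:
    """A gap-free ranked taxonomy path, truncated at ``depth()``.

    ``names`` holds the assigned names from domain downward; its length is
    the number of set ranks.
    """

    names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("lineage must set at least the domain rank")
        if len(self.names) > len(RANKS):
            raise ValueError(
                f"lineage has {len(self.names)} fields; at most {len(RANKS)} allowed"
            )
        for rank, name in zip(RANKS, self.names):
            if not name or not name.strip():
                raise ValueError(f"empty name at rank {rank!r} (gaps are not allowed)")

    @property
    def ranks(self) -> dict[str, str]:
        """Mapping rank -> name for the set ranks, shallowest first."""
        return dict(zip(RANKS, self.names))

    def depth(self) -> str:
        """Deepest set rank."""
        return RANKS[len(self.names) - 1]

    def name_at(self, rank: str) -> str | None:
        i = rank_index(rank)
        return self.names[i] if i < len(self.names) else None

    def truncated(self, rank: str) -> "Lineage":
        """Copy of this lineage cut at *rank* (which must be set)."""
        i = rank_index(rank)
        if i >= len(self.names):
            raise ValueError(f"lineage does not reach rank {rank!r}")
        return Lineage(self.names[: i + 1])

    def __str__(self) -> str:
        return ";".join(self.names)


def parse_lineage(text: str) -> Lineage:
    """Parse a semicolon-delimited lineage string, domain first.

    Accepts 1-7 fields, optional ``d__``/``p__``/... rank prefixes
    (stripped), and surrounding whitespace.  Empty input, more than seven
    fields, or an empty middle field (a gap) is a hard error.

    >>> parse_lineage("d__Bacteria;p__Firmicutes").depth()
    'phylum'
    """
    if text is None or not text.strip():
        raise ValueError("empty lineage string")
    fields = [f.strip() for f in text.split(";")]
    # A trailing semicolon is tolerated; internal gaps are not.
    if fields and fields[-1] == "":
        fields = fields[:-1]
    if not fields:
        raise ValueError("empty lineage string")
    if len(fields) > len(RANKS):
        raise ValueError(f"lineage {text!r} has {len(fields)} fields; at most 7 allowed")
    names = []
    for i, f in enumerate(fields):
        if f == "":
            raise ValueError(f"lineage {text!r} has a gap at rank {RANKS[i]!r}")
        for pfx in _PREFIXES:
            if f.startswith(pfx):
                f = f[len(pfx):].strip()
                break
        if f == "":
            raise ValueError(f"lineage {text!r} has an empty name at rank {RANKS[i]!r}")
        names.append(f)
    return Lineage(tuple(names))


def agreement_rank(a: Lineage, b: Lineage) -> str | None:
    """Deepest rank at which *a* and *b* are both set and equal.

    Comparison is case-insensitive.  Returns ``None`` if the lineages
    already differ at the domain rank.  Symmetric; for any lineage x,
    ``agreement_rank(x, x) == x.depth()``.
    """
    deepest = None
    for rank, na, nb in zip(RANKS, a.names, b.names):
        if na.casefold() == nb.casefold():
            deepest = rank
        else:
            break
    return deepest


def is_taxonomy_deep_enough(target: Lineage, required: str) -> bool:
    """True iff the target lineage reaches *required* rank or deeper."""
    return rank_index(target.depth()) >= rank_index(required)


def read_lineage_table(path: str | Path) -> dict[str, Lineage]:
    """Read a two-column TSV (sequence id, semicolon lineage).

    Blank lines and ``#`` comment lines are skipped.  Duplicate ids and
    malformed rows are hard errors naming the line.
    """
    path = Path(path)
    out: dict[str, Lineage] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            seq_id, lineage_text = parts[0].strip(), parts[1]
            if not seq_id:
                raise ValueError(f"{path}:{lineno}: empty sequence id")
            if seq_id in out:
                raise ValueError(f"{path}:{lineno}: duplicate sequence id {seq_id!r}")
            try:
                out[seq_id] = parse_lineage(lineage_text)
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
    return out
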