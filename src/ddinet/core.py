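"""Shared domain types: proteins, catalogs, interaction records, DDI multisets.

Conventions used throughout the package:

* A protein pair is *unordered*: ``(a, b)`` and ``(b, a)`` denote the same
  record. Pair keys are canonicalized by lexicographic sort at construction
  time so duplicates can never slip through downstream.
* A domain-domain interaction (DDI) is an unordered pair of Pfam
  accessions; a :class:`DDISet` is a multiset of such pairs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

Label = str  # one of {"positive", "negative", "unlabeled"}

VALID_LABELS = frozenset({"positive", "negative", "unlabeled"})

HUMAN = "human"


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered identity of a pair of string ids."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Protein:
    """A protein with its organism tag, Pfam domain content and tissue labels.

    ``organism`` is ``"human"`` for host proteins and a strain identifier
    otherwise. ``pfam_ids`` is stored deduplicated, preserving first
    occurrence; ``tissues`` only makes sense for human proteins and may be
    empty.
    """

    id: str
    organism: str
    pfam_ids: tuple[str, ...]
    gene_name: str = ""
    tissues: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be nonempty")
        deduped = tuple(dict.fromkeys(self.pfam_ids))
        object.__setattr__(self, "pfam_ids", deduped)
        object.__setattr__(self, "tissues", frozenset(self.tissues))

    @property
    def is_human(self) -> bool:
        return self.organism == HUMAN

    @property
    def embeddable(self) -> bool:
        """Whether the protein carries at least one Pfam domain."""
        return len(self.pfam_ids) > 0


class ProteinCatalog:
    """An id-indexed collection of :class:`Protein` with unique ids."""

    def __init__(self, proteins: Iterable[Protein] = ()):
        self._proteins: dict[str, Protein] = {}
        self.rejected: list[tuple[int, str]] = []  # (row number, reason)
        for p in proteins:
            self.add(p)

    def add(self, protein: Protein) -> None:
        if protein.id in self._proteins:
            raise ValueError(f"duplicate protein id: {protein.id}")
        self._proteins[protein.id] = protein

    def __getitem__(self, pid: str) -> Protein:
        return self._proteins[pid]

    def __contains__(self, pid: str) -> bool:
        return pid in self._proteins

    def __len__(self) -> int:
        return len(self._proteins)

    def __iter__(self) -> Iterator[Protein]:
        return iter(self._proteins.values())

    def get(self, pid: str) -> Protein | None:
        return self._proteins.get(pid)

    @property
    def ids(self) -> list[str]:
        return list(self._proteins)

    @property
    def organisms(self) -> set[str]:
        return {p.organism for p in self}

    def humans(self) -> list[Protein]:
        return [p for p in self if p.is_human]

    def bacteria(self) -> list[Protein]:
        return [p for p in self if not p.is_human]


@dataclass(frozen=True)
class PPIRecord:
    """A labeled (or unlabeled) protein pair under unordered identity.

    Endpoints are sorted lexicographically at construction so that equal
    pairs compare and hash equal regardless of input order.
    """

    a: str
    b: str
    label: Label = "unlabeled"
    source: str = ""

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"invalid label: {self.label!r}")
        a, b = pair_key(self.a, self.b)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def key(self) -> tuple[str, str]:
        return (self.a, self.b)


class DDISet:
    """Multiset of unordered Pfam-domain pairs with positive integer counts."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._counts: Counter[tuple[str, str]] = Counter()
        for a, b in pairs:
            self.add(a, b)

    def add(self, a: str, b: str, count: int = 1) -> None:
        if count < 1:
            raise ValueError("count must be >= 1")
        self._counts[pair_key(a, b)] += count

    def count(self, a: str, b: str) -> int:
        return self._counts.get(pair_key(a, b), 0)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair_key(*pair) in self._counts

    def __len__(self) -> int:
        """Number of distinct pairs."""
        return len(self._counts)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self._counts)

    def items(self) -> Iterable[tuple[tuple[str, str], int]]:
        return self._counts.items()

    def total(self) -> int:
        return sum(self._counts.values())

    def pairs(self) -> set[tuple[str, str]]:
        return set(self._counts)

    def issubset(self, other: "DDISet") -> bool:
        """Distinct-pair containment (counts ignored)."""
        return self.pairs() <= other.pairs()

    def union(self, other: "DDISet") -> "DDISet":
        out = DDISet()
        out._counts = self._counts + other._counts
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DDISet):
            return NotImplemented
        return self._counts == other._counts

    def __repr__(self) -> str:
        return f"DDISet({len(self)} pairs, total count {self.total()})"


def validate_disorder_table(table: Mapping[str, float]) -> dict[str, float]:
    """Check disorder fractions lie in [0, 1] and return a plain dict."""
    out = {}
    for pid, frac in table.items():
        f = float(frac)
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"disorder fraction for {pid} outside [0, 1]: {f}")
        out[pid] = f
    return out


@dataclass
class ReaderLog:
    """Bookkeeping for filtering readers: records_in = kept + dropped."""

    n_read: int = 0
    n_kept: int = 0
    dropped: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)
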