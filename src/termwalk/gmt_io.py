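"""Reading and writing gene-set collections (GMT) and ortholog tables.

The GMT dialect is the tab-separated one MSigDB distributes: one gene set
per line, ``name<TAB>description<TAB>gene1<TAB>gene2...``.  Gene symbols are
normalized (stripped, uppercased) on input so that human symbols and
ortholog-converted symbols from other species live in one namespace.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterator, List, Sequence, Set, Tuple

__all__ = [
    "GmtParseError",
    "TermRecord",
    "GeneSetCollection",
    "OrthologMap",
    "RSAnnotation",
    "normalize_symbol",
    "read_gmt",
    "write_gmt",
    "read_ortholog_table",
    "write_ortholog_table",
]


class GmtParseError(ValueError):
    """Raised for malformed GMT or ortholog-table input."""


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace, uppercase.

    Idempotent: ``normalize_symbol(normalize_symbol(s)) == normalize_symbol(s)``.
    """
    return symbol.strip().upper()


@dataclass(frozen=True)
class TermRecord:
    """A named gene set (pathway, function, phenotype, signature...)."""

    term_id: str
    description: str
    genes: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.term_id:
            raise ValueError("term_id must be non-empty")
        if not self.genes:
            raise ValueError(f"term {self.term_id!r} has an empty gene set")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """An ordered collection of terms, each with its member-gene set.

    Term identifiers must be unique; every gene set is non-empty.  The
    ordering of terms is the file order and is preserved through round
    trips (gene order within a set is not meaningful).
    """

    terms: List[TermRecord]
    species_label: str = ""

    def __post_init__(self) -> None:
        seen: Set[str] = set()
        for record in self.terms:
            if record.term_id in seen:
                raise ValueError(f"duplicate term_id {record.term_id!r}")
            seen.add(record.term_id)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[TermRecord]:
        return iter(self.terms)

    def __getitem__(self, i: int) -> TermRecord:
        return self.terms[i]

    @property
    def term_ids(self) -> List[str]:
        return [t.term_id for t in self.terms]

    def get(self, term_id: str) -> TermRecord:
        for record in self.terms:
            if record.term_id == term_id:
                return record
        raise KeyError(term_id)

    def all_genes(self) -> Set[str]:
        """Union of all member-gene sets."""
        out: Set[str] = set()
        for record in self.terms:
            out |= record.genes
        return out


@dataclass(frozen=True)
class RSAnnotation:
    """Manual 0-5 literature-support grade for a term pair.

    5 = strong multi-study evidence ... 0 = biologically implausible.
    Assignment is human curation; this type only stores the result.
    """

    level: int
    note: str = ""

    def __post_init__(self) -> None:
        if self.level not in (0, 1, 2, 3, 4, 5):
            raise ValueError(f"RS level must be in 0..5, got {self.level}")


@dataclass(frozen=True)
class OrthologMap:
    """Source-species symbol -> target-species symbol pairs.

    One source symbol may map to several targets (one-to-many orthology is
    kept as-is); pairs are deduplicated.
    """

    pairs: FrozenSet[Tuple[str, str]]

    def targets(self, source_symbol: str) -> Set[str]:
        s = normalize_symbol(source_symbol)
        return {t for (a, t) in self.pairs if a == s}

    def as_dict(self) -> Dict[str, Set[str]]:
        out: Dict[str, Set[str]] = {}
        for a, b in self.pairs:
            out.setdefault(a, set()).add(b)
        return out

    def __len__(self) -> int:
        return len(self.pairs)


def read_gmt(path: os.PathLike | str, species_label: str = "") -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Each line needs >= 3 tab-separated fields (name, description, >= 1 gene).
    Duplicate genes within a line are collapsed; symbols are normalized.
    Blank lines are ignored.

    Raises
    ------
    GmtParseError
        On a line with fewer than 3 fields (the line number is reported),
        or if two lines share a term identifier.
    """
    records: List[TermRecord] = []
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            term_id = fields[0].strip()
            genes = frozenset(
                normalize_symbol(g) for g in fields[2:] if g.strip()
            )
            if not genes:
                raise GmtParseError(
                    f"{path}: line {lineno}: term {term_id!r} has no genes "
                    "after normalization"
                )
            records.append(TermRecord(term_id, fields[1], genes))
    collection = GeneSetCollection(records, species_label=species_label)
    return collection


def write_gmt(collection: GeneSetCollection, path: os.PathLike | str) -> None:
    """Write a collection as GMT. Genes are written in sorted order.

    Refuses to write an empty collection (a zero-line GMT is indistinguishable
    from a truncated file).
    """
    if len(collection) == 0:
        raise ValueError("refusing to write an empty collection")
    with open(path, "w", encoding="utf-8") as handle:
        for record in collection:
            genes = "\t".join(sorted(record.genes))
            handle.write(f"{record.term_id}\t{record.description}\t{genes}\n")


_HEADER_TOKENS = {
    "source", "target", "gene", "genes", "symbol", "human", "mouse",
    "from", "to", "ortholog", "orthologue", "homolog", "hgnc", "mgi",
    "source_symbol", "target_symbol", "human_symbol", "mouse_symbol",
    "gene_symbol", "human_gene", "mouse_gene",
}


def read_ortholog_table(path: os.PathLike | str) -> OrthologMap:
    """Parse a 2-column TSV of (source symbol, target symbol) pairs.

    An optional single header line is auto-detected: the first line is
    dropped when neither of its fields recurs as data in its column and at
    least one field is a conventional header token (``source``, ``gene``,
    ``human`` ...).  Symbols are normalized as in :func:`read_gmt`; duplicate
    pairs collapse.
    """
    rows: List[Tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected exactly 2 tab-separated "
                    f"columns, got {len(fields)}"
                )
            rows.append((fields[0], fields[1]))
    if rows and _looks_like_header(rows):
        rows = rows[1:]
    pairs = frozenset(
        (normalize_symbol(a), normalize_symbol(b)) for a, b in rows
    )
    return OrthologMap(pairs)


def _looks_like_header(rows: Sequence[Tuple[str, str]]) -> bool:
    first_a, first_b = (normalize_symbol(rows[0][0]), normalize_symbol(rows[0][1]))
    rest_a = {normalize_symbol(a) for a, _ in rows[1:]}
    rest_b = {normalize_symbol(b) for _, b in rows[1:]}
    recurs = first_a in rest_a or first_b in rest_b
    header_like = (
        rows[0][0].strip().lower() in _HEADER_TOKENS
        or rows[0][1].strip().lower() in _HEADER_TOKENS
    )
    return (not recurs) and header_like


def write_ortholog_table(
    orthologs: OrthologMap, path: os.PathLike | str, header: bool = False
) -> None:
    """Write an ortholog map as 2-column TSV, pairs in sorted order."""
    with open(path, "w", encoding="utf-8") as handle:
        if header:
            handle.write("source\ttarget\n")
        for a, b in sorted(orthologs.pairs):
            handle.write(f"{a}\t{b}\n")
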