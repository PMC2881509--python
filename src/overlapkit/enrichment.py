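"""Overlap-based gene-set enrichment against GMT collections.

Each gene set is scored with the same hypergeometric upper-tail p-value used
for pairwise list intersections; there is no rank statistic. Sets are
restricted to the universe before scoring and sets with no in-universe
members are excluded from the table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

import pandas as pd

from .dge import GeneList, InputError, bh_adjust
from .setops import _harmonize_ids, hypergeometric_overlap_p

__all__ = ["GeneSet", "GeneSetCollection", "EnrichmentRow", "EnrichmentTable", "read_gmt", "enrich"]


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Ordered named gene sets with GMT semantics."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise InputError(f"duplicate gene set names: {dup}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def filter(self, pattern: str) -> "GeneSetCollection":
        """Sub-collection whose set names match ``pattern`` (regex search)."""
        rx = re.compile(pattern)
        return GeneSetCollection([s for s in self.sets if rx.search(s.name)])


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Blank member fields are dropped; members are deduplicated per set.
    Lines with fewer than 3 fields raise an error naming the line number.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"GMT line {lineno}: expected >=3 tab-separated fields")
            name, desc = parts[0].strip(), parts[1].strip()
            members = []
            seen: set[str] = set()
            for m in parts[2:]:
                m = m.strip()
                if m and m not in seen:
                    seen.add(m)
                    members.append(m)
            sets.append(GeneSet(name=name, description=desc, members=tuple(members)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    description: str
    set_size: int  # in-universe members
    overlap_size: int
    p_value: float
    overlap_genes: tuple[str, ...]
    q_value: float | None = None


@dataclass
class EnrichmentTable:
    """Enrichment rows sorted by ascending p (ties: larger overlap, name)."""

    query_name: str
    query_size: int
    universe_size: int
    rows: list[EnrichmentRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[EnrichmentRow]:
        return iter(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "set_name": [r.set_name for r in self.rows],
                "description": [r.description for r in self.rows],
                "set_size": [r.set_size for r in self.rows],
                "overlap_size": [r.overlap_size for r in self.rows],
                "p_value": [r.p_value for r in self.rows],
                "q_value": [r.q_value for r in self.rows],
                "overlap_genes": [",".join(r.overlap_genes) for r in self.rows],
            }
        )


def enrich(
    query: GeneList,
    collection: GeneSetCollection,
    universe: GeneList,
    pattern: str | None = None,
    bh: bool = False,
) -> EnrichmentTable:
    """Score every collection set against the query list.

    The query and each set are harmonized and intersected with the universe
    first; sets with zero in-universe members are excluded. With ``bh=True``
    a Benjamini-Hochberg adjusted column is added (raw p drives the sort
    either way).
    """
    uni_ids, _ = _harmonize_ids(universe.genes)
    if not uni_ids:
        raise InputError("empty universe")
    uni = set(uni_ids)
    q_ids, _ = _harmonize_ids(query.genes)
    q = {g for g in q_ids if g in uni}
    if not q:
        raise InputError("empty query after harmonization against the universe")

    if pattern is not None:
        collection = collection.filter(pattern)

    rows: list[EnrichmentRow] = []
    for s in collection:
        m_ids, _ = _harmonize_ids(s.members)
        members = [g for g in m_ids if g in uni]
        if not members:
            continue
        overlap = tuple(g for g in members if g in q)
        p = hypergeometric_overlap_p(len(uni), len(members), len(q), len(overlap))
        rows.append(
            EnrichmentRow(
                set_name=s.name,
                description=s.description,
                set_size=len(members),
                overlap_size=len(overlap),
                p_value=p,
                overlap_genes=overlap,
            )
        )
    rows.sort(key=lambda r: (r.p_value, -r.overlap_size, r.set_name))
    if bh and rows:
        qvals = bh_adjust([r.p_value for r in rows])
        rows = [
            EnrichmentRow(
                set_name=r.set_name,
                description=r.description,
                set_size=r.set_size,
                overlap_size=r.overlap_size,
                p_value=r.p_value,
                overlap_genes=r.overlap_genes,
                q_value=float(qv),
            )
            for r, qv in zip(rows, qvals)
        ]
    return EnrichmentTable(
        query_name=query.name, query_size=len(q), universe_size=len(uni), rows=rows
    )
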