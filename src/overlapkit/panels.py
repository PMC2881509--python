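"""Curated gene panels and their cross-tabulation against gene lists.

A panel is a small table of gene symbols with descriptions and printed
p-value strings (scientific notation in either ``1.51E-73`` or ``4.18e-38``
dialect; blanks carried as missing). Packaged fixture panels ship with an
explicit ``member`` column recording a reference membership flag, which
``cross_tabulate`` recomputes from any reference gene list.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

from .dge import GeneList, InputError
from .setops import _harmonize_ids

__all__ = [
    "PanelRow",
    "Panel",
    "PanelCrossTab",
    "FIXTURE_PANELS",
    "load_fixture_panel",
    "load_fixture_reference",
    "cross_tabulate",
    "read_panel",
    "write_panel",
]

FIXTURE_PANELS = (
    "collagen_tumor",
    "collagen_recurrence",
    "collagen_metastasis",
    "glial",
    "proteomic",
)
_REFERENCE_FILE = "stromal_reference.txt"


@dataclass(frozen=True)
class PanelRow:
    gene_id: str
    description: str
    p_strings: Mapping[str, str | None]  # p-value column -> printed string (None = blank)
    member: bool | None = None  # fixture reference membership flag, if any

    def p_value(self, column: str) -> float | None:
        s = self.p_strings.get(column)
        return None if s is None else float(s)


@dataclass
class Panel:
    name: str
    rows: list[PanelRow] = field(default_factory=list)
    p_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [r.gene_id for r in self.rows]
        if len(ids) != len(set(ids)):
            dup = sorted({g for g in ids if ids.count(g) > 1})
            raise InputError(f"duplicate gene identifiers in panel {self.name!r}: {dup}")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.rows]

    def member_genes(self) -> list[str]:
        """Genes whose fixture membership flag is set."""
        return [r.gene_id for r in self.rows if r.member]


@dataclass(frozen=True)
class PanelCrossTab:
    """Membership of every panel gene in one or more reference lists."""

    panel_name: str
    list_names: tuple[str, ...]
    gene_ids: tuple[str, ...]
    flags: Mapping[str, tuple[bool, ...]]  # gene -> flag per reference list

    def flagged_count(self, list_name: str) -> int:
        j = self.list_names.index(list_name)
        return sum(1 for g in self.gene_ids if self.flags[g][j])

    @property
    def total(self) -> int:
        return len(self.gene_ids)

    def summary(self) -> dict[str, tuple[int, int]]:
        """Per reference list: (flagged, total)."""
        return {name: (self.flagged_count(name), self.total) for name in self.list_names}


def cross_tabulate(panel: Panel, reference: GeneList | Sequence[GeneList]) -> PanelCrossTab:
    """Flag each panel gene by membership in the reference list(s).

    Panel symbols and reference members are harmonized (uppercased) before
    the membership test, so mixed-case mouse-style symbols match their
    human-style uppercase counterparts.
    """
    refs = [reference] if isinstance(reference, GeneList) else list(reference)
    ref_sets = [set(_harmonize_ids(r.genes)[0]) for r in refs]
    flags: dict[str, tuple[bool, ...]] = {}
    for row in panel.rows:
        u = row.gene_id.strip().upper()
        flags[row.gene_id] = tuple(u in s for s in ref_sets)
    return PanelCrossTab(
        panel_name=panel.name,
        list_names=tuple(r.name for r in refs),
        gene_ids=tuple(panel.gene_ids),
        flags=flags,
    )


def _parse_rows(name: str, lines, source: str) -> Panel:
    reader = csv.reader(lines, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        return Panel(name=name, rows=[])
    header = [h.strip() for h in header]
    if header[:2] != ["gene", "description"]:
        raise InputError(f"{source}: panel header must start with gene<TAB>description")
    has_member = header[-1] == "member"
    p_cols = tuple(header[2 : len(header) - 1 if has_member else len(header)])
    rows: list[PanelRow] = []
    for lineno, rec in enumerate(reader, start=2):
        if not rec or not any(f.strip() for f in rec):
            continue
        if len(rec) != len(header):
            raise InputError(f"{source} line {lineno}: expected {len(header)} fields, got {len(rec)}")
        gene, desc = rec[0].strip(), rec[1].strip()
        pvals = {
            col: (rec[2 + i].strip() or None) for i, col in enumerate(p_cols)
        }
        member = None
        if has_member:
            member = rec[-1].strip() == "1"
        rows.append(PanelRow(gene_id=gene, description=desc, p_strings=pvals, member=member))
    return Panel(name=name, rows=rows, p_columns=p_cols)


def read_panel(path, name: str | None = None) -> Panel:
    with open(path) as fh:
        return _parse_rows(name or str(path), fh, source=str(path))


def write_panel(panel: Panel, path) -> None:
    has_member = any(r.member is not None for r in panel.rows)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["gene", "description", *panel.p_columns]
        if has_member:
            header.append("member")
        w.writerow(header)
        for r in panel.rows:
            rec = [r.gene_id, r.description] + [r.p_strings.get(c) or "" for c in panel.p_columns]
            if has_member:
                rec.append("1" if r.member else "0")
            w.writerow(rec)


def load_fixture_panel(name: str) -> Panel:
    """Load one of the packaged panels; unknown names list the choices."""
    if name not in FIXTURE_PANELS:
        raise InputError(
            f"unknown fixture panel {name!r}; available: {', '.join(FIXTURE_PANELS)}"
        )
    ref = resources.files("overlapkit.fixtures").joinpath(f"{name}.tsv")
    with ref.open() as fh:
        return _parse_rows(name, fh, source=f"fixture {name}")


def load_fixture_reference() -> GeneList:
    """The packaged reference membership set the fixture flags were taken from."""
    ref = resources.files("overlapkit.fixtures").joinpath(_REFERENCE_FILE)
    genes = []
    with ref.open() as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return GeneList(name="stromal_reference", genes=genes, provenance={"source": "fixture"})
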