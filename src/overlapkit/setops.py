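"""Gene-list intersection significance under the hypergeometric null.

The overlap p-value is the upper-tail probability that a uniformly random
subset of size |Y| drawn from a universe of N genes shares at least the
observed number of members with the fixed set X. Tail sums are accumulated
in log space from log-gamma binomial coefficients, so genome-scale
configurations (N ~ 2e4, overlaps in the thousands) do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .dge import GeneList, InputError

__all__ = [
    "OverlapResult",
    "VennSummary",
    "hypergeometric_overlap_p",
    "intersect",
    "venn_regions",
    "harmonize_symbols",
]


@dataclass(frozen=True)
class OverlapResult:
    """Scored intersection of two gene lists over a universe."""

    name_x: str
    name_y: str
    size_x: int
    size_y: int
    universe_size: int
    overlap_size: int
    overlap_genes: tuple[str, ...]
    p_value: float
    dropped_x: int = 0  # members of x outside the universe
    dropped_y: int = 0


@dataclass(frozen=True)
class VennSummary:
    """Disjoint region counts for a 2- or 3-list Venn partition.

    ``region_counts`` is keyed by a membership tuple of 0/1 flags, one per
    list (``(1, 0)`` = exclusive to the first list). The all-zero region is
    omitted; counts sum to the size of the union.
    """

    names: tuple[str, ...]
    region_counts: Mapping[tuple[int, ...], int]

    def union_size(self) -> int:
        return sum(self.region_counts.values())


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _validate_overlap_args(universe_size: int, size_x: int, size_y: int, overlap: int) -> None:
    for label, v in (
        ("universe_size", universe_size),
        ("size_x", size_x),
        ("size_y", size_y),
        ("overlap", overlap),
    ):
        if int(v) != v or v < 0:
            raise InputError(f"{label} must be a non-negative integer, got {v}")
    if universe_size < 1:
        raise InputError("universe_size must be >= 1")
    if size_x > universe_size or size_y > universe_size:
        raise InputError(
            f"list sizes ({size_x}, {size_y}) exceed universe size {universe_size}"
        )
    if overlap > min(size_x, size_y):
        raise InputError(f"overlap {overlap} exceeds min list size {min(size_x, size_y)}")
    if overlap < max(0, size_x + size_y - universe_size):
        raise InputError(
            f"overlap {overlap} below forced minimum {size_x + size_y - universe_size}"
        )


def hypergeometric_overlap_p(
    universe_size: int, size_x: int, size_y: int, overlap: int
) -> float:
    """Upper-tail overlap probability P(K >= overlap).

    K is the intersection size between the fixed set X (|X| = ``size_x``)
    and a uniformly random ``size_y``-subset of a ``universe_size`` universe.
    ``overlap == 0`` returns exactly 1.
    """
    _validate_overlap_args(universe_size, size_x, size_y, overlap)
    if overlap == 0:
        return 1.0
    k = np.arange(overlap, min(size_x, size_y) + 1)
    log_pmf = (
        _log_comb(size_x, k)
        + _log_comb(universe_size - size_x, size_y - k)
        - _log_comb(universe_size, size_y)
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def _harmonize_ids(genes: Iterable[str]) -> tuple[list[str], int]:
    """Uppercase and deduplicate, preserving first occurrence order."""
    seen: set[str] = set()
    out: list[str] = []
    dropped = 0
    for g in genes:
        u = str(g).strip().upper()
        if not u:
            dropped += 1
            continue
        if u not in seen:
            seen.add(u)
            out.append(u)
    return out, dropped


def harmonize_symbols(
    gene_list: GeneList, ortholog_map: Mapping[str, str] | None = None
) -> tuple[GeneList, int]:
    """Case-fold identifiers to uppercase, optionally translate through an
    ortholog map, and deduplicate.

    With a map, identifiers are translated after case-folding (map keys and
    values are case-folded too); unmapped identifiers are dropped. Returns
    the harmonized list and the number of dropped identifiers.
    """
    ids, dropped = _harmonize_ids(gene_list.genes)
    if ortholog_map is not None:
        folded = {str(k).strip().upper(): str(v).strip().upper() for k, v in ortholog_map.items()}
        translated = []
        for g in ids:
            if g in folded:
                translated.append(folded[g])
            else:
                dropped += 1
        ids, extra = _harmonize_ids(translated)
        dropped += extra
    pmap = None
    if gene_list.p_values is not None and ortholog_map is None:
        pmap = {}
        for g, p in gene_list.p_values.items():
            u = str(g).strip().upper()
            pmap.setdefault(u, float(p))
    return (
        GeneList(
            name=gene_list.name,
            genes=ids,
            provenance=dict(gene_list.provenance, harmonized=True),
            p_values=pmap,
        ),
        dropped,
    )


def read_ortholog_map(path) -> dict[str, str]:
    """Read a two-column (source, target) tab-separated symbol map."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise InputError(f"malformed ortholog map row at line {lineno}: {line!r}")
            mapping[parts[0].strip()] = parts[1].strip()
    return mapping


def _restrict(gene_list: GeneList, universe: set[str]) -> tuple[list[str], int]:
    ids, _ = _harmonize_ids(gene_list.genes)
    kept = [g for g in ids if g in universe]
    return kept, len(ids) - len(kept)


def intersect(x: GeneList, y: GeneList, universe: GeneList) -> OverlapResult:
    """Intersect two lists over a universe and score the overlap.

    Identifiers are harmonized (uppercased, deduplicated) first; members of
    either list absent from the universe are dropped and counted, not added
    to the universe.
    """
    uni_ids, _ = _harmonize_ids(universe.genes)
    if not uni_ids:
        raise InputError("empty universe")
    uni = set(uni_ids)
    xs, dx = _restrict(x, uni)
    ys, dy = _restrict(y, uni)
    yset = set(ys)
    overlap = tuple(g for g in xs if g in yset)
    p = hypergeometric_overlap_p(len(uni), len(xs), len(ys), len(overlap))
    return OverlapResult(
        name_x=x.name,
        name_y=y.name,
        size_x=len(xs),
        size_y=len(ys),
        universe_size=len(uni),
        overlap_size=len(overlap),
        overlap_genes=overlap,
        p_value=p,
        dropped_x=dx,
        dropped_y=dy,
    )


def venn_regions(lists: Sequence[GeneList], universe: GeneList) -> VennSummary:
    """Exhaustive disjoint region counts for 2 or 3 gene lists."""
    if len(lists) not in (2, 3):
        raise InputError(f"venn_regions supports 2 or 3 lists, got {len(lists)}")
    uni_ids, _ = _harmonize_ids(universe.genes)
    if not uni_ids:
        raise InputError("empty universe")
    uni = set(uni_ids)
    member_sets = [set(_restrict(gl, uni)[0]) for gl in lists]
    counts: dict[tuple[int, ...], int] = {}
    for gene in set().union(*member_sets):
        key = tuple(int(gene in s) for s in member_sets)
        counts[key] = counts.get(key, 0) + 1
    # make every region explicit (except the all-zero one)
    n = len(lists)
    for i in range(1, 2**n):
        key = tuple(int(bool(i & (1 << (n - 1 - j)))) for j in range(n))
        counts.setdefault(key, 0)
    return VennSummary(names=tuple(gl.name for gl in lists), region_counts=counts)
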