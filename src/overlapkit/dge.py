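"""Two-group differential expression by one-sided (upper-tail) t-tests.

Expression values are log2-scale intensities; fold changes are reported both
as a log2 difference of group means and as the corresponding linear ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

CASE = "case"
CONTROL = "control"

__all__ = [
    "ExpressionMatrix",
    "GeneStat",
    "GeneList",
    "one_sided_up_test",
    "build_up_list",
    "bh_adjust",
]


class InputError(ValueError):
    """Raised when an input violates a contract precondition."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples numeric table with a case/control label per sample.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier, one column per sample,
        log2-scale expression.
    groups
        Mapping from sample identifier to ``"case"`` or ``"control"``.
    """

    values: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene identifiers: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise InputError(f"duplicate sample identifiers: {dups[:5]}")
        missing = [s for s in cols if s not in self.groups]
        if missing:
            raise InputError(f"samples without a group label: {missing[:5]}")
        bad = {g for g in self.groups.values() if g not in (CASE, CONTROL)}
        if bad:
            raise InputError(f"group labels must be 'case'/'control', got {sorted(bad)}")
        for grp in (CASE, CONTROL):
            if not any(self.groups[s] == grp for s in cols):
                raise InputError(f"group '{grp}' has no samples")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    def group_columns(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]


@dataclass(frozen=True)
class GeneStat:
    """Per-gene result of the one-sided upregulation test."""

    gene_id: str
    mean_case: float
    mean_control: float
    log_fold_change: float  # mean_case - mean_control, log2 units
    t_statistic: float
    p_value: float  # upper tail: alternative mean_case > mean_control
    degenerate: bool = False  # zero within-group variance in both groups

    @property
    def fold_change(self) -> float:
        """Linear-scale ratio of group means (2 ** log_fold_change)."""
        return float(2.0 ** self.log_fold_change)


@dataclass
class GeneList:
    """A named, deduplicated, order-preserving gene identifier list."""

    name: str
    genes: list[str]
    provenance: dict = field(default_factory=dict)
    p_values: dict[str, float] | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        out = []
        for g in self.genes:
            if g not in seen:
                seen.add(g)
                out.append(g)
        self.genes = out

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def as_set(self) -> set[str]:
        return set(self.genes)


def _welch(m1, m2, v1, v2, n1, n2):
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df, se2


def _pooled(m1, m2, v1, v2, n1, n2):
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se2 = sp2 * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
    df = np.full_like(t, float(n1 + n2 - 2))
    return t, df, se2


def one_sided_up_test(matrix: ExpressionMatrix, pooled: bool = False) -> list[GeneStat]:
    """Test every gene for upregulation in the case group.

    Upper-tail p-value for the alternative ``mean_case > mean_control``.
    Welch (unequal variance) by default; ``pooled=True`` selects the
    classical equal-variance statistic.

    Degenerate genes (zero sample variance in both groups) get p = 0.5 when
    the group means are equal, p = 0 when case > control, and p = 1 when
    case < control; they are flagged via :attr:`GeneStat.degenerate`.
    """
    case_cols = matrix.group_columns(CASE)
    ctrl_cols = matrix.group_columns(CONTROL)
    n1, n2 = len(case_cols), len(ctrl_cols)
    if n1 < 2 or n2 < 2:
        raise InputError(f"need >=2 samples per group, got case={n1}, control={n2}")

    x = matrix.values[case_cols].to_numpy(dtype=float)
    y = matrix.values[ctrl_cols].to_numpy(dtype=float)
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1, v2 = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)

    t, df, se2 = (_pooled if pooled else _welch)(m1, m2, v1, v2, n1, n2)
    p = sps.t.sf(t, df)

    diff = m1 - m2
    degen = se2 == 0.0
    if np.any(degen):
        t = t.copy()
        p = p.copy()
        eq = degen & (diff == 0.0)
        up = degen & (diff > 0.0)
        dn = degen & (diff < 0.0)
        t[eq], p[eq] = 0.0, 0.5
        t[up], p[up] = np.inf, 0.0
        t[dn], p[dn] = -np.inf, 1.0

    return [
        GeneStat(
            gene_id=g,
            mean_case=float(m1[i]),
            mean_control=float(m2[i]),
            log_fold_change=float(diff[i]),
            t_statistic=float(t[i]),
            p_value=float(p[i]),
            degenerate=bool(degen[i]),
        )
        for i, g in enumerate(matrix.gene_ids)
    ]


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    return sps.false_discovery_control(np.asarray(p, dtype=float), method="bh")


def build_up_list(
    stats: Iterable[GeneStat],
    alpha: float,
    fc_threshold: float | None = None,
    name: str = "up",
    bh: bool = False,
) -> GeneList:
    """Build the upregulated gene list at a strict p-value cutoff.

    Members are exactly the genes with (adjusted, if ``bh``) p < ``alpha``,
    and — when ``fc_threshold`` is given — with linear fold change strictly
    greater than the threshold. Members are ordered by ascending p-value.
    """
    if not 0.0 < alpha < 1.0:
        raise InputError(f"alpha must lie in (0, 1), got {alpha}")
    stats = sorted(stats, key=lambda s: (s.p_value, s.gene_id))
    p = [s.p_value for s in stats]
    p_eff = bh_adjust(p) if bh else np.asarray(p)
    genes: list[str] = []
    pmap: dict[str, float] = {}
    for s, pe in zip(stats, p_eff):
        if pe >= alpha:
            continue
        if fc_threshold is not None and not s.fold_change > fc_threshold:
            continue
        genes.append(s.gene_id)
        pmap[s.gene_id] = float(pe)
    prov = {
        "alpha": alpha,
        "fc_threshold": fc_threshold,
        "bh": bh,
        "n_tested": len(stats),
    }
    return GeneList(name=name, genes=genes, provenance=prov, p_values=pmap)
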