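"""Plain-text readers and writers for the pipeline's tabular formats.

Matrices and stats tables are TSV; gene lists are one identifier per line
with ``#`` comment headers carrying provenance; group labels are a
two-column sample<TAB>group TSV.
"""

from __future__ import annotations

import pandas as pd

from .dge import CASE, CONTROL, ExpressionMatrix, GeneList, GeneStat, InputError


def read_matrix(matrix_path, groups_path) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    groups = read_groups(groups_path)
    return ExpressionMatrix(values=values, groups=groups)


def write_matrix(matrix: ExpressionMatrix, matrix_path, groups_path=None) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="gene")
    if groups_path is not None:
        write_groups(matrix.groups, groups_path)


def read_groups(path) -> dict[str, str]:
    groups: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(f"group file line {lineno}: expected sample<TAB>group")
            sample, group = parts[0].strip(), parts[1].strip().lower()
            if group not in (CASE, CONTROL):
                raise InputError(
                    f"group file line {lineno}: group must be '{CASE}' or '{CONTROL}', got {group!r}"
                )
            if sample in groups:
                raise InputError(f"group file line {lineno}: duplicate sample {sample!r}")
            groups[sample] = group
    return groups


def write_groups(groups, path) -> None:
    with open(path, "w") as fh:
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def read_gene_list(path, name: str | None = None) -> GeneList:
    """One identifier per line; an optional second tab-separated column is
    parsed as a per-gene p-value. ``#`` lines are comments."""
    genes: list[str] = []
    pvals: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            gene = parts[0].strip()
            genes.append(gene)
            if len(parts) > 1 and parts[1].strip():
                pvals[gene] = float(parts[1])
    return GeneList(name=name or str(path), genes=genes, p_values=pvals or None)


def write_gene_list(gene_list: GeneList, path) -> None:
    with open(path, "w") as fh:
        for key, val in gene_list.provenance.items():
            fh.write(f"# {key}: {val}\n")
        for g in gene_list.genes:
            if gene_list.p_values and g in gene_list.p_values:
                fh.write(f"{g}\t{gene_list.p_values[g]:.6g}\n")
            else:
                fh.write(f"{g}\n")


def stats_frame(stats: list[GeneStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [s.gene_id for s in stats],
            "mean_case": [s.mean_case for s in stats],
            "mean_control": [s.mean_control for s in stats],
            "log_fold_change": [s.log_fold_change for s in stats],
            "fold_change": [s.fold_change for s in stats],
            "t_statistic": [s.t_statistic for s in stats],
            "p_value": [s.p_value for s in stats],
            "degenerate": [s.degenerate for s in stats],
        }
    )


def write_stats(stats: list[GeneStat], path) -> None:
    stats_frame(stats).to_csv(path, sep="\t", index=False)
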