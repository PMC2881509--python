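"""End-to-end orchestration: simulate or load data, test, build lists,
intersect, enrich, cross-tabulate panels, and select heatmap rows.

Every stage writes plain-text artifacts into the output directory and the
run closes with a manifest recording inputs, thresholds, seed, and the key
numbers, so each figure in the bundle can be recomputed from the bundle's
own intermediate files.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import io as okio
from .dge import ExpressionMatrix, GeneList, GeneStat, InputError, build_up_list, one_sided_up_test
from .enrichment import enrich, read_gmt
from .panels import cross_tabulate, load_fixture_panel, load_fixture_reference
from .setops import _harmonize_ids, intersect, venn_regions
from .simulate import SimulationConfig, simulate_paired_studies

__all__ = ["PipelineConfig", "PipelineError", "heatmap_selection", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, with the stage name attached."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs and thresholds for one pipeline run.

    Either ``simulation`` or both matrix paths may be given; with neither,
    only the fixture-panel stage runs. ``heatmap_fc``/``heatmap_alpha``
    govern the final intersect-and-filter row selection independently of the
    list-building thresholds (``fc_threshold`` may be None = no FC filter;
    ``heatmap_fc=0`` likewise disables the ratio filter there).
    """

    out_dir: Path
    simulation: SimulationConfig | None = None
    matrix_a: Path | None = None
    groups_a: Path | None = None
    matrix_b: Path | None = None
    groups_b: Path | None = None
    alpha: float = 0.05
    fc_threshold: float | None = None
    heatmap_fc: float = 1.5
    heatmap_alpha: float = 0.05
    gmt: Path | None = None
    gmt_pattern: str | None = None
    bh: bool = False
    pooled: bool = False
    panels: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InputError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.fc_threshold is not None and self.fc_threshold <= 0:
            raise InputError(f"fc_threshold must be positive, got {self.fc_threshold}")
        if self.heatmap_fc < 0:
            raise InputError(f"heatmap_fc must be >= 0, got {self.heatmap_fc}")
        if not 0.0 < self.heatmap_alpha <= 1.0:
            raise InputError(f"heatmap_alpha must lie in (0, 1], got {self.heatmap_alpha}")
        if self.simulation is not None:
            # one seed governs the run; the simulation's wins
            self.seed = self.simulation.seed


def heatmap_selection(
    matrix: ExpressionMatrix,
    stats: list[GeneStat],
    other: GeneList,
    fc_threshold: float,
    alpha: float,
) -> ExpressionMatrix:
    """Row subset of ``matrix``: genes passing p < alpha and linear fold
    change > fc_threshold that are also members of ``other`` (harmonized),
    ordered by ascending p-value. ``fc_threshold == 0`` disables the FC
    filter; ``alpha == 1`` keeps every gene regardless of p."""
    by_gene = {s.gene_id: s for s in stats}
    missing = [g for g in matrix.gene_ids if g not in by_gene]
    if missing:
        raise InputError(f"stats missing for genes: {missing[:5]}")
    other_set = set(_harmonize_ids(other.genes)[0])
    selected = []
    for g in matrix.gene_ids:
        s = by_gene[g]
        if alpha < 1.0 and not s.p_value < alpha:
            continue
        if fc_threshold > 0 and not s.fold_change > fc_threshold:
            continue
        if g.strip().upper() not in other_set:
            continue
        selected.append((s.p_value, g))
    selected.sort()
    order = [g for _, g in selected]
    return ExpressionMatrix(values=matrix.values.loc[order], groups=dict(matrix.groups))


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage name attached
                raise PipelineError(name, exc) from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and return the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "alpha": config.alpha,
        "fc_threshold": config.fc_threshold,
        "heatmap_fc": config.heatmap_fc,
        "heatmap_alpha": config.heatmap_alpha,
        "seed": config.seed,
        "stages": [],
    }

    matrices: list[tuple[str, ExpressionMatrix]] = []
    truths: dict[str, frozenset[str]] = {}

    if config.simulation is not None:
        sim = _run_simulate(config, out, manifest)
        matrices = sim[0]
        truths = sim[1]
    elif config.matrix_a is not None:
        matrices = _run_load(config, out, manifest)

    lists: list[GeneList] = []
    stats_by_study: dict[str, list[GeneStat]] = {}
    universe: GeneList | None = None
    if matrices:
        universe = GeneList(name="universe", genes=list(matrices[0][1].gene_ids))
        okio.write_gene_list(universe, out / "universe.txt")
        for label, matrix in matrices:
            stats, up = _run_dge(config, label, matrix, out, manifest)
            stats_by_study[label] = stats
            lists.append(up)
            if label in truths:
                truth = GeneList(name=f"truth_{label}", genes=sorted(truths[label]))
                okio.write_gene_list(truth, out / f"truth_{label}.txt")

    if len(lists) >= 2 and universe is not None:
        _run_overlap(lists, universe, out, manifest)

    if config.gmt is not None and lists and universe is not None:
        _run_enrich(config, lists[0], universe, out, manifest)

    if config.panels:
        _run_panels(config, out, manifest)

    if len(matrices) >= 2 and len(lists) >= 2:
        _run_heatmap(config, matrices[0][1], stats_by_study[matrices[0][0]], lists[1], out, manifest)

    manifest["completed_utc"] = time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


@_stage("simulate")
def _run_simulate(config: PipelineConfig, out: Path, manifest: dict):
    sim_cfg = config.simulation
    study_a, study_b = simulate_paired_studies(sim_cfg)
    matrices = []
    truths = {}
    for label, study in (("a", study_a), ("b", study_b)):
        okio.write_matrix(study.matrix, out / f"matrix_{label}.tsv", out / f"groups_{label}.tsv")
        matrices.append((label, study.matrix))
        truths[label] = study.truth_up
    manifest["stages"].append({"stage": "simulate", "config": vars(sim_cfg).copy()})
    return matrices, truths


@_stage("load")
def _run_load(config: PipelineConfig, out: Path, manifest: dict):
    matrices = [("a", okio.read_matrix(config.matrix_a, config.groups_a))]
    if config.matrix_b is not None:
        matrices.append(("b", okio.read_matrix(config.matrix_b, config.groups_b)))
    manifest["stages"].append(
        {"stage": "load", "matrix_a": str(config.matrix_a), "matrix_b": str(config.matrix_b)}
    )
    return matrices


@_stage("dge")
def _run_dge(config: PipelineConfig, label: str, matrix: ExpressionMatrix, out: Path, manifest: dict):
    stats = one_sided_up_test(matrix, pooled=config.pooled)
    okio.write_stats(stats, out / f"stats_{label}.tsv")
    up = build_up_list(
        stats,
        alpha=config.alpha,
        fc_threshold=config.fc_threshold,
        name=f"up_{label}",
        bh=config.bh,
    )
    up.provenance["contrast"] = f"study {label}: case vs control"
    okio.write_gene_list(up, out / f"up_{label}.txt")
    manifest["stages"].append(
        {"stage": "dge", "study": label, "n_genes": len(stats), "n_up": len(up)}
    )
    return stats, up


@_stage("overlap")
def _run_overlap(lists, universe, out: Path, manifest: dict):
    result = intersect(lists[0], lists[1], universe)
    frame = pd.DataFrame(
        [
            {
                "name_x": result.name_x,
                "name_y": result.name_y,
                "size_x": result.size_x,
                "size_y": result.size_y,
                "universe_size": result.universe_size,
                "overlap_size": result.overlap_size,
                "p_value": result.p_value,
                "dropped_x": result.dropped_x,
                "dropped_y": result.dropped_y,
            }
        ]
    )
    frame.to_csv(out / "overlap.tsv", sep="\t", index=False)
    okio.write_gene_list(
        GeneList(name="overlap_members", genes=list(result.overlap_genes)),
        out / "overlap_members.txt",
    )
    venn = venn_regions(lists[:3] if len(lists) == 3 else lists[:2], universe)
    rows = [
        {"region": "".join(map(str, key)), "count": count}
        for key, count in sorted(venn.region_counts.items())
    ]
    pd.DataFrame(rows).to_csv(out / "venn.tsv", sep="\t", index=False)
    manifest["stages"].append(
        {
            "stage": "overlap",
            "overlap_size": result.overlap_size,
            "p_value": result.p_value,
            "dropped_x": result.dropped_x,
            "dropped_y": result.dropped_y,
        }
    )
    return result


@_stage("enrich")
def _run_enrich(config: PipelineConfig, query, universe, out: Path, manifest: dict):
    collection = read_gmt(config.gmt)
    table = enrich(query, collection, universe, pattern=config.gmt_pattern, bh=config.bh)
    table.to_frame().to_csv(out / "enrichment.tsv", sep="\t", index=False)
    manifest["stages"].append(
        {"stage": "enrich", "n_sets": len(table), "query_size": table.query_size}
    )
    return table


@_stage("panels")
def _run_panels(config: PipelineConfig, out: Path, manifest: dict):
    reference = load_fixture_reference()
    summaries = {}
    for name in config.panels:
        panel = load_fixture_panel(name)
        xtab = cross_tabulate(panel, reference)
        rows = [
            {"gene": g, "member": int(xtab.flags[g][0])}
            for g in xtab.gene_ids
        ]
        pd.DataFrame(rows).to_csv(out / f"crosstab_{name}.tsv", sep="\t", index=False)
        flagged, total = xtab.summary()[reference.name]
        summaries[name] = {"flagged": flagged, "total": total}
    manifest["stages"].append({"stage": "panels", "summaries": summaries})
    return summaries


@_stage("heatmap")
def _run_heatmap(config: PipelineConfig, matrix, stats, other, out: Path, manifest: dict):
    sub = heatmap_selection(matrix, stats, other, config.heatmap_fc, config.heatmap_alpha)
    okio.write_matrix(sub, out / "heatmap_matrix.tsv")
    manifest["stages"].append({"stage": "heatmap", "n_rows": len(sub.gene_ids)})
    return sub
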