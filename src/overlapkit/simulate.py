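"""Synthetic two-group expression studies with planted upregulated genes.

Gaussian log2-intensity noise per gene per sample; planted genes get a mean
shift in the case group. Paired studies share a controlled fraction of their
planted sets so the downstream intersection machinery can be exercised
against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dge import CASE, CONTROL, ExpressionMatrix, InputError

__all__ = ["SimulationConfig", "SimulatedStudy", "simulate_study", "simulate_paired_studies"]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a planted two-group simulation.

    ``effect`` is the log2 mean shift added to planted genes in the case
    group. ``shared_frac`` only matters for paired studies and fixes the
    fraction of planted genes the two studies have in common.
    ``baseline_sd > 0`` draws per-gene baseline means from a Gaussian
    hyperprior instead of using a single flat baseline.
    """

    n_genes: int = 1000
    n_group1: int = 25
    n_group2: int = 25
    baseline_mean: float = 8.0
    noise_sd: float = 0.5
    frac_up: float = 0.1
    effect: float = 2.0
    shared_frac: float = 0.5
    seed: int = 0
    baseline_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.n_group1 < 2 or self.n_group2 < 2:
            raise ConfigurationError(
                f"need >=2 samples per group, got {self.n_group1}/{self.n_group2}"
            )
        if not 0.0 <= self.frac_up <= 1.0:
            raise ConfigurationError(f"frac_up must lie in [0, 1], got {self.frac_up}")
        if not 0.0 <= self.shared_frac <= 1.0:
            raise ConfigurationError(f"shared_frac must lie in [0, 1], got {self.shared_frac}")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.baseline_sd < 0:
            raise ConfigurationError(f"baseline_sd must be >= 0, got {self.baseline_sd}")

    @property
    def n_planted(self) -> int:
        return round(self.frac_up * self.n_genes)


@dataclass(frozen=True)
class SimulatedStudy:
    matrix: ExpressionMatrix
    truth_up: frozenset[str]


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _sample_ids(n1: int, n2: int) -> tuple[list[str], list[str]]:
    case = [f"case_{i + 1:03d}" for i in range(n1)]
    ctrl = [f"ctrl_{i + 1:03d}" for i in range(n2)]
    return case, ctrl


def _build_study(
    config: SimulationConfig, truth_idx: np.ndarray, ss: np.random.SeedSequence
) -> SimulatedStudy:
    rng = np.random.default_rng(ss)
    genes = _gene_ids(config.n_genes)
    case_ids, ctrl_ids = _sample_ids(config.n_group1, config.n_group2)
    n = config.n_group1 + config.n_group2

    baseline = np.full(config.n_genes, config.baseline_mean, dtype=float)
    if config.baseline_sd > 0:
        baseline = baseline + rng.normal(0.0, config.baseline_sd, size=config.n_genes)
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
    values[truth_idx, : config.n_group1] += config.effect

    frame = pd.DataFrame(values, index=genes, columns=case_ids + ctrl_ids)
    groups = {s: CASE for s in case_ids} | {s: CONTROL for s in ctrl_ids}
    truth = frozenset(genes[i] for i in truth_idx)
    return SimulatedStudy(matrix=ExpressionMatrix(values=frame, groups=groups), truth_up=truth)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Simulate one two-group study with ``round(frac_up * n_genes)`` planted
    upregulated genes. Deterministic for a fixed config (seed included)."""
    ss = np.random.SeedSequence(config.seed)
    ss_pick, ss_noise = ss.spawn(2)
    rng = np.random.default_rng(ss_pick)
    truth_idx = np.sort(rng.choice(config.n_genes, size=config.n_planted, replace=False))
    return _build_study(config, truth_idx, ss_noise)


def simulate_paired_studies(config: SimulationConfig) -> tuple[SimulatedStudy, SimulatedStudy]:
    """Simulate two independent studies over the same gene universe whose
    planted sets share exactly ``round(shared_frac * n_planted)`` genes."""
    n_up = config.n_planted
    n_shared = round(config.shared_frac * n_up)
    n_excl = n_up - n_shared
    if n_up + n_excl > config.n_genes:
        raise ConfigurationError(
            f"cannot plant two sets of {n_up} genes sharing {n_shared} in a "
            f"universe of {config.n_genes}"
        )
    ss = np.random.SeedSequence(config.seed)
    ss_pick, ss_a, ss_b = ss.spawn(3)
    rng = np.random.default_rng(ss_pick)
    perm = rng.permutation(config.n_genes)
    truth_a = perm[:n_up]
    shared = truth_a[rng.choice(n_up, size=n_shared, replace=False)] if n_up else truth_a[:0]
    truth_b = np.concatenate([shared, perm[n_up : n_up + n_excl]])
    study_a = _build_study(config, np.sort(truth_a), ss_a)
    study_b = _build_study(config, np.sort(truth_b), ss_b)
    return study_a, study_b
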