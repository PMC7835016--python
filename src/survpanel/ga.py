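"""Genetic-algorithm search for a prognostic gene panel.

The search space is the set of binary chromosomes over a candidate gene list
(48 genes for the RhoA-activity-regulation set); a 1 marks the gene as part
of the panel. A chromosome's fitness (lower is better) is the mean two-group
log-rank p-value over repeated random half-cohort subsamples, each split into
panel-mutant vs wild-type patients — panels whose mutation status separates
survival robustly across subsamples score low. The default operator
configuration follows the study settings: population 40, single-point
crossover with probability 0.1, independent per-bit flip mutation with
probability 0.01, 50 000 generations, 100 subsample repeats at fraction 0.5;
selection is tournament of size max(2, population/10), with elitism.

Subsamples are redrawn at every fitness evaluation from the run-level RNG
stream (no memoization): fitness is deliberately stochastic between
evaluations but the whole run is reproducible from its seed. Degenerate
splits (either group empty, or no events in the subsample) contribute the
penalty p = 1, so a panel that mutates nobody can never win; the all-zero
chromosome scores exactly 1 without subsampling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .survival import (
    CoxFit,
    DegenerateGroupsError,
    KMEstimate,
    LogRankResult,
    SurvivalRecord,
    cox_fit,
    km_estimate,
    logrank_test,
    _logrank_p_sorted,
)
from .variants import MutationMatrix, classify_panel_status

logger = logging.getLogger(__name__)

__all__ = [
    "GAConfig",
    "PanelSolution",
    "GAResult",
    "PanelEvaluation",
    "fitness",
    "ga_run",
    "evaluate_panel",
]


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 40
    crossover_prob: float = 0.1
    mutation_prob: float = 0.01
    max_generations: int = 50_000
    subsample_fraction: float = 0.5
    subsample_repeats: int = 100
    elitism: bool = True
    tournament_size: int | None = None  # default max(2, population_size // 10)
    seed: int = 0
    early_stop_generations: int | None = None

    def effective_tournament_size(self) -> int:
        if self.tournament_size is not None:
            return self.tournament_size
        return max(2, self.population_size // 10)

    def validate(self, n_patients: int | None = None) -> None:
        for name in ("crossover_prob", "mutation_prob", "subsample_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_generations < 0:
            raise ValueError("max_generations must be >= 0")
        if self.subsample_repeats < 1:
            raise ValueError("subsample_repeats must be >= 1")
        if self.effective_tournament_size() < 1:
            raise ValueError("tournament_size must be >= 1")
        if n_patients is not None and _subsample_size(
            self.subsample_fraction, n_patients
        ) < 2:
            raise ValueError(
                "subsample_fraction x cohort size must give >= 2 patients"
            )


@dataclass
class PanelSolution:
    """A binary chromosome over the candidate gene list, with its fitness."""

    chromosome: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome, dtype=bool)

    @property
    def evaluated(self) -> bool:
        return self.fitness is not None

    def selected_genes(self, genes: Sequence[str]) -> list[str]:
        if len(genes) != len(self.chromosome):
            raise ValueError("gene list length does not match chromosome")
        return [g for g, bit in zip(genes, self.chromosome) if bit]


@dataclass
class GAResult:
    best_solution: PanelSolution
    selected_genes: list[str]
    fitness_trajectory: list[float]
    config: GAConfig
    seed: int
    candidate_genes: list[str]


def _subsample_size(fraction: float, n: int) -> int:
    """Round half-up, so 50% of 160 is exactly 80."""
    return int(math.floor(fraction * n + 0.5))


def _align_clinical(
    matrix: MutationMatrix, clinical: Sequence[SurvivalRecord]
) -> tuple[np.ndarray, np.ndarray]:
    by_id = {r.sample_id: r for r in clinical}
    if set(by_id) != set(matrix.samples):
        missing = set(matrix.samples) - set(by_id)
        extra = set(by_id) - set(matrix.samples)
        raise ValueError(
            f"matrix and clinical samples differ (missing clinical: "
            f"{sorted(missing)[:5]}, extra clinical: {sorted(extra)[:5]})"
        )
    time = np.array([by_id[s].time for s in matrix.samples], dtype=float)
    event = np.array([by_id[s].event for s in matrix.samples], dtype=np.int64)
    return time, event


def _fitness_arrays(
    chrom: np.ndarray,
    values: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    n_sub: int,
    repeats: int,
    rng: np.random.Generator,
) -> float:
    """Mean subsample log-rank p. ``values``/``time``/``event`` must already
    be sorted by time (see :func:`_presort`), so a sorted draw of row
    positions yields a time-sorted subsample without re-sorting."""
    if not chrom.any():
        return 1.0
    mutant = values[:, chrom].any(axis=1)
    n = len(time)
    total = 0.0
    for _ in range(repeats):
        idx = np.sort(rng.permutation(n)[:n_sub])
        g = mutant[idx]
        try:
            p = _logrank_p_sorted(
                event[idx], g, time[idx], int(g.sum())
            )
        except DegenerateGroupsError:
            p = 1.0
        total += p
    return total / repeats


def _presort(
    values: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    order = np.argsort(time, kind="stable")
    return values[order], time[order], event[order]


def fitness(
    solution: PanelSolution,
    matrix: MutationMatrix,
    clinical: Sequence[SurvivalRecord],
    config: GAConfig,
    rng: np.random.Generator,
) -> float:
    """Mean subsample log-rank p for one chromosome (lower is better).

    Draws ``subsample_repeats`` simple random subsamples without replacement
    of round(fraction x n) patients, splits each by the chromosome's panel
    status, and averages the log-rank p-values; degenerate splits count as
    p = 1. The all-zero chromosome returns 1.0 without subsampling.
    """
    if len(solution.chromosome) != len(matrix.genes):
        raise ValueError("chromosome length does not match matrix genes")
    time, event = _align_clinical(matrix, clinical)
    n_sub = _subsample_size(config.subsample_fraction, len(time))
    if n_sub < 2:
        raise ValueError("subsample must contain at least 2 patients")
    values, time, event = _presort(matrix.values, time, event)
    return _fitness_arrays(
        solution.chromosome, values, time, event,
        n_sub, config.subsample_repeats, rng,
    )


def ga_run(
    matrix: MutationMatrix,
    clinical: Sequence[SurvivalRecord],
    candidate_genes: Sequence[str],
    config: GAConfig,
    progress_every: int = 0,
) -> GAResult:
    """Run the GA and return the best-ever panel with its fitness trajectory.

    Each generation: tournament selection, single-point crossover with
    probability ``crossover_prob``, independent per-bit mutation with
    probability ``mutation_prob``, then evaluation; with elitism the best
    individual survives unchanged (keeping its recorded fitness, since
    fitness is stochastic). The trajectory records the best fitness in the
    population at each generation. Fully reproducible given ``config.seed``.
    """
    config.validate(n_patients=len(clinical))
    genes = list(candidate_genes)
    idx = matrix.gene_indices(genes)  # raises if any candidate is missing
    values = matrix.values[:, idx]
    time, event = _align_clinical(matrix, clinical)
    values, time, event = _presort(values, time, event)
    n_sub = _subsample_size(config.subsample_fraction, len(time))
    L = len(genes)
    rng = np.random.default_rng(config.seed)

    def evaluate(chrom: np.ndarray) -> float:
        return _fitness_arrays(
            chrom, values, time, event, n_sub, config.subsample_repeats, rng
        )

    pop = [rng.random(L) < 0.5 for _ in range(config.population_size)]
    fits = [evaluate(c) for c in pop]

    best_i = int(np.argmin(fits))
    best_chrom = pop[best_i].copy()
    best_fit = fits[best_i]
    trajectory = [best_fit]
    stall = 0
    tsize = config.effective_tournament_size()

    def tournament() -> np.ndarray:
        contenders = rng.integers(0, config.population_size, size=tsize)
        winner = min(contenders, key=lambda i: fits[i])
        return pop[winner]

    for gen in range(config.max_generations):
        new_pop: list[np.ndarray] = []
        new_fits: list[float] = []
        if config.elitism:
            new_pop.append(best_chrom.copy())
            new_fits.append(best_fit)
        while len(new_pop) < config.population_size:
            p1, p2 = tournament(), tournament()
            if L > 1 and rng.random() < config.crossover_prob:
                point = int(rng.integers(1, L))
                c1 = np.concatenate([p1[:point], p2[point:]])
                c2 = np.concatenate([p2[:point], p1[point:]])
            else:
                c1, c2 = p1.copy(), p2.copy()
            for child in (c1, c2):
                if len(new_pop) >= config.population_size:
                    break
                flips = rng.random(L) < config.mutation_prob
                child = np.where(flips, ~child, child)
                new_pop.append(child)
                new_fits.append(evaluate(child))
        pop, fits = new_pop, new_fits

        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_fit = fits[gen_best]
            best_chrom = pop[gen_best].copy()
            stall = 0
        else:
            stall += 1
        trajectory.append(min(fits))
        if progress_every and (gen + 1) % progress_every == 0:
            logger.info("generation %d: best fitness %.6g", gen + 1, best_fit)
        if (
            config.early_stop_generations is not None
            and stall >= config.early_stop_generations
        ):
            logger.info("early stop at generation %d (stalled %d)", gen + 1, stall)
            break

    best = PanelSolution(chromosome=best_chrom, fitness=best_fit)
    return GAResult(
        best_solution=best,
        selected_genes=best.selected_genes(genes),
        fitness_trajectory=trajectory,
        config=config,
        seed=config.seed,
        candidate_genes=genes,
    )


@dataclass
class PanelEvaluation:
    """Full-cohort evaluation of a fixed panel."""

    panel: list[str]
    mutant_fraction: float
    n_mutant: int
    n: int
    km_mutant: KMEstimate | None
    km_wildtype: KMEstimate | None
    logrank: LogRankResult | None
    cox_univariate: CoxFit | None
    cox_multivariate: CoxFit | None
    degenerate: bool


def evaluate_panel(
    panel: Sequence[str],
    matrix: MutationMatrix,
    clinical: Sequence[SurvivalRecord],
    adjust_for: Sequence[str] = (),
) -> PanelEvaluation:
    """KM curves, log-rank and Cox fits for a fixed gene panel.

    Univariate Cox uses panel status alone; if ``adjust_for`` names clinical
    covariates (e.g. age, gender, Lauren class, stage), a multivariate fit
    adjusting for them is included. A panel with zero mutant (or zero
    wild-type) patients is flagged degenerate: the comparison statistics are
    omitted rather than computed on an empty group.
    """
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    status = classify_panel_status(matrix, list(panel))
    by_id = {r.sample_id: r for r in clinical}
    records = [by_id[s] for s in matrix.samples]
    mutant = [r for r, m in zip(records, status) if m]
    wildtype = [r for r, m in zip(records, status) if not m]
    n = len(records)
    n_mut = len(mutant)

    degenerate = n_mut == 0 or n_mut == n
    km_mut = km_estimate(mutant) if mutant else None
    km_wt = km_estimate(wildtype) if wildtype else None
    lr = None
    cox_uni = None
    cox_multi = None
    if not degenerate:
        try:
            lr = logrank_test(wildtype, mutant)
        except DegenerateGroupsError:
            degenerate = True
    if not degenerate:
        augmented = [
            SurvivalRecord(
                sample_id=r.sample_id,
                time=r.time,
                event=r.event,
                covariates={**dict(r.covariates), "panel": float(m)},
            )
            for r, m in zip(records, status)
        ]
        cox_uni = cox_fit(augmented, ["panel"])
        if adjust_for:
            cox_multi = cox_fit(augmented, ["panel", *adjust_for])
    return PanelEvaluation(
        panel=list(panel),
        mutant_fraction=n_mut / n,
        n_mutant=n_mut,
        n=n,
        km_mutant=km_mut,
        km_wildtype=km_wt,
        logrank=lr,
        cox_univariate=cox_uni,
        cox_multivariate=cox_multi,
        degenerate=degenerate,
    )
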