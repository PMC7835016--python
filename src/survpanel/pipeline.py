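"""End-to-end orchestration: filter -> matrix -> split -> GA -> evaluation.

The pipeline mirrors the cohort workflow of the prognostic-panel analysis:
variants are confidence-filtered, binarized into a patients x genes matrix,
the cohort is split into disjoint training and validation halves, the
genetic algorithm selects a panel on the training half only, and the panel
is then evaluated (KM, log-rank, uni-/multivariate Cox) on the untouched
validation half — the split exists precisely to expose the selection bias a
GA-chosen panel carries on its own training data. Companion per-sample
immunogenomic scores (TMB, optional signature dMMR) and an optional ICB
response contingency report round out the run directory.

Every artifact is stamped with the config hash and seed; deterministic
stages re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as spio
from .ga import GAConfig, PanelEvaluation, evaluate_panel, ga_run
from .immuno import (
    TRINUCLEOTIDE_CHANNELS,
    TrinucleotideSpectrum,
    compute_tmb,
    decompose_signatures,
    dmmr_fraction,
)
from .survival import SurvivalRecord, fisher_exact_2x2
from .variants import MutationMatrix, build_mutation_matrix, classify_panel_status, filter_variants

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ResponseTable",
    "PipelineError",
    "split_cohort",
    "icb_response_report",
    "run_pipeline",
]

RESPONSE_CATEGORIES = ("PD", "SD", "PR")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def split_cohort(
    clinical: Sequence[SurvivalRecord],
    train_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[list[SurvivalRecord], list[SurvivalRecord]]:
    """Disjoint, exhaustive, reproducible simple random train/validation split.

    The training size is round(train_fraction x n) half-up, so a 0.5 split of
    160 patients gives 80/80 and a 160/315 fraction gives 160/155.
    """
    n = len(clinical)
    if n < 4:
        raise ValueError("cohort must contain at least 4 patients to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n_train = int(math.floor(train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    train_idx = set(perm[:n_train].tolist())
    train = [r for i, r in enumerate(clinical) if i in train_idx]
    valid = [r for i, r in enumerate(clinical) if i not in train_idx]
    return train, valid


@dataclass
class ResponseTable:
    """ICB response cross-tabulation by panel status, with a collapsed 2x2.

    ``collapse`` is either ``"PD"`` (progressive disease vs rest) or ``"PR"``
    (responder vs non-responder). Rates are percentages rounded to one
    decimal in the rendered report; an empty group's rates are None rather
    than a division by zero.
    """

    counts: pd.DataFrame  # rows: wild-type/mutant; columns: PD/SD/PR
    rates_pct: pd.DataFrame
    collapse: str
    table_2x2: np.ndarray
    fisher_p: float | None


def icb_response_report(
    clinical: Sequence[SurvivalRecord],
    panel_status: Mapping[str, bool],
    response_key: str = "response",
    collapse: str = "PD",
) -> ResponseTable:
    """Cross-tabulate panel status against PD/SD/PR response categories.

    Every patient needs a response label and a panel status; unknown labels
    raise, listing the offenders. The collapsed 2x2 (by default PD vs
    non-PD; ``collapse="PR"`` gives responder vs non-responder) is tested
    with Fisher's exact test when both groups are non-empty.
    """
    if collapse not in ("PD", "PR"):
        raise ValueError("collapse must be 'PD' or 'PR'")
    offenders = []
    rows = []
    for r in clinical:
        label = r.covariates.get(response_key)
        if label not in RESPONSE_CATEGORIES:
            offenders.append(f"{r.sample_id}={label!r}")
            continue
        if r.sample_id not in panel_status:
            raise ValueError(f"no panel status for sample {r.sample_id}")
        rows.append(("mutant" if panel_status[r.sample_id] else "wild-type", label))
    if offenders:
        shown = ", ".join(offenders[:10])
        more = f" (+{len(offenders) - 10} more)" if len(offenders) > 10 else ""
        raise ValueError(f"unknown response labels: {shown}{more}")

    counts = pd.DataFrame(
        0, index=["wild-type", "mutant"], columns=list(RESPONSE_CATEGORIES)
    )
    for group, label in rows:
        counts.loc[group, label] += 1
    totals = counts.sum(axis=1)
    rates = counts.astype(float)
    for g in rates.index:
        if totals[g] > 0:
            rates.loc[g] = (counts.loc[g] / totals[g] * 100).round(1)
        else:
            rates.loc[g] = np.nan

    hit = counts[collapse]
    miss = totals - hit
    table = np.array(
        [[hit["wild-type"], miss["wild-type"]], [hit["mutant"], miss["mutant"]]],
        dtype=np.int64,
    )
    fisher_p = (
        fisher_exact_2x2(table) if (totals > 0).all() and table.sum() >= 1 else None
    )
    return ResponseTable(
        counts=counts,
        rates_pct=rates,
        collapse=collapse,
        table_2x2=table,
        fisher_p=fisher_p,
    )


@dataclass
class RunConfig:
    """File paths plus stage options for one pipeline run."""

    variants_path: str
    clinical_path: str
    genes_path: str
    out_dir: str
    seed: int = 0
    ga: GAConfig = field(default_factory=GAConfig)
    train_fraction: float = 0.5
    adjust_for: tuple[str, ...] = ()
    signatures_path: str | None = None
    spectra_path: str | None = None
    response_column: str | None = None
    icb_collapse: str = "PD"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        ga = GAConfig(**raw.pop("ga", {}))
        raw["adjust_for"] = tuple(raw.get("adjust_for", ()))
        return cls(ga=ga, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["adjust_for"] = list(self.adjust_for)
        return d

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (the output location
        does not change what is computed)."""
        d = self.to_dict()
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _submatrix(matrix: MutationMatrix, samples: Sequence[str]) -> MutationMatrix:
    pos = {s: i for i, s in enumerate(matrix.samples)}
    rows = [pos[s] for s in samples]
    return MutationMatrix(list(samples), list(matrix.genes), matrix.values[rows])


def _evaluation_dict(ev: PanelEvaluation) -> dict:
    out = {
        "panel": ev.panel,
        "n": ev.n,
        "n_mutant": ev.n_mutant,
        "mutant_fraction": ev.mutant_fraction,
        "degenerate": ev.degenerate,
    }
    if ev.logrank is not None:
        out["logrank_p"] = ev.logrank.p_value
        out["logrank_statistic"] = ev.logrank.statistic
    for key, fit in (("cox_univariate", ev.cox_univariate),
                     ("cox_multivariate", ev.cox_multivariate)):
        if fit is not None:
            out[key] = {
                "hazard_ratios": fit.hazard_ratios,
                "ci_lower": fit.ci_lower,
                "ci_upper": fit.ci_upper,
                "p_values": fit.p_values,
                "converged": fit.converged,
                "separation": fit.separation,
            }
    return out


def _read_spectra(path: str | Path) -> dict[str, TrinucleotideSpectrum]:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if list(df.columns) != list(TRINUCLEOTIDE_CHANNELS):
        raise ValueError(
            f"spectra file {path} must have the 96 trinucleotide channels "
            "as columns, in COSMIC order"
        )
    return {
        str(s): TrinucleotideSpectrum(counts=df.loc[s].to_numpy())
        for s in df.index
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow and write a run directory.

    Stages: read + filter variants -> mutation matrix -> train/validation
    split -> GA panel selection on training data -> panel evaluation on both
    halves -> per-sample TMB (and signature dMMR when spectra are supplied)
    -> optional ICB response report. Any stage error aborts with the stage
    name. Returns the run directory path.
    """
    t0 = _time.time()
    for label, p in (
        ("variants", config.variants_path),
        ("clinical", config.clinical_path),
        ("gene list", config.genes_path),
        ("signatures", config.signatures_path),
        ("spectra", config.spectra_path),
    ):
        if p is not None and not Path(p).exists():
            raise PipelineError(f"stage input-check: {label} file not found: {p}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    results: dict = {"provenance": {**stamp, "config": config.to_dict()}}

    def stage(name):
        logger.info("stage %s (t+%.1fs)", name, _time.time() - t0)

    try:
        stage("ingest")
        variants = spio.read_maf(config.variants_path)
        clinical = spio.read_clinical(config.clinical_path)
        genes = spio.read_gene_list(config.genes_path)
    except (ValueError, OSError) as err:
        raise PipelineError(f"stage ingest: {err}") from err

    try:
        stage("filter")
        filtered = filter_variants(variants)
        results["filter"] = {"n_input": len(variants), "n_retained": len(filtered)}
    except ValueError as err:
        raise PipelineError(f"stage filter: {err}") from err

    try:
        stage("matrix")
        samples = [r.sample_id for r in clinical]
        matrix = build_mutation_matrix(filtered, samples, genes)
    except ValueError as err:
        raise PipelineError(f"stage matrix: {err}") from err

    try:
        stage("split")
        train, valid = split_cohort(clinical, config.train_fraction, config.seed)
        results["split"] = {
            "n_train": len(train),
            "n_validation": len(valid),
            "train_samples": [r.sample_id for r in train],
        }
    except ValueError as err:
        raise PipelineError(f"stage split: {err}") from err

    try:
        stage("select-panel")
        train_matrix = _submatrix(matrix, [r.sample_id for r in train])
        ga_result = ga_run(train_matrix, train, genes, config.ga)
        results["ga"] = {
            "selected_genes": ga_result.selected_genes,
            "best_fitness": ga_result.best_solution.fitness,
            "n_generations": len(ga_result.fitness_trajectory) - 1,
            "fitness_trajectory": ga_result.fitness_trajectory,
            "chromosome": ga_result.best_solution.chromosome.astype(int).tolist(),
        }
    except ValueError as err:
        raise PipelineError(f"stage select-panel: {err}") from err

    try:
        stage("evaluate")
        panel = ga_result.selected_genes
        if panel:
            valid_matrix = _submatrix(matrix, [r.sample_id for r in valid])
            results["evaluation"] = {
                "train": _evaluation_dict(
                    evaluate_panel(panel, train_matrix, train, config.adjust_for)
                ),
                "validation": _evaluation_dict(
                    evaluate_panel(panel, valid_matrix, valid, config.adjust_for)
                ),
            }
        else:
            results["evaluation"] = {"note": "GA selected an empty panel"}
    except ValueError as err:
        raise PipelineError(f"stage evaluate: {err}") from err

    try:
        stage("immunogenomics")
        by_sample: dict[str, list] = {s: [] for s in samples}
        for v in filtered:
            by_sample[v.sample_id].append(v)
        score_rows = []
        spectra = _read_spectra(config.spectra_path) if config.spectra_path else {}
        reference = (
            spio.read_signature_matrix(config.signatures_path)
            if config.signatures_path
            else None
        )
        status = classify_panel_status(matrix, panel) if panel else None
        status_map = (
            dict(zip(matrix.samples, status.tolist())) if status is not None else {}
        )
        for s in samples:
            tmb = compute_tmb(by_sample[s], sample_id=s)
            row = {
                "sample_id": s,
                "panel_status": (
                    "mutant" if status_map.get(s) else "wild-type"
                    if status_map else "NA"
                ),
                "counted_variants": tmb.counted_variants,
                "tmb": tmb.tmb,
                "dmmr_fraction": np.nan,
                "signature_qc_pass": np.nan,
            }
            if reference is not None and s in spectra:
                exposure = decompose_signatures(spectra[s], reference)
                row["signature_qc_pass"] = exposure.qc_pass
                if exposure.qc_pass:
                    row["dmmr_fraction"] = dmmr_fraction(exposure)
            score_rows.append(row)
        scores = pd.DataFrame(score_rows)
    except ValueError as err:
        raise PipelineError(f"stage immunogenomics: {err}") from err

    if config.response_column is not None and panel:
        try:
            stage("icb-report")
            report = icb_response_report(
                clinical, status_map,
                response_key=config.response_column,
                collapse=config.icb_collapse,
            )
            results["icb"] = {
                "counts": report.counts.to_dict(),
                "rates_pct": report.rates_pct.to_dict(),
                "collapse": report.collapse,
                "table_2x2": report.table_2x2.tolist(),
                "fisher_p": report.fisher_p,
            }
        except ValueError as err:
            raise PipelineError(f"stage icb-report: {err}") from err

    stage("write")
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "sample_scores.tsv", "w") as fh:
        fh.write(f"#config_hash={stamp['config_hash']} seed={stamp['seed']}\n")
        scores.to_csv(fh, sep="\t", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    logger.info("pipeline finished in %.1fs", _time.time() - t0)
    return out
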