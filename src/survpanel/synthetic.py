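"""Synthetic cohorts with planted prognostic structure.

Every downstream stage (filtering, matrix construction, GA panel selection,
survival evaluation, signature decomposition) is testable without any data
download by simulating cohorts that carry the statistical structure the
analysis assumes:

* per-gene mutation incidence drawn independently with a configurable
  probability, over a candidate list of 48 genes by default;
* a *planted* sub-panel whose mutation multiplies the hazard — survival is
  exponential with hazard ``baseline * HR^(panel-mutant)``, so proportional
  hazards holds by construction and Cox/log-rank recovery can be checked
  against the planted truth;
* independent uniform censoring on ``[0, horizon]`` (noninformative);
* read depths from a negative-binomial model and VAFs from a beta model, so
  the confidence filters have something to chew on;
* optional 96-channel mutation spectra drawn from known mixtures of a
  reference signature matrix.

Gene-incidence ("driver") variants are drawn so that they pass the three
confidence filters; the generator's truth labels are therefore exactly what
:func:`survpanel.variants.classify_panel_status` recovers after filtering.
Filter behaviour is exercised by separately generated noise variants
(synonymous/noncoding/splice calls and low-coverage records).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .immuno import TRINUCLEOTIDE_CHANNELS, TrinucleotideSpectrum
from .survival import SurvivalRecord
from .variants import EffectClass, VariantRecord

__all__ = [
    "SimConfig",
    "CohortTruth",
    "SimulatedCohort",
    "default_candidate_genes",
    "simulate_cohort",
    "simulate_spectrum",
    "synthetic_reference_signatures",
]

_DRIVER_CLASSES = (
    EffectClass.MISSENSE,
    EffectClass.NONSENSE,
    EffectClass.FRAMESHIFT_INDEL,
    EffectClass.INFRAME_INDEL,
)
_DRIVER_CLASS_P = np.array([0.75, 0.10, 0.10, 0.05])
_BASES = np.array(["A", "C", "G", "T"])


def default_candidate_genes(n: int = 48) -> tuple[str, ...]:
    """Placeholder gene symbols GENE01..GENEnn for simulated candidate lists."""
    return tuple(f"GENE{i:02d}" for i in range(1, n + 1))


@dataclass(frozen=True)
class SimConfig:
    """Conditions for one simulated cohort.

    Defaults emulate a stage II-III gastric-cancer exome cohort: 48 candidate
    genes mutated at ~2% each (a 20-gene panel then yields roughly a quarter
    of patients panel-mutant), baseline hazard 0.03 events/month (median OS
    ~23 months), administrative-style uniform censoring on [0, 120] months
    (~27% censored), mean tumor coverage 100x.
    """

    n_patients: int
    candidate_genes: tuple[str, ...] = field(default_factory=default_candidate_genes)
    per_gene_mutation_prob: float | tuple[float, ...] = 0.02
    planted_panel: tuple[str, ...] = ()
    planted_hazard_ratio: float = 1.0
    baseline_hazard: float = 0.03
    censoring_horizon: float = 120.0
    depth_mean: float = 100.0
    depth_dispersion: float = 10.0
    vaf_alpha: float = 2.0
    vaf_beta: float = 4.0
    noise_variants_mean: float = 2.0
    signature_mixture: tuple[float, ...] | None = None
    mutations_per_sample: float | None = None
    seed: int = 0

    def gene_probs(self) -> np.ndarray:
        p = np.broadcast_to(
            np.asarray(self.per_gene_mutation_prob, dtype=float),
            (len(self.candidate_genes),),
        )
        return np.array(p)

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if len(self.candidate_genes) == 0:
            raise ValueError("candidate gene list is empty")
        p = self.gene_probs()
        if ((p < 0) | (p > 1)).any():
            raise ValueError("per_gene_mutation_prob must lie in [0, 1]")
        if not set(self.planted_panel) <= set(self.candidate_genes):
            extra = set(self.planted_panel) - set(self.candidate_genes)
            raise ValueError(f"planted panel genes not in candidates: {sorted(extra)}")
        if self.planted_hazard_ratio <= 0:
            raise ValueError("planted_hazard_ratio must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_horizon <= 0:
            raise ValueError("censoring_horizon must be > 0")
        if self.signature_mixture is not None:
            w = np.asarray(self.signature_mixture, dtype=float)
            if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError("signature_mixture must be nonnegative, sum to 1")


@dataclass
class CohortTruth:
    """The planted ground truth, for recovery tests."""

    planted_panel: tuple[str, ...]
    panel_status: dict[str, bool]
    signature_mixture: np.ndarray | None = None


@dataclass
class SimulatedCohort:
    variants: list[VariantRecord]
    clinical: list[SurvivalRecord]
    truth: CohortTruth
    spectra: dict[str, TrinucleotideSpectrum] | None = None
    config: SimConfig | None = None

    @property
    def samples(self) -> list[str]:
        return [r.sample_id for r in self.clinical]


def _draw_confident_depths(rng: np.random.Generator, cfg: SimConfig) -> tuple[int, int]:
    """Depth/alt pair guaranteed to pass the 30/7/0.05 confidence filters."""
    k, m = cfg.depth_dispersion, cfg.depth_mean
    p_nb = k / (k + m)
    for _ in range(1000):
        total = int(rng.negative_binomial(k, p_nb))
        if total < 30:
            continue
        vaf_true = rng.beta(cfg.vaf_alpha, cfg.vaf_beta)
        alt = int(rng.binomial(total, vaf_true))
        if alt >= 7 and alt / total >= 0.05:
            return total, alt
    # pathological depth model; fall back to an unambiguously confident call
    return max(30, int(m)), max(7, int(0.3 * max(30, int(m))))


def _random_snv(rng: np.random.Generator) -> tuple[str, int, str, str]:
    chrom = str(rng.integers(1, 23))
    pos = int(rng.integers(1, 50_000_000))
    ref = str(rng.choice(_BASES))
    alt = str(rng.choice(_BASES[_BASES != ref]))
    return chrom, pos, ref, alt


def _make_variant(
    rng: np.random.Generator,
    cfg: SimConfig,
    sample: str,
    gene: str,
    effect: EffectClass,
    confident: bool,
) -> VariantRecord:
    chrom, pos, ref, alt_allele = _random_snv(rng)
    if effect in (EffectClass.FRAMESHIFT_INDEL, EffectClass.INFRAME_INDEL):
        ref, alt_allele = ref + "AC", ref  # simple deletion
    if confident:
        total, alt = _draw_confident_depths(rng, cfg)
    else:
        total = int(rng.integers(10, 30))  # fails the coverage filter
        alt = int(rng.integers(1, max(2, total // 3)))
    return VariantRecord(
        sample_id=sample,
        gene=gene,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt_allele,
        effect_class=effect,
        total_depth=total,
        alt_depth=alt,
    )


def _draw_covariates(rng: np.random.Generator) -> dict[str, object]:
    return {
        "age": float(np.clip(np.round(rng.normal(62.0, 10.0)), 28, 90)),
        "gender": str(rng.choice(["male", "female"], p=[0.65, 0.35])),
        "lauren": str(
            rng.choice(["intestinal", "diffuse", "mixed"], p=[0.50, 0.35, 0.15])
        ),
        "stage": str(rng.choice(["II", "III"], p=[0.45, 0.55])),
    }


def simulate_cohort(
    config: SimConfig,
    reference_signatures: pd.DataFrame | None = None,
) -> SimulatedCohort:
    """Draw one cohort: variants, clinical records, and the planted truth.

    Reproducible bit-for-bit given ``config.seed``; variant, survival,
    covariate and spectrum draws use deterministic sub-streams so partial
    re-runs stay aligned. If ``config.signature_mixture`` and
    ``mutations_per_sample`` are set (and a reference matrix is supplied),
    per-sample trinucleotide spectra are drawn from the mixture as well.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_var, rng_surv, rng_cov, rng_spec = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    genes = list(config.candidate_genes)
    probs = config.gene_probs()
    planted = set(config.planted_panel)
    samples = [f"S{i + 1:04d}" for i in range(config.n_patients)]

    variants: list[VariantRecord] = []
    status: dict[str, bool] = {}
    mutated = rng_var.random((config.n_patients, len(genes))) < probs
    for i, sample in enumerate(samples):
        hit_genes = [g for g, m in zip(genes, mutated[i]) if m]
        status[sample] = any(g in planted for g in hit_genes)
        for g in hit_genes:
            effect = _DRIVER_CLASSES[rng_var.choice(4, p=_DRIVER_CLASS_P)]
            variants.append(
                _make_variant(rng_var, config, sample, g, effect, confident=True)
            )
        n_noise = int(rng_var.poisson(config.noise_variants_mean))
        for _ in range(n_noise):
            g = str(rng_var.choice(genes))
            kind = rng_var.choice(
                ["synonymous", "noncoding", "splice", "lowconf"],
                p=[0.4, 0.3, 0.1, 0.2],
            )
            if kind == "lowconf":
                effect = _DRIVER_CLASSES[rng_var.choice(4, p=_DRIVER_CLASS_P)]
                variants.append(
                    _make_variant(rng_var, config, sample, g, effect, confident=False)
                )
            else:
                variants.append(
                    _make_variant(
                        rng_var, config, sample, g, EffectClass(kind), confident=True
                    )
                )

    clinical: list[SurvivalRecord] = []
    for sample in samples:
        hazard = config.baseline_hazard * (
            config.planted_hazard_ratio if status[sample] else 1.0
        )
        t_event = rng_surv.exponential(1.0 / hazard)
        t_censor = rng_surv.uniform(0.0, config.censoring_horizon)
        clinical.append(
            SurvivalRecord(
                sample_id=sample,
                time=float(min(t_event, t_censor)),
                event=int(t_event <= t_censor),
                covariates=_draw_covariates(rng_cov),
            )
        )

    spectra = None
    mixture = None
    if config.signature_mixture is not None and config.mutations_per_sample:
        if reference_signatures is None:
            reference_signatures = synthetic_reference_signatures()
        mixture = np.asarray(config.signature_mixture, dtype=float)
        spectra = {}
        for sample in samples:
            n_mut = int(rng_spec.poisson(config.mutations_per_sample))
            spectra[sample] = simulate_spectrum(
                mixture, n_mut, rng_spec, reference=reference_signatures
            )

    return SimulatedCohort(
        variants=variants,
        clinical=clinical,
        truth=CohortTruth(
            planted_panel=tuple(config.planted_panel),
            panel_status=status,
            signature_mixture=mixture,
        ),
        spectra=spectra,
        config=config,
    )


def simulate_spectrum(
    mixture: Sequence[float],
    n_mutations: int,
    seed: int | np.random.Generator,
    reference: pd.DataFrame | None = None,
) -> TrinucleotideSpectrum:
    """Multinomial 96-channel spectrum from a known signature mixture.

    Channel probabilities are ``reference @ mixture``; ``n_mutations = 0``
    yields the all-zero spectrum.
    """
    if reference is None:
        reference = synthetic_reference_signatures()
    w = np.asarray(mixture, dtype=float)
    if w.shape != (reference.shape[1],):
        raise ValueError(
            f"mixture length {w.shape} does not match "
            f"{reference.shape[1]} reference signatures"
        )
    if (w < 0).any() or not np.isclose(w.sum(), 1.0):
        raise ValueError("mixture weights must be nonnegative and sum to 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    probs = reference.to_numpy() @ w
    probs = probs / probs.sum()
    counts = rng.multinomial(int(n_mutations), probs)
    return TrinucleotideSpectrum(counts=counts)


def synthetic_reference_signatures(
    n_signatures: int = 30, seed: int = 7, concentration: float = 0.1
) -> pd.DataFrame:
    """Synthetic stand-in for a 96 x K reference signature matrix.

    Columns are sparse Dirichlet-distributed probability profiles labelled
    "1".."K" in the 96-channel pyrimidine-centered ordering — structurally a
    COSMIC-v2-style matrix, but the profiles are random (and deterministic
    for a given seed), not the published catalogue. Sufficient for all
    recovery-based tests; real analyses should load the published TSV via
    :func:`survpanel.io.read_signature_matrix`.
    """
    rng = np.random.default_rng(seed)
    cols = rng.dirichlet(np.full(96, concentration), size=n_signatures).T
    return pd.DataFrame(
        cols,
        index=list(TRINUCLEOTIDE_CHANNELS),
        columns=[str(i + 1) for i in range(n_signatures)],
    )
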