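"""Per-sample immunogenomic scores: TMB, neoantigen burden, signature dMMR.

Three companion scores for a mutation cohort:

* **TMB** — tumor mutational burden: somatic variants in the coding and
  splicing regions divided by the assayed coding footprint (33 Mb default,
  the RefSeq GRCh37 coding-exome estimate).
* **Neoantigen burden** — nonsynonymous mutations are represented as 17-mer
  peptide contexts with the altered residue (ideally) centered; all 9-11-mer
  sliding windows covering the altered residue are candidate epitopes, and
  the burden is the number of windows predicted to bind any patient HLA
  class I allele below 500 nM (strict). The affinity predictor is an
  injectable interface — only deterministic toy predictors ship here, the
  production predictor being an external tool.
* **dMMR fraction** — mutational-signature decomposition of the sample's
  96-channel trinucleotide spectrum against a reference catalogue
  (nonnegative least squares, weights < 0.06 pruned, one refit); deficient
  mismatch repair is the summed exposure of signatures 6, 15, 20 and 26.
  Samples qualify only with reconstruction error < 0.15 and > 30 mutations.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .variants import TMB_QUALIFYING, EffectClass, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TRINUCLEOTIDE_CHANNELS",
    "TMBResult",
    "MutantPeptideContext",
    "PeptideWindow",
    "TrinucleotideSpectrum",
    "SignatureExposure",
    "AffinityPredictor",
    "MotifAffinityPredictor",
    "HashAffinityPredictor",
    "DMMR_SIGNATURES",
    "compute_tmb",
    "enumerate_neoantigen_candidates",
    "annotate_affinities",
    "count_neoantigens",
    "decompose_signatures",
    "dmmr_fraction",
]

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_CTX = "ACGT"

#: The 96 single-base-substitution channels in pyrimidine-centered COSMIC
#: order: six substitution types x 16 flanking-base contexts.
TRINUCLEOTIDE_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in _SUBSTITUTIONS
    for five in _CTX
    for three in _CTX
)

DMMR_SIGNATURES = ("6", "15", "20", "26")

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class TMBResult:
    sample_id: str
    counted_variants: int
    region_size_mb: float = 33.0

    @property
    def tmb(self) -> float:
        """Mutations per megabase."""
        return self.counted_variants / self.region_size_mb


def compute_tmb(
    variants: Sequence[VariantRecord],
    region_size_mb: float = 33.0,
    sample_id: str | None = None,
) -> TMBResult:
    """TMB for one sample: coding + splicing variants per megabase.

    ``variants`` must already be confidence-filtered and belong to a single
    sample. Counted classes: missense, nonsense, frameshift/inframe indel,
    synonymous, splice. Noncoding variants are excluded.
    """
    if region_size_mb <= 0:
        raise ValueError("region_size_mb must be > 0")
    sids = {v.sample_id for v in variants}
    if len(sids) > 1:
        raise ValueError(f"variants span multiple samples: {sorted(sids)}")
    if sample_id is None:
        sample_id = next(iter(sids)) if sids else ""
    counted = sum(1 for v in variants if v.effect_class in TMB_QUALIFYING)
    return TMBResult(sample_id=sample_id, counted_variants=counted,
                     region_size_mb=region_size_mb)


@dataclass(frozen=True)
class MutantPeptideContext:
    """Mutant protein context for one nonsynonymous mutation.

    ``peptide`` is the 17-mer with the altered residue at (0-based)
    ``mutated_index``; contexts truncated at protein termini are shorter.
    """

    peptide: str
    mutated_index: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.mutated_index < len(self.peptide):
            raise ValueError(
                f"mutated_index {self.mutated_index} outside peptide of "
                f"length {len(self.peptide)}"
            )


@dataclass
class PeptideWindow:
    """One candidate epitope: a 9-11-mer covering the altered residue."""

    source: str
    window: str
    mutated_offset: int  # 0-based position of the altered residue in window
    affinities: dict[str, float] = field(default_factory=dict)
    sample_id: str = ""

    def min_affinity(self) -> float:
        if not self.affinities:
            raise ValueError(f"window {self.window} has no affinity annotations")
        return min(self.affinities.values())


class AffinityPredictor(Protocol):
    """Peptide + HLA allele -> predicted binding affinity in nM."""

    def predict(self, peptide: str, allele: str) -> float: ...


class MotifAffinityPredictor:
    """Deterministic toy predictor: binds iff the window contains a motif residue.

    Windows containing any residue in ``motif`` get ``bind_nm`` (default
    100 nM), everything else ``nonbind_nm`` (default 10000 nM), for every
    allele. Useful for fixtures whose expected counts can be enumerated by
    hand.
    """

    def __init__(self, motif: str = "W", bind_nm: float = 100.0,
                 nonbind_nm: float = 10000.0):
        self.motif = set(motif)
        self.bind_nm = bind_nm
        self.nonbind_nm = nonbind_nm

    def predict(self, peptide: str, allele: str) -> float:
        return self.bind_nm if self.motif & set(peptide) else self.nonbind_nm


class HashAffinityPredictor:
    """Deterministic pseudo-random predictor (log-uniform on [1, 50000] nM).

    Affinity depends only on (peptide, allele) through a hash, so results are
    stable across runs and platforms without modelling real binding.
    """

    def __init__(self, lo: float = 1.0, hi: float = 50000.0):
        self.lo, self.hi = lo, hi

    def predict(self, peptide: str, allele: str) -> float:
        h = hashlib.sha256(f"{peptide}|{allele}".encode()).digest()
        u = int.from_bytes(h[:8], "big") / 2**64
        return float(self.lo * (self.hi / self.lo) ** u)


def enumerate_neoantigen_candidates(
    contexts: Iterable[MutantPeptideContext],
    window_sizes: Sequence[int] = (9, 10, 11),
) -> list[PeptideWindow]:
    """All 9-11-mer substrings of each mutant context that cover the mutation.

    Windows not containing the altered residue are wild-type peptides and are
    excluded. Stop-gain contexts (containing ``*``) are skipped with a logged
    reason; any other non-amino-acid letter raises.
    """
    windows: list[PeptideWindow] = []
    for ctx in contexts:
        if "*" in ctx.peptide:
            logger.info(
                "skipping stop-gain context %r (sample %s): truncated protein",
                ctx.peptide, ctx.sample_id or "<unknown>",
            )
            continue
        bad = set(ctx.peptide) - _AA
        if bad:
            raise ValueError(
                f"unknown amino-acid letter(s) {sorted(bad)} in context "
                f"{ctx.peptide!r}"
            )
        n = len(ctx.peptide)
        for size in sorted(window_sizes):
            for start in range(0, n - size + 1):
                if start <= ctx.mutated_index < start + size:
                    windows.append(
                        PeptideWindow(
                            source=ctx.peptide,
                            window=ctx.peptide[start : start + size],
                            mutated_offset=ctx.mutated_index - start,
                            sample_id=ctx.sample_id,
                        )
                    )
    return windows


def annotate_affinities(
    windows: Iterable[PeptideWindow],
    predictor: AffinityPredictor,
    alleles: Sequence[str],
) -> list[PeptideWindow]:
    """Fill per-allele predicted affinities in place; returns the list."""
    if len(alleles) == 0:
        raise ValueError("at least one HLA allele is required")
    out = list(windows)
    for w in out:
        for allele in alleles:
            w.affinities[allele] = float(predictor.predict(w.window, allele))
    return out


def count_neoantigens(
    windows: Sequence[PeptideWindow], threshold_nm: float = 500.0
) -> int:
    """Neoantigen burden: windows binding any allele strictly below threshold.

    499.9 nM counts; 500.0 nM does not.
    """
    if threshold_nm <= 0:
        raise ValueError("threshold_nm must be > 0")
    return sum(1 for w in windows if w.min_affinity() < threshold_nm)


@dataclass
class TrinucleotideSpectrum:
    """96-channel single-base-substitution count vector (COSMIC order)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError(f"spectrum must have 96 channels, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(TRINUCLEOTIDE_CHANNELS))


@dataclass
class SignatureExposure:
    """Per-sample signature weights plus reconstruction diagnostics.

    ``qc_pass`` is True iff error_rate < 0.15 and n_mutations > 30 (both
    strict).
    """

    weights: pd.Series
    error_rate: float
    n_mutations: int

    @property
    def qc_pass(self) -> bool:
        return self.error_rate < 0.15 and self.n_mutations > 30


def decompose_signatures(
    spectrum: TrinucleotideSpectrum,
    reference: pd.DataFrame,
    prune_threshold: float = 0.06,
) -> SignatureExposure:
    """Nonnegative least-squares signature decomposition with pruning.

    Fits nonnegative weights minimizing the Euclidean distance between the
    count-normalized spectrum and ``reference @ weights``; weights below
    ``prune_threshold`` are zeroed and the surviving set refit once.
    ``error_rate`` is the residual norm divided by the spectrum norm.
    Weights are rescaled onto the simplex only if their sum exceeds 1.
    """
    A = reference.to_numpy(dtype=float)
    if A.shape[0] != 96:
        raise ValueError(f"reference must have 96 rows, got {A.shape[0]}")
    colsums = A.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-6):
        raise ValueError("reference signature columns must each sum to 1")
    if spectrum.total == 0:
        raise ValueError("cannot decompose an empty spectrum")

    b = spectrum.counts / spectrum.total
    w, _ = nnls(A, b)
    keep = w >= prune_threshold
    w_final = np.zeros_like(w)
    if keep.any():
        w_sub, _ = nnls(A[:, keep], b)
        w_final[keep] = w_sub
    s = w_final.sum()
    if s > 1.0:
        w_final = w_final / s
    resid = A @ w_final - b
    error_rate = float(np.linalg.norm(resid) / np.linalg.norm(b))
    return SignatureExposure(
        weights=pd.Series(w_final, index=list(reference.columns)),
        error_rate=error_rate,
        n_mutations=spectrum.total,
    )


def dmmr_fraction(exposure: SignatureExposure) -> float:
    """Deficient-mismatch-repair fraction: summed exposure of signatures
    6, 15, 20 and 26.

    Returns NaN (with a warning) when the exposure failed QC; raises if the
    reference lacked any of the four designated signature labels.
    """
    missing = [s for s in DMMR_SIGNATURES if s not in exposure.weights.index]
    if missing:
        raise ValueError(f"reference lacks dMMR signatures: {missing}")
    if not exposure.qc_pass:
        warnings.warn(
            "signature exposure failed QC (error_rate >= 0.15 or <= 30 "
            "mutations); dMMR fraction undefined"
        )
        return float("nan")
    return float(sum(exposure.weights[s] for s in DMMR_SIGNATURES))
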