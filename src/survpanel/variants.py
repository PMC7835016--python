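"""Somatic variant records, confidence filtering, and the binary mutation matrix.

The analysis consumes *called* somatic variants (MAF-like rows or VCF-derived
records); alignment and variant calling happen upstream. Three low-confidence
filters are applied before any downstream statistic: total coverage < 30,
variant allele depth < 7, variant allele frequency < 0.05 (removal conditions
are strict ``<``, so records exactly at 30 / 7 / 0.05 are retained).

The prognostic layer works on a binary patients x candidate-genes incidence
matrix: cell(s, g) = 1 iff sample ``s`` carries at least one filtered variant
in gene ``g`` whose effect is a nonsynonymous substitution or a coding indel.
Splice and synonymous variants count toward mutational burden (see
:mod:`survpanel.immuno`) but not toward this matrix, which is restricted to
coding-region nonsynonymous/indel events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EffectClass",
    "VariantRecord",
    "MutationMatrix",
    "filter_variants",
    "build_mutation_matrix",
    "classify_panel_status",
    "MAF_CLASSIFICATION_MAP",
    "MATRIX_QUALIFYING",
    "TMB_QUALIFYING",
]

MIN_TOTAL_DEPTH = 30
MIN_ALT_DEPTH = 7
MIN_VAF = 0.05


class EffectClass(str, Enum):
    """Functional effect of a somatic variant, as annotated upstream."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SPLICE = "splice"
    SYNONYMOUS = "synonymous"
    NONCODING = "noncoding"


#: Effect classes that set a 1 in the mutation matrix: nonsynonymous
#: substitutions and coding indels.
MATRIX_QUALIFYING = frozenset(
    {
        EffectClass.MISSENSE,
        EffectClass.NONSENSE,
        EffectClass.FRAMESHIFT_INDEL,
        EffectClass.INFRAME_INDEL,
    }
)

#: Effect classes counted for tumor mutational burden: all coding plus splice.
TMB_QUALIFYING = MATRIX_QUALIFYING | {EffectClass.SPLICE, EffectClass.SYNONYMOUS}

#: Mapping from common MAF ``Variant_Classification`` strings to the internal
#: effect vocabulary. Unknown strings raise at ingestion rather than being
#: silently dropped.
MAF_CLASSIFICATION_MAP: dict[str, EffectClass] = {
    "Missense_Mutation": EffectClass.MISSENSE,
    "Nonsense_Mutation": EffectClass.NONSENSE,
    "Nonstop_Mutation": EffectClass.MISSENSE,
    "Frame_Shift_Del": EffectClass.FRAMESHIFT_INDEL,
    "Frame_Shift_Ins": EffectClass.FRAMESHIFT_INDEL,
    "In_Frame_Del": EffectClass.INFRAME_INDEL,
    "In_Frame_Ins": EffectClass.INFRAME_INDEL,
    "Splice_Site": EffectClass.SPLICE,
    "Splice_Region": EffectClass.SPLICE,
    "Silent": EffectClass.SYNONYMOUS,
    "Translation_Start_Site": EffectClass.NONCODING,
    "3'UTR": EffectClass.NONCODING,
    "5'UTR": EffectClass.NONCODING,
    "3'Flank": EffectClass.NONCODING,
    "5'Flank": EffectClass.NONCODING,
    "Intron": EffectClass.NONCODING,
    "IGR": EffectClass.NONCODING,
    "RNA": EffectClass.NONCODING,
}


@dataclass(frozen=True)
class VariantRecord:
    """One somatic call with depths; the unit of filtering.

    Coordinates are 1-based closed (MAF/VCF convention). ``vaf`` is recomputed
    from depths when both are present; a stored VAF disagreeing by more than
    1e-6 triggers a consistency warning, and the depth-derived value wins.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    effect_class: EffectClass
    total_depth: int | None = None
    alt_depth: int | None = None
    vaf: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_class", EffectClass(self.effect_class))
        if self.total_depth is not None and self.alt_depth is not None:
            if self.alt_depth > self.total_depth:
                raise ValueError(
                    f"alt_depth {self.alt_depth} exceeds total_depth "
                    f"{self.total_depth} for {self._label()}"
                )
            derived = (
                self.alt_depth / self.total_depth if self.total_depth > 0 else 0.0
            )
            if self.vaf is not None and abs(self.vaf - derived) > 1e-6:
                warnings.warn(
                    f"stored VAF {self.vaf:.6g} disagrees with alt/total "
                    f"{derived:.6g} for {self._label()}; using depth-derived value",
                    stacklevel=3,
                )
            object.__setattr__(self, "vaf", derived)

    def _label(self) -> str:
        return f"{self.sample_id}:{self.gene}:{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass
class MutationMatrix:
    """Binary patients x genes incidence matrix (the GA's substrate)."""

    samples: list[str]
    genes: list[str]
    values: np.ndarray  # bool, shape (n_samples, n_genes)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.samples), len(self.genes)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.genes)} genes"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.astype(int), index=self.samples, columns=self.genes
        )

    def gene_indices(self, genes: Sequence[str]) -> np.ndarray:
        missing = [g for g in genes if g not in self._gene_pos]
        if missing:
            raise ValueError(f"genes absent from matrix: {', '.join(sorted(missing))}")
        return np.array([self._gene_pos[g] for g in genes], dtype=int)

    @property
    def _gene_pos(self) -> dict[str, int]:
        cache = getattr(self, "_gene_pos_cache", None)
        if cache is None:
            cache = {g: i for i, g in enumerate(self.genes)}
            self._gene_pos_cache = cache
        return cache


def filter_variants(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Apply the three low-confidence filters.

    Retains exactly the records with total_depth >= 30, alt_depth >= 7 and
    VAF >= 0.05. Order is preserved and the input is not modified. Records
    lacking depth fields raise (no silent pass-through).
    """
    kept: list[VariantRecord] = []
    for v in variants:
        if v.total_depth is None or v.alt_depth is None or v.vaf is None:
            raise ValueError(f"variant {v._label()} lacks depth/VAF fields")
        if (
            v.total_depth >= MIN_TOTAL_DEPTH
            and v.alt_depth >= MIN_ALT_DEPTH
            and v.vaf >= MIN_VAF
        ):
            kept.append(v)
    return kept


def build_mutation_matrix(
    variants: Iterable[VariantRecord],
    samples: Sequence[str],
    genes: Sequence[str],
) -> MutationMatrix:
    """Binarize filtered variants into a patients x genes incidence matrix.

    Only coding nonsynonymous substitutions and indels qualify; samples with
    no variants appear as all-zero rows. A variant referencing a sample
    outside ``samples`` raises, guarding against clinical/variant mismatches.
    """
    if len(genes) == 0:
        raise ValueError("gene list is empty")
    if len(samples) == 0:
        raise ValueError("sample list is empty")
    sample_pos = {s: i for i, s in enumerate(samples)}
    gene_pos = {g: i for i, g in enumerate(genes)}
    values = np.zeros((len(samples), len(genes)), dtype=bool)
    for v in variants:
        if v.sample_id not in sample_pos:
            raise ValueError(
                f"variant {v._label()} references sample {v.sample_id!r} "
                "absent from the sample list"
            )
        if v.effect_class not in MATRIX_QUALIFYING:
            continue
        j = gene_pos.get(v.gene)
        if j is not None:
            values[sample_pos[v.sample_id], j] = True
    return MutationMatrix(list(samples), list(genes), values)


def classify_panel_status(
    matrix: MutationMatrix, panel: Sequence[str]
) -> np.ndarray:
    """Per-sample panel status: True (mutant) iff >=1 panel gene is mutated.

    An empty panel labels every sample wild-type. Panel genes missing from
    the matrix raise, listing the offenders.
    """
    if len(panel) == 0:
        return np.zeros(len(matrix.samples), dtype=bool)
    idx = matrix.gene_indices(panel)
    return matrix.values[:, idx].any(axis=1)
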