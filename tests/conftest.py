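import numpy as np
import pytest

from survpanel import (
    SimConfig,
    build_mutation_matrix,
    filter_variants,
    simulate_cohort,
    synthetic_reference_signatures,
)

SIX_GENES = tuple(f"GENE{i:02d}" for i in range(1, 7))
PLANTED = ("GENE01", "GENE02")


def make_planted_cohort(seed, n_patients=300, hazard_ratio=0.25,
                        genes=SIX_GENES, mutation_prob=0.15):
    """Reduced-scale planted-effect scenario: 6 candidate genes, 2 planted,
    per-gene mutation probability 0.15 (the planted pair then mutates ~28% of
    patients, the mutant-fraction regime the panel analysis targets)."""
    cfg = SimConfig(
        n_patients=n_patients,
        candidate_genes=genes,
        per_gene_mutation_prob=mutation_prob,
        planted_panel=PLANTED,
        planted_hazard_ratio=hazard_ratio,
        seed=seed,
    )
    return simulate_cohort(cfg)


def cohort_matrix(cohort):
    genes = list(cohort.config.candidate_genes)
    filtered = filter_variants(cohort.variants)
    return build_mutation_matrix(filtered, cohort.samples, genes)


@pytest.fixture(scope="session")
def planted_cohort():
    return make_planted_cohort(seed=11)


@pytest.fixture(scope="session")
def planted_matrix(planted_cohort):
    return cohort_matrix(planted_cohort)


@pytest.fixture(scope="session")
def reference_signatures():
    return synthetic_reference_signatures()


@pytest.fixture(scope="session")
def truth_status(planted_cohort):
    return np.array(
        [planted_cohort.truth.panel_status[s] for s in planted_cohort.samples]
    )
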