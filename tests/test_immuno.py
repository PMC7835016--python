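"""TMB, neoantigen-candidate enumeration and signature decomposition."""

import numpy as np
import pandas as pd
import pytest

from survpanel import (
    EffectClass,
    MotifAffinityPredictor,
    MutantPeptideContext,
    SignatureExposure,
    TrinucleotideSpectrum,
    annotate_affinities,
    compute_tmb,
    count_neoantigens,
    decompose_signatures,
    dmmr_fraction,
    enumerate_neoantigen_candidates,
    simulate_spectrum,
)
from test_variants import mkvar


def exhaustive_window_oracle(peptide, mut_idx, sizes=(9, 10, 11)):
    """Brute-force substring enumeration: every substring of the allowed
    sizes that contains the mutated position."""
    out = []
    for size in sizes:
        for start in range(len(peptide) - size + 1):
            sub = peptide[start : start + size]
            if start <= mut_idx < start + size:
                out.append(sub)
    return out


class TestTMB:
    def test_sixty_six_variants_over_33_mb(self):
        variants = [mkvar(pos=i) for i in range(66)]
        assert compute_tmb(variants).tmb == pytest.approx(2.0)

    def test_empty_is_zero(self):
        assert compute_tmb([], sample_id="S1").tmb == 0.0

    def test_qualifying_class_count(self):
        variants = (
            [mkvar(pos=i, effect=EffectClass.NONCODING) for i in range(2)]
            + [mkvar(pos=10 + i, effect=EffectClass.MISSENSE) for i in range(3)]
            + [mkvar(pos=20, effect=EffectClass.SPLICE)]
        )
        assert compute_tmb(variants).counted_variants == 4

    def test_synonymous_counts_toward_burden(self):
        assert compute_tmb([mkvar(effect=EffectClass.SYNONYMOUS)]).counted_variants == 1

    def test_additive_and_inverse_in_region_size(self):
        a = [mkvar(pos=i) for i in range(10)]
        b = [mkvar(pos=100 + i) for i in range(23)]
        assert compute_tmb(a + b).counted_variants == (
            compute_tmb(a).counted_variants + compute_tmb(b).counted_variants
        )
        assert compute_tmb(a, region_size_mb=11.0).tmb == pytest.approx(
            3 * compute_tmb(a, region_size_mb=33.0).tmb
        )

    def test_invalid_region_or_mixed_samples(self):
        with pytest.raises(ValueError, match="region_size_mb"):
            compute_tmb([mkvar()], region_size_mb=0)
        with pytest.raises(ValueError, match="multiple samples"):
            compute_tmb([mkvar(sample="A"), mkvar(sample="B")])


FULL_17MER = "ACDEFGHIKLMNPQRST"  # mutation centered at index 8


class TestNeoantigenEnumeration:
    def test_centered_mutation_in_full_17mer_gives_24_windows(self):
        windows = enumerate_neoantigen_candidates(
            [MutantPeptideContext(FULL_17MER, 8)]
        )
        assert len(windows) == 24
        by_size = {9: 0, 10: 0, 11: 0}
        for w in windows:
            by_size[len(w.window)] += 1
        assert by_size == {9: 9, 10: 8, 11: 7}
        assert sorted(w.window for w in windows) == sorted(
            exhaustive_window_oracle(FULL_17MER, 8)
        )

    def test_truncated_context_matches_oracle(self):
        # mutation near the protein start: 11-mer context, altered residue
        # at position 2
        ctx = "MKLVSTAYWDE"
        windows = enumerate_neoantigen_candidates([MutantPeptideContext(ctx, 2)])
        assert sorted(w.window for w in windows) == sorted(
            exhaustive_window_oracle(ctx, 2)
        )

    def test_single_window_when_context_equals_size(self):
        windows = enumerate_neoantigen_candidates(
            [MutantPeptideContext("ACDEFGHIK", 4)], window_sizes=(9,)
        )
        assert len(windows) == 1
        assert windows[0].window == "ACDEFGHIK"

    def test_every_window_is_substring_and_covers_mutation(self):
        rng = np.random.default_rng(6)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(25):
            length = int(rng.integers(9, 18))
            pep = "".join(rng.choice(aa, size=length))
            mut = int(rng.integers(0, length))
            windows = enumerate_neoantigen_candidates(
                [MutantPeptideContext(pep, mut)]
            )
            assert sorted(w.window for w in windows) == sorted(
                exhaustive_window_oracle(pep, mut)
            )
            for w in windows:
                assert w.window in pep
                assert w.window[w.mutated_offset] == pep[mut]

    def test_unknown_letter_rejected_and_stop_gain_skipped(self, caplog):
        with pytest.raises(ValueError, match="unknown amino-acid"):
            enumerate_neoantigen_candidates([MutantPeptideContext("ACDEFGHIX", 4)])
        with caplog.at_level("INFO"):
            out = enumerate_neoantigen_candidates([MutantPeptideContext("ACDE*GHIK", 4)])
        assert out == []


class TestNeoantigenCounting:
    def test_strict_threshold(self):
        w1 = enumerate_neoantigen_candidates(
            [MutantPeptideContext("ACDEFGHIK", 4)], window_sizes=(9,)
        )[0]
        w1.affinities = {"HLA-A*02:01": 499.9}
        w2 = enumerate_neoantigen_candidates(
            [MutantPeptideContext("CDEFGHIKL", 4)], window_sizes=(9,)
        )[0]
        w2.affinities = {"HLA-A*02:01": 500.0}
        assert count_neoantigens([w1, w2]) == 1

    def test_empty_list_and_bad_threshold(self):
        assert count_neoantigens([]) == 0
        with pytest.raises(ValueError):
            count_neoantigens([], threshold_nm=0)

    def test_motif_predictor_count_matches_hand_enumeration(self):
        # W at index 12 of a full 17-mer with mutation at index 8: binding
        # windows are exactly those covering both positions 8 and 12
        pep = "ACDEFGHIKLMNWQRST"
        windows = enumerate_neoantigen_candidates([MutantPeptideContext(pep, 8)])
        annotate_affinities(windows, MotifAffinityPredictor("W"), ["HLA-A*02:01"])
        expected = sum(
            1 for w in exhaustive_window_oracle(pep, 8) if "W" in w
        )
        assert count_neoantigens(windows) == expected
        assert 0 < expected < len(windows)

    def test_min_over_alleles(self):
        w = enumerate_neoantigen_candidates(
            [MutantPeptideContext("ACDEFGHIK", 0)], window_sizes=(9,)
        )[0]
        w.affinities = {"A": 12000.0, "B": 120.0}
        assert count_neoantigens([w]) == 1


class TestSignatureDecomposition:
    def test_pure_signature_identified_exactly(self, reference_signatures):
        counts = np.round(reference_signatures["6"].to_numpy() * 100000).astype(int)
        exposure = decompose_signatures(
            TrinucleotideSpectrum(counts), reference_signatures
        )
        assert exposure.weights["6"] == pytest.approx(1.0, abs=0.01)
        assert exposure.weights.drop("6").abs().max() < 0.01
        assert exposure.error_rate < 0.01
        assert exposure.qc_pass

    def test_two_signature_mixture_recovered(self, reference_signatures):
        mixture = np.zeros(30)
        mixture[5], mixture[0] = 0.6, 0.4
        spec = simulate_spectrum(mixture, 5000, seed=2,
                                 reference=reference_signatures)
        exposure = decompose_signatures(spec, reference_signatures)
        assert exposure.weights["6"] == pytest.approx(0.6, abs=0.05)
        assert exposure.weights["1"] == pytest.approx(0.4, abs=0.05)

    def test_weights_nonnegative_and_sum_bounded(self, reference_signatures):
        rng = np.random.default_rng(10)
        for seed in range(5):
            mixture = rng.dirichlet(np.ones(30) * 0.3)
            spec = simulate_spectrum(mixture, 2000, seed=seed,
                                     reference=reference_signatures)
            exposure = decompose_signatures(spec, reference_signatures)
            assert (exposure.weights >= 0).all()
            assert exposure.weights.sum() <= 1 + 1e-9

    def test_qc_thresholds_are_strict(self, reference_signatures):
        profile = reference_signatures["6"].to_numpy()
        exact30 = np.zeros(96, dtype=int)
        top = np.argsort(profile)[-30:]
        exact30[top] = 1
        exp30 = decompose_signatures(TrinucleotideSpectrum(exact30),
                                     reference_signatures)
        assert exp30.n_mutations == 30
        assert not exp30.qc_pass  # "greater than 30" is strict
        assert not SignatureExposure(
            weights=pd.Series(dtype=float), error_rate=0.15, n_mutations=100
        ).qc_pass  # "less than 0.15" is strict
        assert SignatureExposure(
            weights=pd.Series(dtype=float), error_rate=0.149, n_mutations=31
        ).qc_pass

    def test_dimension_and_empty_spectrum_errors(self, reference_signatures):
        with pytest.raises(ValueError, match="96"):
            decompose_signatures(
                TrinucleotideSpectrum(np.zeros(96, int)),
                reference_signatures.iloc[:50],
            )
        with pytest.raises(ValueError, match="empty"):
            decompose_signatures(
                TrinucleotideSpectrum(np.zeros(96, int)), reference_signatures
            )


class TestDmmrFraction:
    def test_sum_of_designated_signatures(self):
        weights = pd.Series(0.0, index=[str(i) for i in range(1, 31)])
        weights["6"], weights["15"], weights["20"], weights["26"] = 0.10, 0.20, 0.0, 0.05
        weights["1"] = 0.65
        exposure = SignatureExposure(weights=weights, error_rate=0.01,
                                     n_mutations=500)
        assert dmmr_fraction(exposure) == pytest.approx(0.35)

    def test_pure_non_mmr_signature_gives_zero(self, reference_signatures):
        counts = np.round(reference_signatures["1"].to_numpy() * 50000).astype(int)
        exposure = decompose_signatures(TrinucleotideSpectrum(counts),
                                        reference_signatures)
        assert dmmr_fraction(exposure) == pytest.approx(0.0, abs=0.01)

    def test_planted_dmmr_mass_recovered(self, reference_signatures):
        mixture = np.zeros(30)
        mixture[5], mixture[14] = 0.3, 0.2   # signatures "6" and "15"
        mixture[0] = 0.5
        spec = simulate_spectrum(mixture, 5000, seed=4,
                                 reference=reference_signatures)
        exposure = decompose_signatures(spec, reference_signatures)
        assert dmmr_fraction(exposure) == pytest.approx(0.5, abs=0.07)

    def test_failed_qc_flagged_undefined(self, reference_signatures):
        exposure = SignatureExposure(
            weights=pd.Series(0.0, index=[str(i) for i in range(1, 31)]),
            error_rate=0.5,
            n_mutations=500,
        )
        with pytest.warns(UserWarning, match="QC"):
            assert np.isnan(dmmr_fraction(exposure))

    def test_missing_reference_labels_rejected(self):
        exposure = SignatureExposure(
            weights=pd.Series([1.0], index=["1"]), error_rate=0.0, n_mutations=100
        )
        with pytest.raises(ValueError, match="lacks"):
            dmmr_fraction(exposure)
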