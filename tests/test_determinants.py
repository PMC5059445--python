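import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rustseq as rs
from rustseq.codons import GENETIC_CODE, SENSE_CODONS
from rustseq.core import binarize, rust_metafootprint
from rustseq.determinants import (
    HUMAN_MFE_THRESHOLDS,
    PeptideWindowSpec,
    StructureWindowSpec,
    determinant_metafootprint,
    peptide_property_profile,
    peptide_property_value,
    structure_window_profile,
    synonymous_variance_test,
)

from conftest import FULL_CDS, profile, transcript_from_codons


@pytest.fixture(scope="module")
def binary_dataset():
    trs, totals = rs.synthetic_translatome(
        15, seed=31, coverage=rs.CoverageModel(1.5, 0.5), mean_codons=150
    )
    grid = rs.build_dwell_grid("tenfold", "positive")
    ds = rs.simulate_dataset(trs, totals, grid, 32)
    binaries = {t: binarize(p) for t, p in ds.profiles.items()}
    return trs, binaries


class TestDeterminantKinds:
    def test_amino_acid_ratios_aggregate_synonymous_codons(self, binary_dataset):
        trs, binaries = binary_dataset
        pos = (0,)
        codon_meta = rust_metafootprint(binaries, trs, "codon", pos)
        aa_meta = determinant_metafootprint(binaries, trs, "amino_acid", pos)
        for ai, aa in enumerate(aa_meta.determinants):
            syn = [i for i, c in enumerate(SENSE_CODONS) if GENETIC_CODE[c] == aa]
            n = codon_meta.n_obs[syn, 0]
            if n.sum() == 0:
                continue
            ro = np.nansum(codon_meta.ro[syn, 0] * n) / n.sum()
            re = np.nansum(codon_meta.re[syn, 0] * n) / n.sum()
            assert aa_meta.ro[ai, 0] == pytest.approx(ro)
            assert aa_meta.re[ai, 0] == pytest.approx(re)
            assert aa_meta.n_obs[ai, 0] == n.sum()

    def test_alphabet_sizes(self, binary_dataset):
        trs, binaries = binary_dataset
        for kind, size in [
            ("nucleotide", 4),
            ("amino_acid", 20),
            ("dipeptide", 400),
            ("tripeptide", 8000),
        ]:
            meta = determinant_metafootprint(binaries, trs, kind, (0, 1))
            assert len(meta.determinants) == size

    def test_no_signal_ratios_near_one(self):
        trs, totals = rs.synthetic_translatome(
            60, seed=41, coverage=rs.CoverageModel(1.0, 0.3)
        )
        ds = rs.simulate_dataset(trs, totals, rs.DwellTimeGrid(np.ones(61)), 42)
        binaries = {t: binarize(p) for t, p in ds.profiles.items()}
        meta = determinant_metafootprint(binaries, trs, "amino_acid", (0,))
        ratios = meta.ratio[:, 0]
        ok = np.isfinite(ratios)
        assert np.nanmedian(np.abs(np.log2(ratios[ok]))) < 0.1


class TestPeptideProperties:
    @pytest.mark.parametrize(
        "peptide, prop, expected",
        [
            ("KKRHDEGGGG", "positive_charges", 4),
            ("KKRHDEGGGG", "net_charge", 2),
            ("AVILMFYWGG", "hydrophobic_count", 8),
            ("GGGGGGGGGG", "positive_charges", 0),
            ("GGGGGGGGGG", "net_charge", 0),
            ("GGGGGGGGGG", "hydrophobic_count", 0),
        ],
    )
    def test_window_values(self, peptide, prop, expected):
        assert peptide_property_value(peptide, PeptideWindowSpec(10, prop)) == expected

    def test_profile_counts_windows_by_value(self):
        # CDS encodes M K K R H D E G G G G G ... -> known charge windows
        codons = ["ATG"] + ["AAA", "AAA", "CGT", "CAT", "GAT", "GAA"] + ["GGT"] * 13
        tr = transcript_from_codons("t", codons)
        counts = np.zeros(len(codons), dtype=int)
        counts[10] = 3  # single peak -> binary 1 at codon 10
        bp = binarize(profile("t", counts), FULL_CDS)
        meta = peptide_property_profile(
            {"t": bp}, {"t": tr}, PeptideWindowSpec(10, "net_charge"),
            start_positions=range(-10, 1), rule=FULL_CDS,
        )
        # windows starting at codons 0 (MKKRHDEGGG) and 1 (KKRHDEGGGG)
        # both carry net charge +2; only the first sits over the binary 1
        li = meta.position_index(-10)
        vi = meta.determinants.index("2")
        assert meta.n_obs[vi, li] == 2
        assert meta.ro[vi, li] == pytest.approx(0.5)


class TestStructureWindows:
    def test_window_count_arithmetic(self):
        spec = StructureWindowSpec()
        assert len(spec.window_starts(200)) == 13
        assert len(spec.window_starts(79)) == 0

    def test_percentile_threshold_matches_sorted_quantile(self):
        rng = np.random.default_rng(13)
        energies = pd.DataFrame(
            {
                "transcript_id": "t",
                "window_start_nt": np.arange(500) * 10,
                "mfe_kcal_mol": rng.normal(-25, 6, 500),
            }
        )
        # independent quantile: linear interpolation on the sorted sample
        srt = np.sort(energies["mfe_kcal_mol"].to_numpy())
        rank = 0.05 * (len(srt) - 1)
        lo, hi = int(np.floor(rank)), int(np.ceil(rank))
        expected = srt[lo] + (rank - lo) * (srt[hi] - srt[lo])
        assert np.percentile(energies["mfe_kcal_mol"], 5) == pytest.approx(expected)

    @pytest.fixture
    def structure_case(self):
        trs, totals = rs.synthetic_translatome(
            8, seed=51, coverage=rs.CoverageModel(1.5, 0.3), mean_codons=120
        )
        ds = rs.simulate_dataset(
            trs, totals, rs.build_dwell_grid("tenfold", "positive"), 52
        )
        binaries = {t: binarize(p) for t, p in ds.profiles.items()}
        spec = StructureWindowSpec()
        rng = np.random.default_rng(53)
        rows = []
        for tid, tr in trs.items():
            for s in spec.window_starts(len(tr.sequence)):
                rows.append((tid, int(s), float(rng.normal(-25, 6))))
        energies = pd.DataFrame(
            rows, columns=["transcript_id", "window_start_nt", "mfe_kcal_mol"]
        )
        return trs, binaries, energies, spec

    def test_rank_based_classification_shift_invariant(self, structure_case):
        trs, binaries, energies, spec = structure_case
        a = structure_window_profile(binaries, trs, energies, spec)
        shifted = energies.assign(mfe_kcal_mol=energies["mfe_kcal_mol"] + 7.5)
        b = structure_window_profile(binaries, trs, shifted, spec)
        np.testing.assert_array_equal(a.n_obs, b.n_obs)
        np.testing.assert_allclose(
            a.ratio[np.isfinite(a.ratio)], b.ratio[np.isfinite(b.ratio)]
        )

    def test_fixed_human_thresholds_mode(self, structure_case):
        trs, binaries, energies, spec = structure_case
        spec.fixed_thresholds = HUMAN_MFE_THRESHOLDS
        prof = structure_window_profile(binaries, trs, energies, spec)
        assert prof.thresholds == {1: -40.1, 5: -32.8, 10: -29.0}

    def test_missing_transcript_skipped(self, structure_case, caplog):
        trs, binaries, energies, spec = structure_case
        spec.fixed_thresholds = None
        some = energies[energies["transcript_id"] != "SYN00000"]
        prof = structure_window_profile(binaries, trs, some, spec)
        assert prof.n_obs.sum() > 0


class TestSynonymousVariance:
    def test_all_equal_ratios_give_zero_f(self):
        ratios = {c: 1.0 for c in SENSE_CODONS}
        f, p = synonymous_variance_test(ratios)
        assert f == 0.0 and p == 1.0

    def test_pure_between_group_variance_is_significant(self):
        ratios = {c: float(hash(GENETIC_CODE[c]) % 17) for c in SENSE_CODONS}
        f, p = synonymous_variance_test(ratios)
        assert p < 1e-12

    def test_two_group_hand_anova(self):
        # I codons get 1,2,3; P codons get 4,5,6,7 -> F = 21 / (7/5) = 15
        ratios = {"ATT": 1.0, "ATC": 2.0, "ATA": 3.0,
                  "CCT": 4.0, "CCC": 5.0, "CCA": 6.0, "CCG": 7.0}
        f, p = synonymous_variance_test(ratios)
        assert f == pytest.approx(15.0)
        assert p == pytest.approx(stats.f.sf(15.0, 1, 5))

    def test_degenerate_grouping_errors(self):
        with pytest.raises(ValueError):
            synonymous_variance_test({"ATG": 1.0, "TGG": 2.0})
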