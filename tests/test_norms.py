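import math

import numpy as np
import pytest

import rustseq as rs
from rustseq.codons import SENSE_CODONS
from rustseq.ingest import admissible_codon_indices
from rustseq.norms import (
    InsufficientDataError,
    cn_scores,
    lmn_scores,
    rrt_scores,
)

from conftest import FULL_CDS, profile, transcript_from_codons


class TestCN:
    def test_hand_example_single_transcript(self):
        tr = transcript_from_codons("t", ["AAA", "CCC", "GGG"])
        profs = {"t": profile("t", [2, 0, 4])}  # mean 2 -> normalized [1,0,2]
        scores = cn_scores(profs, {"t": tr}, 0, FULL_CDS)
        assert scores.score[SENSE_CODONS.index("GGG")] == pytest.approx(2.0)
        assert scores.score[SENSE_CODONS.index("AAA")] == pytest.approx(1.0)
        assert scores.score[SENSE_CODONS.index("CCC")] == pytest.approx(0.0)

    def test_uniform_profiles_score_one(self, toy_translatome):
        transcripts, _ = toy_translatome
        profs = {t: profile(t, [3] * 6) for t in transcripts}
        scores = cn_scores(profs, transcripts, 0, FULL_CDS)
        defined = ~np.isnan(scores.score)
        assert np.allclose(scores.score[defined], 1.0)

    def test_threshold_excludes_sparse_transcripts(self, toy_translatome):
        transcripts, _ = toy_translatome
        # 0.2 reads/nt on every transcript: below the CN>1 threshold
        profs = {t: profile(t, [1, 1, 0, 1, 0, 0]) for t in transcripts}
        with pytest.raises(InsufficientDataError):
            cn_scores(profs, transcripts, 1, FULL_CDS)


class TestLMN:
    def test_identical_normalized_densities_give_zero(self, toy_translatome):
        transcripts, _ = toy_translatome
        profs = {t: profile(t, [7] * 6) for t in transcripts}
        scores = lmn_scores(profs, transcripts, 0, FULL_CDS)
        defined = ~np.isnan(scores.score)
        assert np.allclose(scores.score[defined], 0.0)

    def test_log_terms_hand_value(self):
        # AAA appears twice with normalized densities 2 and 0.5:
        # its first-term mean is (log2 2 + log2 0.5)/2 = 0
        tr = transcript_from_codons("t", ["AAA", "AAA", "GGG", "CCC"])
        profs = {"t": profile("t", [8, 2, 4, 2])}  # mean 4 -> d = 2, .5, 1, .5
        scores = lmn_scores(profs, {"t": tr}, 0, FULL_CDS)
        aaa = scores.score[SENSE_CODONS.index("AAA")]
        ggg = scores.score[SENSE_CODONS.index("GGG")]
        ccc = scores.score[SENSE_CODONS.index("CCC")]
        # centring term: mean of (0, 0, -1) = -1/3
        assert aaa == pytest.approx(0 + 1 / 3)
        assert ggg == pytest.approx(0 + 1 / 3)
        assert ccc == pytest.approx(-1 + 1 / 3)

    def test_zero_count_coordinates_never_enter(self):
        tr = transcript_from_codons("t", ["AAA", "AAA", "GGG", "CCC"])
        profs = {"t": profile("t", [8, 0, 4, 4])}
        scores = lmn_scores(profs, {"t": tr}, 0, FULL_CDS)
        assert scores.n[SENSE_CODONS.index("AAA")] == 1


class TestRRT:
    def _window_case(self, counts, codons=None):
        codons = codons or [SENSE_CODONS[i] for i in range(19)]
        tr = transcript_from_codons("t", codons)
        return {"t": profile("t", counts)}, {"t": tr}

    def test_uniform_qualifying_window_fractions(self):
        profs, trs = self._window_case([2] * 19)
        scores = rrt_scores(profs, trs, FULL_CDS)
        focal = trs["t"].codons[9]
        assert scores.score[SENSE_CODONS.index(focal)] == pytest.approx(1 / 19)
        mat = scores.extras["position_matrix"]
        assert np.allclose(mat[~np.isnan(mat)], 1 / 19)

    def test_requires_strictly_more_than_19_reads(self):
        profs, trs = self._window_case([1] * 19)  # exactly 19 reads
        with pytest.raises(InsufficientDataError):
            rrt_scores(profs, trs, FULL_CDS)

    def test_rejects_three_empty_codons(self):
        counts = [3] * 19
        counts[2] = counts[7] = counts[12] = 0
        profs, trs = self._window_case(counts)
        with pytest.raises(InsufficientDataError):
            rrt_scores(profs, trs, FULL_CDS)

    def test_rejects_duplicated_focal_codon(self):
        codons = [SENSE_CODONS[i] for i in range(19)]
        codons[3] = codons[9]  # focal identity appears twice
        profs, trs = self._window_case([2] * 19, codons)
        with pytest.raises(InsufficientDataError):
            rrt_scores(profs, trs, FULL_CDS)


class TestScoreSets:
    def test_mean_normalized_has_unit_mean(self, toy_translatome):
        transcripts, profiles = toy_translatome
        scores = cn_scores(profiles, transcripts, 0, FULL_CDS)
        assert np.nanmean(scores.mean_normalized()) == pytest.approx(1.0)

    def test_lmn_linearizes_through_exp2(self):
        s = rs.CodonScoreSet("LMN", np.full(61, 1.0), np.ones(61), log_scale=True)
        assert np.allclose(s.linear(), 2.0)


def brute_force_cn(profiles, transcripts, min_density, rule):
    sums, ns = {}, {}
    for tid, prof in profiles.items():
        tr = transcripts[tid]
        adm = admissible_codon_indices(tr.n_codons, rule)
        region = [int(prof.counts[i]) for i in adm]
        mean = sum(region) / len(region)
        if mean <= 0 or mean / 3 <= min_density:
            continue
        codons = tr.codons
        for i in adm:
            c = codons[i]
            if c not in SENSE_CODONS:
                continue
            sums[c] = sums.get(c, 0.0) + prof.counts[i] / mean
            ns[c] = ns.get(c, 0) + 1
    return {c: sums[c] / ns[c] for c in sums}


def brute_force_lmn(profiles, transcripts, min_density, rule):
    sums, ns = {}, {}
    for tid, prof in profiles.items():
        tr = transcripts[tid]
        adm = admissible_codon_indices(tr.n_codons, rule)
        region = [int(prof.counts[i]) for i in adm]
        mean = sum(region) / len(region)
        if mean <= 0 or mean / 3 <= min_density:
            continue
        codons = tr.codons
        for i in adm:
            c = codons[i]
            if c not in SENSE_CODONS or prof.counts[i] == 0:
                continue
            sums[c] = sums.get(c, 0.0) + math.log2(prof.counts[i] / mean)
            ns[c] = ns.get(c, 0) + 1
    per = {c: sums[c] / ns[c] for c in sums}
    centre = sum(per.values()) / len(per)
    return {c: v - centre for c, v in per.items()}


def brute_force_rrt(profiles, transcripts, rule):
    sums, ns = {}, {}
    for tid, prof in profiles.items():
        tr = transcripts[tid]
        adm = admissible_codon_indices(tr.n_codons, rule)
        codons = tr.codons
        idx = list(adm)
        for w0 in range(len(idx) - 18):
            window = idx[w0 : w0 + 19]
            counts = [int(prof.counts[i]) for i in window]
            w_codons = [codons[i] for i in window]
            focal = w_codons[9]
            if (
                sum(counts) <= 19
                or sum(1 for x in counts if x == 0) >= 3
                or w_codons.count(focal) != 1
                or focal not in SENSE_CODONS
            ):
                continue
            total = sum(counts)
            for pos, (c, x) in enumerate(zip(w_codons, counts)):
                if c not in SENSE_CODONS:
                    continue
                key = (c, pos)
                sums[key] = sums.get(key, 0.0) + x / total
                ns[key] = ns.get(key, 0) + 1
    return {k: sums[k] / ns[k] for k in sums}


@pytest.fixture(scope="module")
def small_dataset():
    trs, totals = rs.synthetic_translatome(
        5, seed=77, coverage=rs.CoverageModel(2.0, 0.5), mean_codons=90,
        min_codons=80,
    )
    grid = rs.build_dwell_grid("tenfold", "positive")
    ds = rs.simulate_dataset(trs, totals, grid, 78)
    return trs, ds.profiles


class TestOracleEquivalence:
    """Each normalization equals an independent brute-force recount."""

    def test_cn(self, small_dataset):
        trs, profiles = small_dataset
        scores = cn_scores(profiles, trs, 0)
        expected = brute_force_cn(profiles, trs, 0, rs.AnalysisWindowRule())
        for c, v in expected.items():
            assert scores.score[SENSE_CODONS.index(c)] == pytest.approx(v)

    def test_lmn(self, small_dataset):
        trs, profiles = small_dataset
        scores = lmn_scores(profiles, trs, 0)
        expected = brute_force_lmn(profiles, trs, 0, rs.AnalysisWindowRule())
        for c, v in expected.items():
            assert scores.score[SENSE_CODONS.index(c)] == pytest.approx(v)

    def test_rrt(self, small_dataset):
        trs, profiles = small_dataset
        scores = rrt_scores(profiles, trs)
        expected = brute_force_rrt(profiles, trs, rs.AnalysisWindowRule())
        mat = scores.extras["position_matrix"]
        assert expected, "fixture must produce qualifying windows"
        for (c, pos), v in expected.items():
            assert mat[SENSE_CODONS.index(c), pos] == pytest.approx(v)
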