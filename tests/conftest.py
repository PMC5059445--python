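"""Shared fixtures and hand-built toy data."""

from __future__ import annotations

import numpy as np
import pytest

from rustseq.ingest import AnalysisWindowRule, CodonProfile, Transcript

#: trimming disabled — toy CDSs are analysed over their full length
FULL_CDS = AnalysisWindowRule(0, 0)


def transcript_from_codons(tid: str, codons: list[str], utr: int = 0) -> Transcript:
    """Build a transcript whose CDS is exactly the given codon list."""
    cds = "".join(codons)
    seq = "A" * utr + cds + "A" * utr
    return Transcript(tid, seq, utr, utr + len(cds), gene_id=tid)


def profile(tid: str, counts) -> CodonProfile:
    return CodonProfile(tid, np.asarray(counts, dtype=np.int64))


@pytest.fixture
def toy_translatome():
    """Three short transcripts with known codons and counts (no trimming)."""
    t1 = transcript_from_codons("t1", ["ATG", "AAA", "CCC", "AAA", "GGG", "TTT"])
    t2 = transcript_from_codons("t2", ["ATG", "AAA", "GGG", "CCC", "CCC", "TTT"])
    t3 = transcript_from_codons("t3", ["ATG", "TTT", "TTT", "GGG", "AAA", "CCC"])
    transcripts = {t.id: t for t in (t1, t2, t3)}
    profiles = {
        "t1": profile("t1", [0, 4, 1, 6, 0, 1]),
        "t2": profile("t2", [2, 2, 2, 2, 2, 2]),
        "t3": profile("t3", [0, 9, 0, 2, 1, 0]),
    }
    return transcripts, profiles
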