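"""The RUST transformation and metafootprint machinery.

A codon count profile is reduced to a Heaviside step function: each codon
scores 1 when its footprint count exceeds the transcript average, else 0.
The mean of this indicator over every occurrence of a sequence determinant
(codon, nucleotide, amino acid, di-/tripeptide) at a fixed position relative
to the A-site is the *observed* RUST value ``ro``; the matching *expected*
value ``re`` is the mean, over the same occurrences, of the transcript-level
mean of the indicator.  ``ro/re > 1`` marks enrichment (slow decoding),
``< 1`` depletion.  The Kullback-Leibler divergence of the normalized ``ro``
against ``re`` per relative position quantifies how strongly sequence
identity at that position shapes footprint density.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import (
    AA_INDEX,
    AMINO_ACIDS,
    SENSE_CODONS,
    encode_codons,
)
from .ingest import (
    AnalysisWindowRule,
    CodonProfile,
    Transcript,
    admissible_codon_indices,
    build_codon_profiles,
)

logger = logging.getLogger(__name__)

DEFAULT_POSITIONS = range(-40, 21)  # codon offsets, A-site at 0

DETERMINANT_KINDS = ("codon", "nucleotide", "amino_acid", "dipeptide", "tripeptide")


@dataclass
class BinaryProfile:
    """Heaviside-transformed codon profile of one transcript."""

    transcript_id: str
    values: np.ndarray  # 0/1 per codon of the CDS
    mean_count: float  # mean footprint count per codon, admissible region
    binary_mean: float  # mean of `values` over the admissible region
    total_count: int = 0

    @property
    def density(self) -> float:
        """Mean footprint density in reads per nucleotide (admissible region)."""
        return self.mean_count / 3.0


def binarize(
    profile: CodonProfile, rule: AnalysisWindowRule | None = None
) -> BinaryProfile:
    """Convert counts to the binary above-transcript-average indicator.

    The threshold is the mean count over the admissible (trimmed) region,
    with strict inequality, so uniform profiles binarize to all zeros.
    An all-zero profile yields an all-zero indicator.
    """
    rule = rule or AnalysisWindowRule()
    counts = profile.counts
    if counts.size == 0:
        raise ValueError("empty profile")
    adm = admissible_codon_indices(counts.size, rule)
    region = counts[adm.start : adm.stop] if len(adm) else counts
    mean = float(region.mean()) if region.size else 0.0
    values = (counts > mean).astype(np.int8)
    bmean = float(values[adm.start : adm.stop].mean()) if len(adm) else 0.0
    return BinaryProfile(
        profile.transcript_id,
        values,
        mean_count=mean,
        binary_mean=bmean,
        total_count=int(region.sum()),
    )


@dataclass
class MetafootprintProfile:
    """Observed/expected RUST values per determinant per relative position."""

    determinant_kind: str
    determinants: tuple[str, ...]
    positions: np.ndarray  # relative positions (codons, or nt for nucleotides)
    ro: np.ndarray  # [n_determinants, n_positions]
    re: np.ndarray
    n_obs: np.ndarray

    @property
    def ratio(self) -> np.ndarray:
        """ro/re; NaN where a cell is unobserved or its expectation is 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.ro / self.re
        r[(self.n_obs == 0) | (self.re <= 0)] = np.nan
        return r

    def position_index(self, position: int) -> int:
        idx = np.flatnonzero(self.positions == position)
        if idx.size != 1:
            raise KeyError(f"position {position} not in profile")
        return int(idx[0])

    def ratio_at(self, determinant: str, position: int) -> float:
        d = self.determinants.index(determinant)
        return float(self.ratio[d, self.position_index(position)])

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: determinant, position, ro, re, ratio, n_obs."""
        det = np.repeat(self.determinants, self.positions.size)
        pos = np.tile(self.positions, len(self.determinants))
        return pd.DataFrame(
            {
                "determinant": det,
                "position": pos,
                "ro": self.ro.ravel(),
                "re": self.re.ravel(),
                "ratio": self.ratio.ravel(),
                "n_obs": self.n_obs.ravel(),
            }
        )


@dataclass
class KLSeries:
    """Kullback-Leibler divergence (bits) per relative position."""

    positions: np.ndarray
    divergence: np.ndarray

    def at(self, position: int) -> float:
        idx = np.flatnonzero(self.positions == position)
        return float(self.divergence[int(idx[0])])


# ---------------------------------------------------------------------------
# determinant context arrays


def _dipeptide_names() -> tuple[str, ...]:
    return tuple(a + b for a, b in itertools.product(AMINO_ACIDS, AMINO_ACIDS))


def _tripeptide_names() -> tuple[str, ...]:
    return tuple(
        a + b + c for a, b, c in itertools.product(AMINO_ACIDS, AMINO_ACIDS, AMINO_ACIDS)
    )


def determinant_alphabet(kind: str) -> tuple[str, ...]:
    if kind == "codon":
        return SENSE_CODONS
    if kind == "nucleotide":
        return ("A", "C", "G", "T")
    if kind == "amino_acid":
        return AMINO_ACIDS
    if kind == "dipeptide":
        return _dipeptide_names()
    if kind == "tripeptide":
        return _tripeptide_names()
    raise ValueError(f"unknown determinant kind: {kind!r}")


def _aa_ids(transcript: Transcript) -> np.ndarray:
    return np.array(
        [AA_INDEX.get(a, -1) for a in transcript.peptide()], dtype=np.int64
    )


def determinant_context(transcript: Transcript, kind: str) -> tuple[np.ndarray, int]:
    """Per-position determinant ids for one transcript.

    Returns ``(ids, scale)`` where ``ids[j]`` is the determinant whose first
    element sits at position ``j`` (codon units, or nucleotide units for
    ``kind='nucleotide'`` with ``scale=3``); -1 marks stop codons, ambiguous
    bases and windows running off the CDS end.
    """
    if kind == "codon":
        return transcript.codon_ids(), 1
    if kind == "nucleotide":
        cds = transcript.sequence[transcript.cds_start : transcript.cds_end]
        lut = {"A": 0, "C": 1, "G": 2, "T": 3}
        return np.array([lut.get(b, -1) for b in cds], dtype=np.int64), 3
    aa = _aa_ids(transcript)
    if kind == "amino_acid":
        return aa, 1
    if kind == "dipeptide":
        ids = np.full(aa.size, -1, dtype=np.int64)
        ok = (aa[:-1] >= 0) & (aa[1:] >= 0)
        ids[:-1][ok] = aa[:-1][ok] * 20 + aa[1:][ok]
        return ids, 1
    if kind == "tripeptide":
        ids = np.full(aa.size, -1, dtype=np.int64)
        ok = (aa[:-2] >= 0) & (aa[1:-1] >= 0) & (aa[2:] >= 0)
        ids[:-2][ok] = aa[:-2][ok] * 400 + aa[1:-1][ok] * 20 + aa[2:][ok]
        return ids, 1
    raise ValueError(f"unknown determinant kind: {kind!r}")


# ---------------------------------------------------------------------------
# aggregation


def rust_metafootprint(
    binary_profiles: dict[str, BinaryProfile] | list[BinaryProfile],
    transcripts: dict[str, Transcript],
    determinant_kind: str = "codon",
    positions=DEFAULT_POSITIONS,
    rule: AnalysisWindowRule | None = None,
) -> MetafootprintProfile:
    """Aggregate observed/expected RUST values across all transcripts.

    For every admissible A-site position on every transcript with at least
    one footprint, the binary value at the A-site is attributed to the
    determinant found at each relative position; occurrences whose context
    runs outside the CDS (or hits a stop codon / ambiguous base) are
    skipped for that position only.  Cells never observed stay NaN.
    """
    rule = rule or AnalysisWindowRule()
    if isinstance(binary_profiles, dict):
        binary_profiles = list(binary_profiles.values())
    alphabet = determinant_alphabet(determinant_kind)
    positions = np.asarray(list(positions), dtype=np.int64)
    n_det, n_pos = len(alphabet), positions.size

    ro_sum = np.zeros((n_det, n_pos))
    re_sum = np.zeros((n_det, n_pos))
    n_obs = np.zeros((n_det, n_pos), dtype=np.int64)

    for bp in binary_profiles:
        if bp.total_count == 0:
            continue  # ro and re would be 0/0
        tr = transcripts[bp.transcript_id]
        adm = admissible_codon_indices(tr.n_codons, rule)
        if not len(adm):
            continue
        ids, scale = determinant_context(tr, determinant_kind)
        a_idx = np.arange(adm.start, adm.stop)
        b = bp.values[a_idx].astype(np.float64)
        tmean = bp.binary_mean
        anchor = a_idx * scale
        for li, l in enumerate(positions):
            j = anchor + l
            ok = (j >= 0) & (j < ids.size)
            if not ok.any():
                continue
            d = ids[j[ok]]
            keep = d >= 0
            if not keep.any():
                continue
            d = d[keep]
            np.add.at(ro_sum[:, li], d, b[ok][keep])
            np.add.at(n_obs[:, li], d, 1)
            re_sum[:, li] += np.bincount(d, minlength=n_det) * tmean

    with np.errstate(invalid="ignore"):
        ro = np.where(n_obs > 0, ro_sum / np.maximum(n_obs, 1), np.nan)
        re = np.where(n_obs > 0, re_sum / np.maximum(n_obs, 1), np.nan)
    return MetafootprintProfile(
        determinant_kind, alphabet, positions, ro, re, n_obs
    )


def kl_series(meta: MetafootprintProfile) -> KLSeries:
    """Per-position K-L divergence of normalized observed vs expected values.

    ``ro`` and ``re`` are each renormalized to probability vectors over the
    determinants defined at that position before computing
    ``D_l = sum_c p_c log2(p_c/q_c)``; observed zero cells contribute 0.
    Positions with fewer than two defined determinants are NaN.
    """
    div = np.full(meta.positions.size, np.nan)
    for li in range(meta.positions.size):
        defined = (meta.n_obs[:, li] > 0) & np.isfinite(meta.ro[:, li])
        if defined.sum() < 2:
            continue
        ro = meta.ro[defined, li]
        re = meta.re[defined, li]
        if ro.sum() <= 0 or re.sum() <= 0:
            continue
        p = ro / ro.sum()
        q = re / re.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / np.where(q > 0, q, 1.0)), 0.0)
        # a p>0 cell with q=0 cannot arise from pooled profiles, but guard
        terms[(p > 0) & (q <= 0)] = np.inf
        div[li] = float(terms.sum())
    return KLSeries(meta.positions.copy(), div)


def rust_codon_scores(
    profiles: dict[str, CodonProfile],
    transcripts: dict[str, Transcript],
    rule: AnalysisWindowRule | None = None,
):
    """A-site RUST ratios per sense codon as a dwell-time score set."""
    from .norms import CodonScoreSet

    rule = rule or AnalysisWindowRule()
    binaries = {tid: binarize(p, rule) for tid, p in profiles.items()}
    meta = rust_metafootprint(binaries, transcripts, "codon", (0,), rule)
    return CodonScoreSet(
        "RUST", meta.ratio[:, 0], meta.n_obs[:, 0].copy(), extras={"meta": meta}
    )


# ---------------------------------------------------------------------------
# A-site offset detection


def footprint_codon_span(read_length: int, offset: int) -> tuple[int, int]:
    """Codon offsets (relative to the A-site) covered by the footprint."""
    first = -((offset + 2) // 3)
    last = (read_length - 1 - offset) // 3
    return first, last


def detect_a_site_offset(
    alignments: pd.DataFrame,
    transcripts: dict[str, Transcript],
    candidate_offsets=(16, 17, 18),
    read_length: int | None = None,
    rule: AnalysisWindowRule | None = None,
    positions=DEFAULT_POSITIONS,
    require_unique: bool = True,
) -> int:
    """Choose the A-site offset maximizing adjacent-pair K-L divergence.

    For each candidate offset the codon metafootprint and its K-L series
    are computed; every adjacent codon pair (l, l+1) lying strictly inside
    the footprint (terminal codons excluded) is scored by D_l + D_{l+1}
    — the convention being that the winning pair is (P-site, A-site).  The
    offset with the largest interior pair score wins; an exact tie (as with
    signal-free data) returns the smallest candidate with a warning.
    """
    from .ingest import length_histogram, select_predominant_length

    candidates = sorted(set(int(o) for o in candidate_offsets))
    if len(candidates) < 2:
        raise ValueError("need at least two candidate offsets")
    if read_length is None:
        read_length = select_predominant_length(length_histogram(alignments))
    rule = rule or AnalysisWindowRule()

    scores: dict[int, float] = {}
    for off in candidates:
        profiles = build_codon_profiles(
            alignments, transcripts, off, read_length, require_unique=require_unique
        )
        binaries = {tid: binarize(p, rule) for tid, p in profiles.items()}
        meta = rust_metafootprint(binaries, transcripts, "codon", positions, rule)
        kl = kl_series(meta)
        first, last = footprint_codon_span(read_length, off)
        best = np.nan
        for li, l in enumerate(kl.positions[:-1]):
            if l < first + 1 or l + 1 > last - 1:
                continue
            pair = kl.divergence[li] + kl.divergence[li + 1]
            if np.isnan(best) or (not np.isnan(pair) and pair > best):
                best = pair
        scores[off] = best

    vals = np.array([scores[o] for o in candidates])
    if np.all(np.isnan(vals)) or (np.nanmax(vals) - np.nanmin(vals)) < 1e-12:
        warnings.warn(
            "no positional signal distinguishes candidate offsets; "
            "returning the smallest",
            stacklevel=2,
        )
        return candidates[0]
    return candidates[int(np.nanargmax(vals))]
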