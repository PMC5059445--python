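"""Competing codon-level normalizations: CN, LMN and RRT.

These are the baselines against which the RUST transformation is compared
when estimating relative codon dwell times:

* CN ("conventional normalization") divides each profile by its own mean
  density and averages the normalized densities per A-site codon, either
  over all covered transcripts (CN>0) or only those above 1 read/nt (CN>1).
* LMN ("logarithmic mean normalization") averages log2 of the normalized
  densities over coordinates with mapped reads, then centres the 61 codon
  values on their mean; scores live on a log2 scale.
* RRT ("ribosome residence time") scores 19-codon windows that pass strict
  coverage and uniqueness rules and averages the per-window read fraction
  for each codon identity at each window position; the focal (10th)
  position estimates the dwell time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import SENSE_CODONS
from .ingest import (
    AnalysisWindowRule,
    CodonProfile,
    Transcript,
    admissible_codon_indices,
)

logger = logging.getLogger(__name__)

#: RRT window length (codons) and 1-based focal position within the window
RRT_WINDOW = 19
RRT_FOCAL = 10


class InsufficientDataError(RuntimeError):
    """No transcript or window passes the method's inclusion threshold."""


@dataclass
class CodonScoreSet:
    """Per-codon scores from one normalization method.

    ``score`` follows :data:`rustseq.codons.SENSE_CODONS` order; NaN marks
    codons the method could not score.  ``log_scale`` is True for LMN,
    whose scores are log2 values centred on 0.
    """

    method: str
    score: np.ndarray
    n: np.ndarray
    log_scale: bool = False
    coverage_threshold: float = 0.0
    extras: dict = field(default_factory=dict)

    def linear(self) -> np.ndarray:
        """Scores on the linear (relative dwell time) scale."""
        return np.exp2(self.score) if self.log_scale else self.score.copy()

    def mean_normalized(self) -> np.ndarray:
        """Linear scores divided by their mean over defined codons."""
        lin = self.linear()
        return lin / np.nanmean(lin)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "codon": SENSE_CODONS,
                "score": self.score,
                "n": self.n,
                "method": self.method,
            }
        )


def _profile_arrays(
    profiles: dict[str, CodonProfile],
    transcripts: dict[str, Transcript],
    rule: AnalysisWindowRule,
):
    """Yield (codon ids, counts) restricted to the admissible region."""
    for tid, prof in profiles.items():
        tr = transcripts[tid]
        adm = admissible_codon_indices(tr.n_codons, rule)
        if not len(adm):
            continue
        ids = tr.codon_ids()[adm.start : adm.stop]
        counts = prof.counts[adm.start : adm.stop].astype(np.float64)
        yield ids, counts


def cn_scores(
    profiles: dict[str, CodonProfile],
    transcripts: dict[str, Transcript],
    min_density: float = 0.0,
    rule: AnalysisWindowRule | None = None,
) -> CodonScoreSet:
    """Conventional normalization (CN>0 with ``min_density=0``, CN>1 with 1).

    Each profile is divided by its own mean count over the admissible
    region; the score of a codon is the mean normalized density over all
    its A-site occurrences in transcripts passing the density threshold
    (strict, in reads per nucleotide).
    """
    rule = rule or AnalysisWindowRule()
    sums = np.zeros(len(SENSE_CODONS))
    ns = np.zeros(len(SENSE_CODONS), dtype=np.int64)
    for ids, counts in _profile_arrays(profiles, transcripts, rule):
        mean = counts.mean()
        if mean <= 0 or mean / 3.0 <= min_density:
            continue
        norm = counts / mean
        ok = ids >= 0
        np.add.at(sums, ids[ok], norm[ok])
        np.add.at(ns, ids[ok], 1)
    if ns.sum() == 0:
        raise InsufficientDataError(
            f"no transcript exceeds {min_density} reads/nt"
        )
    with np.errstate(invalid="ignore"):
        score = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    return CodonScoreSet("CN>%g" % min_density, score, ns, coverage_threshold=min_density)


def lmn_scores(
    profiles: dict[str, CodonProfile],
    transcripts: dict[str, Transcript],
    min_density: float = 1.0,
    rule: AnalysisWindowRule | None = None,
) -> CodonScoreSet:
    """Logarithmic mean normalization over coordinates with mapped reads.

    Only coding regions above ``min_density`` reads/nt enter; zero-count
    coordinates never do.  The per-codon mean of log2(normalized density)
    is centred by subtracting the mean of the 61 codon values (codons with
    no occurrence are excluded from that mean with a warning).
    """
    rule = rule or AnalysisWindowRule()
    sums = np.zeros(len(SENSE_CODONS))
    ns = np.zeros(len(SENSE_CODONS), dtype=np.int64)
    for ids, counts in _profile_arrays(profiles, transcripts, rule):
        mean = counts.mean()
        if mean <= 0 or mean / 3.0 <= min_density:
            continue
        ok = (ids >= 0) & (counts > 0)
        np.add.at(sums, ids[ok], np.log2(counts[ok] / mean))
        np.add.at(ns, ids[ok], 1)
    if ns.sum() == 0:
        raise InsufficientDataError(
            f"no transcript exceeds {min_density} reads/nt"
        )
    with np.errstate(invalid="ignore"):
        per_codon = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    if np.isnan(per_codon).any():
        logger.warning(
            "%d codons had no non-zero occurrence; excluded from the LMN mean",
            int(np.isnan(per_codon).sum()),
        )
    score = per_codon - np.nanmean(per_codon)
    return CodonScoreSet(
        "LMN", score, ns, log_scale=True, coverage_threshold=min_density
    )


def rrt_scores(
    profiles: dict[str, CodonProfile],
    transcripts: dict[str, Transcript],
    rule: AnalysisWindowRule | None = None,
) -> CodonScoreSet:
    """Ribosome residence time from qualifying 19-codon windows.

    Windows tile the admissible region with step 1 and qualify when they
    hold more than 19 reads, fewer than 3 empty codons, and the codon
    identity at the (1-based) 10th position occurs exactly once in the
    window.  Each qualifying window contributes its per-position read
    fractions; the returned score is the mean fraction of the focal
    position per codon, with the full 61 x 19 position matrix in
    ``extras['position_matrix']``.
    """
    rule = rule or AnalysisWindowRule()
    n_codons = len(SENSE_CODONS)
    frac_sum = np.zeros((n_codons, RRT_WINDOW))
    frac_n = np.zeros((n_codons, RRT_WINDOW), dtype=np.int64)

    for ids, counts in _profile_arrays(profiles, transcripts, rule):
        if ids.size < RRT_WINDOW:
            continue
        w_ids = np.lib.stride_tricks.sliding_window_view(ids, RRT_WINDOW)
        w_cnt = np.lib.stride_tricks.sliding_window_view(counts, RRT_WINDOW)
        totals = w_cnt.sum(axis=1)
        empties = (w_cnt == 0).sum(axis=1)
        focal = w_ids[:, RRT_FOCAL - 1]
        unique_focal = (w_ids == focal[:, None]).sum(axis=1) == 1
        ok = (totals > RRT_WINDOW) & (empties < 3) & unique_focal & (focal >= 0)
        if not ok.any():
            continue
        fracs = w_cnt[ok] / totals[ok, None]
        sel_ids = w_ids[ok]
        valid = sel_ids >= 0
        cols = np.broadcast_to(np.arange(RRT_WINDOW), sel_ids.shape)
        np.add.at(frac_sum, (sel_ids[valid], cols[valid]), fracs[valid])
        np.add.at(frac_n, (sel_ids[valid], cols[valid]), 1)

    if frac_n.sum() == 0:
        raise InsufficientDataError("no window satisfies the RRT requirements")
    with np.errstate(invalid="ignore"):
        matrix = np.where(frac_n > 0, frac_sum / np.maximum(frac_n, 1), np.nan)
    score = matrix[:, RRT_FOCAL - 1]
    n = frac_n[:, RRT_FOCAL - 1]
    return CodonScoreSet(
        "RRT", score, n, extras={"position_matrix": matrix, "n_matrix": frac_n}
    )
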