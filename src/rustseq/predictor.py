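"""Footprint-density prediction from codon RUST ratios.

Treating sites independently, the relative weight of a footprint at codon
``k`` is the product of the RUST ratios of the codons occupying each site
of the footprint; normalizing over the coding region turns the weights
into a discrete probability density that can be correlated with observed
profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import MetafootprintProfile
from .ingest import (
    AnalysisWindowRule,
    CodonProfile,
    Transcript,
    admissible_codon_indices,
)

logger = logging.getLogger(__name__)

#: codon sites spanning the footprint: -6..+5 relative to the A-site
#: (12 codons; the P-site/A-site boundary lies between offsets -1 and 0)
DEFAULT_SITES = tuple(range(-6, 6))

#: A-site-only prediction
A_SITE_ONLY = (0,)


def combine_site_ratios(ratios) -> float:
    """Multiplicative combination of per-site RUST ratios.

    E.g. P-site and A-site ratios 0.339 and 1.646 for an AAA-AAA di-codon
    combine to 0.557994.
    """
    return float(np.prod(np.asarray(ratios, dtype=float)))


@dataclass
class PredictedProfile:
    """Predicted footprint probability per admissible codon position."""

    transcript_id: str
    codon_indices: np.ndarray
    p: np.ndarray
    sites_used: tuple[int, ...]
    n_imputed: int = 0


def predict_density(
    transcript: Transcript,
    meta: MetafootprintProfile,
    sites: tuple[int, ...] = DEFAULT_SITES,
    rule: AnalysisWindowRule | None = None,
) -> PredictedProfile:
    """Predict the footprint probability density over the admissible region.

    The unnormalized weight at codon ``k`` is the product over sites ``i``
    of the RUST ratio of the codon at ``k + i`` at relative position ``i``;
    undefined ratios (unobserved codon/site cells, stop codons, context
    outside the CDS) impute to the neutral value 1 and are tallied.
    """
    rule = rule or AnalysisWindowRule()
    adm = admissible_codon_indices(transcript.n_codons, rule)
    if not len(adm):
        raise ValueError(f"{transcript.id}: CDS too short for the analysis window")
    ids = transcript.codon_ids()
    ratio = meta.ratio
    k = np.arange(adm.start, adm.stop)
    weights = np.ones(k.size)
    n_imputed = 0
    for site in sites:
        li = meta.position_index(site)
        j = k + site
        ok = (j >= 0) & (j < ids.size)
        cod = np.where(ok, ids[np.clip(j, 0, ids.size - 1)], -1)
        r = np.where(cod >= 0, ratio[np.clip(cod, 0, None), li], np.nan)
        bad = ~np.isfinite(r)
        n_imputed += int(bad.sum())
        weights *= np.where(bad, 1.0, r)
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"{transcript.id}: degenerate prediction (all-zero weights)")
    if n_imputed:
        logger.debug("%s: %d ratios imputed to 1", transcript.id, n_imputed)
    return PredictedProfile(transcript.id, k, weights / total, tuple(sites), n_imputed)


@dataclass
class PredictionScore:
    transcript_id: str
    pearson_r: float
    spearman_r: float
    n_codons: int


def evaluate_prediction(
    predicted: PredictedProfile,
    observed: CodonProfile,
    min_density: float = 1.0,
    rule: AnalysisWindowRule | None = None,
) -> PredictionScore | None:
    """Correlate predicted probabilities with observed counts.

    Transcripts whose admissible-region density does not exceed
    ``min_density`` reads/nt, or whose observed vector is constant, are
    excluded (returns None).
    """
    rule = rule or AnalysisWindowRule()
    obs = observed.counts[predicted.codon_indices]
    density = obs.mean() / 3.0
    if density <= min_density:
        return None
    if np.all(obs == obs[0]):
        return None
    r = stats.pearsonr(predicted.p, obs).statistic
    rho = stats.spearmanr(predicted.p, obs).statistic
    return PredictionScore(
        predicted.transcript_id, float(r), float(rho), int(obs.size)
    )


def prediction_summary(
    transcripts: dict[str, Transcript],
    profiles: dict[str, CodonProfile],
    meta: MetafootprintProfile,
    sites: tuple[int, ...] = DEFAULT_SITES,
    min_density: float = 1.0,
    rule: AnalysisWindowRule | None = None,
) -> pd.DataFrame:
    """Per-transcript prediction correlations across a dataset."""
    rows = []
    for tid, tr in transcripts.items():
        prof = profiles.get(tid)
        if prof is None:
            continue
        try:
            pred = predict_density(tr, meta, sites, rule)
        except ValueError:
            continue
        score = evaluate_prediction(pred, prof, min_density, rule)
        if score is not None:
            rows.append(
                (score.transcript_id, score.pearson_r, score.spearman_r, score.n_codons)
            )
    return pd.DataFrame(
        rows, columns=["transcript_id", "pearson_r", "spearman_r", "n_codons"]
    )
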