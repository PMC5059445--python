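"""Tripeptide synergy detection.

If residues acted independently, the RUST ratio of a tripeptide would be
the product of its three single-residue ratios at the corresponding
positions.  The standardized log2 difference between the observed
tripeptide ratio and that multiplicative expectation — standardized per
tripeptide against the background of scan positions — flags synergistic
stalling (or anti-stalling) motifs at |S| > 4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MetafootprintProfile

#: default first-residue scan range: 3-residue windows over -40..+19,
#: 58 start positions
DEFAULT_SCAN = range(-40, 18)

FLAG_THRESHOLD = 4.0


def expected_tripeptide_ratio(
    aa_meta: MetafootprintProfile, i: str, j: str, k: str, position: int
) -> float:
    """Multiplicative expectation from single-residue RUST ratios.

    Product of the ratios of residues ``i``, ``j``, ``k`` at positions
    ``position``, ``position+1``, ``position+2``; NaN when any factor is
    undefined.
    """
    r = aa_meta.ratio
    out = 1.0
    for offset, aa in enumerate((i, j, k)):
        d = aa_meta.determinants.index(aa)
        out *= r[d, aa_meta.position_index(position + offset)]
    return float(out)


@dataclass
class SynergyTable:
    """Standard scores of observed vs expected tripeptide ratios."""

    table: pd.DataFrame  # tripeptide, position, observed, expected, S, flagged
    background_range: tuple[int, int]

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table.loc[self.table["flagged"]]

    @property
    def n_combinations(self) -> int:
        return len(self.table)


def synergy_scores(
    tripeptide_meta: MetafootprintProfile,
    aa_meta: MetafootprintProfile,
    scan_positions=DEFAULT_SCAN,
    min_background: int = 3,
    flag_threshold: float = FLAG_THRESHOLD,
) -> SynergyTable:
    """Standard score per tripeptide per first-residue position.

    For each tripeptide the per-position difference
    ``log2(observed ratio) - log2(expected ratio)`` is standardized
    against the mean and standard deviation of its own differences over
    the scan (background) range.  Tripeptides with fewer than
    ``min_background`` defined positions are excluded.  Both
    metafootprints must come from the same binary profiles.
    """
    if tripeptide_meta.determinant_kind != "tripeptide":
        raise ValueError("first argument must be a tripeptide metafootprint")
    if aa_meta.determinant_kind != "amino_acid":
        raise ValueError("second argument must be an amino-acid metafootprint")

    positions = np.asarray(list(scan_positions), dtype=np.int64)
    n_pos = positions.size
    aa_ratio = aa_meta.ratio
    tri_ratio = tripeptide_meta.ratio

    aa_names = aa_meta.determinants
    n_aa = len(aa_names)
    # single-residue log2 ratios aligned on the tripeptide's three positions
    aa_pos_idx = {p: aa_meta.position_index(p) for p in
                  range(int(positions.min()), int(positions.max()) + 3)}
    with np.errstate(divide="ignore", invalid="ignore"):
        log_aa = np.log2(aa_ratio)

    tri_pos_idx = np.array(
        [tripeptide_meta.position_index(int(p)) for p in positions]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        log_tri = np.log2(tri_ratio[:, tri_pos_idx])  # [8000, n_pos]

    # expected log-ratio per tripeptide per position: sum of residue terms
    log_exp = np.empty((len(tripeptide_meta.determinants), n_pos))
    first = np.arange(n_aa).repeat(n_aa * n_aa)
    second = np.tile(np.arange(n_aa).repeat(n_aa), n_aa)
    third = np.tile(np.arange(n_aa), n_aa * n_aa)
    for li, p in enumerate(positions):
        c0 = log_aa[:, aa_pos_idx[int(p)]]
        c1 = log_aa[:, aa_pos_idx[int(p) + 1]]
        c2 = log_aa[:, aa_pos_idx[int(p) + 2]]
        log_exp[:, li] = c0[first] + c1[second] + c2[third]

    diff = log_tri - log_exp
    finite = np.isfinite(diff)
    n_bg = finite.sum(axis=1)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN backgrounds
        masked = np.where(finite, diff, np.nan)
        bg_mean = np.nanmean(masked, axis=1)
        bg_std = np.nanstd(masked, axis=1, ddof=0)
        # a flat background (observed == expected everywhere) scores 0
        s = np.where(
            bg_std[:, None] > 0,
            (masked - bg_mean[:, None]) / np.where(bg_std > 0, bg_std, 1.0)[:, None],
            0.0,
        )
        s[~finite] = np.nan

    keep = n_bg >= min_background
    rows = np.repeat(np.arange(len(tripeptide_meta.determinants)), n_pos)
    cols = np.tile(np.arange(n_pos), len(tripeptide_meta.determinants))
    sel = keep[rows]
    tri_names = np.asarray(tripeptide_meta.determinants, dtype=object)
    table = pd.DataFrame(
        {
            "tripeptide": tri_names[rows[sel]],
            "position": positions[cols[sel]],
            "observed": np.exp2(log_tri)[rows[sel], cols[sel]],
            "expected": np.exp2(log_exp)[rows[sel], cols[sel]],
            "S": s[rows[sel], cols[sel]],
        }
    )
    table["flagged"] = np.abs(table["S"]) > flag_threshold
    return SynergyTable(
        table, (int(positions.min()), int(positions.max()))
    )
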