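"""RUST ratios for non-codon determinants of footprint density.

Beyond single codons, local read density can be shaped by encoded amino
acids and peptides (nascent-chain effects), individual nucleotides
(ligation/cut-site bias) and downstream RNA secondary structure.  All are
scored with the same observed/expected RUST machinery; only the definition
of the determinant changes.
"""

from __future__ import annotations

import logging
import subprocess
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .codons import AA_INDEX, GENETIC_CODE, SENSE_CODONS
from .core import BinaryProfile, MetafootprintProfile, rust_metafootprint
from .ingest import AnalysisWindowRule, Transcript, admissible_codon_indices

logger = logging.getLogger(__name__)

POSITIVE_AA = frozenset("HKR")
NEGATIVE_AA = frozenset("DE")
HYDROPHOBIC_AA = frozenset("AVILMFYW")

#: reference MFE thresholds (kcal/mol) for the human transcriptome,
#: 80-nt windows: top 1st / 5th / 10th stability percentiles
HUMAN_MFE_THRESHOLDS = {1: -40.1, 5: -32.8, 10: -29.0}


def determinant_metafootprint(
    binary_profiles,
    transcripts: dict[str, Transcript],
    kind: str,
    positions=None,
    rule: AnalysisWindowRule | None = None,
) -> MetafootprintProfile:
    """Metafootprint for nucleotide / amino-acid / peptide determinants.

    Nucleotide positions are in nt relative to the A-site codon's first
    nucleotide (default -120..+62); all other kinds use codon offsets
    (default -40..+20, with di-/tripeptides anchored at their first
    residue).  Stop codons are excluded from the amino-acid alphabets.
    """
    if positions is None:
        positions = range(-120, 63) if kind == "nucleotide" else range(-40, 21)
    return rust_metafootprint(binary_profiles, transcripts, kind, positions, rule)


# ---------------------------------------------------------------------------
# peptide physicochemical windows


@dataclass
class PeptideWindowSpec:
    """A peptide window and the physicochemical property to score.

    ``net_charge`` counts {H,K,R} as +1 and {D,E} as -1 per residue.
    """

    length: int = 10
    property: str = "positive_charges"  # {positive_charges, net_charge, hydrophobic_count}

    def __post_init__(self) -> None:
        if self.property not in (
            "positive_charges",
            "net_charge",
            "hydrophobic_count",
        ):
            raise ValueError(f"unknown property {self.property!r}")

    def residue_values(self, peptide: str) -> np.ndarray:
        if self.property == "positive_charges":
            return np.array([aa in POSITIVE_AA for aa in peptide], dtype=np.int64)
        if self.property == "hydrophobic_count":
            return np.array([aa in HYDROPHOBIC_AA for aa in peptide], dtype=np.int64)
        return np.array(
            [(aa in POSITIVE_AA) - (aa in NEGATIVE_AA) for aa in peptide],
            dtype=np.int64,
        )


def peptide_property_value(peptide: str, spec: PeptideWindowSpec) -> int:
    """Property value of one peptide window (set-membership count)."""
    if len(peptide) != spec.length:
        raise ValueError(f"expected a {spec.length}-residue window")
    return int(spec.residue_values(peptide).sum())


def peptide_property_profile(
    binary_profiles,
    transcripts: dict[str, Transcript],
    spec: PeptideWindowSpec | None = None,
    start_positions=range(-40, 12),
    rule: AnalysisWindowRule | None = None,
) -> MetafootprintProfile:
    """RUST ratios per integer property value per window start position.

    The reported position is the window's 5'-most residue relative to the
    A-site codon; windows running outside the translated region (or over a
    stop codon) are skipped for that occurrence.
    """
    spec = spec or PeptideWindowSpec()
    rule = rule or AnalysisWindowRule()
    if isinstance(binary_profiles, dict):
        binary_profiles = list(binary_profiles.values())
    positions = np.asarray(list(start_positions), dtype=np.int64)

    lo = -spec.length if spec.property == "net_charge" else 0
    hi = spec.length
    values = np.arange(lo, hi + 1)
    val_index = {v: i for i, v in enumerate(values)}

    ro_sum = np.zeros((values.size, positions.size))
    re_sum = np.zeros((values.size, positions.size))
    n_obs = np.zeros((values.size, positions.size), dtype=np.int64)

    for bp in binary_profiles:
        if bp.total_count == 0:
            continue
        tr = transcripts[bp.transcript_id]
        adm = admissible_codon_indices(tr.n_codons, rule)
        if not len(adm):
            continue
        pep = tr.peptide()
        res = spec.residue_values(pep)
        bad = np.array([aa in "*X" for aa in pep])
        cs = np.concatenate([[0], np.cumsum(res)])
        cbad = np.concatenate([[0], np.cumsum(bad)])
        n_windows = len(pep) - spec.length + 1
        if n_windows <= 0:
            continue
        # per window start j: property sum and stop/ambiguity flag
        wval = cs[spec.length :] - cs[: n_windows]
        wbad = (cbad[spec.length :] - cbad[: n_windows]) > 0

        a_idx = np.arange(adm.start, adm.stop)
        b = bp.values[a_idx].astype(np.float64)
        for li, l in enumerate(positions):
            j = a_idx + l
            ok = (j >= 0) & (j < n_windows)
            if not ok.any():
                continue
            jj = j[ok]
            keep = ~wbad[jj]
            if not keep.any():
                continue
            rows = np.array([val_index[v] for v in wval[jj[keep]]])
            np.add.at(ro_sum[:, li], rows, b[ok][keep])
            np.add.at(n_obs[:, li], rows, 1)
            np.add.at(re_sum[:, li], rows, np.full(rows.size, bp.binary_mean))

    with np.errstate(invalid="ignore"):
        ro = np.where(n_obs > 0, ro_sum / np.maximum(n_obs, 1), np.nan)
        re = np.where(n_obs > 0, re_sum / np.maximum(n_obs, 1), np.nan)
    return MetafootprintProfile(
        f"peptide:{spec.property}",
        tuple(str(v) for v in values),
        positions,
        ro,
        re,
        n_obs,
    )


# ---------------------------------------------------------------------------
# RNA secondary structure windows


@dataclass
class StructureWindowSpec:
    """Sliding MFE-window scan parameters and stability thresholds."""

    window_nt: int = 80
    step_nt: int = 10
    percentiles: tuple[int, ...] = (1, 5, 10)
    fixed_thresholds: dict[int, float] | None = None  # e.g. HUMAN_MFE_THRESHOLDS

    def __post_init__(self) -> None:
        if not self.window_nt > self.step_nt > 0:
            raise ValueError("require window_nt > step_nt > 0")

    def window_starts(self, transcript_length: int) -> np.ndarray:
        n = (transcript_length - self.window_nt) // self.step_nt + 1
        return np.arange(max(0, n)) * self.step_nt


def load_window_energies(path) -> pd.DataFrame:
    """Per-window MFE table: transcript_id, window_start_nt, mfe_kcal_mol."""
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["transcript_id", "window_start_nt", "mfe_kcal_mol"],
        dtype={"transcript_id": str},
    )


def rnafold_window_energies(
    transcripts: dict[str, Transcript], spec: StructureWindowSpec | None = None
) -> pd.DataFrame:
    """Compute per-window MFEs by shelling out to RNAfold (ViennaRNA)."""
    spec = spec or StructureWindowSpec()
    rows = []
    for tid, tr in transcripts.items():
        for s in spec.window_starts(len(tr.sequence)):
            seq = tr.sequence[s : s + spec.window_nt].replace("T", "U")
            res = subprocess.run(
                ["RNAfold", "--noPS"],
                input=seq + "\n",
                capture_output=True,
                text=True,
                check=True,
            )
            mfe = float(res.stdout.strip().rsplit("(", 1)[1].rstrip(")"))
            rows.append((tid, int(s), mfe))
    return pd.DataFrame(rows, columns=["transcript_id", "window_start_nt", "mfe_kcal_mol"])


@dataclass
class StructureProfile:
    """RUST ratios of stable-structure windows per window-to-A-site offset."""

    offsets: np.ndarray  # window start minus A-site first nt, in nt
    percentiles: tuple[int, ...]
    thresholds: dict[int, float]
    ro: np.ndarray  # [n_percentiles, n_offsets]
    re: np.ndarray
    n_obs: np.ndarray

    @property
    def ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.ro / self.re
        r[(self.n_obs == 0) | (self.re <= 0)] = np.nan
        return r


def structure_window_profile(
    binary_profiles,
    transcripts: dict[str, Transcript],
    energies: pd.DataFrame,
    spec: StructureWindowSpec | None = None,
    offset_range: tuple[int, int] = (-120, 60),
    rule: AnalysisWindowRule | None = None,
) -> StructureProfile:
    """RUST ratios for windows in the top stability percentiles.

    Thresholds are dataset percentiles of the supplied MFEs (rank-based,
    so invariant to an additive energy shift) unless fixed thresholds —
    e.g. the human reference constants — are given in the spec.
    Transcripts absent from the energy table are skipped with a warning.
    """
    spec = spec or StructureWindowSpec()
    rule = rule or AnalysisWindowRule()
    if isinstance(binary_profiles, dict):
        binary_profiles = list(binary_profiles.values())

    if spec.fixed_thresholds is not None:
        thresholds = {p: spec.fixed_thresholds[p] for p in spec.percentiles}
    else:
        mfe = energies["mfe_kcal_mol"].to_numpy(float)
        thresholds = {
            p: float(np.percentile(mfe, p)) for p in spec.percentiles
        }

    by_tid = {tid: grp for tid, grp in energies.groupby("transcript_id")}
    lo, hi = offset_range
    offsets = np.arange(lo, hi + 1)
    n_cls = len(spec.percentiles)
    ro_sum = np.zeros((n_cls, offsets.size))
    re_sum = np.zeros((n_cls, offsets.size))
    n_obs = np.zeros((n_cls, offsets.size), dtype=np.int64)

    for bp in binary_profiles:
        if bp.total_count == 0:
            continue
        tr = transcripts[bp.transcript_id]
        grp = by_tid.get(bp.transcript_id)
        if grp is None:
            logger.warning("no window energies for %s; skipped", bp.transcript_id)
            continue
        adm = admissible_codon_indices(tr.n_codons, rule)
        if not len(adm):
            continue
        a_idx = np.arange(adm.start, adm.stop)
        a_nt = tr.cds_start + 3 * a_idx
        b = bp.values[a_idx].astype(np.float64)
        starts = grp["window_start_nt"].to_numpy(np.int64)
        mfes = grp["mfe_kcal_mol"].to_numpy(float)
        for s, e in zip(starts, mfes):
            offs = s - a_nt
            ok = (offs >= lo) & (offs <= hi)
            if not ok.any():
                continue
            cols = offs[ok] - lo
            for ci, p in enumerate(spec.percentiles):
                if e <= thresholds[p]:
                    np.add.at(ro_sum[ci], cols, b[ok])
                    np.add.at(n_obs[ci], cols, 1)
                    re_sum[ci, cols] += bp.binary_mean
    with np.errstate(invalid="ignore"):
        ro = np.where(n_obs > 0, ro_sum / np.maximum(n_obs, 1), np.nan)
        re = np.where(n_obs > 0, re_sum / np.maximum(n_obs, 1), np.nan)
    return StructureProfile(offsets, tuple(spec.percentiles), thresholds, ro, re, n_obs)


# ---------------------------------------------------------------------------
# synonymous vs nonsynonymous variance


def synonymous_variance_test(a_site_ratios: dict[str, float]):
    """One-way ANOVA of A-site RUST ratios grouped by encoded amino acid.

    Between-group variance captures nonsynonymous differences, within-group
    variance synonymous ones.  Amino acids represented by a single codon
    (M, W) contribute no within-group degrees of freedom and are dropped.
    Returns ``(F, p)``.
    """
    groups: dict[str, list[float]] = {}
    for codon, ratio in a_site_ratios.items():
        if codon not in SENSE_CODONS or not np.isfinite(ratio):
            continue
        groups.setdefault(GENETIC_CODE[codon], []).append(float(ratio))
    usable = [np.asarray(v) for v in groups.values() if len(v) >= 2]
    if len(usable) < 2:
        raise ValueError("need at least two amino-acid groups with >= 2 codons")
    pooled = np.concatenate(usable)
    if np.allclose(pooled, pooled[0]):
        return 0.0, 1.0
    res = stats.f_oneway(*usable)
    return float(res.statistic), float(res.pvalue)
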