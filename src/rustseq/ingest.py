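"""Transcriptome loading and A-site-mapped codon count profiles.

All coordinates are 0-based, half-open, in transcript space.  Annotation
readers convert from 1-based GTF on load.  A read contributes one count to
the codon index ``floor((five_prime_pos + offset - cds_start) / 3)`` of the
transcript it aligns to, irrespective of its sub-codon position.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import codons_of, encode_codons, translate

logger = logging.getLogger(__name__)

#: minimum CDS length, in codons, admitting a full relative-position window
MIN_CDS_CODONS = 61


@dataclass
class Transcript:
    """One mRNA with its coding region.

    ``cds_start`` is the 0-based index of the first nucleotide of the start
    codon; ``cds_end`` is the exclusive index one past the stop codon.
    """

    id: str
    sequence: str
    cds_start: int
    cds_end: int
    gene_id: str = ""

    def __post_init__(self) -> None:
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(
                f"{self.id}: CDS length {self.cds_end - self.cds_start} "
                "not divisible by 3"
            )
        if self.cds_end > len(self.sequence):
            raise ValueError(f"{self.id}: CDS extends past sequence end")

    @property
    def n_codons(self) -> int:
        return (self.cds_end - self.cds_start) // 3

    @property
    def codons(self) -> list[str]:
        return codons_of(self.sequence, self.cds_start, self.cds_end)

    def codon_ids(self) -> np.ndarray:
        """Sense-codon indices per CDS codon (-1 for stop/ambiguous)."""
        return encode_codons(self.codons)

    def peptide(self) -> str:
        return translate(self.codons)


@dataclass
class CodonProfile:
    """A-site-mapped footprint counts per codon of one CDS (index 0 = start)."""

    transcript_id: str
    counts: np.ndarray
    read_length_used: int = 0
    a_site_offset: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class AnalysisWindowRule:
    """CDS trimming used for every statistic in the package.

    A-site positions are kept only 120 nt (40 codons) or more downstream of
    the start codon and 60 nt (20 codons) or more upstream of the stop.
    """

    min_nt_after_start: int = 120
    min_nt_before_stop: int = 60

    def __post_init__(self) -> None:
        if self.min_nt_after_start % 3 or self.min_nt_before_stop % 3:
            raise ValueError("window bounds must be multiples of 3")
        if self.min_nt_after_start < 0 or self.min_nt_before_stop < 0:
            raise ValueError("window bounds must be non-negative")

    @property
    def skip_start(self) -> int:
        return self.min_nt_after_start // 3

    @property
    def skip_end(self) -> int:
        return self.min_nt_before_stop // 3


def admissible_codon_indices(
    n_codons: int, rule: AnalysisWindowRule | None = None
) -> range:
    """Codon indices usable as A-site positions for a CDS of ``n_codons``.

    Returns ``range(40, L - 20)`` under the default rule; empty when the
    CDS is too short.
    """
    rule = rule or AnalysisWindowRule()
    lo = rule.skip_start
    hi = n_codons - rule.skip_end
    return range(lo, max(lo, hi))


# ---------------------------------------------------------------------------
# annotation + sequence loading


def _read_annotation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["transcript_id", "cds_start", "cds_end", "gene_id"],
        dtype={"transcript_id": str, "gene_id": str},
    )
    return df


def _read_annotation_gtf(path) -> pd.DataFrame:
    """Minimal GTF reader for CDS features in transcript coordinates.

    The seqname column must hold the transcript id; 1-based inclusive
    start/end are converted to 0-based half-open.  Multiple CDS lines per
    transcript are merged to their span.
    """
    rows: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "CDS":
                continue
            tid = f[0]
            start = int(f[3]) - 1
            end = int(f[4])
            gene = ""
            for part in f[8].split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    gene = part.split(None, 1)[1].strip().strip('"')
            if tid in rows:
                rows[tid][0] = min(rows[tid][0], start)
                rows[tid][1] = max(rows[tid][1], end)
            else:
                rows[tid] = [start, end, gene]
    return pd.DataFrame(
        [(t, s, e, g) for t, (s, e, g) in rows.items()],
        columns=["transcript_id", "cds_start", "cds_end", "gene_id"],
    )


def read_annotation(path) -> pd.DataFrame:
    """CDS annotation from GTF or 4-column TSV (transcript_id, start, end, gene)."""
    path = str(path)
    if path.endswith((".gtf", ".gff", ".gtf.gz")):
        return _read_annotation_gtf(path)
    return _read_annotation_tsv(path)


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_transcriptome(
    fasta_path,
    annotation_path,
    longest_isoform: bool = True,
    min_codons: int = MIN_CDS_CODONS,
) -> dict[str, Transcript]:
    """Load transcripts, attach CDS coordinates, apply filtering rules.

    Records without annotation are skipped with a warning; CDS lengths not
    divisible by 3 are rejected; CDSs shorter than ``min_codons`` codons are
    skipped.  With ``longest_isoform`` only the longest-CDS transcript per
    gene is retained.
    """
    seqs = read_fasta(fasta_path)
    annot = read_annotation(annotation_path).set_index("transcript_id")

    transcripts: dict[str, Transcript] = {}
    for tid, seq in seqs.items():
        if tid not in annot.index:
            logger.warning("no CDS annotation for %s; skipped", tid)
            continue
        row = annot.loc[tid]
        cds_start, cds_end = int(row["cds_start"]), int(row["cds_end"])
        if (cds_end - cds_start) % 3 != 0:
            logger.warning("%s: CDS length not divisible by 3; rejected", tid)
            continue
        if (cds_end - cds_start) // 3 < min_codons:
            logger.info("%s: CDS shorter than %d codons; skipped", tid, min_codons)
            continue
        gene = str(row.get("gene_id", "") or tid)
        transcripts[tid] = Transcript(tid, seq, cds_start, cds_end, gene)

    if longest_isoform:
        best: dict[str, Transcript] = {}
        for tr in transcripts.values():
            cur = best.get(tr.gene_id)
            if cur is None or tr.n_codons > cur.n_codons:
                best[tr.gene_id] = tr
        transcripts = {tr.id: tr for tr in best.values()}
    return transcripts


# ---------------------------------------------------------------------------
# alignments

#: canonical in-memory alignment table columns
ALIGNMENT_COLUMNS = ("transcript_id", "pos", "length", "reverse", "unique")


def read_sam(path, require_mapped: bool = True) -> pd.DataFrame:
    """Read transcript-space alignments into the canonical alignment table.

    ``pos`` is the 0-based 5' position of the read on the transcript (the
    leftmost aligned base; reverse-strand reads keep their leftmost
    coordinate but are flagged and later discarded).  Uniqueness is taken
    from ``NH`` tags when present, otherwise from MAPQ > 3.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped and require_mapped:
                continue
            try:
                nh = rec.get_tag("NH")
                unique = nh == 1
            except KeyError:
                unique = rec.mapping_quality > 3
            rows.append(
                (
                    rec.reference_name,
                    rec.reference_start,
                    rec.query_length or rec.infer_read_length() or 0,
                    rec.is_reverse,
                    unique,
                )
            )
    return pd.DataFrame(rows, columns=list(ALIGNMENT_COLUMNS))


def length_histogram(alignments: pd.DataFrame) -> dict[int, int]:
    """Read-length histogram of forward-strand alignments."""
    fwd = alignments.loc[~alignments["reverse"], "length"]
    return dict(Counter(int(x) for x in fwd))


def select_predominant_length(histogram: dict[int, int]) -> int:
    """Modal read length; ties broken toward the smaller length."""
    if not histogram:
        raise ValueError("no usable reads: empty length histogram")
    return min(histogram, key=lambda k: (-histogram[k], k))


@dataclass
class IngestStats:
    """Tally of reads retained and discarded at each filtering step."""

    n_input: int = 0
    n_wrong_length: int = 0
    n_reverse: int = 0
    n_not_unique: int = 0
    n_unknown_transcript: int = 0
    n_outside_cds: int = 0
    n_used: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


def build_codon_profiles(
    alignments: pd.DataFrame,
    transcripts: dict[str, Transcript],
    offset: int,
    read_length: int,
    require_unique: bool = True,
    stats: IngestStats | None = None,
) -> dict[str, CodonProfile]:
    """A-site-mapped codon count profiles from an alignment table.

    Each retained read adds one count at codon index
    ``(pos + offset - cds_start) // 3`` when that index lies inside the
    CDS.  Reads of other lengths, reverse-strand reads, non-unique reads
    (under ``require_unique``) and reads landing outside the CDS are
    discarded and tallied.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    stats = stats if stats is not None else IngestStats()
    stats.n_input += len(alignments)

    df = alignments
    wrong_len = df["length"] != read_length
    stats.n_wrong_length += int(wrong_len.sum())
    df = df.loc[~wrong_len]
    rev = df["reverse"].astype(bool)
    stats.n_reverse += int(rev.sum())
    df = df.loc[~rev]
    if require_unique:
        dup = ~df["unique"].astype(bool)
        stats.n_not_unique += int(dup.sum())
        df = df.loc[~dup]

    profiles: dict[str, CodonProfile] = {}
    for tid, tr in transcripts.items():
        profiles[tid] = CodonProfile(
            tid,
            np.zeros(tr.n_codons, dtype=np.int64),
            read_length_used=read_length,
            a_site_offset=offset,
        )

    for tid, grp in df.groupby("transcript_id", sort=False):
        tr = transcripts.get(str(tid))
        if tr is None:
            stats.n_unknown_transcript += len(grp)
            continue
        idx = (grp["pos"].to_numpy(np.int64) + offset - tr.cds_start) // 3
        ok = (idx >= 0) & (idx < tr.n_codons)
        stats.n_outside_cds += int((~ok).sum())
        np.add.at(profiles[tid].counts, idx[ok], 1)
        stats.n_used += int(ok.sum())
    return profiles
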