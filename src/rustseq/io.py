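"""Readers/writers for the package's plain-text exchange formats."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .codons import SENSE_CODONS
from .ingest import CodonProfile, Transcript
from .simulate import DwellTimeGrid


def write_profiles(profiles: dict[str, CodonProfile], path) -> None:
    """Sparse profile TSV: transcript_id, codon_index, count (absent = 0)."""
    rows = []
    for tid, prof in profiles.items():
        nz = np.flatnonzero(prof.counts)
        for i in nz:
            rows.append((tid, int(i), int(prof.counts[i])))
    pd.DataFrame(rows, columns=["transcript_id", "codon_index", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_profiles(
    path, transcripts: dict[str, Transcript]
) -> dict[str, CodonProfile]:
    df = pd.read_csv(path, sep="\t")
    profiles = {
        tid: CodonProfile(tid, np.zeros(tr.n_codons, dtype=np.int64))
        for tid, tr in transcripts.items()
    }
    for tid, grp in df.groupby("transcript_id"):
        prof = profiles.get(str(tid))
        if prof is None:
            continue
        idx = grp["codon_index"].to_numpy(np.int64)
        prof.counts[idx] = grp["count"].to_numpy(np.int64)
    return profiles


def write_truth(grid: DwellTimeGrid, path) -> None:
    """Ground-truth dwell times: codon, t_c."""
    pd.DataFrame({"codon": SENSE_CODONS, "t": grid.t}).to_csv(path, index=False)


def read_truth(path) -> DwellTimeGrid:
    df = pd.read_csv(path).set_index("codon")
    return DwellTimeGrid(df.loc[list(SENSE_CODONS), "t"].to_numpy(float))


def write_annotation(transcripts: dict[str, Transcript], path) -> None:
    """4-column annotation TSV: transcript_id, cds_start, cds_end, gene_id."""
    with open(path, "w") as fh:
        for tr in transcripts.values():
            fh.write(f"{tr.id}\t{tr.cds_start}\t{tr.cds_end}\t{tr.gene_id}\n")


def write_sam(
    alignments: pd.DataFrame, transcripts: dict[str, Transcript], path
) -> None:
    """Write an alignment table as plain-text SAM in transcript coordinates."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": tr.id, "LN": len(tr.sequence)} for tr in transcripts.values()
        ],
    }
    refs = {tr.id: i for i, tr in enumerate(transcripts.values())}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i, row in enumerate(alignments.itertuples(index=False)):
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = f"read{i}"
            rec.reference_id = refs[row.transcript_id]
            rec.reference_start = int(row.pos)
            rec.flag = 16 if row.reverse else 0
            length = int(row.length)
            rec.cigartuples = [(0, length)]
            rec.query_sequence = "N" * length
            rec.mapping_quality = 42 if row.unique else 0
            rec.set_tag("NH", 1 if row.unique else 2)
            fh.write(rec)


def write_fasta(transcripts: dict[str, Transcript], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for tr in transcripts.values():
            fh.write(f">{tr.id}\n")
            for i in range(0, len(tr.sequence), width):
                fh.write(tr.sequence[i : i + width] + "\n")
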