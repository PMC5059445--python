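"""Per-dataset report: metafootprint, K-L, codon ratios, prediction,
synergy and triplet periodicity, written as CSVs and figures."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, determinants, ingest, norms, predictor, synergy
from .codons import GENETIC_CODE, HUMAN_CODON_USAGE, SENSE_CODONS

logger = logging.getLogger(__name__)


def triplet_periodicity(
    alignments: pd.DataFrame, transcripts: dict[str, ingest.Transcript]
) -> pd.DataFrame:
    """Fraction of read 5' ends per frame (relative to the CDS start), by length.

    Columns: length, frame0, frame1, frame2, n; fractions sum to 1 per
    length; lengths with no usable reads are omitted.
    """
    counts: dict[int, np.ndarray] = {}
    df = alignments.loc[~alignments["reverse"].astype(bool)]
    for tid, grp in df.groupby("transcript_id", sort=False):
        tr = transcripts.get(str(tid))
        if tr is None:
            continue
        frames = (grp["pos"].to_numpy(np.int64) - tr.cds_start) % 3
        for length, frame in zip(grp["length"].to_numpy(np.int64), frames):
            counts.setdefault(int(length), np.zeros(3, dtype=np.int64))[frame] += 1
    rows = []
    for length in sorted(counts):
        c = counts[length]
        n = int(c.sum())
        rows.append((length, *(c / n), n))
    return pd.DataFrame(rows, columns=["length", "frame0", "frame1", "frame2", "n"])


@dataclass
class RunConfig:
    """Serializable description of one end-to-end report run."""

    fasta: str
    annotation: str
    alignments: str
    out_dir: str
    offset: int | str = "auto"
    read_length: int | str = "auto"
    candidate_offsets: tuple[int, ...] = (16, 17, 18)
    min_density: float = 1.0
    require_unique: bool = True
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def run_report(config: RunConfig) -> Path:
    """Execute the full pipeline and write the report bundle.

    Sections: metafootprint + K-L (single and adjacent-pair), codon ratios
    grouped by amino acid with usage-scaled markers, prediction
    correlations, synergy map, triplet periodicity, plus a machine-readable
    summary.  Deterministic given config + inputs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())

    transcripts = ingest.load_transcriptome(config.fasta, config.annotation)
    alignments = ingest.read_sam(config.alignments)
    if config.read_length == "auto":
        read_length = ingest.select_predominant_length(
            ingest.length_histogram(alignments)
        )
    else:
        read_length = int(config.read_length)
    if config.offset == "auto":
        offset = core.detect_a_site_offset(
            alignments,
            transcripts,
            config.candidate_offsets,
            read_length=read_length,
            require_unique=config.require_unique,
        )
    else:
        offset = int(config.offset)

    stats = ingest.IngestStats()
    profiles = ingest.build_codon_profiles(
        alignments, transcripts, offset, read_length,
        require_unique=config.require_unique, stats=stats,
    )
    binaries = {tid: core.binarize(p) for tid, p in profiles.items()}

    # metafootprint + K-L
    meta = core.rust_metafootprint(binaries, transcripts, "codon")
    meta.to_frame().to_csv(out / "metafootprint_codon.csv", index=False)
    kl = core.kl_series(meta)
    pair = np.full_like(kl.divergence, np.nan)
    pair[:-1] = kl.divergence[:-1] + kl.divergence[1:]
    pd.DataFrame(
        {"position": kl.positions, "kl_bits": kl.divergence, "kl_pair_bits": pair}
    ).to_csv(out / "kl_divergence.csv", index=False)

    fig, ax = plt.subplots(figsize=(7, 4))
    for d in range(len(meta.determinants)):
        ax.plot(meta.positions, meta.ratio[d], color="0.7", lw=0.5)
    ax2 = ax.twinx()
    ax2.plot(kl.positions, kl.divergence, color="tab:blue", lw=1.5)
    ax.set_xlabel("codon position relative to A-site")
    ax.set_ylabel("RUST ratio (ro/re)")
    ax2.set_ylabel("K-L divergence (bits)", color="tab:blue")
    fig.tight_layout()
    fig.savefig(out / "metafootprint.png", dpi=150)
    plt.close(fig)

    # codon ratios grouped by amino acid, marker size ~ codon usage
    a_idx = meta.position_index(0)
    ratios = meta.ratio[:, a_idx]
    order = sorted(range(len(SENSE_CODONS)), key=lambda i: GENETIC_CODE[SENSE_CODONS[i]])
    codon_df = pd.DataFrame(
        {
            "codon": [SENSE_CODONS[i] for i in order],
            "amino_acid": [GENETIC_CODE[SENSE_CODONS[i]] for i in order],
            "a_site_ratio": [ratios[i] for i in order],
            "usage_per_thousand": [HUMAN_CODON_USAGE[SENSE_CODONS[i]] for i in order],
        }
    )
    codon_df.to_csv(out / "codon_ratios.csv", index=False)
    fig, ax = plt.subplots(figsize=(10, 4))
    x = np.arange(len(codon_df))
    ax.scatter(
        x, codon_df["a_site_ratio"], s=codon_df["usage_per_thousand"] * 4,
        alpha=0.7, edgecolor="k", linewidth=0.3,
    )
    ax.set_xticks(x, codon_df["amino_acid"], fontsize=7)
    ax.axhline(1.0, color="0.5", lw=0.5)
    ax.set_ylabel("A-site RUST ratio")
    fig.tight_layout()
    fig.savefig(out / "codon_ratios.png", dpi=150)
    plt.close(fig)

    # prediction
    pred = predictor.prediction_summary(
        transcripts, profiles, meta, min_density=config.min_density
    )
    pred.to_csv(out / "prediction.csv", index=False)
    if len(pred):
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.hist(pred["pearson_r"].dropna(), bins=30)
        ax.set_xlabel("per-transcript Pearson r")
        ax.set_ylabel("transcripts")
        fig.tight_layout()
        fig.savefig(out / "prediction.png", dpi=150)
        plt.close(fig)

    # synergy
    aa_meta = determinants.determinant_metafootprint(binaries, transcripts, "amino_acid")
    tri_meta = determinants.determinant_metafootprint(
        binaries, transcripts, "tripeptide", positions=range(-40, 21)
    )
    syn = synergy.synergy_scores(tri_meta, aa_meta)
    syn.flagged.to_csv(out / "synergy_flagged.csv", index=False)
    if len(syn.flagged):
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.scatter(syn.flagged["position"], syn.flagged["S"], s=8)
        ax.set_xlabel("first-residue position relative to A-site")
        ax.set_ylabel("synergy standard score S")
        fig.tight_layout()
        fig.savefig(out / "synergy.png", dpi=150)
        plt.close(fig)

    # periodicity
    period = triplet_periodicity(alignments, transcripts)
    period.to_csv(out / "periodicity.csv", index=False)

    summary = {
        "offset": int(offset),
        "read_length": int(read_length),
        "n_transcripts": len(transcripts),
        "read_tallies": stats.as_dict(),
        "kl_max_position": (
            int(kl.positions[int(np.nanargmax(kl.divergence))])
            if np.isfinite(kl.divergence).any()
            else None
        ),
        "n_flagged_synergies": int(len(syn.flagged)),
        "n_predicted_transcripts": int(len(pred)),
        "median_pearson_r": float(pred["pearson_r"].median()) if len(pred) else None,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return out
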