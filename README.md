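# rustseq

Estimation of relative codon decoding (dwell) times and positional
determinants of ribosome-profiling read density, built around the
**Ribo-seq Unit Step Transformation (RUST)**.

## The problem

Ribosome profiling (Ribo-seq) sequences the ~28-nt mRNA fragments protected
by translating ribosomes. The local density of footprints along a coding
region reflects how long the ribosome dwells at each codon — but the raw
signal is contaminated by heterogeneous noise: sporadic density peaks,
dropout of ambiguous alignments, cDNA-library sequencing biases and vast
differences in coverage between transcripts. Naive averaging of normalized
densities lets a handful of outlier sites dominate the inferred decoding
rates.

RUST replaces each transcript's footprint profile with a Heaviside step
function: codon *i* scores 1 if its count exceeds the transcript average,
else 0. The **observed RUST value** `ro(c, l)` of codon *c* at position *l*
relative to the A-site is the mean of this indicator over every occurrence
of *c* at *l* across the transcriptome; the **expected value** `re(c, l)`
is the mean, over the same occurrences, of the transcript-level average of
the indicator, which controls for the non-random distribution of codons
across expression levels. Their ratio `ro/re` exceeds 1 for slowly decoded
determinants and falls below 1 for fast ones, and the Kullback–Leibler
divergence of the normalized `ro(·, l)` against `re(·, l)`,

    D_l = Σ_c p_cl · log2(p_cl / q_cl),

quantifies how strongly sequence identity at position *l* shapes read
density. Because every site contributes at most 1, the statistic is robust
to outliers by construction.

The package implements, as a tested library plus `rustseq` CLI:

- **ingest** — transcriptome FASTA + CDS annotation (GTF or TSV) +
  transcript-space SAM/BAM alignments → A-site-mapped codon count
  profiles, with the standard trimming (A-sites ≥ 120 nt after the start,
  ≥ 60 nt before the stop), predominant-read-length selection and
  uniqueness filtering.
- **metafootprint profiling** — `ro/re` per determinant (codons,
  nucleotides, amino acids, di-/tripeptides, peptide charge and
  hydrophobicity windows, RNA-structure windows) per position relative to
  the A-site, with K–L divergence series and automatic A-site offset
  detection (the offset whose adjacent codon pair maximizes combined K–L).
- **competing normalizations** — conventional normalization (CN>0, CN>1),
  logarithmic mean normalization (LMN) and ribosome residence time (RRT),
  for head-to-head benchmarking.
- **simulator** — Poisson footprint counts with per-codon relative dwell
  times `t_c` (`λ_{m,c} = D_m·t_c / Σ_{c'} n_{c',m}·t_{c'}`), dwell grids
  spanning ~10- or ~100-fold ranges ordered by codon usage, two noise
  models (3×-max peaks, covered-codon dropout) and a synthetic human-like
  translatome whose codon composition covaries with expression.
- **synergy** — standardized deviation of observed tripeptide RUST ratios
  from the product of single-residue ratios; |S| > 4 flags synergistic
  stalling motifs.
- **predictor** — footprint density as a discrete probability
  `p_k ∝ Π_i ro/re(codon at k+i, site i)` over the footprint's codon
  sites, scored per transcript against observed profiles.

## Worked example

Simulate a deeply covered library with a known tenfold dwell-time range,
corrupt it with 20 % peak noise, and compare RUST with conventional
normalization:

```python
import rustseq as rs

transcripts, totals = rs.synthetic_translatome(500, seed=1, coverage="deep")
grid = rs.build_dwell_grid("tenfold", "positive")
data = rs.simulate_dataset(transcripts, totals, grid, seed=2)
noisy = rs.inject_noise(data, rs.NoiseSpec("peaks", 0.20), seed=3)

for label, ds in [("noise-free", data), ("20% peak noise", noisy)]:
    for name, scores in [
        ("RUST", rs.rust_codon_scores(ds.profiles, transcripts)),
        ("CN>0", rs.cn_scores(ds.profiles, transcripts, 0)),
    ]:
        ev = rs.evaluate_estimates(scores, grid)
        print(f"{label:>15}  {name:<5} Spearman={ev.spearman:.3f}  R2={ev.r_squared:.3f}")
```

prints

```
     noise-free  RUST  Spearman=0.998  R2=0.994
     noise-free  CN>0  Spearman=0.984  R2=0.965
 20% peak noise  RUST  Spearman=0.986  R2=0.963
 20% peak noise  CN>0  Spearman=0.895  R2=0.795
```

Without noise both methods rank the 61 dwell times almost perfectly; under
sporadic density peaks the binarized RUST statistic barely degrades while
plain density averaging loses a fifth of its explained variance.

The same pipeline runs from the shell:

```bash
rustseq simulate --n-transcripts 500 --grid tenfold --seed 1 --out sim/
rustseq norm --profiles sim/profiles.tsv --fasta sim/transcripts.fa \
             --annot sim/annotation.tsv --method rust --out scores.csv
rustseq report --fasta t.fa --annot t.gtf --bam aligned.sam --out report/
```

`rustseq report` writes the full per-dataset bundle: codon metafootprint +
K–L series, codon ratios grouped by amino acid with usage-scaled markers,
per-transcript prediction correlations, flagged tripeptide synergies and
triplet periodicity, as CSVs, PNGs and a machine-readable summary.

## Layout

```
src/rustseq/
  codons.py        genetic code, human codon usage
  ingest.py        FASTA/annotation/SAM loading, codon profiles, trimming
  core.py          binarization, metafootprints, K-L, offset detection
  norms.py         CN / LMN / RRT baselines
  simulate.py      dwell grids, Poisson simulator, noise, translatome
  determinants.py  nucleotide/peptide/structure determinants, ANOVA
  synergy.py       tripeptide synergy standard scores
  predictor.py     density prediction and scoring
  report.py        report bundle, triplet periodicity
  cli.py           click command-line interface
```

See `docs/methods.md` for the model details, parameter choices and known
limitations.
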