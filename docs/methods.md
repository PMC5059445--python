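# Methods

## The unit-step statistic

A codon count profile (A-site-mapped footprints per codon of one CDS) is
reduced to a binary indicator: codon *i* scores 1 iff its count strictly
exceeds the transcript's mean count. The mean is taken over the *admissible
region* — A-site positions at least 120 nt (40 codons) downstream of the
start codon and 60 nt (20 codons) upstream of the stop — so that the
threshold and the statistic see the same data; the first and last codons of
a CDS show atypical densities (initiation/termination effects) and are
never used as A-sites. Uniform profiles therefore binarize to all zeros,
and a transcript with no footprints contributes nothing (its observed and
expected values would both be 0/0).

For a determinant *d* (a codon, nucleotide, amino acid, di-/tripeptide,
peptide-property window or structure window) at position *l* relative to
the A-site:

- `ro(d, l)` = mean of the A-site indicator over all occurrences of *d* at
  *l*, pooled over all transcripts with at least one footprint;
- `re(d, l)` = mean, over the same occurrences, of the transcript-level
  mean indicator.

`re` is the value `ro` would take if footprint placement were blind to
sequence: it rises with expression level, so dividing by it removes the
confound that some determinants are enriched in highly expressed genes.
Occurrences whose context runs outside the CDS, over a stop codon or an
ambiguous base are skipped for that position only; cells never observed
stay undefined (NaN), never zero-filled.

The per-position Kullback–Leibler divergence normalizes `ro(·, l)` and
`re(·, l)` to probability vectors over the defined determinants and
computes `D_l = Σ p log2(p/q)` in bits. The printed form of the divergence
in the source literature uses the raw `ro`/`re` values, which are not
probability vectors; we renormalize per position, which changes absolute
but not relative divergences. Observed zero cells contribute 0; a
positive-observed/zero-expected cell cannot arise from pooled profiles
(an occurrence with a 1 forces its transcript mean above 0).

Default relative-position window: codons −40..+20 (61 positions, A-site at
0, asymmetric to cover the nascent-peptide region upstream and the
structure-forming region downstream); nucleotide determinants use
−120..+62 nt relative to the A-site codon's first nucleotide.

## A-site offset detection

A read's A-site codon is located by adding a fixed offset (usually 16–18
nt) to its 5′ end and flooring to codon resolution. For each candidate
offset the codon metafootprint and its K–L series are computed; every
adjacent position pair (l, l+1) strictly inside the footprint (terminal
codons excluded, since ligation bias concentrates divergence at the read
ends) is scored by `D_l + D_{l+1}`, the combined decoding-centre signal of
the P- and A-sites. The offset with the largest interior pair wins; an
exact tie — e.g. data without positional signal — returns the smallest
candidate with a warning. The pairing matters because in some libraries
the P-site divergence exceeds the A-site's.

Detection relies on sub-codon variation of the 5′ cut site: if every read
started at the same frame, all candidate offsets would produce identical
(shifted) metafootprints. The read-level simulator therefore draws each
footprint's 5′ end with frame probabilities (0.70, 0.20, 0.10) around the
true offset — the triplet periodicity real libraries show — and the
correct offset is the one that gathers all three frames into one codon.

## Competing normalizations

- **CN** divides each profile by its own mean and averages the normalized
  density per A-site codon; CN>0 uses every covered transcript, CN>1 only
  those above 1 read/nt (strict, computed over the admissible region).
- **LMN** (Eq.-style: `LMN_c = mean log2 d_cl − (1/61) Σ mean log2 d_c'l`)
  averages log2 normalized densities over coordinates with mapped reads on
  transcripts above 1 read/nt, then centres across the 61 codons. Scores
  are log2-scale; for comparison with dwell times they are linearized as
  `2^LMN` (mean-dividing log-scale values centred on 0 is ill-defined).
  Codons with no non-zero occurrence are excluded from the centring mean
  with a warning.
- **RRT** scores 19-codon windows tiling the admissible region with step 1
  (step unstated in the original description; 1 maximizes data). A window
  qualifies with >19 reads, <3 empty codons, and a unique codon identity
  at the 1-based 10th position; each qualifying window contributes its
  per-position read fractions. The dwell estimate is the mean fraction at
  the focal position; the full 61×19 matrix is kept for metafootprints.

## Simulator

Counts are independent Poisson draws per codon position with
`λ_{m,c} = D_m · t_c / Σ_{c'} n_{c',m} · t_{c'}` — decoding speed depends
only on the A-site codon; the expected total per transcript is exactly
`D_m`. Dwell grids are 61 equally spaced values from 1 (fastest) to
`1 + 61·inc` with `inc` = 0.15 (tenfold range, max 10.15) or 1.5
(hundredfold, max 92.5); note the printed endpoints imply a spacing of
`61·inc/60`, slightly above `inc`. Assignment follows codon-usage rank:
`positive` correlation gives the rarest codon the shortest dwell time.

Noise models: **peaks** — each coordinate (covered or not) is hit with
probability `fraction · n_covered / L` and set to 3× the original profile
maximum, so the expected number of altered codons is `fraction` times the
covered-codon count; **dropout** — each covered codon is zeroed with
probability `fraction`. Both act per transcript with binomial variation in
the number of altered codons.

### Synthetic translatome

Transcripts are random coding sequences (ATG + body + stop, 30-nt UTRs)
with CDS lengths log-normal around 400 codons (floor 150 so every
transcript admits the analysis window). Per-transcript footprint densities
are log-normal; two presets are provided: `typical` (median 0.027 reads/nt,
σ = 2.0, mean ≈ 0.2 reads/nt — the depth of a real mammalian library of a
few million selected footprints) and `deep` (median 0.2, σ = 2.0, mean
≈ 1.5 reads/nt).

Codon composition is not i.i.d.: real transcriptomes couple codon usage to
expression (highly expressed genes use abundant codons) and vary in usage
between genes independently of expression (GC3/isochore effects). Both are
modelled as exponential tilts of the usage-table weights along the
standardized log-usage axis: a coupling of 0.3 times the expression
z-score, plus an independent per-transcript tilt with s.d. 0.3. These
produce synonymous-frequency swings (up to ~e^±0.6 for extreme codons)
milder than those observed across real human genes. This structure is
load-bearing for two documented phenomena: (i) per-transcript mean
normalization cannot remove the covariance between codon identity and the
transcript's composition-weighted mean dwell time, which inflates the
apparent density of rare (fast) codons in fast-composition transcripts —
the systematic overestimation of quickly decoded codons shown by every
method, most acutely on the hundredfold grid; and (ii) under sporadic peak
noise the binarized RUST statistic, which caps each site's influence at 1,
degrades far less than density averaging (CN), log-averaging (LMN) or
window fractions (RRT).

What the generator does **not** emulate: sequencing biases at footprint
termini (cut-site sequence preference), multi-site dwell effects
(the Poisson rate depends only on the A-site codon), isoform structure,
and positional trends along the CDS (ramps). Benchmarks passing on this
generator therefore certify robustness to coverage heterogeneity,
composition confounds and the two noise models — not to ligation bias,
which in real data is diagnosed via the K–L profile's footprint-end peaks.

### Evaluation

Estimates and truth are mean-normalized over the defined codons
(LMN linearized first); the package reports per-codon
`log2(estimated/simulated)`, their distribution summary, the squared
Pearson correlation (coefficient of determination) and the Spearman
correlation. Codons a method cannot score are excluded and listed.

Benchmark problem sizes: noise-free recovery and the peak-noise comparison
use 500 transcripts at the `deep` preset (realized mean density ≈ 1.1–1.5
reads/nt); the fast-codon bias analysis uses 8000 transcripts at `typical`
depth, because the ten fastest codons are rare by construction and their
per-codon sampling noise at small transcript counts swamps the ~0.1–0.2
log2 systematic effect; the offset round trip uses 120–150 transcripts.

## Determinant analyses

Amino-acid, dipeptide and tripeptide determinants are read from the CDS
translation (alphabets 20, 400, 8000; stop codons excluded; multi-residue
determinants are anchored at their first residue). Peptide windows
(default 10 residues, reported at the window's 5′-most residue) score
integer properties: positive charges (#{H,K,R}), net charge
(#{H,K,R} − #{D,E}; histidine counted fully positive) and hydrophobic
count (#{A,V,I,L,M,F,Y,W}).

RNA-structure windows (80 nt, step 10) take per-window minimum free
energies from an adapter: a plain TSV (`transcript_id, window_start_nt,
mfe_kcal_mol`) or a subprocess call to RNAfold. Windows are classified by
dataset percentiles of MFE (rank-based, hence invariant to additive energy
shifts) or by fixed reference thresholds; the shipped human-transcriptome
constants are −40.1 / −32.8 / −29.0 kcal/mol for the 1st/5th/10th
stability percentiles. Ratios are reported per percentile class per
window-start offset in nt relative to the A-site.

The synonymous-variance test is a one-way ANOVA of A-site codon ratios
with amino-acid identity as the factor; amino acids encoded by a single
codon contribute no within-group degrees of freedom and are dropped; an
all-equal input returns F = 0, p = 1 rather than 0/0.

## Tripeptide synergy

If residues acted independently the RUST ratio of tripeptide *ijk*
starting at position *p* would be the product of the single-residue ratios
at *p*, *p+1*, *p+2*. The synergy score standardizes
`log2(observed) − log2(expected)` per tripeptide against the mean and
standard deviation of its own differences over the scan background
(first-residue positions −40..+17, i.e. 58 positions so the window stays
within −40..+19); |S| > 4 is flagged. Subtracting the background mean
makes S invariant to any multiplicative rescaling of a tripeptide's
ratios. Tripeptides with fewer than 3 defined background positions are
excluded; a flat background scores 0 everywhere.

## Density prediction

The predicted footprint probability at codon *k* of the admissible region
is `p_k ∝ Π_{i∈sites} ratio(codon at k+i, site i)`, normalized to sum
to 1. Default sites are codon offsets −6..+5 — the 12 footprint codons,
with the P-site/A-site boundary between offsets −1 and 0; the site set is
configurable (e.g. `(0,)` for A-site-only prediction). Undefined ratios
impute to the neutral value 1 and are tallied. Predictions are scored by
Pearson and Spearman correlation against observed counts on transcripts
above 1 read/nt; constant observed vectors are excluded. On simulated
data, self-prediction (ratios learned from the profiles being predicted)
reaches a median per-transcript Pearson r above 0.9 only at high coverage
(~20 reads/nt) — the Poisson noise floor, not the estimator, limits the
correlation below that.

## Numerical conventions

- Coordinates 0-based, half-open throughout; GTF input converted on load.
- Binarization uses strict inequality; ties score 0.
- Read-length ties in predominant-length selection break to the smaller
  length; offset-detection ties break to the smallest candidate, with a
  warning.
- Undefined cells are NaN and propagate as exclusions, never as zeros.
- All randomness flows through `numpy.random.default_rng(seed)`; a dataset
  is reproducible from (transcripts, totals, grid, seed), and noise
  injection takes its own seed.

## Known limitations

- Reads are attributed by 5′ end + fixed offset only; no soft-clip
  correction and no frame-restricted read selection.
- Reads mapping to several transcripts of one gene are counted only on the
  retained (longest-CDS) transcript.
- The simulator's A-site-only rate model cannot generate genuine
  multi-site dwell signal; the predictor's multi-site benefit is exercised
  with a purpose-built two-site Poisson fixture in the tests.
- LMN here is footprint-only (no mRNA-seq denominator), which is the
  variant appropriate when no matched RNA-seq library exists.
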