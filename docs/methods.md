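# Methods

## The model

`promotif` implements a presence/absence over-representation analysis of
transcription-factor binding motifs in promoter sequences.

**Motif model.** A motif of length `L` is a position frequency matrix
(PFM): per-position counts `c_bj` of bases `b ∈ {A, C, G, T}` observed in
aligned binding sites.  Counts are smoothed into probabilities with a
background-weighted pseudocount,

    p_bj = (c_bj + s · q_b) / (Σ_b c_bj + s),

where `q` is the background base distribution and `s` the *total*
pseudocount spread across bases in proportion to `q`.  The position
weight matrix (PWM) is the log₂-odds `w_bj = log2(p_bj / q_b)`.  Under
the usual independence assumption a window `x₁…x_L` scores
`S(x) = Σ_j w(x_j, j)`, which is the log-likelihood ratio of the window
under the motif versus the background.

**Relative ("confidence") score.** Raw scores are not comparable across
motifs of different length and information content, so hits are called on
the min-max normalised score

    rel(x) = (S(x) − S_min) / (S_max − S_min) ∈ [0, 1],

where `S_min`/`S_max` are the sums of column minima/maxima.  This is the
standard percentage-match semantics used with JASPAR matrices.  A window
is a hit when `rel > 0.95` — strictly greater, so a threshold of 1.0
retains nothing and only (possibly tied) consensus windows reach 1.0
exactly.

**Scanning.** Every offset of every promoter is scored on the forward
strand and, by default, against the reverse complement (implemented by
scoring with the base-complemented, column-reversed PWM, so reverse-strand
hits are reported at their forward offset).  Windows containing N are
skipped (counted in the log); overlapping and nested hits are all
retained.  Per-gene totals form the gene × motif count matrix.

**Enrichment.** A gene *carries* a motif when its promoter holds at least
one called site.  If `K` of the `N` population genes carry the motif and
the foreground is a subset of `n` genes of which `k` carry it, then under
the null that the foreground is an exchangeable draw from the population,
`k` is hypergeometric, and the enrichment p-value is the upper tail
`P(X ≥ k)`.  Presence (not site counts) is used because a hypergeometric
draw is a draw of *genes*; a count-based binomial/Poisson model is a
different statistic and is out of scope.  The population includes the
foreground genes, mirroring a genome-wide upstream-sequence file that
contains the pathway's genes.  Only over-representation is tested (upper
tail); depletion is not reported.  Family-wise error is controlled by
Bonferroni: the per-test cut is `α/m` for `m` motifs tested (for a
62-motif human panel at α = 0.05 this is 0.05/62 ≈ 8.06 × 10⁻⁴), and the
reported `p_bonferroni` is `min(1, m·p)`.

**Co-occurrence.** For each unordered motif pair the per-gene count
profiles (restricted to the foreground in the pipeline) are compared by
Spearman rank correlation.  Count profiles are tie-heavy, so midranks are
used; ρ is the Pearson correlation of the midrank vectors and the
two-sided p-value uses `t = ρ √((n−2)/(1−ρ²))` with `n−2` degrees of
freedom.  Exact (anti-)concordance of the rank vectors yields ρ = ±1 with
p = 0 by convention; a constant profile has no defined correlation and
the pair is flagged `undefined` rather than given a number.  Both ρ and
ρ² are emitted, since ρ² alone destroys the sign.

## Numerical choices

- **Hypergeometric tail.** For populations up to N = 2,000 the tail sum
  is evaluated in exact integer/rational arithmetic (`math.comb` +
  `Fraction`) and rounded once to float, so small-population results are
  correctly rounded.  Larger problems use log-gamma terms combined with
  compensated `fsum`, summing only the combinatorially non-zero range.
  `k = 0` returns exactly 1.0.
- **Log base 2 throughout** (bits), matching sequence-logo conventions;
  per-column information content is `IC_j = 2 + Σ_b p_bj log2 p_bj` with
  `0·log 0 ≡ 0`, assuming the uniform-background 2-bit ceiling.
- **Degenerate motifs.** A motif whose columns are all uniform has
  `S_min = S_max`; the relative score is undefined and scanning raises an
  "uninformative motif" error rather than dividing by zero.  A zero
  probability against a positive background is rejected at PWM
  construction with a pointer to the pseudocount.
- **Tie-breaks.** Hits at the same start report '+' before '−'; the
  enrichment table sorts by ascending p, ties broken by motif id; BED
  output is ordered by gene id then start.
- **Floats in TSV** use Python's shortest round-trip representation so
  outputs are byte-stable across runs.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `pseudocount_total` | 0.8 | total smoothing mass per column, spread by background; the convention widely used with JASPAR matrices |
| `background` | uniform (0.25 each) | base distribution for odds; optionally estimated from the population's mononucleotide frequencies (`background_model = "empirical"`) |
| `rel_threshold` | 0.95 | relative-score cut, strict `>` |
| `strands` | `both` | promoter scans conventionally consider both orientations; `forward` reproduces a single-strand reading |
| `alpha` | 0.05 | family-wise error target for the Bonferroni cut |

The threshold and α defaults correspond to the conventional ">95%
confidence" call and the 0.05 family-wise level.

## The synthetic generator

`promotif.synthetic` emulates the real study design — a pathway-sized
foreground against a genome-scale promoter population — at desk scale:

- **Background promoters** are i.i.d. bases with `P(G) = P(C) = gc/2`
  (default GC 0.5, reflecting the GC enrichment of upstream regulatory
  regions relative to the genome average).  No Markov structure, CpG
  islands or repeats are simulated; passing tests therefore demonstrate
  correctness of the statistics under the stated null, not robustness to
  real promoter composition.
- **Motif panels** (`random_pfm`) draw column distributions from a
  peaked Dirichlet (concentration 0.12) with 20 observations per column
  and lengths 8–14 bp, the range typical of curated vertebrate motifs.
  Very short motifs saturate gene-level presence at a 95% threshold and
  are not representative of a curated collection.
- **Planted sites** per promoter are Poisson with the configured rate;
  each site is sampled column-wise from the pseudocounted probabilities
  (so some planted sites legitimately fall below the 95% threshold — the
  detection rate is part of what is being exercised), placed uniformly on
  a uniform strand among non-overlapping legal offsets (rejection
  sampling with a retry cap), and recorded in a truth table.  A
  `consensus_only` mode plants exact consensus sequences for
  deterministic-recovery tests.
- **Enrichment by construction**: enriched motifs are planted at
  `planting_rate_fg` in foreground promoters and `planting_rate_bg`
  elsewhere; non-enriched motifs at `planting_rate_bg` everywhere.  Equal
  rates give an exact null.  Every output is a pure function of the
  configuration including the seed.
- **Defective collections** (`write_defective_pfm_collection`) corrupt a
  chosen number of records (missing row, ragged rows, negative entry,
  non-numeric entry, all-zero column) to exercise the parser's
  skip-invalid path, emulating curated collections in which some
  matrices are incomplete for weight-matrix reconstruction.

## Reference experiment scales

The planted-recovery experiment uses 65 foreground genes in a population
of 2,000, with 1 kb promoters, a 6-motif panel, foreground rate 2.0 and
background rate 0.05 — a pathway-sized foreground against a population
large enough for a stable carrier baseline, with 1 kb sequences keeping
each study inexpensive while leaving ~2,000 windows per gene and strand.
Null calibration uses 15/200 genes, 200 bp promoters and a 4-motif panel
across hundreds of replicates.  Test-suite and acceptance-script runs
complete in a couple of minutes on one CPU at these scales.

## Known limitations

- Mononucleotide background and independent PWM columns: no dinucleotide
  or higher-order background, no informative-prior motif models.
- Score threshold is a fixed relative score, not a p-value-calibrated
  cut per motif; motifs of different information content have different
  per-window false-positive rates at the same relative threshold.
- Gene-level presence discards site-count information by design; a motif
  that occurs more often per promoter but in the same number of
  promoters will not appear enriched.
- The Spearman p-value is a t approximation; it is accurate for the
  dozens-of-genes profiles it is applied to but not exact for very small
  n (an exact-permutation oracle is used in the tests at small n).
- The correlation analysis applies no multiple-testing correction, by
  design; the pairwise p-values are descriptive.
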