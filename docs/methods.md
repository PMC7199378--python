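# Methods

`methylotime` predicts a cell's position along a differentiation trajectory
("pseudo-time"; lower = more pluripotent) from its DNA methylation, in the
setting of single-cell bisulfite sequencing (scBS-seq) of mouse embryonic
stem cells grown in 2i or serum media. Pseudo-time itself is taken as given
— in practice it is estimated from matched scRNA-seq by trajectory tools —
and the package covers everything downstream of the cytosine-level
methylation calls.

## Methylation quantification

Input is the Bismark cytosine-report dialect: one row per cytosine with
1-based position, strand, methylated/unmethylated read counts and context
(CpG, CHG or CHH; CHG+CHH together form the non-CpG class). Internally,
intervals are 0-based half-open; conversion happens at the I/O boundary. A
1-based position `pos` belongs to interval `[start, end)` iff
`start < pos <= end`. Plus- and minus-strand cytosines are independent
records; CpG dyads are not merged (Bismark reports them separately).

Because scBS-seq coverage is sparse, methylation is quantified over sliding
windows: width `w = 3000` bp every `s = 1500` bp, anchored at position 0 of
each chromosome, trailing windows clipped at the chromosome end. A window's
level for a sample is the **unweighted mean of per-site rates**
(methylated / total reads) over covered cytosines of the requested context
class — at read depth 1 the per-site rate is naturally the binary call, and
rates at depth > 1 are used as ratios, not re-binarized. Windows in which
*any* sample has fewer than `min_covered_cytosines = 4` covered cytosines
are discarded, which is what makes the resulting samples × intervals matrix
complete with no imputation. Both knobs are exposed on `WindowConfig`.

Sample-level QC: bisulfite conversion efficiency is estimated as one minus
the apparent methylation over **all** covered non-CpG sites genome-wide
(non-CpG methylation is rare, so apparent non-CpG methylation is dominated
by conversion failures), and samples below 95% efficiency are excluded
before any matrix is built.

Metagene profiles rescale each of a configurable list of gene regions to 12
equal bins and pool covered-site rates across genes, reversing minus-strand
genes so bin 1 is always 5'-most. The default region list (upstream 1500 bp,
5'UTR, first/internal/last exons and introns, 3'UTR, downstream 1500 bp; 10
regions × 12 bins = 120 windows) is an assumption — the exact decomposition
behind the original 120-window figure is not documented — and any region
subset can be supplied instead. Group summaries sort samples by pseudo-time
and cut them into five contiguous groups I–V, as equal as possible with the
remainder assigned to the earliest groups; each group reports its mean
methylation `m` and coefficient of variation `cv` (sample SD over mean).

## Marker selection and the pseudo-time model

Per context class (CpG, non-CpG), three stages:

1. **Univariate F-test filter.** For each interval, simple linear regression
   of pseudo-time on the interval's methylation level;
   `F = SSR / MSE` with df (1, N−2); intervals with p < 0.05 are kept.
   Zero-variance intervals have an undefined F and are never kept; exact
   fits (SSE numerically 0) are kept with p = 0.
2. **Bootstrap-lasso stability selection.** `B = 1000` bootstrap resamples
   (size N, with replacement; resamples with constant response are redrawn).
   On each resample a lasso is fitted with its penalty chosen by seeded
   10-fold CV **under the one-standard-error rule** — the largest penalty
   whose CV error is within one SE of the minimum. The plain CV-minimum
   lasso is anti-conservative: measured on the default synthetic scenario it
   retains chance-correlated null intervals in more than half the resamples,
   which defeats the majority threshold; the 1-SE rule is the standard
   sparse convention and restores the intended behaviour. An interval
   selected (nonzero coefficient) in at least `threshold = B/2` runs is a
   marker.
3. **Elastic-net fit** on the selected markers:

       argmin over (β₀, β) of (1/2N) Σᵢ (yᵢ − β₀ − xᵢᵀβ)²
                              + λ Σⱼ [ (1−α)/2 · βⱼ² + α·|βⱼ| ]

   with α = 1 by default (pure lasso; ridge mixing made no difference in the
   original analysis) and λ chosen by seeded 10-fold CV minimizing held-out
   RMSE over 100 log-spaced values from λ_max down to λ_max·10⁻⁴, ties
   breaking toward the largest (most parsimonious) λ. Features are
   standardized internally for penalized fitting (glmnet convention,
   toggleable via `standardize`) and coefficients are returned on the
   original methylation scale. Coordinate descent is delegated to
   scikit-learn, whose penalized objective is term-for-term the one above;
   the test suite checks the fitted solutions against the subgradient (KKT)
   conditions of that objective directly, and against OLS at λ = 0 and the
   null model at λ ≥ λ_max.

The **combined model** takes the union of the CpG- and non-CpG-selected
markers (each marker keeps its context class, since the same interval has
distinct CpG and non-CpG levels) and refits jointly. The alternative — joint
selection on concatenated features — is deliberately not the default, so the
class-wise marker counts remain interpretable.

## Evaluation

Leave-one-out cross-validation refits **coefficients only** on each N−1
subset, with the marker set and penalty fixed from the full fit; whether the
original analysis re-ran marker selection inside each fold is unknown, and
markers-fixed is the cheaper, optimistic convention — the caveat is that its
R is an upper bound on a fully nested estimate. Reported metrics: Pearson R
between observed and predicted pseudo-time, RMSE, and the least-squares
slope of predicted-on-observed.

As a classifier of culture condition, LOOCV predictions are scored against
the group labels with serum (the higher-pseudo-time group) as the positive
class: ROC over all score thresholds, trapezoidal AUC (equal to the
Mann–Whitney probability with half-credit ties), and accuracy at the
Youden-J-maximizing threshold. The original accuracy figure's threshold rule
is not stated anywhere, so Youden's J is this package's documented default
and a fixed threshold can be supplied instead.

## Transfer to external datasets

External methylomes rarely cover all markers, so prediction for an external
cohort (a) intersects the model's markers with the externally quantified
intervals — exact identity of chromosome, start, end *and* context class;
the window grid must match, and fuzzy interval matching is refused — then
(b) refits the penalized model on the *training* samples restricted to the
common markers, re-selecting λ with the same seeded CV, and (c) predicts
the external samples. The refit λ and seed are recorded in the report.

## Synthetic data generator

The generator is first-class, tested code that emulates the structure of a
75-cell (14 2i / 61 serum) parallel scRNA-seq/scBS-seq experiment:

- **Pseudo-times** are uniform within group-specific ranges. The 2i-like
  group occupies a narrow early segment (width = 1/4 of the serum-like
  width, default 6 vs 24 time units): 2i holds cells in a tight naive
  ground state while serum permits a spread of differentiation states, so
  the naive group is both earlier and tighter. `group_shift` sets the
  difference between group means and defaults to **two pooled within-group
  SDs** (≈12.6 time units at the default widths) — the clearly-separated
  regime the classifier analysis addresses. Zero shift gives exchangeable
  groups.
- **Markers** are whole tiles of a fixed 3-kb grid, sampled without
  adjacency so that marker identity is exact at the feature level and
  half-overlapping quantification windows cannot blur it; everything else
  is background. CpG markers are always positively associated with
  pseudo-time; non-CpG markers are positive except for a configurable
  fraction (default 0.3) of negative ones. A site in a marker interval of
  the matching context has methylation probability
  `logistic(logit(background) + effect_size · t)` for positive markers;
  negative markers are modelled as *demethylating* loci,
  `logistic(logit(background) + effect_size · (t_max − t))`, because a
  literal negative slope away from the 2% non-CpG background would have no
  dynamic range to detect.
- **Coverage** is sparse and cell-specific: Poisson(15)-many covered
  cytosines per interval per context per cell at zero-truncated-Poisson
  (λ = 1.5) read depth; depth fixed at 1 reproduces the binary single-read
  regime. Context backgrounds default to 30% (CpG) and 2% (non-CpG),
  keeping non-CpG methylation the rare class. No quantitative coverage
  statistics were available to copy, so these are stated defaults, not
  inferred values.
- **Conversion failure** flips each unmethylated read to methylated with a
  given probability (so a 6% failure rate on clean data yields ≈94%
  apparent efficiency, below the 95% QC cutoff).
- **Expression** (optional) gives marker genes log2(TPM+1) linear in
  centred pseudo-time with mixed slope signs plus Gaussian noise; other
  genes are independent of pseudo-time.

What the generator does **not** emulate: read-level data (no FASTQ,
alignment or duplicate structure), chromatin-domain autocorrelation of
methylation along the genome, copy-number or batch effects, and the
CHG/CHH asymmetry (the two non-CpG contexts are split uniformly, since the
pipeline pools them anyway). Passing tests therefore demonstrate that the
statistical machinery recovers planted structure under realistic sparsity —
not that the biological effect sizes in real data are this large.

Everything is deterministic given `seed`: identical configuration and seed
reproduce byte-identical datasets.

## Problem sizes used in the shipped checks

The replicated end-to-end checks run at N = 75 cells, 500 grid tiles
(10 CpG + 10 non-CpG planted markers, 480 background) on five 300-kb
chromosomes, with B = 200 bootstrap resamples and stability threshold B/2,
five seeded replicates; quantification-exactness and QC checks use smaller
2-chromosome genomes. These sizes were chosen so the whole suite runs on a
laptop-class single core in minutes while keeping the Monte-Carlo margins
quoted in the tests.

## Known limitations

- Marker transfer requires an identical window grid; there is no lift-over
  or fuzzy matching between differently-windowed matrices.
- No imputation of missing intervals: an interval under-covered in any
  sample is dropped for all samples.
- LOOCV is markers-fixed (see above) and the classifier threshold rule is a
  package convention, not a reproduction of an undocumented one.
- The F-test filter and stability selection assume an (approximately)
  linear methylation–pseudo-time relationship; saturating trajectories are
  only captured insofar as their linear component is detectable.
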