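# Methods

## The affinity model

A PWM `w` of length `l` gives the probability `P(w_j, base)` of each
nucleotide at each motif position; a background `b` gives genome-scale base
frequencies. The score of one window is the log likelihood ratio of the
motif model to the background, maximized over the two orientations; the
background term always uses the observed plus-strand base, so both
orientation scores are ratios of two models of the same observed window.
Natural logs are used throughout. The total binding affinity (TBA) of a
sequence is the log of the sum of exponentiated window scores over all
`L − l + 1` windows; the occupancy at cutoff `C` restricts that sum to
windows scoring at least `C · S_max`, where `S_max` is the maximum
achievable window score.

Implementation notes:

- **S_max** is computed as the larger of the two orientations'
  position-wise maxima. Each orientation's score is a sum of independent
  per-position terms, so its maximum over windows is the sum of per-position
  maxima; with a non-uniform background the two orientations can genuinely
  differ (the denominator follows the plus strand), and taking the larger
  one makes `S_max` the exact, attainable maximum over all windows and
  orientations.
- **Cutoff comparison** is `score ≥ C·S_max` with a 1e-9 relative
  tolerance. A strict inequality would make the threshold unattainable at
  `C = 1` even for the best possible site; with the tolerance, `C = 1`
  selects exactly the top-scoring sites, which is the intended semantics of
  the maximal cutoff.
- **Strand symmetry.** TBA is invariant under reverse-complementation of
  the sequence *provided the background is strand-symmetric*
  (`P(A)=P(T)`, `P(C)=P(G)`). Backgrounds estimated from double-stranded
  genomic DNA have this property; for a deliberately asymmetric background
  the formula is strand-dependent, which follows directly from the
  plus-strand denominator. Tests assert invariance under symmetric
  backgrounds only.
- **Unscorable windows.** Windows containing `N` or masked positions are
  skipped entirely. A sequence with no scorable window raises a distinct
  error for TBA (the affinity is undefined, not low), while an occupancy
  sum with no passing window is the legitimate value `−inf` (log 0),
  serialized as `-inf` and ranked below all finite scores in ROC analyses.
- **Degenerate PWMs.** If every position of a PWM prefers bases that are
  rarer than background, `S_max` can be negative; the cutoff rule
  `C·S_max` is still applied literally, which then admits *more* windows as
  `C` grows. Such matrices are pathological inputs, not a supported regime.

## PWM input conventions

Count matrices (JASPAR PFM, with or without the bracketed row dialect) have
zero counts replaced by one before normalization — add-one on zero cells
only, not Laplace smoothing. Probability matrices have exact zeros replaced
by a 1e-6 pseudocount and columns renormalized (renormalization keeps the
probabilistic invariant exact; the distortion is below 1e-5 per entry). A
warning is emitted when a matrix's smallest non-zero probability is not
larger than the pseudocount, since then the pseudocount is no longer a
negligible regularizer. Backgrounds estimated from FASTA are case-folded,
skip `N`, and floor never-observed bases at one count; when no background is
supplied, the uniform 0.25 vector is used so the likelihood ratios remain
well-defined without any genome at hand.

## Regions and chromatin refinement

Coordinates are 0-based half-open throughout; a TSS is the 0-based position
of the first transcribed base. The fixed promoter is 1500 bp upstream and
500 bp downstream, oriented by strand and clipped at position 0. Chromatin
refinement (i) removes positions overlapping the two closed states of the
15-state vocabulary ("Polycomb repressed", "Heterochrom; low signal" —
remappable via a 2-column state-map TSV) and (ii) extends a region end
lying inside an open segment to that segment's boundary. The operation is
idempotent and can only add open sequence. A fully closed promoter yields a
flagged empty region; such genes are skipped by sequence extraction and
reported, and drop out of downstream models listwise.

Multi-interval regions are scored as one sequence with a masked junction
base inserted between intervals, so no scoring window spans a genomic gap;
this equals summing per-interval affinities on the exponential scale while
keeping one value per gene.

## Binding evaluation

AUC is computed exactly from ranks (the normalized Mann–Whitney U), not by
trapezoid integration over thresholds: it is tie-safe, and `−inf`
no-predicted-site scores tie among themselves below all finite scores.
P-values come from the two-sided tie-corrected Mann–Whitney test. The sweep
produces one TBA record plus one record per cutoff of the 10-point grid
(0.1–1.0) per experiment/PWM pair; pairs with AUC < 0.5 for every predictor
carry no signal for any variant of the score and are dropped with a count.
Per-PWM summaries average AUC over experiments with equal weights. The
paired Wilcoxon test on per-PWM AUC differences uses the exact null for
≤ 25 informative pairs (when free of ties) and the normal approximation
with continuity correction otherwise.

## Expression model

Raw expression is normalized per cell line by adding that table's smallest
non-zero value as a pseudo-count and taking log2 — a monotone map that
keeps zero-expression genes in the model at the detection floor. The model
`e_g = Σ_i c_i a_g(i) + b + r_g` is fitted by OLS without predictor
standardization; quality is the adjusted R² and the whole-model F-test
against the intercept-only fit. Rank-deficient designs are rejected with
the collinear or constant columns named. Cross-validation is 10-fold over
shuffled genes, reporting the mean held-out R². The lasso standardizes
predictors internally (coefficients are mapped back to the original scale)
and picks the penalty minimizing 10-fold CV error — the minimizing rule,
not the 1-SE rule, which means a handful of noise predictors typically
enter with near-zero coefficients; the held-out R² at the chosen penalty is
reported alongside. The composition baseline regresses expression on A/C/G
frequencies (T is the complement) plus CpG dinucleotide frequency
(`count("CG") / (length − 1)`).

Genes whose design cell is `NaN` (no scorable window) or `−inf` (occupancy
with no passing site) are dropped listwise before fitting: an infinite
predictor has no meaningful least-squares treatment, and imputing it would
silently blend "no site" into the affinity scale.

## Synthetic data: what it emulates and what it does not

The binding benchmark emulates the statistical structure of a ChIP-seq
evaluation: positives are background DNA with `k` motif instances planted
at non-overlapping positions and random orientations; negatives are
length-matched background. Site instances are drawn from the PWM under a
sampling temperature (1 = faithful draws, 0 = consensus only, > 1 weaker
than faithful), producing the mixture of strong and weak sites that makes
cutoff-free scoring matter. Default study conditions for the benchmark
experiments: 300 positives vs 300 negatives of 500 bp, `k = 4` sites at
temperature 1.2, PWMs of length 10 at 1.0 bit per position — typical of
vertebrate motif collections, and enough planted signal for near-ceiling
TBA AUC while high cutoffs visibly collapse. The generator does not attempt
to match real peak-length, GC-heterogeneity or expression distributions;
passing these benchmarks shows the machinery is correct and the qualitative
ordering of predictors holds under the model's own assumptions, not that
real-data AUC/R² magnitudes are reproduced (those depend on external
datasets).

Simulated expression is generated forward from the linear model on a real
affinity design and returned on the raw scale, shifted so the lowest gene
sits exactly at the detection floor; pushing it back through the
normalization recovers the simulated log2 values up to the pseudo-count
distortion, which is negligible except for genes near the floor. Noise is
calibrated by `Var(signal)/Var(noise)`, so SNR 1 implies an expected R² of
0.5. Synthetic segmentations tile the chromosome exactly with
exponential-length segments and hit a requested closed-chromatin fraction
in expectation.

## Problem sizes

The shipped experiments use 100 random fixtures (l ≤ 12, L ≤ 500) for
scorer-vs-brute-force agreement, 5 PWMs × 600 sequences for the cutoff
sweep, 2000 genes × 25 PWMs for expression recovery, 150 genes on a
~0.9 Mb synthetic chromosome for the chromatin-refinement comparison, and
250 genes × 4 PWMs for the shuffled-PWM control — sizes at which every
reported quantity is stable across seeds while the full suite runs in well
under a minute per experiment.

## Known limitations

Mono-nucleotide background only (no dinucleotide or higher-order models);
no PWM trimming, alignment or clustering; single-TSS genes only (callers
pre-filter multi-TSS genes); no liftover; no cooperative-binding or
activator/repressor-switching terms in the expression model (a
principal-component variant would address basis questions but explained
variance is already basis-invariant); scoring is single-threaded and
deterministic rather than parallel.
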