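# affinityscan

Cutoff-free scoring of regulatory DNA for transcription-factor binding, and
evaluation of how well those scores predict binding and gene expression.

Most motif-scanning pipelines call discrete binding sites: a window is a
site if its position-weight-matrix (PWM) score exceeds a cutoff, and the
sequence is summarized by its called sites. Thermodynamically, though, a
factor binds transiently even to weak sequences, so every window contributes
in proportion to its affinity. `affinityscan` implements this view as the
**total binding affinity** (TBA) of a sequence *r* for a PWM *w* of length
*l* over a background *b*:

```
a_rw = log Σ_i max( Π_j P(w_j, r_{i+j}) / P(b, r_{i+j}),
                    Π_j P(w_{l-j+1}, r'_{i+j}) / P(b, r_{i+j}) )
```

The sum runs over every length-*l* window *i* of the sequence, the max over
the two orientations (r' is the complementary base), and the background term
always uses the plus-strand base. The cutoff-based alternative, the
**occupancy** `t_rw(C)`, is the same sum restricted to windows scoring at
least `C · S_max(w)` where `S_max` is the best score the PWM can achieve and
`C ∈ (0, 1]` — at `C = 1` only top-scoring sites remain, and as `C → 0` the
occupancy converges to the TBA.

On top of this scoring core the package provides:

- **PWM handling** — JASPAR-style count matrices and probability-matrix
  TSVs, with the conventional zero handling (zero counts → one count; zero
  probabilities → 1e-6 pseudocount), column shuffling as a specificity
  control, and background estimation from FASTA.
- **Region construction** — fixed promoters (−1500/+500 bp around a TSS,
  BED conventions) and chromatin-state refinement: positions in "closed"
  states (Polycomb-repressed, heterochromatin/low-signal) are masked out of
  scoring, and promoter ends falling inside an "open" state are extended to
  that state's boundary.
- **Binding evaluation** — exact rank-based ROC/AUC (Mann–Whitney), a sweep
  producing 11 AUC values per experiment/PWM pair (TBA plus ten cutoffs
  0.1–1.0), filtering of uninformative pairs, paired Wilcoxon comparison of
  AUC distributions.
- **Expression modeling** — the log-linear model
  `e_g = Σ_i c_i a_g(i) + b + r_g` of log2 expression on per-gene affinity
  profiles, fitted by OLS with adjusted R² and an F-test against the
  intercept-only model; 10-fold cross-validation; lasso with the
  CV-error-minimizing penalty; shuffled-PWM and base/CpG-composition
  baselines.
- **Synthetic data** — planted-motif binding benchmarks, random
  segmentations, and expression simulated forward from the linear model, so
  the whole stack is testable offline.

## Worked example

Generate a benchmark in which each of 50 positive sequences (300 bp) carries
3 sites sampled from a simulated PWM, with 50 background negatives, then
sweep TBA and the ten occupancy cutoffs:

```sh
affinityscan simulate --seed 5 --n-pos 50 --n-neg 50 --length 300 --sites 3 --out bench
affinityscan binding-eval --pos bench/positives.fa --neg bench/negatives.fa \
    --pwms bench/pwms --pwm-format probs --out eval
cat eval/auc_per_pwm.tsv
```

```
pwm             tba     occupancy@0.1  ...  occupancy@0.6  occupancy@0.7  occupancy@0.8  occupancy@0.9  occupancy@1
sim_pwm_s5_l10  0.9972  0.9972         ...  0.9776         0.978          0.74           0.71           0.71
```

Reading the row: TBA separates motif-bearing from background sequences
almost perfectly (AUC 0.997); occupancy matches it at permissive cutoffs
(where nearly every window passes, so occupancy ≈ TBA), and collapses at the
cutoffs conventional site-callers use (AUC 0.74 at `C = 0.8`), because most
planted sites are weaker than 80 % of the maximal score and stop
contributing. The same library functions are available programmatically
(`affinityscan.tba`, `occupancy`, `score_matrix`, `cutoff_sweep`,
`fit_linear`, ...), and `affinityscan expr-model` runs the expression
pipeline end to end from a TSS table, genome FASTA, expression TSV and
optional chromatin segmentation.

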