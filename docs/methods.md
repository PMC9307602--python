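# Methods

## The model

`chromexpr` predicts a gene's mRNA abundance (TPM) from two aligned inputs
assembled over fixed windows around its transcription start site (TSS) and
transcription termination site (TTS):

* an **epigenetic matrix** `L x m` — per-base signal from `m` modification
  tracks (histone-mark / DNase ChIP-seq signal p-values, percent methylation
  from WGBS), piecewise-constant over 20-bp genomic regions and scaled to
  [0, 1];
* a **sequence matrix** `L x 4` — one-hot DNA (columns A, C, G, T; ambiguous
  bases are all-zero rows).

The default windows are [-1000, +500] bp around the TSS plus [-500, +500] bp
around the TTS (`L = 2500`), the combination that performs best in a scan
over candidate window sets (`training.region_scan` reproduces that scan).

Each input passes through its own convolutional branch — conv (kernel
spanning `l = 20` positions times all channels, `k1 = 64` kernels) → batch
norm → ReLU → max-pool(4) → conv (`k2 = 128`) → BN → ReLU → max-pool(5) — so
both branches emit an `L' x k2` representation with `L' = L/20`.  The two
representations are stacked as parallel columns and fused by a convolution
whose kernel spans 20 positions times both columns and all channels (64
kernels), followed by BN, ReLU, max-pool(5), and four fully connected layers
(512 → 256 → 64 → 1) with ReLU and dropout (rate 0.5) between hidden layers.
The output is the expression value on the training target scale.

Training minimizes `MSE + lambda * sum(W^2)` (`lambda = 1e-4` over conv and
dense kernels) with Adam (learning rate 1e-3), batches of 100 genes, up to
200 epochs, early stopping on validation loss (patience 10), and a random
60/20/20 gene-level train/validation/test split.  Evaluation reports
`R^2 = 1 - SS_res/SS_tot` and Pearson correlation on the target scale.

A classification variant (sigmoid output + binary cross-entropy on
above/below-median expression labels) is available via
`ModelConfig(task="classification")`.

### Numerical choices

* The network is implemented directly in NumPy (float32) with explicit
  forward/backward passes: convolutions as sums of shifted BLAS matmuls,
  standard batch-norm/pooling/dropout backprop, and backpropagation to the
  *inputs*, which is what Integrated Gradients needs.  A finite-difference
  test verifies input gradients to 1e-4 relative error.
* Convolutions preserve length via zero padding of `(l-1)//2` left and
  `l//2` right; the choice is recorded in every checkpoint sidecar.
* Batch norm sits between each convolution and its ReLU; evaluation uses
  running statistics (momentum 0.9), so eval-mode prediction and its input
  gradient are deterministic per sample.
* The output bias is initialized to the training-target mean, so the few
  hundred optimizer steps of a small study fit structure rather than the
  offset.
* Regression targets default to `log1p(TPM)`; raw-TPM training is a switch.
  MSE on raw TPM is dominated by the most highly expressed genes, and all
  metrics are reported on the training scale either way.
* Minus-strand genes are mirrored (sequence reverse-complemented, signal and
  coordinates reversed) so row 0 is always the most-upstream base; genes
  whose windows would leave the chromosome are skipped, never zero-padded.
* p-value tracks are `-log10`-transformed and min-max scaled per track over
  the union of assembled gene windows (the population the model sees); a
  constant track maps to zeros.  Values outside the assembled windows can
  exceed the scaling range and are clipped.  When a source interval straddles
  a 20-bp region the region takes the coverage-weighted mean, with the
  track's null value (p = 1, methylation = 0) filling uncovered bases.

## Integrated Gradients

For a trained differentiable predictor `F` and baseline `x'` (zeros by
default; a uniform 0.25 sequence baseline and an all-ones methylation
baseline are selectable), the attribution of feature `j` is

    attr_j(x) = (x_j - x'_j) * sum_s w_s * dF/dx_j (x' + a_s (x - x'))

a quadrature approximation of the straight-line path integral with `S = 200`
points by default.  The default scheme is Gauss-Legendre (the scheme the
mainstream attribution libraries default to); a right-rule Riemann sum is
selectable.  The completeness residual
`sum_j attr_j - (F(x) - F(x'))` is computed and stored with every map, never
dropped.  Downstream analyses:

* **mean profiles** — element-wise mean attribution across genes, per track
  and position (signs kept);
* **high-attribution windows** — the ±50 bp window (101 bases, clipped at
  input edges, leftmost argmax on ties) around each gene's per-track
  attribution maximum, mapped back to genomic coordinates;
* **differential attribution** — the per-site statistic is the absolute
  *mean* (across differentially expressed genes) of the attribution
  difference between the two conditions; averaging cancels the per-gene
  attribution noise so the systematic between-condition difference stands
  out.  Sites at or above the 0.90 quantile of that statistic (and strictly
  positive, so identical conditions return nothing) are merged into maximal
  runs per track.  A per-gene variant — each gene's own difference map
  against a threshold pooled over all genes' sites — is exposed as a flag
  for heterogeneous effects;
* **peak-overlap permutation test** — observed statistic is the mean peak
  signal inside the windows; the null redraws same-count, same-length windows
  uniformly within the assembled input regions;
  `p = (1 + #{null >= obs}) / (n_perm + 1)`.

Motif analysis is a transparent log2-odds PWM scan (pseudocount 0.5, uniform
background, both strands, hit threshold at 80% of the attainable score range)
followed by one-sided Fisher tests of has-hit counts in foreground versus
background windows, Benjamini–Hochberg corrected at 0.05.  Gene-set
over-representation uses the same Fisher + BH machinery over user-supplied
GMT files.  No claim is made that these reproduce AME/FIMO or any web
service's statistics; they are the package's own, fully specified stand-ins.

## Synthetic studies

The generator (`chromexpr.synthetic`) builds complete studies — genome FASTA,
per-gene annotation, bedGraph tracks, expression table, motif file, ground
truth JSON — with the statistical structure the model assumes:

* tracks are piecewise-constant over 20-bp blocks with latent values
  `v ~ U(0,1)`; p-value tracks are emitted as `p = 10^(-3v)` so preprocessing
  inverts them (monotonically) back to `v`; methylation tracks as `100 v`;
* each causal window carries a gene-specific level `mu_g ~ U(0.1, 0.9)` plus
  per-block jitter (sd 0.05);
* expression is `TPM = exp(b0 + sum_k w_k * meanSignal_k + motif_effect * 1[motif
  inserted] + eps)`, `eps ~ N(0, noise_sd)` — multiplicative, so both log1p
  and raw-TPM training modes are exercised realistically;
* a sharp 8-bp motif is inserted (default rate 0.6) only inside causal
  promoter windows, making motif-enrichment tests sharp;
* genes are placed non-overlapping on alternating strands so strand-handling
  bugs surface deterministically;
* random streams are separated by purpose (background signal, each causal
  window, sequence, motif, noise), so two configurations that differ by one
  extra causal window share everything else at the same seed — paired
  conditions for differential-attribution analyses;
* `oracle_r2` gives the analytic ceiling
  `V / (V + noise_sd^2)` with `V = sum w_k^2 Var(U(0.1,0.9)) +
  motif_effect^2 rate (1-rate)`; the defaults put it near 0.8.

The generator does **not** emulate realistic base composition, CpG islands,
spatially autocorrelated background, replicate structure, or read-level
noise.  Passing tests therefore demonstrate that the implementation recovers
planted structure under the model's own assumptions, not that the
architecture attains any particular accuracy on real chromatin data.

## Problem sizes used by the test suite and acceptance script

The reference study defaults describe the full-scale conditions
(2000 genes).  The test suite and `scripts/acceptance.py` run a
reduced-scale version chosen so several networks can be trained in one
sitting on a single CPU:

* 1000 genes, windows [-300, +100] (TSS) + [-100, +100] (TTS), `L = 600`;
* one causal window (H3K4me3, [-220, -160) from the TSS, weight 2.0) among
  three tracks; noise sized for an oracle R^2 of about 0.80;
* model with `k1 = 32`, `k2 = 64`, fully connected widths 256/128/32/1,
  dropout 0.2; Adam batches of 25, at most 50 epochs, patience 10.

At this scale dropout 0.5 (the full-scale default) leaves too few effective
samples and steps to escape the mean predictor, so the reduced study uses
0.2; the full-scale defaults in `ModelConfig`/`TrainSpec` are unchanged.
Typical reduced-scale results: test R^2 around 0.7 against the 0.80 oracle
ceiling, shuffled-target control within ±0.05 of zero.

## Known limitations

* The completeness identity holds only in the quadrature limit.  Along the
  zero-baseline path the integrand of a trained conv/batch-norm/max-pool
  network is a step function with O(1) jumps at ReLU and pooling switches,
  so the residual at 200 points has an absolute floor around 1e-3 (it decays
  as 1/steps; the acceptance script reports the measured worst case).  For
  genes whose prediction sits close to the baseline prediction the residual
  can therefore exceed 1% of `F(x) - F(x')`.
* Per-gene attribution maps of a small-data model are noisy: with a few
  hundred training genes the kernels' weights on uninformative tracks do not
  decay, so an uninformative track's attribution has amplitude comparable to
  the causal track's and its per-gene argmax concentrates wherever the model
  is sensitive.  Gene-averaged profiles and the mean-difference differential
  statistic are the robust summaries; single-gene top windows are not.
* Only cis windows around the TSS/TTS are modeled; distal enhancers are out
  of scope, as is any recurrent or attention-based variant.
* The annotation input is a flat per-gene table; choosing the TSS/TTS for
  multi-isoform genes is the caller's responsibility.
* bigWig inputs are not parsed; tracks arrive as bedGraph (gzip accepted).
* Attribution is Integrated Gradients only; no SHAP or other explainers.
* The hyperparameter grid (kernels 16–128, kernel lengths 20/50/100, lambda
  1e-4–1, dropout 0.1–0.5) is exposed as configuration
  (`training.HYPERPARAMETER_GRID`); running the full grid is a user
  decision, not part of the test suite.
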