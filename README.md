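# chromexpr

Predict per-gene mRNA abundance from epigenetic signal tracks and DNA
sequence, and localize *which modification, at which base,* most influences
the prediction.

`chromexpr` is aimed at regulatory genomics analyses where a handful of
chromatin profiles (histone-mark ChIP-seq, DNase accessibility, WGBS
methylation) and one matched RNA-seq expression table exist for a condition,
and the question is how those profiles relate to expression — not just how
well expression can be predicted.  It provides:

* **A two-branch convolutional regression network.**  Each gene is one
  sample: an `L x m` matrix of m signal tracks over fixed windows around the
  TSS ([-1000, +500] bp) and TTS ([-500, +500] bp), plus the `L x 4` one-hot
  DNA sequence of the same windows.  Two convolutional branches (kernels
  spanning `l = 20` positions times all channels; 64 then 128 kernels; batch
  norm, ReLU, max-pooling) reduce both modalities to aligned `L/20 x 128`
  representations, which a fusion convolution combines position-by-position
  before four dense layers emit the predicted expression (TPM, `log1p`
  scale by default).  Training: Adam on `MSE + lambda ||W||^2`, 60/20/20
  gene split, early stopping on validation loss.  The network, including
  backpropagation to its inputs, is implemented directly in NumPy — no deep
  learning framework required.
* **Integrated-Gradients attribution.**  For a trained model F and baseline
  x', each input cell receives
  `attr_j = (x_j - x'_j) * \int_0^1 dF/dx_j(x' + a(x - x')) da`
  (200-step quadrature), giving per-gene, per-base, per-track attribution
  maps; the completeness residual is reported with every map.  Downstream:
  mean attribution profiles, ±50 bp top-attribution windows, differential
  attribution between conditions (top decile of the gene-averaged
  difference), and a permutation test
  for overlap with ChIP-seq peak signal.
* **Local enrichment statistics.**  PWM log-odds scanning of JASPAR motifs
  over attribution windows and gene-set over-representation over GMT files,
  both via one-sided Fisher's exact tests with Benjamini-Hochberg control.
* **A synthetic-study generator** that writes complete, self-consistent
  studies (FASTA, annotation, bedGraph tracks, expression, motifs, ground
  truth) with planted causal windows and motifs, so the entire pipeline is
  testable end to end without downloads.

## Worked example

Generate a synthetic study (1000 genes, three tracks, one causal H3K4me3
window upstream of the TSS, oracle R² ≈ 0.80), assemble inputs, train, and
attribute — all from the shell (`synth.yaml` contains the single
line `n_genes: 1000`, every other study condition being a documented
default; `subset.txt` lists gene ids to attribute, one per line):

```
chromexpr simulate --config synth.yaml --out study/ --seed 7
chromexpr prepare --fasta study/genome.fa --annotation study/genes.tsv \
    --track H3K4me3:pvalue:study/H3K4me3.bedGraph \
    --track H3K27me3:pvalue:study/H3K27me3.bedGraph \
    --track WGBS:methylation:study/WGBS.bedGraph \
    --tss-up 300 --tss-down 100 --tts-up 100 --tts-down 100 \
    --out data.npz
chromexpr train --data data.npz --out model.npz \
    --k1 32 --k2 64 --dropout 0.2 --epochs 50 --batch 25 --seed 7
chromexpr attribute --data data.npz --model model.npz \
    --genes subset.txt --steps 64 --out attr/
```

The simulate step prints `oracle R^2 = 0.803` — the analytic ceiling set by
the planted noise level — and the train step prints, for the held-out 20%
of genes,

```
test R^2 = 0.5886  Pearson = 0.7799
```

meaning the network recovers most of the learnable variance in
`log1p(TPM)` (a few minutes of single-CPU training; the exact value moves
with the seed).  `attr/top_windows.bed` then holds, per listed gene and track, the ±50 bp
window around the attribution maximum in genomic coordinates, e.g.

```
chr1    113     214     g00000|H3K4me3  0.0245634       +
```

On this study the planted-motif enrichment of the causal windows
(`chromexpr enrich`, Fisher + BH) reaches an adjusted p below 1e-20 while
ten random decoy motifs stay non-significant (these are the quantities
`planted_motif_p_adj` and `n_decoys_significant` in the acceptance output).

The same operations are available as a library (`chromexpr.synthetic`,
`.preprocess`, `.model`, `.training`, `.attribution`, `.enrichment`); the
test suite and `scripts/acceptance.py` are written against that API.

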