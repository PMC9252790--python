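# varbind

**varbind** predicts whether and to what degree a DNA variant weakens or
strengthens transcription factor (TF) binding. Most disease-relevant
non-coding variants act by disturbing TF binding sites in promoters and
enhancers; varbind scores a variant against classical **position weight
matrices (PWMs)** and against **transcription factor flexible models
(TFFMs)** — hidden Markov motif models whose emissions depend on the
previous base and therefore capture adjacent-position dependencies — and
reports one signed score per transcription factor.

It is a library first (with a small `varbind` command-line tool on top),
aimed at people annotating regulatory variants from sequencing studies or
probing individual promoter variants.

## The score

For every motif model, the engine evaluates a sliding window whose start
runs from −15 to +15 nt around the variant, on both strands, in the
reference sequence and in the variant sequence. The best normalized window
scores *WT*, *MT* ∈ [0, 1] are combined into a joint score

```
S = 2 / (1 + 2^(−2F)) − 1

F = −(1 − MT + α)/(1 − WT + α) + 1    if WT > MT
F =  (1 − WT + α)/(1 − MT + α) − 1    if WT ≤ MT
```

with pseudocount α = 0.1. S runs from −1 (likely binding-site loss) to +1
(likely gain) and is exactly 0 when nothing changes. Per transcription
factor the joint scores of the available models are averaged; when a
factor has both TFFMs and PWMs, only the TFFMs enter the combined
prediction by default.

Window scores are model-specific:

* **PWM** — min/max-normalized log2-odds: the consensus scores exactly 1,
  the anti-consensus exactly 0. PWMs are derived from position count
  matrices with a background-weighted pseudocount (default √N per column)
  against the human genomic base composition (~41% GC) by default.
* **TFFM** — the forward–backward posterior probability that the window is
  a complete motif occurrence rather than background, naturally in [0, 1].
  Both first-order TFFMs and their "detailed" per-nucleotide decomposition
  are supported, and the decomposition provably preserves all sequence
  likelihoods.

## Worked example

```bash
python examples/01_score_single_variant.py
```

builds a deterministic synthetic genome with a planted binding site for
factor TF00, destroys the site's most informative position with the SNV
`chrS:113T>C`, and prints:

```
TF      combined S  models   (negative = predicted loss)
TF00       -0.9214  2
TF01        0.0000  1
...
per-model detail for the disrupted factor:
  VB000.pcm      PWM            WT=1.0000 MT=0.8920 S=-0.6344
  VB000.tffm     TFFM_first     WT=0.9330 MT=0.5478 S=-0.9214
```

The reference sequence contains the perfect site (PWM WT = 1.0); the
variant sequence scores markedly lower, so every model reports S < 0 — a
predicted loss of TF00 binding — while the unrelated factors stay at 0.
The combined score (−0.92) averages the two TFFM joint scores.

Other examples: `02_pwm_vs_tffm.py` (model families side by side,
information content), `03_vcf_pipeline.py` (VCF + known-site annotation +
model filters + TSV report), `04_joint_score_curve.py` (the S formula's
range).

## Command line

```bash
varbind single 1:160001799G>C --genome hg.fa --models models/ --out res
varbind single --wt-seq GGCCCTC... --mt-seq GGCCGTC... --models models/
varbind multi variants.txt --genome hg.fa --models models/
varbind vcf sample.vcf --genome hg.fa --models models/ \
    --genes GATA1 --gene-table genes.tsv --max-af 0.01 --known-tfbs-only \
    --known-sites encode.bed
varbind demo --outdir demo --seed 0     # self-contained end-to-end run
```

Inputs: variants as chromosomal notation, explicit sequence pairs, or
VCF 4.x (up to 10 000 variants; multi-allelic records are split); motif
models as JASPAR PFM text, a documented JSON dialect, or GHMM-style TFFM
XML; known binding sites as BED4 (TF name in column 4); genes as BED or
TSV. Variant filters cover genomic regions, candidate-gene vicinity,
depth, homozygosity and allele frequency (from a user-supplied INFO
field); model filters cover kind, source, TF list, and known-TFBS overlap.

### Report format

`<out>.tsv` has one row per (variant, factor), sorted by input variant
order and then decreasing |combined_S|:

```
variant chrom pos ref alt tf_name combined_S category n_models_used
tffm_only known_tfbs known_sources
```

`<out>.models.tsv` holds the per-model WT/MT/S triplets with best-window
offsets and strands; `<out>.summary.tsv` logs the scan settings and filter
counts. `category` bins |S| at 0.2 / 0.5 / 0.8 into weak / moderate /
strong loss or gain — cosmetic only, the raw S is always present.

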