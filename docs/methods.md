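# Methods

## Scope and model

varbind scores the *local, sequence-level* effect of a short DNA variant
(SNV or small indel) on transcription factor binding. It deliberately
ignores chromatin state, expression context and anything else beyond the
primary sequence; predictions are statements about motif match quality,
not occupancy.

Two motif model families are supported.

**PWMs.** A position count matrix (PCM; 4×L non-negative reals) is
converted to a log2-odds weight matrix

    w[b,i] = log2( ((c[b,i] + k·q[b]) / (N_i + k)) / q[b] )

where `q` is the genomic background, `N_i` the column total and `k` a
background-weighted pseudocount, by default `√N_i` per column (a constant
override is accepted; `k = 0` requires strictly positive counts). A window
is scored as `(raw − min)/(max − min)` with the column-wise score extrema
cached, so the consensus scores exactly 1 and the anti-consensus exactly
0; a constant-score (all-columns-degenerate) matrix returns 0.5 by
convention rather than dividing by zero. Per-column information content is
`2 + Σ_b p log2 p` bits, 0 (uniform) to 2 (invariant).

**TFFMs.** A first-order TFFM has one background state and L motif-chain
states; every state emits a base with probabilities conditional on the
*previously emitted* base (position 1 conditions on the last background
base; the very first sequence position uses the background marginal). The
background state self-loops with probability `p_self` and enters the motif
with `p_entry`; the motif chain is deterministic and returns to the
background after position L. `p_self + p_entry` may be < 1, the remainder
being implicit termination mass. The *detailed* flavour decomposes every
state into four per-nucleotide states whose transition probabilities carry
the first-order emissions; the decomposition preserves the likelihood of
every sequence (tested to 1e-9), and background rows of its transition
matrix inherit any termination mass rather than being renormalized —
renormalizing would break exactly that equivalence.

Because emissions condition on the previous *observed* symbol, the
emission term at each position is a known scalar per state and standard
forward–backward machinery applies. Posteriors are computed with
per-position scaling factors; `tffm_posterior_scores` returns, for each
position, the posterior probability that a motif occurrence *ends* there
given the whole sequence. One modelling choice deserves emphasis: the
chain is conditioned on ending in the background state or exactly at the
final motif position. A binding site truncated by the sequence end is not
a binding site, so paths that stop mid-motif are excluded from the
normalization. The brute-force oracle in the test suite enumerates valid
hidden-state paths explicitly and agrees to 1e-9.

**Per-window TFFM score.** For scanning, the score of a window starting at
`s` is the complete-occurrence posterior computed on the *local*
subsequence (one context base plus the window). Under the
end-conditioning above only two state paths exist on that subsequence —
all-background, and background-then-full-motif — so the posterior reduces
to `M/(M+B)`, a closed form over emission products that the scanner
vectorizes across all window starts. Two properties motivated local
rather than whole-sequence posteriors as the *window* score (the
whole-sequence posterior profile remains available as its own function):
the score of a window then depends only on its own bases, so (i) a base
change outside every scorable window provably leaves every model's S at
exactly 0, and (ii) at dependency strength 0 the TFFM ranks all windows
exactly as the equivalent log-odds PWM does. A whole-sequence posterior
has a global normalization and satisfies neither exactly.

**Ambiguity codes.** An `N` (or any unrecognized symbol) at an emitting
position contributes the uniform probability 0.25 (PWMs: the
background-expected column weight); an `N` as conditioning base averages
the conditional rows under the background marginal. Windows containing
`N` are therefore scored, not discarded.

## Scanning and the joint score

Window *starts* from −15 to +15 nt relative to the variant's first base
are evaluated (2·15+1 positions per strand), in the reference and in the
variant sequence, each in its own coordinate frame anchored at the
variant start — well-defined for indels as well. Windows extending past
the sequence ends are skipped. Both strands are scored; a minus-strand
window is the reverse complement read at the same genomic start. Ties
between equal window scores resolve to the smallest |offset|, then the
smaller signed offset, then the forward strand, so outputs are
deterministic. Deletions longer than twice the window halfwidth (30 nt at
defaults) would abolish any completely-contained site and are rejected
per variant with an explanatory error.

The best scores WT and MT feed the signed joint score

    S = 2/(1 + 2^(−2F)) − 1,
    F = −(1−MT+α)/(1−WT+α) + 1  if WT > MT,   (1−WT+α)/(1−MT+α) − 1  otherwise

with α = 0.1. S is antisymmetric in (WT, MT), exactly 0 on the diagonal,
strictly inside (−1, 1) (|F| ≤ 1/α), and monotone in MT at fixed WT — all
verified on a 1001×1001 grid. Inverted scores (1−WT, 1−MT) enter the
ratio because model scores correlate with whether binding is possible at
all and the ratio is most sensitive near the top of the range.

Per transcription factor, the joint scores of the selected models are
averaged. If both TFFMs and PWMs exist for a factor, only TFFMs enter the
combined score by default (PWM-only factors fall back to their PWMs); a
factor with no selected models after filtering is omitted rather than
reported as 0. Display categories bin |S| at 0.2/0.5/0.8 into
weak/moderate/strong loss or gain; raw S is always emitted.

Sequence extraction around a variant covers
`[pos − 15 − (Lmax−1), pos + |ref| − 1 + 15 + (Lmax−1)]` (clipped at
chromosome ends), so every window in range is fully scorable for the
longest selected model. Coordinates are 1-based inclusive at all external
interfaces (chromosomal notation, VCF) and 0-based half-open internally
and in BED; the conversions live in the I/O layer only.

## Synthetic data generator

The generator produces everything the engine consumes, from one explicit
seed per call (no global random state): count matrices with a Dirichlet-
style column model around a random consensus (`concentration` steers
information content from ~0 to 2 bits), first-order TFFMs with a
`dependency_strength` dial (0 = all conditional rows identical, i.e. a
PWM in HMM form; 1 = maximally different rows), background genomes at the
default genomic composition with planted consensus occurrences on both
strands, near-consensus sites (one worst-base mismatch at the most
informative column), engineered neutral zones, and a VCF of
loss/gain/neutral variants with an expected-direction table.

Generator TFFMs use `p_self = 0.999`, `p_entry = 0.001`: roughly one
binding site per kilobase of background, the rarity regime real genomes
operate in. This matters beyond realism — with a high entry probability
the complete-site posterior saturates near 1 for strong and slightly
damaged sites alike, compressing the dynamic range that separates a
disrupted factor from decoy factors.

Neutral variants are engineered, not merely "far from sites": the SNV
sits in a 2-bp-period tandem repeat whose equivalent repeat phase 14 nt
downstream already carries the alternate allele. Within the ±15 start
range, every window string (including one context base, both strands)
readable in the mutated sequence is also readable in the reference
shifted by 14 nt, and vice versa; the multisets of scored strings
coincide, so every model's best-window maxima tie exactly and S = 0 — a
repeat-mediated "the allele already exists nearby" scenario. The
construction is valid for motifs up to 12 nt, which caps the generator's
motif length range.

What the generator does *not* emulate: realistic motif-information
profiles, overlapping or clustered sites, genomic repeat structure beyond
the engineered zones, ChIP-seq peak-length distributions (known-site
fixtures use a flat few-hundred-bp pad), sequencing artefacts. Passing
tests therefore demonstrate the correctness of the scoring machinery and
the recoverability of planted effects under clean conditions, not
real-genome accuracy.

Fixture sizes used by the test suite (chosen for coverage at interactive
runtimes): 5 factors with 6–10-bp motifs on a 6-kb genome for the
sign-recovery study (100 replicates, ~9 variants each), 21 factors for
the decoy-ranking study (100 replicates). The acceptance script's grid is
the full 1001×1001; its window-reach probe plants a 10-mer consensus at
offsets 0–20.

## Numerical and interface choices

* Forward–backward uses per-position scaling; window scores use the exact
  two-path closed form, pinned to the scaled forward–backward posterior
  of the local subsequence by a dedicated consistency test (1e-12).
* Vectorized PWM scoring reduces per-window column weights with the same
  pairwise summation as the cached extrema, so consensus windows score
  *bitwise* 1.0.
* The default background is A=T=0.295, C=G=0.205 (~41% GC, human-like),
  configurable everywhere a background enters.
* VCF records are expanded bi-allelically; symbolic/structural ALTs are
  skipped with a warning; more than 10 000 variants (configurable) is a
  hard error. Depth is taken from INFO/FORMAT `DP`, genotype from `GT`,
  allele frequency from a user-supplied INFO key (default `AF`) — there is
  no bundled population database, deliberately. A variant lacking AF under
  an active rarity filter is kept and flagged, never silently dropped.
* Candidate-gene vicinity defaults to 5 kb upstream / 1 kb downstream of
  the annotated span, strand-aware, symmetric override via `--flank`.
* Known-site queries convert the 1-based variant position to 0-based
  before interval lookup; a BED interval `[s, e)` therefore covers
  1-based positions `s+1 … e`.
* Model files: JASPAR PFM (via Bio.motifs), a JSON dialect that
  round-trips every model type bit-faithfully, and a strict GHMM-style
  TFFM XML (states / discrete emissions / transitions; order-0 and
  order-1 emissions). Unrecognized XML content is a hard error, never a
  silent default.

## Known limitations

* Scores describe motif-match changes; they say nothing about chromatin
  accessibility, cooperative binding or expression consequences.
* Deletions longer than 30 nt are rejected (any completely-contained site
  would simply vanish; there is no meaningful window comparison).
* The ±15 start-offset window is not symmetric under reverse complement
  for motifs longer than 1 nt, so scores of variants whose best windows
  sit exactly at the range boundary can depend on the strand convention;
  interior windows are strand-invariant (tested).
* ChIP-seq-derived known-site intervals span hundreds of bases; an
  overlap flags plausibility, it does not localize the true site.
* TFFM training from ChIP-seq data is out of scope; models are imported,
  or generated synthetically for testing.
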