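# Methods

This note describes the models implemented in `cpgformer`, the synthetic
data they are evaluated on, and the numerical choices made where the
design was genuinely open.  Notation: a bulk sample is a set of sequenced
bisulfite reads r_1..r_N; each read carries the ordered methylation states
of its CpGs; δ denotes tumour purity (the fraction of reads of tumour
origin); P(c|r) is the classifier posterior for cell type c given read r.

## Read classifier

The classifier is a BERT-style Transformer encoder over three summed
per-position embeddings:

* **token** — overlapping 3-mers of the read-level reference DNA sequence
  (stride 1, so a read of L bp yields L−2 tokens; vocabulary = 64 3-mers
  plus `[PAD]`, `[UNK]`, `[MASK]`, `[CLS]`, `[SEP]`, 69 entries; 3-mers
  containing N map to `[UNK]`);
* **methylation** — 0 = unmethylated CpG, 1 = methylated CpG, 2 = non-CpG,
  attached to the token whose middle base is the called cytosine (CpGs at
  the first/last base of a read have no such token and are dropped from
  the encoding, with a log message);
* **position** — a learned absolute position table.

Each encoder block is post-norm multi-head self-attention
(softmax(QKᵀ/√d_k)V per head, concatenated heads projected by W^O)
followed by a GELU feed-forward block.  The implementation is plain
numpy with a small reverse-mode automatic-differentiation engine
(float32 by default; float64 available for verification); AdamW
(β₁ = 0.9, β₂ = 0.98, weight decay 0.01) with linear warm-up, a flat
middle and linear decay over the final steps.

**Pre-training** is a masked language model on fixed-length genome
segments, with the methylation contribution forced to zero (a reference
genome has no methylation states).  Seed tokens are selected i.i.d. at
rate 0.15; each seed draws one corruption category — 80 % `[MASK]`, 10 %
random 3-mer, 10 % unchanged — applied to the seed *and* its immediate
left/right neighbours, all of which enter the cross-entropy loss.
Masking neighbours together prevents the model from reading a masked
3-mer directly off its two overlapping neighbours.  Next-sentence
prediction is not used (reads are unpaired molecules).

**Fine-tuning** trains cell-type classification with softmax
cross-entropy on the read label (or, for many-class deconvolution with
imbalanced corresponding/non-corresponding reads, the focal loss
−α(1−p)^γ log p for the read's own class and −(1−α)p^γ log(1−p)
otherwise, p = sigmoid of the per-class activation, defaults γ = 2,
α = 0.1).  The encoder output (L × hidden) is concatenated with a
learned per-region channel — the region index is embedded into a vector
of length L, one scalar per position, with a reserved row for unseen
regions — then mean-pooled over non-padding positions and passed through
a two-layer feed-forward head.  Pooling keeps the head size independent
of the sequence length.  Class priors P(c) are recorded as training-set
label frequencies.  Metrics are evaluated every 10 steps; when a
validation split exists the weights of the best validation step are
restored at the end.

Presets: the full-scale configuration (12 layers, 12 heads, hidden 768,
510-token pre-training for 120k steps with 10k warm-up/20k decay, batch
256 with 4-step gradient accumulation, lr 4e-4; 6 layers for 500 bp
reads, 4 layers at sequence length 160 for leukocyte deconvolution) is
expressible in `ModelConfig`, but the first-class desk-scale
configuration used throughout the test bench is the tiny preset:
2 layers, 2 heads, hidden 64, batch 32, a few hundred pre-training steps
on the simulator's synthetic genome and 300–600 fine-tuning steps.
Problem sizes in the benchmark suite (e.g. 100 regions × coverage 10,
or 10 regions of 100 bp for the pre-training-effect comparison) were
chosen as the smallest sizes at which the studied effects are clearly
expressed.

## Purity estimation

Bayes inversion under the assumption that every read has the same
marginal probability gives class-conditional scores
s(r,c) = P(c|r)/P(c) ∝ P(r|c).  Scores are normalised per read by their
maximum; every downstream argmax is invariant to per-read rescaling, and
normalised scores lie in (0,1], keeping the log-domain likelihood well
behaved.  The purity MLE maximises

    log L(δ) = Σ_i log[ δ·s_i(T) + (1−δ)·s_i(N) ]

by grid search with step 1e-4 over [0,1]; ties break toward the smallest
δ, and a likelihood flat across the whole grid is flagged rather than
silently returned.  Region-wise purities δ_k apply the same MLE per
region.

**Adjustment.**  When tumour reads are unevenly distributed over regions
(very high or very low purity, or regions where the classifier is
systematically wrong), the distribution of δ_k is skewed, and its
skewness G1 — the adjusted Fisher–Pearson standardised third moment
G1 = m₃√(K(K−1)) / (m₂^{3/2}(K−2)) — correlates negatively with true
purity.  The adjustment finds a mapping W with W_kδ_k ∈ [0,1] that
minimises the skewness of the mapped purities and reports their mean
(1/K)Ŵᵀδ (unweighted: the per-region likelihoods already pool each
region's reads).  Minimising |G1| by rescaling alone is under-determined:
many mappings symmetrise the distribution, and unconstrained optimisers
routinely reach |G1| ≈ 0 by deforming the purities wildly (e.g. scaling
low-purity regions up by large factors), which makes the adjusted
estimate *worse*.  We therefore minimise G1² plus a small
minimal-deformation penalty, 0.1 · mean((W_kδ_k − δ_k)²), with
box-constrained L-BFGS-B started at the identity W = 1.  The penalty
selects, among the near-symmetrising mappings, the one closest to the
identity; the attained |G1| never exceeds the initial value because the
identity is feasible.  All-equal δ_k (skewness undefined) return the
identity mapping.

**Precision.**  The Fisher information is reported as the variance over
reads of the per-read score

    s_i = (s_i(T) − s_i(N)) / (δ·s_i(T) + (1−δ)·s_i(N)),

i.e. the variance of the derivative of the per-read log-likelihood
(sample variance, ddof = 1).  With adjustment enabled it is reported per
region at δ_k (clamped one grid step inside (0,1)); otherwise a single
value at the global MLE.  Higher Fisher information indicates a more
precise estimate; across region sets it anti-correlates with the
absolute purity error.

**Many cell types.**  Reads are grouped by predicted class R_c; with
P(r|c) the inverted score re-normalised per read to sum to one over
classes, θ_c maximises Π_{r∈R_c}[θ_c P(r|c) + (1−θ_c)(1−P(r|c))] on the
grid.  Under a confident classifier every θ_c tends to 1, so raw θ
cannot be the composition; the reported fraction is
fraction_c ∝ θ_c·|R_c|, normalised to sum to one, which reduces to the
read-count fraction in the certainty limit (matching the two-class
behaviour of the purity likelihood).  Classes with no classified reads
get fraction 0.

**Reconstructed methylation.**  For each (region, predicted class) the
mean over assigned reads of the per-read methylated-CpG fraction; a
class absent from a region is missing, not zero.

## HMM baseline

One two-state categorical HMM per cell type over the ordered CpG states
of a read (observations {unmethylated, methylated}; hidden states
{differentially methylated, not}; inter-CpG distances ignored), fitted by
Baum–Welch (hmmlearn) with 5 seeded random restarts, best training
likelihood kept.  A read is assigned to the cell type with the larger
forward-algorithm log-likelihood; exact ties go to the normal class.
Log-likelihoods are converted to pseudo-posteriors by normalised
exponentiation so the purity estimator consumes either classifier.

## Read-level methylome simulator

Per region i a tumour mean methylation d_i ~ Beta(α, β) is drawn
(β = 5; α ∈ {0.1, 1, 2, 3} forms the complexity series a0_b5..a3_b5 —
larger α pushes d_i toward 1−d_i and shrinks the tumour/normal contrast).
Region-level scenario: each CpG on a tumour read is methylated
independently with probability d_i, on a normal read with 1−d_i.
CpG-specific scenario: tumour reads use d_i at odd-indexed CpGs (1-based
within the region) and 1−d_i at even-indexed ones; normal reads use the
opposite phase, so region means coincide while per-CpG patterns
anti-correlate.

Regions are laid on one synthetic chromosome: 500 bp CpG-dense regions
(CpGs every ~10 bp with irregular, uniformly jittered gaps, as in real
CpG islands — the irregular spacing is also the sequence cue that lets a
sequence-aware model identify individual sites) separated by 600 bp
flanks with sparse background CpGs methylated at level 0.5 in both cell
types.  The remaining sequence is random but contains no accidental CG,
so the planted CpGs are exactly the genomic CpGs and XM-tag round trips
are exact.  Read starts are uniform over the valid windows: inside the
region when the read is shorter than the region, covering the whole
region (overhanging into flanks, where reads see background CpGs) when
longer — the 500 bp setting.  Pseudo-bulk mixing draws exactly
round(n·f) tumour reads without replacement and records the truth.
Everything is deterministic under the configured seed.

What the simulator does **not** model: sequencing errors, bisulfite
non-conversion, fragment-length variation, strand asymmetries, copy
number, and real genomic sequence composition.  Tests passing on this
generator show that the pipeline recovers the stated generative
structure; they do not certify performance on real WGBS data.

Synthetic-benchmark generators used by the estimation suite simulate
posteriors directly: per read a tumour probability q ~ Beta(f·k, (1−f)·k)
with the true label Bernoulli(q), so posteriors are calibrated by
construction; k (sharpness) controls informativeness and plays the role
of region separability in the precision sweep.  The miscalibrated
variant makes a minority (10 %) of regions report near-certain tumour
posteriors regardless of truth — the confidently-wrong-outlier failure
mode the skewness adjustment targets (a *flattened*-posterior bias was
also examined, but it barely moves the pooled MLE, which makes any
region-wise adjustment counterproductive; confident errors are the
regime where adjustment can help).

## Numerical choices and degenerate inputs

* Grid step 1e-4 (coarser grids are accepted where the tolerance allows;
  the benchmark workflows use 1e-3).
* Coordinates are 0-based half-open everywhere in memory; BED read
  as-is; BAM through pysam.
* Only the XM tag is trusted for methylation calls; no re-calling from
  the read sequence.
* A read overlapping several regions is assigned to the largest overlap,
  ties to the lower start.
* Zero-score reads are dropped from the likelihood with a warning;
  zero-CpG reads are unclassifiable for the HMM (uniform
  pseudo-posterior) and carry no methylation signal for SEM or
  reconstruction.
* Skewness requires K ≥ 3 and non-zero variance; the adjustment treats a
  near-constant mapped sample (m₂ < 1e-24) as symmetric.
* Fine-tuning uses warm-up over the first 10 % of steps and no final
  decay (the schedule's decay phase is a pre-training-scale feature).
* GELU uses the tanh approximation.

## Known limitations

* The numpy training loop is single-process and CPU-bound; the
  full-scale presets are expressible but not practical to run in it.
* The region embedding wiring (one scalar channel per position from a
  length-L embedding of the region index) is the most literal reading of
  an under-specified design; alternatives (e.g. a hidden-width region
  embedding added to the pooled vector) would also be defensible.
* The fine-tuning input uses the reference sequence under the read's
  coordinates (the simulator's reads are error-free, so observed and
  reference sequences coincide); an observed-sequence mode is the
  `MethylRead.sequence` the caller provides.
* Focal-loss deconvolution of many cell types is implemented and
  unit-tested but not exercised end-to-end at realistic scale.
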