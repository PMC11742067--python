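# cpgformer

Read-level DNA-methylation pattern classification and tumour
deconvolution with a Transformer encoder — in pure numpy.

Bulk bisulfite-sequencing samples are mixtures of molecules from
different cell populations. Because every sequenced read preserves the
joint methylation states of its CpGs, read-level analysis can recover
rare cell-type signals that average (beta-value) methods wash out —
the regime that matters for tumour-purity estimation and circulating
tumour DNA (ctDNA) diagnostics, where the tumour fraction is often
below 5 %. `cpgformer` is for computational (epi)genomics researchers
who want a sequencing-native deconvolution stack they can train,
inspect and extend on a single CPU.

## What it does

1. **Read classification.** A BERT-style encoder embeds each read as a
   sum of 3-mer token, CpG-methylation (0/1/2) and position embeddings,
   and classifies it into cell types (tumour *T* vs normal *N*, or C
   leukocyte types with a focal loss). The encoder is pre-trained as a
   masked language model on genome segments (15 % seed tokens, 80/10/10
   corruption, neighbours masked together) and fine-tuned on labelled
   reads with a per-region embedding channel.
2. **Purity estimation.** Classifier posteriors P(c|r) are inverted via
   Bayes' rule (equal read marginals) and the tumour purity δ maximises
   the single-parameter mixture likelihood

   L(δ) = ∏ᵢ [ δ·P(rᵢ|T) + (1−δ)·P(rᵢ|N) ]

   by grid search (step 1e-4). Region-wise purities δ_k feed an
   adjustment that remaps them to minimise the Fisher–Pearson skewness
   G1 before averaging, and the Fisher information
   FI(δ) = Var[∂/∂δ log L(δ)] is reported as estimation precision.
3. **Simulation.** A read-level methylome simulator (per-region
   d_i ~ Beta(α, β=5); per-CpG Bernoulli states; region-level and
   CpG-specific scenarios; pseudo-bulk mixing at controlled fractions)
   generates fully labelled data, writes XM-tagged BAM/SAM or TSV, and
   is the test bed for everything above.
4. **Baseline.** A two-state HMM read classifier with the same
   posterior-table interface.

Everything runs on one CPU: the Transformer, its autograd and AdamW are
implemented in numpy inside the package. See `docs/methods.md` for the
model details and numerical choices.

## Worked example

Train a tiny classifier on simulated reads (pattern complexity a1_b5),
then deconvolve a 30 %-tumour pseudo-bulk of held-out reads:

```python
import numpy as np
from cpgformer import (MethylomeSimulator, SimConfig, TransformerReadClassifier,
                       PurityEstimator, mix_pseudobulk)
from cpgformer.pipelines import pretrain_segments_from_simulator

sim = MethylomeSimulator(SimConfig(alpha=1.0, n_regions=30, coverage=20, seed=0))
pools = sim.simulate()
train = [r for ct in pools for i, r in enumerate(pools[ct]) if i % 2 == 0]
held = {ct: [r for i, r in enumerate(pools[ct]) if i % 2 == 1] for ct in pools}

clf = TransformerReadClassifier(pretrain_steps=300, finetune_steps=600,
                                random_state=0)
clf.pretrain(pretrain_segments_from_simulator(sim, 150))
clf.fit(train, [r.cell_label for r in train])

bulk, truth = mix_pseudobulk(held["Tumour"], held["Normal"], 0.30, 400,
                             np.random.default_rng(1))
est = PurityEstimator(adjust=True).fit(clf.posterior_table(bulk))
```

Output (about five minutes on one CPU):

```
validation accuracy: 0.925
true tumour fraction: 0.300
estimated purity:     0.2793
adjusted estimate:    0.2763
skewness of region purities: +0.44 -> +0.00
mean Fisher information over 30 regions: 5.20
```

The classifier separates reads at 92.5 % held-out accuracy; the mixture
MLE lands within ~0.02 of the true 30 % tumour content; the adjustment
symmetrises the region-wise purities (G1 from +0.44 to 0); and the
per-region Fisher information quantifies how much each region's reads
constrain δ (higher = more precise).

A thin CLI wraps the same steps:

```bash
cpgformer simulate --alpha 0.1 --coverage 10 --seed 7 --out reads.tsv
cpgformer finetune --reads reads.tsv --posteriors-out post.tsv
cpgformer estimate --posteriors post.tsv --adjust
```

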