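# attune

Cross-modal contrastive integration of paired single-cell multiome data
(scRNA-seq + scATAC-seq measured in the same cells), with three
downstream analyses built on the shared embedding:

1. **Integration** — asymmetric teacher–student encoder pairs embed each
   modality onto a common hypersphere by maximizing the agreement of
   paired cells under an NT-Xent contrastive objective.
2. **Gene–peak regulatory linkage** — a cross-attention transformer
   decoder, fine-tuned on the pretrained encoders with a genomic-distance
   mask (1.2 Mb around each TSS), scores every candidate gene–peak pair
   via the product of its CLS attention rows.
3. **Chromatin potential** — an MLP head predicts expression from the
   ATAC embedding; the residual (predicted − measured expression) along
   pseudotime exposes genes whose chromatin opens before transcription
   starts, a signature of lineage priming.

The package is aimed at computational biologists studying gene
regulation during differentiation who have paired multiome counts, peak
intervals, and gene annotations, and want a single reproducible pipeline
from raw counts to integration metrics, ranked regulatory pairs, and
lag-gene calls. All models run on one CPU; a synthetic-data module
generates realistic paired datasets with planted ground truth for
validation at desk scale.

## The model

For a mini-batch of N paired cells, each modality is encoded twice: a
*teacher* embeds every nonzero feature token as count·E[f] (E a learned
embedding table), aggregates tokens with tanh-MLP/context-vector
attention, and projects through batchnorm → dropout → ReLU dense to
z ∈ R^d (d = 128); a *student* is a plain batchnorm → dropout → ReLU
dense map of the count vector. With s(u, v) = uᵀv / (τ‖u‖‖v‖) and the 2N
in-batch points interleaved (2i ↔ RNA view, 2i+1 ↔ ATAC view of cell i),
the loss for an ordered positive pair (m, m⁺) is

    ℓ(m, m⁺) = −log exp(s_{m,m⁺}) / Σ_{k≠m} [exp(s_{k,m}) + exp(s_{k,m⁺})]

averaged over both orders and all pairs; the pretraining objective is
the mean of the teacher-pair and student-pair losses (τ = 0.1, Adam,
20 epochs, batch 32, lr 10⁻⁴ → 10⁻⁶). The decoder prepends a CLS token
to each modality's token sequence, applies self-attention, then
cross-attention between modalities, masked additively for pairs with
|TSS − peak midpoint| > 1.2 Mb or on different chromosomes; training
combines an NT-Xent loss on the two cross-attention CLS outputs with a
binary matched/mismatched-pair classification loss. The global gene–peak
score matrix is (CLS-attention over genes)ᵀ · (CLS-attention over peaks)
contracted over cells.

## Worked example

```python
import numpy as np
from attune import (generate_multiome, preprocess, ContrastiveConfig,
                    train_pretrain, compute_embeddings, EncoderParams,
                    DecoderConfig, train_decoder, compute_global_attention,
                    foscttm, silhouette_scores)
from sklearn.metrics import roc_auc_score

dataset, truth = generate_multiome(seed=0)   # 600 cells, 300 genes, 600 peaks
proc = preprocess(dataset)

params, history = train_pretrain(proc, ContrastiveConfig(epochs=20, seed=0))
emb = compute_embeddings(params, proc)
random = compute_embeddings(
    EncoderParams.init(len(proc.genes), len(proc.peaks), seed=0), proc)

print(foscttm(random.Z_teacher_RNA, random.Z_teacher_ATAC))   # 0.4966
print(foscttm(emb.Z_teacher_RNA, emb.Z_teacher_ATAC))         # 0.1509

dec, _ = train_decoder(params, proc, DecoderConfig(seed=0))
attn = compute_global_attention(params, dec, proc)
pairs = attn.to_pairs()
labels = np.array([(g, p) in truth.linked_pairs
                   for g, p in zip(pairs.gene_id, pairs.peak_id)])
print(roc_auc_score(labels, pairs.weight))                    # 0.7663
```

FOSCTTM (fraction of other-modality cells closer than the true match;
lower is better) drops from chance (≈0.50) to 0.15 after pretraining:
a cell's ATAC profile now lands next to its own RNA profile in the
shared space. The AUROC of 0.77 says the decoder's global attention
ranks the planted regulatory gene–peak pairs well above the unlinked
same-locus decoys.

The same pipeline is available from the shell:

```bash
attune run --seed 0 --out runs/demo \
    --stages simulate,preprocess,pretrain,embed,interact,predict,evaluate
cat runs/demo/report.json
```

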