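# smtrace

A self-contained toolkit for single-molecule fluorescence time-trace
analysis:

- **`smtrace.simulate`** — a ground-truth-labeled stochastic simulator of
  one- and two-color intensity traces (Markov state paths, photobleaching,
  donor blinking, acceptor brightness, Gaussian noise with controlled SNR).
- **`smtrace.model`** — a patch-tokenized multi-head self-attention encoder
  (pure NumPy, hand-written forward/backward) producing one trace-level
  embedding and per-frame embeddings, plus linear softmax task heads.
- **`smtrace.training`** — a 30-head multitask pre-training loop: quantized
  labels, task-balanced mini-batches, summed cross-entropy loss, Adam.
- **`smtrace.finetune`** — frozen-encoder logistic-regression heads for
  downstream tasks, and the derived analyses: trace classification and
  segmentation, idealization, dwell-time/rate-constant fitting,
  photobleach step counting, kinetic fingerprinting.
- **`smtrace.metrics`** — exact k-NN plus the label Self-Consistency Score
  (SCS, default k=1) and per-trace Local Shannon Entropy (LSE, default
  k=50) with lowest-entropy subset selection.
- **`smtrace.projection`** — low-rank principal-projection operators from
  concatenated task-head weights (SVD, 95% squared-singular-energy rule),
  operator alignment, and attribute contributions of a classifier head.
- **`smtrace.atlas`** — the 22-category smFRET atlas: nomenclature
  enumeration, threshold categorization, balanced corpus generation, a
  fitted global 2-D reducer (UMAP, PCA fallback) and 4-component GMM
  contour annotation at density 1e-2.
- **`smtrace.io`** — HDF5 trace container, per-trace CSV import, projector
  TSV/JSON export, and run configuration with reproducibility hashes.

## CLI

```bash
smtrace simulate --n 1000 --seed 0 --frames 2000 --out traces.h5
smtrace pretrain --container traces.h5 --steps 1000 --seed 0 --out run/
smtrace embed --container traces.h5 --weights run/encoder.h5 --out emb.tsv
smtrace metrics scs --embeddings emb.tsv --labels labels.tsv --k 1 --out scs.json
smtrace metrics lse --embeddings emb.tsv --conditions cond.tsv --k 50 \
    --lowest-fraction 0.1 --out lse.tsv
smtrace atlas categories
smtrace atlas build --weights run/encoder.h5 --per-category 50 --out atlas/
smtrace export --embeddings emb.tsv --reducer pca --out proj.tsv
```

## Notes

- Default trace length is 2000 frames (40 patches of 50 frames); traces
  whose length is not a multiple of the patch width are right-truncated
  with a warning.
- One-color traces are stored as (T, 2) arrays with the second channel
  exactly zero.
- Every stochastic entry point takes an explicit seed; identical seeds give
  bit-identical outputs.
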