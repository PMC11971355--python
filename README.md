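# plantmeth

5-methylcytosine (5mC) calling for plant genomes from nanopore-style raw
signal, in all three sequence contexts — CpG, CHG and CHH (H ∈ {A, C, T}).

Plant methylomes differ from animal ones: beyond CpG, plants methylate
CHG and, crucially, CHH sites, which are asymmetric (strand-specific) and
usually sparsely methylated. Signal-level nanopore callers struggle on
CHH because highly methylated CHH sites — the positive training examples —
are rare, so models overfit the few sequence contexts they have seen.
This package implements, end to end and fully testable at desk scale,
the training and evaluation machinery for a triple-encoder neural
classifier that addresses this:

- **Feature extraction** — per candidate cytosine, a k-mer window of read
  bases centered on the target C; per base a 5-vector (mean and standard
  deviation of its MAD-standardized signal, basecall quality, number of
  raw samples, base code) forming a k×5 matrix, plus 15 signal samples
  per base forming a k×15 matrix. Alignments are pre-filtered at
  MAPQ ≥ 20, aligned fraction ≥ 80%, identity ≥ 80%.
- **Model** — separate sequence and signal encoders (feature dimension
  128 by default), concatenated per position into a collaborative
  encoder (dimension 256), then a feedforward classifier emitting the
  methylation probability P(m). Both a bidirectional-LSTM variant and a
  BERT-like Transformer variant (with sinusoidal positional encoding
  PE(pos, 2i) = sin(pos·10000^(−2i/d)), PE(pos, 2i+1) = cos(·)) implement
  one contract. The network runs on a compact NumPy reverse-mode
  autodiff engine included in the package (`plantmeth.nn`).
- **K-mer balancing** — the strict training-set balancing algorithm:
  only k-mers present among both positives and negatives survive, and
  each contributes min(n_pos, n_neg, k_max) samples per side, so the
  positive:negative ratio is exactly 1:1 overall and per k-mer.
- **Training** — Adam (β₁ = 0.9, β₂ = 0.999), cross-entropy, learning
  rate 0.001 (Bi-LSTM) or 0.0005 (Transformer) decayed ×0.2 per epoch,
  gradient-norm clipping, dropout, early stopping on validation accuracy.
- **Calling & evaluation** — adaptive threshold P_th chosen at the
  least-occupied of 70 probability bins over [0.2, 0.9); per-site
  methylation frequency = methylated reads / total reads, strand-specific,
  with coverage gating; depth downsampling; Pearson correlation against
  BS-seq; read-level F1/accuracy/recall/precision/AUC/AP with SMOTE
  oversampling for scarce positives.
- **Synthetic data** — a seeded simulator producing a reference genome,
  per-site methylation truth, signal-bearing reads with move tables, and
  matched Bismark-style BS-seq reports, so every stage is testable
  without external data. Ground truth for real data comes from BS-seq
  cytosine reports; training positives are selected per CHH motif
  (CAA > 0.95; CAC/CAT/CTA/CTT/CTC > 0.90; CCA/CCT/CCC > 0.85;
  CHG > 0.98; CpG > 0.99), negatives at frequency 0 (CpG < 0.02).

## Worked example

Simulate a small CHH dataset (4 kb genome, 12× depth, methylation shift
δ = 3σ), extract 9-mer features, train a small Transformer model on
BS-seq-selected sites, call and aggregate:

```bash
plantmeth simulate --out-dir sim --motif CHH --genome-length 4000 \
    --depth 12 --delta 3.0 --seed 3
# wrote 48 reads, 969 BS-seq sites to sim

plantmeth extract --ref sim/reference.fasta --reads sim/reads.tsv \
    --motif CHH --kmer 9 --out features.tsv
# 48 reads kept, 0 filtered; 5650 feature records -> features.tsv
```

Label the features against the BS-seq report (library call):

```python
import plantmeth as pm
from plantmeth import io

records = io.read_feature_file("features.tsv")
truth = io.read_cytosine_report("sim/bsseq_report.tsv")
pos, neg = pm.select_reference_sites(truth, "CHH", min_coverage=5)
io.write_feature_file(pm.label_features(records, pos, neg), "labeled.tsv")
```

Train, call, aggregate, evaluate:

```bash
plantmeth train --features labeled.tsv --encoder transformer --kmer 9 \
    --seed 3 --no-balance --out model.npz
# best epoch 1, validation accuracy 0.9231 -> model.npz

plantmeth call --model model.npz --features features.tsv --out calls.tsv
plantmeth aggregate --calls calls.tsv --min-cov 10 --out sites.tsv
# P_th = 0.22; 129/954 sites quantified -> sites.tsv

plantmeth evaluate --calls calls.tsv --truth sim/bsseq_report.tsv --min-cov-each 5
# {"p_th": 0.22, "pearson_r": 0.726, "n_sites": 672}
```

The adaptive threshold P_th = 0.22 is the left endpoint of the emptiest
probability bin; `sites.tsv` is bedMethyl-like (strand-specific rows,
frequency as a percentage); the Pearson r of 0.726 is the site-level
agreement between nanopore calls and the simulated BS-seq report at this
deliberately tiny scale — at the scale the test suite uses (5,000
balanced records, 30× depth) held-out read-level accuracy exceeds 0.95
and site-level r exceeds 0.9 (see `tests/test_acceptance.py`).

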