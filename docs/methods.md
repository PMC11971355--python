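# Methods

## The detection problem

A nanopore read is a time series of current samples; a basecaller's move
table assigns each called base a contiguous span of samples. Cytosine
methylation perturbs the current not only at the methylated base but
across the neighboring bases whose pore context contains it. The caller
therefore classifies each candidate cytosine from a k-mer window (default
k = 13) of read bases centered on the target C, using both summary
statistics per base and raw sampled signal.

Contexts are CpG, CHG and CHH with precedence CpG → CHG → CHH (a
trinucleotide CG* is CpG even though it also matches C-H-H patterns
nowhere; C-H-G is CHG; the rest are CHH). CHH is asymmetric: a site
belongs to one strand, and only reads sequencing that strand observe it.
All coordinates are 0-based internally; the Bismark-style cytosine
report reader/writer and the bedMethyl-like site writer are the only
1-based/percentage surfaces.

## Feature extraction

Per read, the raw signal is standardized once by median shift and MAD
scale, x → (x − median)/MAD with the unscaled MAD; a constant signal maps
to zeros. Per base in the window, exactly 15 standardized values are
taken from the base's own segment: with ≥ 15 samples, deterministic
evenly spaced indices ⌊j·n/15⌋; with fewer, cyclic repetition. Both
rules are deterministic and order-preserving — feature extraction
contains no randomness. The k×5 sequence matrix holds, per base, the
mean and standard deviation of those 15 samples (self-consistent with
the emitted k×15 matrix; full-segment statistics differ only in the
fourth decimal at typical dwells), the basecall quality, the segment
length, and a fixed base code A=0 C=1 G=2 T=3.

The k-mer is taken from the read sequence, not the reference: a site
whose center read base is not C (a basecall or alignment mismatch) is
skipped rather than mislabeled. Site anchoring uses the alignment;
insertions contribute read bases to the window, deletions leave the site
uncovered. Minus-strand sites are processed in the read's own 5'→3'
orientation, so the window always follows the direction the molecule
traversed the pore. Alignments are pre-filtered (MAPQ ≥ 20, aligned
fraction ≥ 0.8, identity ≥ 0.8, all configurable); the coverage gate for
BS-seq site selection is inclusive (≥ 5×) and parameterized.

## Model

Three encoders: the sequence branch embeds the base identity (learned
4-symbol embedding), concatenates the four numeric columns, and projects
to `seq_dim`; the signal branch projects the 15 samples per base to
`sig_dim`; their per-position concatenation (`combine_dim` =
`seq_dim` + `sig_dim`, which is how the printed dimension arithmetic
128 + 128 = 256 type-checks) feeds the collaborative encoder; a
two-layer feedforward classifier with softmax emits P(methylated).

The Bi-LSTM variant stacks bidirectional LSTM layers (hidden size
dim/2 per direction) and takes as terminal representation the
concatenated final forward and backward hidden states of the
collaborative encoder; per-position outputs (not final states) flow
between stacked encoders, which is the only reading under which a
per-position collaborative encoding is possible. The Transformer
variant adds sinusoidal positional encoding at both branch inputs —
PE(pos, 2i) = sin(pos·10000^(−2i/d)), PE(pos, 2i+1) = cos of the same
angle — and uses BERT-style blocks (multi-head attention and
feedforward, each with residual connection and layer normalization),
taking the hidden vector at the center position. Each encoder can be
disabled (identity pass-through) for ablations; with the collaborative
encoder disabled, both variants fall back to the center-position vector.

The network runs on `plantmeth.nn`, a tape-based reverse-mode autodiff
engine over float64 numpy arrays (gradient-checked in the test suite).
Network inputs are rescaled by fixed constants (signal ×0.2, quality
/40, dwell count /20) so all inputs are near unit magnitude;
MAD-standardized signal otherwise reaches ±8 across contexts and
saturates LSTM gates at initialization. These are constants, not fitted
statistics, so featurization is identical everywhere.

Unstated details resolved as: dropout 0.2 between stacked layers
(configurable); gradient clipping at global norm 1.0; residual/layer-norm
machinery only in the Transformer variant; embeddings joined to the
numeric features by concatenation + linear projection.

## Training

Adam with β₁ = 0.9, β₂ = 0.999; cross-entropy loss; initial learning
rate 0.001 (Bi-LSTM) or 0.0005 (Transformer); "decreased by 80% per
epoch" is read as ×0.2 per epoch and exposed as `lr_decay_per_epoch`.
Early stopping monitors validation accuracy: training halts once more
than `patience` consecutive epochs fail to improve on the best. Batch
size (256) and epoch budget (20) are unstated upstream and exposed as
configuration. Per-motif-class models are separate checkpoints sharing
one architecture.

K-mer balancing: K_comm = K_pos ∩ K_neg; for each surviving k-mer,
k_count = min(KNUM_pos, KNUM_neg, k_max) samples drawn uniformly without
replacement from each side. The output ratio is exactly 1:1 overall and
per k-mer; an empty intersection yields empty outputs; deterministic
under the seed.

**Desk-scale schedule.** The ×0.2-per-epoch decay presumes epochs of
~10⁵–10⁶ optimizer steps; with a few thousand records an "epoch" is
~50–100 steps and the schedule freezes learning long before convergence.
Scaled-down runs in the tests therefore use a gentler decay (0.9/epoch)
over 6–20 epochs with batch 64 — matching the intended cumulative
learning budget, not changing the algorithm. The default configuration
keeps the original schedule.

**Held-out evaluation is site-disjoint.** Splitting at the record level
leaks site identity: all reads at a site share its k-mer context and
label, so a memorizing model scores leaked test records without
generalizing (measured: AUC ≈ 0.6 on a null dataset with no signal
effect). `split_train_test_by_site` holds out whole sites; the
stratified record-level split (`split_train_test`) is also provided for
assembling train/validation sets within a training pool.

## Calling and evaluation

Read-level: P(m) > 0.5 ⇒ methylated (exact tie → unmethylated).
Dataset-level quantification instead uses the adaptive threshold P_th:
probabilities are binned over [0.2, 0.9) into 70 intervals of 0.01;
proportions are computed relative to in-range calls (out-of-range calls,
the confident mass near 0 and 1, influence neither numerator nor
denominator — the upstream description leaves this open; exclusion keeps
occupancy profiles comparable across datasets); P_th is the left
endpoint of the least-occupied bin, ties breaking toward the smallest
endpoint (higher sensitivity, configurable). If no call lands in range
the procedure raises with instructions to fall back to P_th = 0.5.
Calls with P(m) ≥ P_th are methylated; per-site frequency is methylated
reads over total reads, strands never merged, sites under the coverage
gate (default 10×) retained but flagged unquantified.

Depth is aligned bases over genome length (not read count); downsampling
draws reads uniformly without replacement until the target is first
reached. Site-level agreement is the Pearson r over sites with nanopore
and BS-seq coverage both ≥ 5× (scipy). Read-level metrics (F1, accuracy,
recall, precision via the confusion matrix; AUC and AP via the
probability ranking — scikit-learn, cross-checked against a brute-force
pair-ordering oracle in the tests) are averaged over seeded balanced
replicates; when positives are scarce, SMOTE synthesizes minority
feature vectors as x + λ(x_nn − x), λ ~ U[0, 1], x_nn among the k
nearest minority neighbors.

## The synthetic data generator

The simulator provides the statistical structure the caller assumes,
not pore physics. Per dataset: an i.i.d. reference with configurable GC
content; a true methylation frequency per motif site drawn from a
user-specified mixture (point masses and callables); per read, a
uniform start, random strand, Gaussian length (10% CV), and per covered
site a Bernoulli(frequency) molecule state; per base, a dwell of
1 + Poisson(dwell_mean − 1) samples (guaranteeing ≥ 1) drawn
Normal(level(context) + δ·[context contains a methylated C], σ). Context
levels come from a seeded order-6 k-mer table; the shift applies to
every base whose context window contains the methylated cytosine,
reproducing the adjacency effect the k-mer features exploit. Matched
BS-seq reports draw Poisson(coverage) totals and Binomial methylated
counts at p = f(1−e) + (1−f)e for conversion error e; zero-coverage
sites are absent. Alignment is exact by default; an optional
substitution rate exercises the mismatch-skip rule. Basecall qualities
are features, not filters, drawn from a fixed high-quality distribution.

Default conditions: δ = 1.5 signal units, σ = 1.0, dwell 9, BS-seq
50× with conversion error 0.005. The k-mer level spread defaults to
1.0 = the noise floor: context effects perturb the signal at noise
order while the methylation shifts of interest (1.5–3σ) dominate any
single context's level — the regime a signal-level caller faces for
contexts absent from training. With context spread at 2σ instead, unseen
contexts mimic a 3σ shift and no classifier separates held-out sites
beyond ~0.91 accuracy (verified with gradient boosting); that regime is
reachable through the `scale` parameter but is not the default study
condition. Test mixtures keep CHH methylation sparse (≈ 15% of sites
fully methylated), consistent with the 1–17% CHH methylation reported
across angiosperms; dense methylation creates adjacency crosstalk in
which a neighbor's shift overlaps an unmethylated center.

What the simulator does **not** emulate — homopolymer-dependent basecall
error, dwell/level correlation, non-Gaussian noise, mapping ambiguity in
repeats, 5hmC as a distinct state (treated jointly with 5mC
throughout) — bounds what passing tests show: the pipeline recovers
planted signal-level effects end to end; it does not certify accuracy on
real flowcell data.

## Problem sizes and numerical choices

Test and acceptance runs use genomes of 1.5–16 kb, 10–30× depth, k = 9
windows, 24-dimensional branch encoders, and 3,000–5,000 balanced
records — sizes chosen so the full suite trains several models from
scratch on one CPU. At these sizes the Transformer variant converges
several-fold faster than the Bi-LSTM per wall-clock unit and is used in
the end-to-end recovery tests; the Bi-LSTM path is exercised by
gradient, contract, schedule and smoke tests. Read-level recovery at
δ = 3σ on site-disjoint held-out data reaches accuracy ≈ 0.986 and
AUC ≈ 0.998 (the tests assert ≥ 0.95 / ≥ 0.98); a null effect gives
AUC ≈ 0.5 ± 0.05; whole-genome frequency recovery at 30× over a 5-point
truth grid exceeds Pearson r = 0.9.

Other numerical choices: float64 throughout the network; forget-gate
bias initialized to 1; Xavier-uniform weights; checkpoint determinism
via seeded construction plus exact weight restoration; feature files
store six decimals (roundtrip-exact at that precision); native
signal-alignment files store full-precision floats (`repr`) and
roundtrip bit-exactly; the SAM dialect carries the move table as an
ONT-style stride-annotated `mv` tag and inline signal in a float tag
(~6 significant digits in text SAM).

## Known limitations

The `count_motif_kmers` enumeration is exponential in k (intended for
k ≤ 9). Real pod5 ingestion is out of scope; the SAM-with-move-tag
adapter covers basecaller-style input. The strict k-mer balancer is
data-hungry at desk scale (distinct 9-mers rarely appear in both
classes on kilobase genomes); the CLI offers `--no-balance` plain class
balancing for small runs. The per-epoch decay schedule is faithful to
its large-scale origin but must be relaxed (as above) whenever epochs
are small.
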