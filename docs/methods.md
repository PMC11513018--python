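# Methods

## Model

Two parallel masked autoencoders — one per modality — plus an attention
fusion and a pairwise KL clustering refinement.

**Corruption.** Each training pass replaces a Bernoulli-selected subset of
entries with values drawn from the same feature in other cells (a
per-feature shuffle), so corrupted entries are *plausible* values placed in
the wrong cell. The per-feature corruption probability `P_j` defaults to a
constant `mask_rate = 0.3`; an `empirical` mode instead uses each feature's
observed zero fraction (clipped to [0.05, 0.9]) as a proxy for its dropout
propensity. Corruption is resampled every epoch so the model cannot
memorise one pattern.

**Networks.** Encoder per modality: input dropout (rate 0.1) → affine
f→256 → layer norm → Mish → affine 256→64 → layer norm → affine 64→64. The
latent width (64) is fixed. The mask decoder is a single affine map with a
sigmoid, clamped to [1e−7, 1−1e−7]; the reconstruction decoder is a single
affine map over `[M′, Z]` with a linear output, since inputs are z-scored
and may be negative. The mask and reconstruction paths share the encoder
but not head parameters. No distributional likelihood (ZINB etc.) is
assumed anywhere.

**Losses.** `L_M` is mean binary cross-entropy between the sampled and
predicted masks, summed over modalities. `L_R` is mean squared error
against the *uncorrupted* preprocessed matrix, weighting corrupted entries
`w_masked = 2` versus `w_unmasked = 1` (the up-weighting follows the
masked-autoencoder convention of emphasising corrupted content; the ratio
is configurable and results are not sensitive to it at desk scale).
`L_kl = Σ_i Σ_{j≠i} p_ij log(p_ij/q_ij)` with natural logs, the Student-t
(df = 1) pairwise soft assignment `q`, and the sharpened,
popularity-discounted target `p_ij ∝ q_ij²/f_j` row-renormalised. `q_ii`
and `p_ii` are zero by construction. Note the sharpening inequality
(row max of P ≥ row max of Q) is guaranteed by squaring alone but can be
violated by the `1/f_j` factor in degenerate tiny problems (observed only
for n < ~10 cells); at realistic sizes it holds empirically.

**Training.** Adam, two phases: reconstruction pretraining (`L_M + L_R`)
for the first `kl_start_epoch` epochs (default `epochs/2`), then the full
objective with the KL target `P` refreshed every `p_update_interval = 20`
epochs and held fixed in between (the usual self-training schedule; a
pure-KL start from random embeddings collapses). Each epoch sweeps shuffled
minibatches (`batch_size = 128`) for the autoencoder losses and takes one
KL step on the full pairwise objective. One gradient step per epoch proved
insufficient in practice — with 100 full-batch steps the mask loss never
leaves the base-rate optimum — which is why epochs iterate minibatches.
For more than 10 000 cells the pairwise KL is computed on a seeded anchor
subsample (2048 cells) to bound the O(n²) cost. Named profiles carry the
published presets: `default` (100 epochs, lr 0.002), `small` (20, 0.001),
`cellline` (50, 0.001), `pbmc10k` (20, 0.002).

All randomness (initialisation, corruption, dropout, batching, K-means
restarts) derives from a single config seed; identical configs reproduce
identical histories and embeddings bitwise.

**Readout.** The final embedding encodes the *clean* preprocessed matrices
in eval mode, fuses them, and K-means (k-means++ seeding, best of 20
restarts) assigns labels. `impute()` likewise runs clean inputs through
encode → mask-predict → decode and returns the decoder outputs as the
denoised matrices, in scaled-data space.

## Preprocessing

RNA: drop genes detected in < 1 % of cells → keep the 3000 most dispersed
genes → per-cell library normalisation to 10⁴ → log1p → per-gene z-score
clipped at ±10. ATAC: same filter/HVG steps on peaks, then binarise and
TF-IDF (`TF` = row-normalised binary matrix, `IDF_j = log(1 + n/(1+df_j))`).
ADT: log-normalise + z-score only (panels are 10–200 antibodies).
Dispersion is the variance of log1p(library-normalised) values — the
simplest fully deterministic criterion; ties break by feature index.
Whether HVG selection precedes or follows normalisation is not dictated by
the pipeline's sources; selection on normalised values was chosen and is
applied consistently. Cells with zero counts (or no open peaks) abort with
an error naming them: they are unusable and silent dropping would
desynchronise the paired modalities.

## Synthetic data

`generate_multiomics` draws k centroids in a 10-d latent space scaled by
`separation`, assigns cells multinomially (every type guaranteed present),
and emits: RNA as negative-binomial counts (dispersion 2) around
per-cluster log-normal means; ATAC as Bernoulli peaks with cluster-specific
logits; ADT as log-normal levels. Dropout then zeroes each *nonzero* entry
with probability `dropout_rate`, using a seed stream separate from the
structure seed so the same cells can be corrupted at several rates. It
emulates: shared cluster structure across modalities, overdispersion,
modality-appropriate sparsity and scale, and dropout as false zeros. It
does **not** emulate batch effects, doublets, gene–gene correlation beyond
the latent factors, or any real dataset's empirical distributions — so
passing tests demonstrate correct mechanics and the method's qualitative
behaviour, not performance on real tissue.

Named fixtures define the reference experiments (all 500 cells, 300 genes):

* **standard** — 4 types, 400 peaks, separation 3.0: linearly separable;
  used for cluster recovery and the dropout sweep.
* **imputation** — separation 0.6: chosen so 60 % dropout actually degrades
  K-means on the raw matrix (at separation 3 the corrupted input still
  clusters perfectly and a before/after comparison has no headroom).
* **mask probe** — 8 types, a 50-feature ADT panel, separation 1.5, no
  dropout: conditions under which corrupted entries are detectable *in
  principle*. On the standard fixture even an oracle knowing the true
  cluster means only reaches AUROC ≈ 0.65 (pre-existing zeros and
  single-cluster-dominated features make most swaps indistinguishable), so
  a probe there would measure data detectability, not learning; on this
  fixture the oracle reaches ≈ 0.88.

## Reference experiments and their sizes

`scdrmae.experiments` fixes the problem sizes used by the tests and the
reproduction script: cluster recovery uses the default profile over 5
seeds; the dropout sweep uses the `small` profile (20 epochs) over
4 rates × 5 seeds; the imputation comparison uses 100 epochs over 20
seeds with the KL term disabled — the KL refinement optimises embedding
compactness at a measurable cost to reconstruction calibration, and
longer KL training makes the decoded matrices strictly worse for
clustering, so imputation reads the reconstruction-phase model. The mask
probe trains 800 epochs at batch 64 (~6400 updates) with the KL term
disabled for the same reason; at 500 cells a 100-epoch run is only ~800
updates, which is far less optimisation than the same epoch count provides
on datasets of thousands of cells, and the decoder's entry-level detection
emerges only after several thousand updates.

## Numerical choices

* Attention uses one head, width-preserving d×d maps (d = 128) and a bias —
  exactly one softmax(QKᵀ/√d) transform, not a full transformer block.
* Softmax rows are stabilised by subtracting the row maximum; pairwise
  squared distances are clamped at 0 to absorb round-off; `q` is floored at
  1e−12 under the KL logarithm; 0·log 0 := 0.
* Constant features z-score to all-zero columns rather than NaN.
* Degenerate metric cases return the conventional values (perfect
  agreement → 1; zero-entropy partitions → 1 by continuity).
* Wilcoxon rank-sum uses the normal approximation with tie correction;
  features rank by the greater-in-cluster one-sided z, ties by feature
  index; two-sided p-values and a per-cluster Benjamini–Hochberg column are
  reported but do not affect ranking.
* The autodiff engine is float64 throughout; every operator's
  vector-Jacobian product is tested against central finite differences.

## Known limitations

* O(n²) pairwise KL limits exact full-batch refinement to ~10⁴ cells; the
  anchor subsample beyond that preserves the objective only in expectation.
* The mask decoder can only detect corruption the data makes detectable;
  with heavy pre-existing dropout or features dominated by a single
  cluster, held-out mask AUROC is bounded well below 1 regardless of
  training (see the mask-probe fixture note above).
* No batch correction, doublet handling or three-modality support.
* `k` must be supplied; no model selection for the number of clusters.
* Checkpoints store parameters only; optimiser state is not resumable.
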