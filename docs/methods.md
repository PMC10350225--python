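# Methods

## Problem setting

Large LC-MS proteomics/metabolomics studies acquire samples in batches;
instrument drift and protocol differences impose systematic, non-biological
structure ("batch effects") on the log-intensity matrix. The package trains
autoencoder models whose bottleneck embedding (i) supports classification of
the biological condition in *batches never seen during training* and (ii)
carries as little batch information as possible. Correction quality is
always judged jointly: batch-mixing metrics alone reward representations
that also destroy biology.

## Model grid

Ten models: backbone ∈ {AE, VAE} × batch-removal head ∈ {none, DANN,
NormAE-style, inverse triplet, reverse triplet}.

Shared architecture: `input → layer1 → bottleneck → layer2 → output`, one
ReLU hidden layer with dropout on each side of the bottleneck, linear
output. The decoder optionally adds a learned per-batch embedding vector to
the bottleneck ("batch mapping") so the bottleneck itself need not encode
batch; the table is zero-initialized, making the mapping an exact no-op at
initialization. Both the batch discriminator and the condition classifier
read the bottleneck (for the VAE, the reparametrized sample z). The
discriminator has one hidden layer: a purely linear adversary can be fooled
by rotations and label flips that leave the cluster geometry — which the
kNN probe measures — fully intact.

Per-minibatch loss:

    total = rec + γ·batch_term + β·KL + label_ce + z_l2

* `rec` — mean squared reconstruction error on the (normalized, log-scale)
  inputs. MSE is the standard choice for continuous intensities.
* `batch_term` — depends on the head:
  * **DANN**: cross-entropy of the batch discriminator applied to the
    bottleneck *through a gradient reversal layer* (identity forward,
    gradient × −λ backward; λ is constant and equals the head weight γ, no
    ramp-up).
  * **NormAE-style**: the same cross-entropy *subtracted without* gradient
    reversal, clamped (`total = max(base − γ·ce_b, 0)`) so the total can
    never go negative; the discriminator itself is trained separately to
    minimize its cross-entropy on a detached bottleneck.
  * **inverse triplet**: `mean max(‖z_A−z_N‖² − ‖z_A−z_P‖² + α, 0)` with
    positive = same batch, negative = different batch — roles swapped
    relative to the classic triplet, so different-batch pairs are pulled
    together and same-batch pairs pushed apart (preventing collapse). This
    is the only head that is genuinely minimized rather than adversarial.
  * **reverse triplet**: the standard batch-grouped triplet hinge routed
    through gradient reversal, making it adversarial. The precise original
    formulation of this variant is not fully specified in public
    descriptions; this package's reading (standard triplet + reversal) is
    declared here as its own choice.
* `KL` — closed-form KL(N(μ,σ²)‖N(0,I)), mean over samples, one
  reparameterization sample per step (VAE only, weight β). The log-variance
  head is initialized small and negative (σ≈e^-2.5) so early training is not
  dominated by reparameterization noise; as β→0 the VAE then degrades
  gracefully to AE-like reconstruction.
* `label_ce` — label-smoothed cross-entropy on labeled (non-QC) samples
  only. Smoothing applies to the condition classifier only.
* `z_l2` — a weak isotropic zero-centred prior on the bottleneck
  (`z_reg·mean(z²)`, default z_reg = 0.01). Without a scale bound the
  encoder can outrun the batch adversary indefinitely by inflating the
  embedding; this term is the AE analogue of the VAE prior and is reported
  as its own loss component.

## Adversarial training dynamics

Two failure modes dominate gradient-reversal training on strongly separated
batches: the encoder overpowering the discriminator (it relabels/flips
clusters — discriminator loss explodes but clusters persist) and the
discriminator saturating (confident predictions give vanishing gradients).
The package therefore trains the discriminator with its own, faster
optimizer (`disc_lr`, default 1e-2) for several cross-entropy steps on the
detached bottleneck per autoencoder step (`disc_steps`, default 5), while
the autoencoder moves slowly (`learning_rate`, default 3e-4). In this
"follower" regime the near-optimal discriminator's reversed gradient points
steadily toward batch overlap, and the reconstruction-plus-batch-mapping
objective anchors the game: the joint optimum stores batch information in
the decoder's batch vectors, not the bottleneck. The supervised phase uses
its own rate (`sup_lr`, default 1e-3); classification needs larger steps
than the delicate adversarial balance tolerates.

## Training protocol

1. **Warmup** (step 1): all unsupervised components — reconstruction, KL,
   batch-removal term — trained on the *whole* table including validation,
   test and QC samples. Feature values of held-out samples are used by
   design; condition labels are never read and the condition classifier is
   untouched.
2. **Scenario "frozen"** (step 2a): the autoencoder is frozen; only the
   condition classifier trains on the training split.
   **Scenario "alternating"** (step 2b): each epoch runs one full
   unsupervised pass (step-1 losses, whole table) then one full supervised
   pass over the training split with gradients flowing through the encoder.
   The alternation granularity (epoch:epoch) is this package's choice.
3. Supervised minibatches are drawn with sampling weights inversely
   proportional to class frequencies (handles imbalance). Batch size 32.
4. Early stopping on validation MCC: up to 1000 post-warmup epochs, stop
   after 100 without improvement (defaults); ties keep the earlier epoch;
   the returned model is the best-validation-MCC snapshot, not the last.
5. **Repetitive holdout**: batches (never individual samples) are
   partitioned into train/valid/test; the test set is resampled each
   iteration; warmup is re-run per iteration for clean determinism. Every
   result is a mean over iterations. With K=3 batches each split holds one
   batch, so batch-mixing metrics are reported on the full representation
   (split "all") and are undefined (absent) on single-batch splits.
6. **Hyperparameter search**: seeded random search (budget default 20) over
   learning rate, weight decay, dropout, warmup epochs, layer widths, label
   smoothing, margin α, β, γ; selection by mean validation MCC only — test
   MCC is reported but never drives selection. The result declares
   `strategy="random-search"`.

Optimizer: Adam with decoupled weight decay throughout.

## Metrics

A kNN batch classifier (k = 20, Euclidean, self excluded, distance ties
broken by sample index) yields per-sample batch-membership probabilities.

* **nBE** = (log K − mean per-sample Shannon entropy of those rows)/log K,
  in [0,1]; 0 = uniform probabilities (ideal mixing), 1 = one-hot rows.
  The entropy is computed from the full probability vector with
  0·log 0 := 0; a surprisal-of-the-true-batch reading is undefined at p = 0
  and is not used.
* **ARI / AMI** — chance-adjusted agreement between the probe's argmax
  predictions and the true batch labels, computed from the contingency
  table (AMI's E[MI] via the hypergeometric expectation in log-gamma form).
  Degenerate case (both partitions a single cluster) returns 1.
* **aPCC** — mean Pearson correlation over all unordered pairs of pooled-QC
  samples (1 ideal); pairs containing a zero-variance profile are dropped,
  all-degenerate input is an error.
* **nMED** — median pairwise Euclidean distance among QCs ÷ the same median
  among non-QC samples (lower better; medians resist outliers).
* **MCC / accuracy** — condition classification on non-QC samples; MCC uses
  the generalized multiclass (Gorodkin) form.

The probe is fit on all samples of the evaluated set (declared in the
report as `probe_fit="all-samples"`). Metrics are computed on whatever
representation is supplied: feature space for scalers, bottleneck space for
the network models.

## Synthetic data generator

Log-scale model for study sample i (batch b, class c, feature j):

    x_ij = baseline_j + loc_bj + s_bj · (δ_cj + ε_ij)

with baseline_j ~ N(20, 2²) (typical log2 LC-MS intensity scale),
loc_bj ~ N(0, batch_shift_sd²) i.i.d. per batch × feature (LC-MS drift is
analyte-specific; this also makes per-batch standardization a non-trivial
baseline), s_bj = exp(g_bj), g_bj ~ N(0, batch_scale_sd²) a multiplicative
distortion of the log-scale deviations, δ the class offset (adjacent
classes differ by `effect_size` on `n_informative` features), and
ε ~ N(0, noise_sd²). QC samples are copies of the baseline profile pushed
through the same batch effects with fresh noise, so their ground truth is
exact. Class is drawn independently of batch by default; the
`batch_class_confound` knob forces a fraction of samples' classes to follow
their batch for stress tests.

Defaults — 300 samples, 200 features, 3 batches, two balanced classes,
20 informative features with a one-log-unit effect, shift SD 1.0, log-scale
SD 0.1, noise SD 0.5, 2 QCs per batch — describe a two-condition experiment
with a strong batch effect (the raw-space probe identifies batches almost
perfectly) and a clearly detectable biological signal. Because batch shifts
are i.i.d. across features, even modest per-feature shifts produce large
between-batch distances in 200 dimensions; mixing such data is a demanding
test of the removal heads.

Not emulated: retention-time drift, missingness, censoring at detection
limits, peptide-to-protein rollup, heavy-tailed noise, correlated feature
blocks. Passing tests on this generator therefore show the mechanisms work
under idealized Gaussian conditions, not that any model is best on a given
real dataset.

## Numerical choices and conventions

* Matrix orientation is samples × features everywhere; the loader
  transposes only when `features_in_rows=True`.
* QC samples carry the reserved condition label `"QC"`, never enter
  supervised losses or MCC, and do participate in warmup and QC metrics.
* Zero-variance / zero-IQR / zero-range features within a scaling fit group
  map to 0 (center-only), avoiding division by zero.
* Splits with fewer than 3 batches are rejected; split fractions apply to
  batch counts with at least one batch per split.
* Triplet mining: per anchor, one random same-batch positive and one random
  different-batch negative within the minibatch; anchors lacking either are
  skipped.
* Model/optimizer determinism: every stochastic component (initialization,
  dropout, reparameterization, mining, sampling, splits) is driven by
  explicit seeded generators; identical seeds give bit-identical results,
  which the benchmark CSV test checks end-to-end.
* Test sizes in the suite are scaled to the generator preset (300×200, 3
  batches) with warmup 30–100 and 150–200 post-warmup epochs; the
  one-sided five-seed comparison against the linear-SVM baseline is a
  paired comparison at the 5% level, since the baseline on this generator
  is itself near-ceiling.

## Corrected features

`export_corrected_features` decodes every sample through a single reference
batch mapping. It exists for completeness and is **not recommended** for
downstream analysis: the decoder cannot improve on the bottleneck, and
reconstruction fidelity is only one of several competing loss terms. Prefer
the bottleneck plus expected-gradients attribution (`feature_attribution`),
whose per-sample contributions are additive and sum to the explained logit
minus the mean background logit.

## Known limitations

* The adversarial heads' mixing quality degrades when between-batch
  separation is extreme (tens of within-batch standard deviations); the
  inverse triplet head, which is minimized directly, is more robust there.
* Validation splits holding a single easy batch saturate at MCC 1.0 and
  stop informing model selection; repetitive holdout mitigates but does not
  remove this.
* The attribution module explains the model, not the biology: features the
  model ignores get no attribution however biologically relevant.
* CPU-only, dense numpy: intended for the tables typical of LC-MS studies
  (hundreds of samples, 10²–10⁴ features), not single-cell-scale data.
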