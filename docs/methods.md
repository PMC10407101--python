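# Methods

## Problem and pipeline

The package classifies the emotional state (high vs. low arousal, or high
vs. low valence) evoked during one-minute multi-channel EEG trials recorded
in the DEAP geometry: 32 EEG channels at 128 Hz, 8064 samples per trial
(63 s, of which the first 3 s are a pre-trial baseline), with continuous 0–9
self-assessment ratings per trial. Ratings are binarized at the conventional
threshold — strictly greater than 5 is "high", everything else including
exactly 5 is "low" — and every trial is cut, after discarding the baseline,
into ten non-overlapping 6-s segments that inherit the trial label. At the
full DEAP scale (32 subjects × 40 trials) this yields 12,800 labeled
segments.

Each segment is reduced to a 32 × 6 table of per-channel time-domain
features: mean, population variance, mean absolute first difference, mean
absolute second difference, standard deviation, and fuzzy entropy. The table
feeds two complementary views of the same data:

* a **sparse feature image** — each channel's six features dropped into its
  electrode's cell of a 9 × 9 grid that mirrors the 10/20 layout seen from
  above (9 × 9 × 6 overall; 49 of 81 cells carry no electrode and stay
  exactly zero), processed by a residual CNN that captures local spatial
  structure among neighbouring electrodes;
* a **channel graph** — 32 nodes with the 6 features as node attributes on a
  fully connected, self-loop-free adjacency, processed by multi-head graph
  attention that learns data-dependent functional connectivity regardless of
  scalp distance.

The flattened outputs of the two branches are concatenated and classified by
a small fully connected head with softmax. Single-branch ablation modes
(`resnet-only`, `gat-only`) route only one branch's features to the head,
keeping everything else identical, so the contribution of each information
source can be isolated on the same folds.

## Fuzzy entropy

For a signal s(1..N), templates of length L start at positions i = 1..N−m
(the same index set for L = m and L = m+1, so the two averages run over
identical template counts) and are centred by their own mean:

    X_i^L = (s_i, …, s_{i+L−1}) − mean(s_i, …, s_{i+L−1})
    d_ij^L = max_k |X_i^L[k] − X_j^L[k]|          (Chebyshev distance)
    D_ij^L = exp(−(d_ij^L / r)^n)                 (fuzzy similarity)
    φ^L   = mean_i [ (N−m−1)^{-1} Σ_{j≠i} D_ij^L ]
    FuzzyEn(m, r, N) = ln φ^m − ln φ^{m+1}

Defaults: m = 2, n = 2, r = 0.2 × SD of the channel-segment (exposed as
`r_coef`; an absolute `r` can be given instead). Template centring makes the
measure invariant to additive shifts; the SD-proportional width makes it
invariant to amplitude rescaling — both are asserted to 1e−9 in the tests.
The exponential kernel is written `exp(−(d/r)^n)` rather than `exp(−d^n/r)`
precisely because only the former preserves scale invariance at n = 2. Two
degenerate conventions: a constant signal returns 0 (all similarities are
1), and signals shorter than m + 2 samples are rejected.

The production path fills the packed upper-triangle distance arrays with a
compiled (numba) kernel specialized for m = 2 and applies the exponential
with vectorized numpy; a pure-numpy full-matrix fallback handles
environments without numba. Both paths follow the input dtype — the pipeline
runs float32 for speed, and float64 inputs reproduce the naive nested-loop
transcription of the definition to better than 1e−10 (asserted on 50 random
signals).

## Network

**Residual branch.** Four residual blocks — two with 64 filters, two with
128, all 3 × 3 kernels, stride 1, zero same-padding. The 9 × 9 plane is
never downsampled: it is too small for pooling to leave useful resolution.
Each block is conv → batch-norm → ReLU → conv → batch-norm, an identity skip
(1 × 1 convolution projection when channel counts differ) added before the
final ReLU. Output flattened: 9·9·128 = 10368.

**Graph branch.** Two graph-attention layers, K = 2 heads of d′ = 16 each.
Per head, e_ij = LeakyReLU(aᵀ[Hx_i ‖ Hx_j]) (negative slope 0.2) over the
first-order neighbourhood, softmax-normalized per row; the aggregated
neighbourhood feature passes through ELU and the head outputs are
concatenated (width 32). The adjacency is all-ones with a zero diagonal, so
every node attends to the 31 others but not to itself; a `self_loops` config
flag adds the diagonal for users who prefer that convention. The flattened
32·32 = 1024 output is batch-normalized (1-D over flattened features) before
fusion. Attention rows are row-stochastic on their neighbourhoods at every
layer, head and sample — this invariant is asserted, and the layer agrees
with a literal per-node transcription to 1e−10 in float64.

**Head.** Concatenation (11392 for the fused model) → fully connected
hidden layer of 128 with ReLU (optional dropout, default 0) → linear →
softmax. The hidden layer is a deliberate choice where the design was open;
`fusion_hidden` exposes it.

The whole network is implemented in NumPy with hand-written backward passes
(im2col convolutions routed through BLAS matmuls) and Adam. Every layer's
gradients are validated against central finite differences, and the full
model passes a capacity check (memorizing 64 random samples with random
labels). Weights are Glorot-uniform from a seeded generator; training is
bit-for-bit reproducible given a seed, since all randomness flows through
`numpy.random.Generator` instances derived from it.

## Training protocol

Cross-entropy minimized with Adam (default learning rate 1e−4, the rate
used for long training horizons of ~750–1000 epochs at full scale; batch
size 64). Folds are stratified at segment level over the pooled cohort —
the subject-dependent protocol. Splitting segments of one trial across
folds is optimistically biased (validation segments share trial context
with training segments); `group_by_trial=True` switches to the stricter
protocol that keeps each trial's segments in one fold. Per fold, the
per-feature z-scoring statistics are fitted on the training split only and
applied unchanged to validation; unmapped image cells remain exactly zero
after normalization. Normalization is not described in the source protocol;
it is adopted because the raw feature scales differ by orders of magnitude
(variance in µV² vs. entropy in nats) and would otherwise dominate the
convolution inputs. Metrics per fold: accuracy, F1 of the positive ("high")
class, ROC by threshold sweep with trapezoidal AUC (verified against the
Mann–Whitney pairwise concordance), confusion counts, and the mean
first-layer attention matrix averaged over heads and validation samples
(exportable as a channel × channel heatmap).

## Synthetic cohorts

Real DEAP recordings are licensed, so the generator emulates the geometry
with controllable class structure. Each channel is an alpha-band sinusoid
(8–13 Hz, random frequency and phase, amplitude 10 µV) plus broadband
Gaussian noise (SD 5 µV). Per trial a balanced latent class is drawn; for
"high" trials a fixed frontal subset (Fp1, Fp2, F3, F4, AF3, AF4) has its
whole signal scaled by (1 + effect_amplitude) — a variance/SD effect — and
its noise-to-sinusoid ratio additionally scaled by (1 + effect_irregularity)
— a fuzzy-entropy effect invisible to pure rescaling. Channel pairs in
`coupled_pairs` (default Fp1–F3 and Fp2–F4) share an additive latent source
(SD 3 µV), giving the graph branch a correlation structure. Ratings are
drawn from (5, 9] for high trials and [1, 5] for low ones on both the
valence and arousal axes, so threshold binarization recovers the latent
class exactly; the latent class is stored in the container so labeling
errors can be distinguished from modeling errors. Concentrating the effect
on frontal channels makes the learned mean-attention heatmap interpretable
(informative channels should attract attention) — a demonstration, not a
claim about brains.

What the generator does **not** emulate: 1/f spectra, artifacts, volume
conduction, non-stationarity, subject heterogeneity. Passing tests on these
cohorts shows the pipeline is implemented correctly and can exploit
variance, irregularity and coupling structure; it says nothing about
accuracy on real EEG.

## Problem sizes and numerical choices

The end-to-end evaluation runs on a 4-subject × 20-trial cohort (800
segments) with strong effects (both effect sizes 1.0, two coupled pairs),
5-fold CV, and reduced-epoch training: 4 epochs at learning rate 1e−3. The
larger step size compensates for the short horizon on this small, cleanly
separable cohort — training loss reaches ~0 within the first epochs, and
validation accuracy saturates near 1.0 in all modes. The label-shuffled
control (training labels permuted per fold, validation labels intact) stays
at chance. Structural counts use the full 32 × 40 geometry, which is cheap
because only segmentation is required.

Numerical details worth knowing: population (divide-by-N) variance so
SD² = variance exactly; softmax computed with row-max subtraction; masked
attention uses an additive −1e30 before the softmax; batch-norm eps 1e−5,
running-stat momentum 0.1; Adam β = (0.9, 0.999), eps 1e−8; a constant
feature column gets unit SD during normalization so it centres to zero
instead of dividing by zero. Ties in argmax predictions resolve to the low
class. Once the loss saturates near zero the backward signal decays into the
float32 subnormal range, which x86 cores evaluate in slow microcode; the
convolution backward pass therefore flushes gradient magnitudes below 1e−30
to zero — a perturbation far below float32 resolution that keeps converged
training at full speed.

## Known limitations

* The NumPy training loop is CPU-bound and meant for desk-scale cohorts;
  full-scale runs (12,800 segments, ~1000 epochs) are possible but slow.
* Only the 32-channel DEAP montage ships; the registry accepts user-defined
  montages but no 62-channel table is provided.
* The segment-level fold protocol is optimistic by construction (see above);
  results under `group_by_trial=True` are the defensible ones for real data.
* Single-trial ratings label all ten segments of the trial; no within-trial
  label dynamics are modelled.
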