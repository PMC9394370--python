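# Methods

## Problem and model

`ecgcs` implements compressed sensing (CS) of single-lead ECG with a learned
measurement operator and a deep reconstruction network, alongside the
classical pipeline it replaces.

In classical CS a segment `x ∈ R^N` (here `N = 256` samples) is measured as
`y = Φx` with a fixed random `M × N` matrix (`M ≪ N`), and reconstruction
exploits sparsity of `x = Ψα` in an orthonormal basis `Ψ`. The sensing rate
is `SR = M/N`. The learned variant replaces `Φ` with three successive 1-D
convolutions (kernel length 4, stride 4, no padding, `C` filters each, no
inter-layer activation), so the 256-sample segment becomes a `C × 4`
measurement grid, `M = 4C` values in total. Because there is no
nonlinearity, the stack is an affine map `y = Φ_eff x + y(0)`; the package
can extract `Φ_eff` by basis probing, which is also how the affinity
contract is tested.

The channel count follows `C = max(1, round(64 · SR))`. `64 · SR` is not an
integer for most sensing rates of interest (e.g. SR 0.05 → 3.2), so the
realized rate `4C/256` can deviate from the requested one by up to `1/128`;
the realized value is always carried in `SensingConfig`.

The decoder has two stages:

1. **Initial reconstruction.** A 1×1 convolution lifts the `C` channels at
   each of the 4 coarse positions to 64 channels (LeakyReLU), and a
   position-major reshape (channel `c` of position `p` lands at sample
   `64p + c`) restores a 256-sample vector. Position-major layout keeps each
   output quarter aligned with the receptive field of the corresponding
   measurement position.
2. **Final reconstruction.** An entry 1×11 convolution (`same` padding)
   produces 16 channels; a modified Inception block runs four parallel
   residual lines with kernel lengths 7/9/11/13 — each line is
   `σ(f2(σ(f1(x)))) + x` with two 16→16 same-padded convolutions and
   LeakyReLU `σ` — and concatenates them into 64 channels; a single-layer
   unidirectional LSTM (hidden size 64, zero initial state) consumes the
   64-feature sequence one time step per sample; a per-step linear head
   projects each hidden state to one sample. No output activation: the
   targets live in [0, 1] and an unsquashed regression head avoids
   saturated gradients.

Residual addition is placed *after* the second activation (the standard
pre-add residual form). The alternative grouping — activation applied after
the skip addition — would be a one-line change in `inception_line`.

## Preprocessing and metrics

Each 256-sample window is min–max normalized onto [0, 1] using its own
extremes; the parameters are kept so reconstructions can be mapped back.
Constant (flat-line) windows have no well-defined map and are sent to the
zero vector with a `degenerate` flag and a warning instead of raising, so
long batch jobs survive sensor drop-outs.

Quality is measured by PRD `= 100·‖x − x̄‖₂/‖x‖₂` (no mean subtraction) and
SNR `= 10·log10(‖x‖²/‖x − x̄‖²)` dB. Per segment the two are tied by
`SNR = −20·log10(PRD/100)`; across a test set the PRD mean and the SNR mean
are taken separately, and the identity intentionally does not survive
averaging (Jensen's inequality) — both means are reported for that reason.
PRD bands: [0, 2) Very good, [2, 9) Good, [9, 19) No good, and Bad from 19
up (the band table is silent above 60; everything ≥ 19 is labelled Bad).
A numerically exact reconstruction reports the 300 dB cap instead of ∞ so
aggregates stay finite. Metrics are computed on the normalized scale by
default — the network's input/label space — with denormalization available
when raw-amplitude evaluation is wanted.

## Training protocol

Joint optimization of compressor and decoder by Adam (initial learning rate
5e-4, moment decays 0.9/0.999), batch size 32, MSE loss
`(1/n) Σ ‖f(x̂ᵢ) − xᵢ‖²₂` (squared norm per segment, averaged over
segments; a per-sample-mean variant is available and only rescales
gradients). No schedule, weight decay, clipping or early stopping. An
optional lower rate (e.g. 1e-4) can be switched in for SR ≥ 0.4, where the
larger measurement steepens the loss surface. Initialization is Glorot
uniform everywhere (including the recurrent block) with zero biases, all
seeded; the train/validation split (80/20 by segment) and the per-epoch
shuffle derive from the same seed, so a full run is reproducible from one
integer.

For the fixed-matrix comparison arms (Gaussian `N(0, 1/M)` entries,
Bernoulli `±1/√M` — both scaled for near-isometry, `E‖Φx‖² = ‖x‖²`) the
matrix is held fixed and only the decoder trains. A `train_compressor`
flag likewise allows freezing the convolutional encoder.

The whole network, including backpropagation through the strided
convolutions, the residual block and 256 steps of the LSTM, is implemented
directly in NumPy (`ecgcs._nn`), with each stage's backward pass
hand-derived and verified against numerical differentiation and against
independent scalar-loop oracles in the tests.

## Greedy baselines

OMP selects atoms of `A = ΦΨ` by largest normalized correlation with the
residual and refits by least squares on the grown support; Subspace Pursuit
keeps a working support of size `K`, merges in the `K` best-correlated new
atoms, prunes back to `K` after a joint least-squares fit, and accepts the
step only while the residual decreases. Atoms are normalized for selection
but not for refitting. Defaults: sparsity budget `K = ⌊M/4⌋` (keeps the
least-squares systems well-posed), 50 iterations max, residual tolerance
1e-10; all exposed as knobs since the classical literature fixes none of
them. The default basis is the orthonormal Daubechies-4 DWT (full
periodized decomposition), a standard sparsifying choice for ECG; an
orthonormal DCT-II and the identity are included for tests and for signals
sparse in other domains. Rank-deficient supports fall back to the
minimum-norm solution with a warning.

## Synthetic data generator

The generator emulates a quasi-periodic single-lead ECG as five Gaussian
bumps (P, Q, R, S, T) per beat at fixed time offsets around each R peak
(P −200 ms, Q −35 ms, R 0, S +35 ms, T +300 ms; widths 45/12/22/15/110 ms;
amplitudes 0.15/−0.12/1.0/−0.25/0.35), with i.i.d. normal RR intervals
(default 72 ± 3 bpm, truncated positive), ±5 % per-beat QRS amplitude
jitter, and a low-frequency (0.15–0.35 Hz) baseline-wander sinusoid of
amplitude 0.05. Sampling rate defaults to 360 Hz, so one 256-sample window
covers ≈ 0.71 s. Gaussian noise is added to the *raw* signal before
normalization (mirroring the pipeline order), and the noise vector is
rescaled so the realized `10·log10(‖x‖²/‖n‖²)` equals the requested dB
figure exactly for each draw — noise-level assertions are therefore exact
rather than statistical.

What the generator does *not* emulate: arrhythmic morphology changes,
ectopic beats, electrode artifacts, multi-lead correlation, and the
abdominal mixture of fetal recordings (a fetal-like setting is approximated
only as "different rate/morphology parameters"). Passing tests on this data
demonstrate that the pipeline's mechanics — compression, reconstruction,
training dynamics, metric orderings — behave correctly; they do not certify
clinical reconstruction quality on real recordings.

One consequence deserves emphasis: a sum of smooth Gaussian bumps is far
sparser in a wavelet basis than real ECG with its noise floor and
morphological variability, so the greedy baselines recover the synthetic
segments much better (relative to the deep pipeline) than they do real
recordings at moderate sensing rates. The comparisons that carry over to
real data are the *orderings within a family* — learned vs. fixed-matrix
measurement for the same decoder, high vs. low sensing rate, clean vs.
noisy test data — not the absolute deep-vs-greedy gap.

## Reference protocol and problem sizes

The canned protocol in `ecgcs.experiments` trains on 1,000 synthetic
segments (80/20 train/validation) and evaluates on 250 held-out segments,
15 epochs per arm, three arms: learned compressor at SR 0.5 and SR 0.05,
and a Gaussian-matrix arm at SR 0.5 (decoder-only training). These sizes
are the package's reference study conditions for a single-CPU NumPy run;
the directional findings they support — training reduces the loss, SR 0.5
reconstructs in the "Good" PRD band while SR 0.05 is markedly worse, the
learned compressor is at least as good as the fixed Gaussian matrix, and
24 dB test noise degrades PRD more than 32 dB noise — are stable across
seeds, while absolute PRD/SNR values at these sizes are naturally far from
what multi-hour training on full ECG databases yields.

## Numerical choices and edge cases

- All arithmetic is float64; checkpoint round-trips are bit-exact (`.npz`).
- LeakyReLU slope defaults to 0.01 (configurable in (0, 1)).
- `compress_conv`/`extract_effective_matrix` tolerate any batch size; the
  probing oracle uses the canonical basis plus the origin, so the extracted
  affine map is exact to round-off.
- Degenerate inputs: all-zero segments are rejected where a ratio is
  undefined (PRD, SNR, RIP ratio, noise scaling); constant segments
  normalize to zeros with a warning; empty datasets and shape mismatches
  raise `ValueError` before any computation.
- A non-finite training loss aborts with a diagnostic naming the epoch and
  step rather than silently continuing.

## Known limitations

- The NumPy training loop is single-threaded BLAS-bound; wall-clock scales
  linearly with epochs × batches and is the binding constraint on protocol
  sizes.
- The LSTM is the smallest topology consistent with the design (single
  layer, unidirectional, hidden 64); no bidirectional or stacked variants.
- WFDB support covers header + signal formats 212 and 16 (the formats of
  the intended arrhythmia databases), single-file records only, and no
  annotation parsing.
- The RIP diagnostic reports isometry ratios; it makes no attempt at formal
  RIP-constant certification (NP-hard in general).
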