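# Methods

## Model

The classifier is a single-hidden-layer feedforward network
f(x) = g(xWᵀ + b)β with L hidden units, trained ELM-style: (W, b) are fixed
and β = H⁺Y is the minimum-norm least-squares solution against the one-hot
target matrix. The activation g is the logistic sigmoid — the canonical ELM
choice, and bounded, which keeps hidden outputs well-scaled when (W, b) are
searched inside a box. Tanh is available via `ElmModel.activation`.

The pseudoinverse solve uses LAPACK's complete orthogonal factorization
(`gelsy`) with singular values below 1e−12 of the largest treated as zero;
it returns the same minimum-norm solution as an SVD pseudoinverse (the test
suite cross-checks against `numpy.linalg.pinv`) at a fraction of the cost,
which matters because the DE objective re-solves β for every candidate.

Class labels are 1-based throughout the public API. Argmax ties — in
prediction and in majority voting — resolve to the smallest class index so
every prediction is deterministic.

## Differential evolution

The optimizer is classical DE (mutation → binomial crossover → boundary
regeneration → greedy selection) over [Xmin, Xmax]^D, with all five standard
mutation strategies implemented (DE/rand/1, DE/best/1, DE/current to best/1,
DE/best/2, DE/rand/2). The multi-strategy mode draws one strategy per
generation uniformly from {DE/rand/2, DE/best/2, DE/current to best/1};
any subset can be configured, which is how the single- and dual-strategy
ablation models are expressed without separate code paths.

Control parameters:

* **F (scaling factor)** — F(t) = F₀ · 2^exp(1 − T/(T+1−t)), F₀ = 0.4.
  F(1) = 2F₀ and the schedule decays monotonically to F₀ at t = T, so
  F ∈ [F₀, 2F₀] ⊂ [0, 2] always: wide early steps, fine late steps.
* **CR (crossover probability)** — CR = 0.5(1 + u), u ~ U(0,1), redrawn
  once per generation and shared by all individuals. One forced dimension
  j_rand per trial always inherits the mutant component.
* **Early stop** — the loop ends when the best fitness drops below the
  threshold y = 1e−6; this fires on benchmark objectives (the sphere) but
  essentially never on classification RMSE.

Choices that were genuinely open and are fixed here: the strategy, F and CR
are drawn per generation (not per individual; a per-individual strategy draw
is available as a flag); mutation partners r1…r5 are sampled without
replacement and exclude the target; boundary violations are regenerated
uniformly component-wise; selection uses strict inequality, so on a tie the
parent survives. The optimizer consumes a single seeded generator in a
documented draw order (see `de.py`), making every run exactly replayable —
the test suite exploits this to compare one full generation against a
hand-executed one with pinned draws. Degenerate equal bounds (Xmin = Xmax)
are permitted and produce the constant population.

## Coupling DE to the ELM

A candidate is the concatenation of W (row-major, one hidden unit's weights
contiguous) and b, giving D = L(K+1). β is *not* searched — it is determined
by the linear solve given (W, b), which keeps the search space minimal. The
fitness is the training-set RMSE between network outputs and one-hot
targets: continuous (unlike the misclassification rate, which is piecewise
constant and gives DE no gradient signal between rank changes) and
compatible with the 1e−6 stopping threshold. A misclassification-rate
objective is available (`fitness_kind="error_rate"`). The fitness is
evaluated on the full training set; no inner validation split is held out.
Search bounds are [−1, 1] for weights and thresholds, matching the random
initialization convention of the plain ELM.

## Ensemble

Ten members with hidden sizes evenly spaced over [4·df, 10·df] (endpoints
included, rounded to integers), each trained with a per-member seed derived
as master seed + member index; combination is unweighted majority vote.
Even spacing is chosen over random sizes for reproducibility and maximal
structural spread; uniform-random sizes within the range remain possible by
passing explicit `hidden_sizes`.

## Feature pipeline

WAV input is averaged to mono and resampled to 16 kHz. The MFCC dialect:
pre-emphasis 0.97, 25 ms Hamming frames with 10 ms hop, FFT at the next
power of two, 26 triangular mel filters up to Nyquist, log, DCT-II
(orthonormal), keeping coefficients 1–13 (c0 excluded, so features are
amplitude-invariant). All knobs live in `MfccConfig`.

Endpoint detection is a double-threshold rule: frames above 10 % of the
maximum short-time energy are voiced; frames above a quarter of that
threshold are also admitted when their zero-crossing rate exceeds the clip
mean, catching noisy syllable edges without admitting the noise floor.
Denoising is a no-op by default (the synthetic fixtures are clean).

The regression difference with window K = 2 is applied along the frame
axis, one cepstral column at a time, with the first K frames using forward
differences, the last K using backward differences, and the interior using
the normalized regression formula Σₖ k(C_{t+k} − C_{t−k}) / √(2Σₖ k²).
Applying the operator along the cepstral axis instead is exposed as a
config option but not the default — across-frame differencing is what makes
Δ-features capture temporal dynamics. ΔΔ is the operator applied twice.
Frames are fused to 39-d and stacked in non-overlapping groups of four into
156-d samples; a trailing remainder is dropped.

## Synthetic data

`gen_clusters` draws class c from an isotropic unit-variance Gaussian whose
mean sits at distance s (the separation, in within-class standard
deviations) along its own unit direction — orthogonal axes while c ≤ df,
random unit directions beyond. This is deliberately the *simplest* structure
under which the qualitative orderings (tuned ≥ plain, ensemble ≥ single) are
observable; it has none of the temporal structure, class overlap asymmetry,
recording noise or label noise of real birdsong features, so passing tests
demonstrate correct mechanics and the direction of the effects, not
field-level accuracy. Heavier-tailed (Student-t₃) noise and geometric class
imbalance are available as options.

`gen_songs` writes 16 kHz mono WAVs: a three-harmonic stack at a
species-specific fundamental, amplitude-modulated at the syllable rate by
a raised cosine, plus white noise at a target SNR, with random phases so
clips of one species differ. This exercises the full audio pipeline
(loading, endpoint detection, MFCC, stacking) end to end; it is not a
realistic syrinx model.

## Evaluation protocol

Splits are stratified 7:3 (per class, round(0.7·n_c) to the training set).
An experiment is n = 10 independent split/train/test cycles with seeds
master + run index; reports give mean ± sample standard deviation (n−1).
Accuracy, precision and F1 are computed from the confusion matrix; the
averaged metrics are macro by default (weighted by support via a flag).
Model pairs are compared with a two-sided pooled-variance Student t-test on
the means and a two-sided F-test on the variance ratio (larger variance in
the numerator) at α = 0.05 — the classical pooled-t workflow in which the
F-test checks the equal-variance assumption and doubles as a stability
comparison. Both tests are exactly calibrated under the null for equal
sample sizes; the acceptance suite verifies ≈5 % type-I error empirically.
When both samples have zero variance the t-test degenerates; the comparison
flags this with a NaN F p-value rather than failing.

## Benchmark problem sizes

The synthetic benchmark used by the test suite and `scripts/acceptance.py`
is 5 classes × 100 samples in 20 dimensions at separation 3. The DE runs
with NP = 30 and T = 15 generations there (the `DeConfig` defaults are
NP = 100, T = 30), and single models use L = 40 = 2·df hidden units — a
capacity-limited regime, L/N_train ≈ 0.11, comparable to the low end of the
4×–10× ensemble grid relative to a field-scale training set. In that regime
hidden-layer tuning is informative; at L ≥ 3·df on this benchmark a random
hidden layer already saturates the data and DE tuning of the training RMSE
yields no test-side gain (the package makes that regime easy to explore).
Ensembles always use the full 4×–10× grid.

## Known limitations

* The DE objective (training RMSE) can overfit when L approaches the
  training-set size; no regularization term is provided (ridge/kernel ELM
  variants are out of scope).
* Endpoint detection is energy/ZCR-based and untested against real field
  noise; the denoising hook is a no-op by default.
* The ensemble supports only unweighted majority voting — no stacking,
  weighting or probability averaging.
* `train_msde_elm` at audio-scale dimensions (L·(K+1) ≈ 10⁵ for 156-d
  features with L = 4·df) is computationally heavy; the end-to-end audio
  test therefore demonstrates the plain-ELM ensemble, and DE-tuned models
  are exercised on the lower-dimensional cluster benchmark.
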