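# Methods

## The classification problem

Four-class motor-imagery EEG: a subject imagines moving the left hand
(class 1), right hand (class 2), both feet (class 3) or tongue (class 4)
while 22 scalp channels are recorded at 250 Hz.  Each trial contributes a
4-second imagery window (2.0–6.0 s after the cue; half-open, 0-based
sample indexing), giving a channels × time matrix per epoch.  A standard
Graz-protocol session has 288 trials, 72 per class.  The task is to
predict the class of an unseen epoch.

## Pipeline

1. **Features.** Per channel: five time-domain statistics (mean absolute
   deviation, mean, sample SD, sample variance, and the *unnormalized*
   fourth central moment with the n−1 denominator — deliberately not
   excess kurtosis) and 12 MFCCs.  The MFCC chain is: pre-emphasis
   `y[n] = x[n] − a·x[n−1]` applied to the whole signal (a = 0.97 by
   default; applying it before framing is the standard use of the
   first-order FIR filter), framing (64 samples = 256 ms, hop 32; the
   session's frame/hop sizes are a package choice — 256 ms balances
   spectral resolution against the quasi-stationarity assumption), a
   Hamming window, the magnitude spectrum on a 128-point FFT, a bank of
   20 triangular filters equally spaced on the mel axis from 0 Hz to
   Nyquist, log compression floored at 1e-10 (so silent frames are
   handled, never raised on), and the cosine transform
   `c_j = sqrt(2/N_f) Σ_m log S̃(m) cos(jπ/N_f (m−1/2))`, dropping the
   zeroth coefficient (mean log energy).  Per epoch the per-frame
   coefficients are averaged, giving one vector per trial; with both
   domains, Q = 22 × (5 + 12) = 374 features.

   The mel map defaults to `m = 2595·log10(1 + f/100)` — denominator
   100, not the conventional 700.  This nonstandard variant is the
   primary definition here; the 700 denominator and the natural-log form
   `1127·ln(1 + f/d)` are selectable for interoperability.

2. **Feature selection.** A wrapper: candidate column sets (by default
   the three domain-level groups time / mfcc / both) are each scored by
   an induction algorithm on a stratified 70/30 holdout split; highest
   validation accuracy wins, ties broken by parsimony then input order.
   The default evaluator is an SVM with library defaults (RBF kernel);
   it is a pluggable callable, so the negative-selection classifier
   itself can serve as the evaluator.

3. **Dimensionality reduction.** Features are min–max normalized to
   [0, 1] (constant columns map to 0.5; test rows are rescaled with the
   *training* bounds and clipped, keeping all geometry inside the unit
   hypercube).  A two-layer stacked sparse autoencoder then reduces
   Q → H1 → H2 (defaults 16 and 8).  Each layer minimizes

       J = (1/N) Σ ||x − x'||² + λ||W'||² + β Σ_j KL(ρ || ρ̂_j)

   with logistic encode/decode, mean-activation ρ̂_j clamped to
   [1e-8, 1−1e-8], weight decay on the decode weights (optionally also
   the encode weights), λ = 1e-4, β = 0.1, ρ = 0.05.  Training is
   full-batch gradient descent (learning rate 0.1, 500 epochs) with a
   seeded symmetric uniform initialization; the analytic gradient is
   verified against central differences in the test suite.  Layers are
   pretrained greedily (layer 2 on layer 1's codes); no fine-tuning
   through the stack.  Reconstruction targets are the normalized
   features — the sigmoid output range forces inputs on [0, 1].

4. **Detector training (negative selection).** In the reduced H2-dim
   unit hypercube, a detector is a hypersphere (center, radius).  For a
   class-k detector set, the SELF set is by default the reduced training
   rows of the *other three* classes (`match_means_class`): detectors
   therefore tile class-k territory, and a monitoring match — Euclidean
   distance strictly below the radius — directly predicts class k.  This
   is the one convention under which "a match labels the sample nonself"
   and "set k predicts class k" are simultaneously coherent; the
   opposite convention (SELF = class k) is retained behind the
   `match_means_nonself` flag.  Every self sample is padded by
   R_self = 0.05 (normalized units; exposed in config), and a candidate
   whose maximal safe radius — min distance to self minus R_self — is
   below r_min = 1e-3 is censored.

5. **GA optimization.** Each detector is matured by its own GA run:
   chromosomes are plain (non-Gray) fixed-point bit strings, 16 bits per
   dimension; raw fitness f = maximal safe radius (floored at 0 when
   infeasible, since roulette selection needs non-negative mass);
   selection fitness f* = δ·f/s with the diversity factor
   s = Σ_i 1/(1 + dist(candidate, accepted_i)), the sum over already
   accepted detectors (s = 1 when none — f* reduces to δ·f).  The
   1/(1+d) similarity is bounded, monotone decreasing and division-safe.
   Operators: roulette-wheel selection (uniform fallback when all
   fitness is zero), 2-point crossover at rate 0.9, per-bit mutation at
   1/chromosome-length, elitism 1 — so the per-generation best f* never
   decreases.  Population 50, 100 generations (these GA constants are
   package choices; all are exposed).  The winning individual becomes a
   detector with radius equal to its full safe radius.  Repeating N_d
   times (default 30) with the diversity term active spreads detectors
   over the class territory.

6. **Classification.** A test vector is normalized with training
   bounds, encoded through the stack and monitored against all four
   sets.  The per-set margin is max over detectors of
   (radius − distance); the set with the largest margin wins — this
   resolves both multiple matches and the no-match case (least negative
   margin), with residual ties going to the lowest class label.
   Accuracy is trace/total of the 4×4 confusion matrix.

7. **Model selection.** A grid over H1 ∈ 15–19, H2 ∈ 6–10,
   N_d ∈ {25, 30, …, 70} (250 cells) scores each cell by the mean
   per-class *detection accuracy* on a stratified holdout: the fraction
   of validation samples whose matched/unmatched outcome agrees with
   their self/nonself status for that set, averaged over the four sets.
   Ties prefer smaller N_d, then smaller H1+H2, then enumeration order.

## Synthetic sessions

The generator emulates an epoched 4-class session: class k places a
narrowband sinusoid (random phase per epoch, ±10% amplitude jitter) on a
class-specific group of five channels — 10 and 12 Hz (mu band) for the
hand classes, 20 and 24 Hz (beta band) for feet and tongue — with equal
amplitude 1.0, plus white Gaussian noise (sd 0.5) on all 22 channels.
Signal and noise use separate seeded streams, so an SNR sweep varies only
the noise realization's scale.

What it does *not* emulate: volume conduction and montage geometry,
1/f background spectra, non-stationarity, inter-subject variability,
artifacts.  Classes are separable by spectral signature alone, so a
passing end-to-end test demonstrates that the chain — features,
reduction, detector geometry, decision rule — is implemented coherently
and recovers recoverable structure; it does not predict accuracy on real
recordings, where class patterns overlap heavily.

## Numerical choices and degenerate inputs

- Sigmoid computed in the numerically stable two-branch form.
- Log floor 1e-10 on filterbank energies; KL clamp 1e-8 on ρ̂.
- Constant feature columns normalize to 0.5; out-of-bounds test values
  clip to [0, 1].
- Match rule is a *strict* inequality (distance exactly equal to the
  radius is no match); monitor ties break to the lowest detector id.
- Divergent autoencoder training (non-finite loss) raises, naming the
  epoch; an infeasible detector space (no candidate clears the padded
  self region) raises with advice rather than looping.
- Each (class, training seed) GA uses an independent PCG64 stream
  derived as `(ga_seed + 1000003·seed + 7919·class) mod 2^31`; the SAE
  seed is derived analogously — everything downstream of one seed is
  bitwise reproducible, and serialized models round-trip byte-exactly.
- Summary SD uses the n−1 denominator; a singleton list reports SD 0
  with an explicit degenerate flag.

## Problem sizes used in the shipped checks

Unit fixtures use 6 epochs/class with a reduced training budget (60 SAE
epochs, 12 GA generations, population 20, 4 detectors); the end-to-end
recovery check and the acceptance script run the full default session
(72 epochs/class, H1 = 16, H2 = 8, N_d = 30, full GA budget) — about
12 s per seed — and the grid-search check runs a 2×2×2 sub-grid after
verifying the full grid's 250-cell enumeration.

## Known limitations

- The Levenberg–Marquardt optimizer sometimes used for autoencoder
  training is an extension point; the shipped optimizer is plain
  full-batch gradient descent, which minimizes the same objective and
  keeps the gradient testable.
- No cepstral liftering or delta coefficients; no r-contiguous-bits
  (binary) negative selection; no niching beyond the diversity factor;
  no online/operational BCI phase.
- Grid search refits the autoencoder per cell; the full 250-cell grid
  at full training budget is hours of CPU, so use the reduced budget or
  a sub-grid for exploration.
- The GDF adapter (for real Graz 2a recordings) is optional, isolated
  behind one loader function, and requires MNE.
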