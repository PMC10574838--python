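# Methods

## Data model and preprocessing

A recording is the Daphnet freezing-of-gait text layout: one row per 64 Hz
sample with a millisecond time stamp, nine acceleration channels in milli-g
(ankle/thigh/trunk × forward/vertical/lateral) and an annotation in
{0, 1, 2} — 0 outside the experiment, 1 walk/stand/turn, 2 freeze.
Annotation-0 rows are retained at read time (so raw corpus statistics stay
observable) and removed in `preprocess`, which also binarizes labels:
freeze (2) → 0, no-freeze (1) → 1. Rows are treated as independent tabular
samples; no windowing, filtering or resampling is applied.

The train/eval split is a seeded uniform row split with
`floor(0.8·N)` training rows. At the published corpus size N = 1,140,835
this gives exactly 912,668 / 228,167. Whether the original split was
random, chronological or subject-wise is not documented; row-level random
is the simplest choice consistent with the printed arithmetic, and the
split seed makes it reproducible.

Features are standardized per feature (zero mean, unit variance) with
parameters fitted on the training split only. Standardization suits the
generator's unbounded linear output head. A constant feature keeps scale 1
so the transform stays invertible; `apply` then `invert` recovers inputs to
1e-9.

## Networks

Both networks and the classifier are dense ReLU stacks implemented directly
in numpy (`foggan.nn`): He-initialized hidden layers, Glorot-scaled heads,
inverted dropout, reverse-mode gradients taken at the head's
pre-activation, and Adam. A finite-difference check pins the gradients; the
closed-form parameter count Σ(fan_in+1)·fan_out is tested against
enumeration of the realized arrays.

* **Generator**: input 8 (standard normal), hidden widths
  1536-1278-1024-512-384-256-128-64-32-16, linear 9-unit output;
  4,152,071 parameters. The noise dimension is not stated anywhere
  directly, but the first layer's printed 13,824 parameters force
  (d+1)·1536 = 13,824 ⇒ d = 8. Standard normal is the conventional choice
  for an otherwise unspecified noise source.
* **Discriminator**: input 9, the same hidden widths, dropout 0.2 after
  every hidden layer, one sigmoid unit. The printed discriminator table
  duplicates the generator's rows verbatim — an 8-wide input and a 9-unit
  sigmoid head, which cannot produce the scalar probability the value
  function needs — so it is treated as a table artifact:
  `printed_discriminator_spec()` preserves its arithmetic (total
  4,152,071), while the functional network takes the 9 features and ends in
  one unit. Dropout placement follows the table (after every hidden layer)
  rather than the narrower prose description, the table being the more
  complete specification.
* **Classifier**: input 9, hidden 64-32-16-8 with dropout 0.2 after each,
  softmax pair head; 3,402 parameters; cross-entropy, Adam at 0.001,
  batch 64, 250 epochs by default. Deliberately un-tuned: it is an
  instrument for judging data, not a detector. Per-class recalls are
  reported alongside accuracy because freeze is a heavy minority class and
  headline accuracy alone can hide it.

## Adversarial training

One discriminator step then one generator step per minibatch (the update
ratio is otherwise unspecified; 1:1 is the baseline convention). The
discriminator step does a single forward pass over the concatenated real
and generated half-batches, so one dropout mask spans both. The generator
step backpropagates through a frozen discriminator (fresh noise, fresh
dropout mask) into the generator. Non-finite losses abort with the epoch
named. All randomness — initialization, shuffling, noise, dropout — derives
from one config seed through spawned `SeedSequence` children, making runs
bit-reproducible.

Default hyperparameters are the published protocol: 500 epochs, batch 50,
learning rates 0.001 (D) and 0.01 (G), here given to Adam (the optimizer is
otherwise unnamed; the rates match common Adam usage). The generator loss
defaults to the non-saturating form with a `literal` switch; both modes are
tested.

Labels for synthetic data come from **per-class generators**: the 9-unit
output leaves no room for a label channel and nothing specifies a
conditioning mechanism, so one GAN is trained per class and
`sample_synthetic` apportions a requested class mix by largest remainder
(defaulting to the training prevalence), then inverse-standardizes to
original units.

### Fixture-scale stability

At reduced widths on simulated corpora, Adam with the published generator
rate 0.01 reliably collapses the generator (output SD → 0 within a few
thousand steps); at 1e-3 the same runs recover a ρ = 0.8 Gaussian's
correlation to 0.90–0.98. `GanTrainConfig` keeps the published defaults;
the pipeline configuration (`RunConfig`) trains its reduced-width fixture
GANs at 1e-3. The point-mass sanity oracle converges under either rate.

## Similarity diagnostics

All metrics compare two original-unit feature matrices:

* **Correlation**: Pearson (the specific coefficient is otherwise
  unnamed; Pearson is the default reading), symmetric with unit diagonal;
  a constant column gets off-diagonal 0 and a flag. Magnitude bands use
  half-open intervals |r| < 0.01 negligible, [0.01, 0.1) moderate,
  [0.1, 0.16) high, ≥ 0.16 highly significant — closing the gaps between
  the published interior points (0.01–0.1, 0.1–0.15, 0.16–0.3) without
  moving them.
* **Cumulative sums**: running totals per feature in row order — the one
  diagnostic that is deliberately not row-permutation invariant.
* **Log mean/SD**: per feature, (log₁₀(|mean|+ε), log₁₀(SD+ε)) with
  ε = 1e-12 guarding zeros. Base 10 chosen (the base is unstated).
* **PCA**: fitted on the standardized real matrix only; the synthetic cloud
  is standardized with the real parameters and projected with the real
  loadings, so shifts and shape differences remain visible. Explained
  variance ratios are non-increasing by construction.
* **Distributions**: two-sample KS statistic (empirical-CDF supremum, via
  scipy) and Jensen–Shannon divergence with natural log over 50 equal-width
  bins spanning the pooled per-feature range — bounded by ln 2, attained on
  disjoint supports.
* **Scalars**: no closed formula for a "similarity score" is given
  anywhere, so the report defines two: max|Δcorr| and mean per-feature
  KS — simple, bounded, monotone in dissimilarity.

Reports serialize to JSON losslessly; cumulative-sum curves and PCA
projections are stored downsampled (512 / 2000 points) to keep files small.
Five PNG figure families (correlations, cumsums, log mean/SD, PCA,
per-feature histograms) can be rendered on demand.

## The simulator

`foggan.simulate` emulates the corpus schema, not its biomechanics. Every
channel carries a gravity-projection baseline (≈980 milli-g on vertical
axes) plus white sensor noise (SD 30 milli-g). Walk segments add a coherent
2 Hz sinusoid (one gait phase per recording, amplitude 100 milli-g forward,
attenuated 0.6/0.3 on vertical/lateral); freeze segments add independent
band-limited 3–8 Hz trembling (amplitude 60 milli-g, strongest vertical,
forward attenuated to 0.35 — trembling in place with little forward
progress). The regimes are therefore separable both spectrally (1–3 Hz vs
3–8 Hz band power, asserted by a periodogram test) and by cross-channel
coherence, giving the classifier genuine structure.

`make_fixture_dataset` plans segments in exact row counts (6% annotation-0
margins, freeze bursts of ~3 s spread through walking bouts), so the
planned class counts survive preprocessing exactly and the freeze share
after preprocessing matches the requested prevalence. Default study
conditions for the pipeline: ~50,000 rows over 8 recordings, 10% freeze
prevalence — large enough for stable training, small enough that the whole
pipeline (two GANs, classifier, diagnostics) finishes in about a minute on
one CPU.

What the simulator does **not** reproduce: real gait spectra and their
subject variability, sensor saturation and drift, autocorrelated noise,
freeze-onset dynamics, or between-subject heterogeneity. Passing fixtures
therefore demonstrates that the machinery is correct and that the GAN can
capture a low-dimensional structured distribution — not that it reproduces
clinical FoG data; published headline accuracies on the real corpus
(90.29 / 92.09 / 90.66%) require the external download and are out of this
package's desk-reproducible scope.

## Fixture-scale problem sizes

The pipeline defaults train reduced-width GANs (64-32-16) for 60 epochs and
the classifier for 40 epochs on the ~50k-row fixture; the Gaussian-recovery
checks use width 32-16 nets, 200 epochs, 2–4k rows. These sizes were chosen
once as the smallest at which the behaviors of interest (distribution
recovery, utility preservation) are stable across seeds; the full published
schedule remains available through the config.

## Degenerate inputs and numerical choices

Probabilities are clipped at 1e-7 inside log losses; ε = 1e-12 guards the
log-scale summary; constant features get scale 1 in the standardizer and
correlation 0 with a flag; a class mix is apportioned by largest remainder
so counts always sum exactly; empty preprocessing output, single-class
training sets, unfitted scalers, malformed file lines (named by line
number) and infeasible fixture targets all raise immediately with specific
messages rather than propagating NaNs.

## Known limitations

* Adversarial training in pure numpy is single-threaded and minibatch-bound;
  the full-width 500-epoch schedule on a million-row corpus is out of
  interactive reach here, which is why the pipeline defaults are
  fixture-scale.
* Per-class GANs assume the class label is the only conditioning worth
  preserving; cross-class temporal structure (freeze onset following gait
  deterioration) is not modeled — rows are i.i.d. by design.
* The similarity scalars are descriptive, not inferential: no significance
  testing or privacy/memorization auditing is performed.
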