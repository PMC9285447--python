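# Methods

## The transfer design

The unit of inference is a *transfer condition*: a sequence model is trained
to map phone-feature sequences to target vectors in five languages and
evaluated, without any further training, on concepts it has never seen, in a
language (and language family) it has never seen.  If the form→target
mapping learned in the training languages transfers, the phonological cues
it exploits must be shared across languages; etymological relatedness is
excluded by the family-level holdout, and concept memorization by the
concept-level split.  Chance level is estimated empirically by a *randomized
baseline*: a model with the identical architecture, seed, and inputs, trained
on the same targets after a uniform random permutation of the input–output
pairing.  The permutation is drawn once over the whole concatenated
five-language training set (a per-language variant is available through the
`groups` argument of `shuffle_targets`).

Six languages, one per family, give six conditions; each language is held
out exactly once.  The concept split is drawn once per run and reused across
folds, with |train| = round-half-up(ratio·n) — the rounding convention that
reproduces the published split sizes 1161 → 929/232 and 24612 → 19690/4922
at ratio 0.8, where floor would give 928/19689.

## The synthetic lexicon generator

No public multilingual resource provides ground truth about iconicity, so
the generator plants one.  Its defaults are the study conditions used
throughout the tests.

* Concepts: `n_concepts = 600` latent meanings `m_i ~ N(0, I_16)`; word
  class `c_i ~ Categorical(p)` with `p ∝ 1/rank` over `C = 5` classes
  (skewed, as natural tag distributions are).
* Targets: visual `v_i = max(0, A m_i + σ ε)` (nonnegative, 64-dim,
  emulating rectified convolutional feature maps), semantic
  `s_i = B m_i + σ ε` (signed, 32-dim, emulating corpus embeddings), with
  `σ = 0.1` and fixed random readouts `A`, `B`.
* Forms: for concept *i* in language *l*, word length is uniform on [3, 9]
  and each phone is drawn i.i.d. from a softmax over the 40-phone inventory
  with scores `[β·iconic + γ·systematic + λ·bias] / τ`, `τ = 0.5`, `λ = 1`.
  The iconic component is `cos(feat(p), u_i)` with `u_i = tanh(G m_i)`; the
  systematic component is `s_c · cos(feat(p), w_c)` with
  `w_c = tanh(H·onehot(c))`; the bias `b_{l,p}` is i.i.d. standard normal
  per (language, phone).  `G` and `H` are shared by all languages, so β and
  γ control a genuinely cross-lingual signal while λ controls
  language-specific phonotactics.
* Feature table: 40 distinct nonzero vectors in {−1, 0, +1}^24.  The
  all-zero vector is reserved for padding, which is why feature tables
  reject all-zero rows.

Two normalization choices matter and were made on analytic grounds:

1. **Component standardization.**  Raw cosines over a random 40-phone
   inventory have spread ≈ 1/√F ≈ 0.2 across phones while the bias is
   unit-spread, so without rescaling, β = 1 against λ = 1 would be a ~5:1
   mismatch in favor of the bias and the "strength" parameters would not
   mean what they claim.  Each score component is therefore centered per
   row and scaled by one pooled (not per-row) standard deviation, keeping
   β, γ, λ commensurable while preserving relative spread *between* rows.
2. **Class distinctiveness.**  Real word classes differ enormously in
   phonological markedness (interjections and small closed classes are far
   more phonetically stereotyped than large open classes).  Under cosine
   scores this heterogeneity cannot emerge from the class-direction draw —
   the spread of `cos(feat(p), w)` across phones is set by the phones'
   dimensionality, not by `w` — so it is modeled explicitly: a per-class
   profile `s_c` (default log-spaced from 6 to 0.1 in class-frequency
   order, rms-normalized, configurable via `class_distinctiveness`).
   Without it, every class is equally transparent by construction and the
   cross-language consistency of per-class accuracy — the very quantity the
   follow-up analysis measures — is degenerate at zero.

What the generator does *not* emulate: syllable structure and sonority
constraints, morphology, polysemy and translation noise, class systems that
disagree across languages, and multiple exemplars (images) per concept.
Passing tests therefore demonstrate that the pipeline detects a shared
form–meaning/form–class signal when one exists and stays quiet when none
does — not that natural lexicons contain such a signal.

## The sequence mapper

A single masked LSTM layer (Glorot-uniform kernels, orthogonal recurrent
weights, forget-gate bias 1) reads the padded 15×F input; masked positions
carry the hidden and cell state forward unchanged, so predictions are a
function of the unmasked prefix only.  A dense head produces the output:
ReLU for nonnegative visual targets, linear for semantic targets, softmax
for classes.  Training minimizes negative mean cosine (the only sensible
reading of "cosine as objective") or categorical cross-entropy, with Adam
(lr 0.01), batch size 32, dropout 0.2 and recurrent dropout 0.2 in the
variational convention (one input mask and one recurrent mask per sample,
shared across timesteps, training only).  Prediction is deterministic.

The implementation is plain NumPy.  At the problem sizes used here (≤ 64
hidden units, ≤ 15 timesteps, thousands of samples) this is fast enough,
dependency-free, and bitwise reproducible from a single seed; the analytic
backward pass is validated against central finite differences to 1e-5
relative error in the test suite.  Cosine gradients clamp the prediction
norm at 1e-7 so an all-zero ReLU output cannot divide by zero; Adam bounds
the resulting step size.  Reference layer widths for the three experiments
are 500 (visual), 50 (semantic) and 25 (word class); the synthetic-scale
analyses use 64/50/32 units and 5 epochs so that a full sixfold run takes
tens of seconds on one CPU.

## Statistics

* Per-fold cosine summaries: mean, sample SD (n−1), and the normal 95% CI
  `mean ± 1.96·SD/√n`.  The 1.96 multiplier (rather than a t quantile)
  reproduces the published CIs at n in the thousands.
* Paired contrast: `t = mean(d)/(sd(d)/√n)`, two-sided p on n−1 df, and
  the paired effect size `d = mean(d)/sd(d)`.  A zero-variance difference
  is reported as t = ±∞, p = 0 (or t = 0, p = 1 when the mean is also
  zero) rather than NaN.
* McNemar on paired correctness: χ² = (b−c)²/(b+c) with 1 df, no
  continuity correction by default (a corrected variant is behind a flag);
  b + c = 0 is reported as χ² = 0, p = 1 with a degenerate flag.
* Classification metrics: accuracy, support-weighted precision and F1
  (scikit-learn; a class never predicted contributes precision 0), and
  per-class accuracy = per-class recall.  Support-weighted recall equals
  accuracy and is not reported separately.
* Cross-language consistency: per-class accuracy profiles per held-out
  language, their per-class mean across languages, and the mean Pearson r
  over all unordered language pairs; zero-variance profiles are excluded
  and flagged.  Classes with no test support in some language (NaN recall)
  are dropped from the profiles first.

No multiple-testing correction is applied across the six folds, matching
the original reporting.

## Calibration and problem sizes

The test suite exercises three regimes, chosen to fit one CPU in minutes:

* **Signal recovery** (β = 1, γ = 0): 600 concepts, hidden 64, 5 epochs;
  the experimental model beats its baseline at p < 0.01 in ≥ 5/6 folds for
  every seed tried.
* **Word-class recovery** (γ = 1): 600 concepts, ratio 0.5, hidden 32,
  5 epochs; McNemar p < 0.01 in ≥ 5/6 folds and mean pairwise r > 0.5.
  Occasional lexicon draws produce one adversarial held-out fold whose
  transfer collapses (the zero-shot analogue of a genuinely distant
  language — the naturalistic study had such a fold too), which depresses
  the consistency statistic; the planted effect itself is robust.
* **Null calibration** (β = γ = 0): 240 concepts, hidden 32, 2 epochs, 20
  independent single-fold runs with rotating held-out language; rejections
  at α = 0.05 stay within binomial tolerance of the nominal rate.

## Known limitations

* The generator's phone-choice model is position-independent (no
  phonotactics); the LSTM's sequential capacity is therefore not stressed
  beyond order-invariant aggregation.
* Per-class accuracy profiles over only five classes make the pairwise
  Pearson r a coarse statistic with few degrees of freedom.
* With one entry per (concept, language), per-concept exemplar counts
  (multiple images per concept in the naturalistic design) are not
  represented; published sample sizes that depend on them are reproduced
  arithmetically, not by simulation.
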