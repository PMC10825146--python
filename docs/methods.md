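# Methods

## The translation model

`autotransop` couples two biological systems — two cell lines, or two species
— each observed through its own omics panel. The panels need not share any
features. Each system *s* gets its own encoder E_s and decoder D_s (no weight
sharing); the encoders map profiles into one **global latent space**, and the
model is trained so that embeddings of samples that underwent the *same
experimental condition* in different systems end up close together. A
condition is a perturbagen + dose + time triple for perturbation data, a
diagnosis label for disease data, or a protection label for serology panels.
Translation of a profile from system A into system B is then simply
D_B(E_A(x)): encode with the source encoder, decode with the target decoder.

Encoders and decoders are stacks of fully-connected → batch-normalization →
ELU → dropout blocks with a final bias-free linear projection. In count mode
the encoder first multiplies the log10(count+1)-transformed input elementwise
by a trainable per-gene scaling vector, and the decoder emits two heads —
negative-binomial mean μ and inverse-dispersion θ, both passed through
softplus with a 1e-8 floor — with Var = μ + μ²/θ (θ → ∞ recovers the Poisson
limit).

### Objective

The training loss combines, with configurable non-negative weights λ:

- **Reconstruction** — per-sample sum of squared errors averaged over samples
  (z-score mode), or the negative-binomial negative log-likelihood summed per
  sample and averaged (count mode).
- **Alignment of paired conditions** — over all in-batch positive pairs
  (same condition, different system): the mean Euclidean distance is
  *minimized* and the mean cosine similarity is *maximized* (it enters the
  total with a negative sign). The cosine term doubles as a soft
  normalization pressure on the embeddings.
- **Jensen–Shannon mutual-information bound** — a discriminator (three shared
  FC+ReLU layers plus a linear skip; pair score = inner product of the two
  transformed embeddings) scores every ordered pair in the batch. With a
  binary mask M of positives,
  E_p = mean over positives of [ln 2 − softplus(−D)] and
  E_q = mean over off-diagonal negatives of [softplus(−D) + D − ln 2];
  the loss term is −(E_p − E_q). Self-pairs are excluded from the negatives:
  counting a sample against itself as a "different condition" is degenerate.
  Batches with no positives (or no negatives) skip the term.
- **Prior term** — a second discriminator scores whether a latent vector was
  drawn from a uniform [0,1] reference. The framework *adds*
  mean[log D(v) + log(1 − D(z))] to its objective, i.e. the encoders are
  pushed to make embeddings distinguishable from the uniform reference
  (divergence from the prior is maximized, not minimized — embeddings resist
  being uniformized without a performance cost). The discriminator itself is
  updated in its own alternating step to keep discriminating; an encoder-side
  sign flag is exposed for the conventional prior-matching direction.
- **Classifier cross-entropies** — task classifiers (softmax MLPs) on the
  latent space, one entropy term each, plus L2 penalties on all encoder,
  decoder and classifier weights.

Three variants:

- **v1** — the basic model above.
- **v2** — adds (a) trainable covariate vectors: the **composed space**
  z_c = z_g + v_system (+ v_celltype), from which the decoders reconstruct
  and in which the task classifiers operate (an intermediate-network
  alternative to the additive vectors is available); (b) an **adverse system
  classifier** on the global space, trained in alternating steps on its own
  cross-entropy while the framework receives −λ_adverse · entropy_adverse
  (the encoders are rewarded for fooling it); and (c) an L2 penalty on the
  covariate vectors. Before joint training the adverse classifier is
  pre-trained together with the encoders and discriminators only (decoders
  and task classifiers frozen), for a default 10% of the epoch budget.
- **v3** — adds a *cooperatively* trained system classifier on the global
  space (its entropy joins the classifier sum), deliberately embedding some
  system information in a subset of latent variables.

The adverse classifier and the prior discriminator are excluded from the main
optimizer; everything else trains simultaneously with adaptive-moment
gradient descent (plain SGD selectable) at a single learning rate. Batches
are sampled condition-wise so both members of a paired condition co-occur;
the mask of positives is rebuilt per batch. A side of a batch with fewer than
two samples is dropped (batch normalization needs ≥ 2 rows).

Published defaults per study mode are available via
`ModelConfig.for_study_mode` (978-gene perturbation panels: latent 292,
encoder [640, 384], batch 512, 1000 epochs, lr 0.001; 10,086-gene: latent
1024; single-cell lung fibrosis: latent 512, 200 epochs; serology: latent 32,
batch 50, 2000 epochs). The λ weights default to 1.0 and are fully
config-exposed; the small-scale experiments in this repository use the
weights recorded in the test-suite (`small_weights()`): recon/distance/cosine
1.0, MI 0.1, prior 1e-3, L2 1e-6, chosen once so that all terms are active
without any one dominating at these layer sizes.

### Cross-validation

`make_folds` assigns *conditions*, not samples, to k folds, so a paired
condition is hidden from training in both systems at once. Fold sizes differ
by at most one condition.

## Compute engine

The networks, losses and attribution run on a small tape-based reverse-mode
automatic-differentiation engine over numpy float64 arrays
(`autodiff.Tensor`), with the layers in `nn.py`. Numerical choices: softplus
is computed in the stable branch form max(x,0) + log1p(exp(−|x|)); the
logistic is tanh-based; discriminator and classifier probabilities are
clamped to (1e-7, 1 − 1e-7) before entering logs during training; the
Euclidean pair distance adds 1e-12 inside the square root so its gradient is
defined at coincident embeddings. Training is seed-deterministic given fixed
thread settings: one generator seeds initialization, dropout, batch order and
prior draws.

## Synthetic data: what it emulates and what it does not

`synthdata` generates the structure the model assumes. Every condition c has
a true latent state u_c ~ N(0, I); system s observes
x = W_s g(u_c) + b_s + ε with W_s entries ~ N(0, 1/√d) (outputs O(1)),
an additive system offset b_s, ε ~ N(0, noise_sd²), and g identity or tanh.
A `paired_fraction` of conditions appears in both systems; the rest are
split alternately between them. Defaults — 300 conditions, half paired,
50/80 disjoint features, true latent dimension 10, unit system-effect scale,
noise_sd 0.25 (a quarter of the O(1) signal scale) — are the benchmark
conditions used by the acceptance experiments. Count mode exponentiates the
clean profiles into per-gene means and draws gamma–Poisson counts with
inverse-dispersion θ (default 3). Serology mode draws per-subject protection
labels (exactly balanced), plants the protection effect on a known 20% of
features per species through a dedicated latent direction, and returns the
planted sets for recovery tests.

The generator reproduces: disjoint feature spaces, a shared low-rank
condition effect, additive system effects, replicate noise, NB counts, and a
protection-linked factor with no 1-to-1 feature homology. It does **not**
reproduce gene-regulatory covariance structure, heavy-tailed or batch-derived
artefacts, dose–response monotonicity, or realistic class imbalance — so
passing tests show the machinery recovers the structure it models, not that
it will perform identically on real panels.

**The no-model translation baseline.** "Direct translation" (use the source
profile as the prediction) needs a shared feature space. On disjoint panels
the benchmark defines the baseline as the Pearson r between index-matched
columns (the first min(p_A, p_B) features) of paired source and target
profiles — the closest analogue of using one system's profile for the other.
With independent loadings this baseline fluctuates around zero, which is the
point: it carries no cross-system mapping.

## Evaluation, attribution and selection

- Classification: accuracy and (micro-)F1 from one-vs-rest confusion counts.
- Fidelity: global Pearson r on flattened matrices; per-sample Spearman
  (average-rank ties); sign accuracy with a 1e-6 "true zero" tolerance;
  per-gene R² = 1 − RSS/TSS for count-mode means and variances.
- Separation: cosine distance (0 identical … 2 opposite) distributions for
  random / same-system / same-condition / replicate pairs, with Cohen's d
  (pooled-SD) against random pairs; negative d means the category is closer
  than random.
- GSEA rank distance: for each threshold t, the top-t and bottom-t genes of
  each profile are scored in the other profile's ranking with an unweighted
  running-sum enrichment score (hit +1/|S|, miss −1/(N−|S|), signed maximum
  deviation); the two directions are combined so identical rankings give 0
  and exactly reversed rankings give 2, averaged over thresholds
  {100, 250, 500} (scaled proportionally for universes under 1000 genes; a
  threshold may equal, but not exceed, half the universe). The same ES kernel
  drives pre-ranked gene-set enrichment with gene-label permutation p-values.
- Integrated gradients from a zero baseline, left-Riemann rule with 50 steps
  by default (midpoint/trapezoid selectable); completeness
  Σᵢ scoreᵢ = F(x) − F(0) holds up to the quadrature error, so convergence
  checks use the trapezoid rule.
- Latent-variable selection: (a) 3-means on absolute importance scores —
  lowest-centroid cluster is the unimportant bulk, highest is a small outlier
  cluster, and the threshold is the midpoint between the highest unimportant
  and lowest important score; (b) per-latent likelihood-ratio tests of
  `latent ~ protection + vaccination + species` against the nested model
  without protection (Gaussian OLS likelihoods, 1-df χ², Benjamini–Hochberg
  FDR, t-value of the protection coefficient reported; no interaction
  terms). The final protective set intersects FDR-significant latents with
  IG-important ones (average per-fold percentage of the maximum |score|
  ≥ 10%) whose signs agree.
- Serology feature identification: IG of every source feature w.r.t. each
  protective latent (or, cross-species, w.r.t. selected translated target
  features), averaged over that species' samples; percentage scores with a
  ≥ 20% flag; Wilcoxon rank-sum (Bonferroni) between protected and
  unprotected for same-species features; the four-filter network rule
  (reconstruction r ≥ 0.75 inclusive; fold-SD in the bottom quartile of all
  pairs; raw |score| > 10 — the magnitude filter operates on the raw signed
  scale; survivors' top |score| quartile).

## Baselines

- DeepCellState-style: one shared encoder, two decoders, input dropout 0.5,
  L1 penalty on latent activations, leaky-ReLU hidden layers, tanh output.
  `original` keeps an additive linear skip from the dropped input to the
  output layer; `mod1` removes it; `mod3` adds a same-condition latent
  distance term; `mod2` additionally penalizes direct cross-system
  translation error. Hidden sizes default to the main framework's for
  comparability.
- TransCompR-style: PCA of the target system; source profiles are projected
  into that space and regressed (linear by default, MLP selectable) onto
  target profiles. Zero components degenerate to the target mean.
- FIT-style: per-gene regression on paired conditions minimizing
  Σ(y − (a x + b))² + λ_f[(a − 1)² + b²]; λ_f → ∞ gives the identity map,
  λ_f = 0 ordinary least squares. The quadratic penalty form is this
  package's choice; only the constraint direction (slope 1, intercept 0) is
  prescribed.
- Direct translation: the identity, defined only on shared feature spaces.

## Problem sizes used by the test-suite and acceptance experiments

Training experiments run at reduced width and epoch counts chosen so the full
suite completes comfortably on one CPU: translation recovery trains v1
(latent 16, hidden 64, batch 128, 150 epochs) on the default benchmark
conditions with one cross-validation fold held out, for five seeds; the
globality experiment trains v2 the same way with a composed-space system
classifier and the adverse classifier; the serology recovery experiment uses
120 subjects per species, 40/60 features, protection effect 2.0 and a
latent-8 v2 model. LRT calibration uses 1000 independent null latent
variables at n = 100.

## Known limitations

- Exactly two systems per model; multi-system translation requires chaining.
- The MI estimator follows the Jensen–Shannon bound construction; it is a
  relative training signal, not a calibrated mutual-information estimate.
- The LRT assumes a linear Gaussian relation between latent embeddings and
  the covariates.
- K-means latent selection assumes three score bands exist; it refuses
  degenerate inputs rather than guessing.
- The prior term's adversarial game is deliberately asymmetric (divergence
  maximized); swapping the sign flag changes the dynamics and is untested
  beyond smoke level.
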