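# Methods

## Point-process likelihoods

A single neuron's spiking on `(0, T]` is modeled through its conditional
intensity `λ(t | H_t)`; within-trial history dependence enters only through
the latent state (below), and trials are treated as independent. The
interval is discretized into `J` bins of width `Δ` chosen so that at most
one spike falls in a bin; binning uses half-open, 0-based bins
`[t0 + kΔ, t0 + (k+1)Δ)`, with a spike exactly at the interval end assigned
to the last bin (the convention is otherwise arbitrary and is fixed here
once). Two spikes in one bin are an error, not a silent merge — the remedy
is a smaller `Δ`, and the error says which bin overflowed.

Two discrete likelihood forms are exposed:

- **local-Poisson** (default): `Σ ΔN_k ln(λ_k Δ) − Σ λ_k Δ`. This is the
  discrete counterpart of the continuous-time density
  `Σ_j ln λ(u_j) − ∫ λ`, which exponentiates the integrated intensity, and
  it remains valid when `λΔ` is not small.
- **Bernoulli**: `Σ [ΔN ln(λΔ) + (1−ΔN) ln(1−λΔ)]`, the exact product
  mass over binary vectors. The two agree to `O((λΔ)²)` per bin. The
  Bernoulli form is the right one whenever a *normalized* distribution over
  binary response vectors is needed — it is what the information module's
  enumeration oracle and Monte-Carlo estimator use.

All likelihood arithmetic is in log space (nats; the information module
alone converts to bits): products over `J ≈ 1000` bins underflow in linear
space. The binned and continuous log-likelihoods differ by the Jacobian
`n ln Δ` of the discretization; `binning_jacobian` removes it when the two
must be compared.

## EKF intensity estimation

The log-intensity is a linear-Gaussian latent state, `x_k = F x_{k−1} + ε_k`
with `ε_k ~ N(0, Q)`, observed through the exponential link
`λ_k = exp(c·x_k)` (guaranteeing positivity). Counts are pooled per bin
across the `M` trials of one stimulus; the observation model is linearized
about the one-step prediction mean with expected count `MλΔ`, Jacobian
`MλΔ·c`, and observation-noise variance set equal to the expected count —
the Poisson-like choice appropriate for small `Δ`. A single state path is
filtered through the pooled counts; the fitted `λ̂_k = exp(c·x̂_k)` is the
intensity of one trial (multiplicity lives in the observation model, not the
link).

Defaults and their reasoning:

- `F = I` (random walk): no basis for richer dynamics is assumed.
- `Q = q·I` with `q = 1e-5` per bin, user-set; there is no hyperparameter
  estimation (EM) step. `q` should be on the order of the squared per-bin
  drift of the log-intensity it must track: a 2 Hz sinusoidal modulation of
  amplitude 0.7 at `Δ = 1 ms` drifts ~0.009 per bin, so `q ≈ 1e-3` tracks it
  (correlation ≥ 0.9 at 50 trials), while the stationary default favors
  smoothness. With `q = 0` the filter collapses to a static estimator and
  converges to the closed-form homogeneous rate MLE.
- `x0 = ln(max(mean rate, 1 Hz))`, `S0 = I`: a data-scaled neutral start.
  The diffuse start causes a short upward-biased transient (Jensen: the
  exponential of a noisy state overestimates the rate); it decays within
  ~100 bins.
- `λΔ` is clamped to `[1e-6, 0.99]` so it stays a valid per-bin probability
  and the link cannot overflow; hitting the upper clamp warns.
- Covariance updates use `(I − KC)S`, symmetrized each step; the Joseph form
  `(I−KC)S(I−KC)' + KRK'` is available and agrees to 1e-8.

No backward smoothing pass and no nonlinear state dynamics are provided.

## Populations

`K` simultaneously observed neurons are pooled into a marked point process:
the ground process has intensity `λ_G = Σ_c λ_c` and each event's mark is
multinomial with `p_c = λ_c/λ_G`. Intensities at event times are read off
the bin grid as step functions (no interpolation); simultaneous spikes
across neurons are ordered by neuron index, an explicit documented
convention (a warning flags such ties). Under conditional independence the
population log-likelihood
`Σ_j [ln λ_G(w_j) + ln p_{c_j}(w_j)] − ∫ λ_G` is algebraically identical to
the sum of per-neuron log-likelihoods; the test suite asserts the identity
to 1e-10 on random instances rather than assuming it. Cross-neuron
dependence is out of scope.

## Likelihood space

Coordinates are log-likelihoods (raw likelihoods are available for
plotting). The Bayes rule `argmax_i [coord_i + ln p(s_i)]` in this space is
the observation-space plug-in Bayes rule by construction; the test suite
verifies exact (100%) agreement against an independent route through
per-bin Bernoulli pmfs. Decision regions in the likelihood space are
intersections of half-spaces, hence convex; the convexity check is a guard
against implementation error, sampling point pairs and re-classifying 11
equispaced convex combinations.

Separability is quantified by the Fisher discriminant ratio: clusters are
projected on `w = (S_a + S_b)^{-1}(m_a − m_b)` (population covariances,
ridge `1e-8·I` if singular, with a warning) and the ratio
`(m̃_a−m̃_b)²/(s̃_a²+s̃_b²)` of the 1-D projections is reported; for more
than two stimuli the mean over unordered pairs is used. Observation space
and likelihood space are compared through the Fisher ratios of their 2-D
classical-MDS embeddings (Euclidean distances of binary spike vectors vs
distances of likelihood vectors). Comparing instead in the raw
`J`-dimensional binary space is misleading when `J` is of the order of the
trial count: the whitened Fisher direction there contains the
log-likelihood-ratio axis itself and its sample-scatter inverse inflates
the ratio. On two stimuli with matched 20 Hz rates and opposite linear
temporal profiles (100 trials each), the embedding-based improvement
measures ~25–50% depending on the draw.

## Information

Specific information is the KL divergence between the stimulus-conditional
response distribution and the stimulus-averaged one, in bits (log base 2 —
chosen for comparability with the neural-coding literature; no base is
canonical). For point-process models the response alphabet (all binary
vectors) is intractable, so `I_ssi` is estimated as the Monte-Carlo mean of
`log2[p(obs|s_i)/p̄(obs)]` over trains observed under `s_i`, using the
Bernoulli likelihood form. Estimates computed on the same trials the models
were fitted to are biased upward (each model over-fits its own sample);
where the distinction matters — e.g. attributing information to tuning
rather than estimation noise — use held-out observations or ground-truth
models. No bias-correction scheme is implemented.

The between-stimulus distance is `|I_ssi(s_i) − I_ssi(s_j)|` — the absolute
value is a documented choice that guarantees symmetry and nonnegativity; as
a difference of scalars it is a pseudo-metric (distinct stimuli may sit at
distance zero).

Sliding-window analyses use 100 ms windows at 10 ms steps (so a 1 s trial
yields 91 windows); models are refit per window. The rate-framework
baseline estimates per-window spike-count histograms with Laplace smoothing
α = 0.5 to avoid `log 0`.

## Goodness of fit

Time rescaling maps inter-spike intervals through the integrated intensity;
`z = 1 − exp(−τ)` is uniform under the true model. The KS statistic is the
standard one-sample `D_n` against the uniform CDF, with the asymptotic 95%
band `1.36/√n` (the literature cites bounds without printing a formula; the
KS asymptotic constant is used). The KS plot pairs model quantiles
`(k−½)/n` with the sorted `z`; its sup distance differs from `D_n` by at
most `0.5/n`. For exclusively binned data, spike times are placed at bin
centers — a documented approximation; no differential correction for coarse
bins is applied. Under the true intensity, ~95% of simulated realizations
fall inside the band (measured 94–97.5% over 200-run batches).

## Geometry

Classical MDS is the Torgerson construction: `B = −½ J D² J`,
eigendecomposition, top-two eigenvectors scaled by the root eigenvalues.
(Eigenvectors of the dissimilarity matrix itself do not yield a valid
embedding; the double-centered form is the standard reading and is exact —
to 1e-8 — for genuinely planar Euclidean input.) Negative eigenvalues mark
non-Euclidean input; they are truncated with a warning and the retained
fraction of positive dispersion is reported. Proximity matrices are
optionally normalized by their maximum entry — the normalization rule is
otherwise unconstrained, and this choice is recorded here. Rate vectors
average each neuron's firing over the 70–270 ms response window, z-score
across stimuli per neuron, and scale each stimulus vector to unit length;
the correlation distance `1 − r` compares them. Sliding-window distances
(rate: correlation of per-neuron rate vectors, requiring ≥ 2 neurons;
likelihood: `|ΔI_ssi|`) report the window center of maximum dissimilarity
as the peak latency.

## Synthetic sessions

The generator emulates a passive-fixation categorization session: 36
stimuli in 6 categories, 50 repetitions, 300 ms stimulus + 700 ms
interstimulus interval + 100 ms pre-stimulus baseline, up to 100 neurons at
`Δ = 1 ms` — these are the generator defaults. Each neuron has a baseline
rate (5–10 Hz), a preferred category (log-gain 1.2–1.8, i.e. evoked peaks
~4–5× baseline, weak gains 0–0.4 elsewhere), a 70–110 ms onset latency,
and an evoked log-intensity shape mixing an alpha-function transient
(τ = 50 ms) with a sustained plateau (weight 0.4) that decays at stimulus
offset; 15% per-stimulus gain modulation distinguishes category members.

Spikes are drawn either by Lewis–Shedler thinning (exact in continuous
time) or by per-bin Bernoulli sampling. Thinning is the default; it can
place two spikes inside one millisecond-scale bin (the generator has no
refractory period), which downstream binning rejects by design, so
pipelines that re-bin at the generator's `Δ` should use the Bernoulli
sampler — the CLI's `simulate` does. What the generator does *not* emulate:
refractoriness and bursting, trial-to-trial gain drift, cross-neuron
correlations, and eye-movement or attentional covariates. Passing tests
therefore demonstrate correctness of the estimators under the stated
point-process assumptions, not robustness to these real-data features.

## Problem sizes and numerical choices

The test suite and the acceptance script run scaled-down sessions (2–6
stimuli, 10–100 trials, 1–3 neurons, `Δ` of 1–20 ms) — sizes chosen so the
full pipeline is exercised in seconds while keeping per-test Monte-Carlo
noise far from the asserted margins. Stochastic assertions are seeded;
tolerances follow the quantity being tested (1e-12 to 1e-8 for algebraic
identities, sampling-theory margins for Monte-Carlo ones). Degenerate
inputs are handled explicitly: empty trains are valid (likelihood
`−∫λ`), empty recordings cost the integrated ground intensity,
classification ties resolve to the smallest stimulus index, zero-prior
stimuli are excluded from the argmax, and a singular innovation covariance
or a non-probability input raises instead of propagating NaNs.
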