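# likspace — likelihood-space analysis of neural spike trains

Most spike-train analyses reduce a neuron's response to a firing rate and
discard the temporal arrangement of its spikes; purely temporal analyses do
the opposite. `likspace` implements a point-process framework that uses both
sources at once: each spike train is modeled by its conditional intensity
function, and every observed train is *projected* into a low-dimensional
**likelihood space** whose coordinates are its log-likelihoods under each
stimulus-conditional model. In that space, distribution-based classification
becomes a unit-slope linear discriminant, decision regions are convex, and
information-theoretic distances between stimuli fall out of the same
likelihoods. The package targets experiments of the visual-categorization
kind (many stimuli in a few categories, tens of repetitions, single neurons
up to ~100-neuron populations) and ships a synthetic-session generator so
every claim is testable without recorded data.

## The model

A spike train with spike times `u_1 < … < u_n` on `(0, T]` is characterized
by its conditional intensity `λ(t | H_t)`. Discretized into `J` bins of
width `Δ` (at most one spike per bin), its log-likelihood under an intensity
model is

```
log p(ΔN_1..J | λ) = Σ_k ΔN_k ln(λ_k Δ) − Σ_k λ_k Δ
```

(the local-Poisson form; the exact Bernoulli product mass is available as an
option). Components:

- **EKF intensity estimation** (`ekf`): the log-intensity is a latent
  linear-Gaussian state, `x_k = F x_{k−1} + ε_k`, with exponential link
  `λ_k = exp(c·x_k)`. Spike counts pooled across the `M` repeated trials of
  one stimulus drive an extended Kalman predict/update recursion with
  linearized observation mean `MλΔ` and observation-noise variance `MλΔ`.
- **Populations as marked point processes** (`population`): pooling `K`
  neurons gives a ground process with intensity `λ_G = Σ_c λ_c` and
  multinomial marks `p_c = λ_c / λ_G`; the population log-likelihood
  decomposes exactly into per-neuron terms under conditional independence.
- **Likelihood projection and classification** (`likelihood_space`): a train
  maps to `(log p(x|s_1), …, log p(x|s_P))`; Bayes classification is
  `argmax_i [coord_i + ln p(s_i)]`. Fisher discriminant ratios quantify how
  much more separable stimulus clusters are after projection.
- **Information** (`information`): stimulus-specific information
  `I_ssi(s_i) = Σ_r p(r|s_i) log2[p(r|s_i)/p̄(r)]` (bits), estimated by
  Monte Carlo over observed trains; `|I_ssi(s_i) − I_ssi(s_j)|` serves as a
  between-stimulus distance, also in 100 ms sliding windows.
- **Goodness of fit** (`gof`): time rescaling `τ_j = ∫ λ` between spikes
  turns a correct model's intervals into unit exponentials; a KS plot
  against the uniform CDF with the 95% band `1.36/√n` is the test.
- **Geometry** (`geometry`): classical (Torgerson) MDS of dissimilarity
  matrices, rate-vector correlation-distance baselines, sliding-window
  distance dynamics with peak latency.
- **Simulation** (`synth`): Lewis–Shedler thinning (exact) or per-bin
  Bernoulli sampling of category-tuned neurons with the session layout
  36 stimuli × 6 categories × ~50 trials, 300 ms stimulus + 700 ms ISI +
  100 ms baseline.

The estimators follow scikit-learn conventions (`PointProcessFilter`,
`LikelihoodSpaceClassifier`, `ClassicalMDS` with `fit`/`transform`/
`predict` and trailing-underscore attributes); module-level functions wrap
them for one-off use.

## Worked example

`examples/worked_example.py` simulates two stimuli with a matched 20 Hz
mean rate but opposite temporal profiles (decaying vs rising), fits each
conditional intensity by EKF, validates the fit by time rescaling, and
classifies in the likelihood space:

```
estimated mean rate (early): 23.1 Hz
correlation with ground truth: 0.978
KS statistic 0.0720 vs 95% band 0.1279 -> PASS
likelihood-space classifier accuracy: 0.975
separability improvement in likelihood space: 82.5%
```

A rate code cannot distinguish these stimuli at all (equal mean rates); the
likelihood space classifies 97.5% of trials correctly and its clusters are
substantially more separable than the raw binary-vector observation space.

There is also a CLI over the same pipeline:

```
likspace simulate --stimuli 6 --categories 3 --trials 20 --neurons 2 --out run/
likspace fit      --spikes run/spikes.csv --t-end 1.1 --out run/fit/
likspace gof      --spikes run/spikes.csv --intensity run/fit/intensity_0.csv \
                  --t-end 1.1 --out run/gof/
likspace classify --spikes run/spikes.csv --t-end 1.1 --out run/clf/
```

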