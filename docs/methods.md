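# Methods

## The model

`neurocast` forecasts regional brain activity as a graph-structured
sequence-to-sequence problem. The data are a matrix `X ∈ R^{N×T}` of N
parcel-averaged time courses (e.g. BOLD at TR = 0.72 s) and a weighted
undirected structural graph `G = (V, E, A_w)` whose edge weights come from
diffusion tractography. The model learns a map

    [x(t−T_p+1), …, x(t); G]  →  [x(t+1), …, x(t+T_f)]

with an encoder–decoder of stacked diffusion-convolutional GRU (DCGRU)
cells.

**Spatial term.** Information flow on the graph is modelled as a random
walk with transition matrix `T = D⁻¹ A_w`, `D = diag(A_w·1)`. A diffusion
convolution is a polynomial in this operator truncated at walk order K:

    y = Σ_{k=0..K} θ_k T^k x   (+ the analogous sum in Tᵀ),

computed by iterated sparse mat-vec products, never by materializing
`T^k`. The transpose (reverse-walk) direction is included by default; for
an undirected graph `T` is *not* symmetric unless all degrees are equal,
so forward and reverse walks genuinely differ. For spectral analysis and
testing, the symmetrically normalized operator `S = D^{−1/2} A_w D^{−1/2}`
— similar to `T`, hence with the same eigenvalues, but orthogonally
diagonalizable — provides a graph Fourier basis in which the same
polynomial filter can be applied exactly; the equivalence of the two
routes (to 1e−8 over random graphs) is a standing test. Both
normalizations are selectable; row-normalized is the default used by the
model.

**Temporal term.** A GRU whose dense products are replaced by diffusion
convolutions over the node-wise concatenation `[x, H]`:

    r = σ(Θ_r ⋆ [x, H] + b_r),  u = σ(Θ_u ⋆ [x, H] + b_u)
    c = tanh(Θ_c ⋆ [x, r⊙H] + b_c),  H′ = u⊙H + (1−u)⊙c

Two such layers form the encoder and two the decoder; a per-node linear
readout (shared across nodes) maps the top hidden state (Q features) to
the predicted frame. The decoder starts from a zero "go" frame and feeds
back its own predictions at test time. Filter weights are shared across
nodes, so the parameter count is independent of N and checkpoints can be
re-applied to a different graph.

**Objective and training.** Mean absolute error over the forecast window,
minimized by Adam on shuffled mini-batches (default 32) with gradient-norm
clipping at 5. During training, the decoder receives the ground-truth
previous frame with probability ε_i = τ/(τ + exp(i/τ)) at global
iteration i (scheduled sampling; one Bernoulli draw per decoder time-step
per batch), and its own prediction otherwise. Validation and testing are
always free-running. The learning rate starts at 0.1 by default and is
multiplied by 0.1 at epochs 20/40/60 or after a 10-epoch validation
plateau; before every decay, and at the end, the weights with the lowest
validation MAE are restored.

The published form of the sampling-decay formula contains a typo (it is
negative for all positive iterations); the implementation uses the
standard inverse-sigmoid decay above, which reproduces the documented
behaviour (ε ≈ 1 initially, 0.5 exactly at i = τ·ln τ, → 0 late).

**Autodifferentiation.** No deep-learning framework is used: gradients
come from a compact reverse-mode engine (`neurocast.autodiff`) over numpy
arrays, with exactly the primitives the model needs. Every primitive and
the full unrolled seq2seq loss are gradient-checked against central
finite differences in the test suite. The model runs in float32 by
default (float64 available for gradient checks).

## Preprocessing

Per session: zero-phase band-pass (order-5 Butterworth, forward–backward,
default 0.04–0.07 Hz), optional global signal regression (per-row OLS
residual on the across-region mean with intercept), then scaling —
min–max to [0, 1] per session for model input, or z-scoring for
population-unit reporting. Windows of T_p past and T_f future frames are
cut at every offset (T − T_p − T_f + 1 samples per session) and split
80/10/10 in temporal order per session. The flooring rule assigns the
*last* ⌊0.1·S⌋ samples to test and the preceding ⌊0.1·S⌋ to validation,
which makes a T = 1200, T_p = T_f = 30 session yield exactly 114 test
samples. Consecutive windows overlap across split boundaries; an optional
`gap` argument discards boundary samples for leakage-free evaluation
(default off, matching the reference protocol).

## VAR baseline

The linear baseline is a VAR(P) (default P = 30, the full-scale setting;
the desk-scale benchmark uses P = window length = 12). Two fits: (i)
closed-form least squares on the session time courses, pooling the lagged
design across sessions without crossing session boundaries — verified
against `statsmodels`' VAR on single sessions; (ii) a stochastic-gradient
fit (batch 1, lr 0.005, 100 epochs, decays ×0.1 at 70/90) minimizing the
*iterated* T_f-step forecast MAE on the same windowed samples the
recurrent model uses, so both model families optimize the same objective.
Multi-step forecasts always feed predictions back. An augmented
Dickey–Fuller unit-root check (AIC lag selection, α = 0.01) is reported
per region but not enforced. Note the MAE objective has sign gradients,
so the SGD fit's attainable precision is set by its final learning rate;
it approaches, but does not exactly reach, the OLS solution.

## Causal influence

For a trained model, the influence of source region(s) n′ on target n is

    I_n(n′) = (1/S) Σ_s (1/T_f) Σ_t | x̂_n(t) − x̂′_n(t) |,

where x̂′ is the forecast after replacing the sources' input rows with the
data-distribution mean (0 in z-units; the stored session mean for min–max
data). Evaluation samples default to the test partition. Multi-source
perturbation is supported (a functional area spanning several parcels can
be silenced jointly). Influence maps can be rescaled to [0, 100]; by
default the source self-entries are excluded from the scale (and clipped),
since self-influence conflates self-prediction with causal effect.
Normalization is applied last, after any averaging across sessions.

## Synthetic benchmark generator

The generator provides ground truth that real neuroimaging data cannot:
an undirected weighted connected random graph (Erdős–Rényi support,
Uniform(0.5, 1.5) weights), a directed coupling matrix supported on its
edges (each direction planted independently with probability 0.5; total
incoming strength fixed at `coupling_strength` per node so saturation
depth is comparable across nodes), and node dynamics

    x(t) = tanh(a·x(t−1) + C x(t−lag) + u(t)),

with `a = 0.8`, `coupling_strength = 1.2`, `lag = 2`. The innovations
`u(t)` are *band-limited* (white noise band-passed to 0.04–0.07 Hz,
scaled to sd 2.0 in pre-saturation units), so the recursion operates on
narrowband signals and the tanh saturation appears inside the band as
amplitude compression. This construction is deliberate: driving the
recursion with broadband noise and band-passing the *output* would remove
the tanh distortion together with the out-of-band noise, leaving an
observable that a linear VAR predicts as well as any nonlinear model —
the generator would no longer probe what distinguishes the two model
families. A small broadband observation-noise floor (sd 0.02) is added
last; besides realism it keeps the lagged design of a high-order VAR full
rank, which perfectly band-limited signals would not. Burn-in of 200
frames precedes each session.

Desk-scale defaults are N = 10 regions and 3 sessions of T = 500 frames,
which train in minutes on one CPU core.

What the generator does *not* emulate: hemodynamic convolution and its
regional variability, scanner drift and motion artifacts, spatially
correlated physiological noise, and tractography errors in the graph.
Passing benchmarks here therefore demonstrates that the pipeline recovers
planted structure under its own assumptions, not that it will do so on
any particular real dataset.

### What the desk-scale benchmark does and does not show

On this generator the graph-aware forecaster consistently beats the
linear VAR (the saturating in-band dynamics defeat iterated linear
prediction) and its influence maps recover the planted directed couplings
well above a shuffled null — the model demonstrably learns *which*
neighbours matter. One contrast from the full-scale setting does not
carry over: removing the spatial filters altogether (walk order K = 0)
costs little or nothing in scalar forecast MAE here. At a 12-frame
horizon (~a third of the oscillation period) forecasting band-limited
signals is dominated by extrapolating each region's own phase and
amplitude, which a purely temporal model does equally well even when the
underlying dynamics are neighbour-driven; the unique cross-node
information is smaller than the generalization cost of the K = 1 model's
threefold filter parameters at this size. On real broadband-noise
recordings with hundreds of regions, where own-past extrapolation is far
weaker, spatial modelling has been reported to matter substantially; a
ten-node narrowband simulation cannot reproduce that contrast, and the
benchmark documents this rather than hiding it.

## Desk-scale experiment conditions

The bundled experiments (`neurocast.workflows`) fix one configuration so
tests, the acceptance script and the examples all measure the same thing:
windows T_p = T_f = 12 frames, hidden size Q = 16, 30 training epochs of
Adam at lr 0.03 (decay ×0.1 at epoch 20), scheduled-sampling τ = 40, VAR
lag 12. Two of these deliberately differ from the full-scale defaults,
both as run-length calibrations: a desk run makes ~10³ gradient updates
rather than ~10⁵, so τ is scaled so that the sampling probability
actually traverses its 1 → 0 schedule within the run (at τ = 5000 a short
run would remain in pure teacher forcing while being evaluated
free-running), and the learning rate is lowered from 0.1 to 0.03 for
stability of the much smaller model. The transfer experiment fine-tunes
at lr 0.001 on a data-poor cohort (one session of 260 frames from an
independent generator draw) and compares with from-scratch training under
the same epoch budget.

## Numerical choices and edge cases

- Isolated graph nodes are a hard error (silent self-loops would change
  the K = 1 locality semantics).
- Transition rows must sum to 1 within 1e−10; adjacency symmetry within
  1e−8 (symmetrized on read).
- The restart-probability α of the stationary-distribution diagnostic has
  no published value and must be supplied explicitly.
- Constant sessions cannot be scaled; constant global signals cannot be
  regressed out; both raise.
- MAE subgradient at exact ties is 0.
- Training aborts with a diagnostic on non-finite loss.
- All file writes are atomic (temp + rename); delimited text everywhere;
  checkpoints are `.npz` archives with a JSON architecture manifest
  (version-tagged, node-count independent).

## Known limitations

- The autodiff engine is single-threaded numpy; it is sized for
  desk-scale problems (tens of nodes), not the full 360-region,
  100-session setting the architecture itself supports.
- The influence measure quantifies what the *model* uses, which tracks
  true causal structure only insofar as the model generalizes; on the
  benchmark this is validated against planted couplings.
- The overlapping-window split reproduces the reference protocol exactly,
  including its timepoint leakage across split boundaries; use the gapped
  split for leakage-free numbers.
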