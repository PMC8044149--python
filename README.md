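# neurocast

Graph-constrained forecasting of regional brain activity, with a
perturbation-based measure of directed ("causal") connectivity and a
VAR/Granger baseline.

## The problem

Structural connectivity (SC, from diffusion tractography) tells us which
brain regions are anatomically wired together; functional recordings
(e.g. parcel-averaged resting-state BOLD) show how activity actually
evolves. `neurocast` couples the two: it learns to forecast the next
`T_f` frames of every region's activity from the previous `T_p` frames,
*constrained by the structural graph*, and then asks which regions' past
activity the trained model relies on to predict which others — a
directed, multi-modal connectivity measure in the spirit of Granger
causality.

The forecaster is a diffusion-convolutional recurrent network (DCRNN): a
sequence-to-sequence encoder–decoder of GRU cells in which every dense
product is replaced by a diffusion convolution, a learned polynomial in
the random-walk operator of the structural graph:

    y = Σ_{k=0..K} θ_k T^k x,     T = D⁻¹ A_w

Filters reach only K-hop structural neighbourhoods and their parameter
count is independent of the number of regions. The influence of region
n′ on region n is measured by silencing n′ in the input (replacing it
with the data mean) and averaging the change in the model's forecast of
n over test samples and horizons:

    I_n(n′) = (1/S) Σ_s (1/T_f) Σ_t | x̂_n(t) − x̂′_n(t) |

A linear VAR(P) baseline (closed-form and gradient-fitted), an augmented
Dickey–Fuller stationarity check, and a synthetic benchmark generator
with *known* planted directed couplings round out the package. Everything
runs on plain numpy — gradients come from a small, fully tested
reverse-mode engine — so no GPU or deep-learning framework is needed.

Intended users: researchers in network neuroscience and systems biology
who want a testable, desk-scale implementation of graph-recurrent
forecasting and perturbation-based connectivity, with ground-truth
validation on synthetic data.

## Worked example

```bash
python examples/02_forecasting_workflow.py
```

simulates 10 regions with saturating lag-2 couplings on a random
structural graph, trains the K=1 forecaster for 30 epochs, and prints:

```
simulated 10 regions, 13 planted directed couplings
trained 30 epochs; best validation MAE 0.0963 at epoch 29

horizon   DCRNN-K1   VAR
      1   0.0197    0.0287
      4   0.0512    0.0962
      8   0.1005    0.1561
     12   0.1024    0.1193
overall   0.0742    0.1130
```

MAE is in min–max-scaled signal units (session range mapped to [0, 1]);
lower is better. The VAR matches the recurrent model at short horizons
but falls behind as its iterated linear predictions accumulate error on
the nonlinear dynamics. `examples/03_causal_influence.py` then recovers
the planted directed couplings from the trained model's influence map,
and `examples/04_transfer_learning.py` shows pretraining + fine-tuning
beating from-scratch training on a data-poor cohort.

A thin CLI mirrors the library (`neurocast simulate | preprocess | train |
finetune | evaluate | var | influence`); run `neurocast --help`.

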