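# modetime

Machine-learning interpretation of post-transition-state dissociation
dynamics: predict *when* a molecule falls apart from nothing but its state at
the transition state, then read the trained model to learn *which* nuclear
motions control that time.

After a thermally activated molecule crosses a transition state, the time it
takes to complete the bond-breaking step controls observable chemistry (for
chemiluminescent systems, the light yield).  Simulating enough ab initio
trajectories to resolve such timescales is expensive, and the resulting
terabytes rarely explain themselves.  `modetime` packages the alternative: a
Bayesian neural network (BNN) trained on a modest set of trajectories learns
the map from initial nuclear positions and velocities — expressed in normal-
mode coordinates, so the features are translation- and rotation-invariant —
to the dissociation time, and its sparsity-inducing priors make the trained
weights themselves interpretable.

The package is aimed at computational chemists who want to reproduce this
analysis pipeline end to end, or reuse its stages, without access to
proprietary trajectory data: a surrogate-dynamics stage generates ensembles
with the statistical signatures of real post-transition-state data
(dissociation-time spread of tens of fs, "frustrated" bond stretches that
recontract, acceleration under vibrational excitation) and a *planted*,
recoverable ground truth of causally relevant modes.

## The model

A single Bayesian neuron computes `y = f_act(w·x + b)`; layers of such
neurons form the regressor.  Every weight and bias carries a Laplace(0, b)
prior — the Bayesian analogue of L1 regularisation — and a mean-field
Gaussian variational posterior `q(w) = N(mu, sigma^2)` optimised with Adam
against the evidence lower bound,

    ELBO = E_q[log N(y | f(x; w), sigma_n^2)] − KL(q || p),

with the Gaussian-vs-Laplace KL evaluated in closed form.  Predictions are
Monte-Carlo forward passes with weights drawn from `q`; their spread is the
model's uncertainty.  Relevance of input feature `j` is the distribution of
first-layer `|mu|` values into the hidden neurons: Laplace shrinkage prunes
connections from uninformative inputs, so large coefficient magnitudes mark
the nuclear coordinates that matter.

Around the regressor, the pipeline implements: normal-mode analysis of a
transition-state Hessian (Eckart-projected, imaginary mode first); Wigner
sampling of vibrational ground and singly excited states with a 1 kcal/mol
kick along the reaction coordinate; velocity-Verlet surrogate dynamics with
a 10 au (~0.24 fs) step and a 2.4 A C–C dissociation criterion;
frame labelling (every fifth frame, labelled with time-to-dissociation);
80/10/10 train/validation/test curation with farthest-point selection in PCA
space; and an interpretation layer that predicts dissociation *half-times*
(the time by which half of a 250-member ensemble has dissociated) for
vibrationally excited ensembles, singly and in pairs, with bootstrap
confidence intervals and z-scores.

## Worked example

The default study: an 8-atom synthetic transition-state system (18 normal
modes, four of them coupled to the dissociation barrier), 200 Wigner-sampled
trajectories, position+velocity features.

```python
from modetime.fixtures import build_synthetic_system
from modetime.harmonic import normal_mode_analysis
from modetime.dynamics import default_study_potential, generate_study
from modetime.labels import label_study
from modetime.curation import assemble
from modetime.bnn import BNNConfig, DissociationTimeBNN
from modetime.interpret import (
    predict_half_times, simulate_half_times, compare_to_simulation,
)
from modetime.wigner import VibrationalStateSpec

basis = normal_mode_analysis(build_synthetic_system(8, seed=0))
potential = default_study_potential(basis)
study = generate_study(
    basis, potential,
    [VibrationalStateSpec(quanta={}, ensemble_size=200)], seed=1,
)["ground"]
frames = label_study(study, stride=5, with_velocities=True)
results = DissociationTimeBNN(assemble(frames, seed=1), BNNConfig(seed=1)).fit()
print(results.summary())
```

```
Dissociation-time BNN (Laplace prior, mean-field VI)
====================================================
architecture      : 36 -> 64 -> 32 -> 1
activation        : tanh
prior scale       : 0.7
epochs / batch    : 900 / 256
final ELBO loss   : 0.4183 (per frame)
noise scale       : 4.69 fs
train             : RMSD 3.00 fs, MAD 2.27 fs, r^2 0.995 (n=4226)
val               : RMSD 5.61 fs, MAD 3.26 fs, r^2 0.973 (n=529)
test              : RMSD 4.05 fs, MAD 3.03 fs, r^2 0.989 (n=528)
overfit bound     : 8319.92 fs
top features      : r_1, v_2, v_1, r_3, v_3, r_2
```

Held-out frames are predicted to ~3 fs mean absolute deviation (r^2 = 0.99),
and the top coefficient magnitudes point at modes 1–4 — exactly the modes the
surrogate potential couples to the barrier.  (The "overfit bound" is a loose
norm-based capacity diagnostic, not an error estimate.)  The trained model
then answers a hypothesis question — *does exciting one quantum of a given
mode speed up dissociation?* — in seconds instead of fresh trajectory
batches, and the surrogate lets us check the answer by actually propagating
the same ensembles:

```python
specs = [VibrationalStateSpec(quanta={})] + [
    VibrationalStateSpec(quanta={m: 1}) for m in potential.planted_modes
]
predicted = predict_half_times(results, basis, specs, n=250, seed=71)
simulated = simulate_half_times(basis, potential, specs, n=250, seed=71)
report = compare_to_simulation(predicted, simulated)
print(report.to_frame().to_string(index=False))
print(f"RMSD {report.rmsd:.2f} fs, Kendall tau {report.kendall_tau:.2f}")
```

```
ensemble  predicted_fs  simulated_fs  error_fs
  ground     27.087901     26.849615  0.238286
   mode1     26.016850     25.640173  0.376677
   mode2     25.190988     23.221289  1.969699
   mode3     23.462110     22.495624  0.966486
   mode4     24.028197     22.737512  1.290685
RMSD 1.16 fs, Kendall tau 1.00
```

The model reproduces the propagated half-times to within ~2 fs and ranks the
five ensembles in exactly the simulated order.

The same pipeline is scriptable from the shell (`modetime fixture`,
`sample`, `simulate`, `label`, `curate`, `train`, `predict`, `halftimes`,
`pipeline`); `modetime pipeline --config config.yaml --out run/` executes
every stage and writes all artifacts, logs and the resolved configuration to
one directory.

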