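# Methods

`modetime` studies a question from post-transition-state reaction dynamics:
given only a molecule's state at the moment it passes a transition state —
its nuclear geometry and velocities expressed in normal-mode coordinates —
how well can a machine-learning surrogate predict the time until a bond
actually breaks, and can the trained surrogate be *read* to identify which
nuclear motions control that time?  The package implements the full chain:
harmonic analysis, quantum-informed (Wigner) sampling of initial conditions,
a classical surrogate for the dissociation dynamics with a planted ground
truth, trajectory labelling, dataset curation, a sparsity-inducing Bayesian
neural network (BNN), and the interpretation layer built on it.

## Normal-mode analysis

The vibrational basis comes from diagonalising the mass-weighted Hessian
after explicit projection of the six translation/rotation vectors (Eckart
frame at the reference geometry).  Projection, rather than discarding the
six smallest eigenvalues, is required at a transition state, where one
eigenvalue is negative: the imaginary-frequency mode is the reaction
coordinate and is forced to index 0.  Remaining modes are sorted by
ascending frequency; mode-vector signs are fixed by making each column's
largest-magnitude component positive so that feature signs are reproducible.
All internal quantities are in Hartree atomic units; user-facing I/O uses
angstrom, femtoseconds and kcal/mol (1 bohr = 0.52917721067 A,
1 au time = 0.02418884254 fs, 1 kcal/mol = 1.593601e-3 hartree).
More than one imaginary frequency is an error, as is any retained mode
below a configurable frequency floor (default 1e-6 au), which would signal
incomplete projection.

## Wigner sampling

For a harmonic mode of angular frequency `w` (mass-weighted, hbar = 1) the
ground-state Wigner function factorises into Gaussians with Var(r) = 1/(2w)
and Var(v) = w/2, giving the zero-point energy w/2 per mode.  The first
excited state's Wigner function is negative near the origin and cannot be
sampled as a density; we draw `r` and `v` independently from the quantum
marginals |psi_1|^2 and |phi_1|^2 instead.  Both marginals of the true
Wigner function are matched and the mean energy is exactly 3w/2.  Because
|psi_1(r)|^2 ∝ r^2 exp(-2w r^2 / (2)) is the law of a random sign times the
norm of a 3-vector of iid N(0, 1/(2w)) draws, the marginals are sampled
*exactly* (a scaled chi-3 variate) — no tabulated inverse CDF and no
rejection step.  The reaction coordinate is never Wigner-sampled: it starts
at r = 0 and receives only a kinetic-energy kick (default 1 kcal/mol,
v_rc = sign * sqrt(2E)) directed toward the product side.  Each mode has its
own deterministic child RNG stream derived from the ensemble seed, so adding
an excitation to one mode leaves every other mode's draws bit-identical.

## Surrogate dissociation dynamics

The package's synthetic-data stage replaces on-the-fly electronic-structure
dynamics with a model potential in mass-weighted normal-mode coordinates:

    V(q) = A g(q0) (1 + sum_i lambda_i q_i) + sum_i w_i^2 q_i^2 / 2
           + w_wall^2 q0^2 / 2            (q0 < 0 only)
    g(q0) = (q0/s)^2 exp(1 - (q0/s)^2)    (q0 >= 0, else 0)

The reaction coordinate `q0` starts in a shallow well between a reflecting
harmonic wall (the region behind the already-crossed first barrier) and a
bump of height `A` at `q0 = s` whose instantaneous height is modulated
linearly by a sparse set of coupled bath modes.  A trajectory kicked with
1 kcal/mol (< A) bounces against the barrier until the coupled modes swing
the barrier low enough to let it through; failed attempts in which the bond
stretches substantially and recontracts are exactly the "frustrated
dissociation" phenomenology the labelling stage counts.  The C–C distance is
a linear readout, cc = d_TS + slope * q0, and dissociation is declared at
cc > 2.4 A (twice the carbon van der Waals radius).  Integration is velocity
Verlet at 10 au (~0.24 fs) per step, vectorised across an ensemble; energy
drift over 250 fs is below 1e-6 relative for the uncoupled case and below
1e-5 hartree with couplings.

Default study conditions (frozen once, used by tests and the acceptance
script alike): 18 modes from the packaged 8-atom synthetic transition-state
spectrum, barrier height 1.45 kcal/mol, width 12 au, wall frequency 1e-2 au,
d_TS = 1.55 A, slope 0.06 A per unit q0, and four coupled ("planted") modes
1–4 with dimensionless effect sizes (0.65, 0.50, 0.55, 0.50); a mode's
coupling is c * sqrt(2w) so a one-standard-deviation ground-state
displacement modulates the barrier by the fraction c.  Under these
conditions a 250-trajectory ground ensemble dissociates to >= 95% within
250 fs, the dissociation times have an interquartile range above 30 fs, and
frustrated dissociations occur at a rate of roughly 0.4–1.3 per trajectory.

Two design choices deserve explanation:

* **The coupled modes are the slowest bath modes.**  The packaged spectrum
  places the four coupled modes at 200–420 cm^-1 and every uncoupled mode
  at 800 cm^-1 or above.  The regression task splits frames, not
  trajectories, so frames of one trajectory appear on both sides of the
  split; along a trajectory the uncoupled modes evolve freely, and any
  *slow* uncoupled mode would then let a network interpolate labels along
  each trajectory's smooth curve in feature space — a shortcut that predicts
  well without learning any causal structure and swamps coefficient-based
  relevance readings.  Fast uncoupled modes wrap their phase tori many times
  between frames, so exploiting them requires high-frequency functions of
  the inputs that the Laplace prior effectively prices out; the slow coupled
  modes, whose phases genuinely gate the escape, then carry the weight.
  This mirrors the physical situation the method is meant for (slow skeletal
  deformations control the barrier; fast X–H stretches are spectators), and
  it is what makes "recover the planted modes" a well-posed test.
* **Escape is quasi-static in the coupled modes.**  The barrier-attempt
  cycle (~8 fs, set by the wall frequency) is fast against the coupled
  modes' periods (80–170 fs), so the time until the barrier next dips below
  the available energy is a smooth function of the coupled modes' current
  phases.  This keeps the true regression function learnable; in regimes
  where the modulation fluctuates between attempts the map becomes
  effectively chaotic and no regressor recovers it.

The surrogate reproduces the *statistical shape* of real post-transition-
state data — dissociation-time spread of tens of fs, frustrated
dissociations, acceleration upon vibrational excitation of coupled modes —
but not real electronic-structure forces, anharmonic mode mixing,
translation/rotation coupling, or any non-adiabatic physics.  Passing tests
therefore demonstrate that the inference pipeline recovers planted causal
structure under realistic statistics, not that it would recover the true
mechanism of any particular molecule.

## Labelling

Dissociation time is the time of the first frame with cc > 2.4 A, at frame
resolution (no interpolation; relative comparisons are insensitive to the
threshold).  Trajectories that never cross within the simulated window are
censored (+inf) and contribute no training frames.  Every fifth frame
strictly before the crossing becomes a training example whose label is the
time *remaining* until dissociation — each frame acts as an initial
condition for the prediction; a switch selects total-trajectory-time labels
instead.  A frustrated dissociation is a local maximum of cc that exceeds
2.0 A, stays at or below 2.4 A and recedes by at least 0.1 A before the next
rise (both thresholds configurable; only events before the successful
crossing count).  The ensemble half-time is the ceil(n/2)-th smallest
dissociation time — the first time at which half of the ensemble has
dissociated — with censored entries sorting last and a censored result
whenever more than half of the ensemble is censored.

## Dataset curation

The test split is a uniform random 10% of the frames.  From the remaining
90%, the training split (80% of the total, floor-rounded; 11650 frames give
exactly 9320/1165/1165) is chosen by greedy farthest-point selection in a
reduced PCA space: starting from the two mutually farthest points, the point
with the largest minimum distance to the selected set is added repeatedly
(ties to the lowest index; the classic guarantee puts the greedy min-pairwise
distance within a factor 2 of the exhaustive optimum).  The PCA keeps the
smallest number of leading components reaching 90% cumulative explained
variance (configurable); labels are excluded from the PCA.  Frames not
selected form the validation split.  Features and labels are z-scored with
constants fitted on the training split only.

## The Bayesian neural network

A feedforward network with tanh hidden layers (default 64 and 32 units) and
a linear output regresses standardized time-remaining on standardized mode
features (18 for positions, 36 with velocities).  Every weight and bias has
a Laplace(0, b) prior (default b = 0.7) — the Bayesian counterpart of L1
regularisation — and an independent Gaussian variational factor N(mu,
sigma^2).  Training maximises the evidence lower bound with Adam (3e-3, 900
epochs, batches of 256): the Gaussian-likelihood term uses one
reparameterised weight draw per step with a learned homoscedastic noise
scale, while the KL term against the Laplace prior is analytic,

    KL = -log(sigma sqrt(2 pi e)) + log(2b) + E|w|/b,
    E|w| = sigma sqrt(2/pi) exp(-mu^2/(2 sigma^2)) + mu erf(mu/(sigma sqrt 2)),

with closed-form gradients — no Monte-Carlo noise enters the regulariser.
The reported posterior is the Polyak average of the variational parameters
over the final 15% of epochs, which removes the stochastic-gradient jitter
of any single end state from both predictions and relevance readings.
Two hidden layers are needed in practice: the map from coupled-mode phases
to time-to-next-escape-window is too curved for a single hidden layer at
these widths, which plateaus near r^2 ~ 0.87 on the default study, while the
two-layer default reaches r^2 ~ 0.95–0.99.

Predictions are Monte-Carlo: `n_draws` forward passes with weights sampled
from the variational posterior; the reported uncertainty is the spread of
the network output (parameter uncertainty only, de-standardized to fs) and
correlates positively with the absolute prediction error on held-out frames.
Evaluation reports RMSD, MAD and r^2 of the predictive means; r^2 is
undefined (NaN) for constant labels.

Feature relevance reads the variational *locations* of first-layer weights:
for input feature j, the distribution over hidden neurons of |mu_{j->h}|,
summarised by its median.  For position+velocity models the mode-level
relevance is the larger of the mode's r- and v-feature summaries — a mode
counts as relevant if either its coordinate or its velocity carries weight.
An optional norm-based generalisation bound (product over layers of the
largest incoming 1-norm, times the largest standardized input norm, over
sqrt(m)) is exposed as a diagnostic; it is homogeneous in the weight scale
and shrinks as 1/sqrt(m), but is not a tight error estimate.

Hyperparameter search is plain random search over user-supplied candidate
lists, scored by validation MAD, with diverged candidates recorded at
infinite score.

## Interpretation

A trained model predicts a vibrational state's dissociation half-time by
sampling a fresh Wigner ensemble for that state (ground, or one quantum in
one or two modes; never the reaction coordinate), predicting the individual
dissociation times from the t = 0 features and taking the ensemble
half-time; 95% confidence intervals are percentile bootstrap over the n
predicted times (2000 resamples, seeded).  The pairwise scan evaluates every
unordered pair of singly excited modes once and mirrors it, storing
single-excitation half-times on the diagonal.  z-scores normalise each
column of the pairwise matrix to mean 0 / variance 1 (population std; the
conditioning mode indexes the column), flagging zero-spread columns as
degenerate NaN.  `compare_to_simulation` aligns a predicted table with a
table obtained by actually propagating the same ensembles (sharing the seed
shares the initial conditions) and reports per-ensemble errors, RMSD,
Kendall's tau for the rank trend, and the RMSD ratio when a second model is
supplied.

## Problem sizes and numerical choices

The default study used by the tests and the acceptance script is 200
trajectories per ensemble (~4–5.5k labelled frames), 250 for ensemble-level
statistics, 10,000 Wigner samples for moment checks, 10 seeded end-to-end
replicates for the recovery rate and 5 for the velocity-benefit comparison;
these sizes make the planted-structure checks statistically meaningful while
a full replicate runs in well under a minute.  Ties in farthest-point
selection break to the lowest index; mode-vector signs are fixed as above;
the variational scales are initialised at 0.05 and the noise scale at 0.2
(standardized units); Adam uses (0.9, 0.999, 1e-8).  Degenerate inputs are
handled explicitly: constant feature matrices are rejected by the PCA,
constant labels disable r^2, zero-spread z-score columns are flagged, and
non-finite states abort propagation with the offending frame named.

## Known limitations

* The surrogate potential is one-dimensional in its reaction coordinate
  with a linear bond-length readout; no recrossing to the reactant side and
  no competing channels exist.
* The excited-state sampler matches the v = 1 marginals but not the joint
  (signed) Wigner function; correlations between r and v of an excited mode
  are absent.
* The posterior is mean-field: parameter correlations are ignored and
  predictive uncertainties are typically underdispersed.
* Relevance is read from first-layer locations only; relevance that emerges
  purely from deeper-layer interactions would be invisible.
* Half-times for states far outside the training distribution (e.g. many
  simultaneous excitations) extrapolate and carry no validity guarantee.
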