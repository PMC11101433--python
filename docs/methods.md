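# Methods

`fossildiv` estimates biodiversity through time from fossil occurrence
data by simulation-based supervised learning: a mechanistic generative
model produces labelled (fossil record, true diversity) pairs, a
recurrent neural network is trained on them, and the trained network is
applied to empirical occurrence tables summarised with the same
features. A shareholder-quorum-subsampling (SQS) baseline is included
for comparison. This note records the model, its assumptions, the
defaults we chose where choices were open, and what the tests do and do
not establish.

## Generative model

### Diversification

Species origination and extinction ages are produced by a time-forward
birth-death process. The clade origin t_O ~ U[30, 100] Ma; per-lineage
speciation and extinction rates are drawn independently from
U[0.05, 0.5] events/lineage/Myr and vary through time as piecewise
constants, with Poisson(4) shift counts per process and shift times
uniform on [t_O, 0]. Each 1-Myr unit hosts a mass extinction with
probability 0.01, applied only when at least 10 lineages are standing,
killing each lineage with probability mu_ME ~ U[0.8, 0.95]. Accepted
simulations contain between 100 and 5,000 total species; failing draws
are rejected and redrawn (parameters included), with a hard cap of
10,000 attempts.

The process is stepped in discrete increments of 0.1 Myr with per-step
event probabilities lambda\*dt and mu\*dt. We chose discrete stepping
over an exact event-time algorithm because mass extinctions are defined
per time bin, and a 0.1-Myr step keeps the discretisation bias of the
pure-birth mean below ~2% (checked against the closed form e^{lambda t}
in the tests). The step size is a config knob.

Two rare-pattern regimes extend the menu for stress-test corpora:
pulses of mass speciation (rate redrawn from U(1, 5) for the unit) and
mass extinction (70–90% loss), each placed per 1-Myr unit with
probability 0.05; and diversity-dependent speciation
lambda(t) = lambda0 \* max(0, 1 − N/K) with K ~ U(50, 200) and two
fixed mass extinctions at 66 and 16 Ma. In the second regime the
piecewise speciation timeline is replaced by a single base rate; the
extinction timeline is kept.

Ages are Ma before present, 0 = present; vectors run oldest to
youngest. A bin with edges (older, younger) owns the ages
(younger, older], the youngest bin also contains age 0, and a species
is counted in every bin its lifespan [extinction, origination]
intersects. Extant species carry extinction age exactly 0.0.

### Biogeography

The world is A = 5 abstract regions (6 in the marine scenario).
Relative sizes d ~ Dir(alpha, ..., alpha) × A with alpha = 3; relative
carrying capacities kappa ~ Dir(d·k) with link strength k = 5;
distances delta_ij ~ U(0, 3) symmetrised. Capacities drift through time
as kappa(t) = SoftMax(log kappa0 + c·t) with per-region slopes
c ~ N(0, 0.05). The slope scale matters: it controls how far a region's
share of originations can wander over a clade's history, and with
near-zero slopes every region's richness curve is simply proportional
to the global one, which would make spatially concentrated sampling
harmless to any estimator. At 0.05/Myr relative capacities can drift by
orders of magnitude over 100 Myr.

Each species draws an initial region from a multinomial on kappa
evaluated at its origination bin (bin midpoints; the evaluation time is
not prescribed by the model), then occupies every other region j
independently with probability exp(−delta_ij / w_s), where the species
dispersal rate w_s ~ Weibull(shape 1.5, scale 1.0). Ranges are static
over the species' life. Optional per-region availability windows
(used by the proboscidean scenario) exclude a region from initial
assignment before its opening age, bar species that die before the
opening from ever occupying it, and mask presence in any bin that
starts before the opening.

### Fossilisation

Localities are placed per (region, bin) cell with expectation
lambda_at = r_a · q_t · z_at · eps_at · Delta_t and realized counts
Poisson(lambda_at), where r_a ~ Gamma(1.5, 1.5) · d_a is the
region-specific rate scaled by region size; q_t is the temporal rate
under one of two patterns chosen uniformly at random per dataset — a
log-linear trend log q_t ~ N(log q0 + zeta·t, sigma) with zeta ≤ 0
(sampling never improves back in time), or a piecewise-constant model
with Poisson(4) shifts and log q_t ~ N(log q0, sigma) between shifts;
z_at ~ Bernoulli(1 − p_gap) knocks whole cells out; and
eps_at = eta·e^m with m ~ U(log 1/b, log b) is a per-cell random
effect.

Species preservation rates psi_s ~ Gamma(shape, theta) set the
per-locality detection probability p_s = 1 − exp(−psi_s). A species
present in a cell enters each of its l_at localities independently with
probability p_s, which is distributionally identical to drawing
Bin(l_at, p_s) occupied localities placed uniformly without
replacement. A fossil occurrence is a species–locality presence;
multiple specimens collapse to one occurrence.

Unprinted hyperpriors were fixed once by matching the scale of the
compiled occurrence archives this class of analyses uses (a few
thousand localities over tens of Myr and a handful of regions, i.e.
roughly 0.5–20 localities per region-Myr, and completeness spanning
sparse to near-complete): q0 log-uniform on (0.5, 20) per region-Myr,
sigma ~ U(0.1, 1), zeta ~ U(−0.02, 0), p_gap ~ U(0, 0.3), eta = 1,
b ~ U(1.5, 5), psi mean log-uniform on (0.05, 2), psi shape
~ U(0.5, 2). All are config fields, not constants.

Three named stress presets reparameterise sampling only: temporal
(rate ×0.1 between 33 and 22 Ma, ×10 from 2 Ma to the present — a
100-fold spread over four frames), taxonomic (bimodal psi mixture with
means 0.05 and 0.5, an order of magnitude apart), spatial (one of five
regions ×10, another ×0.1 — two orders of magnitude). With all
multipliers at 1 the presets consume no extra randomness and reproduce
the default corpus draw-for-draw at the same seed (tested).

## Features

Each record is summarised per bin as: sampled species, occurrences,
localities, singletons, endemics, bin duration, range-through
diversity, plus per-region species/locality/occurrence counts —
7 + 3A features in a fixed, recorded order. A singleton is a species
sampled at exactly one locality *within the bin* (so the feature is a
time series); an endemic is a species sampled in exactly one region
*across the record* (region fidelity is a species property). Both
scopes are switchable. Region-summed locality and occurrence blocks
equal their global counterparts exactly; the species block does not
(a species in several regions is counted once globally), which is an
identity no definition of "sampled species" could satisfy.

Count features are normalized by log(x+1) followed by division by the
per-feature maximum of the transformed training corpus; durations are
divided by their training maximum. The fitted constants travel with
model checkpoints so validation, test and empirical data are scaled
identically.

## Sequence model

A bidirectional LSTM stack (1–4 layers of 32 or 128 units, tanh cell
and sigmoid recurrent activations, concatenated directions) maps the
(t × f) feature matrix to per-bin log(1 + diversity); an optional dense
head (up to two ReLU layers of 32 or 64 units) sits between the stack
and a SoftPlus output that keeps predictions positive. The network,
backpropagation through time and the Adam optimiser are implemented
directly in NumPy; the backward pass is verified against central finite
differences in the test suite (relative error < 1e-4 per parameter
block). Training minimises MSE on log(x+1) labels with batch size 100,
a 20% validation split, early stopping with patience 50 and restoration
of the best-validation-epoch weights; gradients are clipped to global
norm 5 for stability. Learning rate (1e-3), merge mode (concatenate)
and the epoch cap (1,000) are defaults the source model family leaves
open.

Uncertainty comes from Monte Carlo dropout: an inverted-dropout layer
(default fraction 0.1, config-exposed) ahead of the output stays active
at inference; n draws per model, pooled across any supplied models,
give a per-bin mean and empirical 2.5–97.5% interval on the natural
scale after inverting log(x+1). Pooling across architecture variants
uses plain concatenation of draws followed by empirical quantiles.

## Evaluation and the SQS baseline

SQS estimates coverage-standardised richness per bin from per-species
occurrence counts: coverage is Good's u = 1 − singletons/occurrences
(bins with u below the quorum cannot be standardised and return NaN);
occurrences are drawn in random order and distinct species counted
until their u-corrected summed frequency reaches the quorum (0.6
throughout); 100 trials are averaged. Because coverage only grows when
a new species first appears, the implementation samples species'
first-occurrence order directly (the first token of a species with n
occurrences arrives as the minimum of n uniform keys), which is exact
and avoids materialising tokens. Corrections beyond the
single-occurrence correction (e.g. dominant-taxon exclusion) are off by
default but exposed; small numerical differences from other published
SQS implementations are expected.

Trajectory metrics: `mse` (we report it on log(x+1) diversity), the
spec-style `r_squared` (1 − SSres/SStot on raw values) and
`pearson_r2`, `rmse_rescaled` (MSE after min–max rescaling both curves
to [0, 1]; NaN for constant curves, and such datasets are excluded from
medians with a logged count), and 95%-interval `coverage_95`. The
*comparison harness* scores every estimator on the complete binned
frame: bins where an estimator is undefined count as 0 (a bin that
cannot be standardised has not been recovered), both curves are min–max
rescaled, and R2 = 1 − SSres/SStot of the rescaled curves. For a
relative estimator such as SQS this is the only score of the
coefficient-of-determination family that is both scale-free and
sensitive to missing bins; raw-scale 1 − SSres/SStot is meaningless for
an estimator with arbitrary units, and plain squared correlation is
insensitive to precisely the failure modes (coverage gaps, scope
changes) the comparison is about.

## Problem sizes

Default study conditions are 100 one-Myr bins, origins U[30, 100] Ma,
five regions. The package's desk-scale conditions
(`SimulationConfig.desk_scale()`) use 50 one-Myr bins with origins
U[20, 50] Ma and are what the test suite trains on: 2,000 training
datasets, a 1-layer 32-unit model, 250 epoch cap. The SQS baseline is
evaluated on 300 freshly generated default-condition datasets and 100
spatial-bias datasets. Corpus sizes of 100,000+ training simulations
and the full architecture sweep are cluster-scale experiments; the
configuration objects express them, but no result at that scale is
claimed by this package's tests.

## Known limitations

- Biotic interactions, traits and continuous space are not modelled;
  regions are abstract discrete units.
- Regional richness trajectories in this generative model remain
  strongly correlated with the global trajectory (static species
  ranges; capacity drift moves origination shares only), so
  concentrating sampling in one region degrades the SQS baseline far
  less here than reported for other simulators of this model family;
  the spatial-bias preset reproduces the sampling-rate contrast, not
  necessarily the damage it causes elsewhere.
- Monte Carlo dropout is known to understate predictive uncertainty;
  interval coverage should be checked per application and the dropout
  fraction treated as a tunable.
- The binned-presence treatment counts a species in every bin its
  lifespan touches; within-bin singletons are not distinguished from
  boundary crossers.
- Empirical age uncertainty is handled by uniform resampling within
  each locality's age range (100 replicates by default), at the
  locality level so co-located occurrences stay temporally coherent;
  correlated age errors between localities are not modelled.
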