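# Methods

## Problem and model

Glaucomatous damage thins the retinal nerve fiber layer (RNFL) in arcuate
bundles that converge on the optic disc, and produces corresponding
sensitivity loss in the 24-2 visual field. The package estimates the 52
age-corrected total-deviation (TD) values of a 24-2 test, and their Mean
Deviation (MD) summary, from the 768-sample peripapillary RNFL thickness
profile (TSNIT order on the 3.45 mm scan circle).

Anatomy fixes the wiring. Fibers do not cross the horizontal raphe, so the
superior hemiretina (profile samples 0..383, temporal through superior into
nasal) serves the inferior chart hemifield and vice versa; every model here
is therefore a pair of independent hemiretina sub-networks, and perturbing
one profile half provably cannot change the opposite-name chart block.

The core architecture (`RecursiveNet`) traces bundles outward from the disc
by *recursion*: block 1 (conv/pool stack with a strided convolutional skip)
compresses a 384-sample half-profile into a 96-long, 12-channel state; block
2 is the Recursive Progression Layer (RPL), a single length-preserving
convolution with linear activation applied seven times, each pass modelling
one step of outward movement along the arcuate trajectories; blocks 3-4 (a
second conv/pool/skip stack and a single-channel convolution with pools)
read the state out into 5 values after every pass. Pass t emits its first
{5,4,4,4,4,4,1}[t-1] values as the chart points of that pass, ordered by
distance from the blind spot, so seven passes yield the 26 points of a
hemifield. A fixed, normalized weight mask applied to the assembled
52-vector gives the multi-task MD output (the uniform 1/52 mask by default;
the instrument's proprietary eccentricity weights are not public, and the
synthetic ground truth uses the same mask, keeping the system
self-consistent).

Baselines: a per-hemifield linear map without intercepts (2 x 26 x 384 =
19,968 weights), a fully connected model (384-32-32-26 per sub-network,
biases everywhere, 28,468 parameters), and a non-recursive convolutional
ablation that replaces the seven recursive passes by seven independent
convolutions of the RPL's shape and removes both skip connections (27,840
parameters). The recursive model has 18,864 parameters. The kernel/channel
configuration (C1=12, C2=24, kernels 9/10/13 | 6 | 9/6/2 | 5) is an integer
solution found by constraint search so that the closed-form parameter
arithmetic reproduces all four totals simultaneously; it is one consistent
realization of the block structure, not a uniqueness claim.
"Linear activation" on skip and final convolutions is read as "no ReLU",
with biases kept except on the final single-channel convolution — the
placement the totals force.

Convention notes. Convolutions use length-preserving ("same") padding;
strided skip convolutions pad so the output length is exactly input/stride.
Pooling is max pooling, width 2 throughout (strides 2,2 within blocks and a
final width-2 stride-1 pool mapping 6 to 5). Thickness is divided by 100
on entry so activations are O(1). Both eyes are represented in the
eye-local, temporal-positive convention, under which left and right eyes
share one layout; display-convention left-eye exports must be mirrored
before import (the 24-2 chart is not symmetric in x, so no within-chart
permutation can do this after the fact).

## Loss

Training minimizes a doubly weighted squared error on TD, optionally
blended with an MD term:

    L    = (1 - beta) * L_VF + beta * L_MD
    L_VF = sum_i lambda_i sum_j rho_j (y_ij - yhat_ij)^2
    L_MD = sum_i lambda_i (z_i - zhat_i)^2

with per-record weights counteracting the long-tailed severity distribution
via the four MD intervals (> -6, (-6,-16], (-16,-26], <= -26 dB):
lambda_i = (1-alpha)/N + alpha/(4 N_I(i)), and per-location weights
rho_j = softmax(-d_j^2 / 2 gamma^2) over the 52 center distances d_j
(measured in 6-degree grid steps). Both weight vectors sum to one exactly
when all four intervals are populated; an empty interval with alpha > 0 is
an error, not a silent patch. alpha = beta = 0 with any gamma recovers the
basic single-task model. Interval membership always uses the *label* MD.
Mini-batches contribute the sum of their records' weighted losses with
lambda precomputed on the full training split, so the expected stochastic
gradient matches the full-data objective up to a constant factor; batch
losses are not normalized by batch size (this choice only rescales the
learning rate).

## Training protocol

Mini-batch Adam (lr 1e-3, batch 256 by default; the scaled-down studies
below use 128), at most 2000 epochs with early stopping on validation loss
(patience 50), n independent seeded runs (5 by default) with the winner
chosen by lowest best validation loss, ties to the lowest seed. Validation
loss is the same objective with lambda recomputed from validation interval
counts. All randomness (initialization and batch order jointly) flows from
the per-run seed. The hyperparameter sweep runs gamma over {0.5, 5, 50} at
(alpha, beta) = (0, 0) first, then (alpha, beta) over
{0.01, 0.25, 0.5, 0.75, 0.99}^2 at the chosen gamma.

Exception: the linear baseline with beta = 0 is fitted in closed form by
sqrt(lambda)-weighted least squares per hemifield (rho rescales each
output's independent subproblem and cannot move its argmin). Its objective
is a convex quadratic whose optimum needs large mutually-canceling weights
along near-null data directions — the model has no intercept, so absorbing
the TD offset rides on directions with almost no data variance, where
first-order descent is impractically slow (we measured Adam stalling at
~4.4 dB MAE where the exact solution reaches 0.82 dB). Reporting the exact
minimizer is both faster and the honest statement of what the architecture
can represent.

## Synthetic data generator

No public dataset pairs SDOCT scans with 24-2 fields, so the generator
produces records with *known* ground truth for pipeline tests and
parameter-recovery studies. It emulates, qualitatively:

* the long-tailed severity distribution: latent eye severity (MD scale) is
  a 70/30 mixture of a truncated normal bulk (mean -1.5 dB, SD 2 dB,
  clipped above +2 dB) and an exponential left tail (onset -6 dB, scale
  8 dB, floor -35 dB), so most eyes are near 0 dB and all four MD intervals
  are populated at n in the thousands;
* arcuate structure-function coupling: each chart location owns a disjoint
  angular window ("bundle") on the scan circle — 26 equal windows per
  hemiretina half, assigned in the pass/slot order so near-disc locations
  sit at the temporal pole and successive passes march nasally (a stylized
  stand-in for the anatomical map; the assignment is configurable).
  Damage is piecewise-constant per window and arrives as 1-3 contiguous
  wedges of windows plus a diffuse component that grows linearly with
  severity (fully diffuse at -30 dB);
* the measurement floor: thickness is clamped at 45 um (residual non-neural
  tissue), so realized structural loss — and with it the true TD — saturates
  while latent severity keeps worsening;
* severity-dependent perimetric noise: TD noise SD interpolates linearly
  from 1 dB at TD 0 to 4 dB at TD -30.

The healthy profile is a double-hump TSNIT template (von-Mises bumps of
amplitude 58 um over a 58 um base, concentration 2.5, peaks at the superior
and inferior poles), giving mean ~89 um, peaks ~116 um and troughs ~68 um;
with the severity mixture this puts the early/no-disease group's mean
thickness in the mid-80s um, matching the configured calibration target of
87.5 um. True TD is, by default, -1 dB per um of mean thickness loss inside
the location's window (a log-linear variant is available), clipped to the
instrument range [-38, +6] dB. The record's MD is the mask-weighted mean of
the *true* TD, so labels are exact. Measured profiles add 2 um iid noise
(clipped at 0); repeat tests of an eye share its damage pattern and differ
only in noise. Default scale is 500 patients x 2 eyes x 2 tests = 2,000
QC-clean records. Everything is deterministic under the config seed.

Because damage is piecewise-constant per window, the linear-link,
noise-free-profile configuration makes true TD an *exactly* linear function
of the profile. This yields a well-posed recovery study: with 1 dB
homoscedastic TD noise and the floor lowered to 15 um (so the clamp is
rarely active), the exactly-fitted linear baseline should approach the
noise-floor MAE sqrt(2/pi) ~ 0.80 dB — and does (0.81-0.82 dB measured).

What the generator does *not* emulate: real bundle trajectories and their
inter-subject variability, OCT segmentation artifacts and speckle, media
opacity, fixation instability, longitudinal progression, or between-eye
correlation. Passing recovery tests therefore demonstrates that the
pipeline is correct and can exploit the modelled structure, not that the
architecture attains any particular accuracy on clinical data.

## Evaluation

A test's pointwise MAE is its mean absolute TD error over the 52 locations;
group summaries (overall and per disease stage: early/no MD > -6, moderate
-12 < MD <= -6, advanced MD <= -12, staged on true MD) report the mean and
standard error of the per-test MAEs, so n is the test count. Sectoral
metrics average TD within each of six Garway-Heath-style sectors per test
and score the sector means across tests (MAE +/- SE and R^2; the R^2 is on
TD-based sector means — pattern-deviation-based sectoral metrics are out of
scope). The shipped sector table is a documented geometric approximation
(central: the |y| = 3 points with -3 <= x <= 9; temporal: x >= 15 around
the blind spot; nasal points x <= -9 split by hemifield; the remaining
arcuate points split by hemifield); the published correspondence map is not
reproduced numerically, and the table is an editable YAML keyed by chart
coordinates (`data/sector_map.yaml`). TD-binned error curves pool all
(test, location) pairs into 1 dB bins of true TD with the overall MAE as a
reference line; empty groups report NaN, never zero.

## Numerical core

No deep-learning framework is assumed: the architectures run on a compact
in-repo reverse-mode autodiff engine (`retinerve.nn`) over numpy — conv1d
as a blocked im2col feeding BLAS matmuls (channels-last, so each gather row
is a contiguous block; buffers are blocked to ~8 MB and regathered in
backward, which on a memory-bandwidth-limited single core is substantially
faster than materializing the full column matrix), width-2 max pooling as
pairwise maxima with ties routed to the earlier sample, and input gradients
as shift-accumulated gemms. Gradients are verified against central finite
differences in the test suite, and the full recursive forward is verified
against an independently coded, loop-based unrolled reference to below
1e-6 in float64. Training uses float32; float64 is available via the
architecture spec and is used wherever oracle equivalence is asserted.

## Problem sizes used in the shipped studies

Clinical registries pairing SDOCT scans with 24-2 fields at scale are
private, so the shipped experiments run on generator output at desk scale,
chosen as the package's own defaults: recovery uses 2,000 records with the
linear link (exact-WLS linear fit; the recursive model trains 200 epochs,
batch 128, patience 50, one run), and the class-weighting trade-off uses
the default 2,000-record mixture with 3 seeded runs of 20 epochs per
(alpha, beta) cell at alpha in {0.01, 0.99}, beta = 0.25, gamma = 5. At
these sizes the trade-off is already unambiguous: upweighting the rare
advanced interval roughly halves its validation MAE while the early-interval
error worsens — the direction, not the magnitude, is the claim.

## Known limitations

* The pass-to-location assignment within a hemifield (nearest-the-blind-spot
  ordering with a documented tie-break) and the bundle-window ordering are
  deterministic conventions consistent with the architecture's description,
  not anatomical ground truth.
* The uniform MD mask is a stand-in for the instrument's unpublished
  weights; all MD quantities are defined relative to the configured mask.
* The generator's structure-function link is statistical, not biophysical;
  absolute MAEs on synthetic data are not comparable to clinical MAEs.
* The linear baseline's closed-form fit applies only to beta = 0; a
  multi-task linear fit falls back to the generic optimizer.
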