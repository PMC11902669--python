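# Methods

## Overview

`gridcellnet` studies how grid-cell-like spatial codes emerge in a recurrent
network trained, with supervision, to track its own position and heading from
self-motion alone (path integration). The pipeline has four parts: a
kinematic trajectory simulator for a wheeled agent in a square arena; two
closed-form "ground-truth" population codes that serve as soft supervision
targets; an LSTM network with a linear readout and dual softmax decoders; and
a tuning analysis that scores every readout unit for grid-, border- and
head-direction-like structure.

## Trajectory simulation

The arena is a 6.4 m square (coordinates in metres, origin at the centre,
bounds ±3.2 m on both axes). Episodes are 100 steps long and start from a
uniform random pose inside the central 2.1 × 2.1 m region. Each step the
agent receives one of seven discrete yaw-rate commands spanning −2.25 to
+2.25 rad/s in 0.75 rad/s increments, turns for one control interval, then
translates at constant forward speed. The command value is treated as an
angular velocity; the control interval (dt = 0.5 s) and forward speed
(0.4 m/s, within a small UGV's envelope) are model choices — together they
let one episode traverse the arena a few times over. Heading is wrapped to
(−π, π].

Wall avoidance is a look-ahead policy, not physics. When the straight-ahead
point several steps out would come within `wall_margin` (0.30 m) of a wall,
the command is resampled from those that turn the heading toward the arena
centre, preferring commands whose resulting position keeps the margin. The
look-ahead horizon is the number of steps a full heading reversal takes at
the maximum yaw rate (⌈π / 1.125⌉ = 3 steps at defaults): any shorter
horizon can strand the agent in a corner with too little room to swing away,
because the minimum turning arc covers ~0.56 m of travel. With this policy
we observe zero wall contacts in 10⁶ simulated steps while an 8 × 8
partition of the interior is fully covered by 1,000 episodes. A hard
position clamp remains in the step function as a safety net; the test suite
asserts it never engages.

Per-trajectory random streams are spawned from (master seed, trajectory
index), so any single file of a dataset can be regenerated independently.

## Population codes

Position is encoded by N place cells with centres scattered uniformly over
the arena and a shared Gaussian scale σ:

    pcact_i(p) = softmax_i( −‖p − c_i‖² / 2σ² )

Heading is encoded by M head-direction cells with uniformly random preferred
angles μ_i and shared Von Mises concentration κ:

    hdcact_i(φ) = softmax_i( κ cos(φ − μ_i) )

Both are mixture-model posteriors: probability vectors that sum to one. The
softmaxes are evaluated through log-sum-exp so small σ or large κ cannot
underflow. Defaults are N = 256, M = 12, σ = 0.35 m, κ = 20 — a place field
roughly a tenth of the arena wide and a head-direction tuning width of ~25°.
The ensembles are fixed after initialisation; their parameters are embedded
in the dataset manifest so labels are always reproducible from stored poses.

Decoding helpers invert the codes approximately for evaluation: the
activation-weighted mean of place centres, and the circular mean of
preferred angles. These are evaluation aids only; the network never sees
them.

## Dataset store

Datasets are directories of HDF5 shards plus a JSON manifest; 100 shards
with the first 70 forming the training split and the remaining 30 the
evaluation split. Shards store kinematics (initial pose, per-step inputs
(v, sin φ̇, cos φ̇), per-step target poses) rather than activation matrices;
labels are rematerialised on read from the manifest's ensemble parameters.
This keeps shards small and lets one dataset serve sweeps over ensemble size
or scale without regeneration.

## Network

A single LSTM cell (128 hidden units) consumes the per-step self-motion
triple. Its initial cell and hidden states are linear functions (no bias) of
the ground-truth population codes of the starting pose, through four learned
matrices — the network is told where it starts, in the language of the codes
it must predict, and must path-integrate from there. Each hidden state maps
through a linear layer to 256 activations; two affine heads with softmax
produce the predicted place and head-direction codes. Dropout (p = 0.5) is
applied to the 256 linear activations during training only; all analyses use
eval-mode activations. The dropout on the readout is the regularisation
under which grid-like solutions are known to be favoured in networks of this
family.

The loss is the soft-target cross-entropy of both heads, equally weighted,
averaged over steps and batch. Training uses Adam with global-norm gradient
clipping at 1.0 and full-sequence backpropagation (no truncation; sequences
are 100 steps). The forward pass, backpropagation through time and the
optimiser are implemented directly on NumPy arrays; analytic gradients are
verified against central finite differences (relative error < 10⁻⁴,
including through the dropout mask) in the test suite. Parameters use
variance-scaled (Glorot) uniform initialisation with forget-gate biases of
1; weights default to float32, with float64 available for gradient checks.

The package-wide default learning rate is 10⁻⁴ for long full-scale runs.

## Tuning analysis

For each readout unit, eval-mode activations are paired with the
ground-truth positions of the evaluation split and binned into a 32 × 32
ratemap over the full arena (arithmetic mean per visited bin; unvisited bins
are flagged, not zero-filled).

The spatial autocorrelogram (SAC) holds the Pearson correlation between the
ratemap and every integer (dx, dy) shift of itself, computed over bins where
both copies are defined and masked invalid below 20 overlapping bins. All
shifts are obtained at once from six cross-correlation maps of the masked
ratemap. The ratemap is first restricted to its inscribed disk: on the full
square the overlap window of a shift is a rectangle whose shape depends on
the shift direction, which imprints a spurious four-fold symmetry on the
correlogram (a perfectly radial field would correlate better with its 90°
rotation than any other); disk overlaps depend only on the shift magnitude.

Gridness follows the rotation method: the SAC is rotated by 30°, 60°, 90°,
120° and 150° (bilinear interpolation; invalid bins poison their stencils)
and each rotation is correlated with the unrotated SAC over an annulus. The
annulus excludes the central peak — the inner radius is the first radius at
which the angularly averaged correlation drops below zero — and the outer
radius is swept from inner + 2 bins up to 2.5 × inner, reporting the best
score min(r₆₀, r₁₂₀) − max(r₃₀, r₉₀, r₁₅₀). The 2.5× cap keeps the annulus
around the first ring of correlogram peaks, the structure the score probes:
with an uncapped sweep, far-field rings of plainly non-hexagonal banded
patterns can realign in phase under rotation and collect spuriously positive
scores (a pure stripe field scores +0.15 uncapped versus −0.33 capped, while
an ideal hexagonal field scores > 1 either way).

Head-direction tuning is the length of the activation-weighted circular
resultant over a 36-bin tuning curve (activations clipped at zero — the
linear layer can go negative, and only the non-negative part is meaningful
as a firing-rate analogue). The border score contrasts mean activation in
bins within 0.4 m of a wall against the interior, normalised to [−1, 1].

Units are tagged grid-like (gridness > 0.37), border-like (border score
> 0.5) or hd-like (resultant length > 0.5), in that precedence, else
untuned. All thresholds are configuration and are recorded in the report.

## Scaled-down experiment

The emergence experiment in the test suite runs at desk scale: 64 place
cells, 12 head-direction cells, 500 episodes (350 train / 150 eval), 50
epochs, learning rate 10⁻³ (the conventional Adam default, suited to a short
schedule), batch 32. Under these conditions, across master seeds 1–3, the
median position-decoding error of the trained network beats the uninformed
baseline (the median distance of eval positions from the place-centre
centroid) by ~0.2–0.3 m, and every seed produces at least one linear unit
above the 0.37 grid-like threshold (best units ~0.45–0.55). Longer training
at full ensemble size is expected to sharpen periodicity further; the
desk-scale run demonstrates the emergence effect, not its asymptotic
strength.

## What the synthetic data does and does not capture

The simulator reproduces the statistics that matter for path integration in
a bounded arena — bounded uniform exploration, discrete yaw commands,
constant forward speed, collision-free trajectories — but has no wheel slip,
motor dynamics, sensor noise or odometry drift. Supervision targets are
exact posteriors of the true pose, so passing tests demonstrate that the
architecture can learn spatial codes from clean self-motion; they do not
demonstrate robustness to the noise a physical robot's odometry would add.

## Numerical choices and degenerate inputs

Softmaxes (codes, decoders, loss) are computed in log space. Activation
vectors sum to 1 within 10⁻⁹. A non-finite activation during the unroll
raises an error naming the failing step; a non-finite training loss restores
the last finite-loss parameters and stops. Constant ratemaps have no
defined SAC (zero variance) and raise; units whose SAC has no valid annulus
are reported untuned rather than scored. Heading decoding raises when the
resultant vector vanishes. Ties in the wall-avoidance eligibility set are
broken uniformly at random from the episode's own stream.
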