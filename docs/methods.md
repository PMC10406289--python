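# Methods

This note documents the models behind `mrseqopt`: what is simulated, what
is assumed, which knobs matter, and where the design was genuinely open.

## Sequence model

A sequence is described by 12 parameters (echo type, readout type, matrix,
TE, TR, ETL, EPI factor, readout duration, excitation/refocussing angle,
measurements, prescans).  Echo type × readout type selects one of four
Cartesian families, each compiled to an explicit timing plan:

* **RARE** — CPMG echo train (excitation phase 0°, refocussing phase 90°);
  refocussing pulse *m* at (m−½)·esp, echo *m* at m·esp.  The echo spacing
  is chosen so the echo that acquires the k-space center falls exactly at
  TE; PE lines are interleaved over shots (line *j* of shot *s* has index
  j·n_shots + s), so echo number maps to contiguous k-space bands.
* **EPI / SE-EPI** — echo-planar train with alternating readout polarity and
  echo spacing = readout duration + 0.1 ms ramp allowance; the center line
  is sampled at TE; SE-EPI adds a refocussing pulse at TE/2.
* **bSSFP** — one line per TR, echo at TE, excitation phase alternating
  0°/180°; a linear flip-angle ramp of dummy prescans (no ADC) precedes the
  first measurement and the receiver demodulates by the transmit phase.

RF pulses are instantaneous rotations (hard-pulse approximation) with a
nominal 1 ms duration reserved in the timing checks; there are no gradient
waveforms at this abstraction level, so "gradient spoiling" is modeled as
ideal destruction of transverse magnetization at its flagged location
(crusher pairs around refocussing pulses and balanced readouts preserve
magnetization and are no-ops).  Validity checking enforces TE < TR, matrix
divisibility by the train length, minimum TE implied by the readout timing,
train-fits-in-TR, and refocussing consistency with the echo type.  These
rules prune the shipped parameter grid the way a scanner's protocol checker
would; the surviving grid is the Cartesian product of the per-family value
lists in `dataset.TRAINING_GRID`.

Acquisition time is TR · shots/measurement · measurements + TR · prescans
(the bSSFP default: 8·64·1 + 8·8 = 576 ms).

## Phantoms

Two deterministic 2D phantoms on a 100×100 mm field of view, with 3 T
brain-tissue parameters (CSF 4000/2000 ms, GM 1350/110 ms, WM 850/80 ms;
proton densities 1.0/0.8/0.65 — literature values, config-overridable):

* **Square phantom** (4 spins/mm², 40 000 spins): CSF, GM and WM panels
  plus a section of 3 mm CSF stripes used as the sharpness target.  The
  object spans only 46 mm in PE so its N/2 ghost replica lands entirely
  outside the object; evaluation masks cover each tissue, the structure
  area, a CSF window including its boundary (the homogeneity reference
  would otherwise be constant), the ghost region (the object support
  translated by half the PE field of view), and a noise region in the image
  corners — placed there because truncation-ringing tails of the object and
  its ghost replica run along the image axes and would otherwise
  contaminate the noise estimate.
* **Circular phantom** (2 spins/mm², 20 000 spins): a 15 mm disk, optionally
  with uniform 50 Hz off-resonance or a sawtooth translation along PE
  (default 5 mm amplitude, period = one measurement duration, sampled at
  each excitation).  Motion and distortion sensitivity compare against the
  *reconstruction* of the plain disk, not the ground-truth map, so
  sequence-intrinsic blurring does not leak into those metrics.

Spins sit on a regular sub-grid (the most isotropic integer factorization
of the density), making every phantom — and hence every simulation —
deterministic.

## Simulation

One magnetization vector per spin.  RF events apply exact rotation
formulas; between events the transverse component decays with T2 and
precesses at the spin's off-resonance while Mz relaxes toward the proton
density.  Spatial encoding is analytic: sample *a* of a line sums
m_xy · exp(−i2π k·r) over spins, with the within-readout T2 decay and
off-resonance phase propagated in closed form from the echo center (no RF
occurs inside a line, so this is exact).  That propagation is what makes
EPI distortion, T2 blurring and Nyquist ghosts emerge rather than being
painted on.  All measurements are simulated back-to-back and only the last
one is recorded, so steady-state effects (including the first-shot
transient that ghosts single-measurement RARE) are captured.  Motion
displaces spin positions once per excitation ("slow drift" regime).  Coil
sensitivity is homogeneous.

**Noise.**  Complex Gaussian noise is added per k-space sample with a
*fixed receiver noise floor per unit readout bandwidth*: `noise_level`
(default 0.02) is calibrated as 1/SNR of a fully relaxed unit-PD tissue at
a 64×64 matrix with a 2 ms readout.  Under this model SNR scales with voxel
size (∝ 1/matrix²·samples ⇒ ∝ 1/matrix), with √(readout duration), and
with the magnetization the sequence actually refocuses — the dependencies
the training grid is designed to probe.  A self-normalized alternative
(noise proportional to each image's own maximum) was rejected because it
makes SNR almost independent of the sequence.

Reconstruction reverses negative-polarity EPI lines, zero-pads k-space to
the 1×1 mm grid and takes the magnitude of the orthonormal inverse FFT
(energy-preserving, so Parseval holds exactly).

## Metrics

Contrasts are ratios of mean signal between tissue masks; SNR is the
single-image background method with the Rayleigh correction 0.655 (capped
at 10⁶ for degenerate noiseless input); ghost level is mean ghost-region
over mean object-region signal — the orientation is chosen so that *small
is good* and a bound like GHOST < 0.05 is satisfiable, the inverse of the
ratio's other possible reading; sharpness and homogeneity are Pearson
correlations against the simulated target (scale- and offset-invariant);
motion sensitivity is 1 − max PCC over all integer circular PE shifts (a
pure shift of the object scores 0 by construction); distortion sensitivity
is the circular distance of the argmax shift divided by the PE matrix size,
with ties broken toward the smaller shift.

## Surrogates

Inputs are the 10 numeric parameters (echo/readout type are recoverable
from refocussing angle and EPI factor and are excluded).  Three model types
per metric: SVR (tolerance ∈ [0.001, 0.9], epsilon ∈ [0.1, 0.9], kernel ∈
{rbf, linear, poly}; z-scored inputs), kNN (Minkowski exponent ∈ [0.1, 20]
with brute-force distances since the exponent may be < 1, neighbor-weight
kernel ∈ {rectangular, triangular, gaussian}, k = 7), and random forest
(depth 0–20 with 0 = unlimited, 1–20 trees).  Each type gets a random-search
budget (default 200 draws) scored by 10-fold cross-validated RMSE on the
training partition; the tuned candidates are compared by RMSE on the test
partition and only the winner is evaluated on the validation partition
(three-way 60/20/20 holdout, so validation rows never influence tuning or
selection — a property the test suite asserts by corrupting them).  Error
metrics: RMSE, RRSE (relative to the constant-mean predictor, which scores
exactly 1) and RMSLE.  A standardized-column PCA of inputs or outputs is
available as a diagnostic.

## Optimizer

Genomes are 10 genes in [0, 1] affinely mapped to the ranges the training
grid spans — one gene per numeric parameter.  (Twelve genes, one per named
input, would leave two dead genes since echo and readout type are decoded
from the refocussing angle and EPI factor; ten was chosen for that reason.)
Repair recovers the categoricals by rounding (refocussing angle → {0, 180},
EPI factor → grid values with 1 meaning line readout), snaps every
parameter to the nearest admissible family grid value (train lengths
restricted to divisors of the matrix), and replaces an infeasible TE/TR
pair with the nearest feasible family grid pair under range-normalized
distance — values beyond the family maximum clamp to the largest pair, so
a line-readout gradient echo asking for 130/4300 ms becomes the bSSFP grid
maximum 17/36 ms.  Repair is idempotent and every repaired candidate passes
validation.

Fitness penalties: 1000 per violated strict constraint (far above any
attainable goal magnitude; acquisition-time goals are range-normalized
first, so a positive fitness certifies a penalty-free incumbent), 0.1·|goal|
per violated vague constraint, and exp(50·violation) for the artifact
metrics; a prediction exactly at a bound counts as violated (penalty
exp(0) = 1).  The loop is elitist (2 elites) with tournament selection
(size 3), line crossover with probability 0.1 sampling u ∈ [−0.1, 1.1]
along the parent segment, and Gaussian mutation with probability 0.9,
step 0.1, applied per gene at rate 1/d (single-coordinate moves refine the
incumbent far better than all-coordinate kicks under elitism).  Population
50, 100 generations.  The penalty constants, crossover interval and
mutation granularity are this package's own defaults and are
config-overridable.

## Ordinal dictionary

Vague wording maps to numeric bounds: avoid → metric < 0.05 and allow →
metric < 0.20 for ghost/motion/distortion; "have ⟨quantifier⟩" gives lower
bounds rising monotonically very_low → very_high: 1/2/5/10/20 for
contrasts, 5/10/20/30/50 for SNRs, 0.5/0.65/0.75/0.85/0.95 for
sharpness/homogeneity (artifact quantifiers give upper bounds 0.01–0.5).
The anchors are the documented translations (high contrast → >10,
sharpness > 0.85, ghost < 0.05); the remaining bands interpolate
monotonically and live in a config.

## Problem sizes used by tests and the acceptance script

The shipped grid (32/64 matrices) yields 452 valid sequences and is meant
for offline campaigns.  Tests and `scripts/acceptance.py` use the reduced
16×16 / single-measurement grid (42 sequences, four simulations each),
surrogate search budgets of 12–25 draws, and the closed-form simulator
checks at 16–32 matrices — sizes chosen so the whole acceptance flow is a
desk-scale run while still exercising every stage end to end.

## What the synthetic setup does and does not show

The phantoms are 2D, piecewise-constant, noise is stationary Gaussian, the
coil is homogeneous, and motion is a slow drift sampled per excitation.
Passing tests therefore demonstrate correctness of the encoding/relaxation
physics, the metric definitions, the holdout protocol and the optimizer's
constraint handling — not fidelity to in-vivo anatomy, flow, chemical
shift, T2*, multi-coil reception or fast intra-shot motion, none of which
are modeled.  Surrogate quality is assessed against this simulator's own
outputs; absolute error levels on scanner data would differ.

## Known limitations

* Non-Cartesian trajectories, partial Fourier, parallel imaging and
  preparation modules (inversion recovery, fat saturation) are out of scope.
* EPI line ordering is linear bottom-up; other orderings would change the
  distortion/ghost phenomenology.
* The EA assumes the surrogate is cheap and trusts it entirely; there is no
  re-simulation of the incumbent inside the loop.
* Param-vs-param strict constraints (e.g. TE > TR/10) parse and evaluate,
  but their interplay with repair is untested territory.
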