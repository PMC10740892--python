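# Methods

This note records the models, parameter choices and numerical decisions
behind vestibsim, and what the synthetic world does and does not
establish.

## Stimulus model

A biphasic pulse is two mirror-image phases separated by an interphase
gap of `gap_frac × phase_us` (default 10 %), the gap carrying exactly
zero current (open-circuit idealization). The first-phase sign follows
the polarity (cathodic = negative). Because the second phase is the exact
negation of the first, every rendered pulse is charge balanced to machine
precision before quantization; half-away-from-zero rounding keeps the
quantized pulse antisymmetric too, so quantization does not introduce net
charge.

**Ramp geometry.** The slope of a ramped phase is quoted in degrees on
normalized axes — one phase duration maps to 1 in time, the nominal
amplitude to 1 in current. The envelope rises at tan θ until it reaches
the nominal amplitude and plateaus (a trapezoid); for tan θ ≤ 1 there is
no plateau and the phase peaks at tan θ·A at the phase offset (at 45° this
is the triangle that just reaches A). The symmetric rise-and-fall shape
applies the same slope on both flanks. This convention makes the
closed-form charge (plateau·A + ramp·A_peak/2) consistent with the
triangle picture at every slope, and keeps charge monotone in θ at fixed
phase and amplitude. The alternative convention — fixed peak, slope sets
ramp duration — was considered and not implemented; the envelope function
is the single extension point if it is ever needed.

**Sampling.** Waveforms are sampled at segment midpoints at the emulated
2 µs hardware resolution, so the discrete sum reproduces the continuous
charge of piecewise-linear envelopes to ≪ 0.1 %. Simulations consume the
unquantized rendering: the linear field scaling used to batch amplitudes
would otherwise be broken by the step nonlinearity, and 20 µA steps are a
hardware artifact, not physiology.

**PFM trains.** Pulse onsets are the integer crossings of the closed-form
integral of r(t); deterministic, jitter-free. Onsets are located by
inverse interpolation on a dense grid of the exact integral (no
quadrature error).

## Synthetic labyrinth

The anatomy module replaces a CT/µMRI-segmented labyrinth with parametric
geometry in mm, right-handed frame. Three cristae (LH, LA, LP) sit 4–6 mm
apart; each carries 100 afferents whose start positions are sampled on a
0.36 mm disc in three zones (peripheral 40 %, intermediate 30 %, central
30 % — the literature values live in prior morphometry work, so these
proportions are explicit, configurable placeholders). Fibers run straight
past the common trunk at the origin (total length ≈ 5.5–6.5 mm) with
nodes of Ranvier every 100 × diameter. Diameters are truncated-normal
(mean 3 µm, sd 0.5, bounds [2, 4]): the spread creates graded thresholds.
A stimulating electrode sits 0.2 mm outside each crista center, one
distant return serves all (monopolar), and each branch has a
recording/reference pair near its trunk for differential eCAPs.

Default canal axes: horizontal (0,0,1); anterior and posterior at ±45°
azimuth in the horizontal plane. They are exactly orthogonal — a
deliberate idealization (real canal planes deviate by ~10–20°); axes are
user-overridable and normalized on input.

The optional facial-nerve branch is a 50-fiber bundle placed beyond the
crista belt, strictly farther from every stimulating electrode than that
electrode's own target fibers (verified at construction); its lowest
threshold defines the upper stimulation limit UL.

Everything is generated from a single seed and round-trips exactly
through JSON (floats serialized at full repr precision).

## Volume conductor

Potentials are analytic point-source solutions in an unbounded
homogeneous medium: V = I/(4πσr), with the uniaxial anisotropic closed
form 1/(4π√σₜ·√(σₜ r∥² + σₗ r⊥²)) for nerve tissue. This replaces a
finite-element solve of real geometry: it preserves linearity,
superposition and reciprocity exactly — which is what every downstream
computation uses — at the cost of ignoring boundaries, compartment
inhomogeneity and electrode interfaces. Any callable with the same
signature can stand in as a numerical kernel. Defaults: saline 1.4 S/m
(0.9 % NaCl, bench mode), soft tissue 0.3 S/m, nerve 10:1
longitudinal:transverse — stated as configurable defaults, not measured
values. The bench "current spread" test reports open-circuit potentials
at neighboring electrodes plus a spread index normalized to a fixed
0.1 mm reference distance.

## Afferent membrane model

Nodes of Ranvier are excitable patches (node length 1.5 µm) coupled by
internodal axial conductance (axoplasm resistivity 70 Ω·cm, axon/fiber
diameter ratio 0.7, myelin a perfect insulator). Extracellular potentials
force the cable through the activating function (discrete second
difference along the fiber, zero-flux sealed ends — which makes the
transmembrane currents sum to zero at every instant, the prerequisite for
physical eCAPs).

Kinetics are the classic squid-derived rate functions, but with **nodal**
channel densities: g_Na = 480, g_K = 36, g_leak = 20 mS/cm², C = 1 µF/cm²,
and a ×8 acceleration of all gating rates. The leak reversal is computed
at construction so rest is an exact equilibrium. This corner was
calibrated once, against stated physical ranges rather than test
outcomes: with squid somatic densities (120/0.3 mS/cm²) the node
integrates charge almost perfectly (no rheobase floor; a
strength–duration fit gives a degenerate, negative chronaxie) and strong
stimuli produce a conduction-block window at 4–8× threshold, so a 1 mA
sweep top would not be supramaximal. With nodal densities the default
population has thresholds of 24–61 µA at 0.2 mm electrode standoff, a
rheobase floor with chronaxie ≈ 300 µs (inside the 50–700 µs range for
myelinated fibers), and reliable propagation to at least 3 mA.

**Integration.** IMEX scheme at the 2 µs stimulus resolution:
Crank–Nicolson on the constant axial operator (one banded solve per step,
batched over stimulus amplitudes), exponential Euler on the gates,
explicit ionic currents. Divergence is declared when |v| exceeds 500 mV
*plus the peak applied extracellular potential* (a 1 mA source 0.3 mm
away legitimately impresses ~700 mV on the nearest node, and the stable
membrane response tracks a fraction of it) or becomes non-finite.

**Spike criterion.** An upward crossing of 0 mV (absolute; rest −65 mV)
at ≥ 3 consecutive nodes — local non-propagating depolarizations don't
count. Activation additionally requires the first crossing within 2 ms of
pulse onset.

**Surrogate tier.** A leaky integrator (τ = 150 µs) of the activating
function per node, thresholded at 170 mV — the threshold calibrated so
surrogate amplitude-thresholds match the cable tier's on the default
geometry (their rank order agrees with Spearman ρ ≈ 0.99). Being linear,
each fiber has an exact amplitude threshold: sweeps are instant and
recruitment exactly monotone. Fibers may carry planted amplitude
thresholds that the sweep functions honor directly. Activated surrogate
fibers emit a stylized propagating biphasic current template (peak set by
the nodal sodium conductance, conduction at 6 m/s per µm of diameter) so
the eCAP pipeline remains usable; the template is zero-charge per node but
not charge-conserving across the fiber at each instant — only the cable
tier's currents are.

## eCAP synthesis and metrics

Recorded voltage is the reciprocity sum v(t) = Σ w_j·i_m,j(t) over all
compartments of all fibers, with lead-field weights in ohms and currents
in µA (so traces come out in µV); bipolar differential subtracts the
reference electrode. Traces pass a causal 4th-order Butterworth at
7.5 kHz (the cutoff is given; the order and causality are package
choices, with a zero-phase variant behind a flag). The stimulus artifact
is not modeled; instead the P–N measurement window opens at pulse offset,
mirroring hardware blanking. The eCAP detection criterion defaults to
1 µV — a free analysis parameter; on the default geometry it makes the
eCAP threshold land on the same grid amplitude as the 10 % recruitment
rule. Growth-function slope is least squares over the segment from first
detection to saturation (within 5 % of maximum); the abscissa is stimulus
current by default with charge per phase selectable — charge is the
abscissa on which ramped shapes show their efficiency, and is what the
ramp-vs-rectangle regression tests use.

## Oculomotor mapping

Predicted eye-rotation axis = normalize(Σᵢ wᵢ aᵢ) over canal axes aᵢ. The
default weights are the per-branch fractions of fibers activated;
axial-current weighting can be substituted since both are computed
upstream. Misalignment is arccos of the clamped dot product with the
target axis. eVOR traces map a PFM train to velocity
gain·(r(t) − baseline) along the predicted axis, projected onto the canal
frame; gain and baseline are free parameters (eye-velocity calibration is
animal-specific) with defaults 1 and the train's base rate, and a global
excitatory-sign switch covers the display convention in which excitation
of the horizontal canal plots negative.

## What the synthetic world establishes — and what it doesn't

The generator emulates population structure (zones, diameter spread,
converging trajectories), electrode arrangement, and the scale of
realistic thresholds. It does **not** emulate real labyrinth boundaries,
perilymph shunting, electrode interface impedance, stochastic channel
behavior, or hair-cell synaptic drive. Green tests therefore establish
internal consistency (charge formulas vs integration, reciprocity vs
brute force, threshold rules, monotone recruitment, filter conformance)
and qualitative orderings (ramps need less charge at threshold and show
steeper charge-referenced growth than rectangles), not quantitative
agreement with any animal's thresholds or axes. Published in-vivo numbers
depend on individual imaging-derived geometry and are out of reach of a
desk-scale stand-in by design.

Known limitations, beyond the above: off-target canal recruitment is
essentially zero below 1 mA in the default geometry (cristae are 4–6 mm
apart and the medium unbounded), so misalignment at threshold is ~0° and
spillover behavior must be studied with constructed scenarios or custom
geometry; cable-tier recruitment can become non-monotone far above
threshold if parameters are pushed back toward somatic densities; and the
surrogate tier's eCAP amplitudes are larger and more synchronized than
the cable tier's, so the two tiers' growth functions should not be
compared against each other.
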