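# Methods

## Physical model and assumptions

The simulator is built on three standard approximations of
peripheral-nerve electrophysiology:

1. **Quasi-static volume conduction.**  Capacitive, inductive and
   propagative effects in the tissue are neglected, so the
   extracellular potential decouples into a static transfer resistance
   ("footprint", V/A) per electrode–point pair and the instantaneous
   electrode current.  Footprints are computed once and reused across
   every time step.
2. **Linear material impedance.**  Contributions of multiple
   electrodes — and, for recordings, of every fiber compartment —
   superpose linearly.  The stimulation artifact at a recording site
   is therefore the stimulation field evaluated there, and can be
   added to the neural signal.
3. **No ephaptic coupling.**  Each axon is an independent
   computational problem; population simulations are embarrassingly
   parallel and are distributed over a process pool.

Electrodes are dimensionless point sources in an infinite homogeneous
medium, isotropic or diagonally anisotropic.  This deliberately trades
geometric fidelity (electrode shape, perineurial sheaths, nerve
boundaries — the domain of finite-element models) for speed; the
package targets the regime where that trade is appropriate, and every
field quantity flows through a footprint interface that a
finite-element backend could implement without touching the solver.

Material presets (S/m): endoneurium σ_x = 0.57 longitudinal,
σ_y = σ_z = 0.085 transverse; epineurium 0.085; perineurium 0.002;
saline 2.0.  These are the values commonly used in nerve
volume-conductor modeling; all are overridable.

## Fiber models

**Unmyelinated fibers** use the classic squid-axon channel set
(m³h sodium, n⁴ potassium, leak; rest −65 mV) on a uniform
single-cable discretization.  The default spatial step is 2.5 % of the
passive length constant.  Axoplasm resistivity defaults to 100 Ω·cm.
This is a generic small-fiber stand-in: mammalian C-fiber kinetics
(slower, 37 °C) are out of scope.

**Myelinated fibers** use the double-cable motor-fiber architecture:
1 µm active nodes of Ranvier (fast Na with gates m/h, persistent Na
mp, slow K s, leak; rest −80 mV; kinetics at 36 °C), flanked by
passive myelin-attachment (MYSA, 3 µm), paranode (FLUT) and six
internode (STIN) sections per internodal repeat.  Each internodal
compartment carries two radial layers: the axolemma (2 µF/cm², low
passive conductance) facing a periaxonal space with its own axial
conduction path, and the myelin sheath (0.1 µF/cm² and 1 mS/cm² *per
membrane*, divided by twice the lamella count) facing the bath.  At
nodes the sheath is replaced by a large shunt (10⁴ S/cm²) so the
periaxonal space opens into the medium.  Axoplasmic and periaxonal
resistivity are 70 Ω·cm.

Morphological parameters are published for nine discrete diameters
(5.7–16 µm).  We interpolate each parameter with a monotone
piecewise-cubic (PCHIP) through the table, extended by a
proportional-to-diameter anchor at 1 µm and a linear-slope anchor at
20 µm.  This guarantees strictly positive outputs over the whole
1–20 µm domain (naive polynomial fits of the same table go negative
below ≈2 µm) and monotone internode length and axon diameter, while
reproducing the table exactly at the tabulated diameters.  Exact
coefficient parity with any other interpolation of the same table is
not claimed.

## Numerical scheme

Per time step the voltage unknowns (membrane potential V per
compartment; additionally the periaxonal potential W for myelinated
fibers, interleaved to bandwidth 3) satisfy a linear system assembled
from backward-Euler discretization with the ionic conductances frozen
at the freshly updated gate values; the system is solved by a banded
LAPACK factorization.  Gates advance by exponential Euler evaluated at
the previous voltage (staggered update), which keeps them in [0, 1]
for any bounded voltage trace.  The default dt of 1 µs resolves
40 kHz sinusoidal drive (25 samples per period); halving dt moves
threshold estimates by well under 2 %.  Boundary conditions are sealed
ends.  Removable singularities of the rate functions are evaluated by
their analytic limits.

**Initialization.**  The nodal channel set is not exactly balanced at
the nominal −80 mV, so every simulation starts from the model's true
resting equilibrium, found once per fiber by implicit relaxation with
large steps (0.05 ms then 0.5 ms until the voltage update falls below
1e-9 mV).  An unstimulated simulation is then a fixed point of the
integrator to ≈1e-5 mV over 5 ms.  Recorded membrane currents are
referenced to this equilibrium (the static baseline, which sums to
zero over the fiber, is subtracted), so recordings are zero at rest.

**Membrane current for recordings.**  The recorded per-compartment
current is the current actually delivered to the extracellular medium:
the through-sheath current for myelinated internodes and the full
membrane current elsewhere.  By construction its sum over compartments
equals the injected clamp current at every instant (verified to 0.1 %
in the tests), which is the discrete form of current conservation.

## Populations, packing, recordings

Diameter distributions are named, parameterized families: truncated
lognormal (inverse-CDF sampling, exact truncation) and truncated
bimodal Gaussian mixtures.  The `sciatic_myelinated` preset — bimodal,
weights 0.7/0.3, modes 5.0/11.0 µm, s.d. 1.7/2.2, truncated to
[2, 16] µm — emulates the shape of published mammalian sciatic/tibial
histograms (small-diameter mode holding roughly two thirds of the
count); `sciatic_unmyelinated` is a truncated lognormal (median
0.9 µm, σ = 0.35, [0.2, 2] µm).  These are *shape emulations*, not
fits to a specific dataset.

Packing initializes fibers on a seeded grid whose pitch is set by the
rms fiber radius, then iterates: overlapping fibers repel along their
center line by slightly more than half the overlap; non-overlapping
fibers step toward the origin with a speed that decays geometrically
(default 0.999 per iteration); after the compaction phase (60 % of the
iteration budget) attraction switches off and repulsion alone removes
residual overlaps.  Termination requires zero overlapping pairs and a
maximum displacement below 1e-3 µm; otherwise a packing failure is
raised with diagnostics.  The result is bit-reproducible for a fixed
seed, preserves the diameter multiset, and reaches a packing density
of ≈0.5 (1000 mixed fibers pack into a ≈116 µm disk).  The minimal
inter-fiber gap defaults to 0 µm (touching allowed) and is
configurable.

Recording footprints come in point-source form (any diagonal
anisotropy) and line-source form (isotropic only), the latter
evaluated with the numerically stable asinh expression; the
line-source value matches numerical quadrature of point sources along
the segment to 0.5 % and converges to the point-source value in the
far field.  Population eCAPs are accumulated streamingly (footprint
matrix × membrane-current vector per recorded instant), so per-fiber
traces never need to be retained.

## Endpoint analyses

Thresholds are found by bisection on a monotone activate/block
predicate with automatic geometric bracket expansion; the returned
value is the *responding* (upper) bracket edge, so reported thresholds
always elicit (or block).  Default relative tolerances: 0.1 % for
activation, 1 % for conduction block.  Spike detection is an upward
0 mV crossing at the excitable compartment nearest the query position
— for myelinated fibers detection is restricted to nodes of Ranvier,
because the internodal axolemma depolarizes only partially as a spike
passes.

The kilohertz-block assay models a 51-node myelinated fiber in a
0.2 S/m isotropic medium with a point source over the central node.
The kHz sine runs from 3 ms; a test spike is launched at the first
node during the kHz steady state (default 10 ms, i.e. after a 5 ms
onset-response exclusion window) and block means no upward crossing at
the node three quarters down the fiber before the kHz burst ends.  The
default search horizon (kHz off at 15 ms, 15 ms simulated) is shorter
than a full illustrative trace to keep the bisection affordable; all
protocol times are parameters.

Near threshold, whether a single test spike passes depends on its
arrival phase within the kHz cycle, so block classification uses two
test spikes at carrier-decorrelated times and requires both to be
blocked; this removes the phase lottery at no extra cost (both spikes
ride one simulation).

Block thresholds rise with frequency and with electrode distance and
are far higher for the smallest fibers (at 2 mm, 4 kHz: ≈6100 µA pp
for 7.3 µm versus ≈2500 for 10 µm).  The diameter dependence is,
however, not globally monotone in this implementation: the 16 µm fiber
blocks slightly *above* the 10 µm one (≈2950 µA pp at 2 mm), because
its internode spacing (1.5 mm) is comparable to the electrode distance
and the field depolarizes fewer of its nodes.  The same close-field
regime shows a block *window* — conduction resumes ≈15 % above the
lower block edge.  Reported block thresholds are always the lower
(minimum blocking) edge.

The eCAP amplitude–latency study activates a packed, 100 % myelinated
population synchronously via an intracellular clamp (6 nA, 50 µs) at
each fiber's first node of Ranvier, with nodes randomly offset across
fibers, and records at eight points on the fascicle surface spaced
2.5 mm starting 2.5 mm from the clamp, in homogeneous (anisotropic)
endoneurium.  Per point, the peak search opens only after the clamp
transient *and* no earlier than distance/(80 m/s): signal arriving
faster than any fiber conducts is volume-conducted activation
artifact, not a propagating spike.  The first recording point is
excluded from the log-log amplitude–latency fit because its window is
dominated by that artifact.  Default problem sizes (100 fibers, 23 mm
fibers, 2.5 µs step, 4.5 ms simulated) were chosen as the smallest
population for which the per-point peaks are population- rather than
single-fiber-dominated while a full study completes in about a minute
and a half.

**Known limitation.**  With this population the fitted slope is
shallow (≈ −0.3 to −0.5), not the inverse-square (−2) scaling reported
for dispersed compound potentials in vivo.  The cause is structural,
not statistical: the preset places ≈30 % of fibers in the fast
(≈11 µm) mode, whose conduction velocities span less than a factor of
1.5, so their spikes stay mutually coherent over the entire 20 mm span
and the per-point peak locks onto this non-decaying front (a synthetic
arrival-time model reproduces the same shallow slope at 2000 fibers,
ruling out small-sample noise).  Inverse-square scaling requires the
peak to sit in a dispersing continuum of arrival times, i.e. a
diameter distribution with a much thinner fast tail than this preset;
real recordings additionally low-pass the sharp coherent front
(electrode/amplifier bandwidth), which the analytic recorder does not
model.  The experiment, not the preset, is reported as computed.

## Optimization layer

A cost function composes an optional input filter (identity by
default), a static simulable context (never mutated — modifiers work
on deep copies), a context modifier realizing a candidate vector as a
stimulus, and a cost evaluation.  Waveform search spaces: cathodic
square pulse (amplitude, width) and N-knot splines (monotone-safe
PCHIP through the sorted knots, clamped to zero at the window edges,
clipped to cathodic polarity; 2N dimensions).  The energy term of the
energy/recruitment cost is the plain sum of squared stimulus samples
on the solver grid; a dt-weighted variant (`stimulus_energy_dt`) is
provided separately for physical energy comparisons across step sizes.

The solver is a global-best particle swarm: inertia 0.7, cognitive and
social coefficients 1.5, velocities initialized at 10 % of the box
span, reflecting bounds.  The best-cost trace is nonincreasing by
bookkeeping, runs are reproducible under a seed, and one generation's
evaluations can be mapped over a process pool.  Defaults (25
particles, 60 iterations) drive a 2-D sphere cost below 1e-3.  A
scipy-based continuous optimizer can be slotted in wherever a callable
with the same (cost, bounds) signature is accepted; none is bundled.

## Reproducibility

All stochastic components (population generation, packing
initialization, node offsets, swarm initialization) consume
`numpy.random.default_rng` seeds; per-fiber streams derive from the
master seed plus the fiber index, so results are invariant to the
worker count.  Config-driven runs embed a SHA-256 hash of the
canonicalized configuration and the package version in every output.
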