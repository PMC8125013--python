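# Methods

## Scope and model

`znsh` simulates the photoinduced ring-closing (pericyclic) reaction of
a diarylethene-type photoswitch as mixed quantum–classical dynamics on
two electronic states, S0 and S1, along a single reaction coordinate:
the distance r between the two bond-forming carbons (C1–C6).  Classical
nuclei are propagated on one adiabatic surface at a time; near avoided
crossings the trajectory may switch surfaces stochastically with a
Zhu–Nakamura (ZN) transition probability, which needs only local
energies and gradients — no non-adiabatic coupling vectors.  The same
machinery runs on analytic linear-crossing models, for which an exact
grid quantum-dynamics oracle and the classic Landau–Zener (LZ) formula
provide ground truth.

Internal units are Hartree atomic units; interfaces use kcal/mol, Å,
fs, amu (1 Hartree = 627.509474 kcal/mol, 1 Bohr = 0.529177210903 Å,
1 fs = 41.341374575751 a.u.).

## The surrogate surfaces

The two adiabatic curves are built from published multireference
anchor energies (relative to the open-form S0 minimum, which defines
zero):

* **scan variant** — the S1-relaxed profile along r: S1 passes through
  (3.302 Å, 73.0), (2.103 Å, 45.6), (1.517 Å, 52.0) kcal/mol and S0
  through (3.302, 34.4), (2.103, 44.0), (1.517, 18.9).  Used for
  calibration checks.
* **reactive variant** — the same S1 curve over a ground-state curve
  that supports both wells: S0 through (3.302, 0.0), (2.103, 44.0),
  (1.945, 40.8), (1.517, −5.6).  The 2.103 Å point is the published
  intersection-region energy; anchoring S0 there keeps the minimum
  S1–S0 gap at 1.6 kcal/mol at 2.103 Å, consistent with the reported
  hop-point gaps (0–4 kcal/mol).  Default for dynamics.  Note the two
  states are anchored at partly different geometries (S0 at the
  transition state, 1.945 Å; S1 at the gap minimum, 2.103 Å), so anchor
  tables carry per-state point lists.

Each curve is a C¹ piecewise cubic through its anchors with
shape-preserving (PCHIP) interior slopes — no oscillation is possible
between anchors — and zero end slopes, so the harmonic continuations
beyond the anchored range place true minima at the terminal anchors:
the open-form well at 3.302 Å and the closed-form well at 1.517 Å.
Wall curvatures are set by configurable frequencies for the effective
mass: 300 cm⁻¹ on the open side (this is the reactant-well frequency
the Wigner sampler sees; the soft inter-fragment mode of a large
molecule) and 1000 cm⁻¹ on the closed side (bond compression is much
stiffer; a soft inner wall would let high-energy trajectories reach
unphysically short r).  A configurable **gap floor** (default
1.0 kcal/mol) lifts the upper curve wherever the raw interpolants pinch
closer, keeping the adiabatic representation non-degenerate; floors
that would bind at an anchor are rejected because they would break the
exact calibration.  Under the default configuration the floor never
activates (minimum raw gap 1.6 kcal/mol).

The effective 1-D mass defaults to 6 amu — the reduced mass of two
carbon-like fragments approaching along an inter-fragment distance —
and is configurable; the reference calculations work in full
dimensionality and state no such number.

## Initial conditions

Sampling emulates photoexcitation of the thermalized open form: a
harmonic mode is extracted from the curvature of the S0 open-form well
(minimum located to gradient < 1e-8 Hartree/Bohr; curvature by central
finite difference), positions and momenta are drawn from the ground
vibrational state's Wigner density — independent Gaussians with
σ_x = √(ħ/2μω) and σ_p = √(ħμω/2) — and the electronic state is then
set to S1 without touching the nuclei (vertical excitation).  Only the
0 K ground-state Wigner distribution is implemented.

## Hop machinery

A hop is attempted at every strict local minimum of the adiabatic gap
along the trajectory (gap[k−1] > gap[k] < gap[k+1]) with gap below the
30 kcal/mol gate, once per minimum, with a 2-step refractory window
after an accepted hop.  At the minimum:

1. **Local diabatization.**  V12 is half the minimum gap and Ex the
   mean adiabatic energy there.  Diabatic forces are recovered by
   inverting the two-state model with locally constant coupling: the
   splitting obeys |∇(H22−H11)| = gap·∇gap/√(gap² − 4V12²) (opposite
   signs on the two sides of the crossing; one-sided estimates from the
   two bracketing steps are averaged) and the trace obeys
   ∇(H11+H22) = ∇E_lower + ∇E_upper exactly.  This inversion is exact
   on the linear crossing model at any bracket spacing; a naive swap of
   adiabatic gradients across the crossing underestimates the forces
   severely when the 1-fs brackets lie inside the coupling zone, which
   is the typical situation here.
2. **ZN probability.**  With mass-scaled reductions
   G = Σᵢ(1/mᵢ)Σ_α F2ᵢα F1ᵢα and D² = Σᵢ(1/mᵢ)Σ_α (F2ᵢα−F1ᵢα)²,
   a² = ħ²√G √D² / (2(2V12)³) and b² = (E_t−E_x)√D² / (2V12√G), where
   E_t adds the kinetic-energy component along the hopping direction to
   the active potential energy.  The single-passage probability is
   p = exp[−(π/4a)·√(2/(b² + √(b⁴+1)))] (curve-crossing branch, b²
   signed), which is continuous and monotone in E_t and reduces to
   p_LZ = exp(−2πV12²/(ħv|ΔF|)) in the weak-coupling high-energy limit.
   The nonadiabatic-tunneling branch (−1 under the inner root, with
   √(b⁴−1) clamped to zero for b⁴<1 and p = 0 for a non-positive root
   argument) is available but not used for LZ-type crossings; for the
   surrogate's intersection topology (diabatic forces of opposite sign,
   G < 0) |G| is used, with a logged notice.
3. **Hop decision and momentum adjustment.**  The hop is accepted when
   a uniform draw falls below p.  On acceptance the velocity component
   along the hopping direction (the normalized mass-weighted diabatic
   force difference) is changed so total energy is conserved exactly
   (quadratic solve, smaller root); an upward hop whose direction
   carries insufficient kinetic energy is frustrated: rejected, state
   and velocities untouched, no velocity reversal.

## Propagation protocol

Velocity-Verlet integration with one surface evaluation per step;
defaults mirror the reference protocol: dt = 1.0 fs, 500 fs per
trajectory, 40 trajectories, initial state S1.  A trajectory is marked
failed (and excluded from statistics) if it leaves the surface domain
or its total energy drifts by more than 10 kcal/mol; under the default
configuration no trajectory fails.  Accepted hops are applied
retroactively at the detected gap minimum: the trajectory is rewound
one step, switched, rescaled and re-propagated.  Reproducibility: one
master seed (default 2021) is split with `numpy` SeedSequence spawning —
child 0 drives Wigner sampling of all initial conditions, child i+1
the hop decisions of trajectory i — so any single trajectory can be
re-run in isolation.

Integrator fidelity: on a harmonic oscillator at dt = 0.01 a.u. the
energy error per period is < 1e-6 Hartree and the drift scales O(dt²).
On the surrogate at dt = 1.0 fs the steep closed-well descent
(44.0 → −5.6 kcal/mol over 0.59 Å, traversed at ~75 kcal/mol kinetic
energy with the 6 amu mass) costs a few tenths of a kcal/mol per
traversal; whole-trajectory drift is 2–6 kcal/mol over 500 fs,
dropping fourfold per halving of dt (measured: 6.1 / 1.3 / 0.6 kcal/mol
at dt = 1.0 / 0.5 / 0.25 fs).  This is inherent to the printed
energetics at the printed time step, and is well inside the 10 kcal/mol
failure gate.

## Ensemble statistics

Populations are occupation fractions on the common time grid (they sum
to 1 exactly by construction); the S1 decay constant comes from an
unweighted full-window least-squares fit of exp(−t/τ).  Hop statistics
use each trajectory's first accepted hop (time, C1–C6 distance, gap),
with histograms in 20 fs / 0.1 Å / 0.5 kcal/mol bins by default.  A
trajectory is a ring-closing product iff its final r < 1.70 Å
(strictly; exactly 1.70 Å counts as open), the quantum yield is
#closed/#successful with a normal-approximation binomial standard
error, and the ring-closing time is the first instant r drops below
the threshold.

## Exact oracle

The two-component wavepacket propagator uses Strang splitting with the
exact kinetic factor in momentum space (FFT) and the analytic 2×2
exponential of the diabatic potential per grid point (default 4096
points); norm is conserved to 1e-8 per 1000 steps.  Scattering runs
start a quasi-monochromatic Gaussian (energy spread ≤ 5% at the
crossing) on one diabat; the linear diabats are continued as constants
beyond |x| > 25 Bohr so outgoing channels stop accelerating, and a cos²
absorbing mask at the grid edges removes outgoing flux with
per-channel bookkeeping — neither affects the asymptotic populations,
since the diabatic splitting at the clamp radius dwarfs the coupling.
The population remaining on the initial diabat after the passage is
the exact single-passage surface-hop probability, compared against ZN
(agreement ≤ 0.05 absolute required; measured ≤ 0.007 over an 11-point
collision-energy scan at moderate coupling a² ≈ 0.07) and against LZ
in the weak-coupling high-energy regime (≤ 5% relative required;
measured ≤ 0.3%).

## What the surrogate does and does not show

The 1-D surrogate reproduces the calibrated energetics exactly and the
qualitative photochemistry faithfully: barrierless S1 descent, first
hops within ~40–120 fs concentrated at C1–C6 ≈ 2.0–2.2 Å with gaps
≈ 1.7 kcal/mol, and both open and closed products.  Two effects of the
reduced dimensionality must be kept in mind when comparing with
full-dimensional results:

* **No vibrational energy redistribution.**  A single conservative
  coordinate keeps all ~75 kcal/mol in the reaction coordinate, so
  after the first hop trajectories re-cross the coupling region and
  the long-time S1 population equilibrates near 0.5 instead of
  decaying to zero; the fitted decay constant (~600 fs) is therefore
  much longer than the ~143 fs reported for the full system, and the
  quantum yield (~10–25% depending on seed) reflects the fraction of
  oscillation phase spent in the closed well at 500 fs rather than a
  committed branching ratio.
* **Early sub-threshold excursions.**  At these energies the S1 curve
  itself can carry r below 1.70 Å transiently, so in ensemble mean the
  ring-closing time can precede the mean first-hop time even though
  each product individually closes at or after its own first hop in
  nearly all cases.

Passing tests therefore validate the hop machinery, the calibration,
the statistics pipeline and the semiclassical probabilities against
exact references — not the quantitative excited-state lifetime or
yield of the real molecule.

## Numerical choices

* Gap-minimum refinement for reporting uses a parabolic fit through
  the three bracketing gaps; hop bookkeeping uses the grid point.
* `fit_decay` seeds the optimizer at the 1/e crossing; all-ones or
  all-zeros curves are rejected as carrying no decay information.
* Product classification guards the strict 1.70 Å tie-break with a
  1e-9 Å tolerance against unit-roundtrip noise.
* Surrogate domain: anchors padded by 0.9 Å below and 3.5 Å above,
  wide enough for the ~75 kcal/mol wall turning points; evaluation
  outside raises, and the dynamics marks such trajectories failed.
* Problem sizes used in the validation suite: 40 × 500 fs ensembles
  (seconds), 1e5 Wigner draws, 11-energy oracle scans at 4096 grid
  points (tens of seconds), 100-replicate decay-fit recovery.
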