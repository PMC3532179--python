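# Methods

## Model and encoding

The bundled network describes cisplatin-induced apoptosis as 51
irreversible mass-action steps over 52 species (44 dynamic, 8 constant
inputs). Every concentration and rate constant is dimensionless; initial
conditions are 0 or 1 (pre-expressed components such as procaspases,
IAP, Bcl-2 and mitochondrial cytochrome *c* start at 1; stimulus-induced
components start at 0). The constant species — Cisplatin, OCT2, ER, DNA,
ATR, Mit, mitPTP, FasL — act as fixed boundary inputs: they appear only
as catalysts, and the cisplatin dose is the value of the `Cisplatin`
species (maximum 1).

Two encoding rules resolve how a step written `A + B → C` is turned into
kinetics:

* **Catalyst semantics.** A species that participates in a rate law
  without being depleted is a catalyst: it multiplies the rate and takes
  stoichiometry 0. This covers the constant inputs, the signal species
  that act without turnover (aquated cisplatin, DNA damage,
  mitochondrial ROS, open MPTP, Bax·Bak), the active caspases in the
  three apoptosis-producing steps, and caspase-2* in the AIF-release
  step. The choice of which reactants are depleted follows the ODE
  system the scheme defines, not the surface notation of the reaction
  list.
* **Activator recycling.** The four catalytic activation steps that
  convert a bound complex into an activated product (`Calpain*·Casp12 →
  Casp12*`-type steps at k8, k10, k19, k36) regenerate their activator
  (Casp12*, Casp9*, P53*, Casp8*) on the product side. This is required
  for the caspase-8/-9/-12 and p53 moieties to be conserved, which the
  conservation-law machinery verifies independently; the variant without
  recycling destroys those pools and also agrees less well with the
  reference readouts.

Reversible bindings are encoded as forward/reverse step pairs
(`k3±, k5±, k7±, k9±, k12±, k13±, k16±, k18±, k22±, k24±, k25±, k27±,
k33±, k35±`); the 37 forward constants span 0.1–10 with the IAP
dissociation constants (`k12-`, `k13-` = 0.0035) the slowest processes in
the system.

Conserved moieties are computed as an integer basis of the left null
space of the net stoichiometric matrix (rational null space via sympy,
denominators cleared). The caspase-3/-8/-9/-12, p53, Bax, IAP and AIF
pools each total 1 at t = 0 and must stay there within 1e-6 along the
baseline trajectory — this is the main end-to-end integration oracle,
since it is exact for the true flow and independent of the integrator.

One behaviour worth knowing: Bcl-2 and Bax both start at 1 and their
association (`k24±`) runs regardless of the stimulus, so at dose 0 the
state is *not* frozen — the Bcl-2/Bax subsystem relaxes to its binding
equilibrium while apoptosis and everything downstream of cisplatin stay
exactly at 0. Tests assert this corrected statement rather than global
constancy.

## Time convention and horizon calibration

For a pure mass-action system, scaling every rate constant by s and time
by 1/s leaves trajectories unchanged; the time unit is therefore not
identifiable from the rate constants, and the reporting horizon is the
single free convention. Integrated naively to the nominal 24-unit
exposure window the bundled constants give a full-dose apoptosis readout
of ≈ 20.9, far above the reference level 0.22512 — the published
readouts evidently correspond to a different effective time scale. The
package therefore pins the convention by root-finding the horizon t* at
which the full-dose baseline reaches 0.22512; with the bundled constants
t* ≈ 6.4547 (equivalently: keep the 24-unit window and scale all rate
constants by t*/24 ≈ 0.269). Because the baseline readout is strictly
increasing, t* is unique, and all remaining quantities are genuine
predictions at that horizon.

At t* the qualitative reference structure is reproduced: the exclusive
pathway ordering II > I > III, a positive cross-talk residual near a
quarter of the total, dose monotonicity, the signs of every ±30 %
perturbation response (including the inverse response of the
caspase-3/IAP association rate `k13+`), and the sensitivity rankings
(`k1+` leading the rate constants; caspase-8 and IAP leading the initial
conditions). The quantitative agreement is mixed, and the acceptance
tests report it without smoothing: the `k13+` and `k34+` perturbation
levels land within ~3 % of their reference values, while the exclusive
pathway levels, the cross-talk residual and the sub-maximal dose levels
deviate by 10–60 %. Since the baseline pins the only free convention,
no choice of time scale can reconcile those remaining values with the
bundled constants; the corresponding checks are left failing by design
rather than loosened.

## Numerical choices

* **Integrator:** LSODA (adaptive, stiffness-switching) with rtol 1e-8,
  atol 1e-10; BDF and Radau are selectable and agree to ~1e-5 relative.
  The system is only mildly stiff (rate constants span 0.0035–10).
* **Output grid:** 2401 evenly spaced samples including both endpoints,
  so end-of-horizon readouts are solver outputs, not extrapolations.
  Readouts at interior times use nearest-grid-point lookup and are exact
  at grid points.
* **Convergence guard:** tightening tolerances tenfold moves the
  24-unit baseline readout by < 1e-6 (tested).
* **Horizon calibration:** Brent root-finding on the dense solver
  interpolant, xtol 1e-12.
* **Degenerate inputs:** dose 0 gives an identically zero apoptosis
  readout; an empty network compiles to the zero derivative; knockouts
  and scalings are pure functions (the bundled network is never
  mutated) and identity arguments return an equal network.

## Sensitivity analysis

Local sensitivities are central finite differences on multiplicative
perturbations: with step factor h = 1.01, the entry for input x and
output f is (ln f(xh) − ln f(x/h)) / (2 ln h), the log-log sensitivity.
When a perturbed output is non-positive the entry falls back to the
semi-relative form (f(xh) − f(x/h)) / (h − 1/h) and is flagged
per entry; inputs with nominal value 0 are reported as 0 and flagged,
since a multiplicative perturbation of zero is the identity (for the
same reason the `initial_conditions` selector covers only species with
nonzero initial value). Finite differences were chosen over forward
sensitivity equations because the problem is ~50 inputs × 1 output at
desk scale and the scheme is integrator-independent; the step scheme
and size are recorded in the result metadata, and halving the step does
not reorder the top-ranked parameters (tested). Serial steps with equal
constants on the same branch (`k14+`, `k15+`) receive equal
sensitivities, as they must by symmetry.

## Knockouts and species modulation

The decomposition experiment requires removing a pathway's signal
source while leaving the shared caspase-9/-3/IAP core responsive to the
other branches. Knockouts therefore zero the constant input species
(FasL for I; DNA and Mit for II, covering both the DNA-damage and ROS
branches; ER for III) rather than deleting reactions — equivalent to
zeroing the branch's first rate constant, and exactly the intervention
whose residual defines cross-talk.

"Scale species X by f" experiments distinguish two cases. Species with
a nonzero baseline initial value (IAP, Bcl-2, mitochondrial cytochrome
*c*, …) scale that initial value. Activated species start at 0, so an
initial-value scale would be vacuous; they are modulated through the
rate constant of their activation step (`Casp8*` via k34+, `Casp12*`
via k6+, `P53*` via k17+, …), which realises the intended sustained
change in their level.

## Interchange formats

Networks serialise to a plain YAML dialect (one mapping per species and
reaction, a flat parameter table); the bundled model ships as
`data/cisplatin.yaml` so user edits can be diffed against it. SBML
export targets a deliberate mass-action subset of Level 3 Core: one
compartment, constant species marked boundary/constant, catalysts as
modifiers, and explicit `k·∏c` MathML kinetic laws. Identifiers that
are not valid SBML SIds are escaped deterministically with the original
name preserved in the `name` attribute, so export → import reproduces
the network exactly (round-trip right-hand sides agree to 1e-12 at
random states, tested). Structural self-checks (unique ids, resolvable
references) stand in for full-schema validation.

## Random fixtures and what the tests show

Property tests run the compiled right-hand side against an
independently hand-assembled term-by-term oracle on seeded random
networks (≤ 6 species, unit stoichiometries, rate constants in
[0.01, 10], optional catalysts). These fixtures exercise the compiler,
validator and SBML writer on networks the bundled model does not cover
(isolated species, zero reactions, catalyst-free steps); they are not
meant to resemble biological networks, and passing them says nothing
about the biological adequacy of any particular model.

More generally, the suite establishes that the simulator solves the
encoded equations correctly (oracle equivalence, conservation,
convergence) and that the bundled model reproduces the reference
*structure* of dose-dependence, pathway dominance, cross-talk and
parameter robustness. It does not establish that the bundled rate
constants are biologically calibrated — they are order-of-magnitude
dimensionless choices — nor that the quantitative reference levels are
all mutually consistent (see the calibration section).

## Known limitations

* Deterministic mass action only: no stochastic (Gillespie) semantics,
  no compartments or transport, no synthesis/degradation turnover.
* The apoptosis readout is an unbounded accumulator, not a probability;
  comparisons are meaningful at a fixed horizon only.
* Constant-input catalysis makes several upstream signals grow
  polynomially in time (aquated cisplatin linearly, DNA damage
  quadratically, …), so very long horizons are outside the model's
  intended regime.
* Sensitivity entries for zero-valued inputs are reported as flagged
  zeros rather than one-sided derivatives.
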