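# Methods

## The model

`msnsig` implements a mass-action kinetic model of how striatal medium spiny
neurons (MSNs) expressing the dopamine D1 receptor integrate two transient
inputs: an NMDA-receptor-driven intracellular calcium signal (the stimulus)
and a dopamine transient (the reinforcement). The read-out is the
phosphorylation of a generic postsynaptic-density (PSD) substrate that is
phosphorylated by CaMKII and dephosphorylated by PP1 — the kinase/phosphatase
pair that gates corticostriatal potentiation.

Every reaction is an elementary uni- or bimolecular mass-action step,

    A + B  <-(kr)-(kf)->  AB,        v = kf [A][B] - kr [AB],

with irreversible steps represented by kr = 0 and every enzymatic
transformation written as an explicit binding + catalysis pair
(E + S <-> ES -> E + P). Concentrations are in uM, time in seconds, and the
volume is a single well-mixed compartment; "cytosol"/"PSD" tags on species
are bookkeeping only. Calcium and dopamine are *clamped inputs*: their
trajectories are prescribed by the stimulus generator and reactions may read
but never change them.

### Network topology

**Calcium axis.** Calcium loads calmodulin in two sequential steps
(CaM -> CaMCa2 -> CaMCa4), an Adair–Klotz factoring whose constants are
pinned so that an isolated calmodulin + calcium titration reproduces a Hill
fit of fully loaded calmodulin with h ~ 1 and K ~ 6.3 uM. Fully loaded
calmodulin activates CaMKII and PP2B (calcineurin); both targets also bind
the half-loaded intermediate, closing two reaction cycles whose equilibrium
constants satisfy detailed balance (the loop product of Keq is exactly 1;
`detailed_balance_check` verifies this and the builder re-derives the
closing constant if a transcription error ever breaks it). Active CaMKII
autophosphorylates pairwise — the rate is proportional to the square of the
CaM-bound fraction, a holoenzyme-free approximation of the intersubunit
mechanism — and exchanges between an F-actin-rich cytosolic pool and the PSD,
with the active and autophosphorylated forms partitioned toward the PSD.
Autophosphorylated subunits trap calmodulin (slow off-rate) and are
dephosphorylated by PP1. The PSD substrate is phosphorylated by the
*autophosphorylated* PSD forms; because autophosphorylation is second order
in activation, substrate kinase activity grows supralinearly with the
calcium signal and is negligible at basal calcium. This is the package's
main structural choice beyond the published topology: it makes the substrate
response a coincidence read-out rather than a basal-tone read-out, and it
squares the effect of calmodulin sequestration on the response.

**Dopamine axis.** Dopamine binds D1R; the bound receptor catalytically
activates G_olf (activation fit constant ~19 1/s at saturating agonist,
within the published 10–100 1/s band); active G_olf binds AC5. cAMP is
produced by free AC5 (weak) and G_olf-bound AC5 (strong) and degraded by two
phosphodiesterase activities: a low-Km PDE10 component (whose catalysis can
be set to zero to emulate papaverine) and a lumped high-Km component sized
so that cAMP decay from 50 uM fits a monoexponential k ~ 0.5 1/s. PKA is
modeled as a regulatory–catalytic unit that binds two cAMP sequentially and
then releases the catalytic subunit; constants are tuned so an isolated
PKA + cAMP titration fits a Hill curve with h ~ 1.4, K ~ 0.5 uM. PKA
phosphorylates DARPP-32 at Thr-34 (making it a PP1 inhibitor, modeled as
reversible PP1·p34 binding), ARPP-21 at Ser-55 (making it a Ca2+/calmodulin
sequestrant), PP2A (producing a form with high Thr-75 phosphatase capacity)
and the AKAR-like reporter. CDK5 phosphorylates DARPP-32 at Thr-75, which
weakly sequesters the PKA catalytic subunit; Thr-75 is dephosphorylated by
the calcium-stimulated and PKA-stimulated PP2A forms. PP2B (active,
CaM-loaded) dephosphorylates Thr-34.

**ARPP-21 branch (wild type only).** Ser-55-phosphorylated ARPP-21 binds
fully loaded calmodulin with Kd = 30 nM. Its dephosphorylation runs through
the free and calcium-bound PP2A forms plus a pseudo-first-order phosphatase
action on the calmodulin-bound complex (a shortcut for phosphatase access to
the sequestered form that keeps Ser-55 turnover independent of sequestration
state; a three-product enzymatic release step cannot be written within the
bimolecular reaction limit).

**Reporter.** A 0.1 uM AKAR-like PKA/PP1 substrate is included so the slice
PKA-dynamics phenotype (difference-of-two-exponentials response to a single
dopamine transient) is measured on the same kind of probe the experiment
uses. At 0.1 uM it does not perturb the network.

The wild-type network has 68 species and 69 reactions; 17 conserved moieties
(protein totals) are declared and checked. Model variants are built by
removing reactions (D32T34A: the PKA->Thr-34 pair; A21S55A: the PKA->Ser-55
pair), removing species (the without-ARPP-21 model), or scaling the
calmodulin total (overexpression).

## Inputs

The stimulus generator produces the study's standard inputs: 10 calcium
pulses at 10 Hz, each a difference of exponentials (rise 5 ms, decay 30 ms —
fast NMDAR-like kinetics; the constants are config-exposed because no published values pin them), auto-scaled so the summed train peaks at 5 uM over a 60 nM
basal; and a 1.5 uM, 1.0 s dopamine transient over a 20 nM basal, shaped as
a plateau with 10 ms exponential edges so the integrator never sees a true
discontinuity. The input interval Dt = t_dopamine - t_calcium is measured
start-to-start; multi-trial protocols repeat the pair with the inter-trial
interval measured calcium-onset to calcium-onset.

## Numerics

The ODEs are integrated with SciPy's variable-order BDF using an analytic
Jacobian assembled from the stoichiometry (numba-compiled right-hand side
when numba is available, with an identical pure-numpy fallback). Relative
tolerance 1e-6, absolute tolerance 1e-9 uM. Stimulus onsets and offsets are
passed as integration breakpoints so no input edge is stepped over, and the
maximum step is capped (0.01 s by default, mirroring a stiff-solver cap
that bounds interpolation error of the pulsed input). Because the inputs
are evaluated in closed form inside the right-hand side, the experiment
suites run with a 0.05–0.1 s cap; a grid-refinement test verifies that
halving the cap changes trajectories by < 1e-4 relative. Tiny negative
excursions (within solver tolerance) are clamped to zero. Steady states are
found by long integration (chunked, up to 1e4 s) with the convergence
criterion max |d[X]/dt| / max([X], 1e-6) < 1e-8 1/s. Conservation drift of
every declared moiety stays below 1e-6 in all packaged experiments.

## Calibration

No complete rate-constant table for this pathway ships as an input, so all
rate constants not fixed by a published point measurement are tagged
``calibrated`` in `striatal_parameters.yaml` and were tuned against the
published constraint set: the molecular phenotype table (basal levels,
slice fold-changes, monoexponential / difference-of-exponential / Hill
parameterizations) and the published dynamic landmarks (deep transient PP1
inhibition with dopamine, flat PP1 under calcium alone, pARPP-21 rising ~1 s
after dopamine and returning to basal within ~30 s, CaMKII deactivation
tau ~ 6 s). Published totals (DARPP-32 50 uM, ARPP-21 20 uM) are
used as-is. Fold-change phenotypes are evaluated exactly as in the slice
experiments they mirror: sustained clamps (dopamine 10 uM sampled at 5 min;
calcium 1 uM — the NMDA-bath surrogate — sampled at 10 min) referenced to
the basal steady state. Divergences are reported as log2(sim/exp) and
classified into +-30% / +-80% bands; with the packaged file all 20
phenotypic variables are inside +-80% and 19 inside +-30% (the saturating
cAMP level is within +-80%).

Three calibration choices deserve explicit mention:

* **PP2B–calmodulin affinity.** The Kd for fully loaded calmodulin is
  1.7 nM (published estimates argue for a sub-nanomolar value). With the limiting
  calmodulin pool used here (1.4 uM), a 0.5 nM Kd leaves PP2B almost fully
  loaded at basal calcium and the slice-calcium Thr-34 fold becomes
  unreachable. At 1.7 nM the affinity is still ~20x tighter than
  pARPP-21's, so sequestration never touches PP2B — the mechanism the
  affinity separation is meant to protect. Exchange is slow (koff
  ~1e-3 1/s), so PP2B activation is an equilibrium property, not a
  pulse-by-pulse one.
* **Calmodulin is scarce.** The free calmodulin total (1.4 uM) is far below
  the summed demand of its targets, which is the precondition for
  sequestration-based input-order discrimination.
* **Saturable, multi-route ARPP-21 dephosphorylation.** The Ser-55
  phosphatase capacity is split across PP2A forms so that the basal
  turnover is fast (~0.1 1/s; return to basal in ~30 s after a transient)
  while sustained dopamine engages the PKA-stimulated form, holding the
  slice fold near 7x.

## What the experiments compute

All in-silico experiments read out the *activation area*: the trapezoidal
integral of an observable's excursion above its pre-stimulus basal over a
window from the trial's calcium onset to onset + 100 s, normalized by a
calcium-alone baseline with identical calcium input. Problem sizes used by
the packaged suites (and the acceptance script): Dt grids of 10–29 points
spanning -6 to +8 s; two-trial refractoriness at ITIs 10–100 s with the
100 s protocol as the well-separated reference; a 10-trial train at 10 s
ITI; robustness grids over dopamine amplitudes 0.01–3 uM and calcium
frequencies 5–40 Hz; and a one-at-a-time sensitivity scan of all 127
parameters (rate constants and moiety totals) at +-20%, using a reduced
Dt grid (-2, -1, +1, +2 s) and a 60 s window. Everything is deterministic;
no random numbers enter any computation.

For overlapping trials the "activation area in trial k" is defined as the
excursion of the k-trial trajectory above the (k-1)-trial trajectory over
trial k's window, which attributes a decaying earlier response to the trial
that produced it. With well-separated trials this reduces to the plain
definition, so REF(reference ITI) = 0 exactly by construction. The default
refractoriness grid starts at ITI = 10 s: at 5 s the second trial's calcium
overlaps the first trial's dopamine response and the two-trial protocol no
longer represents two discrete conditioning events.

## What the synthetic inputs do and do not capture

The stimulus module generates idealized concentration transients: identical
calcium pulses, a rectangular dopamine transient, exact trial timing. Real
inputs vary in amplitude and timing from trial to trial, dopamine diffuses
and is actively cleared, and NMDAR calcium depends on membrane potential.
Passing the packaged experiments therefore demonstrates that the *network*
implements interval/order/refractoriness computations for prescribed
inputs; it says nothing about robustness to input stochasticity, spatial
gradients, or electrical feedback, all of which are outside the model's
well-mixed, prescribed-input scope.

## Known limitations

* The CaMKII holoenzyme is approximated by pairwise autophosphorylation and
  a single trapped state; no subunit-resolved cooperativity.
* The translocation loop (cytosol/PSD exchange of CaM-bound CaMKII) is not
  thermodynamically balanced — translocation is treated as a driven process;
  detailed balance is enforced (and tested) only on the two
  calcium/calmodulin/target binding cycles, as required.
* PP2A regulation is phenomenological: a calcium-bound and a PKA-phosphorylated
  form with fixed activities; no B-subunit diversity.
* The dopamine-axis gain is tuned to the published slice constraints; the
  saturating cAMP level sits ~30% below the published 10 uM (within the
  +-80% band) because the same gain must also reproduce the basal cAMP
  band and the 50-uM decay fit.
* The +-20% one-at-a-time perturbation distribution has an interquartile
  range of about [-0.011, +0.011] on the full Dt grid (about [-0.016,
  +0.015] on the reduced scan grid, which over-samples the sensitive Dt
  region). This network is leaner than typical published striatal models,
  so individual parameters carry more of the response than they would in a
  more redundant network.
* Mutant curves below the calcium-alone baseline at negative Dt (e.g. the
  T34A model with a preceding dopamine input) reflect calmodulin
  sequestration suppressing the baseline response itself; the substrate
  response to calcium alone is small but not zero, so suppression below 1
  is visible in normalized units.
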