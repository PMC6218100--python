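# Methods

## Model structure

Both size-control models are deterministic ODE systems in molecule
*numbers* (not concentrations), punctuated by two discrete events. The
state of one cell comprises the mother and bud volumes `Vm`, `Vd`
(total `Vt = Vm + Vd`), the transcription-machinery pools, cyclins,
Whi5/SBF species and the APC/C activities; gene copy counts and the
binary growth flags `Grm`/`Grd` are discrete state carried alongside
the ODE vector.

### Gene expression core

A limiting transcription machinery TM binds size-independent genes
(`GIt` copies, dissociation constant `kGiTmDs/kGiTmAs = 2e-5 AU/AV`)
and size-dependent genes (`GDt` copies, `1e-2 AU/AV`); all bimolecular
rates are divided by `Vt`. TM and volume are synthesised in proportion
to the number of active size-dependent genes, which makes growth
autocatalytic. Consequences used throughout:

* exponential growth at `mu = kTmSy*GCN/GDt` while genes are far from
  saturation and almost all TM is bound;
* the TM concentration settles at `kTmSy/kVoSy` (1 AU/AV by default);
* size-independent genes saturate in small cells, so their output is a
  fixed number of molecules per unit time — the Whi5 gene (`GIt = GWt`)
  is the only gene of this class;
* in very large cells the size-dependent genes saturate too and volume
  growth becomes linear. This saturation also acts as a global
  stabiliser of the lineage dynamics (see *Numerical and dynamical
  notes*).

### Cell-cycle layer

Cln3 is produced from size-dependent genes scaled by its own copy
number relative to the genome, `rCln3Sy ∝ GDTM*GCt/GDt`, so its rate
depends on the copy-number-to-ploidy ratio; Whi5 production
`rWhiSy ∝ GITM*GWt/GIt` depends only on its copy number, runs only
during the budded period (`Grd = 1`) into a separate pool `WHIn`, and
the whole of `WHIn` goes to the daughter at division. SBF, Cdh1 and
Cdc20 are synthesised at the volume-synthesis rate so their
concentrations sit near 1 AU/AV. Cln1/2 synthesis requires free
(Whi5-less) and unphosphorylated SBF; Clb1/2 carries a Michaelis-type
auto-activation and is degraded by APC/C-Cdh1; Cdc20 is activated by
Clb1/2 and in turn re-activates Cdh1 — a relaxation oscillator that
times mitotic exit.

Events: Start fires on the upward crossing of `CLN/Vt` through
`StartThr` (arming only in G1) and doubles every gene count (plus the
nuclear sites and the SBF-phosphorylation bookkeeping in the titration
model); division fires on the downward crossing of `(CLN+CLB)/Vt`
through `MitosisThr` (arming only when budded), halves the gene
counts, multiplies every freely diffusing amount by `Vr = Vd/Vm`,
moves `WHIn` into the daughter's free Whi5 pool, and the daughter
becomes the new cell. In the titration model the site-bound complexes
are also multiplied by `Vr`; should the occupied sites exceed the
halved capacity (possible when `Vr > 1/2`), the occupancies are
renormalised proportionally and the displaced Whi5 returned to the
free pool, with a warning.

### The two Start mechanisms

*Dilution*: Whi5 binds free SBF tightly and in a concentration-based
manner; phosphorylation of the complex (by Cln3, Cln1/2 and Clb1/2)
releases active SBF. Whi5's molecule number is constant through G1
while SBF's grows with volume, so free SBF appears at a threshold
volume proportional to the Whi5 amount; the Cln1/2 feedback makes the
transition a bistable switch.

*Titration*: total SBF equals the number of genomic sites `NSt`
(freely diffusing SBF is neglected; free active SBF follows from the
conservation `SBF = NSt − WHISBF − CLN3WHISBF − WHIpSBF`). Cln3 binds
Whi5:SBF complexes tightly and hypo-phosphorylates Whi5, dissociating
in the process; the hypo-phosphorylated complex is either
dephosphorylated or hyper-phosphorylated by free Cln3 / Cln1/2, which
liberates SBF. Free Cln3 stays near zero until the total Cln3 made by
the growing cell exceeds what the sites can hold, so the threshold
scales with `NSt` — doubling ploidy (hence sites) doubles the size.

## Parameters

Reference values for the published parameterisation were not available
to this implementation, so the bundled defaults were calibrated from
scratch, in the documented order implemented by
`experiments.calibrate_defaults`:

1. **expression core** — affinities chosen so size-independent genes
   are >98% saturated over the whole operating range while
   size-dependent occupancy stays proportional to volume
   (`kGiTmAs/kGiTmDs = 5e4`, `kGdTmAs/kGdTmDs = 1e2`), and
   `kTmSy = kVoSy = 1.4` with `GDt = 200` for a specific growth rate
   of 0.007 per time unit;
2. **Start threshold** — cyclin synthesis/decay and the
   phosphorylation constants set so the switch sits in the 15–50 AV
   range and is bistable;
3. **Clb/APC oscillator** — a Clb1/2 auto-activation latch
   (`kClbClbSy ≫ kClbSy`, small `jClbSy`), strong Cdh1-mediated
   degradation, and a slow Cdc20 activation that acts as the S/G2/M
   timer (~40 time units, size-independent because every rate in the
   loop is concentration-based);
4. **Whi5 partitioning** — `kWhiSy` fixed last so the steady-state
   Whi5 amount covers the SBF pool (dilution) or roughly 2.5-3x the
   site count (titration).

The committed YAML files under `src/sizecycle/data/` are the frozen
output of this procedure. If published table values are supplied to
`calibrate_defaults`, they pass through verbatim.

Tunable quantities that matter most (defaults for the titration
variant): `NSt = 4` sites per haploid genome; Cln3 concentration
`kCln3Sy*GCt/(GDt*kCln3De) ≈ 0.15 AU/AV`, which sets the titration
threshold near `NSt/0.15 ≈ 27 AV` before Whi5 corrections;
`StartThr = 0.05 AU/AV` and `MitosisThr = 0.04 AU/AV` for the two
events; growth-rate factor `f ∈ [0.75, 1.25]` scaling `kVoSy` and
`kTmSy` jointly. The growth-rate inheritance rule at division is
`mu' = 0.5*mu + 0.5*mu_bar*(1 + eps)` with `eps ~ N(0, variance 0.04)`
(the stated variance convention; sigma = 0.2); a non-positive draw
would be rejected and redrawn, though at this variance that is a
~6-sigma event.

## Numerical and dynamical notes

* Integration uses LSODA with `rtol = 1e-8`, `atol = 1e-10`; events
  use the integrator's root finding with directional crossings, and
  the two-phase state machine (Start armed only in G1, division only
  when budded) makes re-triggering impossible. Halving the tolerances
  moves the next generation's birth volume by well under 0.1%.
* Negative-state guard: rates are evaluated with components clipped at
  zero, the solution vector is never clipped, and any excursion below
  −1e−9 (relative to the state scale) aborts the run.
* The literal `Vr = Vd/Vm` partition at division boosts the daughter's
  concentrations by `(Vm+Vd)/Vm`; species synthesised at the volume
  rate (TM, SBF, Cdh1, Cdc20) therefore cycle between an elevated
  birth concentration (~1.5 AU/AV at the default asymmetry) and a
  slow relaxation toward 1 AU/AV at rate ~mu. One consequence is that
  the *concentration* of Cln3 drifts downward through G1 even though
  its amount tracks the active-gene count exactly; the invariant
  quantity is the Cln3-to-GDTM ratio.
* Gene saturation stabilises the lineage globally: in a very large
  cell the TM pool caps at the gene count, growth turns linear and the
  daughter/mother ratio falls, pulling sizes back. A second,
  large-cell attractor nevertheless exists in the titration model: a
  daughter born above the Start threshold has an almost instantaneous
  G1, so the post-division concentration boost never relaxes, the TM
  concentration ratchets up by ~(1+Vr) each division, and the
  daughter/mother ratio can exceed one. The wild type never reaches
  this regime because large daughters inherit proportionally more
  Whi5, which raises their threshold. The constant-Whi5-at-birth
  intervention removes exactly that feedback, and on a substantial
  fraction of random seeds a tail draw of the growth-rate process
  pushes the clamped lineage into the large-cell regime within a few
  hundred generations, where its whole-cycle statistics turn
  timer-like instead of sizer-like (see *Known limitations*).
* The bistable window of the titration model's Start switch at the
  committed defaults is narrow in volume (folds near 20.72 and 20.74 AV for the wild-type G1 Whi5 amount) — the titration readout
  itself is nearly a hard threshold, so little hysteresis is needed —
  whereas the dilution model's window spans several AV.
  `trace_branches` therefore refines its volume grid adaptively
  wherever the active-SBF branch jumps discontinuously, so thin
  windows are still found from coarse grids.
* Steady states of the clamped Start module (`CLB = 0`, `SBFp = 0`,
  Whi5 total fixed at the G1 amount, Cln3 at its quasi-steady balance,
  volume a parameter) are computed exactly by a scalar reduction in
  the dilution model and by multi-start Newton iteration on the vector
  residual in the titration model; stability comes from central-
  difference Jacobian eigenvalues (relative step 1e-6). Roots are
  validated in the test suite against forward integration of the
  clamped ODEs and against a 20'000-point dense root scan.

## What the simulations do and do not show

The lineage simulations emulate a single daughter lineage of an
asymmetrically dividing cell with growth-rate variability as the only
stochastic element (molecular noise, mother lineages, population
structure and nutrient shifts are all outside scope). Passing tests
demonstrate the internal consistency of the two mechanisms and their
differing ploidy predictions at the committed parameter set; they do
not calibrate the models to measured yeast data, and the arbitrary
units preclude quantitative comparison of absolute sizes or durations
with experiment. The mutant panel inherits the idealisations of the
copy-number overlays: ploidy changes scale `GDt`, `GCN` (and `NSt`)
exactly, the S/G2/M delay of diploids is modelled by a single knob
(weakening Cdh1-mediated Clb degradation by the squared delay factor),
and the "+70%" single-copy Cln3 compensation is a direct scale factor
on `kCln3Sy`.

## Known limitations

* The sizer/timer/adder regression values vary noticeably between
  random seeds at a few hundred generations; the signs (sizer < 0 <
  timer) and the near-zero whole-cycle correlation are the robust
  statements.
* Under the constant-Whi5-at-birth intervention the homeostatic margin
  shrinks (the Whi5-inheritance feedback is exactly what the
  intervention removes). At the committed calibration, lineages of a
  few hundred generations escape to the large-cell regime described
  above on roughly half of the random seeds tried; when that happens
  the G1 sizer read-out survives but the whole-cycle added-volume
  slope flips positive. A calibration that suppresses the escape
  (stronger Cln-mediated Whi5 phosphorylation, or a shorter budded
  phase) was found to sacrifice either the wild-type adder balance or
  the bistability of the Start switch, so the trade-off was resolved
  in favour of the wild-type behaviour.
* The mother cell is summarised and discarded at division; questions
  about mother-daughter asymmetry beyond the first division are out of
  scope.
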