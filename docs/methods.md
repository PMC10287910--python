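# Methods

## The ATPase-cycle model

ParA2 of *Vibrio cholerae* is modelled as a constitutive dimer (SEC-MALS
shows dimers with and without nucleotide), so all internal state is on the
dimer basis; user-facing concentrations are monomer-based, as printed on
instrument protocols, and halved internally.  Each dimer binds two
nucleotides that load and unload as a single kinetic step: the sandwich
dimer is treated as one state with no half-loaded intermediate.  The rate
laws of the loading steps are first order in the free nucleotide pool even
though the stoichiometry consumes two copies — this is how the
pseudo-first-order experiments read out, and it keeps kobs = kon·[S] + koff
exact.

States: apo dimer `D`; closed sandwich dimer `D·ATP2`; remodeled active
dimer `D*·ATP2` (DNA-binding competent); DNA-bound `B`; post-hydrolysis
`D·ADP2`; free ATP/ADP pools with MANT-labelled twins, and labelled
variants of every loaded state so that fluorescent-nucleotide experiments
are represented exactly (total nucleotide, free + bound, labelled +
unlabelled, is conserved except by hydrolysis, which converts ATP- to
ADP-equivalents one-for-one).

One refinement beyond the minimal cycle proved necessary: the active dimer
exchanges its nucleotide *without* collapsing back to the ground state.
Release from `D*·ATP2` (at k₋₁) passes through a transient apo active
dimer `D*` that rebinds nucleotide at k₁ and only slowly relaxes to `D`
(`k_star_relax`, default 0.01 s⁻¹, a declared assumption).  Without this
intermediate, release from the active state recycles through the ground
state and the tryptophan switch would relax at k₂ + k₋₁ ≈ 0.035 s⁻¹,
incompatible with the measured 0.015–0.018 s⁻¹; with it, the switch
relaxes at k₂ while a cold chase reads out release at k₋₁ — both as
observed.

Nucleotide exchange (k₆) is an effective one-step swap on the loaded
dimer, not a release-then-rebind sequence: the measured exchange constants
are far from the composition of k₋₅ and k₁, so the two descriptions are
alternative coarse-grainings of the same flux.  Because including both in
one scheme would double-count, each assay forward model activates the
representation its protocol measures: the chase generator (1 mM cold
nucleotide, release-limited) drops the swap reactions, and the exchange
generator (pre-loaded dimers + labelled nucleotide) drops the free
binding/release reactions.

### Two regimes of release from DNA

The bound state releases by two routes with very different rates in the
data: the radiolabel ATPase assay caps the hydrolysis flux at the
kcat × stimulation scale (≲ 4×10⁻³ s⁻¹ even fully stimulated), while the
DNA-carpet wash shows bound protein leaving at 0.1 s⁻¹.  Read as a single
rate these are irreconcilable — a 0.1 s⁻¹ hydrolysis-coupled release would
imply an ATPase rate two orders of magnitude above the measured one.  The
package therefore distinguishes them: in closed well-mixed schemes the
bound dimer turns over at the catalysis-limited rate kcat × stim (matching
the radiolabel data), and `k4` = 0.08 s⁻¹ is the wash/stimulated-regime
hydrolysis-coupled release used by the carpet model (wash fast rate
k₋₃ + k₄ = 0.1 s⁻¹) and by the spatial model's ParB2-stimulated focus.

## Default rate constants

All defaults live in `src/para2cycle/presets/defaults.toml` (first-order
s⁻¹, second-order µM⁻¹s⁻¹) and were calibrated once against the measured
observables; they are not adjusted per analysis.

| constant | value | calibration |
|---|---|---|
| k1 / k₋1 | 3.6×10⁻³ / 0.018 | MANT-ATP binding kobs ≈ 0.11 s⁻¹ at 25 µM; chase slow phase ≈ 0.018 s⁻¹ |
| k2, k2_dna_factor | 0.017, 3 | tryptophan switch 0.015–0.018 s⁻¹, 0.03–0.07 s⁻¹ with DNA |
| k3 / k₋3 | 0.05 / 0.02 | carpet association 0.05 s⁻¹ at 1 µM; ATPγS wash 0.02 s⁻¹ |
| k4 | 0.08 | carpet wash fast rate k₋₃ + k₄ = 0.1 s⁻¹ |
| kcat; stim (DNA, ParB2, both) | 5×10⁻⁴; 2, 3, 8 | weak basal ATPase (~1.4% of 100 µM ATP in 30 min at 1.5 µM protein) and its fold-stimulations |
| k5 / k₋5 | 9.4×10⁻³ / 0.075 | MANT-ADP chase 0.07–0.08 s⁻¹ with KD = 8 µM |
| k6 (ADP→ATP, ADP→ADP, ATP→ATP) | 6.5, 6.1, 14 ×10⁻⁴ | exchange-series slopes |
| coop_omega | 4 | mean-field stand-in for the Hill-4 cooperative loading |

The printed nucleotide kinetics over-determine (k₁, k₋₁): no pair
satisfies the binding kobs band, the chase slow phase *and* KD = 8 µM
simultaneously under a two-step scheme.  The defaults honour the directly
measured rate brackets, giving an equilibrium KD of 5 µM — the same order
as the 8–11 µM equilibrium estimates.  Similarly, the MANT-ADP defaults
honour the chase rate and KD; the qualitative observation that ADP binding
is slightly slower than ATP binding is not reproduced.

## Assay forward models

Each generator emulates one instrument readout: its kinetic shape, its
sampling grid (stopped flow 0.01 s steps to 30 s then 0.1 s; carpet 1 s
frames; FRAP 0.5 s frames; melts 23→63 °C in 2 °C steps) and iid Gaussian
noise with sigma given as a fraction of the trace's dynamic range (default
0.02 — instrument noise magnitudes are not published; this is a declared
assumption).  Fraction-valued outputs are clipped to [0, 1] with the clip
count recorded in the trace metadata.  Tryptophan controls without a
rising signal carry a linear photobleaching drift of 0.02% s⁻¹.

The cycle-driven assays (MANT kinetics, tryptophan switch, radiolabel
ATPase) integrate the assembled scheme.  The tryptophan weights are
calibrated so the signal-carrying species reaches the observed plateau
increment at steady state (+5% remodeled, +13% DNA-bound, 11.5% with
ParB2, +3% for ATPγS on DNA): the percentages are plateau values of the
assay, and arbitrary-unit instrument weights carry no other information.
The radiolabel model lumps hydrolysis into kcat × stimulation on loaded
dimers (the TLC readout does not resolve DNA-bound intermediates), with a
finite labelled-ATP pool so the steady-state series saturates by substrate
depletion.

The DNA-carpet generator is a reduced piecewise model rather than the full
scheme, because the flowcell continuously replaces the solution phase,
which a closed system cannot represent: one-phase association at k₃ ×
[ParA2] toward a cooperative plateau, then, at the flow switch, biphasic
decay with fast rate k₋₃ + k₄ and slow rate k₋₃, amplitudes split by the
k₄ : k₋₃ branching.  ATPγS slows loading 2.5-fold and removes the
hydrolysis path (single-exponential wash at k₋₃); ADP or no nucleotide
give a near-zero plateau.  ATP-start mode (no preincubation) delays the
rise by 1/k₂ + 1/(k₁[ATP]) plus a fixed 10 s cooperative nucleation lag
and reduces the plateau, reproducing the ~1 min lag of mixing experiments.

EMSA, FRAP and melt generators use their standard closed forms (Hill
isotherm; double exponential with immobile fraction; two-state Boltzmann
sigmoid).  Hill coefficients for conditions other than WT+ATP (n = 4) and
the FRAP mobile fractions of the ParB2 and high-density conditions are not
published; the preset values are declared assumptions recorded in the
preset files.

What passing tests show — and what they do not: the generators reproduce
the *shape and noise structure* of each readout under the published
parameters.  They do not emulate instrument-specific artefacts (gel
smearing, TIRF illumination drift, radioactive counting statistics), and
agreement of fits on synthetic data bounds only the procedure's intrinsic
bias, not its robustness to such artefacts.

## Fitting procedures

Nonlinear fits are trust-region least squares (lmfit) with multi-start
from five log-spaced rate guesses and an SSE tolerance of 1e-10; ties go
to the lowest SSE, then the smaller model.  Single- vs two-phase decay is
selected by AICc with a threshold of 2; the RSS entering AICc is floored
at the numerical precision of the signal so that an exact fit cannot
reward extra parameters with meaningless 1e-20-level gains.  Lag exclusion
takes the fit start at the first time the smoothed derivative exceeds 20%
of its maximum, and the fitted window is always reported.  A fitted
amplitude below 3 residual standard deviations is reported as a flat
trace, not a rate.  Identifiability guards: the Hill coefficient is fixed
to 1 (and flagged) when no point reaches 80% of the fitted plateau;
saturated hyperbolic titrations, flat melts and fully immobile FRAP curves
are flagged rather than fitted.  Pseudo-first-order analysis is ordinary
least squares on (substrate, kobs) pairs — kon from the slope, koff from
the intercept, KD = koff/kon with propagated standard error; a negative
intercept is reported as koff = 0 with the KD flagged undefined.  Units
follow the bench conventions: nucleotide KDs in µM, DNA KDs in nM.

`recover_cycle` consolidates binding, exchange, switch and carpet traces:
stage 1 maps each assay's own fit onto the constants it determines, stage
2 refines by weighted global least squares, re-simulating every trace
through the same forward models.  Identifiability diagnostics are
curvature-based relative widths from the refinement Jacobian plus
structural coverage flags (a parameter whose informing assay is absent is
flagged and left at the prior, never pinned); full profile likelihoods
were judged not worth their cost here since the structural flags and
curvature widths carry the same decisions.  Zero-noise round trips recover
all informed constants to better than 2% (machine precision after
refinement); the titration/relaxation generator–fitter pairs round-trip
to <1% individually.  The exchange pipeline carries an intrinsic ~2%
depletion bias (the protocol's 5:1 label excess consumes a few percent of
the pool), which the global refinement absorbs.

## The spatial tug-of-war model

A 1D lattice (default 2 µm, 100 sites, reflecting boundaries, nucleoid
spanning the full length) carries four fields: cytoplasmic `D·ADP2`,
`D·ATP2`, active `D*·ATP2` (all diffusing at D_cyto, default 3 µm²/s) and
bound `B` (immobile).  Per site:

* recovery chain: `D·ADP2 → D·ATP2` at k₆(ADP→ATP)·[ATP] (ATP fixed at
  1 mM), then `D·ATP2 → D*·ATP2` at the uncatalyzed k₂ — DNA catalysis
  acts on dimers engaging the nucleoid, not on the diffusing pool, and
  this ~60 s step is the delay the observed 30–60 s transit times rest on;
* cooperative loading: rate k_on (1 + (ω−1) θ̄²)(1 − θ) per active dimer,
  with θ the local occupancy of a finite capacity and θ̄ its three-site
  neighbourhood average.  The quadratic (nucleation–elongation) form —
  insertion is strongly favoured only within growing oligomer regions —
  is essential: a linear contact factor has flux elasticity below 1 at
  every occupancy and provably cannot destabilize the uniform state;
* release: unbinding without hydrolysis (`B → D*·ATP2`, k₋₃, instantly
  rebindable) everywhere, plus hydrolysis-coupled release
  (`B → D·ADP2`, delayed recovery) at kcat × stim_dna, locally multiplied
  ~100-fold under the ParB2-parS2 focus — which puts focal release at the
  k₄ wash-regime scale (~0.1 s⁻¹).

The focus is a Gaussian profile (width 0.25 µm).  In `fixed` mode it
stays put; linear stability analysis of the homogeneous state shows the
pole-to-pole mode then carries only stationary instabilities — stable
polarized gradients, never deterministic oscillation.  In the default
`gradient` mode the focus drifts toward nearby bound ParA2 (bound-density-
weighted mean displacement within a 0.4 µm tether reach, speed capped at
0.02 µm/s): the locus chases the wave, erodes it through stimulated
hydrolysis, and the released protein rebuilds the wave on the far side
after the recovery delay — sustained pole-to-pole relaxation oscillations
with a period near 4 min at the defaults, and a sharp onset in the focus
stimulation factor (non-oscillatory below ~30, strongly oscillatory at
100).  The two modes mirror the two observed cell classes: persistent
polar gradients and pole-to-pole oscillators.

Free parameters the measurements do not fix — copy number (2000), nucleoid
capacity (4000), lattice cooperativity ω (100, deliberately distinct from
the mean-field Hill-derived factor: a 1D contact factor on full-length DNA
is not bounded by the Hill coefficient of a 69 bp probe), k_on (0.1 s⁻¹),
focus speed/reach/strength — were fixed once inside the oscillatory regime
located by a coarse scan and are recorded in `SpatialConfig` defaults.
Whether the in-vitro rate set alone places a *fixed-focus* cell in an
oscillatory regime is answered in the negative by the stability analysis;
oscillation requires the focus to respond to the wave.

Numerics: the PDE engine uses operator splitting — an exact
matrix-exponential propagator for diffusion (mass-conserving to machine
precision) and RK4 for the local reactions at dt = 0.05 s, with a guard
that raises a step-size error when dt × (fastest local rate) exceeds 0.5.
Total ParA2 is conserved to better than 1e-6 over a full run.  The SSA
engine is an exact RDME Gillespie loop (diffusive hops at D/dx² plus the
five reaction channels), numba-compiled when available, conserving copies
exactly; in gradient mode it runs frame-wise with the focus frozen within
each 2 s frame.  Ensemble means of SSA runs agree with the PDE solution
within sampling error at ≥5000 copies.

Kymograph metrics: the oscillation period is the lag of the first
autocorrelation peak of the left–right bound-mass difference, accepted
only above the 95th percentile of 100 time-shuffled surrogates; transit is
the mean time for the bound-mass centroid to cross from the 25% to the 75%
cell-length position; the asymmetry index is (left − right)/total bound
mass.

## Known limitations

* The elementary constants behind figure-level observed rates are a
  modelling commitment: where the data determine only an observed rate at
  a stated concentration, the defaults reproduce that observation and the
  decomposition into elementary steps is the package's own.
* The oligomer size on DNA is not resolved; cooperativity enters as a
  mean-field factor (well-mixed) or a local lattice factor (spatial), not
  as an explicit filament with length-dependent kinetics.
* The carpet model is phenomenological (open-flow system); its association
  rate constant is calibrated at 1 µM and the cooperative plateau shape is
  a smooth interpolation of three measured concentrations.
* The spatial model's in-vivo parameters are assumptions; its results are
  regime statements (oscillation exists here, not there), not quantitative
  predictions of period or amplitude.
* No heteroscedastic noise models and no Bayesian uncertainty: standard
  errors are curvature-based.
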