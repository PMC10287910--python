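# para2cycle

Simulate-then-fit toolkit for the ATPase cycle of ParA2, the Walker-type
partition ATPase that positions and segregates chromosome 2 of *Vibrio
cholerae*.  The package is for quantitative microbiologists and modellers
who want to (i) regenerate every in-vitro kinetic readout of the ParA2
system from an explicit reaction scheme, (ii) recover the underlying rate
constants with the same fitting procedures used at the bench, and
(iii) ask whether those rates support pole-to-pole "tug-of-war"
oscillations in a cell-scale spatial model.

## The model

ParA2 is a constitutive dimer.  The cycle tracked throughout (dimer basis,
two nucleotides loading per dimer as one step) is

```
D + 2 ATP  <--k1/k-1-->  D·ATP2          closed sandwich dimer
D·ATP2     --k2------->  D*·ATP2         slow conformational switch
                                          (x k2_dna_factor with DNA)
D*·ATP2 + site <--k3/k-3-->  B           cooperative loading on DNA
B          --hydrolysis-->  D·ADP2 + site release from the nucleoid
D·ADP2     <--k5/k-5-->  D + 2 ADP       ADP handling
D·AXP2 + AXP  --k6-->  swapped           slow one-step nucleotide exchange
```

The slow switch to the DNA-binding-competent state D\*·ATP₂
(k₂ ≈ 0.017 s⁻¹, accelerated ~3-fold by DNA) and the slow nucleotide
exchange (k₆ ~ 10⁻³–10⁻⁴ µM⁻¹s⁻¹) are the delays that let ParA2 released
from the nucleoid redistribute before rebinding — the kinetic core of the
tug-of-war oscillation mechanism.

Five modules cover the workflow:

| module | contents |
|---|---|
| `para2cycle.scheme` / `simulate` | reaction-scheme assembly per assay condition; stiff ODE integration and exact Gillespie SSA; linear observable projection |
| `para2cycle.assays` | forward models of each instrument readout: stopped-flow MANT-nucleotide kinetics, tryptophan switch, EMSA titrations, DNA-carpet TIRF flow, FRAP, radiolabel ATPase, CD thermal melts |
| `para2cycle.inference` | single/two-phase exponential fits, pseudo-first-order analysis, Hill and hyperbolic isotherms, FRAP and Boltzmann-melt fits |
| `para2cycle.recover` | global recovery of the full rate set from a multi-assay dataset with identifiability flags |
| `para2cycle.spatial` | 1D reaction–diffusion cell model (PDE and RDME-SSA engines) with kymograph metrics: period, transit time, asymmetry index |

## Worked example

```python
import numpy as np
from para2cycle import default_rates
from para2cycle.assays import HillParams, gen_emsa, gen_trp_switch
from para2cycle.inference import fit_hill, fit_single_exponential

rates = default_rates()

# gel-shift titration of a 69 bp probe at 2% instrument noise
titration = gen_emsa(HillParams.preset("wt-atp"), noise_sigma=0.02, seed=7)
fit = fit_hill(titration)
print(f"DNA binding: KD = {fit['kd']:.1f} nM, n = {fit['n']:.2f}")

# tryptophan conformational switch in the presence of DNA
switch = gen_trp_switch(rates, "ATP+DNA", noise_sigma=0.02, seed=7)
kfit = fit_single_exponential(switch, "rise", exclude_lag=True)
print(f"switch with DNA: kobs = {kfit['kobs']:.4f} /s")

# cell-scale tug-of-war simulation
from para2cycle.spatial import SpatialConfig, simulate_cell, measure_period
kymo = simulate_cell(SpatialConfig(t_end_s=2000.0, seed=1))
pr = measure_period(kymo)
print(f"oscillation period = {pr.period_s:.0f} s")
```

prints

```
DNA binding: KD = 46.5 nM, n = 3.82
switch with DNA: kobs = 0.0450 /s
oscillation period = 230 s
```

KD ≈ 46 nM with a Hill coefficient near 4 is the cooperative, ATP-licensed
DNA binding of the active dimer (two dimers per 69 bp probe); the
0.045 s⁻¹ switch rate is the DNA-catalysed conformational activation; and
the ~4 min period with pole-to-pole swings of the bound-ParA2 wave is the
emergent tug-of-war oscillation, in the range observed in live cells.
Setting the focus hydrolysis stimulation to 1 (no ParB2 effect) abolishes
the oscillation.

A command-line interface wraps the same operations:

```sh
para2cycle generate --assay emsa --preset wt-atp --seed 1 --out emsa.csv
para2cycle fit --op hill --input emsa.csv --out hill.json
para2cycle spatial --t-end 2000 --seed 1 --out kymo.csv
```

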