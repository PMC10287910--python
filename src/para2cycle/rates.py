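"""Rate constants of the ParA2 ATPase cycle.

The cycle tracked by this package is the one worked out for *Vibrio
cholerae* ParA2, the Walker-type ATPase that positions chromosome 2:

    apo dimer  --k1/k_minus1-->  closed sandwich dimer (ParA2_2-ATP_2)
    closed     --k2----------->  remodeled active dimer (ParA2*_2-ATP_2)
    active + DNA site --k3/k_minus3--> nucleoid-bound oligomer
    bound --k4 (hydrolysis)---> ParA2_2-ADP_2 released from DNA
    ADP dimer --k_minus5/k5---> apo dimer  (ADP off/on)
    ADP dimer + nucleotide --k6--> direct nucleotide exchange

All concentrations are micromolar.  The model tracks *dimers*; user-facing
protein concentrations are monomer-based (as printed on instrument
protocols, e.g. "1.5 uM ParA2") and halved internally via
:func:`monomer_to_dimer`.  Each dimer carries two nucleotides that load and
unload as a single kinetic step (the sandwich dimer is one state; there is
no half-loaded intermediate).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

from .io import read_toml, write_toml

__all__ = [
    "RateSet",
    "monomer_to_dimer",
    "dimer_to_monomer",
    "default_rates",
    "preset_rates",
    "PRESET_DIR",
]

PRESET_DIR = Path(__file__).parent / "presets"

#: second-order rate constants, per-uM per-s
_SECOND_ORDER = ("k1", "k3", "k5", "k6_adp_to_atp", "k6_adp_to_adp", "k6_atp_to_atp")
#: dimensionless factors that must be >= 1
_FACTORS = ("k2_dna_factor", "coop_omega", "stim_dna", "stim_parb", "stim_both")


def monomer_to_dimer(conc_monomer_uM: float) -> float:
    """Convert a printed monomer concentration to the internal dimer basis."""
    return conc_monomer_uM / 2.0


def dimer_to_monomer(conc_dimer_uM: float) -> float:
    return conc_dimer_uM * 2.0


@dataclass(frozen=True)
class RateSet:
    """Full parameter vector of the ParA2 ATPase cycle.

    Defaults are the wild-type values calibrated against the in-vitro
    kinetics of the *V. cholerae* protein (stopped-flow nucleotide
    kinetics, tryptophan switch, DNA-carpet binding/wash, radiolabel
    ATPase).  Units: first-order rates per-s, second-order per-uM per-s,
    factors dimensionless.
    """

    #: ATP association to the apo dimer (two ATP load as one step)
    k1: float = 3.6e-3
    #: ATP dissociation from the closed sandwich dimer
    k_minus1: float = 0.018
    #: slow conformational remodeling, closed -> active (rate-limiting)
    k2: float = 0.017
    #: fold-acceleration of k2 when nonspecific DNA is present
    k2_dna_factor: float = 3.0
    #: DNA-site association of the active dimer, per-uM(site) per-s
    k3: float = 0.05
    #: dissociation of the DNA-bound dimer without hydrolysis
    k_minus3: float = 0.02
    #: mean-field nearest-neighbour cooperativity of DNA loading
    coop_omega: float = 4.0
    #: hydrolysis-coupled release of ParA2_2-ADP_2 from DNA in the
    #: wash/stimulated regime (DNA-carpet flow switch; ParB2-stimulated
    #: release in the spatial model).  Closed bulk schemes turn the bound
    #: state over at the catalysis-limited rate kcat x stimulation instead:
    #: reading the carpet-wash rate as a bulk hydrolysis flux would exceed
    #: the measured radiolabel ATPase rate a hundred-fold.
    k4: float = 0.08
    #: fold-stimulation of hydrolysis by nonspecific DNA (basal = 1)
    stim_dna: float = 2.0
    #: fold-stimulation by ParB2
    stim_parb: float = 3.0
    #: fold-stimulation by DNA and ParB2 together
    stim_both: float = 8.0
    #: basal solution ATP-hydrolysis rate of loaded dimers
    kcat: float = 5e-4
    #: ADP association / dissociation
    k5: float = 9.4e-3
    k_minus5: float = 0.075
    #: effective one-step nucleotide-exchange constants (bound + incoming)
    k6_adp_to_atp: float = 6.5e-4
    k6_adp_to_adp: float = 6.1e-4
    k6_atp_to_atp: float = 1.4e-3
    #: collapse of the nucleotide-free active dimer back to the ground
    #: state.  The remodeled dimer exchanges its nucleotide without losing
    #: its conformation on the binding timescale (so the conformational
    #: switch relaxes at k2 while a chase reads out release at k_minus1);
    #: slow collapse of the transient apo form closes the loop.
    k_star_relax: float = 0.01

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v!r}")
        for name in _FACTORS:
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1 (basal = 1)")
        # Equilibrium KDs must be well defined whenever binding is active.
        if self.k1 > 0 and not (0 < self.kd_atp < math.inf):
            raise ValueError("k_minus1/k1 must define a finite positive KD")
        if self.k5 > 0 and not (0 < self.kd_adp < math.inf):
            raise ValueError("k_minus5/k5 must define a finite positive KD")
        # Exchange is slower than direct binding of the apo dimer.
        for name in ("k6_adp_to_atp", "k6_adp_to_adp", "k6_atp_to_atp"):
            if getattr(self, name) > self.k1:
                raise ValueError(f"{name} must not exceed k1 (exchange is slow)")

    @property
    def kd_atp(self) -> float:
        """Equilibrium ATP dissociation constant k_minus1/k1 (uM)."""
        return self.k_minus1 / self.k1 if self.k1 > 0 else math.inf

    @property
    def kd_adp(self) -> float:
        """Equilibrium ADP dissociation constant k_minus5/k5 (uM)."""
        return self.k_minus5 / self.k5 if self.k5 > 0 else math.inf

    def stimulation(self, dna: bool, parb2: bool) -> float:
        """Fold-stimulation of ATP hydrolysis under the given cofactors."""
        if dna and parb2:
            return self.stim_both
        if dna:
            return self.stim_dna
        if parb2:
            return self.stim_parb
        return 1.0

    def replace(self, **changes: float) -> "RateSet":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_toml(self, path: str | Path) -> None:
        write_toml(path, {"rates": self.to_dict()})

    @classmethod
    def from_dict(cls, d: dict) -> "RateSet":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown rate parameters: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RateSet":
        data = read_toml(path)
        return cls.from_dict(data.get("rates", data))


def default_rates() -> RateSet:
    """Wild-type rate set (the versioned defaults file)."""
    return RateSet.from_toml(PRESET_DIR / "defaults.toml")


def preset_rates(name: str) -> RateSet:
    """Load a named variant preset (wt, k124r, k124q, k124e).

    The K124 Walker-A substitutions are modelled as parameter limits of the
    wild-type cycle: K124R binds ATP but cannot hydrolyse it, K124Q retains
    partial hydrolysis with blunted DNA stimulation, K124E cannot bind ATP
    at all.
    """
    path = PRESET_DIR / f"{name}.toml"
    if not path.exists():
        raise FileNotFoundError(f"no rate preset named {name!r} under {PRESET_DIR}")
    return RateSet.from_toml(path)
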