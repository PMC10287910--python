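"""Assembly of the ParA2 ATPase cycle as elementary mass-action reactions.

Species (all dimer-basis concentrations in uM, except ParB2 which is
monomer-basis and nucleotides which are free pools):

==============  =====================================================
``D``           apo ParA2 dimer
``D_ATP``       closed sandwich dimer ParA2_2-ATP_2
``Dstar_ATP``   remodeled, DNA-binding-competent ParA2*_2-ATP_2
``B``           nucleoid/DNA-bound dimer [ParA2*_2-ATP_2]_n
``D_ADP``       post-hydrolysis ParA2_2-ADP_2
``ATP/ADP``     free unlabelled nucleotide pools
``MANT_ATP``    free fluorescent MANT-ATP (``MANT_ADP`` likewise)
``*_M`` forms   dimers carrying MANT-labelled nucleotide
``sites``       free nonspecific DNA binding sites (30 bp each)
``ParB2``       ParB2 (hydrolysis stimulation cofactor)
==============  =====================================================

Nucleotides load/unload two-per-dimer in a single step; reaction rate laws
are first order in the free nucleotide even where the stoichiometry
consumes two copies, matching how the pseudo-first-order experiments read
out.  Exchange (k6) is an effective one-step swap on the loaded dimer, not
a k5-then-k1 sequence — the measured exchange constants are not the
composition of release and binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rates import RateSet

__all__ = ["AssayCondition", "Reaction", "ReactionScheme", "SPECIES", "assemble_scheme", "ConfigurationError"]

SPECIES = (
    "D",
    "D_ATP",
    "D_ATP_M",
    "Dstar",
    "Dstar_ATP",
    "Dstar_ATP_M",
    "B",
    "B_M",
    "D_ADP",
    "D_ADP_M",
    "ATP",
    "ADP",
    "MANT_ATP",
    "MANT_ADP",
    "sites",
    "ParB2",
)

#: species whose dimer carries ParA2 (conserved total)
PARA2_SPECIES = (
    "D", "D_ATP", "D_ATP_M", "Dstar", "Dstar_ATP", "Dstar_ATP_M",
    "B", "B_M", "D_ADP", "D_ADP_M",
)

#: adenine-nucleotide content (per uM of species, labelled + unlabelled)
NUCLEOTIDE_CONTENT = {
    "D_ATP": 2, "D_ATP_M": 2, "Dstar_ATP": 2, "Dstar_ATP_M": 2,
    "B": 2, "B_M": 2, "D_ADP": 2, "D_ADP_M": 2,
    "ATP": 1, "ADP": 1, "MANT_ATP": 1, "MANT_ADP": 1,
}

#: ADP-equivalent content (hydrolysis converts ATP- to ADP-equivalents)
ADP_CONTENT = {"D_ADP": 2, "D_ADP_M": 2, "ADP": 1, "MANT_ADP": 1}

_NUCLEOTIDES = ("ATP", "ADP", "ATPgS", "none")


class ConfigurationError(ValueError):
    """A condition references an unknown species or inconsistent setup."""


@dataclass(frozen=True)
class AssayCondition:
    """Which cofactors an assay mixes with ParA2.

    ``nucleotide`` is the dominant unlabelled pool ("ATP", "ADP", "ATPgS"
    or "none"); ``mant`` optionally names a labelled pool.  ``dna`` makes
    DNA sites available for loading; ``parb2`` adds the hydrolysis
    stimulator; ``mg`` gates remodeling (no Mg2+ means no conformational
    switch, hence no ATP-specific chemistry).
    """

    nucleotide: str = "ATP"
    mant: str | None = None  # "ATP" or "ADP"
    dna: bool = False
    parb2: bool = False
    mg: bool = True

    def __post_init__(self):
        if self.nucleotide not in _NUCLEOTIDES:
            raise ConfigurationError(f"unknown nucleotide {self.nucleotide!r}")
        if self.mant not in (None, "ATP", "ADP"):
            raise ConfigurationError(f"unknown MANT nucleotide {self.mant!r}")

    @property
    def hydrolysis_active(self) -> bool:
        # ATPgS is non-hydrolysable; no Mg2+ blocks catalysis outright.
        return self.nucleotide != "ATPgS" and self.mg

    @property
    def remodeling_active(self) -> bool:
        # The switch to the active state needs ATP-type nucleotide + Mg2+.
        return self.mg and (self.nucleotide in ("ATP", "ATPgS") or self.mant == "ATP")


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction: stoichiometry, rate constant, rate law.

    ``order`` gives the rate-law exponents; it defaults to the reactant
    stoichiometry but may differ (nucleotide loading consumes two copies
    while the rate law is first order in the free pool).
    ``modifier='coop'`` multiplies the propensity by the mean-field
    cooperativity factor 1 + (omega - 1) * bound_site_fraction.
    """

    name: str
    reactants: dict = field(default_factory=dict)
    products: dict = field(default_factory=dict)
    rate: float = 0.0
    order: dict | None = None
    modifier: str | None = None

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError(f"reaction {self.name}: negative rate {self.rate}")
        for sp in list(self.reactants) + list(self.products):
            if sp not in SPECIES:
                raise ConfigurationError(f"reaction {self.name}: unknown species {sp!r}")

    @property
    def rate_law(self) -> dict:
        return self.order if self.order is not None else self.reactants


class ReactionScheme:
    """A list of elementary reactions plus vectorized mass-action kinetics."""

    def __init__(self, reactions: list[Reaction], rates: RateSet, condition: AssayCondition):
        self.reactions = [r for r in reactions if r.rate > 0]
        self.rates = rates
        self.condition = condition
        self.species = list(SPECIES)
        self.index = {s: i for i, s in enumerate(self.species)}
        n_r, n_s = len(self.reactions), len(self.species)
        self.stoich = np.zeros((n_r, n_s))
        self._order_idx: list[list[tuple[int, int]]] = []
        self._k = np.array([r.rate for r in self.reactions])
        self._coop = np.array([r.modifier == "coop" for r in self.reactions])
        for j, r in enumerate(self.reactions):
            for sp, nu in r.reactants.items():
                self.stoich[j, self.index[sp]] -= nu
            for sp, nu in r.products.items():
                self.stoich[j, self.index[sp]] += nu
            self._order_idx.append([(self.index[sp], int(e)) for sp, e in r.rate_law.items()])
        self._i_B = self.index["B"]
        self._i_BM = self.index["B_M"]
        self._i_sites = self.index["sites"]

    def __len__(self) -> int:
        return len(self.reactions)

    def names(self) -> list[str]:
        return [r.name for r in self.reactions]

    def coop_factor(self, y: np.ndarray) -> float:
        """Mean-field nearest-neighbour loading enhancement.

        1 + (omega - 1) * theta, with theta the currently bound fraction of
        DNA sites; an exact lattice treatment is the spatial simulator's job.
        """
        bound = y[self._i_B] + y[self._i_BM]
        total = bound + y[self._i_sites]
        theta = bound / total if total > 0 else 0.0
        return 1.0 + (self.rates.coop_omega - 1.0) * theta

    def fluxes(self, y: np.ndarray) -> np.ndarray:
        v = self._k.copy()
        for j, terms in enumerate(self._order_idx):
            for i, e in terms:
                v[j] *= y[i] if e == 1 else y[i] ** e
        if self._coop.any():
            v[self._coop] *= self.coop_factor(y)
        return v

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.fluxes(np.maximum(y, 0.0)) @ self.stoich


def _exchange_reactions(r: RateSet) -> list[Reaction]:
    """One-step nucleotide swaps on loaded dimers (both label directions)."""
    swaps = [
        # (bound_from, bound_to, incoming, outgoing, k)
        ("D_ADP", "D_ATP", "ATP", "ADP", r.k6_adp_to_atp),
        ("D_ADP", "D_ATP_M", "MANT_ATP", "ADP", r.k6_adp_to_atp),
        ("D_ADP_M", "D_ATP", "ATP", "MANT_ADP", r.k6_adp_to_atp),
        ("D_ADP", "D_ADP_M", "MANT_ADP", "ADP", r.k6_adp_to_adp),
        ("D_ADP_M", "D_ADP", "ADP", "MANT_ADP", r.k6_adp_to_adp),
        ("D_ATP", "D_ATP_M", "MANT_ATP", "ATP", r.k6_atp_to_atp),
        ("D_ATP_M", "D_ATP", "ATP", "MANT_ATP", r.k6_atp_to_atp),
    ]
    out = []
    for bf, bt, inc, outg, k in swaps:
        out.append(
            Reaction(
                name=f"exchange_{bf}_to_{bt}",
                reactants={bf: 1, inc: 2},
                products={bt: 1, outg: 2},
                rate=k,
                order={bf: 1, inc: 1},
            )
        )
    return out


def assemble_scheme(rates: RateSet, condition: AssayCondition) -> ReactionScheme:
    """Realize the ATPase cycle under an assay condition.

    Returns the elementary reactions present given the cofactors: reversible
    nucleotide loading (k1/k_minus1, k5/k_minus5, two nucleotides per dimer
    as one step), the slow remodeling switch (k2, accelerated
    k2_dna_factor-fold with DNA, absent without Mg2+ or ATP), cooperative
    DNA loading (k3/k_minus3 with the mean-field omega factor),
    hydrolysis-coupled release from DNA (k4, ParB2-boosted), basal solution
    hydrolysis (kcat x fold-stimulation), ADP handling and the slow
    one-step exchange reactions (k6).  With ATPgS the hydrolysis branch is
    removed (k4 -> 0; DNA unbinding is k_minus3-only) but DNA binding is
    retained — hydrolysis is not required for DNA binding.
    """
    r = rates
    c = condition
    rx: list[Reaction] = []

    # --- reversible nucleotide loading on the apo dimer ----------------
    # ATPgS is treated as ATP for binding/remodeling but never hydrolyses.
    rx.append(Reaction("bind_ATP", {"D": 1, "ATP": 2}, {"D_ATP": 1}, r.k1, order={"D": 1, "ATP": 1}))
    rx.append(Reaction("release_ATP", {"D_ATP": 1}, {"D": 1, "ATP": 2}, r.k_minus1))
    rx.append(Reaction("bind_MANT_ATP", {"D": 1, "MANT_ATP": 2}, {"D_ATP_M": 1}, r.k1, order={"D": 1, "MANT_ATP": 1}))
    rx.append(Reaction("release_MANT_ATP", {"D_ATP_M": 1}, {"D": 1, "MANT_ATP": 2}, r.k_minus1))
    rx.append(Reaction("bind_ADP", {"D": 1, "ADP": 2}, {"D_ADP": 1}, r.k5, order={"D": 1, "ADP": 1}))
    rx.append(Reaction("release_ADP", {"D_ADP": 1}, {"D": 1, "ADP": 2}, r.k_minus5))
    rx.append(Reaction("bind_MANT_ADP", {"D": 1, "MANT_ADP": 2}, {"D_ADP_M": 1}, r.k5, order={"D": 1, "MANT_ADP": 1}))
    rx.append(Reaction("release_MANT_ADP", {"D_ADP_M": 1}, {"D": 1, "MANT_ADP": 2}, r.k_minus5))

    # --- slow conformational switch to the DNA-binding-competent state -
    if c.remodeling_active:
        k2_eff = r.k2 * (r.k2_dna_factor if c.dna else 1.0)
        rx.append(Reaction("remodel", {"D_ATP": 1}, {"Dstar_ATP": 1}, k2_eff))
        rx.append(Reaction("remodel_M", {"D_ATP_M": 1}, {"Dstar_ATP_M": 1}, k2_eff))
        # The active (open) dimer exchanges its nucleotide without losing
        # its conformation on the binding timescale: release at k_minus1
        # to a transient apo active form that rebinds at k1, and only
        # slowly collapses back to the ground state (k_star_relax).  This
        # is what lets the conformational switch relax at k2 while a cold
        # chase reads out release at k_minus1.
        rx.append(Reaction("star_release_ATP", {"Dstar_ATP": 1}, {"Dstar": 1, "ATP": 2}, r.k_minus1))
        rx.append(Reaction("star_release_MANT_ATP", {"Dstar_ATP_M": 1}, {"Dstar": 1, "MANT_ATP": 2}, r.k_minus1))
        rx.append(Reaction("star_rebind_ATP", {"Dstar": 1, "ATP": 2}, {"Dstar_ATP": 1}, r.k1, order={"Dstar": 1, "ATP": 1}))
        rx.append(Reaction("star_rebind_MANT_ATP", {"Dstar": 1, "MANT_ATP": 2}, {"Dstar_ATP_M": 1}, r.k1, order={"Dstar": 1, "MANT_ATP": 1}))
        rx.append(Reaction("star_relax", {"Dstar": 1}, {"D": 1}, r.k_star_relax))

    # --- cooperative loading on DNA ------------------------------------
    # Loading requires the remodeled state, so without ATP (or Mg2+) the
    # scheme carries no DNA-loading reactions at all.
    if c.dna and c.remodeling_active:
        rx.append(Reaction("dna_load", {"Dstar_ATP": 1, "sites": 1}, {"B": 1}, r.k3, modifier="coop"))
        rx.append(Reaction("dna_load_M", {"Dstar_ATP_M": 1, "sites": 1}, {"B_M": 1}, r.k3, modifier="coop"))
        rx.append(Reaction("dna_unbind", {"B": 1}, {"Dstar_ATP": 1, "sites": 1}, r.k_minus3))
        rx.append(Reaction("dna_unbind_M", {"B_M": 1}, {"Dstar_ATP_M": 1, "sites": 1}, r.k_minus3))

    # --- hydrolysis ----------------------------------------------------
    # Bound-state release is catalysis-limited in a closed bulk system
    # (kcat x stimulation); the wash-regime release constant k4 belongs to
    # the flow-cell and spatial-focus regimes, not here.
    if c.hydrolysis_active:
        if c.dna:
            k4_bulk = r.kcat * (r.stim_both if c.parb2 else r.stim_dna)
            rx.append(Reaction("hydrolyse_release", {"B": 1}, {"D_ADP": 1, "sites": 1}, k4_bulk))
            rx.append(Reaction("hydrolyse_release_M", {"B_M": 1}, {"D_ADP_M": 1, "sites": 1}, k4_bulk))
        kcat_eff = r.kcat * r.stimulation(c.dna, c.parb2)
        for sp, prod in (("D_ATP", "D_ADP"), ("Dstar_ATP", "D_ADP"),
                         ("D_ATP_M", "D_ADP_M"), ("Dstar_ATP_M", "D_ADP_M")):
            rx.append(Reaction(f"hydrolyse_{sp}", {sp: 1}, {prod: 1}, kcat_eff))

    # --- slow nucleotide exchange --------------------------------------
    rx.extend(_exchange_reactions(r))

    return ReactionScheme(rx, rates, condition)
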