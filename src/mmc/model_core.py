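"""Constraint-based model representation, construction, validation and editing.

The central objects are :class:`MetabolicNetwork` (a stoichiometric matrix with
flux bounds and tagged biomass/uptake reactions), :class:`BiomassComposition`
(macromolecule mass fractions plus their nitrogen/carbon contents, which
determine the biomass reaction's nutrient demands), and :class:`ModelVariant`
(a network + composition + trophic mode, the unit the controller operates on).

Networks come from three places: :func:`build_toy_model` (a small,
composition-parameterized network whose biomass nitrogen demand is
``sum_m fractions[m] * n_content[m]`` mmol N per gDW, and likewise for carbon),
:func:`load_sbml` (genome-scale models via cobrapy), or the JSON dialect
(:meth:`MetabolicNetwork.to_json_dict` / :meth:`MetabolicNetwork.from_json_dict`).

Elemental bookkeeping in the toy network uses abstract N-unit and C-unit
metabolites; :func:`validate_mass_balance` checks that every internal reaction
balances these exactly, with exchange and biomass columns exempted.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "MACROMOLECULES",
    "MetabolicNetwork",
    "BiomassComposition",
    "ModelVariant",
    "MassBalanceReport",
    "build_toy_model",
    "load_sbml",
    "set_amino_acid_fraction",
    "validate_mass_balance",
    "replete_autotrophic_composition",
    "replete_heterotrophic_composition",
    "nitrogen_starved_composition",
]

#: Macromolecule classes every composition must cover.
MACROMOLECULES = (
    "amino_acid",
    "carbohydrate",
    "lipid",
    "chlorophyll",
    "nucleotide",
    "other",
)

_FRACTION_TOL = 1e-9


class ModelError(ValueError):
    """Raised for invalid model structure or invalid edits."""


@dataclass
class BiomassComposition:
    """Macromolecular biomass composition.

    Parameters
    ----------
    fractions
        Mass fraction of each macromolecule class (dimensionless, sum to 1).
    n_content
        mmol nitrogen per gram of macromolecule.
    c_content
        mmol carbon per gram of macromolecule.
    """

    fractions: dict[str, float]
    n_content: dict[str, float]
    c_content: dict[str, float]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [m for m in MACROMOLECULES if m not in self.fractions]
        if missing:
            raise ModelError(f"composition missing macromolecules: {missing}")
        for name, f in self.fractions.items():
            if f < 0:
                raise ModelError(f"negative fraction for {name}: {f}")
        total = math.fsum(self.fractions.values())
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ModelError(f"fractions sum to {total!r}, not 1 (normalize first)")
        for tag, table in (("n_content", self.n_content), ("c_content", self.c_content)):
            for name, v in table.items():
                if v < 0:
                    raise ModelError(f"negative {tag} for {name}: {v}")

    @property
    def nitrogen_demand(self) -> float:
        """Biomass nitrogen demand, mmol N per gDW."""
        return math.fsum(
            f * self.n_content.get(m, 0.0) for m, f in self.fractions.items()
        )

    @property
    def carbon_demand(self) -> float:
        """Biomass carbon demand, mmol C per gDW."""
        return math.fsum(
            f * self.c_content.get(m, 0.0) for m, f in self.fractions.items()
        )

    def with_amino_acid_fraction(self, target_aa: float) -> "BiomassComposition":
        """Return a copy with the amino-acid fraction set to ``target_aa``.

        All other fractions are rescaled by ``(1 - target_aa) / (1 - old_aa)``
        so the composition re-normalizes to 1.
        """
        if not 0.0 < target_aa < 1.0:
            raise ModelError(f"target amino-acid fraction must be in (0, 1): {target_aa}")
        old_aa = self.fractions["amino_acid"]
        if old_aa >= 1.0:
            raise ModelError("cannot rescale: amino acids are the entire biomass")
        scale = (1.0 - target_aa) / (1.0 - old_aa)
        fractions = {
            m: (target_aa if m == "amino_acid" else f * scale)
            for m, f in self.fractions.items()
        }
        # fsum drift from the rescale is below the validation tolerance
        return BiomassComposition(fractions, dict(self.n_content), dict(self.c_content))


def replete_autotrophic_composition() -> BiomassComposition:
    """Nitrogen-replete autotrophic composition (config default, representative)."""
    return BiomassComposition(
        fractions={
            "amino_acid": 0.45,
            "carbohydrate": 0.25,
            "lipid": 0.15,
            "chlorophyll": 0.03,
            "nucleotide": 0.05,
            "other": 0.07,
        },
        n_content={"amino_acid": 11.1, "nucleotide": 10.7, "chlorophyll": 4.5},
        c_content={
            "amino_acid": 40.0,
            "carbohydrate": 37.0,
            "lipid": 63.0,
            "chlorophyll": 61.6,
            "nucleotide": 29.0,
            "other": 30.0,
        },
    )


def replete_heterotrophic_composition() -> BiomassComposition:
    """Nitrogen-replete heterotrophic composition (config default, representative)."""
    comp = replete_autotrophic_composition()
    comp.fractions.update(
        {
            "amino_acid": 0.42,
            "carbohydrate": 0.28,
            "lipid": 0.17,
            "chlorophyll": 0.01,
            "nucleotide": 0.05,
            "other": 0.07,
        }
    )
    comp.validate()
    return comp


def nitrogen_starved_composition() -> BiomassComposition:
    """Nitrogen-starved composition with 16% amino acids (config default)."""
    comp = replete_autotrophic_composition()
    comp.fractions.update(
        {
            "amino_acid": 0.16,
            "carbohydrate": 0.28,
            "lipid": 0.40,
            "chlorophyll": 0.01,
            "nucleotide": 0.03,
            "other": 0.12,
        }
    )
    comp.validate()
    return comp


@dataclass
class MetabolicNetwork:
    """Stoichiometric model: S matrix, bounds, tagged biomass and uptakes.

    Fluxes are mmol·gDW⁻¹·h⁻¹; the biomass column is gDW-normalized so its
    flux is the specific growth rate in h⁻¹. ``formulas`` carries per-metabolite
    bookkeeping-element counts (e.g. ``{"N": 1.0}``) used by
    :func:`validate_mass_balance`; metabolites without an entry are skipped.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    biomass_rxn: str
    uptake_rxns: dict[str, str]
    formulas: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def validate(self) -> None:
        m, n = self.n_metabolites, self.n_reactions
        if self.S.shape != (m, n):
            raise ModelError(f"S shape {self.S.shape} != ({m}, {n})")
        if self.lb.shape != (n,) or self.ub.shape != (n,):
            raise ModelError("bounds must have one entry per reaction")
        bad = [
            self.reaction_ids[j]
            for j in range(n)
            if self.lb[j] > self.ub[j]
        ]
        if bad:
            raise ModelError(f"lb > ub for reactions: {bad}")
        if n and self.biomass_rxn not in self.reaction_ids:
            raise ModelError(f"biomass reaction {self.biomass_rxn!r} not in network")
        for nutrient, rxn in self.uptake_rxns.items():
            if rxn not in self.reaction_ids:
                raise ModelError(f"uptake reaction for {nutrient!r} ({rxn!r}) not in network")

    def reaction_index(self, rxn_id: str) -> int:
        try:
            return self.reaction_ids.index(rxn_id)
        except ValueError:
            raise KeyError(f"reaction {rxn_id!r} not in network") from None

    def uptake_index(self, nutrient: str) -> int:
        if nutrient not in self.uptake_rxns:
            raise KeyError(
                f"nutrient {nutrient!r} has no mapped uptake reaction "
                f"(available: {sorted(self.uptake_rxns)})"
            )
        return self.reaction_index(self.uptake_rxns[nutrient])

    def exchange_reactions(self) -> list[str]:
        """Reactions touching a single metabolite (boundary exchanges)."""
        nz = np.count_nonzero(self.S, axis=0)
        return [r for r, k in zip(self.reaction_ids, nz) if k <= 1]

    # -- editing -----------------------------------------------------------
    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            list(self.metabolite_ids),
            list(self.reaction_ids),
            self.S.copy(),
            self.lb.copy(),
            self.ub.copy(),
            self.biomass_rxn,
            dict(self.uptake_rxns),
            copy.deepcopy(self.formulas),
        )

    def set_bounds(self, rxn_id: str, lb: float | None = None, ub: float | None = None) -> None:
        j = self.reaction_index(rxn_id)
        if lb is not None:
            self.lb[j] = lb
        if ub is not None:
            self.ub[j] = ub
        if self.lb[j] > self.ub[j]:
            raise ModelError(f"lb > ub for reaction {rxn_id!r}")

    # -- JSON dialect ------------------------------------------------------
    def to_json_dict(self) -> dict:
        reactions = []
        for j, rid in enumerate(self.reaction_ids):
            stoich = {
                self.metabolite_ids[i]: float(self.S[i, j])
                for i in np.nonzero(self.S[:, j])[0]
            }
            reactions.append(
                {"id": rid, "stoich": stoich, "lb": float(self.lb[j]), "ub": float(self.ub[j])}
            )
        return {
            "metabolites": list(self.metabolite_ids),
            "reactions": reactions,
            "biomass": self.biomass_rxn,
            "uptakes": dict(self.uptake_rxns),
            "formulas": self.formulas,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "MetabolicNetwork":
        mets = list(d["metabolites"])
        rids = [r["id"] for r in d["reactions"]]
        S = np.zeros((len(mets), len(rids)))
        lb = np.zeros(len(rids))
        ub = np.zeros(len(rids))
        for j, r in enumerate(d["reactions"]):
            for met, coeff in r["stoich"].items():
                S[mets.index(met), j] = coeff
            lb[j], ub[j] = r["lb"], r["ub"]
        return cls(mets, rids, S, lb, ub, d["biomass"], dict(d["uptakes"]), d.get("formulas", {}))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MetabolicNetwork":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


@dataclass
class ModelVariant:
    """A network tied to the composition and trophic mode it was built for."""

    name: str
    network: MetabolicNetwork
    composition: BiomassComposition
    trophic_mode: str  # "autotrophic" | "heterotrophic"
    _builder: Callable[["BiomassComposition"], MetabolicNetwork] | None = None

    def __post_init__(self) -> None:
        if self.trophic_mode not in ("autotrophic", "heterotrophic"):
            raise ModelError(f"unknown trophic_mode {self.trophic_mode!r}")

    def copy(self) -> "ModelVariant":
        return replace(self, network=self.network.copy())


# ---------------------------------------------------------------------------
# Toy network
# ---------------------------------------------------------------------------

#: Default flux bounds for the toy network, overridable via ``bounds=``.
#: Uptakes for the alternative carbon source (acetate) and the recycled
#: nitrogen pool exist but are closed by default.
_TOY_DEFAULT_UB = {
    "EX_no3": 1000.0,
    "EX_glc": 10.0,
    "EX_ac": 0.0,
    "EX_nrec": 0.0,
    "EX_photon": 1000.0,
    "EX_co2": 1000.0,
    "BIOMASS": 10.0,
}

#: mmol of carbon units released per mmol of carbon substrate.
GLUCOSE_CARBON = 6.0
ACETATE_CARBON = 2.0
#: energy units released per mmol glucose catabolized.
GLUCOSE_ENERGY = 2.0


def build_toy_model(
    composition: BiomassComposition | None = None,
    trophic_mode: str = "autotrophic",
    bounds: dict[str, tuple[float, float]] | None = None,
    name: str | None = None,
) -> ModelVariant:
    """Build a small composition-parameterized network.

    The network routes nitrate through an N-assimilation step into an abstract
    N-unit pool, glucose/acetate/CO2 into a C-unit pool (CO2 fixation costs one
    photon-derived energy unit), and synthesizes one pool metabolite per
    macromolecule class with stoichiometry taken from ``composition``. The
    biomass reaction consumes the macromolecule pools in their mass fractions,
    so its nitrogen demand is exactly ``composition.nitrogen_demand`` and its
    carbon demand ``composition.carbon_demand``.

    Autotrophic variants have glucose closed and photons open; heterotrophic
    variants the reverse.
    """
    if composition is None:
        composition = (
            replete_autotrophic_composition() if trophic_mode == "autotrophic" else replete_heterotrophic_composition()
        )
    composition.validate()
    if trophic_mode not in ("autotrophic", "heterotrophic"):
        raise ModelError(f"unknown trophic_mode {trophic_mode!r}")

    mets = ["NO3", "GLC", "AC", "PHO", "CO2", "N", "C", "E"] + [
        f"M_{m}" for m in MACROMOLECULES
    ]
    formulas: dict[str, dict[str, float]] = {
        "NO3": {"N": 1.0},
        "GLC": {"C": GLUCOSE_CARBON},
        "AC": {"C": ACETATE_CARBON},
        "PHO": {},
        "CO2": {"C": 1.0},
        "N": {"N": 1.0},
        "C": {"C": 1.0},
        "E": {},
    }
    for m in MACROMOLECULES:
        formulas[f"M_{m}"] = {
            "N": composition.n_content.get(m, 0.0),
            "C": composition.c_content.get(m, 0.0),
        }

    reactions: list[tuple[str, dict[str, float]]] = [
        ("EX_no3", {"NO3": 1.0}),
        ("EX_glc", {"GLC": 1.0}),
        ("EX_ac", {"AC": 1.0}),
        ("EX_nrec", {"N": 1.0}),
        ("EX_photon", {"PHO": 1.0}),
        ("EX_co2", {"CO2": 1.0}),
        ("NAR", {"NO3": -1.0, "N": 1.0}),
        ("GLK", {"GLC": -1.0, "C": GLUCOSE_CARBON, "E": GLUCOSE_ENERGY}),
        ("ACS", {"AC": -1.0, "C": ACETATE_CARBON}),
        ("CFX", {"CO2": -1.0, "E": -1.0, "C": 1.0}),
        ("PSII", {"PHO": -1.0, "E": 1.0}),
        # energy dissipation; raise its lb to impose non-growth maintenance
        ("ATPD", {"E": -1.0}),
    ]
    for m in MACROMOLECULES:
        stoich = {f"M_{m}": 1.0}
        n = composition.n_content.get(m, 0.0)
        c = composition.c_content.get(m, 0.0)
        if n:
            stoich["N"] = -n
        if c:
            stoich["C"] = -c
        reactions.append((f"SYN_{m}", stoich))
    # biomass: consume macromolecule pools in mass-fraction proportions (sink)
    reactions.append(
        ("BIOMASS", {f"M_{m}": -f for m, f in composition.fractions.items() if f})
    )

    rids = [r for r, _ in reactions]
    S = np.zeros((len(mets), len(rids)))
    for j, (_, stoich) in enumerate(reactions):
        for met, coeff in stoich.items():
            S[mets.index(met), j] = coeff

    lb = np.zeros(len(rids))
    ub = np.full(len(rids), 1000.0)
    for rid, u in _TOY_DEFAULT_UB.items():
        ub[rids.index(rid)] = u
    if trophic_mode == "autotrophic":
        ub[rids.index("EX_glc")] = 0.0
    else:
        # dark growth: no photons, and no net CO2 fixation from glucose energy
        ub[rids.index("EX_photon")] = 0.0
        ub[rids.index("EX_co2")] = 0.0
    if bounds:
        for rid, (lo, hi) in bounds.items():
            if rid not in rids:
                raise ModelError(f"bounds override for unknown reaction {rid!r}")
            lb[rids.index(rid)], ub[rids.index(rid)] = lo, hi

    network = MetabolicNetwork(
        mets,
        rids,
        S,
        lb,
        ub,
        biomass_rxn="BIOMASS",
        uptake_rxns={
            "nitrate": "EX_no3",
            "glucose": "EX_glc",
            "acetate": "EX_ac",
            "n_recycle": "EX_nrec",
            "photon": "EX_photon",
            "co2": "EX_co2",
        },
        formulas=formulas,
    )

    user_bounds = dict(bounds) if bounds else None

    def _builder(comp: BiomassComposition) -> MetabolicNetwork:
        return build_toy_model(comp, trophic_mode, user_bounds).network

    return ModelVariant(
        name=name or f"toy-{trophic_mode}",
        network=network,
        composition=composition,
        trophic_mode=trophic_mode,
        _builder=_builder,
    )


def set_amino_acid_fraction(variant: ModelVariant, target_aa: float) -> ModelVariant:
    """Return a new variant with the amino-acid mass fraction set to ``target_aa``.

    Other macromolecule fractions are rescaled to keep the composition
    normalized, and the biomass stoichiometry is rebuilt from the new
    composition. The input variant is left unmodified.
    """
    new_comp = variant.composition.with_amino_acid_fraction(target_aa)
    if variant._builder is None:
        raise ModelError(
            "composition editing requires a rebuildable (toy) network; "
            "genome-scale biomass columns cannot be rebuilt from mass fractions"
        )
    network = variant._builder(new_comp)
    return ModelVariant(
        name=f"{variant.name}-{round(100 * target_aa)}%AA",
        network=network,
        composition=new_comp,
        trophic_mode=variant.trophic_mode,
        _builder=variant._builder,
    )


# ---------------------------------------------------------------------------
# Mass balance
# ---------------------------------------------------------------------------


@dataclass
class MassBalanceReport:
    residuals: dict[str, dict[str, float]]  # reaction -> element -> residual
    exempt: list[str]
    max_residual: float
    passed: bool

    def flagged(self, tol: float = 1e-6) -> list[str]:
        return [
            r
            for r, elems in self.residuals.items()
            if any(abs(v) > tol for v in elems.values())
        ]


def validate_mass_balance(network: MetabolicNetwork, tol: float = 1e-6) -> MassBalanceReport:
    """Check bookkeeping-element balance of every internal reaction.

    Exchange columns (single-metabolite) and the biomass column are exempt and
    listed in the report. Passes iff the largest internal residual is < tol.
    """
    exempt = set(network.exchange_reactions())
    if network.n_reactions:
        exempt.add(network.biomass_rxn)
    elements = sorted({e for f in network.formulas.values() for e in f})
    residuals: dict[str, dict[str, float]] = {}
    max_res = 0.0
    for j, rid in enumerate(network.reaction_ids):
        if rid in exempt:
            continue
        res = {}
        for e in elements:
            r = math.fsum(
                network.S[i, j] * network.formulas.get(met, {}).get(e, 0.0)
                for i, met in enumerate(network.metabolite_ids)
                if network.S[i, j]
            )
            res[e] = r
            max_res = max(max_res, abs(r))
        residuals[rid] = res
    return MassBalanceReport(
        residuals=residuals,
        exempt=sorted(exempt),
        max_residual=max_res,
        passed=max_res < tol,
    )


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------


def load_sbml(
    path,
    biomass_rxn: str | None = None,
    uptake_map: dict[str, str] | None = None,
    trophic_mode: str = "autotrophic",
    composition: BiomassComposition | None = None,
) -> ModelVariant:
    """Load an SBML model (FBC bounds via cobrapy) into a :class:`ModelVariant`.

    The biomass reaction is auto-detected from the objective coefficients, or
    by an id/name containing "biomass" as a fallback; pass ``biomass_rxn`` to
    override. ``uptake_map`` maps nutrient names to exchange reaction ids
    (e.g. ``{"nitrate": "EX_no3_e"}``); nutrients left unmapped simply cannot
    be minimized later.
    """
    import cobra.io

    try:
        model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises a zoo of parse errors
        raise ModelError(f"could not read SBML file {path}: {exc}") from exc

    if biomass_rxn is None:
        flagged = [
            r.id for r in model.reactions if r.objective_coefficient not in (0, 0.0)
        ]
        if len(flagged) == 1:
            biomass_rxn = flagged[0]
        elif len(flagged) > 1:
            raise ModelError(
                f"ambiguous biomass reaction, multiple objective-flagged candidates: {flagged}"
            )
        else:
            named = [r.id for r in model.reactions if "biomass" in r.id.lower()]
            if len(named) == 1:
                biomass_rxn = named[0]
            else:
                raise ModelError(
                    "no biomass reaction candidate found; pass biomass_rxn explicitly"
                )

    mets = [m.id for m in model.metabolites]
    rids = [r.id for r in model.reactions]
    S = np.zeros((len(mets), len(rids)))
    lb = np.zeros(len(rids))
    ub = np.zeros(len(rids))
    met_index = {m: i for i, m in enumerate(mets)}
    for j, rxn in enumerate(model.reactions):
        for met, coeff in rxn.metabolites.items():
            S[met_index[met.id], j] = coeff
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound

    network = MetabolicNetwork(
        mets, rids, S, lb, ub, biomass_rxn, dict(uptake_map or {}), formulas={}
    )
    return ModelVariant(
        name=model.id or "sbml-model",
        network=network,
        composition=composition or replete_autotrophic_composition(),
        trophic_mode=trophic_mode,
    )
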