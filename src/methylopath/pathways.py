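"""Formaldehyde assimilation pathway extensions.

Three heterologous routes feed formaldehyde into central carbon metabolism:

* **RuMP** (ribulose monophosphate pathway, prokaryotic): hexulose-6-phosphate
  synthase condenses formaldehyde with ribulose 5-phosphate; the hexulose is
  isomerised to fructose 6-phosphate.  No ATP cost.
* **XuMP** (xylulose monophosphate pathway, methylotrophic yeasts):
  dihydroxyacetone synthase condenses formaldehyde with xylulose 5-phosphate
  into dihydroxyacetone + glyceraldehyde 3-phosphate; dihydroxyacetone kinase
  then spends one ATP per formaldehyde.
* **Serine cycle** (alpha-proteobacterial): formaldehyde enters as
  methylene-THF, condenses with glycine to serine, and is carried through
  glycerate, PEP carboxylation and malyl-CoA cleavage back to glycine,
  netting one acetyl-CoA per formaldehyde + CO2 at a cost of two ATP.

All extension reactions are cytosolic, carbon-balanced and cofactor-explicit.
The methanol entry point is the native NAD-dependent alcohol dehydrogenase,
which ships closed in the core model and is opened when an extension is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelReaction,
    ModelError,
    fba,
    parse_equation,
    yield_and_oxygen,
)

class PathwayError(ModelError):
    """Raised for invalid pathway names or extension operations."""


PATHWAY_NAMES = ("RuMP", "XuMP", "serine_cycle")

#: metabolites an extension may create on demand: id -> (name, carbon atoms)
EXTENSION_METABOLITES: dict[str, tuple[str, int]] = {
    "fald": ("formaldehyde", 1),
    "h6p": ("D-arabino-3-hexulose 6-phosphate", 6),
    "dha": ("dihydroxyacetone", 3),
    "thf": ("tetrahydrofolate (carrier)", 0),
    "mlthf": ("5,10-methylene-THF (carrier + C1)", 1),
    "gly": ("glycine", 2),
    "ser": ("L-serine", 3),
    "glx": ("glyoxylate", 2),
    "hpyr": ("hydroxypyruvate", 3),
    "glyc_r": ("D-glycerate", 3),
    "malcoa": ("malyl-CoA (acyl carbon)", 4),
}

#: reaction id -> (equation, reversible, enzyme)
_EXTENSION_REACTIONS: dict[str, list[tuple[str, str, bool, str]]] = {
    "RuMP": [
        ("HPS", "fald + ru5p -> h6p", False,
         "3-hexulose-6-phosphate synthase (EC 4.1.2.43)"),
        ("PHI", "h6p <-> f6p", True,
         "6-phospho-3-hexuloisomerase (EC 5.3.1.27)"),
    ],
    "XuMP": [
        ("DHAS", "fald + x5p -> dha + gap", False,
         "dihydroxyacetone synthase (EC 2.2.1.3)"),
        ("DAK", "dha + atp -> dhap + adp", False, "dihydroxyacetone kinase"),
    ],
    "serine_cycle": [
        ("FALD_THF", "fald + thf -> mlthf", False,
         "spontaneous/enzymatic formaldehyde-THF condensation"),
        ("SHMT", "mlthf + gly <-> ser + thf", True,
         "serine hydroxymethyltransferase"),
        ("SGAT", "ser + glx -> hpyr + gly", False,
         "serine-glyoxylate aminotransferase"),
        ("HPR", "hpyr + nadh -> glyc_r + nad", False,
         "hydroxypyruvate reductase"),
        ("GLYCK", "glyc_r + atp -> pg2 + adp", False, "glycerate 2-kinase"),
        ("PPC", "pep + co2 -> oaa", False, "PEP carboxylase"),
        ("MDH_SC", "oaa + nadh <-> mal + nad", True,
         "malate dehydrogenase (cycle copy)"),
        ("MTK", "mal + atp + coa -> malcoa + adp", False, "malate thiokinase"),
        ("MCL", "malcoa -> accoa + glx", False, "malyl-CoA lyase"),
    ],
}


@dataclass
class PathwayExtension:
    """A named, carbon-balanced reaction set to graft onto a host model."""

    name: str
    reactions: list[ModelReaction] = field(default_factory=list)
    compartment: str = "c"

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]


def build_extension(
    name: str,
    compartment: str = "c",
    curated_override: Mapping[str, str] | None = None,
) -> PathwayExtension:
    """Construct one of the three formaldehyde assimilation extensions.

    ``curated_override`` maps reaction ids to replacement equations, the hook
    through which a curated genome-scale reaction list can replace the
    canonical defaults.
    """
    if name not in _EXTENSION_REACTIONS:
        raise PathwayError(
            f"unknown pathway {name!r}; choose from {PATHWAY_NAMES}"
        )
    reactions = []
    for rid, eq, reversible, enzyme in _EXTENSION_REACTIONS[name]:
        if curated_override and rid in curated_override:
            eq = curated_override[rid]
        stoich, _ = parse_equation(eq)
        reactions.append(
            ModelReaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=-DEFAULT_BOUND if reversible else 0.0,
                upper_bound=DEFAULT_BOUND,
                name=enzyme,
            )
        )
    return PathwayExtension(name=name, reactions=reactions, compartment=compartment)


def apply_extension(
    model: MetabolicModel,
    extension: PathwayExtension,
    enable_adh: bool = True,
    adh_reaction_id: str = "ADH_meoh",
) -> MetabolicModel:
    """Return a new model with the extension grafted on (input unmodified).

    Missing metabolites are created on demand in the extension compartment.
    ``enable_adh`` opens the methanol <-> formaldehyde alcohol dehydrogenase
    reaction reversibly.
    """
    clash = [rid for rid in extension.reaction_ids() if rid in model.reactions]
    if clash:
        raise PathwayError(f"extension reaction ids already in model: {clash}")
    new = model.copy()
    for rxn in extension.reactions:
        for mid in rxn.stoichiometry:
            if mid not in new.metabolites:
                try:
                    mname, n_c = EXTENSION_METABOLITES[mid]
                except KeyError:
                    raise ModelError(
                        f"no carbon annotation for on-demand metabolite {mid!r}"
                    )
                new.add_metabolite(
                    Metabolite(
                        id=mid,
                        name=mname,
                        compartment=extension.compartment,
                        carbon_atoms=n_c,
                    )
                )
        new.add_reaction(
            ModelReaction(
                id=rxn.id,
                stoichiometry=dict(rxn.stoichiometry),
                lower_bound=rxn.lower_bound,
                upper_bound=rxn.upper_bound,
                name=rxn.name,
            )
        )
    if enable_adh and adh_reaction_id in new.reactions:
        adh = new.reactions[adh_reaction_id]
        adh.lower_bound = -DEFAULT_BOUND
        adh.upper_bound = DEFAULT_BOUND
    return new


def remove_extension(
    model: MetabolicModel, extension: PathwayExtension,
    disable_adh: bool = True, adh_reaction_id: str = "ADH_meoh",
) -> MetabolicModel:
    """Inverse of :func:`apply_extension` (plumbing for round-trip checks)."""
    new = model.copy()
    for rid in extension.reaction_ids():
        new.remove_reaction(rid)
    used = {m for r in new.reactions.values() for m in r.stoichiometry}
    for mid in list(new.metabolites):
        if mid not in used and mid in EXTENSION_METABOLITES and mid not in (
            "fald",
        ):
            del new.metabolites[mid]
    if disable_adh and adh_reaction_id in new.reactions:
        adh = new.reactions[adh_reaction_id]
        adh.lower_bound = 0.0
        adh.upper_bound = 0.0
    return new


def _single_substrate_uptake(
    model: MetabolicModel, substrate_exchange: str, rate: float
) -> dict[str, tuple[float, float]]:
    """Bounds overrides opening one carbon source and closing the others."""
    overrides: dict[str, tuple[float, float]] = {}
    for rid in model.exchange_ids():
        rxn = model.reactions[rid]
        mets = list(rxn.stoichiometry)
        carbon = any(model.metabolites[m].carbon_atoms > 0 for m in mets)
        if rid == substrate_exchange:
            overrides[rid] = (-abs(rate), rxn.upper_bound)
        elif carbon and rxn.lower_bound < 0:
            overrides[rid] = (0.0, rxn.upper_bound)
    return overrides


def compare_pathways(
    model: MetabolicModel,
    uptake: float = 6.0,
    objectives: Sequence[str] = ("growth", "tag"),
    pathways: Iterable[str] = PATHWAY_NAMES,
    substrate_exchange: str = "EX_meoh",
    oxygen_exchange: str = "EX_o2",
) -> pd.DataFrame:
    """Growth/TAG optimisation of each pathway on methanol as sole carbon.

    ``uptake`` is the methanol uptake rate on the model's flux basis (the
    published comparison states 6 on a carbon-mole basis).  Returns one row
    per pathway x objective with the objective value, the carbon yield
    (cmol product per cmol methanol) and the oxygen demand both per mmol and
    per cmol of substrate carbon.  Deterministic given model and settings.
    """
    if not model.biomass_reaction_id or not model.tag_reaction_id:
        raise ModelError("model must declare biomass and TAG reactions")
    rows = []
    for pathway in pathways:
        ext = build_extension(pathway)
        extended = apply_extension(model, ext)
        for rid, (lb, ub) in _single_substrate_uptake(
            extended, substrate_exchange, uptake
        ).items():
            extended.reactions[rid].lower_bound = lb
            extended.reactions[rid].upper_bound = ub
        for objective in objectives:
            target = (
                extended.biomass_reaction_id
                if objective == "growth"
                else extended.tag_reaction_id
            )
            sol = fba(extended, target)
            if sol.status != "optimal":
                # no feasible steady state (e.g. maintenance demand without
                # usable carbon): report zero production, keep the status
                rows.append(
                    {
                        "pathway": pathway,
                        "objective": objective,
                        "status": sol.status,
                        "objective_value": 0.0,
                        "carbon_yield": 0.0,
                        "o2_per_mmol_c": 0.0,
                        "o2_per_cmol": 0.0,
                    }
                )
                continue
            if abs(sol[substrate_exchange]) > 1e-12 and sol.objective_value > 1e-12:
                cy, o2_cmol = yield_and_oxygen(
                    sol, extended, substrate_exchange, target, oxygen_exchange
                )
            else:
                cy, o2_cmol = 0.0, 0.0
            rows.append(
                {
                    "pathway": pathway,
                    "objective": objective,
                    "status": sol.status,
                    "objective_value": sol.objective_value,
                    "carbon_yield": cy,
                    "o2_per_mmol_c": o2_cmol / 1000.0,
                    "o2_per_cmol": o2_cmol,
                }
            )
    return pd.DataFrame(rows)
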