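"""Constraint-based metabolic modelling kernel.

A small flux-balance-analysis stack: model container with a stoichiometric
matrix, tabular and SBML input, LP optimisation (scipy HiGHS, deterministic),
flux-variability analysis, carbon bookkeeping and yield/oxygen-demand
accounting on a carbon-mole basis.

Conventions follow the constraint-based modelling field: exchange reactions
consume their metabolite (coefficient -1) so that uptake is a negative flux;
fluxes are mmol gDW^-1 h^-1; growth is the flux of the biomass reaction in
h^-1.
"""

from __future__ import annotations

import copy
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

DEFAULT_BOUND = 1000.0
FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-6


class ModelError(ValueError):
    """Raised on structurally invalid models or model files."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    carbon_atoms: int = 0
    formula: str | None = None

    def __post_init__(self) -> None:
        if self.carbon_atoms < 0:
            raise ModelError(f"metabolite {self.id}: negative carbon count")
        if self.formula:
            n = carbon_from_formula(self.formula)
            if n is not None and self.carbon_atoms and n != self.carbon_atoms:
                raise ModelError(
                    f"metabolite {self.id}: formula {self.formula} has {n} C, "
                    f"carbon_atoms says {self.carbon_atoms}"
                )


def carbon_from_formula(formula: str) -> int | None:
    m = re.search(r"C(\d*)(?![a-z])", formula)
    if not m:
        return 0 if re.fullmatch(r"[A-Z][a-z]?\d*(?:[A-Z][a-z]?\d*)*", formula) else None
    return int(m.group(1)) if m.group(1) else 1


@dataclass
class ModelReaction:
    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    gene_note: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def is_boundary(self) -> bool:
        """True for pure sources/sinks (all coefficients of one sign)."""
        coeffs = list(self.stoichiometry.values())
        return not coeffs or all(c < 0 for c in coeffs) or all(c > 0 for c in coeffs)


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: pd.Series

    def __getitem__(self, reaction_id: str) -> float:
        return float(self.fluxes[reaction_id])


class MetabolicModel:
    """Metabolites + reactions + bounds + objective.

    The stoichiometric matrix S has one row per metabolite and one column per
    reaction; steady state imposes S v = 0.
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[ModelReaction] = (),
        objective: Mapping[str, float] | None = None,
        biomass_reaction_id: str = "",
        tag_reaction_id: str = "",
        name: str = "",
    ):
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, ModelReaction] = {}
        self.name = name
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)
        self.objective: dict[str, float] = dict(objective or {})
        self.biomass_reaction_id = biomass_reaction_id
        self.tag_reaction_id = tag_reaction_id
        self.validate()

    # -- construction -----------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: ModelReaction) -> None:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        dangling = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if dangling:
            raise ModelError(
                f"reaction {rxn.id!r} references missing metabolites {dangling}"
            )
        self.reactions[rxn.id] = rxn

    def remove_reaction(self, reaction_id: str) -> None:
        del self.reactions[reaction_id]

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def validate(self) -> None:
        for rid in self.objective or {}:
            if rid not in self.reactions:
                raise ModelError(f"objective references unknown reaction {rid!r}")
        for rid in (self.biomass_reaction_id, self.tag_reaction_id):
            if rid and rid not in self.reactions:
                raise ModelError(f"unknown special reaction {rid!r}")

    # -- matrix view ------------------------------------------------------

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    def stoichiometric_matrix(self) -> pd.DataFrame:
        S = pd.DataFrame(
            0.0, index=self.metabolite_ids, columns=self.reaction_ids
        )
        for rid, rxn in self.reactions.items():
            for mid, coeff in rxn.stoichiometry.items():
                S.loc[mid, rid] = coeff
        return S

    def exchange_ids(self) -> list[str]:
        return [rid for rid, r in self.reactions.items() if r.is_boundary]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            self.metabolites == other.metabolites
            and self.reactions == other.reactions
            and self.objective == other.objective
            and self.biomass_reaction_id == other.biomass_reaction_id
            and self.tag_reaction_id == other.tag_reaction_id
        )


# -- equation syntax -------------------------------------------------------

_ARROWS = ("<->", "<=>", "->", "=>")


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse ``2 A + B -> C`` into signed stoichiometry.

    Returns (stoichiometry, reversible).  An empty side denotes a boundary
    reaction, e.g. ``glc_e ->`` for an exchange.
    """
    for arrow in _ARROWS:
        if arrow in equation:
            lhs, rhs = equation.split(arrow, 1)
            reversible = arrow in ("<->", "<=>")
            break
    else:
        raise ModelError(f"no reaction arrow in equation {equation!r}")
    stoich: dict[str, float] = {}

    def consume(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ModelError(f"empty term in equation {equation!r}")
            parts = term.split()
            if len(parts) == 1:
                coeff, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coeff = float(parts[0])
                except ValueError:
                    raise ModelError(f"bad coefficient in term {term!r}")
                met = parts[1]
            else:
                raise ModelError(f"cannot parse term {term!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff
        return

    consume(lhs, -1.0)
    consume(rhs, +1.0)
    return {m: c for m, c in stoich.items() if c != 0.0}, reversible


def format_equation(stoich: Mapping[str, float], reversible: bool) -> str:
    def side(items: list[tuple[str, float]]) -> str:
        return " + ".join(
            (f"{abs(c):g} {m}" if abs(c) != 1 else m) for m, c in items
        )

    lhs = side(sorted((m, c) for m, c in stoich.items() if c < 0))
    rhs = side(sorted((m, c) for m, c in stoich.items() if c > 0))
    arrow = "<->" if reversible else "->"
    return f"{lhs} {arrow} {rhs}".strip()


# -- tabular and SBML I/O --------------------------------------------------


def write_model(model: MetabolicModel, path) -> None:
    """Write the two-file tabular format (metabolites.tsv, reactions.tsv)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "carbon": m.carbon_atoms,
                "formula": m.formula or "",
            }
            for m in model.metabolites.values()
        ]
    ).to_csv(path / "metabolites.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "id": r.id,
                "equation": format_equation(r.stoichiometry, r.lower_bound < 0),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "name": r.name,
            }
            for r in model.reactions.values()
        ]
    ).to_csv(path / "reactions.tsv", sep="\t", index=False)
    meta = {
        "objective": model.objective,
        "biomass_reaction_id": model.biomass_reaction_id,
        "tag_reaction_id": model.tag_reaction_id,
        "name": model.name,
    }
    import json

    (path / "model.json").write_text(json.dumps(meta, indent=1))


def _read_tabular(path: Path) -> MetabolicModel:
    mets_df = pd.read_csv(path / "metabolites.tsv", sep="\t").fillna("")
    rxns_df = pd.read_csv(path / "reactions.tsv", sep="\t").fillna("")
    metabolites = [
        Metabolite(
            id=str(row.id),
            name=str(row.name),
            compartment=str(row.compartment) or "c",
            carbon_atoms=int(row.carbon),
            formula=str(row.formula) or None,
        )
        for row in mets_df.itertuples(index=False)
    ]
    seen: set[str] = set()
    for m in metabolites:
        if m.id in seen:
            raise ModelError(f"duplicate metabolite id {m.id!r}")
        seen.add(m.id)
    reactions = []
    for row in rxns_df.itertuples(index=False):
        stoich, _ = parse_equation(str(row.equation))
        reactions.append(
            ModelReaction(
                id=str(row.id),
                stoichiometry=stoich,
                lower_bound=float(row.lb),
                upper_bound=float(row.ub),
                name=str(getattr(row, "name", "")),
            )
        )
    meta_path = path / "model.json"
    meta = {}
    if meta_path.exists():
        import json

        meta = json.loads(meta_path.read_text())
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective=meta.get("objective"),
        biomass_reaction_id=meta.get("biomass_reaction_id", ""),
        tag_reaction_id=meta.get("tag_reaction_id", ""),
        name=meta.get("name", ""),
    )


def _read_sbml(path: Path) -> MetabolicModel:
    """Read an SBML Level 3 model via the COBRA toolchain and convert.

    Boundary metabolites and unknown annotations are dropped (cobra already
    removes boundary species); carbon counts come from formulas.
    """
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    metabolites = []
    for m in cm.metabolites:
        n_c = carbon_from_formula(m.formula) if m.formula else 0
        metabolites.append(
            Metabolite(
                id=m.id,
                name=m.name or "",
                compartment=m.compartment or "c",
                carbon_atoms=n_c or 0,
                formula=m.formula or None,
            )
        )
    reactions = []
    for r in cm.reactions:
        reactions.append(
            ModelReaction(
                id=r.id,
                stoichiometry={m.id: c for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                name=r.name or "",
            )
        )
    objective = {}
    for r in cm.reactions:
        if r.objective_coefficient:
            objective[r.id] = float(r.objective_coefficient)
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective=objective,
        name=cm.id or "",
    )


def read_model(path, format: str = "tabular") -> MetabolicModel:
    """Read a model in the tabular (directory) or SBML (file) format."""
    path = Path(path)
    if format == "tabular":
        return _read_tabular(path)
    if format == "sbml":
        return _read_sbml(path)
    raise ModelError(f"unknown model format {format!r}")


# -- linear programming ----------------------------------------------------


def _lp(
    model: MetabolicModel,
    c: np.ndarray,
    extra_A_ub: np.ndarray | None = None,
    extra_b_ub: np.ndarray | None = None,
    bounds_override: Mapping[str, tuple[float, float]] | None = None,
):
    rids = model.reaction_ids
    mids = [m for m in model.metabolite_ids]
    S = np.zeros((len(mids), len(rids)))
    midx = {m: i for i, m in enumerate(mids)}
    for j, rid in enumerate(rids):
        for mid, coeff in model.reactions[rid].stoichiometry.items():
            S[midx[mid], j] = coeff
    bounds = []
    for rid in rids:
        r = model.reactions[rid]
        lb, ub = r.lower_bound, r.upper_bound
        if bounds_override and rid in bounds_override:
            lb, ub = bounds_override[rid]
        bounds.append((lb, ub))
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(len(mids)),
        A_ub=extra_A_ub,
        b_ub=extra_b_ub,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
    )
    return res, rids


def fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    uptake: Mapping[str, float] | None = None,
) -> FluxSolution:
    """Maximise an objective flux subject to S v = 0 and bounds.

    ``uptake`` maps exchange reaction ids to maximal uptake rates; the
    exchange lower bound is set to -rate (uptake is negative flux).  The
    optimal objective value is unique to the solver tolerance even when the
    flux vector is degenerate.
    """
    objective: dict[str, float]
    if objective_id is not None:
        if objective_id not in model.reactions:
            raise ModelError(f"unknown objective reaction {objective_id!r}")
        objective = {objective_id: 1.0}
    elif model.objective:
        objective = model.objective
    else:
        raise ModelError("no objective given and model has none")
    override: dict[str, tuple[float, float]] = {}
    if uptake:
        for rid, rate in uptake.items():
            if rid not in model.reactions:
                raise ModelError(f"unknown exchange reaction {rid!r}")
            if not model.reactions[rid].is_boundary:
                raise ModelError(f"{rid!r} is not an exchange reaction")
            ub = model.reactions[rid].upper_bound
            override[rid] = (-abs(rate), ub)
    rids = model.reaction_ids
    c = np.zeros(len(rids))
    for rid, w in objective.items():
        c[rids.index(rid)] = -w  # linprog minimises
    res, rids = _lp(model, c, bounds_override=override)
    if res.status == 2:
        return FluxSolution("infeasible", None, pd.Series(dtype=float))
    if res.status == 3:
        return FluxSolution("unbounded", None, pd.Series(dtype=float))
    if not res.success:
        raise ModelError(f"LP solver failure: {res.message}")
    fluxes = pd.Series(res.x, index=rids)
    return FluxSolution("optimal", float(-res.fun), fluxes)


def fva(
    model: MetabolicModel,
    objective_id: str,
    fraction: float = 1.0,
    uptake: Mapping[str, float] | None = None,
    reactions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Flux ranges per reaction at >= ``fraction`` of the optimal objective."""
    if not 0.0 <= fraction <= 1.0:
        raise ModelError("fraction must lie in [0, 1]")
    base = fba(model, objective_id, uptake)
    if base.status != "optimal":
        raise ModelError(f"base problem is {base.status}")
    override: dict[str, tuple[float, float]] = {}
    if uptake:
        for rid, rate in uptake.items():
            override[rid] = (-abs(rate), model.reactions[rid].upper_bound)
    rids = model.reaction_ids
    n = len(rids)
    obj_row = np.zeros((1, n))
    obj_row[0, rids.index(objective_id)] = -1.0  # -v_obj <= -fraction*opt
    b_ub = np.array([-fraction * base.objective_value])
    targets = list(reactions) if reactions is not None else rids
    records = []
    for rid in targets:
        j = rids.index(rid)
        lo_hi = []
        for sign in (+1.0, -1.0):
            c = np.zeros(n)
            c[j] = sign
            res, _ = _lp(model, c, extra_A_ub=obj_row, extra_b_ub=b_ub,
                         bounds_override=override)
            if not res.success:
                raise ModelError(f"FVA subproblem failed for {rid}: {res.message}")
            lo_hi.append(sign * res.fun)
        records.append({"reaction": rid, "min": lo_hi[0], "max": lo_hi[1]})
    return pd.DataFrame(records).set_index("reaction")


# -- accounting ------------------------------------------------------------


def reaction_carbon_flux(model: MetabolicModel, rxn: ModelReaction) -> float:
    """Carbon atoms removed from the network per unit flux (consumed side)."""
    return sum(
        -coeff * model.metabolites[mid].carbon_atoms
        for mid, coeff in rxn.stoichiometry.items()
        if coeff < 0
    )


def yield_and_oxygen(
    solution: FluxSolution,
    model: MetabolicModel,
    substrate_exchange: str,
    product_id: str,
    oxygen_exchange: str = "EX_o2",
) -> tuple[float, float]:
    """Carbon yield (cmol/cmol) and oxygen demand of an optimal solution.

    ``product_id`` is the reaction whose flux drains the product (biomass or
    TAG sink); its carbon content per unit flux comes from the consumed
    metabolites.  Oxygen demand is reported as mmol O2 per cmol substrate
    (flux ratio on the mmol basis times 1000).
    """
    v_s = solution[substrate_exchange]
    if v_s == 0:
        raise ModelError("substrate uptake flux is zero")
    sub_rxn = model.reactions[substrate_exchange]
    sub_met = max(sub_rxn.stoichiometry, key=lambda m: abs(sub_rxn.stoichiometry[m]))
    n_c_sub = model.metabolites[sub_met].carbon_atoms
    if n_c_sub == 0:
        raise ModelError(f"substrate {sub_met!r} has no carbon count")
    substrate_cflux = abs(v_s) * n_c_sub
    prod_rxn = model.reactions[product_id]
    product_cflux = solution[product_id] * reaction_carbon_flux(model, prod_rxn)
    carbon_yield = product_cflux / substrate_cflux
    v_o2 = abs(solution[oxygen_exchange]) if oxygen_exchange in solution.fluxes.index else 0.0
    oxygen_demand = v_o2 / substrate_cflux * 1000.0
    return float(carbon_yield), float(oxygen_demand)


def carbon_balance_check(
    model: MetabolicModel, exempt: Sequence[str] = (), tol: float = 1e-9
) -> list[str]:
    """Ids of reactions whose summed carbon does not balance.

    Boundary reactions (pure sources/sinks) and any explicitly exempted ids
    (biomass, TAG sink) are skipped.
    """
    exempt_set = set(exempt) | {model.biomass_reaction_id, model.tag_reaction_id}
    bad = []
    for rid, rxn in model.reactions.items():
        if rid in exempt_set or rxn.is_boundary:
            continue
        net = sum(
            coeff * model.metabolites[mid].carbon_atoms
            for mid, coeff in rxn.stoichiometry.items()
        )
        if abs(net) > tol:
            bad.append(rid)
    return bad
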