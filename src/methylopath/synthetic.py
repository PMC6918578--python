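"""Synthetic fixture generators.

Three generators make every pipeline stage testable without external data:

* :func:`generate_core_model` — a reduced, carbon-balanced, yeast-like core
  network (glycolysis, non-oxidative pentose phosphate recycling, TCA,
  oxidative phosphorylation, glycerol/glucose/methanol/O2/CO2 exchanges,
  biomass and triacylglycerol sinks, and a closed NAD-dependent alcohol
  dehydrogenase for methanol).  It stands in for a genome-scale yeast model
  in qualitative pathway comparisons; it does not mimic any published model
  numerically.
* :func:`generate_thermo_records` — Gaussian scatter of literature-style
  formation-energy estimates around a known true value.
* :func:`generate_protein_family` — protein sequences evolved by per-site
  substitution along a known tree, for clustering and tree-building tests.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
from skbio import TreeNode

from .model import MetabolicModel, Metabolite, ModelReaction, parse_equation
from .thermo import ThermoRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class CoreModelParams:
    """Parameters of the reduced core network.

    p_o_ratio: ATP per NADH oxidised in the respiratory chain (FADH2 lumped
    into the NADH pool).  biomass_carbon: mmol carbon drained per unit of
    biomass flux, so growth is h^-1 when fluxes are mmol gDW^-1 h^-1.
    biomass_atp: growth-associated ATP cost per unit biomass flux.
    tag_carbon_atoms: carbon atoms per triacylglycerol molecule (glycerol
    backbone + even-chain acyls).  atp_maintenance: non-growth ATP drain.
    """

    p_o_ratio: float = 1.5
    biomass_carbon: float = 40.0
    biomass_atp: float = 100.0
    tag_carbon_atoms: int = 51
    atp_maintenance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.p_o_ratio, self.biomass_carbon, self.biomass_atp) <= 0:
            raise ValueError("core model parameters must be positive")
        if self.tag_carbon_atoms < 5 or (self.tag_carbon_atoms - 3) % 2:
            raise ValueError("tag_carbon_atoms must be 3 + an even acyl carbon count")
        if self.atp_maintenance < 0:
            raise ValueError("atp_maintenance must be >= 0")


#: metabolite id -> (name, carbon atoms).  Carrier moieties (CoA, THF, the
#: adenine nucleotides and NAD) are carbon-free in the bookkeeping: only the
#: transferred carbon is counted, so carrier-paired reactions balance.
CORE_METABOLITES: dict[str, tuple[str, int]] = {
    "glc": ("D-glucose", 6),
    "glyc": ("glycerol", 3),
    "meoh": ("methanol", 1),
    "fald": ("formaldehyde", 1),
    "o2": ("oxygen", 0),
    "co2": ("carbon dioxide", 1),
    "g6p": ("glucose 6-phosphate", 6),
    "f6p": ("fructose 6-phosphate", 6),
    "fbp": ("fructose 1,6-bisphosphate", 6),
    "dhap": ("dihydroxyacetone phosphate", 3),
    "gap": ("glyceraldehyde 3-phosphate", 3),
    "pg3": ("3-phosphoglycerate", 3),
    "pg2": ("2-phosphoglycerate", 3),
    "pep": ("phosphoenolpyruvate", 3),
    "pyr": ("pyruvate", 3),
    "accoa": ("acetyl-CoA (acyl carbon)", 2),
    "oaa": ("oxaloacetate", 4),
    "akg": ("2-oxoglutarate", 5),
    "mal": ("malate", 4),
    "glx": ("glyoxylate", 2),
    "g3p": ("glycerol 3-phosphate", 3),
    "ru5p": ("ribulose 5-phosphate", 5),
    "r5p": ("ribose 5-phosphate", 5),
    "x5p": ("xylulose 5-phosphate", 5),
    "s7p": ("sedoheptulose 7-phosphate", 7),
    "e4p": ("erythrose 4-phosphate", 4),
    "atp": ("ATP (carrier)", 0),
    "adp": ("ADP (carrier)", 0),
    "nad": ("NAD+ (carrier)", 0),
    "nadh": ("NADH (carrier)", 0),
    "coa": ("coenzyme A (carrier)", 0),
    "biomass": ("biomass", 0),  # carbon set from the biomass equation
    "tag": ("triacylglycerol", 0),  # carbon set from params
}


def generate_core_model(params: CoreModelParams | None = None) -> MetabolicModel:
    """Build the reduced core network.

    Feasible for growth on glycerol and glucose; methanol alone supports no
    growth because the network lacks any formaldehyde assimilation route and
    the alcohol dehydrogenase entry reaction ships closed (bounds 0,0) —
    pathway extensions open it.  Always carbon-balanced.
    """
    p = params or CoreModelParams()
    n_accoa = (p.tag_carbon_atoms - 3) // 2
    # chain condensations: n_accoa - 3 across the three acyls, each costing
    # 1 ATP and 2 NADH (NADPH folded into the NAD pool)
    n_cond = n_accoa - 3
    po = p.p_o_ratio

    # biomass drain: carbon split over F6P/pyruvate/acetyl-CoA/oxaloacetate
    # (12 + 12 + 10 + 6 = 40 mmol C at the default biomass_carbon)
    scale = p.biomass_carbon / 40.0
    bm = {
        "f6p": 2.0 * scale,
        "pyr": 4.0 * scale,
        "accoa": 5.0 * scale,
        "oaa": 1.5 * scale,
        "atp": p.biomass_atp,
    }
    biomass_eq = (
        f"{bm['f6p']:g} f6p + {bm['pyr']:g} pyr + {bm['accoa']:g} accoa + "
        f"{bm['oaa']:g} oaa + {bm['atp']:g} atp -> biomass + "
        f"{bm['atp']:g} adp + {bm['accoa']:g} coa"
    )
    tag_eq = (
        f"g3p + {n_accoa:g} accoa + {n_cond + 1:g} atp + {2 * n_cond:g} nadh -> "
        f"tag + {n_accoa:g} coa + {n_cond + 1:g} adp + {2 * n_cond:g} nad"
    )

    reactions_spec: list[tuple[str, str, float, float, str]] = [
        # exchanges: metabolite leaves the network at positive flux
        ("EX_glc", "glc ->", 0.0, 1000.0, "glucose exchange"),
        ("EX_glyc", "glyc ->", 0.0, 1000.0, "glycerol exchange"),
        ("EX_meoh", "meoh ->", 0.0, 1000.0, "methanol exchange"),
        ("EX_o2", "o2 ->", -1000.0, 1000.0, "oxygen exchange"),
        ("EX_co2", "co2 ->", 0.0, 1000.0, "CO2 exchange"),
        ("DM_biomass", "biomass ->", 0.0, 1000.0, "biomass sink"),
        ("DM_tag", "tag ->", 0.0, 1000.0, "TAG sink"),
        # substrate entry
        ("HXK", "glc + atp -> g6p + adp", 0.0, 1000.0, "hexokinase"),
        ("GLYK", "glyc + atp -> g3p + adp", 0.0, 1000.0, "glycerol kinase"),
        ("G3PDH", "g3p + nad <-> dhap + nadh", -1000.0, 1000.0,
         "glycerol-3-phosphate dehydrogenase"),
        # methanol entry, closed by default (opened by pathway extensions)
        ("ADH_meoh", "meoh + nad <-> fald + nadh", 0.0, 0.0,
         "alcohol dehydrogenase on methanol"),
        # glycolysis
        ("PGI", "g6p <-> f6p", -1000.0, 1000.0, "phosphoglucose isomerase"),
        ("PFK", "f6p + atp -> fbp + adp", 0.0, 1000.0, "phosphofructokinase"),
        ("FBA", "fbp <-> dhap + gap", -1000.0, 1000.0, "aldolase"),
        ("TPI", "dhap <-> gap", -1000.0, 1000.0, "triose phosphate isomerase"),
        ("GAPD", "gap + adp + nad <-> pg3 + atp + nadh", -1000.0, 1000.0,
         "GAPDH + phosphoglycerate kinase (lumped)"),
        ("PGM", "pg3 <-> pg2", -1000.0, 1000.0, "phosphoglycerate mutase"),
        ("ENO", "pg2 <-> pep", -1000.0, 1000.0, "enolase"),
        ("PYK", "pep + adp -> pyr + atp", 0.0, 1000.0, "pyruvate kinase"),
        ("FBPase", "fbp -> f6p", 0.0, 1000.0, "fructose bisphosphatase"),
        # pentose phosphate recycling (non-oxidative) + oxidative branch
        ("G6PDH_lump", "g6p + 2 nad -> ru5p + co2 + 2 nadh", 0.0, 1000.0,
         "oxidative PPP (lumped, NADPH folded into NAD pool)"),
        ("RPI", "ru5p <-> r5p", -1000.0, 1000.0, "ribose-5-phosphate isomerase"),
        ("RPE", "ru5p <-> x5p", -1000.0, 1000.0, "ribulose-5-phosphate epimerase"),
        ("TKT1", "x5p + r5p <-> s7p + gap", -1000.0, 1000.0, "transketolase 1"),
        ("TAL", "s7p + gap <-> e4p + f6p", -1000.0, 1000.0, "transaldolase"),
        ("TKT2", "x5p + e4p <-> f6p + gap", -1000.0, 1000.0, "transketolase 2"),
        # pyruvate node and TCA (two lumped oxidative segments)
        ("PDH", "pyr + coa + nad -> accoa + co2 + nadh", 0.0, 1000.0,
         "pyruvate dehydrogenase"),
        ("PYC", "pyr + co2 + atp -> oaa + adp", 0.0, 1000.0,
         "pyruvate carboxylase"),
        ("CS_AKG", "accoa + oaa + nad -> akg + co2 + nadh + coa", 0.0, 1000.0,
         "citrate synthase .. isocitrate dehydrogenase (lumped)"),
        ("AKG_MAL", "akg + 2 nad + adp -> mal + co2 + 2 nadh + atp", 0.0,
         1000.0, "2-oxoglutarate .. malate (lumped; FADH2 counted as NADH)"),
        ("MDH", "mal + nad <-> oaa + nadh", -1000.0, 1000.0,
         "malate dehydrogenase"),
        # glyoxylate shunt and gluconeogenic PEP supply (native in yeast)
        ("ICL_lump", "accoa + oaa + nad -> glx + mal + nadh + coa", 0.0, 1000.0,
         "citrate synthase .. isocitrate lyase + succinate->malate (lumped)"),
        ("MS", "accoa + glx -> mal + coa", 0.0, 1000.0, "malate synthase"),
        ("PEPCK", "oaa + atp -> pep + co2 + adp", 0.0, 1000.0,
         "PEP carboxykinase"),
        # energy metabolism
        ("OXPHOS", f"nadh + 0.5 o2 + {po:g} adp -> nad + {po:g} atp", 0.0,
         1000.0, "respiratory chain (lumped)"),
        ("ATPM", "atp -> adp", p.atp_maintenance, 1000.0, "ATP maintenance"),
        # sinks
        ("BIOMASS", biomass_eq, 0.0, 1000.0, "biomass formation"),
        ("TAG_SYN", tag_eq, 0.0, 1000.0, "triacylglycerol synthesis (lumped)"),
    ]

    metabolites = []
    for mid, (name, n_c) in CORE_METABOLITES.items():
        if mid == "biomass":
            n_c = 0  # biomass carbon accounted at the forming reaction
        if mid == "tag":
            n_c = p.tag_carbon_atoms
        metabolites.append(Metabolite(id=mid, name=name, carbon_atoms=n_c))

    reactions = []
    for rid, eq, lb, ub, name in reactions_spec:
        stoich, _ = parse_equation(eq)
        reactions.append(
            ModelReaction(id=rid, stoichiometry=stoich, lower_bound=lb,
                          upper_bound=ub, name=name)
        )
    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective={"BIOMASS": 1.0},
        biomass_reaction_id="BIOMASS",
        tag_reaction_id="TAG_SYN",
        name=f"methylopath-core (seed {p.seed})",
    )
    return model


def generate_thermo_records(
    true_value: float,
    sigmas,
    n: int | None = None,
    seed: int = 0,
    species_id: str = "synthetic_species",
    property: str = "formation_gibbs",
) -> list[ThermoRecord]:
    """Gaussian literature-style scatter around a known true value.

    ``sigmas`` is a scalar (used for all ``n`` records) or a sequence of
    per-record standard deviations.  Reproducible under a fixed seed.
    """
    if np.isscalar(sigmas):
        if n is None or n < 1:
            raise ValueError("n >= 1 required when sigmas is scalar")
        sigma_arr = np.full(n, float(sigmas))
    else:
        sigma_arr = np.asarray(sigmas, dtype=float)
        if n is not None and n != sigma_arr.size:
            raise ValueError("n disagrees with the number of sigmas")
    if sigma_arr.size < 1:
        raise ValueError("need at least one record")
    rng = np.random.default_rng(seed)
    values = true_value + rng.standard_normal(sigma_arr.size) * sigma_arr
    return [
        ThermoRecord(
            species_id=species_id,
            property=property,
            value=float(v),
            uncertainty=float(s),
            source_label=f"synthetic_{i}",
        )
        for i, (v, s) in enumerate(zip(values, sigma_arr))
    ]


@dataclass(frozen=True)
class FamilyParams:
    """Parameters of a simulated protein family.

    substitution_rate_per_site is the per-branch probability that a site is
    redrawn; the replacement is uniform over the 19 other residues (uniform
    20-letter model, no rate heterogeneity).
    """

    n_taxa: int = 8
    seq_length: int = 200
    substitution_rate_per_site: float = 0.05
    tree_shape: str = "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if not 0.0 <= self.substitution_rate_per_site < 1.0:
            raise ValueError("substitution rate must lie in [0, 1)")
        if self.tree_shape not in ("balanced", "caterpillar", "random"):
            raise ValueError(f"unknown tree shape {self.tree_shape!r}")


def _build_topology(params: FamilyParams, rng: np.random.Generator) -> TreeNode:
    labels = [f"T{i:02d}" for i in range(params.n_taxa)]
    rate = params.substitution_rate_per_site

    def leaf(name: str) -> TreeNode:
        return TreeNode(name=name, length=rate)

    if params.tree_shape == "balanced":
        nodes = [leaf(l) for l in labels]
        while len(nodes) > 1:
            nxt = []
            for i in range(0, len(nodes) - 1, 2):
                parent = TreeNode(length=rate, children=[nodes[i], nodes[i + 1]])
                nxt.append(parent)
            if len(nodes) % 2:
                nxt.append(nodes[-1])
            nodes = nxt
        root = nodes[0]
    elif params.tree_shape == "caterpillar":
        root = TreeNode(length=rate, children=[leaf(labels[0]), leaf(labels[1])])
        for l in labels[2:]:
            root = TreeNode(length=rate, children=[root, leaf(l)])
    else:  # random: sequential random joins
        nodes = [leaf(l) for l in labels]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            b = nodes.pop(j)
            a = nodes.pop(i)
            nodes.append(TreeNode(length=rate, children=[a, b]))
        root = nodes[0]
    root.length = None
    return root


def generate_protein_family(
    params: FamilyParams | None = None,
) -> tuple[dict[str, str], TreeNode]:
    """Evolve a protein family along a known tree.

    Returns (sequences keyed by taxon, the generating tree).  Expected
    pairwise identity decreases with tree path length; at vanishing rate all
    sequences coincide.  Byte-identical output under a fixed seed.
    """
    p = params or FamilyParams()
    rng = np.random.default_rng(p.seed)
    tree = _build_topology(p, rng)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    root_seq = rng.choice(aa, size=p.seq_length)
    sequences: dict[str, str] = {}

    def evolve(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            mutated = seq.copy()
            hit = rng.random(p.seq_length) < p.substitution_rate_per_site
            if hit.any():
                idx = np.where(hit)[0]
                for i in idx:
                    choices = aa[aa != mutated[i]]
                    mutated[i] = rng.choice(choices)
            if child.is_tip():
                sequences[child.name] = mutated.tobytes().decode()
            else:
                evolve(child, mutated)

    evolve(tree, root_seq)
    # report sequences in stable taxon order
    ordered = {name: sequences[name] for name in sorted(sequences)}
    return ordered, tree


def family_to_fasta(sequences: dict[str, str]) -> str:
    out = StringIO()
    for name, seq in sequences.items():
        out.write(f">{name}\n")
        for i in range(0, len(seq), 60):
            out.write(seq[i : i + 60] + "\n")
    return out.getvalue()
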