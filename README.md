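# methylopath

Thermodynamic and stoichiometric analysis of synthetic methylotrophy in an
oleaginous yeast host: how much formaldehyde does an engineered
methanol-oxidation step supply at equilibrium, and which formaldehyde
assimilation pathway (RuMP, XuMP, or the serine cycle) best supports growth
and lipid production?

The package has six parts:

| module | contents |
| --- | --- |
| `methylopath.thermo` | literature-record reconciliation (inverse-variance + Birge ratio), Gibbs–Helmholtz temperature extrapolation with polynomial heat capacities, a pooled formaldehyde/methylene-glycol pseudo-species, and the alcohol-dehydrogenase equilibrium that sets the attainable formaldehyde concentration |
| `methylopath.model` | a small constraint-based modelling kernel: model container, tabular and SBML input, FBA and FVA on top of `scipy.optimize.linprog` (HiGHS), carbon-mole yields, oxygen demand, carbon-balance audit |
| `methylopath.pathways` | the three assimilation pathways as named reaction sets that can be applied to and removed from any host model, plus a side-by-side comparison table |
| `methylopath.synthetic` | fixture generators: a feasible yeast-like core network with biomass and TAG sinks, Gaussian-scatter thermodynamic records, and protein families evolved along a known tree |
| `methylopath.seqsearch` | global alignment identity, greedy ≥90 %-identity clustering, Saitou–Nei neighbour joining, Newick I/O |
| `methylopath.cli` / `methylopath.pipeline` | a `click` command line and a validated (`pydantic`) end-to-end pipeline |

## Worked example

Equilibrium formaldehyde-pool concentration sustained by an ADH-type methanol
oxidation at 0.5 M methanol and unit NAD⁺/NADH ratio:

```text
$ methylopath thermo-report --temperatures 28,30,50
T_C     delta_r_G_kJ_mol  K            HCHO_pool_uM
28      24.0179           6.82222e-05  34.1111
30      23.785            7.97156e-05  39.8578
50      21.455            0.000340285  170.143
```

The pool is far below what assimilation enzymes would like to see — tens of
micromolar at growth temperatures — which is the core thermodynamic obstacle
this kind of engineering faces.

Pathway comparison on the bundled synthetic core model (methanol as sole
carbon source, uptake 6 flux units):

```text
$ methylopath compare --pathway all --objective growth
pathway       objective  status   objective_value  carbon_yield  o2_per_mmol_c  o2_per_cmol
RuMP          growth     optimal  0.130862         0.87241       0.720284       720.284
XuMP          growth     optimal  0.112432         0.74955       0.83009        830.09
serine_cycle  growth     optimal  0.105799         0.705324      0.869617       869.617
```

The ordering — RuMP best, then XuMP, then the serine cycle, with oxygen
demand rising in the same order — follows from the ATP cost per formaldehyde
assimilated (0, 1 and 2 ATP respectively, plus reductant costs for the serine
cycle). On this reduced network the spread between pathways is smaller than
on a genome-scale model; the comparison is qualitative by design (see
`docs/methods.md`).

Other entry points:

```bash
methylopath hps-cluster --fasta candidates.fa --threshold 0.9 --tree-out tree.nwk
methylopath synth family --seed 3 --out family.fa     # + family.nwk (true tree)
methylopath synth core --seed 0 --out core_model/
methylopath run --config config.yaml --out results/   # full pipeline
```

A pipeline config is plain YAML validated against `PipelineConfig`; unknown
keys are rejected:

```yaml
stages: [thermo, compare, hps]
temperatures_c: [28, 30, 50]
medium:
  methanol_m: 0.5
  nad_ratio: 1.0
fasta_path: candidates.fa
```

## Library use

```python
from methylopath import thermo as th
from methylopath.synthetic import CoreModelParams, generate_core_model
from methylopath.pathways import build_extension, apply_extension, compare_pathways
from methylopath.model import fba

table = th.reference_table()
g = th.pool_formation_energy(th.FORMALDEHYDE_POOL, table, 298.15)   # 130.54

core = generate_core_model(CoreModelParams())
extended = apply_extension(core, build_extension("RuMP"))
sol = fba(extended, "BIOMASS", uptake={"EX_meoh": 6.0, "EX_glc": 0.0,
                                       "EX_glyc": 0.0})
print(sol.objective_value)                                          # 0.1309
```

See `docs/methods.md` for the model formulation, parameter defaults and
their rationale, numerical choices, and stated limitations.
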