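# Methods

This note records the mathematical formulation, the packaged parameter sets,
the defaults and their rationale, and the limitations of each module.

## 1. Thermodynamics (`methylopath.thermo`)

### Record reconciliation

Independent literature estimates `x_i ± s_i` of one property of one species
are combined by the inverse-variance weighted mean,

    m = Σ w_i x_i / Σ w_i,   w_i = 1/s_i²,   σ_m = (Σ w_i)^(-1/2).

When the scatter exceeds what the stated uncertainties allow
(reduced chi-square χ²_red = Σ w_i (x_i − m)² / (n − 1) > 1), the pooled
uncertainty is inflated by the Birge ratio, σ_m → σ_m √χ²_red. A single
record is returned unchanged. Records for different species or different
properties cannot be mixed and raise an error.

### Temperature extrapolation

Species carry a reference-state formation Gibbs energy and enthalpy at
`temperature_ref` (298.15 K by default) and an optional heat-capacity
polynomial Cp(T) = a + bT + cT² (J mol⁻¹ K⁻¹). The reaction Gibbs energy at
temperature T follows Gibbs–Helmholtz with closed-form polynomial integrals:

    ΔrH(T) = ΔrH(T₀) + ∫_{T₀}^{T} ΔrCp dT
    ΔrS(T) = ΔrS(T₀) + ∫_{T₀}^{T} ΔrCp/T dT
    ΔrG(T) = ΔrH(T) − T ΔrS(T),   ΔrS(T₀) = (ΔrH(T₀) − ΔrG(T₀)) / T₀.

The closed forms are verified against numerical quadrature in the tests.
First-order (linear) uncertainty propagation gives
σ(ΔrG) = (Σ ν_i² σ_i²)^(1/2); it is checked against Monte Carlo.

### The formaldehyde pool

In water, formaldehyde equilibrates with its hydrate methylene glycol,
CH₂(OH)₂, which dominates. The two forms are treated as one pooled
pseudo-species whose formation energy is the Boltzmann-weighted combination

    ΔfG_pool = −RT ln Σ_i exp(−ΔfG_i / RT)

(evaluated with `logsumexp`), which is always at or below the most stable
component. Pool uncertainty propagates through the Boltzmann weights.

### ADH equilibrium

The engineered entry reaction is methanol + NAD⁺ ⇌ formaldehyde-pool + NADH
(+ H⁺, absorbed into the reference state at the fixed pH). With
K(T) = exp(−ΔrG(T)/RT), the dilute-limit closed form is

    [pool] = K(T) · [MeOH] · [NAD⁺] / [NADH].

An `exact` mode instead solves the mass-balance root problem with `brentq`,
accounting for the methanol consumed; at the default conditions the two
agree to better than 1 %.

### Packaged parameter set

`data/formaldehyde_thermo_synthetic.tsv` is a self-consistent synthetic
stand-in for a literature compilation (the real supplementary compilation is
not redistributable). It was calibrated once, at design time, so that the
package's published-style outputs are: pool formation energy
130.54 ± 3.30 kJ mol⁻¹, and equilibrium pool concentrations of roughly 34,
40 and 170 µM at 28, 30 and 50 °C for 0.5 M methanol at unit NAD⁺/NADH. The
enthalpies come from a van't Hoff least-squares fit to those three
temperature anchors; heat capacities are set equal across the reaction
(ΔrCp = 0) so the fit is preserved while the Cp code path stays exercised.
`data/formaldehyde_pool_compilation_synthetic.tsv` holds three scattered
"literature" records whose reconciliation reproduces the same value and
uncertainty. These numbers are frozen inputs, not fitted at runtime.

## 2. Constraint-based kernel (`methylopath.model`)

Flux balance analysis solves max c·v subject to S·v = 0 and
lb ≤ v ≤ ub with `scipy.optimize.linprog` (HiGHS). Conventions:

- Exchange reactions consume their metabolite (coefficient −1), so uptake is
  a negative flux; `fba(..., uptake={"EX_x": r})` sets the lower bound of
  `EX_x` to −r.
- Fluxes are mmol gDW⁻¹ h⁻¹; the biomass flux is h⁻¹.
- `fba` returns a status (`optimal` / `infeasible` / `unbounded`) instead of
  raising, because infeasibility is an expected answer (e.g. maintenance ATP
  with no usable carbon source).

Flux variability analysis fixes the objective to ≥ `fraction` of its optimum
and minimises/maximises each reaction flux in turn.

Yields are on a carbon-mole basis: carbon_yield = (product flux × product
carbon) / (substrate flux × substrate carbon). Oxygen demand is reported
both as a mol ratio per mol substrate carbon (`o2_per_mmol_c`) and scaled by
1000 (`o2_per_cmol`); published tables of this kind print the mol-ratio
numbers. `carbon_balance_check` flags every non-boundary reaction whose
carbon does not balance, given per-metabolite carbon counts.

The LP is verified against an independent brute-force vertex-enumeration
oracle on small networks, and the SBML path (read via COBRApy) against a
round trip that preserves the optimum.

## 3. Pathway extensions (`methylopath.pathways`)

Each pathway is a named, carbon-balanced reaction set applied to a copy of
the host model; on-demand metabolites (formaldehyde, hexulose-6-P, THF
carriers, …) are created with known carbon counts.

- **RuMP**: HPS (formaldehyde + ribulose-5-P → hexulose-6-P), PHI
  (hexulose-6-P ⇌ fructose-6-P). Zero ATP per formaldehyde.
- **XuMP**: DHAS (formaldehyde + xylulose-5-P → DHA + GAP), DAK
  (DHA + ATP → DHAP). One ATP per formaldehyde.
- **Serine cycle**: spontaneous/enzymatic formaldehyde–THF condensation,
  SHMT, transamination, hydroxypyruvate reduction, glycerate kinase, PEP
  carboxylation, malate activation (MTK) and malyl-CoA cleavage (MCL). Two
  ATP plus reductant per net assimilation; its net product is acetyl-CoA.

`apply_extension` also opens the host's methanol→formaldehyde ADH step
(closed by default so the base model never uses methanol); `enable_adh=False`
leaves it closed, which the tests use to show the extensions cannot create
growth out of nothing. `compare_pathways` closes all carbon exchanges except
methanol, optimises growth and TAG for each pathway, and reports objective
value, carbon yield and oxygen demand per row; non-optimal rows keep their
status and report zeros.

## 4. Synthetic fixtures (`methylopath.synthetic`)

### Core model

A ~40-reaction yeast-like network: glycolysis and pentose-phosphate lumps,
pyruvate and acetyl-CoA nodes, a TCA/oxidative lump, oxidative
phosphorylation with a configurable P/O ratio, maintenance ATP, uptake of
glucose/glycerol/methanol, and biomass and TAG sinks. It includes the
host-native glyoxylate shunt (isocitrate lyase + malate synthase, lumped)
and PEP carboxykinase; without them the serine cycle's acetyl-CoA output
cannot reach sugar-phosphate precursors and the pathway would be
artificially infeasible on this reduced network.

Defaults and rationale (`CoreModelParams`):

- `p_o_ratio = 1.5` — mid-range for non-fermentative yeast respiration.
- `biomass_atp = 100` ATP per biomass unit (growth-associated maintenance)
  and `atp_maintenance = 1` mmol gDW⁻¹ h⁻¹ (non-growth) — chosen at design
  time so growth is ATP-limited; this is what makes the pathway ranking
  strict, because the three pathways differ exactly in ATP per formaldehyde.
- `tag_carbon_atoms = 51` — a C51 triacylglycerol; the TAG sink consumes
  glycerol-3-P plus 24 acetyl-CoA with ATP and NADH costs.

The glucose optimum has a frozen hand-derived closed form (22 ATP per
glucose at P/O 1.5; 7.25 glucose and 69.75 net ATP per biomass unit):
μ = (U − NGAM/22) / (7.25 + 69.75/22), checked exactly in the tests.

### Thermo records and protein families

`generate_thermo_records` draws Gaussian scatter with stated per-record
sigmas around a known true value. `generate_protein_family` evolves a root
sequence along a balanced or caterpillar topology; per branch, each site is
redrawn with probability `substitution_rate_per_site`, uniformly over the 19
other residues (no rate heterogeneity, no indels). Both are byte-reproducible
under a fixed seed, and both state the truth they were generated from so
recovery can be tested.

## 5. Sequence analysis (`methylopath.seqsearch`)

Global alignment uses Biopython's `PairwiseAligner` in true global mode with
BLOSUM62 and affine gaps (open 11, extend 1, BLAST convention: a run of
length L costs open + L·extend); scores are verified against exhaustive
alignment enumeration for short pairs. Identity is matches over aligned
columns, excluding terminal-gap columns (so a perfect prefix match of a
shorter sequence counts as 100 % under the default denominator); a
`shorter`-denominator option matches common clustering tools.

Clustering is greedy in canonical order (length descending): each sequence
joins the first cluster whose representative it matches at ≥ threshold,
otherwise founds a new cluster — the BLASTclust-style scheme, deterministic
and input-order invariant.

Neighbour joining is implemented directly (Saitou–Nei Q-criterion,
deterministic tie-breaking, negative branch lengths clamped to zero with the
deficit moved to the sibling so pair path lengths are preserved) and returns
a scikit-bio `TreeNode`; it is exact on additive matrices. Newick output uses
6 significant digits, escalating where needed; Robinson–Foulds distances come
from scikit-bio.

## 6. Pipeline and CLI

`PipelineConfig` is a pydantic model with `extra="forbid"`: unknown or
invalid keys fail fast with exit code 2 from the CLI. Stage failures
(infeasible models and the like) exit with code 3. All artifacts are TSV or
Newick text, and a full run is byte-deterministic for a fixed config.

## Limitations

- The packaged thermodynamic table is a calibrated synthetic stand-in, not a
  literature compilation; only its *outputs* (pool energy, equilibrium
  concentrations) are meaningful, not its per-species entries.
- The synthetic core model supports the qualitative pathway ranking and
  ordering of oxygen demands, not the genome-scale magnitudes; yields on the
  reduced network are higher and flatter than a genome-scale model would
  give. The genome-scale reproduction requires the external iNL895 file.
- The serine-cycle reaction set is the classical α-proteobacterial cycle in
  lumped form; cofactor specificities are simplified to NAD(H).
- Alignment identity is a pairwise global measure; no profile or HMM search
  is provided, and the clustering stage consumes whatever FASTA it is given.
- The family simulator has no indels, so alignment columns map one-to-one to
  sites; identity-based p-distances are uncorrected (no Poisson/Gamma
  correction), adequate for the short divergences generated by default.
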