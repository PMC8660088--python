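# Methods

## The analysis model

`synerkit` operates on an undirected bipartite component–target (C-T)
network: chemical components of a two-herb formula on one side, predicted
protein targets on the other. The synergy argument rests on three layers.

1. **Topology.** Targets reachable from components of *both* herbs ("common
   targets") are compared with herb-unique targets; the degree-threshold
   sweep reports each class's share among targets of degree ≥ t for every
   integer t up to the maximum target degree. If common targets dominate the
   high-degree end, the two herbs converge on the most influential nodes.
2. **Synergy Contribution Degree.** Per component,
   `SCD(i) = Σ_j [C_i((Ce_i/Te_i + B_i)·T_j) + NORM(d_i)]` over its targets
   j. The sum telescopes to the closed form
   `C_i(Ce_i/Te_i + B_i)·ΣT_j + Ce_i·NORM(d_i)`, which is what the
   implementation evaluates; a dedicated test keeps it equal to the
   term-by-term sum. Both network prominence and dose therefore matter, and
   dose weight scales with the component's target count (the normalised dose
   sits inside the per-target sum; a `dose-term` interpretation note is
   recorded in the run manifest). Components with no targets keep SCD 0 and
   stay in the table so share accounting is auditable.
3. **Docking-informed ranking.** The therapeutic response index adds binding
   evidence: TRI = NORM(CDI) + NORM(SCD), with CDI aggregating per-component
   HRDR gene counts (GI), mean affinity (AI) and eight NetworkAnalyzer-style
   topology parameters (degree, betweenness, closeness, average shortest
   path length, eccentricity, radiality, neighborhood connectivity,
   topological coefficient) computed on the C-T network restricted to the
   HCGSC and its targets. That restriction is the pipeline default because
   the docking panel *is* the core group; `compute_cdi` accepts any
   extended-topology table, so the full-network reading is available by
   passing `extended_topology` of the whole graph.

### Assumptions

- The C-T network is undirected and unweighted; activation vs inhibition is
  not modelled.
- Betweenness follows the Cytoscape convention: shortest-path betweenness
  normalised by (n−1)(n−2)/2 *within each connected component*. SCD compares
  components only through products of these centralities, so the convention
  matters only if applied inconsistently; the package applies it everywhere.
- The inter-herb balance term treats a *chemical* present in both herbs
  (matched by component name across herb labels) as one entity: each record
  inherits the partner's single-herb-subgraph betweenness for the missing
  side. Chemicals present in one herb only get B = 1; an exactly balanced
  chemical gets the floor 1e-6 rather than 0 so the multiplicative term
  cannot erase a component single-handedly.

## Tunable parameters

| Parameter | Default | Units / meaning |
|---|---|---|
| `caco2_min` | −0.4 (exclusive) | TCMSP permeability score; below ⇒ not permeable |
| `dl_min` | 0.18 (inclusive) | Tanimoto drug-likeness threshold |
| `cum_threshold` | 0.95 | cumulative SCD share defining the HCGSC |
| `hub_degree` | 120 | degree above which a component counts as a hub |
| `fdr_cut` | 0.05 | BH-adjusted significance cut for ORA |
| ORA term-size bounds | 2–500 | genes per term admitted to the tested family |
| `cdi_form` | `default` | CDI uses signed AI; `abs-ai` uses its magnitude |

The CDI expression is ambiguous about whether mean affinity enters signed or
as a magnitude. The default keeps the signed value — `R = 2 + GI²/(mean GI ·
|AI|)` for negative affinities, so gene count dominates and stronger binding
(larger |AI|) tempers R — and the chosen form is pinned in the TRI output
metadata and the run manifest so any downstream reader can audit it.

## Numerical choices

- Reported percentages and means are rounded half-up (not banker's
  rounding) at 2 decimals, 1 decimal for the hub share, matching how such
  tables are conventionally printed.
- `minmax_norm` maps a constant vector to all ones, not zeros: equal doses
  still credit dose, a single docked component scores the degenerate CDI of
  8.0, and the convention is shared by every NORM in the package.
- HCGSC selection at the cumulative threshold includes every component tied
  (in SCD) with the component at the cut; ordering ties are broken by id so
  results are permutation-invariant.
- Best-pose reduction keeps the first-seen record among tied minima and logs
  the tie count; the HRDR filter is strict (`affinity < mean`), so an
  all-equal affinity table yields an empty HRDR.
- Duplicate C-T edges are collapsed with a logged count; self-pairs and
  unknown component ids are validation errors, not warnings.
- The degree-threshold sweep emits a null-share row when no target survives
  a threshold rather than stopping early.

## The synthetic-study generator

The generator emulates the statistical structure the analysis assumes, at the
scale of a screened two-herb formula study: 92 + 21 components (the
candidate-active scale, of which ~90% clear the default screen), 780 targets,
mean degree 40 (≈4,500 edges), two dominant-dose components, affinities
centred at −6.7 kcal/mol (SD 1.6) truncated above at −0.5, and 20 planted
strong binders at or below −10 kcal/mol.

- **Degrees** are negative-binomial (dispersion 2) around `edge_density`,
  giving the heavy right tail — a few hub components with degree > 120 —
  that real component–target tables show.
- **Common targets** are a designated pool (32% of targets by default)
  selectable by both herbs and weighted 3× (10× for planted components)
  during edge sampling; herb-unique pools are selectable only by their own
  herb, so a zero common fraction provably yields an empty common partition.
- **Planted core** components receive the dominant doses (25× the log-normal
  mean), a degree floor of twice the mean degree, edges concentrated on
  common targets, ADME properties that pass the screen, and the strong-binder
  docking tail. They are the ground truth for the recovery checks: across 20
  seeds, ≥90% of planted components must land in the HCGSC and a planted
  component must reach the TRI top 3 in ≥90% of runs.
- **Doses** are log-normal(0, 1); the distributional family is a modelling
  convention (real dose tables come from chromatographic quantification and
  publish no distribution), chosen for its positive support and right skew.
- **DEG list and annotation** are sampled directly: 25% of targets plus a
  tranche of off-target disease genes; 40 GMT terms of 10–60 genes drawn from
  the target universe, the first three biased toward DEG genes. No count
  matrix is simulated — differential-expression calling is upstream of this
  package's scope.

What the generator does *not* emulate: real chemical descriptor covariance,
gene-identifier semantics (targets are synthetic symbols `T0001…`), term
hierarchies or inter-term correlation in the annotation, docking-pose
geometry, and any directionality of regulation. Passing the recovery tests
therefore shows the pipeline's internal consistency and sensitivity to
planted dose/topology/affinity signal — not predictive validity on real
pharmacology, which requires real inputs (the stage commands accept them as
plain TSV).

## Problem sizes used in tests and the acceptance script

Unit and property tests run on toy graphs (≤ 12 nodes, checked against
exhaustive path-enumeration and draw-enumeration oracles) and on the
default-scale generator. The Monte-Carlo checks (common-vs-unique degree,
planted-core recovery, TRI top-3) share one sweep of 20 seeded replicates at
the default scale; `scripts/acceptance.py` re-runs the same 20-replicate
sweep plus one fully reported pipeline pass, about five minutes on one CPU.

## Known limitations

- The SCD and CDI models are semi-quantitative rankings, not effect-size
  estimates; their absolute values have no units and depend on the
  betweenness normalisation convention (applied consistently here).
- The undirected network ignores activation/inhibition, and the balance term
  collapses to 1 for every single-herb chemical, so formulas with no shared
  chemicals derive no discrimination from it.
- The ORA universe defaults to all annotated genes in the supplied GMT; with
  query sets approaching the universe size (as happens for the full HCGSC
  target set on the synthetic annotation), little or nothing is significant —
  the informative use is on focused query sets.
- Whether the 95% HCGSC threshold should be treated as fixed or tuned per
  study is left to the user; it is exposed as `--cum-threshold`.
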