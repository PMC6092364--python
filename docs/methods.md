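# Methods

## Model representation and I/O

A `MetabolicModel` holds the signed stoichiometric matrix S (n×m), a binary
reversibility vector r, flux bounds lb/ub in mmol/gDW/h, a 0/1 objective
indicator c, and optional pathway/compartment annotations. SBML (L3 + fbc)
and BiGG-style JSON are read through cobrapy; a minimal three-file TSV format
(stoichiometric triplets, reaction attributes, metabolite attributes) is
defined for fixtures and round-trips bit-exactly (floats written with
shortest-unique formatting). Boundary species (SBML `boundaryCondition` or a
`_b` suffix) sit outside the mass balance and are dropped from S; exchange
pseudo-reactions are kept as ordinary columns. For models read from files,
r_j = 1 iff the lower bound is negative (cobrapy folds the SBML reversible
flag into the bounds on read).

`load_e_coli_core()` returns the core *E. coli* model from the copy
distributed with cobrapy (72 metabolites, 95 reactions after dropping
boundary species) and restores two features of the canonical COBRA
distribution that the bundled SBML omits: the 20 exchange reactions are
marked reversible — in the original distribution their bounds are open, and
with them the unfolding yields the canonical 154 direction nodes
(95 + 59) — and the 11-pathway subsystem annotation, shipped as a
transcribed plain-text table (`data/e_coli_core_subsystems.tsv`). FBA bounds
themselves are left exactly as distributed.

## Flux balance analysis

`solve_fba` maximises cᵀv subject to S v = 0, lb ≤ v ≤ ub using scipy's
HiGHS dual simplex (feasibility/optimality tolerances 1e−9), which returns a
reproducible vertex of the flux polytope. Infeasible and unbounded problems
return a typed status, never a silent zero vector. FBA optima are generally
degenerate; an optional second stage (`minimize_total_flux=True`) minimises
Σ|v| at the fixed optimal objective and records the mode in the solution.
The default is the single-stage solution; for the core-model scenarios used
here the two stages coincide.

Four built-in growth scenarios cover the standard core-model environments.
Each keeps the distributed defaults for every exchange it does not mention
(rich media) and sets any available carbon uptake to 18.5 mmol/gDW/h:
aerobic glucose; aerobic ethanol (glucose shut off); anaerobic glucose
(oxygen intake capped at 0); and aerobic glucose with ammonium and phosphate
intakes capped at 4.5 and 3.04 mmol/gDW/h (half the unrestricted levels).
Limited intakes are encoded as caps (exchange lower bound = −u), the
standard FBA encoding of a restricted nutrient; the exact exchange set of
the ethanol scenario is not canonical, so results there should be treated as
scenario-sensitive.

## Graph constructions

All constructions share the unfolded system S₂ₘ = [S, −S·diag(r)] with
production/consumption splits S⁺/S⁻ and per-metabolite totals w⁺, w⁻.
Reverse columns of irreversible reactions are identically zero and are
excluded from graph node sets, so the NFG of the core model has
95 + 59 = 154 nodes. Pseudoinverses of diagonal matrices take reciprocals of
non-zero entries and leave zeros, so metabolites lacking a producer or a
consumer contribute nothing rather than breaking normalisation.

Numerical conventions that affect reported counts:

* Edge weights below 1e−15 are not stored (`EDGE_THRESHOLD`, configurable).
* MFG direction nodes with flux below 1e−9 × max|v| are pruned
  (`FLUX_PRUNE_REL`): LP solvers return numerical dust, and zero-flux
  reactions carry no mass. Self-loops are kept — they are the flux of
  autocatalytic reactions.
* Edges between the forward and reverse directions of the same reaction are
  kept when the formulas produce them.
* Undirected edge counts include self-loops; the RAG census of the core
  model (1,158) is 1,063 reaction pairs plus 95 self-loops.

`average_graphs` averages an ensemble of same-semantics graphs over the
union of their node sets, treating absent edges as zero — the operation used
to aggregate per-objective mass flow graphs into a condition-level graph.

## PageRank

The teleported transition matrix is B = λM + (1/N)[(1−λ)I + λ·diag(a)]11ᵀ
with M the out-strength-normalised walk (dangling out-strengths set to 1,
their rows fully teleported via the indicator a) and λ = 0.85 by default —
the damping is not canonical for these graphs, so it is configurable, and
the same value is used inside Markov Stability for consistency. The score
vector is the stationary distribution, computed by power iteration to an L1
residual of 1e−12 (cap 1e5 iterations; failure raises with the residual).
Percentiles use average-rank tie handling; each direction node of a
reversible reaction gets its own score. Pathway scores are plain sums of
node scores per subsystem label.

## Markov Stability

The diffusion is the continuous-time teleported process with rate matrix
I − B; its transition kernel is P(t) = e^{−t(I−B)}. A partition H is scored
by the clustered autocovariance R(t, H) = Hᵀ(Π P(t) − ππᵀ)H and its trace
r(t, H). With this orientation the one-community partition scores exactly 0
for every t, the all-singleton partition scores 1 − Σπᵢ² at t = 0, and
r → 0 as t → ∞. The trace only depends on the symmetric part of the kernel,
so optimisation runs on (X + Xᵀ)/2.

Optimisation is generalised Louvain: sweeps over nodes in seed-shuffled
order taking the best strictly-improving move (ties to the lowest community
index), aggregation, and repeat; after convergence, leaf-level sweeps over
the original nodes (re-aggregating after each) run until the objective stops
improving. Plain Louvain never revisits individual nodes after aggregation;
the refinement recovers most of that lost objective and empirically lowers
the ensemble VI. Everything is deterministic given the seed. The matrix
exponential is computed densely (scaling-and-squaring) once per Markov time;
this is comfortable up to a few thousand nodes, the scale of the graphs the
package targets.

Robustness of a partition is assessed two ways, following standard practice:

* VI(t): mean normalised variation of information across ℓ independent
  Louvain runs at the same t (ℓ = 100 by default). VI is normalised by
  log n, making it a [0, 1] metric on partitions.
* VI(t, t′): VI between the best partitions at different times. A scale is
  flagged robust when VI(t) < 0.05 **and** the mean of VI(t, t′) over a
  5-grid-point diagonal block around t is ≤ 0.05. Block-averaging (rather
  than requiring every pairwise value to clear the threshold) tolerates a
  single noisy optimisation inside an otherwise persistent plateau; both
  thresholds are configurable, since scale selection is ultimately a
  judgement call.

The default time grid is log-spaced over [1e−2, 1e2]. For the core-model
analyses we use 200 grid points: observed plateaus are as narrow as
~0.05 decades, and a coarser grid under-samples them relative to the
5-point detection window.

## Synthetic data

`toy_network()` is a hand-written 8-reaction, 5-metabolite network with the
canonical anatomy of a metabolic model — nutrient uptake, intermediate
biosynthesis, one reversible interconversion (R4), waste secretion, and a
biomass sink R8 consuming X3 + 2 X4 + X5. The stoichiometry beyond those
anchoring facts is this package's own construction.

`random_model(spec)` draws sparse stoichiometries with small integer
coefficients; every reaction consumes and produces at least one metabolite,
and (by default) every metabolite is guaranteed a producer and a consumer
after unfolding — where coverage is missing, one touching reaction is marked
reversible, which adds capability without disturbing the rest of the row.
This is the regime in which the NFG weights sum to exactly 1, and it is what
the property suite exercises. `random_balanced_flux` returns a random vertex
of {S v = 0, lb ≤ v ≤ ub} (random seeded LP objective), so generated fluxes
are balanced to solver precision and feasible even under irreversibility.
Some random stoichiometries admit only the zero steady state; those raise
rather than returning a degenerate flux.

What the generator does *not* emulate: realistic pathway structure, pool
metabolites with hub-like degree, biologically meaningful bounds, or
thermodynamic consistency. Passing property tests on these fixtures
establishes algebraic correctness of the constructions (normalisation,
conservation, oracle equivalence), not biological validity on real models —
that is what the *E. coli* core analyses are for.

## Known limitations

* FBA optima can be degenerate; a different optimal vertex changes the MFG's
  edge set. The minimum-total-flux mode pins a canonical representative, but
  published flux distributions obtained with other solvers may still differ.
* Community detection at coarse Markov times can be glassy: near-degenerate
  optima with different community counts keep VI(t) high even with 100
  restarts, and no partition is flagged robust there. The robust-scale lists
  should be read alongside the VI(t) curve, not as ground truth.
* At very large Markov times the autocovariance kernel decays to numerical
  noise and the optimiser returns arbitrary partitions; these show up as
  high-VI tails and are never flagged robust.
* Ethanol-scenario exchange composition is under-specified (see above).
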