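# Methods

## Model representation and conventions

A metabolic network is a set of metabolites `base[compartment]` (reserved
codes: `c` cytosol, `m` mitochondria, `e` extracellular, `lu` gut lumen,
`g` golgi, `l` lysosome, `n` nucleus) and reactions with a signed
stoichiometry map (negative = consumed), flux bounds, an optional boolean
GPR rule, and a subsystem label. Steady state is `S·v = 0` with
`lb ≤ v ≤ ub`; fluxes are labelled mmol·gDW⁻¹·h⁻¹ (the unit string is a
label and is never rescaled — community outputs may be relabelled, e.g. to
mol·gDW⁻¹·day⁻¹, without changing numbers).

Exchanges are written `m →` (coefficient −1) on boundary compartments
(`e`, `lu`): negative flux is uptake, positive flux is secretion. Sinks are
unconstrained supply/removal pseudo-reactions, demands removal-only.
Default bounds: irreversible [0, 1000], reversible [−1000, 1000]; applying
a medium sets each listed exchange's lower bound to minus its uptake value
(default 1.0) and closes the lower bound of every unlisted exchange,
leaving secretion untouched.

Boolean GPR rules are parsed by a small recursive-descent grammar
(`or` over `and` over parenthesized atoms). Evaluation: AND = conjunction
(enzyme complex), OR = disjunction (isozymes), empty rule = `True`,
genes missing from the state map = `False` (conservative knockout
semantics). The same AST folds gene activities into reaction scores with
AND→min, OR→max.

Consensus merging takes the union of the drafts' reaction sets minus
reactions unique to a designated draft; entry-level data (stoichiometry,
bounds, GPR) come from an optional template model, otherwise from the first
draft carrying the reaction, and disagreement on stoichiometry between
drafts is an error, never a silent pick. The lumen module adds, per
extracellular metabolite, the `[lu]` species, a reversible apical transport
and a lumen exchange; it is idempotent and each added transport conserves
mass.

## LP engine

All LPs solve with HiGHS through `scipy.optimize.linprog`. FBA maximizes
`c·v`; FVA solves two LPs per reaction, optionally under
`c·v ≥ fraction × optimum`. The feasibility/direction tolerance is 1e−6
everywhere (argument-exposed). FVA's `fraction_of_optimum` defaults to 0
for exchange-direction analyses (the full flux capability of the network)
and is irrelevant for knockout screens because the screened target is the
objective itself. A reaction is blocked when its unconstrained FVA interval
is within tolerance of zero on both sides; since a blocked reaction carries
zero flux at every feasible point, removing blocked reactions cannot block
anything else, so one pass reaches the fixpoint. Knockout records report
(WT−KO)/WT on the target's flux maximum; WT = 0 is flagged undefined rather
than coerced, and an infeasible knockout submodel counts as complete loss
(KO = 0, ratio 1).

## Validation protocol

A metabolic task closes all exchange and sink lower bounds, grants each
input at an uptake bound of exactly 1 (through its existing
exchange/sink, or a dedicated supply sink if it has none), then adds one
sink per product and maximizes each product sink in sequence; the task
passes when every product exceeds 1e−6 flux. Multi-output tasks must
achieve each product individually. Tasks never mutate the input model.

Sanity checks: the **leak test** closes every boundary reaction in both
directions and probes a temporary demand per metabolite — any demand able
to carry flux marks mass created from nothing. The **energy tests** close
everything except water (optionally also oxygen), maximize the
ATP-hydrolysis demand (located by id or by its ATP+H2O→ADP+Pi signature)
and require a zero optimum; a second variant reverses the ATP demand and
re-runs the leak test, counting only leaks *introduced* by the reversal
(pre-existing leaks belong to the leak test proper). **Flux consistency**
requires no blocked reactions on the open model.

## Context extraction

Expression preprocessing follows the standard recipe: the cutoff is the
linear-interpolation percentile (default 30th) over all matrix entries;
ubiquity = fraction of samples strictly above the cutoff; gene activity =
per-gene median across samples, 0 below the cutoff and log2 otherwise
(values equal to the cutoff count as expressed; activities clip at 0).
Reaction scores fold activities through GPRs; the **high set** is score
strictly above the median of the non-zero scores (an exposed threshold —
the partition rule is this package's choice), the **low set** is score 0
with a non-empty GPR, and everything else is unscored.

The iMAT MILP maximizes `Σ_{i∈high}(y⁺_i + y⁻_i) + Σ_{i∈low} x_i` subject
to `S·v = 0`, bounds, activation constraints
`v_i + y⁺_i(lb_i − ε) ≥ lb_i` and `v_i + y⁻_i(ub_i + ε) ≤ ub_i`
(plus `y⁺_i + y⁻_i ≤ 1`), and suppression constraints
`lb_i(1 − x_i) ≤ v_i ≤ ub_i(1 − x_i)`, with ε = 1.0 flux units (the classic
choice). The context model keeps unscored reactions, high reactions with an
active binary in the returned optimum and unsuppressed low reactions, then
prunes newly blocked reactions. iMAT optima need not be unique; membership
follows the single optimum HiGHS returns, which is deterministic for fixed
inputs, and the MILP objective is verified against exhaustive binary
enumeration in the tests.

## ACHR sampling

Warmup points are the FVA extreme flux vectors (two per reaction, capped at
min(2·n, 2000)); the running center starts at their mean and is updated as
the mean of all visited states. Each step draws a random warmup point,
takes the direction from the current center to it, computes the feasible
step interval from the box bounds and moves a uniform random distance;
every `thinning`-th state (default 1000) is recorded. Directions are
differences of feasible points, so all states satisfy `S·v = 0` exactly up
to floating-point drift; a least-squares reprojection every 1000 steps
removes the drift (observed ~1e−12). A degenerate single-point polytope
returns that point with a warning. Seeded `numpy` Generators make runs
exactly reproducible.

## Disease statistics

Each sample is integrated separately (per-sample cutoff by default; a
global-cutoff mode exists). Group tests are equal-variance two-sample
Student's t-tests at α = 0.05 with no multiplicity correction in the
headline call — a Benjamini–Hochberg-adjusted column is always emitted
alongside. Degenerate zero-pooled-variance comparisons report p = 1 when
the means agree and p = 0 (infinite t) when they differ, both flagged.
FVA-maxima tests cover only reactions present in ≥ 2 context models per
group; maxima are compared (minima are reported but not tested).

Knockout volcano coordinates are `log2(disease mean / healthy mean)` of the
per-sample (WT−KO)/WT ratios against the t-test p-value; genes absent from
a context model contribute ratio 0 for that sample. A zero healthy mean
with a positive disease mean has no sign-stable finite coordinate and is
flagged `undefined` and excluded from plot tables (the outlier rule); the
symmetric zero-disease-mean case is kept as −inf with an `infinite` flag so
fully disease-silenced genes remain reportable with a correct sign.

Direction consistency compares measured medium concentration changes
against exchange FVA: a concentration fall is observed uptake and needs a
negative FVA minimum, a rise is observed secretion and needs a positive FVA
maximum; percent change is (before − after)/before. A bundled reference
panel of Caco-2 spent-medium metabolomics with matching exchange flux
ranges drives the packaged example (acetate falls 53.9%, classified
uptake-consistent; histidine is the panel's one inconsistency).

## Community model

Members are namespaced `taxon__reaction`; each member exchange whose
metabolite has a luminal counterpart becomes a coupling reaction
`member_species → a_i · m[lu]`, so the community-level flux of member *i*
is its abundance times its member-level flux (abundances are normalized to
sum to 1). Diet applies uptake bounds to the lumen exchanges only; the
host's serosal (blood-side) exchanges keep their medium. The cooperative
tradeoff runs in stages: (1) maximize community growth `Σ a_i μ_i`;
(2) constrain it to `tradeoff_fraction` (default 0.5) of the optimum and
maximize host biomass maintenance; (3) optionally fix the host optimum and
minimize `Σ μ_i²` (SLSQP warm-started from the stage-2 vertex; on failure
the stage-2 solution is kept). The staging order and the default fraction
are this package's design choices; each stage is optional. Exchange
accounting sums abundance-weighted member secretion/uptake per lumen
metabolite and reads host uptake/secretion off the host's lumen transport;
the percentage of production taken by the host is defined only when the
community secretes above tolerance and is clipped to [0, 100] (diet inflow
can otherwise let the host take up more than the members produced).

## Synthetic study design

The toy template (41 reactions, 33 metabolites, 33 genes, compartments
c/m/e/lu) is built to make every example hand-checkable: lumped glycolysis
(2 ATP + 2 lactate per glucose), lumped mitochondrial β-oxidation with
fixed integer ATP yields (butyrate 5, acetate 2, propionate 3), a lumped
lactate respiration, an ATP-hydrolysis demand, and a biomass-maintenance
objective consuming one precursor + one ATP. The precursor is producible
through two disjointly gene-controlled routes: a tryptophan-like route
(capacity 10; the planted disease-relevant pathway, genes `g_p1..3`) and a
glutamine route (capacity 4; `g_q1..2`), so the wild-type optimum is 14 and
knockout effects are exact rationals (10/14 for planted genes, 4/14 for the
glutamine route). Cytosolic ADP/phosphate sinks keep the adenylate moiety
open (otherwise mitochondrial ATP import would be frozen by strict moiety
conservation); all closed-model protocols shut these sinks, so the leak and
energy tests retain their meaning.

Expression uses three baseline tiers — expressed 150, intermediate 50,
off 2 — with multiplicative log-normal noise (σ = 0.25) and a planted
fold-change (disease mean = healthy mean × 2^−fold, default fold = 2, i.e.
37.5). The tier design pins the within-sample 30th-percentile cutoff inside
the intermediate tier (~45–60), cleanly between disease-planted and healthy
expression. Intermediate genes are redundant OR-isozymes on reactions that
also carry an expressed gene, so their binarization flicker cannot change
any context model's flux capability; off-tier genes control a decoy pathway
excluded everywhere. This makes planted-pathway exclusion nearly
deterministic at the default noise while keeping the null configuration
(fold = 0) stable — the property the recovery and type-I acceptance checks
quantify over 20 seeded replicates at 5 vs 5 samples.

Toy microbes ferment luminal glucose to one SCFA each with growth coupled
to fermentation; abundances are Dirichlet-drawn and seeded. The 20-task
suite contains 18 tasks feasible by construction (including SCFA
β-oxidation to ATP) and 2 negative controls, giving a 90% ground-truth pass
rate.

What the synthetic study does *not* emulate: realistic transcriptome
marginals or dropout, GPR complexity at genome scale, thermodynamic
constraints, or inter-sample correlation. Passing the recovery checks shows
the pipeline's statistics faithfully propagate a planted signal of
realistic size through extraction, FVA and knockout screens — not that real
IBD effect sizes are detectable at n = 5.

## Problem sizes and numerical choices

Oracle batteries use ≥ 50 random networks (≤ 6 reactions) for the LP/vertex
check and 20 instances (≤ 6 scored reactions) for the iMAT/enumeration
check; the sampler check draws 5000 samples (thinning 10) on a 2-D box
polytope; the recovery study runs 20 replicates per configuration at 5 vs 5
samples. These sizes make the whole battery run in a couple of minutes on
one CPU while keeping every Monte-Carlo margin wide. Tolerances: 1e−6
(feasibility, direction, task threshold), 1e−9 solver-side bound slack in
the L2 stage. Ties: values equal to the expression cutoff count as
expressed; reaction scores equal to the high threshold stay unscored.

## Known limitations

No loopless/thermodynamic constraints; FVA-maxima statistics inherit the
non-uniqueness of alternative optima (mitigated by comparing maxima, which
are unique, rather than flux vectors); iMAT membership depends on the
solver's returned optimum among possibly many; the L2 community stage is a
local QP solve warm-started from an LP vertex; SBML round-trips preserve
ids, bounds, GPRs, objectives and subsystems but not annotation metadata.
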