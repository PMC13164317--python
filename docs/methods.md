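# Methods

`nbhub` implements a hub-discovery and annotation workflow for the protein
neighborhood of a membraneless organelle (the motivating case is PML nuclear
bodies and the deubiquitinase USP7). The pipeline consumes static snapshot
files — interaction tables, proteome lists, gene-set libraries, predictor
scores — and produces overlap matrices, a hub table, a clustered hub
network, enrichment statistics, and per-protein condensation/disorder
annotations. This note records the models, the parameters that matter, and
the design choices made where the procedure was genuinely open.

## Evidence model and the hub rule

An interactome is a focal protein's partner set with per-pair **evidence
counts**. Evidence is defined as the number of *distinct (publication,
experimental system)* records supporting a pair: duplicated rows never
inflate it, and counting is invariant to row order. Interaction databases
expose several related "evidence" notions; this definition is the one the
package commits to, and it is printed in every run report.

A candidate protein's **qualifying-core count** is the number of core
interactomes that still contain it after partners with evidence <
`evidence_min` are removed. Candidates with count ≥ `k_min` are **hubs**.

Defaults: `k_min = 4`, `evidence_min = 2`. One or two core associations are
weak evidence of organelle residency, and a threshold of three remains
dominated by single-record support and by any core with an anomalously large
interactome (TP53-scale, >2500 partners); raising `k_min` to 4 — rather than
excluding such cores — is the package's default posture, and
`hub_sensitivity` exposes the full (k, evidence) grid so the choice is
inspectable. Hub counts are provably non-increasing in both thresholds,
which the tests assert on the grid. Core proteins themselves are excluded
from the candidate universe by default (`exclude_cores_as_candidates`),
since the rule is about *partners* of the cores; a flag restores them.

## Hub network and topology

Nodes are the hubs plus the core proteins; an edge requires evidence ≥
`evidence_min` somewhere in the supplied snapshots. When a pair occurs in
several snapshots the **maximum** evidence count is kept: snapshots overlap
in their underlying records, so summing would double-count. The graph is
simple and undirected; self-loops cannot occur by construction.

The topology summary reports average clustering C, characteristic path
length L on the largest component, and a small-world coefficient

    sigma = (C / <C_rand>) / (L / <L_rand>)

against a degree-preserving rewired ensemble (double-edge swaps, 10 swaps
per edge, `rewires` replicates, seeded). sigma > 1 indicates small-world
structure. sigma is null for graphs under 4 nodes or when rewiring
degenerates; the default ensemble size (20) trades precision for runtime
and is configurable.

## MCODE

Clustering uses a from-scratch MCODE implementation:

1. **Weighting.** Each vertex v is scored on its closed neighborhood N[v]:
   find the highest k-core of the induced subgraph, then
   weight(v) = k × density(core). Vertices with degree < `degree_cutoff`
   get weight 0. Density is 2E/(V(V−1)) for V ≥ 2, else 0.
2. **Expansion.** From the highest-weight unassigned vertex, neighbors join
   while their weight exceeds (1 − `node_score_cutoff`) × seed weight and
   they lie within `max_depth` of the seed; a vertex joins at most one
   complex at this stage.
3. **Post-processing.** Complexes lacking a `k_core`-core are discarded.
   Optional *fluff* adds boundary vertices whose closed-neighborhood density
   exceeds `fluff_density_cutoff` (fluffed vertices may be shared); optional
   *haircut* then removes singly connected members in one pass. If the
   haircut removes the seed, the heaviest surviving member is recorded as
   seed so the seed-membership invariant holds.

Complexes are ranked by score = density × size. All ties — seed order,
neighbor visitation, ranking — break lexicographically by vertex label, so
identical inputs give identical ordered output. Defaults match the standard
parameterization: degree cutoff 2, node score cutoff 0.2, k-core 2, max
depth 100, haircut and fluff off. Clustering runs on the unweighted simple
graph (the algorithm's standard setting); edge evidence is carried as an
attribute but does not influence clustering.

On planted-partition benchmarks MCODE recovers blocks cleanly when block
densities (hence vertex weights) separate by more than the node-score
cutoff; blocks of near-equal weight joined by stray edges can merge — a
property of greedy seeded expansion, not of this implementation. The fixed
benchmark instance used in the tests (blocks 20/16/14/11, p_in = 0.9,
p_out = 0.02) is one where the size-induced weight separation suffices for
exact recovery.

## Enrichment statistics

For a query of size n in a universe of size N, a term of size K with
overlap k is scored by the hypergeometric upper tail P(X ≥ k), computed by
log-space summation of log-binomials (gammaln + logsumexp), exact to ~1e-14
relative against rational-arithmetic enumeration. Benjamini–Hochberg
adjustment runs across all terms of the library (delegated to statsmodels;
validated against a hand step-up oracle). Effect sizes:

* odds ratio on the 2×2 table (a=k, b=n−k, c=K−k, d=N−n−K+k), with the
  Haldane–Anscombe +0.5 correction applied iff any cell is zero;
* combined score c = −ln(p) × z with z = (k − μ)/σ from the hypergeometric
  null (z = 0 when σ = 0). Web enrichment platforms calibrate z against a
  rank-permutation background that is not reproducible offline; this
  package standardizes the observed overlap instead, and says so in the
  output metadata. p and adjusted p are the comparable quantities.

The default background is the library universe (a user override is
supported); query genes outside the universe are dropped, not added to N.
Because the p-values are discrete, the global-null probability of any BH
discovery at 0.05 is *below* 5% (about 1.5–2% on the synthetic null); the
calibration tests therefore assert Type-I control as an upper bound.

## Condensation and disorder classifiers

Thresholds, with strictness exactly as documented by the predictors:

| rule | threshold |
|---|---|
| granule propensity (catGRANULE-style) | LLPS iff score > 0.5 (strict) |
| three-band classifier (PSPHunter-style) | likely iff > 0.61; non-LLPS iff < 0.36; endpoints → "unlikely" |
| two-predictor consensus | LLPS iff sequence score > 0.5 AND condensation score > 0.6; both fail → non-LLPS; exactly one → *controversial* |
| driver | pLLPS ≥ 0.60 (inclusive) |
| client | not a driver, and a run of ≥ `min_region_length` consecutive residues with pDP ≥ 0.60 (inclusive) |
| PPIDR | 100 × fraction of residues with disorder score > 0.5 (strict) |
| disorder class | < 10% highly ordered; 10–30% (inclusive) moderately disordered; > 30% highly disordered |

`min_region_length` defaults to 10 residues: droplet-promoting regions are
defined only as "consecutive residues" by their source, and a one-residue
region is biologically meaningless; the parameter is exposed and recorded
in the report rather than hidden. Missing scores always yield `unknown`,
never a default class, and unknowns are excluded from summary counts.
SUMO/ubiquitin flags are tri-state inputs (true/false/unknown) read from an
annotation table; no site prediction is attempted.

GRAVY is the mean Kyte–Doolittle hydropathy (scale bounded in [−4.5, 4.5]);
non-standard residues are a hard error naming the position. Net charge at
pH is a Henderson–Hasselbalch sum over the termini and D/E/C/Y/H/K/R side
chains using the EMBOSS pKa set shipped as `data/pka.tsv`; published pKa
tables differ by a few tenths, which shifts charge estimates slightly but
never the ordering in pH.

## Synthetic data: what it emulates, what it does not

The generators are pure functions of (spec, seed) and write byte-identical
files on reruns. The default spec mirrors the target study shape: 10 core
interactomes, 61 planted hubs, 500 decoys, evidence counts from a truncated
geometric (most pairs 1–3 records, long tail), deliberate duplicate rows,
a 205-protein organelle proteome list, two aging gene lists seeded with
part of the focal-pair overlap, a 4-block planted cluster graph, one
planted enriched term, and per-protein scores sampled on the correct side
of every threshold above (with a margin, so float round-trips cannot flip
a label). Every planted structure is recorded in `ledger.json`, and
re-deriving labels from the files reproduces the ledger exactly.

What the generator does *not* emulate: scale-free degree structure,
correlated evidence across cores, organism/throughput metadata beyond
pass-through columns, homology-driven symbol ambiguity, or realistic
gene-set nesting. Passing tests therefore demonstrate algorithmic
correctness on controlled inputs — exact hub recovery, calibrated
enrichment, faithful classifier boundaries — not robustness to the noise
modes of live databases. Problem sizes (561 candidates, ~76-node cluster
benchmark, 100 + 200 calibration runs) are chosen so the whole suite runs
in about a minute while keeping every planted effect far from chance.

## Determinism

Every output iterates in sorted order; the JSON report sorts keys; GraphML
inserts nodes and edges sorted; all tie-breaks are lexicographic. The
contract — identical (inputs, config, seed) gives byte-identical outputs —
is asserted end to end in the tests.
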