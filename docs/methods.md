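# Methods

This note documents the models and procedures `inflamnet` implements, the
parameter defaults and why they were chosen, what the synthetic generators
do and do not emulate, and the numerical choices that affect results.

## Problem setting

CAR T-cell engagement with its target tumor releases T-cell–derived
cytokines (IFN-γ, IL-2, GM-CSF, TNF, IL-15) that activate macrophages and
vascular endothelium; the resulting myeloid and endothelial programs (IL-6,
IL-8/CXCL8, MCP-1/CCL2, VEGF, …) drive cytokine release syndrome and
neurotoxicity. The package asks two computational questions about an
in-vitro model of this axis:

1. Which intracellular mediators are topologically positioned to control the
   flow from measured upstream cytokines to measured downstream cytokines in
   a cell-specific signaling network?
2. Do measured secretion profiles show the expected dose dependence on
   CAR T-cell exposure and the expected (non-)response to treatment?

## Network arm

### Identifier handling and merging

Node identifiers are matched case-insensitively by exact string; no
alias/synonym resolution is attempted, because any mapping table would
import hidden state that the analysis could not audit. Merging is plain set
union of nodes and edges with provenance labels accumulated per source
network. Role tags (ligand / receptor / secondary-messenger /
transcription-factor / other) reconcile to the most specific role; a
conflict between two specific roles resolves to the lexicographically
smaller one deterministically and is logged and recorded on the merged
network — such conflicts indicate curation disagreement between source
models and deserve inspection. Self-loops are dropped at load time with a
logged count: simple paths can never traverse them and they distort degree
centrality.

SIF dialect: tab- or whitespace-delimited fields are accepted on read
(both occur in the wild); tabs are emitted on write, in sorted line order so
outputs are byte-reproducible. Single-field lines are honored as lone-node
declarations (part of the Cytoscape format, and required for the read/write
round trip to preserve node sets exactly).

### Simple-path pruning

A simple path is a directed path with no repeated node. The pruning step
enumerates **all** simple paths from any panel input to any panel output
with at most `max_nodes = 8` total nodes (7 edges). The cap counts nodes,
including both endpoints, since "depth of 8 nodes" is only coherent with
node count as the unit; an edge-count convention is available via
`count_mode="edges"` for sensitivity analysis. Enumeration is an iterative
depth-first search with explicit stack and on-path membership set, so
correctness never depends on the Python recursion limit; with sorted
successor lists the emitted order is lexicographic and runs are
reproducible byte for byte. Panel mediators may appear mid-path of a
different input→output pair — the simple-path definition does not forbid
it, and excluding them would silently delete biology.

The induced subnetwork keeps exactly the path-traversed edges, **not** the
full node-induced subgraph: a shortcut edge between two retained nodes that
lies on no admissible path would re-admit signaling the pruning was meant to
remove.

### Expression filtering

A node is called expressed in a cell type when its abundance strictly
exceeds `threshold = 1.0` in normalized-TPM-like units — the conventional
"expressed" call for Human Protein Atlas-style RNA data; the value is
configurable because the original analysis states no cutoff. Nodes absent
from the expression table count as unexpressed and are dropped with a
logged count (prior-knowledge networks always contain identifiers missing
from any one expression dataset; the count makes the loss visible). Panel
mediators are retained regardless of expression: they are measured
extracellular species, and dropping a cytokine because the profiled cell
does not transcribe it would disconnect the anchors of the pruning step.
The pipeline order is prune → filter, matching the narrative order of the
analysis it reimplements; `order = "filter-prune"` is available for
sensitivity analysis (the two orders agree only in trivial cases).

### Topology metrics

All metrics run on the simple-digraph view: parallel edges differing only in
interaction label collapse to a single adjacency.

- **In/out-degree centrality**: `k_in/(n−1)`, `k_out/(n−1)`.
- **Closeness**: incoming-distance convention — a node is central when
  signals reach it quickly — with the Wasserman–Faust correction for
  disconnected graphs, `C(v) = ((r−1)/(n−1))·((r−1)/D)` where `r` nodes
  reach `v` at total distance `D`; unreached nodes score 0.
- **Eigenvector**: in-edge (left-eigenvector) convention — an influential
  mediator is one that central nodes point into. Power iteration converges
  when successive iterates differ by less than `tol·n` in L1; scores are
  L2-normalized. Signaling networks are nearly acyclic, where undamped
  eigenvector centrality is ill-defined (dominant eigenvalue 0); on failure
  a uniform `0.15/n` is added to the iteration matrix (a small teleport
  term) and the retry is flagged `damped=True` on the result. Persistent
  failure raises a convergence error carrying the iteration trace rather
  than returning silently.
- **VoteRank**: votes flow along edge direction (a node is voted for by its
  in-neighbors' voting ability); the highest-scoring unelected node is
  elected each round, its ability zeroed, and its in-neighbors' ability
  reduced by `1/⟨k_out⟩`, floored at 0. Election stops when all remaining
  scores are 0. Note that networkx's directed `voterank` implements the
  opposite (spreader / out-edge) convention; the two agree on mutually
  reversed graphs, which is how the implementation is cross-checked.

**Aggregation** is the mean of ranks, not of scores — the five raw scores
live on incomparable scales. Continuous metrics are converted to descending
mid-ranks (ties share the mean of occupied positions); VoteRank election
positions are used directly as ranks, with unelected nodes sharing the mean
of the remaining positions. Ties everywhere break lexicographically by node
id for reproducibility.

## Secretion arm

### 4PL quantification

"Four-point sigmoidal" fitting is read as the four-parameter logistic model
`f(x) = d + (a−d)/(1 + (x/c)^b)` — the universal immunoassay calibration
model — with at least 4 distinct standard concentrations required as a
separate precondition. Ordinary least squares is the default (inverse-y²
weighting available); initialization is data-driven (`a` ← min signal, `d` ←
max signal, `c` ← geometric-mean concentration, `b` sign from the empirical
trend), with `c` bounded positive. A curve is accepted iff R² ≥ 0.95 on the
standards; back-calculation refuses rejected curves outright. Mean blank
signal, when blank wells exist, is subtracted before fitting (floored at 0).
Samples whose blank-corrected signal falls at or outside the open asymptote
interval are flagged `below-range`/`above-range` with no numeric
extrapolation — assay practice dilutes samples into the curve's reference
range, implying in-range-only quantification. Constant standard signals
raise a fit error (SS_tot = 0) rather than dividing by zero.

### Normalization and fold changes

Each measurement is divided by the mean of its on-plate control within its
analyte × experiment cell; control values map to mean 1 by construction, and
the operation is invariant to rescaling any experiment's raw values. A
missing control raises an error naming the orphan cell. TEER resistance
readings use the same machinery against the media control.

Log fold changes are `log2((mean_cond + ε)/(mean_baseline + ε))`. Base 2 is
the pathway-analysis convention (configurable). The default pseudocount ε is
half the smallest nonzero concentration in the dataset — it matters only
when zeros occur; for fold-change recovery on strictly positive data pass
`pseudocount=0`.

### Dose–response and group comparisons

Dose–response is the Pearson correlation of concentration against the
numeric effector:target ratio (1:5 → 0.2, 1:1 → 1, 5:1 → 5) across all
replicate observations, requiring ≥3 distinct doses; zero variance in either
variable yields an explicit `undefined` flag instead of NaN propagation.

Group comparisons are gated per analyte: Shapiro–Wilk on every group, and
only if all pass at α = 0.05 does the parametric branch run (one-way ANOVA,
Tukey HSD post-hoc); otherwise Kruskal–Wallis with Dunn post-hoc (the
standard nonparametric pairings). A group with zero variance cannot be
tested for normality and routes the analyte to the nonparametric branch; an
analyte with no variance anywhere returns a flagged non-result. Post-hoc
p-values are *additionally* Bonferroni-scaled by the number of post-hoc
comparisons in the analyte family (`min(1, m·p)`). Tukey already controls
the family-wise error rate, so this double correction is conservative; it is
implemented literally for fidelity to the procedure being reproduced, with
`bonferroni_posthoc=False` as the escape hatch. The normality gate is
decided per analyte across all its groups — the coarsest defensible unit.
By default all N×n wells enter the tests as observations (matching the
"n = 9" usage); averaging triplicates first is a caller-side aggregation.

## Synthetic data: what it emulates, what it does not

Nothing from the original study is deposited, so the generators create
structural stand-ins, not imitations of measured values.

- **Networks**: a layered ligand → receptor → secondary-messenger →
  transcription-factor → output architecture (5 inputs named for T-cell
  cytokines, 6 outputs for interface cytokines, 8/8/6 internal nodes),
  background layer-respecting edges at density 0.08, and optionally a
  planted transcription-factor bottleneck ("STAT3") wired from 12 upstream
  nodes into every output. The generator verifies post hoc that the planted
  node lies on strictly more admissible input→output simple paths than any
  other intermediate and raises otherwise. Edges are split into two
  overlapping "published" component models (35/35/30% A-only/B-only/both) to
  exercise merging. Real data differ in scale (thousands of nodes), in
  having no clean layering, and in identifier noise — a green recovery test
  establishes that the pipeline ranks a genuine bottleneck first, not that
  it would resolve curation conflicts in real databases.
- **Expression**: log-normal abundances (median ≈ 20 units) with a seeded
  dropout fraction zeroed per cell type; the planted mediator and panel are
  always expressed in their designated cell type. No attempt to model
  HPA-style normalization artifacts.
- **Plates**: 8-point, 2-fold standard series with top concentration 20× the
  4PL midpoint; per-analyte 4PL parameters (a∈[0.02,0.08], d∈[2.0,3.5],
  b∈[0.9,1.4], c near the analyte's baseline so samples fall in range);
  multiplicative log-normal noise at 3% CV per well. Replicate plates of a
  study share the scenario's programmed parameters and differ only in a
  noise seed.
- **Studies**: 27-analyte panel (the standard human inflammatory multiplex
  panel), baselines log-normal around 100 pg/mL-like units, conditioned
  media at dose d scaling dose-responsive analytes by (1 + slope·d) with
  slopes in [0.5, 1.5], LPS at 3× baseline and media at 0.2× baseline,
  treatment multiplying "responsive" analytes (IL-1β, IL-1ra, TNF-a, MIP-1a,
  MIP-1b, IL-10) by 0.2 while "refractory" analytes (IL-6, IL-8, MCP-1,
  VEGF, GM-CSF — the endothelial-type program) ignore it; remaining analytes
  have no dose effect. Replicate structure defaults to 3 independent
  experiments × triplicate, with an experiment-level log-normal scale
  (σ = 0.10) shared by all of an experiment's wells plus 3% technical CV.
  The generator does not model cytokine kinetics, analyte cross-reactivity,
  plate position effects, or below-detection censoring.

All generators are pure functions of (scenario, seed) using
`numpy.random.default_rng`; identical inputs give identical outputs, and
every generated artifact is accompanied by a ground-truth record so tests
never reach into generator internals.

## Numerical and engineering choices

- Determinism: sorted iteration everywhere, lexicographic tie-breaks,
  seeded RNGs; both pipeline arms are byte-reproducible under a fixed
  config, which is why the run manifest records the config dump, its
  SHA-256, the seed, and the package version but no wall-clock timestamp.
- Eigenvector convergence: `tol = 1e-10` (L1 change < tol·n), `max_iter =
  1000`, damping 0.15/n on fallback only; both the damped flag and the
  failure trace are surfaced.
- 4PL optimizer: `scipy.optimize.curve_fit` (trust-region with `c > 0`
  bound), `maxfev = 20000`; optimizer failure raises a fit error with the
  analyte named.
- Degenerate inputs are explicit outcomes, not crashes: empty path sets,
  networks too small to rank (< 2 nodes), constant groups, zero-variance
  dose vectors, and missing controls each produce a warning, a flagged
  result, or a named error as appropriate.

## Known limitations

- No identifier harmonization across source networks beyond case folding;
  real prior-knowledge models need gene-symbol mapping upstream.
- Path enumeration is exponential in the depth cap; the default cap of 8
  nodes is also the practical wall for dense networks.
- The double (Tukey + Bonferroni) post-hoc correction is conservative;
  interpret borderline significance accordingly.
- Experiment-level clustering is not modelled in the tests (no mixed
  effects); all wells enter as independent observations, as in the
  procedure reproduced here.
- The IPA pathway-enrichment step of the original analysis depends on a
  proprietary knowledge base and is out of scope; only its input
  transformation (baseline-normalized log fold changes in a two-column
  export) is provided.
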