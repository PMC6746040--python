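# Methods

## The model

`marrowmap` treats a flow-cytometry sample as a point cloud in the
space spanned by its fluorescence markers plus side scatter (SSC), and
normal bone marrow as a fixed geography in that space. The geography is
learned once from a merged cohort of healthy donors and then frozen;
every later sample — healthy or leukemic — is interpreted by where its
events fall on that fixed map.

### Preprocessing

1. **Compensation.** With spillover matrix S (row = source stain,
   column = detector) the observed fluorescences satisfy
   `observed = true · S`; compensation solves the linear system
   (`observed · S⁻¹`, implemented as a solve, never an explicit
   inverse). Spillover matrices with condition number above 1e12 are
   rejected as singular. Scatter and time channels are untouched.
2. **Transform.** Each fluorescence channel is mapped through
   `x ↦ arcsinh(x / c)` with cofactor `c = 150` (the usual conventional
   choice for PMT-based cytometers: linear near zero, logarithmic for
   bright signals). SSC is transformed the same way with `c = 10,000`
   so its much larger dynamic range lands on a scale commensurate with
   fluorescence. Forward scatter and time stay linear and are excluded
   from clustering by default (SSC carries the granularity information
   the display tradition uses; FSC can be opted in per panel).
3. **Selection and scaling.** The clustering space is all fluorescence
   channels plus SSC — 11 dimensions for a 10-color panel. Each
   retained channel is standardized by its median (robust location) and
   standard deviation, spread floored at 1e-6. These statistics are
   computed **once** on the merged normal cohort and stored in the
   template; patient samples are always scaled with the stored values.
   This frozen-scaling rule is what makes node identity comparable
   across samples: without it, a pathological sample would warp its own
   coordinate system.

### Batch self-organizing map

The SOM quantizes the scaled events into a `10 × 10` rectangular grid
(100 nodes), each node a codebook vector. Training is the batch
formulation — deterministic given a seed and independent of event
order:

* codebook initialized by seeded sampling of events without
  replacement;
* per epoch, every event is assigned to its best-matching unit (BMU,
  nearest codebook vector, Euclidean metric; ties to the lowest node
  id), then every codebook vector becomes the Gaussian-weighted mean of
  events assigned in its grid neighborhood
  (`w = exp(-d² / 2r²)`, Chebyshev grid distance `d`);
* the radius `r` decays linearly from half the grid diagonal (4.5) to
  1.0 over 10 epochs — this is the topology-forming phase that makes
  grid-adjacent nodes phenotype-adjacent;
* **refinement:** 3 further epochs at radius zero (plain Lloyd/k-means
  updates). During refinement an *empty* node may be recycled onto the
  single worst-quantized event when that event lies further than 4x the
  RMS quantization distance from its BMU (at most 2 recycles per
  epoch). This is the classic empty-cluster handling of k-means, with a
  conservative threshold: it gives rare, well-separated populations —
  the CD34/CD38 progenitor subsets at a few events per thousand — nodes
  of their own, while leaving most empty nodes where the neighborhood
  phase left them, *between* populations. Those interpolating nodes are
  load-bearing: they are the near-empty positions onto which aberrant
  (leukemia-associated) phenotypes fall at mapping time.

The recorded quantization error (mean squared BMU distance) is
non-increasing through the refinement phase: Lloyd updates never
increase it, and recycling an empty node can only capture events at a
shorter distance.

The trade-off behind the recycle threshold: at 4x RMS only gross
underfit triggers (a merged pair of distinct rare clusters sits ~7x RMS
out); aggressive settings (~1.5x) turn the refinement into ordinary
k-means, maximizing quantization quality but consuming the
interpolating empties.

### MST, layout, metaclustering

The minimal spanning tree is built over the complete Euclidean graph of
the 100 codebook vectors with Kruskal's algorithm; equal-weight ties
resolve in lexicographic `(node_a, node_b)` order, so the tree is
deterministic. The 2-D display layout is a seeded force-directed
embedding of the tree. Average-linkage metaclustering of codebook
vectors is available as a display aid; population assignment proper
goes through phenotype rules.

### Node phenotypes and rules

For every marker, the merged cohort's transformed intensity
distribution is cut at three quantile edges into `neg / lo / pos / hi`
bins; a node's level per marker is the bin of its median. The default
edges are the 20th/50th/80th percentiles. Markers positive on only a
small minority of marrow cells (CD34, CD117, CD56, CD19, CD123, HLA-DR,
CD7, CD14, CD16) carry upper-tail overrides (e.g. CD34 uses the 97.5,
98.8 and 99.7th percentiles): with a 98%-negative marker all three
default edges would fall inside the negative mode and the levels would
be noise. Edges are configurable per marker; the template stores a
201-point quantile grid per marker so bins can be re-derived from a
saved bundle without the original events.

Rules are conjunctions of `(marker, level)` clauses; a `pos` clause
accepts `pos` or `hi`. A node receives every matching label; identical
rule pairs are flagged as ambiguous. Node groups for display are
connected components of same-labeled nodes on the MST.

### Normal ranges and patient comparison

Per node, the occupancy fractions of the donor cohort give mean, min,
max and a spread used as the z-score denominator. Three corrections
keep that spread honest for a 19-donor cohort:

* the sample sd is replaced by its one-sided 95% upper confidence
  limit, `s · sqrt((n-1)/χ²₀.₀₅,ₙ₋₁)` (≈1.39x at n = 19) — standard
  tolerance-interval practice when reference ranges are estimated from
  few subjects;
* a per-node binomial counting floor `sqrt(p(1-p)/n_donor)` — a
  fraction measured from 10,000 events cannot be known better than its
  sampling error;
* an absolute floor of one event in the merged cohort, which keeps z
  finite (and very large) for nodes empty in every donor.

Without the first two corrections, a map whose largest population is
spread over ~45 nodes performs that many nearly independent z-tests per
sample with noisy denominators, and healthy samples are flagged at a
rate a z-threshold of 3 cannot control.

A patient sample is flagged **excess** at a node when `z > 3` and its
occupancy exceeds 0.05% (five events in a 10,000-event sample), and
**deficit** when a node that holds > 0.5% of normal marrow drops below
20% of its normal mean. The abnormal burden is the summed occupancy of
excess nodes in percent of all analyzed events; log2 fold changes use a
pseudocount of one event. All thresholds are parameters of
`Thresholds` and are printed in every report. Mapping and comparison
never modify the template (verified by content hash in the tests).

## The simulator: what it emulates, and what it does not

The generator draws each of 21 normal-marrow populations as a diagonal
Gaussian in transformed space (per-channel sd 0.30, SSC 0.22), using a
hand-authored phenotype table of qualitative levels
(`neg/lo/pos/hi` ↦ 0.2/1.6/3.2/4.4 arcsinh units). Frequencies are
realistic for adult marrow (45% neutrophils, 22% T cells, ~1.7% CD34+
progenitors, rare subsets at 0.4-1%). Donor-to-donor variation is a
Dirichlet draw around the base frequencies with concentration 150,
giving mid-size subsets a 25-35% coefficient of variation. Events are
inverse-transformed to the instrument scale, mixed through a mild
nearest-neighbor spillover matrix (6% forward bleed) and shuffled; FSC
is linear and correlated with SSC; a TIME channel is appended. Every
event keeps a hidden population-of-origin label that the analysis never
sees — it is used only by tests and purity diagnostics.

Blast spike-ins replace a random fraction of events. Two kinds are
provided: fixed aberrant phenotypes (CD34+ backbones with CD7 or CD56
co-expression), and template-guided blasts synthesized around the
emptiest nodes of a built reference (`blast_from_nodes`) — the
in-silico analogue of a leukemia-associated immunophenotype, which by
definition occupies marker-space regions that healthy marrow leaves
near-empty. The spike-recovery validation uses the latter; the former
land adjacent to normal progenitors and illustrate the harder,
contaminated scenario.

What the simulator does **not** emulate: autofluorescence and
acquisition drift, debris/doublets, heavy-tailed or skewed population
shapes, correlated marker noise (full covariance is supported but not
default), batch effects between donors, and instrument-specific channel
resolutions. Passing tests therefore demonstrate the correctness and
calibration of the machinery under clean, well-separated conditions —
not clinical sensitivity on real marrows.

## Numerical and design choices

* Euclidean distance everywhere (SOM, MST, metaclustering), in the
  frozen scaled space.
* BMU ties break to the lowest node id; MST ties lexicographically;
  all stochastic steps (sampling, initialization, layout, simulation)
  consume explicit seeds, and identical inputs + seed reproduce a
  byte-identical serialized template.
* Template bundles are plain CSV/JSON/YAML; floats are written with
  shortest-roundtrip repr and parsed with round-trip precision so a
  reloaded template reproduces assignments bit-exactly.
* Degenerate inputs: constant channels are floored and logged; empty
  nodes report undefined phenotype levels; a cohort of fewer than two
  samples is rejected, fewer than five warns.
* Problem sizes in the test-suite: the full study conditions (19
  donors x 10,000 events, 100 nodes) build in ~15 s on one CPU and are
  reused session-wide; unit tests run on 5 x 3,000-event cohorts.

## Known limitations

* One template per panel; no cross-panel node alignment.
* No batch-effect correction or outlier-donor rejection when building
  the reference — discordant donors widen the normal ranges instead.
* The deficit rule compares single nodes; a maturation shift that
  redistributes occupancy among neighboring nodes without emptying any
  single one is not flagged.
* Rule-based labels are only as good as the declared criteria; the
  bundled rule set encodes the simulator's phenotype table and is not
  a clinical gating standard.
* Hexagonal grids, online SOM training and GPU execution are out of
  scope.
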