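# Methods

## The problem

Probabilistic tractography is not deterministic: two runs of the same
workflow on the same diffusion MRI data yield different streamline sets,
hence different braingraphs. `braincons` implements the standard
robustification: repeat the tractography k times, keep only edges found
in *every* run, and average each surviving edge's weights after
discarding the extremal fiber counts. It also implements the analysis
used to choose k, and a stochastic simulator that stands in for real
tractography output so the whole pipeline is testable at desk scale.

## Consensus construction

Given k per-run graphs over a common node set (one node per
parcellation region):

1. **Collection.** For each unordered node pair, gather the per-run
   observations (fiber count, mean streamline length in mm, mean FA)
   from the runs in which the pair was connected. An edge exists in a
   run only if at least one streamline was found, so per-run counts are
   integers ≥ 1.
2. **Filtering.** Keep a pair as a consensus edge only if it was
   observed in all k runs (`required_presence` is configurable; the
   default is "all").
3. **Trimmed averaging.** Sort the edge's observation rows by
   (count, length, FA), drop the first and last row (one minimal and one
   maximal fiber count; `n_trim_low`/`n_trim_high` configurable), and
   average the remaining rows column-wise into the edge's three weights.
   With k = 10 this averages 8 observations, so consensus fiber counts
   are typically non-integer and are stored (and serialised) as floats.

**Tie-breaking and order invariance.** When several runs tie at the
extremal fiber count, which run's length/FA co-observations get dropped
is ambiguous. We resolve it by sorting full observation rows
lexicographically before trimming: the dropped rows are then a function
of the observation multiset alone, so consensus weights are exactly
invariant under any permutation of the input runs — including tied
configurations, where an "earliest-run" rule would not be.

**Length/FA population.** Whether the published averaging applied the
fiber-count trim to lengths and FA as well is not determined by the
construction rule alone; we average lengths and FA over the same rows
retained by the fiber-count trim (one consistent run subset per edge).
The alternative — averaging them over all k runs — is available via
`ConsensusPolicy(length_fa_population="all")`. Lengths and FA are never
trimmed independently of the count.

**Degenerate configurations** (e.g. 2 runs with the default 1+1 trim)
are rejected loudly rather than silently averaging nothing.

## Multi-resolution contraction

Consensus graphs are built at the finest parcellation level only.
Coarser resolutions come from contracting all vertices that share a
coarse label in a nested parcellation hierarchy (finest level first,
strictly decreasing label counts, consecutive-level maps total and
composable):

* coarse fiber count = sum of the fiber counts of all fine edges
  crossing the coarse pair;
* coarse mean length and mean FA = fiber-count-weighted means of the
  merged fine edges. The hierarchy fixes only the count summation; the
  weighted mean is our choice — each fine mean represents that many
  streamlines, so the weighted mean is the pooled streamline-population
  mean, and it makes contraction functorial (fine→mid→coarse equals
  fine→coarse exactly for counts, to rounding for the means);
* fine edges internal to one coarse region become self-loops and are
  dropped — released connectomes carry no self-loops — with their fiber
  mass recorded in a `ContractionReport`, so
  `mass_after + self_loop_mass_dropped == mass_before` is auditable
  (exact on integer inputs, ≤ 1e-9 relative otherwise);
* coarse node position = unweighted centroid of the constituent fine
  nodes; hemisphere is kept only when all constituents agree.

## Choosing the repetition count k

For each candidate k, build n (default 10) independent replicate graphs
G_k_i, each the average of k fresh runs; discard edges not present in
all n replicates; for each remaining edge compute the coefficient of
variation of its n replicate weights,

    c_v = s / m,   m = (1/n) Σ w_i,   s = sqrt( (1/(n−1)) Σ (w_i − m)² ),

i.e. the sample standard deviation with the Bessel (n−1) denominator.
Because a run's deviation from its expected count has mean zero,
averaging k i.i.d. runs scales c_v like 1/sqrt(k); the per-k summary
(median, quartiles, min, max over edges) exposes this decay as a box
series.

**Averaged-replicate presence semantics.** Whether an edge absent from
some of the k runs contributes zeros to the average or is averaged only
over the runs where it appears is a genuine ambiguity. The default
(`presence_rule="union"`) includes an edge in G_k_i if it appears in ≥ 1
of the k runs and counts absences as zero; `"all"` requires presence in
every run and averages the k observations. Neither is asserted to be
the published convention; both are implemented.

**Quartiles** use the median-of-halves convention (middle element
excluded at odd n), since a box summary does not fix an interpolation
rule.

**Recommendation rule** (`recommend_k`): scan adjacent sampled k values
and return the first k whose relative decrease in median c_v to the next
k falls below a tolerance (default 5%) — the point where one more full
tractography buys almost no stability. If the median sequence is not
monotone non-increasing (Monte-Carlo noise), a centered 3-point moving
average is applied first; a monotone sequence is evaluated raw. If the
tolerance is never met the largest sampled k is returned with a warning.
With an exact c/sqrt(k) decay and a step-1 grid, the 5% tolerance is
first met near k = 10; small-ensemble noise can pull the answer a few
steps earlier.

**Seeding.** One master seed; the (k, replicate) substream seeds are
derived through `numpy.random.SeedSequence` spawn keys, and run i of a
batch uses the seed pair (seed, i), so every sweep is reproducible
bit-for-bit and replicates are independent.

## The simulator

The simulator emulates the *stochastic structure* of probabilistic
tractography output, not its anatomy. A latent ground truth holds the
node set and true edges; per run, each true edge is detected
independently with probability p, and a detected edge reports

* fiber count ~ zero-truncated Poisson(λ) — the edge-definition rule
  ("≥ 1 streamline") makes the count law conditional on ≥ 1, while p
  models detection separately;
* mean length ~ Normal(μ_len, σ_len) truncated positive (mm);
* mean FA ~ Beta parameterised by (mean, concentration), so FA ∈ [0, 1]
  holds by construction.

No false-positive edges are generated by default, which keeps the
noiseless limit exact (p = 1 plus `noiseless=True` reproduces the
ground-truth edge set and central values every run); an optional
spurious-edge rate exists for stress tests.

Default parameter ranges for randomly drawn models, chosen once as
plausible for repeated-tractography output and fixed: detection
probability U(0.8, 1.0) (stable core plus flickering weak edges — the
population the all-runs filter is designed to prune), fiber rate
log-uniform on [3, 300] (per-edge streamline counts span orders of
magnitude), length mean U(20, 160) mm with sd U(2, 12) mm, FA mean
U(0.25, 0.65) with Beta concentration U(50, 200).

**What the simulator does not model:** spatial correlation between
edges, run-to-run correlation, anatomically realistic geometry or
label layouts, and the true (uncharacterised) variability law of any
particular tractography implementation. Tests passing on simulated
data therefore validate the *aggregation machinery* — filtering,
trimming, averaging, contraction, the c_v computation — not any claim
about real MRI-derived graphs.

## File formats

Graphs are read and written as GraphML in the CMTK-style dialect
(attribute keys first, then nodes with label/coordinates, then
undirected edges with the three weights). The attribute key strings are
site-specific and therefore configurable via `AttributeMap` (CMTK-style
defaults: `number_of_fibers`, `fiber_length_mean`, `FA_mean`,
`dn_name`, `dn_position_x/y/z`, `dn_hemisphere`). Directed input is
rejected, not symmetrised; duplicate edges and self-loops are errors.
Floats are serialised with shortest round-trip precision, so write∘read
is the exact identity — including non-integer averaged fiber counts.
Hierarchies are delimited text (header = level names, finest first, one
row per finest label). Edge endpoint pairs are stored canonically
(smaller 1-based node id first).

## Problem sizes

The test suite and the acceptance script run on simulated subjects of
12–30 regions with 10 runs, sweeps up to k = 25 with 500 replicates for
the decay law (and k = 1..20 with 50 replicates for the recommendation),
and 20,000 model replicates for the retention-probability check; these
sizes give Monte-Carlo errors comfortably inside the asserted
tolerances while keeping a full run in the order of seconds.

## Known limitations

* The per-edge c_v decay deviates from 1/sqrt(k) at small k when
  detection probability < 1 under the union presence rule (absence
  zeros inflate the variance, and the all-replicates edge filter
  selects differently at k = 1); the scaling checks therefore use
  always-detected edges.
* `recommend_k` assumes the median sequence is dominated by a
  decreasing trend; with very small replicate ensembles the rule can
  fire a few k early.
* Contraction assumes the input graph's labels all exist at the source
  hierarchy level; partial atlases must be subset beforehand.
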