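# Methods

## Data model

An **event log** is a table with columns `Time` (seconds from
observation start), `Subject`, `Behavior`, `Status` and optionally
`Modifier` (the recipient individual of a directed behavior) and
`Behavioral category`. Column names are matched case-insensitively after
stripping whitespace; extra columns are ignored; CSV (RFC 4180, UTF-8,
header row) and XLSX (first sheet) are read identically. Status values
are normalized case-insensitively to `START`/`STOP`/`POINT`; a blank or
absent status means `POINT` — logging dialects vary, and an instantaneous
reading is the only safe default. Records are ordered by time with ties
broken by original row order, which makes all downstream sequences
deterministic. Categories come from the category column when present,
else from an optional behavior→category JSON map, else the label
`"None"`.

**Bout reconstruction** pairs each `START` with the earliest subsequent
`STOP` of the same (subject, behavior); `POINT` rows become zero-duration
bouts. Malformed logs are repaired, not rejected: a `STOP` without an
open `START` is dropped with a warning, and a `START` never closed is
closed at the last timestamp in the log, also with a warning. The
rationale is to preserve the observable duration without inventing data.
The `Modifier` cell is taken verbatim as a single recipient label (no
separator splitting). Times are used as-is and assumed to be seconds; no
unit conversion is attempted.

Exclusion filters (subjects, behaviors, categories) act on the bout list
before any computation, so a deselected behavior's predecessors and
successors become adjacent in the transition sequences — deselection
means "as if never logged", not "break the sequence".

## Summaries

Counts and total durations are aggregated per behavior or category;
relative columns normalize by the column sums, so they sum to 1 whenever
any bout exists (when all bouts are instantaneous the duration sum is
zero and relative durations are reported as 0). Cumulative occurrence
curves count a bout at its **start** time; this matches the row order of
the underlying log and keeps the curves monotone with final value equal
to the bout count.

## Interaction network

Nodes are individuals; an edge A→B accumulates one unit per bout emitted
by A with recipient B — a START/STOP pair and a point event each count
once. Emitters and receivers can be deselected separately. An edge
weight threshold sets a per-edge `display` flag; edges below it stay in
the data. Self-interactions are kept as self-loop edges (they can be
logging artifacts worth inspecting) but never enter centralities.

Node metrics: distinct-partner counts (`in_edges`/`out_edges`) and
weight sums (`in_interactions`/`out_interactions`) are computed on the
full edge set, so their totals always balance the number of
recipient-bearing bouts regardless of the threshold. The four
centralities are computed on the **displayed** subgraph — the metrics
describe the network the drawing shows. Shortest paths are unweighted
(hop counts); degree centralities are normalized by n−1, betweenness by
(n−1)(n−2); closeness uses outgoing distances from the focal node with
the Wasserman–Faust reachable-fraction correction
C(u) = (r/(n−1)) · (r/Σd), r = reachable nodes, which degrades
gracefully on disconnected groups (an individual reaching nobody gets
closeness 0).

## Behavior transition network

Per subject, bouts ordered by start time (row order on ties) give a
label sequence; adjacent pairs are counted and accumulated over subjects
into directed edge weights. Self-loops arise when a behavior is halted
and resumed. In **relative** mode each weight is divided by the sum of
all outgoing weights of its source — including the edge itself and any
self-loop — so outgoing frequencies sum to 1 per node. Frequencies are
always computed on the full edge set *before* display thresholding;
hiding an edge can therefore never distort the remaining frequencies.
Category mode substitutes each behavior's category before counting; the
resulting graph is exactly the quotient of the behavior-mode graph with
weights summed.

Node statistics (total/average time, occurrences, distinct
in-/out-transitions) follow the same full-set/displayed-set split as the
interaction network, with centralities as above.

Style mappings for node size, color saturation, in-node labels and edge
widths use `v ↦ lo + (hi−lo)(v−vmin)/(vmax−vmin)`, optionally after the
log transform `ln(1+v)` (defined at 0, monotone). Constant inputs map to
the midpoint of the output range — there is nothing to rank, and the
midpoint avoids a divide-by-zero. Edge widths span
`[base, base + edge_width_factor]`. Negative inputs are rejected.

## Network comparison

Two transition networks rarely share a behavior repertoire. Each pair is
aligned over the **union** of node labels (lexicographic order); a
behavior absent from one network becomes a zero row/column there, so a
differing repertoire contributes to the distance rather than being
silently intersected away.

The six measures, and the graph representation each uses:

- **Portrait divergence** (symmetrized, binarized). The portrait
  B(ℓ,k) counts nodes with exactly k nodes at unweighted shortest-path
  distance ℓ (B(0,1)=n). Each portrait induces the joint distribution
  P(ℓ,k) ∝ k·B(ℓ,k) over ordered node pairs; the distance is the
  Jensen–Shannon divergence in base 2 between the two distributions,
  hence in [0,1]. Unreachable pairs simply do not contribute.
- **Frobenius** (directed, weighted): entrywise ℓ2 norm of the adjacency
  difference.
- **Hamming** (directed, binarized): fraction of differing entries over
  all n² positions. The diagonal is included because self-loops are
  meaningful transitions.
- **Degree divergence** (symmetrized, binarized): base-2 JSD between the
  total-degree distributions; disjoint point masses give exactly 1 bit.
- **Ipsen–Mikhailov** (symmetrized, binarized): vibrational frequencies
  ω_i = √λ_i of the graph Laplacian (zero mode dropped) are broadened
  into Lorentzians of common width γ, normalized in closed form on
  [0,∞) (∫ = π/2 + arctan(ω_i/γ)); the distance is the L2 norm of the
  density difference, integrated adaptively. γ is calibrated per node
  count by root-finding so that d(empty_n, complete_n) = 1 (cached per
  n; the calibration reproduces 1 to ~1e-14).
- **Non-backtracking spectral distance** (symmetrized, binarized):
  the eigenvalue cloud of the non-backtracking (Hashimoto) edge operator
  is computed from the 2n×2n pseudo-Hashimoto block matrix
  [[A, I−D],[I, 0]], corrected by the Ihara–Bass identity (adding or
  removing |m−n| trivial ±1 pairs) to the exact 2m-point spectrum. The
  distance is the mean optimal-assignment (earth-mover) distance between
  the two complex clouds, the smaller cloud zero-padded — missing
  spectral mass is treated as mass at the origin. The measures named in
  the literature for undirected graphs operate on the symmetrized
  binarized adjacency; the matrix-norm measures extend naturally to the
  directed (and weighted, for Frobenius) case.

All measures are symmetric, nonnegative and exactly zero on identical
graphs; the pairwise matrix computes each unordered pair once, so it is
exactly symmetric with an exactly zero diagonal. Network labels are the
first two characters of each network's name, enumerated on collision.

**MDS** is metric SMACOF stress majorization: raw stress
σ(X) = Σ_{i<j} (d_ij − ‖x_i−x_j‖)², Guttman-transform updates, at most
300 iterations, stopping when the stress improvement falls below 1e-6.
Restart k of n_init draws its initial configuration from a generator
seeded `seed + k`, and the best (lowest-stress) restart wins. Because
the restart streams nest, increasing n_init can only lower the returned
stress, and a fixed (D, seed, n_init) reproduces the embedding bitwise.
scikit-learn's SMACOF would serve the same purpose but does not expose
per-restart seeds, which this nesting guarantee needs; it is used as an
independent cross-check in development, not in the pipeline.

**Hierarchical clustering** is scipy agglomerative linkage (average,
complete or single) on the condensed distance matrix. Merge heights are
nondecreasing for these criteria on metric inputs. The dendrogram color
threshold partitions the leaves into the maximal clusters merged
*strictly below* the threshold; unmerged leaves are singletons.

## Synthetic data generators

`generate_markov_log` emits, per subject, a first-order Markov chain
over the behavior list (uniform initial state), each bout as a
START/STOP pair with Exponential(mean) duration and a fixed 0.5 s
inter-bout gap — large enough to keep start-time order equal to chain
order, small enough to keep a 500-bout recording within a realistic
session length. Transition recovery converges to the generating matrix
at the multinomial rate ∝ 1/√n; at 20 subjects × 500 bouts the expected
max-abs error is ≈ 0.01 (observed 0.01–0.02 across seeds, against an
acceptance bound of 0.03 ≳ 3σ). `generate_interaction_log` draws Poisson
counts per ordered pair of individuals at the specified expected rates
and emits them as recipient-bearing point events.

The cichlid sample stand-ins (`synthetic_multifasciatus_log`,
`synthetic_ocellatus_log`) are synthetic BORIS-style recordings of
shell-dwelling Lamprologini groups: a 13-behavior ethogram in five
categories (aggression, maintenance, shelter, locomotion, escape), fixed
per-subject repertoires, exponential bout durations (~7 s mean over a
20-minute session), directed aggressive bouts with random recipients,
and point events for instantaneous behaviors. Repertoire facts are
guaranteed by construction for every seed (each subject's sequence
begins with a shuffled copy of its full repertoire): the 7-individual
recording has a dominant subject "1" with 11 distinct behaviors
including overt aggression and a subordinate subject "5" with 6,
restricted to restrained aggression plus escapes; the second recording
has 10 individuals.

What the generators do *not* emulate: diurnal or contest dynamics in
bout timing, semi-Markov dwell-time dependence, higher-order sequence
structure, observer effects, or real cichlid repertoire frequencies.
Tests passing on these fixtures demonstrate the correctness of the
bookkeeping and the algorithms, not ecological validity of any
particular analysis.

## Numerical and design notes

- Tie-breaks everywhere are by original row order; all iteration orders
  are sorted, so identical inputs give byte-identical CSV/GML/DOT
  outputs.
- Centralities on the thresholded subgraph (not the full edge set) is a
  deliberate choice: the exported table should describe the drawn
  network. Setting the threshold to 0 gives full-graph metrics.
- The Hamming denominator is n² (diagonal included); the degree
  distribution excludes self-loops (they are dropped in symmetrization).
- Ipsen–Mikhailov on graphs with fewer than two nodes is defined as 0
  (no vibrational spectrum exists).
- Test oracles are deliberately independent routes: BFS dictionaries and
  explicit path enumeration for centralities, Floyd–Warshall portraits,
  trapezoid-grid integration with bisection calibration for the spectral
  distance, and the explicit 2m×2m edge matrix for the non-backtracking
  spectrum.
- Problem sizes in the test suite and acceptance script (50 random
  fixture graphs; exhaustive digraph sweeps at 2–3 nodes with seeded
  4–5-node samples; 1000 random logs for transition-count checking;
  10,000 bouts for Markov recovery) were chosen to make the statistical
  bounds sharp at interactive runtimes.

## Limitations

- Only first-order transitions (chains of two behaviors) are modeled.
- No statistical testing: transition significance (permutation tests),
  Mantel tests on adjacency matrices and cluster-separation inference
  are out of scope.
- Distance measures treat repertoire differences as signal via
  union-alignment; for comparing recordings with wildly different
  ethogram granularity, map behaviors to a common category scheme first.
- DOT output is written in a simple dialect (plain attributes, HSV fill
  colors); layout is left to GraphViz or to the built-in matplotlib
  spring-layout rendering.
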