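# ethograph

Behavioral researchers quantify animal behavior with event-logging
software (BORIS, CowLog and similar): the result is a table with one row
per logged event — the time, the focal subject, the behavior, a status
flag (`START`/`STOP` for behaviors with a duration, `POINT` for
instantaneous ones) and optionally the recipient individual and a
behavioral category. `ethograph` turns such logs into six analysis
products, as a library and a command-line tool:

1. **Distinct behavior summaries** — counts and total durations per
   behavior or category, absolute and relative.
2. **Behavioral timelines** — per-subject interval tracks showing when
   each behavior occurs.
3. **Cumulative temporal occurrences** — monotone step curves of bout
   counts over time, per individual (or per individual × behavior).
4. **Interaction networks** — directed weighted graphs over individuals:
   an edge A→B counts bouts emitted by A toward recipient B, with
   in-/out-degree, closeness and betweenness centralities per individual.
5. **Behavior transition networks** — directed weighted graphs over
   behaviors (or categories): an edge a→b counts how often b immediately
   followed a within one individual's bout sequence, or carries the
   *transitional frequency* w(a→b) / Σ_c w(a→c); node statistics include
   occurrence counts, total/average time and the four centralities.
6. **Network comparison** — pairwise distances between transition
   networks under six graph distance measures (network portrait
   divergence, Frobenius norm, Hamming fraction, degree divergence,
   Ipsen–Mikhailov spectral distance, non-backtracking spectral
   distance), embedded in 2-D by metric MDS and clustered hierarchically
   (average/complete/single linkage) with a threshold-colored dendrogram.

Filtering (deselecting subjects, behaviors or categories), edge display
thresholds, linear/log style normalization and node/edge style mappings
are available throughout. Graphs export to GML and GraphViz DOT, tables
to CSV, figures to SVG.

## Worked example

Generate a synthetic 20-minute group recording of shell-dwelling
cichlids (7 individuals, BORIS-style CSV) and analyse it:

```
$ ethograph simulate --kind multifasciatus --seed 0 -o Nm_sample.csv
wrote 332 events to Nm_sample.csv

$ ethograph summary Nm_sample.csv --group-by category -o summary_out
$ head -4 summary_out/counts.csv
category,count,total_duration,relative_count,relative_duration
Aggression,35,265.4531142679463,0.19230769230769232,0.20976011317104384
Escape,15,145.1741033758504,0.08241758241758242,0.11471606365441035
Locomotion,42,335.9702604467359,0.23076923076923078,0.265482512976952
```

The group performed 35 aggressive bouts (19% of all bouts) totalling
265 s of the observation. The transition network over categories, with
relative edge weights and edges below frequency 0.1 hidden from the
drawing:

```
$ ethograph transitions Nm_sample.csv --node-mode category \
      --edge-values relative --threshold 0.1 -o trans_out
$ head -3 trans_out/transition_stats.csv
node,total_time,average_time,occurrences,in_transitions,out_transitions,in_degree_centrality,out_degree_centrality,closeness_centrality,betweenness_centrality
Aggression,265.4531142679464,7.584374693369896,35,5,5,1.0,0.75,0.8,0.0
Escape,145.1741033758504,9.678273558390027,15,5,5,0.25,1.0,1.0,0.0
```

Aggression is observed 35 times for 7.6 s on average and can be reached
from every other category (in-degree centrality 1.0). Comparing two
recordings by the portrait divergence of their transition networks:

```
$ ethograph simulate --kind ocellatus --seed 0 -o Lo_sample.csv
$ ethograph compare Nm_sample.csv Lo_sample.csv --measure portrait \
      --linkage average --seed 0 --n-init 400 -o cmp_out
$ cat cmp_out/distances.csv
,Nm,Lo
Nm,0.0,0.29136589688238396
Lo,0.29136589688238396,0.0
```

The two recordings' transition structures differ by a portrait
divergence of 0.29 (on a 0–1 scale); `cmp_out/` also contains the MDS
scatter (`mds.svg`/`mds.csv`) and the dendrogram. The matrix is
symmetric with a zero diagonal by construction, and the MDS result is
bit-for-bit reproducible for a fixed `--seed`/`--n-init`.

The same operations are available as functions
(`ethograph.parse_event_log`, `reconstruct_bouts`,
`build_transition_graph`, `pairwise_distance_matrix`, `mds_embed`, ...)
for scripted analyses.

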