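# Methods

## The model

A discharge cohort is reduced to one deduplicated ICD-10 code set per
admission. The comorbidity network is the multiset union of per-patient
clique expansions: nodes are diagnosis codes, and the weight of edge
(u, v) is the number of patients whose code set contains both u and v. The
graph is undirected by design — discharge lists carry no information about
disease causality, and imposing a direction would encode a bias the data
cannot support. Codes are used at the granularity recorded (J45.0 and
J45.9 stay distinct; no rollup to three-character roots), because the
phenotype clusters of interest distinguish four-character codes.

Phenotype candidates are modularity communities of this weighted graph:
groups of diagnoses whose mutual co-occurrence is heavier than expected
from their overall connectivity under the configuration-model null. The
objective is weighted Newman–Girvan modularity with a resolution parameter
γ (default 1.0),

    Q = Σ_c [ w_in,c / W − γ (w_tot,c / W)² ],  W = 2 Σ_e w_e,

where w_in,c is twice the intra-community edge weight and w_tot,c the
summed weighted degree of community c. Q is maximised with the two-phase
Louvain heuristic: a local-move phase visiting nodes in a seeded random
order and moving each to the neighbouring community with the largest
strictly positive gain, then aggregation of communities into super-nodes,
repeated until no pass improves Q. Tie-breaks go to the lowest community
id (candidate communities are scanned in ascending order and only strict
improvements, beyond a 1e-12 slack, replace the incumbent), so the result
is fully determined by (graph, resolution, seed). Modularity is asserted
non-decreasing across passes. Louvain is a heuristic: on a given graph it
returns a local optimum whose Q typically sits a few percent below the
global maximum, and different seeds may return different partitions.

Bridging diagnoses are ranked by betweenness centrality, computed with
Brandes' dependency accumulation, unnormalised, with each unordered pair
counted once. The default uses hop-count shortest paths; an optional
weighted mode uses edge distance 1/weight, so strong co-occurrence means
proximity. Which convention the original network tooling used is not
recorded, hence both are exposed; the default is the hop-count variant.

## Cohort statistics

- Age is completed years at admission (birthday-aware), length of stay is
  the calendar-date difference in whole days: a same-day discharge is 0
  regardless of clock times. Zero-day J46 stays are excluded (optionally)
  as non-cases.
- Cohort split: any record carrying a J46 code goes to the J46 cohort;
  otherwise a J45-root code puts it in the J45 cohort; J46 precedence makes
  the J45 cohort "J45 only". Records carrying other roots alongside J45
  (e.g. J44) are not excluded — only J46 is.
- Descriptives use the sample standard deviation (n−1), linear-interpolated
  quartiles, and bias-corrected sample skewness and *excess* kurtosis
  (normal ≈ 0); with n < 3 (skewness) or n < 4 (kurtosis), or zero
  variance, the moment is NaN.
- The 2×2 chi-squared applies the Yates continuity correction with df = 1.
  On the ventilation table (4/83 vs 124/13,612) the corrected test gives
  p = 0.0018 where the uncorrected gives p ≈ 0.0002; the corrected variant
  is the one whose output matches the reference analysis, and is the
  appropriate choice at an expected cell count below 1.
- The odds-ratio interval is Woolf's log-normal CI,
  exp(ln OR ± z·√(1/a+1/b+1/c+1/d)), with no Haldane–Anscombe correction;
  all four cells must be positive. Cohort sex counts are reconstructed
  from printed percentages by rounding half away from zero
  (83 × 66.26% → 55 women, 28 men; 13,612 × 58.36% → 7944 / 5668).
- Monthly profiles pool all years: for each sex, month m gets
  100 × n_sex(m) / n_sex, so each sex's 12 values sum to 100; a sex with
  no cases is flagged and reported as zeros.

## Reporting and rendering

The cluster summary orders communities by descending node count (ties:
lower id), reports node shares as percentages of all nodes rounded to two
decimals (half away from zero), and counts distinct intra- and
inter-community edges ignoring weights; intra plus inter always equals the
network's edge count. Graph density is the simple-graph form 2E/(N(N−1)),
ignoring weights — this is the formula that reproduces both published
densities from their printed node/edge counts. Render attributes follow
the figure conventions: node size = 1 + 99·(ln(1+b) − ln(1+b_min)) /
(ln(1+b_max) − ln(1+b_min)) (the ln(1+·) form handles zero betweenness),
edge width linear from weight onto [0.1, 1]; a degenerate span (all values
equal) maps to the lower bound.

## Synthetic cohorts

The generator emulates the statistical structure the analysis relies on,
not clinical realism. Per patient: a phenotype cluster is drawn from the
prevalence vector; a code count k from a truncated Poisson (mean 5,
minimum 1); each of the k draws comes from the own-cluster vocabulary with
probability 1−ε, otherwise uniformly from the background plus other
clusters' vocabularies; the anchor code (J46) is prepended to every
record. Sex is Bernoulli (female probability 0.6626, the J46 cohort's
share), age and length of stay are truncated normals matched to the
published cohort moments (57.59 ± 15.96 years, truncated at 18; 6.02 ±
4.98 days, floored at 0), admission dates are drawn over 2013–2023 with a
winter-skewed monthly intensity (cold-month peak with a small late-spring
shoulder — the reference series is published only as a figure, so the
default profile is qualitative), and birth dates are back-computed so that
re-deriving age recovers the drawn value exactly.

Defaults: five clusters with vocabulary sizes 21/13/12/9/6 — proportional
to the five phenotype clusters' published node counts (60/36/33/25/16),
scaled to ~60 codes so that a 500-patient cohort covers each vocabulary
densely — prevalences proportional to those node counts, 15 background
codes, ε = 0.1, 500 patients.

What the generator does **not** emulate: ICD-10 ontology structure,
code-frequency skew within a vocabulary, patients belonging to several
phenotypes, repeat admissions, or any geospatial signal. Passing recovery
tests therefore show that the pipeline recovers planted block structure at
realistic sizes and mixing levels — not that real discharge data contains
such structure.

Recovery is scored with the adjusted Rand index between the Louvain
partition and the planted code labels, excluding the anchor code (present
in every patient, so it carries no cluster signal and would only add a
degenerate penalty) and background codes. At ε = 0 the non-anchor
vocabularies share no edges by construction and recovery is exact on
essentially every seed; at ε = 0.1 the median ARI over 10 seeds stays at
1.0; at ε = 0.9 the block structure is destroyed and ARI drops to chance
(≈ 0). One caveat: the anchor hub connects all blocks, and on rare draws
modularity's resolution limit makes merging the two smallest clusters
with the anchor *genuinely* optimal (the merged partition's Q exceeds the
planted partition's), so an occasional ε = 0 run can score ARI ≈ 0.92
without any search failure. This is a documented property of the
modularity objective, not of the implementation.

## Numerical and design notes

- All randomness flows through numpy `default_rng` seeded from explicit
  `seed` arguments/flags; iteration orders are sorted everywhere outputs
  are written, so every command is byte-reproducible.
- Edge files use the `Source,Target,Weight` header dialect for
  interoperability with desktop graph tools; undirectedness is semantic
  (pairs are stored canonically sorted), and isolated nodes travel in a
  companion `Id,Label` node file. GEXF export is version 1.2 with an
  undirected edge declaration.
- The published density/label pairing is internally inconsistent: the
  prose attaches 0.028 to the smaller network and 0.106 to the larger,
  while the printed node/edge counts imply the reverse. The implementation
  computes density from N and E only; the acceptance test documents the
  swap rather than guessing authorial intent.
- The published J45 length-of-stay quartiles (Q3 = 8, max = 7) are
  mutually inconsistent; the descriptive summary here enforces
  min ≤ q1 ≤ median ≤ q3 ≤ max and cannot reproduce that pair.
- Problem sizes in the test and acceptance runs (500-patient cohorts, 10
  seeds, exhaustive oracles on ≤6-node graphs) are chosen so the full
  suite completes in seconds while still exercising every code path at
  the study's own cohort scale for the J46 arm.

## Known limitations

Louvain offers no significance control — small communities may be noise
(the study's own sixth cluster is a single patient's clique). The
resolution default γ = 1.0 is the conventional choice, not a fitted one.
Betweenness on co-occurrence graphs is sensitive to coding noise in sparse
regions. The generator's single-membership patients make recovery easier
than mixed-membership reality; treat recovery numbers as an upper bound on
what the method could do on real data.
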