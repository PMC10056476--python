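# plastdeg

Meta-analysis tools for microbial plastic-biodegradation literature.

Plastic biodegradation reports are scattered across hundreds of publications
that link a microorganism (by taxonomy id and lineage) to a plastic type.
`plastdeg` turns such a record table into a quantitative picture of *which
kinds of plastics are degraded by which kinds of microbes*:

1. **Curation funnel** — drop exact duplicate rows, "uncultured" organisms,
   records whose lineage lacks a genus, and plastic types reported by fewer
   than 10 distinct taxonomy ids; every stage's in/dropped/out counts are
   logged.
2. **Association matrix** — a binary genus × plastic incidence matrix
   `M[g, p] = 1` iff at least one report pairs genus *g* with plastic *p*.
3. **Pattern analysis** — cosine distance between plastic columns,
   `d(p, q) = 1 − u·v / (‖u‖‖v‖)`, average-linkage (UPGMA) clustering with
   deterministic tie-breaking, and non-metric MDS (Kruskal stress-1)
   ordination. The two-cluster cut is compared with the chemical backbone
   classification — C-C plastics (PE, HDPE, LDPE, PP, PS, PVC, PVA: all-carbon
   backbone, non-hydrolyzable) versus C-X plastics (polyesters, polyamides,
   polyurethanes: heteroatom backbone) — via the adjusted Rand index.
4. **Enrichment** — per genus, the fraction of each group's plastic types it
   is reported to degrade (e.g. 2 of 7 C-C → 0.29, 2 of 13 C-X → 0.15), with
   a twofold tendency rule: a genus is labeled C-C (or C-X) when that group's
   proportion is at least double the other's, on exact fractions.
5. **Inference** — per-genus differences `prop_CC − prop_CX` are checked for
   normality (KS) and tested with the Wilcoxon signed-rank test (exact null
   for ≤ 25 tie-free pairs, else normal approximation with tie and continuity
   corrections); the same test is run on the raw report-count differences.
6. **Synthetic corpora** — a seeded generator plants genus biases and the
   plastic bipartition, plus the noise the funnel removes (duplicates,
   uncultured organisms, truncated lineages), so the whole pipeline can be
   validated against known ground truth.

The package is used from Python (see `examples/`); a thin `plastdeg` CLI
(`simulate`, `curate`, `matrix`, `cluster`, `enrich`, `test`, `run-all`)
wraps the same functions for shell use.

## Worked example

```python
from plastdeg import (SimParams, generate_corpus, curation_funnel,
                      build_association_matrix, select_genera, group_proportions,
                      class_lookup_from_records, run_group_tests)

params = SimParams(n_genera_cc_biased=10, n_genera_cx_biased=40,
                   n_genera_neutral=10, seed=11)
records, _ = generate_corpus(params)
table = curation_funnel(records)
matrix = select_genera(build_association_matrix(table), min_plastics=4)
rows = group_proportions(matrix, params.scheme(),
                         class_lookup=class_lookup_from_records(table.records))
res = run_group_tests(rows)
print(res.proportion_test.p_value)
```

Running `python examples/03_enrichment_and_tests.py` (which does the above
and prints the first enrichment rows) outputs:

```
60 genera selected (>= 4 plastic types)
genus            class                  prop_cc prop_cx tendency
Genus002         Actinomycetia             0.57    0.00 CC
Genus008         Actinomycetia             0.43    0.15 CC
Genus014         Actinomycetia             0.14    0.69 CX
...
KS normality of proportion differences: p = 0.0147
signed-rank on proportions: p = 0.000763 (approximate, n = 60)
signed-rank on raw counts:  p = 2.19e-08
```

`prop_cc = 0.57` means that genus is reported for 4 of the 7 C-C plastic
types; the `CC` tendency says its C-C proportion is at least twice its C-X
proportion. The small signed-rank p-values confirm the planted excess of
C-X-leaning genera in this corpus. `examples/02_cluster_plastics.py` shows
the complementary result: the k=2 cut of the degradation-profile dendrogram
reproduces the chemical C-C/C-X split exactly (ARI = 1.00).

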