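# Methods

## Data model

A *degradation record* is one literature report that a taxon degrades a
plastic type: `(tax_id, organism, lineage, plastic, reference)`. The lineage
is an ordered list of `(rank, name)` pairs parsed from a semicolon- or
pipe-delimited string against a configurable rank template
(`domain, phylum, class, order, family, genus, species` by default); ranks are
paired positionally and unnamed positions are skipped. The genus of a record
comes **only** from the lineage's genus rank — the free-text organism name is
never parsed, so a record labeled "Bacillus sp." whose lineage stops at the
family level has no genus and is dropped by the funnel. Plastic tokens are
trimmed and internal whitespace collapsed but otherwise preserved verbatim:
no synonym merging, so PE, LDPE and HDPE are distinct types by design.

## Curation funnel

Four filters applied in a fixed order, each logging `(n_in, n_dropped, n_out)`:

1. **duplicates** — rows identical on all of
   `(tax_id, organism, plastic, reference)` collapse to their first
   occurrence. Reference is part of the identity key: the same taxon–plastic
   pair from two publications is evidence, not redundancy.
2. **uncultured** — organisms matching a case-insensitive `uncultured`
   substring are removed (identification is too uncertain to place them).
3. **genus** — records without a genus-rank lineage entry are removed.
4. **rare plastics** — plastic types reported by fewer than `min_taxa = 10`
   **distinct taxonomy ids** are removed with their records. Distinct ids,
   not raw rows, so repeated reports of one organism cannot carry a plastic
   over the threshold; the rule is inclusive (exactly 10 ids is kept) and the
   count is taken before genus-level collapsing.

The order matters — the rare-plastic counts depend on what earlier stages
removed — so the composed funnel always runs in this order and asserts the
bookkeeping identities (`n_in = n_dropped + n_out` per stage, stages chain).

Reporting unevenness is summarized by the empirical cumulative distribution
of per-taxon report counts at species (tax_id) and genus level; collapsing
species into genera moves the curve rightward and lowers the singleton
fraction, which is the empirical motivation for analyzing at genus level.

## Association matrix and group scheme

The genus × plastic matrix is binary incidence (1 = at least one report),
with lexicographically sorted axes for cross-run determinism. Genus selection
keeps rows reported for at least `min_plastics = 4` plastic types, so the
enrichment statistic is computed only for genera with enough breadth to have
a meaningful group preference.

The shipped group scheme maps the 7 all-carbon-backbone types
(PE, HDPE, LDPE, PVC, PVA, PP, PS) to C-C and 13 heteroatom-backbone types
(PHB, PHA, PHBH, PCL, PU, PES, PBS, PLA, PHBV, Nylon, PBSA, PET, PBAT) to
C-X. The scheme is data (a two-column TSV), not code: curated databases grow
new plastic types, and `validate_group_scheme` reports unmapped matrix
columns (fatal unless explicitly allowed) and unused scheme entries
(informational).

## Pattern analysis

Plastic types are compared through their binary genus profiles (matrix
columns) with cosine distance `d(p,q) = 1 − u·v/(‖u‖‖v‖)`, which is in
[0, 1] for non-negative profiles. Cosine distance violates the triangle
inequality in general; both downstream procedures tolerate that, so it is
documented rather than "fixed".

**Agglomerative clustering.** Average linkage (UPGMA) by default — the
standard choice for profile similarity, with monotone merge heights —
complete and single linkage selectable. The agglomerator is implemented in
the package (inter-cluster distances recomputed from the input matrix each
step, equivalent to naive O(n³) agglomeration) because we guarantee
platform-independent determinism: ties in the minimum inter-cluster distance
are broken toward the pair whose lexicographically smallest member labels
sort first. scipy's linkage does not specify tie order; the test suite uses
it as an independent cross-check on tie-free random matrices, alongside a
from-scratch exhaustive agglomerator. Dendrograms export to newick with
ultrametric branch lengths (node depth = merge height / 2), and `cut_tree`
removes the k−1 highest merges.

**Ordination.** Non-metric MDS (monotone/isotonic disparity fit, Kruskal
stress-1), best of 8 random restarts, seeded and bit-reproducible. The
solver runs to tight convergence (eps 1e-12, ≤ 1000 iterations per restart —
cheap at ≤ a few dozen plastic types) so that exactly embeddable
configurations (e.g. any 3-point metric in 2-D) reach stress ≈ 0.

**Partition agreement.** The k=2 cut is scored against the chemical C-C/C-X
labels with the adjusted Rand index (chance-corrected; 1 = identical).

## Enrichment and the twofold rule

For genus *g*, `prop_CC = n_CC / |CC|` and `prop_CX = n_CX / |CX|`, where the
denominators are the number of scheme-mapped plastic columns per group in the
analyzed matrix (7 and 13 when all 20 default types are present). Proportions
are kept as exact `Fraction`s; the 2-decimal values (0.29, 0.15 for a 2-of-7,
2-of-13 genus) are display formatting only.

The tendency rule assigns C-C when `prop_CC ≥ fold · prop_CX` (default
`fold = 2`, inclusive; a strict `>` variant is exposed because "twice the
other" is ambiguous at exactly twofold), symmetrically for C-X, else no
assignment. Comparisons use the exact fractions — rounding first would flip
boundary cases like 0.30 vs 2 × 0.15. Zero-vs-zero is never assigned;
positive-vs-zero always is (infinite ratio). The rule is scale-free and
monotone in `fold` (raising it can only blank assignments), and swapping the
group labels swaps every assignment; all three properties are tested.

Heatmap rows are ordered by the leaf order of a user-supplied newick
phylogeny when given (the tree must cover all selected genera), otherwise by
(class, genus); the class label per genus is the majority class rank seen in
that genus's record lineages.

## Inference

The per-genus differences `prop_CC − prop_CX` are paired, bounded and
lattice-valued, so normality is not expected; a one-sample KS test of the
standardized differences against N(0,1) (asymptotic p) makes that explicit.
The parameters are estimated from the sample, so the classical KS p is
conservative for normality — it is a descriptive check, and a Lilliefors-style
correction was deliberately not layered on top.

The group test is the Wilcoxon signed-rank test, two-sided: zeros dropped
(Wilcoxon's treatment; Pratt's is an option), mid-ranks for tied absolute
values, statistic `min(W+, W−)`. The exact null distribution is used when
`n_effective ≤ 25` with no ties, otherwise the normal approximation with tie
correction and continuity correction; the mode used is recorded in the
result. Exact p-values are validated against full 2ⁿ sign enumeration in the
tests. The same test applied to raw count differences `n_CC − n_CX` answers a
different question (absolute breadth rather than group-normalized
preference), and the two can disagree — the denominators 7 vs 13 make equal
proportions correspond to unequal counts.

No multiple-testing correction is applied: the analysis runs exactly two
planned tests and reports raw p-values.

## Synthetic corpora

`SimParams` defaults define the generator's study conditions: 20 C-C-biased,
20 C-X-biased and 10 neutral genera; the 7+13 default plastic lists;
`p_within = 0.6`, `p_cross = 0.05` (a biased genus degrades each own-group
plastic with 0.6, each other-group plastic with 0.05; neutral genera use
`p_within` everywhere); geometric species count per genus with mean 2;
shifted-geometric report multiplicity per (taxon, plastic) pair with success
parameter 0.6, so ~60 % of pairs are single-reported; duplicate, uncultured
and genus-less noise at rates 0.02 / 0.02 / 0.03 — light contamination whose
only purpose is to exercise the funnel. Each noise channel draws from its own
child stream of the single seed, so enabling a channel never perturbs the
clean core, and the same seed reproduces the corpus byte for byte.

What the generator emulates: the record schema, nested species-in-genus
taxonomy with class ranks, planted group structure, pair-level singleton
domination, and the funnel's noise classes. What it does not emulate: real
corpora are dominated by taxa reported for a single plastic type, while the
planted-recovery conditions (`p_within = 0.6`) give every biased genus a
dense profile, so the corpus-level singleton fraction at the defaults is far
below the ~60 % seen in real literature databases (the pair-level
multiplicity, which `report_multiplicity` controls, does match, and the
singleton fraction is monotone in it — tested). It also does not simulate
realistic taxon name distributions, blended plastics, or publication-level
structure. Passing recovery tests therefore show the pipeline recovers
planted structure of this shape; they do not certify power on sparse real
corpora.

`recovery_benchmark` reruns the full pipeline (generate → funnel → matrix →
distance → cluster → cut → ARI; and funnel → selection → enrichment →
signed-rank) over consecutive seeds and summarizes the ARI distribution and
the rejection rate.

**Calibration caveat.** The signed-rank calibration benchmark uses
`p_within = p_cross = 0.5`: both group proportions are then symmetric
binomial fractions (the symmetry null holds exactly) and every plastic is
reported by ~20 of 40 genera, so the rare-plastic filter never binds and the
per-genus differences are independent. When the frequency filter does bind
(sparser corpora), retention conditions on column sums couple the genera and
the test becomes conservative — measured rejection rates of 0.004–0.024 at a
shared degradation probability of 0.3 with 40 genera. That conservatism is a
property of applying the test downstream of a frequency filter, worth knowing
when interpreting borderline p-values on small real corpora.

## Numerical and degenerate-input choices

- Cosine distances are symmetrized and clipped at 0 to absorb floating-point
  jitter; an all-zero plastic column is an error naming the column.
- Clustering requires ≥ 2 labels; NMDS requires ≥ 3.
- Funnel stages accept empty inputs and record `(0, 0, 0)` counters; the
  association matrix constructor rejects an empty record table.
- The signed-rank test errors on an all-zero difference vector; the KS check
  errors on constant input (zero variance) or fewer than 3 values.
- All stochastic components take explicit integer seeds; pipeline artifacts
  contain no timestamps, so reruns are byte-identical.

## Problem sizes used in validation

The bundled validation works at deliberately modest scale: random matrices up
to 12×12 for the distance oracle, up to 7 labels for the exhaustive
agglomeration oracle, up to n = 10 for 2ⁿ sign enumeration, 100 seeded
corpora (40 genera × 20 plastics) for bipartition recovery and 500 for null
calibration. These sizes make every oracle exhaustive or near-exhaustive
while keeping the full suite fast.
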