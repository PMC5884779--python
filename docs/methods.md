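# Methods

## The model

The pipeline treats a multi-herb drug as a set of compounds with predicted
protein targets and asks which diseases' target sets are over-represented
among the disease-database targets that the drug network can reach.

**Network assembly.** Predictions with fit score ≥ `score_threshold`
(default 4.0, inclusive — a prediction scoring exactly 4.0 is retained, and
the cutoff is configurable) define compound→protein edges; compounds link
to every herb that lists them. A disease-database target is *connected*
when it is itself a drug target or a PPI path of length ≤ `max_path_length`
(default 1, i.e. a direct interaction) joins it to a drug target; all other
disease targets are discarded. Targets that are simultaneously drug targets
and disease targets are retained with both annotations. For hop budgets
above 1, bridging interaction proteins within `max_path_length − 1` hops of
a drug target are added so retained targets remain topologically connected;
at the default budget this adds nothing. The final graph is simple and
undirected; edge weights are not used anywhere downstream.

**Disease enrichment.** With universe size N (all distinct disease-database
targets), connected count n, disease size K and overlap k, the default
statistic is the hypergeometric **point probability** P(X = k). The point
mass — rather than the conventional tail P(X ≥ k) — is what published
compound–disease enrichment tables of this kind print under the name
"p-value": their K = 1, k = 1 rows equal exactly n/N, which only the point
mass does, and their (k = 2, K = 5) rows equal the point mass where the
tail would be ≈ 0.26. We reproduce that statistic as the default and expose
`variant="upper_tail"` for the statistically conventional alternative. We
note, without endorsing, that a point probability is not a tail p-value.
Both are computed with exact binomial-coefficient rationals
(`math.comb` + `fractions.Fraction`), so results are exact to double
precision; the scipy log-gamma route serves as an independent cross-check
in the tests only. No multiple-testing correction is applied by default
(published tables of this kind print raw values); Benjamini–Hochberg is
available as an option and never alters the ranking. Diseases with k = 0
are reported, not dropped, so the output is a total ranking; ties are
broken by descending match count, then name — a convention of ours, as the
source tables print no tie rule. *Major predicted diseases* are those with
p < `alpha` (default 0.05) and match > `min_match` (default 2).

**Candidate-target screen.** Degree, betweenness and closeness are computed
on the full heterogeneous network by default (a protein-only scope is
available). Betweenness is pair-normalized to [0, 1] by 2/((m−1)(m−2));
closeness is component-restricted, (reachable nodes)/(sum of distances),
0 for isolated nodes — both the NetworkAnalyzer conventions under which
published absolute thresholds such as (8, 0.0004, 0.3681) are meaningful.
Hubs have degree strictly greater than `degree_multiplier` (default 2) ×
median degree; candidates are hubs strictly above the median betweenness
and median closeness. Medians use the midpoint-of-two-central-values
convention (fractional medians are expected). Explicit threshold triples
can override the medians; the derived thresholds are always reported next
to the candidate list. Only protein nodes are nominated as candidate
*targets* even when the medians are taken over all nodes.

**Pathway ORA.** Query targets are tested against GMT gene sets over a
declared background (default: the union of the sets) with the exact
hypergeometric upper tail, or the conservative EASE variant that scores
P(X ≥ count − 1). Published ORA p-values from web services are not
reproducible without their hidden background universe and database
version, so this module guarantees enumeration-exact results on declared
backgrounds instead. The default report suppresses pathways with overlap
below 2.

**Herb attribution.** For each herb and target, the component count is the
number of distinct compounds of that herb with a retained edge to the
target. A target is *major* for a herb when its count is **not less than**
(≥, inclusive) the herb's median count. The median is taken over targets
the herb actually touches (count > 0) among the disease-connected targets —
the reading that matches fractional published medians such as 11.5 —
and can be widened to all targets or overridden outright.

## Synthetic data

The generator emulates the four inputs at the study's scale: 6 herbs whose
per-herb compound counts are drawn from 19–79, 219 distinct compounds
(shared membership allowed), 229 drug targets, and 63 disease sets over a
749-target universe with log-uniform sizes on [1, 370] (curated
disease-gene sets are heavily right-skewed; log-uniform is the simplest
such law). Calibrations chosen once and documented here:

* fit scores ~ Normal(4.2, 0.8) truncated at 0, so the 4.0 threshold
  removes a nontrivial minority of predictions;
* per-compound target counts ~ max(1, Poisson(10));
* 25% of drug targets are drawn from the disease universe (direct
  drug–disease overlap ≈ 57 at full scale);
* PPI: Erdős–Rényi with edge probability 6.4 × 10⁻⁴ over universe +
  drug-only targets + 150 unrelated interactors, chosen so the expected
  connected-target count at full scale is ≈ 151 (measured 153 ± 9 over
  seeds); a preferential-attachment model is available;
* a coverage floor adds one suprathreshold prediction for any compound or
  drug target that would otherwise drop out, so the assembled network has
  exactly the configured compound and drug-target dimensions.

A *planted* disease draws ⌈overlap × size⌉ of its targets (default size
20) from the drug-connected pool, creating a known enrichment signal whose
recovery as the top-ranked disease is the end-to-end probe: at 0.8 overlap
it ranks first in ≥ 95% of replicates, and its median rank improves
monotonically with the overlap fraction.

What the generator does **not** emulate: chemical similarity between
compounds of one herb, scale-free PPI degree structure (unless the PA model
is selected), correlated disease sets (real diseases share pathways), and
docking-score physics. Passing tests therefore demonstrate correctness of
the pipeline's computations and its statistical behaviour under the assumed
structure, not biological validity of any particular prediction.

The published 34-row worked example (N = 749, n = 151) is carried verbatim
as `reference_fixture()` and feeds the enrichment stage directly; its
(k, K) inputs are data, and every p-value is recomputed, never stored.

## Numerical and design notes

* Hypergeometric values outside the support return 0; inconsistent
  arguments raise. Tail sums are exact rationals, floated once at the end.
* Report p-values print as six decimal places with trailing zeros stripped,
  matching the style of the published tables so reports diff cleanly;
  JSON/Python APIs keep full precision.
* All writers emit UTF-8, TAB-delimited, LF-terminated text sorted by
  stable keys, so identical inputs give byte-identical outputs; the
  pipeline manifest records SHA-256 checksums of inputs and contains no
  timestamps.
* Edge lists are normalized (unordered pairs, lexicographically smaller id
  first), self-loops dropped and counted; the network is order-independent
  of input rows.
* The empty-PPI degenerate case warns and retains only direct drug–disease
  overlaps. A network with no drug targets cannot be disease-connected and
  raises.
* Test and acceptance problem sizes: exhaustive enumeration oracles run at
  N ≤ 15, centrality brute-force oracles at 30 nodes, recovery experiments
  at 100 replicates of the full-scale generator — sizes at which the
  oracles are exact and the whole suite runs in seconds.

## Known limitations

* The point-probability default reproduces the published statistic but is
  not a calibrated tail test; use `variant="upper_tail"` (optionally with
  Benjamini–Hochberg) for conventional inference.
* "Connected" defaults to one PPI hop; deeper connection pulls in rapidly
  growing bridge neighbourhoods and the retained set is monotone in the
  hop budget, so results should be compared at a fixed budget.
* Published candidate-target rosters from studies of this kind are not
  recoverable: they depend on private networks. The screening *rule* is the
  tested object; specific rosters are not.
* Disease names are stored verbatim; no ontology normalization or term
  expansion is attempted.
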