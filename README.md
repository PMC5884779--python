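# netpharm

Network-pharmacology drug repositioning for multi-compound drugs such as
multi-herb traditional-medicine formulae. Given (1) docking-based
compound→protein target predictions with fit scores, (2) a disease→target
database as named gene sets, (3) an undirected protein–protein interaction
(PPI) network and (4) a herb→compound membership table, the package

* assembles a **compound–target–disease network**: predictions are kept at a
  fit-score threshold (default ≥ 4.0), drug targets are linked to compounds
  and compounds to herbs, and disease targets are attached through PPI —
  disease targets that cannot be connected to any drug target are discarded;
* ranks candidate **disease indications** with an exact hypergeometric
  statistic: with N targets in the disease universe, n of them connected to
  the drug network, and a disease covering K universe targets of which k are
  connected, the score is the point probability

      P(X = k) = C(K, k) · C(N−K, n−k) / C(N, n),

  computed with exact integer arithmetic (the conventional upper tail
  P(X ≥ k) is available as a variant); diseases with p < 0.05 and match > 2
  are called *major predicted diseases*;
* screens **candidate protein targets** by a median-based centrality rule:
  hubs are nodes with degree > 2 × median degree, and candidates are hubs
  whose betweenness and closeness centralities both exceed the network
  medians (NetworkAnalyzer normalization conventions);
* runs generic **pathway over-representation** (hypergeometric tail or the
  conservative EASE variant) against GMT pathway collections; and
* attributes targets to **individual herbs** by counting each herb's
  components connected to a target and flagging targets at or above the
  herb's median component count.

A fully seeded synthetic-data generator reproduces the statistical structure
and scale of such studies (6 herbs, 219 compounds, 229 drug targets, 63
diseases over a 749-target universe), so the entire pipeline is testable
without any external downloads.

## Worked example

The package ships the published 34-disease worked example of this analysis
(a six-herb hepatoprotective formula against liver diseases, N = 749,
n = 151) as a direct input to the enrichment stage:

```python
from netpharm import enrich_from_counts, select_major_diseases, reference_fixture

triples, config = reference_fixture()          # 34 (disease, k, K) rows; N=749, n=151
rows = enrich_from_counts(triples, config)     # ranked by ascending p
for r in rows[:6]:
    print(f"{r.disease:<24s} {r.match}\\{r.total}  p={r.p_value:.6f}")
print([r.disease for r in select_major_diseases(rows, config)])
```

prints

```
Hepatitis                48\176  p=0.002593
Liver Failure, Acute     4\5  p=0.006421
Hypertension, Portal     6\11  p=0.009634
Hepatitis B              18\57  p=0.012610
Fatty Liver              15\45  p=0.013305
Liver Failure            15\52  p=0.038202
['Hepatitis', 'Liver Failure, Acute', 'Hypertension, Portal', 'Hepatitis B', 'Fatty Liver', 'Liver Failure']
```

The p-values are the exact point probabilities (e.g. the 1\1 diseases score
exactly n/N = 151/749 = 0.201602), and the p < 0.05 & match > 2 filter
returns the six major predicted indications, hepatitis and (acute) liver
failure leading.

For a full run on synthetic data:

```python
from netpharm import NetworkPharmacologyModel, SyntheticConfig, generate_inputs

inp = generate_inputs(SyntheticConfig(seed=1))
model = NetworkPharmacologyModel(inp.predictions, inp.herb_membership,
                                 inp.disease_db, inp.ppi)
results = model.fit()
print(results.summary())      # N, n, major diseases, screen thresholds, medians
results.save_reports("out/")  # deterministic TSV/JSON reports
```

The same pipeline is available from the shell via the `netpharm` command
(`simulate`, `build`, `enrich-diseases`, `screen-targets`,
`enrich-pathways`, `attribute-herbs`, and a one-shot `run` driven by a YAML
config that writes a manifest with input checksums and derived quantities).

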