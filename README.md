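# dmrg — weighted knowledge-based differential network gene ranking

`dmrg` prioritises disease-relevant (in particular metabolism-related) genes
from a two-condition transcriptome by asking not *which genes change level*
but *which genes rewire their co-expression neighbourhood* — and by trusting a
rewired link only when curated protein–protein interaction (PPI) evidence
backs it. It is aimed at systems-biology analyses of paired tumour/normal
cohorts (the motivating use case is prostate cancer glucose-metabolism
regulators), where differential co-expression alone is noisy at small sample
sizes.

## Method

Given a genes × samples expression matrix with tumour/normal labels and a
confidence-scored PPI edge list (STRING dialect):

1. **Differential network (S-DN).** For every gene pair the Spearman rank
   correlation is computed separately per condition, `PCC_T` and `PCC_N`. An
   edge is created iff `ΔPCC = |PCC_T − PCC_N| > τ` (strict; default
   `τ = 0.8`), with edge weight `w_DN = ΔPCC`.
2. **Knowledge weights.** Raw PPI confidences are quantile-discretized: edges
   are mid-ranked by confidence and mapped to `n_bins` equal-frequency bins
   (default deciles), giving `w_PPI = bin / n_bins ∈ (0, 1]` — rank-based,
   hence invariant to the confidence scale.
3. **Fusion (W-K-DN).** The weighted knowledge-based differential network
   keeps the edges present in *both* networks with weight `w_DN · w_PPI`.
4. **Ranking.** Each gene is scored by weighted degree centrality,
   `s(v) = Σ_{u∈neighbor(v)} w_DN(u,v)·w_PPI(u,v)`, ranked (lexicographic
   tie-break), confirmed by the unfolded per-gene ROC AUC of expression vs the
   tumour label (normalised Mann–Whitney U, ties count ½), and flagged against
   a metabolic-enzyme gene set.
5. **Subnetworks.** First-neighbour (ego) subnetworks of a seed gene, gene-set
   overlap annotation, and an optional bipartite protein–RNA interaction
   overlay; gene–metabolite Spearman tables for metabolomics follow-up.

A synthetic-data module generates paired cohorts with planted differential
hubs and a matching noisy PPI, so the whole pipeline is testable with known
ground truth and no downloads.

## Worked example

```python
import dmrg

expr, ppi, enzymes, truth = dmrg.generate(dmrg.SyntheticConfig(seed=1))
table, ranker = dmrg.rank_genes_dmrg(expr, ppi, enzymes)
print("planted hubs:", truth.hub_ids)
print(table.head(6).to_string(index=False))
```

prints

```
planted hubs: ['G0275', 'G0241', 'G0035', 'G0165', 'G0411']
 gene    score      auc  rank  is_metabolic
G0411 9.736348 0.552083     1         False
G0035 9.001652 0.442708     2          True
G0241 8.640087 0.595486     3          True
G0275 8.196609 0.579861     4          True
G0165 7.824174 0.482639     5         False
G0185 1.646087 0.434028     6         False
```

All five planted differential hubs occupy ranks 1–5 out of 500 genes: their
scores (≈8–10, the summed fused weights of their rewired, PPI-backed module
edges) separate cleanly from the best background gene (≈1.6). The `auc`
column stays near 0.5 because these hubs *rewire* without changing expression
level — exactly the kind of gene a differential-expression screen misses.
`dmrg.metabolic_shortlist(table, 3)` filters the ranking to enzyme-set
members (here ranks 2–4).

The same flow is scriptable as an sklearn transformer
(`DMRGRanker(tau=0.8, n_bins=10, top_k=25).fit(X, y, ppi=ppi)`, where `X` is
samples × genes) or from the shell:

```sh
dmrg simulate --seed 1 --out-dir fixtures/
dmrg build --expr fixtures/expression.tsv --labels fixtures/labels.tsv \
     --ppi fixtures/ppi.tsv --enzymes fixtures/enzymes.txt \
     --out-graph wkdn.graphml --out-table scores.tsv
dmrg subnet --graph wkdn.graphml --seed-gene G0411 --out sub.graphml
dmrg report-groups --counts counts.tsv
dmrg run --config run.yaml          # full pipeline + manifest
```

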