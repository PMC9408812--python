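# Methods

## Model and assumptions

The method treats disease as a *rewiring* phenomenon: a gene matters when the
rank correlations between it and its partners differ strongly between the
tumour and normal states, and when those partnerships are supported by curated
protein–protein interaction evidence. Three assumptions follow:

- **Condition-wise exchangeability.** Correlations are estimated separately
  per condition; samples within a condition are treated as i.i.d. The paired
  structure of a cohort (tumour and normal tissue from the same patient) is
  carried in the data model (`pair_id`) but does not enter the statistics —
  the differential edge rule uses only condition-wise Spearman correlations.
- **Monotone association suffices.** Spearman's coefficient (Pearson on
  mid-rank-transformed vectors, average ranks for ties) is used throughout,
  so any monotone transform of the expression scale (log, quantile
  normalisation) leaves the network unchanged.
- **Knowledge as a filter, not a prior.** PPI evidence enters
  multiplicatively and only on edges present in both networks; it can
  down-weight or remove a differential edge but never create one.

## The pipeline, numerically

1. **Differential network.** For each gene pair, `ΔPCC = |PCC_T − PCC_N|`
   (range [0, 2]); an edge exists iff `ΔPCC > τ` with *strict* inequality —
   a pair sitting exactly at the threshold gets no edge. Pairs involving a
   gene constant within a condition have an undefined correlation and are
   excluded rather than imputed; imputing 0 would fabricate a ΔPCC of the
   size of the other condition's correlation. All O(p²) pairs are scanned
   (no variance pre-filter); an optional restriction to PPI genes bounds
   cost on large transcriptomes. Each condition needs ≥ 3 samples.
2. **Quantile discretization.** With `m` PPI edges and `n_bins` bins, edge
   ranks (mid-ranks for ties, so ties always share a bin) map to
   `bin = ceil(rank · n_bins / m)`, computed in integer arithmetic on
   doubled ranks so the ceiling is exact. `w_PPI = bin / n_bins`. Defaults:
   `n_bins = 10` (deciles give a (0,1] ladder of granularity comparable to
   ΔPCC) and bin value = upper index / n_bins so the top decile weighs 1.0
   and fused weights never exceed the ΔPCC scale. Discretization happens on
   the full loaded PPI, before intersection with the differential network.
3. **Fusion and scoring.** Fused weight `w_DN · w_PPI ∈ (0, 2]`. The node
   score is the weighted degree `s(v) = Σ incident weights`; genes of the
   expression matrix with no fused edge are kept with score 0, so the
   ranking covers the whole transcriptome. Ties in the ranking are broken
   lexicographically by gene id — deterministic output across runs.
4. **AUC confirmation.** Per-gene ROC AUC of expression against the tumour
   label, equal to Mann–Whitney U / (n_T·n_N) with ties counted ½, reported
   *unfolded* (a tumour-down gene scores < 0.5). Tumour is the positive
   class, higher expression scores positive.
5. **Subnetworks.** The default ego network is non-induced (seed plus
   incident edges); induced mode adds neighbour–neighbour fused edges. In
   the protein–RNA overlay an RNA id colliding with an existing protein node
   is namespaced `rna:<id>` to preserve the bipartite protein–RNA edge
   invariant; overlay edges are unweighted, and the operation is idempotent.
6. **Clinical summary.** Per-group high-expression proportions are
   `100·n_high/n_total` rounded half-up to one decimal, matching the printed
   precision of published group percentages; the high/low cut-off is taken
   as given with the counts.

## Tunable parameters

| parameter | default | meaning / why |
|---|---|---|
| `tau` | 0.8 | strict ΔPCC edge threshold, domain [0, 2); at 24 pairs the null sd of ΔPCC is ≈ 0.3, so 0.8 admits ≈ 0.6% of null pairs |
| `n_bins` | 10 | quantile bins for `w_PPI`; deciles, configurable |
| `top_k` (ranker) | None | genes kept by `transform`; None keeps all positive-score genes |
| `induced` | off | ego-network mode |

## Synthetic-data generator

Each planted hub carries a latent factor; its `hub_degree` neighbours are
`ρ·hub + √(1−ρ²)·ε` with `ρ = rho_base = 0.9` in the normal state and
`ρ = rho_flip = −0.4` in the tumour state (a one-factor Gaussian-copula
module; the implied module correlation matrix is checked for positive
semi-definiteness before sampling). Population hub–neighbour Spearman is
`(6/π)·asin(ρ/2)` ≈ 0.89 and −0.39, so planted pairs have population
ΔSPCC ≈ 1.27 — comfortably above τ = 0.8 — while neighbour–neighbour pairs
(Pearson ρ²) stay below it; hub–neighbour pairs are therefore the ground-truth
differential edges. Background genes are independent. Observed values are
`8 + latent + noise_sd·ε` (noise_sd = 0.1), an arbitrary log-intensity-like
scale that Spearman ignores. Defaults mirror a 24-paired-tissue cohort with
500 genes and 5 hubs of degree 8, so users see realistic estimator noise at
τ = 0.8. Hubs are planted at uniformly random gene positions so the
lexicographic tie-break carries no hub signal. The PPI includes 90% of true
edges plus 200 false edges, confidences ~N(800, 100²) vs ~N(450, 150²)
clipped to [150, 999] — overlapping, so discretization is exercised
non-trivially while true edges stochastically dominate. The enzyme set holds
half the hubs plus 50 random non-module decoys.

What the generator does *not* emulate: count-based mean–variance structure,
library-size or batch effects, differential mean expression (planted hubs
rewire at constant level, hence AUC ≈ 0.5), realistic PPI topology
(hubby scale-free structure), or identifier mapping noise. Passing tests
therefore demonstrate correctness of the algorithmic chain and recoverability
under the stated correlation model, not performance on real cohorts.

## Verification design and problem sizes

Statistical primitives are verified against independent oracles: Spearman
against the `1 − 6Σd²/(n(n²−1))` formula (exhaustive permutations, no ties)
and hand-computed mid-rank Pearson (ties); AUC against exhaustive
Mann–Whitney pair enumeration (≤ 20 samples, tolerance 1e−12); discretization
against an exact-Fraction quantile oracle; the edge rule against a
brute-force pairwise scan on ≤ 8-gene matrices. Property tests cover
threshold monotonicity, tumour/normal-swap symmetry, rescaling invariance of
discretization, the handshake identity of the score, and idempotence of the
protein–RNA overlay.

End-to-end recovery runs ten cohorts at the default configuration
(500 genes × 24 pairs) — the size at which a full ranking takes about a
second — and requires every planted hub in the top 5% of ranks in the median
run; the same cohorts with uniformly permuted condition labels must give hub
ranks consistent with uniformity (KS p > 0.01). The null edge rate of the
ΔPCC rule is measured on hub-free cohorts of 300 genes (the rate is per-pair
and size-free). `scripts/acceptance.py` recomputes all of these from scratch
plus the five per-Gleason-group percentages from their published counts.

## Edge cases and limitations

- Exactly-at-threshold correlation differences produce no edge (strict rule);
  users probing the boundary should feed correlations via
  `dn_from_correlations`, since empirical Spearman values rarely hit a
  threshold exactly in floating point.
- Constant genes: flagged undefined in correlation matrices, excluded from
  edges; their AUC is 0.5 (all ties).
- Reversed-duplicate PPI rows keep the maximum confidence (conservative
  toward evidence); self-loops and non-numeric scores are dropped with
  counts.
- Identifiers are opaque, case-sensitive strings; mapping between protein
  and transcript namespaces is the user's responsibility (a two-column map
  file is accepted).
- The quantile bin count and bin-value convention are free choices of this
  implementation (documented defaults above); rankings are insensitive to
  monotone re-labelling of bins but scores are not.
- With fewer than ~20 samples per condition the ΔPCC estimator is noisy
  enough that τ = 0.8 trades recall for precision; raising n or lowering τ
  moves along that trade-off.
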