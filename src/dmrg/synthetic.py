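"""Synthetic paired two-condition data with planted differential hubs.

The generator emulates the shape of a paired tumour/normal transcriptome
cohort (default 24 pairs) together with a confidence-scored PPI, so the whole
pipeline is testable with known ground truth and no downloads.

Model. Gene expression is Gaussian-copula structured: each planted hub gene
carries a latent factor, and each of its module neighbours is
``rho * hub + sqrt(1 - rho^2) * noise`` with ``rho = rho_base`` in the normal
condition and ``rho = rho_flip`` in the tumour condition. Hub-neighbour
rank correlation therefore flips between conditions (population Spearman of a
bivariate Gaussian with Pearson rho is (6/pi) asin(rho/2), about 0.89 at
rho = 0.9), giving planted pairs a population dPCC well above the 0.8 edge
threshold under the defaults, while neighbour-neighbour pairs (Pearson rho^2)
stay below it. Background genes are independent noise. Observed values are
``8 + latent + noise_sd * eps`` — an arbitrary log-intensity-like scale;
Spearman is invariant to it.

PPI. A fraction ``ppi_coverage`` of the true hub-neighbour edges is included,
plus ``ppi_fp`` random false edges; confidences are drawn from overlapping
high-mean (true) and low-mean (false) distributions so that true edges
stochastically dominate but quantile discretization is exercised
non-trivially. The enzyme gene set contains half of the hubs plus random
decoy genes.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .types import NORMAL, TUMOR, ExpressionMatrix, GeneSet


@dataclass
class SyntheticConfig:
    """Study-shaped generator settings (defaults mirror a 24-pair cohort)."""

    n_genes: int = 500
    n_pairs: int = 24          # paired samples per condition
    n_hubs: int = 5
    hub_degree: int = 8        # neighbours per planted hub
    rho_base: float = 0.9      # hub-neighbour correlation, normal state
    rho_flip: float = -0.4     # hub-neighbour correlation, tumour state
    noise_sd: float = 0.1      # observation noise on top of unit-sd signal
    ppi_coverage: float = 0.9  # fraction of true edges present in the PPI
    ppi_fp: int = 200          # random false PPI edges
    n_enzyme_decoys: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_pairs < 1:
            raise ValueError("n_genes and n_pairs must be positive")
        if self.n_hubs < 0 or self.hub_degree < 1:
            raise ValueError("n_hubs must be >= 0 and hub_degree >= 1")
        if abs(self.rho_base) > 1 or abs(self.rho_flip) > 1:
            raise ValueError("|rho_base| and |rho_flip| must be <= 1")
        if self.noise_sd < 0 or not (0 <= self.ppi_coverage <= 1) or self.ppi_fp < 0:
            raise ValueError("noise_sd, ppi_coverage, ppi_fp out of range")
        if self.n_hubs * (1 + self.hub_degree) > self.n_genes:
            raise ValueError("modules do not fit: n_hubs*(1+hub_degree) > n_genes")
        for rho in (self.rho_base, self.rho_flip):
            _check_module_psd(rho, self.hub_degree)


@dataclass
class GroundTruth:
    """What was planted: hubs, population differential edges, PPI truth."""

    hub_ids: list[str]
    true_dn_edges: list[tuple[str, str]]
    ppi_edges: list[tuple[str, str, float, bool]]  # (u, v, confidence, is_true)
    hub_neighbors: dict[str, list[str]] = field(default_factory=dict)


def _check_module_psd(rho: float, hub_degree: int) -> None:
    """One-factor module correlation matrix must be positive semi-definite."""
    k = hub_degree + 1
    c = np.full((k, k), rho * rho)
    c[0, :] = c[:, 0] = rho
    np.fill_diagonal(c, 1.0)
    if np.linalg.eigvalsh(c).min() < -1e-8:
        raise ValueError(f"infeasible module correlation matrix at rho={rho}")


def _sample_condition(
    rng: np.random.Generator,
    n_genes: int,
    n_samples: int,
    modules: list[tuple[int, list[int]]],
    rho: float,
    noise_sd: float,
) -> np.ndarray:
    z = rng.standard_normal((n_genes, n_samples))
    for hub, nbrs in modules:
        z[nbrs] = rho * z[hub] + np.sqrt(1.0 - rho * rho) * z[nbrs]
    x = 8.0 + z
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(x.shape)
    return x


def generate(
    config: SyntheticConfig | None = None, **overrides
) -> tuple[ExpressionMatrix, nx.Graph, GeneSet, GroundTruth]:
    """Draw (expression, ppi, enzyme gene set, ground truth) from the model."""
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    # hubs planted at random positions so gene-id order carries no signal
    perm = rng.permutation(config.n_genes)
    modules: list[tuple[int, list[int]]] = []
    cursor = 0
    for _ in range(config.n_hubs):
        hub = int(perm[cursor])
        nbrs = [int(i) for i in perm[cursor + 1 : cursor + 1 + config.hub_degree]]
        modules.append((hub, nbrs))
        cursor += 1 + config.hub_degree

    x_t = _sample_condition(
        rng, config.n_genes, config.n_pairs, modules, config.rho_flip, config.noise_sd
    )
    x_n = _sample_condition(
        rng, config.n_genes, config.n_pairs, modules, config.rho_base, config.noise_sd
    )
    t_ids = [f"T{i:02d}" for i in range(1, config.n_pairs + 1)]
    n_ids = [f"N{i:02d}" for i in range(1, config.n_pairs + 1)]
    p_ids = [f"P{i:02d}" for i in range(1, config.n_pairs + 1)]
    values = pd.DataFrame(
        np.hstack([x_t, x_n]), index=genes, columns=t_ids + n_ids
    )
    condition = pd.Series([TUMOR] * config.n_pairs + [NORMAL] * config.n_pairs,
                          index=values.columns)
    pair_id = pd.Series(p_ids + p_ids, index=values.columns)
    expr = ExpressionMatrix(values=values, condition=condition, pair_id=pair_id)

    # ground-truth differential edges: hub-neighbour pairs only
    true_edges = [
        (genes[min(h, j)], genes[max(h, j)]) for h, nbrs in modules for j in nbrs
    ]
    n_cov = int(round(config.ppi_coverage * len(true_edges)))
    cov_idx = rng.choice(len(true_edges), size=n_cov, replace=False) if true_edges else []
    covered = [true_edges[i] for i in sorted(cov_idx)]

    true_set = set(true_edges)
    max_fp = config.n_genes * (config.n_genes - 1) // 2 - len(true_set)
    n_fp = min(config.ppi_fp, max_fp)
    false_edges: list[tuple[str, str]] = []
    seen = set(true_set)
    while len(false_edges) < n_fp:
        i, j = rng.integers(0, config.n_genes, size=2)
        if i == j:
            continue
        e = (genes[min(i, j)], genes[max(i, j)])
        if e in seen:
            continue
        seen.add(e)
        false_edges.append(e)

    ppi = nx.Graph(self_loops_dropped=0, rows_rejected=0)
    ppi_records: list[tuple[str, str, float, bool]] = []
    conf_true = np.clip(rng.normal(800.0, 100.0, size=len(covered)), 150.0, 999.0)
    conf_false = np.clip(rng.normal(450.0, 150.0, size=len(false_edges)), 150.0, 999.0)
    for (u, v), c in zip(covered, conf_true):
        ppi.add_edge(u, v, confidence=float(np.round(c, 1)))
        ppi_records.append((u, v, float(np.round(c, 1)), True))
    for (u, v), c in zip(false_edges, conf_false):
        ppi.add_edge(u, v, confidence=float(np.round(c, 1)))
        ppi_records.append((u, v, float(np.round(c, 1)), False))

    hub_ids = [genes[h] for h, _ in modules]
    n_enzyme_hubs = (config.n_hubs + 1) // 2
    enzyme_hubs = hub_ids[:n_enzyme_hubs]
    non_module = [g for g in genes if g not in {genes[i] for i in perm[:cursor]}]
    n_decoys = min(config.n_enzyme_decoys, len(non_module))
    decoys = (
        [non_module[i] for i in rng.choice(len(non_module), n_decoys, replace=False)]
        if n_decoys
        else []
    )
    enzymes = GeneSet(name="metabolic_enzymes", members=frozenset(enzyme_hubs + decoys))

    truth = GroundTruth(
        hub_ids=hub_ids,
        true_dn_edges=true_edges,
        ppi_edges=ppi_records,
        hub_neighbors={genes[h]: [genes[j] for j in nbrs] for h, nbrs in modules},
    )
    return expr, ppi, enzymes, truth


def write_fixture_dir(out_dir, config: SyntheticConfig | None = None) -> dict:
    """Materialise one draw as text files in the package's IO dialects.

    Writes ``expression.tsv``, ``labels.tsv``, ``ppi.tsv``, ``enzymes.txt``
    and ``truth.txt`` under ``out_dir``; returns the paths.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, ppi, enzymes, truth = generate(config or SyntheticConfig())

    expr_path = out / "expression.tsv"
    expr.values.to_csv(expr_path, sep="\t", float_format="%.6f")
    labels_path = out / "labels.tsv"
    with open(labels_path, "w") as fh:
        for s in expr.sample_ids:
            fh.write(f"{s}\t{expr.condition[s]}\t{expr.pair_id[s]}\n")
    ppi_path = out / "ppi.tsv"
    with open(ppi_path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for u, v, c, _ in truth.ppi_edges:
            fh.write(f"{u}\t{v}\t{c}\n")
    enz_path = out / "enzymes.txt"
    with open(enz_path, "w") as fh:
        fh.write("# synthetic metabolic-enzyme gene set\n")
        for g in sorted(enzymes.members):
            fh.write(g + "\n")
    truth_path = out / "truth.txt"
    with open(truth_path, "w") as fh:
        fh.write("# planted differential hubs\n")
        for h in truth.hub_ids:
            fh.write(h + "\n")
    return {
        "expression": expr_path,
        "labels": labels_path,
        "ppi": ppi_path,
        "enzymes": enz_path,
        "truth": truth_path,
    }
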