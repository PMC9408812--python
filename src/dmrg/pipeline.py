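"""End-to-end pipeline: differential network -> discretize -> fuse -> rank.

A :class:`RunConfig` (flat-key YAML file, every key overridable from the CLI)
names the inputs and parameters; :func:`run_pipeline` validates all paths up
front, executes the stages with per-stage timing logged to stderr, writes the
artifacts (differential network, W-K-DN, score table, optional subnetwork)
and a machine-readable manifest with input checksums, and is deterministic:
identical config and inputs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__, diffnet, io as dio, subnetwork as subnet, wkdn
from .types import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the underlying cause."""


@dataclass
class RunConfig:
    expression: str = ""
    labels: str = ""
    ppi: str = ""
    enzymes: str | None = None
    gene_sets: list[str] = field(default_factory=list)
    rna_edges: str | None = None
    id_map: str | None = None
    seed_gene: str | None = None
    induced: bool = False
    tau: float = 0.8
    n_bins: int = 10
    seed: int = 0
    out_dir: str = "dmrg_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**known)

    def validate(self) -> None:
        if not (0.0 <= self.tau < 2.0):
            raise ValueError(f"tau must be in [0, 2), got {self.tau}")
        if self.n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins}")
        required = [("expression", self.expression), ("labels", self.labels),
                    ("ppi", self.ppi)]
        optional = [("enzymes", self.enzymes), ("rna_edges", self.rna_edges),
                    ("id_map", self.id_map)] + [
            ("gene_sets", p) for p in self.gene_sets
        ]
        for name, p in required:
            if not p:
                raise ValueError(f"config is missing required path: {name}")
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} input not found: {p}")
        for name, p in optional:
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{name} input not found: {p}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)

    return _Timer()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full method; returns paths of the written artifacts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("read-inputs"):
        label_map, pair_map = dio.read_labels(config.labels)
        expr = dio.read_expression(config.expression, label_map, pair_map=pair_map)
        ppi = dio.read_ppi(config.ppi)
        if config.id_map:
            ppi = dio.apply_id_map(ppi, dio.read_id_map(config.id_map))
        enzymes = (
            dio.read_gene_set(config.enzymes, "metabolic_enzymes")
            if config.enzymes
            else None
        )

    with _stage("diffnet"):
        dn = diffnet.build_dn(expr, tau=config.tau)
    with _stage("discretize"):
        ppi_d = wkdn.discretize_confidence(ppi, n_bins=config.n_bins)
    with _stage("fuse"):
        fused = wkdn.fuse(dn, ppi_d)
    with _stage("rank"):
        table = wkdn.rank_genes(fused, expr, enzymes)

    artifacts: dict[str, str] = {}
    with _stage("write-outputs"):
        dn_path = out / "dn.tsv"
        dio.write_graph(dn, dn_path)
        wk_path = out / "wkdn.graphml"
        dio.write_graph(fused, wk_path)
        scores_path = out / "scores.tsv"
        table.to_csv(scores_path, sep="\t", index=False)
        artifacts = {"dn": str(dn_path), "wkdn": str(wk_path),
                     "scores": str(scores_path)}

    if config.seed_gene:
        with _stage("subnet"):
            sub = subnet.first_neighbor_subnetwork(
                fused, config.seed_gene, induced=config.induced
            )
            if config.rna_edges:
                sub = subnet.overlay_protein_rna(
                    sub, dio.read_rna_edges(config.rna_edges)
                )
            sub_path = out / "subnetwork.graphml"
            dio.write_graph(sub, sub_path, fmt="graphml")
            artifacts["subnetwork"] = str(sub_path)
            if config.gene_sets:
                sets = [
                    dio.read_gene_set(p, Path(p).stem) for p in config.gene_sets
                ]
                overlap = subnet.annotate_overlap(sub, sets)
                overlap_path = out / "overlap.json"
                with open(overlap_path, "w") as fh:
                    json.dump(overlap, fh, indent=2, sort_keys=True)
                artifacts["overlap"] = str(overlap_path)

    with _stage("manifest"):
        inputs = {"expression": config.expression, "labels": config.labels,
                  "ppi": config.ppi}
        for name, p in (("enzymes", config.enzymes),
                        ("rna_edges", config.rna_edges),
                        ("id_map", config.id_map)):
            if p:
                inputs[name] = p
        manifest = {
            "dmrg_version": __version__,
            "config": asdict(config),
            "input_sha256": {k: _sha256(v) for k, v in inputs.items()},
            "n_genes": expr.n_genes,
            "n_samples": expr.n_samples,
            "n_dn_edges": dn.number_of_edges(),
            "n_wkdn_edges": fused.number_of_edges(),
            "artifacts": artifacts,
        }
        manifest_path = out / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        artifacts["manifest"] = str(manifest_path)
    return artifacts
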