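"""End-to-end pipeline: assemble -> refine -> cross-talk -> report.

A run is described by a single YAML config (paths, stage boundaries,
score threshold, fitting mode, core size, seed) so that every artifact on
disk can be regenerated from one file.  The pipeline writes, per stage, the
refined network in SIF and GraphML plus a fit table, and overall the CTRV
table, the stage-wise ranking, the bow-tie core list, node colour
attributes (signed log2 ratio vs the first time point) and a manifest
recording the config hash, package versions and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crosstalk import (
    assign_pathways,
    compute_ctrv,
    rank_crosstalk,
    select_core,
    top_per_stage,
)
from .model import PROXY
from .network import (
    BIOGRID_LIKE,
    DEFAULT_MIN_SCORE,
    STRING_LIKE,
    assemble_rough_ppan,
    read_edge_list,
    write_graphml,
)
from .pool import load_receptor_list, read_protein_pool
from .results import DynamicPPANModel
from .simulate import generate_truth, rough_with_decoys, simulate_timecourse
from .timecourse import (
    DEFAULT_STAGE_BOUNDARIES_HOURS,
    build_stage_windows,
    canonical_grid_minutes,
    collapse_probes,
    read_expression_file,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated description of one pipeline run."""

    pool_path: Path
    expression_path: Path
    out_dir: Path
    edge_lists: list[dict] = field(default_factory=list)
    probe_map_path: Path | None = None
    mrna_path: Path | None = None
    stage_boundaries_hours: tuple[float, ...] = DEFAULT_STAGE_BOUNDARIES_HOURS
    min_score: float = DEFAULT_MIN_SCORE
    mode: str = PROXY
    core_k: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        base = Path(path).parent
        def _p(key):
            return (base / raw[key]) if key in raw and raw[key] else None
        cfg = cls(
            pool_path=_p("pool"),
            expression_path=_p("expression"),
            out_dir=(
                Path(overrides["out_dir"])
                if overrides.get("out_dir") is not None
                else base / raw.get("out_dir", "out")
            ),
            edge_lists=[
                {**e, "path": base / e["path"]} for e in raw.get("edge_lists", [])
            ],
            probe_map_path=_p("probe_map"),
            mrna_path=_p("mrna"),
            stage_boundaries_hours=tuple(
                raw.get("stage_boundaries_hours", DEFAULT_STAGE_BOUNDARIES_HOURS)
            ),
            min_score=float(raw.get("min_score", DEFAULT_MIN_SCORE)),
            mode=raw.get("mode", PROXY),
            core_k=int(raw.get("core_k", 10)),
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        """Fail fast before any compute."""
        for label, p in [
            ("pool", self.pool_path),
            ("expression", self.expression_path),
            ("probe_map", self.probe_map_path),
            ("mrna", self.mrna_path),
        ]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} path does not exist: {p}")
        if self.pool_path is None or self.expression_path is None:
            raise ValueError("config must name pool and expression paths")
        for e in self.edge_lists:
            if not Path(e["path"]).exists():
                raise FileNotFoundError(f"edge list does not exist: {e['path']}")
            if e.get("source", BIOGRID_LIKE) not in (BIOGRID_LIKE, STRING_LIKE):
                raise ValueError(f"bad edge-list source: {e.get('source')}")
        if self.mode not in ("proxy", "full"):
            raise ValueError(f"mode must be proxy or full, got {self.mode!r}")
        if not 0 <= self.min_score <= 1:
            raise ValueError("min_score must be in [0, 1]")

    def digest(self) -> str:
        payload = {
            k: str(v) for k, v in vars(self).items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline described by ``config``.

    Returns a dict of the key artifacts (results object, CTRV table, core)
    after writing everything under ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pool = read_protein_pool(config.pool_path)
    sources = [
        read_edge_list(
            e["path"],
            e.get("source", BIOGRID_LIKE),
            float(e.get("min_score", config.min_score)),
        )
        for e in config.edge_lists
    ]
    rough = assemble_rough_ppan(pool, sources)
    logger.info(
        "rough network: %d nodes, %d edges (%d excluded)",
        len(rough.nodes), rough.n_edges, rough.excluded_edges,
    )

    expr = read_expression_file(config.expression_path)
    missing: list[str] = []
    if config.probe_map_path is not None:
        pm = pd.read_csv(
            config.probe_map_path, sep="\t", header=None, names=["probe", "symbol"]
        )
        expr, missing = collapse_probes(expr, dict(zip(pm.probe, pm.symbol)))
    mrna = read_expression_file(config.mrna_path) if config.mrna_path else None

    windows = build_stage_windows(expr.times, config.stage_boundaries_hours)
    model = DynamicPPANModel(expr, rough, windows, mode=config.mode, mrna=mrna)
    results = model.fit()
    results.export(out)

    assignment = assign_pathways(pool)
    table = results.ctrv(assignment)
    table.to_tsv(out / "ctrv.tsv")
    top_per_stage(table).to_csv(out / "ranking_per_stage.tsv", sep="\t", index=False)
    core = select_core(table, config.core_k, load_receptor_list())
    (out / "core.txt").write_text("\n".join(core["core"]) + "\n", encoding="utf-8")
    results.node_color_attributes().to_csv(
        out / "node_colors.tsv", sep="\t", index_label="symbol"
    )
    # annotated overall network for rendering tools
    union = nx.Graph()
    for net in results.networks:
        union.add_edges_from(net.graph.edges)
    for node in union.nodes:
        union.nodes[node]["pathway"] = assignment[node]
        union.nodes[node]["core"] = node in core["core"]
    write_graphml(union, out / "union_annotated.graphml")

    manifest = {
        "config_sha256": config.digest(),
        "package": "ppanet",
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "stages": len(windows),
        "missing_symbols": missing,
        "rough_nodes": len(rough.nodes),
        "rough_edges": rough.n_edges,
        "excluded_edges": rough.excluded_edges,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return {"results": results, "ctrv": table, "core": core, "manifest": manifest}


def make_demo_fixture(outdir: str | Path, seed: int = 0) -> Path:
    """Write a self-contained synthetic study into ``outdir``.

    Emulates the real design: 20 proteins over 5 pathway classes, the
    canonical 25-point 0-8 h grid, six stage windows, proxy-mode input.
    The planted network plus decoy candidates becomes the edge list; the
    simulated mRNA matrix is the expression input.  Returns the path of
    the written config file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(
        n_proteins=20, n_classes=5, edge_density=0.08,
        cross_class_fraction=0.5, seed=seed, noise_sigma=0.05,
    )
    mrna, protein = simulate_timecourse(truth, canonical_grid_minutes())
    rough = rough_with_decoys(truth, decoy_fraction=1.0, seed=seed + 10_000)

    # pool file: one column per class, padded rows
    by_class: dict[str, list[str]] = {}
    for s, c in truth.labels.items():
        by_class.setdefault(c, []).append(s)
    classes = sorted(by_class)
    depth = max(len(v) for v in by_class.values())
    lines = ["\t".join(classes)]
    for i in range(depth):
        lines.append(
            "\t".join(by_class[c][i] if i < len(by_class[c]) else "" for c in classes)
        )
    (outdir / "pool.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    with open(outdir / "candidates.tsv", "w", encoding="utf-8") as fh:
        fh.write("# candidate associations (planted + decoys)\n")
        for a, b in sorted(tuple(sorted(e)) for e in rough.graph.edges):
            fh.write(f"{a}\t{b}\n")
    with open(outdir / "truth_edges.tsv", "w", encoding="utf-8") as fh:
        for (q, p), b in sorted(truth.coefficients.items()):
            fh.write(f"{q}\t{p}\t{b:.6f}\n")
    mrna.to_tsv(outdir / "mrna.tsv")
    protein.to_tsv(outdir / "protein.tsv")

    config = {
        "pool": "pool.tsv",
        "expression": "mrna.tsv",
        "edge_lists": [{"path": "candidates.tsv", "source": BIOGRID_LIKE}],
        "stage_boundaries_hours": list(DEFAULT_STAGE_BOUNDARIES_HOURS),
        "mode": "proxy",
        "core_k": 10,
        "seed": seed,
        "out_dir": "out",
    }
    cfg_path = outdir / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=True), encoding="utf-8")
    return cfg_path
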