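"""End-to-end orchestration: simulate/ingest -> integrate -> trajectory ->
phases -> graph attention -> selection -> validation/GRN.

A run is driven by a single `RunConfig` (JSON/YAML serializable, unknown keys
rejected) and a global seed that fans out to per-stage derived seeds
(seed + stage index), so stages are independently reproducible. Every stage
writes its artifacts under its own subdirectory with a completion marker
holding the config hash; re-running with the same config skips completed
stages and resumes from the first missing one. The final manifest records
the config hash, seed, per-stage files with checksums, and wall-clock times.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from . import io as bio
from .branching import PhaseClassifier, phase_cells
from .downstream import GRNInference, reconstruct_with_selected, stage_de
from .hgt import GASMatrix, GeneAttentionHGT
from .integration import GeneIntegrationMatrix, MultiomeIntegrator
from .selection import BranchGeneSelector
from .synthetic import read_multiome, simulate_bifurcation, write_multiome
from .trajectory import TrajectoryInference

logger = logging.getLogger(__name__)

STAGES = ["simulate", "integrate", "trajectory", "phases", "hgt", "select",
          "downstream"]


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run."""

    out_dir: str = "branchgas_run"
    seed: int = 7
    input_dir: str = None  # existing multiome directory; None -> simulate
    # simulation
    n_cells: int = 300
    n_genes: int = 200
    n_branch_genes: int = 20
    noise: float = 0.3
    # integration
    mode: str = "average"
    decay_bp: int = 10_000
    window_bp: int = 50_000
    # trajectory
    n_components: int = 20
    k: int = None  # None -> BIC scan
    root: int = None
    # branching phases
    rho: int = 2
    theta: float = 0.3
    assoc_frac: float = 0.2
    dominant_frac: float = 0.8
    # graph transformer
    embed_dim: int = 256
    hidden_dim: int = 128
    n_heads: int = 16
    n_layers: int = 2
    epochs: int = 100
    lr: float = 0.01
    edge_threshold: float = 0.0
    # selection
    top_n: int = 40
    gas_threshold: float = None
    prevalence: float = 0.5
    # downstream
    grn_trees: int = 100
    grn_top_edges: int = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.n_branch_genes >= self.n_genes:
            raise ValueError("n_branch_genes must be < n_genes")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            if str(path).endswith((".yaml", ".yml")):
                import yaml

                return cls.from_dict(yaml.safe_load(fh))
            return cls.from_dict(json.load(fh))

    def to_dict(self):
        return dataclasses.asdict(self)

    def config_hash(self):
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        return (self.seed + STAGES.index(stage)) % (2**31)


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _stage_dir(cfg, stage):
    return os.path.join(cfg.out_dir, stage)


def _marker(cfg, stage):
    return os.path.join(_stage_dir(cfg, stage), ".done")


def _stage_complete(cfg, stage):
    marker = _marker(cfg, stage)
    if not os.path.exists(marker):
        return False
    with open(marker) as fh:
        return fh.read().strip() == cfg.config_hash()


def _mark_complete(cfg, stage):
    with open(_marker(cfg, stage), "w") as fh:
        fh.write(cfg.config_hash())


def _write_gim(gim: GeneIntegrationMatrix, directory):
    os.makedirs(directory, exist_ok=True)
    spio.mmwrite(os.path.join(directory, "gim.mtx"),
                 sparse.csr_matrix(gim.X))
    pd.Series(gim.cell_ids).to_csv(os.path.join(directory, "cells.tsv"),
                                   sep="\t", index=False, header=False)
    pd.Series(gim.gene_ids).to_csv(os.path.join(directory, "genes.tsv"),
                                   sep="\t", index=False, header=False)
    with open(os.path.join(directory, "provenance.json"), "w") as fh:
        json.dump(gim.provenance, fh)


def load_gim(directory) -> GeneIntegrationMatrix:
    X = sparse.csr_matrix(spio.mmread(os.path.join(directory, "gim.mtx"))).toarray()
    cells = pd.read_csv(os.path.join(directory, "cells.tsv"), sep="\t",
                        header=None)[0].tolist()
    genes = pd.read_csv(os.path.join(directory, "genes.tsv"), sep="\t",
                        header=None)[0].tolist()
    prov_path = os.path.join(directory, "provenance.json")
    prov = {}
    if os.path.exists(prov_path):
        with open(prov_path) as fh:
            prov = json.load(fh)
    return GeneIntegrationMatrix(X=X, cell_ids=cells, gene_ids=genes,
                                 provenance=prov)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns the run manifest.

    Completed stages (matching config hash) are reloaded, not recomputed.
    """
    cfg = config
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest = {"config": cfg.to_dict(), "config_hash": cfg.config_hash(),
                "seed": cfg.seed, "stages": {}, "warnings": []}
    state = {}

    def finish(stage, t0, skipped=False):
        sdir = _stage_dir(cfg, stage)
        files = {}
        for base, _, names in os.walk(sdir):
            for name in sorted(names):
                if name == ".done":
                    continue
                path = os.path.join(base, name)
                files[os.path.relpath(path, cfg.out_dir)] = _sha256(path)
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "skipped": skipped,
            "files": files,
        }

    for stage in STAGES:
        t0 = time.time()
        sdir = _stage_dir(cfg, stage)
        os.makedirs(sdir, exist_ok=True)
        resumed = _stage_complete(cfg, stage)
        try:
            _run_stage(cfg, stage, sdir, state, resumed, manifest)
        except Exception:
            manifest["stages"][stage] = {"failed": True}
            _write_manifest(cfg, manifest, partial=True)
            logger.exception("stage %s failed", stage)
            raise
        if not resumed:
            _mark_complete(cfg, stage)
        finish(stage, t0, skipped=resumed)
    _write_manifest(cfg, manifest)
    return manifest


def _write_manifest(cfg, manifest, partial=False):
    name = "manifest.partial.json" if partial else "manifest.json"
    with open(os.path.join(cfg.out_dir, name), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _run_stage(cfg, stage, sdir, state, resumed, manifest):
    if stage == "simulate":
        if cfg.input_dir is not None:
            src = cfg.input_dir
        else:
            if not resumed:
                sim = simulate_bifurcation(
                    cfg.n_cells, cfg.n_genes, cfg.n_branch_genes, cfg.noise,
                    seed=cfg.stage_seed("simulate"))
                write_multiome(sim, sdir)
            src = sdir
        (state["rna"], state["cells"], state["genes"], state["atac"],
         state["peak_names"], state["peak_bed"], state["annotation"],
         state["truth_cells"], state["truth_genes"]) = read_multiome(src)

    elif stage == "integrate":
        if resumed and os.path.exists(os.path.join(sdir, "gim.mtx")):
            state["gim"] = load_gim(sdir)
        else:
            integ = MultiomeIntegrator(mode=cfg.mode, decay_bp=cfg.decay_bp,
                                       window_bp=cfg.window_bp)
            state["gim"] = integ.fit_transform(
                state["rna"], state["atac"], state["peak_bed"],
                state["annotation"], cell_ids=state["cells"],
                gene_ids=state["genes"])
            _write_gim(state["gim"], sdir)

    elif stage == "trajectory":
        gim = state["gim"]
        traj = TrajectoryInference(n_components=cfg.n_components, k=cfg.k,
                                   root=cfg.root,
                                   seed=cfg.stage_seed("trajectory"))
        traj.fit(gim.X, cell_totals=gim.X.sum(axis=1))
        state["trajectory"] = traj
        model = traj.lineage_model_
        pd.DataFrame({
            "cell_id": gim.cell_ids, "cluster": traj.labels_,
        }).to_csv(os.path.join(sdir, "clusters.tsv"), sep="\t", index=False)
        pd.DataFrame(model.pseudotime, index=gim.cell_ids,
                     columns=[f"lineage{i}" for i in range(model.n_lineages)]
                     ).to_csv(os.path.join(sdir, "pseudotime.tsv"), sep="\t")
        pd.DataFrame(model.lineage_weights, index=gim.cell_ids,
                     columns=[f"lineage{i}" for i in range(model.n_lineages)]
                     ).to_csv(os.path.join(sdir, "lineage_weights.tsv"), sep="\t")
        with open(os.path.join(sdir, "lineages.json"), "w") as fh:
            json.dump({"root": model.root, "lineages": model.lineages,
                       "mst_edges": model.mst_edges}, fh)

    elif stage == "phases":
        classifier = PhaseClassifier(rho=cfg.rho, theta=cfg.theta,
                                     assoc_frac=cfg.assoc_frac,
                                     dominant_frac=cfg.dominant_frac)
        classifier.fit(state["trajectory"].lineage_model_)
        state["phases"] = classifier
        rows = [{"cluster": c, "phase": p,
                 **{k: v for k, v in
                    classifier.labeling_.evidence.get(c, {}).items()
                    if not isinstance(v, (list, dict))}}
                for c, p in classifier.phase_.items()]
        pd.DataFrame(rows).to_csv(os.path.join(sdir, "phases.tsv"),
                                  sep="\t", index=False)

    elif stage == "hgt":
        gim = state["gim"]
        if resumed and os.path.exists(os.path.join(sdir, "gas.mtx")):
            scores = sparse.csr_matrix(
                spio.mmread(os.path.join(sdir, "gas.mtx"))).toarray()
            genes = pd.read_csv(os.path.join(sdir, "genes.tsv"), sep="\t",
                                header=None)[0].tolist()
            cells = pd.read_csv(os.path.join(sdir, "cells.tsv"), sep="\t",
                                header=None)[0].tolist()
            state["gas"] = GASMatrix(scores=scores, gene_ids=genes,
                                     cell_ids=cells)
            return
        est = GeneAttentionHGT(
            embed_dim=cfg.embed_dim, hidden_dim=cfg.hidden_dim,
            n_heads=cfg.n_heads, n_layers=cfg.n_layers, epochs=cfg.epochs,
            lr=cfg.lr, edge_threshold=cfg.edge_threshold,
            seed=cfg.stage_seed("hgt"))
        est.fit(gim)
        state["hgt"] = est
        state["gas"] = est.gas_
        spio.mmwrite(os.path.join(sdir, "gas.mtx"),
                     sparse.csr_matrix(est.gas_.scores))
        pd.Series(est.gas_.gene_ids).to_csv(
            os.path.join(sdir, "genes.tsv"), sep="\t", index=False, header=False)
        pd.Series(est.gas_.cell_ids).to_csv(
            os.path.join(sdir, "cells.tsv"), sep="\t", index=False, header=False)
        pd.DataFrame({"epoch": range(len(est.log_.losses)),
                      "kl_loss": est.log_.losses,
                      "lr": est.log_.lrs}).to_csv(
            os.path.join(sdir, "loss_trace.csv"), index=False)

    elif stage == "select":
        gim = state["gim"]
        cells = phase_cells(state["phases"].labeling_,
                            state["trajectory"].clustering_, "branching")
        selector = BranchGeneSelector(gas_threshold=cfg.gas_threshold,
                                      top_n=cfg.top_n,
                                      prevalence=cfg.prevalence)
        if len(cells) == 0:
            logger.warning("no branching-phase cells; selection is empty")
            selector.selected_genes_ = []
            selector.table_ = pd.DataFrame(
                columns=["mean_gas", "mean_rank", "expr_frac", "selected"])
        else:
            selector.fit(state["gas"], gim, cells)
        state["selector"] = selector
        state["branch_cells"] = cells
        selector.table_.to_csv(os.path.join(sdir, "gene_table.tsv"), sep="\t")
        pd.Series(selector.selected_genes_).to_csv(
            os.path.join(sdir, "selected_genes.tsv"), sep="\t", index=False,
            header=False)

    elif stage == "downstream":
        gim = state["gim"]
        traj = state["trajectory"]
        selected = state["selector"].selected_genes_
        report = {}
        if len(selected) >= 2:
            _, recon = reconstruct_with_selected(
                gim, selected, full_model=traj.lineage_model_,
                n_components=cfg.n_components, k=cfg.k,
                seed=cfg.stage_seed("trajectory"))
            report["reconstruction"] = recon
        # adjacent-stage DE along each lineage
        pairs = []
        for path in traj.lineage_model_.lineages:
            for a, b in zip(path[1:], path[:-1]):
                if (a, b) not in pairs:
                    pairs.append((a, b))
        de = stage_de(gim, selected or gim.gene_ids, traj.labels_, pairs)
        de.to_csv(os.path.join(sdir, "de.tsv"), sep="\t", index=False)
        # per-phase regulatory networks over the selected genes
        grn_genes = selected if len(selected) >= 3 else list(gim.gene_ids[:20])
        for phase in ("pre", "branching", "post"):
            cells = phase_cells(state["phases"].labeling_,
                                traj.clustering_, phase)
            if len(cells) < 10:
                continue
            grn = GRNInference(n_trees=cfg.grn_trees,
                               seed=cfg.stage_seed("downstream"),
                               top_k=cfg.grn_top_edges)
            sub = gim.restrict_genes(grn_genes)
            grn.fit(GeneIntegrationMatrix(sub.X[cells],
                                          [sub.cell_ids[i] for i in cells],
                                          sub.gene_ids))
            grn.network_.phase = phase
            grn.network_.edges.to_csv(
                os.path.join(sdir, f"grn_{phase}.tsv"), sep="\t", index=False)
            try:
                import networkx as nx

                nx.write_graphml(grn.network_.to_networkx(),
                                 os.path.join(sdir, f"grn_{phase}.graphml"))
            except ImportError:  # pragma: no cover
                pass
        report["n_selected"] = len(selected)
        with open(os.path.join(sdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        state["report"] = report
    else:  # pragma: no cover
        raise AssertionError(stage)
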