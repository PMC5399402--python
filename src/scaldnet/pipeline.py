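"""End-to-end orchestration: data -> MB-PLS/VIP -> clusters -> networks -> ORA.

Stage order is fixed: read (or simulate) and validate inputs, filter
genes, autoscale, per-block PCA overview, MB-PLS-DA, VIP computation/
selection/sign-splitting, PCA-smoothed k-means summarization, windowed
correlation networks, anchor first-neighbor subnetworks, member
refinement, and over-representation analysis.  Every artifact is a
plain-text table, GraphML file or JSON document, and a manifest records
the configuration, seed and library versions needed to reproduce the
bundle byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import cluster_means, kmeans_summarize, pca_smooth
from .data import (
    OmicsBlock,
    read_annotation,
    read_block,
    read_metadata,
)
from .errors import PipelineError, ValidationError
from .multivariate import assign_signs, compute_vip, fit_mbpls, fit_pca, select_vips
from .network import (
    R2_MIN,
    TWO_MONTH_DAYS,
    build_network,
    cluster_node_name,
    edge_table,
    first_neighbors,
    node_metrics,
    refine_members,
    write_graphml,
)
from .ora import fisher_ora
from .preprocess import autoscale, build_response, filter_genes, log2_transform
from .synthetic import generate_dataset, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; ``seed`` is mandatory for reproducibility."""

    seed: int
    outdir: str
    # either a synthetic-generation block ...
    synthetic: dict | None = None  # keys: n_genes, n_metabolites, noise_sd
    # ... or paths to the four input tables
    inputs: dict | None = None  # keys: expression, metabolites, metadata, annotation
    n_components: int = 3
    rpkm_threshold: float = 5.0
    n_pcs: int = 10
    k_init: int = 100
    r2_min: float = R2_MIN
    vip_p: float = 0.33
    response: str = "scald"
    anchor_early: str = "CTOL"
    anchor_late: str = "methanol"
    early_window: tuple[int, ...] = TWO_MONTH_DAYS
    log2_metabolites: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("config must set a seed")
        if (self.synthetic is None) == (self.inputs is None):
            raise ValidationError(
                "config needs exactly one of 'synthetic' or 'inputs'"
            )
        if not 0 < self.vip_p <= 0.5:
            raise ValidationError("vip_p must be in (0, 0.5]")
        if not 0 < self.r2_min <= 1:
            raise ValidationError("r2_min must be in (0, 1]")
        for name in ("n_components", "n_pcs", "k_init"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        self.early_window = tuple(int(d) for d in self.early_window)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(
                "unknown config key(s): " + ", ".join(sorted(unknown))
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["early_window"] = list(self.early_window)
        return d


def demo_config(
    outdir: str, seed: int = 7, n_genes: int = 2000, n_metabolites: int = 120
) -> PipelineConfig:
    """The one-command synthetic demo configuration."""
    return PipelineConfig(
        seed=seed,
        outdir=str(outdir),
        synthetic={
            "n_genes": n_genes,
            "n_metabolites": n_metabolites,
            "noise_sd": 0.25,
        },
    )


@contextmanager
def _stage(name: str):
    logger.info("stage: %s", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:  # abort naming the stage and cause
        raise PipelineError(name, exc) from exc


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False, **kw) -> None:
    df.to_csv(path, sep="\t", index=index, **kw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    counts: dict[str, int] = {}

    def register(key: str, path: Path) -> Path:
        artifacts[key] = path.name
        return path

    # ---- load or simulate ------------------------------------------------
    with _stage("load_data"):
        if config.synthetic is not None:
            syn = dict(config.synthetic)
            expr, metab, meta, annotation, truth = generate_dataset(
                n_genes=int(syn.get("n_genes", 2000)),
                n_metabolites=int(syn.get("n_metabolites", 120)),
                noise_sd=float(syn.get("noise_sd", 0.25)),
                seed=config.seed,
            )
            paths = write_dataset(outdir / "dataset", expr, metab, meta, annotation, truth)
            for key, p in paths.items():
                artifacts[f"dataset_{key}"] = str(p.relative_to(outdir))
        else:
            expr = read_block(config.inputs["expression"], "transcriptome")
            metab = read_block(config.inputs["metabolites"], "metabolome")
            meta = read_metadata(config.inputs["metadata"])
            annotation = read_annotation(config.inputs["annotation"])
        meta = meta.set_index("sample_id", drop=False).loc[expr.sample_ids].reset_index(drop=True)
        if metab.sample_ids != expr.sample_ids:
            metab = metab.select_samples(expr.sample_ids)
        for anchor in (config.anchor_early, config.anchor_late):
            if anchor not in metab.variable_ids:
                raise ValidationError(
                    f"anchor metabolite '{anchor}' absent from metabolite block"
                )

    # ---- filter + scale --------------------------------------------------
    with _stage("filter_genes"):
        expr_f, report = filter_genes(expr, meta, threshold=config.rpkm_threshold)
        counts["genes_input"] = report.n_input
        counts["genes_kept"] = report.n_kept
        _write_tsv(report.table, register("filter_report", outdir / "filter_report.tsv"))

    with _stage("autoscale"):
        if config.log2_metabolites:
            metab = log2_transform(metab)
        expr_s = autoscale(expr_f)
        metab_s = autoscale(metab)
        response = build_response(meta)

    # ---- per-block PCA overview -----------------------------------------
    with _stage("pca"):
        pca_summary = {}
        for blk in (expr_s.block, metab_s.block):
            a = min(config.n_components, blk.n_samples - 1, blk.n_variables)
            pca = fit_pca(blk.values, a)
            pca_summary[blk.name] = {
                "n_components": a,
                "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
            }
        path = register("pca_summary", outdir / "pca_summary.json")
        path.write_text(json.dumps(pca_summary, indent=1, sort_keys=True))

    # ---- MB-PLS-DA + VIP -------------------------------------------------
    with _stage("mbpls"):
        model = fit_mbpls(
            [expr_s.block, metab_s.block], response, n_components=config.n_components
        )
        path = register("mbpls_summary", outdir / "mbpls_summary.json")
        path.write_text(json.dumps(model.summary(), indent=1, sort_keys=True))

    with _stage("vip"):
        vip = compute_vip(model, config.response)
        vip = select_vips(vip, p=config.vip_p)
        scald = meta["scald"].to_numpy(dtype=float)
        vip = assign_signs(vip, [expr_s.block, metab_s.block], scald)
        _write_tsv(vip, register("vip_table", outdir / "vip_table.tsv"))
        sel = vip[vip["selected"]]
        counts["vip_selected"] = int(len(sel))
        gene_sel = sel[sel["block"] == "transcriptome"]
        vip_pos = list(gene_sel.loc[gene_sel["sign"] == "+", "variable"])
        vip_neg = list(gene_sel.loc[gene_sel["sign"] == "-", "variable"])
        counts["vip_genes_positive"] = len(vip_pos)
        counts["vip_genes_negative"] = len(vip_neg)
        met_sel = sel[sel["block"] == "metabolome"]
        counts["vip_metabolites_positive"] = int((met_sel["sign"] == "+").sum())
        counts["vip_metabolites_negative"] = int((met_sel["sign"] == "-").sum())

    # ---- k-means summarization ------------------------------------------
    with _stage("clustering"):
        profiles = expr_s.block.data.T  # genes x samples
        smoothed = pca_smooth(profiles.to_numpy(), n_pcs=config.n_pcs)
        cm_model = kmeans_summarize(
            smoothed,
            gene_ids=list(profiles.index),
            k_init=config.k_init,
            seed=config.seed,
        )
        counts["gene_clusters"] = cm_model.n_clusters
        _write_tsv(
            cm_model.assignments(),
            register("cluster_assignments", outdir / "cluster_assignments.tsv"),
        )
        cmeans = cluster_means(cm_model, profiles)
        _write_tsv(
            cmeans,
            register("cluster_means", outdir / "cluster_means.tsv"),
            index=True,
        )

    # ---- correlation networks -------------------------------------------
    with _stage("networks"):
        all_days = tuple(sorted(meta["day"].unique()))
        windows = {
            "2month": tuple(d for d in config.early_window if d in all_days),
            "6month": all_days,
        }
        nets = {}
        for label, days in windows.items():
            net = build_network(
                cmeans, metab_s.block, meta, days, r2_min=config.r2_min, label=label
            )
            nets[label] = net
            write_graphml(net, register(f"network_{label}", outdir / f"network_{label}.graphml"))
            _write_tsv(edge_table(net), register(f"edges_{label}", outdir / f"edges_{label}.tsv"))
            _write_tsv(
                node_metrics(net),
                register(f"node_metrics_{label}", outdir / f"node_metrics_{label}.tsv"),
            )
            counts[f"edges_{label}"] = net.graph.number_of_edges()

    # ---- anchor subnetworks + refinement ---------------------------------
    anchors = {
        "early": (config.anchor_early, "2month"),
        "late": (config.anchor_late, "6month"),
    }
    refined: dict[str, list[str]] = {}
    with _stage("subnetworks"):
        subnets = {}
        for phase, (anchor, label) in anchors.items():
            sub = first_neighbors(nets[label], anchor)
            subnets[phase] = sub
            write_graphml(
                sub,
                register(f"subnetwork_{phase}", outdir / f"subnetwork_{phase}_{anchor}.graphml"),
            )
            counts[f"subnetwork_{phase}_nodes"] = sub.graph.number_of_nodes()

    with _stage("refine_members"):
        for phase, (anchor, label) in anchors.items():
            net = nets[label]
            window_samples = list(
                meta.loc[meta["day"].isin(net.window_days), "sample_id"]
            )
            neighbor_clusters = [
                n for n in subnets[phase].graph.nodes
                if subnets[phase].graph.nodes[n].get("kind") == "gene_cluster"
            ]
            members: list[str] = []
            for node in neighbor_clusters:
                cid = int(node.split("_", 1)[1])
                members.extend(cm_model.members(cid))
            trace = metab_s.block.data[anchor]
            kept = refine_members(
                members, expr_s.block, trace, window_samples, r2_min=config.r2_min
            )
            refined[phase] = kept
            counts[f"refined_{phase}"] = len(kept)
            path = register(f"refined_{phase}", outdir / f"refined_{phase}_{anchor}.tsv")
            _write_tsv(pd.DataFrame({"gene_id": kept}), path)

    # ---- over-representation analysis ------------------------------------
    with _stage("ora"):
        background = expr_s.block.variable_ids
        ora_lists = {
            "vip_pos": vip_pos,
            "vip_neg": vip_neg,
            "refined_early": refined["early"],
            "refined_late": refined["late"],
        }
        for name, genes in ora_lists.items():
            table = fisher_ora(genes, background, annotation)
            _write_tsv(table, register(f"ora_{name}", outdir / f"ora_{name}.tsv"))

    # ---- manifest --------------------------------------------------------
    with _stage("manifest"):
        cfg = config.to_dict()
        manifest = {
            "config": cfg,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()
            ).hexdigest(),
            "seed": config.seed,
            "versions": {
                "scaldnet": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "networkx": nx.__version__,
            },
            "counts": counts,
            "artifacts": artifacts,
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True)
        )
    return manifest


def simulate(config: PipelineConfig) -> dict[str, Path]:
    """Generate and write a synthetic dataset without running the analysis."""
    if config.synthetic is None:
        raise ValidationError("simulate requires a 'synthetic' config block")
    syn = dict(config.synthetic)
    expr, metab, meta, annotation, truth = generate_dataset(
        n_genes=int(syn.get("n_genes", 2000)),
        n_metabolites=int(syn.get("n_metabolites", 120)),
        noise_sd=float(syn.get("noise_sd", 0.25)),
        seed=config.seed,
    )
    return write_dataset(Path(config.outdir), expr, metab, meta, annotation, truth)
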