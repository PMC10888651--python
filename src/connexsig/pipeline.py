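"""End-to-end orchestration of the five workflow steps.

Step A: differential expression and signature extraction per experiment;
Step B/C: connectivity query against the reference compendium with tau
scoring and top-k selection; Step D: compendium subsetting and consensus gene
selection; Step E: cross-dataset correlation/Ward clustering and pathway
enrichment. A run manifest records seeds, input hashes and per-stage counts;
reruns under the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (
    ConnectivityConfig,
    ReferenceCompendium,
    heatmap_matrix,
    query_compendium,
    top_k,
    write_connectivity_table,
)
from .consensus import ConsensusConfig, consensus_select, consensus_table, subset_compendium
from .diffexpr import (
    ExpressionExperiment,
    filter_degs,
    fit_differential,
    quantile_normalize,
    write_deg_table,
)
from .downstream import (
    compound_pathway_matrix,
    feature_vectors,
    hypergeom_enrich,
    signature_correlation,
    ward_cluster,
)
from .errors import StageError
from .formats_io import read_gct, read_gmt, read_metadata_table, write_gct
from .signature import SignatureConfig, build_signature, write_signature

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run; defaults are the workflow's
    published thresholds (q 0.05, 150/150/300 tags, top-10, |tau| > 90,
    70% consensus, enrichment q 0.05)."""

    experiments: list[dict]  # each: {id, expression, groups}
    reference: str
    outdir: str
    pathways: str | None = None
    allowed_genes: str | None = None
    cell_ids: list[str] | None = None
    seed: int = 0
    normalize: bool = False
    method: str = "moderated_t"
    q_cutoff: float = 0.05
    max_per_direction: int = 150
    max_total: int = 300
    k: int = 10
    tau_cutoff: float = 90.0
    min_direction_fraction: float = 0.70
    enrichment_cutoff: float = 0.05
    landmark_only: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path


@contextmanager
def _stage(name: str):
    try:
        yield
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, exc) from exc


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _read_groups(path) -> pd.Series:
    table = read_metadata_table(path, ("sample_id", "group"))
    return pd.Series(table["group"].values, index=table["sample_id"].values)


def run_all(cfg: PipelineConfig) -> dict:
    """Execute deg -> signature -> connect -> consensus -> cluster + enrich.

    Returns the manifest (also written to ``<outdir>/manifest.json``). Any
    stage failure aborts with a :class:`StageError` naming the stage.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "outdir": str(outdir),
        "seed": cfg.seed,
        "inputs": {},
        "experiments": {},
        "stages": {},
    }

    deg_full: dict[str, pd.DataFrame] = {}
    signatures = {}
    with _stage("deg"):
        allowed = None
        if cfg.allowed_genes:
            allowed = frozenset(Path(cfg.allowed_genes).read_text().split())
        sig_cfg = SignatureConfig(
            max_per_direction=cfg.max_per_direction,
            max_total=cfg.max_total,
            allowed_genes=allowed,
        )
        for entry in cfg.experiments:
            exp_id = entry["id"]
            manifest["inputs"][entry["expression"]] = _sha256(entry["expression"])
            manifest["inputs"][entry["groups"]] = _sha256(entry["groups"])
            matrix = read_gct(entry["expression"]).to_frame()
            if cfg.normalize:
                matrix = quantile_normalize(matrix)
            expr = ExpressionExperiment(matrix, _read_groups(entry["groups"]))
            table = fit_differential(expr, method=cfg.method)
            deg_full[exp_id] = table
            degs = filter_degs(table, q_cutoff=cfg.q_cutoff)
            write_deg_table(degs, outdir / f"{exp_id}.degs.tsv")
            sig = build_signature(degs, sig_cfg, signature_id=exp_id)
            write_signature(sig, outdir / f"{exp_id}.sig.txt")
            signatures[exp_id] = sig
            manifest["experiments"][exp_id] = {
                "n_samples": int(matrix.shape[1]),
                "n_degs": int(len(degs)),
                "n_up_tags": len(sig.up_tags),
                "n_down_tags": len(sig.down_tags),
            }
    manifest["stages"]["deg"] = {"experiments": len(cfg.experiments)}

    conn_cfg = ConnectivityConfig(tau_cutoff=cfg.tau_cutoff, k=cfg.k)
    tables = {}
    with _stage("connect"):
        ref_dir = Path(cfg.reference)
        if not ref_dir.is_dir():
            raise FileNotFoundError(f"reference directory {ref_dir} does not exist")
        ref = ReferenceCompendium.load(ref_dir)
        for exp_id, sig in signatures.items():
            table = query_compendium(sig, ref, conn_cfg)
            tables[exp_id] = table
            write_connectivity_table(table, outdir / f"{exp_id}.connectivity.tsv")
            top = top_k(table, cfg.k)
            write_connectivity_table(top, outdir / f"{exp_id}.top{cfg.k}.tsv")
            info = manifest["experiments"][exp_id]
            info["n_connected"] = int(table["connected"].sum())
            info["top_pert_id"] = str(top["pert_id"].iloc[0]) if len(top) else None
            info["top_tau"] = float(top["tau"].iloc[0]) if len(top) else None
        write_gct(heatmap_matrix(tables, cfg.k), outdir / "heatmap.gct", dialect="gct1.3")
    manifest["stages"]["connect"] = {
        "profiles": int(ref.zscores.shape[1]),
        "records": int(sum(len(t) for t in tables.values())),
    }

    consensus_frames = []
    with _stage("consensus"):
        for exp_id, sig in signatures.items():
            selected = list(dict.fromkeys(top_k(tables[exp_id], cfg.k)["pert_id"]))
            cons_cfg = ConsensusConfig(
                min_direction_fraction=cfg.min_direction_fraction,
                pert_ids=selected,
                cell_ids=cfg.cell_ids,
                landmark_only=cfg.landmark_only,
            )
            subset = subset_compendium(ref, cons_cfg)
            consensus_frames.append(
                consensus_table(consensus_select(sig, subset, cons_cfg))
            )
        consensus = pd.concat(consensus_frames, ignore_index=True)
        consensus.to_csv(outdir / "consensus.tsv", sep="\t", index=False)
    manifest["stages"]["consensus"] = {"genes": int(len(consensus))}

    if len(signatures) >= 2 and len(consensus):
        with _stage("cluster"):
            genes = list(dict.fromkeys(consensus["gene_id"]))
            vectors = feature_vectors(deg_full, genes)
            corr = signature_correlation(vectors)
            corr.to_csv(outdir / "correlation.tsv", sep="\t")
            result = ward_cluster(vectors)
            payload = {
                "labels": {str(k): int(v) for k, v in result.labels.items()},
                "n_clusters": result.n_clusters,
                "merge_heights": [float(h) for h in result.linkage[:, 2]],
            }
            (outdir / "cluster.json").write_text(json.dumps(payload, sort_keys=True, indent=1))
        manifest["stages"]["cluster"] = {"n_clusters": result.n_clusters}

    if cfg.pathways and len(consensus):
        with _stage("enrich"):
            manifest["inputs"][cfg.pathways] = _sha256(cfg.pathways)
            sets = read_gmt(cfg.pathways)
            universe = ref.landmark_ids if cfg.landmark_only else ref.zscores.row_ids
            per_compound = {}
            frames = []
            for pert_id, grp in consensus.groupby("pert_id", sort=True):
                genes = sorted(set(grp["gene_id"]))
                table = hypergeom_enrich(genes, sets, universe, q_cutoff=cfg.enrichment_cutoff)
                table.insert(0, "pert_id", pert_id)
                per_compound[pert_id] = table
                frames.append(table)
            enrich = pd.concat(frames, ignore_index=True)
            enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            write_gct(
                compound_pathway_matrix(per_compound),
                outdir / "pathway_matrix.gct",
                dialect="gct1.3",
            )
        manifest["stages"]["enrich"] = {
            "compounds": len(per_compound),
            "significant_pairs": int(enrich["significant"].sum()),
        }

    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest


def make_demo_scenario(directory, seed: int = 1) -> Path:
    """Build a self-contained synthetic scenario and return its config path.

    Two treated-vs-control experiments with planted DE genes; a compendium in
    which one compound per experiment is planted as connected (strength 1); a
    pathway collection with one planted set drawn from the first experiment's
    landmark up tags. The written ``config.yaml`` runs the whole pipeline at
    the default thresholds; ``truth.json`` records the planted compounds.
    """
    from .formats_io import DenseMatrixFile, write_gmt
    from .synthetic_data import (
        CompendiumSpec,
        ExperimentSpec,
        simulate_compendium,
        simulate_experiment,
        simulate_pathways,
    )

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    experiments, signatures = [], []
    for i, exp_id in enumerate(("expA", "expB")):
        spec = ExperimentSpec(
            n_genes=2000, n_per_group=3, n_up=150, n_down=150,
            effect_size=2.0, noise_sd=0.3, seed=seed + i,
        )
        expr, _ = simulate_experiment(spec)
        gct = directory / f"{exp_id}.gct"
        write_gct(DenseMatrixFile.from_frame(expr.matrix), gct)
        groups = directory / f"{exp_id}.groups.tsv"
        pd.DataFrame({"sample_id": expr.groups.index, "group": expr.groups.values}).to_csv(
            groups, sep="\t", index=False
        )
        experiments.append({"id": exp_id, "expression": str(gct), "groups": str(groups)})
        degs = filter_degs(fit_differential(expr), q_cutoff=0.05)
        signatures.append(build_signature(degs, signature_id=exp_id))

    comp_spec = CompendiumSpec(
        n_landmark=300,
        n_nonlandmark=1700,
        compounds=[(f"BRD-S{i:04d}", f"cpd-{i}") for i in range(8)],
        cell_ids=("A375", "MCF7", "PC3"),
        profiles_per_pair=2,
        planted_connections=[
            ("expA", "BRD-S0000", 1.0),
            ("expB", "BRD-S0001", 1.0),
        ],
        seed=seed + 100,
    )
    ref, truth = simulate_compendium(comp_spec, signatures)
    ref_dir = directory / "reference"
    ref.save(ref_dir)

    landmarks = ref.landmark_ids
    planted_genes = [g for g in signatures[0].up_tags if g in set(landmarks)]
    gmt_path = directory / "pathways.gmt"
    write_gmt(
        simulate_pathways(
            12, (10, 40), landmarks,
            planted=("PLANTED_PATHWAY", planted_genes) if len(planted_genes) >= 3 else None,
            seed=seed + 200,
        ),
        gmt_path,
    )

    cfg = PipelineConfig(
        experiments=experiments,
        reference=str(ref_dir),
        pathways=str(gmt_path),
        outdir=str(directory / "out"),
        seed=seed,
    )
    cfg_path = cfg.to_yaml(directory / "config.yaml")
    (directory / "truth.json").write_text(
        json.dumps({"planted": truth.to_dict(orient="records")}, sort_keys=True, indent=1)
    )
    return cfg_path
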