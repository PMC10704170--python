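"""Configuration-driven orchestration of the full analysis:

SIF / edge list / dissimilarity / synthetic input -> spring-model stiffness ->
dissimilarity -> embeddings in the three model spaces -> minimum-stress
geometry selection -> (if hyperbolic) radial-coordinate clustering with elbow,
stability, driver report, and the spectral baseline.

All outputs are CSV/JSON; a manifest records the configuration hash, the
master seed, per-stage wall times, and a content hash of every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (
    driver_cluster,
    eigengap_k,
    elbow_k,
    intra_cluster_edge_fractions,
    intra_cluster_pairs,
    kmeans_radial,
    radial_coordinates,
    spectral_clustering,
    stability_analysis,
)
from .embedding import (
    EmbeddingResult,
    embed_euclidean,
    embed_hyperbolic,
    embed_spherical,
    select_geometry,
)
from .network_io import (
    GeneNetwork,
    build_graph,
    node_masses,
    oriented_incidence,
    parse_sif,
    write_edge_list,
    write_node_table,
)
from .spring_model import (
    DissimilarityMatrix,
    StiffnessMatrix,
    rescale_stiffness,
    stiffness_equilibrium,
    stiffness_to_dissimilarity,
    vibrational_centrality,
    weighted_incidence,
    write_square_csv,
)

logger = logging.getLogger(__name__)

#: hard cap on dense all-pairs matrices (memory contract)
MAX_NODES = 5000


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    # exactly one input source
    sif_path: str | None = None
    dissimilarity_path: str | None = None
    synthetic: dict | None = None  # {"model", "n", "dim", "scale", "threshold"}

    allowed_types: list[str] | None = None
    temperature: float = 1.0
    k0: float = 1.0
    nullspace_tol: float = 1e-10

    dims: list[int] = field(default_factory=lambda: list(range(3, 11)))
    kappa: float = 1.0
    refine: bool = True

    k_max: int = 25
    restarts: int = 25
    stability_runs: int = 1000
    min_pairs: int = 30

    seed: int = 0
    outdir: str = "springgeo_out"

    def __post_init__(self) -> None:
        sources = [
            s is not None
            for s in (self.sif_path, self.dissimilarity_path, self.synthetic)
        ]
        if sum(sources) != 1:
            raise ValueError(
                "exactly one of sif_path, dissimilarity_path, synthetic "
                "must be given"
            )
        if not self.dims:
            raise ValueError("dims must be non-empty")
        if self.temperature <= 0 or self.k0 <= 0 or self.kappa <= 0:
            raise ValueError("temperature, k0 and kappa must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    state = np.random.SeedSequence(master).generate_state(n)
    return [int(s % (2**31)) for s in state]


def write_coordinates_csv(emb: EmbeddingResult, path: Path) -> None:
    n, p = emb.coordinates.shape
    ids = emb.node_ids if emb.node_ids is not None else tuple(
        f"n{i:04d}" for i in range(n)
    )
    data = {"node_id": list(ids)}
    for j in range(p):
        data[f"x{j + 1}"] = emb.coordinates[:, j]
    if emb.radial is not None:
        data["radial"] = emb.radial
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def _load_input(
    config: PipelineConfig,
) -> tuple[GeneNetwork | None, DissimilarityMatrix | None]:
    if config.sif_path is not None:
        table = parse_sif(config.sif_path)
        return build_graph(table, config.allowed_types), None
    if config.dissimilarity_path is not None:
        return None, DissimilarityMatrix.from_csv(config.dissimilarity_path)
    from .synthetic import geometric_graph, sample_points

    spec = dict(config.synthetic or {})
    threshold = spec.pop("threshold")
    cfg = sample_points(
        spec["model"],
        n=int(spec["n"]),
        dim=int(spec.get("dim", 2)),
        scale=float(spec.get("scale", 1.0)),
        seed=int(spec.get("seed", config.seed)),
    )
    return geometric_graph(cfg, threshold), None


def _drop_isolated(g: GeneNetwork) -> GeneNetwork:
    deg = g.degrees()
    if not np.any(deg == 0):
        return g
    keep = [g.node_ids[i] for i in np.flatnonzero(deg > 0)]
    logger.warning("excluding %d isolated node(s) from the spring model",
                   int(np.sum(deg == 0)))
    idx = {name: i for i, name in enumerate(keep)}
    edges = tuple(
        sorted(
            (idx[g.node_ids[i]], idx[g.node_ids[j]])
            for i, j in g.edges
        )
    )
    return GeneNetwork(
        node_ids=tuple(keep),
        edges=edges,
        multi_edge_count=g.multi_edge_count,
        self_loop_count=g.self_loop_count,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full method and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
        "files": {},
        "notes": [],
    }
    outputs: list[Path] = []

    def record(path: Path) -> None:
        outputs.append(path)

    def stage(name: str):
        return _StageTimer(name, manifest)

    try:
        with stage("input"):
            g, dissim = _load_input(config)
            stiffness: StiffnessMatrix | None = None
            if g is not None:
                g = _drop_isolated(g)
                if g.n_nodes > MAX_NODES:
                    raise ValueError(
                        f"dense all-pairs matrices capped at {MAX_NODES} "
                        f"nodes; got {g.n_nodes}"
                    )
                manifest["stages"]["input"] = {
                    "n_nodes": g.n_nodes,
                    "n_edges": g.n_edges,
                }
                p_edges = outdir / "edges.csv"
                write_edge_list(g, p_edges)
                record(p_edges)
                p_nodes = outdir / "nodes.csv"
                write_node_table(g, p_nodes)
                record(p_nodes)
            else:
                if dissim.n > MAX_NODES:
                    raise ValueError(
                        f"dense all-pairs matrices capped at {MAX_NODES} "
                        f"nodes; got {dissim.n}"
                    )

        if g is not None:
            with stage("spring_model"):
                masses = node_masses(g)
                incidence = oriented_incidence(g)
                c = weighted_incidence(incidence, masses)
                stiffness = stiffness_equilibrium(
                    c, tol=config.nullspace_tol, node_ids=g.node_ids
                )
                stiffness = rescale_stiffness(stiffness)
                dissim = stiffness_to_dissimilarity(stiffness)
                vib = vibrational_centrality(
                    g, temperature=config.temperature, k0=config.k0
                )
                manifest["stages"]["spring_model"].update(
                    {"kernel_dim": stiffness.kernel_dim}
                )
                p_stiff = outdir / "stiffness.csv"
                write_square_csv(stiffness.rescaled, p_stiff, node_ids=g.node_ids)
                record(p_stiff)
                p_vib = outdir / "vibrational_centrality.csv"
                pd.DataFrame(
                    {"node_id": list(g.node_ids),
                     "displacement": vib.displacement}
                ).to_csv(p_vib, index=False, float_format="%.17g")
                record(p_vib)
                p_diss = outdir / "dissimilarity.csv"
                dissim.to_csv(p_diss)
                record(p_diss)

        with stage("geometry_selection"):
            table = select_geometry(
                dissim, dims=config.dims, kappa=config.kappa,
                refine=config.refine,
            )
            best_model, best_dim = table.best
            manifest["stages"]["geometry_selection"].update(
                {"best_model": best_model, "best_dimension": best_dim}
            )
            p_table = outdir / "stress_table.csv"
            pd.DataFrame(
                table.rows, columns=["model", "dimension", "stress"]
            ).to_csv(p_table, index=False, float_format="%.17g")
            record(p_table)
            p_sel = outdir / "selection.json"
            p_sel.write_text(
                json.dumps(
                    {
                        "best_model": best_model,
                        "best_dimension": best_dim,
                        "best_stress": table.best_stress,
                        "stresses": [
                            {"model": m, "dimension": p, "stress": s}
                            for m, p, s in table.rows
                        ],
                    },
                    indent=2,
                )
            )
            record(p_sel)

        with stage("best_embedding"):
            if best_model == "euclidean":
                emb = embed_euclidean(dissim, best_dim)
            elif best_model == "hyperbolic":
                emb = embed_hyperbolic(
                    dissim, best_dim, kappa=config.kappa, refine=config.refine
                )
            else:
                emb = embed_spherical(dissim, best_dim)
            p_coords = outdir / "coordinates.csv"
            write_coordinates_csv(emb, p_coords)
            record(p_coords)

        if best_model == "hyperbolic":
            with stage("radial_clustering"):
                radial = radial_coordinates(emb)
                k_max = min(config.k_max, max(2, len(np.unique(radial)) - 1))
                k = elbow_k(radial, k_max=k_max, seed=seeds[1])
                k = max(k, 2)
                clustering = kmeans_radial(
                    radial, k, restarts=config.restarts, seed=seeds[2]
                )
                stability = stability_analysis(
                    radial, k, runs=config.stability_runs, seed=seeds[3]
                )
                manifest["stages"]["radial_clustering"].update(
                    {
                        "k": k,
                        "median_bss_wss_ratio": float(
                            np.median(
                                stability.bss_distribution
                                / np.where(
                                    stability.wss_distribution > 0,
                                    stability.wss_distribution,
                                    np.inf,
                                )
                            )
                        ),
                    }
                )
                ids = dissim.node_ids or tuple(
                    f"n{i:04d}" for i in range(len(radial))
                )
                p_clusters = outdir / "clusters.csv"
                pd.DataFrame(
                    {
                        "node_id": list(ids),
                        "radial": radial,
                        "cluster": clustering.labels,
                    }
                ).to_csv(p_clusters, index=False, float_format="%.17g")
                record(p_clusters)
                p_stab = outdir / "stability.csv"
                pd.DataFrame(
                    {
                        "run": np.arange(1, stability.runs + 1),
                        "wss": stability.wss_distribution,
                        "bss": stability.bss_distribution,
                    }
                ).to_csv(p_stab, index=False, float_format="%.17g")
                record(p_stab)

                pairs = intra_cluster_pairs(clustering.labels)
                summary = pairs.merge(
                    pd.DataFrame(
                        {
                            "cluster": np.arange(1, k + 1),
                            "centroid": clustering.centroids,
                        }
                    ),
                    on="cluster",
                )
                if stiffness is not None:
                    report = driver_cluster(
                        stiffness, clustering.labels,
                        min_pairs=config.min_pairs,
                    )
                    summary = summary.merge(
                        report.table[["cluster", "ks"]], on="cluster"
                    )
                    manifest["stages"]["radial_clustering"][
                        "driver_cluster"
                    ] = report.driver_cluster
                else:
                    manifest["notes"].append(
                        "driver report skipped: no stiffness matrix "
                        "(dissimilarity-only input)"
                    )
                p_summary = outdir / "cluster_summary.csv"
                summary.to_csv(p_summary, index=False, float_format="%.17g")
                record(p_summary)
                if g is not None:
                    p_edge_frac = outdir / "cluster_edge_fractions.csv"
                    intra_cluster_edge_fractions(
                        g, clustering.labels
                    ).to_csv(p_edge_frac, index=False, float_format="%.17g")
                    record(p_edge_frac)

            with stage("spectral_baseline"):
                if stiffness is not None:
                    affinity = stiffness.rescaled
                else:
                    d = dissim.values
                    sigma = float(np.median(d[np.triu_indices(d.shape[0], 1)]))
                    affinity = np.exp(-(d**2) / (2.0 * sigma**2))
                    np.fill_diagonal(affinity, 0.0)
                k_spec = max(2, eigengap_k(affinity, k_max=config.k_max))
                baseline = spectral_clustering(
                    affinity, k_spec, seed=seeds[4],
                    restarts=config.restarts,
                )
                p_spec = outdir / "spectral.json"
                p_spec.write_text(
                    json.dumps(
                        {
                            "k_eigengap": k_spec,
                            "cluster_sizes": baseline.cluster_sizes.tolist(),
                            "wss_per_cluster":
                                baseline.wss_per_cluster.tolist(),
                            "wss": baseline.wss,
                            "bss": baseline.bss,
                        },
                        indent=2,
                    )
                )
                record(p_spec)
        else:
            manifest["notes"].append(
                f"radial clustering skipped: best geometry is {best_model}, "
                "not hyperbolic"
            )
    except Exception as exc:
        manifest["error"] = {"stage": _StageTimer.current, "message": str(exc)}
        _write_manifest(manifest, outputs, outdir)
        raise

    _write_manifest(manifest, outputs, outdir)
    return manifest


def _write_manifest(manifest: dict, outputs: list[Path], outdir: Path) -> None:
    for path in outputs:
        manifest["files"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


class _StageTimer:
    """Context manager recording wall time per stage in the manifest."""

    current: str | None = None

    def __init__(self, name: str, manifest: dict) -> None:
        self.name = name
        self.manifest = manifest

    def __enter__(self) -> "_StageTimer":
        _StageTimer.current = self.name
        self.start = time.perf_counter()
        self.manifest["stages"].setdefault(self.name, {})
        logger.info("stage %s: started", self.name)
        return self

    def __exit__(self, exc_type, exc, tb) -> None:
        elapsed = time.perf_counter() - self.start
        self.manifest["stages"][self.name]["wall_time_s"] = round(elapsed, 6)
        logger.info("stage %s: finished in %.2fs", self.name, elapsed)
        if exc_type is None:  # keep the stage name visible to error handling
            _StageTimer.current = None
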