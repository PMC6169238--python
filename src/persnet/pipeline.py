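"""End-to-end workflow: expression matrices -> networks -> diagrams ->
distance matrix -> clustering, with a packaged study manifest.

The packaged manifest transcribes the 38 Arabidopsis pathogen-stress
microarray experiments (GEO accessions with their stress-group labels: PTI,
bacteria, induced resistance, fungi).  The accessions are metadata only:
running on real data requires the user to supply already-normalized
expression matrices, while `simulate` mode generates a labeled synthetic
study in their place.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .clustering import (
    KSelectionResult,
    cut_dendrogram,
    select_k,
    ward_linkage,
)
from .distances import NetworkDistanceMatrix, pairwise_distance_matrix
from .homology import PersistenceDiagram, rips_persistence
from .network import ExpressionMatrix, expression_to_dissimilarity
from .simulate import SimulationConfig, simulate_study

__all__ = [
    "StudyManifest",
    "PipelineConfig",
    "PipelineResult",
    "load_table1",
    "summarize_manifest",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

STRESS_GROUPS = ("PTI", "Bacteria", "Induced resistance", "Fungi")


@dataclass(frozen=True)
class StudyManifest:
    """Study metadata: one row per experiment/network."""

    table: pd.DataFrame  # columns: id, geo_accession, plant, stress_group, stress

    def __post_init__(self) -> None:
        required = {"id", "stress_group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if self.table["id"].duplicated().any():
            raise ValueError("manifest ids must be unique")

    def __len__(self) -> int:
        return len(self.table)

    def filter_group(self, group: str) -> "StudyManifest":
        return StudyManifest(
            self.table[self.table["stress_group"] == group].reset_index(drop=True)
        )


def load_table1() -> StudyManifest:
    """The packaged 38-experiment Arabidopsis stress study manifest."""
    with resources.files("persnet.data").joinpath("table1.tsv").open() as fh:
        return StudyManifest(pd.read_csv(fh, sep="\t"))


def summarize_manifest(manifest: StudyManifest) -> dict[str, int]:
    """Counts per stress group plus the total; unknown groups are an error."""
    counts = dict.fromkeys(STRESS_GROUPS, 0)
    for g in manifest.table["stress_group"] if len(manifest) else []:
        if g not in counts:
            raise ValueError(f"unknown stress group {g!r}")
        counts[g] += 1
    counts["total"] = len(manifest)
    return counts


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the workflow, echoed to the run log.

    ``keep_genes=None`` skips the spread filter (synthetic matrices are
    generated at the size to analyze); on real data the customary default is
    400.  ``homology_dimension=0`` compares component structure (the headline
    analysis); dimension 1 compares loops and needs ``max_dim=2`` triangles,
    which is cubic in gene count — keep networks small or cap the filtration.
    """

    keep_genes: "int | None" = None
    filter_statistic: str = "variance"
    homology_dimension: int = 0
    metric: str = "bottleneck"
    wasserstein_q: float = 1.0
    max_filtration_value: float = 1.0
    k_max: int = 10
    kmeans_restarts: int = 25
    seed: int = 1
    n_clusters: "int | None" = None  # None: use the BIC-selected k

    def __post_init__(self) -> None:
        if self.homology_dimension not in (0, 1):
            raise ValueError("homology_dimension must be 0 or 1")
        if self.metric not in ("bottleneck", "wasserstein"):
            raise ValueError("metric must be 'bottleneck' or 'wasserstein'")


@dataclass(frozen=True)
class PipelineResult:
    """In-memory artifacts of one run, mirroring what is written to disk."""

    network_ids: tuple[str, ...]
    group_labels: "tuple[str, ...] | None"
    diagrams: tuple[PersistenceDiagram, ...]
    distance_matrix: NetworkDistanceMatrix
    dendrogram: "object"
    cluster_labels: np.ndarray
    k_selection: KSelectionResult
    summary: pd.DataFrame


def _compute_diagram(
    expr: ExpressionMatrix, config: PipelineConfig
) -> PersistenceDiagram:
    D = expression_to_dissimilarity(
        expr, keep=config.keep_genes, statistic=config.filter_statistic
    )
    max_dim = 2 if config.homology_dimension == 1 else 1
    return rips_persistence(
        D.values, max_dim=max_dim, max_value=config.max_filtration_value
    )


def run_pipeline(
    matrices: Sequence[tuple[str, ExpressionMatrix]],
    config: PipelineConfig = PipelineConfig(),
    out_dir: "str | Path | None" = None,
    group_labels: "Sequence[str] | None" = None,
) -> PipelineResult:
    """Run networks -> diagrams -> distances -> Ward clustering -> k selection.

    ``matrices`` is a list of (network_id, ExpressionMatrix).  When
    ``out_dir`` is given, every stage's output is written there (diagram TSVs,
    distance matrix, Newick dendrogram, cluster assignments, k-selection
    table, run log, summary).  Deterministic given the config seed.
    """
    ids = [i for i, _ in matrices]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate network ids")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "diagrams").mkdir(exist_ok=True)
    log_lines: list[str] = [f"config: {config}"]
    t0 = time.time()

    diagrams: list[tuple[str, PersistenceDiagram]] = []
    gene_counts: list[int] = []
    for net_id, expr in matrices:
        try:
            dgm = _compute_diagram(expr, config)
        except Exception:
            if out is not None:
                (out / "FAILED").write_text(f"failed at network {net_id}\n")
            raise
        diagrams.append((net_id, dgm))
        kept = config.keep_genes if config.keep_genes is not None else expr.n_genes
        gene_counts.append(kept)
        log_lines.append(
            f"network {net_id}: {kept} genes, {len(dgm)} diagram pairs, "
            f"input sha1 {hashlib.sha1(expr.values.tobytes()).hexdigest()[:12]}"
        )
        if out is not None:
            pio.write_diagram(dgm, out / "diagrams" / f"{net_id}.tsv")

    dist = pairwise_distance_matrix(
        diagrams,
        dimension=config.homology_dimension,
        metric=config.metric,
        q=config.wasserstein_q,
    )
    log_lines.append(f"distance matrix: {len(ids)} x {len(ids)} ({config.metric})")

    tree = ward_linkage(dist)
    ksel = select_k(
        dist,
        k_max=min(config.k_max, len(ids) - 1),
        restarts=config.kmeans_restarts,
        seed=config.seed,
    )
    k = config.n_clusters if config.n_clusters is not None else ksel.k_selected
    labels = cut_dendrogram(tree, k)
    log_lines.append(
        f"selected k={k} (BIC elbow {ksel.k_elbow}, BIC argmin {ksel.k_bic}); "
        f"wall {time.time()-t0:.1f}s"
    )

    summary = pd.DataFrame(
        {
            "network_id": ids,
            "n_genes": gene_counts,
            "n_h0_pairs": [len(d.in_dimension(0)) for _, d in diagrams],
            "n_h1_pairs": [len(d.in_dimension(1)) for _, d in diagrams],
            "cluster": labels,
        }
    )
    if group_labels is not None:
        summary["group"] = list(group_labels)

    if out is not None:
        pio.write_labeled_matrix(ids, dist.values, out / "distance_matrix.tsv")
        (out / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
        summary[["network_id", "cluster"]].to_csv(
            out / "clusters.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {"k": ksel.k_grid, "WSS": ksel.wss_curve, "BIC": ksel.bic_curve}
        ).to_csv(out / "kselection.tsv", sep="\t", index=False, float_format="%.12g")
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        (out / "run.log").write_text("\n".join(log_lines) + "\n")

    return PipelineResult(
        network_ids=tuple(ids),
        group_labels=tuple(group_labels) if group_labels is not None else None,
        diagrams=tuple(d for _, d in diagrams),
        distance_matrix=dist,
        dendrogram=tree,
        cluster_labels=labels,
        k_selection=ksel,
        summary=summary,
    )


def run_simulated_study(
    sim_config: SimulationConfig = SimulationConfig(),
    pipeline_config: "PipelineConfig | None" = None,
    out_dir: "str | Path | None" = None,
) -> PipelineResult:
    """Simulate a labeled study and push it through the full pipeline."""
    if pipeline_config is None:
        pipeline_config = PipelineConfig(seed=sim_config.seed)
    labeled = simulate_study(sim_config)
    matrices = [(f"net{idx:03d}", m) for idx, (_, m) in enumerate(labeled)]
    groups = [g for g, _ in labeled]
    return run_pipeline(
        matrices, pipeline_config, out_dir=out_dir, group_labels=groups
    )
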