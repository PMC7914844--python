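"""End-to-end probability density analysis runs.

``run_pda`` executes the full pipeline

    sample -> attribute_samples -> pre_cluster -> single_linkage
    (or local_cluster) -> spin_correlation -> extract_motifs -> writers

deterministically for a given seed; ``recluster`` starts from an
archived maxima set and runs the clustering and motif stages only, so
externally produced maxima can be analyzed.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pda_io
from .clustering import ClusteringParams, local_cluster, pre_cluster, single_linkage
from .errors import ContractError
from .maximization import MaximizerOptions, attribute_samples
from .motifs import DEFAULT_EPSILON, build_dot_structure, correlation_histogram
from .sampling import sample
from .wavefunctions import DensityModel

logger = logging.getLogger("pda")


@dataclass
class RunConfig:
    """Everything one analysis run needs; lengths in bohr."""

    model: DensityModel
    n_samples: int
    seed: int
    step: float | str = "auto"
    burn_in: int = 1000
    thinning: int = 1
    walkers: int = 1
    maximizer: MaximizerOptions = field(default_factory=MaximizerOptions)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    local: tuple | None = None          # (center (3,), k)
    motif_epsilon: float = DEFAULT_EPSILON
    out_dir: str | Path | None = None
    write_samples: bool = False

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ContractError("n_samples must be >= 1")


def _analyse(maxima, n_total, model_geometry, params, local, epsilon, extra):
    """Shared clustering + motif stages for run_pda and recluster."""
    t0 = time.perf_counter()
    if local is not None:
        center, k = local
        clusters = local_cluster(maxima, np.asarray(center, float), int(k),
                                 params, n_total=n_total)
    else:
        clusters = single_linkage(maxima, params, n_total=n_total)
    logger.info(
        "stage=clustering n_maxima=%d n_clusters=%d wall=%.3fs",
        len(maxima), len(clusters), time.perf_counter() - t0,
    )
    report = pda_io.cluster_report_dict(clusters, model_geometry, extra=extra)
    return clusters, report


def _write_outputs(out_dir, report, clusters, geometry, epsilon, maxima=None,
                   model_id=None, n_total=None, samples=None):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pda_io.write_yaml(out / "report.yaml", report)
    for i, cluster in enumerate(clusters):
        dot = build_dot_structure(cluster, geometry, epsilon)
        pda_io.write_dot_structure(out / f"dot_structure_{i:03d}.yaml", dot)
        pda_io.write_dot_structure_xyz(out / f"dot_structure_{i:03d}.xyz", dot)
    hist, edges = correlation_histogram(clusters)
    pda_io.write_histogram_csv(out / "spin_correlation_histogram.csv", hist, edges)
    if maxima is not None:
        pda_io.write_maxima_archive(out / "maxima.h5", maxima, model_id, n_total)
    if samples is not None:
        pda_io.write_sample_archive(out / "samples.h5", samples)


def run_pda(config: RunConfig) -> dict:
    """Run the full analysis; returns the (YAML-identical) report dict."""
    model = config.model
    t0 = time.perf_counter()
    samples = sample(
        model,
        config.n_samples,
        seed=config.seed,
        step=config.step,
        burn_in=config.burn_in,
        thinning=config.thinning,
        walkers=config.walkers,
    )
    logger.info(
        "stage=sampling n=%d acceptance=%.3f step=%.4f wall=%.3fs",
        len(samples), samples.acceptance_ratio, samples.step,
        time.perf_counter() - t0,
    )
    t0 = time.perf_counter()
    maxima = attribute_samples(
        model, samples, options=config.maximizer,
        merge_radius=config.clustering.precluster_radius,
    )
    n_converged = sum(m.count for m in maxima)
    logger.info(
        "stage=maximization n_maxima=%d converged=%d wall=%.3fs",
        len(maxima), n_converged, time.perf_counter() - t0,
    )
    extra = {
        "model": model.model_id,
        "n_samples": config.n_samples,
        "n_converged": int(n_converged),
        "seed": config.seed,
        "step": float(samples.step),
        "d_sim": float(config.clustering.d_sim),
        "precluster_radius": float(config.clustering.precluster_radius),
        "n_maxima": len(maxima),
    }
    clusters, report = _analyse(
        maxima, config.n_samples, model.geometry, config.clustering,
        config.local, config.motif_epsilon, extra,
    )
    if config.out_dir is not None:
        _write_outputs(
            config.out_dir, report, clusters, model.geometry,
            config.motif_epsilon, maxima=maxima, model_id=model.model_id,
            n_total=config.n_samples,
            samples=samples if config.write_samples else None,
        )
    return report


def recluster(
    archive_path: str | Path,
    params: ClusteringParams | None = None,
    local: tuple | None = None,
    motif_epsilon: float = DEFAULT_EPSILON,
    geometry=None,
    out_dir: str | Path | None = None,
    precluster: bool = True,
) -> dict:
    """Clustering and motif analysis of an archived maxima set.

    Spin counts must be consistent across the archive (they are, by the
    archive layout: one shared spin vector). ``geometry`` is optional
    and only used for the per-nucleus diagnostic and dot structures.
    """
    from .geometry import MoleculeGeometry

    maxima, meta = pda_io.read_maxima_archive(archive_path)
    params = params or ClusteringParams()
    if precluster:
        maxima = pre_cluster(maxima, params.precluster_radius)
    geometry = geometry if geometry is not None else MoleculeGeometry.empty()
    n_total = meta["n_total_samples"]
    extra = {
        "model": meta["model"],
        "n_samples": int(n_total),
        "n_converged": int(sum(m.count for m in maxima)),
        "seed": None,
        "d_sim": float(params.d_sim),
        "precluster_radius": float(params.precluster_radius),
        "n_maxima": len(maxima),
    }
    clusters, report = _analyse(
        maxima, n_total, geometry, params, local, motif_epsilon, extra
    )
    if out_dir is not None:
        _write_outputs(out_dir, report, clusters, geometry, motif_epsilon)
    return report
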