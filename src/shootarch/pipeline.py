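"""End-to-end orchestration: annotations -> traits -> topology -> statistics -> genetics.

A run reads every image's XML/JSON pair, computes geometric traits and a
persistence barcode per image, embeds the pairwise bottleneck distances
with classical MDS, averages front/back records per plant, and then runs
the population statistics (replicate concordance, trait correlation and
clustering, heritability) and, when a VCF is supplied, the marker-trait
association.  Outputs are plain CSVs in the run directory; identical
inputs and configuration produce byte-identical outputs.

A single unparseable image is skipped with a logged reason — one corrupt
annotation must never abort a population run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation_io, association, geometry, topology
from .geometry import GEOMETRIC_TRAITS, TOPO_TRAITS, TraitConfig

logger = logging.getLogger(__name__)

#: traits whose replicate concordance is reported (geometry first)
CONCORDANCE_TRAITS = [
    "PH", "MBL", "PN", "TBL", "APBL", "FNH", "PN10", "FPH",
    "NPB", "FIL", "SIL", "TIL",
]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location of one run.

    Defaults carry the analysis constants: a 10 cm pod-height boundary,
    1%/5% pod-height quantiles, three topological dimensions, a 50 kb
    marker-matching window, and a mean split for the pod-number classes.
    """

    pods_dir: str | Path = "pods"
    skeleton_dir: str | Path = "skeletons"
    out_dir: str | Path = "run"
    vcf: str | Path | None = None
    traits_csv: str | Path | None = None        # external traits, e.g. canopy cover
    published_markers_csv: str | Path | None = None
    scale_override: float | None = None
    short_internode_cm: float = 0.5
    pod_height_boundary_cm: float = 10.0
    quantiles: tuple[float, float] = (0.01, 0.05)
    topo_dims: int = 3
    split: str = "mean"
    window_bp: int = 50_000
    fdr: bool = False
    snap_tol_px: float = 2.0
    seed: int = 0

    def trait_config(self) -> TraitConfig:
        return TraitConfig(
            short_internode_cm=self.short_internode_cm,
            pod_height_boundary_cm=self.pod_height_boundary_cm,
            quantiles=self.quantiles,
        )

    def validate(self) -> None:
        if self.short_internode_cm <= 0 or self.pod_height_boundary_cm <= 0:
            raise ValueError("thresholds must be positive")
        if self.topo_dims < 1:
            raise ValueError("topo_dims must be >= 1")
        if not all(0 < q < 1 for q in self.quantiles):
            raise ValueError("quantiles must lie in (0, 1)")


def _barcode_digest(barcodes: list[topology.Barcode], dims: int) -> str:
    payload = json.dumps(
        [[bc.image_id, list(map(list, bc.intervals))] for bc in barcodes]
    ) + f"|dims={dims}"
    return hashlib.sha256(payload.encode()).hexdigest()


def _topo_distance_matrix(
    barcodes: list[topology.Barcode], cache_dir: Path, dims: int
) -> np.ndarray:
    """Pairwise bottleneck distances, cached by content hash.

    The distance matrix is the slow stage; reruns with unchanged barcodes
    (e.g. statistics-only changes) reuse the cached copy.
    """
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = _barcode_digest(barcodes, dims)
    cached = cache_dir / f"topo_{key}.npz"
    if cached.exists():
        logger.info("topology: reusing cached distance matrix %s", cached.name)
        return np.load(cached)["d"]
    d = topology.pairwise_topo_distances(barcodes)
    np.savez_compressed(cached, d=d)
    return d


ALL_STAGES = ("traits", "topology", "stats", "genetics")


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Execute a run; returns output paths and in-memory tables.

    ``stages`` selects a prefix of the workflow (traits, topology, stats,
    genetics); later stages need the earlier ones.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    pkg_logger = logging.getLogger("shootarch")
    pkg_logger.addHandler(handler)
    pkg_logger.setLevel(logging.INFO)
    try:
        return _run(config, out_dir, set(stages))
    finally:
        pkg_logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out_dir: Path, stages: set[str]) -> dict:
    tcfg = config.trait_config()
    images = annotation_io.load_annotation_dir(
        config.pods_dir, config.skeleton_dir,
        scale_override=config.scale_override,
        snap_tol_px=config.snap_tol_px,
    )
    if not images:
        raise ValueError("no parseable plant images found")
    logger.info("loaded %d images", len(images))

    records, barcodes = [], []
    for ann, graph in images:
        rec = geometry.image_traits(graph, ann, tcfg)
        dist = topology.geodesic_distances(graph)
        barcodes.append(topology.persistence_barcode(graph, dist))
        records.append(rec)

    # --- topology: pairwise bottleneck distances + MDS coordinates per image
    if "topology" in stages and len(barcodes) >= 2:
        d = _topo_distance_matrix(barcodes, out_dir / "cache", config.topo_dims)
        emb = topology.classical_mds(d, k=config.topo_dims)
        k_eff = emb.coordinates.shape[1]
        for i, rec in enumerate(records):
            for dim in range(min(3, config.topo_dims)):
                rec[f"MDS{dim + 1}"] = (
                    float(emb.coordinates[i, dim]) if dim < k_eff else 0.0
                )
        dist_df = pd.DataFrame(
            d, index=[bc.image_id for bc in barcodes],
            columns=[bc.image_id for bc in barcodes],
        )
        dist_df.to_csv(out_dir / "topo_distances.csv")
        pd.DataFrame({
            "dimension": np.arange(1, k_eff + 1),
            "variance_explained": emb.variance_explained,
        }).to_csv(out_dir / "mds_variance.csv", index=False)

    barcode_rows = [
        {"image_id": bc.image_id, "birth": b, "death": dth}
        for bc in barcodes for b, dth in bc.intervals
    ]
    pd.DataFrame(barcode_rows).to_csv(out_dir / "barcodes.csv", index=False)

    image_table = pd.DataFrame(records)
    image_table.to_csv(out_dir / "traits_per_image.csv", index=False)
    logger.info("traits_per_image: %d rows", len(image_table))

    # --- per-plant averaging
    groups = annotation_io.pair_replicates(records)
    plant_table = geometry.plant_trait_table(groups)
    if config.traits_csv is not None:
        external = pd.read_csv(config.traits_csv)
        plant_table = plant_table.merge(external, on="accession_id", how="left")
    plant_table.to_csv(out_dir / "traits_per_plant.csv", index=False)
    logger.info("traits_per_plant: %d rows", len(plant_table))

    results: dict = {
        "out_dir": out_dir,
        "image_table": image_table,
        "plant_table": plant_table,
    }

    # --- statistics
    if "stats" in stages:
        concordance = association.replicate_concordance(
            image_table, CONCORDANCE_TRAITS
        )
        concordance.to_csv(out_dir / "concordance.csv", index=False)
        results["concordance"] = concordance

        stat_traits = [
            t for t in GEOMETRIC_TRAITS + TOPO_TRAITS
            if t in plant_table.columns and t != "SIN"
        ]
        try:
            corr, order = association.trait_correlation_cluster(
                plant_table, stat_traits
            )
            corr.loc[order, order].to_csv(out_dir / "correlation_matrix.csv")
            results["correlation"] = corr
            results["cluster_order"] = order
        except ValueError as exc:
            logger.warning("correlation stage skipped: %s", exc)

        herit = association.heritability_table(plant_table, stat_traits)
        herit.to_csv(out_dir / "heritability.csv", index=False)
        results["heritability"] = herit
        logger.info("heritability: %d traits", len(herit))

    # --- genetics
    if "genetics" in stages and config.vcf is not None:
        genotypes = annotation_io.read_genotype_table(config.vcf)
        acc_means = plant_table.groupby("accession_id")["PN"].mean()
        labels = association.classify_pod_number(acc_means, split=config.split)
        assoc = association.marker_association(genotypes, labels, fdr=config.fdr)
        assoc.to_csv(out_dir / "association.csv", index=False)
        results["association"] = assoc
        logger.info("association: %d markers", len(assoc))
        if config.published_markers_csv is not None:
            published = pd.read_csv(config.published_markers_csv)
            matches = association.marker_window_match(
                published, genotypes.markers, window_bp=config.window_bp
            )
            matches.to_csv(out_dir / "marker_matches.csv", index=False)
            results["marker_matches"] = matches
    return results
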