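"""Synthetic edamame plants, populations, and genotypes.

The generator emulates the data a shoot-architecture imaging campaign
produces: per-image pod annotations (VOC-style XML) and branch skeletons
(JSON polylines), for a panel of accessions with two to four replicate
plants each, imaged front and back.  Plants are bilateral 2-D skeletons —
one vertical main branch with primary branches attached at junctions,
alternating left/right — with pods placed along the branches.

Statistical structure:

* each accession draws genetic target values (mean + N(0, genetic_sd^2))
  for the generative dials (main branch length, first node height,
  internode spacing, number of primary branches, pod number);
* each replicate plant realizes target + N(0, residual_sd^2);
* each image adds independent labeling jitter on vertex and pod
  coordinates, plus optional junction-occlusion noise that displaces a
  primary branch's attachment point along the main branch (mimicking
  junctions hidden on one side of a flattened plant);
* an optional biallelic marker panel includes exactly one causal marker
  that shifts an accession's pod-number target by ``marker_effect`` per
  non-reference allele, before plants are realized.

Every quantity the downstream analysis measures is recorded as ground
truth, so trait extraction can be tested for exact recovery when all noise
terms are zero.  Files are written in pixel coordinates with a declared
scale object so the calibration path is exercised.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .annotation_io import PodAnnotation
from .graph import MAIN, PRIMARY, PlantGraph, build_graph

SIDES = ("front", "back")

#: generative dials an accession's genetics can move
TRAIT_DIALS = (
    "main_length_cm",
    "first_node_height_cm",
    "internode_mean_cm",
    "n_primary_branches",
    "PN",
)

DEFAULT_TRAIT_MEANS = {
    "main_length_cm": 55.0,       # population average main branch ~56 cm
    "first_node_height_cm": 5.5,  # first junction ~5.5 cm above ground
    "internode_mean_cm": 2.5,     # successive junction gaps ~2-3 cm
    "n_primary_branches": 5.0,
    "PN": 60.0,
}
DEFAULT_GENETIC_SD = {
    "main_length_cm": 8.0,
    "first_node_height_cm": 1.5,
    "internode_mean_cm": 0.5,
    "n_primary_branches": 1.5,
    "PN": 15.0,
    # per-accession internode spacing profile (absolute cm wiggle per gap);
    # accession identity, shared by all replicates of the accession
    "internode_profile_cm": 0.6,
}
DEFAULT_RESIDUAL_SD = {
    "main_length_cm": 2.0,
    "first_node_height_cm": 0.5,
    "internode_mean_cm": 0.2,
    "n_primary_branches": 0.8,
    "PN": 6.0,
}


@dataclass
class PlantSimParams:
    """Geometry of one synthetic plant."""

    n_primary_branches: int = 5
    main_length_cm: float = 55.0
    first_node_height_cm: float = 5.5
    internode_mean_cm: float = 2.5
    internode_sd_cm: float = 0.6
    primary_length_frac_mean: float = 0.5
    pods_per_cm: float = 0.35
    n_pods: int | None = None        # explicit pod count overrides pods_per_cm
    branch_angle_deg: float = 35.0
    jitter_sd_cm: float = 0.0
    junction_shift_prob: float = 0.0
    junction_shift_sd_cm: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        positive = (
            "main_length_cm", "first_node_height_cm", "internode_mean_cm",
            "primary_length_frac_mean", "pods_per_cm",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.internode_sd_cm < 0 or self.jitter_sd_cm < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.n_primary_branches < 0:
            raise ValueError("n_primary_branches must be >= 0")
        if not 0 < self.primary_length_frac_mean <= 1:
            raise ValueError("primary_length_frac_mean must be in (0, 1]")


@dataclass
class PopulationSimParams:
    """Design of a synthetic accession panel."""

    n_accessions: int = 24
    reps_per_accession: int | list[int] | None = None  # None -> cycle 2,3,4
    trait_means: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    genetic_sd: dict = field(default_factory=lambda: dict(DEFAULT_GENETIC_SD))
    residual_sd: dict = field(default_factory=lambda: dict(DEFAULT_RESIDUAL_SD))
    internode_sd_cm: float = 0.6
    primary_length_frac_mean: float = 0.5
    branch_angle_deg: float = 35.0
    jitter_sd_cm: float = 0.15
    junction_shift_prob: float = 0.0
    junction_shift_sd_cm: float = 2.0
    n_markers: int = 0
    marker_effect: float = 0.0
    het_prob: float = 0.0
    missing_prob: float = 0.0
    px_per_cm: float = 10.0
    seed: int = 0

    def rep_counts(self) -> list[int]:
        if self.reps_per_accession is None:
            return [(2, 3, 4)[i % 3] for i in range(self.n_accessions)]
        if isinstance(self.reps_per_accession, int):
            return [self.reps_per_accession] * self.n_accessions
        reps = list(self.reps_per_accession)
        if len(reps) != self.n_accessions:
            raise ValueError(
                f"reps_per_accession has {len(reps)} entries for "
                f"{self.n_accessions} accessions"
            )
        return reps

    def validate(self) -> None:
        if self.n_accessions < 2:
            raise ValueError("need at least two accessions")
        if any(r < 1 for r in self.rep_counts()):
            raise ValueError("every accession needs at least one replicate")
        for d in (self.genetic_sd, self.residual_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("standard deviations must be nonnegative")


# ---------------------------------------------------------------------------
# single-plant layout


@dataclass
class _Layout:
    """Shared-vertex representation of one plant, in cm, base at (0, 0)."""

    vertices: np.ndarray             # (n, 2)
    main_path: list[int]
    primaries: list[list[int]]       # each starts at a main-path junction index
    junction_idx: list[int]          # vertex index per primary junction
    pods: np.ndarray                 # (m, 2)
    truth: dict


def _nearest_rank(sorted_heights: np.ndarray, q: float) -> float:
    n = len(sorted_heights)
    return float(sorted_heights[min(math.ceil(q * n), n) - 1])


def _pod_truth(heights: np.ndarray) -> dict:
    heights = np.sort(heights)
    pn = len(heights)
    if pn == 0:
        return {"PN": 0, "PN10": 0, "FPH": math.nan, "P1H": math.nan,
                "P5H": math.nan}
    return {
        "PN": pn,
        "PN10": int((heights > 10.0).sum()),
        "FPH": float(heights[0]),
        "P1H": _nearest_rank(heights, 0.01),
        "P5H": _nearest_rank(heights, 0.05),
    }


def _internode_truth(junctions: list[float], threshold: float = 0.5) -> dict:
    sin = False
    eff: list[float] = []
    for h in junctions:
        if eff and h - eff[-1] < threshold:
            sin = True
        else:
            eff.append(h)
    gaps = [b - a for a, b in zip(eff[:-1], eff[1:])]
    get = lambda i: gaps[i] if i < len(gaps) else math.nan  # noqa: E731
    return {"FNH": eff[0] if eff else math.nan, "FIL": get(0),
            "SIL": get(1), "TIL": get(2), "SIN": sin}


def _build_layout(
    params: PlantSimParams,
    rng: np.random.Generator,
    gap_noise: np.ndarray | None = None,
) -> _Layout:
    params.validate()
    n = params.n_primary_branches
    length = params.main_length_cm

    # Junction heights along the main branch: first node + noisy internodes.
    # ``gap_noise`` (absolute cm deviations) lets a caller pin the spacing
    # profile, e.g. to share it between replicates of an accession.
    if gap_noise is not None:
        noise = np.asarray(gap_noise, dtype=float)[: max(n - 1, 0)]
        if len(noise) < max(n - 1, 0):
            raise ValueError("gap_noise shorter than the number of internodes")
    else:
        noise = params.internode_sd_cm * rng.standard_normal(max(n - 1, 0))
    gaps = params.internode_mean_cm + noise
    gaps = np.maximum(gaps, 0.1)
    junctions = params.first_node_height_cm + np.concatenate(
        [[0.0], np.cumsum(gaps)]
    )[:n]
    # Keep the branching zone in the lower part of the plant.
    ceiling = 0.9 * length
    if n and junctions[-1] > ceiling:
        junctions = junctions * (ceiling / junctions[-1])
    junctions = list(map(float, junctions))

    verts: list[tuple[float, float]] = [(0.0, 0.0)]
    main_path = [0]
    junction_idx = []
    for h in junctions:
        verts.append((0.0, h))
        junction_idx.append(len(verts) - 1)
        main_path.append(len(verts) - 1)
    verts.append((0.0, length))
    main_path.append(len(verts) - 1)

    theta = math.radians(params.branch_angle_deg)
    lp = params.primary_length_frac_mean * length
    primaries = []
    for k, h in enumerate(junctions):
        sign = 1.0 if k % 2 == 0 else -1.0  # bilateral alternation
        tip = (sign * lp * math.sin(theta), h + lp * math.cos(theta))
        verts.append(tip)
        primaries.append([junction_idx[k], len(verts) - 1])

    pods = _place_pods(params, junctions, length, lp, theta)

    truth = {
        "PH": length,
        "MBL": length,
        "TBL": length + n * lp,
        "APBL": (length + n * lp) / (n + 1),
        "NPB": n,
        **_internode_truth(junctions),
        **_pod_truth(pods[:, 1] if len(pods) else np.empty(0)),
    }
    return _Layout(
        vertices=np.array(verts, dtype=float),
        main_path=main_path,
        primaries=primaries,
        junction_idx=junction_idx,
        pods=pods,
        truth=truth,
    )


def _place_pods(
    params: PlantSimParams,
    junctions: list[float],
    length: float,
    lp: float,
    theta: float,
) -> np.ndarray:
    """Place pods evenly along the pod-bearing branch segments.

    Pods appear on the main branch above the branching zone and along each
    primary branch; counts per branch are proportional to segment length
    (largest-remainder rounding, so totals are exact when ``n_pods`` is
    given).
    """
    n = params.n_primary_branches
    main_start = junctions[-1] if junctions else 0.0
    seg_lengths = [length - main_start] + [lp] * n
    total_len = sum(seg_lengths)
    if params.n_pods is not None:
        total = max(int(params.n_pods), 0)
        quota = [total * sl / total_len for sl in seg_lengths]
        counts = [int(q) for q in quota]
        remainders = sorted(
            range(len(quota)), key=lambda i: (quota[i] - counts[i], -i),
            reverse=True,
        )
        for i in remainders[: total - sum(counts)]:
            counts[i] += 1
    else:
        counts = [int(sl * params.pods_per_cm) for sl in seg_lengths]

    pods: list[tuple[float, float]] = []
    # main branch segment, vertical from main_start to the top
    for i in range(counts[0]):
        arc = main_start + (i + 1) * (length - main_start) / (counts[0] + 1)
        pods.append((0.0, arc))
    for k in range(n):
        sign = 1.0 if k % 2 == 0 else -1.0
        h = junctions[k]
        for i in range(counts[k + 1]):
            arc = (i + 1) * lp / (counts[k + 1] + 1)
            pods.append((sign * arc * math.sin(theta), h + arc * math.cos(theta)))
    return np.array(pods, dtype=float).reshape(-1, 2)


def generate_plant(
    params: PlantSimParams,
) -> tuple[PlantGraph, PodAnnotation, dict]:
    """One noiseless plant in cm space, with its ground-truth traits.

    The returned graph and annotation are already calibrated (cm, height
    upward from the base); labeling jitter belongs to the per-image
    rendering step, not to the plant itself.  Fixed seed, fixed output.
    """
    rng = np.random.default_rng(params.seed)
    layout = _build_layout(params, rng)
    graph = _layout_to_graph(layout, image_id="synthetic")
    ann = PodAnnotation(
        image_id="synthetic",
        accession_id="synthetic",
        replicate_id="r1",
        side="front",
        pods=[tuple(p) for p in layout.pods],
        top=tuple(layout.vertices[layout.main_path[-1]]),
        bottom=tuple(layout.vertices[layout.main_path[0]]),
        px_per_cm=1.0,
        calibrated=True,
    )
    return graph, ann, dict(layout.truth)


def _layout_to_graph(layout: _Layout, image_id: str = "") -> PlantGraph:
    polylines = [(MAIN, [tuple(layout.vertices[i]) for i in layout.main_path])]
    for path in layout.primaries:
        polylines.append((PRIMARY, [tuple(layout.vertices[i]) for i in path]))
    # junction coordinates coincide exactly; tiny tolerance merges them
    return build_graph(
        polylines, base_point=(0.0, 0.0), snap_tol=1e-9, image_id=image_id
    )


# ---------------------------------------------------------------------------
# per-image rendering and file writers


def _render_image(
    layout: _Layout,
    side: str,
    jitter_sd: float,
    shift_prob: float,
    shift_sd: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[int], list[list[int]], np.ndarray]:
    """Jittered copy of the layout for one image side.

    Junction vertices are shared between the main and primary polylines
    (the labeler clicks a junction once), so jitter never disconnects the
    skeleton.  The back image mirrors x, as the plant is physically
    flipped.
    """
    verts = layout.vertices.copy()
    length = verts[layout.main_path[-1], 1]
    for k in layout.junction_idx:
        if shift_prob > 0 and rng.random() < shift_prob:
            shifted = verts[k, 1] + rng.normal(0.0, shift_sd)
            verts[k, 1] = min(max(shifted, 0.5), length - 0.5)
    if jitter_sd > 0:
        verts = verts + rng.normal(0.0, jitter_sd, size=verts.shape)
    pods = layout.pods.copy()
    if jitter_sd > 0 and len(pods):
        pods = pods + rng.normal(0.0, jitter_sd, size=pods.shape)

    # Occlusion shifts can reorder junctions along the main branch.
    inner = sorted(layout.main_path[1:-1], key=lambda i: verts[i, 1])
    main_path = [layout.main_path[0], *inner, layout.main_path[-1]]

    if side == "back":
        verts = verts.copy()
        verts[:, 0] = -verts[:, 0]
        if len(pods):
            pods = pods.copy()
            pods[:, 0] = -pods[:, 0]
    return verts, main_path, layout.primaries, pods


SCALE_BAR_CM = 10.0
POD_BOX_HALF_PX = 3.0
ANCHOR_BOX_HALF_PX = 2.0


def _to_pixels(
    verts: np.ndarray, pods: np.ndarray, px_per_cm: float
) -> tuple[np.ndarray, np.ndarray]:
    """cm -> pixel transform: y flipped (origin top-left), all coords positive."""
    all_pts = verts if len(pods) == 0 else np.vstack([verts, pods])
    x_off = 20.0 - all_pts[:, 0].min() * px_per_cm
    y_off = 20.0 + all_pts[:, 1].max() * px_per_cm

    def tx(pts: np.ndarray) -> np.ndarray:
        out = np.empty_like(pts)
        out[:, 0] = pts[:, 0] * px_per_cm + x_off
        out[:, 1] = y_off - pts[:, 1] * px_per_cm
        return out

    return tx(verts), tx(pods) if len(pods) else pods


def write_pod_xml(
    path: Path,
    image_id: str,
    accession: str,
    replicate: str,
    side: str,
    pods_px: np.ndarray,
    top_px: tuple[float, float],
    bottom_px: tuple[float, float],
    px_per_cm: float,
) -> None:
    """Write a VOC-style pod annotation XML (schema in docs/annotation_schema.md)."""
    root = etree.Element("annotation")
    for tag, text in (
        ("filename", image_id),
        ("accession", accession),
        ("replicate", replicate),
        ("side", side),
    ):
        etree.SubElement(root, tag).text = text

    def add_object(name: str, xmin, ymin, xmax, ymax, length_cm=None) -> None:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = name
        box = etree.SubElement(obj, "bndbox")
        for t, v in zip(("xmin", "ymin", "xmax", "ymax"), (xmin, ymin, xmax, ymax)):
            etree.SubElement(box, t).text = repr(float(v))
        if length_cm is not None:
            etree.SubElement(obj, "length_cm").text = repr(float(length_cm))

    for x, y in pods_px:
        add_object("pod", x - POD_BOX_HALF_PX, y - POD_BOX_HALF_PX,
                   x + POD_BOX_HALF_PX, y + POD_BOX_HALF_PX)
    for name, (x, y) in (("top", top_px), ("bottom", bottom_px)):
        add_object(name, x - ANCHOR_BOX_HALF_PX, y - ANCHOR_BOX_HALF_PX,
                   x + ANCHOR_BOX_HALF_PX, y + ANCHOR_BOX_HALF_PX)
    add_object("scale", 10.0, 5.0, 10.0 + SCALE_BAR_CM * px_per_cm, 5.0,
               length_cm=SCALE_BAR_CM)

    path.write_bytes(etree.tostring(root, pretty_print=True))


def write_skeleton_json(
    path: Path,
    image_id: str,
    accession: str,
    replicate: str,
    side: str,
    verts_px: np.ndarray,
    main_path: list[int],
    primaries: list[list[int]],
    px_per_cm: float,
) -> None:
    """Write the skeleton JSON for one image."""
    doc = {
        "image_id": image_id,
        "accession": accession,
        "replicate": replicate,
        "side": side,
        "px_per_cm": px_per_cm,
        "base": list(map(float, verts_px[main_path[0]])),
        "polylines": [
            {"role": MAIN,
             "points": [list(map(float, verts_px[i])) for i in main_path]},
            *(
                {"role": PRIMARY,
                 "points": [list(map(float, verts_px[i])) for i in path]}
                for path in primaries
            ),
        ],
    }
    path.write_text(json.dumps(doc, indent=1) + "\n")


def emit_plant_images(
    layout: _Layout,
    out_pods: Path,
    out_skels: Path,
    accession: str,
    replicate: str,
    px_per_cm: float,
    jitter_sd: float,
    shift_prob: float,
    shift_sd: float,
    rng: np.random.Generator,
) -> list[str]:
    """Write the front/back XML + JSON pair for one plant; returns image ids."""
    ids = []
    for side in SIDES:
        verts, main_path, primaries, pods = _render_image(
            layout, side, jitter_sd, shift_prob, shift_sd, rng
        )
        verts_px, pods_px = _to_pixels(verts, pods, px_per_cm)
        image_id = f"{accession}_{replicate}_{side}"
        write_pod_xml(
            out_pods / f"{image_id}.xml", image_id, accession, replicate, side,
            pods_px, tuple(verts_px[main_path[-1]]), tuple(verts_px[main_path[0]]),
            px_per_cm,
        )
        write_skeleton_json(
            out_skels / f"{image_id}.json", image_id, accession, replicate, side,
            verts_px, main_path, primaries, px_per_cm,
        )
        ids.append(image_id)
    return ids


# ---------------------------------------------------------------------------
# genotypes


def generate_genotypes(
    params: PopulationSimParams,
    accessions: list[str],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, str | None, pd.Series]:
    """Biallelic marker panel with one causal marker for pod number.

    Returns (markers, calls, causal_marker_id, alt_dose) where ``alt_dose``
    counts non-reference alleles (0, 1 or 2) of the causal marker per
    accession — the pod-number shift applied before plant realization is
    ``marker_effect * alt_dose``.  Positions are sampled on one chromosome.
    """
    n = params.n_markers
    if n <= 0:
        return (
            pd.DataFrame(columns=["marker_id", "chrom", "pos"]),
            pd.DataFrame(columns=accessions),
            None,
            pd.Series(0.0, index=accessions),
        )
    positions = np.unique(rng.integers(1, 50_000_000, size=2 * n))
    while len(positions) < n:  # collisions are vanishingly rare
        positions = np.unique(
            np.concatenate([positions, rng.integers(1, 50_000_000, size=n)])
        )
    positions = np.sort(rng.permutation(positions)[:n])
    markers = pd.DataFrame(
        {"marker_id": [f"sim_m{i:04d}" for i in range(n)],
         "chrom": "Gm11", "pos": positions}
    )
    mafs = rng.uniform(0.2, 0.5, size=n)
    dose = rng.binomial(2, mafs[:, None], size=(n, len(accessions)))
    state = np.where(dose == 0, "reference",
                     np.where(dose == 2, "non_reference", "heterozygous"))
    if params.het_prob == 0:
        # collapse hets to a random homozygote so 2x2 tables stay full
        state = np.where(state == "heterozygous",
                         np.where(rng.random(state.shape) < 0.5,
                                  "reference", "non_reference"),
                         state)
        dose = np.where(state == "non_reference", 2,
                        np.where(state == "reference", 0, 1))
    if params.missing_prob > 0:
        state = np.where(rng.random(state.shape) < params.missing_prob,
                         "missing", state)
    calls = pd.DataFrame(state, index=markers["marker_id"], columns=accessions)
    causal_i = int(rng.integers(n))
    causal_id = markers["marker_id"].iloc[causal_i]
    alt_dose = pd.Series(
        dose[causal_i].astype(float), index=accessions, name="alt_dose"
    )
    return markers, calls, causal_id, alt_dose


def write_vcf(markers: pd.DataFrame, calls: pd.DataFrame, path: Path) -> None:
    """Write the marker panel as an uncompressed VCF v4.2."""
    gt = {"reference": "0/0", "non_reference": "1/1",
          "heterozygous": "0/1", "missing": "./."}
    accessions = list(calls.columns)
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=Gm11>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(accessions),
    ]
    for (_, m), (_, row) in zip(markers.iterrows(), calls.iterrows()):
        fields = [str(m["chrom"]), str(int(m["pos"])), str(m["marker_id"]),
                  "A", "T", ".", "PASS", ".", "GT"]
        fields += [gt[row[acc]] for acc in accessions]
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# population


def generate_population(
    params: PopulationSimParams, out_dir: str | Path
) -> dict[str, Path]:
    """Write a full synthetic study to ``out_dir``.

    Layout: ``pods/*.xml``, ``skeletons/*.json``, ``truth_plants.csv``
    (per-plant ground-truth traits), ``truth_accessions.csv`` (genetic
    targets), and ``genotypes.vcf`` when ``n_markers > 0``.  Everything is
    a pure function of ``params`` (seed included).
    """
    params.validate()
    out_dir = Path(out_dir)
    pods_dir = out_dir / "pods"
    skels_dir = out_dir / "skeletons"
    pods_dir.mkdir(parents=True, exist_ok=True)
    skels_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(params.seed)
    accessions = [f"PI{i + 1:03d}" for i in range(params.n_accessions)]
    reps = params.rep_counts()

    markers, calls, causal_id, alt_dose = generate_genotypes(
        params, accessions, rng
    )

    # user-supplied dials override the defaults; unspecified ones keep them
    means = {**DEFAULT_TRAIT_MEANS, **params.trait_means}
    gsd = {**DEFAULT_GENETIC_SD, **params.genetic_sd}
    rsd = {**DEFAULT_RESIDUAL_SD, **params.residual_sd}

    acc_rows, plant_rows = [], []
    for acc, n_rep in zip(accessions, reps):
        targets = {
            dial: means[dial] + gsd.get(dial, 0.0) * rng.standard_normal()
            for dial in TRAIT_DIALS
        }
        targets["PN"] += params.marker_effect * alt_dose[acc]
        # internode spacing profile: accession identity, shared by replicates
        gap_profile = gsd.get("internode_profile_cm", 0.0) * rng.standard_normal(10)
        acc_rows.append({"accession_id": acc, "causal_dose": alt_dose[acc],
                         **{f"target_{k}": v for k, v in targets.items()}})
        for r in range(1, n_rep + 1):
            realized = {
                dial: targets[dial]
                + rsd.get(dial, 0.0) * rng.standard_normal()
                for dial in TRAIT_DIALS
            }
            plant_params = PlantSimParams(
                n_primary_branches=int(np.clip(round(realized["n_primary_branches"]), 0, 10)),
                main_length_cm=max(realized["main_length_cm"], 10.0),
                first_node_height_cm=max(realized["first_node_height_cm"], 0.5),
                internode_mean_cm=max(realized["internode_mean_cm"], 0.3),
                internode_sd_cm=0.0,
                primary_length_frac_mean=params.primary_length_frac_mean,
                branch_angle_deg=params.branch_angle_deg,
                n_pods=max(int(round(realized["PN"])), 0),
            )
            layout = _build_layout(plant_params, rng, gap_noise=gap_profile)
            replicate = f"r{r}"
            emit_plant_images(
                layout, pods_dir, skels_dir, acc, replicate,
                params.px_per_cm, params.jitter_sd_cm,
                params.junction_shift_prob, params.junction_shift_sd_cm, rng,
            )
            plant_rows.append(
                {"accession_id": acc, "replicate_id": replicate, **layout.truth}
            )

    truth_plants = pd.DataFrame(plant_rows)
    truth_acc = pd.DataFrame(acc_rows)
    paths = {
        "pods_dir": pods_dir,
        "skeleton_dir": skels_dir,
        "truth_plants": out_dir / "truth_plants.csv",
        "truth_accessions": out_dir / "truth_accessions.csv",
    }
    truth_plants.to_csv(paths["truth_plants"], index=False)
    truth_acc.to_csv(paths["truth_accessions"], index=False)
    if params.n_markers > 0:
        paths["vcf"] = out_dir / "genotypes.vcf"
        write_vcf(markers, calls, paths["vcf"])
        (out_dir / "causal_marker.txt").write_text(f"{causal_id}\n")
        paths["causal_marker"] = out_dir / "causal_marker.txt"
    return paths


def simulate_trait(
    n_accessions: int,
    reps: list[int] | int,
    mean: float,
    genetic_sd: float,
    residual_sd: float,
    seed: int,
) -> tuple[pd.DataFrame, float]:
    """Directly simulated trait values y_ij = mu + g_i + e_ij.

    Returns the long table (accession_id, value) and the true entry-mean
    heritability implied by the design's harmonic-mean replicate count —
    the closed-form target the REML estimator should recover.
    """
    rng = np.random.default_rng(seed)
    if isinstance(reps, int):
        reps = [reps] * n_accessions
    if len(reps) != n_accessions:
        raise ValueError("reps list length must equal n_accessions")
    rows = []
    for i, n_rep in enumerate(reps):
        g = genetic_sd * rng.standard_normal()
        for r in range(n_rep):
            rows.append({
                "accession_id": f"PI{i + 1:03d}",
                "value": mean + g + residual_sd * rng.standard_normal(),
            })
    r_bar = len(reps) / sum(1.0 / r for r in reps)
    s2g, s2e = genetic_sd ** 2, residual_sd ** 2
    h2_true = s2g / (s2g + s2e / r_bar) if (s2g + s2e) > 0 else 0.0
    return pd.DataFrame(rows), h2_true
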