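"""Reading and validating plant annotation files and genotype tables.

Two files describe each plant image:

* a VOC-style XML with one ``object`` per labeled item — ``pod`` bounding
  boxes, the ``top`` and ``bottom`` anchors of the plant, and a ``scale``
  object whose pixel extent spans a segment of declared physical length
  (``length_cm``), from which the pixel-per-cm calibration is derived;
* a skeleton JSON listing role-labeled polylines (one ``main``, any number
  of ``primary``) in pixel coordinates plus the base point.

Pixel convention: origin top-left, y increases downward.  Calibration
divides by px_per_cm and flips the y axis so that height is measured in cm
upward from the labeled bottom anchor (the soil-line cut).

The full schema is documented in ``docs/annotation_schema.md``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .graph import PlantGraph, build_graph

logger = logging.getLogger(__name__)

ALLELE_STATES = ("reference", "non_reference", "heterozygous", "missing")


@dataclass
class PodAnnotation:
    """Pod centers and plant anchors for one image.

    Coordinates are pixels as labeled unless ``calibrated`` is True, in
    which case they are cm with height measured upward from the bottom
    anchor.
    """

    image_id: str
    accession_id: str
    replicate_id: str
    side: str                           # "front" | "back"
    pods: list[tuple[float, float]]
    top: tuple[float, float]
    bottom: tuple[float, float]
    px_per_cm: float
    calibrated: bool = False

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        if self.side not in ("front", "back"):
            raise ValueError(f"side must be front or back, got {self.side!r}")

    @property
    def plant_key(self) -> tuple[str, str]:
        return (self.accession_id, self.replicate_id)

    def pod_heights(self) -> np.ndarray:
        """Heights above ground in cm; requires calibration first."""
        if not self.calibrated:
            raise ValueError("calibrate the annotation before reading heights")
        return np.array([y for _, y in self.pods])

    @property
    def plant_height(self) -> float:
        if not self.calibrated:
            raise ValueError("calibrate the annotation first")
        return self.top[1] - self.bottom[1]


@dataclass
class Skeleton:
    """Raw (pixel-space) polylines of one image, before graph assembly."""

    image_id: str
    accession_id: str
    replicate_id: str
    side: str
    base: tuple[float, float]
    polylines: list[tuple[str, list[tuple[float, float]]]]
    px_per_cm: float | None = None


@dataclass
class GenotypeTable:
    """Biallelic marker calls for a set of accessions.

    ``markers`` has columns ``marker_id``, ``chrom``, ``pos`` (1-based);
    ``calls`` is a DataFrame indexed by marker_id with one column per
    accession, values in :data:`ALLELE_STATES`.
    """

    markers: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.markers["pos"] < 1).any():
            raise ValueError("marker positions must be >= 1")
        if self.calls.columns.duplicated().any():
            raise ValueError("duplicate accession ids in genotype table")
        bad = set(np.unique(self.calls.values)) - set(ALLELE_STATES)
        if bad:
            raise ValueError(f"unknown allele states: {bad}")

    @property
    def accessions(self) -> list[str]:
        return list(self.calls.columns)


def parse_pod_annotation(path: str | Path) -> PodAnnotation:
    """Parse a VOC-style pod annotation XML file.

    Pod centers are bounding-box midpoints.  The scale object's pixel
    extent (the longer side of its box) divided by its declared length_cm
    gives px_per_cm.  Exactly one ``top`` and one ``bottom`` object are
    required.
    """
    tree = etree.parse(str(path))  # raises XMLSyntaxError on malformed input
    root = tree.getroot()

    def meta(tag: str) -> str:
        el = root.find(tag)
        if el is None or not (el.text or "").strip():
            raise ValueError(f"{path}: missing <{tag}>")
        return el.text.strip()

    pods: list[tuple[float, float]] = []
    anchors: dict[str, list[tuple[float, float]]] = {"top": [], "bottom": []}
    px_per_cm = None
    for obj in root.findall("object"):
        name = obj.findtext("name", "").strip()
        box = obj.find("bndbox")
        if box is None:
            raise ValueError(f"{path}: object {name!r} has no bndbox")
        xmin, ymin, xmax, ymax = (
            float(box.findtext(t)) for t in ("xmin", "ymin", "xmax", "ymax")
        )
        center = ((xmin + xmax) / 2.0, (ymin + ymax) / 2.0)
        if name == "pod":
            pods.append(center)
        elif name in anchors:
            anchors[name].append(center)
        elif name == "scale":
            declared = obj.findtext("length_cm")
            if declared is None:
                raise ValueError(f"{path}: scale object lacks <length_cm>")
            extent = max(xmax - xmin, ymax - ymin)
            px_per_cm = extent / float(declared)
        else:
            logger.warning("%s: ignoring unknown object %r", path, name)

    for which, found in anchors.items():
        if len(found) != 1:
            raise ValueError(
                f"{path}: expected exactly one {which} anchor, found {len(found)}"
            )
    if px_per_cm is None:
        raise ValueError(f"{path}: no scale object; pass a scale override")

    return PodAnnotation(
        image_id=meta("filename"),
        accession_id=meta("accession"),
        replicate_id=meta("replicate"),
        side=meta("side"),
        pods=pods,
        top=anchors["top"][0],
        bottom=anchors["bottom"][0],
        px_per_cm=px_per_cm,
    )


def parse_skeleton(path: str | Path) -> Skeleton:
    """Parse a skeleton JSON file into raw polylines."""
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("image_id", "accession", "replicate", "side", "base", "polylines"):
        if key not in doc:
            raise ValueError(f"{path}: skeleton JSON missing {key!r}")
    polylines = [
        (pl["role"], [(float(x), float(y)) for x, y in pl["points"]])
        for pl in doc["polylines"]
    ]
    return Skeleton(
        image_id=doc["image_id"],
        accession_id=doc["accession"],
        replicate_id=doc["replicate"],
        side=doc["side"],
        base=tuple(map(float, doc["base"])),
        polylines=polylines,
        px_per_cm=doc.get("px_per_cm"),
    )


def calibrate_annotation(
    ann: PodAnnotation, px_per_cm: float | None = None
) -> PodAnnotation:
    """Convert a pixel-space annotation to cm with height measured upward.

    All heights are measured from the bottom anchor; pods that land a hair
    below ground under labeling jitter are clipped to 0 with a warning.
    """
    if ann.calibrated:
        return ann
    ppc = px_per_cm if px_per_cm is not None else ann.px_per_cm
    if ppc is None or ppc <= 0:
        raise ValueError("no usable px_per_cm for calibration")
    by = ann.bottom[1]

    def to_cm(p: tuple[float, float]) -> tuple[float, float]:
        return (p[0] / ppc, (by - p[1]) / ppc)

    pods = []
    clipped = 0
    for p in ann.pods:
        x, y = to_cm(p)
        if y < 0:
            clipped += 1
            y = 0.0
        pods.append((x, y))
    if clipped:
        logger.warning("%s: clipped %d pod(s) below ground to 0", ann.image_id, clipped)
    return replace(
        ann,
        pods=pods,
        top=to_cm(ann.top),
        bottom=to_cm(ann.bottom),
        px_per_cm=ppc,
        calibrated=True,
    )


def calibrate_skeleton(
    skel: Skeleton,
    px_per_cm: float | None = None,
    snap_tol_px: float = 2.0,
) -> PlantGraph:
    """Build a cm-space :class:`PlantGraph` from a pixel-space skeleton.

    Junction snapping happens in pixel space (default tolerance 2 px); the
    base point maps to height 0.
    """
    ppc = px_per_cm if px_per_cm is not None else skel.px_per_cm
    if ppc is None or ppc <= 0:
        raise ValueError("no usable px_per_cm for calibration")
    bx, by = skel.base

    def to_cm(p: tuple[float, float]) -> tuple[float, float]:
        return ((p[0] - bx) / ppc, (by - p[1]) / ppc)

    polylines = [(role, [to_cm(p) for p in pts]) for role, pts in skel.polylines]
    return build_graph(
        polylines,
        base_point=(0.0, 0.0),
        snap_tol=snap_tol_px / ppc,
        image_id=skel.image_id,
        accession_id=skel.accession_id,
        replicate_id=skel.replicate_id,
        side=skel.side,
    )


def pair_replicates(items: list) -> dict[tuple[str, str], dict[str, object]]:
    """Group per-image records by plant, keyed (accession, replicate).

    Each plant may have a front and a back image.  A plant with a single
    image is kept with a warning; more than two images (or two images with
    the same side label) is an error.
    """
    def get(item, name: str):
        return item[name] if isinstance(item, dict) else getattr(item, name)

    groups: dict[tuple[str, str], dict[str, object]] = {}
    for item in items:
        key = (get(item, "accession_id"), get(item, "replicate_id"))
        side = get(item, "side")
        sides = groups.setdefault(key, {})
        if side in sides:
            raise ValueError(f"plant {key}: duplicate {side} image")
        if len(sides) >= 2:
            raise ValueError(f"plant {key}: more than two images")
        sides[side] = item
    for key, sides in groups.items():
        if len(sides) == 1:
            logger.warning("plant %s: only one image (%s)", key, next(iter(sides)))
    return groups


def read_genotype_table(vcf_path: str | Path) -> GenotypeTable:
    """Load a VCF into a :class:`GenotypeTable`.

    Genotype mapping: 0/0 -> reference, 1/1 -> non_reference,
    0/1 -> heterozygous, ./. -> missing.  Multi-allelic records are
    rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    accessions = list(vcf.samples)
    rows, calls = [], []
    state = {0: "reference", 1: "heterozygous", 2: "non_reference", 3: "missing"}
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {var.CHROM}:{var.POS} is not supported"
            )
        marker_id = var.ID or f"{var.CHROM}:{var.POS}"
        rows.append({"marker_id": marker_id, "chrom": var.CHROM, "pos": var.POS})
        calls.append([state[int(g)] for g in var.gt_types])
    vcf.close()
    markers = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos"])
    calls_df = pd.DataFrame(
        calls, index=markers["marker_id"], columns=accessions
    )
    return GenotypeTable(markers=markers, calls=calls_df)


def load_annotation_dir(
    pods_dir: str | Path,
    skeleton_dir: str | Path,
    scale_override: float | None = None,
    snap_tol_px: float = 2.0,
    on_error: str = "skip",
) -> list[tuple[PodAnnotation, PlantGraph]]:
    """Load and calibrate every image with both an XML and a JSON file.

    ``on_error='skip'`` logs and drops unparseable images (a single corrupt
    annotation must not abort a population run); ``'raise'`` propagates.
    """
    pods_dir, skeleton_dir = Path(pods_dir), Path(skeleton_dir)
    out = []
    for xml_path in sorted(pods_dir.glob("*.xml")):
        stem = xml_path.stem
        json_path = skeleton_dir / f"{stem}.json"
        try:
            ann = parse_pod_annotation(xml_path)
            if not json_path.exists():
                raise FileNotFoundError(f"no skeleton JSON for {stem}")
            skel = parse_skeleton(json_path)
            ppc = scale_override if scale_override is not None else ann.px_per_cm
            graph = calibrate_skeleton(skel, px_per_cm=ppc, snap_tol_px=snap_tol_px)
            ann = calibrate_annotation(ann, px_per_cm=ppc)
        except Exception as exc:  # noqa: BLE001 - any bad file is one skipped image
            if on_error == "raise":
                raise
            logger.warning("SKIP image %s: %s", stem, exc)
            continue
        out.append((ann, graph))
    return out
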