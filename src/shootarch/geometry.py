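"""Geometric shoot-architecture traits.

Sixteen traits per image, averaged per plant over the front/back pair:

======  =====================================================
PH      plant height (vertical base-to-top distance, cm)
MBL     main branch length (arc length, cm)
TBL     total branch length (main + primaries, cm)
APBL    average branch length: TBL / number of branches,
        the main branch included in the denominator
NPB     number of primary branches
FNH     first node height (arc length from ground to the first
        primary-branch junction, cm)
FIL/SIL/TIL  first/second/third internode lengths: successive
        gaps between junctions along the main branch (cm)
SIN     short-internode flag: any junction gap below the short
        threshold (such junction pairs are merged before the
        internodes are indexed)
PN      pod number
PN10    pods strictly above 10 cm from ground
FPH     first (lowest) pod height (cm)
P1H/P5H heights below which 1% / 5% of pods lie (nearest-rank)
======  =====================================================
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import PodAnnotation
from .graph import PlantGraph

logger = logging.getLogger(__name__)

GEOMETRIC_TRAITS = [
    "PH", "MBL", "TBL", "APBL", "NPB",
    "FNH", "FIL", "SIL", "TIL", "SIN",
    "PN", "PN10", "FPH", "P1H", "P5H",
]
TOPO_TRAITS = ["MDS1", "MDS2", "MDS3"]
BOOLEAN_TRAITS = {"SIN"}

DEFAULT_SHORT_INTERNODE_CM = 0.5
DEFAULT_POD_HEIGHT_BOUNDARY_CM = 10.0


@dataclass
class TraitConfig:
    """Thresholds used by the trait extractors.

    ``fnh_vertical`` switches FNH from arc length along the main branch
    (default) to the junction's vertical height; ``apbl_main_in_denominator``
    switches between TBL/(NPB+1) (default) and TBL/NPB.
    """

    short_internode_cm: float = DEFAULT_SHORT_INTERNODE_CM
    pod_height_boundary_cm: float = DEFAULT_POD_HEIGHT_BOUNDARY_CM
    quantiles: tuple[float, float] = (0.01, 0.05)
    fnh_vertical: bool = False
    apbl_main_in_denominator: bool = True


def branch_traits(plant: PlantGraph, config: TraitConfig | None = None) -> dict:
    """PH, MBL, TBL, APBL and NPB of a calibrated plant graph."""
    config = config or TraitConfig()
    if plant.graph.number_of_nodes() == 0:
        raise ValueError("empty plant graph")
    ph = plant.pos(plant.top_vertex)[1] - plant.pos(plant.base_vertex)[1]
    mbl = plant.branch_length(plant.main_branch)
    primaries = plant.primary_branches
    tbl = mbl + sum(plant.branch_length(b) for b in primaries)
    npb = len(primaries)
    denom = npb + 1 if config.apbl_main_in_denominator else max(npb, 1)
    return {"PH": ph, "MBL": mbl, "TBL": tbl, "APBL": tbl / denom, "NPB": npb}


def _main_arc_positions(plant: PlantGraph) -> dict[int, float]:
    """Arc length from the base to each main-branch vertex."""
    pos, acc = {}, 0.0
    path = plant.main_branch.path
    pos[path[0]] = 0.0
    for u, v in zip(path[:-1], path[1:]):
        acc += plant.graph.edges[u, v]["length"]
        pos[v] = acc
    return pos


def junction_positions(plant: PlantGraph, vertical: bool = False) -> list[float]:
    """Sorted positions of primary-branch junctions along the main branch.

    Arc length from the base by default; vertical height if ``vertical``.
    """
    arc = _main_arc_positions(plant)
    base_y = plant.pos(plant.base_vertex)[1]
    out = []
    for b in plant.primary_branches:
        j = b.path[0]
        out.append(plant.pos(j)[1] - base_y if vertical else arc[j])
    return sorted(out)


def merge_short_internodes(
    positions: list[float], threshold: float
) -> tuple[list[float], bool]:
    """Collapse junctions closer than ``threshold`` onto the earlier one.

    Returns the effective junction positions and whether any merge happened
    (the SIN flag).  Very short internodes are a known soybean feature; they
    are flagged but excluded from internode indexing.
    """
    if not positions:
        return [], False
    merged = [positions[0]]
    sin = False
    for p in positions[1:]:
        if p - merged[-1] < threshold:
            sin = True
        else:
            merged.append(p)
    return merged, sin


def internode_traits(plant: PlantGraph, config: TraitConfig | None = None) -> dict:
    """FNH, FIL, SIL, TIL and SIN.  Traits beyond the available junctions are NaN."""
    config = config or TraitConfig()
    pos = junction_positions(plant, vertical=config.fnh_vertical)
    eff, sin = merge_short_internodes(pos, config.short_internode_cm)
    gaps = [b - a for a, b in zip(eff[:-1], eff[1:])]
    return {
        "FNH": eff[0] if eff else math.nan,
        "FIL": gaps[0] if len(gaps) > 0 else math.nan,
        "SIL": gaps[1] if len(gaps) > 1 else math.nan,
        "TIL": gaps[2] if len(gaps) > 2 else math.nan,
        "SIN": sin,
    }


def pod_traits(pods: PodAnnotation, config: TraitConfig | None = None) -> dict:
    """PN, PN10, FPH, P1H and P5H from calibrated pod heights.

    P1H/P5H use the nearest-rank quantile: the height of the
    ceil(q * PN)-th lowest pod.  PN10 counts pods strictly above the
    boundary (a pod at exactly 10 cm counts as low — close-to-ground pods
    are the ones at risk during mechanical harvest).
    """
    config = config or TraitConfig()
    heights = np.sort(pods.pod_heights())
    pn = len(heights)
    if pn == 0:
        return {"PN": 0, "PN10": 0, "FPH": math.nan, "P1H": math.nan, "P5H": math.nan}
    q1, q5 = config.quantiles
    rank = lambda q: heights[min(math.ceil(q * pn), pn) - 1]  # noqa: E731
    return {
        "PN": pn,
        "PN10": int((heights > config.pod_height_boundary_cm).sum()),
        "FPH": float(heights[0]),
        "P1H": float(rank(q1)),
        "P5H": float(rank(q5)),
    }


def image_traits(
    plant: PlantGraph, pods: PodAnnotation, config: TraitConfig | None = None
) -> dict:
    """All geometric traits of one image, plus identifying metadata."""
    config = config or TraitConfig()
    rec = {
        "accession_id": plant.accession_id,
        "replicate_id": plant.replicate_id,
        "side": plant.side,
        "image_id": plant.image_id,
    }
    rec.update(branch_traits(plant, config))
    rec.update(internode_traits(plant, config))
    rec.update(pod_traits(pods, config))
    return rec


def average_replicates(front: dict, back: dict) -> dict:
    """Average the two images of one plant into a single trait record.

    Numeric traits are arithmetic means; the short-internode flag is OR'd
    (seen on either side means present); a trait observed on only one side
    uses that side's value with a warning.
    """
    if (front["accession_id"], front["replicate_id"]) != (
        back["accession_id"],
        back["replicate_id"],
    ):
        raise ValueError("cannot average trait records from different plants")
    out = {
        "accession_id": front["accession_id"],
        "replicate_id": front["replicate_id"],
    }
    keys = [k for k in front if k in GEOMETRIC_TRAITS + TOPO_TRAITS]
    for k in keys:
        a, b = front.get(k), back.get(k)
        if k in BOOLEAN_TRAITS:
            out[k] = bool(a) or bool(b)
            continue
        a_ok = a is not None and not (isinstance(a, float) and math.isnan(a))
        b_ok = b is not None and not (isinstance(b, float) and math.isnan(b))
        if a_ok and b_ok:
            out[k] = (a + b) / 2.0
        elif a_ok or b_ok:
            out[k] = a if a_ok else b
            logger.warning(
                "plant (%s, %s): trait %s present on one side only",
                out["accession_id"], out["replicate_id"], k,
            )
        else:
            out[k] = math.nan
    return out


def plant_trait_table(
    groups: dict[tuple[str, str], dict[str, dict]]
) -> pd.DataFrame:
    """Per-plant trait table from per-image records grouped by plant.

    Plants with a single usable image keep that image's traits unchanged.
    """
    rows = []
    for key in sorted(groups):
        sides = groups[key]
        recs = [sides[s] for s in ("front", "back") if s in sides]
        if len(recs) == 2:
            rows.append(average_replicates(recs[0], recs[1]))
        else:
            rec = dict(recs[0])
            rec.pop("side", None)
            rec.pop("image_id", None)
            rows.append(rec)
    df = pd.DataFrame(rows)
    cols = ["accession_id", "replicate_id"] + [
        c for c in GEOMETRIC_TRAITS + TOPO_TRAITS if c in df.columns
    ]
    return df[cols]
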