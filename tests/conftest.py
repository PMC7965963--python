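"""Shared fixtures: synthetic populations generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

import shootarch as sa
from shootarch.graph import build_graph
from shootarch.synthetic import TRAIT_DIALS


def zero_noise_sds() -> dict:
    """All-zero residual/genetic SD dictionaries share these keys."""
    return {**{k: 0.0 for k in TRAIT_DIALS}, "internode_profile_cm": 0.0}


@pytest.fixture(scope="session")
def jitterfree_population(tmp_path_factory):
    """Small panel with every noise source off: files must reproduce truth."""
    out = tmp_path_factory.mktemp("popzero")
    params = sa.PopulationSimParams(
        n_accessions=6,
        reps_per_accession=2,
        jitter_sd_cm=0.0,
        seed=101,
    )
    paths = sa.generate_population(params, out)
    return params, paths


@pytest.fixture(scope="session")
def noisy_population(tmp_path_factory):
    """Panel with labeling jitter and a genotyped causal marker."""
    out = tmp_path_factory.mktemp("popnoisy")
    params = sa.PopulationSimParams(
        n_accessions=10,
        reps_per_accession=2,
        jitter_sd_cm=0.15,
        n_markers=30,
        marker_effect=40.0,
        seed=202,
    )
    paths = sa.generate_population(params, out)
    return params, paths


@pytest.fixture()
def y_tree():
    """Main 0->(0,3)->(0,7) with one primary (0,3)->tip at geodesic 5."""
    # primary tip placed so its arc length from the junction is exactly 2
    return build_graph(
        [("main", [(0.0, 0.0), (0.0, 3.0), (0.0, 7.0)]),
         ("primary", [(0.0, 3.0), (2.0, 3.0)])],
        base_point=(0.0, 0.0),
        snap_tol=1e-9,
    )


def random_plant_graph(seed: int):
    """A random synthetic plant graph for oracle sweeps."""
    rng = np.random.default_rng(seed)
    params = sa.PlantSimParams(
        n_primary_branches=int(rng.integers(0, 8)),
        main_length_cm=float(rng.uniform(25, 80)),
        first_node_height_cm=float(rng.uniform(2, 9)),
        internode_mean_cm=float(rng.uniform(1.5, 4)),
        internode_sd_cm=float(rng.uniform(0, 1)),
        primary_length_frac_mean=float(rng.uniform(0.3, 0.8)),
        branch_angle_deg=float(rng.uniform(15, 60)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    graph, _, _ = sa.generate_plant(params)
    return graph
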