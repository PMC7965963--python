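"""Annotation parsing, calibration, replicate pairing, and VCF loading."""

import math

import networkx as nx
import numpy as np
import pytest
from lxml import etree

import shootarch as sa
from shootarch.annotation_io import (
    PodAnnotation,
    Skeleton,
    calibrate_annotation,
    calibrate_skeleton,
    load_annotation_dir,
    parse_pod_annotation,
    parse_skeleton,
)
from shootarch.graph import PlantGraph, build_graph
from shootarch.synthetic import write_vcf


def minimal_xml(tmp_path, objects, meta=True):
    root = etree.Element("annotation")
    if meta:
        for tag, text in (("filename", "img1"), ("accession", "PI001"),
                          ("replicate", "r1"), ("side", "front")):
            etree.SubElement(root, tag).text = text
    for name, (xmin, ymin, xmax, ymax), extra in objects:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = name
        box = etree.SubElement(obj, "bndbox")
        for t, v in zip(("xmin", "ymin", "xmax", "ymax"), (xmin, ymin, xmax, ymax)):
            etree.SubElement(box, t).text = str(v)
        for tag, v in extra.items():
            etree.SubElement(obj, tag).text = str(v)
    path = tmp_path / "img1.xml"
    path.write_bytes(etree.tostring(root))
    return path


SCALE = ("scale", (0, 0, 100, 0), {"length_cm": 10})
TOP = ("top", (48, 198, 52, 202), {})
BOTTOM = ("bottom", (48, 998, 52, 1002), {})


class TestParsePodAnnotation:
    def test_pod_center_is_bounding_box_midpoint(self, tmp_path):
        path = minimal_xml(
            tmp_path, [("pod", (10, 20, 20, 30), {}), TOP, BOTTOM, SCALE]
        )
        ann = parse_pod_annotation(path)
        assert ann.pods == [(15.0, 25.0)]
        assert ann.px_per_cm == pytest.approx(10.0)

    def test_zero_pods_allowed(self, tmp_path):
        ann = parse_pod_annotation(minimal_xml(tmp_path, [TOP, BOTTOM, SCALE]))
        assert ann.pods == []

    def test_missing_bottom_anchor_rejected(self, tmp_path):
        path = minimal_xml(tmp_path, [TOP, SCALE])
        with pytest.raises(ValueError, match="bottom"):
            parse_pod_annotation(path)

    def test_malformed_xml_raises_parse_error(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<annotation><object>")
        with pytest.raises(etree.XMLSyntaxError):
            parse_pod_annotation(bad)

    def test_missing_scale_rejected(self, tmp_path):
        path = minimal_xml(tmp_path, [TOP, BOTTOM])
        with pytest.raises(ValueError, match="scale"):
            parse_pod_annotation(path)


class TestCalibration:
    def test_plant_height_from_anchor_pixels(self, tmp_path):
        ann = parse_pod_annotation(minimal_xml(tmp_path, [TOP, BOTTOM, SCALE]))
        cal = calibrate_annotation(ann)
        # bottom at y=1000 px, top at y=200 px, 10 px/cm -> 80 cm
        assert cal.plant_height == pytest.approx(80.0)
        assert cal.bottom[1] == pytest.approx(0.0)

    def test_identity_scale_only_flips_axis(self):
        ann = PodAnnotation(
            image_id="i", accession_id="a", replicate_id="r", side="front",
            pods=[(3.0, 4.0)], top=(0.0, 0.0), bottom=(0.0, 10.0), px_per_cm=1.0,
        )
        cal = calibrate_annotation(ann)
        assert cal.pods == [(3.0, 6.0)]
        assert cal.plant_height == pytest.approx(10.0)

    def test_below_ground_pods_clipped_to_zero(self):
        ann = PodAnnotation(
            image_id="i", accession_id="a", replicate_id="r", side="front",
            pods=[(0.0, 10.5)], top=(0.0, 0.0), bottom=(0.0, 10.0), px_per_cm=1.0,
        )
        cal = calibrate_annotation(ann)
        assert cal.pods[0][1] == 0.0


class TestParseSkeleton:
    def test_single_main_polyline(self):
        g = build_graph(
            [("main", [(0.0, 0.0), (0.0, 5.0), (0.0, 9.0)])], base_point=(0, 0)
        )
        assert g.graph.number_of_nodes() == 3
        assert g.graph.number_of_edges() == 2
        assert len(g.primary_branches) == 0

    def test_near_junction_snapped_onto_main(self):
        g = build_graph(
            [("main", [(0.0, 0.0), (0.0, 5.0), (0.0, 10.0)]),
             ("primary", [(0.3, 5.0), (4.0, 8.0)])],
            base_point=(0, 0), snap_tol=2.0,
        )
        junction = g.primary_branches[0].path[0]
        assert junction in g.main_branch.path
        assert g.pos(junction) == (0.0, 5.0)

    def test_two_main_polylines_rejected(self):
        with pytest.raises(ValueError, match="main"):
            build_graph(
                [("main", [(0, 0), (0, 5)]), ("main", [(1, 0), (1, 5)])],
                base_point=(0, 0),
            )

    def test_disconnected_primary_rejected(self):
        with pytest.raises(ValueError, match="disconnected"):
            build_graph(
                [("main", [(0.0, 0.0), (0.0, 5.0)]),
                 ("primary", [(50.0, 50.0), (60.0, 60.0)])],
                base_point=(0, 0), snap_tol=2.0,
            )

    def test_cycle_rejected_by_validation(self):
        g = nx.cycle_graph(3)
        for v in g.nodes:
            g.nodes[v]["pos"] = (float(v), 0.0)
        for u, v in g.edges:
            g.edges[u, v]["length"] = 1.0
        pg = PlantGraph(g, [], base_vertex=0, top_vertex=2)
        with pytest.raises(ValueError, match="cycle|main"):
            pg.validate()

    def test_skeleton_json_roundtrip(self, tmp_path, jitterfree_population):
        _, paths = jitterfree_population
        any_json = sorted(paths["skeleton_dir"].glob("*.json"))[0]
        skel = parse_skeleton(any_json)
        assert skel.side in ("front", "back")
        graph = calibrate_skeleton(skel)
        graph.validate()
        assert graph.pos(graph.base_vertex)[1] == pytest.approx(0.0)

    def test_missing_keys_rejected(self, tmp_path):
        bad = tmp_path / "s.json"
        bad.write_text('{"image_id": "x"}')
        with pytest.raises(ValueError, match="missing"):
            parse_skeleton(bad)


class TestPairReplicates:
    def records(self, *sides, acc="PI001", rep="r1"):
        return [
            {"accession_id": acc, "replicate_id": rep, "side": s} for s in sides
        ]

    def test_front_back_pair_grouped(self):
        groups = sa.pair_replicates(self.records("front", "back"))
        assert set(groups[("PI001", "r1")]) == {"front", "back"}

    def test_three_images_rejected(self):
        with pytest.raises(ValueError, match="duplicate|more than two"):
            sa.pair_replicates(self.records("front", "back", "front"))

    def test_single_side_kept_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="shootarch.annotation_io"):
            groups = sa.pair_replicates(self.records("front"))
        assert len(groups[("PI001", "r1")]) == 1
        assert "only one image" in caplog.text


class TestRoundTrip:
    def test_written_files_parse_to_identical_structure(self, jitterfree_population):
        _, paths = jitterfree_population
        images = load_annotation_dir(
            paths["pods_dir"], paths["skeleton_dir"], on_error="raise"
        )
        assert len(images) == 2 * 2 * 6  # accessions x reps x sides
        for ann, graph in images:
            assert ann.calibrated
            graph.validate()
            assert len(ann.pods) == len(ann.pod_heights())

    def test_corrupt_file_skipped_not_fatal(self, tmp_path, caplog):
        params = sa.PopulationSimParams(
            n_accessions=2, reps_per_accession=1, jitter_sd_cm=0.0, seed=5
        )
        paths = sa.generate_population(params, tmp_path)
        victim = sorted(paths["pods_dir"].glob("*.xml"))[0]
        victim.write_text("<annotation><object>")
        with caplog.at_level("WARNING"):
            images = load_annotation_dir(paths["pods_dir"], paths["skeleton_dir"])
        assert len(images) == 3
        assert "SKIP" in caplog.text


class TestGenotypeIO:
    def test_vcf_roundtrip_preserves_states(self, tmp_path):
        import pandas as pd

        markers = pd.DataFrame({
            "marker_id": ["m1", "m2"], "chrom": ["Gm11", "Gm11"],
            "pos": [100, 2000],
        })
        calls = pd.DataFrame(
            [["reference", "non_reference", "heterozygous"],
             ["missing", "reference", "non_reference"]],
            index=pd.Index(["m1", "m2"], name="marker_id"),
            columns=["PI001", "PI002", "PI003"],
        )
        path = tmp_path / "g.vcf"
        write_vcf(markers, calls, path)
        table = sa.read_genotype_table(path)
        pd.testing.assert_frame_equal(
            table.calls, calls, check_names=False
        )
        assert list(table.markers["pos"]) == [100, 2000]

    def test_multiallelic_record_rejected(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=Gm11>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "Gm11\t100\tm1\tA\tT,C\t.\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.raises(ValueError, match="multi-allelic"):
            sa.read_genotype_table(path)
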