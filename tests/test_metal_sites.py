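"""Geometry measurement, contact classification and cluster detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_metal_model
from tetrare.metal_sites import (
    RadiiTable,
    classify_contact,
    clusters_frame,
    contacts_frame,
    detect_clusters,
    distance,
    distance_sigma,
    find_metal_sites,
    quasi_bite_angle,
    site_report,
)
from tetrare.pdbio import AtomRecord, StructureModel, read_pdb
from tetrare.synthetic import MotifSpec, SyntheticSpec, generate_structure


def _atom(serial, element, xyz, name=None, resnum=1, het=True, occ=1.0):
    return AtomRecord(
        serial=serial, name=name or element.upper(), element=element,
        residue_name="LIG", chain="A", residue_number=resnum, xyz=np.array(xyz),
        occupancy=occ, b_factor=10.0, is_het=het,
    )


class TestDistances:
    def test_coincident_points(self):
        a = _atom(1, "Re", (1.0, 2.0, 3.0))
        assert distance(a, a) == 0.0

    def test_pythagorean_triple(self):
        assert distance(_atom(1, "Re", (0, 0, 0)), _atom(2, "O", (3, 4, 0))) == 5.0

    def test_sigma_is_sqrt2_dpi(self):
        assert distance_sigma(0.0) == 0.0
        # the poorly determined one-year structure: esd rounds to the 0.2 Å
        # quoted with every distance there
        assert distance_sigma(0.129) == pytest.approx(0.182, abs=5e-4)
        # the atomic-resolution two-year structure: esd ~0.03 Å
        assert distance_sigma(0.018) == pytest.approx(0.025, abs=5e-4)

    def test_sigma_rejects_negative(self):
        with pytest.raises(ValueError):
            distance_sigma(-0.1)


class TestContactClassification:
    # every distance/class pair reported for the Re-soaked lysozyme sites
    PRINTED = [
        (("Re", "O"), 2.07, "coordination"),
        (("Re", "O"), 2.1, "coordination"),
        (("Re", "O"), 2.2, "coordination"),
        (("Re", "O"), 2.27, "coordination"),
        (("Re", "O"), 2.3, "coordination"),
        (("Re", "O"), 2.4, "coordination"),
        (("Re", "N"), 2.16, "coordination"),
        (("Re", "N"), 2.5, "coordination"),
        (("Re", "N"), 2.6, "coordination"),
        (("Re", "N"), 2.9, "van_der_waals"),
        (("Re", "O"), 2.9, "van_der_waals"),
        (("Re", "N"), 4.7, "none"),
        (("Re", "O"), 3.9, "none"),
    ]

    @pytest.mark.parametrize("pair, d, expected", PRINTED)
    def test_reported_classifications(self, pair, d, expected, radii):
        assert classify_contact(pair, d, radii) == expected

    def test_pair_lookup_is_symmetric(self, radii):
        assert classify_contact(("O", "Re"), 2.1, radii) == "coordination"

    def test_unknown_pair_raises(self, radii):
        with pytest.raises(KeyError):
            classify_contact(("Re", "Xx"), 2.0, radii)

    @given(d=st.floats(0.5, 8.0))
    @settings(max_examples=200, deadline=None)
    def test_class_is_monotone_in_distance(self, d):
        order = {"coordination": 0, "van_der_waals": 1, "none": 2}
        table = RadiiTable()
        a = classify_contact(("Re", "N"), d, table)
        b = classify_contact(("Re", "N"), d + 0.25, table)
        assert order[b] >= order[a]

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            RadiiTable(
                covalent_sum={("Re", "N"): 3.5}, vdw_limit={("Re", "N"): 3.7},
                bond_tolerance=0.8,
            )


class TestQuasiBiteAngle:
    def test_collinear_is_180(self):
        m = _atom(1, "Re", (0, 0, 0))
        assert quasi_bite_angle(m, _atom(2, "O", (1, 0, 0)), _atom(3, "O", (-2, 0, 0))) == pytest.approx(180.0)

    def test_orthogonal_is_90(self):
        m = _atom(1, "Re", (0, 0, 0))
        assert quasi_bite_angle(m, _atom(2, "O", (1, 0, 0)), _atom(3, "O", (0, 3, 0))) == pytest.approx(90.0)

    def test_symmetric_in_arguments(self):
        m = _atom(1, "Re", (0, 0, 0))
        a1, a2 = _atom(2, "O", (1.1, 0.3, 0)), _atom(3, "N", (0, 2, 1))
        assert quasi_bite_angle(m, a1, a2) == pytest.approx(quasi_bite_angle(m, a2, a1))

    def test_coincident_atom_raises(self):
        m = _atom(1, "Re", (0, 0, 0))
        with pytest.raises(ValueError):
            quasi_bite_angle(m, _atom(2, "O", (0, 0, 0)), _atom(3, "O", (1, 0, 0)))

    def test_bidentate_carboxylate_matches_law_of_cosines(self):
        model, truth = generate_structure(
            SyntheticSpec(
                seed=0,
                motifs=[MotifSpec(kind="carboxylate_site", params={"mode": "bidentate", "re_o": 2.2})],
            )
        )
        by = {a.name: a for a in model.atoms}
        measured = quasi_bite_angle(by["RE"], by["OD1"], by["OD2"])
        oo = distance(by["OD1"], by["OD2"])
        expected = math.degrees(
            math.acos((2.2**2 + 2.2**2 - oo**2) / (2 * 2.2 * 2.2))
        )
        assert measured == pytest.approx(expected, abs=1e-9)
        assert measured == pytest.approx(60.6, abs=1.0)
        assert truth.bite_angles[0]["angle_deg"] == pytest.approx(measured, abs=1e-3)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_rigid_motion_invariance(self, seed):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(3, 3)) * 3.0
        m, a1, a2 = (_atom(i + 1, "Re", p) for i, p in enumerate(pts))
        before = quasi_bite_angle(m, a1, a2)
        rot = Rotation.from_quat(rng.normal(size=4) / np.linalg.norm(rng.normal(size=4)))
        shift = rng.normal(size=3) * 10
        moved = [x.moved(rot.apply(x.xyz) + shift) for x in (m, a1, a2)]
        assert quasi_bite_angle(*moved) == pytest.approx(before, abs=1e-9)


def _union_find_components(coords, cutoff):
    """Brute-force all-pairs union-find oracle for cluster detection."""
    parent = list(range(len(coords)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(coords)):
        groups.setdefault(find(i), set()).add(i)
    return sorted((frozenset(g) for g in groups.values()), key=lambda s: min(s))


class TestClusterDetection:
    def test_cubane_is_one_tetranuclear_cluster(self, cubane_model):
        model, _ = cubane_model
        clusters = detect_clusters(model)
        assert len(clusters) == 1
        assert clusters[0].nuclearity == 4
        assert clusters[0].n_formal_edges == 6
        for *_ij, d, label in clusters[0].edges:
            assert d == pytest.approx(3.43, abs=1e-6)
            assert label == "formal"

    def test_pair_at_formal_distance(self):
        model = StructureModel(
            atoms=[_atom(1, "Re", (0, 0, 0)), _atom(2, "Re", (3.2, 0, 0))]
        )
        clusters = detect_clusters(model)
        assert [c.nuclearity for c in clusters] == [2]
        assert clusters[0].edges[0][3] == "formal"

    def test_distant_monomer_not_merged_with_cubane(self):
        # a lone Re 5.53 Å from the nearest cluster member stays separate
        spec = SyntheticSpec(
            seed=0,
            allow_close=True,
            motifs=[
                MotifSpec(kind="cubane", center=(0.0, 0.0, 0.0)),
                MotifSpec(kind="lone_metal", center=(1.213 + 5.53, 1.213, 1.213)),
            ],
        )
        model, _ = generate_structure(spec)
        clusters = detect_clusters(model)
        assert [c.nuclearity for c in clusters] == [4, 1]

    def test_no_metals_gives_empty_list(self):
        model = StructureModel(atoms=[_atom(1, "O", (0, 0, 0))])
        assert detect_clusters(model) == []

    def test_invalid_cutoffs(self, cubane_model):
        with pytest.raises(ValueError):
            detect_clusters(cubane_model[0], vdw_cutoff=3.0, formal_cutoff=3.6)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        model = random_metal_model(rng)
        coords = model.coords()
        expected = _union_find_components(coords, 4.3)
        got = sorted(
            (frozenset(a.serial - 1 for a in c.members) for c in detect_clusters(model)),
            key=lambda s: min(s),
        )
        assert got == expected


class TestSiteScan:
    def test_his_fixture_has_the_re_n_bond(self, two_year_like_model):
        model, _ = two_year_like_model
        reports = find_metal_sites(model)
        hits = [
            r for r in reports
            if r.partner.name == "NE2" and r.contact_class == "coordination"
        ]
        assert len(hits) == 1
        assert hits[0].distance == pytest.approx(2.16, abs=1e-6)
        assert hits[0].sigma == pytest.approx(math.sqrt(2) * 0.018)

    def test_remote_metal_sees_nothing(self):
        model = StructureModel(
            atoms=[_atom(1, "Re", (0, 0, 0)), _atom(2, "O", (6.0, 0, 0), het=False)]
        )
        assert find_metal_sites(model, scan_radius=5.0) == []

    def test_bridging_metal_reports_both_residue_contacts(self):
        # Re midway between an Arg NH2 and an Asp OD2, both at 2.4 Å
        model = StructureModel(
            atoms=[
                _atom(1, "Re", (0, 0, 0)),
                _atom(2, "N", (2.4, 0, 0), name="NH2", resnum=125, het=False),
                _atom(3, "O", (-2.4, 0, 0), name="OD2", resnum=119, het=False),
            ]
        )
        reports = find_metal_sites(model)
        assert [r.contact_class for r in reports] == ["coordination", "coordination"]

    def test_deterministic_ordering(self, two_year_like_model):
        model, _ = two_year_like_model
        reports = find_metal_sites(model)
        keys = [(r.metal.serial, r.distance) for r in reports]
        assert keys == sorted(keys)

    def test_unknown_pair_strict_raises(self):
        model = StructureModel(
            atoms=[_atom(1, "Re", (0, 0, 0)), _atom(2, "S", (2.4, 0, 0), het=False)]
        )
        assert find_metal_sites(model) == []
        with pytest.raises(KeyError):
            find_metal_sites(model, strict=True)


class TestSiteReport:
    def test_two_year_like_report(self, two_year_like_model):
        model, truth = two_year_like_model
        report = site_report(model)
        coord_n = [
            c for c in report["contacts"]
            if c["class"] == "coordination" and c["atom"] == "NE2"
        ]
        assert len(coord_n) == 1
        assert [c["nuclearity"] for c in report["clusters"]] == [4, 1]

    def test_empty_model_reports_empty_sections(self):
        model = StructureModel(atoms=[_atom(1, "O", (0, 0, 0), het=False)])
        report = site_report(model)
        assert report["contacts"] == []
        assert report["clusters"] == []
        assert report["quasi_bite_angles"] == []

    def test_bidentate_gives_exactly_one_bite_angle(self):
        model, _ = generate_structure(
            SyntheticSpec(
                seed=0,
                motifs=[MotifSpec(kind="carboxylate_site", params={"mode": "bidentate"})],
            )
        )
        report = site_report(model)
        assert len(report["quasi_bite_angles"]) == 1
        assert report["quasi_bite_angles"][0]["atoms"] == ["OD1", "OD2"] or report[
            "quasi_bite_angles"
        ][0]["atoms"] == ["OD2", "OD1"]

    def test_csv_tables_have_contract_columns(self, two_year_like_model):
        model, _ = two_year_like_model
        report = site_report(model)
        contacts = contacts_frame(report)
        clusters = clusters_frame(report)
        assert list(contacts.columns) == [
            "metal_serial", "partner_serial", "chain", "residue", "atom",
            "distance_A", "sigma_A", "class",
        ]
        assert list(clusters.columns) == [
            "cluster_id", "nuclearity", "member_serials", "n_formal_edges",
        ]
        assert clusters["nuclearity"].tolist() == [4, 1]

    def test_min_occupancy_filters_metals(self):
        model = StructureModel(
            atoms=[
                _atom(1, "Re", (0, 0, 0), occ=0.13),
                _atom(2, "O", (2.1, 0, 0), het=False),
            ]
        )
        assert site_report(model)["contacts"]  # reported by default
        assert site_report(model, min_occupancy=0.5)["contacts"] == []
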