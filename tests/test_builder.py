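"""Scaling formulas and geometric construction of model graphs."""

import numpy as np
import pytest

import junctiongraph as jg
from junctiongraph.builder import (
    DEFAULT_PARAMETERS,
    FamilyTemplate,
    ScalingParameters,
    TemplateError,
    arrangement_angle,
    arrangement_distance,
    coaxial_spacing,
    derive_family_template,
    helix_edge_length,
    intervening_loop_nt,
)
from junctiongraph.compare import angle_between
from junctiongraph.topology import JunctionTopology

from conftest import junction_with, random_rotation


def point_line_distance(point, line_a, line_b):
    u = line_b - line_a
    u = u / np.linalg.norm(u)
    w = point - line_a
    return float(np.linalg.norm(w - np.dot(w, u) * u))


class TestFormulas:
    def test_coaxial_spacing_values(self):
        assert coaxial_spacing(0) == pytest.approx(3.91)
        assert coaxial_spacing(4) == pytest.approx(14.91)

    def test_coaxial_spacing_monotonic(self):
        assert coaxial_spacing(5) > coaxial_spacing(4)

    def test_coaxial_spacing_negative_raises(self):
        with pytest.raises(ValueError):
            coaxial_spacing(-1)

    def test_helix_edge_length_values(self):
        assert helix_edge_length(2) == pytest.approx(2.87)
        assert helix_edge_length(10) == pytest.approx(25.83)

    def test_helix_edge_length_b1_raises(self):
        with pytest.raises(ValueError):
            helix_edge_length(1)

    def test_arrangement_distances(self):
        assert arrangement_distance("parallel") == pytest.approx(20.48)
        assert arrangement_distance("perpendicular") == pytest.approx(19.95)
        assert arrangement_distance("diagonal") == pytest.approx(21.17)

    def test_unknown_class_raises(self):
        with pytest.raises(ValueError):
            arrangement_distance("sideways")
        with pytest.raises(ValueError):
            arrangement_angle("sideways")

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ScalingParameters(d_parallel=-1.0)
        with pytest.raises(ValueError):
            ScalingParameters(angle_diagonal=200.0)


class TestInterveningLoop:
    def test_adjacent_pairs(self):
        j = junction_with([3, 3, 3], [1, 2, 3])
        assert intervening_loop_nt(j, "H1", "H2") == 1
        assert intervening_loop_nt(j, "H2", "H3") == 2
        assert intervening_loop_nt(j, "H1", "H3") == 3  # wraps via L3

    def test_four_way_wrap_and_diagonal(self):
        j = junction_with([3, 3, 3, 3], [1, 2, 3, 4])
        assert intervening_loop_nt(j, "H1", "H4") == 4
        assert intervening_loop_nt(j, "H1", "H3") == min(1 + 2, 3 + 4)


class TestBuildGraphThreeWay:
    def topo(self, stacks, family):
        return JunctionTopology.from_labels(stacks, family)

    def test_vertex_and_edge_counts(self, three_way_junction):
        g = jg.build_graph(three_way_junction, self.topo("H1H2", "A"))
        assert g.n_vertices == 2 * 3 + 1
        assert g.n_edges == 2 * 3

    def test_unstacked_helix_perpendicular_family_A(self, three_way_junction):
        g = jg.build_graph(three_way_junction, self.topo("H1H2", "A"))
        d = point_line_distance(g.proximal("H3"), g.proximal("H1"), g.proximal("H2"))
        assert d == pytest.approx(19.95)
        axis = g.proximal("H2") - g.proximal("H1")
        ang = angle_between(axis, g.helix_vector("H3"))
        assert ang == pytest.approx(90.0)

    def test_family_C_parallel_direction(self, three_way_junction):
        g = jg.build_graph(three_way_junction, self.topo("H1H2", "C"))
        axis = g.proximal("H2") - g.proximal("H1")
        ang = angle_between(axis, g.helix_vector("H3"))
        assert ang == pytest.approx(0.0, abs=1e-9)
        d = point_line_distance(g.proximal("H3"), g.proximal("H1"), g.proximal("H2"))
        assert d == pytest.approx(20.48)

    def test_family_B_diagonal(self, three_way_junction):
        g = jg.build_graph(three_way_junction, self.topo("H1H2", "B"))
        axis = g.proximal("H2") - g.proximal("H1")
        ang = angle_between(axis, g.helix_vector("H3"))
        assert ang == pytest.approx(45.0)
        d = point_line_distance(g.proximal("H3"), g.proximal("H1"), g.proximal("H2"))
        assert d == pytest.approx(21.17)

    def test_stack_gap_equals_coaxial_spacing(self):
        for L in (0, 1, 5):
            j = junction_with([4, 4, 4], [L, 2, 2])
            g = jg.build_graph(j, self.topo("H1H2", "A"))
            gap = np.linalg.norm(g.proximal("H1") - g.proximal("H2"))
            assert gap == pytest.approx(coaxial_spacing(L), abs=1e-12)

    def test_stacked_edges_antiparallel_collinear(self, three_way_junction):
        g = jg.build_graph(three_way_junction, self.topo("H1H2", "A"))
        v1, v2 = g.helix_vector("H1"), g.helix_vector("H2")
        assert angle_between(v1, v2) == pytest.approx(180.0)
        # lateral offset of H2 line from H1 line is zero
        off = point_line_distance(g.proximal("H2"), g.proximal("H1"), g.distal("H1"))
        assert off < 1e-9

    def test_centroid_is_mean_of_proximal(self, three_way_junction):
        g = jg.build_graph(three_way_junction, self.topo("H1H2", "B"))
        assert np.allclose(g.vertex("centroid"), g.proximal_mean())

    def test_planarity(self, three_way_junction):
        g = jg.build_graph(three_way_junction, self.topo("H1H3", "C"))
        assert np.allclose(g.coordinates()[:, 2], 0.0)

    def test_helix_edge_lengths(self):
        j = junction_with([2, 5, 10], [1, 1, 1])
        g = jg.build_graph(j, self.topo("H1H2", "A"))
        for hid, b in (("H1", 2), ("H2", 5), ("H3", 10)):
            assert np.linalg.norm(g.helix_vector(hid)) == pytest.approx(
                helix_edge_length(b)
            )

    def test_deterministic(self, three_way_junction):
        g1 = jg.build_graph(three_way_junction, self.topo("H1H2", "A"))
        g2 = jg.build_graph(three_way_junction, self.topo("H1H2", "A"))
        assert g1.to_json() == g2.to_json()

    def test_unknown_stack_helix_raises(self, three_way_junction):
        with pytest.raises(ValueError):
            jg.build_graph(three_way_junction, self.topo("H1H9", "A"))

    def test_no_stack_radial(self, three_way_junction):
        g = jg.build_graph(three_way_junction, self.topo("none", "none"))
        assert g.n_vertices == 7 and g.n_edges == 6
        radii = [np.linalg.norm(g.proximal(h)) for h in g.helix_ids]
        assert all(r == pytest.approx(DEFAULT_PARAMETERS.radial_radius) for r in radii)


class TestBuildGraphFourWay:
    @pytest.mark.parametrize("family,angle", [("cL", 90.0), ("cH", 0.0), ("cX", 45.0)])
    def test_two_stack_inter_axis_angle(self, four_way_junction, family, angle):
        topo = JunctionTopology.from_labels("H1H4+H2H3", family)
        g = jg.build_graph(four_way_junction, topo)
        a1 = g.proximal("H4") - g.proximal("H1")
        a2 = g.proximal("H3") - g.proximal("H2")
        got = angle_between(a1, a2)
        assert min(got, 180.0 - got) == pytest.approx(angle, abs=1e-9)

    def test_counts_law(self, four_way_junction):
        for label, fam in [("H1H4+H2H3", "cL"), ("H1H2", "pi"), ("none", "none")]:
            g = jg.build_graph(four_way_junction, JunctionTopology.from_labels(label, fam))
            assert g.n_vertices == 9 and g.n_edges == 8

    def test_single_stack_two_unstacked_placed(self, four_way_junction):
        topo = JunctionTopology.from_labels("H1H2", "cW")
        g = jg.build_graph(four_way_junction, topo)
        # unstacked H3, H4 distinct and off the stack axis
        assert not np.allclose(g.proximal("H3"), g.proximal("H4"))
        for h in ("H3", "H4"):
            d = point_line_distance(g.proximal(h), g.proximal("H1"), g.proximal("H2"))
            assert d > 10.0

    def test_both_gaps_scale_with_loops(self):
        j = junction_with([3, 3, 3, 3], [2, 0, 2, 3])
        topo = JunctionTopology.from_labels("H1H4+H2H3", "cL")
        g = jg.build_graph(j, topo)
        gap14 = np.linalg.norm(g.proximal("H1") - g.proximal("H4"))
        gap23 = np.linalg.norm(g.proximal("H2") - g.proximal("H3"))
        assert gap14 == pytest.approx(coaxial_spacing(3))  # L4 = 3
        assert gap23 == pytest.approx(coaxial_spacing(0))  # L2 = 0

    def test_unicode_family_alias(self, four_way_junction):
        topo = JunctionTopology.from_labels("H1H2", "π")  # pi
        assert topo.family == "pi"
        g = jg.build_graph(four_way_junction, topo)
        assert g.meta["family"] == "pi"

    def test_too_many_stacks_rejected(self, three_way_junction):
        with pytest.raises(ValueError):
            JunctionTopology.from_labels("H1H2+H1H3", "A")  # overlapping
        topo = JunctionTopology.from_labels("H1H2", "A")
        four = JunctionTopology(frozenset({frozenset({"H1", "H2"}), frozenset({"H3", "H4"})}), "cH")
        with pytest.raises(ValueError):
            four.validate_for_degree(3)
        assert topo.stack_label == "H1H2"


class TestFamilyTemplates:
    def _graph(self, family="A", stacks="H1H2"):
        j = junction_with([4, 4, 4], [1, 2, 2])
        return jg.build_graph(j, JunctionTopology.from_labels(stacks, family))

    def test_single_graph_template_matches_directions(self):
        g = self._graph()
        tpl = derive_family_template([g])["A"]
        for h in g.helix_ids:
            v = g.helix_vector(h)
            assert np.allclose(tpl.directions[h], v / np.linalg.norm(v))
        assert not tpl.degenerate

    def test_rotation_invariance(self, rng):
        g1 = self._graph()
        rot = random_rotation(rng)
        g2 = jg.TreeGraph(
            g1.helix_ids,
            {k: rot @ v for k, v in g1.vertices.items()},
            g1.bp_counts,
            dict(g1.meta),
        )
        tpl = derive_family_template([g1, g2])["A"]
        ref = derive_family_template([g1])["A"]
        for h in g1.helix_ids:
            assert np.allclose(tpl.directions[h], ref.directions[h], atol=1e-8)

    def test_opposed_directions_flagged_degenerate(self):
        g1 = self._graph()
        g3 = jg.TreeGraph(
            g1.helix_ids,
            dict(g1.vertices),
            g1.bp_counts,
            dict(g1.meta),
        )
        # reverse H3's edge while keeping everything else identical
        prox = g3.proximal("H3")
        g3.vertices["H3.distal"] = prox - g1.helix_vector("H3")
        tpl = derive_family_template([g1, g3])["A"]
        assert "H3" in tpl.degenerate

    def test_missing_family_label_raises(self):
        g = self._graph()
        g.meta.pop("family")
        with pytest.raises(TemplateError):
            derive_family_template([g])
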