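"""Tree model, perfect-binary generator, carry-forward tables, CV, and I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemofractal.errors import (
    ConfigurationError,
    DataError,
    DegenerateInputError,
    TopologyError,
    TreeFormatError,
)
from hemofractal.tree import (
    SplitRatioConfig,
    VesselSegment,
    VascularTree,
    carry_forward_table,
    coefficient_of_variation,
    make_perfect_binary_tree,
    perfect_tree_cv,
    read_tree_table,
    write_tree_table,
)

from conftest import build_tree, random_pruned_tree


class TestPerfectBinaryGenerator:
    @pytest.mark.parametrize(
        "r, expected_flows",
        [(1.0, {1.0, 0.5}), (0.5, {1.0, 2.0 / 3.0, 1.0 / 3.0})],
    )
    def test_single_bifurcation_split(self, r, expected_flows):
        tree = make_perfect_binary_tree(SplitRatioConfig(1, r))
        assert tree.n_segments == 3
        assert set(np.round(tree.flows(), 12)) == {
            round(f, 12) for f in expected_flows
        }

    def test_size_and_depth(self):
        tree = make_perfect_binary_tree(SplitRatioConfig(9, 0.37))
        assert tree.n_segments == 1023
        assert tree.max_generation == 9
        tree.check_flow_conservation()

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_invalid_split_ratio_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            SplitRatioConfig(3, bad)

    def test_invalid_depth_rejected(self):
        with pytest.raises(ConfigurationError):
            SplitRatioConfig(0, 0.5)


class TestCarryForward:
    def test_early_terminals_carried_to_final_generation(self, irregular_tree):
        """A branch terminating at generation n joins every cross-section > n."""
        table = carry_forward_table(irregular_tree)
        assert table.max_generation == 3
        assert table.n_cells(3) == 8
        # generation 3: two true generation-3 segments + terminals from
        # generations 1 and 2, carried forward with their full flows
        assert table.counts_included[3] == 4
        assert sorted(np.round(table.probabilities[3], 12)) == [
            0.2, 0.25, 0.25, 0.3
        ]
        # generation 2: segments 3, 4 plus the generation-1 terminal
        assert table.counts_included[2] == 3

    def test_perfect_tree_cross_sections_are_full(self):
        tree = make_perfect_binary_tree(SplitRatioConfig(6, 0.7))
        table = carry_forward_table(tree)
        for n in range(7):
            assert table.counts_included[n] == 2**n

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_probabilities_sum_to_one_on_random_trees(self, seed):
        tree = random_pruned_tree(np.random.default_rng(seed))
        table = carry_forward_table(tree)
        for n in range(table.max_generation + 1):
            assert table.probabilities[n].sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_root_flow_rejected(self):
        tree = build_tree(
            [
                (0, None, 0, 10.0, 5.0, 0.0),
                (1, 0, 1, 8.0, 4.0, 0.0),
                (2, 0, 1, 8.0, 4.0, 0.0),
            ]
        )
        with pytest.raises(DegenerateInputError):
            carry_forward_table(tree)

    def test_conservation_violation_rejected(self):
        tree = build_tree(
            [
                (0, None, 0, 10.0, 5.0, 1.0),
                (1, 0, 1, 8.0, 4.0, 0.7),
                (2, 0, 1, 8.0, 4.0, 0.2),
            ]
        )
        with pytest.raises(DataError, match="conservation"):
            carry_forward_table(tree)

    def test_active_flow_fraction_tracks_terminals(self, irregular_tree):
        table = carry_forward_table(irregular_tree)
        frac = table.active_flow_fraction
        assert frac[0] == pytest.approx(1.0)
        assert frac[1] == pytest.approx(0.75)  # generation-1 terminal holds 0.25
        assert frac[2] == pytest.approx(0.50)
        assert frac[3] == pytest.approx(0.0)


class TestCoefficientOfVariation:
    def test_uniform_flows_give_zero(self):
        tree = build_tree(
            [
                (0, None, 0, 10.0, 5.0, 2.0),
                (1, 0, 1, 8.0, 4.0, 2.0),
                (2, 0, 1, 8.0, 4.0, 2.0),
            ]
        )
        assert coefficient_of_variation(tree) == pytest.approx(0.0)

    @pytest.mark.parametrize("r", [0.05, 0.2, 0.5, 0.8, 1.0])
    @pytest.mark.parametrize("G", [3, 7, 9, 12])
    def test_closed_form_matches_enumeration(self, r, G):
        """CV of constant-split trees matches the analytic expression."""
        tree = make_perfect_binary_tree(SplitRatioConfig(G, r))
        assert coefficient_of_variation(tree) == pytest.approx(
            perfect_tree_cv(r, G), rel=1e-12
        )

    def test_depth9_endpoints_match_printed_values(self):
        """The generation-9 tree spans CV 10.1 (r->0) down to 4.4 (r=1)."""
        assert round(perfect_tree_cv(0.0, 9), 1) == 10.1
        assert round(perfect_tree_cv(1.0, 9), 1) == 4.4

    def test_degenerate_inputs_rejected(self):
        single = VascularTree(
            {0: VesselSegment(0, None, 0, 10.0, 5.0, 1.0)}, root_id=0
        )
        with pytest.raises(DegenerateInputError):
            coefficient_of_variation(single)
        zeros = build_tree(
            [
                (0, None, 0, 10.0, 5.0, 0.0),
                (1, 0, 1, 8.0, 4.0, 0.0),
                (2, 0, 1, 8.0, 4.0, 0.0),
            ]
        )
        with pytest.raises(DegenerateInputError):
            coefficient_of_variation(zeros)


class TestTreeValidation:
    def test_orphan_segment_rejected(self):
        segs = {
            0: VesselSegment(0, None, 0, 10.0, 5.0),
            1: VesselSegment(1, 5, 1, 8.0, 4.0),
        }
        with pytest.raises(TopologyError):
            VascularTree(segs, root_id=0)

    def test_single_child_rejected(self):
        segs = {
            0: VesselSegment(0, None, 0, 10.0, 5.0, child_ids=[1]),
            1: VesselSegment(1, 0, 1, 8.0, 4.0),
        }
        with pytest.raises(TopologyError, match="children"):
            VascularTree(segs, root_id=0)

    def test_generation_mismatch_rejected(self):
        segs = {
            0: VesselSegment(0, None, 0, 10.0, 5.0, child_ids=[1, 2]),
            1: VesselSegment(1, 0, 2, 8.0, 4.0),
            2: VesselSegment(2, 0, 1, 8.0, 4.0),
        }
        with pytest.raises(TopologyError, match="generation"):
            VascularTree(segs, root_id=0)


class TestTreeTableIO:
    def test_round_trip_is_lossless(self, tmp_path):
        tree = make_perfect_binary_tree(SplitRatioConfig(2, 1.0))
        path = tmp_path / "tree.csv"
        write_tree_table(tree, path)
        back = read_tree_table(path)
        assert back.n_segments == 7
        assert back.root_id == tree.root_id
        for sid, seg in tree.segments.items():
            other = back.segments[sid]
            assert other.parent_id == seg.parent_id
            assert other.generation == seg.generation
            assert sorted(other.child_ids) == sorted(seg.child_ids)
            assert other.diameter == pytest.approx(seg.diameter)
            assert other.length == pytest.approx(seg.length)
            assert other.flow == pytest.approx(seg.flow)

    @settings(max_examples=10, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_round_trip_on_random_trees(self, seed):
        import io

        tree = random_pruned_tree(np.random.default_rng(seed))
        buf = io.StringIO()
        write_tree_table(tree, buf)
        buf.seek(0)
        back = read_tree_table(buf)
        assert back.n_segments == tree.n_segments
        np.testing.assert_allclose(back.flows(), tree.flows(), rtol=1e-12)

    def test_unset_flows_survive_round_trip(self, tmp_path):
        tree = build_tree(
            [
                (0, None, 0, 10.0, 5.0, math.nan),
                (1, 0, 1, 8.0, 4.0, math.nan),
                (2, 0, 1, 8.0, 4.0, math.nan),
            ]
        )
        path = tmp_path / "unset.csv"
        write_tree_table(tree, path)
        back = read_tree_table(path)
        assert not back.flows_populated

    def test_single_child_row_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "id,parent_id,generation,diameter_um,length_um,flow\n"
            "0,-1,0,10,5,1.0\n"
            "1,0,1,8,4,1.0\n"
        )
        with pytest.raises(TreeFormatError, match="children"):
            read_tree_table(path)

    def test_missing_parent_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "id,parent_id,generation,diameter_um,length_um,flow\n"
            "0,-1,0,10,5,1.0\n"
            "1,7,1,8,4,0.5\n"
            "2,0,1,8,4,0.5\n"
        )
        with pytest.raises(TreeFormatError):
            read_tree_table(path)

    def test_negative_diameter_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "id,parent_id,generation,diameter_um,length_um,flow\n"
            "0,-1,0,-10,5,1.0\n"
        )
        with pytest.raises(TreeFormatError, match="diameter"):
            read_tree_table(path)

    def test_generation_column_optional_and_cross_validated(self, tmp_path):
        base = (
            "id,parent_id,diameter_um,length_um,flow\n"
            "0,-1,10,5,1.0\n1,0,8,4,0.5\n2,0,8,4,0.5\n"
        )
        path = tmp_path / "nogen.csv"
        path.write_text(base)
        tree = read_tree_table(path)
        assert tree.segments[1].generation == 1
        bad = tmp_path / "badgen.csv"
        bad.write_text(
            "id,parent_id,generation,diameter_um,length_um,flow\n"
            "0,-1,0,10,5,1.0\n1,0,2,8,4,0.5\n2,0,1,8,4,0.5\n"
        )
        with pytest.raises(TreeFormatError, match="generation"):
            read_tree_table(bad)
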