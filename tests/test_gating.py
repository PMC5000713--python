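"""Gating engine: geometry vs. brute force, Boolean algebra, gate trees."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemoflow as hf
from hemoflow.core import ConfigurationError
from hemoflow.gating import (
    BooleanExpr,
    GateNode,
    GateTree,
    Polygon,
    QuadrantCell,
    Rectangle,
    Threshold,
    TransformSet,
    eval_boolean,
    eval_geometric_gate,
    stats_from_counts,
)


@pytest.fixture
def display_table():
    """Small table whose two channels already live on a [0,1]-ish scale."""
    rng = np.random.default_rng(42)
    n = 600
    data = pd.DataFrame({
        "FL1": rng.uniform(-0.2, 1.2, n),
        "FL2": rng.uniform(-0.2, 1.2, n),
    })
    return hf.EventTable(data=data)


@pytest.fixture
def identity_transforms():
    ts = TransformSet()
    ts.set("FL1", "linear", 1.0)
    ts.set("FL2", "linear", 1.0)
    return ts


def _brute_force(gate, x, y=None):
    """Independent per-event evaluation with explicit half-open rules."""
    out = []
    for i in range(len(x)):
        if isinstance(gate, Threshold):
            out.append(gate.lo <= x[i] < gate.hi)
        elif isinstance(gate, Rectangle):
            out.append(gate.x_lo <= x[i] < gate.x_hi and gate.y_lo <= y[i] < gate.y_hi)
        elif isinstance(gate, QuadrantCell):
            mx = x[i] >= gate.x_split if gate.cell[0] == "+" else x[i] < gate.x_split
            my = y[i] >= gate.y_split if gate.cell[1] == "+" else y[i] < gate.y_split
            out.append(mx and my)
        else:
            raise AssertionError
    return np.array(out)


@pytest.mark.parametrize("gate", [
    Threshold("FL1", lo=0.5),
    Threshold("FL1", hi=0.3),
    Threshold("FL1", lo=0.25, hi=0.75),
    Rectangle("FL1", "FL2", 0.1, 0.6, 0.2, 0.9),
    Rectangle("FL1", "FL2", -np.inf, 0.5, 0.5, np.inf),
    QuadrantCell("FL1", "FL2", 0.4, 0.6, "++"),
    QuadrantCell("FL1", "FL2", 0.4, 0.6, "-+"),
    QuadrantCell("FL1", "FL2", 0.4, 0.6, "+-"),
    QuadrantCell("FL1", "FL2", 0.4, 0.6, "--"),
])
def test_geometric_gates_match_brute_force(display_table, identity_transforms, gate):
    mask = eval_geometric_gate(display_table, gate, identity_transforms)
    x = display_table.data["FL1"].to_numpy()
    y = display_table.data["FL2"].to_numpy()
    np.testing.assert_array_equal(mask, _brute_force(gate, x, y))


def test_universal_rectangle_selects_everything(display_table, identity_transforms):
    gate = Rectangle("FL1", "FL2", -np.inf, np.inf, -np.inf, np.inf)
    assert eval_geometric_gate(display_table, gate, identity_transforms).all()


def test_quadrant_cells_partition_exactly(display_table, identity_transforms):
    masks = [
        eval_geometric_gate(
            display_table, QuadrantCell("FL1", "FL2", 0.37, 0.61, cell), identity_transforms
        )
        for cell in ("--", "+-", "-+", "++")
    ]
    total = np.sum(masks, axis=0)
    assert (total == 1).all()  # disjoint and covering


def test_polygon_gate_matches_rectangle_on_square(display_table, identity_transforms):
    # a square polygon and the corresponding rectangle agree except on the
    # boundary, which has measure zero for continuous data
    poly = Polygon("FL1", "FL2", ((0.1, 0.2), (0.6, 0.2), (0.6, 0.9), (0.1, 0.9)))
    rect = Rectangle("FL1", "FL2", 0.1, 0.6, 0.2, 0.9)
    pm = eval_geometric_gate(display_table, poly, identity_transforms)
    rm = eval_geometric_gate(display_table, rect, identity_transforms)
    assert (pm != rm).mean() < 0.01


def test_unknown_channel_raises(display_table, identity_transforms):
    with pytest.raises(ConfigurationError, match="unknown channel"):
        eval_geometric_gate(display_table, Threshold("FL9", lo=0.5), identity_transforms)


# ---------------------------------------------------------------------------
# Boolean gates
# ---------------------------------------------------------------------------

def test_union_counts_each_event_once():
    masks = {
        "t8hi": np.array([1, 1, 0, 0], dtype=bool),
        "t8lo": np.array([0, 0, 1, 0], dtype=bool),
    }
    tc = eval_boolean("t8hi | t8lo", masks)
    np.testing.assert_array_equal(tc, [True, True, True, False])
    assert tc.sum() == 3


@given(st.integers(0, 255))
@settings(max_examples=60, deadline=None)
def test_three_gate_expression_matches_truth_table(bits):
    # eight events = all 2^3 membership patterns; any fixed expression must
    # agree with per-event Python evaluation
    a = np.array([(i >> 0) & 1 for i in range(8)], dtype=bool)
    b = np.array([(i >> 1) & 1 for i in range(8)], dtype=bool)
    c = np.array([(i >> 2) & 1 for i in range(8)], dtype=bool)
    masks = {"a": a, "b": b, "c": c}
    expr = "a & !(b | c) | (b & c)"
    got = eval_boolean(expr, masks)
    want = np.array([
        (a[i] and not (b[i] or c[i])) or (b[i] and c[i]) for i in range(8)
    ])
    np.testing.assert_array_equal(got, want)


def test_nested_rest_of_b_style_expression():
    rng = np.random.default_rng(7)
    masks = {k: rng.random(200) < 0.3 for k in ("b", "pre", "nai", "mem", "tra", "pla")}
    got = eval_boolean("b & !(pre | (nai | (mem | (tra | pla))))", masks)
    want = masks["b"] & ~(masks["pre"] | masks["nai"] | masks["mem"] | masks["tra"] | masks["pla"])
    np.testing.assert_array_equal(got, want)


def test_not_of_empty_gate_is_parent():
    masks = {"empty": np.zeros(10, dtype=bool)}
    assert eval_boolean("!empty", masks).sum() == 10


def test_unresolved_gate_id_raises():
    with pytest.raises(ConfigurationError, match="unknown gate"):
        eval_boolean("a | missing", {"a": np.ones(3, dtype=bool)})


@pytest.mark.parametrize("bad", ["a &", "(a | b", "a | | b", ")a("])
def test_malformed_expressions_rejected(bad):
    with pytest.raises(ConfigurationError):
        BooleanExpr.parse(bad)


# ---------------------------------------------------------------------------
# gate trees
# ---------------------------------------------------------------------------

def test_two_level_tree_matches_hidden_labels_exactly(profile, schema_by_id):
    prof = profile.zero_spread()
    schema = schema_by_id["P01"]
    table = hf.simulate_panel_acquisition(prof, schema, 10_000, seed=5)
    nodes = [
        GateNode("cd3", "all_cells",
                 geometry=Threshold("FL9", lo=schema.transforms.apply("FL9", np.array([600.0]))[0]),
                 display_name="T cells", report=True),
        GateNode("cd4hi", "cd3",
                 geometry=Threshold("FL4", lo=schema.transforms.apply("FL4", np.array([8660.0]))[0]),
                 display_name="CD4hi", report=True),
    ]
    tree = GateTree(nodes, major_id="cd3")
    stats = hf.apply_gate_tree(table, tree, schema.transforms)
    by_name = {s.name: s for s in stats}
    labels = table.labels
    n_t = sum(1 for l in labels if l.startswith("t."))
    n_cd4hi = sum(1 for l in labels if l.startswith(("t.th.", "t.dpt")))
    assert by_name["T cells"].count == n_t
    assert by_name["CD4hi"].count == n_cd4hi


def test_root_only_tree_and_percentage_conventions():
    counts = {"all_cells": 500}
    tree = GateTree([], major_id=None)
    assert stats_from_counts(tree, counts, "PX") == []
    tree2 = GateTree([GateNode("x", "all_cells", geometry=Threshold("FL1"), report=True)])
    stats = stats_from_counts(tree2, {"all_cells": 500, "x": 500}, "PX")
    assert stats[0].pct_parent == pytest.approx(100.0)


def test_sibling_quadrant_percentages_sum_to_100(profile, schema_by_id, p01_table):
    from conftest import prep_and_masks

    schema = schema_by_id["P01"]
    _, masks, _ = prep_and_masks(p01_table, schema)
    parent = masks["th"].sum()
    total = sum(masks[f"{m}_th"].sum() for m in ("naive", "eff", "em", "cm"))
    assert total == parent


def test_cycle_and_orphan_detection():
    with pytest.raises(ConfigurationError):
        GateTree([
            GateNode("a", "b", geometry=Threshold("FL1")),
            GateNode("b", "a", geometry=Threshold("FL1")),
        ])
    with pytest.raises(ConfigurationError):
        GateTree([GateNode("a", "ghost", geometry=Threshold("FL1"))])


def test_node_must_have_exactly_one_predicate():
    with pytest.raises(ConfigurationError):
        GateNode("x", "all_cells")
    with pytest.raises(ConfigurationError):
        GateNode("x", "all_cells", geometry=Threshold("FL1"), boolean="a | b")


def test_validity_flag_follows_event_count():
    tree = GateTree([GateNode("x", "all_cells", geometry=Threshold("FL1"), report=True)])
    low = stats_from_counts(tree, {"all_cells": 1000, "x": 99}, "PX")[0]
    high = stats_from_counts(tree, {"all_cells": 1000, "x": 100}, "PX")[0]
    assert not low.valid
    assert high.valid
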