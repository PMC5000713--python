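"""Generic gate evaluation: geometric gates, Boolean gates and gate trees.

Gate coordinates live in *display* space (logicle for fluorescence, linear
or log for scatter) because that is the space gates are drawn in; a
:class:`TransformSet` maps each channel to its display transform. All
boundaries follow the half-open convention ``[lo, hi)`` so that sibling
quadrant cells partition their parent exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from matplotlib.path import Path as MplPath

from .core import ConfigurationError, EventTable, PopulationStats
from .preprocess import LogicleParams, to_logicle


# ---------------------------------------------------------------------------
# channel transforms
# ---------------------------------------------------------------------------

class TransformSet:
    """Per-channel display transforms.

    Each channel is mapped to one of ``("logicle", LogicleParams)``,
    ``("linear", top)`` (display = value/top) or ``("log10", top, decades)``.
    """

    def __init__(self, spec: Mapping[str, tuple] | None = None):
        self.spec: dict[str, tuple] = dict(spec or {})

    def set(self, channel: str, kind: str, *args) -> None:
        self.spec[channel] = (kind, *args)

    def __contains__(self, channel: str) -> bool:
        return channel in self.spec

    def apply(self, channel: str, values: np.ndarray) -> np.ndarray:
        if channel not in self.spec:
            raise ConfigurationError(f"no display transform defined for channel {channel!r}")
        kind, *args = self.spec[channel]
        v = np.asarray(values, dtype=float)
        if kind == "linear":
            (top,) = args
            return v / top
        if kind == "log10":
            top, decades = args
            with np.errstate(divide="ignore"):
                return 1.0 + np.log10(np.maximum(v, 1e-12) / top) / decades
        if kind == "logicle":
            (params,) = args
            return to_logicle(v, params)
        raise ConfigurationError(f"unknown transform kind {kind!r}")


# ---------------------------------------------------------------------------
# geometric gates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Threshold:
    """1-D half-open interval ``[lo, hi)`` on one channel (display units)."""

    channel: str
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ConfigurationError(f"threshold on {self.channel}: lo must be < hi")


@dataclass(frozen=True)
class Rectangle:
    """2-D half-open box (display units)."""

    x_channel: str
    y_channel: str
    x_lo: float = -np.inf
    x_hi: float = np.inf
    y_lo: float = -np.inf
    y_hi: float = np.inf


@dataclass(frozen=True)
class QuadrantCell:
    """One cell of a quadrant gate defined by an (x, y) split point.

    ``cell`` is two characters from {'-', '+'} for (x, y); '+' selects
    values ``>= split`` (half-open, so the four cells partition the plane).
    """

    x_channel: str
    y_channel: str
    x_split: float
    y_split: float
    cell: str

    def __post_init__(self) -> None:
        if self.cell not in ("--", "+-", "-+", "++"):
            raise ConfigurationError(f"quadrant cell must be one of --,+-,-+,++; got {self.cell!r}")


@dataclass(frozen=True)
class Polygon:
    """Simple polygon in display space."""

    x_channel: str
    y_channel: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ConfigurationError("polygon needs at least three vertices")
        arr = np.asarray(self.vertices, dtype=float)
        if not np.isfinite(arr).all():
            raise ConfigurationError("polygon vertices must be finite")


GateGeometry = Threshold | Rectangle | QuadrantCell | Polygon


def eval_geometric_gate(
    table: EventTable, gate: GateGeometry, transforms: TransformSet
) -> np.ndarray:
    """Boolean mask of events inside ``gate`` (deterministic, half-open)."""

    def disp(channel: str) -> np.ndarray:
        if channel not in table.data.columns:
            raise ConfigurationError(
                f"gate references unknown channel {channel!r} "
                f"(panel {table.panel_id or '?'})"
            )
        return transforms.apply(channel, table.data[channel].to_numpy())

    if isinstance(gate, Threshold):
        x = disp(gate.channel)
        return (x >= gate.lo) & (x < gate.hi)
    if isinstance(gate, Rectangle):
        x, y = disp(gate.x_channel), disp(gate.y_channel)
        return (x >= gate.x_lo) & (x < gate.x_hi) & (y >= gate.y_lo) & (y < gate.y_hi)
    if isinstance(gate, QuadrantCell):
        x, y = disp(gate.x_channel), disp(gate.y_channel)
        mx = x >= gate.x_split if gate.cell[0] == "+" else x < gate.x_split
        my = y >= gate.y_split if gate.cell[1] == "+" else y < gate.y_split
        return mx & my
    if isinstance(gate, Polygon):
        x, y = disp(gate.x_channel), disp(gate.y_channel)
        path = MplPath(np.asarray(gate.vertices, dtype=float))
        return path.contains_points(np.column_stack([x, y]))
    raise ConfigurationError(f"unknown gate geometry {type(gate).__name__}")


# ---------------------------------------------------------------------------
# Boolean gates
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*(\(|\)|&|\||!|[A-Za-z_][\w./+-]*)")


class BooleanExpr:
    """Expression tree over gate ids with AND (&), OR (|), NOT (!).

    Parsed from strings like ``"t8hi | t8lo"`` or
    ``"b_cells & !(naive | memory)"``. Evaluation is elementwise over
    equal-length masks, so a union counts every event exactly once.
    """

    def __init__(self, node: tuple):
        self.node = node

    # grammar: expr := term ('|' term)* ; term := factor ('&' factor)* ;
    #          factor := '!' factor | '(' expr ')' | ID
    @classmethod
    def parse(cls, text: str) -> "BooleanExpr":
        tokens = []
        pos = 0
        while pos < len(text):
            m = _TOKEN.match(text, pos)
            if not m:
                if text[pos:].strip():
                    raise ConfigurationError(f"cannot tokenize boolean expression at {text[pos:]!r}")
                break
            tokens.append(m.group(1))
            pos = m.end()

        def expr(i: int) -> tuple[tuple, int]:
            node, i = term(i)
            while i < len(tokens) and tokens[i] == "|":
                rhs, i = term(i + 1)
                node = ("or", node, rhs)
            return node, i

        def term(i: int) -> tuple[tuple, int]:
            node, i = factor(i)
            while i < len(tokens) and tokens[i] == "&":
                rhs, i = factor(i + 1)
                node = ("and", node, rhs)
            return node, i

        def factor(i: int) -> tuple[tuple, int]:
            if i >= len(tokens):
                raise ConfigurationError(f"unexpected end of boolean expression {text!r}")
            tok = tokens[i]
            if tok == "!":
                node, i = factor(i + 1)
                return ("not", node), i
            if tok == "(":
                node, i = expr(i + 1)
                if i >= len(tokens) or tokens[i] != ")":
                    raise ConfigurationError(f"unbalanced parentheses in {text!r}")
                return node, i + 1
            if tok in ("&", "|", ")"):
                raise ConfigurationError(f"misplaced {tok!r} in {text!r}")
            return ("id", tok), i + 1

        node, i = expr(0)
        if i != len(tokens):
            raise ConfigurationError(f"trailing tokens in boolean expression {text!r}")
        return cls(node)

    def gate_ids(self) -> set[str]:
        out: set[str] = set()

        def walk(node: tuple) -> None:
            if node[0] == "id":
                out.add(node[1])
            elif node[0] == "not":
                walk(node[1])
            else:
                walk(node[1])
                walk(node[2])

        walk(self.node)
        return out

    def evaluate(self, masks: Mapping[str, np.ndarray]) -> np.ndarray:
        def walk(node: tuple) -> np.ndarray:
            kind = node[0]
            if kind == "id":
                if node[1] not in masks:
                    raise ConfigurationError(f"boolean expression references unknown gate {node[1]!r}")
                return np.asarray(masks[node[1]], dtype=bool)
            if kind == "not":
                return ~walk(node[1])
            a, b = walk(node[1]), walk(node[2])
            if a.shape != b.shape:
                raise ConfigurationError("boolean operands have different lengths")
            return a & b if kind == "and" else a | b

        return walk(self.node)


def eval_boolean(expr: BooleanExpr | str, masks: Mapping[str, np.ndarray]) -> np.ndarray:
    if isinstance(expr, str):
        expr = BooleanExpr.parse(expr)
    return expr.evaluate(masks)


# ---------------------------------------------------------------------------
# gate trees
# ---------------------------------------------------------------------------

@dataclass
class GateNode:
    """One node of a gate tree.

    ``geometry`` XOR ``boolean`` defines the node predicate; the node mask
    is always intersected with the parent mask. ``link_id`` marks
    geometry shared across panels (identical gates on linked channels).
    """

    node_id: str
    parent_id: str | None
    geometry: GateGeometry | None = None
    boolean: BooleanExpr | str | None = None
    display_name: str = ""
    report: bool = False
    link_id: str | None = None

    def __post_init__(self) -> None:
        if self.parent_id is not None and (self.geometry is None) == (self.boolean is None):
            raise ConfigurationError(
                f"node {self.node_id!r} must define exactly one of geometry or boolean"
            )
        if isinstance(self.boolean, str):
            self.boolean = BooleanExpr.parse(self.boolean)
        if not self.display_name:
            self.display_name = self.node_id


ROOT_ID = "all_cells"


class GateTree:
    """Hierarchy of gates rooted at the All Cells gate."""

    def __init__(self, nodes: Sequence[GateNode], major_id: str | None = None):
        self.nodes: dict[str, GateNode] = {}
        root = GateNode(ROOT_ID, None, display_name="All Cells", report=False)
        self.nodes[ROOT_ID] = root
        for node in nodes:
            if node.node_id in self.nodes:
                raise ConfigurationError(f"duplicate gate id {node.node_id!r}")
            self.nodes[node.node_id] = node
        self.major_id = major_id
        self.order = self._toposort()

    def _toposort(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}

        def deps(node: GateNode) -> list[str]:
            out = []
            if node.parent_id is not None:
                out.append(node.parent_id)
            if node.boolean is not None:
                out.extend(sorted(node.boolean.gate_ids()))
            return out

        def visit(nid: str) -> None:
            if state.get(nid) == 2:
                return
            if state.get(nid) == 1:
                raise ConfigurationError(f"cycle in gate tree involving {nid!r}")
            if nid not in self.nodes:
                raise ConfigurationError(f"gate tree references unknown node {nid!r}")
            state[nid] = 1
            for d in deps(self.nodes[nid]):
                visit(d)
            state[nid] = 2
            order.append(nid)

        for nid in self.nodes:
            visit(nid)
        # orphan check: everything must reach the root through parents
        for nid, node in self.nodes.items():
            cur = node
            seen = set()
            while cur.parent_id is not None:
                if cur.node_id in seen:
                    raise ConfigurationError(f"parent cycle at {cur.node_id!r}")
                seen.add(cur.node_id)
                cur = self.nodes[cur.parent_id]
            if cur.node_id != ROOT_ID:
                raise ConfigurationError(f"node {nid!r} does not descend from the root")
        return order

    def evaluate(
        self, table: EventTable, transforms: TransformSet, root_mask: np.ndarray | None = None
    ) -> dict[str, np.ndarray]:
        """Masks for every node (each intersected with its parent)."""
        n = len(table)
        masks: dict[str, np.ndarray] = {}
        masks[ROOT_ID] = (
            np.ones(n, dtype=bool) if root_mask is None else np.asarray(root_mask, dtype=bool)
        )
        for nid in self.order:
            if nid == ROOT_ID:
                continue
            node = self.nodes[nid]
            parent = masks[node.parent_id]
            if node.geometry is not None:
                own = eval_geometric_gate(table, node.geometry, transforms)
            else:
                own = node.boolean.evaluate(masks)
            masks[nid] = own & parent
        return masks


def stats_from_counts(
    tree: GateTree,
    counts: Mapping[str, int],
    panel_id: str,
    reported_only: bool = False,
) -> list[PopulationStats]:
    """Population statistics from per-node event counts.

    ``%parent`` is relative to the immediate parent, ``%major`` to the
    tree's major-cell-type node and ``%all cells`` to the root mask.
    """
    all_cells = counts[ROOT_ID]
    major = counts.get(tree.major_id) if tree.major_id else None
    out: list[PopulationStats] = []
    pid = panel_id
    for nid in tree.order:
        if nid == ROOT_ID:
            continue
        node = tree.nodes[nid]
        if reported_only and not node.report:
            continue
        out.append(
            PopulationStats.make(
                name=node.display_name,
                panel_id=pid,
                count=counts[nid],
                parent_count=counts[node.parent_id],
                major_count=major,
                all_cells_count=all_cells,
                parent=tree.nodes[node.parent_id].display_name
                if node.parent_id != ROOT_ID
                else "All Cells",
            )
        )
    return out


def apply_gate_tree(
    table: EventTable,
    tree: GateTree,
    transforms: TransformSet,
    root_mask: np.ndarray | None = None,
    panel_id: str | None = None,
    reported_only: bool = False,
) -> list[PopulationStats]:
    """Evaluate a tree on an event table and emit population statistics."""
    masks = tree.evaluate(table, transforms, root_mask)
    counts = {nid: int(m.sum()) for nid, m in masks.items()}
    pid = panel_id if panel_id is not None else table.panel_id
    return stats_from_counts(tree, counts, pid, reported_only=reported_only)
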