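"""The 12-panel whole-blood immunophenotyping schema.

Eleven staining panels (P01–P11) each characterize one cell type — T cells
(P01–P03), B cells (P04), T/B activation (P05), NK/NKT cells (P06/P07),
monocytes (P08), neutrophils/eosinophils (P09), basophils and dendritic
cells (P10) and circulating non-leukocytes (P11) — and the twelfth (P12)
adds counting beads for absolute cell numbers. Together they resolve 34
immune and 3 non-immune subsets plus 27 activation-marker readouts, and a
standard report enumerates 208 populations per sample.

Marker split thresholds are *display-space* gate boundaries converted from
raw-intensity cut points at schema build time. The shipped defaults are
calibrated to the synthetic generator's intensity templates; analyzing
real instrument data requires recalibrating them (the original gates were
placed manually against fluorescence-minus-one controls).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    FL_CHANNELS,
    FSC_INT,
    FSC_PEAK,
    FSC_TOF,
    RAW_SCALE_TOP,
    SSC,
    ConfigurationError,
    EventTable,
    PopulationStats,
)
from .gating import (
    GateNode,
    GateTree,
    QuadrantCell,
    Rectangle,
    Threshold,
    TransformSet,
    apply_gate_tree,
)
from .preprocess import LogicleParams, QcConfig, all_cells_gate, flow_gate, singlet_gate

# ---------------------------------------------------------------------------
# split thresholds (raw intensity units)
# ---------------------------------------------------------------------------

#: named raw-intensity cut points per marker; geometric midpoints between
#: the negative/low/positive/high template levels of the default generator
DEFAULT_THRESHOLDS: dict[str, dict[str, float]] = {
    "CD3": {"pos": 600.0},
    "CD4": {"pos": 210.0, "hi": 8_660.0},
    "CD8": {"pos": 210.0, "hi": 8_660.0},
    "CD45RA": {"pos": 775.0},
    "CD197": {"pos": 490.0},
    "CD183": {"pos": 490.0},
    "CD196": {"pos": 490.0},
    "CD25": {"pos": 350.0, "hi": 10_954.0},
    "CD127": {"lo": 1_789.0},
    "CD38": {"pos": 490.0, "hi": 6_928.0},
    "TCRab": {"pos": 600.0},
    "TCRgd": {"pos": 600.0},
    "CD152": {"pos": 350.0},
    "CD19": {"pos": 490.0},
    "CD20": {"pos": 775.0},
    "CD19/20": {"pos": 1_300.0},
    "CD27": {"pos": 490.0},
    "CD5": {"pos": 490.0},
    "CD24": {"pos": 350.0, "hi": 15_492.0},
    "CD69": {"pos": 424.0},
    "CD80": {"pos": 424.0},
    "CD279": {"pos": 424.0},
    "CD86": {"pos": 424.0, "mono_pos": 490.0, "mono_hi": 20_000.0},
    "HLA-DR": {"pos": 775.0, "act": 424.0, "mono_pos": 4_000.0, "mono_hi": 44_721.0},
    "CD16": {"pos": 600.0},
    "CD16b": {"pos": 600.0},
    "CD56": {"pos": 274.0, "hi": 12_247.0},
    "CD314": {"pos": 490.0},
    "CD94": {"pos": 490.0},
    "CD159a": {"pos": 490.0},
    "CD159c": {"pos": 490.0},
    "CD14": {"pos": 274.0, "hi": 12_247.0},
    "CD64": {"pos": 600.0, "mono_hi": 30_984.0},
    "CD66": {"pos": 775.0},
    "CD123": {"pos": 600.0},
    "CD11c": {"pos": 949.0},
    "CD1c": {"pos": 490.0},
    "CD83": {"pos": 424.0},
    "CD274": {"pos": 424.0},
    "CD45": {"pos": 949.0, "lo": 6_708.0},
    "CD146": {"pos": 600.0},
    "CD133": {"pos": 490.0},
    "CD34": {"pos": 600.0},
    "LIN": {"pos": 1_200.0},
}

#: scatter-region boundaries (raw side-scatter units)
SSC_PBL_MAX = 55_000.0
SSC_MO_MAX = 150_000.0

#: panel channel→marker maps (one row of the staining-panel overview each)
PANEL_CHANNELS: dict[str, dict[str, str]] = {
    "P01": {"FL1": "CD8", "FL2": "CD197", "FL4": "CD4", "FL5": "CD45RA", "FL6": "CD38", "FL9": "CD3"},
    "P02": {"FL1": "CD127", "FL2": "CD196", "FL4": "CD4", "FL5": "CD25", "FL6": "CD183", "FL9": "CD3"},
    "P03": {"FL1": "TCRgd", "FL2": "TCRab", "FL6": "CD152", "FL9": "CD3"},
    "P04": {"FL1": "CD20", "FL4": "CD24", "FL5": "CD5", "FL6": "CD38", "FL9": "CD27", "FL10": "CD19"},
    "P05": {"FL1": "CD19/20", "FL2": "CD25", "FL4": "CD86", "FL5": "CD69", "FL6": "CD279",
            "FL8": "CD80", "FL9": "CD3", "FL10": "HLA-DR"},
    "P06": {"FL1": "CD69", "FL2": "CD16", "FL4": "CD56", "FL6": "CD314", "FL9": "CD25", "FL10": "CD3"},
    "P07": {"FL1": "CD159c", "FL2": "CD16", "FL4": "CD56", "FL5": "CD94", "FL6": "CD159a", "FL10": "CD3"},
    "P08": {"FL1": "CD14", "FL2": "CD16", "FL4": "CD86", "FL6": "CD80", "FL9": "CD64", "FL10": "HLA-DR"},
    "P09": {"FL1": "CD66", "FL9": "CD64", "FL10": "CD16b"},
    "P10": {"FL1": "LIN", "FL2": "CD274", "FL4": "CD123", "FL5": "CD83", "FL6": "CD1c",
            "FL9": "CD11c", "FL10": "HLA-DR"},
    "P11": {"FL1": "CD146", "FL2": "CD133", "FL5": "CD45", "FL6": "CD34"},
    "P12": {"FL1": "CD19/20", "FL2": "CD16b", "FL4": "CD56", "FL5": "CD45", "FL9": "CD3"},
}

PANEL_CELL_TYPES: dict[str, str] = {
    "P01": "T cells", "P02": "T cells", "P03": "T cells", "P04": "B cells",
    "P05": "T/B activation", "P06": "NK cells", "P07": "NK cells",
    "P08": "Monocytes", "P09": "Neutrophils/Eosinophils",
    "P10": "Basophils/Dendritic cells", "P11": "Non-leukocytes",
    "P12": "Absolute counts",
}

#: stained blood volume equivalents (µL); rare-cell panels use 3x blood,
#: the counting tube 50 µL
PANEL_VOLUMES: dict[str, float] = {
    **{p: 100.0 for p in ("P01", "P02", "P03", "P04", "P05", "P06", "P07", "P08", "P09")},
    "P10": 300.0,
    "P11": 300.0,
    "P12": 50.0,
}

ALL_PANEL_IDS = tuple(PANEL_CHANNELS)


@dataclass
class PanelSchema:
    """One panel: channels, display transforms, gate tree, anchors."""

    panel_id: str
    cell_type: str
    channel_map: dict[str, str]
    volume_ul: float
    transforms: TransformSet
    logicle_params: dict[str, LogicleParams]
    tree: GateTree
    #: gate id -> major-cell-type key used to anchor absolute counts
    anchors: dict[str, str] = field(default_factory=dict)
    uncentrifuged: bool = False

    def marker_channel(self, marker: str) -> str:
        for ch, m in self.channel_map.items():
            if m == marker:
                return ch
        raise KeyError(f"{marker!r} is not stained in {self.panel_id}")

    def reported_populations(self) -> list[str]:
        return [
            self.tree.nodes[nid].display_name
            for nid in self.tree.order
            if nid != "all_cells" and self.tree.nodes[nid].report
        ]

    def anchor_for(self, node_id: str) -> tuple[str, str]:
        """(anchor gate id, major key) for a node: nearest anchored
        ancestor, falling back to all leukocytes at the root."""
        cur = self.tree.nodes[node_id]
        while cur.parent_id is not None:
            if cur.node_id in self.anchors:
                return cur.node_id, self.anchors[cur.node_id]
            cur = self.tree.nodes[cur.parent_id]
        return "all_cells", "Leu"


# ---------------------------------------------------------------------------
# schema construction
# ---------------------------------------------------------------------------

def _default_transforms(channel_map: dict[str, str]) -> tuple[TransformSet, dict]:
    params = {ch: LogicleParams() for ch in FL_CHANNELS}
    ts = TransformSet()
    for ch in FL_CHANNELS:
        ts.set(ch, "logicle", params[ch])
    for ch in (FSC_INT, FSC_TOF, FSC_PEAK):
        ts.set(ch, "linear", RAW_SCALE_TOP)
    ts.set(SSC, "log10", RAW_SCALE_TOP, 4.5)
    return ts, params


class _PanelBuilder:
    """Helper translating marker-level gate definitions into display-space
    geometry for one panel."""

    def __init__(self, panel_id: str, thresholds: dict[str, dict[str, float]]):
        self.panel_id = panel_id
        self.channel_map = PANEL_CHANNELS[panel_id]
        self.thresholds = thresholds
        self.transforms, self.logicle_params = _default_transforms(self.channel_map)
        self.nodes: list[GateNode] = []

    # -- coordinate helpers -------------------------------------------
    def channel(self, marker: str) -> str:
        for ch, m in self.channel_map.items():
            if m == marker:
                return ch
        raise ConfigurationError(f"{marker!r} is not stained in panel {self.panel_id}")

    def cut(self, marker: str, name: str = "pos") -> float:
        """Display-space split threshold for a marker."""
        try:
            raw = self.thresholds[marker][name]
        except KeyError:
            raise ConfigurationError(
                f"missing split threshold {name!r} for marker {marker!r} "
                f"in panel {self.panel_id}"
            ) from None
        ch = self.channel(marker)
        return float(self.transforms.apply(ch, np.array([raw]))[0])

    def ssc_display(self, raw: float) -> float:
        return float(self.transforms.apply(SSC, np.array([raw]))[0])

    # -- node helpers --------------------------------------------------
    def add(self, node: GateNode) -> GateNode:
        self.nodes.append(node)
        return node

    def thr_pos(self, nid, parent, marker, name, cut="pos", report=True, link=None):
        return self.add(GateNode(
            nid, parent,
            geometry=Threshold(self.channel(marker), lo=self.cut(marker, cut)),
            display_name=name, report=report, link_id=link,
        ))

    def thr_neg(self, nid, parent, marker, name, cut="pos", report=True, link=None):
        return self.add(GateNode(
            nid, parent,
            geometry=Threshold(self.channel(marker), hi=self.cut(marker, cut)),
            display_name=name, report=report, link_id=link,
        ))

    def rect(self, nid, parent, name, x=None, y=None, report=True, link=None):
        """x/y are (marker, lo_cut_name|None, hi_cut_name|None)."""

        def bounds(spec):
            marker, lo, hi = spec
            ch = self.channel(marker)
            return (
                ch,
                -np.inf if lo is None else self.cut(marker, lo),
                np.inf if hi is None else self.cut(marker, hi),
            )

        xc, xlo, xhi = bounds(x)
        yc, ylo, yhi = bounds(y)
        return self.add(GateNode(
            nid, parent,
            geometry=Rectangle(xc, yc, xlo, xhi, ylo, yhi),
            display_name=name, report=report, link_id=link,
        ))

    def quad(self, nid, parent, name, xmarker, xcut, ymarker, ycut, cell,
             report=True, link=None):
        return self.add(GateNode(
            nid, parent,
            geometry=QuadrantCell(
                self.channel(xmarker), self.channel(ymarker),
                self.cut(xmarker, xcut), self.cut(ymarker, ycut), cell,
            ),
            display_name=name, report=report, link_id=link,
        ))

    def boolean(self, nid, parent, expr, name, report=True):
        return self.add(GateNode(nid, parent, boolean=expr, display_name=name, report=report))

    def build(self, major_id: str | None, anchors: dict[str, str],
              uncentrifuged: bool = False) -> PanelSchema:
        return PanelSchema(
            panel_id=self.panel_id,
            cell_type=PANEL_CELL_TYPES[self.panel_id],
            channel_map=dict(self.channel_map),
            volume_ul=PANEL_VOLUMES[self.panel_id],
            transforms=self.transforms,
            logicle_params=self.logicle_params,
            tree=GateTree(self.nodes, major_id=major_id),
            anchors=anchors,
            uncentrifuged=uncentrifuged,
        )


_MEMORY_CELLS = {
    # (CD197, CD45RA) quadrant cell -> memory subset name
    "++": "Naive", "-+": "Eff", "--": "EM", "+-": "CM",
}


def _build_p01(th: dict) -> PanelSchema:
    b = _PanelBuilder("P01", th)
    b.thr_pos("cd3pos", "all_cells", "CD3", "T cells", link="cd3")
    b.rect("th", "cd3pos", "TH", x=("CD4", "hi", None), y=("CD8", None, "pos"))
    b.rect("t8hi", "cd3pos", "T8hi", x=("CD8", "hi", None), y=("CD4", None, "pos"))
    b.rect("t8lo", "cd3pos", "T8lo", x=("CD8", "pos", "hi"), y=("CD4", None, "pos"))
    b.boolean("tc", "cd3pos", "t8hi | t8lo", "TC")
    b.rect("dnt", "cd3pos", "DNT", x=("CD4", None, "pos"), y=("CD8", None, "pos"))
    b.rect("dpt", "cd3pos", "DPT", x=("CD4", "hi", None), y=("CD8", "hi", None))
    b.rect("cd4lo", "cd3pos", "CD4lo T", x=("CD4", "pos", "hi"), y=("CD8", None, "pos"))
    b.rect("cd4hi8lo", "cd3pos", "CD4hi CD8lo T", x=("CD4", "hi", None), y=("CD8", "pos", "hi"))
    b.rect("cd8hi4lo", "cd3pos", "CD8hi CD4lo T", x=("CD8", "hi", None), y=("CD4", "pos", "hi"))
    for pid, tag in (("th", "TH"), ("t8hi", "T8hi"), ("t8lo", "T8lo")):
        for cell, mem in _MEMORY_CELLS.items():
            nid = f"{mem.lower()}_{pid}"
            b.quad(nid, pid, f"{mem} {tag}", "CD197", "pos", "CD45RA", "pos", cell)
            b.thr_pos(f"cd38_{nid}", nid, "CD38", f"CD38+ {mem} {tag}", cut="pos")
    return b.build("cd3pos", {"cd3pos": "T"})


def _build_p02(th: dict) -> PanelSchema:
    b = _PanelBuilder("P02", th)
    b.thr_pos("cd3pos", "all_cells", "CD3", "T cells", link="cd3")
    b.thr_pos("th", "cd3pos", "CD4", "TH", cut="hi")
    for cell, name in (("+-", "TH1"), ("--", "TH2"), ("-+", "TH17"), ("++", "TH1-17")):
        b.quad(f"th_{name.lower().replace('-', '_')}", "th", name, "CD183", "pos", "CD196", "pos", cell)
    b.rect("treg", "th", "TREG", x=("CD25", "hi", None), y=("CD127", None, "lo"))
    return b.build("cd3pos", {"cd3pos": "T"})


def _build_p03(th: dict) -> PanelSchema:
    b = _PanelBuilder("P03", th)
    b.thr_pos("cd3pos", "all_cells", "CD3", "T cells", link="cd3")
    b.quad("tcrab", "cd3pos", "TCRab T", "TCRab", "pos", "TCRgd", "pos", "+-")
    b.quad("tcrgd", "cd3pos", "TCRgd T", "TCRab", "pos", "TCRgd", "pos", "-+")
    b.thr_pos("cd152", "cd3pos", "CD152", "CD152+ T")
    return b.build("cd3pos", {"cd3pos": "T"})


def _build_p04(th: dict) -> PanelSchema:
    b = _PanelBuilder("P04", th)
    b.thr_pos("cd19b", "all_cells", "CD19", "CD19+ B")
    b.thr_pos("cd20b", "all_cells", "CD20", "CD20+ B")
    b.boolean("b", "all_cells", "cd19b | cd20b", "B cells")
    # alignment view: the same pan-marker union restricted to the lymphoid
    # scatter region (used to align sparse B gates)
    b.add(GateNode(
        "pbl", "all_cells",
        geometry=Rectangle(SSC, FSC_INT, -np.inf, b.ssc_display(SSC_PBL_MAX), -np.inf, np.inf),
        display_name="PBL scatter", report=False,
    ))
    b.boolean("b_pbl", "pbl", "cd19b | cd20b", "B cells (PBL)")
    for cell, nid, name in (
        ("--", "q_nn", "CD27- CD38-/lo B"),
        ("+-", "q_pn", "CD27+ CD38-/lo B"),
        ("-+", "q_nh", "CD27- CD38hi B"),
        ("++", "q_ph", "CD27+ CD38hi B"),
    ):
        b.quad(nid, "b", name, "CD27", "pos", "CD38", "hi", cell)
    b.thr_pos("prenaive", "q_nn", "CD5", "Pre-naive B")
    b.thr_neg("naive", "q_nn", "CD5", "Naive B")
    b.rect("memoryb", "q_pn", "Memory B", x=("CD5", None, "pos"), y=("CD24", "pos", None))
    b.rect("transitional", "q_nh", "Transitional B", x=("CD5", "pos", None), y=("CD24", "hi", None))
    b.rect("plasmablast", "q_ph", "Plasmablasts", x=("CD5", None, "pos"), y=("CD24", None, "pos"))
    b.boolean(
        "restb", "b",
        "b & !(prenaive | naive | memoryb | transitional | plasmablast)",
        "Rest of B",
    )
    b.rect("breg", "restb", "BREG", x=("CD27", "pos", None), y=("CD24", "hi", None))
    return b.build("b", {"b": "B"})


def _build_p05(th: dict) -> PanelSchema:
    b = _PanelBuilder("P05", th)
    b.thr_pos("cd3pos", "all_cells", "CD3", "T cells", link="cd3")
    b.thr_pos("b1920", "all_cells", "CD19/20", "B cells")
    for marker in ("CD25", "CD69", "CD80", "CD86", "CD279"):
        b.thr_pos(f"t_{marker.lower()}", "cd3pos", marker, f"{marker}+ T")
    b.thr_pos("t_hladr", "cd3pos", "HLA-DR", "HLA-DR+ T", cut="act")
    for marker in ("CD25", "CD69", "CD80", "CD86"):
        b.thr_pos(f"b_{marker.lower()}", "b1920", marker, f"{marker}+ B")
    b.thr_pos("b_hladr", "b1920", "HLA-DR", "HLA-DR+ B", cut="act")
    return b.build("cd3pos", {"cd3pos": "T", "b1920": "B"})


def _nk_base(b: _PanelBuilder) -> None:
    """Shared (linked) NK identification gates of P06/P07."""
    b.thr_neg("cd3neg", "all_cells", "CD3", "CD3- cells", link="cd3neg")
    b.thr_pos("nk", "cd3neg", "CD56", "NK cells", link="nk")
    b.thr_pos("nk1", "nk", "CD16", "NK1", link="nk1")
    b.rect("nk2", "nk", "NK2", x=("CD56", "hi", None), y=("CD16", None, "pos"), link="nk2")
    b.rect("nk3", "nk", "NK3", x=("CD56", None, "hi"), y=("CD16", None, "pos"), link="nk3")
    b.thr_pos("cd3pos", "all_cells", "CD3", "T cells", link="cd3")


def _build_p06(th: dict) -> PanelSchema:
    b = _PanelBuilder("P06", th)
    _nk_base(b)
    for marker in ("CD314", "CD25", "CD69"):
        mid = marker.lower()
        b.thr_pos(f"nk_{mid}", "nk", marker, f"{marker}+ NK")
        for sub in ("nk1", "nk2", "nk3"):
            b.boolean(f"{sub}_{mid}", sub, f"{sub} & nk_{mid}", f"{marker}+ {sub.upper()}")
    # identification cross-check: the NK subsets recovered from CD314
    b.thr_pos("cd314cd3neg", "cd3neg", "CD314", "CD314+ CD3-")
    b.thr_pos("v_nk1", "cd314cd3neg", "CD16", "NK1 (CD314 check)")
    b.rect("v_nk2", "cd314cd3neg", "NK2 (CD314 check)", x=("CD56", "hi", None), y=("CD16", None, "pos"))
    b.rect("v_nk3", "cd314cd3neg", "NK3 (CD314 check)", x=("CD56", None, "hi"), y=("CD16", None, "pos"))
    # NKT: CD3+ cells carrying any of the NK markers of this panel,
    # counted once per event by the Boolean union
    for marker in ("CD56", "CD16", "CD314"):
        b.thr_pos(f"nkt_{marker.lower()}", "cd3pos", marker, f"{marker}+ NKT")
    b.boolean("nkt", "cd3pos", "nkt_cd56 | nkt_cd16 | nkt_cd314", "NKT")
    return b.build("nk", {"nk": "NK", "cd3pos": "T"})


def _build_p07(th: dict) -> PanelSchema:
    b = _PanelBuilder("P07", th)
    _nk_base(b)
    b.thr_pos("nk_cd94", "nk", "CD94", "CD94+ NK")
    b.rect("nk_nkg2a", "nk", "CD159a/CD94+ NK", x=("CD159a", "pos", None), y=("CD94", "pos", None))
    b.rect("nk_nkg2c", "nk", "CD159c/CD94+ NK", x=("CD159c", "pos", None), y=("CD94", "pos", None))
    for rid, tag in (("nk_cd94", "CD94+"), ("nk_nkg2a", "CD159a/CD94+"), ("nk_nkg2c", "CD159c/CD94+")):
        for sub in ("nk1", "nk2", "nk3"):
            b.boolean(f"{sub}_{rid}", sub, f"{sub} & {rid}", f"{tag} {sub.upper()}")
    for marker in ("CD56", "CD16", "CD94", "CD159a", "CD159c"):
        b.thr_pos(f"nkt_{marker.lower()}", "cd3pos", marker, f"{marker}+ NKT")
    b.boolean(
        "nkt", "cd3pos",
        "nkt_cd56 | nkt_cd16 | nkt_cd94 | nkt_cd159a | nkt_cd159c", "NKT",
    )
    return b.build("nk", {"nk": "NK", "cd3pos": "T"})


_MO_READOUTS = (
    ("cd80", "CD80", "pos", "CD80+"),
    ("cd86pos", "CD86", "mono_pos", "CD86+"),
    ("cd86hi", "CD86", "mono_hi", "CD86hi"),
    ("cd64pos", "CD64", "pos", "CD64+"),
    ("cd64hi", "CD64", "mono_hi", "CD64hi"),
    ("drpos", "HLA-DR", "mono_pos", "HLA-DR+"),
    ("drhi", "HLA-DR", "mono_hi", "HLA-DRhi"),
)


def _build_p08(th: dict) -> PanelSchema:
    b = _PanelBuilder("P08", th)
    b.thr_pos("mo", "all_cells", "CD14", "Monocytes")
    for cell, nid, name in (
        ("+-", "mo1", "Mo1"), ("-+", "mo2", "Mo2"), ("++", "mo3", "Mo3"), ("--", "mo4", "Mo4"),
    ):
        b.quad(nid, "mo", name, "CD14", "hi", "CD16", "pos", cell)
    for rid, marker, cut, tag in _MO_READOUTS:
        b.thr_pos(f"mo_{rid}", "mo", marker, f"{tag} Mo", cut=cut)
        for sub in ("mo1", "mo2", "mo3", "mo4"):
            b.boolean(f"{sub}_{rid}", sub, f"{sub} & mo_{rid}", f"{tag} {sub.title()}")
    return b.build("mo", {"mo": "Mo"})


def _build_p09(th: dict) -> PanelSchema:
    b = _PanelBuilder("P09", th)
    b.add(GateNode(
        "gran", "all_cells",
        geometry=Rectangle(
            b.channel("CD66"), SSC,
            b.cut("CD66", "pos"), np.inf,
            b.ssc_display(SSC_MO_MAX), np.inf,
        ),
        display_name="Granulocytes", report=True,
    ))
    b.thr_pos("neu", "gran", "CD16b", "Neutrophils")
    b.thr_neg("eos", "gran", "CD16b", "Eosinophils")
    b.thr_pos("cd64neu", "neu", "CD64", "CD64+ Neu")
    b.thr_pos("cd64eos", "eos", "CD64", "CD64+ Eos")
    return b.build("gran", {"gran": "Gr"})


def _build_p10(th: dict) -> PanelSchema:
    b = _PanelBuilder("P10", th)
    b.thr_neg("linneg", "all_cells", "LIN", "LIN- cells")
    b.thr_neg("drneg", "linneg", "HLA-DR", "HLA-DR- LIN-")
    b.thr_pos("baso", "drneg", "CD123", "Basophils")
    b.thr_pos("dcs", "linneg", "HLA-DR", "DCs (HLA-DR+)")
    b.quad("pdc", "dcs", "pDC", "CD11c", "pos", "CD123", "pos", "-+")
    b.quad("mdc", "dcs", "mDC", "CD11c", "pos", "CD123", "pos", "+-")
    b.thr_pos("mdc1", "mdc", "CD1c", "mDC-1")
    b.thr_neg("mdc2", "mdc", "CD1c", "mDC-2")
    b.boolean("alldc", "dcs", "mdc | pdc", "All DCs")
    b.thr_pos("cd83dc", "alldc", "CD83", "CD83+ DC")
    b.thr_pos("cd274dc", "alldc", "CD274", "CD274+ DC")
    return b.build("dcs", {})


def _build_p11(th: dict) -> PanelSchema:
    b = _PanelBuilder("P11", th)
    b.rect("epcgate", "all_cells", "CD146-CD133+ EPC",
           x=("CD146", None, "pos"), y=("CD133", "pos", None))
    b.thr_pos("epc45p", "epcgate", "CD45", "CD45+ EPC")
    b.thr_neg("epc45n", "epcgate", "CD45", "CD45- EPC")
    b.thr_neg("cd45lo", "all_cells", "CD45", "CD45-/lo cells", cut="lo")
    b.rect("cec", "cd45lo", "CEC", x=("CD146", "pos", None), y=("CD133", None, "pos"))
    b.rect("hscg", "cd45lo", "HSC", x=("CD146", None, "pos"), y=("CD34", "pos", None))
    b.thr_pos("hsc133p", "hscg", "CD133", "CD133+ HSC")
    b.thr_neg("hsc133n", "hscg", "CD133", "CD133- HSC")
    # rare-cell gates are aligned against expression on the All Cells level
    b.thr_pos("cd34all", "all_cells", "CD34", "CD34+ All Cells")
    b.thr_pos("cd133all", "all_cells", "CD133", "CD133+ All Cells")
    b.boolean("hspc", "all_cells", "epcgate | cec | hscg", "HSPC")
    return b.build(None, {})


def _build_p12(th: dict) -> PanelSchema:
    b = _PanelBuilder("P12", th)
    b.thr_pos("leu", "all_cells", "CD45", "Leukocytes (CD45+)")
    b.thr_pos("t12", "leu", "CD3", "T cells")
    b.boolean("rest1", "leu", "leu & !t12", "Rest 1")
    b.thr_pos("b12", "rest1", "CD19/20", "B cells")
    b.boolean("rest2", "rest1", "rest1 & !b12", "Rest 2")
    mo_lo, mo_hi = b.ssc_display(SSC_PBL_MAX), b.ssc_display(SSC_MO_MAX)
    b.add(GateNode(
        "mo12", "rest2",
        geometry=Rectangle(SSC, FSC_INT, mo_lo, mo_hi, -np.inf, np.inf),
        display_name="Monocytes", report=True,
    ))
    b.add(GateNode(
        "gr12", "rest2",
        geometry=Rectangle(SSC, FSC_INT, mo_hi, np.inf, -np.inf, np.inf),
        display_name="Granulocytes", report=True,
    ))
    b.boolean("rest3", "rest2", "rest2 & !(mo12 | gr12)", "Rest 3")
    b.quad("nk56p16p", "rest3", "CD56+CD16+ NK", "CD56", "pos", "CD16b", "pos", "++")
    b.quad("nk56p16n", "rest3", "CD56+CD16- NK", "CD56", "pos", "CD16b", "pos", "+-")
    b.boolean("nk12", "rest3", "nk56p16p | nk56p16n", "NK cells")
    b.boolean("rest4", "rest3", "rest3 & !nk12", "Rest 4")
    b.add(GateNode(
        "restpbl", "rest4",
        geometry=Rectangle(SSC, FSC_INT, -np.inf, mo_lo, -np.inf, np.inf),
        display_name="Rest of PBL", report=True,
    ))
    b.boolean("restcells", "rest4", "rest4 & !restpbl", "Rest of cells")
    b.thr_pos("gr16pos", "gr12", "CD16b", "Neutrophils (CD16+)")
    b.thr_neg("gr16neg", "gr12", "CD16b", "Eosinophils (CD16-)")
    b.thr_pos("mo16pos", "mo12", "CD16b", "CD16+ Mo")
    b.thr_neg("mo16neg", "mo12", "CD16b", "CD16- Mo")
    return b.build("leu", {"leu": "Leu"}, uncentrifuged=True)


_BUILDERS = {
    "P01": _build_p01, "P02": _build_p02, "P03": _build_p03, "P04": _build_p04,
    "P05": _build_p05, "P06": _build_p06, "P07": _build_p07, "P08": _build_p08,
    "P09": _build_p09, "P10": _build_p10, "P11": _build_p11, "P12": _build_p12,
}


def build_diob_schema(config: dict | None = None) -> list[PanelSchema]:
    """Build the full 12-panel schema.

    ``config`` may supply ``thresholds`` (nested ``{marker: {cut: raw}}``
    overrides) and ``panels`` (subset of panel ids to build, in standard
    order). Raises :class:`ConfigurationError` naming marker and panel if
    a required split threshold is missing.
    """
    config = config or {}
    thresholds = {m: dict(c) for m, c in DEFAULT_THRESHOLDS.items()}
    for marker, cuts in (config.get("thresholds") or {}).items():
        thresholds.setdefault(marker, {}).update(cuts)
    panel_ids = config.get("panels") or ALL_PANEL_IDS
    unknown = [p for p in panel_ids if p not in _BUILDERS]
    if unknown:
        raise ConfigurationError(f"unknown panel ids {unknown}")
    return [_BUILDERS[pid](thresholds) for pid in ALL_PANEL_IDS if pid in panel_ids]


# ---------------------------------------------------------------------------
# subset definitions and enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubsetDefinition:
    """One monitored cell subset: its phenotype and where it is read out."""

    name: str
    major_type: str
    requirements: tuple[tuple[str, str], ...]
    panel_id: str
    population: str  # display name of the reporting gate
    plant_leaf: str  # generator leaf realizing the phenotype
    immune: bool = True
    context: str = ""


def subset_definitions() -> list[SubsetDefinition]:
    """The 34 immune + 3 non-immune monitored subsets."""
    S = SubsetDefinition
    t = lambda *req: (("CD3", "+"),) + req  # noqa: E731
    th = lambda *req: t(("CD4", "+"), ("CD8", "-")) + req  # noqa: E731
    tc = lambda *req: t(("CD8", "+"), ("CD4", "-")) + req  # noqa: E731
    b = lambda *req: (("CD19", "+|CD20+"),) + req  # noqa: E731
    lin_neg = tuple((m, "-") for m in ("CD3", "CD14", "CD16", "CD19", "CD20", "CD56"))
    out = [
        S("TH1", "T", th(("CD183", "+"), ("CD196", "-")), "P02", "TH1", "t.th.cm.th1"),
        S("TH2", "T", th(("CD183", "-"), ("CD196", "-")), "P02", "TH2", "t.th.cm.th2"),
        S("TH17", "T", th(("CD183", "-"), ("CD196", "+")), "P02", "TH17", "t.th.cm.th17"),
        S("TREG", "T", th(("CD25", "hi"), ("CD127", "-/lo")), "P02", "TREG", "t.th.treg"),
        S("Naive TH", "T", th(("CD197", "+"), ("CD45RA", "+")), "P01", "Naive TH", "t.th.naive.th2"),
        S("Effector TH", "T", th(("CD197", "-"), ("CD45RA", "+")), "P01", "Eff TH", "t.th.eff.th2"),
        S("EM TH", "T", th(("CD197", "-"), ("CD45RA", "-")), "P01", "EM TH", "t.th.em.th2"),
        S("CM TH", "T", th(("CD197", "+"), ("CD45RA", "-")), "P01", "CM TH", "t.th.cm.th2"),
        S("Naive TC", "T", tc(("CD197", "+"), ("CD45RA", "+")), "P01", "Naive T8hi", "t.tc8hi.naive"),
        S("Effector TC", "T", tc(("CD197", "-"), ("CD45RA", "+")), "P01", "Eff T8hi", "t.tc8hi.eff"),
        S("EM TC", "T", tc(("CD197", "-"), ("CD45RA", "-")), "P01", "EM T8hi", "t.tc8hi.em"),
        S("CM TC", "T", tc(("CD197", "+"), ("CD45RA", "-")), "P01", "CM T8hi", "t.tc8hi.cm"),
        S("TCRab T", "T", t(("TCRab", "+"), ("TCRgd", "-")), "P03", "TCRab T", "t.th.em.th2"),
        S("TCRgd T", "T", t(("TCRgd", "+"), ("TCRab", "-")), "P03", "TCRgd T", "t.dnt"),
        S("Pre-naive B", "B", b(("CD27", "-"), ("CD38", "-/lo"), ("CD5", "+")), "P04", "Pre-naive B", "b.prenaive"),
        S("Naive B", "B", b(("CD27", "-"), ("CD38", "-/lo"), ("CD5", "-")), "P04", "Naive B", "b.naive"),
        S("Memory B", "B", b(("CD27", "+"), ("CD38", "-/lo"), ("CD5", "-"), ("CD24", "+")), "P04", "Memory B", "b.memory"),
        S("Transitional B", "B", b(("CD27", "-"), ("CD38", "hi"), ("CD5", "+"), ("CD24", "hi")), "P04", "Transitional B", "b.transitional"),
        S("Plasmablasts", "B", b(("CD27", "+"), ("CD38", "hi"), ("CD5", "-"), ("CD24", "-")), "P04", "Plasmablasts", "b.plasmablast"),
        S("BREG", "B", b(("CD27", "+"), ("CD24", "hi")), "P04", "BREG", "b.breg",
          context="after exclusion of the other five B subsets"),
        S("NK1", "NK", (("CD3", "-"), ("CD56", "+"), ("CD16", "+")), "P06", "NK1", "nk.nk1"),
        S("NK2", "NK", (("CD3", "-"), ("CD56", "hi"), ("CD16", "-")), "P06", "NK2", "nk.nk2"),
        S("NK3", "NK", (("CD3", "-"), ("CD56", "lo"), ("CD16", "-")), "P06", "NK3", "nk.nk3"),
        S("NKT", "T", (("CD3", "+"), ("CD56", "+|CD16+|CD314+")), "P06", "NKT", "t.nkt56"),
        S("Neutrophils", "Gr", (("CD66", "+"), ("CD16", "+")), "P09", "Neutrophils", "gr.neu"),
        S("Eosinophils", "Gr", (("CD66", "+"), ("CD16", "-")), "P09", "Eosinophils", "gr.eos"),
        S("Basophils", "Gr", lin_neg + (("HLA-DR", "-"), ("CD123", "+")), "P10", "Basophils", "gr.baso"),
        S("mDC-1", "DC", lin_neg + (("HLA-DR", "+"), ("CD11c", "hi"), ("CD123", "-/lo"), ("CD1c", "+")),
          "P10", "mDC-1", "dc.mdc1"),
        S("mDC-2", "DC", lin_neg + (("HLA-DR", "+"), ("CD11c", "hi"), ("CD123", "-/lo"), ("CD1c", "-")),
          "P10", "mDC-2", "dc.mdc2"),
        S("pDC", "DC", lin_neg + (("HLA-DR", "+"), ("CD123", "hi"), ("CD11c", "-")),
          "P10", "pDC", "dc.pdc"),
        S("Mo1", "Mo", (("CD14", "hi"), ("CD16", "-")), "P08", "Mo1", "mo.mo1"),
        S("Mo2", "Mo", (("CD14", "lo"), ("CD16", "+")), "P08", "Mo2", "mo.mo2"),
        S("Mo3", "Mo", (("CD14", "hi"), ("CD16", "+")), "P08", "Mo3", "mo.mo3"),
        S("Mo4", "Mo", (("CD14", "lo"), ("CD16", "-")), "P08", "Mo4", "mo.mo4"),
        S("HSC", "NonLeuk", (("CD45", "-/lo"), ("CD146", "-"), ("CD34", "+")), "P11", "HSC",
          "nl.hsc.cd133neg", immune=False),
        S("CEC", "NonLeuk", (("CD45", "-/lo"), ("CD146", "+"), ("CD133", "-")), "P11", "CEC",
          "nl.cec", immune=False),
        S("EPC", "NonLeuk", (("CD146", "-"), ("CD133", "+")), "P11", "CD146-CD133+ EPC",
          "nl.epc.cd45neg", immune=False),
    ]
    return out


#: the 27 activation-marker readouts as (cell type, marker) assignments
ACTIVATION_MARKERS: tuple[tuple[str, str], ...] = (
    ("T", "CD38"), ("T", "CD25"), ("T", "CD69"), ("T", "CD80"), ("T", "CD86"),
    ("T", "HLA-DR"), ("T", "CD279"), ("T", "CD152"),
    ("B", "CD25"), ("B", "CD69"), ("B", "CD80"), ("B", "CD86"), ("B", "HLA-DR"),
    ("NK", "CD314"), ("NK", "CD94"), ("NK", "CD159a"), ("NK", "CD159c"),
    ("NK", "CD25"), ("NK", "CD69"),
    ("Mo", "CD80"), ("Mo", "CD86"), ("Mo", "CD64"), ("Mo", "HLA-DR"),
    ("Neu", "CD64"), ("Eos", "CD64"),
    ("DC", "CD83"), ("DC", "CD274"),
)


def activation_markers(schemas: list[PanelSchema] | None = None) -> list[tuple[str, str]]:
    """The activation-state readouts of the full schema."""
    return list(ACTIVATION_MARKERS)


def list_reported_populations(schemas: list[PanelSchema]) -> list[tuple[str, str]]:
    """Deterministic enumeration of every reported population statistic.

    Returns ``(panel_id, population name)`` pairs in panel/tree order; the
    full 12-panel schema enumerates 208 populations per sample.
    """
    out: list[tuple[str, str]] = []
    for schema in schemas:
        out.extend((schema.panel_id, name) for name in schema.reported_populations())
    return out


# ---------------------------------------------------------------------------
# P12 major-cell-type classification
# ---------------------------------------------------------------------------

P12_MAJOR_POPULATIONS = (
    "Leukocytes (CD45+)", "T cells", "B cells", "Monocytes", "Granulocytes",
    "NK cells", "Rest of PBL", "Rest of cells",
)


def classify_p12_majors(
    table: EventTable,
    schema: PanelSchema | None = None,
    qc: QcConfig | None = None,
    root_mask: np.ndarray | None = None,
) -> list[PopulationStats]:
    """Sequential major-cell-type gating of the counting tube.

    Leukocytes (CD45+) are split strictly sequentially — T, then B, then
    monocytes and granulocytes by scatter, then NK — each step excluding
    the previously identified cells, so the majors plus the two rests
    partition the CD45+ events. Returns stats for the majors and the CD16
    splits of granulocytes and monocytes.
    """
    if schema is None:
        schema = build_diob_schema({"panels": ["P12"]})[0]
    if root_mask is None:
        if table.spillover is not None:
            from .preprocess import compensate

            table = compensate(table, table.spillover)
        cfg = (qc or QcConfig()).adapted_for_p12()
        root_mask = flow_gate(table, cfg) & singlet_gate(table, cfg)
        root_mask &= all_cells_gate(table, cfg).mask
    return apply_gate_tree(
        table, schema.tree, schema.transforms, root_mask=root_mask,
        panel_id="P12", reported_only=True,
    )
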