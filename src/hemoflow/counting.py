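"""Bead-based absolute cell counting for the counting tube.

A known number of fluorescent beads is spiked into a fixed blood volume
and acquired together with the cells. Beads sit in a dense FSC-low /
SSC-high scatter region and fluoresce in five channels; each channel
shows a singlet and a small doublet population separated in forward
scatter. Doublets are added twice to the singlets and the five effective
counts are averaged. The absolute count then follows

    cells/µL = (cells acquired / beads acquired)
               x (beads per tube / blood volume [µL])

and the per-µL numbers of the major cell types are transferred onto the
other panels to obtain an absolute count for every subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import FSC_INT, SSC, ConfigurationError, EventTable, PopulationStats
from .gating import GateGeometry, TransformSet, eval_geometric_gate
from .panels import PanelSchema

DEFAULT_BEAD_CHANNELS = ("FL1", "FL2", "FL3", "FL4", "FL8")

#: default beads gate in raw scatter units; generous on the low-FSC side
#: so small beads are not discarded with debris
BEADS_GATE_FSC_MAX = 250_000.0
BEADS_GATE_SSC_MIN = 400_000.0
#: raw fluorescence above which a bead-gate event counts as bead-positive
BEAD_POSITIVE_CUT = 5_000.0


class BeadCountError(ValueError):
    """Bead enumeration is impossible (no beads found in the gate)."""


@dataclass
class ChannelBeadCount:
    singlets: int
    doublets: int

    @property
    def effective(self) -> float:
        # a doublet event is two beads
        return self.singlets + 2.0 * self.doublets

    @property
    def singlet_fraction(self) -> float:
        total = self.singlets + self.doublets
        return self.singlets / total if total else float("nan")


@dataclass
class BeadCountResult:
    """Per-channel singlet/doublet bead counts and their average."""

    channels: dict[str, ChannelBeadCount]
    beads_per_tube: int | None = None
    blood_volume_ul: float | None = None

    @property
    def mean_effective(self) -> float:
        vals = [c.effective for c in self.channels.values()]
        return float(np.mean(vals))

    @property
    def mean_singlet_fraction(self) -> float:
        vals = [c.singlet_fraction for c in self.channels.values()]
        return float(np.mean(vals))


def _split_threshold(fsc: np.ndarray) -> float:
    """FSC value separating bead singlets from doublets.

    Looks for the histogram valley between the singlet mode and its
    doubled-FSC doublet population; falls back to 1.5x the singlet mode
    when no valley is resolvable.
    """
    med = float(np.median(fsc))  # inside the singlet mode (>97% singlets)
    fallback = 1.5 * med
    window = fsc[(fsc > 1.15 * med) & (fsc < 1.85 * med)]
    if window.size == 0:
        return fallback
    counts, edges = np.histogram(window, bins=24)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[np.argmin(counts)]) if counts.min() < counts.max() else fallback


def count_beads(
    table: EventTable,
    beads_gate: GateGeometry | None = None,
    channels: Sequence[str] = DEFAULT_BEAD_CHANNELS,
    transforms: TransformSet | None = None,
    positive_cut: float = BEAD_POSITIVE_CUT,
    beads_per_tube: int | None = None,
    event_mask: np.ndarray | None = None,
) -> BeadCountResult:
    """Enumerate counting beads in an uncentrifuged acquisition.

    The beads gate defaults to the raw-scatter box FSC < 250k / SSC > 400k.
    Beads must be counted *before* pulse-shape doublet exclusion, which
    would otherwise remove the very bead doublets that need to be added
    back twice. Raises :class:`BeadCountError` when the gate is empty.
    """
    fsc = table.data[FSC_INT].to_numpy(dtype=float)
    ssc = table.data[SSC].to_numpy(dtype=float)
    if beads_gate is not None:
        if transforms is None:
            raise ConfigurationError("a custom beads gate needs its TransformSet")
        in_gate = eval_geometric_gate(table, beads_gate, transforms)
    else:
        in_gate = (fsc < BEADS_GATE_FSC_MAX) & (ssc > BEADS_GATE_SSC_MIN)
    if event_mask is not None:
        in_gate &= np.asarray(event_mask, dtype=bool)
    if not in_gate.any():
        raise BeadCountError("no events in the beads gate; bead counting impossible")

    per_channel: dict[str, ChannelBeadCount] = {}
    for ch in channels:
        if ch not in table.data.columns:
            raise ConfigurationError(f"bead channel {ch!r} not present in table")
        positive = in_gate & (table.data[ch].to_numpy(dtype=float) > positive_cut)
        n_pos = int(positive.sum())
        if n_pos == 0:
            per_channel[ch] = ChannelBeadCount(0, 0)
            continue
        split = _split_threshold(fsc[positive])
        doublets = int((fsc[positive] >= split).sum())
        per_channel[ch] = ChannelBeadCount(n_pos - doublets, doublets)
    if all(c.singlets + c.doublets == 0 for c in per_channel.values()):
        raise BeadCountError("beads gate contains no bead-positive events")
    return BeadCountResult(
        channels=per_channel,
        beads_per_tube=beads_per_tube,
        blood_volume_ul=table.volume_ul,
    )


def absolute_count(
    cells_acquired: float,
    beads_acquired: float,
    beads_per_tube: float,
    blood_volume_ul: float,
) -> float:
    """Cells per µL of blood from simultaneous cell/bead acquisition."""
    if beads_acquired <= 0:
        raise ValueError("beads_acquired must be positive")
    if blood_volume_ul <= 0:
        raise ValueError("blood_volume_ul must be positive")
    return (cells_acquired / beads_acquired) * (beads_per_tube / blood_volume_ul)


def absolute_counts_per_ml(per_ul: Mapping[str, float]) -> dict[str, float]:
    """Convenience conversion of per-µL results to per-mL."""
    return {k: v * 1_000.0 for k, v in per_ul.items()}


def propagate_absolute(
    stats: Iterable[PopulationStats],
    schema: PanelSchema,
    p12_abs: Mapping[str, float],
    node_counts: Mapping[str, int],
) -> None:
    """Fill ``abs_per_ul`` on a panel's population stats in place.

    Each population anchors to the nearest gated ancestor with a known
    per-µL number from the counting tube (T, B, NK, Mo, Gr) or, for
    populations without such an anchor (DCs, basophils, non-leukocytes),
    to the all-leukocyte count; the subset absolute is the anchor absolute
    times the subset's within-anchor fraction measured in its own panel.
    """
    by_name = {node.display_name: nid for nid, node in schema.tree.nodes.items()}
    for stat in stats:
        nid = by_name.get(stat.name)
        if nid is None:
            continue
        anchor_id, major = schema.anchor_for(nid)
        if major not in p12_abs:
            raise ConfigurationError(
                f"no absolute count available for anchor {major!r} "
                f"(population {stat.name!r} in {schema.panel_id})"
            )
        anchor_count = node_counts.get(anchor_id, 0)
        stat.abs_per_ul = (
            p12_abs[major] * stat.count / anchor_count if anchor_count else 0.0
        )
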