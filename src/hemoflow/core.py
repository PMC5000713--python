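"""Shared containers: per-event acquisition tables and spillover matrices.

An acquisition is held as a :class:`EventTable` — a thin wrapper around a
``pandas.DataFrame`` whose columns are the cytometer parameters (TIME, the
three forward-scatter pulse measurements, side scatter and the fluorescence
channels FL1..FL10) plus acquisition metadata such as the channel→marker
assignment of the staining panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: canonical non-fluorescence parameter names
TIME = "TIME"
FSC_INT = "FSC-INT"
FSC_TOF = "FSC-TOF"
FSC_PEAK = "FSC-PEAK"
SSC = "SSC"

SCATTER_COLUMNS = (FSC_INT, FSC_TOF, FSC_PEAK, SSC)

#: all fluorescence detectors of a 3-laser / 10-color instrument
FL_CHANNELS = tuple(f"FL{i}" for i in range(1, 11))

#: top of the raw digitizer scale (20-bit ADC)
RAW_SCALE_TOP = 1_048_576.0


class ConfigurationError(ValueError):
    """A panel/gate/profile configuration is inconsistent."""


@dataclass
class EventTable:
    """Per-event measurements for one acquisition plus panel metadata.

    Parameters
    ----------
    data
        One row per event. Must contain ``TIME``, the scatter columns and
        any fluorescence channels referenced by ``channel_map``.
    panel_id, sample_id
        Identifiers carried through to reports.
    channel_map
        Fluorescence channel -> marker (antigen) name for the staining
        panel, e.g. ``{"FL1": "CD8", "FL9": "CD3"}``.
    duration
        Acquisition duration in seconds.
    volume_ul
        Equivalent volume of the original blood sample that this
        acquisition represents, in microlitres.
    labels
        Optional hidden per-event ground-truth labels (simulator only;
        never serialized to FCS).
    truth
        Optional simulator bookkeeping (true frequencies, cells/µL, ...).
    spillover
        The spillover matrix that was mixed into (or shipped with) the
        acquisition, if known.
    """

    data: pd.DataFrame
    panel_id: str = ""
    sample_id: str = ""
    channel_map: dict[str, str] = field(default_factory=dict)
    duration: float = 60.0
    volume_ul: float = 100.0
    labels: np.ndarray | None = None
    truth: dict = field(default_factory=dict)
    spillover: "SpilloverMatrix | None" = None

    def __post_init__(self) -> None:
        if self.labels is not None and len(self.labels) != len(self.data):
            raise ValueError("labels length does not match event count")

    # -- basic protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def fluorescence_channels(self) -> list[str]:
        return [c for c in self.data.columns if c in FL_CHANNELS]

    def marker_channel(self, marker: str) -> str:
        """Return the fluorescence channel a marker is detected in."""
        for ch, m in self.channel_map.items():
            if m == marker:
                return ch
        raise KeyError(f"marker {marker!r} is not stained in panel {self.panel_id or '?'}")

    def column_for(self, ref: str) -> np.ndarray:
        """Values for a channel name or a marker name."""
        if ref in self.data.columns:
            return self.data[ref].to_numpy()
        return self.data[self.marker_channel(ref)].to_numpy()

    def subset(self, mask: np.ndarray) -> "EventTable":
        """New table restricted to ``mask`` (labels follow)."""
        mask = np.asarray(mask, dtype=bool)
        return EventTable(
            data=self.data.loc[mask].reset_index(drop=True),
            panel_id=self.panel_id,
            sample_id=self.sample_id,
            channel_map=dict(self.channel_map),
            duration=self.duration,
            volume_ul=self.volume_ul,
            labels=None if self.labels is None else self.labels[mask],
            truth=dict(self.truth),
            spillover=self.spillover,
        )

    def copy(self) -> "EventTable":
        out = self.subset(np.ones(len(self), dtype=bool))
        out.data = out.data.copy()
        return out


class SpilloverMatrix:
    """Square spillover matrix over fluorescence channels.

    Row = source fluorochrome, column = detecting channel; the diagonal is
    one. Observed signals relate to true signals by ``observed = true @ S``.
    """

    def __init__(self, channels: Iterable[str], matrix: np.ndarray):
        self.channels = list(channels)
        matrix = np.asarray(matrix, dtype=float)
        n = len(self.channels)
        if matrix.shape != (n, n):
            raise ValueError(f"spillover matrix must be {n}x{n}, got {matrix.shape}")
        if not np.allclose(np.diag(matrix), 1.0):
            raise ValueError("spillover diagonal must be 1")
        if (matrix < 0).any():
            raise ValueError("spillover entries must be non-negative")
        self.matrix = matrix

    @classmethod
    def identity(cls, channels: Iterable[str] = FL_CHANNELS) -> "SpilloverMatrix":
        channels = list(channels)
        return cls(channels, np.eye(len(channels)))

    @classmethod
    def from_pairs(
        cls,
        pairs: Mapping[tuple[str, str], float],
        channels: Iterable[str] = FL_CHANNELS,
    ) -> "SpilloverMatrix":
        """Build from ``{(source, detector): coefficient}`` off-diagonals."""
        channels = list(channels)
        m = np.eye(len(channels))
        idx = {c: i for i, c in enumerate(channels)}
        for (src, det), v in pairs.items():
            m[idx[src], idx[det]] = v
        return cls(channels, m)

    def inverse(self) -> np.ndarray:
        cond = np.linalg.cond(self.matrix)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError("spillover matrix is singular or near-singular")
        return np.linalg.inv(self.matrix)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.channels, columns=self.channels)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return (
            isinstance(other, SpilloverMatrix)
            and self.channels == other.channels
            and np.allclose(self.matrix, other.matrix)
        )


@dataclass
class PopulationStats:
    """Report line for one gated population."""

    name: str
    panel_id: str
    count: int
    pct_parent: float
    pct_major: float
    pct_all_cells: float
    abs_per_ul: float | None = None
    valid: bool = True
    parent: str | None = None

    #: populations smaller than this many events carry no informative value
    MIN_EVENTS = 100

    @classmethod
    def make(
        cls,
        name: str,
        panel_id: str,
        count: int,
        parent_count: int,
        major_count: int | None,
        all_cells_count: int,
        parent: str | None = None,
    ) -> "PopulationStats":
        def pct(num: int, den: int | None) -> float:
            if den is None or den == 0:
                return float("nan")
            return 100.0 * num / den

        return cls(
            name=name,
            panel_id=panel_id,
            count=int(count),
            pct_parent=pct(count, parent_count),
            pct_major=pct(count, major_count),
            pct_all_cells=pct(count, all_cells_count),
            valid=count >= cls.MIN_EVENTS,
            parent=parent,
        )


def stats_to_frame(stats: Iterable[PopulationStats]) -> pd.DataFrame:
    rows = [
        {
            "panel": s.panel_id,
            "population": s.name,
            "parent": s.parent,
            "events": s.count,
            "pct_parent": s.pct_parent,
            "pct_major": s.pct_major,
            "pct_all_cells": s.pct_all_cells,
            "abs_per_ul": s.abs_per_ul,
            "valid": s.valid,
        }
        for s in stats
    ]
    return pd.DataFrame(rows)
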