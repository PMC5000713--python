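"""Compensation, logicle display transform and universal morphology gates.

Every panel is pre-processed identically before any marker gating:

1. spillover compensation (``observed = true @ S`` solved per event),
2. a Flow-gate removing time windows with irregular event rates,
3. two doublet gates on the forward-scatter pulse shape
   (area vs. width, then area vs. height),
4. the All Cells gate excluding debris and dead cells (reduced forward
   scatter), with an informative lymphoid/monocyte/granulocyte scatter
   classification of the retained leukocytes.

The original gates were drawn by eye; the automated analogues here are
deterministic rules (median/MAD rate test, ratio bands around the singlet
median, fixed scatter bounds) whose parameters live in :class:`QcConfig`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .core import FSC_INT, FSC_PEAK, FSC_TOF, RAW_SCALE_TOP, SSC, TIME, EventTable, SpilloverMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# compensation
# ---------------------------------------------------------------------------

def compensate(table: EventTable, spill: SpilloverMatrix) -> EventTable:
    """Return a copy with fluorescence columns replaced by compensated values.

    Solves ``observed = true @ S`` for each event; scatter and time columns
    are untouched. Raises ``numpy.linalg.LinAlgError`` for a singular matrix.
    """
    missing = [c for c in spill.channels if c not in table.data.columns]
    if missing:
        raise KeyError(f"spillover channels not present in table: {missing}")
    inv = spill.inverse()
    out = table.copy()
    observed = out.data[spill.channels].to_numpy(dtype=float)
    out.data[spill.channels] = observed @ inv
    return out


# ---------------------------------------------------------------------------
# logicle (biexponential) display scale
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogicleParams:
    """Parameters of the logicle display scale.

    T : top of the data scale (maps to display 1.0)
    M : total display width in decades
    W : linearization width in decades (W = 0 degenerates to log10)
    A : additional negative decades below zero
    """

    T: float = RAW_SCALE_TOP
    M: float = 4.5
    W: float = 0.5
    A: float = 0.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.M <= 0:
            raise ValueError("M must be positive")
        if not (0 <= self.W <= self.M / 2):
            raise ValueError("W must satisfy 0 <= W <= M/2")
        if self.A < 0:
            raise ValueError("A must be non-negative")


class _LogicleScale:
    """Numerical realization of one logicle parameterization.

    The inverse map (display -> data) is the closed-form biexponential; the
    forward map seeds from a cached dense grid and polishes with Newton
    steps, giving round trips accurate to ~1e-12 relative.
    """

    def __init__(self, p: LogicleParams):
        self.p = p
        total = p.M + p.A
        self.w = p.W / total
        self.x2 = p.A / total
        self.x1 = self.x2 + self.w
        self.x0 = self.x2 + 2 * self.w
        self.b = total * np.log(10.0)
        self.d = self._solve_d()
        c_a = np.exp(self.x0 * (self.b + self.d))
        f_a = np.exp(self.b * self.x1) - c_a * np.exp(-self.d * self.x1)
        self.a = p.T / (np.exp(self.b) - f_a - c_a * np.exp(-self.d))
        self.c = c_a * self.a
        self.f = f_a * self.a
        # dense monotone grid used to seed the forward map
        self._grid_x = np.linspace(-0.5, 1.5, 1 << 14)
        self._grid_v = self._inverse_scalar(self._grid_x)

    def _solve_d(self) -> float:
        b, w = self.b, self.w
        if w == 0:
            return b
        fn = lambda d: w * (b + d) - 2.0 * (np.log(b) - np.log(d))
        return brentq(fn, 1e-12, b, xtol=1e-14, rtol=8.9e-16)

    def _biexp(self, x: np.ndarray) -> np.ndarray:
        return self.a * np.exp(self.b * x) - self.c * np.exp(-self.d * x) - self.f

    def _biexp_deriv(self, x: np.ndarray) -> np.ndarray:
        return self.a * self.b * np.exp(self.b * x) + self.c * self.d * np.exp(-self.d * x)

    def _inverse_scalar(self, x: np.ndarray) -> np.ndarray:
        # reflect below x1 so negative data values get a symmetric scale
        x = np.asarray(x, dtype=float)
        lo = x < self.x1
        out = np.empty_like(x)
        out[~lo] = self._biexp(x[~lo])
        out[lo] = -self._biexp(2 * self.x1 - x[lo])
        return out

    def inverse(self, display: np.ndarray) -> np.ndarray:
        return self._inverse_scalar(np.asarray(display, dtype=float))

    def forward(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        x = np.interp(v, self._grid_v, self._grid_x)
        for _ in range(3):  # Newton polish; map is strictly monotone
            fx = self._inverse_scalar(x)
            lo = x < self.x1
            deriv = np.where(
                lo, self._biexp_deriv(2 * self.x1 - x), self._biexp_deriv(x)
            )
            x = x - (fx - v) / deriv
        return x


_scale_cache: dict[LogicleParams, _LogicleScale] = {}


def _scale(params: LogicleParams) -> _LogicleScale:
    if params not in _scale_cache:
        _scale_cache[params] = _LogicleScale(params)
    return _scale_cache[params]


def to_logicle(values, params: LogicleParams = LogicleParams()):
    """Map raw intensities to logicle display units (data T -> display 1.0)."""
    return _scale(params).forward(np.asarray(values, dtype=float))


def from_logicle(display, params: LogicleParams = LogicleParams()):
    """Inverse of :func:`to_logicle`."""
    return _scale(params).inverse(np.asarray(display, dtype=float))


# ---------------------------------------------------------------------------
# QC / morphology gates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QcConfig:
    """Parameters of the automated morphology/QC gates (raw units).

    The scatter bounds default to the whole-blood acquisition geometry of
    the synthetic generator; ``adapted_for_p12`` shifts the forward-scatter
    bounds up for the uncentrifuged counting tube.
    """

    # Flow-gate
    flow_window_s: float = 1.0
    flow_mad_multiplier: float = 5.0
    # doublet gates: keep ratio within (1 +/- half_width) x median
    tof_band_half_width: float = 0.25
    peak_band_half_width: float = 0.25
    # All Cells gate
    fsc_min: float = 130_000.0
    fsc_max: float = RAW_SCALE_TOP
    ssc_min: float = 1_000.0
    # exclusion-reason split: debris is low-FSC AND low-SSC
    debris_fsc_max: float = 65_000.0
    debris_ssc_max: float = 18_000.0
    # informative scatter classes for retained events
    ssc_pbl_max: float = 55_000.0
    ssc_mo_max: float = 150_000.0

    def __post_init__(self) -> None:
        for name in (
            "flow_window_s", "flow_mad_multiplier", "tof_band_half_width",
            "peak_band_half_width", "fsc_min", "ssc_pbl_max", "ssc_mo_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def adapted_for_p12(self, fsc_shift: float = 1.3) -> "QcConfig":
        """Scatter bounds for the uncentrifuged counting tube (elevated FSC)."""
        return replace(
            self,
            fsc_min=self.fsc_min * fsc_shift,
            debris_fsc_max=self.debris_fsc_max * fsc_shift,
        )


def flow_gate(table: EventTable, cfg: QcConfig = QcConfig()) -> np.ndarray:
    """Keep events in time windows with a regular acquisition rate.

    Windows whose event count deviates from the median by more than
    ``flow_mad_multiplier`` x MAD are excluded wholesale.
    """
    n = len(table)
    if n == 0:
        return np.zeros(0, dtype=bool)
    t = table.data[TIME].to_numpy()
    t0, t1 = float(t.min()), float(t.max())
    width = cfg.flow_window_s
    duration = max(t1 - t0, 0.0)
    n_windows = max(int(np.ceil(duration / width)), 1) if duration > 0 else 1
    if n_windows < 3:
        warnings.warn("acquisition shorter than three flow windows; all events kept")
        return np.ones(n, dtype=bool)
    # merge a short trailing partial window into its neighbour so its
    # inflated/deflated rate cannot trip the outlier test
    if duration - (n_windows - 1) * width < 0.5 * width:
        n_windows -= 1
    idx = np.clip((t - t0) // width, 0, n_windows - 1).astype(int)
    counts = np.bincount(idx, minlength=n_windows).astype(float)
    widths = np.full(n_windows, width)
    widths[-1] = duration - (n_windows - 1) * width
    rates = counts / widths
    med = np.median(rates)
    mad = np.median(np.abs(rates - med))
    # Poisson floor keeps a perfectly flat stream from zero-MAD artifacts
    mad = max(mad, np.sqrt(max(med * width, 1.0)) / width * 0.6745)
    bad = np.abs(rates - med) > cfg.flow_mad_multiplier * mad
    return ~bad[idx]


def _ratio_band(num: np.ndarray, den: np.ndarray, half_width: float) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    ratio[~np.isfinite(ratio)] = np.inf
    med = np.median(ratio[np.isfinite(ratio)]) if np.isfinite(ratio).any() else 1.0
    return (ratio >= med * (1 - half_width)) & (ratio < med * (1 + half_width))


def singlet_gate(table: EventTable, cfg: QcConfig = QcConfig()) -> np.ndarray:
    """Two-stage doublet exclusion on the forward-scatter pulse shape.

    Stage one keeps events whose area/width (INT/TOF) ratio lies in a band
    around the median; stage two applies the same rule to area/height
    (INT/PEAK), where doublets — summed area at single-event height —
    stand out.
    """
    if len(table) == 0:
        return np.zeros(0, dtype=bool)
    fsc = table.data[FSC_INT].to_numpy(dtype=float)
    tof = table.data[FSC_TOF].to_numpy(dtype=float)
    peak = table.data[FSC_PEAK].to_numpy(dtype=float)
    stage1 = _ratio_band(fsc, tof, cfg.tof_band_half_width)
    # stage-two band is anchored on the stage-one survivors' median
    mask = stage1.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = fsc / peak
    r2[~np.isfinite(r2)] = np.inf
    med2 = np.median(r2[stage1]) if stage1.any() else 1.0
    stage2 = (r2 >= med2 * (1 - cfg.peak_band_half_width)) & (
        r2 < med2 * (1 + cfg.peak_band_half_width)
    )
    mask &= stage2
    return mask


@dataclass
class AllCellsResult:
    """Mask plus per-event annotations from the All Cells gate."""

    mask: np.ndarray
    #: 'PBL' / 'Mo' / 'Gr' for retained events, '' otherwise
    scatter_class: np.ndarray
    #: '' for retained events, else 'debris' or 'low_fsc'
    exclusion_reason: np.ndarray

    def excluded_fraction(self, reason: str | None = None) -> float:
        if len(self.mask) == 0:
            return 0.0
        if reason is None:
            return float((~self.mask).mean())
        return float((self.exclusion_reason == reason).mean())


def all_cells_gate(table: EventTable, cfg: QcConfig = QcConfig()) -> AllCellsResult:
    """Exclude debris and dead (reduced-FSC) events; classify the rest.

    The retained events represent circulating leukocytes and non-leukocytes;
    the PBL/Mo/Gr scatter classes are informative only — downstream marker
    gating always runs on the full All Cells mask.
    """
    n = len(table)
    if n == 0:
        empty = np.zeros(0, dtype=bool)
        return AllCellsResult(empty, np.array([], dtype=object), np.array([], dtype=object))
    fsc = table.data[FSC_INT].to_numpy(dtype=float)
    ssc = table.data[SSC].to_numpy(dtype=float)
    mask = (fsc >= cfg.fsc_min) & (fsc <= cfg.fsc_max) & (ssc >= cfg.ssc_min)

    reason = np.full(n, "", dtype=object)
    excl = ~mask
    is_debris = excl & (fsc < cfg.debris_fsc_max) & (ssc < cfg.debris_ssc_max)
    reason[is_debris] = "debris"
    reason[excl & ~is_debris] = "low_fsc"

    sclass = np.full(n, "", dtype=object)
    sclass[mask & (ssc < cfg.ssc_pbl_max)] = "PBL"
    sclass[mask & (ssc >= cfg.ssc_pbl_max) & (ssc < cfg.ssc_mo_max)] = "Mo"
    sclass[mask & (ssc >= cfg.ssc_mo_max)] = "Gr"
    return AllCellsResult(mask, sclass, reason)
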