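"""Synthetic whole-blood flow-cytometry acquisitions with known ground truth.

The generator emulates a fresh, stained, lysed whole-blood sample measured
on a 3-laser/10-color instrument: a mixture of leaf cell populations (each
a full surface-marker phenotype drawn from lognormal intensity templates),
plus debris, dead cells (reduced forward scatter), cell doublets, optional
acquisition-rate bursts, fluorescence spillover between detectors and
counting beads for the absolute-count tube. Every event carries a hidden
ground-truth label so each downstream gating stage can be scored against
what was actually generated.

Default population frequencies reflect normal adult blood: T cells ~25%
of leukocytes, B ~5%, NK ~4%, monocytes ~8.5%, neutrophils ~50%,
eosinophils ~3%, basophils ~0.8%, dendritic cells ~0.6%, and circulating
stem/progenitor/endothelial cells below 0.01%. Dead cells default to 0.5%
(<1%) and bead doublets to 2% (<3%), matching fresh-blood acquisitions.

Intensities are modelled per marker as lognormals around four canonical
levels (neg/lo/pos/hi) in raw linear units on a [0, 1048576] digitizer
scale; this is a standard approximation that yields realistic logicle
displays. The generator makes no claim of biological realism beyond what
gating needs — no cytokine dynamics, no cell cycle, no donor biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core import (
    FL_CHANNELS,
    FSC_INT,
    FSC_PEAK,
    FSC_TOF,
    RAW_SCALE_TOP,
    SSC,
    TIME,
    ConfigurationError,
    EventTable,
    SpilloverMatrix,
)

# ---------------------------------------------------------------------------
# canonical intensity levels (raw linear units)
# ---------------------------------------------------------------------------

NEG = 30.0
LO = 800.0
POS = 12_000.0
HI = 150_000.0

#: markers that are physically a cocktail read in one channel; the channel
#: intensity is the sum of the component markers' intensities
DERIVED_MARKERS: dict[str, tuple[str, ...]] = {
    "CD19/20": ("CD19", "CD20"),
    # lineage cocktail; CD16 via the pan clone that also binds neutrophils
    "LIN": ("CD3", "CD14", "CD16b", "CD19", "CD20", "CD56"),
}

Level = float  # a raw-intensity location
#: a template entry is either a location or ("bern", p, loc_pos[, loc_neg])
TemplateSpec = Level | tuple


@dataclass(frozen=True)
class MarkerTemplate:
    """Lognormal intensity template for one marker on one population."""

    marker: str
    location: float
    spread: float = 0.25

    def __post_init__(self) -> None:
        if self.location <= 0 or self.spread < 0:
            raise ValueError("template location must be > 0 and spread >= 0")


@dataclass
class BeadConfig:
    """Counting-bead parameters for the absolute-count tube."""

    beads_per_tube: int = 10_000
    blood_volume_ul: float = 50.0
    fsc_location: float = 60_000.0
    ssc_location: float = 600_000.0
    fluorescence_location: float = 50_000.0
    channels: tuple[str, ...] = ("FL1", "FL2", "FL3", "FL4", "FL8")
    doublet_rate: float = 0.02
    scatter_cv: float = 0.04
    fluorescence_cv: float = 0.10

    def __post_init__(self) -> None:
        if self.beads_per_tube <= 0:
            raise ValueError("beads_per_tube must be positive")
        if self.blood_volume_ul <= 0:
            raise ValueError("blood_volume_ul must be positive")
        if not 0 <= self.doublet_rate <= 0.1:
            raise ValueError("doublet_rate must be in [0, 0.1]")


# ---------------------------------------------------------------------------
# default leaf-population table
# ---------------------------------------------------------------------------

def _bern(p: float, pos: float, neg: float = NEG) -> tuple:
    return ("bern", p, pos, neg)


def _t_common(memory: str) -> dict[str, TemplateSpec]:
    cd38_p = {"naive": 0.60, "cm": 0.30, "em": 0.15, "eff": 0.15}[memory]
    ra = 20_000.0 if memory in ("naive", "eff") else NEG
    ccr7 = 8_000.0 if memory in ("naive", "cm") else NEG
    return {
        "CD3": POS,
        "CD45RA": ra,
        "CD197": ccr7,
        "TCRab": POS,
        "CD5": 8_000.0,
        "CD127": 8_000.0,
        "CD38": _bern(cd38_p, 8_000.0),
        "CD25": _bern(0.08, 4_000.0),
        "CD69": _bern(0.03, 6_000.0),
        "CD80": _bern(0.01, 6_000.0),
        "CD86": _bern(0.02, 6_000.0),
        "HLA-DR": _bern(0.05, 6_000.0),
        "CD279": _bern(0.15, 6_000.0),
        "CD152": _bern(0.02, 4_000.0),
    }


def _b_common() -> dict[str, TemplateSpec]:
    return {
        "CD19": 8_000.0,
        "CD20": 20_000.0,
        "HLA-DR": 20_000.0,
        "CD25": _bern(0.10, 4_000.0),
        "CD69": _bern(0.03, 6_000.0),
        "CD80": _bern(0.05, 6_000.0),
        "CD86": _bern(0.10, 6_000.0),
    }


def _default_leaves() -> tuple[dict, dict, dict, dict]:
    """Return (frequencies, nonleuk_frequencies, templates, scatter_class)."""
    freq: dict[str, float] = {}
    templates: dict[str, dict[str, TemplateSpec]] = {}
    sclass: dict[str, str] = {}

    def leaf(name: str, f: float, cls: str, spec: dict[str, TemplateSpec]) -> None:
        freq[name] = f
        templates[name] = spec
        sclass[name] = cls

    # ---- T cells: 25% of leukocytes --------------------------------------
    t_total = 0.25
    th_memory = {"naive": 0.40, "cm": 0.25, "em": 0.22, "eff": 0.13}
    th_lineage = {"th1": 0.30, "th2": 0.40, "th17": 0.20, "th117": 0.10}
    tc_memory = {"naive": 0.30, "eff": 0.20, "em": 0.30, "cm": 0.20}
    for mem, fm in th_memory.items():
        for lin, fl in th_lineage.items():
            spec = _t_common(mem) | {
                "CD4": 50_000.0,
                "CD183": 8_000.0 if lin in ("th1", "th117") else NEG,
                "CD196": 8_000.0 if lin in ("th17", "th117") else NEG,
            }
            leaf(f"t.th.{mem}.{lin}", t_total * 0.57 * 0.95 * fm * fl, "PBL", spec)
    leaf(
        "t.th.treg",
        t_total * 0.57 * 0.05,
        "PBL",
        _t_common("cm") | {"CD4": 50_000.0, "CD25": 30_000.0, "CD127": 400.0},
    )
    for mem, fm in tc_memory.items():
        leaf(
            f"t.tc8hi.{mem}",
            t_total * 0.26 * fm,
            "PBL",
            _t_common(mem) | {"CD8": 50_000.0},
        )
    leaf("t.tc8lo", t_total * 0.02, "PBL", _t_common("em") | {"CD8": 1_500.0})
    leaf(
        "t.dnt",
        t_total * 0.05,
        "PBL",
        _t_common("eff") | {"TCRab": NEG, "TCRgd": POS},
    )
    leaf("t.dpt", t_total * 0.01, "PBL", _t_common("naive") | {"CD4": 50_000.0, "CD8": 50_000.0})
    leaf("t.cd4lo", t_total * 0.03, "PBL", _t_common("em") | {"CD4": 1_500.0})
    leaf(
        "t.nkt56",
        t_total * 0.05,
        "PBL",
        _t_common("eff")
        | {"CD56": 8_000.0, "CD314": 8_000.0, "CD94": 8_000.0, "CD159a": _bern(0.5, 8_000.0)},
    )
    leaf(
        "t.nkt16",
        t_total * 0.01,
        "PBL",
        _t_common("eff") | {"CD16": POS, "CD16b": POS, "CD314": 8_000.0},
    )

    # ---- B cells: 5% ------------------------------------------------------
    b_total = 0.05
    b_subsets: dict[str, tuple[float, dict[str, TemplateSpec]]] = {
        "prenaive": (0.02, {"CD27": NEG, "CD38": LO, "CD5": 8_000.0, "CD24": 4_000.0}),
        "naive": (0.62, {"CD27": NEG, "CD38": LO, "CD5": NEG, "CD24": 4_000.0}),
        "memory": (0.25, {"CD27": 8_000.0, "CD38": LO, "CD5": NEG, "CD24": 4_000.0}),
        "transitional": (0.03, {"CD27": NEG, "CD38": 60_000.0, "CD5": 8_000.0, "CD24": 60_000.0}),
        "plasmablast": (0.02, {"CD27": 8_000.0, "CD38": 60_000.0, "CD5": NEG, "CD24": NEG}),
        "breg": (0.03, {"CD27": 8_000.0, "CD38": LO, "CD5": 8_000.0, "CD24": 60_000.0}),
        "other": (0.03, {"CD27": NEG, "CD38": 60_000.0, "CD5": NEG, "CD24": 4_000.0}),
    }
    for name, (f, spec) in b_subsets.items():
        leaf(f"b.{name}", b_total * f, "PBL", _b_common() | spec)

    # ---- NK cells: 4% -----------------------------------------------------
    nk_total = 0.04
    nk_common = {
        "CD314": 8_000.0,
        "CD159c": _bern(0.10, 8_000.0),
        "CD25": _bern(0.03, 4_000.0),
        "CD69": _bern(0.05, 6_000.0),
    }
    leaf(
        "nk.nk1",
        nk_total * 0.90,
        "PBL",
        nk_common
        | {
            "CD56": 2_500.0,
            "CD16": POS,
            "CD16b": POS,
            "CD94": _bern(0.40, 8_000.0),
            "CD159a": _bern(0.30, 8_000.0),
        },
    )
    leaf(
        "nk.nk2",
        nk_total * 0.06,
        "PBL",
        nk_common | {"CD56": 60_000.0, "CD94": 8_000.0, "CD159a": 8_000.0},
    )
    leaf(
        "nk.nk3",
        nk_total * 0.04,
        "PBL",
        nk_common | {"CD56": 2_500.0, "CD94": 8_000.0, "CD159a": _bern(0.30, 8_000.0)},
    )

    # ---- monocytes: 8.5% --------------------------------------------------
    mo_total = 0.085
    mo_common = {
        "CD64": _bern(0.20, 80_000.0, 12_000.0),  # constitutive, sometimes upshifted
        "CD86": _bern(0.30, 50_000.0, 8_000.0),
        "HLA-DR": _bern(0.25, 100_000.0, 20_000.0),
        "CD80": _bern(0.02, 6_000.0),
        "CD14": 60_000.0,
    }
    leaf("mo.mo1", mo_total * 0.85, "Mo", dict(mo_common))
    leaf("mo.mo2", mo_total * 0.05, "Mo", mo_common | {"CD14": 2_500.0, "CD16": POS, "CD16b": POS})
    leaf("mo.mo3", mo_total * 0.05, "Mo", mo_common | {"CD16": POS, "CD16b": POS})
    leaf("mo.mo4", mo_total * 0.05, "Mo", mo_common | {"CD14": 2_500.0, "HLA-DR": LO})

    # ---- granulocytes -----------------------------------------------------
    leaf("gr.neu", 0.50, "Gr", {"CD66": 20_000.0, "CD16b": POS, "CD64": _bern(0.05, POS)})
    leaf("gr.eos", 0.03, "Gr", {"CD66": 20_000.0, "CD64": _bern(0.05, POS)})
    leaf("gr.baso", 0.008, "PBL", {"CD123": POS})

    # ---- dendritic cells: 0.6% -------------------------------------------
    dc_total = 0.006
    dc_common = {
        "HLA-DR": 20_000.0,
        "CD83": _bern(0.10, 6_000.0),
        "CD274": _bern(0.05, 6_000.0),
    }
    leaf("dc.pdc", dc_total * 0.45, "PBL", dc_common | {"CD123": 60_000.0})
    leaf("dc.mdc1", dc_total * 0.45, "PBL", dc_common | {"CD11c": 30_000.0, "CD1c": 8_000.0})
    leaf("dc.mdc2", dc_total * 0.10, "PBL", dc_common | {"CD11c": 30_000.0})

    # ---- remaining lymphoid cells ----------------------------------------
    leaf("other.pbl", 0.021, "PBL", {})

    # ---- non-leukocytes (fractions of all intact cells) -------------------
    nonleuk: dict[str, float] = {}
    nl_templates = {
        "nl.hsc.cd133pos": {"CD45": 1_500.0, "CD34": POS, "CD133": 8_000.0},
        "nl.hsc.cd133neg": {"CD45": 1_500.0, "CD34": POS},
        "nl.epc.cd45pos": {"CD45": 1_500.0, "CD133": 8_000.0},
        "nl.epc.cd45neg": {"CD133": 8_000.0},
        "nl.cec": {"CD146": POS},
    }
    nl_freq = {
        "nl.hsc.cd133pos": 2.5e-5,
        "nl.hsc.cd133neg": 1.5e-5,
        "nl.epc.cd45pos": 1.2e-5,
        "nl.epc.cd45neg": 0.8e-5,
        "nl.cec": 2.0e-5,
    }
    for name, f in nl_freq.items():
        nonleuk[name] = f
        templates[name] = dict(nl_templates[name])
        sclass[name] = "nonleuk"

    # every leukocyte expresses CD45 unless the template overrides it
    for name, spec in templates.items():
        if not name.startswith("nl."):
            spec.setdefault("CD45", 30_000.0)

    total = sum(freq.values())
    freq = {k: v / total for k, v in freq.items()}
    return freq, nonleuk, templates, sclass


#: scatter (FSC, SSC) locations per scatter class, raw units
SCATTER_LOCATIONS: dict[str, tuple[float, float]] = {
    "PBL": (220_000.0, 30_000.0),
    "Mo": (330_000.0, 80_000.0),
    "Gr": (430_000.0, 250_000.0),
    "nonleuk": (230_000.0, 25_000.0),
}
#: per-leaf scatter overrides (basophils sit between PBL and monocytes,
#: DCs slightly above the lymphoid cloud)
SCATTER_OVERRIDES: dict[str, tuple[float, float]] = {
    "gr.baso": (240_000.0, 38_000.0),
    "dc.pdc": (250_000.0, 40_000.0),
    "dc.mdc1": (250_000.0, 40_000.0),
    "dc.mdc2": (250_000.0, 40_000.0),
}

DEBRIS_SCATTER = (35_000.0, 8_000.0)


def default_spillover() -> SpilloverMatrix:
    """Modest within-laser spillover typical for this fluorochrome set."""
    return SpilloverMatrix.from_pairs(
        {
            ("FL1", "FL2"): 0.08,
            ("FL2", "FL1"): 0.02,
            ("FL2", "FL3"): 0.05,
            ("FL2", "FL4"): 0.03,
            ("FL3", "FL4"): 0.05,
            ("FL4", "FL3"): 0.03,
            ("FL4", "FL5"): 0.04,
            ("FL5", "FL4"): 0.02,
            ("FL6", "FL7"): 0.03,
            ("FL7", "FL8"): 0.03,
            ("FL9", "FL10"): 0.04,
            ("FL10", "FL9"): 0.02,
        }
    )


@dataclass
class GroundTruthProfile:
    """The complete recipe for a synthetic donor: frequencies, marker
    templates, artifact rates and instrument model. The recovery target
    of every downstream test."""

    frequencies: dict[str, float]
    templates: dict[str, dict[str, TemplateSpec]]
    scatter_class: dict[str, str]
    nonleuk_frequencies: dict[str, float] = field(default_factory=dict)
    scatter_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    dead_fraction: float = 0.005
    debris_fraction: float = 0.02
    doublet_fraction: float = 0.02
    p12_debris_fraction: float = 0.08
    spread_scale: float = 1.0
    marker_sigma: float = 0.25
    scatter_fsc_sigma: float = 0.08
    scatter_ssc_sigma: float = 0.12
    pulse_jitter: float = 0.05
    noise_sd: float = 10.0
    dead_fsc_factor: float = 0.25
    p12_fsc_shift: float = 1.3
    leukocytes_per_ul: float = 6_000.0
    duration: float = 60.0
    spillover: SpilloverMatrix = field(default_factory=default_spillover)
    #: optional acquisition irregularity: (start_s, duration_s, rate_multiplier)
    burst: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.frequencies:
            total = sum(self.frequencies.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"leukocyte frequencies sum to {total!r}, not 1")
        for name, f in {**self.frequencies, **self.nonleuk_frequencies}.items():
            if not 0 <= f <= 1:
                raise ConfigurationError(f"frequency of {name!r} out of [0,1]")
        for frac in (self.dead_fraction, self.debris_fraction, self.doublet_fraction):
            if not 0 <= frac <= 1:
                raise ConfigurationError("artifact fractions must be in [0,1]")
        for name in self.all_leaves():
            if name not in self.templates:
                raise ConfigurationError(f"population {name!r} has no marker templates")
            if name not in self.scatter_class:
                raise ConfigurationError(f"population {name!r} has no scatter class")

    # -- structure ------------------------------------------------------
    def all_leaves(self) -> list[str]:
        return list(self.frequencies) + list(self.nonleuk_frequencies)

    def leaf_probability(self, name: str) -> float:
        """Fraction of intact single cells that carry this label."""
        nl_total = sum(self.nonleuk_frequencies.values())
        if name in self.nonleuk_frequencies:
            return self.nonleuk_frequencies[name]
        return self.frequencies[name] * (1.0 - nl_total)

    def major_frequencies(self) -> dict[str, float]:
        """True fractions of intact cells per major cell type."""
        prefix_major = {
            "t.": "T", "b.": "B", "nk.": "NK", "mo.": "Mo",
            "gr.neu": "Neu", "gr.eos": "Eos", "gr.baso": "Baso",
            "dc.": "DC", "other.": "RestPBL", "nl.": "NonLeuk",
        }
        out: dict[str, float] = {}
        for name in self.all_leaves():
            for prefix, major in prefix_major.items():
                if name.startswith(prefix):
                    out[major] = out.get(major, 0.0) + self.leaf_probability(name)
                    break
        out["Gr"] = out.get("Neu", 0.0) + out.get("Eos", 0.0)
        return out

    def check_panel(self, channel_map: Mapping[str, str]) -> None:
        """Raise if a panel stains a marker the profile cannot generate."""
        known = {m for spec in self.templates.values() for m in spec}
        known |= set(DERIVED_MARKERS) | {"CD45"}
        for comps in DERIVED_MARKERS.values():
            known |= set(comps)
        # any marker appearing in no template is still generatable at
        # background level, but an entirely unknown name is a config error
        universe = known | _MARKER_UNIVERSE
        for channel, marker in channel_map.items():
            if marker not in universe:
                raise ConfigurationError(
                    f"panel stains unknown marker {marker!r} in channel {channel}"
                )

    # -- variants ---------------------------------------------------------
    def zero_spread(self) -> "GroundTruthProfile":
        """Deterministic-intensity variant: no spread, no spillover, no
        artifacts. Gated fractions then equal label fractions exactly."""
        return replace(
            self,
            spread_scale=0.0,
            noise_sd=0.0,
            dead_fraction=0.0,
            debris_fraction=0.0,
            doublet_fraction=0.0,
            p12_debris_fraction=0.0,
            spillover=SpilloverMatrix.identity(),
            burst=None,
        )

    def with_frequencies(
        self,
        frequencies: dict[str, float],
        nonleuk: dict[str, float] | None = None,
    ) -> "GroundTruthProfile":
        return replace(
            self, frequencies=dict(frequencies), nonleuk_frequencies=dict(nonleuk or {})
        )

    def perturbed(self, sigma: float, rng: np.random.Generator) -> "GroundTruthProfile":
        """Multiplicative lognormal jitter on frequencies (replicate noise)."""
        if sigma == 0:
            return self
        jitter = {
            k: v * float(np.exp(sigma * rng.standard_normal()))
            for k, v in self.frequencies.items()
        }
        total = sum(jitter.values())
        jitter = {k: v / total for k, v in jitter.items()}
        nl = {
            k: min(1.0, v * float(np.exp(sigma * rng.standard_normal())))
            for k, v in self.nonleuk_frequencies.items()
        }
        return self.with_frequencies(jitter, nl)

    # -- config round-trip ------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "frequencies": {k: float(v) for k, v in self.frequencies.items()},
            "nonleuk_frequencies": {k: float(v) for k, v in self.nonleuk_frequencies.items()},
            "dead_fraction": self.dead_fraction,
            "debris_fraction": self.debris_fraction,
            "doublet_fraction": self.doublet_fraction,
            "leukocytes_per_ul": self.leukocytes_per_ul,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    def updated_from_yaml(self, path) -> "GroundTruthProfile":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        out = self
        if "frequencies" in doc:
            out = out.with_frequencies(doc["frequencies"], doc.get("nonleuk_frequencies"))
        for key in ("dead_fraction", "debris_fraction", "doublet_fraction", "leukocytes_per_ul"):
            if key in doc:
                out = replace(out, **{key: float(doc[key])})
        return out


#: all marker names the default generator knows about
_MARKER_UNIVERSE = {
    "CD3", "CD4", "CD8", "CD45RA", "CD197", "CD38", "CD127", "CD196", "CD183",
    "CD25", "TCRab", "TCRgd", "CD152", "CD19", "CD20", "CD24", "CD5", "CD27",
    "CD69", "CD80", "CD86", "CD279", "HLA-DR", "CD16", "CD16b", "CD56",
    "CD314", "CD94", "CD159a", "CD159c", "CD14", "CD64", "CD66", "CD123",
    "CD11c", "CD1c", "CD83", "CD274", "CD45", "CD146", "CD133", "CD34",
}


def build_default_profile(seed: int = 0) -> GroundTruthProfile:
    """The default synthetic donor.

    Frequencies are fixed at the midpoints of the normal ranges the assay
    is designed around; the seed only matters for explicitly requested
    jitter (see :meth:`GroundTruthProfile.perturbed`).
    """
    freq, nonleuk, templates, sclass = _default_leaves()
    return GroundTruthProfile(
        frequencies=freq,
        nonleuk_frequencies=nonleuk,
        templates=templates,
        scatter_class=sclass,
        scatter_overrides=dict(SCATTER_OVERRIDES),
    )


# ---------------------------------------------------------------------------
# event synthesis
# ---------------------------------------------------------------------------

def _panel_seed(master_seed: int, panel_id: str) -> np.random.Generator:
    # one master seed spawns an independent substream per panel, so adding
    # or dropping a panel never perturbs the events of the others
    digits = "".join(c for c in panel_id if c.isdigit())
    sub = int(digits) if digits else (abs(hash(panel_id)) % 1000 + 100)
    return np.random.default_rng(np.random.SeedSequence((int(master_seed), sub)))


def _draw_marker(
    rng: np.random.Generator, spec: TemplateSpec, n: int, sigma: float
) -> np.ndarray:
    def lognorm(loc: float) -> np.ndarray:
        if sigma == 0:
            return np.full(n, loc)
        return loc * np.exp(sigma * rng.standard_normal(n))

    if isinstance(spec, tuple):
        kind = spec[0]
        if kind != "bern":
            raise ConfigurationError(f"unknown template spec {spec!r}")
        p, pos_loc = spec[1], spec[2]
        neg_loc = spec[3] if len(spec) > 3 else NEG
        hot = rng.random(n) < p
        out = lognorm(neg_loc)
        if hot.any():
            out[hot] = lognorm(pos_loc)[hot]
        return out
    return lognorm(float(spec))


def _event_times(
    rng: np.random.Generator, n: int, duration: float, burst: tuple | None
) -> np.ndarray:
    if burst is None:
        return np.sort(rng.uniform(0.0, duration, n))
    start, length, mult = burst
    end = min(start + length, duration)
    w_out = duration - (end - start)
    w_in = (end - start) * mult
    p_in = w_in / (w_in + w_out)
    inside = rng.random(n) < p_in
    t = np.empty(n)
    t[inside] = rng.uniform(start, end, int(inside.sum()))
    u = rng.uniform(0.0, w_out, int((~inside).sum()))
    t[~inside] = np.where(u < start, u, u + (end - start))
    return np.sort(t)


def _needed_markers(channel_map: Mapping[str, str]) -> set[str]:
    needed: set[str] = set()
    for marker in channel_map.values():
        if marker in DERIVED_MARKERS:
            needed |= set(DERIVED_MARKERS[marker])
        else:
            needed.add(marker)
    return needed


def _synthesize_cells(
    profile: GroundTruthProfile,
    channel_map: Mapping[str, str],
    n_events: int,
    rng: np.random.Generator,
    fsc_shift: float,
    debris_fraction: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Build scatter block, FL block (true signals) and labels for all
    non-bead events, in leaf-block order (caller shuffles)."""
    leaves = profile.all_leaves()
    p_leaf = np.array([profile.leaf_probability(k) for k in leaves], dtype=float)
    if p_leaf.sum() <= 0:
        raise ConfigurationError("profile has no populations to draw from")
    p_leaf = p_leaf / p_leaf.sum()

    p_debris = debris_fraction
    p_dead = profile.dead_fraction
    p_doublet = profile.doublet_fraction
    p_intact = 1.0 - p_debris - p_dead - p_doublet
    if p_intact <= 0:
        raise ConfigurationError("artifact fractions leave no intact events")
    n_debris, n_dead, n_doublet = rng.multinomial(
        n_events, [p_debris, p_dead, p_doublet, p_intact]
    )[:3]
    n_intact = n_events - n_debris - n_dead - n_doublet

    # cell draws: intact + dead + 2 parents per doublet
    n_cells = n_intact + n_dead + 2 * n_doublet
    leaf_counts = rng.multinomial(n_cells, p_leaf)

    sigma_m = profile.marker_sigma * profile.spread_scale
    needed = sorted(_needed_markers(channel_map))
    marker_cols = {m: np.empty(n_cells) for m in needed}
    fsc = np.empty(n_cells)
    ssc = np.empty(n_cells)
    cell_labels: list[str] = []
    pos = 0
    for leaf_name, cnt in zip(leaves, leaf_counts):
        if cnt == 0:
            continue
        sl = slice(pos, pos + cnt)
        spec = profile.templates[leaf_name]
        for m in needed:
            marker_cols[m][sl] = _draw_marker(rng, spec.get(m, NEG), cnt, sigma_m)
        floc, sloc = profile.scatter_overrides.get(
            leaf_name, SCATTER_LOCATIONS[profile.scatter_class[leaf_name]]
        )
        sf = profile.scatter_fsc_sigma * profile.spread_scale
        ss = profile.scatter_ssc_sigma * profile.spread_scale
        fsc[sl] = floc * fsc_shift * (1.0 + sf * rng.standard_normal(cnt)) if sf else floc * fsc_shift
        ssc[sl] = sloc * (np.exp(ss * rng.standard_normal(cnt)) if ss else 1.0)
        cell_labels.extend([leaf_name] * cnt)
        pos += cnt
    fsc = np.clip(fsc, 1.0, RAW_SCALE_TOP)

    # shuffle the cell pool so the dead/doublet roles assigned below are
    # independent of the leaf-block build order
    perm = rng.permutation(n_cells)
    for m in needed:
        marker_cols[m] = marker_cols[m][perm]
    fsc = fsc[perm]
    ssc = ssc[perm]
    cell_labels = [cell_labels[i] for i in perm]

    # channel intensities (true, pre-spillover)
    fl_cols = list(FL_CHANNELS)
    fl = np.empty((n_cells, len(fl_cols)))
    bg_sigma = sigma_m
    for j, ch in enumerate(fl_cols):
        marker = channel_map.get(ch)
        if marker is None:
            fl[:, j] = _draw_marker(rng, NEG, n_cells, bg_sigma)
        elif marker in DERIVED_MARKERS:
            fl[:, j] = sum(marker_cols[c] for c in DERIVED_MARKERS[marker])
        else:
            fl[:, j] = marker_cols[marker]

    # pulse shape: width and height follow the area with small jitter
    jit = profile.pulse_jitter * profile.spread_scale

    def jitter(n: int) -> np.ndarray:
        return np.exp(jit * rng.standard_normal(n)) if jit else np.ones(n)

    # partition cells: intact | dead | doublet parents
    i0, i1, i2 = n_intact, n_intact + n_dead, n_cells
    labels = list(cell_labels[:i0])

    tof = fsc / 1000.0 * jitter(n_cells)
    peak = fsc / 8.0 * jitter(n_cells)

    # dead cells: reduced forward scatter, pulse shape scales along
    dead_f = profile.dead_fsc_factor
    fsc[i0:i1] *= dead_f
    tof[i0:i1] *= dead_f
    peak[i0:i1] *= dead_f
    labels.extend(["dead"] * n_dead)

    # doublets: areas add, width adds, height is the larger single height
    a, b = slice(i1, i1 + n_doublet), slice(i1 + n_doublet, i2)
    d_fsc = fsc[a] + fsc[b]
    d_ssc = ssc[a] + ssc[b]
    d_tof = tof[a] + tof[b]
    d_peak = np.maximum(peak[a], peak[b])
    d_fl = fl[a] + fl[b]
    labels.extend(["doublet"] * n_doublet)

    # debris: low scatter, background fluorescence
    deb_fsc = DEBRIS_SCATTER[0] * np.exp(
        0.18 * profile.spread_scale * rng.standard_normal(n_debris)
    )
    deb_ssc = DEBRIS_SCATTER[1] * np.exp(
        0.15 * profile.spread_scale * rng.standard_normal(n_debris)
    )
    deb_tof = deb_fsc / 1000.0 * jitter(n_debris)
    deb_peak = deb_fsc / 8.0 * jitter(n_debris)
    deb_fl = np.column_stack(
        [_draw_marker(rng, NEG, n_debris, bg_sigma) for _ in fl_cols]
    ) if n_debris else np.empty((0, len(fl_cols)))
    labels.extend(["debris"] * n_debris)

    scatter = np.column_stack(
        [
            np.concatenate([fsc[:i1], d_fsc, deb_fsc]),
            np.concatenate([tof[:i1], d_tof, deb_tof]),
            np.concatenate([peak[:i1], d_peak, deb_peak]),
            np.concatenate([ssc[:i1], d_ssc, deb_ssc]),
        ]
    )
    fl_all = np.vstack([fl[:i1], d_fl, deb_fl])
    return scatter, fl_all, np.array(labels, dtype=object), fl_cols


def _finalize_table(
    profile: GroundTruthProfile,
    scatter: np.ndarray,
    fl_true: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    panel_id: str,
    channel_map: Mapping[str, str],
    volume_ul: float,
    truth: dict,
) -> EventTable:
    n = len(labels)
    order = rng.permutation(n)
    scatter = scatter[order]
    fl_true = fl_true[order]
    labels = labels[order]

    observed = fl_true @ profile.spillover.matrix
    if profile.noise_sd > 0:
        observed = observed + profile.noise_sd * rng.standard_normal(observed.shape)

    times = _event_times(rng, n, profile.duration, profile.burst)
    data = pd.DataFrame(
        np.column_stack([times, scatter, observed]),
        columns=[TIME, FSC_INT, FSC_TOF, FSC_PEAK, SSC, *FL_CHANNELS],
    )
    return EventTable(
        data=data,
        panel_id=panel_id,
        sample_id="synthetic",
        channel_map={ch: m for ch, m in channel_map.items()},
        duration=profile.duration,
        volume_ul=volume_ul,
        labels=labels,
        truth=truth,
        spillover=profile.spillover,
    )


def simulate_panel_acquisition(
    profile: GroundTruthProfile,
    panel,
    n_events: int,
    seed: int,
) -> EventTable:
    """Simulate one stained-panel acquisition.

    ``panel`` provides ``panel_id``, ``channel_map`` and ``volume_ul``
    (duck-typed; a mapping with those keys also works). Bit-identical for
    identical ``(profile, panel, n_events, seed)``.
    """
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    if isinstance(panel, Mapping):
        panel_id = panel["panel_id"]
        channel_map = panel["channel_map"]
        volume = panel.get("volume_ul", 100.0)
        uncentrifuged = bool(panel.get("uncentrifuged", False))
    else:
        panel_id = panel.panel_id
        channel_map = panel.channel_map
        volume = getattr(panel, "volume_ul", 100.0)
        uncentrifuged = bool(getattr(panel, "uncentrifuged", False))
    profile.check_panel(channel_map)

    rng = _panel_seed(seed, panel_id)
    fsc_shift = profile.p12_fsc_shift if uncentrifuged else 1.0
    debris = profile.p12_debris_fraction if uncentrifuged else profile.debris_fraction
    scatter, fl_true, labels, _ = _synthesize_cells(
        profile, channel_map, n_events, rng, fsc_shift, debris
    )
    truth = {
        "frequencies": {k: profile.leaf_probability(k) for k in profile.all_leaves()},
        "major_frequencies": profile.major_frequencies(),
    }
    return _finalize_table(
        profile, scatter, fl_true, labels, rng, panel_id, channel_map, volume, truth
    )


def simulate_trucount_acquisition(
    profile: GroundTruthProfile,
    bead_config: BeadConfig,
    acquired_fraction: float = 1.0,
    seed: int = 0,
    channel_map: Mapping[str, str] | None = None,
) -> EventTable:
    """Simulate the uncentrifuged counting tube: cells plus counting beads.

    The expected number of acquired beads is ``beads_per_tube x
    acquired_fraction``; bead doublets (doubled forward scatter, identical
    side scatter) occur at the configured fraction of bead events. The
    hidden truth records the true cells/µL of every major cell type.
    """
    if not 0 < acquired_fraction <= 1:
        raise ValueError("acquired_fraction must be in (0, 1]")
    if channel_map is None:
        channel_map = {"FL1": "CD19/20", "FL2": "CD16b", "FL4": "CD56", "FL5": "CD45", "FL9": "CD3"}
    profile.check_panel(channel_map)
    rng = _panel_seed(seed, "P12")

    # --- cells ---------------------------------------------------------
    n_cells_intact = int(round(profile.leukocytes_per_ul * bead_config.blood_volume_ul * acquired_fraction))
    # artifacts ride on top of the intact count
    denom = 1.0 - profile.p12_debris_fraction - profile.dead_fraction - profile.doublet_fraction
    n_cell_events = max(int(round(n_cells_intact / denom)), 1)
    scatter, fl_true, labels, _ = _synthesize_cells(
        profile, channel_map, n_cell_events, rng, profile.p12_fsc_shift,
        profile.p12_debris_fraction,
    )

    # --- beads ---------------------------------------------------------
    if acquired_fraction < 1.0:
        n_beads = int(rng.binomial(bead_config.beads_per_tube, acquired_fraction))
    else:
        n_beads = bead_config.beads_per_tube
    dr = bead_config.doublet_rate
    n_events_beads = int(round(n_beads / (1.0 + dr)))
    n_dbl = int(round(n_events_beads * dr))
    n_sgl = n_beads - 2 * n_dbl
    n_bead_events = n_sgl + n_dbl

    cv = bead_config.scatter_cv * (1.0 if profile.spread_scale else 0.0)
    fcv = bead_config.fluorescence_cv * (1.0 if profile.spread_scale else 0.0)

    def beadvals(loc: float, n: int, s: float) -> np.ndarray:
        return loc * np.exp(s * rng.standard_normal(n)) if s else np.full(n, loc)

    b_fsc = beadvals(bead_config.fsc_location, n_bead_events, cv)
    b_fsc[n_sgl:] *= 2.0  # doublets: doubled FSC at the same SSC
    b_ssc = beadvals(bead_config.ssc_location, n_bead_events, cv)
    b_tof = b_fsc / 1000.0
    b_peak = np.concatenate([b_fsc[:n_sgl] / 8.0, b_fsc[n_sgl:] / 16.0])
    b_fl = np.empty((n_bead_events, len(FL_CHANNELS)))
    for j, ch in enumerate(FL_CHANNELS):
        if ch in bead_config.channels:
            b_fl[:, j] = beadvals(bead_config.fluorescence_location, n_bead_events, fcv)
            b_fl[n_sgl:, j] *= 2.0
        else:
            b_fl[:, j] = NEG
    b_scatter = np.column_stack([b_fsc, b_tof, b_peak, b_ssc])
    b_labels = np.array(["bead"] * n_sgl + ["bead_doublet"] * n_dbl, dtype=object)

    scatter = np.vstack([scatter, b_scatter])
    fl_true = np.vstack([fl_true, b_fl])
    labels = np.concatenate([labels, b_labels])

    majors = profile.major_frequencies()
    cells_per_ul = {
        major: profile.leukocytes_per_ul * frac for major, frac in majors.items()
    }
    truth = {
        "cells_per_ul": cells_per_ul,
        "leukocytes_per_ul": profile.leukocytes_per_ul,
        "beads_acquired": n_beads,
        "bead_events": {"singlets": n_sgl, "doublets": n_dbl},
        "acquired_fraction": acquired_fraction,
        "major_frequencies": majors,
    }
    return _finalize_table(
        profile, scatter, fl_true, labels, rng, "P12", channel_map,
        bead_config.blood_volume_ul, truth,
    )
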