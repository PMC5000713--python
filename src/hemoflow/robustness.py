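"""Replicate-based assay robustness: per-population CV and its summary.

Robustness is quantified by processing the same (synthetic) donor several
times independently, re-running the full analysis on each replicate and
computing the coefficient of variation (CV in %: standard deviation /
mean x 100) of every reported population. Populations with fewer than
100 events in any replicate carry no informative value and are excluded
before summarizing; the summary bins the remaining CVs into <5%, 5–10%,
10–15% and >=15% (a CV of exactly 5 falls in the 5–10 band).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import BeadConfig, GroundTruthProfile

MIN_EVENTS = 100


def cv(values) -> float:
    """Coefficient of variation in percent (sample sd, n-1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least two replicate values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(arr.std(ddof=1) / mean * 100.0)


def validity_filter(
    counts_per_replicate, min_events: int = MIN_EVENTS, mode: str = "any"
) -> np.ndarray:
    """Validity flags for populations from their replicate event counts.

    ``counts_per_replicate`` is (n_populations, n_replicates). With
    ``mode='any'`` (default, strictest) a population is invalid if any
    replicate falls below ``min_events``; ``mode='mean'`` uses the
    replicate mean instead. The threshold itself is still valid
    ("less than 100" excludes only counts below 100).
    """
    arr = np.atleast_2d(np.asarray(counts_per_replicate, dtype=float))
    if mode == "any":
        return (arr >= min_events).all(axis=1)
    if mode == "mean":
        return arr.mean(axis=1) >= min_events
    raise ValueError(f"unknown validity mode {mode!r}")


@dataclass
class CvBins:
    """Fractions of valid populations per CV band (percent)."""

    n: int
    lt5: float
    lt10: float  # cumulative, includes lt5
    from10to15: float
    ge15: float

    def counts(self) -> dict[str, int]:
        return {
            "lt5": round(self.lt5 * self.n / 100),
            "5to10": round((self.lt10 - self.lt5) * self.n / 100),
            "10to15": round(self.from10to15 * self.n / 100),
            "ge15": round(self.ge15 * self.n / 100),
        }


def cv_summary(cvs) -> CvBins:
    """Bin the CVs of the valid populations."""
    arr = np.asarray(cvs, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("cv_summary needs at least one valid CV")
    n = arr.size
    lt5 = (arr < 5).sum() / n * 100
    lt10 = (arr < 10).sum() / n * 100
    b1015 = ((arr >= 10) & (arr < 15)).sum() / n * 100
    ge15 = (arr >= 15).sum() / n * 100
    return CvBins(n=n, lt5=lt5, lt10=lt10, from10to15=b1015, ge15=ge15)


@dataclass
class RobustnessSummary:
    """Per-population replicate values, CVs and the binned summary."""

    table: pd.DataFrame  # one row per population
    n_replicates: int
    bins: CvBins
    total_populations: int
    excluded_populations: int

    @property
    def valid_populations(self) -> int:
        return self.total_populations - self.excluded_populations

    def to_json_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "total_populations": self.total_populations,
            "excluded_populations": self.excluded_populations,
            "valid_populations": self.valid_populations,
            "cv_bins_pct": {
                "lt5": self.bins.lt5,
                "lt10_cumulative": self.bins.lt10,
                "10to15": self.bins.from10to15,
                "ge15": self.bins.ge15,
            },
        }


def replicate_experiment(
    profile: GroundTruthProfile,
    n_replicates: int = 3,
    noise_sigma: float = 0.02,
    n_events: int = 50_000,
    seed: int = 0,
    schemas=None,
    bead_config: BeadConfig | None = None,
    identical_replicates: bool = False,
    validity_mode: str = "any",
) -> RobustnessSummary:
    """Simulate and analyze replicate acquisitions of one donor.

    Each replicate perturbs the profile's population frequencies by a
    multiplicative lognormal factor (``noise_sigma``; 0 keeps only
    counting noise), simulates all selected panels independently and runs
    the full pipeline. ``identical_replicates=True`` reuses the same seed
    for every replicate (a pipeline-determinism control: all CVs are 0).
    """
    from .panels import build_diob_schema
    from .pipeline import analyze_sample, simulate_sample

    if schemas is None:
        schemas = build_diob_schema()
    bead_config = bead_config or BeadConfig()
    master = np.random.default_rng(seed)

    per_rep: list[dict[tuple[str, str], tuple[float, int]]] = []
    for _ in range(n_replicates):
        rep_seed = seed if identical_replicates else int(master.integers(2**31 - 1))
        prof_r = profile.perturbed(noise_sigma, master) if noise_sigma else profile
        tables = simulate_sample(prof_r, schemas, n_events=n_events, seed=rep_seed,
                                 bead_config=bead_config)
        report = analyze_sample(tables, schemas, bead_config=bead_config)
        values: dict[tuple[str, str], tuple[float, int]] = {}
        for stat in report.all_stats():
            values[(stat.panel_id, stat.name)] = (stat.pct_parent, stat.count)
        per_rep.append(values)

    keys = list(per_rep[0])
    rows = []
    for key in keys:
        vals = np.array([per_rep[r][key][0] for r in range(n_replicates)])
        counts = np.array([per_rep[r][key][1] for r in range(n_replicates)])
        valid = bool(validity_filter(counts[None, :], mode=validity_mode)[0])
        mean = float(vals.mean())
        if valid and mean > 0:
            value_cv = cv(vals)
        else:
            value_cv = float("nan")
        rows.append({
            "panel": key[0],
            "population": key[1],
            **{f"rep{r + 1}_pct": vals[r] for r in range(n_replicates)},
            **{f"rep{r + 1}_events": int(counts[r]) for r in range(n_replicates)},
            "mean_pct": mean,
            "mean_events": float(counts.mean()),
            "cv_pct": value_cv,
            "valid": valid,
        })
    table = pd.DataFrame(rows)
    valid_cvs = table.loc[table["valid"], "cv_pct"].to_numpy()
    bins = cv_summary(valid_cvs)
    return RobustnessSummary(
        table=table,
        n_replicates=n_replicates,
        bins=bins,
        total_populations=len(table),
        excluded_populations=int((~table["valid"]).sum()),
    )


def binomial_cv_prediction(pct_parent: float, parent_events: float) -> float:
    """Expected CV (%) of a gated fraction under pure counting noise.

    For a population that is a binomial draw of probability p out of n
    parent events, CV(p_hat) = 100 x sqrt((1-p)/(p n)).
    """
    p = pct_parent / 100.0
    if p <= 0 or parent_events <= 0:
        return float("inf")
    return 100.0 * float(np.sqrt((1.0 - p) / (p * parent_events)))
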