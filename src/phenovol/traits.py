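"""Digital Biovolume (DB) and Digital Biovolume Ratio (DBR) time series.

The digital biovolume is a pixel-based proxy for above-ground plant mass
computed from two orthogonal side views and one top view:

    DB = s0 + s90 + log(top / top_divisor)

with the side-view pixel sums entering linearly and the top view through a
logarithm (default natural log, divisor 3).  The published typography of the
index is ambiguous about the grouping of the top-view term; the literal
reading log(top-sum / 3) is implemented, with the divisor and the log base
configurable.  The log term is numerically negligible against the side sums,
so any reading preserves downstream conclusions.

The DBR compares a treated group to its control on cell means:
DBR = mean DB (treated) / mean DB (control), per genotype (or arm) per day.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class PixelCounts(NamedTuple):
    """Foreground pixel sums of the three views of one plant at one time."""

    s0: int
    s90: int
    top: int


@dataclass(frozen=True)
class DBConfig:
    """log base ('natural' or '10'), top-view divisor, and the policy for a
    zero top-view count ('omit_term' keeps DB = s0 + s90; 'error' raises)."""

    log_base: str = "natural"
    top_divisor: float = 3.0
    zero_top_policy: str = "omit_term"

    def __post_init__(self) -> None:
        if self.log_base not in ("natural", "10"):
            raise ValueError(f"log_base must be 'natural' or '10', got {self.log_base!r}")
        if not self.top_divisor > 0:
            raise ValueError("top_divisor must be > 0")
        if self.zero_top_policy not in ("omit_term", "error"):
            raise ValueError(f"unknown zero_top_policy {self.zero_top_policy!r}")


def compute_db(counts: PixelCounts | tuple[int, int, int],
               cfg: DBConfig = DBConfig()) -> float:
    """Digital biovolume of one plant at one time point."""
    s0, s90, top = counts
    if s0 < 0 or s90 < 0 or top < 0:
        raise ValueError(f"pixel counts must be >= 0, got {counts}")
    if top == 0:
        if cfg.zero_top_policy == "error":
            raise ValueError("top view count is 0")
        logger.debug("top view count 0: log term omitted (pre-emergence?)")
        return float(s0 + s90)
    log = math.log if cfg.log_base == "natural" else math.log10
    return float(s0 + s90 + log(top / cfg.top_divisor))


def _db_column(counts: pd.DataFrame, cfg: DBConfig) -> np.ndarray:
    s = counts["s0"].to_numpy(float) + counts["s90"].to_numpy(float)
    top = counts["top"].to_numpy(float)
    if np.any((counts[["s0", "s90", "top"]] < 0).to_numpy()):
        raise ValueError("pixel counts must be >= 0")
    zero = top == 0
    if zero.any() and cfg.zero_top_policy == "error":
        raise ValueError("top view count is 0 for some rows")
    with np.errstate(divide="ignore"):
        term = np.log(top / cfg.top_divisor)
        if cfg.log_base == "10":
            term = term / math.log(10)
    term[zero] = 0.0
    if zero.any():
        logger.debug("%d rows with top = 0: log term omitted", int(zero.sum()))
    return s + term


def db_series(counts: pd.DataFrame, plants: pd.DataFrame,
              cfg: DBConfig = DBConfig()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant-level DB records plus per-(genotype, treatment, day) summaries.

    ``counts`` needs columns plant_id, day, s0, s90, top; ``plants`` maps
    plant_id to genotype, treatment and replicate.  Missing replicates reduce
    the cell n; nothing is imputed, and the sd of a singleton cell is missing.
    """
    unknown = set(counts["plant_id"]) - set(plants["plant_id"])
    if unknown:
        raise ValueError(f"counts reference unknown plant_id(s): {sorted(unknown)[:5]}")
    traits = counts.merge(
        plants[["plant_id", "genotype", "treatment", "replicate"]],
        on="plant_id", how="left")
    traits["db"] = _db_column(traits, cfg)
    traits = traits[["plant_id", "genotype", "treatment", "replicate",
                     "day", "db"]].sort_values(
        ["genotype", "treatment", "replicate", "day"],
        kind="stable").reset_index(drop=True)
    summary = (traits.groupby(["genotype", "treatment", "day"], sort=False)
               ["db"].agg(mean="mean", sd=lambda v: v.std(ddof=1), n="size")
               .reset_index())
    return traits, summary


def compute_dbr(db_treated_mean: float, db_control_mean: float) -> float:
    """Digital biovolume ratio: treated cell mean over control cell mean."""
    if not db_control_mean > 0:
        raise ValueError(f"control mean must be > 0, got {db_control_mean}")
    return float(db_treated_mean) / float(db_control_mean)


def _pivot_ratio(summary: pd.DataFrame, num: pd.DataFrame, den: pd.DataFrame,
                 index: str) -> pd.DataFrame:
    num_m = num.pivot(index=index, columns="day", values="mean")
    den_m = den.pivot(index=index, columns="day", values="mean")
    den_m = den_m.reindex(index=num_m.index, columns=num_m.columns)
    if (den_m <= 0).any().any():
        bad = den_m.le(0).stack()
        bad = bad[bad].index.tolist()[:5]
        raise ValueError(f"non-positive control means at {bad}")
    return num_m / den_m


def dbr_table(summary: pd.DataFrame, *, control_treatment: str | None = None,
              treated_treatment: str | None = None,
              control_genotype: str | None = None) -> pd.DataFrame:
    """Genotype (or arm) x day DBR matrix from a db_series summary.

    Factorial designs: pass ``control_treatment`` (and optionally
    ``treated_treatment`` when more than two treatments exist); the ratio is
    taken per genotype across treatments.  Single-treatment multi-arm designs:
    pass ``control_genotype``; every arm (including the control itself, which
    is identically 1) is divided by the control arm, day by day.
    """
    if (control_treatment is None) == (control_genotype is None):
        raise ValueError("pass exactly one of control_treatment / control_genotype")
    if control_treatment is not None:
        others = [t for t in summary["treatment"].unique()
                  if t != control_treatment]
        if treated_treatment is None:
            if len(others) != 1:
                raise ValueError(
                    f"ambiguous treated treatment among {others}; specify one")
            treated_treatment = others[0]
        num = summary[summary["treatment"] == treated_treatment]
        den = summary[summary["treatment"] == control_treatment]
        ratio = _pivot_ratio(summary, num, den, "genotype")
        ratio = ratio.reindex([g for g in summary["genotype"].unique()
                               if g in ratio.index])
    else:
        den_rows = summary[summary["genotype"] == control_genotype]
        num_m = summary.pivot_table(index="genotype", columns="day",
                                    values="mean", aggfunc="mean", sort=False)
        den_m = den_rows.pivot(index="genotype", columns="day", values="mean")
        if den_m.empty:
            raise ValueError(f"control genotype {control_genotype!r} not found")
        den_v = den_m.iloc[0].reindex(num_m.columns)
        if (den_v <= 0).any():
            raise ValueError("non-positive control means")
        ratio = num_m.div(den_v, axis=1)
    ratio.index.name = "genotype"
    return ratio
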