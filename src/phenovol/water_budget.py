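"""Per-pot water bookkeeping, water-use efficiency and the WUE-ratio heatmap.

Evapotranspiration is reconstructed from consecutive weighings: the loss over
an interval is the post-irrigation weight at its start minus the pre-irrigation
weight at its end, which conserves mass under partial refills.  Bare-soil
control pots give a per-interval evaporation baseline; subtracting it isolates
transpiration.  Two accounting modes are provided because trials without bare
pots (the wheat screen) can only use whole-pot evapotranspiration:

* ``subtract_evap`` — Tr_i = max(loss_i - evap_i, 0), then cumulated;
* ``evapotranspiration`` — raw losses cumulated (evaporation included).

Water-use efficiency over a window [t0, tn] is the digital-biovolume gain per
gram of water used:

    WUE = (DB_tn - DB_t0) / sum of Tr over [t0, tn]

in pixels per gram; no absolute-biomass conversion is applied.  The WUE ratio
(stressed / control, per genotype per day) is classed green when >= 1
(efficiency maintained under stress) and red when < 1, the boundary landing on
the green side as in the published legend (green spans 1.32 down to 1).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import WeightSeries

logger = logging.getLogger(__name__)

MODES = ("subtract_evap", "evapotranspiration")


# ---------------------------------------------------------------------------
# interval bookkeeping
# ---------------------------------------------------------------------------

def interval_losses(ws: WeightSeries) -> pd.DataFrame:
    """Per-interval evapotranspiration (g) from consecutive weighings.

    Returns one row per interval with columns ``day_start, day_end, loss_g,
    clipped``; negative raw losses (scale noise, condensation) are clipped to
    zero and flagged.
    """
    d = np.asarray(ws.days, dtype=float)
    if d.size < 2:
        raise ValueError(f"pot {ws.pot_id}: need at least 2 weighings")
    if np.any(np.diff(d) <= 0):
        raise ValueError(f"pot {ws.pot_id}: unordered weighing days")
    raw = np.asarray(ws.weight_post_g[:-1]) - np.asarray(ws.weight_pre_g[1:])
    clipped = raw < 0
    if clipped.any():
        logger.warning("pot %s: %d negative interval loss(es) clipped to 0",
                       ws.pot_id, int(clipped.sum()))
    return pd.DataFrame({
        "day_start": d[:-1], "day_end": d[1:],
        "loss_g": np.maximum(raw, 0.0), "clipped": clipped,
    })


def evaporation_baseline(bare_series: Sequence[WeightSeries],
                         days: Sequence[float]) -> np.ndarray:
    """Per-interval mean bare-soil evaporation (g) across bare pots.

    ``days`` are the weighing days shared by all pots; with no bare pots
    (the wheat trial) a zero baseline is returned with a warning.
    """
    d = np.asarray(days, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 days for an interval baseline")
    if len(bare_series) == 0:
        warnings.warn("no bare-soil pots: evaporation baseline set to zero "
                      "(losses are whole-pot evapotranspiration)", stacklevel=2)
        return np.zeros(d.size - 1)
    losses = []
    for ws in bare_series:
        if not np.array_equal(np.asarray(ws.days, float), d):
            raise ValueError(f"bare pot {ws.pot_id}: weighing days misaligned")
        losses.append(interval_losses(ws)["loss_g"].to_numpy())
    return np.mean(losses, axis=0)


def cumulative_transpiration(losses: Sequence[float],
                             evap_baseline: Sequence[float],
                             mode: str = "subtract_evap") -> np.ndarray:
    """Cumulative transpiration series (g), one value per interval end."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    lo = np.asarray(losses, dtype=float)
    ev = np.asarray(evap_baseline, dtype=float)
    if lo.shape != ev.shape:
        raise ValueError(f"length mismatch: {lo.shape} losses vs {ev.shape} baseline")
    tr = lo if mode == "evapotranspiration" else np.maximum(lo - ev, 0.0)
    return np.cumsum(tr)


def compute_wue(db_t0: float, db_tn: float, cum_transpiration_tn: float,
                pot_id: str = "?") -> float:
    """WUE over [t0, tn]: biovolume gain per gram of water (may be negative
    when the plant shrinks under late drought; reported as-is)."""
    if not cum_transpiration_tn > 0:
        raise ValueError(
            f"pot {pot_id}: cumulative transpiration must be > 0, "
            f"got {cum_transpiration_tn}")
    return (float(db_tn) - float(db_t0)) / float(cum_transpiration_tn)


def heat_class(ratio: float) -> str:
    """Heatmap class of a WUE ratio: 'green' for >= 1, 'red' for < 1."""
    if not np.isfinite(ratio):
        return ""
    return "green" if ratio >= 1.0 else "red"


def wue_ratio(wue_stress: float, wue_control: float) -> tuple[float, str]:
    """Stress-to-control WUE ratio and its heatmap class; a zero control WUE
    flags the record as missing (nan, '') rather than erroring."""
    if wue_control == 0:
        logger.warning("zero control WUE: ratio flagged missing")
        return float("nan"), ""
    r = float(wue_stress) / float(wue_control)
    return r, heat_class(r)


# ---------------------------------------------------------------------------
# table-level pipeline
# ---------------------------------------------------------------------------

def wue_table(traits: pd.DataFrame, weights: Mapping[str, WeightSeries],
              plants: pd.DataFrame, *, t0: float,
              mode: str | None = None) -> pd.DataFrame:
    """Per-plant WUE at every weighing day after ``t0``.

    ``traits`` is the plant-level DB table (plant_id, genotype, treatment,
    day, db), ``weights`` maps pot_id to its series (bare pots included).
    ``mode`` defaults to ``subtract_evap`` when bare pots exist and
    ``evapotranspiration`` otherwise.  ``t0`` snaps forward to the first
    observed day at or after the requested value (stress may be imposed
    between two imaging days).
    """
    obs_days = np.sort(traits["day"].unique())
    at_or_after = obs_days[obs_days >= t0]
    if at_or_after.size == 0:
        raise ValueError(f"no observation day at or after t0={t0}")
    t0 = float(at_or_after[0])
    bare = [ws for ws in weights.values() if ws.is_bare]
    if mode is None:
        mode = "subtract_evap" if bare else "evapotranspiration"
    pot_of = dict(zip(plants["plant_id"], plants["pot_id"]))
    db_lookup = {(r.plant_id, r.day): r.db for r in traits.itertuples()}
    meta = plants.set_index("plant_id")

    rows = []
    baseline_cache: dict[tuple, np.ndarray] = {}
    for plant_id in plants["plant_id"]:
        ws = weights.get(pot_of[plant_id])
        if ws is None:
            logger.warning("plant %s: no weight series; skipped", plant_id)
            continue
        days = np.asarray(ws.days, dtype=float)
        key = tuple(days)
        if key not in baseline_cache:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                baseline_cache[key] = evaporation_baseline(bare, days) if bare \
                    else np.zeros(days.size - 1)
        ev = baseline_cache[key]
        losses = interval_losses(ws)["loss_g"].to_numpy()
        # restrict the budget window to intervals starting at or after t0
        sel = days[1:] > t0
        cum = cumulative_transpiration(losses[sel], ev[sel], mode)
        db0 = db_lookup.get((plant_id, float(t0)))
        if db0 is None:
            logger.warning("plant %s: no DB at t0=%g; skipped", plant_id, t0)
            continue
        g = meta.loc[plant_id, "genotype"]
        tr = meta.loc[plant_id, "treatment"]
        for day, c in zip(days[1:][sel], cum):
            dbn = db_lookup.get((plant_id, float(day)))
            if dbn is None or c <= 0:
                continue
            rows.append((plant_id, g, tr, day,
                         compute_wue(db0, dbn, c, pot_id=plant_id)))
    return pd.DataFrame(rows, columns=[
        "plant_id", "genotype", "treatment", "day", "wue"])


def wue_summary(wue: pd.DataFrame) -> pd.DataFrame:
    """Cell means of plant-level WUE per (genotype, treatment, day)."""
    return (wue.groupby(["genotype", "treatment", "day"], sort=False)["wue"]
            .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="size")
            .reset_index())


def wue_ratio_table(summary: pd.DataFrame, *,
                    control_treatment: str | None = None,
                    stress_treatment: str | None = None,
                    control_genotype: str | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype (or arm) x day WUE-ratio matrix plus its green/red class matrix.

    Mirrors :func:`phenovol.traits.dbr_table`: across treatments for factorial
    designs, against a reference arm for single-treatment designs.  Cells with
    a zero control WUE are missing, not zero.
    """
    if (control_treatment is None) == (control_genotype is None):
        raise ValueError("pass exactly one of control_treatment / control_genotype")
    if control_treatment is not None:
        others = [t for t in summary["treatment"].unique()
                  if t != control_treatment]
        if stress_treatment is None:
            if len(others) != 1:
                raise ValueError(f"ambiguous stress treatment among {others}")
            stress_treatment = others[0]
        num = summary[summary["treatment"] == stress_treatment].pivot(
            index="genotype", columns="day", values="mean")
        den = summary[summary["treatment"] == control_treatment].pivot(
            index="genotype", columns="day", values="mean")
        den = den.reindex(index=num.index, columns=num.columns)
        order = [g for g in summary["genotype"].unique() if g in num.index]
        num = num.reindex(order)
        den = den.reindex(order)
    else:
        num = summary.pivot_table(index="genotype", columns="day",
                                  values="mean", aggfunc="mean", sort=False)
        den_rows = summary[summary["genotype"] == control_genotype].pivot(
            index="genotype", columns="day", values="mean")
        if den_rows.empty:
            raise ValueError(f"control genotype {control_genotype!r} not found")
        den = pd.DataFrame(np.tile(den_rows.iloc[0].reindex(num.columns)
                                   .to_numpy(), (len(num.index), 1)),
                           index=num.index, columns=num.columns)
    ratio = num / den.where(den != 0)
    classes = ratio.map(lambda r: heat_class(r) if pd.notna(r) else "")
    ratio.index.name = classes.index.name = "genotype"
    return ratio, classes


def export_heatmap(ratio: pd.DataFrame, out_csv: str | Path,
                   classes: pd.DataFrame | None = None,
                   class_csv: str | Path | None = None,
                   plot_path: str | Path | None = None) -> None:
    """Write the genotype x day WUE-ratio matrix (CSV is the contract; the
    PNG heatmap is a convenience).  Missing cells stay empty, not zero."""
    if ratio.empty:
        raise ValueError("empty WUE ratio table")
    ratio.to_csv(out_csv, float_format="%.6g")
    if classes is not None and class_csv is not None:
        classes.to_csv(class_csv)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(max(6, 0.25 * ratio.shape[1]),
                                        max(4, 0.22 * ratio.shape[0])))
        im = ax.imshow(ratio.to_numpy(float), aspect="auto", cmap="RdYlGn",
                       vmin=0.52, vmax=1.32)
        ax.set_yticks(range(len(ratio.index)), ratio.index, fontsize=6)
        ax.set_xticks(range(len(ratio.columns)),
                      [f"{c:g}" for c in ratio.columns], fontsize=6, rotation=90)
        ax.set_xlabel("day")
        fig.colorbar(im, ax=ax, label="WUE ratio")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)


# ---------------------------------------------------------------------------
# weights.csv I/O
# ---------------------------------------------------------------------------

def read_weights(path: str | Path) -> dict[str, WeightSeries]:
    """Read a weights.csv (pot_id, day, weight_pre_g, weight_post_g, is_bare,
    fc_weight[, target_fraction]) into per-pot series."""
    df = pd.read_csv(path, comment="#")
    required = {"pot_id", "day", "weight_pre_g", "weight_post_g",
                "is_bare", "fc_weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    out = {}
    for pot_id, sub in df.groupby("pot_id", sort=False):
        sub = sub.sort_values("day", kind="stable")
        n = len(sub)
        out[str(pot_id)] = WeightSeries(
            pot_id=str(pot_id),
            is_bare=bool(sub["is_bare"].iloc[0]),
            fc_weight=float(sub["fc_weight"].iloc[0]),
            days=sub["day"].to_numpy(float),
            weight_pre_g=sub["weight_pre_g"].to_numpy(float),
            weight_post_g=sub["weight_post_g"].to_numpy(float),
            target_fraction=(sub["target_fraction"].to_numpy(float)
                             if "target_fraction" in sub else np.ones(n)),
            true_evap_g=np.full(max(n - 1, 0), np.nan),
            true_transp_g=np.full(max(n - 1, 0), np.nan),
            truncated=np.zeros(max(n - 1, 0), dtype=bool),
        )
    return out
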