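"""Seeded synthetic phenotyping experiments.

Generates complete pot experiments — logistic growth trajectories, gravimetric
pot-weight logs with irrigation events, and renderable multi-view plant images
with exact ground-truth masks — matching the statistical structure of two
greenhouse trials:

* ``wheat_ssd``: a durum-wheat drought screen, 36 single-seed-descent genotypes
  plus 3 named varieties x {control, drought} x 3 replicates, imaged every
  2 days from 55 to 147 days after sowing (DAS), water withheld to ~50% field
  capacity from 104 DAS.
* ``tomato_rwm``: a tomato biostimulant screen under reduced water management,
  7 arms (untreated control + 6 prototypes) x 5 replicates at 70% field
  capacity for 22 days after treatment (DAT), with 10 bare-soil evaporation
  pots.

Everything is driven by a single integer seed; identical seeds and
configurations produce identical bundles.  The per-plant observation-noise
stream is keyed by (genotype, replicate, day) and *shared across treatments*
(common random numbers), so that before stress imposition a drought plant and
its control twin are exactly identical and any treatment contrast reflects the
treatment alone.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: fraction of the side-view projected area shown by the top view (erect habit)
TOP_VIEW_FRACTION = 0.3
#: pot weight below this fraction of field capacity is unphysical (dry-soil floor)
DRY_FLOOR_FRACTION = 0.4

VIEWS = ("side0", "side90", "top")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth of projected plant area with a piecewise stress factor.

    Parameters
    ----------
    K : float
        Asymptotic projected area, pixels.
    r : float
        Relative growth rate, per day.
    t_mid : float
        Inflection day of the unstressed trajectory.
    treatment_factor : float
        Multiplier in (0, 1] applied to both K and r after ``stress_start_day``.
    stress_start_day : float or None
        Day at which the factor kicks in; ``None`` disables stress.
    cv_noise : float
        Lognormal coefficient of variation of the per-observation multiplicative
        noise (biological + measurement scatter).
    """

    K: float
    r: float
    t_mid: float
    treatment_factor: float = 1.0
    stress_start_day: float | None = None
    cv_noise: float = 0.05

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if not self.r > 0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if not 0 < self.treatment_factor <= 1:
            raise ValueError(
                f"treatment_factor must be in (0, 1], got {self.treatment_factor}")
        if self.cv_noise < 0:
            raise ValueError(f"cv_noise must be >= 0, got {self.cv_noise}")


@dataclass(frozen=True)
class WaterParams:
    """Gravimetric water-budget parameters of a pot.

    ``fc_weight`` is the pot weight at field capacity (g); irrigation restores
    the pot to ``target_fraction * fc_weight``.  Water leaves the pot as bare
    soil evaporation (``evap_rate`` g/day) plus transpiration proportional to
    the current projected area (``transp_coeff`` g/pixel/day).
    """

    fc_weight: float
    target_fraction: float = 1.0
    evap_rate: float = 5.0
    transp_coeff: float = 3e-4
    weigh_interval: float = 2.0
    floor_fraction: float = DRY_FLOOR_FRACTION

    def __post_init__(self) -> None:
        if not self.fc_weight > 0:
            raise ValueError(f"fc_weight must be > 0, got {self.fc_weight}")
        if not 0 < self.target_fraction <= 1:
            raise ValueError(
                f"target_fraction must be in (0, 1], got {self.target_fraction}")
        if self.evap_rate < 0 or self.transp_coeff < 0:
            raise ValueError("evap_rate and transp_coeff must be >= 0")


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout of an experiment.

    ``genotypes`` doubles as the arm list in single-treatment (tomato-style)
    designs.  ``treatment_targets`` maps each treatment to its irrigation
    target fraction of field capacity; treatments absent from the mapping
    default to 1.0 (full irrigation).  For stressed treatments the target
    applies only after ``GrowthParams.stress_start_day``.
    """

    genotypes: tuple[str, ...]
    treatments: tuple[str, ...]
    replicates: int
    timepoints: tuple[float, ...]
    n_bare_pots: int = 0
    control_treatment: str | None = None
    control_genotype: str | None = None
    treatment_targets: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size == 0 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be non-empty and strictly increasing")
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ValueError("duplicate genotype labels")
        if len(set(self.treatments)) != len(self.treatments):
            raise ValueError("duplicate treatment labels")

    @property
    def n_plants(self) -> int:
        return len(self.genotypes) * len(self.treatments) * self.replicates


@dataclass(frozen=True)
class RenderParams:
    """Canvas and palette for rendering the three orthogonal views."""

    height: int = 352
    width: int = 352
    top_fraction: float = TOP_VIEW_FRACTION
    noise_sd: float = 0.0
    margin: int = 2

    @property
    def capacity(self) -> int:
        # leave headroom so the random accretion never saturates the canvas
        return ((self.height - 2 * self.margin) *
                (self.width - 2 * self.margin)) // 2


@dataclass
class WeightSeries:
    """Timestamped pot weights with irrigation events and ground truth.

    ``weight_pre_g[i]`` is the weight measured on ``days[i]`` before
    irrigation, ``weight_post_g[i]`` after restoring to the day's target.
    ``true_evap_g``/``true_transp_g`` hold the noise-free per-interval water
    components (length ``len(days) - 1``) for recovery tests.
    """

    pot_id: str
    is_bare: bool
    fc_weight: float
    days: np.ndarray
    weight_pre_g: np.ndarray
    weight_post_g: np.ndarray
    target_fraction: np.ndarray
    true_evap_g: np.ndarray
    true_transp_g: np.ndarray
    truncated: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.days, dtype=float)
        if d.size >= 2 and np.any(np.diff(d) <= 0):
            raise ValueError(f"pot {self.pot_id}: days must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pot_id": self.pot_id,
            "day": self.days,
            "weight_pre_g": self.weight_pre_g,
            "weight_post_g": self.weight_post_g,
            "is_bare": self.is_bare,
            "fc_weight": self.fc_weight,
            "target_fraction": self.target_fraction,
        })


@dataclass
class ExperimentBundle:
    """A full synthetic experiment: design, ground truth and observations."""

    design: ExperimentDesign
    growth: Mapping[str, GrowthParams]
    water: WaterParams
    seed: int
    plants: pd.DataFrame          # plant_id, genotype, treatment, replicate, pot_id
    truth: pd.DataFrame           # plant_id, day, true_area, fresh_weight_g
    counts: pd.DataFrame          # plant_id, day, s0, s90, top
    weights: dict[str, WeightSeries]
    images: dict[tuple[str, float, str], np.ndarray] | None = None
    masks: dict[tuple[str, float, str], np.ndarray] | None = None

    def weights_frame(self) -> pd.DataFrame:
        return pd.concat([ws.to_frame() for ws in self.weights.values()],
                         ignore_index=True)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write manifest CSVs (and PNG images/masks when rendered)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [("plants", self.plants), ("counts", self.counts),
                         ("truth", self.truth), ("weights", self.weights_frame())]:
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False, float_format="%.10g")
            paths[name] = p
        if self.images is not None:
            import imageio.v3 as iio
            img_dir = outdir / "images"
            msk_dir = outdir / "masks"
            img_dir.mkdir(exist_ok=True)
            msk_dir.mkdir(exist_ok=True)
            for (pid, day, view), img in sorted(self.images.items()):
                stem = f"{pid}_{day:g}_{view}.png"
                iio.imwrite(img_dir / stem, img)
                iio.imwrite(msk_dir / stem,
                            (self.masks[(pid, day, view)] * 255).astype(np.uint8))
            paths["images"] = img_dir
            paths["masks"] = msk_dir
        return paths


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def _logistic(t: np.ndarray, K: float, r: float, t_mid: float) -> np.ndarray:
    return K / (1.0 + np.exp(-r * (t - t_mid)))


def deterministic_area(params: GrowthParams, days: Sequence[float]) -> np.ndarray:
    """Noise-free piecewise-logistic projected area at the given days.

    Before ``stress_start_day`` the area follows the logistic with (K, r).
    From the stress day onward the trajectory continues the logistic ODE
    dA/dt = r' A (1 - A/K') with (K', r') = (K f, r f), re-anchored at the
    stress-day area so the series is continuous at the changeover.  If the
    plant is already above the reduced asymptote K', the continuation
    declines toward it — the growth-then-decline pattern seen under drought.
    """
    t = np.asarray(days, dtype=float)
    pre = _logistic(t, params.K, params.r, params.t_mid)
    f = params.treatment_factor
    s = params.stress_start_day
    if s is None or f == 1.0:
        return pre
    a_s = float(_logistic(np.asarray([s]), params.K, params.r, params.t_mid)[0])
    Kp, rp = params.K * f, params.r * f
    c = (Kp - a_s) / a_s
    post = Kp / (1.0 + c * np.exp(-rp * (t - s)))
    return np.where(t < s, pre, post)


def simulate_growth(params: GrowthParams, days: Sequence[float],
                    seed: int | np.random.SeedSequence) -> np.ndarray:
    """Realized projected-area series: deterministic trajectory x lognormal noise.

    The noise multipliers depend only on the seed, ``cv_noise`` and the number
    of days — never on the growth parameters — so two parameter sets sharing a
    seed share their noise exactly (common random numbers).
    """
    t = np.asarray(days, dtype=float)
    if t.size == 0:
        raise ValueError("days must be non-empty")
    if np.any(np.diff(t) <= 0):
        raise ValueError("days must be strictly increasing")
    area = deterministic_area(params, t)
    if params.cv_noise > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log1p(params.cv_noise ** 2))
        mult = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=t.size)
        area = area * mult
    return area


# ---------------------------------------------------------------------------
# water
# ---------------------------------------------------------------------------

def simulate_water_series(
    area_series: Sequence[float],
    days: Sequence[float],
    wp: WaterParams,
    seed: int | np.random.SeedSequence,
    *,
    target_fractions: float | Sequence[float] | None = None,
    noise_sd: float = 0.0,
    pot_id: str = "pot",
    is_bare: bool = False,
) -> WeightSeries:
    """Simulate a pot-weighing log for one pot.

    Per interval the true water loss is ``evap_rate*dt + transp_coeff *
    mean(area)*dt``; at each weighing the pot is irrigated back up to the
    day's target fraction of field capacity (never drained, so a lowered
    target is approached by withholding water).  If a loss would push the pot
    below the dry-soil floor (``floor_fraction * fc_weight``) both components
    are scaled down to the available water and the interval is flagged.

    ``noise_sd`` adds Gaussian measurement noise (g) to the *recorded*
    weights only; ground truth is kept exact.
    """
    d = np.asarray(days, dtype=float)
    a = np.asarray(area_series, dtype=float)
    if a.shape != d.shape:
        raise ValueError("area series must be aligned to weigh days")
    if np.any(np.diff(d) <= 0):
        raise ValueError("days must be strictly increasing")
    n = d.size
    if target_fractions is None:
        tf = np.full(n, wp.target_fraction)
    else:
        tf = np.broadcast_to(np.asarray(target_fractions, dtype=float), (n,)).copy()
    floor = wp.floor_fraction * wp.fc_weight

    pre = np.empty(n)
    post = np.empty(n)
    evap = np.zeros(max(n - 1, 0))
    transp = np.zeros(max(n - 1, 0))
    truncated = np.zeros(max(n - 1, 0), dtype=bool)

    pre[0] = post[0] = tf[0] * wp.fc_weight
    for i in range(1, n):
        dt = d[i] - d[i - 1]
        e = wp.evap_rate * dt
        tr = wp.transp_coeff * 0.5 * (a[i] + a[i - 1]) * dt
        available = post[i - 1] - floor
        if e + tr > available:
            scale = max(available, 0.0) / (e + tr) if e + tr > 0 else 0.0
            e, tr = e * scale, tr * scale
            truncated[i - 1] = True
            logger.warning("pot %s: interval %g-%g hit the dry-soil floor, "
                           "loss truncated", pot_id, d[i - 1], d[i])
        evap[i - 1], transp[i - 1] = e, tr
        pre[i] = post[i - 1] - e - tr
        post[i] = max(pre[i], tf[i] * wp.fc_weight)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pre = pre + rng.normal(0.0, noise_sd, n)
        post = post + rng.normal(0.0, noise_sd, n)
        post = np.maximum(post, pre)  # a refilled pot never weighs less
    return WeightSeries(pot_id=pot_id, is_bare=is_bare, fc_weight=wp.fc_weight,
                        days=d, weight_pre_g=pre, weight_post_g=post,
                        target_fraction=tf, true_evap_g=evap,
                        true_transp_g=transp, truncated=truncated)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_PLUS = ((0, 0), (-1, 0), (1, 0), (0, -1), (0, 1))


def _compact_fill(n: int, h: int, w: int) -> set[tuple[int, int]]:
    # small components (< 25 px, below the analysis min-component filter):
    # a compact near-square raster block with the exact pixel count
    side = max(int(math.ceil(math.sqrt(n))), 1)
    i0, j0 = h // 2 - side // 2, w // 2 - side // 2
    cells = set()
    for k in range(n):
        cells.add((i0 + k // side, j0 + k % side))
    return cells


def _blob_cells(n: int, h: int, w: int, rng: np.random.Generator,
                margin: int) -> set[tuple[int, int]]:
    """A 4-connected pixel set of exactly n pixels built as a union of
    plus-shaped stamps, hence invariant under morphological opening with the
    3x3 cross.  Grown as upward-biased random-walk strokes for a loosely
    plant-like silhouette."""
    if n < 25:
        return _compact_fill(n, h, w)

    lo_i, hi_i = margin + 1, h - margin - 2
    lo_j, hi_j = margin + 1, w - margin - 2

    def in_bounds(c):
        return lo_i <= c[0] <= hi_i and lo_j <= c[1] <= hi_j

    def new_cells(c):
        return [(c[0] + di, c[1] + dj) for di, dj in _PLUS
                if (c[0] + di, c[1] + dj) not in fg]

    def scan_for_gain(remaining):
        """Exhaustive scan: a stamp center overlapping fg whose gain is exactly
        `remaining` if possible, else the largest gain <= remaining."""
        rows = [c[0] for c in fg]
        cols = [c[1] for c in fg]
        best, best_gain = None, 0
        for ci in range(max(min(rows) - 1, lo_i), min(max(rows) + 1, hi_i) + 1):
            for cj in range(max(min(cols) - 1, lo_j), min(max(cols) + 1, hi_j) + 1):
                nc = new_cells((ci, cj))
                g = len(nc)
                if g == 0 or g == 5 or g > remaining:
                    continue  # g == 5 would disconnect
                if g == remaining:
                    return (ci, cj), g
                if g > best_gain:
                    best, best_gain = (ci, cj), g
        return best, best_gain

    fg: set[tuple[int, int]] = set()
    start = (min(hi_i, h - margin - 3), w // 2)
    for di, dj in _PLUS:
        fg.add((start[0] + di, start[1] + dj))
    remaining = n - 5
    pos = start
    heading = (-1, 0)
    fg_list = [start]
    stall = 0
    while remaining > 0:
        if remaining < 5 or stall > 4000:
            c, g = scan_for_gain(min(remaining, 4))
            if c is None:
                raise RuntimeError("blob growth stalled; canvas too crowded")
            for cell in new_cells(c):
                fg.add(cell)
                fg_list.append(cell)
            remaining -= g
            stall = 0
            continue
        if rng.random() < 0.25:
            heading = ((-1, 0), (-1, 0), (-1, -1), (-1, 1), (0, -1),
                       (0, 1), (1, 0))[rng.integers(0, 7)]
        nxt = (pos[0] + heading[0], pos[1] + heading[1])
        if not in_bounds(nxt) or rng.random() < 0.02:
            pos = fg_list[rng.integers(0, len(fg_list))]  # new stroke
            heading = ((-1, 0), (-1, -1), (-1, 1), (0, -1), (0, 1))[
                rng.integers(0, 5)]
            continue
        pos = nxt
        nc = new_cells(pos)
        g = len(nc)
        if 0 < g <= min(remaining, 4):
            for cell in nc:
                fg.add(cell)
                fg_list.append(cell)
            remaining -= g
            stall = 0
        else:
            stall += 1
    return fg


def _colorize(mask: np.ndarray, rng: np.random.Generator,
              noise_sd: float) -> np.ndarray:
    """Green-dominant foreground over a gray/blue background.

    In clean mode (``noise_sd == 0``) every foreground pixel satisfies
    2G - R - B >= 180 and every background pixel 2G - R - B <= 0, so an
    excess-green threshold separates the classes exactly.
    """
    h, w = mask.shape
    img = np.empty((h, w, 3), dtype=np.uint8)
    nbg = int((~mask).sum())
    base = rng.integers(100, 161, nbg)
    img[~mask, 0] = base
    img[~mask, 1] = base - rng.integers(0, 31, nbg)       # G <= R
    img[~mask, 2] = base + rng.integers(0, 41, nbg)       # bluish cast
    nfg = int(mask.sum())
    img[mask, 0] = rng.integers(10, 61, nfg)
    img[mask, 1] = rng.integers(150, 231, nfg)
    img[mask, 2] = rng.integers(10, 61, nfg)
    if noise_sd > 0:
        noisy = img.astype(np.float64) + rng.normal(0.0, noise_sd, (h, w, 3))
        img = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    return img


def render_views(true_area: int, rp: RenderParams = RenderParams(),
                 seed: int | np.random.SeedSequence = 0,
                 ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Render the three orthogonal views of a plant of the given projected area.

    Returns ``{view: (rgb_image, bool_mask)}``.  Both side views carry exactly
    ``true_area`` foreground pixels; the top view carries
    ``round(top_fraction * true_area)``.
    """
    true_area = int(true_area)
    if true_area < 0:
        raise ValueError("true_area must be >= 0")
    if true_area > rp.capacity:
        raise ValueError(
            f"requested area {true_area} exceeds canvas capacity {rp.capacity}")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    child = ss.spawn(len(VIEWS))
    out = {}
    for view, cs in zip(VIEWS, child):
        rng = np.random.default_rng(cs)
        area = (true_area if view != "top"
                else int(round(rp.top_fraction * true_area)))
        mask = np.zeros((rp.height, rp.width), dtype=bool)
        if area > 0:
            for attempt in range(20):
                try:
                    cells = _blob_cells(area, rp.height, rp.width, rng, rp.margin)
                    break
                except RuntimeError:
                    if attempt == 19:
                        raise
            rows, cols = zip(*cells)
            mask[list(rows), list(cols)] = True
        out[view] = (_colorize(mask, rng, rp.noise_sd), mask)
    return out


# ---------------------------------------------------------------------------
# full experiments
# ---------------------------------------------------------------------------

def _child_seed(root: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence((int(root),) + tuple(int(k) for k in key))


def generate_experiment(
    design: ExperimentDesign,
    growth: Mapping[str, GrowthParams],
    wp: WaterParams,
    seed: int,
    *,
    with_images: bool = False,
    render_params: RenderParams | None = None,
    weight_noise_sd: float = 0.0,
    c_fw: float = 1e-3,
    fw_cv: float = 0.03,
) -> ExperimentBundle:
    """Generate a complete, seeded experiment bundle.

    One :class:`GrowthParams` per genotype: the control cell runs it with
    ``treatment_factor`` forced to 1, stressed cells run it as given.  Fresh
    weight ground truth is ``c_fw`` g/pixel times the realized area, with its
    own small lognormal measurement scatter ``fw_cv``.
    """
    missing = [g for g in design.genotypes if g not in growth]
    if missing:
        raise ValueError(f"no GrowthParams for genotypes: {missing}")
    days = np.asarray(design.timepoints, dtype=float)
    rp = render_params or RenderParams()

    plants_rows, truth_rows, counts_rows = [], [], []
    weights: dict[str, WeightSeries] = {}
    images: dict[tuple[str, float, str], np.ndarray] = {}
    masks: dict[tuple[str, float, str], np.ndarray] = {}
    seen = set()

    # weigh days: timepoints hit by the weighing cadence (first day included)
    step = max(int(round(wp.weigh_interval / (days[1] - days[0]))), 1) \
        if days.size > 1 else 1
    weigh_idx = np.arange(0, days.size, step)
    weigh_days = days[weigh_idx]

    fw_sigma = math.sqrt(math.log1p(fw_cv ** 2)) if fw_cv > 0 else 0.0

    for gi, genotype in enumerate(design.genotypes):
        gp = growth[genotype]
        for ti, treatment in enumerate(design.treatments):
            is_control = (design.control_treatment is not None
                          and treatment == design.control_treatment)
            params = dataclasses.replace(gp, treatment_factor=1.0) \
                if is_control else gp
            target = design.treatment_targets.get(treatment, 1.0)
            for rep in range(1, design.replicates + 1):
                plant_id = f"{genotype}_{treatment}_r{rep}"
                key = (genotype, treatment, rep)
                if key in seen:
                    raise ValueError(f"duplicate design key {key}")
                seen.add(key)
                # noise stream shared across treatments: common random numbers
                area = simulate_growth(params, days, _child_seed(seed, 1, gi, rep))
                plants_rows.append((plant_id, genotype, treatment, rep, plant_id))
                fw_rng = np.random.default_rng(_child_seed(seed, 3, gi, ti, rep))
                fw_mult = (fw_rng.lognormal(-0.5 * fw_sigma ** 2, fw_sigma, days.size)
                           if fw_sigma > 0 else np.ones(days.size))
                for k, day in enumerate(days):
                    s0 = s90 = int(round(area[k]))
                    top = int(round(rp.top_fraction * s0))
                    truth_rows.append((plant_id, day, area[k],
                                       c_fw * area[k] * fw_mult[k]))
                    counts_rows.append((plant_id, day, s0, s90, top))
                    if with_images:
                        rendered = render_views(
                            s0, rp, _child_seed(seed, 5, gi, ti, rep, k))
                        for view, (img, msk) in rendered.items():
                            images[(plant_id, day, view)] = img
                            masks[(plant_id, day, view)] = msk
                tf = np.full(weigh_days.size, target)
                if gp.stress_start_day is not None and not is_control:
                    tf[weigh_days < gp.stress_start_day] = 1.0
                weights[plant_id] = simulate_water_series(
                    area[weigh_idx], weigh_days, wp,
                    _child_seed(seed, 7, gi, ti, rep),
                    target_fractions=tf, noise_sd=weight_noise_sd,
                    pot_id=plant_id)

    for b in range(1, design.n_bare_pots + 1):
        pot_id = f"bare_{b:02d}"
        weights[pot_id] = simulate_water_series(
            np.zeros(weigh_days.size), weigh_days, wp,
            _child_seed(seed, 9, b),
            target_fractions=design.treatment_targets.get(
                design.treatments[0], 1.0),
            noise_sd=weight_noise_sd, pot_id=pot_id, is_bare=True)

    bundle = ExperimentBundle(
        design=design, growth=dict(growth), water=wp, seed=seed,
        plants=pd.DataFrame(plants_rows, columns=[
            "plant_id", "genotype", "treatment", "replicate", "pot_id"]),
        truth=pd.DataFrame(truth_rows, columns=[
            "plant_id", "day", "true_area", "fresh_weight_g"]),
        counts=pd.DataFrame(counts_rows, columns=[
            "plant_id", "day", "s0", "s90", "top"]),
        weights=weights,
        images=images if with_images else None,
        masks=masks if with_images else None,
    )
    return bundle


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def wheat_ssd_preset(
    *,
    n_genotypes: int = 39,
    replicates: int = 3,
    cv_noise: float = 0.05,
    weight_noise_sd: float = 0.0,
    stress_start_day: float = 104.0,
    factor_range: tuple[float, float] = (0.5, 1.0),
) -> tuple[ExperimentDesign, dict[str, GrowthParams], WaterParams]:
    """Durum-wheat drought screen: 36 SSD lines + 3 varieties x {control,
    drought} x 3 reps, imaged 55-147 DAS every 2 days, drought at ~50% FC from
    104 DAS, no bare pots.  Genotype drought-tolerance factors span
    ``factor_range`` and asymptotic sizes vary deterministically around 150k px.
    """
    named = ("Cappelli", "Saragolla", "Svevo")
    labels = tuple(f"SSD_{i + 1:03d}" for i in range(max(n_genotypes - 3, 0)))
    labels = (labels + named)[:n_genotypes]
    lo, hi = factor_range
    factors = np.linspace(lo, hi, n_genotypes) if n_genotypes > 1 \
        else np.asarray([hi])
    growth = {
        g: GrowthParams(
            K=150_000.0 * (1.0 + 0.15 * math.sin(2.3 * i)),
            r=0.08, t_mid=100.0,
            treatment_factor=float(factors[i]),
            stress_start_day=stress_start_day, cv_noise=cv_noise)
        for i, g in enumerate(labels)
    }
    design = ExperimentDesign(
        genotypes=labels, treatments=("control", "drought"),
        replicates=replicates,
        timepoints=tuple(float(d) for d in range(55, 148, 2)),
        n_bare_pots=0, control_treatment="control",
        treatment_targets={"control": 1.0, "drought": 0.5},
    )
    wp = WaterParams(fc_weight=1200.0, target_fraction=1.0,
                     evap_rate=5.0, transp_coeff=3e-4, weigh_interval=2.0)
    return design, growth, wp


#: per-arm asymptote multipliers emulating biostimulant efficacy; prototype
#: 2148 is the clear top performer, UTC_70 the untreated reference
TOMATO_ARM_BOOSTS = {
    "UTC_70": 1.00, "P2197": 1.05, "P2219": 1.08, "P2220": 1.12,
    "P2221": 1.16, "P2390": 1.22, "P2148": 1.30,
}


def tomato_rwm_preset(
    *,
    replicates: int = 5,
    cv_noise: float = 0.05,
    weight_noise_sd: float = 0.0,
) -> tuple[ExperimentDesign, dict[str, GrowthParams], WaterParams]:
    """Tomato biostimulant screen: 7 arms x 5 reps at 70% FC over 22 DAT,
    imaged every 2 days, with 10 bare-soil evaporation pots."""
    arms = tuple(TOMATO_ARM_BOOSTS)
    growth = {
        a: GrowthParams(K=80_000.0 * TOMATO_ARM_BOOSTS[a], r=0.18, t_mid=10.0,
                        treatment_factor=1.0, stress_start_day=None,
                        cv_noise=cv_noise)
        for a in arms
    }
    design = ExperimentDesign(
        genotypes=arms, treatments=("rwm70",), replicates=replicates,
        timepoints=tuple(float(d) for d in range(0, 23, 2)),
        n_bare_pots=10, control_genotype="UTC_70",
        treatment_targets={"rwm70": 0.7},
    )
    wp = WaterParams(fc_weight=1800.0, target_fraction=0.7,
                     evap_rate=5.0, transp_coeff=3e-4, weigh_interval=2.0)
    return design, growth, wp


PRESETS = {"wheat_ssd": wheat_ssd_preset, "tomato_rwm": tomato_rwm_preset}


def generate_preset(name: str, seed: int, *, with_images: bool = False,
                    render_params: RenderParams | None = None,
                    **overrides) -> ExperimentBundle:
    """Generate one of the bundled presets (``wheat_ssd`` or ``tomato_rwm``)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    weight_noise_sd = overrides.pop("weight_noise_sd", 0.0)
    design, growth, wp = PRESETS[name](
        weight_noise_sd=weight_noise_sd, **overrides)
    if with_images and render_params is None:
        render_params = RenderParams(height=704, width=704)
    return generate_experiment(design, growth, wp, seed,
                               with_images=with_images,
                               render_params=render_params,
                               weight_noise_sd=weight_noise_sd)
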