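"""Plant/background segmentation of RGB views and foreground pixel counting.

The greenhouse platform's own segmentation is proprietary, so a standard
greenhouse-RGB baseline is used: the excess-green index ExG = 2G - R - B,
thresholded either by Otsu's method or at a fixed value, followed by a
morphological opening and removal of small connected components.  All
components above the minimum size are kept — wheat canopies fragment into
disconnected tillers and leaves in side view, so keeping only the largest
component would undercount.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import disk, opening, remove_small_objects

VIEWS = ("side0", "side90", "top")


@dataclass(frozen=True)
class SegmentationParams:
    """Threshold mode ('otsu' or 'fixed'), small-component cutoff (px) and
    opening radius (px; 0 disables the opening).

    In Otsu mode the threshold is floored at ``otsu_floor`` (default 0): the
    excess-green index is signed and a pixel with 2G - R - B <= 0 is not
    vegetation by definition, whereas Otsu alone drifts into the background
    cluster when the plant covers a tiny fraction of the frame.
    """

    threshold_mode: str = "otsu"
    fixed_threshold: float = 90.0
    otsu_floor: float = 0.0
    min_component_px: int = 25
    opening_radius: int = 1

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold mode {self.threshold_mode!r}")


@dataclass
class SegmentationResult:
    mask: np.ndarray
    pixel_count: int
    threshold_used: float
    n_components_kept: int


def excess_green(image: np.ndarray) -> np.ndarray:
    """Per-pixel excess-green index 2G - R - B as a signed int16 map."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("empty image")
    x = img.astype(np.int16)
    return 2 * x[..., 1] - x[..., 0] - x[..., 2]


def segment_view(image: np.ndarray,
                 params: SegmentationParams = SegmentationParams(),
                 ) -> SegmentationResult:
    """Segment the plant in one RGB view.

    All-background and all-foreground inputs are valid results (a count of 0
    can be a legitimate pre-emergence observation); only empty rasters error.
    """
    exg = excess_green(image)
    if params.threshold_mode == "fixed":
        thr = float(params.fixed_threshold)
    else:
        lo, hi = int(exg.min()), int(exg.max())
        # Otsu needs at least two distinct values; a flat map has no plant edge
        thr = float(lo) if lo == hi else float(threshold_otsu(exg))
        thr = max(thr, params.otsu_floor)
    mask = exg > thr
    if params.opening_radius > 0:
        mask = opening(mask, disk(params.opening_radius))
    if params.min_component_px > 1:
        mask = remove_small_objects(mask, max_size=params.min_component_px - 1,
                                    connectivity=1)
    n_comp = int(label(mask, connectivity=1).max())
    return SegmentationResult(mask=mask, pixel_count=int(mask.sum()),
                              threshold_used=thr, n_components_kept=n_comp)


def count_series(
    images: Mapping[tuple[str, float, str], np.ndarray]
    | Iterable[tuple[str, float, str, np.ndarray]],
    params: SegmentationParams = SegmentationParams(),
) -> pd.DataFrame:
    """Segment a whole image collection into a wide per-(plant, day) count table.

    Accepts a mapping ``{(plant_id, day, view): image}`` or an iterable of
    ``(plant_id, day, view, image)`` records.  Keys with any of the three
    views missing are skipped with a warning; duplicate keys are an error.

    Returns columns ``plant_id, day, s0, s90, top, threshold_side0,
    threshold_side90, threshold_top``.
    """
    if isinstance(images, Mapping):
        items = images.items()
        store: dict[tuple[str, float, str], np.ndarray] = dict(images)
    else:
        store = {}
        for pid, day, view, img in images:
            key = (pid, day, view)
            if key in store:
                raise ValueError(f"duplicate image key {key}")
            store[key] = img
        items = store.items()
    for (pid, day, view), _ in items:
        if view not in VIEWS:
            raise ValueError(f"unknown view {view!r} for ({pid}, {day})")

    keys = sorted({(pid, day) for (pid, day, _v) in store})
    rows = []
    for pid, day in keys:
        missing = [v for v in VIEWS if (pid, day, v) not in store]
        if missing:
            warnings.warn(f"({pid}, day {day}): missing view(s) {missing}; "
                          "row skipped", stacklevel=2)
            continue
        res = {v: segment_view(store[(pid, day, v)], params) for v in VIEWS}
        rows.append((pid, day,
                     res["side0"].pixel_count, res["side90"].pixel_count,
                     res["top"].pixel_count,
                     res["side0"].threshold_used, res["side90"].threshold_used,
                     res["top"].threshold_used))
    return pd.DataFrame(rows, columns=[
        "plant_id", "day", "s0", "s90", "top",
        "threshold_side0", "threshold_side90", "threshold_top"])


_NAME_RE = re.compile(r"^(?P<plant>.+)_(?P<day>[0-9.]+)_(?P<view>side0|side90|top)$")


def load_image_dir(images_dir: str | Path) -> dict[tuple[str, float, str], np.ndarray]:
    """Load ``<plant>_<day>_<view>.png|.tif`` images from a directory."""
    import imageio.v3 as iio
    images = {}
    for path in sorted(Path(images_dir).iterdir()):
        if path.suffix.lower() not in (".png", ".tif", ".tiff"):
            continue
        m = _NAME_RE.match(path.stem)
        if m is None:
            warnings.warn(f"unparseable image name {path.name!r}; skipped",
                          stacklevel=2)
            continue
        img = iio.imread(path)
        if img.ndim == 3 and img.shape[2] == 4:
            img = img[..., :3]
        images[(m["plant"], float(m["day"]), m["view"])] = img
    return images


def counts_to_long(counts: pd.DataFrame) -> pd.DataFrame:
    """Reshape the wide count table to the exported long layout
    (plant_id, day, view, pixel_count, threshold)."""
    frames = []
    for col, view in (("s0", "side0"), ("s90", "side90"), ("top", "top")):
        frames.append(pd.DataFrame({
            "plant_id": counts["plant_id"], "day": counts["day"],
            "view": view, "pixel_count": counts[col],
            "threshold": counts.get(f"threshold_{view}", np.nan),
        }))
    return (pd.concat(frames, ignore_index=True)
            .sort_values(["plant_id", "day", "view"], kind="stable")
            .reset_index(drop=True))
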