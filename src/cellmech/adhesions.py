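"""Focal-adhesion morphometry from TIRF-style two-channel images.

Reproduces an NIS-Elements-style general-analysis recipe: the cell is
segmented on a whole-cell stain by a fixed offset (default 100 AU) above the
estimated background; adhesion foci are segmented on the reporter channel by
a fixed intensity threshold (default 10000 AU), restricted to the cell mask,
and filtered by a minimum area (default 0.5 um^2); each focus's minimum
Euclidean distance to the cell edge is read off an exact distance transform
of the cell mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as _label
from skimage.measure import regionprops


@dataclass
class MorphometryConfig:
    """Fixed-threshold segmentation parameters (intensities in AU)."""

    cell_threshold_offset: float = 100.0
    foci_threshold: float = 10000.0
    min_focus_area_um2: float = 0.5
    px_size_um: float = 0.1
    connectivity: int = 8  # 4 or 8
    background: float | None = None  # fixed background; None = estimate
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.cell_threshold_offset <= 0 or self.foci_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_focus_area_um2 <= 0:
            raise ValueError("min_focus_area_um2 must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def _skimage_connectivity(self) -> int:
        return 1 if self.connectivity == 4 else 2


@dataclass
class CellMask:
    mask: np.ndarray
    area_um2: float
    background: float


def estimate_background(image: np.ndarray) -> float:
    """Median of the pixels below Otsu's threshold.

    The median is robust to the bright cell occupying a large fraction of
    the field; falls back to the global median for (near-)constant images.
    """
    img = np.asarray(image, dtype=float)
    if img.max() == img.min():
        return float(np.median(img))
    t = threshold_otsu(img)
    below = img[img < t]
    if below.size == 0:
        return float(np.median(img))
    return float(np.median(below))


def segment_cell(mask_channel: np.ndarray, config: MorphometryConfig) -> CellMask:
    """Threshold the whole-cell stain at background + offset; keep the
    largest connected component and fill holes."""
    img = np.asarray(mask_channel, dtype=float)
    bg = config.background if config.background is not None else estimate_background(img)
    raw = img > bg + config.cell_threshold_offset
    if not raw.any():
        raise ValueError("cell segmentation produced an empty mask")
    lab = _label(raw, connectivity=config._skimage_connectivity)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    mask = lab == sizes.argmax()
    if config.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    area = float(mask.sum()) * config.px_size_um**2
    return CellMask(mask=mask, area_um2=area, background=float(bg))


def detect_foci(
    foci_channel: np.ndarray,
    cell_mask: CellMask | np.ndarray,
    config: MorphometryConfig,
    extra_channels: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Label adhesion foci and tabulate per-focus measurements.

    Foci are connected components above ``foci_threshold`` clipped to the
    cell mask before the area test; components smaller than
    ``min_focus_area_um2`` are discarded.  Mean intensities are reported for
    the foci channel and any named extra channels.  Zero foci is a valid
    result.
    """
    img = np.asarray(foci_channel, dtype=float)
    mask = cell_mask.mask if isinstance(cell_mask, CellMask) else np.asarray(cell_mask, bool)
    binary = (img > config.foci_threshold) & mask
    lab = _label(binary, connectivity=config._skimage_connectivity)
    px_area = config.px_size_um**2
    records = []
    keep_labels = []
    for rp in regionprops(lab, intensity_image=img):
        area = rp.area * px_area
        if area < config.min_focus_area_um2:
            continue
        keep_labels.append(rp.label)
        row = {
            "label": rp.label,
            "area_um2": area,
            "x_um": (rp.centroid[1] + 0.5) * config.px_size_um,
            "y_um": (rp.centroid[0] + 0.5) * config.px_size_um,
            "mean_intensity": rp.intensity_mean,
        }
        if extra_channels:
            for name, ch in extra_channels.items():
                row[f"mean_intensity_{name}"] = float(
                    np.asarray(ch, dtype=float)[lab == rp.label].mean()
                )
        records.append(row)
    out_lab = np.where(np.isin(lab, keep_labels), lab, 0)
    # relabel compactly so label ids are stable and contiguous
    out_lab = _label(out_lab > 0, connectivity=config._skimage_connectivity)
    if records:
        # regionprops order and our records order both follow label order
        for new_rp, row in zip(regionprops(out_lab), sorted(records, key=lambda r: r["label"])):
            row["label"] = new_rp.label
        records = sorted(records, key=lambda r: r["label"])
    return out_lab, pd.DataFrame(
        records,
        columns=["label", "area_um2", "x_um", "y_um", "mean_intensity"]
        + ([f"mean_intensity_{n}" for n in (extra_channels or {})]),
    )


def focus_edge_distances(
    label_map: np.ndarray,
    cell_mask: CellMask | np.ndarray,
    px_size_um: float,
) -> tuple[pd.DataFrame, float]:
    """Minimum distance of each focus to the outside of the cell (um).

    Per focus: the minimum, over its pixels, of the exact Euclidean
    distance to the nearest non-cell pixel.  Returns the per-focus table and
    the per-image mean (NaN if there are no foci).
    """
    mask = cell_mask.mask if isinstance(cell_mask, CellMask) else np.asarray(cell_mask, bool)
    dist = ndimage.distance_transform_edt(mask, sampling=px_size_um)
    labels = np.unique(label_map)
    labels = labels[labels > 0]
    rows = [
        {"label": int(l), "min_edge_distance_um": float(dist[label_map == l].min())}
        for l in labels
    ]
    table = pd.DataFrame(rows, columns=["label", "min_edge_distance_um"])
    mean = float(table["min_edge_distance_um"].mean()) if len(table) else float("nan")
    return table, mean


def image_summary(
    cell: CellMask, records: pd.DataFrame, edge_distances: pd.DataFrame | None = None
) -> dict:
    """Per-image aggregate: cell area, focus count, mean focus area, mean
    minimum edge distance and mean intensities.  Distance and intensity
    summaries are NaN-flagged when there are no foci."""
    n = len(records)
    out = {
        "cell_area_um2": cell.area_um2,
        "background": cell.background,
        "focus_count": n,
        "mean_focus_area_um2": float(records["area_um2"].mean()) if n else float("nan"),
        "mean_focus_intensity": float(records["mean_intensity"].mean()) if n else float("nan"),
    }
    if edge_distances is not None:
        out["mean_edge_distance_um"] = (
            float(edge_distances["min_edge_distance_um"].mean()) if len(edge_distances) else float("nan")
        )
    return out


def quantify_image(
    image: np.ndarray, config: MorphometryConfig, foci_channel: int = 1, mask_channel: int = 0
) -> dict:
    """End-to-end morphometry of one multi-channel image.

    Returns dict with keys ``cell`` (CellMask), ``labels``, ``records``
    (per-focus table incl. edge distances) and ``summary``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3:
        raise ValueError("expected a (channels, H, W) image")
    cell = segment_cell(img[mask_channel], config)
    labels, records = detect_foci(
        img[foci_channel], cell, config, extra_channels={"cellmask": img[mask_channel]}
    )
    dists, _ = focus_edge_distances(labels, cell, config.px_size_um)
    if len(records):
        records = records.merge(dists, on="label")
    else:
        records["min_edge_distance_um"] = pd.Series(dtype=float)
    return {
        "cell": cell,
        "labels": labels,
        "records": records,
        "summary": image_summary(cell, records, dists),
    }
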