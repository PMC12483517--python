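"""Per-track migration/invasion statistics, QC filters and group comparisons.

A *track* is a time-ordered sequence of cell positions (t in seconds,
x/y in micrometres).  The module computes the standard chemotaxis
descriptors -- accumulated distance, straightness (net displacement over
path length), signed displacements parallel and perpendicular to the
chemoattractant axis, the forward motion index (FMI, parallel net
displacement over path length) and mean speed -- applies the track-quality
filters used for time-lapse data (minimum number of timepoints, first
timepoint cut-off, proximity exclusion), and compares metric distributions
between conditions with non-parametric tests.

Sign convention: positive parallel displacement points toward the
chemoattractant; the gradient axis defaults to +y.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests


class UndefinedMetricError(ValueError):
    """Raised when a metric is requested for a track too short to define it."""


TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]


@dataclass
class Track:
    """One cell trajectory: strictly increasing times, finite coordinates."""

    track_id: object
    t: np.ndarray  # s
    x: np.ndarray  # um
    y: np.ndarray  # um

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.t) < 1 or len(self.t) != len(self.x) or len(self.t) != len(self.y):
            raise ValueError("track needs equal-length, non-empty t/x/y")
        if not (np.isfinite(self.t).all() and np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("track coordinates must be finite")
        if len(self.t) > 1 and not (np.diff(self.t) > 0).all():
            raise ValueError("track timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("gradient axis must be nonzero")
    return v / n


def accumulated_distance(track: Track) -> float:
    """Total path length: sum of Euclidean steps between consecutive points."""
    if len(track) < 2:
        return 0.0
    return float(np.hypot(np.diff(track.x), np.diff(track.y)).sum())


def net_displacement(track: Track) -> np.ndarray:
    """Vector from first to last point (um).

    Computed as the sum of per-step increments so that a straight
    constant-direction track yields straightness and FMI of exactly 1 (the
    same floating-point sum appears in numerator and denominator).
    """
    if len(track) < 2:
        return np.zeros(2)
    return np.array([np.sum(np.diff(track.x)), np.sum(np.diff(track.y))])


def straightness(track: Track) -> float:
    """Net displacement magnitude over accumulated distance; 0 for a
    zero-length path by convention."""
    if len(track) < 2:
        raise UndefinedMetricError("straightness needs >= 2 points")
    acc = accumulated_distance(track)
    if acc == 0:
        return 0.0
    return float(np.linalg.norm(net_displacement(track)) / acc)


def vertical_displacement(track: Track, gradient_axis=(0.0, 1.0)) -> float:
    """Signed net displacement along the chemoattractant axis (um)."""
    if len(track) < 2:
        raise UndefinedMetricError("displacement needs >= 2 points")
    return float(net_displacement(track) @ _unit(gradient_axis))


def lateral_displacement(track: Track, gradient_axis=(0.0, 1.0)) -> float:
    """Signed net displacement perpendicular to the chemoattractant axis (um).

    The perpendicular is the gradient axis rotated +90 deg.
    """
    if len(track) < 2:
        raise UndefinedMetricError("displacement needs >= 2 points")
    g = _unit(gradient_axis)
    perp = np.array([-g[1], g[0]])
    return float(net_displacement(track) @ perp)


def fmi_parallel(track: Track, gradient_axis=(0.0, 1.0)) -> float:
    """Forward motion index: vertical displacement over accumulated distance.

    Lies in [-1, 1]; 0 by convention when the accumulated distance is 0.
    """
    if len(track) < 2:
        raise UndefinedMetricError("FMI needs >= 2 points")
    acc = accumulated_distance(track)
    if acc == 0:
        return 0.0
    return vertical_displacement(track, gradient_axis) / acc


def mean_speed(track: Track) -> float:
    """Accumulated distance divided by elapsed time (um/s)."""
    if len(track) < 2:
        raise UndefinedMetricError("speed needs >= 2 points")
    dt = track.t[-1] - track.t[0]
    if dt <= 0:
        raise ValueError("elapsed time must be positive")
    return accumulated_distance(track) / dt


def iter_tracks(table: pd.DataFrame):
    """Yield ``(first_frame, Track)`` per track_id, in time order."""
    for tid, g in table.groupby("track_id", sort=True):
        g = g.sort_values("t_s")
        yield int(g["frame"].iloc[0]), Track(tid, g["t_s"].to_numpy(), g["x_um"].to_numpy(), g["y_um"].to_numpy())


def track_metrics_table(table: pd.DataFrame, gradient_axis=(0.0, 1.0)) -> pd.DataFrame:
    """Per-track metrics for a long-format track table.

    Single-point tracks get NaN for the path metrics and are flagged
    ``degenerate``; zero-motion tracks get straightness and FMI 0 and the
    same flag, keeping condition summaries total.
    """
    rows = []
    for first_frame, tr in iter_tracks(table):
        row = {
            "track_id": tr.track_id,
            "n_timepoints": len(tr),
            "first_timepoint": first_frame,
        }
        if len(tr) < 2:
            row.update(
                accumulated_distance_um=0.0, net_displacement_um=np.nan,
                straightness=np.nan, lateral_um=np.nan, vertical_um=np.nan,
                fmi_parallel=np.nan, mean_speed_um_s=np.nan, degenerate=True,
            )
        else:
            acc = accumulated_distance(tr)
            row.update(
                accumulated_distance_um=acc,
                net_displacement_um=float(np.linalg.norm(net_displacement(tr))),
                straightness=straightness(tr),
                lateral_um=lateral_displacement(tr, gradient_axis),
                vertical_um=vertical_displacement(tr, gradient_axis),
                fmi_parallel=fmi_parallel(tr, gradient_axis),
                mean_speed_um_s=mean_speed(tr),
                degenerate=acc == 0.0,
            )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class FilterSpec:
    """Track retention rules: minimum length and latest allowed start frame."""

    min_timepoints: int = 3
    max_first_timepoint: int | None = None

    def __post_init__(self) -> None:
        if self.min_timepoints < 1:
            raise ValueError("min_timepoints must be >= 1")


def filter_tracks(table: pd.DataFrame, spec: FilterSpec) -> pd.DataFrame:
    """Keep tracks with >= min_timepoints rows and (if set) a first frame
    strictly below max_first_timepoint.  Order-preserving and idempotent."""
    g = table.groupby("track_id", sort=False)
    n = g["frame"].transform("size")
    keep = n >= spec.min_timepoints
    if spec.max_first_timepoint is not None:
        first = g["frame"].transform("min")
        keep &= first < spec.max_first_timepoint
    return table[keep].copy()


def exclude_proximal(
    table: pd.DataFrame, radius_um: float = 35.0, mode: str = "start"
) -> pd.DataFrame:
    """Drop tracks starting (or, in ``every_frame`` mode, ever found) within
    ``radius_um`` of another cell present in the same frame.

    Emulates the tracking QC rule of skipping cells in proximity to other
    cells; the default evaluates the rule at each track's first frame.
    """
    if mode not in ("start", "every_frame"):
        raise ValueError("mode must be 'start' or 'every_frame'")
    by_frame = {f: g[["track_id", "x_um", "y_um"]] for f, g in table.groupby("frame")}
    drop: set = set()
    for tid, g in table.groupby("track_id"):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy() if mode == "every_frame" else g["frame"].to_numpy()[:1]
        for f, x, y in zip(frames, g["x_um"].to_numpy(), g["y_um"].to_numpy()):
            others = by_frame[f]
            others = others[others["track_id"] != tid]
            if len(others) == 0:
                continue
            d = np.hypot(others["x_um"].to_numpy() - x, others["y_um"].to_numpy() - y)
            if (d <= radius_um).any():
                drop.add(tid)
                break
    return table[~table["track_id"].isin(drop)].copy()


SUMMARY_METRICS = [
    "n_timepoints", "mean_speed_um_s", "straightness",
    "accumulated_distance_um", "fmi_parallel", "lateral_um", "vertical_um",
]


def summarize_condition(
    metrics: pd.DataFrame, columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """Mean, sample SD (n-1 denominator) and n per metric.

    With a single observation the SD is reported as missing (NaN).  An
    empty table raises ``ValueError``.
    """
    if len(metrics) == 0:
        raise ValueError("cannot summarize an empty condition")
    columns = [c for c in (columns or SUMMARY_METRICS) if c in metrics.columns]
    rows = []
    for c in columns:
        v = metrics[c].dropna().to_numpy(dtype=float)
        rows.append(
            {
                "metric": c,
                "mean": v.mean() if len(v) else np.nan,
                "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
                "n": len(v),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    test: str
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame | None = None


def _dunn_posthoc(groups: Mapping[str, np.ndarray], p_adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based post-hoc z tests with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with the
    tie term T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p-values,
    multiplicity-adjusted (Holm by default).
    """
    names = list(groups)
    values = np.concatenate([groups[k] for k in names])
    sizes = np.array([len(groups[k]) for k in names])
    n_total = len(values)
    ranks = _stats.rankdata(values)
    mean_ranks = {}
    start = 0
    for k, sz in zip(names, sizes):
        mean_ranks[k] = ranks[start:start + sz].mean()
        start += sz
    _, counts = np.unique(values, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            na, nb = sizes[a], sizes[b]
            se = np.sqrt(base_var * (1.0 / na + 1.0 / nb))
            z = (mean_ranks[names[a]] - mean_ranks[names[b]]) / se
            p = 2.0 * _stats.norm.sf(abs(z))
            rows.append({"group1": names[a], "group2": names[b], "z": z, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"].to_numpy(), method=p_adjust)[1]
    return out


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    test: str = "kruskal_dunn",
    p_adjust: str = "holm",
) -> GroupComparison:
    """Compare metric distributions between conditions.

    ``test`` is one of ``kruskal_dunn`` (Kruskal-Wallis omnibus with Dunn's
    adjusted pairwise z tests; >= 3 groups), ``ks_two_sample``,
    ``mann_whitney``, ``t_unpaired`` or ``t_paired`` (exactly 2 groups).
    Deterministic for fixed input.
    """
    clean = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in clean.items():
        if len(v) < 2:
            raise ValueError(f"group '{k}' has fewer than 2 observations")
    names = list(clean)
    if test == "kruskal_dunn":
        if len(clean) < 3:
            raise ValueError("kruskal_dunn needs >= 3 groups")
        stat, p = _stats.kruskal(*clean.values())
        return GroupComparison("kruskal_dunn", float(stat), float(p),
                               _dunn_posthoc(clean, p_adjust))
    if len(clean) != 2:
        raise ValueError(f"test '{test}' needs exactly 2 groups")
    a, b = clean[names[0]], clean[names[1]]
    if test == "ks_two_sample":
        r = _stats.ks_2samp(a, b)
    elif test == "mann_whitney":
        r = _stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "t_unpaired":
        r = _stats.ttest_ind(a, b)
    elif test == "t_paired":
        if len(a) != len(b):
            raise ValueError("t_paired needs equal-length groups")
        r = _stats.ttest_rel(a, b)
    else:
        raise ValueError(f"unknown test '{test}'")
    return GroupComparison(test, float(r.statistic), float(r.pvalue))
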