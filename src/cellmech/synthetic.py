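"""Synthetic data generators with exact ground truth.

Every generator in this module emulates one of the pipeline's input data
streams -- cell tracks, micropillar centroid fields, TIRF adhesion images,
two-channel colocalisation pairs and adhesion label movies -- and returns,
alongside the observable data, a ground-truth record sufficient to score
the corresponding analysis stage without re-deriving anything.

All randomness is drawn from a single ``numpy.random.Generator`` seeded per
call; identical configs with identical seeds produce byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from shapely import affinity
from shapely.geometry import Point, Polygon
from skimage.draw import disk as _draw_disk
from skimage.draw import ellipse as _draw_ellipse


class ConfigError(ValueError):
    """Raised when a simulation config violates its invariants."""


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ConfigError("gradient axis must be a nonzero vector")
    return v / n


# ---------------------------------------------------------------------------
# Cell tracks: persistent random walk with chemotactic drift
# ---------------------------------------------------------------------------

@dataclass
class TrackSimConfig:
    """Persistent-random-walk track generator settings.

    The walk mimics single-cell chemotaxis in a gradient chamber: headings
    decorrelate at a rate set by ``persistence`` and are pulled toward
    ``gradient_axis`` with weight ``drift_bias``; step lengths are drawn
    from a normal truncated at zero.  Defaults emulate a 12 h time lapse at
    10 min intervals of smooth-muscle cells moving ~0.01 um/s.
    """

    n_tracks: int = 100
    n_frames: int = 73
    dt: float = 600.0  # seconds between frames
    speed_mean: float = 0.01  # um/s
    speed_sd: float = 0.003  # um/s
    persistence: float = 0.7  # heading correlation in [0, 1]
    drift_bias: float = 0.0  # taxis weight in [0, 1]
    gradient_axis: tuple[float, float] = (0.0, 1.0)
    arena: tuple[float, float] | None = None  # (width, height) um; None = unbounded
    seed: int = 0

    def validate(self) -> None:
        if self.n_tracks < 1:
            raise ConfigError("n_tracks must be >= 1")
        if self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.speed_mean <= 0:
            raise ConfigError("speed_mean must be positive")
        if self.speed_sd < 0:
            raise ConfigError("speed_sd must be >= 0")
        if not 0.0 <= self.persistence <= 1.0:
            raise ConfigError("persistence must be in [0, 1]")
        if not 0.0 <= self.drift_bias <= 1.0:
            raise ConfigError("drift_bias must be in [0, 1]")


def generate_tracks(config: TrackSimConfig) -> pd.DataFrame:
    """Simulate cell tracks; returns columns track_id, frame, t_s, x_um, y_um.

    Heading update per step::

        h <- normalize((1 - b) * (p * h_prev + (1 - p) * u_rand) + b * g)

    with persistence ``p``, drift bias ``b``, random unit vector ``u_rand``
    and unit gradient axis ``g``.  At ``b == 1`` every step lies exactly
    along the gradient axis; at ``b == 0`` the walk is an undirected
    persistent random walk.  Step length ~ Normal(speed_mean*dt,
    speed_sd*dt) truncated at zero.  Tracks reflect at the arena edges when
    an arena is given.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, nf = config.n_tracks, config.n_frames
    g = _unit(config.gradient_axis)
    p, b = config.persistence, config.drift_bias

    if config.arena is not None:
        w, h = config.arena
        pos = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
    else:
        pos = np.column_stack([rng.uniform(0, 500.0, n), rng.uniform(0, 500.0, n)])

    ang0 = rng.uniform(0, 2 * np.pi, n)
    head = np.column_stack([np.cos(ang0), np.sin(ang0)])

    mean_len = config.speed_mean * config.dt
    sd_len = config.speed_sd * config.dt

    xs = np.empty((nf, n))
    ys = np.empty((nf, n))
    xs[0], ys[0] = pos[:, 0], pos[:, 1]
    for t in range(1, nf):
        ang = rng.uniform(0, 2 * np.pi, n)
        rand = np.column_stack([np.cos(ang), np.sin(ang)])
        v = (1.0 - b) * (p * head + (1.0 - p) * rand) + b * g
        norm = np.linalg.norm(v, axis=1)
        degenerate = norm < 1e-12
        if degenerate.any():
            v[degenerate] = head[degenerate]
            norm[degenerate] = 1.0
        head = v / norm[:, None]
        if sd_len > 0:
            a = -mean_len / sd_len
            lengths = _stats.truncnorm.rvs(
                a, np.inf, loc=mean_len, scale=sd_len, size=n, random_state=rng
            )
        else:
            lengths = np.full(n, mean_len)
        pos = pos + lengths[:, None] * head
        if config.arena is not None:
            for axis, lim in enumerate(config.arena):
                c = pos[:, axis]
                c = np.where(c < 0, -c, c)
                c = np.where(c > lim, 2 * lim - c, c)
                pos[:, axis] = c
        xs[t], ys[t] = pos[:, 0], pos[:, 1]

    frames = np.tile(np.arange(nf), n)
    return pd.DataFrame(
        {
            "track_id": np.repeat(np.arange(n), nf),
            "frame": frames,
            "t_s": frames * config.dt,
            "x_um": xs.T.ravel(),
            "y_um": ys.T.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# Micropillar lattices with imposed displacement fields
# ---------------------------------------------------------------------------

@dataclass
class PillarSimConfig:
    """Regular pillar lattice with imposed deflections and localisation noise.

    Geometry defaults to the 0.5 um diameter / 1 um pitch PDMS array used
    for smooth-muscle-cell traction measurements.  ``displacement_field``
    maps lattice index (i, j) -> imposed deviation (dx, dy) in nm; pillars
    outside ``cell_region`` (or, if no region is given, pillars without an
    imposed displacement) are flagged as force-free reference pillars.
    """

    spacing: float = 1.0  # um, centre-to-centre
    diameter: float = 0.5  # um
    n_rows: int = 20
    n_cols: int = 20
    lattice_angle: float = 0.0  # radians
    origin: tuple[float, float] = (0.0, 0.0)  # um
    cell_region: Polygon | None = None
    displacement_field: Mapping[tuple[int, int], tuple[float, float]] = field(
        default_factory=dict
    )
    localisation_noise_sd: float = 0.0  # nm per axis
    render_mode: str = "centroids"  # or "image"
    px_size: float = 0.1  # um/px (image mode)
    spot_sigma: float | None = None  # um; default diameter / 2.355 (FWHM = diameter)
    peak_intensity: float = 10000.0
    background: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if self.spacing <= self.diameter:
            raise ConfigError("spacing must exceed pillar diameter")
        if self.localisation_noise_sd < 0:
            raise ConfigError("localisation_noise_sd must be >= 0")
        if self.render_mode not in ("centroids", "image"):
            raise ConfigError("render_mode must be 'centroids' or 'image'")
        for (i, j) in self.displacement_field:
            if not (0 <= i < self.n_cols and 0 <= j < self.n_rows):
                raise ConfigError(
                    f"displacement assigned to pillar ({i}, {j}) outside the lattice"
                )


def generate_pillar_data(config: PillarSimConfig):
    """Simulate a pillar field; returns ``(observations, truth)``.

    ``truth`` is a DataFrame with one row per pillar: lattice index,
    ideal position (um), imposed displacement (nm) and reference flag.
    In ``centroids`` mode ``observations`` is a DataFrame (i, j, x_um,
    y_um, is_reference); in ``image`` mode it is a 2D float image of
    Gaussian spots at the observed positions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ca, sa = math.cos(config.lattice_angle), math.sin(config.lattice_angle)
    u1 = config.spacing * np.array([ca, sa])
    u2 = config.spacing * np.array([-sa, ca])
    o = np.asarray(config.origin, dtype=float)

    ii, jj = np.meshgrid(np.arange(config.n_cols), np.arange(config.n_rows))
    ii, jj = ii.ravel(), jj.ravel()
    ideal = o + ii[:, None] * u1 + jj[:, None] * u2

    disp_nm = np.zeros((len(ii), 2))
    for (i, j), (dx, dy) in config.displacement_field.items():
        k = int(np.flatnonzero((ii == i) & (jj == j))[0])
        disp_nm[k] = (dx, dy)

    if config.cell_region is not None:
        in_cell = np.array(
            [config.cell_region.contains(Point(x, y)) for x, y in ideal]
        )
        is_ref = ~in_cell
    else:
        is_ref = ~np.any(disp_nm != 0, axis=1)
        if not config.displacement_field:
            is_ref = np.ones(len(ii), dtype=bool)

    noise_nm = (
        rng.normal(0.0, config.localisation_noise_sd, size=(len(ii), 2))
        if config.localisation_noise_sd > 0
        else np.zeros((len(ii), 2))
    )
    observed = ideal + (disp_nm + noise_nm) * 1e-3  # nm -> um

    truth = pd.DataFrame(
        {
            "i": ii,
            "j": jj,
            "ideal_x_um": ideal[:, 0],
            "ideal_y_um": ideal[:, 1],
            "dx_nm": disp_nm[:, 0],
            "dy_nm": disp_nm[:, 1],
            "is_reference": is_ref,
        }
    )
    if config.render_mode == "centroids":
        obs = pd.DataFrame(
            {
                "i": ii,
                "j": jj,
                "x_um": observed[:, 0],
                "y_um": observed[:, 1],
                "is_reference": is_ref,
            }
        )
        return obs, truth

    margin = 2.0 * config.spacing
    w_um = observed[:, 0].max() + margin
    h_um = observed[:, 1].max() + margin
    shape = (int(round(h_um / config.px_size)), int(round(w_um / config.px_size)))
    sigma_um = config.spot_sigma if config.spot_sigma is not None else config.diameter / 2.355
    img = np.full(shape, config.background, dtype=float)
    yy = (np.arange(shape[0]) + 0.5) * config.px_size
    xx = (np.arange(shape[1]) + 0.5) * config.px_size
    for x0, y0 in observed:
        r0 = int((y0 - 4 * sigma_um) / config.px_size)
        r1 = int((y0 + 4 * sigma_um) / config.px_size) + 1
        c0 = int((x0 - 4 * sigma_um) / config.px_size)
        c1 = int((x0 + 4 * sigma_um) / config.px_size) + 1
        r0, c0 = max(r0, 0), max(c0, 0)
        gy = np.exp(-((yy[r0:r1] - y0) ** 2) / (2 * sigma_um**2))
        gx = np.exp(-((xx[c0:c1] - x0) ** 2) / (2 * sigma_um**2))
        img[r0:r1, c0:c1] += config.peak_intensity * np.outer(gy, gx)
    return img, truth


# ---------------------------------------------------------------------------
# TIRF-style adhesion images
# ---------------------------------------------------------------------------

@dataclass
class FocusSpec:
    """One elliptical adhesion focus: centre (um), semi-axes (um), orientation
    (radians, CCW from +x) and uniform fill intensity (AU)."""

    center_um: tuple[float, float]
    semi_axes_um: tuple[float, float]
    orientation_rad: float = 0.0
    peak_intensity: float = 20000.0

    @property
    def area_um2(self) -> float:
        a, b = self.semi_axes_um
        return math.pi * a * b

    def polygon(self) -> Polygon:
        circ = Point(self.center_um).buffer(1.0, quad_segs=90)
        ell = affinity.scale(
            circ, self.semi_axes_um[0], self.semi_axes_um[1], origin=self.center_um
        )
        return affinity.rotate(
            ell, math.degrees(self.orientation_rad), origin=self.center_um
        )


@dataclass
class AdhesionSimConfig:
    """Two-channel adhesion image: channel 0 is the cell-mask stain, channel 1
    the focal-adhesion reporter with uniformly filled elliptical foci."""

    shape: tuple[int, int] = (256, 256)  # px (rows, cols)
    px_size: float = 0.1  # um/px
    cell_polygon: Polygon | None = None
    background: float = 100.0  # AU
    cell_intensity: float = 500.0  # AU, absolute level of cell pixels in channel 0
    foci: Sequence[FocusSpec] = field(default_factory=list)
    noise_sd: float = 0.0  # AU
    min_focus_area: float = 0.5  # um^2, used only to flag truth rows
    seed: int = 0

    def validate(self) -> None:
        if self.cell_polygon is None:
            raise ConfigError("cell_polygon is required")
        if self.background < 0 or self.cell_intensity < 0:
            raise ConfigError("intensities must be >= 0")
        h, w = self.shape
        for f in self.foci:
            if f.peak_intensity < 0:
                raise ConfigError("focus intensity must be >= 0")
            if not self.cell_polygon.contains(Point(f.center_um)):
                raise ConfigError(f"focus centroid {f.center_um} outside cell polygon")
            minx, miny, maxx, maxy = f.polygon().bounds
            if minx < 0 or miny < 0 or maxx > w * self.px_size or maxy > h * self.px_size:
                raise ConfigError(f"focus at {f.center_um} extends outside the image")


def generate_adhesion_image(config: AdhesionSimConfig):
    """Render the two-channel image and an analytic truth table.

    Truth columns: area (analytic, um^2), pixel area, centroid, minimum
    distance from the focus boundary to the cell edge (um, via exact polygon
    geometry) and a ``below_min_size`` flag.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    px = config.px_size

    ch_mask = np.full((h, w), config.background, dtype=float)
    ext = np.asarray(config.cell_polygon.exterior.coords)
    from skimage.draw import polygon as _draw_polygon

    rr, cc = _draw_polygon(ext[:, 1] / px - 0.5, ext[:, 0] / px - 0.5, shape=(h, w))
    ch_mask[rr, cc] = config.cell_intensity

    ch_foci = np.full((h, w), config.background, dtype=float)
    records = []
    boundary = config.cell_polygon.exterior
    for idx, f in enumerate(config.foci):
        cx, cy = f.center_um
        a_px = f.semi_axes_um[0] / px
        b_px = f.semi_axes_um[1] / px
        # skimage.draw.ellipse rotates CCW in (row, col); our orientation is CCW
        # from +x in (x, y) with y down, so pass the angle directly.
        rr, cc = _draw_ellipse(
            cy / px - 0.5, cx / px - 0.5, b_px, a_px,
            shape=(h, w), rotation=f.orientation_rad,
        )
        ch_foci[rr, cc] = f.peak_intensity
        records.append(
            {
                "focus_id": idx,
                "x_um": cx,
                "y_um": cy,
                "area_um2": f.area_um2,
                "pixel_area_um2": len(rr) * px * px,
                "peak_intensity": f.peak_intensity,
                "min_edge_distance_um": boundary.distance(f.polygon()),
                "below_min_size": f.area_um2 < config.min_focus_area,
            }
        )

    img = np.stack([ch_mask, ch_foci])
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    return img, pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Two-channel colocalisation pairs
# ---------------------------------------------------------------------------

@dataclass
class ColocSimConfig:
    """Noiseless two-channel pair with a specified colocalised fraction.

    Channel 2 signal occupies the left half of the image; channel 1 signal
    is split between pixels inside and outside that region so that exactly
    ``round(colocalised_fraction * n_signal_px)`` of its pixels (hence, at
    constant intensity, the same fraction of its summed intensity) fall
    where channel 2 is above threshold.  The realised fraction is returned
    as ground truth and is exact.
    """

    shape: tuple[int, int] = (64, 64)
    colocalised_fraction: float = 0.5
    n_signal_px: int = 400
    ch1_intensity: float = 1000.0
    ch2_intensity: float = 1000.0
    background: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.colocalised_fraction <= 1.0:
            raise ConfigError("colocalised_fraction must be in [0, 1]")
        h, w = self.shape
        if self.n_signal_px > (w // 2 - 1) * h:
            raise ConfigError("n_signal_px too large for the image shape")
        if self.ch1_intensity <= 0 or self.ch2_intensity <= 0:
            raise ConfigError("signal intensities must be positive")


def generate_coloc_pair(config: ColocSimConfig):
    """Return ``(ch1, ch2, truth)`` where truth holds the realised fraction
    and the thresholds under which it is exact."""
    config.validate()
    h, w = config.shape
    half = w // 2
    ch2 = np.full((h, w), config.background, dtype=float)
    ch2[:, :half] = config.background + config.ch2_intensity

    n_in = int(round(config.colocalised_fraction * config.n_signal_px))
    n_out = config.n_signal_px - n_in
    ch1 = np.full((h, w), config.background, dtype=float)
    inside = [(r, c) for r in range(h) for c in range(half)]
    outside = [(r, c) for r in range(h) for c in range(half, w)]
    for r, c in inside[:n_in]:
        ch1[r, c] = config.background + config.ch1_intensity
    for r, c in outside[:n_out]:
        ch1[r, c] = config.background + config.ch1_intensity

    t1 = config.background + 0.5 * config.ch1_intensity
    t2 = config.background + 0.5 * config.ch2_intensity
    truth = {
        "colocalised_fraction": n_in / config.n_signal_px if config.n_signal_px else 0.0,
        "threshold1": t1,
        "threshold2": t2,
        "n_in": n_in,
        "n_out": n_out,
    }
    return ch1, ch2, truth


# ---------------------------------------------------------------------------
# Adhesion label time series
# ---------------------------------------------------------------------------

@dataclass
class TurnoverSimConfig:
    """Label movie of static disk adhesions that disappear with per-frame
    probability ``disappear_prob`` and appear at Poisson rate
    ``appear_rate`` on free lattice sites."""

    n_frames: int = 20
    n_initial: int = 50
    disappear_prob: float = 0.1
    appear_rate: float = 5.0
    shape: tuple[int, int] = (256, 256)
    site_pitch_px: int = 10
    adhesion_radius_px: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if not 0.0 <= self.disappear_prob <= 1.0:
            raise ConfigError("disappear_prob must be in [0, 1]")
        if self.appear_rate < 0:
            raise ConfigError("appear_rate must be >= 0")
        if self.adhesion_radius_px * 2 >= self.site_pitch_px:
            raise ConfigError("adhesions must fit inside lattice sites")


def generate_fa_timeseries(config: TurnoverSimConfig):
    """Return ``(label_stack, truth)``.

    ``label_stack`` is an int32 array (n_frames, H, W); ``truth`` is a
    DataFrame with one row per adhesion: label, site centre, birth frame and
    death frame (first frame where the object is absent; -1 if it survives
    to the end).  Sites freed by a death are withheld for one frame so a new
    object never overlaps its predecessor's pixels.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    pitch, rad = config.site_pitch_px, config.adhesion_radius_px
    rows = np.arange(pitch // 2 + rad, h - rad, pitch)
    cols = np.arange(pitch // 2 + rad, w - rad, pitch)
    sites = [(r, c) for r in rows for c in cols]
    if config.n_initial > len(sites):
        raise ConfigError("n_initial exceeds available lattice sites")

    order = rng.permutation(len(sites))
    free = [sites[k] for k in order]
    alive: dict[int, tuple[int, int]] = {}
    next_label = 1
    birth: dict[int, int] = {}
    death: dict[int, int] = {}
    site_of: dict[int, tuple[int, int]] = {}

    stack = np.zeros((config.n_frames, h, w), dtype=np.int32)

    def draw_frame(t: int) -> None:
        for lab, (r, c) in alive.items():
            rr, cc = _draw_disk((r, c), rad, shape=(h, w))
            stack[t, rr, cc] = lab

    for _ in range(config.n_initial):
        site = free.pop()
        alive[next_label] = site
        birth[next_label] = 0
        site_of[next_label] = site
        next_label += 1
    draw_frame(0)

    for t in range(1, config.n_frames):
        freed_now: list[tuple[int, int]] = []
        for lab in list(alive):
            if rng.random() < config.disappear_prob:
                freed_now.append(alive.pop(lab))
                death[lab] = t
        n_new = rng.poisson(config.appear_rate)
        n_new = min(n_new, len(free))
        for _ in range(n_new):
            site = free.pop()
            alive[next_label] = site
            birth[next_label] = t
            site_of[next_label] = site
            next_label += 1
        free.extend(freed_now)  # reusable only from the next frame on
        draw_frame(t)

    truth = pd.DataFrame(
        {
            "label": list(birth),
            "site_row": [site_of[k][0] for k in birth],
            "site_col": [site_of[k][1] for k in birth],
            "birth_frame": [birth[k] for k in birth],
            "death_frame": [death.get(k, -1) for k in birth],
        }
    )
    return stack, truth
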