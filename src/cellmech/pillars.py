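"""Micropillar traction-force analysis.

The workflow mirrors the reference-grid method for elastic pillar arrays:

1. localise pillar tops (sub-pixel centroids) in a fluorescence image, or
   take a centroid table directly;
2. fit an ideal lattice (origin + two basis vectors) by least squares to
   the *reference* pillars outside the cell, so that cellular forces cannot
   bias the grid;
3. deviations of every pillar from its ideal site are the displacements;
4. the displacement noise floor is estimated from the reference pillars
   (mean + 2 SD of their deviation magnitudes, ~20 nm in practice);
5. displacements above the floor, within a band at the cell edge, are
   converted to forces with the corrected pillar spring constant.

The spring constant combines Euler-Bernoulli cantilever bending with a
substrate-warping correction accounting for shear, base tilt and base
displacement of a pillar on an elastic half space::

    k_bend = (3/64) pi E D^4 / H^3
    corr   = (16/3)(L/D)^3 / [ (16/3)(L/D)^3 + ((7+6v)/3)(L/D)
                               + 8 T_tilt(v) (L/D)^2 ]
    T_tilt(v) = (1+v)/(2 pi) * { 2(1-v) + (1 - 1/(4(1-v))) }
    k      = k_bend * corr
    E_eff  = 9 k / (4 pi a)

with Young's modulus E (Pa), pillar diameter D, height H, bending length L
(= H unless stated otherwise), Poisson ratio v and pillar radius a = D/2.
Unit conventions: positions um, displacements nm, stiffness N/m
(1 N/m = 1 nN/nm), forces nN.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max


# ---------------------------------------------------------------------------
# Centroid detection
# ---------------------------------------------------------------------------

def detect_pillar_centroids(
    image: np.ndarray, expected_spacing_um: float, px_size_um: float
) -> pd.DataFrame:
    """Sub-pixel pillar centroids from a quasi-periodic spot image.

    Local maxima at roughly the expected spacing seed an iterative
    background-subtracted intensity-weighted centroid in a circular window
    of radius spacing/3 (small enough that neighbouring pillar tails are
    negligible); the window is re-centred on the running estimate until
    convergence.  Returns x_um, y_um with pixel centres at (index + 0.5)
    * px_size.
    """
    img = np.asarray(image, dtype=float)
    spacing_px = expected_spacing_um / px_size_um
    min_dist = max(1, int(round(0.5 * spacing_px)))
    thresh = img.min() + 0.2 * (img.max() - img.min())
    peaks = peak_local_max(img, min_distance=min_dist, threshold_abs=thresh)
    if len(peaks) == 0:
        raise ValueError("no pillar-like maxima found")

    r_win = spacing_px / 3.0
    rows = []
    yy, xx = np.mgrid[0: img.shape[0], 0: img.shape[1]]
    for pr, pc in peaks:
        cy, cx = float(pr), float(pc)
        for _ in range(8):
            r0 = max(int(cy - r_win) - 1, 0)
            r1 = min(int(cy + r_win) + 2, img.shape[0])
            c0 = max(int(cx - r_win) - 1, 0)
            c1 = min(int(cx + r_win) + 2, img.shape[1])
            sub = img[r0:r1, c0:c1]
            sy, sx = yy[r0:r1, c0:c1], xx[r0:r1, c0:c1]
            inside = (sy - cy) ** 2 + (sx - cx) ** 2 <= r_win**2
            wts = np.where(inside, sub - sub[inside].min(), 0.0)
            total = wts.sum()
            if total <= 0:
                break
            ny = float((wts * sy).sum() / total)
            nx = float((wts * sx).sum() / total)
            if abs(ny - cy) < 1e-4 and abs(nx - cx) < 1e-4:
                cy, cx = ny, nx
                break
            cy, cx = ny, nx
        rows.append({"x_um": (cx + 0.5) * px_size_um, "y_um": (cy + 0.5) * px_size_um})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Lattice fitting and displacements
# ---------------------------------------------------------------------------

@dataclass
class PillarLattice:
    """Ideal grid: position(i, j) = origin + i*u1 + j*u2 (um)."""

    origin: np.ndarray
    u1: np.ndarray
    u2: np.ndarray
    residual_rms_um: float = 0.0

    @property
    def spacing(self) -> float:
        return 0.5 * (np.linalg.norm(self.u1) + np.linalg.norm(self.u2))

    @property
    def angle_rad(self) -> float:
        return math.atan2(self.u1[1], self.u1[0])

    def ideal_positions(self, i, j) -> np.ndarray:
        i = np.asarray(i, dtype=float)[:, None]
        j = np.asarray(j, dtype=float)[:, None]
        return self.origin + i * self.u1 + j * self.u2


def fit_reference_grid(observations: pd.DataFrame) -> PillarLattice:
    """Least-squares lattice fit to reference pillars only.

    ``observations`` needs columns i, j, x_um, y_um, is_reference.  Requires
    at least 6 references spanning at least two distinct rows and columns;
    collinear layouts are rejected.
    """
    ref = observations[observations["is_reference"]]
    if len(ref) < 6:
        raise ValueError("need >= 6 reference pillars to fit the grid")
    i = ref["i"].to_numpy(dtype=float)
    j = ref["j"].to_numpy(dtype=float)
    if len(np.unique(i)) < 2 or len(np.unique(j)) < 2:
        raise ValueError("reference pillars must span >= 2 rows and >= 2 columns")
    design = np.column_stack([np.ones_like(i), i, j])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("degenerate (collinear) reference layout")
    target = ref[["x_um", "y_um"]].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coef
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return PillarLattice(origin=coef[0], u1=coef[1], u2=coef[2], residual_rms_um=rms)


def assign_lattice_indices(points_um: np.ndarray, lattice: PillarLattice) -> np.ndarray:
    """Nearest ideal-site index (i, j) for each observed point."""
    basis = np.column_stack([lattice.u1, lattice.u2])
    frac = np.linalg.solve(basis, (np.asarray(points_um) - lattice.origin).T).T
    return np.rint(frac).astype(int)


def index_and_fit(
    points_um: np.ndarray,
    is_reference: np.ndarray,
    spacing_guess_um: float | None = None,
    angle_guess_rad: float | None = None,
    n_iter: int = 3,
) -> tuple[pd.DataFrame, PillarLattice]:
    """Assign lattice indices to raw centroids and fit the reference grid.

    Spacing and orientation default to estimates from the nearest-neighbour
    difference vectors (median distance; circular mean of angles modulo
    90 deg), which tolerates globally rotated lattices.  Nearest-site
    assignment then alternates with least-squares refitting.  Returns the
    indexed observation table and the fitted lattice.
    """
    from scipy.spatial import cKDTree

    pts = np.asarray(points_um, dtype=float)
    if spacing_guess_um is None or angle_guess_rad is None:
        d, nbr = cKDTree(pts).query(pts, k=2)
        vec = pts[nbr[:, 1]] - pts
        if spacing_guess_um is None:
            spacing_guess_um = float(np.median(d[:, 1]))
        if angle_guess_rad is None:
            ang = np.arctan2(vec[:, 1], vec[:, 0])
            angle_guess_rad = float(np.angle(np.exp(4j * ang).mean()) / 4.0)
    ca, sa = math.cos(angle_guess_rad), math.sin(angle_guess_rad)
    lattice = PillarLattice(
        origin=pts.min(axis=0),
        u1=spacing_guess_um * np.array([ca, sa]),
        u2=spacing_guess_um * np.array([-sa, ca]),
    )
    obs = None
    for _ in range(n_iter):
        idx = assign_lattice_indices(pts, lattice)
        idx -= idx.min(axis=0)
        obs = pd.DataFrame(
            {
                "i": idx[:, 0], "j": idx[:, 1],
                "x_um": pts[:, 0], "y_um": pts[:, 1],
                "is_reference": np.asarray(is_reference, dtype=bool),
            }
        )
        lattice = fit_reference_grid(obs)
    return obs, lattice


def compute_displacements(
    observations: pd.DataFrame, lattice: PillarLattice
) -> pd.DataFrame:
    """Deviation of every pillar from its ideal lattice site, in nm.

    Observations farther than spacing/2 from their assigned site are kept
    but flagged ``assignable = False``.
    """
    ideal = lattice.ideal_positions(
        observations["i"].to_numpy(), observations["j"].to_numpy()
    )
    dev_um = observations[["x_um", "y_um"]].to_numpy(dtype=float) - ideal
    dev_nm = dev_um * 1e3
    mag = np.linalg.norm(dev_nm, axis=1)
    return pd.DataFrame(
        {
            "i": observations["i"].to_numpy(),
            "j": observations["j"].to_numpy(),
            "dx_nm": dev_nm[:, 0],
            "dy_nm": dev_nm[:, 1],
            "magnitude_nm": mag,
            "is_reference": observations["is_reference"].to_numpy(dtype=bool),
            "assignable": mag <= 0.5 * lattice.spacing * 1e3,
        }
    )


# ---------------------------------------------------------------------------
# Noise floor and cell-edge band
# ---------------------------------------------------------------------------

@dataclass
class NoiseFloorResult:
    value_nm: float
    n_reference: int
    method: str
    low_confidence: bool


def estimate_noise_floor(
    reference_magnitudes_nm, method: str = "mean_plus_2sd"
) -> NoiseFloorResult:
    """Displacement noise floor from reference-pillar deviation magnitudes.

    Default statistic is mean + 2 SD (a conservative exclusion bound);
    ``p95`` and ``rms`` are available alternatives.  Fewer than 10
    references triggers a warning and a low-confidence flag.
    """
    mags = np.asarray(reference_magnitudes_nm, dtype=float)
    if len(mags) == 0:
        raise ValueError("no reference displacements given")
    low = len(mags) < 10
    if low:
        warnings.warn(
            f"only {len(mags)} reference pillars; noise-floor estimate is low-confidence",
            stacklevel=2,
        )
    if method == "mean_plus_2sd":
        value = mags.mean() + 2.0 * (mags.std(ddof=1) if len(mags) > 1 else 0.0)
    elif method == "p95":
        value = float(np.percentile(mags, 95))
    elif method == "rms":
        value = float(np.sqrt((mags**2).mean()))
    else:
        raise ValueError(f"unknown noise-floor method '{method}'")
    return NoiseFloorResult(float(value), len(mags), method, low)


def select_edge_region(
    cell_mask: np.ndarray, band_width_um: float = 10.0, px_size_um: float = 0.1
) -> np.ndarray:
    """Pixels inside the cell within ``band_width_um`` of the cell boundary.

    The traction read-out is restricted to this peripheral band, where
    adhesions concentrate.  A cell thinner than twice the band is selected
    entirely; a zero band selects nothing.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cell mask")
    dist = ndimage.distance_transform_edt(mask, sampling=px_size_um)
    return mask & (dist <= band_width_um)


# ---------------------------------------------------------------------------
# Pillar mechanics
# ---------------------------------------------------------------------------

def pillar_bending_stiffness(E_pa: float, diameter_um: float, height_um: float) -> float:
    """Cantilever bending stiffness k_bend = (3/64) pi E D^4 / H^3, in N/m."""
    if E_pa <= 0 or diameter_um <= 0 or height_um <= 0:
        raise ValueError("E, D and H must be positive")
    d_m = diameter_um * 1e-6
    h_m = height_um * 1e-6
    return (3.0 / 64.0) * math.pi * E_pa * d_m**4 / h_m**3


def tilt_term(nu: float) -> float:
    """Dimensionless base-tilt factor of the substrate-warping correction.

    T_tilt(v) = (1+v)/(2 pi) * { 2(1-v) + (1 - 1/(4(1-v))) }; equals
    11/(8 pi) at v = 0 and stays finite and positive on [0, 0.5).
    """
    if not 0.0 <= nu < 0.5:
        raise ValueError("Poisson ratio must satisfy 0 <= nu < 0.5")
    return (1.0 + nu) / (2.0 * math.pi) * (
        2.0 * (1.0 - nu) + (1.0 - 1.0 / (4.0 * (1.0 - nu)))
    )


def warping_correction(length_um: float, diameter_um: float, nu: float) -> float:
    """Multiplicative stiffness correction for substrate warping, in (0, 1].

    Ratio of the bending compliance to the total compliance including shear
    and base tilt; tends to 1 for slender pillars (L/D -> inf) and to 0 for
    stubby ones.
    """
    if length_um <= 0 or diameter_um <= 0:
        raise ValueError("L and D must be positive")
    r = length_um / diameter_um
    bend = (16.0 / 3.0) * r**3
    return bend / (bend + (7.0 + 6.0 * nu) / 3.0 * r + 8.0 * tilt_term(nu) * r**2)


def corrected_stiffness(k_bend: float, corr: float) -> float:
    """Warping-corrected spring constant k = k_bend * corr (N/m)."""
    if k_bend <= 0 or not 0 < corr <= 1:
        raise ValueError("k_bend must be positive and corr in (0, 1]")
    return k_bend * corr


def effective_modulus(k_n_per_m: float, radius_um: float) -> float:
    """Equivalent continuous-substrate rigidity E_eff = 9k / (4 pi a), Pa."""
    if k_n_per_m <= 0 or radius_um <= 0:
        raise ValueError("k and a must be positive")
    return 9.0 * k_n_per_m / (4.0 * math.pi * radius_um * 1e-6)


@dataclass
class PillarMechanics:
    """Pillar stiffness chain evaluated from material and geometry inputs.

    E is the substrate Young's modulus in Pa (a required input, never
    defaulted); D, H and the bending length L are in um (L = H unless
    given); nu is the Poisson ratio.
    """

    E_pa: float
    D_um: float
    H_um: float
    nu: float = 0.45
    L_um: float | None = None
    a_um: float = field(init=False)
    k_bend: float = field(init=False)
    T_tilt: float = field(init=False)
    corr: float = field(init=False)
    k: float = field(init=False)
    E_eff: float = field(init=False)

    def __post_init__(self) -> None:
        if self.L_um is None:
            self.L_um = self.H_um
        self.a_um = self.D_um / 2.0
        self.k_bend = pillar_bending_stiffness(self.E_pa, self.D_um, self.H_um)
        self.T_tilt = tilt_term(self.nu)
        self.corr = warping_correction(self.L_um, self.D_um, self.nu)
        self.k = corrected_stiffness(self.k_bend, self.corr)
        self.E_eff = effective_modulus(self.k, self.a_um)

    def report(self) -> dict:
        return {
            "E_pa": self.E_pa, "D_um": self.D_um, "H_um": self.H_um,
            "L_um": self.L_um, "nu": self.nu, "a_um": self.a_um,
            "k_bend_n_per_m": self.k_bend, "T_tilt": self.T_tilt,
            "corr": self.corr, "k_n_per_m": self.k, "E_eff_pa": self.E_eff,
        }


# ---------------------------------------------------------------------------
# Forces
# ---------------------------------------------------------------------------

def displacements_to_forces(
    displacements: pd.DataFrame,
    k_n_per_m: float,
    noise_floor_nm: float = 0.0,
    in_region: np.ndarray | None = None,
    pillar_radius_um: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Convert per-pillar displacements to forces F = k * deviation (nN).

    Only non-reference pillars in the optional region mask whose deviation
    magnitude exceeds the noise floor contribute.  With ``pillar_radius_um``
    given, a per-pillar stress (force over pillar cross-section, kPa) is
    also reported.  Returns the force table and a summary (count, mean,
    median, total magnitude).
    """
    if k_n_per_m <= 0:
        raise ValueError("stiffness must be positive")
    d = displacements
    keep = (~d["is_reference"].to_numpy(dtype=bool)) & d.get(
        "assignable", pd.Series(True, index=d.index)
    ).to_numpy(dtype=bool)
    if in_region is not None:
        keep &= np.asarray(in_region, dtype=bool)
    keep &= d["magnitude_nm"].to_numpy() > noise_floor_nm
    sel = d[keep]
    # 1 N/m * 1 nm = 1 nN
    forces = pd.DataFrame(
        {
            "i": sel["i"].to_numpy(),
            "j": sel["j"].to_numpy(),
            "fx_nN": k_n_per_m * sel["dx_nm"].to_numpy(),
            "fy_nN": k_n_per_m * sel["dy_nm"].to_numpy(),
            "magnitude_nN": k_n_per_m * sel["magnitude_nm"].to_numpy(),
        }
    )
    if pillar_radius_um is not None:
        area_m2 = math.pi * (pillar_radius_um * 1e-6) ** 2
        forces["stress_kpa"] = forces["magnitude_nN"] * 1e-9 / area_m2 / 1e3
    mags = forces["magnitude_nN"].to_numpy()
    summary = {
        "count": int(len(mags)),
        "mean_nN": float(mags.mean()) if len(mags) else 0.0,
        "median_nN": float(np.median(mags)) if len(mags) else 0.0,
        "total_nN": float(mags.sum()),
        "noise_floor_nm": float(noise_floor_nm),
    }
    return forces, summary
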