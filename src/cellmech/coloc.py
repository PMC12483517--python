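"""Thresholded Manders colocalisation and Pearson correlation above threshold.

Implements the analysis of the ImageJ "Colocalisation Threshold" / Coloc2
family: channel thresholds are set automatically by the Costes procedure
(the largest thresholds on the orthogonal-regression line between the two
channels such that the sub-threshold pixels are uncorrelated), and the
thresholded Manders split coefficients report, per channel, the fraction of
above-threshold intensity residing where the *other* channel is also above
its threshold::

    tM1 = sum(ch1 | ch1 > T1, ch2 > T2) / sum(ch1 | ch1 > T1)

and symmetrically for tM2.  Pearson's r above threshold is computed over
pixels where at least one channel exceeds its threshold (zero-zero pixels
excluded).  "Percent volume colocalised" uses pixel counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ColocResult:
    threshold1: float
    threshold2: float
    tm1: float
    tm2: float
    pearson_above_threshold: float
    percent_volume_ch1: float
    percent_volume_ch2: float

    def as_dict(self) -> dict:
        return {
            "threshold1": self.threshold1,
            "threshold2": self.threshold2,
            "tM1": self.tm1,
            "tM2": self.tm2,
            "pearson_above_threshold": self.pearson_above_threshold,
            "percent_volume_ch1": self.percent_volume_ch1,
            "percent_volume_ch2": self.percent_volume_ch2,
        }


def _flat(ch1, ch2, roi=None):
    a = np.asarray(ch1, dtype=float)
    b = np.asarray(ch2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must share a shape")
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        a, b = a[roi], b[roi]
    return a.ravel(), b.ravel()


def _orthogonal_regression(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Total-least-squares line b = intercept + slope * a via the principal
    axis of the joint covariance."""
    cov = np.cov(a, b)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    if abs(v[0]) < 1e-12:
        # principal axis vertical (e.g. uncorrelated channels with unequal
        # variances): fall back to ordinary least squares of ch2 on ch1
        if cov[0, 0] == 0:
            raise ValueError("degenerate regression (constant channel)")
        slope = cov[0, 1] / cov[0, 0]
    else:
        slope = v[1] / v[0]
    intercept = b.mean() - slope * a.mean()
    return slope, intercept


def costes_thresholds(ch1, ch2, roi=None, step: float | None = None) -> tuple[float, float]:
    """Automatic channel thresholds by the iterative Costes procedure.

    Walks candidate T1 values down the channel-1 range (default step: one
    grey level for integer-valued data, else range/512), setting
    T2 = intercept + slope * T1 on the orthogonal regression line, and
    returns the first (highest; ties resolve toward higher threshold) pair
    for which the pixels below *both* thresholds are uncorrelated
    (Pearson <= 0).  Degenerate below-threshold sets count as uncorrelated.
    """
    a, b = _flat(ch1, ch2, roi)
    if a.max() == a.min() or b.max() == b.min():
        raise ValueError("constant channel: thresholds undefined")
    slope, intercept = _orthogonal_regression(a, b)
    if step is None:
        integral = np.all(a == np.round(a)) and np.all(b == np.round(b))
        step = 1.0 if integral else (a.max() - a.min()) / 512.0
    t1 = float(a.max())
    lo = float(a.min())
    while t1 >= lo:
        t2 = intercept + slope * t1
        below = (a <= t1) & (b <= t2)
        r = 1.0
        if below.sum() >= 2:
            sa, sb = a[below], b[below]
            if sa.std() == 0 or sb.std() == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(sa, sb)[0, 1])
        else:
            r = 0.0
        if r <= 0:
            return t1, float(intercept + slope * t1)
        t1 -= step
    return lo, float(intercept + slope * lo)


def manders_split(ch1, ch2, t1: float, t2: float, roi=None, mode: str = "dual") -> tuple[float, float]:
    """Thresholded Manders split coefficients (tM1, tM2).

    ``dual`` (default, the Coloc2 convention): numerator requires both
    channels above threshold, denominator the own channel above threshold.
    ``classical``: denominators over all own signal, colocalised where the
    other channel is merely positive.  Empty above-threshold sets yield NaN.
    """
    a, b = _flat(ch1, ch2, roi)
    if mode == "dual":
        own1, own2 = a > t1, b > t2
        both = own1 & own2
        num1, den1 = a[both].sum(), a[own1].sum()
        num2, den2 = b[both].sum(), b[own2].sum()
    elif mode == "classical":
        num1, den1 = a[b > 0].sum(), a.sum()
        num2, den2 = b[a > 0].sum(), b.sum()
    else:
        raise ValueError("mode must be 'dual' or 'classical'")
    tm1 = num1 / den1 if den1 > 0 else float("nan")
    tm2 = num2 / den2 if den2 > 0 else float("nan")
    return float(tm1), float(tm2)


def pearson_above_threshold(ch1, ch2, t1: float, t2: float, roi=None) -> float:
    """Pearson's r over pixels with at least one channel above threshold.

    NaN when fewer than 2 such pixels exist or either channel is constant
    on the evaluation set.
    """
    a, b = _flat(ch1, ch2, roi)
    sel = (a > t1) | (b > t2)
    if sel.sum() < 2:
        return float("nan")
    sa, sb = a[sel], b[sel]
    if sa.std() == 0 or sb.std() == 0:
        return float("nan")
    return float(np.corrcoef(sa, sb)[0, 1])


def percent_volume_colocalized(ch1, ch2, t1: float, t2: float, roi=None) -> tuple[float, float]:
    """Percent of above-threshold pixels of each channel where the other
    channel is also above threshold (pixel-count convention)."""
    a, b = _flat(ch1, ch2, roi)
    own1, own2 = a > t1, b > t2
    both = own1 & own2
    p1 = 100.0 * both.sum() / own1.sum() if own1.sum() else float("nan")
    p2 = 100.0 * both.sum() / own2.sum() if own2.sum() else float("nan")
    return float(p1), float(p2)


def coloc_analysis(ch1, ch2, roi=None, thresholds: tuple[float, float] | None = None) -> ColocResult:
    """Full two-channel colocalisation read-out.

    Thresholds default to the Costes automatic estimate; pass a pair to
    override (e.g. the exact thresholds of a synthetic construction).
    """
    if thresholds is None:
        t1, t2 = costes_thresholds(ch1, ch2, roi)
    else:
        t1, t2 = thresholds
    tm1, tm2 = manders_split(ch1, ch2, t1, t2, roi)
    r = pearson_above_threshold(ch1, ch2, t1, t2, roi)
    p1, p2 = percent_volume_colocalized(ch1, ch2, t1, t2, roi)
    return ColocResult(float(t1), float(t2), tm1, tm2, r, p1, p2)
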