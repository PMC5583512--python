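"""Quantifying inter-arm alignment from log-scale contact matrices.

The chromosome's two arms meet at *ori*; loci equidistant from *ori* on
opposite arms sit on the anti-diagonal ("secondary diagonal") of an
ori-centred contact map.  This module extracts score profiles along that
secondary diagonal and along single-bin rows ("vertical line"), estimates
how far from the anchor the alignment extends, fits the rate at which that
extent grows in time-resolved experiments, characterises asymmetric
("vertical streak") inter-arm geometries, and provides the paired-t and
Pearson comparisons used on such profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .genome import GenomeSpec
from .hic import ContactMatrix

__all__ = [
    "ScoreProfile",
    "ExtentEstimate",
    "RateFit",
    "RidgeFit",
    "StatResult",
    "secondary_diagonal",
    "vertical_line",
    "arm_marginal",
    "alignment_extent",
    "alignment_rate",
    "ridge_asymmetry",
    "paired_t",
    "pearson",
]


@dataclass
class ScoreProfile:
    """Inter-arm score as a function of genomic offset from the anchor.

    ``offsets_kb`` ascend; for the secondary diagonal they run from 0 to
    half the genome, for vertical-line profiles they are signed ori-offsets.
    ``excluded`` flags offsets dominated by intra-arm contacts (near the
    anchor or its antipode) or masked bins.
    """

    offsets_kb: np.ndarray
    scores: np.ndarray
    excluded: np.ndarray
    anchor_bp: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        self.offsets_kb = np.asarray(self.offsets_kb, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if not (len(self.offsets_kb) == len(self.scores) == len(self.excluded)):
            raise ValueError("profile arrays must have equal length")

    def valid(self) -> tuple[np.ndarray, np.ndarray]:
        keep = ~self.excluded & np.isfinite(self.scores)
        return self.offsets_kb[keep], self.scores[keep]


@dataclass(frozen=True)
class ExtentEstimate:
    extent_kb: float
    background: float
    peak: float
    threshold: float
    method: str = "half_rise_first_down_crossing"
    no_signal: bool = False


@dataclass(frozen=True)
class RateFit:
    slope_kb_per_min: float
    intercept_kb: float
    window_min: tuple[float, float]
    residual_rms: float
    n_points: int


@dataclass
class RidgeFit:
    left_offsets_kb: np.ndarray
    argmax_right_kb: np.ndarray
    lad_slope: float
    angle_deg: float
    deviation_deg: float
    streak: bool
    n_cloud: int


@dataclass(frozen=True)
class StatResult:
    estimate: float
    statistic: float
    p_value: float
    n: int
    sidedness: str = "two-sided"


# ---------------------------------------------------------------------------
# profile extraction


def _require_log(m: ContactMatrix) -> None:
    if m.stage != "log":
        raise ValueError(f"expected a log-stage matrix, got {m.stage!r}")


def _exclusion(offsets_kb: np.ndarray, genome: GenomeSpec, radius_kb: float) -> np.ndarray:
    half = genome.length_bp / 2000.0
    return (offsets_kb <= radius_kb) | (offsets_kb >= half - radius_kb)


def secondary_diagonal(
    m: ContactMatrix,
    genome: GenomeSpec | None = None,
    anchor_bp: int | None = None,
    exclusion_kb: float = 30.0,
) -> ScoreProfile:
    """Score along the secondary diagonal through the anchor (default *ori*).

    score(d) = m[(b_a - k) mod n, (b_a + k) mod n] with d = k * bin_size:
    the contact of loci k bins either side of the anchor.  Offsets within
    ``exclusion_kb`` of the anchor or of its antipode are flagged excluded
    (those bins are dominated by intra-arm contacts on a circle).
    """
    _require_log(m)
    genome = genome or m.genome
    anchor = genome.ori_bp if anchor_bp is None else anchor_bp
    n = m.n_bins
    b = m.bin_of(anchor)
    k = np.arange(n // 2 + 1)
    rows = (b - k) % n
    cols = (b + k) % n
    scores = m.values[rows, cols]
    offsets = k * m.bin_size / 1000.0
    excluded = _exclusion(offsets, genome, exclusion_kb)
    excluded |= m.mask[rows] | m.mask[cols]
    return ScoreProfile(offsets, scores, excluded, anchor_bp=anchor,
                        label="secondary_diagonal")


def vertical_line(
    m: ContactMatrix,
    genome: GenomeSpec | None = None,
    anchor_bp: int | None = None,
) -> ScoreProfile:
    """Contacts of the anchor bin with every bin, indexed by signed ori-offset."""
    _require_log(m)
    genome = genome or m.genome
    anchor = genome.ori_bp if anchor_bp is None else anchor_bp
    n = m.n_bins
    b = m.bin_of(anchor)
    row = m.values[b, :]
    # signed offset of each bin centre from ori, in kb
    idx = np.arange(n)
    base = (idx - m.bin_shift) % n  # un-rotated genomic bin index
    centre = base * m.bin_size + m.bin_size / 2.0
    rel = (centre - genome.ori_bp) % genome.length_bp
    signed = np.where(rel <= genome.length_bp / 2, rel, rel - genome.length_bp) / 1000.0
    order = np.argsort(signed)
    excluded = (m.mask | ~np.isfinite(row))[order]
    return ScoreProfile(signed[order], row[order], excluded, anchor_bp=anchor,
                        label="vertical_line")


def arm_marginal(
    m: ContactMatrix,
    genome: GenomeSpec | None = None,
    anchor_bp: int | None = None,
    arm: str = "left",
    exclusion_kb: float = 30.0,
    median_filter_bins: int = 3,
) -> ScoreProfile:
    """Per-arm inter-arm profile: for each offset d on one arm, the maximum
    (median-filtered) contact score with any offset on the opposite arm.

    Unlike the strict secondary diagonal this follows the alignment band even
    when it runs off the 45-degree line (unequal arm speeds, stalled arms),
    so its down-crossing measures how far alignment has progressed along
    *this* arm.  The inter-arm quadrant is 3x3 median filtered before the
    maximum to keep single noisy bins from inflating it.
    """
    _require_log(m)
    genome = genome or m.genome
    anchor = genome.ori_bp if anchor_bp is None else anchor_bp
    if arm not in ("left", "right"):
        raise ValueError("arm must be 'left' or 'right'")
    n = m.n_bins
    b = m.bin_of(anchor)
    k = np.arange(n // 2 + 1)
    left_bins = (b - k) % n
    right_bins = (b + k) % n
    quad = m.values[np.ix_(left_bins, right_bins)]  # [dL, dR]
    quad_f = ndimage.median_filter(
        np.nan_to_num(quad, nan=np.nanmedian(quad)), size=median_filter_bins
    )
    scores = np.nanmax(quad_f, axis=1) if arm == "left" else np.nanmax(quad_f, axis=0)
    offsets = k * m.bin_size / 1000.0
    excluded = _exclusion(offsets, genome, exclusion_kb)
    excluded |= m.mask[left_bins] if arm == "left" else m.mask[right_bins]
    return ScoreProfile(offsets, scores, excluded, anchor_bp=anchor,
                        label=f"arm_marginal_{arm}")


# ---------------------------------------------------------------------------
# extent and rate


def _moving_median(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x.copy()
    return ndimage.median_filter(x, size=w, mode="nearest")


def alignment_extent(
    profile: ScoreProfile,
    background_window_kb: tuple[float, float] = (1200.0, 1800.0),
    fraction: float = 0.5,
    smooth_bins: int = 3,
) -> ExtentEstimate:
    """Half-rise alignment extent of a secondary-diagonal-type profile.

    background = median score over the distal background window; peak =
    maximum smoothed score (moving median over ``smooth_bins``); threshold =
    background + fraction * (peak - background); extent = largest offset d
    such that every unmasked smoothed score at offsets <= d stays at or above
    the threshold (first down-crossing).  A profile whose peak does not rise
    above background yields extent 0 with the no-signal flag set.
    """
    off, sc = profile.valid()
    if off.size == 0:
        raise ValueError("profile has no usable offsets")
    in_bg = (off >= background_window_kb[0]) & (off <= background_window_kb[1])
    if not in_bg.any():
        raise ValueError("no unmasked offsets inside the background window")
    if not (~in_bg).any():
        raise ValueError("no unmasked offsets outside the background window")
    smoothed = _moving_median(sc, smooth_bins)
    background = float(np.median(sc[in_bg]))
    peak = float(smoothed.max())
    if peak <= background:
        return ExtentEstimate(0.0, background, peak, background, no_signal=True)
    threshold = background + fraction * (peak - background)
    below = smoothed < threshold
    if below[0]:
        extent = 0.0
    else:
        first_down = np.argmax(below) if below.any() else off.size
        extent = float(off[first_down - 1])
    return ExtentEstimate(extent, background, peak, threshold)


def alignment_rate(
    extents: list[tuple[float, float]],
    window_min: tuple[float, float] = (10.0, 25.0),
) -> RateFit:
    """Ordinary least-squares slope of extent (kb) vs time (min) inside the
    window (inclusive)."""
    pts = [(t, e) for t, e in extents if window_min[0] <= t <= window_min[1]]
    if len(pts) < 2:
        raise ValueError("need at least two time points inside the window")
    t = np.array([p[0] for p in pts], dtype=float)
    e = np.array([p[1] for p in pts], dtype=float)
    A = np.vstack([t, np.ones_like(t)]).T
    (slope, intercept), *_ = np.linalg.lstsq(A, e, rcond=None)
    resid = e - (slope * t + intercept)
    return RateFit(float(slope), float(intercept), tuple(window_min),
                   float(np.sqrt(np.mean(resid**2))), len(pts))


# ---------------------------------------------------------------------------
# ridge asymmetry ("vertical streak" geometry)


def ridge_asymmetry(
    m: ContactMatrix,
    genome: GenomeSpec | None = None,
    anchor_bp: int | None = None,
    left_range_kb: tuple[float, float] = (30.0, 500.0),
    right_range_kb: tuple[float, float] = (30.0, 500.0),
    fraction: float = 0.5,
    streak_iqr_ratio: float = 0.25,
) -> RidgeFit:
    """Characterise the geometry of the inter-arm interaction band.

    The inter-arm quadrant (left-arm offset dL x right-arm offset dR from the
    anchor) is 3x3 median filtered; cells scoring above
    background + fraction*(peak - background) form the signal cloud.  The
    band's angle is the principal axis of that cloud (45 deg = symmetric
    alignment; -> 90 deg = vertical streak), reported as the deviation from
    45 deg.  The streak flag is set when the interquartile spread of dL in the
    cloud is less than ``streak_iqr_ratio`` times that of dR.  The
    per-left-offset argmax over dR and its least-absolute-deviation slope are
    retained for inspection.
    """
    _require_log(m)
    genome = genome or m.genome
    anchor = genome.ori_bp if anchor_bp is None else anchor_bp
    n = m.n_bins
    b = m.bin_of(anchor)
    bs_kb = m.bin_size / 1000.0
    kL = np.arange(int(round(left_range_kb[0] / bs_kb)), int(round(left_range_kb[1] / bs_kb)) + 1)
    kR = np.arange(int(round(right_range_kb[0] / bs_kb)), int(round(right_range_kb[1] / bs_kb)) + 1)
    if kL.size == 0 or kR.size == 0:
        raise ValueError("empty offset range")
    quad = m.values[np.ix_((b - kL) % n, (b + kR) % n)]
    filled = np.nan_to_num(quad, nan=np.nanmedian(quad))
    sm = ndimage.median_filter(filled, size=3)
    dL = kL * bs_kb
    dR = kR * bs_kb

    argmax_right = dR[np.argmax(sm, axis=1)]
    lad_slope = _lad_slope(dL, argmax_right)

    peak = float(sm.max())
    background = float(np.median(sm))
    thr = background + fraction * (peak - background)
    sel = sm >= thr
    ii, jj = np.nonzero(sel)
    cloud_L, cloud_R = dL[ii], dR[jj]
    if cloud_L.size < 3:
        angle = 45.0
    else:
        pts = np.vstack([cloud_L - cloud_L.mean(), cloud_R - cloud_R.mean()])
        cov = pts @ pts.T / cloud_L.size
        w, v = np.linalg.eigh(cov)
        principal = v[:, np.argmax(w)]
        angle = float(np.degrees(np.arctan2(abs(principal[1]), abs(principal[0]))))
    deviation = abs(45.0 - angle)
    iqr_L = float(np.subtract(*np.percentile(cloud_L, [75, 25]))) if cloud_L.size else 0.0
    iqr_R = float(np.subtract(*np.percentile(cloud_R, [75, 25]))) if cloud_R.size else 0.0
    streak = cloud_L.size >= 3 and iqr_L < streak_iqr_ratio * iqr_R
    return RidgeFit(dL, argmax_right, lad_slope, angle, deviation, streak,
                    n_cloud=int(cloud_L.size))


def _lad_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-absolute-deviation line slope (median regression)."""
    import statsmodels.api as sm_api

    X = sm_api.add_constant(np.asarray(x, dtype=float))
    try:
        fit = sm_api.QuantReg(np.asarray(y, dtype=float), X).fit(q=0.5)
        return float(fit.params[1])
    except Exception:  # degenerate designs fall back to OLS
        (slope, _), *_ = np.linalg.lstsq(
            np.vstack([x, np.ones_like(x)]).T, y, rcond=None
        )
        return float(slope)


# ---------------------------------------------------------------------------
# statistical comparisons


def paired_t(
    a: ScoreProfile,
    b: ScoreProfile,
    sidedness: str = "two-sided",
) -> StatResult:
    """Paired Student's t test on two score profiles over their shared
    unmasked offsets: d_i = a_i - b_i, t = mean(d) / (sd(d)/sqrt(n)), df = n-1.

    ``sidedness``: "two-sided", "greater" (mean difference > 0) or "less".
    """
    keep = ~a.excluded & ~b.excluded & np.isfinite(a.scores) & np.isfinite(b.scores)
    if len(a.offsets_kb) != len(b.offsets_kb) or not np.allclose(
        a.offsets_kb[keep], b.offsets_kb[keep]
    ):
        raise ValueError("profiles must share offsets")
    d = a.scores[keep] - b.scores[keep]
    n = d.size
    if n < 2:
        raise ValueError("need at least two paired observations")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate differences (zero variance)")
    t = d.mean() / (sd / np.sqrt(n))
    p = _t_pvalue(t, n - 1, sidedness)
    return StatResult(float(d.mean()), float(t), p, n, sidedness)


def pearson(x, y, sidedness: str = "two-sided") -> StatResult:
    """Sample Pearson correlation with p-value from the t transform
    t = r * sqrt((n-2)/(1-r^2)), df = n-2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least three observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("zero variance in x or y")
    r = float((xc * yc).sum() / denom)
    n = x.size
    r_ = min(max(r, -1.0), 1.0)
    if abs(r_) == 1.0:
        t = np.inf * np.sign(r_)
    else:
        t = r_ * np.sqrt((n - 2) / (1 - r_**2))
    p = _t_pvalue(t, n - 2, sidedness)
    return StatResult(r, float(t), p, n, sidedness)


def _t_pvalue(t: float, df: int, sidedness: str) -> float:
    if sidedness == "two-sided":
        return float(2 * stats.t.sf(abs(t), df))
    if sidedness == "greater":
        return float(stats.t.sf(t, df))
    if sidedness == "less":
        return float(stats.t.cdf(t, df))
    raise ValueError(f"unknown sidedness {sidedness!r}")
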