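"""FRAP quantification: normalization, biexponential fits, photobleach correction.

Line FRAP: a thin stripe across condensates is bleached; the bleached
ROI trace is background-subtracted and normalized by the average of
unbleached condensates, (I_frap(t)/I_frap(0)) / (I_unb(t)/I_unb(0)),
which cancels acquisition photobleaching. The normalized recovery is
fit to a biexponential and the half-recovery time t_1/2 extracted from
the fitted curve.

Whole-droplet FRAP: an entire condensate is bleached and recovery
watched over minutes, long enough that photobleaching of the unbleached
droplets matters and varies across the field of view (non-homogeneous
illumination). The decay of each unbleached droplet is fit to
a*exp(-k1 t) + b*exp(-k2 t); the rates are regressed linearly on droplet
position, k_i(x, y) = k_i0 + alpha_i*x + beta_i*y, and the bleached
droplet's trace is divided by the model decay evaluated at its own
centroid, ybar(t) = <a> e^{-k1(x,y) t} + <b> e^{-k2(x,y) t}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize
from scipy.ndimage import binary_dilation, binary_erosion, label
from scipy.optimize import brentq
from skimage.filters import threshold_otsu


@dataclass
class FrapTrace:
    """Measured intensities for one FRAP experiment."""

    time: np.ndarray
    I_frap: np.ndarray                    # bleached-ROI mean intensity
    I_unbleached: list[np.ndarray]        # one trace per unbleached droplet
    I_background: np.ndarray | float
    bleach_frame: int
    unbleached_centroids: np.ndarray | None = None   # (n, 2) as (x, y) = (col, row)
    frap_centroid: tuple[float, float] | None = None

    def __post_init__(self):
        if not self.I_unbleached and self.unbleached_centroids is None:
            pass
        if not (0 < self.bleach_frame < len(self.time)):
            raise ValueError("bleach_frame must fall inside the trace")


@dataclass
class BiExpFit:
    a: float
    b: float
    k1: float                 # 1/s, fast
    k2: float                 # 1/s, slow
    plateau: float
    t_half: float | None      # s; None when the fit failed
    residual_sd: float
    converged: bool


@dataclass
class SpatialDecayModel:
    """Biexponential photobleach decay with rates linear in position."""

    a_mean: float
    b_mean: float
    k1_0: float
    k2_0: float
    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    per_droplet: list[BiExpFit] = field(default_factory=list)

    def k1(self, x: float, y: float) -> float:
        return self.k1_0 + self.alpha1 * x + self.beta1 * y

    def k2(self, x: float, y: float) -> float:
        return self.k2_0 + self.alpha2 * x + self.beta2 * y

    def decay(self, t: np.ndarray, x: float, y: float) -> np.ndarray:
        k1, k2 = self.k1(x, y), self.k2(x, y)
        if k1 <= 0 or k2 <= 0:
            raise ValueError("model predicts non-positive decay rate at this position")
        return self.a_mean * np.exp(-k1 * t) + self.b_mean * np.exp(-k2 * t)


# ---------------------------------------------------------------------------
# Trace extraction from movies
# ---------------------------------------------------------------------------

def segment_droplets_threshold(
    frame: np.ndarray, erode_px: int = 2, min_area: int = 9
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Threshold-segment bright droplets in a (pre-bleach) frame.

    Otsu threshold, connected components, then erosion by ``erode_px``
    so boundary pixels — noisy due to droplet motion — are omitted from
    the averages. Returns (label image, eroded masks, centroids (x, y)).
    """
    thresh = threshold_otsu(frame)
    binary = frame > thresh
    labeled, n = label(binary)
    masks, centroids = [], []
    structure = np.ones((3, 3), dtype=bool)
    for lab in range(1, n + 1):
        mask = labeled == lab
        if mask.sum() < min_area:
            continue
        core = mask
        for _ in range(erode_px):
            core = binary_erosion(core, structure)
        if not core.any():
            core = mask
        rows, cols = np.nonzero(mask)
        masks.append(core)
        centroids.append((cols.mean(), rows.mean()))
    return labeled, masks, np.asarray(centroids).reshape(-1, 2)


def measure_frap_traces(
    movie: np.ndarray,
    bleach_frame: int,
    bleach_roi: tuple[int, int, int, int],
    frame_interval: float = 1.0,
    erode_px: int = 2,
    exclusion_factor: float = 3.0,
) -> FrapTrace:
    """Extract bleached/unbleached/background traces from a FRAP movie.

    Droplets are segmented by threshold on the mean pre-bleach frame.
    The bleached ROI trace averages droplet pixels inside ``bleach_roi``
    (row0, col0, row1, col1). Unbleached droplets within
    ``exclusion_factor`` times the ROI diagonal of the ROI center are
    affected by the bleach strike and removed. Background is the mean
    over non-droplet pixels, per frame.
    """
    movie = np.asarray(movie, dtype=float)
    n = movie.shape[0]
    ref = movie[:bleach_frame].mean(axis=0)
    labeled, masks, centroids = segment_droplets_threshold(ref, erode_px)
    if not masks:
        raise ValueError("no droplets found in the pre-bleach image")
    r0, c0, r1, c1 = bleach_roi
    roi = np.zeros(ref.shape, dtype=bool)
    roi[r0:r1, c0:c1] = True
    droplet_any = labeled > 0
    bleach_mask = roi & droplet_any
    if not bleach_mask.any():
        raise ValueError("bleach ROI contains no droplet pixels")

    roi_center = np.array([(c0 + c1) / 2.0, (r0 + r1) / 2.0])
    exclusion = exclusion_factor * float(np.hypot(r1 - r0, c1 - c0))
    unb_traces, unb_centroids = [], []
    for mask, (cx, cy) in zip(masks, centroids):
        if (mask & roi).any():
            continue
        if np.hypot(cx - roi_center[0], cy - roi_center[1]) < exclusion:
            continue
        unb_traces.append(movie[:, mask].mean(axis=1))
        unb_centroids.append((cx, cy))

    bg_mask = ~binary_dilation(droplet_any, np.ones((3, 3), bool), iterations=2)
    background = movie[:, bg_mask].mean(axis=1) if bg_mask.any() else np.zeros(n)

    return FrapTrace(
        time=np.arange(n) * frame_interval,
        I_frap=movie[:, bleach_mask].mean(axis=1),
        I_unbleached=unb_traces,
        I_background=background,
        bleach_frame=bleach_frame,
        unbleached_centroids=np.asarray(unb_centroids).reshape(-1, 2),
        frap_centroid=tuple(roi_center),
    )


# ---------------------------------------------------------------------------
# Line FRAP
# ---------------------------------------------------------------------------

def normalize_line_frap(trace: FrapTrace) -> np.ndarray:
    """Double-normalized recovery (I_frap/I_frap(0)) / (I_unb/I_unb(0)).

    Background is subtracted from the bleached-ROI trace and every
    unbleached trace; the unbleached traces are averaged; I(0) is the
    mean over pre-bleach frames. Dividing by the unbleached ratio
    cancels acquisition photobleaching that is common to the field.
    """
    if not trace.I_unbleached:
        raise ValueError("no unbleached droplets to normalize against")
    bg = np.asarray(trace.I_background, dtype=float)
    frap = trace.I_frap - bg
    unb = np.mean([u - bg for u in trace.I_unbleached], axis=0)
    pre = slice(0, trace.bleach_frame)
    frap0 = frap[pre].mean()
    unb0 = unb[pre].mean()
    if frap0 <= 0 or unb0 <= 0:
        raise ValueError("non-positive pre-bleach intensity; check background")
    return (frap / frap0) / (unb / unb0)


def _biexp_recovery(t, plateau, a, b, k1, k2):
    return plateau - a * np.exp(-k1 * t) - b * np.exp(-k2 * t)


def _init_rates(t: np.ndarray, deficit: np.ndarray) -> tuple[float, float]:
    """Seed (k_fast, k_slow) from a two-segment log-linear fit of the deficit."""
    pos = deficit > max(1e-9, 1e-6 * np.max(np.abs(deficit)))
    t, d = t[pos], deficit[pos]
    if t.size < 4:
        return 1.0, 0.1
    mid = t.size // 2
    def slope(ts, ds):
        if ts.size < 2 or np.ptp(ts) == 0:
            return 0.5
        return max(-np.polyfit(ts, np.log(ds), 1)[0], 1e-3)
    k_fast = slope(t[: max(mid, 2)], d[: max(mid, 2)])
    k_slow = slope(t[mid:], d[mid:])
    if k_fast < k_slow:
        k_fast, k_slow = k_slow, k_fast
    if k_fast / max(k_slow, 1e-12) < 2:
        k_fast, k_slow = 5 * k_slow, k_slow
    return float(k_fast), float(k_slow)


def fit_biexponential(
    series: np.ndarray,
    time: np.ndarray,
    min_depth: float = 1e-3,
) -> BiExpFit:
    """Fit y(t) = plateau - a e^{-k1 t} - b e^{-k2 t} to a recovery series.

    ``time`` is measured from the bleach; at least 8 points required.
    Rates are bounded to (1e-4, 1e3) 1/s and amplitudes to >= 0; k1/k2
    are seeded from a two-segment log-linear fit of the deficit from the
    final level. t_1/2 is the time at which the fitted curve crosses
    halfway between its post-bleach floor y(0) and fitted plateau,
    solved numerically. A flat series (no recovery depth) is flagged as
    non-converged with t_half = None.
    """
    series = np.asarray(series, dtype=float)
    time = np.asarray(time, dtype=float)
    if series.size < 8:
        raise ValueError("need >= 8 post-bleach points")
    t = time - time[0]
    depth = float(series[-3:].mean() - series[:2].mean())
    if abs(depth) < min_depth or np.ptp(series) < min_depth:
        return BiExpFit(0.0, 0.0, np.nan, np.nan, float(series.mean()),
                        None, float(series.std()), converged=False)

    plateau0 = float(series[-3:].mean())
    k1_0, k2_0 = _init_rates(t, plateau0 - series)
    params = Parameters()
    params.add("plateau", value=plateau0, min=0)
    params.add("a", value=max(0.7 * depth, min_depth), min=0)
    params.add("b", value=max(0.3 * depth, min_depth), min=0)
    params.add("k1", value=k1_0, min=1e-4, max=1e3)
    params.add("k2", value=k2_0, min=1e-4, max=1e3)

    def resid(p):
        return _biexp_recovery(t, p["plateau"], p["a"], p["b"], p["k1"], p["k2"]) - series

    out = minimize(resid, params, method="leastsq")
    p = out.params
    a, b = float(p["a"]), float(p["b"])
    k1, k2 = float(p["k1"]), float(p["k2"])
    if k1 < k2:                       # report fast component first
        k1, k2, a, b = k2, k1, b, a
    plateau = float(p["plateau"])
    residual_sd = float(np.std(resid(p)))
    converged = bool(out.success) and (a + b) > min_depth

    t_half = None
    if converged:
        floor = _biexp_recovery(0.0, plateau, a, b, k1, k2)
        target = 0.5 * (floor + plateau)
        def g(tt):
            return _biexp_recovery(tt, plateau, a, b, k1, k2) - target
        hi = 5.0 / max(min(k1, k2), 1e-4)
        try:
            t_half = float(brentq(g, 0.0, hi))
        except ValueError:
            t_half = None
            converged = False
    return BiExpFit(a, b, k1, k2, plateau, t_half, residual_sd, converged)


# ---------------------------------------------------------------------------
# Whole-droplet FRAP
# ---------------------------------------------------------------------------

def fit_biexp_decay(series: np.ndarray, time: np.ndarray) -> BiExpFit:
    """Fit y(t) = a e^{-k1 t} + b e^{-k2 t} to a photobleach decay.

    The series is normalized by its initial value before fitting so
    a + b ~ 1 and the amplitudes are population fractions.
    """
    series = np.asarray(series, dtype=float)
    time = np.asarray(time, dtype=float)
    if series.size < 8:
        raise ValueError("need >= 8 points for a biexponential decay fit")
    y0 = series[0]
    if y0 <= 0:
        raise ValueError("decay trace must start positive")
    y = series / y0
    t = time - time[0]
    k1_0, k2_0 = _init_rates(t, y)
    params = Parameters()
    params.add("a", value=0.7, min=0)
    params.add("b", value=0.3, min=0)
    params.add("k1", value=k1_0, min=1e-5, max=1e3)
    params.add("k2", value=k2_0, min=1e-5, max=1e3)

    def resid(p):
        return p["a"] * np.exp(-p["k1"] * t) + p["b"] * np.exp(-p["k2"] * t) - y

    out = minimize(resid, params, method="leastsq")
    p = out.params
    a, b, k1, k2 = (float(p[n]) for n in ("a", "b", "k1", "k2"))
    if k1 < k2:
        k1, k2, a, b = k2, k1, b, a
    return BiExpFit(a, b, k1, k2, plateau=0.0, t_half=None,
                    residual_sd=float(np.std(resid(p))),
                    converged=bool(out.success))


def fit_spatial_decay(
    traces: list[np.ndarray],
    centroids: np.ndarray,
    time: np.ndarray,
    min_droplets: int = 6,
) -> SpatialDecayModel:
    """Fit the spatially varying photobleach decay model to unbleached droplets.

    Each droplet's background-subtracted trace is fit to a biexponential
    decay; its fast/slow rates are then regressed linearly on the
    droplet centroid (x, y), giving intercepts (k1_0, k2_0) and
    gradients (alpha, beta) for each component. Amplitudes are averaged
    over droplets.
    """
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if len(traces) != len(centroids):
        raise ValueError("one centroid per trace required")
    if len(traces) < min_droplets:
        raise ValueError(f"need >= {min_droplets} unbleached droplets")
    fits = [fit_biexp_decay(tr, time) for tr in traces]
    k1s = np.array([f.k1 for f in fits])
    k2s = np.array([f.k2 for f in fits])
    design = np.column_stack([np.ones(len(fits)), centroids[:, 0], centroids[:, 1]])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("droplet centroids are collinear; spatial fit is rank-deficient")
    coef1, *_ = np.linalg.lstsq(design, k1s, rcond=None)
    coef2, *_ = np.linalg.lstsq(design, k2s, rcond=None)
    return SpatialDecayModel(
        a_mean=float(np.mean([f.a for f in fits])),
        b_mean=float(np.mean([f.b for f in fits])),
        k1_0=float(coef1[0]), alpha1=float(coef1[1]), beta1=float(coef1[2]),
        k2_0=float(coef2[0]), alpha2=float(coef2[1]), beta2=float(coef2[2]),
        per_droplet=fits,
    )


def correct_whole_drop_frap(
    trace: np.ndarray,
    centroid: tuple[float, float],
    model: SpatialDecayModel,
    time: np.ndarray,
    bleach_frame: int,
    unbleached: list[np.ndarray] | None = None,
    unbleached_centroids: np.ndarray | None = None,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Photobleach-correct a whole-droplet FRAP trace.

    The (background-subtracted) bleached-droplet trace is normalized by
    its pre-bleach mean and divided by the model decay ybar(t) evaluated
    at its centroid (itself normalized to 1 at t=0). The unbleached
    traces, normalized the same way at their own centroids, form the
    expected spread of the data around 1. Returns
    (corrected bleached trace, corrected unbleached traces).
    """
    trace = np.asarray(trace, dtype=float)
    time = np.asarray(time, dtype=float)

    def correct(y, cxy):
        ybar = model.decay(time - time[0], cxy[0], cxy[1])
        if np.any(ybar <= 0):
            raise ValueError("model decay non-positive along the trace")
        # both numerator and denominator are referenced to the same
        # pre-bleach window, so a perfectly modeled droplet maps to 1
        pre = slice(0, bleach_frame)
        return (y / y[pre].mean()) / (ybar / ybar[pre].mean())

    corrected = correct(trace, centroid)
    spread = []
    if unbleached is not None and unbleached_centroids is not None:
        spread = [
            correct(np.asarray(u, dtype=float), c)
            for u, c in zip(unbleached, np.asarray(unbleached_centroids).reshape(-1, 2))
        ]
    return corrected, spread
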