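"""DNA-curtain strand finding and compaction end-tracking.

A curtain movie shows many vertically oriented DNA strands tethered at a
barrier (row 0). Each strand is reduced to a kymogram (time x position)
by averaging the three pixel columns local to the strand. The free DNA
end is tracked per frame as the minimum of the positional derivative of
the Gaussian-smoothed kymogram (the steep intensity drop from DNA to
background), with two filters: positions within an edge margin of the
image border are excluded, and positions deviating more than a few
pixels from a Savitzky-Golay-smoothed trajectory are rejected as
outliers (flagged, never interpolated). A straight line through the
accepted points gives the compaction rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import find_peaks, savgol_filter
from scipy.stats import linregress


class FrameFlag(str, Enum):
    ACCEPTED = "accepted"
    EDGE_EXCLUDED = "edge_excluded"
    OUTLIER_REJECTED = "outlier_rejected"


@dataclass
class Kymogram:
    """Time x position intensity matrix for one DNA strand."""

    intensity: np.ndarray          # [n_frames, n_pixels]
    frame_interval: float = 1.0    # s
    pixel_size: float = 0.16       # um
    strand_id: str = ""

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("kymogram must be 2D (frames x positions)")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("kymogram intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.intensity.shape[1]


@dataclass
class TrackingParams:
    """Knobs of the end tracker; defaults are declared, not fitted."""

    smooth_sigma: float = 1.0    # px, Gaussian smoothing along position
    smooth_sigma_t: float = 0.0  # frames; temporal smoothing biases a moving end
    edge_margin: int = 3         # px excluded at either border
    savgol_window: int = 11      # frames
    savgol_order: int = 2
    outlier_px: float = 3.0      # max deviation from the smoothed trajectory


@dataclass
class EndTrack:
    """Per-frame end positions with quality flags."""

    frame_index: np.ndarray
    end_position: np.ndarray          # px; NaN where not accepted
    raw_position: np.ndarray          # px, unfiltered argmin
    flags: list[FrameFlag]
    frame_interval: float = 1.0
    pixel_size: float = 0.16

    @property
    def accepted(self) -> np.ndarray:
        return np.array([f is FrameFlag.ACCEPTED for f in self.flags])

    @property
    def n_accepted(self) -> int:
        return int(self.accepted.sum())


@dataclass
class CompactionFit:
    """Linear fit of end position vs time over the compaction window."""

    rate_px_per_frame: float
    rate_um_per_s: float
    intercept_px: float
    fit_window: tuple[int, int]
    residual_sd_px: float
    n_points: int
    manually_rejected: bool = False


def find_strands(
    frame: np.ndarray,
    min_separation: int = 3,
    min_strand_rows: int = 10,
    snr: float = 3.0,
) -> list[int]:
    """Locate DNA strands as persistent columns of elevated intensity.

    Columns are candidates when their row-mean profile is a local
    maximum at least ``snr`` robust noise units above the median profile
    and the column stays bright over at least ``min_strand_rows`` rows;
    maxima closer than ``min_separation`` columns merge into one.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        return []
    profile = frame.mean(axis=0)
    med = np.median(profile)
    mad = np.median(np.abs(profile - med))
    noise = 1.4826 * mad
    if noise <= 0:
        noise = profile.std()
    if noise <= 0:
        return []  # perfectly uniform image
    peaks, _ = find_peaks(
        profile, height=med + snr * noise, distance=min_separation
    )
    # snap each peak to the intensity-weighted centroid of its 3-px
    # neighborhood: a strand ROI is 3 columns wide, so the raw argmax
    # inside that plateau is decided by noise
    refined = []
    for p in peaks:
        lo_i, hi_i = max(p - 2, 0), min(p + 3, profile.size)
        w = np.clip(profile[lo_i:hi_i] - med, 0, None)
        if w.sum() > 0:
            p = int(round(np.average(np.arange(lo_i, hi_i), weights=w)))
        refined.append(p)
    peaks = refined
    # persistence along the strand: enough rows above the local threshold
    col_med = np.median(frame)
    col_noise = 1.4826 * np.median(np.abs(frame - col_med))
    thresh = col_med + max(col_noise, 1e-12)
    out = [
        int(p)
        for p in peaks
        if np.count_nonzero(frame[:, p] > thresh) >= min_strand_rows
    ]
    return out


def extract_kymogram(
    movie: np.ndarray,
    strand_column: int,
    frame_interval: float = 1.0,
    pixel_size: float = 0.16,
    strand_id: str = "",
) -> Kymogram:
    """Average the 3 pixel columns centered on a strand, stacked over frames."""
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be 3D (frames x rows x columns)")
    n_cols = movie.shape[2]
    if strand_column < 1 or strand_column > n_cols - 2:
        raise ValueError("strand within 1 px of the image edge")
    kym = movie[:, :, strand_column - 1 : strand_column + 2].mean(axis=2)
    return Kymogram(kym, frame_interval, pixel_size, strand_id or str(strand_column))


def track_dna_end(kymogram: Kymogram, params: TrackingParams | None = None) -> EndTrack:
    """Track the free DNA end through a kymogram.

    Per frame: Gaussian-smooth, take the positional derivative oriented
    from the tether (index 0) outward, and take its argmin within the
    edge margins — the end of the DNA is where intensity drops to
    background. A Savitzky-Golay curve through the raw positions then
    rejects frames deviating by more than ``outlier_px``; rejected and
    edge-locked frames are flagged, never interpolated.
    """
    params = params or TrackingParams()
    n_f, n_p = kymogram.n_frames, kymogram.n_pixels
    if n_f < params.savgol_window:
        raise ValueError("kymogram shorter than the Savitzky-Golay window")
    lo = params.edge_margin
    hi = n_p - params.edge_margin
    if hi - lo < 2:
        raise ValueError("edge margins leave no interior pixels")

    smoothed = gaussian_filter(
        kymogram.intensity, sigma=(params.smooth_sigma_t, params.smooth_sigma)
    )
    deriv = np.gradient(smoothed, axis=1)
    window = deriv[:, lo:hi]
    raw = lo + np.argmin(window, axis=1).astype(float)

    flags = [FrameFlag.ACCEPTED] * n_f
    flags = list(flags)
    at_edge = (raw <= lo) | (raw >= hi - 1)
    for i in np.flatnonzero(at_edge):
        flags[i] = FrameFlag.EDGE_EXCLUDED

    smooth_traj = savgol_filter(raw, params.savgol_window, params.savgol_order)
    deviation = np.abs(raw - smooth_traj)
    for i in np.flatnonzero(deviation > params.outlier_px):
        if flags[i] is FrameFlag.ACCEPTED:
            flags[i] = FrameFlag.OUTLIER_REJECTED

    if not any(f is FrameFlag.ACCEPTED for f in flags):
        raise ValueError("all frames rejected; nothing to track")

    end = raw.copy()
    end[[f is not FrameFlag.ACCEPTED for f in flags]] = np.nan
    return EndTrack(
        frame_index=np.arange(n_f),
        end_position=end,
        raw_position=raw,
        flags=flags,
        frame_interval=kymogram.frame_interval,
        pixel_size=kymogram.pixel_size,
    )


def fit_compaction_rate(
    track: EndTrack,
    fit_window: tuple[int, int] | None = None,
    min_points: int = 2,
) -> CompactionFit:
    """Least-squares line through accepted (time, position) points.

    ``fit_window`` restricts the fit to a frame range (half-open), e.g.
    the portion of the trace before the end reaches the tether. The
    slope is reported both in px/frame and, via the kymogram's pixel
    size and frame interval, in um/s.
    """
    ok = track.accepted
    frames = track.frame_index
    if fit_window is not None:
        lo, hi = fit_window
        ok = ok & (frames >= lo) & (frames < hi)
    else:
        lo, hi = 0, len(frames)
    x = frames[ok].astype(float)
    y = track.end_position[ok]
    if x.size < min_points:
        raise ValueError(f"need >= {min_points} accepted points, got {x.size}")
    if x.size == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        resid_sd = 0.0
    else:
        res = linregress(x, y)
        slope, intercept = res.slope, res.intercept
        resid_sd = float(np.std(y - (slope * x + intercept), ddof=2))
    rate_um_s = slope * track.pixel_size / track.frame_interval
    return CompactionFit(
        rate_px_per_frame=float(slope),
        rate_um_per_s=float(rate_um_s),
        intercept_px=float(intercept),
        fit_window=(int(lo), int(hi)),
        residual_sd_px=resid_sd,
        n_points=int(x.size),
    )
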