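"""Per-track motility statistics for intravital plasma-cell imaging.

A track is one cell's time-ordered 2D/3D positions (micrometres, minutes)
plus two fluorescence channels (YFP and TdTomato). The statistics mirror
common intravital-imaging practice: track velocity (path length / duration),
track displacement velocity (net displacement / duration), time-averaged
mean-squared displacement, the fraction of fast movers (velocity strictly
above 1 um/min), and a two-way subset classification on the mean YFP/TdTomato
intensity ratio (threshold 1.02; LLPCs, with stronger TdTomato, ratio below).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "TrackStats",
    "MSDCurve",
    "track_statistics",
    "msd",
    "fast_fraction",
    "classify_by_ratio",
    "split_at_gaps",
]

FAST_THRESHOLD_UM_MIN = 1.0
RATIO_THRESHOLD = 1.02


@dataclass
class Track:
    """One cell's time-ordered positions and channel intensities.

    ``t`` is in minutes (strictly increasing), ``positions`` is ``(n, d)``
    micrometres with d in {2, 3}; ``ch_yfp``/``ch_tomato`` are per-frame
    intensities. ``metadata`` may carry mouse ID, timepoint day, age group,
    subset/phenotype labels.
    """

    track_id: str
    t: np.ndarray
    positions: np.ndarray
    ch_yfp: np.ndarray
    ch_tomato: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.ch_yfp = np.asarray(self.ch_yfp, dtype=float)
        self.ch_tomato = np.asarray(self.ch_tomato, dtype=float)
        n = self.t.shape[0]
        if self.positions.shape[0] != n or self.ch_yfp.shape[0] != n or self.ch_tomato.shape[0] != n:
            raise ValueError("t, positions and channels must share length")
        if self.positions.shape[1] not in (2, 3):
            raise ValueError("positions must be 2D or 3D")
        if n > 1 and not (np.diff(self.t) > 0).all():
            raise ValueError(f"track {self.track_id}: times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.t.shape[0]


@dataclass
class TrackStats:
    track_id: str
    track_velocity: float        # um/min, path length / duration
    displacement_velocity: float  # um/min, net displacement / duration
    duration: float              # min
    path_length: float           # um
    mean_ratio: float            # mean over frames of ch_yfp / ch_tomato
    subset_label: str | None = None


@dataclass
class MSDCurve:
    """Mean-squared displacement vs time lag.

    ``lags`` in minutes (lag 0 included, MSD 0), ``msd`` in um^2, ``n_pairs``
    the number of frame pairs contributing at each lag; ``ensemble`` marks an
    unweighted mean over per-track curves.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    ensemble: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_min": self.lags, "msd_um2": self.msd, "n_pairs": self.n_pairs}
        )


def track_statistics(track: Track) -> TrackStats:
    """Path-length and displacement velocities plus mean channel ratio.

    Requires at least two frames. Path length sums consecutive-frame
    Euclidean displacements; both velocities divide by total elapsed time,
    so displacement velocity never exceeds track velocity.
    """
    if track.n_frames < 2:
        raise ValueError(
            f"track {track.track_id}: >=2 frames required for velocity statistics"
        )
    if (track.ch_tomato <= 0).any():
        raise ValueError(
            f"track {track.track_id}: non-positive TdTomato intensity, ratio undefined"
        )
    steps = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
    duration = float(track.t[-1] - track.t[0])
    path_length = float(steps.sum())
    net = float(np.linalg.norm(track.positions[-1] - track.positions[0]))
    return TrackStats(
        track_id=track.track_id,
        track_velocity=path_length / duration,
        displacement_velocity=net / duration,
        duration=duration,
        path_length=path_length,
        mean_ratio=float(np.mean(track.ch_yfp / track.ch_tomato)),
        subset_label=track.metadata.get("subset"),
    )


def _track_msd(track: Track, max_lag_frames: int) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged squared displacement over all overlapping frame pairs."""
    pos = track.positions
    n = pos.shape[0]
    msd_vals = np.zeros(max_lag_frames + 1)
    n_pairs = np.zeros(max_lag_frames + 1, dtype=int)
    n_pairs[0] = n
    for lag in range(1, min(max_lag_frames, n - 1) + 1):
        disp = pos[lag:] - pos[:-lag]
        sq = np.einsum("ij,ij->i", disp, disp)
        msd_vals[lag] = sq.mean()
        n_pairs[lag] = sq.shape[0]
    return msd_vals, n_pairs


def msd(tracks, max_lag: float) -> MSDCurve:
    """Ensemble MSD: time-average per track, then unweighted mean over tracks.

    All tracks must share the same frame interval (5% tolerance). The
    per-track time average runs over every overlapping frame pair at each
    integer-frame lag up to ``max_lag`` minutes; the ensemble curve averages
    per-track curves without weighting, so long tracks do not dominate.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("empty track set")
    intervals = []
    for tr in tracks:
        if tr.n_frames < 2:
            continue
        intervals.append(np.diff(tr.t))
    if not intervals:
        raise ValueError("no track has >=2 frames")
    all_dt = np.concatenate(intervals)
    dt = float(np.median(all_dt))
    if (np.abs(all_dt - dt) > 0.05 * dt).any():
        raise ValueError("tracks do not share a common frame interval")
    if max_lag < dt:
        raise ValueError("max_lag is below one frame interval")
    max_lag_frames = int(np.floor(max_lag / dt + 1e-9))
    per_track = np.full((len(tracks), max_lag_frames + 1), np.nan)
    pair_tot = np.zeros(max_lag_frames + 1, dtype=int)
    for i, tr in enumerate(tracks):
        vals, pairs = _track_msd(tr, max_lag_frames)
        avail = pairs > 0
        per_track[i, avail] = vals[avail]
        pair_tot += pairs
    curve = np.nanmean(per_track, axis=0)
    return MSDCurve(
        lags=np.arange(max_lag_frames + 1) * dt,
        msd=curve,
        n_pairs=pair_tot,
        ensemble=True,
    )


def fast_fraction(stats, threshold: float = FAST_THRESHOLD_UM_MIN) -> float:
    """Fraction of tracks with velocity strictly above ``threshold`` um/min."""
    velocities = np.asarray([s.track_velocity for s in stats], dtype=float)
    if velocities.size == 0:
        raise ValueError("empty statistics collection")
    return float((velocities > threshold).mean())


def classify_by_ratio(stats, threshold: float = RATIO_THRESHOLD) -> list[str]:
    """Classify tracks into LLPC-bright vs bulk-dim on the mean YFP/TdTomato ratio.

    LLPCs express more TdTomato, so their YFP/TdTomato ratio falls *below* the
    threshold (default 1.02); a ratio at exactly the threshold is assigned to
    ``bulk_dim``.
    """
    labels = []
    for s in stats:
        r = s.mean_ratio
        if not np.isfinite(r) or r <= 0:
            raise ValueError(f"track {s.track_id}: mean ratio must be finite and positive")
        labels.append("llpc_bright" if r < threshold else "bulk_dim")
    return labels


def split_at_gaps(track: Track, interval: float, tol: float = 0.5) -> list[Track]:
    """Split a track into contiguous segments at missing-frame gaps.

    Frames more than ``(1 + tol) * interval`` minutes apart open a new
    segment; velocities on segments then use actual elapsed time rather than
    interpolating unobserved motion. Segments with a single frame are kept
    (they contribute no velocity statistic).
    """
    if track.n_frames < 2:
        return [track]
    gaps = np.flatnonzero(np.diff(track.t) > (1 + tol) * interval)
    if gaps.size == 0:
        return [track]
    bounds = [0, *list(gaps + 1), track.n_frames]
    out = []
    for seg, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        out.append(
            Track(
                track_id=f"{track.track_id}.{seg}",
                t=track.t[a:b],
                positions=track.positions[a:b],
                ch_yfp=track.ch_yfp[a:b],
                ch_tomato=track.ch_tomato[a:b],
                metadata=dict(track.metadata),
            )
        )
    return out
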