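"""Per-track and ensemble motility statistics for 3D cell tracks.

Quantities follow intravital-imaging conventions: mean velocity (μm/min) is
the mean of per-step speeds; displacement is the straight-line distance from
first to last frame; the meandering index MI = displacement / path length is
1 for perfectly straight motion and tends to 0 for confined motion; the MSD
anomalous exponent α is the log–log slope of the ensemble mean squared
displacement (α≈1 diffusive, α≈2 ballistic, α<1 subdiffusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gcsearch.errors import ValidationError
from gcsearch.tracks_io import Track, TrackSet


@dataclass
class MotilityStats:
    """Scalar motility descriptors of one track."""

    track_id: str
    mean_velocity: float  # μm/min
    displacement: float  # μm
    track_length: float  # μm
    meandering_index: float  # dimensionless, in [0, 1]
    duration: float  # s


@dataclass
class MSDCurve:
    """Ensemble mean squared displacement with a fitted log–log slope."""

    lags: np.ndarray  # seconds, strictly increasing
    msd: np.ndarray  # μm² at each lag
    n_tracks: np.ndarray  # tracks contributing at each lag
    alpha: float  # fitted log-log slope over fit_range
    fit_range: tuple[int, int]  # (first, last) lag index (1-based frames) of the fit


def _step_vectors(track: Track) -> np.ndarray:
    return np.diff(track.positions, axis=0)


def track_stats(track: Track) -> MotilityStats:
    """Compute mean velocity, displacement, path length, MI and duration.

    Mean velocity is the average over steps of step length / step duration,
    reported in μm/min.  With gap-free uniformly sampled tracks this equals
    total path length / total duration.  Zero-length steps contribute zero to
    the speed average (they are real observations of a stationary interval).
    """
    if track.n_frames < 2:
        raise ValidationError(f"track {track.track_id!r}: need >=2 frames for statistics")
    steps = _step_vectors(track)
    step_len = np.linalg.norm(steps, axis=1)
    step_dt = np.diff(track.times)
    mean_velocity = float(np.mean(step_len / step_dt)) * 60.0
    displacement = float(np.linalg.norm(track.positions[-1] - track.positions[0]))
    track_length = float(step_len.sum())
    mi = displacement / track_length if track_length > 0 else 0.0
    return MotilityStats(
        track_id=track.track_id,
        mean_velocity=mean_velocity,
        displacement=displacement,
        track_length=track_length,
        meandering_index=float(min(mi, 1.0)),
        duration=track.duration,
    )


def turn_angles(track: Track) -> np.ndarray:
    """Angles (radians, in [0, π]) between consecutive displacement vectors.

    Zero-length steps have no direction and are skipped: the angle is taken
    between consecutive *moving* steps.  Tracks with fewer than 3 frames give
    an empty result.
    """
    if track.n_frames < 3:
        return np.empty(0)
    steps = _step_vectors(track)
    lens = np.linalg.norm(steps, axis=1)
    moving = steps[lens > 0]
    if moving.shape[0] < 2:
        return np.empty(0)
    a, b = moving[:-1], moving[1:]
    cosang = np.einsum("ij,ij->i", a, b) / (
        np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    )
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def _track_time_avg_msd(track: Track, max_lag: int) -> np.ndarray:
    """Time-averaged MSD of one track at lags 1..max_lag frames (NaN beyond
    the track's reach).  All overlapping frame pairs are used."""
    pos = track.positions
    n = pos.shape[0]
    out = np.full(max_lag, np.nan)
    for lag in range(1, min(max_lag, n - 1) + 1):
        d = pos[lag:] - pos[:-lag]
        out[lag - 1] = np.mean(np.einsum("ij,ij->i", d, d))
    return out


def msd(ts: TrackSet, max_lag_frames: int | None = None, fit_range: tuple[int, int] | None = None) -> MSDCurve:
    """Ensemble MSD curve and anomalous exponent α.

    Each track contributes its time-averaged MSD (over all overlapping pairs)
    at every lag it can reach; the ensemble value at a lag is the unweighted
    mean over contributing tracks.  α is the least-squares slope of
    log(MSD) vs log(lag) over ``fit_range`` (1-based lag frames, inclusive),
    defaulting to lags 1..⌊max observed lag / 4⌋ where the time average is
    well populated.
    """
    if len(ts) == 0:
        raise ValidationError("empty TrackSet")
    longest = max(t.n_frames for t in ts.tracks) - 1
    if max_lag_frames is None:
        max_lag_frames = longest
    if max_lag_frames < 1 or max_lag_frames > longest:
        raise ValidationError(
            f"max_lag_frames={max_lag_frames} exceeds the longest track ({longest} lags)"
        )
    per_track = np.vstack([_track_time_avg_msd(t, max_lag_frames) for t in ts.tracks])
    n_tracks = np.sum(~np.isnan(per_track), axis=0)
    with np.errstate(invalid="ignore"):
        ens = np.nanmean(per_track, axis=0)

    if fit_range is None:
        fit_range = (1, max(2, max_lag_frames // 4))
    lo, hi = fit_range
    lo = max(lo, 1)
    hi = min(hi, max_lag_frames)
    lags_f = np.arange(1, max_lag_frames + 1)
    sel = (lags_f >= lo) & (lags_f <= hi) & (n_tracks > 0) & (ens > 0)
    if sel.sum() >= 2:
        slope, _ = np.polyfit(np.log(lags_f[sel]), np.log(ens[sel]), 1)
        alpha = float(slope)
    else:
        alpha = float("nan")
    return MSDCurve(
        lags=lags_f * ts.frame_interval,
        msd=ens,
        n_tracks=n_tracks,
        alpha=alpha,
        fit_range=(lo, hi),
    )


def stats_table(ts: TrackSet):
    """Per-track MotilityStats as a pandas DataFrame (one row per track)."""
    import pandas as pd

    rows = [track_stats(t).__dict__ | {"category": t.category} for t in ts.tracks]
    return pd.DataFrame(rows)
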