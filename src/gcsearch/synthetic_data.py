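"""Seeded generators for synthetic track tables and centroid sets.

These emulate the statistical structure of tracker exports from intravital
GC imaging so every analysis stage is testable without raw imaging data:
fragment-mode tracks follow the same forward movement law as the agent-based
simulator (speeds LogNormal, turns Beta, per-cell meander probability
LogNormal), sampled at the 30-s imaging cadence; ballistic, brownian, and
stationary modes provide analytically known references (MI = 1, MSD α ≈ 1,
α ≈ 0).  Optional lognormal track-duration censoring mimics objects entering
and leaving the imaging volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gcsearch.abm import SimConfig, init_state, step
from gcsearch.calibration import MotilityModel
from gcsearch.errors import ValidationError
from gcsearch.spatial_stats import HardSphereNullConfig, nnd, place_hard_spheres
from gcsearch.tracks_io import PointSet3D, Track, TrackSet

_MODES = ("fragment", "ballistic", "brownian", "stationary")


@dataclass
class SynthTrackConfig:
    """Parameters of one synthetic track table.

    ``n_frames`` is the nominal track length at ``frame_interval`` seconds;
    if ``duration_censoring`` is set, per-track frame counts are drawn from a
    lognormal with that log-sd around the nominal length (minimum 2 frames),
    emulating tracks truncated by the imaging volume.
    """

    n_tracks: int = 100
    n_frames: int = 60
    frame_interval: float = 30.0  # s
    motility: MotilityModel = field(default_factory=MotilityModel)
    mode: str = "fragment"
    arena_radius: float | None = 81.0  # μm; None = unbounded (non-fragment modes)
    speed: float = 3.4  # μm/min, ballistic/brownian step scale
    jitter: float = 0.05  # μm, stationary-mode positional noise
    duration_censoring: float | None = None  # lognormal sigma on track length
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValidationError(f"unknown mode {self.mode!r}; one of {_MODES}")
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")


def _censored_lengths(cfg: SynthTrackConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.duration_censoring is None:
        return np.full(cfg.n_tracks, cfg.n_frames, dtype=int)
    draws = rng.lognormal(np.log(cfg.n_frames), cfg.duration_censoring, size=cfg.n_tracks)
    return np.clip(np.round(draws).astype(int), 2, cfg.n_frames)


def _fragment_positions(cfg: SynthTrackConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_frames, n_tracks, 3) fragment-law trajectories at the imaging cadence.

    Delegates to the agent-based simulator's own step law (no macrophages),
    run at its native 15-s step and subsampled to ``frame_interval`` — the
    generator and any fitter under test share only the forward model."""
    arena = cfg.arena_radius if cfg.arena_radius is not None else 81.0
    dt = 15.0
    stride = max(1, int(round(cfg.frame_interval / dt)))
    n_steps = (cfg.n_frames - 1) * stride
    sim_cfg = SimConfig(
        gc_radius=arena,
        n_tbm=0,
        tbm_diameter=min(27.0, arena),
        n_fragments=cfg.n_tracks,
        dt=dt,
        duration=max(n_steps * dt / 60.0, dt / 60.0),
        motility=cfg.motility,
        boundary="reflect",  # continuous tracks, no mid-track respawn
    )
    state = init_state(sim_cfg, rng)
    out = np.empty((cfg.n_frames, cfg.n_tracks, 3))
    out[0] = state.frag_pos
    for i in range(n_steps):
        step(state, sim_cfg)
        if (i + 1) % stride == 0:
            out[(i + 1) // stride] = state.frag_pos
    return out


def gen_tracks(cfg: SynthTrackConfig) -> TrackSet:
    """Generate a seeded synthetic TrackSet in the requested mode."""
    rng = np.random.default_rng(cfg.seed)
    n, f = cfg.n_tracks, cfg.n_frames
    dt_min = cfg.frame_interval / 60.0

    if cfg.mode == "fragment":
        pos = _fragment_positions(cfg, rng)
    elif cfg.mode == "ballistic":
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        speeds = cfg.speed * dt_min  # μm per frame
        start = rng.normal(scale=10.0, size=(n, 3))
        t_idx = np.arange(f)[:, None, None]
        pos = start[None] + t_idx * (v * speeds)[None]
    elif cfg.mode == "brownian":
        # isotropic Gaussian steps with RMS step length speed·Δt
        sigma = cfg.speed * dt_min / np.sqrt(3.0)
        steps = rng.normal(scale=sigma, size=(f - 1, n, 3))
        start = rng.normal(scale=10.0, size=(1, n, 3))
        pos = np.concatenate([start, start + np.cumsum(steps, axis=0)])
    else:  # stationary
        start = rng.normal(scale=10.0, size=(1, n, 3))
        pos = start + rng.normal(scale=cfg.jitter, size=(f, n, 3))

    lengths = _censored_lengths(cfg, rng)
    tracks = []
    for j in range(n):
        lj = lengths[j]
        times = np.arange(lj) * cfg.frame_interval
        tracks.append(Track(f"synth-{j:04d}", times, pos[:lj, j, :], category=cfg.mode))
    return TrackSet(tracks, frame_interval=cfg.frame_interval, provenance=f"synthetic:{cfg.mode}")


def gen_centroids(
    n: int,
    mode: str = "random",
    container_radius: float = 81.0,
    exclusion_radius: float = 10.0,
    target_mean_nnd: float | None = None,
    nnd_tolerance: float = 2.0,
    seed: int | None = None,
    max_configs: int = 200_000,
) -> PointSet3D:
    """Centroid sets mirroring the simulator's macrophage placements.

    ``random``: non-overlapping hard spheres uniform in the container.
    ``dispersed``: whole configurations resampled until the mean
    nearest-neighbor distance is within ``nnd_tolerance`` of
    ``target_mean_nnd``.
    """
    if mode not in ("random", "dispersed"):
        raise ValidationError(f"unknown mode {mode!r}")
    cfg = HardSphereNullConfig(
        container_radius=container_radius,
        sphere_radius=exclusion_radius,
        n_spheres=n,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    if mode == "random" or n < 2:
        return place_hard_spheres(cfg, rng)
    if target_mean_nnd is None:
        raise ValidationError("dispersed mode needs target_mean_nnd")
    from gcsearch.errors import PackingError

    for _ in range(max_configs):
        pts = place_hard_spheres(cfg, rng)
        if abs(nnd(pts).mean - target_mean_nnd) <= nnd_tolerance:
            pts.label = f"dispersed n={n} target={target_mean_nnd}"
            return pts
    raise PackingError(
        f"no {n}-point configuration with mean NND within {nnd_tolerance} of "
        f"{target_mean_nnd} μm in {max_configs} resamples"
    )
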