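"""Synthetic optic-flow stimuli: dot clouds, dense flow fields, trial grids.

The stimulus is simulated forward translation of an observer through a rigid
3D cloud of dots.  Heading is an azimuth angle in the horizontal plane
(positive rightward, 0 deg = straight ahead).  Each frame, every visible dot
contributes its instantaneous angular velocity at its rasterized pixel; the
result is a dense grid of (horizontal, vertical) flow components in degrees
of visual angle per frame.

Image geometry is a single linear angle<->pixel mapping (fov/resolution
degrees per pixel) used consistently for rasterization, template placement
and decoding: a dot at 3D position (X, Y, Z) projects to the angular
coordinates (atan(X/Z), atan(Y/Z)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SceneConfig",
    "DotCloud",
    "TrialSpec",
    "FlowSample",
    "make_dot_cloud",
    "flow_frame",
    "render_sequence",
    "make_condition_grid",
    "fit_foe",
]


class ConfigurationError(ValueError):
    """Invalid scene or trial configuration."""


class DegenerateFrameError(RuntimeError):
    """No dot was visible in a frame: the scene is too sparse."""


@dataclass(frozen=True)
class SceneConfig:
    """Scene and camera geometry for flow synthesis.

    Defaults reproduce the simulation stimulus: 10,000 dots viewed through a
    90 deg square field digitized at 128x128 pixels, observer translating at
    1.5 m/s through a volume spanning depths 1.5-9 m.  ``lateral_extent`` is
    the half-width of the dot volume in X and Y; the default fills the field
    of view out to the far depth plane.  ``frame_rate_equivalent`` converts
    metres per second into metres per frame; one frame is one model time
    step.
    """

    n_dots: int = 10_000
    depth_range: tuple[float, float] = (1.5, 9.0)
    lateral_extent: float = 9.0
    speed: float = 1.5
    fov: float = 90.0
    resolution: int = 128
    frame_rate_equivalent: float = 60.0

    def __post_init__(self) -> None:
        near, far = self.depth_range
        if self.n_dots <= 0:
            raise ConfigurationError("n_dots must be positive")
        if not (0.0 < near < far):
            raise ConfigurationError("depth_range must satisfy 0 < near < far")
        if self.fov <= 0 or self.resolution <= 0:
            raise ConfigurationError("fov and resolution must be positive")
        if self.lateral_extent <= 0 or self.speed < 0:
            raise ConfigurationError("lateral_extent/speed out of range")

    @property
    def deg_per_px(self) -> float:
        return self.fov / self.resolution

    @property
    def center_px(self) -> float:
        # symmetric mapping: azimuth 0 falls midway between the two center
        # columns, so the stimulus grid and template bank are mirror-symmetric
        return (self.resolution - 1) / 2.0

    def azimuth_of_col(self, col):
        return (np.asarray(col, float) - self.center_px) * self.deg_per_px

    def col_of_azimuth(self, az_deg):
        return np.asarray(az_deg, float) / self.deg_per_px + self.center_px

    def elevation_of_row(self, row):
        return (self.center_px - np.asarray(row, float)) * self.deg_per_px

    def row_of_elevation(self, el_deg):
        return self.center_px - np.asarray(el_deg, float) / self.deg_per_px


@dataclass
class DotCloud:
    """Positions (n, 3) of cloud dots in the observer frame, metres.

    Axes: X rightward, Y upward, Z forward (depth).  ``rng`` carries the
    stream used for recycling so that a trial is one reproducible draw.
    """

    positions: np.ndarray
    rng: np.random.Generator

    @property
    def n_dots(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class TrialSpec:
    """One trial of the heading-switch paradigm.

    Frames are 1-based.  Frames before ``switch_frame`` use the preswitch
    heading, frames at and after it the postswitch heading.  Frames listed
    in ``blackout_frames`` carry no optic flow (all-zero, masked invalid).
    """

    preswitch_heading: float
    switch_angle: float
    n_frames: int
    switch_frame: int
    blackout_frames: frozenset[int] = frozenset()
    condition_label: str = "exp1"
    repetition: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.switch_frame > self.n_frames or self.switch_frame < 1:
            raise ConfigurationError("switch_frame must lie within the trial")
        if any(f < 1 or f > self.n_frames for f in self.blackout_frames):
            raise ConfigurationError("blackout_frames outside [1, n_frames]")

    @property
    def postswitch_heading(self) -> float:
        return self.preswitch_heading + self.switch_angle

    def heading_at(self, frame: int) -> float:
        return (
            self.preswitch_heading
            if frame < self.switch_frame
            else self.postswitch_heading
        )


@dataclass
class FlowSample:
    """A trial's dense flow sequence: (n_frames, H, W, 2) plus metadata.

    Last axis is (horizontal, vertical) flow in degrees per frame, positive
    rightward/upward.  ``valid_mask[t]`` is False on blackout frames.
    """

    flow: np.ndarray
    valid_mask: np.ndarray
    spec: TrialSpec

    @property
    def n_frames(self) -> int:
        return self.flow.shape[0]


def make_dot_cloud(config: SceneConfig, seed: int) -> DotCloud:
    """Draw ``config.n_dots`` dots uniformly in the scene volume.

    The volume is the box |X|, |Y| <= lateral_extent, near <= Z <= far.
    Identical seeds give bitwise-identical clouds.
    """
    rng = np.random.default_rng(seed)
    near, far = config.depth_range
    ext = config.lateral_extent
    xy = rng.uniform(-ext, ext, size=(config.n_dots, 2))
    z = rng.uniform(near, far, size=(config.n_dots, 1))
    return DotCloud(positions=np.concatenate([xy, z], axis=1), rng=rng)


def _heading_velocity(heading_deg: float, config: SceneConfig) -> np.ndarray:
    """Observer translation per frame (metres) for a horizontal-plane heading."""
    th = math.radians(heading_deg)
    step = config.speed / config.frame_rate_equivalent
    return np.array([step * math.sin(th), 0.0, step * math.cos(th)])


def dot_flow(positions: np.ndarray, heading: float, config: SceneConfig):
    """Per-dot angular position and instantaneous angular velocity.

    Returns ``(az, el, u, v)`` in degrees: azimuth/elevation of each dot and
    its flow components in degrees per frame.  Translation-only motion: the
    dot velocity in the observer frame is minus the observer velocity, and
    the angular rates follow from differentiating atan(X/Z) and atan(Y/Z).
    """
    X, Y, Z = positions[:, 0], positions[:, 1], positions[:, 2]
    vel = _heading_velocity(heading, config)  # metres per frame
    dX, dY, dZ = -vel[0], -vel[1], -vel[2]
    az = np.degrees(np.arctan2(X, Z))
    el = np.degrees(np.arctan2(Y, Z))
    u = np.degrees((dX * Z - X * dZ) / (X**2 + Z**2))
    v = np.degrees((dY * Z - Y * dZ) / (Y**2 + Z**2))
    return az, el, u, v


def flow_frame(
    cloud: DotCloud, heading: float, config: SceneConfig
) -> tuple[np.ndarray, DotCloud]:
    """Rasterize one frame of flow and advect the cloud one frame forward.

    Each visible dot deposits its angular-velocity vector at its nearest
    pixel; multiple dots on a pixel are averaged, empty pixels stay zero.
    Dots that leave the volume or pass the near plane are recycled into the
    far half of the volume at a fresh lateral position.
    """
    if abs(heading) > config.fov / 2:
        raise ConfigurationError("heading outside the field of view")
    pos = cloud.positions
    az, el, u, v = dot_flow(pos, heading, config)

    half = config.fov / 2.0
    vis = (pos[:, 2] > 0) & (np.abs(az) < half) & (np.abs(el) < half)
    if not np.any(vis):
        raise DegenerateFrameError("no visible dots in frame")

    res = config.resolution
    cols = np.rint(config.col_of_azimuth(az[vis])).astype(int)
    rows = np.rint(config.row_of_elevation(el[vis])).astype(int)
    cols = np.clip(cols, 0, res - 1)
    rows = np.clip(rows, 0, res - 1)

    grid = np.zeros((res, res, 2))
    counts = np.zeros((res, res))
    np.add.at(grid, (rows, cols, 0), u[vis])
    np.add.at(grid, (rows, cols, 1), v[vis])
    np.add.at(counts, (rows, cols), 1.0)
    hit = counts > 0
    grid[hit] /= counts[hit][:, None]

    # advect and recycle
    new_pos = pos - _heading_velocity(heading, config)
    near, far = config.depth_range
    ext = config.lateral_extent
    out = (
        (new_pos[:, 2] < near)
        | (new_pos[:, 2] > far)
        | (np.abs(new_pos[:, 0]) > ext)
        | (np.abs(new_pos[:, 1]) > ext)
    )
    n_out = int(out.sum())
    if n_out:
        rng = cloud.rng
        fresh = np.empty((n_out, 3))
        fresh[:, :2] = rng.uniform(-ext, ext, size=(n_out, 2))
        fresh[:, 2] = rng.uniform((near + far) / 2.0, far, size=n_out)
        new_pos = new_pos.copy()
        new_pos[out] = fresh
    return grid, DotCloud(positions=new_pos, rng=cloud.rng)


def render_sequence(spec: TrialSpec, config: SceneConfig | None = None) -> FlowSample:
    """Render the full flow sequence for one trial.

    Blackout frames are emitted as all-zero flow with ``valid_mask`` False;
    the scene still advances underneath them (the world keeps moving while
    the display is dark).
    """
    config = config or SceneConfig()
    cloud = make_dot_cloud(config, spec.seed)
    res = config.resolution
    flow = np.zeros((spec.n_frames, res, res, 2))
    valid = np.ones(spec.n_frames, dtype=bool)
    for t in range(1, spec.n_frames + 1):
        grid, cloud = flow_frame(cloud, spec.heading_at(t), config)
        if t in spec.blackout_frames:
            valid[t - 1] = False
        else:
            flow[t - 1] = grid
    return FlowSample(flow=flow, valid_mask=valid, spec=spec)


PRESWITCH_HEADINGS = (0.0, -6.0, 6.0)
SWITCH_ANGLES = (-12.0, -6.0, -3.0, 3.0, 6.0, 12.0)

#: Experiment-2 blackout schedule: preswitch flow on frames 1..29, postswitch
#: from frame 30.  preblackout blanks frame 28 (one preswitch frame between
#: blackout and switch); midblackout inserts one blank frame at the switch
#: (33-frame trial, postswitch frames 31-33); postblackout blanks frames
#: 31-32, so a single postswitch frame precedes a blackout that runs to the
#: end of the trial.
EXP2_SCHEDULE: dict[str, dict] = {
    "noblackout": {"n_frames": 32, "blackout": frozenset(), "switch_frame": 30},
    "preblackout": {"n_frames": 32, "blackout": frozenset({28}), "switch_frame": 30},
    "midblackout": {"n_frames": 33, "blackout": frozenset({30}), "switch_frame": 31},
    "postblackout": {
        "n_frames": 32,
        "blackout": frozenset({31, 32}),
        "switch_frame": 30,
    },
}


def _trial_seeds(base_seed: int, n: int) -> np.ndarray:
    # one independent stream per trial; values kept in int32 range
    state = np.random.SeedSequence(entropy=base_seed).generate_state(n, dtype=np.uint64)
    return (state % (2**31)).astype(np.int64)


def make_condition_grid(
    experiment: int, n_reps: int = 10, base_seed: int = 0
) -> list[TrialSpec]:
    """Build the full trial grid for an experiment, switch plus no-switch.

    Experiment 1: 3 preswitch headings x 6 switch angles = 18 conditions,
    34-frame trials, switch at frame 30.  Experiment 2: the same 18 heading
    conditions crossed with 4 blackout conditions, 32-frame protocol (33 for
    midblackout).  Each switch spec is paired with a no-switch spec at the
    same postswitch heading, trial length and seed (identical dot
    placement), so the bias subtraction is matched; duplicate no-switch
    specs are dropped.  Only dot placement varies across repetitions.
    """
    if experiment not in (1, 2):
        raise ConfigurationError(f"unknown experiment {experiment!r}")

    if experiment == 1:
        variants = [
            ("exp1", {"n_frames": 34, "blackout": frozenset(), "switch_frame": 30})
        ]
    else:
        variants = list(EXP2_SCHEDULE.items())
    n_switch = n_reps * len(PRESWITCH_HEADINGS) * len(SWITCH_ANGLES) * len(variants)
    seeds = _trial_seeds(base_seed, n_switch)

    specs: list[TrialSpec] = []
    seen_noswitch = set()
    idx = 0
    for rep in range(n_reps):
        for pre in PRESWITCH_HEADINGS:
            for sw in SWITCH_ANGLES:
                for label, sched in variants:
                    seed = int(seeds[idx])
                    idx += 1
                    specs.append(
                        TrialSpec(
                            preswitch_heading=pre,
                            switch_angle=sw,
                            n_frames=sched["n_frames"],
                            switch_frame=sched["switch_frame"],
                            blackout_frames=sched["blackout"],
                            condition_label=label,
                            repetition=rep,
                            seed=seed,
                        )
                    )
                    key = (pre + sw, sched["n_frames"], rep)
                    if key not in seen_noswitch:
                        seen_noswitch.add(key)
                        specs.append(
                            TrialSpec(
                                preswitch_heading=pre + sw,
                                switch_angle=0.0,
                                n_frames=sched["n_frames"],
                                switch_frame=sched["switch_frame"],
                                blackout_frames=frozenset(),
                                condition_label="noswitch",
                                repetition=rep,
                                seed=seed,
                            )
                        )
    return specs


def fit_foe(grid: np.ndarray, config: SceneConfig) -> tuple[float, float]:
    """Least-squares focus of expansion of one dense flow frame, in degrees.

    Each nonzero flow vector defines a line through its pixel along the
    vector; the FoE is the least-squares intersection of those lines.  The
    fit is done in gnomonic (tangent-plane) coordinates, where flow from
    pure translation is exactly radial, so the equidistant pixel grid's
    mild angular distortion does not bias the estimate.  Returns
    (azimuth, elevation) in degrees.
    """
    rows, cols = np.nonzero(np.any(grid != 0.0, axis=2))
    if rows.size < 2:
        raise DegenerateFrameError("too few flow vectors to locate the FoE")
    az = np.radians(config.azimuth_of_col(cols))
    el = np.radians(config.elevation_of_row(rows))
    u = np.radians(grid[rows, cols, 0])
    v = np.radians(grid[rows, cols, 1])
    # gnomonic position and flow: x = tan(az), xdot = azdot * sec^2(az)
    x, y = np.tan(az), np.tan(el)
    xd = u * (1.0 + x**2)
    yd = v * (1.0 + y**2)
    # line constraint: yd*(x0 - x) - xd*(y0 - y) = 0
    A = np.stack([yd, -xd], axis=1)
    b = yd * x - xd * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return float(np.degrees(np.arctan(sol[0]))), float(np.degrees(np.arctan(sol[1])))
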