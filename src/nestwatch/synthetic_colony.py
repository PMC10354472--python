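"""Synthetic colony generator.

Produces trajectories, thermal stacks, probe logs and censuses with the
statistical structure the downstream analysis assumes, plus ground truth for
parameter-recovery tests:

* two-state (moving/stationary) bee motion whose active->inactive rate rises
  at low body temperature, and rises further under imidacloprid below a
  threshold body temperature;
* cold-induced drift toward the brood centre of mass;
* a 2-D thermal field warmer near brood and where bees aggregate, seen by a
  linear sensor with Gaussian noise;
* a smooth (affine + sinusoidal) warp between tracking and thermal cameras;
* Poisson colony productivity with a size x cold x imidacloprid interaction.

Body temperature equals the local field temperature at the bee's position
(no thermal inertia).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import CensusRecord, Detection, NestMap, VideoSegment


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# temperature protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolSegment:
    duration_min: float
    start_C: float
    end_C: float


@dataclass(frozen=True)
class TemperatureProtocol:
    """Piecewise-linear air-temperature programme."""

    segments: tuple[ProtocolSegment, ...]

    def __post_init__(self) -> None:
        prev_end = None
        for seg in self.segments:
            if seg.duration_min <= 0:
                raise SimulationError(f"segment duration must be > 0, got {seg.duration_min}")
            if prev_end is not None and abs(seg.start_C - prev_end) > 1e-9:
                raise SimulationError(
                    f"discontinuous protocol: segment starts at {seg.start_C}degC "
                    f"but previous ended at {prev_end}degC"
                )
            prev_end = seg.end_C

    @property
    def total_duration_min(self) -> float:
        return sum(s.duration_min for s in self.segments)

    @property
    def min_temperature_C(self) -> float:
        return min(min(s.start_C, s.end_C) for s in self.segments)

    def temperature_at(self, t_min):
        """Air temperature (degC) at time(s) in minutes from protocol start."""
        t = np.asarray(t_min, dtype=float)
        out = np.empty_like(t)
        start = 0.0
        remaining = np.ones(t.shape, dtype=bool)
        for seg in self.segments:
            end = start + seg.duration_min
            m = remaining & (t <= end + 1e-12)
            frac = np.clip((t[m] - start) / seg.duration_min, 0.0, 1.0)
            out[m] = seg.start_C + frac * (seg.end_C - seg.start_C)
            remaining &= ~m
            start = end
        out[remaining] = self.segments[-1].end_C  # hold past the end
        out[np.asarray(t_min, dtype=float) < 0] = self.segments[0].start_C
        return out if out.shape else float(out)


def make_queenright_protocol() -> TemperatureProtocol:
    """Queenright cold-exposure profile: 4.5 h total, minimum 10 degC."""
    return TemperatureProtocol((
        ProtocolSegment(10.0, 24.0, 24.0),
        ProtocolSegment(60.0, 24.0, 10.0),
        ProtocolSegment(120.0, 10.0, 10.0),
        ProtocolSegment(60.0, 10.0, 24.0),
        ProtocolSegment(20.0, 24.0, 24.0),
    ))


def make_microcolony_protocol() -> TemperatureProtocol:
    """Microcolony cold-stress trial: 22->10 degC over 65 min, 3 h hold, ramp back."""
    return TemperatureProtocol((
        ProtocolSegment(65.0, 22.0, 10.0),
        ProtocolSegment(180.0, 10.0, 10.0),
        ProtocolSegment(65.0, 10.0, 22.0),
    ))


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WarpSpec:
    """Smooth tracking->thermal mapping: affine plus a sinusoidal ripple."""

    scale_x: float = 0.16
    scale_y: float = 0.16
    shear: float = 0.01
    offset_x_px: float = 8.0
    offset_y_px: float = 5.0
    ripple_amp_px: float = 2.0
    ripple_wavelength_px: float = 2000.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) tracking-px points into thermal-px coordinates."""
        p = np.asarray(points, dtype=float)
        x, y = p[..., 0], p[..., 1]
        w = 2.0 * np.pi / self.ripple_wavelength_px
        u = self.offset_x_px + self.scale_x * x + self.shear * y \
            + self.ripple_amp_px * np.sin(w * y)
        v = self.offset_y_px + self.scale_y * y + self.shear * x \
            + self.ripple_amp_px * np.cos(w * x)
        return np.stack([u, v], axis=-1)


@dataclass(frozen=True)
class GrowthCoefficients:
    """Poisson log-link productivity model coefficients."""

    b0: float = np.log(60.0)
    b_size: float = 0.8
    b_cold: float = -0.4
    b_imid: float = -0.4
    b_3way: float = 0.5   # cold x imid x log10(size): combined deficit shrinks with size
    block_sd: float = 0.05


@dataclass(frozen=True)
class SimParams:
    """All knobs of the colony simulator; seed-fixed output is reproducible."""

    n_bees: int = 8
    seed: int = 0
    imidacloprid: bool = False
    # activity transition model (per-frame probabilities)
    p_ai_base: float = 0.08
    p_ia_base: float = 0.15
    p_ai_slope_per_C: float = 0.010   # added per degC of body temp below 24
    delta_ai_imid: float = 0.0        # added below T_thresh when imidacloprid
    T_thresh_C: float = 18.0
    # movement
    thermotaxis_gain_px_per_C: float = 0.1  # drift per degC of air temp below 24
    step_scale_px: float = 12.0
    init_spread_px: float = 250.0
    # thermal field (kernel K is Gaussian)
    body_heat_C: float = 0.6
    brood_heat_C: float = 0.8
    kernel_sd_px: float = 70.0        # in thermal px
    # sensor model
    sensor_gain: float = 0.04         # degC per count
    sensor_offset: float = -10.0      # degC
    sensor_noise_sd: float = 1.25     # in counts (~0.05 degC at default gain)
    warp: WarpSpec = field(default_factory=WarpSpec)
    growth: GrowthCoefficients = field(default_factory=GrowthCoefficients)
    # recording cadence (queenright defaults); clip_interval None -> emit all
    frame_rate_hz: float = 1.5
    clip_duration_s: float = 120.0
    clip_interval_min: float | None = 9.5

    def __post_init__(self) -> None:
        for name in ("p_ai_base", "p_ia_base", "delta_ai_imid"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.n_bees < 1:
            raise SimulationError("n_bees must be >= 1")

    def p_ai(self, T_body) -> np.ndarray:
        """Active->inactive per-frame probability as a function of body temp."""
        T = np.asarray(T_body, dtype=float)
        p = self.p_ai_base + self.p_ai_slope_per_C * np.maximum(0.0, 24.0 - T)
        if self.imidacloprid and self.delta_ai_imid:
            p = p + self.delta_ai_imid * (T < self.T_thresh_C)
        return np.clip(p, 0.0, 1.0)


@dataclass
class GroundTruth:
    """Oracle record aligned 1:1 with emitted detections."""

    per_frame: pd.DataFrame  # video_id, frame_index, time_s, bee_id, active, T_body_C, T_air_C
    warp: WarpSpec
    sensor_gain: float
    sensor_offset: float
    growth: GrowthCoefficients | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# colony simulation
# ---------------------------------------------------------------------------

def _gaussian_kernel_sums(targets: np.ndarray, sources: np.ndarray, sd: float) -> np.ndarray:
    """Sum over sources of exp(-d^2 / (2 sd^2)) at each target point."""
    if len(sources) == 0:
        return np.zeros(len(targets))
    d2 = ((targets[:, None, :] - sources[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * sd * sd)).sum(axis=1)


def local_field_temperature(
    points_thermal: np.ndarray,
    bee_points_thermal: np.ndarray,
    brood_points_thermal: np.ndarray,
    ambient_C: float,
    params: SimParams,
) -> np.ndarray:
    """True field temperature at points (thermal-px coords): ambient + heat sources."""
    t = ambient_C + params.brood_heat_C * _gaussian_kernel_sums(
        points_thermal, brood_points_thermal, params.kernel_sd_px
    )
    t = t + params.body_heat_C * _gaussian_kernel_sums(
        points_thermal, bee_points_thermal, params.kernel_sd_px
    )
    return t


def simulate_colony(
    params: SimParams,
    protocol: TemperatureProtocol,
    nest: NestMap,
    colony_id: str = "sim",
) -> tuple[list[VideoSegment], GroundTruth]:
    """Simulate tagged-bee motion under a temperature protocol.

    Per frame, each bee's body temperature is the local field temperature at
    its position; the activity state updates as a two-state Markov chain with
    ``p_ai`` rising at low body temperature (plus an imidacloprid offset below
    the threshold); active bees take a Gaussian step plus a drift toward the
    brood centre of mass proportional to how far air temperature is below
    24 degC. Detections are emitted on the configured clip cadence.
    """
    if not nest.brood_centroids:
        raise SimulationError("nest has no brood centroids: thermotaxis target undefined")
    rng = np.random.default_rng(params.seed)
    x0, y0, x1, y1 = nest.arena_bounds
    brood_track = np.asarray(nest.brood_centroids, dtype=float)
    com = brood_track.mean(axis=0)
    brood_thermal = params.warp.apply(brood_track)
    kernel_sd_track = params.kernel_sd_px / ((params.warp.scale_x + params.warp.scale_y) / 2.0)

    dt_s = 1.0 / params.frame_rate_hz
    n_frames = int(round(protocol.total_duration_min * 60.0 * params.frame_rate_hz))
    times_s = np.arange(n_frames) * dt_s
    t_air = protocol.temperature_at(times_s / 60.0)

    # emission mask on the clip cadence
    if params.clip_interval_min is None:
        clip_id = np.zeros(n_frames, dtype=int)
        emit = np.ones(n_frames, dtype=bool)
    else:
        interval_s = params.clip_interval_min * 60.0
        clip_id = np.floor(times_s / interval_s).astype(int)
        within = times_s - clip_id * interval_s
        emit = within < params.clip_duration_s

    if np.isfinite(params.init_spread_px):
        pos = com[None, :] + rng.normal(0.0, params.init_spread_px,
                                        size=(params.n_bees, 2))
    else:  # inf -> uniform over the arena (stationary under pure diffusion)
        pos = rng.uniform((x0, y0), (x1, y1), size=(params.n_bees, 2))
    pos[:, 0] = np.clip(pos[:, 0], x0, x1)
    pos[:, 1] = np.clip(pos[:, 1], y0, y1)
    active = rng.random(params.n_bees) < 0.5

    n_emit = int(emit.sum())
    rec_video = np.empty(n_emit * params.n_bees, dtype=object)
    rec = {
        "frame_index": np.empty(n_emit * params.n_bees, dtype=int),
        "time_s": np.empty(n_emit * params.n_bees),
        "bee": np.empty(n_emit * params.n_bees, dtype=int),
        "x": np.empty(n_emit * params.n_bees),
        "y": np.empty(n_emit * params.n_bees),
        "active": np.empty(n_emit * params.n_bees, dtype=bool),
        "T_body": np.empty(n_emit * params.n_bees),
        "T_air": np.empty(n_emit * params.n_bees),
    }
    positions_per_emitted_frame = np.empty((n_emit, params.n_bees, 2))
    emitted_times = np.empty(n_emit)
    emitted_clip = np.empty(n_emit, dtype=int)
    emitted_local_frame = np.empty(n_emit, dtype=int)

    k = 0
    local_frame_counter: dict[int, int] = {}
    for i in range(n_frames):
        # body temperature = field temperature at own position (tracking coords
        # mapped through the true warp so kernels act in thermal px)
        pos_thermal = params.warp.apply(pos)
        T_body = local_field_temperature(pos_thermal, pos_thermal, brood_thermal,
                                         float(t_air[i]), params)
        if emit[i]:
            cid = int(clip_id[i])
            lf = local_frame_counter.get(cid, 0)
            local_frame_counter[cid] = lf + 1
            sl = slice(k * params.n_bees, (k + 1) * params.n_bees)
            rec["frame_index"][sl] = lf
            rec["time_s"][sl] = times_s[i] - (0 if params.clip_interval_min is None
                                              else cid * params.clip_interval_min * 60.0)
            rec["bee"][sl] = np.arange(params.n_bees)
            rec["x"][sl] = pos[:, 0]
            rec["y"][sl] = pos[:, 1]
            rec["active"][sl] = active
            rec["T_body"][sl] = T_body
            rec["T_air"][sl] = t_air[i]
            rec_video[sl] = f"{colony_id}_v{cid:03d}"
            positions_per_emitted_frame[k] = pos
            emitted_times[k] = times_s[i]
            emitted_clip[k] = cid
            emitted_local_frame[k] = lf
            k += 1

        # movement of currently active bees (affects next frame's position)
        if active.any():
            delta = rng.normal(0.0, params.step_scale_px, size=(params.n_bees, 2))
            to_com = com[None, :] - pos
            dist = np.linalg.norm(to_com, axis=1)
            drift_mag = params.thermotaxis_gain_px_per_C * max(0.0, 24.0 - float(t_air[i]))
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = np.where(dist[:, None] > 1e-9, to_com / np.maximum(dist, 1e-9)[:, None], 0.0)
            step = delta + unit * np.minimum(drift_mag, dist)[:, None]
            pos = np.where(active[:, None], pos + step, pos)
            pos[:, 0] = np.clip(pos[:, 0], x0, x1)
            pos[:, 1] = np.clip(pos[:, 1], y0, y1)
        else:
            rng.normal(size=(params.n_bees, 2))  # keep stream alignment

        # state update (depends on body temperature this frame)
        u = rng.random(params.n_bees)
        p_ai = params.p_ai(T_body)
        next_active = np.where(active, u >= p_ai, u < params.p_ia_base)
        active = next_active

    df = pd.DataFrame({
        "video_id": rec_video,
        "frame_index": rec["frame_index"],
        "time_s": rec["time_s"],
        "bee_id": [f"bee{int(b):03d}" for b in rec["bee"]],
        "x_px": rec["x"],
        "y_px": rec["y"],
        "active": rec["active"],
        "T_body_C": rec["T_body"],
        "T_air_C": rec["T_air"],
    })

    segments: list[VideoSegment] = []
    for vid, g in df.groupby("video_id", sort=True):
        seg = VideoSegment(
            video_id=str(vid),
            colony_id=colony_id,
            start_time="1970-01-01T00:00:00",
            duration_s=params.clip_duration_s if params.clip_interval_min is not None
            else protocol.total_duration_min * 60.0,
            frame_rate_hz=params.frame_rate_hz,
        )
        for row in g.sort_values(["bee_id", "frame_index"]).itertuples(index=False):
            seg.detections.append(Detection(int(row.frame_index), float(row.time_s),
                                            str(row.bee_id), float(row.x_px), float(row.y_px)))
        segments.append(seg)

    gt = GroundTruth(
        per_frame=df,
        warp=params.warp,
        sensor_gain=params.sensor_gain,
        sensor_offset=params.sensor_offset,
        growth=params.growth,
        extras={
            "positions_per_frame": positions_per_emitted_frame,
            "frame_times_s": emitted_times,
            "clip_id": emitted_clip,
            "local_frame": emitted_local_frame,
            "kernel_sd_track_px": kernel_sd_track,
        },
    )
    return segments, gt


# ---------------------------------------------------------------------------
# thermal rendering
# ---------------------------------------------------------------------------

def render_thermal(
    positions_per_frame: np.ndarray,
    params: SimParams,
    protocol: TemperatureProtocol,
    nest: NestMap,
    probe_locations: Sequence[tuple[float, float]],
    frame_times_s: np.ndarray,
    frame_shape: tuple[int, int] = (128, 160),
    probe_log_interval_s: float = 20.0,
) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Render a raw-count thermal stack, probe logs and true fields.

    ``positions_per_frame`` is (n_frames, n_bees, 2) in *tracking* px; bee and
    brood positions are mapped through the true warp before rendering. Probe
    logs report the true temperature at the probe pixels (probes are ground
    truth). Raw counts = (T - offset) / gain + Gaussian noise.
    """
    h, w = frame_shape
    probes = np.asarray(probe_locations, dtype=float)
    if probes.ndim != 2 or len(probes) < 2:
        raise SimulationError("need >= 2 probe locations")
    if ((probes[:, 0] < 0) | (probes[:, 0] > w - 1)
            | (probes[:, 1] < 0) | (probes[:, 1] > h - 1)).any():
        raise SimulationError("probe location outside thermal frame")

    rng = np.random.default_rng(params.seed + 7_777)
    frame_times_s = np.asarray(frame_times_s, dtype=float)
    n_frames = len(frame_times_s)
    brood_thermal = params.warp.apply(np.asarray(nest.brood_centroids, dtype=float))

    yy, xx = np.mgrid[0:h, 0:w]
    grid = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)

    true_stack = np.empty((n_frames, h, w), dtype=float)
    for i in range(n_frames):
        ambient = float(protocol.temperature_at(frame_times_s[i] / 60.0))
        bees_thermal = params.warp.apply(np.asarray(positions_per_frame[i], dtype=float))
        field_vals = local_field_temperature(grid, bees_thermal, brood_thermal, ambient, params)
        true_stack[i] = field_vals.reshape(h, w)

    raw_stack = (true_stack - params.sensor_offset) / params.sensor_gain
    if params.sensor_noise_sd > 0:
        raw_stack = raw_stack + rng.normal(0.0, params.sensor_noise_sd, size=raw_stack.shape)

    # probe logs: true temperature at probe pixels on their own cadence
    t_end = frame_times_s[-1] if n_frames else 0.0
    log_times = np.arange(0.0, t_end + probe_log_interval_s, probe_log_interval_s)
    rows = []
    pi = probes.round().astype(int)
    for t in log_times:
        idx = int(np.argmin(np.abs(frame_times_s - t))) if n_frames else 0
        for j, (cx, cy) in enumerate(pi):
            rows.append({"time_s": float(t), "probe_id": f"p{j}",
                         "temp_C": float(true_stack[idx, cy, cx])})
    probe_log = pd.DataFrame(rows, columns=["time_s", "probe_id", "temp_C"])

    gt_fields = {
        "true_stack_C": true_stack,
        "sensor_gain": params.sensor_gain,
        "sensor_offset": params.sensor_offset,
        "probe_px": probes,
        "frame_times_s": frame_times_s,
    }
    return raw_stack, probe_log, gt_fields


# ---------------------------------------------------------------------------
# census simulation
# ---------------------------------------------------------------------------

def simulate_census(
    growth: GrowthCoefficients,
    colony_sizes: Sequence[int],
    arms: Sequence[tuple[bool, bool]],
    seed: int,
    n_blocks: int = 3,
) -> tuple[list[CensusRecord], pd.DataFrame]:
    """Draw Poisson censuses: log rate = b0 + b_size*log10(size) + b_cold*cold
    + b_imid*imid + b_3way*cold*imid*log10(size) + block effect.

    ``arms`` is a (cold, imidacloprid) boolean pair per colony. Returns the
    census records plus a tidy table carrying arms, blocks and the truth.
    """
    if len(colony_sizes) != len(arms):
        raise SimulationError("colony_sizes and arms must align")
    for name in ("b0", "b_size", "b_cold", "b_imid", "b_3way"):
        if not np.isfinite(getattr(growth, name)):
            raise SimulationError(f"non-finite growth coefficient {name}")
    rng = np.random.default_rng(seed)
    block_eff = rng.normal(0.0, growth.block_sd, size=n_blocks)
    records: list[CensusRecord] = []
    rows = []
    for i, (size, (cold, imid)) in enumerate(zip(colony_sizes, arms)):
        block = i % n_blocks
        ls = np.log10(size)
        eta = (growth.b0 + growth.b_size * ls + growth.b_cold * cold
               + growth.b_imid * imid + growth.b_3way * cold * imid * ls
               + block_eff[block])
        if eta > 30:
            raise SimulationError(f"rate overflow: linear predictor {eta:.2f} for colony {i}")
        prod = int(rng.poisson(np.exp(eta)))
        cid = f"c{i:03d}"
        records.append(CensusRecord(cid, int(size), 0, 1, prod, 40.0))
        rows.append({"colony_id": cid, "size": int(size), "cold": bool(cold),
                     "imid": bool(imid), "block": f"b{block}", "productivity": prod})
    table = pd.DataFrame(rows)
    table.attrs["truth"] = growth
    return records, table


def cold_experiment_setup(
    n_bees: int,
    imidacloprid: bool,
    seed: int,
    delta_ai_imid: float = 0.5,
) -> tuple[SimParams, TemperatureProtocol, NestMap]:
    """A compact cold-ramp experiment (hold 24, ramp to 10, hold 10).

    Sized so a small colony (n=4) cools below the imidacloprid threshold while
    a large colony (n=80) stays warm through collective heating; used by the
    direction-of-effect recovery tests and the acceptance harness.
    """
    nest = default_nest_map(arena=(2000.0, 1500.0), n_brood=3, n_pots=2,
                            mm_per_px=0.16, seed=1)
    protocol = TemperatureProtocol((
        ProtocolSegment(8.0, 24.0, 24.0),
        ProtocolSegment(12.0, 24.0, 10.0),
        ProtocolSegment(16.0, 10.0, 10.0),
    ))
    params = SimParams(
        n_bees=n_bees, seed=seed, imidacloprid=imidacloprid,
        delta_ai_imid=delta_ai_imid, frame_rate_hz=0.75,
        clip_interval_min=4.0, clip_duration_s=120.0,
    )
    return params, protocol, nest


# ---------------------------------------------------------------------------
# default nest map
# ---------------------------------------------------------------------------

def default_nest_map(
    arena: tuple[float, float] = (4096.0, 3000.0),
    n_brood: int = 5,
    n_pots: int = 3,
    mm_per_px: float = 0.08,
    seed: int = 0,
) -> NestMap:
    """A nest map with brood clustered centrally and pots toward the edge."""
    rng = np.random.default_rng(seed)
    w, h = arena
    centre = np.array([w / 2.0, h / 2.0])
    brood = centre + rng.normal(0.0, min(w, h) * 0.05, size=(n_brood, 2))
    pots = centre + rng.normal(0.0, min(w, h) * 0.3, size=(n_pots, 2))
    brood = np.clip(brood, [0, 0], [w, h])
    pots = np.clip(pots, [0, 0], [w, h])
    return NestMap(
        brood_centroids=tuple(map(tuple, brood)),
        pot_centroids=tuple(map(tuple, pots)),
        arena_bounds=(0.0, 0.0, w, h),
        mm_per_px=mm_per_px,
    )
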