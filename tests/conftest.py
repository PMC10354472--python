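import numpy as np
import pytest

from nestwatch.io_formats import Detection, NestMap, VideoSegment
from nestwatch import synthetic_colony as sc


@pytest.fixture
def small_nest() -> NestMap:
    return NestMap(
        brood_centroids=((40.0, 30.0), (60.0, 35.0)),
        pot_centroids=((90.0, 80.0),),
        arena_bounds=(0.0, 0.0, 100.0, 100.0),
        mm_per_px=0.5,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_segment(tracks: dict[str, list[tuple[int, float, float]]],
                 video_id: str = "v0", frame_rate: float = 1.5) -> VideoSegment:
    """Segment from {bee_id: [(frame, x, y), ...]}."""
    seg = VideoSegment(video_id, "c0", "2024-01-01T00:00:00", 120.0, frame_rate)
    for bee, rows in tracks.items():
        for f, x, y in rows:
            seg.detections.append(Detection(f, f / frame_rate, bee, x, y))
    seg.detections.sort(key=lambda d: (d.bee_id, d.frame_index))
    return seg


def random_segment(rng: np.random.Generator, n_bees: int = 4, n_frames: int = 20,
                   bounds=(0.0, 0.0, 100.0, 100.0), video_id: str = "v0") -> VideoSegment:
    x0, y0, x1, y1 = bounds
    tracks = {}
    for b in range(n_bees):
        pts = rng.uniform((x0, y0), (x1, y1), size=(n_frames, 2))
        tracks[f"bee{b:02d}"] = [(f, float(p[0]), float(p[1]))
                                 for f, p in enumerate(pts)]
    return make_segment(tracks, video_id=video_id)


@pytest.fixture
def quick_sim(small_nest):
    """A tiny deterministic simulation shared by several suites."""
    protocol = sc.TemperatureProtocol((
        sc.ProtocolSegment(4.0, 24.0, 24.0),
        sc.ProtocolSegment(6.0, 24.0, 10.0),
        sc.ProtocolSegment(6.0, 10.0, 10.0),
    ))
    params = sc.SimParams(n_bees=4, seed=7, frame_rate_hz=1.0,
                          clip_interval_min=None, step_scale_px=4.0,
                          init_spread_px=30.0)
    segments, gt = sc.simulate_colony(params, protocol, small_nest)
    return params, protocol, segments, gt
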