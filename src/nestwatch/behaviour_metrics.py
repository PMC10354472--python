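"""Per-bee, per-video behavioural metrics from trajectories and the nest map.

Eleven headline metrics per (bee, video): brood and wax-pot interaction rates,
mean spatial correlation to nest-mates, mean contact rate, degree centrality,
moving speed, mean distance to the (social) nest centre, median distance to
all brood / all pots, and median distance to the closest brood / closest pot.
Activity fraction, mean distance to nest-mates and contact events are kept as
auxiliary outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import gaussian_kde

from .io_formats import Detection, NestMap, VideoSegment

logger = logging.getLogger("nestwatch.behaviour")

#: maximum detection gap (frames) across which a speed is still computed
MAX_SPEED_GAP_FRAMES = 3

QUEENRIGHT_11 = [
    "brood_interaction_rate", "pot_interaction_rate", "mean_spatial_correlation",
    "mean_contact_rate", "degree_centrality", "moving_speed", "distance_to_centre",
    "median_dist_all_brood", "median_dist_all_pots",
    "min_dist_closest_brood", "min_dist_closest_pot",
]


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class OccupancyGrid:
    bee_id: str
    video_id: str
    probabilities: np.ndarray  # (ny, nx)
    x_edges: np.ndarray
    y_edges: np.ndarray
    bin_size_px: float


@dataclass(frozen=True)
class BehaviourRecord:
    bee_id: str
    video_id: str
    brood_interaction_rate: float
    pot_interaction_rate: float
    mean_spatial_correlation: float
    mean_contact_rate: float
    degree_centrality: float
    moving_speed: float
    distance_to_centre: float
    median_dist_all_brood: float
    median_dist_all_pots: float
    min_dist_closest_brood: float
    min_dist_closest_pot: float
    activity_fraction: float
    mean_dist_nestmates: float
    n_detections: int


@dataclass(frozen=True)
class ContactEvent:
    frame_index: int
    bee_a: str  # canonical: bee_a < bee_b
    bee_b: str
    distance_mm: float


# ---------------------------------------------------------------------------
# occupancy and element interaction
# ---------------------------------------------------------------------------

def _grid_edges(bounds: tuple[float, float, float, float], bin_size_px: float):
    x0, y0, x1, y1 = bounds
    nx = max(int(np.ceil((x1 - x0) / bin_size_px)), 1)
    ny = max(int(np.ceil((y1 - y0) / bin_size_px)), 1)
    return (x0 + bin_size_px * np.arange(nx + 1), y0 + bin_size_px * np.arange(ny + 1))


def occupancy_distribution(
    segment: VideoSegment,
    bee_id: str,
    bin_size_px: float,
    bounds: tuple[float, float, float, float],
    _track: Sequence[Detection] | None = None,
) -> OccupancyGrid:
    """Normalized 2-D histogram of a bee's detections over arena bins."""
    track = segment.track(bee_id) if _track is None else _track
    if not track:
        raise MetricsError(f"no detections for bee {bee_id} in {segment.video_id}")
    x_edges, y_edges = _grid_edges(bounds, bin_size_px)
    xs = np.array([d.x_px for d in track])
    ys = np.array([d.y_px for d in track])
    # points on the outer edge fall in the last bin
    xs = np.minimum(xs, x_edges[-1] - 1e-9)
    ys = np.minimum(ys, y_edges[-1] - 1e-9)
    h, _, _ = np.histogram2d(ys, xs, bins=(y_edges, x_edges))
    return OccupancyGrid(bee_id, segment.video_id, h / h.sum(), x_edges, y_edges,
                         bin_size_px)


def element_interaction_rate(grid: OccupancyGrid, nest: NestMap, element_kind: str) -> float:
    """Sum over bins of occupancy probability times element count in the bin."""
    pts = {"brood": nest.brood_centroids, "pot": nest.pot_centroids}.get(element_kind)
    if pts is None:
        raise MetricsError(f"unknown element kind {element_kind!r}")
    if (grid.x_edges[0] < nest.arena_bounds[0] - 1e-9
            or grid.y_edges[0] < nest.arena_bounds[1] - 1e-9):
        raise MetricsError("grid does not match nest arena bounds")
    if not pts:
        return 0.0
    xs = np.minimum(np.array([p[0] for p in pts]), grid.x_edges[-1] - 1e-9)
    ys = np.minimum(np.array([p[1] for p in pts]), grid.y_edges[-1] - 1e-9)
    counts, _, _ = np.histogram2d(ys, xs, bins=(grid.y_edges, grid.x_edges))
    return float((grid.probabilities * counts).sum())


def spatial_correlation(grid_i: OccupancyGrid, grid_j: OccupancyGrid) -> float | None:
    """Pearson correlation of two occupancy grids over flattened bins.

    Returns None (and logs) when either grid is constant.
    """
    if grid_i.probabilities.shape != grid_j.probabilities.shape:
        raise MetricsError("occupancy grids have mismatched bins")
    a = grid_i.probabilities.ravel()
    b = grid_j.probabilities.ravel()
    if a.std() == 0 or b.std() == 0:
        logger.info("constant occupancy grid; skipping pair (%s, %s)",
                    grid_i.bee_id, grid_j.bee_id)
        return None
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def mean_spatial_correlations(grids: dict[str, OccupancyGrid]) -> dict[str, float]:
    """Per-bee mean Pearson correlation to all nest-mates' occupancy grids.

    Vectorized equivalent of calling :func:`spatial_correlation` over every
    pair; constant grids are skipped pairwise.
    """
    bees = sorted(grids)
    if len(bees) < 2:
        return {b: np.nan for b in bees}
    G = np.stack([grids[b].probabilities.ravel() for b in bees])
    mu = G.mean(axis=1, keepdims=True)
    sd = G.std(axis=1)
    valid = sd > 0
    Z = np.zeros_like(G)
    Z[valid] = (G[valid] - mu[valid]) / sd[valid, None]
    C = (Z @ Z.T) / G.shape[1]
    out = {}
    for i, b in enumerate(bees):
        ok = valid.copy()
        ok[i] = False
        if not valid[i] or not ok.any():
            out[b] = np.nan
        else:
            out[b] = float(C[i, ok].mean())
    return out


def contact_events(
    segment: VideoSegment,
    mm_per_px: float,
    threshold_mm: float = 10.0,
) -> list[ContactEvent]:
    """All unordered same-frame pairs closer than the physical threshold."""
    if not mm_per_px > 0:
        raise MetricsError("mm_per_px must be positive")
    by_frame: dict[int, list[Detection]] = {}
    for d in segment.detections:
        by_frame.setdefault(d.frame_index, []).append(d)
    events: list[ContactEvent] = []
    for fi in sorted(by_frame):
        dets = by_frame[fi]
        if len(dets) < 2:
            continue
        pts = np.array([[d.x_px, d.y_px] for d in dets])
        dist_mm = squareform(pdist(pts)) * mm_per_px
        ii, jj = np.triu_indices(len(dets), k=1)
        close = dist_mm[ii, jj] < threshold_mm
        for i, j in zip(ii[close], jj[close]):
            a, b = sorted((dets[i].bee_id, dets[j].bee_id))
            events.append(ContactEvent(fi, a, b, float(dist_mm[i, j])))
    return events


def contact_stats(
    segment: VideoSegment,
    events: Sequence[ContactEvent],
) -> pd.DataFrame:
    """Per-bee contact rate (contacts / frames detected) and degree centrality."""
    frames_detected: dict[str, int] = {}
    for d in segment.detections:
        frames_detected[d.bee_id] = frames_detected.get(d.bee_id, 0) + 1
    contacts: dict[str, int] = {b: 0 for b in frames_detected}
    partners: dict[str, set[str]] = {b: set() for b in frames_detected}
    for e in events:
        contacts[e.bee_a] += 1
        contacts[e.bee_b] += 1
        partners[e.bee_a].add(e.bee_b)
        partners[e.bee_b].add(e.bee_a)
    rows = [{"bee_id": b, "mean_contact_rate": contacts[b] / frames_detected[b],
             "degree_centrality": len(partners[b])} for b in sorted(frames_detected)]
    return pd.DataFrame(rows, columns=["bee_id", "mean_contact_rate", "degree_centrality"])


def contact_graph(events: Sequence[ContactEvent]):
    """Contact network as an undirected graph weighted by contact counts."""
    import networkx as nx

    g = nx.Graph()
    for e in events:
        if g.has_edge(e.bee_a, e.bee_b):
            g[e.bee_a][e.bee_b]["weight"] += 1
        else:
            g.add_edge(e.bee_a, e.bee_b, weight=1)
    return g


# ---------------------------------------------------------------------------
# speed, activity and the bimodal threshold
# ---------------------------------------------------------------------------

def frame_speeds(track: Sequence[Detection], max_gap: int = MAX_SPEED_GAP_FRAMES):
    """Frame-wise speeds (px/frame) assigned to the first frame of each pair.

    Gaps of up to ``max_gap`` frames use displacement / gap; longer gaps break
    the track.
    """
    track = sorted(track, key=lambda d: d.frame_index)
    frames, speeds = [], []
    for a, b in zip(track[:-1], track[1:]):
        gap = b.frame_index - a.frame_index
        if gap <= 0 or gap > max_gap:
            continue
        disp = float(np.hypot(b.x_px - a.x_px, b.y_px - a.y_px))
        frames.append(a.frame_index)
        speeds.append(disp / gap)
    return np.asarray(frames, dtype=int), np.asarray(speeds, dtype=float)


def activity_threshold(speeds: np.ndarray, n_grid: int = 512) -> tuple[float, str]:
    """Speed threshold at the KDE valley between the two largest modes.

    Falls back to a 2-component Gaussian-mixture boundary when the KDE shows a
    single mode; the method used is returned alongside the threshold.
    """
    speeds = np.asarray(speeds, dtype=float)
    speeds = speeds[np.isfinite(speeds)]
    if len(speeds) < 100:
        raise MetricsError(f"need >= 100 speed samples, got {len(speeds)}")
    if np.ptp(speeds) < 1e-12:
        raise MetricsError("all speeds identical: no bimodality")
    kde = gaussian_kde(speeds)
    grid = np.linspace(speeds.min(), speeds.max(), n_grid)
    dens = kde(grid)
    # local maxima of the density
    inner = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.where(inner)[0] + 1
    if dens[0] > dens[1]:
        peaks = np.concatenate([[0], peaks])
    if dens[-1] > dens[-2]:
        peaks = np.concatenate([peaks, [len(dens) - 1]])
    if len(peaks) >= 2:
        top2 = peaks[np.argsort(dens[peaks])[-2:]]
        lo, hi = int(top2.min()), int(top2.max())
        valley = lo + int(np.argmin(dens[lo:hi + 1]))
        # a genuine valley must dip well below the lower of the two modes
        if dens[valley] < 0.8 * min(dens[lo], dens[hi]):
            return float(grid[valley]), "kde_valley"
    # unimodal: mixture-boundary fallback
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(n_components=2, random_state=0, n_init=3)
    gm.fit(speeds.reshape(-1, 1))
    post = gm.predict_proba(grid.reshape(-1, 1))
    hot = int(np.argmax(gm.means_.ravel()))
    crossing = np.where(np.diff((post[:, hot] > 0.5).astype(int)) != 0)[0]
    if len(crossing):
        return float(grid[crossing[0] + 1]), "gmm_boundary"
    return float(np.median(speeds)), "median_fallback"


def moving_speed_and_activity(
    track: Sequence[Detection],
    threshold: float,
) -> tuple[float, float]:
    """(mean speed while moving, fraction of speed-defined frames moving).

    Moving speed is NaN when the bee never exceeds the threshold.
    """
    _, speeds = frame_speeds(track)
    if len(speeds) == 0:
        return np.nan, np.nan
    moving = speeds > threshold
    ms = float(speeds[moving].mean()) if moving.any() else np.nan
    return ms, float(moving.mean())


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def nest_centre(segment: VideoSegment) -> tuple[float, float]:
    """Social nest centre: mean position of all detections of all bees."""
    if not segment.detections:
        raise MetricsError("no detections: nest centre undefined")
    xs = np.array([d.x_px for d in segment.detections])
    ys = np.array([d.y_px for d in segment.detections])
    return float(xs.mean()), float(ys.mean())


def distance_metrics(
    track: Sequence[Detection],
    centre: tuple[float, float],
    nest: NestMap,
) -> dict[str, float]:
    """Distance-based metrics for one bee's track (all in px).

    Per frame: distance to the nest centre (mean over frames); distances to
    every brood/pot (median over frames and elements); minimum over elements
    (median over frames). Missing elements yield NaN.
    """
    if not track:
        raise MetricsError("empty track")
    pts = np.array([[d.x_px, d.y_px] for d in track])
    out: dict[str, float] = {}
    out["distance_to_centre"] = float(
        np.hypot(pts[:, 0] - centre[0], pts[:, 1] - centre[1]).mean())
    for kind, elements in (("brood", nest.brood_centroids), ("pot", nest.pot_centroids)):
        suffix = "brood" if kind == "brood" else "pots"
        if not elements:
            out[f"median_dist_all_{suffix}"] = np.nan
            out[f"min_dist_closest_{kind}"] = np.nan
            continue
        el = np.asarray(elements, dtype=float)
        d = np.sqrt(((pts[:, None, :] - el[None, :, :]) ** 2).sum(axis=2))  # (frames, elements)
        out[f"median_dist_all_{suffix}"] = float(np.median(d))
        out[f"min_dist_closest_{kind}"] = float(np.median(d.min(axis=1)))
    return out


def classify_on_off_nest(
    position: tuple[float, float],
    nest: NestMap,
    on_mm: float = 10.0,
    off_mm: float = 20.0,
) -> str:
    """'on' within 10 mm of the nearest brood, 'off' beyond 20 mm, else 'intermediate'."""
    if not nest.brood_centroids:
        raise MetricsError("no brood centroids: on/off-nest undefined")
    el = np.asarray(nest.brood_centroids, dtype=float)
    d_mm = float(np.min(np.hypot(el[:, 0] - position[0], el[:, 1] - position[1]))
                 * nest.mm_per_px)
    if d_mm < on_mm:
        return "on"
    if d_mm > off_mm:
        return "off"
    return "intermediate"


# ---------------------------------------------------------------------------
# full per-video behaviour table
# ---------------------------------------------------------------------------

def compute_behaviour_records(
    segment: VideoSegment,
    nest: NestMap,
    threshold: float,
    bin_size_mm: float = 20.0,
    contact_threshold_mm: float = 10.0,
) -> list[BehaviourRecord]:
    """All metrics for every bee of one video segment."""
    bin_size_px = bin_size_mm / nest.mm_per_px
    tracks: dict[str, list[Detection]] = {}
    for d in segment.detections:
        tracks.setdefault(d.bee_id, []).append(d)
    for t in tracks.values():
        t.sort(key=lambda d: d.frame_index)
    bees = list(tracks)
    grids = {}
    for b in bees:
        try:
            grids[b] = occupancy_distribution(segment, b, bin_size_px, nest.arena_bounds,
                                              _track=tracks[b])
        except MetricsError:
            pass
    events = contact_events(segment, nest.mm_per_px, contact_threshold_mm)
    cstats = contact_stats(segment, events).set_index("bee_id")
    centre = nest_centre(segment)
    mean_corrs = mean_spatial_correlations(grids)

    by_frame: dict[int, dict[str, tuple[float, float]]] = {}
    for d in segment.detections:
        by_frame.setdefault(d.frame_index, {})[d.bee_id] = (d.x_px, d.y_px)

    # per-frame mean distance to co-detected nest-mates, median over frames
    dist_nm: dict[str, list[float]] = {b: [] for b in bees}
    for fi, dd in by_frame.items():
        ids = list(dd)
        if len(ids) < 2:
            continue
        P = np.array([dd[i] for i in ids])
        D = squareform(pdist(P))
        means = D.sum(axis=1) / (len(ids) - 1)
        for idx, bid in enumerate(ids):
            dist_nm[bid].append(float(means[idx]))

    records = []
    for b in sorted(bees):
        track = tracks[b]
        grid = grids.get(b)
        if grid is None:
            continue
        brood_rate = element_interaction_rate(grid, nest, "brood")
        pot_rate = element_interaction_rate(grid, nest, "pot")
        mean_corr = mean_corrs[b]
        ms, act = moving_speed_and_activity(track, threshold)
        dm = distance_metrics(track, centre, nest)
        mean_dist_nm = float(np.median(dist_nm[b])) if dist_nm[b] else np.nan
        records.append(BehaviourRecord(
            bee_id=b, video_id=segment.video_id,
            brood_interaction_rate=brood_rate, pot_interaction_rate=pot_rate,
            mean_spatial_correlation=mean_corr,
            mean_contact_rate=float(cstats.loc[b, "mean_contact_rate"]),
            degree_centrality=float(cstats.loc[b, "degree_centrality"]),
            moving_speed=ms, distance_to_centre=dm["distance_to_centre"],
            median_dist_all_brood=dm["median_dist_all_brood"],
            median_dist_all_pots=dm["median_dist_all_pots"],
            min_dist_closest_brood=dm["min_dist_closest_brood"],
            min_dist_closest_pot=dm["min_dist_closest_pot"],
            activity_fraction=act, mean_dist_nestmates=mean_dist_nm,
            n_detections=len(track),
        ))
    return records


def pooled_activity_threshold(segments: Sequence[VideoSegment]) -> tuple[float, str]:
    """Threshold from frame-wise speeds pooled over all bees and videos."""
    speeds = []
    for seg in segments:
        for b in seg.bee_ids():
            _, s = frame_speeds(seg.track(b))
            speeds.append(s)
    pooled = np.concatenate(speeds) if speeds else np.array([])
    return activity_threshold(pooled)
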