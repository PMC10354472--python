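"""Thermal calibration, tracking->thermal registration and temperature extraction.

Each thermal frame is calibrated independently against in-nest temperature
probes with a linear (gain + offset) sensor model. Tracking-camera coordinates
are mapped into thermal frames through a smooth tensor-product B-spline
displacement field fitted to manually annotated control-point pairs. Body and
brood temperatures are disc means around the mapped centroid (default radius
20 thermal px).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .io_formats import Detection, NestMap


class CalibrationError(ValueError):
    pass


class RegistrationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# per-frame calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameCalibration:
    frame_index: int
    gain: float            # degC per count
    offset: float          # degC
    residual_rmse: float   # degC
    n_probes_used: int
    ok: bool = True


def _disc_mean(frame: np.ndarray, cx: float, cy: float, radius: float) -> tuple[float, int]:
    """Mean over pixels whose centre lies within ``radius`` of (cx, cy)."""
    h, w = frame.shape
    x_lo = max(int(np.floor(cx - radius)), 0)
    x_hi = min(int(np.ceil(cx + radius)) + 1, w)
    y_lo = max(int(np.floor(cy - radius)), 0)
    y_hi = min(int(np.ceil(cy + radius)) + 1, h)
    if x_lo >= x_hi or y_lo >= y_hi:
        return np.nan, 0
    yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
    n = int(mask.sum())
    if n == 0:
        return np.nan, 0
    return float(frame[y_lo:y_hi, x_lo:x_hi][mask].mean()), n


def interpolate_probe_temps(probe_log: pd.DataFrame, time_s: float) -> dict[str, float]:
    """Linear time interpolation of each probe's log to ``time_s``."""
    out = {}
    for pid, g in probe_log.groupby("probe_id"):
        g = g.sort_values("time_s")
        out[str(pid)] = float(np.interp(time_s, g["time_s"].to_numpy(),
                                        g["temp_C"].to_numpy()))
    return out


def calibrate_frame(
    raw_frame: np.ndarray,
    probe_annotations: Sequence[tuple[float, float]],
    probe_temps: Sequence[float],
    frame_index: int = 0,
    probe_disc_radius_px: float = 3.0,
) -> tuple[FrameCalibration, np.ndarray | None]:
    """Least-squares linear fit T = gain * counts + offset over the probes.

    Probe counts are disc means at the annotated pixel locations. Returns the
    calibration and the frame mapped into degC, or ``None`` with ``ok=False``
    when the fit is degenerate (identical probe readings over differing counts).
    """
    raw_frame = np.asarray(raw_frame, dtype=float)
    probes = list(probe_annotations)
    temps = np.asarray(probe_temps, dtype=float)
    if len(probes) < 2 or len(temps) < 2:
        raise CalibrationError(f"need >= 2 probes, got {min(len(probes), len(temps))}")
    if len(probes) != len(temps):
        raise CalibrationError("probe annotations and temperatures must align")
    counts = np.array([_disc_mean(raw_frame, x, y, probe_disc_radius_px)[0]
                       for x, y in probes])
    if np.isnan(counts).any():
        raise CalibrationError("probe annotation outside frame")
    if np.ptp(counts) < 1e-12:
        raise CalibrationError("identical counts at all probes: gain not identifiable")
    A = np.column_stack([counts, np.ones_like(counts)])
    (gain, offset), *_ = np.linalg.lstsq(A, temps, rcond=None)
    resid = temps - (gain * counts + offset)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    if abs(gain) < 1e-12 and np.ptp(temps) < 1e-12:
        # probes all read the same temperature over differing counts
        return FrameCalibration(frame_index, float(gain), float(offset), rmse,
                                len(probes), ok=False), None
    calibrated = gain * raw_frame + offset
    return FrameCalibration(frame_index, float(gain), float(offset), rmse,
                            len(probes), ok=True), calibrated


def calibrate_stack(
    raw_stack: np.ndarray,
    probe_annotations: Sequence[tuple[float, float]],
    probe_log: pd.DataFrame,
    frame_times_s: Sequence[float],
) -> tuple[list[FrameCalibration], np.ndarray]:
    """Calibrate every frame of a stack; probe temps interpolated in time."""
    raw_stack = np.asarray(raw_stack, dtype=float)
    out = np.empty_like(raw_stack)
    cals = []
    probe_ids = sorted(probe_log["probe_id"].unique())
    for i, t in enumerate(frame_times_s):
        temps_by_id = interpolate_probe_temps(probe_log, float(t))
        temps = [temps_by_id[p] for p in probe_ids]
        cal, frame = calibrate_frame(raw_stack[i], probe_annotations, temps, frame_index=i)
        cals.append(cal)
        out[i] = frame if frame is not None else np.nan
    return cals, out


# ---------------------------------------------------------------------------
# warp model
# ---------------------------------------------------------------------------

def _uniform_knots(lo: float, hi: float, spacing: float, degree: int) -> np.ndarray:
    """Clamped-free uniform knot vector covering [lo, hi] with given spacing."""
    span = max(hi - lo, spacing)
    n_int = max(int(np.ceil(span / spacing)), 1)
    inner = np.linspace(lo, hi, n_int + 1)
    step = inner[1] - inner[0] if len(inner) > 1 else spacing
    left = inner[0] - step * np.arange(degree, 0, -1)
    right = inner[-1] + step * np.arange(1, degree + 1)
    return np.concatenate([left, inner, right])


def _design_matrix_1d(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    return BSpline.design_matrix(x, knots, degree, extrapolate=True).toarray()


def _second_diff_penalty(nx: int, ny: int) -> np.ndarray:
    """Rows penalizing second differences of the coefficient grid along each axis."""
    rows = []
    for i in range(nx):
        for j in range(ny):
            idx = lambda a, b: a * ny + b
            if i + 2 < nx:
                r = np.zeros(nx * ny)
                r[idx(i, j)], r[idx(i + 1, j)], r[idx(i + 2, j)] = 1.0, -2.0, 1.0
                rows.append(r)
            if j + 2 < ny:
                r = np.zeros(nx * ny)
                r[idx(i, j)], r[idx(i, j + 1)], r[idx(i, j + 2)] = 1.0, -2.0, 1.0
                rows.append(r)
    return np.array(rows) if rows else np.zeros((0, nx * ny))


@dataclass
class WarpModel:
    """Smooth tracking->thermal mapping fitted to control-point pairs."""

    knots_x: np.ndarray
    knots_y: np.ndarray
    degree: int
    coef_u: np.ndarray  # (nx * ny,) coefficients for thermal x
    coef_v: np.ndarray
    control_src: np.ndarray
    control_dst: np.ndarray
    fit_residual_px: float
    grid_spacing_px: float
    smooth_weight: float

    def _basis(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        bx = _design_matrix_1d(p[:, 0], self.knots_x, self.degree)
        by = _design_matrix_1d(p[:, 1], self.knots_y, self.degree)
        # row-wise Kronecker product
        return (bx[:, :, None] * by[:, None, :]).reshape(len(p), -1)

    def transform(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) tracking-px points to thermal-px coordinates."""
        B = self._basis(points)
        out = np.column_stack([B @ self.coef_u, B @ self.coef_v])
        return out if np.asarray(points).ndim == 2 else out[0]

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "knots_x": self.knots_x.tolist(),
            "knots_y": self.knots_y.tolist(),
            "coef_u": self.coef_u.tolist(),
            "coef_v": self.coef_v.tolist(),
            "control_src": self.control_src.tolist(),
            "control_dst": self.control_dst.tolist(),
            "fit_residual_px": self.fit_residual_px,
            "grid_spacing_px": self.grid_spacing_px,
            "smooth_weight": self.smooth_weight,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WarpModel":
        return cls(
            knots_x=np.asarray(d["knots_x"]), knots_y=np.asarray(d["knots_y"]),
            degree=int(d["degree"]),
            coef_u=np.asarray(d["coef_u"]), coef_v=np.asarray(d["coef_v"]),
            control_src=np.asarray(d["control_src"]),
            control_dst=np.asarray(d["control_dst"]),
            fit_residual_px=float(d["fit_residual_px"]),
            grid_spacing_px=float(d["grid_spacing_px"]),
            smooth_weight=float(d["smooth_weight"]),
        )


def fit_warp(
    control_pairs: Sequence[tuple[tuple[float, float], tuple[float, float]]],
    grid_spacing_px: float = 64.0,
    smooth_weight: float = 1e-3,
    degree: int = 3,
) -> WarpModel:
    """Fit a regularized tensor-product B-spline displacement field.

    The penalty is on second differences of the coefficient grid, so any
    affine map incurs zero penalty and is reproduced exactly from exact pairs.
    """
    pairs = list(control_pairs)
    if len(pairs) < 4:
        raise RegistrationError(f"need >= 4 control pairs, got {len(pairs)}")
    src = np.asarray([p[0] for p in pairs], dtype=float)
    dst = np.asarray([p[1] for p in pairs], dtype=float)
    if len(np.unique(src, axis=0)) < len(src):
        raise RegistrationError("duplicate control points in tracking coordinates")
    # collinearity check: rank of [1 x y]
    A = np.column_stack([np.ones(len(src)), src])
    if np.linalg.matrix_rank(A, tol=1e-8 * max(1.0, np.abs(src).max())) < 3:
        raise RegistrationError(f"control points are collinear: {src.tolist()}")

    pad = grid_spacing_px * 0.5
    kx = _uniform_knots(src[:, 0].min() - pad, src[:, 0].max() + pad, grid_spacing_px, degree)
    ky = _uniform_knots(src[:, 1].min() - pad, src[:, 1].max() + pad, grid_spacing_px, degree)
    nx = len(kx) - degree - 1
    ny = len(ky) - degree - 1

    bx = _design_matrix_1d(src[:, 0], kx, degree)
    by = _design_matrix_1d(src[:, 1], ky, degree)
    B = (bx[:, :, None] * by[:, None, :]).reshape(len(src), -1)
    P = _second_diff_penalty(nx, ny) * np.sqrt(smooth_weight)
    # tiny ridge keeps the underdetermined system well-posed without biasing
    # smooth solutions noticeably
    R = np.eye(nx * ny) * 1e-8
    A_full = np.vstack([B, P, R])
    rhs_u = np.concatenate([dst[:, 0], np.zeros(len(P)), np.zeros(nx * ny)])
    rhs_v = np.concatenate([dst[:, 1], np.zeros(len(P)), np.zeros(nx * ny)])
    coef_u, *_ = np.linalg.lstsq(A_full, rhs_u, rcond=None)
    coef_v, *_ = np.linalg.lstsq(A_full, rhs_v, rcond=None)

    model = WarpModel(kx, ky, degree, coef_u, coef_v, src, dst, 0.0,
                      grid_spacing_px, smooth_weight)
    pred = model.transform(src)
    model.fit_residual_px = float(np.sqrt(np.mean((pred - dst) ** 2)))
    return model


# ---------------------------------------------------------------------------
# temperature extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BodyTempReading:
    bee_id: str
    frame_index: int
    temp_C: float
    radius_px: float
    n_pixels_averaged: int
    valid: bool


def extract_body_temp(
    calibrated_frame: np.ndarray,
    detection: Detection,
    warp: WarpModel,
    radius_px: float = 20.0,
) -> BodyTempReading:
    """Disc-mean temperature around the warped tag centroid.

    The disc is clipped at frame edges; a mapped centre off-frame yields
    ``valid=False`` rather than an exception.
    """
    frame = np.asarray(calibrated_frame, dtype=float)
    if np.isnan(frame).all():
        raise CalibrationError("frame is uncalibrated (all-NaN)")
    h, w = frame.shape
    cx, cy = warp.transform(np.array([[detection.x_px, detection.y_px]]))[0]
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        return BodyTempReading(detection.bee_id, detection.frame_index, np.nan,
                               radius_px, 0, valid=False)
    mean, n = _disc_mean(frame, cx, cy, radius_px)
    return BodyTempReading(detection.bee_id, detection.frame_index, mean,
                           radius_px, n, valid=n > 0)


def extract_brood_temp(
    calibrated_frame: np.ndarray,
    nest: NestMap,
    warp: WarpModel,
    radius_px: float = 20.0,
) -> list[BodyTempReading]:
    """Disc-mean temperatures at every brood centroid (warped into thermal px)."""
    out = []
    for i, (x, y) in enumerate(nest.brood_centroids):
        det = Detection(frame_index=0, time_s=0.0, bee_id=f"brood{i}", x_px=x, y_px=y)
        out.append(extract_body_temp(calibrated_frame, det, warp, radius_px))
    return out


def extract_body_temps_for_segment(
    calibrated_stack: np.ndarray,
    stack_times_s: np.ndarray,
    segment,
    warp: WarpModel,
    radius_px: float = 20.0,
    clip_time_offset_s: float = 0.0,
) -> pd.DataFrame:
    """Body temperatures for every detection of a segment.

    Each detection is matched to the nearest-in-time thermal frame.
    """
    stack_times_s = np.asarray(stack_times_s, dtype=float)
    rows = []
    for det in segment.detections:
        t_abs = det.time_s + clip_time_offset_s
        fi = int(np.argmin(np.abs(stack_times_s - t_abs)))
        reading = extract_body_temp(calibrated_stack[fi], det, warp, radius_px)
        rows.append({"video_id": segment.video_id, "bee_id": det.bee_id,
                     "frame_index": det.frame_index, "time_s": det.time_s,
                     "T_body_C": reading.temp_C, "valid": reading.valid})
    return pd.DataFrame(rows, columns=["video_id", "bee_id", "frame_index",
                                       "time_s", "T_body_C", "valid"])
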