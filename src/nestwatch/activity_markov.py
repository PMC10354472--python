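"""Activity-state labelling and body-temperature-conditioned Markov analysis.

Per-frame states (active = moving centroid, inactive = stationary) come from
frame-wise speeds against the bimodal activity threshold. Transition
probabilities between states are estimated per body-temperature bin (each
consecutive same-bee frame pair is one Bernoulli trial conditioned on the
first frame's state and temperature), with Wilson confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .behaviour_metrics import MAX_SPEED_GAP_FRAMES, frame_speeds
from .io_formats import Detection

DEFAULT_TEMP_BINS = np.arange(10.0, 32.0, 2.0)  # 2 degC bins, 10..30
DEFAULT_MIN_COUNT = 50


class MarkovError(ValueError):
    pass


@dataclass(frozen=True)
class ActivitySequence:
    bee_id: str
    video_id: str
    frames: np.ndarray        # strictly increasing
    active: np.ndarray        # bool per frame
    body_temp_C: np.ndarray   # NaN where missing


@dataclass(frozen=True)
class TransitionEstimate:
    temp_lo: float
    temp_hi: float
    arm: str
    n_active_frames: int
    n_ai_transitions: int
    p_ai: float
    p_ai_lo: float
    p_ai_hi: float
    n_inactive_frames: int
    n_ia_transitions: int
    p_ia: float
    p_ia_lo: float
    p_ia_hi: float


def label_states(
    track: Sequence[Detection],
    threshold: float,
    bee_id: str | None = None,
    video_id: str = "",
    body_temps: dict[int, float] | None = None,
) -> ActivitySequence:
    """Per-frame activity states from frame-wise speed versus the threshold.

    Only frames with a defined speed (gap <= 3 to the next detection) carry a
    state; others are excluded from transition counting by omission.
    """
    frames, speeds = frame_speeds(track, max_gap=MAX_SPEED_GAP_FRAMES)
    if bee_id is None:
        bee_id = track[0].bee_id if track else ""
    temps = np.array([body_temps.get(int(f), np.nan) if body_temps else np.nan
                      for f in frames])
    return ActivitySequence(bee_id, video_id, frames, speeds > threshold, temps)


def sequences_from_truth(per_frame: pd.DataFrame) -> list[ActivitySequence]:
    """Build sequences from a simulator ground-truth table.

    Expects columns video_id, bee_id, frame_index, active, T_body_C; used for
    estimator-recovery tests where the labelling stage is bypassed.
    """
    out = []
    for (vid, bee), g in per_frame.groupby(["video_id", "bee_id"], sort=True):
        g = g.sort_values("frame_index")
        out.append(ActivitySequence(
            str(bee), str(vid),
            g["frame_index"].to_numpy(dtype=int),
            g["active"].to_numpy(dtype=bool),
            g["T_body_C"].to_numpy(dtype=float),
        ))
    return out


def _wilson(k: int, n: int) -> tuple[float, float, float]:
    if n == 0:
        return np.nan, np.nan, np.nan
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return k / n, float(lo), float(hi)


def _transition_pairs(seq: ActivitySequence, max_gap: int = MAX_SPEED_GAP_FRAMES):
    """(state_t, state_t+1, T_body_t) for consecutive labelled frames."""
    if len(seq.frames) < 2:
        return np.empty(0, bool), np.empty(0, bool), np.empty(0)
    gaps = np.diff(seq.frames)
    ok = gaps <= max_gap
    return seq.active[:-1][ok], seq.active[1:][ok], seq.body_temp_C[:-1][ok]


def estimate_transitions(
    sequences: Sequence[ActivitySequence],
    temp_bins: np.ndarray = DEFAULT_TEMP_BINS,
    arm: str = "control",
    min_count: int = DEFAULT_MIN_COUNT,
) -> list[TransitionEstimate]:
    """Binned transition probabilities with Wilson CIs.

    Each consecutive labelled frame pair is one trial, assigned to the bin of
    the *first* frame's body temperature; pairs with missing temperature are
    skipped. Bins where both conditioning states have fewer than ``min_count``
    opportunities are suppressed.
    """
    temp_bins = np.asarray(temp_bins, dtype=float)
    if len(temp_bins) < 2:
        raise MarkovError("need at least one temperature bin")
    s0_all, s1_all, t_all = [], [], []
    for seq in sequences:
        s0, s1, t = _transition_pairs(seq)
        s0_all.append(s0)
        s1_all.append(s1)
        t_all.append(t)
    s0 = np.concatenate(s0_all) if s0_all else np.empty(0, bool)
    s1 = np.concatenate(s1_all) if s1_all else np.empty(0, bool)
    t = np.concatenate(t_all) if t_all else np.empty(0)
    keep = np.isfinite(t)
    s0, s1, t = s0[keep], s1[keep], t[keep]
    bin_idx = np.digitize(t, temp_bins) - 1

    out = []
    for b in range(len(temp_bins) - 1):
        m = bin_idx == b
        a0 = m & s0
        i0 = m & ~s0
        n_a, n_i = int(a0.sum()), int(i0.sum())
        if n_a < min_count and n_i < min_count:
            continue
        k_ai = int((a0 & ~s1).sum())
        k_ia = int((i0 & s1).sum())
        p_ai, ai_lo, ai_hi = _wilson(k_ai, n_a)
        p_ia, ia_lo, ia_hi = _wilson(k_ia, n_i)
        out.append(TransitionEstimate(
            float(temp_bins[b]), float(temp_bins[b + 1]), arm,
            n_a, k_ai, p_ai, ai_lo, ai_hi,
            n_i, k_ia, p_ia, ia_lo, ia_hi,
        ))
    return out


def transitions_to_frame(estimates: Sequence[TransitionEstimate]) -> pd.DataFrame:
    import dataclasses

    cols = [f.name for f in dataclasses.fields(TransitionEstimate)]
    return pd.DataFrame([dataclasses.asdict(e) for e in estimates], columns=cols)


def activity_vs_temp(
    sequences: Sequence[ActivitySequence],
    temp_bins: np.ndarray = DEFAULT_TEMP_BINS,
    min_count: int = DEFAULT_MIN_COUNT,
) -> pd.DataFrame:
    """Share of active frames per body-temperature bin, with Wilson CIs."""
    temp_bins = np.asarray(temp_bins, dtype=float)
    if len(temp_bins) < 2:
        raise MarkovError("need at least one temperature bin")
    states, temps = [], []
    for seq in sequences:
        states.append(seq.active)
        temps.append(seq.body_temp_C)
    s = np.concatenate(states) if states else np.empty(0, bool)
    t = np.concatenate(temps) if temps else np.empty(0)
    keep = np.isfinite(t)
    s, t = s[keep], t[keep]
    bin_idx = np.digitize(t, temp_bins) - 1
    rows = []
    for b in range(len(temp_bins) - 1):
        m = bin_idx == b
        n = int(m.sum())
        if n < min_count:
            continue
        k = int(s[m].sum())
        p, lo, hi = _wilson(k, n)
        rows.append({"temp_lo": temp_bins[b], "temp_hi": temp_bins[b + 1],
                     "n_frames": n, "n_active": k, "activity": p,
                     "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows, columns=["temp_lo", "temp_hi", "n_frames", "n_active",
                                       "activity", "ci_lo", "ci_hi"])


# ---------------------------------------------------------------------------
# treatment-arm contrast
# ---------------------------------------------------------------------------

def _per_bee_bin_counts(
    seqs: Sequence[ActivitySequence],
    temp_bins: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Active->inactive (opportunities, transitions) per (bee, temp bin)."""
    groups: dict[str, list[ActivitySequence]] = {}
    for s in seqs:
        groups.setdefault(s.bee_id, []).append(s)
    nb = len(temp_bins) - 1
    n = np.zeros((len(groups), nb))
    k = np.zeros((len(groups), nb))
    for row, bee in enumerate(sorted(groups)):
        for seq in groups[bee]:
            s0, s1, t = _transition_pairs(seq)
            keep = np.isfinite(t) & s0
            s1k, tk = s1[keep], t[keep]
            idx = np.digitize(tk, temp_bins) - 1
            ok = (idx >= 0) & (idx < nb)
            np.add.at(n[row], idx[ok], 1.0)
            np.add.at(k[row], idx[ok], (~s1k[ok]).astype(float))
    return n, k


def _pooled_diff(
    n_c: np.ndarray, k_c: np.ndarray,
    n_i: np.ndarray, k_i: np.ndarray,
    region: np.ndarray,
) -> float:
    """Opportunity-weighted mean of per-bin p_ai differences over a bin region.

    Weights (combined opportunity counts) are shared between arms, so
    within-bin effects pool without composition bias.
    """
    ok = region & (n_c > 0) & (n_i > 0)
    if not ok.any():
        return np.nan
    w = n_c[ok] + n_i[ok]
    diff = k_i[ok] / n_i[ok] - k_c[ok] / n_c[ok]
    return float(np.sum(w * diff) / np.sum(w))


def arm_contrast(
    seqs_control: Sequence[ActivitySequence],
    seqs_imid: Sequence[ActivitySequence],
    temp_bins: np.ndarray = DEFAULT_TEMP_BINS,
    T_thresh: float = 18.0,
    n_boot: int = 400,
    seed: int = 0,
) -> dict:
    """Imidacloprid-vs-control difference in p_ai below and above ``T_thresh``.

    Point estimates pool per-bin differences with shared opportunity weights;
    percentile CIs come from a bees-resampling bootstrap within each arm.
    """
    temp_bins = np.asarray(temp_bins, dtype=float)
    mids = (temp_bins[:-1] + temp_bins[1:]) / 2.0
    region_below = mids < T_thresh
    region_above = mids >= T_thresh
    N_c, K_c = _per_bee_bin_counts(seqs_control, temp_bins)
    N_i, K_i = _per_bee_bin_counts(seqs_imid, temp_bins)
    below = _pooled_diff(N_c.sum(0), K_c.sum(0), N_i.sum(0), K_i.sum(0), region_below)
    above = _pooled_diff(N_c.sum(0), K_c.sum(0), N_i.sum(0), K_i.sum(0), region_above)
    if np.isnan(below):
        return {"estimable": False, "reason": "no shared sub-threshold bins"}
    rng = np.random.default_rng(seed)

    boot_below, boot_above = [], []
    for _ in range(n_boot):
        rc = rng.integers(0, len(N_c), len(N_c))
        ri = rng.integers(0, len(N_i), len(N_i))
        nc, kc = N_c[rc].sum(0), K_c[rc].sum(0)
        ni, ki = N_i[ri].sum(0), K_i[ri].sum(0)
        boot_below.append(_pooled_diff(nc, kc, ni, ki, region_below))
        boot_above.append(_pooled_diff(nc, kc, ni, ki, region_above))
    boot_below = np.asarray(boot_below)
    boot_above = np.asarray(boot_above)

    def _ci(x):
        x = x[np.isfinite(x)]
        if len(x) < 10:
            return (np.nan, np.nan)
        return (float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5)))

    return {
        "estimable": True,
        "T_thresh": float(T_thresh),
        "diff_below": float(below),
        "diff_below_ci": _ci(boot_below),
        "diff_above": float(above) if np.isfinite(above) else None,
        "diff_above_ci": _ci(boot_above),
        "n_boot": n_boot,
    }
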