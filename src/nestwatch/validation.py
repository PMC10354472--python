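"""Seeded recovery experiments used by the acceptance suite and report.

Each function runs one self-contained replicate of a parameter-recovery or
direction-of-effect experiment on synthetic data, returning plain dicts so the
harness can aggregate across seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import activity_markov as am
from . import behaviour_metrics as bm
from . import centrality as ct
from . import stats_stage as st
from . import synthetic_colony as sc

MARKOV_BINS = np.arange(10.0, 26.0, 2.0)


def _markov_protocol() -> sc.TemperatureProtocol:
    return sc.TemperatureProtocol((
        sc.ProtocolSegment(8.0, 24.0, 24.0),
        sc.ProtocolSegment(12.0, 24.0, 10.0),
        sc.ProtocolSegment(12.0, 10.0, 10.0),
        sc.ProtocolSegment(12.0, 10.0, 24.0),
    ))


def markov_recovery_replicate(seed: int, delta: float = 0.1,
                              n_bees: int = 14) -> dict:
    """One control-vs-imidacloprid replicate of the transition-rate recovery.

    Bees experience ambient temperature directly (no collective heating) so
    the true transition curve is known exactly; states come from the
    simulator's ground truth (the estimator, not the labeller, is under test).
    """
    nest = sc.default_nest_map(arena=(800.0, 600.0), mm_per_px=0.16, seed=1)
    proto = _markov_protocol()
    seqs = {}
    params_by_arm = {}
    for imid in (False, True):
        params = sc.SimParams(
            n_bees=n_bees, seed=2 * seed + int(imid) + 10_000, imidacloprid=imid,
            delta_ai_imid=delta, body_heat_C=0.0, brood_heat_C=0.0,
            thermotaxis_gain_px_per_C=0.0, frame_rate_hz=1.5,
            clip_interval_min=None, step_scale_px=8.0,
        )
        _, gt = sc.simulate_colony(params, proto, nest)
        seqs[imid] = am.sequences_from_truth(gt.per_frame)
        params_by_arm[imid] = params

    contrast = am.arm_contrast(seqs[False], seqs[True], MARKOV_BINS,
                               n_boot=400, seed=seed)
    lo_b, hi_b = contrast["diff_below_ci"]
    lo_a, hi_a = contrast["diff_above_ci"]

    # Wilson coverage against the exact opportunity-weighted truth (control arm)
    params = params_by_arm[False]
    s0_all, t_all = [], []
    for s in seqs[False]:
        s0, _, t = am._transition_pairs(s)
        s0_all.append(s0)
        t_all.append(t)
    s0 = np.concatenate(s0_all)
    t = np.concatenate(t_all)
    t_active = t[s0]
    idx = np.digitize(t_active, MARKOV_BINS) - 1
    hits = total = 0
    for e in am.estimate_transitions(seqs[False], MARKOV_BINS):
        b = int(round((e.temp_lo - MARKOV_BINS[0]) / 2.0))
        truth = float(params.p_ai(t_active[idx == b]).mean())
        total += 1
        hits += int(e.p_ai_lo <= truth <= e.p_ai_hi)
    return {
        "below_covers_delta": bool(lo_b <= delta <= hi_b),
        "above_covers_zero": bool(lo_a <= 0.0 <= hi_a),
        "diff_below": contrast["diff_below"],
        "wilson_hits": hits,
        "wilson_total": total,
    }


def centrality_direction_replicate(n_bees: int, seed: int,
                                   delta: float = 0.5) -> dict:
    """Cold-response of oriented PC1 for paired control/imidacloprid colonies.

    Arms share the random seed (common random numbers), so they diverge only
    through the imidacloprid transition offset. Returns each arm's cold-warm
    score difference.
    """
    dfs = []
    for imid in (False, True):
        params, proto, nest = sc.cold_experiment_setup(n_bees, imid, seed,
                                                       delta_ai_imid=delta)
        segs, gt = sc.simulate_colony(params, proto, nest)
        thr, _ = bm.pooled_activity_threshold(segs)
        recs = []
        for s in segs:
            recs.extend(bm.compute_behaviour_records(s, nest, thr))
        df = pd.DataFrame([r.__dict__ for r in recs])
        vid_temp = gt.per_frame.groupby("video_id")["T_air_C"].mean()
        df["T_air"] = df["video_id"].map(vid_temp)
        df["imid"] = imid
        dfs.append(df)
    both = pd.concat(dfs, ignore_index=True)
    model = ct.orient_pc1(ct.fit_pca(both, "queenright_11"))
    scores = ct.scores_to_frame(ct.score(both, model))
    scores[["imid", "T_air"]] = both[["imid", "T_air"]].values
    out = {}
    for imid in (False, True):
        d = scores[scores["imid"] == imid]
        cold = d.loc[d["T_air"] < 12, "pc1_transformed"].mean()
        warm = d.loc[d["T_air"] > 22, "pc1_transformed"].mean()
        out["imid" if imid else "control"] = float(cold - warm)
    return out


def growth_recovery_replicate(seed: int, n_colonies: int = 50,
                              growth: sc.GrowthCoefficients | None = None) -> dict:
    """One simulated census experiment: recovery CI and AIC model choice."""
    growth = growth or sc.GrowthCoefficients()
    r = np.random.default_rng(seed)
    sizes = list(r.integers(2, 41, size=n_colonies))
    arms = [(bool(r.integers(2)), bool(r.integers(2))) for _ in sizes]
    _, table = sc.simulate_census(growth, sizes, arms, seed=seed)
    fit, _ = st.productivity_analysis(table)
    est = float(fit.params["imid:cold:log10_size"])
    se = float(fit.bse["imid:cold:log10_size"])
    table2 = table.copy()
    table2["log10_size"] = np.log10(table2["size"].astype(float))
    full = st.ModelSpec("full", "productivity", "imid * cold * log10_size",
                        "poisson-log", group="block")
    reduced = st.ModelSpec("reduced", "productivity",
                           "imid * cold + imid * log10_size + cold * log10_size",
                           "poisson-log", group="block")
    chosen, _ = st.select_by_aic([reduced, full], table2)
    return {
        "covered": bool(est - 1.96 * se <= growth.b_3way <= est + 1.96 * se),
        "estimate": est,
        "chose_interaction": chosen.name == "full",
    }
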