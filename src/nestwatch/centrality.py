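"""Spatial-centrality scoring: PCA of behaviour records plus Yeo-Johnson.

PC1 of the scaled-and-centred behavioural metrics is the "spatial centrality"
score, oriented so that higher values mean closer to the nest centre, then
transformed toward normality with a maximum-likelihood Yeo-Johnson power
transform.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .behaviour_metrics import QUEENRIGHT_11

logger = logging.getLogger("nestwatch.centrality")

#: microcolony variant: five variables tied to spatial centrality
MICROCOLONY_5 = [
    "mean_dist_nestmates", "min_dist_closest_brood", "brood_interaction_rate",
    "distance_to_centre", "degree_centrality",
]

VARIABLE_SETS = {"queenright_11": QUEENRIGHT_11, "microcolony_5": MICROCOLONY_5}


class CentralityError(ValueError):
    pass


@dataclass
class PCAModel:
    variables: list[str]
    centre: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray           # (n_vars, n_components), columns orthonormal
    variance_fractions: np.ndarray
    pc1_sign: float = 1.0
    dropped_constant: list[str] = field(default_factory=list)
    n_rows_used: int = 0
    n_rows_dropped: int = 0
    yj_lambda: float | None = None

    def to_json(self, path) -> None:
        doc = {
            "variables": self.variables,
            "centre": self.centre.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "pc1_sign": self.pc1_sign,
            "dropped_constant": self.dropped_constant,
            "n_rows_used": self.n_rows_used,
            "n_rows_dropped": self.n_rows_dropped,
            "yj_lambda": self.yj_lambda,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PCAModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            variables=d["variables"], centre=np.asarray(d["centre"]),
            scale=np.asarray(d["scale"]), loadings=np.asarray(d["loadings"]),
            variance_fractions=np.asarray(d["variance_fractions"]),
            pc1_sign=float(d["pc1_sign"]), dropped_constant=d["dropped_constant"],
            n_rows_used=int(d["n_rows_used"]), n_rows_dropped=int(d["n_rows_dropped"]),
            yj_lambda=d["yj_lambda"],
        )


@dataclass(frozen=True)
class CentralityScore:
    bee_id: str
    video_id: str
    pc1_raw: float
    pc1_transformed: float
    yj_lambda: float
    imputed: bool = False


def fit_pca(records: pd.DataFrame, variable_set: str = "queenright_11") -> PCAModel:
    """PCA of the scaled-and-centred metric columns (correlation-matrix PCA).

    Rows with any missing metric are dropped (and counted); constant columns
    are removed with a warning and recorded in the model.
    """
    if variable_set not in VARIABLE_SETS:
        raise CentralityError(f"unknown variable set {variable_set!r}")
    variables = list(VARIABLE_SETS[variable_set])
    missing_cols = [v for v in variables if v not in records.columns]
    if missing_cols:
        raise CentralityError(f"records missing columns {missing_cols}")
    X = records[variables].to_numpy(dtype=float)
    complete = np.isfinite(X).all(axis=1)
    n_dropped = int((~complete).sum())
    X = X[complete]
    if len(X) < 2:
        raise CentralityError(f"need >= 2 complete records, got {len(X)}")

    sd = X.std(axis=0, ddof=1)
    constant = sd < 1e-12
    dropped_constant = [v for v, c in zip(variables, constant) if c]
    if dropped_constant:
        logger.warning("dropping constant variables %s", dropped_constant)
        variables = [v for v, c in zip(variables, constant) if not c]
        X = X[:, ~constant]
        sd = sd[~constant]
    centre = X.mean(axis=0)
    Z = (X - centre) / sd
    # SVD of the standardized matrix == eigendecomposition of the correlation matrix
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    var = s ** 2 / (len(Z) - 1)
    fractions = var / var.sum()
    return PCAModel(
        variables=variables, centre=centre, scale=sd, loadings=vt.T,
        variance_fractions=fractions, dropped_constant=dropped_constant,
        n_rows_used=len(Z), n_rows_dropped=n_dropped,
    )


def orient_pc1(model: PCAModel) -> PCAModel:
    """Flip PC1 so the distance-to-centre loading is negative (higher = central)."""
    if "distance_to_centre" not in model.variables:
        raise CentralityError("model lacks distance_to_centre; cannot orient PC1")
    i = model.variables.index("distance_to_centre")
    effective = model.pc1_sign * model.loadings[i, 0]
    if effective > 0:
        return replace(model, pc1_sign=-model.pc1_sign)
    return model


def yeo_johnson(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Maximum-likelihood Yeo-Johnson transform of a sample."""
    values = np.asarray(values, dtype=float)
    bad = np.where(~np.isfinite(values))[0]
    if len(bad):
        raise CentralityError(f"non-finite inputs at indices {bad.tolist()[:20]}")
    if len(values) < 10:
        raise CentralityError(f"need >= 10 values, got {len(values)}")
    transformed, lmbda = stats.yeojohnson(values)
    return np.asarray(transformed), float(lmbda)


def yeo_johnson_transform(values: np.ndarray, lmbda: float) -> np.ndarray:
    """Apply the Yeo-Johnson formula with a fixed lambda."""
    return stats.yeojohnson(np.asarray(values, dtype=float), lmbda=lmbda)


def score(records: pd.DataFrame, model: PCAModel) -> list[CentralityScore]:
    """Project records onto oriented PC1 and apply the stored Yeo-Johnson lambda.

    Rows with missing metrics are mean-imputed (flagged). If the model carries
    no lambda yet, one is fitted on these scores and stored on the model.
    """
    missing_cols = [v for v in model.variables if v not in records.columns]
    if missing_cols:
        raise CentralityError(f"records missing model variables {missing_cols}")
    X = records[model.variables].to_numpy(dtype=float)
    imputed = ~np.isfinite(X).all(axis=1)
    X = np.where(np.isfinite(X), X, model.centre[None, :])
    Z = (X - model.centre) / model.scale
    pc1 = model.pc1_sign * (Z @ model.loadings[:, 0])
    if model.yj_lambda is None:
        if len(pc1) >= 10:
            _, model.yj_lambda = yeo_johnson(pc1)
        else:
            model.yj_lambda = 1.0
    transformed = yeo_johnson_transform(pc1, model.yj_lambda)
    bees = records["bee_id"].astype(str).tolist() if "bee_id" in records else [""] * len(pc1)
    vids = records["video_id"].astype(str).tolist() if "video_id" in records else [""] * len(pc1)
    return [
        CentralityScore(b, v, float(r), float(t), float(model.yj_lambda), bool(m))
        for b, v, r, t, m in zip(bees, vids, pc1, transformed, imputed)
    ]


def scores_to_frame(scores: list[CentralityScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"bee_id": s.bee_id, "video_id": s.video_id, "pc1_raw": s.pc1_raw,
          "pc1_transformed": s.pc1_transformed, "yj_lambda": s.yj_lambda,
          "imputed": s.imputed} for s in scores],
        columns=["bee_id", "video_id", "pc1_raw", "pc1_transformed",
                 "yj_lambda", "imputed"],
    )
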