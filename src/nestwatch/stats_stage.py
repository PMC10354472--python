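"""Mixed-model fits for pipeline outputs and the AIC selection ledger.

Gaussian responses with random effects use ``statsmodels`` MixedLM (nested
grouping via variance components: block > colony > bee). Poisson (log link)
responses are fitted as GLMs with grouping factors absorbed as fixed
categorical effects, since crossed/nested Poisson GLMMs are outside
statsmodels' frequentist surface; the fit result flags this. Degrees of
freedom use the normal approximation (flagged) — Satterthwaite is not
available from the backend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    name: str
    response: str
    fixed: str                       # patsy right-hand side
    family: str = "gaussian"         # gaussian | poisson-log
    group: str | None = None         # outermost random grouping column
    nested: tuple[str, ...] = ()     # variance components nested inside group
    reml: bool = False               # ML by default so AICs are comparable

    @property
    def formula(self) -> str:
        return f"{self.response} ~ {self.fixed}"


@dataclass
class FitResult:
    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    stats: pd.Series                 # t/z statistics
    pvalues: pd.Series | None
    aic: float
    llf: float
    n_fixed_params: int
    converged: bool
    singular: bool = False
    method: str = ""
    df_method: str = "normal-approximation"
    notes: list[str] = field(default_factory=list)
    model_result: object = None


def _check_columns(table: pd.DataFrame, spec: ModelSpec) -> None:
    cols = {spec.response}
    if spec.group:
        cols.add(spec.group)
    cols.update(spec.nested)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise StatsError(f"table missing columns {missing} for model {spec.name!r}")


def fit_model(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit one model spec; never raises on non-convergence (flags instead)."""
    _check_columns(table, spec)
    data = table.dropna(subset=[spec.response]).copy()
    if spec.group is not None and data[spec.group].nunique() < 2:
        raise StatsError(f"grouping factor {spec.group!r} has < 2 levels")

    if spec.family == "poisson-log":
        fixed = spec.fixed
        notes = []
        if spec.group is not None:
            # grouping absorbed as fixed categorical effects (no Poisson GLMM
            # backend); estimates of within-group fixed effects are unchanged
            extra = [spec.group, *spec.nested]
            fixed = fixed + " + " + " + ".join(f"C({g})" for g in extra)
            notes.append(f"random terms {extra} absorbed as fixed categoricals")
        model = smf.glm(f"{spec.response} ~ {fixed}", data=data,
                        family=sm.families.Poisson())
        res = model.fit()
        return FitResult(
            spec=spec, params=res.params, bse=res.bse, stats=res.tvalues,
            pvalues=res.pvalues, aic=float(res.aic), llf=float(res.llf),
            n_fixed_params=int(res.df_model) + 1, converged=bool(res.converged),
            method="glm-poisson", notes=notes, model_result=res,
        )

    if spec.family != "gaussian":
        raise StatsError(f"unknown family {spec.family!r}")

    if spec.group is None:
        res = smf.ols(spec.formula, data=data).fit()
        return FitResult(
            spec=spec, params=res.params, bse=res.bse, stats=res.tvalues,
            pvalues=res.pvalues, aic=float(res.aic), llf=float(res.llf),
            n_fixed_params=int(res.df_model) + 1, converged=True,
            method="ols", model_result=res,
        )

    vc = {g: f"0 + C({g})" for g in spec.nested}
    model = smf.mixedlm(spec.formula, data=data, groups=data[spec.group],
                        vc_formula=vc or None, re_formula="1")
    converged = True
    singular = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(reml=spec.reml, method="lbfgs")
        except (np.linalg.LinAlgError, ValueError) as exc:
            return FitResult(
                spec=spec, params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
                stats=pd.Series(dtype=float), pvalues=None, aic=np.nan, llf=np.nan,
                n_fixed_params=0, converged=False, method="mixedlm",
                notes=[f"fit failed: {exc}"],
            )
        for w in caught:
            msg = str(w.message).lower()
            if "convergence" in msg or "converge" in msg:
                converged = False
            if "singular" in msg or "boundary" in msg:
                singular = True
    fe = res.fe_params.index
    aic = float(res.aic) if not spec.reml else np.nan
    return FitResult(
        spec=spec, params=res.params[fe], bse=res.bse[fe], stats=res.tvalues[fe],
        pvalues=res.pvalues[fe] if converged else None,
        aic=aic, llf=float(res.llf),
        n_fixed_params=len(res.fe_params), converged=converged, singular=singular,
        method="mixedlm-" + ("reml" if spec.reml else "ml"), model_result=res,
    )


def select_by_aic(
    candidates: list[ModelSpec],
    table: pd.DataFrame,
    delta_threshold: float = 4.0,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Choose the simplest candidate within ``delta_threshold`` AIC of the best.

    "Simpler" means fewer fixed-effect parameters; ties break by candidate
    order. Returns the chosen spec and a ledger of (name, AIC, dAIC, params).
    """
    if len(candidates) < 2:
        raise StatsError("need >= 2 candidate specs")
    fits = [fit_model(table, spec) for spec in candidates]
    ok = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not ok:
        diag = "; ".join(f"{f.spec.name}: {f.notes}" for f in fits)
        raise StatsError(f"all candidates failed: {diag}")
    best_aic = min(f.aic for f in ok)
    ledger = pd.DataFrame([
        {"name": f.spec.name, "aic": f.aic, "delta_aic": f.aic - best_aic,
         "n_fixed_params": f.n_fixed_params, "converged": f.converged}
        for f in fits
    ])
    eligible = [f for f in ok if f.aic - best_aic <= delta_threshold]
    chosen = min(eligible, key=lambda f: (f.n_fixed_params, fits.index(f)))
    return chosen.spec, ledger


def productivity_analysis(
    census: pd.DataFrame,
    min_size: int = 2,
    max_size: int = 40,
    reference_sizes: tuple[int, ...] = (4, 40),
) -> tuple[FitResult, pd.DataFrame]:
    """Poisson-log productivity fit with the size x cold x imidacloprid interaction.

    Expects columns: productivity, size, cold, imid, block. Colonies of a
    single individual and colonies larger than ``max_size`` at treatment are
    excluded. Returns the fit and per-arm predictions (with CIs) at the
    reference sizes.
    """
    for col in ("productivity", "size", "cold", "imid", "block"):
        if col not in census.columns:
            raise StatsError(f"census table missing column {col!r}")
    data = census[(census["size"] >= min_size) & (census["size"] <= max_size)].copy()
    if data.empty:
        raise StatsError("no colonies left after size filter")
    data["log10_size"] = np.log10(data["size"].astype(float))
    data["cold"] = data["cold"].astype(int)
    data["imid"] = data["imid"].astype(int)
    strata = data.groupby(["cold", "imid"]).size()
    if len(strata) < 4:
        warnings.warn("some treatment arms unpopulated; fit proceeds", stacklevel=2)
    spec = ModelSpec(
        name="productivity_3way", response="productivity",
        fixed="imid * cold * log10_size", family="poisson-log", group="block",
    )
    fit = fit_model(data, spec)

    rows = []
    res = fit.model_result
    blocks = sorted(data["block"].unique())
    for size in reference_sizes:
        for cold in (0, 1):
            for imid in (0, 1):
                newd = pd.DataFrame({
                    "imid": imid, "cold": cold,
                    "log10_size": np.log10(float(size)),
                    "block": blocks,
                })
                pred = res.get_prediction(newd)
                mean = float(np.mean(pred.predicted_mean))
                ci = pred.conf_int()
                rows.append({"size": size, "cold": bool(cold), "imid": bool(imid),
                             "predicted": mean,
                             "ci_lo": float(np.mean(ci[:, 0])),
                             "ci_hi": float(np.mean(ci[:, 1]))})
    return fit, pd.DataFrame(rows)
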