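"""Bias statistics for volume-to-biomass conversion and the VWWD
correction-model family m1-m6.

Per-tree relative error, its mean (bias B) and a coefficient of variation:

    b_i  = (AGB_est_i - AGB_obs_i) / AGB_obs_i * 100        [%]
    B    = mean(b_i)                                        [%]
    RMSE = sqrt(mean((AGB_est_i - AGB_obs_i)^2))            [g]
    CV   = 100 * RMSE / mean(AGB_obs)                       [%]

Note there are two residual-error quantities with similar names: the
regression residual SE of a VWWD model (``model_rse``, g.cm^-3) and the
AGB-level root-mean-square error above (``agb_rmse``, g). Both are reported
under distinct names.

The correction models predict the volume-weighted wood density from cheap
predictors (OLS):

    m1: VWWD ~ WD_Stu                 m4: VWWD ~ WD_GWD
    m2: VWWD ~ WD_Stu + DBH           m5: VWWD ~ WD_GWD + DBH
    m3: VWWD ~ WD_Stu + DBH + Sm      m6: VWWD ~ WD_GWD + DBH + Sm

``PUBLISHED_MODELS`` ships reference coefficient sets fitted on a large
multi-site Central-African destructive dataset, usable directly via
:func:`predict_vwwd` when no local calibration data exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .vwwd import agb_estimates_table

__all__ = [
    "BiasReport",
    "LinearModelFit",
    "MODEL_PREDICTORS",
    "PUBLISHED_MODELS",
    "relative_error",
    "bias_report",
    "fit_vwwd_model",
    "predict_vwwd",
    "loso_crossval",
]

#: Predictors (beyond the intercept) of each model in the family.
MODEL_PREDICTORS: dict[str, tuple[str, ...]] = {
    "m1": ("WD_Stu",),
    "m2": ("WD_Stu", "DBH"),
    "m3": ("WD_Stu", "DBH", "Sm"),
    "m4": ("WD_GWD",),
    "m5": ("WD_GWD", "DBH"),
    "m6": ("WD_GWD", "DBH", "Sm"),
}

_COEF_NAMES = ("a", "b", "c", "d")


@dataclass
class BiasReport:
    """Bias and total-error statistics of paired AGB estimates."""

    b_i: np.ndarray  # per-tree relative errors, %
    B: float  # mean of b_i, %
    sd_b: float  # SD of b_i, %
    agb_rmse: float  # root-mean-square AGB error, g
    MAGB_obs: float  # mean observed AGB, g
    CV: float  # 100 * agb_rmse / MAGB_obs, %


@dataclass
class LinearModelFit:
    """One fitted (or published) VWWD correction model."""

    model_id: str
    coefficients: dict[str, float]  # a (intercept), b, c, d
    std_errors: dict[str, float] = field(default_factory=dict)
    r2: float = float("nan")
    r2_adj: float = float("nan")
    model_rse: float = float("nan")  # residual SE of the VWWD regression, g.cm^-3
    aic: float = float("nan")
    n: int = 0
    bias: BiasReport | None = None  # AGB-level B/CV on the fitting set

    @property
    def predictors(self) -> tuple[str, ...]:
        return MODEL_PREDICTORS[self.model_id]


#: Reference coefficient sets (multi-site Central-African calibration).
PUBLISHED_MODELS: dict[str, LinearModelFit] = {
    "m1": LinearModelFit(
        "m1",
        {"a": 0.07842, "b": 0.78915},
        {"a": 0.00682, "b": 0.01076},
        r2=0.87, model_rse=0.049, aic=-2629.1,
    ),
    "m2": LinearModelFit(
        "m2",
        {"a": 0.05455, "b": 0.78326, "c": 0.00048},
        {"a": 0.00679, "b": 0.01011, "c": 0.00005},
        r2=0.88, model_rse=0.046, aic=-2732.3,
    ),
    "m3": LinearModelFit(
        "m3",
        {"a": 0.10013, "b": 0.77299, "c": 0.00042, "d": -0.05819},
        {"a": 0.01077, "b": 0.01012, "c": 0.00005, "d": 0.0108},
        r2=0.89, model_rse=0.045, aic=-2759.0,
    ),
    "m4": LinearModelFit(
        "m4",
        {"a": 0.1721, "b": 0.63638},
        {"a": 0.00763, "b": 0.01189},
        r2=0.78, model_rse=0.063, aic=-2200.6,
    ),
    "m5": LinearModelFit(
        "m5",
        {"a": 0.13406, "b": 0.63614, "c": 0.00067},
        {"a": 0.00783, "b": 0.01105, "c": 0.00006},
        r2=0.81, model_rse=0.059, aic=-2320.9,
    ),
    "m6": LinearModelFit(
        "m6",
        {"a": 0.18233, "b": 0.62656, "c": 0.0006, "d": -0.06258},
        {"a": 0.01325, "b": 0.01113, "c": 0.00006, "d": 0.01395},
        r2=0.81, model_rse=0.058, aic=-2338.9,
    ),
}


def relative_error(AGB_est: float, AGB_obs: float) -> float:
    """Signed per-tree relative AGB error in percent."""
    if AGB_obs <= 0:
        raise ValueError(f"AGB_obs must be positive, got {AGB_obs}")
    return (AGB_est - AGB_obs) / AGB_obs * 100.0


def bias_report(estimates, observations) -> BiasReport:
    """Bias (B), per-tree error SD, AGB RMSE, mean observed AGB and CV."""
    est = np.asarray(estimates, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if est.shape != obs.shape or est.ndim != 1:
        raise ValueError("estimates and observations must be equal-length vectors")
    if np.any(obs <= 0):
        raise ValueError("all observed AGB values must be positive")
    b_i = (est - obs) / obs * 100.0
    rmse = float(np.sqrt(np.mean((est - obs) ** 2)))
    magb = float(obs.mean())
    return BiasReport(
        b_i=b_i,
        B=float(b_i.mean()),
        sd_b=float(b_i.std(ddof=1)) if b_i.size > 1 else 0.0,
        agb_rmse=rmse,
        MAGB_obs=magb,
        CV=100.0 * rmse / magb,
    )


def _design_matrix(model_id: str, data: pd.DataFrame) -> np.ndarray:
    preds = MODEL_PREDICTORS[model_id]
    missing = [p for p in preds if p not in data.columns]
    if missing:
        raise KeyError(f"model {model_id} requires predictors {missing}")
    X = data[list(preds)].to_numpy(dtype=float)
    return sm.add_constant(X, has_constant="add")


def fit_vwwd_model(trees: pd.DataFrame, model_id: str) -> LinearModelFit:
    """OLS fit of one VWWD correction model on a calibrated tree table.

    ``trees`` must carry ``VWWD`` plus the model's predictors; when
    ``V_obs`` and ``AGB_obs`` are present, the fitting-set AGB bias report
    (apparent B and CV) is attached.

    AIC uses the Gaussian log-likelihood with the error variance counted as
    a parameter (k = p + 1); the absolute level depends on that convention
    but differences across m1-m6 do not.
    """
    if model_id not in MODEL_PREDICTORS:
        raise ValueError(f"unknown model {model_id!r}")
    y = trees["VWWD"].to_numpy(dtype=float)
    X = _design_matrix(model_id, trees)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"model {model_id} needs more than {p} observations, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(f"model {model_id}: design matrix is rank deficient")

    res = sm.OLS(y, X).fit()
    ssr = float(res.ssr)
    names = _COEF_NAMES[:p]
    coefficients = dict(zip(names, res.params.tolist()))
    std_errors = dict(zip(names, res.bse.tolist()))
    aic = n * math.log(2 * math.pi) + n * math.log(ssr / n) + n + 2 * (p + 1)

    fit = LinearModelFit(
        model_id=model_id,
        coefficients=coefficients,
        std_errors=std_errors,
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
        model_rse=math.sqrt(ssr / (n - p)),
        aic=aic,
        n=n,
    )
    if {"V_obs", "AGB_obs"}.issubset(trees.columns):
        pred = predict_vwwd(fit, trees)
        est = agb_estimates_table(trees, "VWWD_model", wd_values=pred)
        fit.bias = bias_report(est["AGB_est"], est["AGB_obs"])
    return fit


def predict_vwwd(fit: LinearModelFit | str, predictors) -> np.ndarray:
    """Predicted VWWD from a fitted model, or a published preset by id.

    ``predictors`` is a DataFrame (or dict of arrays/scalars) carrying the
    model's predictor columns.
    """
    if isinstance(fit, str):
        fit = PUBLISHED_MODELS[fit]
    if isinstance(predictors, dict):
        predictors = pd.DataFrame(
            {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in predictors.items()}
        )
    X = _design_matrix(fit.model_id, predictors)
    beta = np.array([fit.coefficients[c] for c in _COEF_NAMES[: X.shape[1]]])
    return X @ beta


def loso_crossval(trees: pd.DataFrame, model_id: str) -> pd.DataFrame:
    """Leave-one-site-out cross-validation of one correction model.

    For each site, the model is calibrated on all other sites and used to
    predict VWWD -- hence AGB -- for the focal site. Returns one row per
    site (n, B, sd_b, agb_rmse, CV) plus a pooled row over all held-out
    predictions.
    """
    sites = sorted(trees["site"].unique())
    if len(sites) < 2:
        raise ValueError("leave-one-site-out requires at least 2 sites")
    p = len(MODEL_PREDICTORS[model_id]) + 1
    rows = []
    pooled_est: list[np.ndarray] = []
    pooled_obs: list[np.ndarray] = []
    for site in sites:
        train = trees[trees["site"] != site]
        test = trees[trees["site"] == site]
        if len(train) <= p:
            raise ValueError(
                f"site {site}: complement has {len(train)} trees, too few to fit {model_id}"
            )
        fit = fit_vwwd_model(train, model_id)
        pred = predict_vwwd(fit, test)
        est = agb_estimates_table(test, "VWWD_model", wd_values=pred)
        rep = bias_report(est["AGB_est"], est["AGB_obs"])
        rows.append(
            {
                "site": site,
                "n": len(test),
                "B": rep.B,
                "sd_b": rep.sd_b,
                "agb_rmse": rep.agb_rmse,
                "CV": rep.CV,
            }
        )
        pooled_est.append(est["AGB_est"].to_numpy())
        pooled_obs.append(est["AGB_obs"].to_numpy())
    rep = bias_report(np.concatenate(pooled_est), np.concatenate(pooled_obs))
    rows.append(
        {
            "site": "(pooled)",
            "n": len(trees),
            "B": rep.B,
            "sd_b": rep.sd_b,
            "agb_rmse": rep.agb_rmse,
            "CV": rep.CV,
        }
    )
    return pd.DataFrame(rows)
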