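"""Temperature x chlorophyll regression prediction of cyanophage abundance.

The deployment model regresses log10 cyanophage abundance on temperature,
chlorophyll and their interaction:

    log10(V) = k0 + k1*T + k2*Chl + k3*(T x Chl)

Candidate predictor sets (host abundances, log chlorophyll, the
Prochlorococcus:Synechococcus ratio, each with temperature interactions) are
compared by test-set RMSE under a train/test split; the chlorophyll model is
kept as the deployment default because gridded chlorophyll is far more widely
available than host abundances.  Gridded prediction is masked to the domain
where picocyanobacteria grow (T > 5 °C) and the regression was trained
(Chl < 0.4 mg m^-3).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import schema

__all__ = [
    "rmse",
    "fit_model",
    "train_test_evaluate",
    "predict_with_interval",
    "grid_predict",
    "RegressionModel",
    "PredictionGrid",
    "DEFAULT_FEATURES",
    "CANDIDATE_SETS",
]

MASK_TEMP_MIN_C = 5.0
MASK_CHL_MAX = 0.4

#: deployment predictors: temperature, chlorophyll and their interaction
DEFAULT_FEATURES = (schema.TEMP, schema.CHL, (schema.TEMP, schema.CHL))


def rmse(predicted, observed) -> float:
    """Root-mean-square error between paired predictions and observations."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.size == 0 or p.shape != o.shape:
        raise ValueError("predicted and observed must be equal-length and non-empty")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def _feature_name(f) -> str:
    return f"{f[0]}*{f[1]}" if isinstance(f, tuple) else str(f)


def _design(df: pd.DataFrame, features) -> np.ndarray:
    cols = [np.ones(len(df))]
    for f in features:
        if isinstance(f, tuple):
            cols.append(df[f[0]].to_numpy(dtype=float) * df[f[1]].to_numpy(dtype=float))
        else:
            cols.append(df[f].to_numpy(dtype=float))
    return np.column_stack(cols)


@dataclass
class RegressionModel:
    """Fitted linear predictor of (transformed) cyanophage abundance."""

    target: str
    features: tuple
    coefficients: np.ndarray
    cov_params: np.ndarray
    scale: float            # residual variance on the response scale
    df_resid: float
    rmse_train: float
    n_train: int
    response_transform: str = "log10"
    rmse_test: float | None = None
    n_test: int = 0
    mask_temp_min: float = MASK_TEMP_MIN_C
    mask_chl_max: float = MASK_CHL_MAX

    @property
    def feature_names(self) -> list[str]:
        return ["intercept"] + [_feature_name(f) for f in self.features]

    def design(self, df: pd.DataFrame) -> np.ndarray:
        return _design(df, self.features)

    def predict_response(self, df: pd.DataFrame) -> np.ndarray:
        """Prediction on the (possibly log) response scale."""
        return self.design(df) @ self.coefficients

    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def to_json(self, path) -> None:
        payload = {
            "target": self.target,
            "features": [list(f) if isinstance(f, tuple) else f for f in self.features],
            "coefficients": self.coefficients.tolist(),
            "cov_params": self.cov_params.tolist(),
            "scale": self.scale,
            "df_resid": self.df_resid,
            "rmse_train": self.rmse_train,
            "n_train": self.n_train,
            "response_transform": self.response_transform,
            "rmse_test": self.rmse_test,
            "n_test": self.n_test,
            "mask": {"temp_min_c": self.mask_temp_min, "chl_max": self.mask_chl_max},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RegressionModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            target=d["target"],
            features=tuple(tuple(f) if isinstance(f, list) else f for f in d["features"]),
            coefficients=np.asarray(d["coefficients"]),
            cov_params=np.asarray(d["cov_params"]),
            scale=d["scale"],
            df_resid=d["df_resid"],
            rmse_train=d["rmse_train"],
            n_train=d["n_train"],
            response_transform=d["response_transform"],
            rmse_test=d["rmse_test"],
            n_test=d["n_test"],
            mask_temp_min=d["mask"]["temp_min_c"],
            mask_chl_max=d["mask"]["chl_max"],
        )


def fit_model(
    df: pd.DataFrame,
    target_col: str = schema.PHAGE_TOTAL,
    features=DEFAULT_FEATURES,
    response_transform: str = "log10",
) -> RegressionModel:
    """Ordinary least squares of the (log10) abundance on the feature design.

    Requires at least 8 usable samples and positive abundances for the log
    transform.  Rank-deficient designs raise an error naming the collinear
    column.
    """
    y_raw = df[target_col].to_numpy(dtype=float)
    ok = np.isfinite(y_raw)
    if response_transform == "log10":
        ok &= y_raw > 0
    data = df.loc[ok]
    if len(data) < 8:
        raise ValueError("need at least 8 usable samples")
    X = _design(data, features)
    names = ["intercept"] + [_feature_name(f) for f in features]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        for j in range(X.shape[1]):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(f"rank-deficient design: column {names[j]!r} is collinear")
        raise ValueError("rank-deficient design")
    y = np.log10(data[target_col].to_numpy(dtype=float)) if response_transform == "log10" \
        else data[target_col].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    return RegressionModel(
        target=target_col,
        features=tuple(features),
        coefficients=np.asarray(res.params),
        cov_params=np.asarray(res.cov_params()),
        scale=float(res.scale),
        df_resid=float(res.df_resid),
        rmse_train=rmse(res.fittedvalues, y),
        n_train=len(data),
        response_transform=response_transform,
    )


#: the candidate predictor sets screened by the train/test comparison
CANDIDATE_SETS: dict[str, tuple] = {
    "T+Chl+TxChl": (schema.TEMP, schema.CHL, (schema.TEMP, schema.CHL)),
    "T+Chl": (schema.TEMP, schema.CHL),
    "T": (schema.TEMP,),
    "Chl": (schema.CHL,),
    "T+logChl+TxlogChl": (schema.TEMP, "log_chl", (schema.TEMP, "log_chl")),
    "T+logPro+TxlogPro": (schema.TEMP, "log_pro", (schema.TEMP, "log_pro")),
    "T+logSyn+TxlogSyn": (schema.TEMP, "log_syn", (schema.TEMP, "log_syn")),
    "T+logPico+TxlogPico": (schema.TEMP, "log_pico", (schema.TEMP, "log_pico")),
    "T+ProSynRatio+TxRatio": (schema.TEMP, "pro_syn_ratio", (schema.TEMP, "pro_syn_ratio")),
}

DEPLOYMENT_CANDIDATE = "T+Chl+TxChl"


def _derived_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Add the transformed predictor columns used by the candidate sets."""
    out = df.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        if schema.CHL in out:
            out["log_chl"] = np.log10(out[schema.CHL])
        if schema.PRO in out:
            out["log_pro"] = np.log10(out[schema.PRO])
        if schema.SYN in out:
            out["log_syn"] = np.log10(out[schema.SYN])
        if schema.PRO in out and schema.SYN in out:
            out["log_pico"] = np.log10(out[schema.PRO] + out[schema.SYN])
            out["pro_syn_ratio"] = out[schema.PRO] / out[schema.SYN]
    return out


def train_test_evaluate(
    train: pd.DataFrame,
    test: pd.DataFrame,
    candidates: dict[str, tuple] | None = None,
    target_col: str = schema.PHAGE_TOTAL,
) -> pd.DataFrame:
    """Fit candidate predictor sets on the training split, rank by test RMSE.

    Returns a DataFrame (one row per candidate, sorted by ``rmse_test``) with
    a ``deployment_default`` flag on the chlorophyll-interaction model, which
    is used for prediction regardless of rank because gridded chlorophyll is
    widely available.  Candidates with missing columns are skipped with a
    warning.
    """
    candidates = dict(candidates) if candidates is not None else dict(CANDIDATE_SETS)
    tr = _derived_columns(train)
    te = _derived_columns(test)
    rows = []
    for name, feats in candidates.items():
        needed = {c for f in feats for c in (f if isinstance(f, tuple) else (f,))}
        missing = needed - set(tr.columns) | needed - set(te.columns)
        if missing:
            warnings.warn(f"candidate {name!r} skipped; missing columns {sorted(missing)}",
                          stacklevel=2)
            continue
        model = fit_model(tr, target_col=target_col, features=feats)
        y_te = np.log10(te[target_col].to_numpy(dtype=float))
        pred = model.predict_response(te)
        model.rmse_test = rmse(pred, y_te)
        model.n_test = len(te)
        rows.append({
            "candidate": name,
            "rmse_train": model.rmse_train,
            "rmse_test": model.rmse_test,
            "n_train": model.n_train,
            "n_test": model.n_test,
            "deployment_default": name == DEPLOYMENT_CANDIDATE,
        })
    if not rows:
        raise ValueError("no candidate could be evaluated")
    out = pd.DataFrame(rows).sort_values("rmse_test", ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def predict_with_interval(
    model: RegressionModel,
    temperature,
    chlorophyll,
    level: float = 0.95,
    kind: str = "prediction",
    apply_mask: bool = True,
):
    """Back-transformed point prediction with a 95% interval.

    ``kind="prediction"`` (default) is an interval for a new observation —
    the flavour required for observation-coverage statements; ``kind="mean"``
    is a confidence interval for the regression mean.  Intervals are computed
    on the log scale and back-transformed, hence asymmetric on the natural
    scale.  Points outside the validity mask return NaN with a mask flag.
    Returns (point, lo, hi, masked) arrays (scalars for scalar input).
    """
    from scipy.stats import t as t_dist

    scalar = np.isscalar(temperature) and np.isscalar(chlorophyll)
    T = np.atleast_1d(np.asarray(temperature, dtype=float))
    C = np.atleast_1d(np.asarray(chlorophyll, dtype=float))
    df = pd.DataFrame({schema.TEMP: T, schema.CHL: C})
    X = model.design(df)
    mean = X @ model.coefficients
    var_mean = np.einsum("ij,jk,ik->i", X, model.cov_params, X)
    if kind == "prediction":
        var = var_mean + model.scale
    elif kind == "mean":
        var = var_mean
    else:
        raise ValueError(f"unknown interval kind {kind!r}")
    q = t_dist.ppf(1 - (1 - level) / 2, model.df_resid)
    lo = mean - q * np.sqrt(var)
    hi = mean + q * np.sqrt(var)
    if model.response_transform == "log10":
        point_n, lo_n, hi_n = 10**mean, 10**lo, 10**hi
    else:
        point_n, lo_n, hi_n = mean, lo, hi
    masked = np.zeros(T.shape, dtype=bool)
    if apply_mask:
        masked = ~((T > model.mask_temp_min) & (C < model.mask_chl_max)
                   & np.isfinite(T) & np.isfinite(C))
        point_n = np.where(masked, np.nan, point_n)
        lo_n = np.where(masked, np.nan, lo_n)
        hi_n = np.where(masked, np.nan, hi_n)
    if scalar:
        return float(point_n[0]), float(lo_n[0]), float(hi_n[0]), bool(masked[0])
    return point_n, lo_n, hi_n, masked


@dataclass
class PredictionGrid:
    """Masked gridded prediction (and optional lineage-ratio raster)."""

    temperature: np.ndarray
    chlorophyll: np.ndarray
    predicted: dict[str, np.ndarray]
    valid: np.ndarray
    ratio_t4_t7b: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)


def grid_predict(
    models: dict[str, RegressionModel],
    temperature_grid,
    chlorophyll_grid,
) -> PredictionGrid:
    """Apply fitted models over congruent temperature/chlorophyll rasters.

    Cells are predicted only where T > 5 °C and Chl < 0.4 mg m^-3; missing
    input cells propagate as masked.  When both "t4" and "t7b" models are
    supplied their abundance ratio is computed on jointly valid cells.
    """
    T = np.asarray(temperature_grid, dtype=float)
    C = np.asarray(chlorophyll_grid, dtype=float)
    if T.shape != C.shape:
        raise ValueError("temperature and chlorophyll rasters must have the same shape")
    any_model = next(iter(models.values()))
    valid = (T > any_model.mask_temp_min) & (C < any_model.mask_chl_max) \
        & np.isfinite(T) & np.isfinite(C)
    flat = pd.DataFrame({schema.TEMP: T.ravel(), schema.CHL: C.ravel()})
    predicted = {}
    for name, model in models.items():
        resp = model.predict_response(flat).reshape(T.shape)
        vals = 10**resp if model.response_transform == "log10" else resp
        predicted[name] = np.where(valid, vals, np.nan)
    ratio = None
    if "t4" in predicted and "t7b" in predicted:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = predicted["t4"] / predicted["t7b"]
        ratio = np.where(valid, ratio, np.nan)
    return PredictionGrid(T, C, predicted, valid, ratio)
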