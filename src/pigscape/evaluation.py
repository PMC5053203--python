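"""Goodness-of-fit metrics, variable-importance tables and partial dependence.

Model skill is summarized per response and per prediction scale by the
Pearson correlation COR between observed and predicted densities (a
measure of precision, 1 for a perfect linear agreement) and the root mean
square error

    RMSE = sqrt( (1/n) * sum_i (yhat_i - y_i)^2 ),

an absolute measure of accuracy in the density units.  Variable
importance combines the split-selection count of each predictor with a
permutation-based secondary measure, and partial-dependence profiles
trace the model's mean prediction as one predictor sweeps a quantile grid
while the others stay at their observed values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import forest as rf
from . import hurdle as hd
from .covariates import PREDICTOR_NAMES

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitMetrics:
    response_name: str
    scale: str  # 'zonal' or 'pixel'
    cor: float
    rmse: float
    n: int


@dataclass(frozen=True)
class DependenceProfile:
    variable: str
    grid: np.ndarray
    profile: np.ndarray
    response_name: str

    @property
    def direction(self) -> int:
        """Sign of (end - start) of the profile."""
        return int(np.sign(self.profile[-1] - self.profile[0]))


def rmse(observed, predicted) -> float:
    y = np.asarray(observed, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("observed and predicted differ in length")
    if y.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def pearson_cor(observed, predicted) -> float:
    """Sample Pearson correlation; NaN (with a warning) for constant input."""
    y = np.asarray(observed, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("observed and predicted differ in length")
    if y.size < 3:
        raise ValueError("correlation needs at least three pairs")
    if np.std(y) == 0 or np.std(yhat) == 0:
        log.warning("correlation undefined for a constant vector; returning NaN")
        return float("nan")
    return float(np.corrcoef(y, yhat)[0, 1])


def fit_metrics(response_name: str, scale: str, observed, predicted) -> FitMetrics:
    y = np.asarray(observed, dtype=float).ravel()
    return FitMetrics(
        response_name=response_name,
        scale=scale,
        cor=pearson_cor(observed, predicted),
        rmse=rmse(observed, predicted),
        n=y.size,
    )


def _model_predict(model, frame: pd.DataFrame) -> np.ndarray:
    if isinstance(model, hd.HurdleRFModel):
        return hd.predict_density(model, frame, scale="zonal").to_numpy()
    if isinstance(model, rf.ForestModel):
        return rf.predict(model, frame[list(model.feature_names)])
    raise TypeError(f"cannot predict with a {type(model).__name__}")


def partial_dependence(model, frame: pd.DataFrame, variable: str, n_grid: int = 20) -> DependenceProfile:
    """Average-prediction profile of one predictor over a quantile grid.

    For each grid value v the variable is forced to v in every row of the
    evaluation frame and the model's mean prediction recorded; the grid
    is the set of distinct quantiles of the observed values (robust to
    skewed covariates such as travel times).
    """
    if variable not in frame.columns:
        raise KeyError(f"unknown predictor variable '{variable}'")
    if n_grid < 2:
        raise ValueError("n_grid must be at least 2")
    values = frame[variable].to_numpy(dtype=float)
    grid = np.unique(np.quantile(values, np.linspace(0.0, 1.0, n_grid)))
    prof = np.empty(grid.size)
    work = frame.copy()
    for i, v in enumerate(grid):
        work[variable] = v
        prof[i] = float(np.mean(_model_predict(model, work)))
    response = getattr(model, "response_name", "response")
    return DependenceProfile(variable=variable, grid=grid, profile=prof, response_name=response)


def plot_dependence_profiles(profiles: list[DependenceProfile], path) -> None:
    """Save a panel of partial-dependence curves (one axis per variable,
    one line per response) as an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    variables = sorted({p.variable for p in profiles})
    fig, axes = plt.subplots(1, len(variables), figsize=(3 * len(variables), 3), squeeze=False)
    for ax, var in zip(axes[0], variables):
        for p in profiles:
            if p.variable == var:
                ax.plot(p.grid, p.profile, label=p.response_name)
        ax.set_xlabel(var)
    axes[0][0].set_ylabel("mean predicted density")
    axes[0][-1].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def across_response_median(table: pd.DataFrame) -> pd.Series:
    """Median of each importance column across responses (table rows)."""
    return table.median(axis=0)


def importance_table(
    models: dict[str, hd.HurdleRFModel],
    frame: pd.DataFrame | None = None,
    metrics: dict[str, dict[str, FitMetrics]] | None = None,
) -> pd.DataFrame:
    """Per-response variable importance of the quantitative (abundance)
    forests, one row per response, with a median row across responses.

    Columns: selection percentage per predictor, permutation importance
    per predictor (when the zonal frame is supplied), and the per-response
    COR/RMSE at both prediction scales (when metrics are supplied).
    """
    from .covariates import RESPONSE_NAMES

    missing = [r for r in RESPONSE_NAMES if r not in models]
    if missing:
        raise ValueError(f"missing fitted response(s): {missing}")
    rows = {}
    for resp in RESPONSE_NAMES:
        model = models[resp]
        ab = model.abundance_model
        if frame is not None:
            pos = frame[frame[resp] > 0]
            imp = rf.selection_importance(ab, pos[list(PREDICTOR_NAMES)], np.log10(pos[resp] + 1.0))
        else:
            imp = rf.selection_importance(ab)
        row = {f"sel_pct_{v}": imp.loc[v, "selection_pct"] for v in PREDICTOR_NAMES}
        if "permutation_importance" in imp.columns:
            row.update({f"perm_{v}": imp.loc[v, "permutation_importance"] for v in PREDICTOR_NAMES})
        if metrics is not None and resp in metrics:
            for scale, m in metrics[resp].items():
                row[f"cor_{scale}"] = m.cor
                row[f"rmse_{scale}"] = m.rmse
        rows[resp] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.loc["median"] = table.median(axis=0)
    return table
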