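"""Weight-based global sensitivity analysis and goodness-of-fit metrics.

Yoon's interpretation method reads the signed relative importance of each
network input directly off the trained weights: with ``w_ik`` the weight
from input ``i`` to hidden neuron ``k`` and ``w_k`` the weight from hidden
neuron ``k`` to the output,

    RI_i = 100 * sum_k(w_ik * w_k) / sum_i |sum_k(w_ik * w_k)|,

so absolute importances sum to 100% per output and the sign carries the
direction of the effect.  Biases are excluded; the importance is computed
on the normalized scale the network was trained on.

The goodness-of-fit suite compares observed and predicted vectors with the
standard drying-literature metrics: reduced chi-square, RMSE, MBE, MPE,
SSE, AARD and r2, plus residual moments.  As conventionally printed in this
literature MPE and AARD are the same absolute-relative-deviation formula;
both are provided verbatim rather than silently replacing MPE with its
signed textbook variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ann import MLPModel, TrainedResponse

__all__ = ["FitReport", "yoon_ri", "relative_importance_matrix", "gof_report"]


def yoon_ri(model: MLPModel) -> pd.Series:
    """Signed relative importance (%) of each input of a trained network.

    Invariant by construction: the absolute importances sum to 100.  Raises
    if every input-to-output weight product cancels (e.g. an all-zero
    network), in which case the measure is undefined.
    """
    inner = model.W1.T @ model.w2          # sum_k w_ik * w_k, one per input
    denom = np.abs(inner).sum()
    if denom == 0:
        raise ValueError("all connection-weight products are zero; relative "
                         "importance undefined")
    ri = 100.0 * inner / denom
    return pd.Series(ri, index=list(model.input_names), name=model.response or "RI")


def relative_importance_matrix(
        results: Sequence[TrainedResponse | MLPModel]) -> pd.DataFrame:
    """Stack per-response importances into an inputs x outputs matrix."""
    columns = {}
    for item in results:
        model = item.model if isinstance(item, TrainedResponse) else item
        series = yoon_ri(model)
        columns[series.name] = series
    return pd.DataFrame(columns)


@dataclass(frozen=True)
class FitReport:
    """Fit metrics and residual moments for one observed/predicted pair.

    ``chi2`` uses ``n_params`` in its denominator (the trained network's
    free-parameter count, when scoring a network).  ``resid_skew`` and
    ``resid_kurt`` are moment estimators without small-sample bias
    correction; kurtosis is excess (normal -> 0).  By construction
    ``rmse**2 * n == sse`` and ``chi2 * (n - n_params) == sse``.
    """

    n: int
    n_params: int
    chi2: float
    rmse: float
    mbe: float
    mpe: float
    sse: float
    aard: float
    r2: float
    resid_mean: float
    resid_sd: float
    resid_var: float
    resid_skew: float
    resid_kurt: float

    def to_series(self) -> pd.Series:
        return pd.Series({
            "chi2": self.chi2, "RMSE": self.rmse, "MBE": self.mbe,
            "MPE": self.mpe, "SSE": self.sse, "AARD": self.aard, "r2": self.r2,
            "skew": self.resid_skew, "kurt": self.resid_kurt,
            "mean": self.resid_mean, "stdev": self.resid_sd,
            "var": self.resid_var,
        })


def gof_report(observed: Sequence[float], predicted: Sequence[float],
               n_params: int = 0, bias_correction: bool = False) -> FitReport:
    """Goodness-of-fit metrics between observed and predicted vectors.

    ``n_params`` enters only the reduced chi-square denominator ``N - n``.
    MPE and AARD divide by the predicted values; if any prediction is zero
    they are reported as NaN with a warning.
    """
    x = np.asarray(observed, dtype=float)
    xhat = np.asarray(predicted, dtype=float)
    if x.shape != xhat.shape or x.ndim != 1:
        raise ValueError("observed and predicted must be 1-D vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 records")
    if n <= n_params:
        raise ValueError(f"need N > n_params for reduced chi-square (N={n}, n={n_params})")

    resid = x - xhat
    sse = float(resid @ resid)
    rmse = float(np.sqrt(sse / n))
    mbe = float(resid.mean())
    chi2 = sse / (n - n_params)
    if np.any(xhat == 0):
        warnings.warn("zero predicted value: MPE and AARD undefined, reported as NaN",
                      stacklevel=2)
        mpe = aard = np.nan
    else:
        aard = float(100.0 / n * np.sum(np.abs(resid / xhat)))
        mpe = aard  # identical formulas, kept verbatim (see module docstring)
    sst = float(np.sum((x - x.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan

    sd = float(np.std(resid, ddof=1))
    return FitReport(
        n=n, n_params=n_params, chi2=chi2, rmse=rmse, mbe=mbe, mpe=mpe,
        sse=sse, aard=aard, r2=r2,
        resid_mean=float(resid.mean()), resid_sd=sd, resid_var=sd * sd,
        resid_skew=float(stats.skew(resid, bias=not bias_correction)),
        resid_kurt=float(stats.kurtosis(resid, fisher=True, bias=not bias_correction)),
    )


def fit_report_table(results: Sequence[TrainedResponse], table,
                     n_params: int | None = None) -> pd.DataFrame:
    """Fit-report rows (one per trained response) over the full table.

    ``n_params`` defaults to each network's free-parameter count, capped at
    ``N - 1`` with a warning -- a network wider than the table has more
    parameters than records and the reduced chi-square denominator would
    otherwise be non-positive.
    """
    rows = {}
    X = table.factors().to_numpy(dtype=float)
    y_all = table.responses()
    for res in results:
        predicted = res.model.predict(X)
        n = len(predicted)
        k = n_params if n_params is not None else res.model.n_parameters
        if k >= n:
            warnings.warn(
                f"{res.response}: {k} free parameters >= {n} records; "
                f"capping the reduced chi-square denominator at 1", stacklevel=2)
            k = n - 1
        report = gof_report(y_all[res.response].to_numpy(dtype=float), predicted,
                            n_params=k)
        rows[res.response] = report.to_series()
    return pd.DataFrame(rows).T
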