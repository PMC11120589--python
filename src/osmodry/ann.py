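"""Multilayer-perceptron response models trained by BFGS.

Each response is modeled by a 3-H-1 feedforward network on min-max
normalized factors and response,

    y = f_out( w2 . f_hid(W1 x + b1) + b2 ),

with activations drawn from {identity, logistic, tanh, exponential}.  The
sum-of-squares training error is minimized with the quasi-Newton BFGS
algorithm (analytic gradients) from many random restarts; the hidden-layer
width ``H`` is searched over a configurable range and the restart/topology
combination with the highest test-split coefficient of determination is
kept.  The table is split 60/20/20 into training / test / validation rows
by a seeded shuffle; the validation split is reported but never used for
selection.  Normalization bounds are taken from the training split only.

On this problem scale (15 runs, a handful of parameters) training a full
topology sweep takes seconds; the restart count is the only accuracy knob
that matters, because BFGS converges to a local minimum of a non-convex
surface.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .dataset import FACTORS, DesignTable

__all__ = [
    "ACTIVATIONS",
    "MLPModel",
    "TrainConfig",
    "TrainedResponse",
    "minmax_normalize",
    "minmax_denormalize",
    "split_sizes",
    "mlp_forward",
    "train_response",
    "topology_search",
]

logger = logging.getLogger(__name__)

_CLIP = 40.0  # exp/logistic argument clip; keeps the loss finite

# activation -> (f, f' expressed through (z, f(z)))
ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "identity": (lambda z: z, lambda z, a: np.ones_like(z)),
    "logistic": (lambda z: expit(z), lambda z, a: a * (1.0 - a)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a * a),
    "exponential": (lambda z: np.exp(np.clip(z, -_CLIP, _CLIP)), lambda z, a: a),
}


# ---------------------------------------------------------------------------
# normalization

def minmax_normalize(values: np.ndarray, bounds: tuple[np.ndarray, np.ndarray],
                     warn_outside: bool = True) -> np.ndarray:
    """Map columns to [0, 1] via ``(x - min) / (max - min)``.

    ``bounds`` are (min, max) per column, estimated from training data only;
    values outside the bounds map outside [0, 1] and trigger a warning.
    """
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    if np.any(hi <= lo):
        col = int(np.argmax(hi <= lo)) if lo.ndim else 0
        raise ValueError(f"degenerate bounds (max <= min) in column {col}")
    x = np.asarray(values, dtype=float)
    out = (x - lo) / (hi - lo)
    if warn_outside and ((out < 0).any() or (out > 1).any()):
        warnings.warn("values outside the normalization bounds map outside [0, 1]",
                      stacklevel=2)
    return out


def minmax_denormalize(values: np.ndarray,
                       bounds: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Exact inverse of :func:`minmax_normalize` on the same bounds."""
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    return np.asarray(values, dtype=float) * (hi - lo) + lo


# ---------------------------------------------------------------------------
# model

@dataclass
class MLPModel:
    """Weights, activations and normalization bounds of one trained network."""

    W1: np.ndarray          # (H, n_inputs)
    b1: np.ndarray          # (H,)
    w2: np.ndarray          # (H,)
    b2: float
    f_hidden: str
    f_output: str
    x_bounds: tuple[np.ndarray, np.ndarray]   # per-factor (min, max)
    y_bounds: tuple[float, float]             # response (min, max)
    input_names: tuple[str, ...] = tuple(FACTORS)
    response: str = ""

    def __post_init__(self) -> None:
        self.W1 = np.atleast_2d(np.asarray(self.W1, dtype=float))
        self.b1 = np.asarray(self.b1, dtype=float).ravel()
        self.w2 = np.asarray(self.w2, dtype=float).ravel()
        if self.W1.shape[0] < 1:
            raise ValueError("need at least one hidden neuron")
        if not (self.W1.shape[0] == self.b1.size == self.w2.size):
            raise ValueError("inconsistent hidden-layer dimensions")
        for name in (self.f_hidden, self.f_output):
            if name not in ACTIVATIONS:
                raise ValueError(f"unknown activation {name!r}")

    @property
    def hidden_units(self) -> int:
        return self.W1.shape[0]

    @property
    def n_parameters(self) -> int:
        """Free parameters: H*n_in + H + H + 1."""
        return self.W1.size + self.b1.size + self.w2.size + 1

    @property
    def name(self) -> str:
        return f"MLP {self.W1.shape[1]}-{self.hidden_units}-1"

    def forward_normalized(self, Xn: np.ndarray) -> np.ndarray:
        """Forward pass on the normalized scale; ``Xn`` is (n, n_inputs)."""
        Xn = np.atleast_2d(np.asarray(Xn, dtype=float))
        if Xn.shape[1] != self.W1.shape[1]:
            raise ValueError(
                f"expected {self.W1.shape[1]} inputs, got {Xn.shape[1]}")
        f_hid = ACTIVATIONS[self.f_hidden][0]
        f_out = ACTIVATIONS[self.f_output][0]
        hidden = f_hid(Xn @ self.W1.T + self.b1)
        return f_out(hidden @ self.w2 + self.b2)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict on physical units: normalize, forward, denormalize."""
        Xn = minmax_normalize(np.atleast_2d(np.asarray(X, dtype=float)), self.x_bounds)
        yn = self.forward_normalized(Xn)
        lo, hi = self.y_bounds
        return yn * (hi - lo) + lo

    # -- JSON round trip -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": float(self.b2),
            "f_hidden": self.f_hidden, "f_output": self.f_output,
            "x_min": np.asarray(self.x_bounds[0]).tolist(),
            "x_max": np.asarray(self.x_bounds[1]).tolist(),
            "y_min": float(self.y_bounds[0]), "y_max": float(self.y_bounds[1]),
            "input_names": list(self.input_names), "response": self.response,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MLPModel":
        return cls(
            W1=np.array(payload["W1"]), b1=np.array(payload["b1"]),
            w2=np.array(payload["w2"]), b2=payload["b2"],
            f_hidden=payload["f_hidden"], f_output=payload["f_output"],
            x_bounds=(np.array(payload["x_min"]), np.array(payload["x_max"])),
            y_bounds=(payload["y_min"], payload["y_max"]),
            input_names=tuple(payload["input_names"]), response=payload["response"],
        )


def mlp_forward(model: MLPModel, x: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`MLPModel.forward_normalized`."""
    return model.forward_normalized(x)


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainConfig:
    """Topology-search and optimizer settings.

    ``hidden_range`` defaults to 3..10 hidden neurons; ``split`` to a
    60/20/20 train/test/validation division; ``restarts`` random
    reinitializations are run per topology and the best test-split r2 wins.
    ``max_iter`` caps BFGS iterations (the batch analogue of an epoch limit).
    """

    hidden_range: Sequence[int] = tuple(range(3, 11))
    restarts: int = 50
    max_iter: int = 200
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    f_hidden: str = "tanh"
    f_output: str = "identity"
    init_scale: float = 0.5
    min_train_rows: int = 5

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if not self.hidden_range or min(self.hidden_range) < 1:
            raise ValueError("hidden_range must contain integers >= 1")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split}")
        for name in (self.f_hidden, self.f_output):
            if name not in ACTIVATIONS:
                raise ValueError(f"unknown activation {name!r}")


@dataclass
class TrainedResponse:
    """Best network found for one response, with per-split diagnostics."""

    response: str
    model: MLPModel
    r2: dict[str, float]       # train/test/valid coefficient of determination
    sos: dict[str, float]      # sum-of-squares error per split, physical units
    hidden_units: int
    n_iter: int
    split_indices: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def name(self) -> str:
        return self.model.name


def split_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Rows per split: round the first two fractions, remainder validates.

    Uses Python banker's rounding; e.g. 15 rows at (0.6, 0.2, 0.2) give
    9/3/3 and at (0.8, 0.1, 0.1) give 12/2/1.
    """
    n_train = round(fractions[0] * n)
    n_test = round(fractions[1] * n)
    n_valid = n - n_train - n_test
    if min(n_train, n_test, n_valid) < 0:
        raise ValueError("split fractions produce a negative split size")
    return n_train, n_test, n_valid


def _pack(W1, b1, w2, b2):
    return np.concatenate([W1.ravel(), b1, w2, [b2]])


def _unpack(theta: np.ndarray, H: int, n_in: int):
    W1 = theta[: H * n_in].reshape(H, n_in)
    b1 = theta[H * n_in: H * n_in + H]
    w2 = theta[H * n_in + H: H * n_in + 2 * H]
    b2 = theta[-1]
    return W1, b1, w2, b2


def _sos_loss_grad(theta, Xn, yn, H, f_hidden, f_output):
    """Sum-of-squares loss and its analytic gradient (backpropagation)."""
    n_in = Xn.shape[1]
    W1, b1, w2, b2 = _unpack(theta, H, n_in)
    f_h, df_h = ACTIVATIONS[f_hidden]
    f_o, df_o = ACTIVATIONS[f_output]
    Z1 = Xn @ W1.T + b1
    A1 = f_h(Z1)
    z2 = A1 @ w2 + b2
    yhat = f_o(z2)
    resid = yhat - yn
    loss = float(resid @ resid)
    d2 = 2.0 * resid * df_o(z2, yhat)            # (n,)
    g_b2 = d2.sum()
    g_w2 = A1.T @ d2                             # (H,)
    d1 = (d2[:, None] * w2[None, :]) * df_h(Z1, A1)  # (n, H)
    g_b1 = d1.sum(axis=0)
    g_W1 = d1.T @ Xn                             # (H, n_in)
    return loss, _pack(g_W1, g_b1, g_w2, g_b2)


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return np.nan
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def train_response(table: DesignTable, response: str,
                   cfg: TrainConfig | None = None) -> TrainedResponse:
    """Fit the best MLP for one response by restart-and-topology search."""
    cfg = cfg or TrainConfig()
    if response not in table.response_columns:
        raise KeyError(f"unknown response column {response!r}")
    X = table.factors().to_numpy(dtype=float)
    y = table.responses()[response].to_numpy(dtype=float)
    run_ids = np.asarray(table.run_ids)
    n = len(y)

    rng = np.random.default_rng(cfg.seed)
    n_train, n_test, n_valid = split_sizes(n, cfg.split)
    if n_train < cfg.min_train_rows:
        raise ValueError(f"need at least {cfg.min_train_rows} training rows, got {n_train}")
    perm = rng.permutation(n)
    idx = {
        "train": np.sort(perm[:n_train]),
        "test": np.sort(perm[n_train:n_train + n_test]),
        "valid": np.sort(perm[n_train + n_test:]),
    }

    x_bounds = (X[idx["train"]].min(axis=0), X[idx["train"]].max(axis=0))
    y_bounds = (float(y[idx["train"]].min()), float(y[idx["train"]].max()))
    if y_bounds[1] <= y_bounds[0]:
        raise ValueError(f"response {response!r} is constant on the training split")
    with warnings.catch_warnings():
        # test/validation rows may legitimately fall outside the training bounds
        warnings.simplefilter("ignore")
        Xn = minmax_normalize(X, x_bounds)
        yn = minmax_normalize(y, (np.array(y_bounds[0]), np.array(y_bounds[1])))

    n_in = X.shape[1]
    best: tuple[float, MLPModel, int] | None = None
    for H in cfg.hidden_range:
        n_par = H * n_in + 2 * H + 1
        for restart in range(cfg.restarts):
            theta0 = rng.normal(0.0, cfg.init_scale, size=n_par)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # BFGS line-search chatter
                    result = minimize(
                        _sos_loss_grad, theta0, jac=True, method="BFGS",
                        args=(Xn[idx["train"]], yn[idx["train"]], H,
                              cfg.f_hidden, cfg.f_output),
                        options={"maxiter": cfg.max_iter, "gtol": 1e-10},
                    )
            except (FloatingPointError, OverflowError):  # pragma: no cover
                logger.info("discarding diverged restart %d (H=%d)", restart, H)
                continue
            if not np.all(np.isfinite(result.x)) or not np.isfinite(result.fun):
                logger.info("discarding non-finite restart %d (H=%d)", restart, H)
                continue
            W1, b1, w2, b2 = _unpack(result.x, H, n_in)
            model = MLPModel(W1=W1, b1=b1, w2=w2, b2=float(b2),
                             f_hidden=cfg.f_hidden, f_output=cfg.f_output,
                             x_bounds=x_bounds, y_bounds=y_bounds,
                             response=response)
            yhat_test = model.forward_normalized(Xn[idx["test"]])
            r2_test = _r2(yn[idx["test"]], yhat_test)
            score = -np.inf if np.isnan(r2_test) else r2_test
            if best is None or score > best[0]:
                best = (score, model, int(result.nit))
    if best is None:
        raise RuntimeError(f"all restarts diverged for response {response!r}")

    _, model, n_iter = best
    lo, hi = y_bounds
    r2, sos = {}, {}
    for split_name, rows in idx.items():
        yhat = model.forward_normalized(Xn[rows]) * (hi - lo) + lo
        r2[split_name] = _r2(y[rows], yhat)
        sos[split_name] = float(np.sum((y[rows] - yhat) ** 2))
    return TrainedResponse(
        response=response, model=model, r2=r2, sos=sos,
        hidden_units=model.hidden_units, n_iter=n_iter,
        split_indices={k: run_ids[v] for k, v in idx.items()},
    )


def topology_search(table: DesignTable, responses: Sequence[str] | None = None,
                    cfg: TrainConfig | None = None) -> list[TrainedResponse]:
    """Train one network per response column; empty input gives an empty list."""
    cfg = cfg or TrainConfig()
    if responses is None:
        responses = list(table.response_columns)
    return [train_response(table, name, cfg) for name in responses]


def summary_table(results: Sequence[TrainedResponse]) -> pd.DataFrame:
    """Per-response performance summary (network name, r2 and SOS per split)."""
    rows = []
    for res in results:
        rows.append({
            "response": res.response,
            "net": res.name,
            "r2_train": res.r2["train"], "r2_test": res.r2["test"],
            "r2_valid": res.r2["valid"],
            "sos_train": res.sos["train"], "sos_test": res.sos["test"],
            "sos_valid": res.sos["valid"],
            "bfgs_iterations": res.n_iter,
            "hidden_activation": res.model.f_hidden,
            "output_activation": res.model.f_output,
        })
    return pd.DataFrame(rows)
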