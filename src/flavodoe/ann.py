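"""Feed-forward neural-network surrogate of the extraction response surface.

A single-hidden-layer perceptron (3 inputs, tanh hidden units, 1 linear
output) is trained on min-max normalized data by damped least squares
(Levenberg-Marquardt): each epoch solves (J'J + mu*I) d = J'r for the full
21-parameter weight vector, multiplying the damping mu by 10 after a
rejected step and dividing by 10 after an accepted one. Training stops on
the normalized-MSE goal, the epoch cap, six consecutive validation-set
failures (returning the best-validation weights), or damping overflow.

The reported "learning rate 0.01" of the reference workflow is interpreted
as the initial LM damping, since LM has no learning rate; a plain
gradient-descent fallback is retained behind ``TrainConfig.optimizer``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MLPSurrogate",
    "TrainConfig",
    "TrainHistory",
    "FitMetrics",
    "split_data",
    "train",
    "evaluate",
    "select_hidden_size",
]


@dataclass
class _MinMax:
    """Per-column min-max map onto [-1, 1]."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_MinMax":
        X = np.atleast_2d(X)
        lo, hi = X.min(axis=0), X.max(axis=0)
        if np.any(hi <= lo):
            raise ValueError("cannot normalize a constant column")
        return cls(lo=lo, hi=hi)

    def normalize(self, X):
        return 2.0 * (X - self.lo) / (self.hi - self.lo) - 1.0

    def denormalize(self, Z):
        return (Z + 1.0) * (self.hi - self.lo) / 2.0 + self.lo


@dataclass
class MLPSurrogate:
    """Trained k-h-1 network with its normalization state.

    ``W1`` (h x k), ``b1`` (h): hidden layer; ``w2`` (h), ``b2``: linear
    output. Predictions accept and return original-scale values.
    """

    W1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    x_norm: _MinMax
    y_norm: _MinMax

    @property
    def hidden_size(self) -> int:
        return self.W1.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    def _forward_normalized(self, Zx: np.ndarray) -> np.ndarray:
        return np.tanh(Zx @ self.W1.T + self.b1) @ self.w2 + self.b2

    def predict(self, X) -> np.ndarray | float:
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        Zx = self.x_norm.normalize(np.atleast_2d(X))
        zy = self._forward_normalized(Zx)
        y = self.y_norm.denormalize(zy[:, None])[:, 0]
        return float(y[0]) if single else y

    def to_dict(self) -> dict:
        return {
            "topology": [self.n_inputs, self.hidden_size, 1],
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "x_lo": self.x_norm.lo.tolist(),
            "x_hi": self.x_norm.hi.tolist(),
            "y_lo": self.y_norm.lo.tolist(),
            "y_hi": self.y_norm.hi.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPSurrogate":
        return cls(
            W1=np.array(d["W1"], dtype=float),
            b1=np.array(d["b1"], dtype=float),
            w2=np.array(d["w2"], dtype=float),
            b2=float(d["b2"]),
            x_norm=_MinMax(np.array(d["x_lo"], float), np.array(d["x_hi"], float)),
            y_norm=_MinMax(np.array(d["y_lo"], float), np.array(d["y_hi"], float)),
        )


@dataclass
class TrainConfig:
    max_epochs: int = 1000
    initial_damping: float = 0.01  # "learning rate" of the reference settings
    goal: float = 1e-6  # normalized training MSE target
    max_validation_failures: int = 6
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    optimizer: str = "lm"  # "lm" | "gd"
    gd_learn_rate: float = 0.01
    damping_overflow: float = 1e10

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.fractions) <= 0 or self.max_epochs <= 0 or self.goal <= 0:
            raise ValueError("fractions, max_epochs and goal must be positive")


@dataclass
class TrainHistory:
    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    test_mse: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stop_reason: str = ""
    final_gradient_norm: float = np.nan
    final_damping: float = np.nan

    @property
    def n_epochs(self) -> int:
        return len(self.train_mse)


@dataclass
class FitMetrics:
    mse: float
    mae: float
    rmse: float
    r_squared: float
    pearson_r: float
    scale: str
    n: int


def split_data(n: int, fractions=(0.70, 0.15, 0.15), seed: int = 0):
    """Random disjoint train/validation/test index sets covering range(n).

    Sizes are the rounded train and validation fractions of ``n``; the
    remainder goes to the test set (so 51 points split 36/8/7).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"n={n} too small for a {fractions} split")
    perm = np.random.default_rng(seed).permutation(n)
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def _init_params(k: int, h: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.uniform(-0.5, 0.5, size=h * k + h + h + 1)


def _unpack(theta: np.ndarray, k: int, h: int):
    W1 = theta[: h * k].reshape(h, k)
    b1 = theta[h * k : h * k + h]
    w2 = theta[h * k + h : h * k + 2 * h]
    b2 = theta[-1]
    return W1, b1, w2, b2


def _forward_residuals(theta, Zx, zy, k, h):
    W1, b1, w2, b2 = _unpack(theta, k, h)
    T = np.tanh(Zx @ W1.T + b1)  # n x h
    pred = T @ w2 + b2
    return pred - zy, T


def _jacobian(theta, Zx, T, k, h):
    """d(residual_i)/d(theta) for the k-h-1 tanh network; n x (hk+2h+1)."""
    _, _, w2, _ = _unpack(theta, k, h)
    n = Zx.shape[0]
    dtanh = (1.0 - T**2) * w2  # n x h
    J = np.empty((n, h * k + 2 * h + 1))
    J[:, : h * k] = (dtanh[:, :, None] * Zx[:, None, :]).reshape(n, h * k)
    J[:, h * k : h * k + h] = dtanh
    J[:, h * k + h : h * k + 2 * h] = T
    J[:, -1] = 1.0
    return J


def train(X, y, hidden: int = 4, config: TrainConfig | None = None):
    """Train the surrogate; returns (MLPSurrogate, TrainHistory).

    Deterministic under ``config.seed`` (which controls both the 70/15/15
    split and the uniform [-0.5, 0.5] weight initialization).
    """
    config = config or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y lengths differ")
    h = int(hidden)
    n_params = h * k + 2 * h + 1
    idx_tr, idx_val, idx_te = split_data(n, config.fractions, config.seed)
    if len(idx_tr) < n_params:
        import warnings

        warnings.warn(
            f"{len(idx_tr)} training rows for {n_params} network parameters; "
            "the surrogate may interpolate noise",
            stacklevel=2,
        )

    x_norm = _MinMax.fit(X)
    y_norm = _MinMax.fit(y[:, None])
    Zx = x_norm.normalize(X)
    zy = y_norm.normalize(y[:, None])[:, 0]

    theta = _init_params(k, h, config.seed)
    mu = config.initial_damping
    hist = TrainHistory()

    def mse_on(idx, th):
        r, _ = _forward_residuals(th, Zx[idx], zy[idx], k, h)
        return float(np.mean(r**2))

    best_theta = theta.copy()
    best_val = np.inf
    val_fails = 0
    stop = "max_epochs"
    grad_norm = np.nan

    for epoch in range(config.max_epochs):
        r, T = _forward_residuals(theta, Zx[idx_tr], zy[idx_tr], k, h)
        sse = float(r @ r)
        if not np.isfinite(sse):
            raise FloatingPointError("non-finite training loss; aborting")
        J = _jacobian(theta, Zx[idx_tr], T, k, h)
        g = J.T @ r
        grad_norm = float(np.linalg.norm(g))

        if config.optimizer == "gd":
            theta = theta - config.gd_learn_rate * g / len(idx_tr)
        else:
            JtJ = J.T @ J
            accepted = False
            while mu <= config.damping_overflow:
                try:
                    step = np.linalg.solve(JtJ + mu * np.eye(n_params), g)
                except np.linalg.LinAlgError:
                    mu *= 10.0
                    continue
                trial = theta - step
                r_new, _ = _forward_residuals(trial, Zx[idx_tr], zy[idx_tr], k, h)
                if float(r_new @ r_new) < sse:
                    theta = trial
                    mu = max(mu / 10.0, 1e-12)
                    accepted = True
                    break
                mu *= 10.0
            if not accepted:
                stop = "damping_overflow"
                hist.train_mse.append(mse_on(idx_tr, theta))
                hist.val_mse.append(mse_on(idx_val, theta))
                hist.test_mse.append(mse_on(idx_te, theta))
                break

        tr_mse = mse_on(idx_tr, theta)
        va_mse = mse_on(idx_val, theta)
        hist.train_mse.append(tr_mse)
        hist.val_mse.append(va_mse)
        hist.test_mse.append(mse_on(idx_te, theta))

        if va_mse < best_val - 1e-15:
            best_val = va_mse
            best_theta = theta.copy()
            hist.best_epoch = epoch
            val_fails = 0
        else:
            val_fails += 1
            if val_fails >= config.max_validation_failures:
                stop = "validation_failures"
                break
        if tr_mse <= config.goal:
            stop = "goal"
            break

    hist.stop_reason = stop
    hist.final_gradient_norm = grad_norm
    hist.final_damping = mu
    # early-stopping contract: hand back the best-validation weights
    W1, b1, w2, b2 = _unpack(best_theta, k, h)
    model = MLPSurrogate(W1=W1, b1=b1, w2=w2, b2=float(b2), x_norm=x_norm, y_norm=y_norm)
    return model, hist


def evaluate(model: MLPSurrogate, X, y, scale: str = "original") -> FitMetrics:
    """MSE/MAE/RMSE/R2/Pearson-R of the surrogate on (X, y).

    ``scale`` selects whether metrics are computed in original units
    (mg/g) or on the network's normalized [-1, 1] output scale.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y lengths differ")
    yhat = np.atleast_1d(model.predict(X))
    if scale == "normalized":
        y = model.y_norm.normalize(y[:, None])[:, 0]
        yhat = model.y_norm.normalize(yhat[:, None])[:, 0]
    elif scale != "original":
        raise ValueError("scale must be 'original' or 'normalized'")
    err = yhat - y
    mse = float(np.mean(err**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        r2 = r = np.nan
    else:
        r2 = 1.0 - float(np.sum(err**2)) / sst
        sd_hat = np.std(yhat)
        r = float(np.corrcoef(yhat, y)[0, 1]) if sd_hat > 0 else np.nan
    return FitMetrics(
        mse=mse,
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(mse)),
        r_squared=r2,
        pearson_r=r,
        scale=scale,
        n=len(y),
    )


def select_hidden_size(X, y, candidate_sizes, config: TrainConfig | None = None):
    """Train one surrogate per hidden size; pick the lowest validation MSE.

    Validation losses within 1e-9 of the minimum count as ties and resolve
    to the smaller network. Returns (chosen_size, per-size list of dicts).
    """
    candidate_sizes = list(candidate_sizes)
    if not candidate_sizes:
        raise ValueError("candidate_sizes must be non-empty")
    config = config or TrainConfig()
    rows = []
    for hsize in candidate_sizes:
        mdl, hist = train(X, y, hidden=hsize, config=config)
        rows.append(
            {
                "hidden": hsize,
                "val_mse": min(hist.val_mse) if hist.val_mse else np.inf,
                "train_mse": min(hist.train_mse) if hist.train_mse else np.inf,
                "epochs": hist.n_epochs,
                "stop_reason": hist.stop_reason,
            }
        )
    best_loss = min(r["val_mse"] for r in rows)
    tied = [r for r in rows if r["val_mse"] <= best_loss + 1e-9]
    best = min(tied, key=lambda r: r["hidden"])
    return best["hidden"], rows
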