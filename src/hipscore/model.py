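"""Suitability model: LSTM regression of image quality on covariates.

Predicts an infant's final weighted image-quality score from sex, age,
height and weight, and turns the prediction into a suitability decision
(predicted score > 3 means the infant is a good candidate for ultrasound
DDH examination).

The regressor is a minimal LSTM: the four-feature vector is presented as a
length-one sequence to a single LSTM cell layer, whose hidden state feeds
one linear output unit.  With initial states ``h0 = c0 = 0`` the cell
computes

    i = sigmoid(x Wi + bi)        input gate
    g = tanh(x Wg + bg)           candidate
    o = sigmoid(x Wo + bo)        output gate
    c = i * g                     (the forget gate acts on c0 = 0)
    h = o * tanh(c)
    y = h Wy + by

Training minimises mean-squared error with the Adam optimiser, full batch
by default, with hand-derived gradients.  Everything is deterministic given
the seed.

Continuous covariates are z-scored with parameters estimated on the
training split only; sex is coded 0/1 (female = 1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import InfantRecord, substream
from .exceptions import (
    ConfigurationError,
    DivergenceError,
    UndefinedStatisticError,
    ValidationError,
)

#: Feature columns, in design-matrix order.
FEATURE_COLUMNS = ("sex_code", "age_z", "height_z", "weight_z")
_CONTINUOUS = ("age_months", "height_cm", "weight_kg")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture, optimisation and split settings."""

    hidden_units: int = 32
    epochs: int = 500
    learning_rate: float = 1e-2
    batch_size: int | None = None  # None = full batch
    train_size: int = 240
    test_size: int = 50
    seed: int = 0

    def validate(self, n: int | None = None) -> None:
        if self.hidden_units <= 0 or self.epochs <= 0 or self.learning_rate <= 0:
            raise ConfigurationError("hidden_units, epochs and learning_rate must be positive")
        if self.train_size <= 0 or self.test_size <= 0:
            raise ConfigurationError("train_size and test_size must be positive")
        if n is not None and self.train_size + self.test_size != n:
            raise ConfigurationError(
                f"train_size + test_size = {self.train_size + self.test_size} "
                f"but the cohort has {n} records"
            )


@dataclass(frozen=True)
class StandardizationParams:
    """Training-split means/SDs used to z-score the continuous covariates."""

    means: dict[str, float]
    sds: dict[str, float]


@dataclass(frozen=True)
class FitResult:
    """Held-out evaluation of the suitability model."""

    r_squared: float
    relative_errors: np.ndarray
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int


@dataclass(frozen=True)
class SuitabilityDecision:
    q_pred: float
    suitable: bool


def encode_features(
    records: pd.DataFrame, params: StandardizationParams | None = None
) -> tuple[np.ndarray, StandardizationParams]:
    """Design matrix (sex code, z-age, z-height, z-weight) and its parameters.

    With ``params=None`` the standardization parameters are estimated from
    ``records`` (use this on the training split); pass the returned params
    to encode validation/test records on the training scale.  Note the
    transform is not idempotent: re-applying stored parameters to already
    standardized values rescales them again.
    """
    cols = ["sex", *_CONTINUOUS]
    missing_cols = [c for c in cols if c not in records.columns]
    if missing_cols:
        raise ValidationError(f"records are missing columns {missing_cols}")
    for c in _CONTINUOUS:
        na = records[c].isna()
        if na.any():
            rid = records.loc[na, "id"].iloc[0] if "id" in records.columns else na.idxmax()
            raise ValidationError(f"record {rid!r}: missing {c}")
    bad_sex = ~records["sex"].isin(["male", "female"])
    if bad_sex.any():
        rid = records.loc[bad_sex, "id"].iloc[0] if "id" in records.columns else "?"
        raise ValidationError(f"record {rid!r}: sex must be 'male' or 'female'")

    if params is None:
        means = {c: float(records[c].mean()) for c in _CONTINUOUS}
        sds = {c: float(records[c].std(ddof=0)) or 1.0 for c in _CONTINUOUS}
        params = StandardizationParams(means=means, sds=sds)

    X = np.column_stack(
        [(records["sex"] == "female").to_numpy(float)]
        + [
            (records[c].to_numpy(float) - params.means[c]) / params.sds[c]
            for c in _CONTINUOUS
        ]
    )
    return X, params


def split_indices(n: int, config: ModelConfig) -> tuple[np.ndarray, np.ndarray]:
    """Single seeded random train/test split (default 240/50)."""
    config.validate(n)
    perm = substream(config.seed, "split").permutation(n)
    return perm[: config.train_size], perm[config.train_size :]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class LSTMRegressor:
    """One LSTM cell over a length-1 sequence, linear head, Adam training."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        self._params: dict[str, np.ndarray] | None = None
        self.loss_history: list[float] = []

    # -- parameters ------------------------------------------------------
    def _init_params(self, n_features: int) -> dict[str, np.ndarray]:
        H = self.config.hidden_units
        rng = substream(self.config.seed, "model")

        def glorot(fan_in, fan_out, shape):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, shape)

        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget-gate bias: conventional init (inert at T=1)
        return {
            "Wx": glorot(n_features, H, (n_features, 4 * H)),
            "Wh": glorot(H, H, (H, 4 * H)),  # recurrent weights; unused at T=1
            "b": b,
            "Wy": glorot(H, 1, (H, 1)),
            "by": np.zeros(1),
        }

    # -- forward/backward ------------------------------------------------
    def _forward(self, X: np.ndarray):
        p = self._params
        H = self.config.hidden_units
        z = X @ p["Wx"] + p["b"]
        i = _sigmoid(z[:, :H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c = i * g
        tc = np.tanh(c)
        h = o * tc
        yhat = (h @ p["Wy"] + p["by"]).ravel()
        return yhat, (X, i, g, o, tc, h)

    def _backward(self, yhat: np.ndarray, y: np.ndarray, cache) -> dict[str, np.ndarray]:
        X, i, g, o, tc, h = cache
        p = self._params
        H = self.config.hidden_units
        n = y.size
        dy = (2.0 / n) * (yhat - y)[:, None]
        grads = {
            "Wy": h.T @ dy,
            "by": dy.sum(axis=0),
            "Wh": np.zeros_like(p["Wh"]),
        }
        dh = dy @ p["Wy"].T
        do = dh * tc
        dc = dh * o * (1.0 - tc**2)
        dz = np.zeros((n, 4 * H))
        dz[:, :H] = dc * g * i * (1.0 - i)  # input gate
        dz[:, 2 * H : 3 * H] = dc * i * (1.0 - g**2)  # candidate
        dz[:, 3 * H :] = do * o * (1.0 - o)  # output gate
        grads["Wx"] = X.T @ dz
        grads["b"] = dz.sum(axis=0)
        return grads

    # -- training --------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTMRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] < 10:
            raise ConfigurationError(
                f"training needs at least 10 samples, got {X.shape[0]}"
            )
        if X.shape[0] != y.size:
            raise ValidationError("feature matrix and targets disagree in length")
        cfg = self.config
        self._params = self._init_params(X.shape[1])
        m = {k: np.zeros_like(v) for k, v in self._params.items()}
        v = {k: np.zeros_like(vv) for k, vv in self._params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        # batching stream, distinct from the init stream
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 16, 1]))
        n = X.shape[0]
        batch = cfg.batch_size or n
        self.loss_history = []
        t = 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(n) if batch < n else np.arange(n)
            epoch_loss = 0.0
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                yhat, cache = self._forward(X[idx])
                loss = float(np.mean((yhat - y[idx]) ** 2))
                if not np.isfinite(loss):
                    raise DivergenceError(epoch)
                epoch_loss += loss * idx.size
                grads = self._backward(yhat, y[idx], cache)
                t += 1
                for k, p in self._params.items():
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                    mhat = m[k] / (1 - beta1**t)
                    vhat = v[k] / (1 - beta2**t)
                    p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            self.loss_history.append(epoch_loss / n)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._params is None:
            raise ValidationError("model is not fitted")
        yhat, _ = self._forward(np.asarray(X, dtype=float))
        return yhat

    # -- persistence (plain-text JSON-able dict) -------------------------
    def to_dict(self) -> dict:
        if self._params is None:
            raise ValidationError("model is not fitted")
        return {
            "config": dataclasses.asdict(self.config),
            "params": {k: v.tolist() for k, v in self._params.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LSTMRegressor":
        model = cls(ModelConfig(**d["config"]))
        model._params = {k: np.asarray(v, dtype=float) for k, v in d["params"].items()}
        return model


def evaluate(model, X_test: np.ndarray, y_test: np.ndarray,
             train_idx=None, test_idx=None, seed: int = 0) -> FitResult:
    """Test-split R-squared and per-sample relative errors.

    ``R^2 = 1 - SS_res / SS_tot`` on the held-out targets; relative error is
    ``|pred - actual| / actual`` (safe: rubric scores are >= 1).
    """
    y = np.asarray(y_test, dtype=float).ravel()
    if y.size == 0:
        raise ValidationError("test set is empty")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedStatisticError("zero variance in actuals: R-squared undefined")
    pred = np.asarray(model.predict(X_test), dtype=float).ravel()
    ss_res = float(np.sum((pred - y) ** 2))
    rel = np.abs(pred - y) / np.abs(y)
    return FitResult(
        r_squared=1.0 - ss_res / ss_tot,
        relative_errors=rel,
        train_indices=np.asarray(train_idx if train_idx is not None else [], dtype=int),
        test_indices=np.asarray(test_idx if test_idx is not None else [], dtype=int),
        seed=seed,
    )


def fit_suitability_model(
    cohort: pd.DataFrame, q: np.ndarray, config: ModelConfig
) -> tuple[LSTMRegressor, StandardizationParams, FitResult]:
    """Split, encode, train and evaluate in one call.

    ``q`` is the vector of final weighted quality scores aligned with the
    cohort rows.  Returns the trained model, the training-split
    standardization parameters, and the held-out :class:`FitResult`.
    """
    q = np.asarray(q, dtype=float).ravel()
    if len(cohort) != q.size:
        raise ValidationError("cohort and score vector disagree in length")
    train_idx, test_idx = split_indices(len(cohort), config)
    X_train, params = encode_features(cohort.iloc[train_idx])
    X_test, _ = encode_features(cohort.iloc[test_idx], params)
    model = LSTMRegressor(config).fit(X_train, q[train_idx])
    result = evaluate(model, X_test, q[test_idx], train_idx, test_idx, config.seed)
    return model, params, result


def decide(
    model: LSTMRegressor,
    record: InfantRecord | pd.DataFrame,
    params: StandardizationParams,
    threshold: float = 3.0,
) -> SuitabilityDecision:
    """Suitability decision for one infant: predicted score > threshold.

    Mirrors the composite-score rule: an infant whose predicted image
    quality exceeds 3 is a suitable candidate for ultrasound examination.
    """
    if isinstance(record, InfantRecord):
        frame = pd.DataFrame([dataclasses.asdict(record)])
    else:
        frame = record
        if len(frame) != 1:
            raise ValidationError("decide() takes exactly one record")
    X, _ = encode_features(frame, params)
    q_pred = float(model.predict(X)[0])
    return SuitabilityDecision(q_pred=q_pred, suitable=q_pred > threshold)


def linear_baseline(X_train: np.ndarray, y_train: np.ndarray):
    """Ordinary least-squares baseline (extension, for sanity comparison).

    Returns a ``predict(X)`` callable.  Not part of the study's method; it
    exists so users can check the recurrent model against a linear fit.
    """
    A = np.column_stack([np.ones(len(X_train)), X_train])
    coef, *_ = np.linalg.lstsq(A, np.asarray(y_train, float).ravel(), rcond=None)

    def predict(X: np.ndarray) -> np.ndarray:
        return np.column_stack([np.ones(len(X)), X]) @ coef

    return predict
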