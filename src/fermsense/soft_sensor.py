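"""Inverse-model soft sensor for the unmeasured fermentation states.

The measurable channels (dissolved oxygen x4, hydrogen-ion concentration
x5, volume x6), the derivative information of x4 and x5, the four feed
rates and the environment (Tw, Sa, Fa) form a 13-dimensional feature
vector; three independently trained networks map it to the unmeasured
states x1 (cell), x2 (substrate) and x3 (enzyme concentration). Cascading
the trained inverse model with the process yields an approximate identity
("pseudo-linear") map from true to reconstructed states, which
:func:`cascade_identity_check` quantifies.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .model import Trajectory
from .network import TrainConfig, forward, train
from .preprocessing import (
    FilterConfig,
    NormalizationStats,
    SampledSeries,
    align_offline_samples,
    five_point_derivative,
    moving_average_filter,
)

__all__ = [
    "FEATURE_NAMES",
    "TARGET_NAMES",
    "SoftSensorDataset",
    "SoftSensorRegressor",
    "EvaluationReport",
    "build_features",
    "evaluate",
    "cascade_identity_check",
]

FEATURE_NAMES = (
    "x4", "x5", "x6",
    "x4_dot", "x4_ddot", "x5_dot",
    "u1", "u2", "u3", "u4",
    "Tw", "Sa", "Fa",
)
TARGET_NAMES = ("x1", "x2", "x3")
MEASURED_CHANNELS = ("x4", "x5", "x6")


@dataclass
class SoftSensorDataset:
    """Rows of feature vectors plus (optionally) the three assay targets."""

    t: np.ndarray
    X: pd.DataFrame
    y: np.ndarray | None = None
    split: np.ndarray | None = None   # "train" / "test" per row
    batch_id: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if len(self.X) != len(self.t):
            raise ValueError("features and timestamps must align")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != (len(self.t), 3):
                raise ValueError(f"targets must be (n, 3), got {self.y.shape}")
        if self.split is not None and len(self.split) != len(self.t):
            raise ValueError("split tags must align with rows")

    def __len__(self) -> int:
        return len(self.t)

    def assign_chronological_split(self, train_frac: float = 0.7) -> "SoftSensorDataset":
        """Tag the first fraction of rows (in time order) as train, the rest
        as test — time-series hygiene for a single batch."""
        n_train = int(round(train_frac * len(self)))
        split = np.array(["train"] * n_train + ["test"] * (len(self) - n_train))
        self.split = split
        return self

    def assign_interleaved_split(self, test_every: int = 3) -> "SoftSensorDataset":
        """Hold out every ``test_every``-th row. Suits within-range
        validation of the static inverse map (test error comparable to train
        error), as opposed to the chronological split's extrapolation."""
        idx = np.arange(len(self))
        self.split = np.where(idx % test_every == test_every - 1, "test", "train")
        return self

    def rows(self, tag: str) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
        if self.split is None:
            raise ValueError("dataset has no split tags")
        mask = self.split == tag
        y = self.y[mask] if self.y is not None else None
        return self.X.values[mask], y, self.t[mask]


def _sample_indices(dense_t: np.ndarray, sample_times: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(dense_t, sample_times)
    idx = np.clip(idx, 0, len(dense_t) - 1)
    # accept the left neighbour when rounding placed us one past
    left = np.clip(idx - 1, 0, len(dense_t) - 1)
    use_left = np.abs(dense_t[left] - sample_times) < np.abs(dense_t[idx] - sample_times)
    idx = np.where(use_left, left, idx)
    if np.any(np.abs(dense_t[idx] - sample_times) > 1e-6 * np.maximum(np.abs(sample_times), 1.0)):
        raise ValueError("sample times must lie on the trajectory time grid (nested grids)")
    return idx


def build_features(
    traj: Trajectory,
    sample_times: np.ndarray | None = None,
    filter_cfg: FilterConfig | dict | None = None,
    filter_channels: tuple = MEASURED_CHANNELS,
    targets: np.ndarray | None = None,
    offline: tuple | None = None,
    include_x6_dot: bool = False,
) -> SoftSensorDataset:
    """Assemble the soft-sensing dataset from a trajectory record.

    Pipeline: sample the measured channels at ``sample_times`` (defaults to
    the full grid), optionally moving-average filter them, differentiate x4
    (orders 1 and 2) and x5 (order 1) with the five-point stencils, and
    stack the 13 features in physical units (normalization happens inside
    the estimator, on training rows only). Targets come from ``targets``
    (values at the sample times), from ``offline=(t_off, Y_off)`` assay
    tables aligned by local least squares, or — for synthetic campaigns —
    directly from the trajectory's true states.
    """
    if sample_times is None:
        sample_times = traj.t
    sample_times = np.asarray(sample_times, dtype=float)
    if len(sample_times) < 5:
        raise ValueError("need >= 5 sample times for the five-point derivative features")
    idx = _sample_indices(traj.t, sample_times)

    measured = {
        "x4": traj.states[idx, 3],
        "x5": traj.states[idx, 4],
        "x6": traj.states[idx, 5],
    }
    if filter_cfg is not None:
        cfg_map = filter_cfg if isinstance(filter_cfg, dict) else {ch: filter_cfg for ch in filter_channels}
        for ch, cfg in cfg_map.items():
            if ch not in measured:
                raise KeyError(f"unknown filter channel {ch!r}")
            measured[ch] = moving_average_filter(SampledSeries(sample_times, measured[ch]), cfg).values

    x4_series = SampledSeries(sample_times, measured["x4"])
    x5_series = SampledSeries(sample_times, measured["x5"])
    cols = {
        "x4": measured["x4"],
        "x5": measured["x5"],
        "x6": measured["x6"],
        "x4_dot": five_point_derivative(x4_series, 1).values,
        "x4_ddot": five_point_derivative(x4_series, 2).values,
        "x5_dot": five_point_derivative(x5_series, 1).values,
        "u1": traj.feeds[idx, 0],
        "u2": traj.feeds[idx, 1],
        "u3": traj.feeds[idx, 2],
        "u4": traj.feeds[idx, 3],
        "Tw": traj.env[idx, 0],
        "Sa": traj.env[idx, 1],
        "Fa": traj.env[idx, 2],
    }
    if include_x6_dot:
        cols["x6_dot"] = five_point_derivative(SampledSeries(sample_times, measured["x6"]), 1).values
    X = pd.DataFrame(cols)

    y: np.ndarray | None
    if targets is not None:
        y = np.asarray(targets, dtype=float)
    elif offline is not None:
        t_off, Y_off = offline
        Y_off = np.atleast_2d(np.asarray(Y_off, dtype=float))
        y = np.column_stack(
            [align_offline_samples(SampledSeries(t_off, Y_off[:, j]), sample_times) for j in range(3)]
        )
    else:
        y = traj.states[idx, 0:3].copy()
    return SoftSensorDataset(t=sample_times, X=X, y=y)


class StatsMismatchError(RuntimeError):
    pass


class SoftSensorRegressor(BaseEstimator):
    """Three-network inverse-model soft sensor (scikit-learn conventions).

    One network per target state, sharing normalization statistics computed
    from the training rows only; predictions are returned in physical units.
    """

    def __init__(
        self,
        hidden_layer_sizes=(32, 16),
        learning_rate: float = 1e-3,
        optimizer: str = "adam",
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        max_epochs: int = 3000,
        norm_method: str = "minmax",
        random_state: int = 0,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.max_epochs = max_epochs
        self.norm_method = norm_method
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    def _check_X(self, X) -> np.ndarray:
        names = None
        if isinstance(X, pd.DataFrame):
            names = tuple(X.columns)
            X = X.values
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if hasattr(self, "n_features_in_") and X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"this soft sensor was fitted on {self.n_features_in_} features "
                f"({', '.join(self.feature_names_in_)}), got {X.shape[1]}"
            )
        if names is not None and hasattr(self, "feature_names_in_") and names != self.feature_names_in_:
            raise ValueError(f"feature columns {names} do not match the fitted layout {self.feature_names_in_}")
        return X

    def stats_fingerprint(self) -> str:
        h = hashlib.sha256()
        for stats in (self.x_stats_, self.y_stats_):
            h.update(np.ascontiguousarray(stats.offset).tobytes())
            h.update(np.ascontiguousarray(stats.scale).tobytes())
            h.update(stats.method.encode())
        return h.hexdigest()[:16]

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = tuple(X.columns)
        else:
            self.feature_names_in_ = tuple(f"f{i}" for i in range(np.atleast_2d(X).shape[1]))
        Xv = np.atleast_2d(np.asarray(X.values if isinstance(X, pd.DataFrame) else X, dtype=float))
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 3:
            raise ValueError(f"targets must be (n, 3) for (x1, x2, x3), got {y.shape}")
        if len(Xv) == 0:
            raise ValueError("empty training set")
        if np.any(y.std(axis=0) == 0):
            warnings.warn("degenerate (constant) target channel; fitting anyway", stacklevel=2)
        self.n_features_in_ = Xv.shape[1]
        self.x_stats_ = NormalizationStats.fit(Xv, method=self.norm_method)
        self.y_stats_ = NormalizationStats.fit(y, method=self.norm_method)
        Xn = self.x_stats_.apply(Xv)
        Yn = self.y_stats_.apply(y)

        self.networks_ = []
        self.loss_histories_ = []
        dims = [Xn.shape[1], *self.hidden_layer_sizes, 1]
        for j in range(3):
            cfg = TrainConfig(
                max_epochs=self.max_epochs,
                lam=self.learning_rate,
                optimizer=self.optimizer,
                beta1=self.beta1,
                beta2=self.beta2,
                eps=self.eps,
                seed=[self.random_state, j],
            )
            params, history = train(Xn, Yn[:, j : j + 1], dims, cfg)
            self.networks_.append(params)
            self.loss_histories_.append(history["train_loss"])
        # labeled buffer for online correction (physical units)
        self._buffer_X = Xv.copy()
        self._buffer_y = y.copy()
        self._n_fit_rows = len(Xv)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "networks_"):
            raise RuntimeError("soft sensor is not fitted")
        Xn = self.x_stats_.apply(self._check_X(X))
        Yn = np.column_stack([forward(net, Xn)[0][:, 0] for net in self.networks_])
        return self.y_stats_.invert(Yn)

    def predict_normalized(self, Xn: np.ndarray, stats_hash: str | None = None) -> np.ndarray:
        """Predict from already-normalized features; refuses a mismatching
        normalization fingerprint."""
        if stats_hash is not None and stats_hash != self.stats_fingerprint():
            raise StatsMismatchError(
                "normalization statistics mismatch: features were built with "
                f"stats {stats_hash}, model carries {self.stats_fingerprint()}"
            )
        Xn = np.atleast_2d(np.asarray(Xn, dtype=float))
        return np.column_stack([forward(net, Xn)[0][:, 0] for net in self.networks_])

    def online_correct(self, X_new, y_new, epochs: int = 50, window: int = 20) -> "SoftSensorRegressor":
        """Continue Adam training on the train set plus a sliding window of
        the most recent labeled samples; normalization stats stay frozen."""
        X_new = self._check_X(X_new)
        y_new = np.atleast_2d(np.asarray(y_new, dtype=float))
        if len(X_new) == 0:
            warnings.warn("online correction called with no new samples; model unchanged", stacklevel=2)
            return self
        self._buffer_X = np.vstack([self._buffer_X, X_new])
        self._buffer_y = np.vstack([self._buffer_y, y_new])
        if epochs <= 0:
            return self
        n_train = getattr(self, "_n_fit_rows", len(self._buffer_X) - len(X_new))
        recent = slice(max(n_train, len(self._buffer_X) - window), len(self._buffer_X))
        Xw = np.vstack([self._buffer_X[:n_train], self._buffer_X[recent]])
        yw = np.vstack([self._buffer_y[:n_train], self._buffer_y[recent]])
        Xn = self.x_stats_.apply(Xw)
        Yn = self.y_stats_.apply(yw)
        from .network import AdamState, adam_step, backward, mse_loss

        for j in range(3):
            params = self.networks_[j]
            target = Yn[:, j : j + 1]
            state = AdamState.init(params, lam=self.learning_rate, beta1=self.beta1,
                                   beta2=self.beta2, eps=self.eps)
            best_params, best_loss = params, mse_loss(forward(params, Xn)[0], target)
            for _ in range(epochs):
                Y_hat, cache = forward(params, Xn)
                grads = backward(params, cache, target)
                params, state = adam_step(params, grads, state)
                loss = mse_loss(forward(params, Xn)[0], target)
                if loss < best_loss:
                    best_loss, best_params = loss, params
            # accept the update only at its best point on the correction pool,
            # so a fresh-optimizer transient can never degrade the model
            self.networks_[j] = best_params
        return self


@dataclass
class EvaluationReport:
    """Per-target errors of a fitted soft sensor on a tagged dataset."""

    mse_train: dict
    mse_test: dict | None
    mse_train_physical: dict
    mse_test_physical: dict | None
    rel_error: pd.DataFrame          # per-timepoint |yhat - y| / |y| with exclusion flags
    medians: dict                    # median relative error per target (guarded points excluded)
    pred_curve: pd.DataFrame         # predictions interpolated to the display grid

    def to_dict(self) -> dict:
        return {
            "mse_train": self.mse_train,
            "mse_test": self.mse_test,
            "mse_train_physical": self.mse_train_physical,
            "mse_test_physical": self.mse_test_physical,
            "median_relative_error": self.medians,
        }


def _split_mse(model: SoftSensorRegressor, X, y) -> tuple[dict, dict]:
    pred = model.predict(X)
    yn, pn = model.y_stats_.apply(y), model.y_stats_.apply(pred)
    norm = {TARGET_NAMES[j]: float(np.mean((pn[:, j] - yn[:, j]) ** 2)) for j in range(3)}
    phys = {TARGET_NAMES[j]: float(np.mean((pred[:, j] - y[:, j]) ** 2)) for j in range(3)}
    return norm, phys


def evaluate(
    model: SoftSensorRegressor,
    dataset: SoftSensorDataset,
    interp_minutes: float = 30.0,
    rel_floor: float = 1e-6,
) -> EvaluationReport:
    """Per-target MSE on the train/test splits plus relative-error series.

    MSE is reported in normalized units (comparable across targets) and in
    physical units. Relative errors are computed at the dataset's own
    timestamps, excluding points where |y| falls below ``rel_floor``;
    predictions are additionally interpolated onto an ``interp_minutes``
    display grid by local quadratic least squares.
    """
    if dataset.y is None:
        raise ValueError("evaluation needs targets")
    if dataset.split is None:
        dataset.assign_chronological_split()
    X_tr, y_tr, _ = dataset.rows("train")
    X_te, y_te, _ = dataset.rows("test")
    mse_train, mse_train_phys = _split_mse(model, X_tr, y_tr)
    if len(X_te):
        mse_test, mse_test_phys = _split_mse(model, X_te, y_te)
    else:
        warnings.warn("no test rows; reporting train metrics only", stacklevel=2)
        mse_test = mse_test_phys = None

    pred = model.predict(dataset.X)
    rel = pd.DataFrame({"t": dataset.t})
    medians = {}
    for j, name in enumerate(TARGET_NAMES):
        denom = np.abs(dataset.y[:, j])
        excluded = denom < rel_floor
        r = np.abs(pred[:, j] - dataset.y[:, j]) / np.where(excluded, 1.0, denom)
        r[excluded] = np.nan
        rel[f"rel_{name}"] = r
        rel[f"excluded_{name}"] = excluded
        medians[name] = float(np.nanmedian(r)) if (~excluded).any() else float("nan")

    grid = np.arange(dataset.t[0], dataset.t[-1] + 1e-9, interp_minutes / 60.0)
    curve = {"t_h": grid}
    for j, name in enumerate(TARGET_NAMES):
        curve[f"{name}_hat"] = align_offline_samples(SampledSeries(dataset.t, pred[:, j]), grid)
    return EvaluationReport(
        mse_train=mse_train,
        mse_test=mse_test,
        mse_train_physical=mse_train_phys,
        mse_test_physical=mse_test_phys,
        rel_error=rel,
        medians=medians,
        pred_curve=pd.DataFrame(curve),
    )


def cascade_identity_check(
    model: SoftSensorRegressor,
    traj: Trajectory,
    sample_times: np.ndarray,
    filter_cfg: FilterConfig | dict | None = None,
    rel_floor: float = 1e-6,
) -> dict:
    """Cascade the inverse model with the simulated process and measure how
    close the composition is to the identity map on (x1, x2, x3).

    Simulate -> sample -> build features -> predict, then compare the
    reconstruction with the simulator's true states at the sample times.
    Returns the median relative error per target (points with |y| below
    ``rel_floor`` excluded).
    """
    sample_times = np.asarray(sample_times, dtype=float)
    if len(sample_times) < 5:
        raise ValueError("horizon shorter than the derivative stencil support (need >= 5 samples)")
    ds = build_features(traj, sample_times=sample_times, filter_cfg=filter_cfg)
    pred = model.predict(ds.X)
    out = {}
    for j, name in enumerate(TARGET_NAMES):
        denom = np.abs(ds.y[:, j])
        keep = denom >= rel_floor
        r = np.abs(pred[keep, j] - ds.y[keep, j]) / denom[keep]
        out[name] = float(np.median(r)) if keep.any() else float("nan")
    return out
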