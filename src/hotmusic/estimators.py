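"""Scikit-learn-style regressors wrapping the two network forms.

``fit`` minimises the mean-squared dTm error by gradient-based
optimisation with multiple random restarts; each restart tracks a held-out
validation error every iteration and the parameters of the best-validation
iteration are kept (early stopping).  The restart with the lowest
validation RMSE wins.

Optimisers: plain batch gradient descent (``"gd"``, the default), Adam
(``"adam"``) and L-BFGS (``"lbfgs"``, recommended in practice: the model
mixes kT-scale energy terms with cubic-angstrom volume terms and a fixed
learning rate conditions poorly on that mix).
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .features import HOT_FEATURE_COLUMNS, TMHOT_FEATURE_COLUMNS
from .models import (
    HotParams,
    N_HOT_PARAMS,
    N_TMHOT_PARAMS,
    TmHotParams,
    hot_loss_grad,
    hot_predict_vec,
    tmhot_loss_grad,
    tmhot_predict_vec,
)


class _TrackedRun:
    """Best-validation-iterate bookkeeping shared by all optimisers."""

    def __init__(self, val_fn: Callable[[np.ndarray], float], patience: int):
        self.val_fn = val_fn
        self.patience = patience
        self.best_val = np.inf
        self.best_theta: np.ndarray | None = None
        self.since_best = 0
        self.n_iter = 0

    def update(self, theta: np.ndarray) -> bool:
        """Record one iterate; returns True when patience is exhausted."""
        self.n_iter += 1
        v = self.val_fn(theta)
        if v < self.best_val:
            self.best_val = v
            self.best_theta = theta.copy()
            self.since_best = 0
        else:
            self.since_best += 1
        return self.since_best > self.patience


class _BaseNetRegressor(RegressorMixin, BaseEstimator):
    _n_params: int
    _feature_columns: tuple[str, ...]

    def __init__(
        self,
        n_restarts: int = 30,
        max_iter: int = 2000,
        learning_rate: float = 1e-3,
        early_stop_patience: int = 50,
        validation_fraction: float = 1.0 / 9.0,
        optimizer: str = "gd",
        init_scale: float = 0.1,
        random_state: int | None = None,
    ):
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.learning_rate = learning_rate
        self.early_stop_patience = early_stop_patience
        self.validation_fraction = validation_fraction
        self.optimizer = optimizer
        self.init_scale = init_scale
        self.random_state = random_state

    # subclass hooks ------------------------------------------------------
    def _loss_grad(self, theta, X, y):
        raise NotImplementedError

    def _predict_vec(self, theta, X):
        raise NotImplementedError

    def _init_theta(self, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def _warm_start_theta(self, X, y) -> np.ndarray | None:
        """Flat-weight linear least-squares initialisation (one restart)."""
        return None

    def _params_from_vector(self, theta):
        raise NotImplementedError

    # ---------------------------------------------------------------------
    def _resolve_X(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self._feature_columns if c not in X.columns]
            if missing:
                raise ValueError(f"feature frame lacks columns {missing}")
            X = X[list(self._feature_columns)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self._feature_columns):
            raise ValueError(
                f"expected {len(self._feature_columns)} feature columns, "
                f"got shape {X.shape}"
            )
        return X

    def fit(self, X, y, X_val=None, y_val=None):
        X = self._resolve_X(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if len(X) < 1:
            raise ValueError("need at least one training example")
        if not np.isfinite(y).all():
            raise ValueError("targets must be finite")
        rng = np.random.default_rng(self.random_state)

        if X_val is not None:
            X_tr, y_tr = X, y
            X_va = self._resolve_X(X_val)
            y_va = np.asarray(y_val, dtype=float).ravel()
        elif self.validation_fraction > 0 and len(X) >= 10:
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            perm = rng.permutation(len(X))
            X_tr, y_tr = X[perm[n_val:]], y[perm[n_val:]]
            X_va, y_va = X[perm[:n_val]], y[perm[:n_val]]
        else:
            X_tr, y_tr = X, y
            X_va, y_va = X, y

        def val_sigma(theta: np.ndarray) -> float:
            resid = self._predict_vec(theta, X_va) - y_va
            return float(np.sqrt(np.mean(resid**2)))

        best_theta = None
        best_val = np.inf
        restart_sigmas = []
        total_iter = 0
        failures = []
        warm = self._warm_start_theta(X_tr, y_tr)
        for k in range(max(1, self.n_restarts)):
            theta0 = warm if (k == 0 and warm is not None) else self._init_theta(rng)
            try:
                theta, run = self._optimize(theta0, X_tr, y_tr, val_sigma)
            except FloatingPointError as exc:  # diverged restart: skip it
                failures.append(str(exc))
                continue
            total_iter += run.n_iter
            restart_sigmas.append(run.best_val)
            if run.best_val < best_val:
                best_val = run.best_val
                best_theta = theta
        if best_theta is None:
            raise RuntimeError(
                f"all {self.n_restarts} restarts diverged: {failures[:3]}"
            )
        self.theta_ = best_theta
        self.params_ = self._params_from_vector(best_theta)
        self.validation_sigma_ = best_val
        self.restart_sigmas_ = restart_sigmas
        self.n_iter_ = total_iter
        train_resid = self._predict_vec(best_theta, X_tr) - y_tr
        self.training_sigma_ = float(np.sqrt(np.mean(train_resid**2)))
        return self

    def _optimize(self, theta0, X, y, val_fn) -> tuple[np.ndarray, _TrackedRun]:
        run = _TrackedRun(val_fn, self.early_stop_patience)
        run.update(theta0)
        if self.optimizer == "lbfgs":
            def cb(theta):
                if run.update(theta):
                    raise StopIteration

            res = minimize(
                lambda t: self._loss_grad(t, X, y),
                theta0,
                jac=True,
                method="L-BFGS-B",
                callback=cb,
                options={"maxiter": self.max_iter, "maxfun": 20 * self.max_iter,
                         "ftol": 1e-16, "gtol": 1e-12},
            )
            run.update(res.x)
            return np.asarray(run.best_theta), run
        if self.optimizer not in ("gd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        theta = theta0.copy()
        m = np.zeros_like(theta)
        v = np.zeros_like(theta)
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        for t in range(1, self.max_iter + 1):
            loss, grad = self._loss_grad(theta, X, y)
            if not np.isfinite(loss) or not np.isfinite(grad).all():
                raise FloatingPointError(f"non-finite loss at iteration {t}")
            if self.optimizer == "adam":
                m = beta1 * m + (1 - beta1) * grad
                v = beta2 * v + (1 - beta2) * grad**2
                mhat = m / (1 - beta1**t)
                vhat = v / (1 - beta2**t)
                theta = theta - self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            else:
                theta = theta - self.learning_rate * grad
            if run.update(theta):
                break
        return np.asarray(run.best_theta), run

    def predict(self, X):
        check_is_fitted(self, "theta_")
        return self._predict_vec(self.theta_, self._resolve_X(X))


class HotMusicRegressor(_BaseNetRegressor):
    """Temperature-independent dTm predictor (50 free parameters).

    Features, in order: the nine standard-potential ddW terms, dv_plus,
    dv_minus, the mutated residue's solvent accessibility (percent) and
    the chain length N_r.
    """

    _n_params = N_HOT_PARAMS
    _feature_columns = HOT_FEATURE_COLUMNS

    def __init__(
        self,
        n_restarts: int = 30,
        max_iter: int = 2000,
        learning_rate: float = 1e-3,
        early_stop_patience: int = 50,
        validation_fraction: float = 1.0 / 9.0,
        optimizer: str = "gd",
        init_scale: float = 0.1,
        random_state: int | None = None,
        normalize_length: bool = True,
    ):
        super().__init__(
            n_restarts=n_restarts,
            max_iter=max_iter,
            learning_rate=learning_rate,
            early_stop_patience=early_stop_patience,
            validation_fraction=validation_fraction,
            optimizer=optimizer,
            init_scale=init_scale,
            random_state=random_state,
        )
        self.normalize_length = normalize_length

    def _loss_grad(self, theta, X, y):
        return hot_loss_grad(theta, X, y, normalize_length=self.normalize_length)

    def _predict_vec(self, theta, X):
        return hot_predict_vec(theta, X, normalize_length=self.normalize_length)

    def _init_theta(self, rng):
        theta = np.empty(N_HOT_PARAMS)
        theta[0:12] = rng.normal(0.0, self.init_scale, 12)    # phi
        theta[12:24] = rng.normal(0.0, self.init_scale, 12)   # r
        theta[24:36] = rng.normal(0.0, 0.05, 12)              # omega, per %
        theta[36:48] = rng.uniform(0.0, 100.0, 12)            # b, percent
        theta[48] = 1.0 + rng.normal(0.0, self.init_scale)    # a
        theta[49] = rng.normal(0.0, self.init_scale)          # c
        return theta

    def _params_from_vector(self, theta):
        return HotParams.from_vector(theta)

    def _warm_start_theta(self, X, y):
        terms = np.concatenate([X[:, :11], np.ones((len(X), 1))], axis=1)
        scale = X[:, 12] if self.normalize_length else np.ones(len(X))
        design = np.concatenate([terms / scale[:, None], np.ones((len(X), 1))], axis=1)
        sol, *_ = np.linalg.lstsq(design, y, rcond=None)
        theta = np.zeros(N_HOT_PARAMS)
        theta[0:12] = sol[:12]        # phi carries the flat weights
        theta[24:36] = 0.05           # gentle slope so sigmoids can wake up
        theta[36:48] = 50.0
        theta[48] = 1.0
        theta[49] = sol[12]
        return theta


class TmHotMusicRegressor(_BaseNetRegressor):
    """Tm-aware dTm predictor (67 free parameters).

    Features, in order: five mesostable and five thermostable grouped ddW
    terms, dv_plus, dv_minus, accessibility, chain length, wild-type Tm.
    """

    _n_params = N_TMHOT_PARAMS
    _feature_columns = TMHOT_FEATURE_COLUMNS

    def _loss_grad(self, theta, X, y):
        return tmhot_loss_grad(theta, X, y)

    def _predict_vec(self, theta, X):
        return tmhot_predict_vec(theta, X)

    def _init_theta(self, rng):
        theta = np.empty(N_TMHOT_PARAMS)
        theta[0:13] = rng.normal(0.0, self.init_scale, 13)
        theta[13:26] = rng.normal(0.0, self.init_scale, 13)
        theta[26:39] = rng.normal(0.0, 0.05, 13)
        theta[39:52] = rng.uniform(0.0, 100.0, 13)
        q = np.zeros((3, 5))
        q[:, 0] = rng.normal(0.0, 0.5, 3)      # constant part of F_I
        q[:, 1:] = rng.normal(0.0, 1e-3, (3, 4))
        theta[52:67] = q.ravel()
        return theta

    def _params_from_vector(self, theta):
        return TmHotParams.from_vector(theta)

    def _warm_start_theta(self, X, y):
        # flat weights with all three output factors pinned at 1
        terms = np.concatenate([X[:, :12], np.ones((len(X), 1))], axis=1)
        sol, *_ = np.linalg.lstsq(terms, y, rcond=None)
        theta = np.zeros(N_TMHOT_PARAMS)
        theta[0:13] = sol
        theta[26:39] = 0.05
        theta[39:52] = 50.0
        q = np.zeros((3, 5))
        q[:, 0] = 1.0
        theta[52:67] = q.ravel()
        return theta
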