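"""The two melting-temperature prediction functions.

Both models are shallow feed-forward networks whose input weights are
sigmoid functions of the solvent accessibility A of the mutated residue,

    alpha(A) = phi + r / (1 + exp(-omega (A - b))),

modelling the smooth change of the energy-term weights from the protein
core to the surface.

* The temperature-independent model (50 parameters) combines the nine
  standard potential terms, the two volume terms and an independent
  (accessibility-only) term:

      dTm = c + a [ sum_nu alpha_nu(A) x_nu ] / N_r

  with x = (ddW_1..ddW_9, dV+, dV-, 1) and N_r the chain length (the 1/N_r
  scaling follows the small-perturbation thermodynamics, where the
  proportionality coefficient between dTm and ddG carries 1/dHm and the
  folding enthalpy grows with chain length; it can be disabled).

* The wild-type-Tm-aware model (67 parameters) feeds three perceptrons
  (five mesostable terms, five thermostable terms, volume + independent
  terms) into an output perceptron whose weights are polynomials in the
  wild-type Tm and 1/N_r:

      dTm = F_M(Tm, N_r) S_M + F_T(Tm, N_r) S_T + F_V(Tm, N_r) S_V
      F_I(Tm, N_r) = q0 + q1 Tm + q2 Tm^2 + q3 / N_r + q4 Tm / N_r.

The final prediction is the mean of the two model outputs, falling back
to the Tm-free model when the wild-type Tm is unknown.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
import numpy as np
from scipy.special import expit

from .features import (
    FEATURE_COLUMNS,
    HOT_FEATURE_COLUMNS,
    TMHOT_FEATURE_COLUMNS,
    FeatureVector,
)

N_HOT_PARAMS = 50
N_TMHOT_PARAMS = 67

HOT_TERM_NAMES: tuple[str, ...] = (
    "sd", "sds", "sad", "std", "sa", "saa", "st", "stt", "sst",
    "dv_plus", "dv_minus", "independent",
)
TMHOT_TERM_NAMES: tuple[str, ...] = (
    "meso_sd", "meso_sds", "meso_sad", "meso_acc", "meso_tor",
    "thermo_sd", "thermo_sds", "thermo_sad", "thermo_acc", "thermo_tor",
    "dv_plus", "dv_minus", "independent",
)


@dataclass
class SigmoidWeight:
    """One accessibility-dependent weight alpha(A) = phi + r sigma(omega (A-b))."""

    phi: float
    r: float
    omega: float
    b: float

    def __call__(self, A: float | np.ndarray):
        return sigmoid_weight(self, A)


def sigmoid_weight(w: SigmoidWeight, A: float | np.ndarray):
    """Evaluate a sigmoid weight at accessibility A (percent)."""
    return w.phi + w.r * expit(w.omega * (np.asarray(A, dtype=float) - w.b))


@dataclass
class PolyFactor:
    """Output-perceptron weight F(Tm, N_r) = q0 + q1 Tm + q2 Tm^2 + q3/N_r + q4 Tm/N_r."""

    q: tuple[float, float, float, float, float]

    def __call__(self, tm_wild: float | np.ndarray, n_res: float | np.ndarray):
        return poly_factor(self, tm_wild, n_res)


def poly_factor(pf: PolyFactor, tm_wild, n_res):
    tm = np.asarray(tm_wild, dtype=float)
    nr = np.asarray(n_res, dtype=float)
    q0, q1, q2, q3, q4 = pf.q
    return q0 + q1 * tm + q2 * tm**2 + q3 / nr + q4 * tm / nr


# ---------------------------------------------------------------------------
# flat parameter vectors
#
# Tm-free model, theta (50,):
#   [phi(12), r(12), omega(12), b(12), a, c]
# Tm-aware model, theta (67,):
#   [phi(13), r(13), omega(13), b(13), qM(5), qT(5), qV(5)]
# ---------------------------------------------------------------------------


@dataclass
class HotParams:
    """Parameters of the temperature-independent model (50 scalars)."""

    weights: list[SigmoidWeight]        # 12, HOT_TERM_NAMES order
    a: float
    c: float

    def __post_init__(self) -> None:
        if len(self.weights) != 12:
            raise ValueError("the Tm-free model takes exactly 12 sigmoid weights")

    def to_vector(self) -> np.ndarray:
        v = np.empty(N_HOT_PARAMS)
        v[0:12] = [w.phi for w in self.weights]
        v[12:24] = [w.r for w in self.weights]
        v[24:36] = [w.omega for w in self.weights]
        v[36:48] = [w.b for w in self.weights]
        v[48] = self.a
        v[49] = self.c
        return v

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "HotParams":
        v = np.asarray(v, dtype=float)
        if v.shape != (N_HOT_PARAMS,):
            raise ValueError(f"expected {N_HOT_PARAMS} parameters, got {v.shape}")
        weights = [
            SigmoidWeight(v[k], v[12 + k], v[24 + k], v[36 + k]) for k in range(12)
        ]
        return cls(weights=weights, a=float(v[48]), c=float(v[49]))

    def n_free_parameters(self) -> int:
        return self.to_vector().size

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "model": "hot",
            "weights": {
                name: [w.phi, w.r, w.omega, w.b]
                for name, w in zip(HOT_TERM_NAMES, self.weights)
            },
            "a": self.a,
            "c": self.c,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "HotParams":
        d = json.loads(Path(path).read_text())
        if d.get("model") != "hot":
            raise ValueError("not a Tm-free model parameter file")
        weights = [SigmoidWeight(*d["weights"][name]) for name in HOT_TERM_NAMES]
        return cls(weights=weights, a=float(d["a"]), c=float(d["c"]))


@dataclass
class TmHotParams:
    """Parameters of the Tm-aware model (67 scalars)."""

    meso_weights: list[SigmoidWeight]     # 5
    thermo_weights: list[SigmoidWeight]   # 5
    vol_ind_weights: list[SigmoidWeight]  # 3: dv_plus, dv_minus, independent
    f_meso: PolyFactor
    f_thermo: PolyFactor
    f_vol: PolyFactor

    def __post_init__(self) -> None:
        if (len(self.meso_weights), len(self.thermo_weights),
                len(self.vol_ind_weights)) != (5, 5, 3):
            raise ValueError("the Tm-aware model takes 5+5+3 sigmoid weights")

    @property
    def weights(self) -> list[SigmoidWeight]:
        return self.meso_weights + self.thermo_weights + self.vol_ind_weights

    def to_vector(self) -> np.ndarray:
        v = np.empty(N_TMHOT_PARAMS)
        ws = self.weights
        v[0:13] = [w.phi for w in ws]
        v[13:26] = [w.r for w in ws]
        v[26:39] = [w.omega for w in ws]
        v[39:52] = [w.b for w in ws]
        v[52:57] = self.f_meso.q
        v[57:62] = self.f_thermo.q
        v[62:67] = self.f_vol.q
        return v

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "TmHotParams":
        v = np.asarray(v, dtype=float)
        if v.shape != (N_TMHOT_PARAMS,):
            raise ValueError(f"expected {N_TMHOT_PARAMS} parameters, got {v.shape}")
        ws = [SigmoidWeight(v[k], v[13 + k], v[26 + k], v[39 + k]) for k in range(13)]
        return cls(
            meso_weights=ws[:5],
            thermo_weights=ws[5:10],
            vol_ind_weights=ws[10:],
            f_meso=PolyFactor(tuple(v[52:57])),
            f_thermo=PolyFactor(tuple(v[57:62])),
            f_vol=PolyFactor(tuple(v[62:67])),
        )

    def n_free_parameters(self) -> int:
        return self.to_vector().size

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "model": "tm_hot",
            "weights": {
                name: [w.phi, w.r, w.omega, w.b]
                for name, w in zip(TMHOT_TERM_NAMES, self.weights)
            },
            "f_meso": list(self.f_meso.q),
            "f_thermo": list(self.f_thermo.q),
            "f_vol": list(self.f_vol.q),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "TmHotParams":
        d = json.loads(Path(path).read_text())
        if d.get("model") != "tm_hot":
            raise ValueError("not a Tm-aware model parameter file")
        ws = [SigmoidWeight(*d["weights"][name]) for name in TMHOT_TERM_NAMES]
        return cls(
            meso_weights=ws[:5], thermo_weights=ws[5:10], vol_ind_weights=ws[10:],
            f_meso=PolyFactor(tuple(d["f_meso"])),
            f_thermo=PolyFactor(tuple(d["f_thermo"])),
            f_vol=PolyFactor(tuple(d["f_vol"])),
        )


# ---------------------------------------------------------------------------
# vectorised prediction and gradients on flat parameter vectors
# ---------------------------------------------------------------------------


def _hot_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a (n, 13) Tm-free feature matrix into terms, A and N_r."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(HOT_FEATURE_COLUMNS):
        raise ValueError(
            f"expected {len(HOT_FEATURE_COLUMNS)} feature columns "
            f"({', '.join(HOT_FEATURE_COLUMNS)}), got shape {X.shape}"
        )
    terms = np.concatenate([X[:, :11], np.ones((len(X), 1))], axis=1)  # (n, 12)
    A = X[:, 11]
    n_res = X[:, 12]
    return terms, A, n_res


def hot_predict_vec(theta: np.ndarray, X: np.ndarray,
                    normalize_length: bool = True) -> np.ndarray:
    terms, A, n_res = _hot_matrix(X)
    phi, r, omega, b = theta[0:12], theta[12:24], theta[24:36], theta[36:48]
    a, c = theta[48], theta[49]
    sig = expit(omega[None, :] * (A[:, None] - b[None, :]))
    alpha = phi[None, :] + r[None, :] * sig
    S = (alpha * terms).sum(axis=1)
    scale = n_res if normalize_length else 1.0
    return c + a * S / scale


def hot_loss_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                  normalize_length: bool = True) -> tuple[float, np.ndarray]:
    """Mean-squared-error cost and its analytic gradient."""
    terms, A, n_res = _hot_matrix(X)
    phi, r, omega, b = theta[0:12], theta[12:24], theta[24:36], theta[36:48]
    a, c = theta[48], theta[49]
    z = omega[None, :] * (A[:, None] - b[None, :])
    sig = expit(z)
    alpha = phi[None, :] + r[None, :] * sig
    S = (alpha * terms).sum(axis=1)
    inv_scale = 1.0 / n_res if normalize_length else np.ones_like(n_res)
    pred = c + a * S * inv_scale
    resid = pred - np.asarray(y, dtype=float)
    n = len(resid)
    loss = float(np.mean(resid**2))
    g_out = 2.0 * resid / n                       # dL/dpred, (n,)
    common = (g_out * a * inv_scale)[:, None] * terms   # (n, 12)
    dsig = sig * (1.0 - sig)
    grad = np.empty_like(theta)
    grad[0:12] = common.sum(axis=0)
    grad[12:24] = (common * sig).sum(axis=0)
    grad[24:36] = (common * r[None, :] * dsig * (A[:, None] - b[None, :])).sum(axis=0)
    grad[36:48] = (common * r[None, :] * dsig * (-omega[None, :])).sum(axis=0)
    grad[48] = float((g_out * S * inv_scale).sum())
    grad[49] = float(g_out.sum())
    return loss, grad


def _tmhot_matrix(X: np.ndarray):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(TMHOT_FEATURE_COLUMNS):
        raise ValueError(
            f"expected {len(TMHOT_FEATURE_COLUMNS)} feature columns "
            f"({', '.join(TMHOT_FEATURE_COLUMNS)}), got shape {X.shape}"
        )
    terms = np.concatenate([X[:, :12], np.ones((len(X), 1))], axis=1)  # (n, 13)
    A = X[:, 12]
    n_res = X[:, 13]
    tm = X[:, 14]
    if not np.isfinite(tm).all():
        raise ValueError(
            "the Tm-aware model needs a finite wild-type Tm for every "
            "mutation; use the Tm-free model when it is unknown"
        )
    return terms, A, n_res, tm


_GROUP_SLICES = (slice(0, 5), slice(5, 10), slice(10, 13))


def _poly_basis(tm: np.ndarray, n_res: np.ndarray) -> np.ndarray:
    return np.stack([np.ones_like(tm), tm, tm**2, 1.0 / n_res, tm / n_res], axis=1)


def tmhot_predict_vec(theta: np.ndarray, X: np.ndarray) -> np.ndarray:
    terms, A, n_res, tm = _tmhot_matrix(X)
    phi, r, omega, b = theta[0:13], theta[13:26], theta[26:39], theta[39:52]
    q = theta[52:67].reshape(3, 5)
    sig = expit(omega[None, :] * (A[:, None] - b[None, :]))
    alpha = phi[None, :] + r[None, :] * sig
    contrib = alpha * terms
    basis = _poly_basis(tm, n_res)          # (n, 5)
    F = basis @ q.T                         # (n, 3)
    pred = np.zeros(len(X))
    for g, sl in enumerate(_GROUP_SLICES):
        pred += F[:, g] * contrib[:, sl].sum(axis=1)
    return pred


def tmhot_loss_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    terms, A, n_res, tm = _tmhot_matrix(X)
    phi, r, omega, b = theta[0:13], theta[13:26], theta[26:39], theta[39:52]
    q = theta[52:67].reshape(3, 5)
    z = omega[None, :] * (A[:, None] - b[None, :])
    sig = expit(z)
    alpha = phi[None, :] + r[None, :] * sig
    contrib = alpha * terms                 # (n, 13)
    basis = _poly_basis(tm, n_res)
    F = basis @ q.T                         # (n, 3)
    S = np.stack([contrib[:, sl].sum(axis=1) for sl in _GROUP_SLICES], axis=1)
    pred = (F * S).sum(axis=1)
    resid = pred - np.asarray(y, dtype=float)
    n = len(resid)
    loss = float(np.mean(resid**2))
    g_out = 2.0 * resid / n
    # per-term factor F_g broadcast to the 13 input terms
    Fterm = np.empty_like(terms)
    for g, sl in enumerate(_GROUP_SLICES):
        Fterm[:, sl] = F[:, g][:, None]
    common = g_out[:, None] * Fterm * terms
    dsig = sig * (1.0 - sig)
    grad = np.empty_like(theta)
    grad[0:13] = common.sum(axis=0)
    grad[13:26] = (common * sig).sum(axis=0)
    grad[26:39] = (common * r[None, :] * dsig * (A[:, None] - b[None, :])).sum(axis=0)
    grad[39:52] = (common * r[None, :] * dsig * (-omega[None, :])).sum(axis=0)
    gq = (g_out[:, None, None] * S[:, :, None] * basis[:, None, :]).sum(axis=0)
    grad[52:67] = gq.ravel()
    return loss, grad


# ---------------------------------------------------------------------------
# convenience single-vector interfaces over the parameter dataclasses
# ---------------------------------------------------------------------------


def _hot_row(f: FeatureVector) -> np.ndarray:
    s = f.to_series()
    return s[list(HOT_FEATURE_COLUMNS)].to_numpy(dtype=float)[None, :]


def _tmhot_row(f: FeatureVector) -> np.ndarray:
    s = f.to_series()
    return s[list(TMHOT_FEATURE_COLUMNS)].to_numpy(dtype=float)[None, :]


def predict_hot(params: HotParams, f: FeatureVector,
                normalize_length: bool = True) -> float:
    """dTm (deg C) from the temperature-independent model."""
    return float(hot_predict_vec(params.to_vector(), _hot_row(f), normalize_length)[0])


def predict_tm_hot(params: TmHotParams, f: FeatureVector) -> float:
    """dTm (deg C) from the Tm-aware model; requires ``f.tm_wild``."""
    if f.tm_wild is None or not np.isfinite(f.tm_wild):
        raise ValueError(
            "feature vector has no wild-type Tm; use predict_hot instead"
        )
    if f.ddw_meso is None or f.ddw_thermo is None:
        raise ValueError("feature vector lacks temperature-dependent ddW terms")
    return float(tmhot_predict_vec(params.to_vector(), _tmhot_row(f))[0])


def predict_final(hot: HotParams, tmhot: TmHotParams, f: FeatureVector,
                  normalize_length: bool = True) -> float:
    """Mean of the two model predictions; falls back to the Tm-free model
    (with a warning) when the wild-type Tm is unavailable."""
    p_hot = predict_hot(hot, f, normalize_length)
    if f.tm_wild is None or not np.isfinite(f.tm_wild):
        warnings.warn(
            "wild-type Tm unavailable; returning the Tm-free prediction only",
            stacklevel=2,
        )
        return p_hot
    return 0.5 * (p_hot + predict_tm_hot(tmhot, f))
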