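"""Dataset curation, training orchestration and performance evaluation.

The curation rules mirror how experimental dTm collections are cleaned
before training: only single substitutions in monomeric proteins of
well-resolved X-ray structure, measured without chemical denaturants on a
two-state transition, with |dTm| <= 20 deg C (larger changes likely imply
structural rearrangements the fixed-backbone model cannot express).
Replicate measurements of the same mutation are reduced to the entries at
pH closest to 7 and averaged.

Performance is summarised by sigma (the RMSE between predicted and
experimental dTm), the Pearson correlation r, their 10%-outlier-trimmed
variants, and the same metrics stratified by the solvent accessibility of
the mutated residue (core < 15%, partially buried 15-50%, surface > 50%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .estimators import HotMusicRegressor, TmHotMusicRegressor, _BaseNetRegressor
from .features import MutationRecord

ACCESSIBILITY_STRATA: tuple[tuple[str, float, float], ...] = (
    ("core", 0.0, 15.0),
    ("partially_buried", 15.0, 50.0),
    ("surface", 50.0, 100.0001),
)

FilterReason = Literal[
    "monomeric", "resolution", "denaturant", "two_state", "multi_point",
    "dtm_magnitude", "missing_dtm",
]


@dataclass
class TrainConfig:
    """Training and cross-validation protocol parameters."""

    n_restarts: int = 30
    max_iter: int = 2000
    learning_rate: float = 1e-3
    early_stop_patience: int = 50
    optimizer: str = "gd"
    seed: int = 0
    k_folds: int = 5
    validation_fraction: float = 1.0 / 9.0   # 10% of the full set per fold

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        import yaml

        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


@dataclass
class StratumReport:
    name: str
    sigma: float
    r: float | None
    sigma_over_std: float | None
    n: int


@dataclass
class EvalReport:
    sigma: float
    r: float | None
    sigma_trimmed: float
    r_trimmed: float | None
    n_mut: int
    trim_frac: float
    strata: list[StratumReport] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def filter_dataset(
    records: Sequence[MutationRecord],
    max_abs_dtm: float = 20.0,
    max_resolution: float = 2.5,
) -> tuple[list[MutationRecord], list[tuple[MutationRecord, str]]]:
    """Apply the curation rules; each rejection is labelled with the first
    failing rule.  An all-rejected outcome is valid."""
    kept: list[MutationRecord] = []
    rejected: list[tuple[MutationRecord, str]] = []
    for rec in records:
        reason: str | None = None
        if not rec.monomeric:
            reason = "monomeric"
        elif rec.resolution is None or rec.resolution >= max_resolution:
            reason = "resolution"
        elif not rec.no_denaturants:
            reason = "denaturant"
        elif not rec.two_state:
            reason = "two_state"
        elif rec.n_substitutions != 1:
            reason = "multi_point"
        elif rec.dtm_exp is None:
            reason = "missing_dtm"
        elif abs(rec.dtm_exp) > max_abs_dtm:
            reason = "dtm_magnitude"
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((rec, reason))
    return kept, rejected


def merge_duplicates(
    records: Sequence[MutationRecord], ph_tolerance: float = 0.5
) -> list[MutationRecord]:
    """Collapse replicate measurements of the same mutation.

    Within a duplicate group, only the entries measured at pH closest to 7
    (within ``ph_tolerance`` units of the closest) are retained and their
    dTm values averaged with equal weights.  Records without a pH are
    treated as measured at pH 7.
    """
    groups: dict[tuple, list[MutationRecord]] = {}
    order: list[tuple] = []
    for rec in records:
        if rec.key not in groups:
            groups[rec.key] = []
            order.append(rec.key)
        groups[rec.key].append(rec)
    merged: list[MutationRecord] = []
    for key in order:
        group = groups[key]
        if len(group) == 1:
            merged.append(group[0])
            continue
        dist = [abs((r.ph if r.ph is not None else 7.0) - 7.0) for r in group]
        closest = min(dist)
        chosen = [r for r, d in zip(group, dist) if d <= closest + ph_tolerance]
        with_dtm = [r.dtm_exp for r in chosen if r.dtm_exp is not None]
        rep = chosen[0]
        rep = MutationRecord(
            protein_id=rep.protein_id, chain=rep.chain, position=rep.position,
            wt_aa=rep.wt_aa, mut_aa=rep.mut_aa,
            dtm_exp=float(np.mean(with_dtm)) if with_dtm else None,
            tm_wild=rep.tm_wild, ph=rep.ph, resolution=rep.resolution,
            monomeric=rep.monomeric, no_denaturants=rep.no_denaturants,
            two_state=rep.two_state, n_substitutions=rep.n_substitutions,
            provenance=[
                f"merged {len(chosen)}/{len(group)} replicates at pH nearest 7"
            ],
        )
        merged.append(rep)
    return merged


def _pearson(pred: np.ndarray, exp: np.ndarray) -> float | None:
    if len(pred) < 2 or np.std(exp) == 0 or np.std(pred) == 0:
        return None
    return float(stats.pearsonr(pred, exp)[0])


def evaluate(
    pred: Sequence[float],
    exp: Sequence[float],
    accessibility: Sequence[float] | None = None,
    trim_frac: float = 0.10,
) -> EvalReport:
    """sigma, r and their outlier-trimmed variants for a prediction batch.

    Trimming removes exactly ``floor(trim_frac * n)`` points with the
    largest absolute error (ties broken by dataset order), so the trimmed
    sigma can never exceed the raw one.
    """
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if pred.shape != exp.shape or pred.ndim != 1:
        raise ValueError("pred and exp must be equal-length 1-d sequences")
    n = len(pred)
    if n < 2:
        raise ValueError("need at least two points")
    err = np.abs(pred - exp)
    sigma = float(np.sqrt(np.mean((pred - exp) ** 2)))
    r = _pearson(pred, exp)
    n_trim = int(np.floor(trim_frac * n))
    keep = np.argsort(-err, kind="stable")[n_trim:] if n_trim else np.arange(n)
    sigma_t = float(np.sqrt(np.mean((pred[keep] - exp[keep]) ** 2)))
    r_t = _pearson(pred[keep], exp[keep])
    report = EvalReport(
        sigma=sigma, r=r, sigma_trimmed=sigma_t, r_trimmed=r_t,
        n_mut=n, trim_frac=trim_frac,
    )
    if accessibility is not None:
        acc = np.asarray(accessibility, dtype=float)
        for name, lo, hi in ACCESSIBILITY_STRATA:
            mask = (acc >= lo) & (acc < hi)
            if name == "surface":
                mask = acc >= lo
            m = int(mask.sum())
            if m == 0:
                continue
            s = float(np.sqrt(np.mean((pred[mask] - exp[mask]) ** 2)))
            spread = float(np.std(exp[mask]))
            report.strata.append(
                StratumReport(
                    name=name,
                    sigma=s,
                    r=_pearson(pred[mask], exp[mask]),
                    sigma_over_std=s / spread if spread > 0 else None,
                    n=m,
                )
            )
    return report


def make_estimator(model_kind: str, cfg: TrainConfig,
                   seed: int | None = None) -> _BaseNetRegressor:
    common = dict(
        n_restarts=cfg.n_restarts,
        max_iter=cfg.max_iter,
        learning_rate=cfg.learning_rate,
        early_stop_patience=cfg.early_stop_patience,
        validation_fraction=cfg.validation_fraction,
        optimizer=cfg.optimizer,
        random_state=cfg.seed if seed is None else seed,
    )
    if model_kind == "hot":
        return HotMusicRegressor(**common)
    if model_kind == "tm_hot":
        return TmHotMusicRegressor(**common)
    raise ValueError(f"unknown model kind {model_kind!r} (use 'hot' or 'tm_hot')")


def train(X, y, model_kind: str = "hot",
          cfg: TrainConfig | None = None) -> _BaseNetRegressor:
    """Fit one model on a feature matrix/frame; returns the fitted estimator
    (parameters of the best restart, early-stopped on the internal
    validation split)."""
    cfg = cfg or TrainConfig()
    est = make_estimator(model_kind, cfg)
    return est.fit(X, y)


@dataclass
class CVResult:
    fold_reports: list[EvalReport]
    pooled: EvalReport
    oof_pred: np.ndarray
    fold_assignment: np.ndarray
    estimators: list[_BaseNetRegressor]


def crossvalidate(
    X,
    y,
    model_kind: str = "hot",
    cfg: TrainConfig | None = None,
    accessibility: Sequence[float] | None = None,
) -> CVResult:
    """k-fold cross-validation with an inner train/validation split.

    The k test folds are disjoint and cover the dataset; within each fold
    the non-test remainder is split 8:1 into the actual training set and
    the early-stopping validation set, mutation-wise.  The pooled report
    concatenates the out-of-fold predictions.
    """
    cfg = cfg or TrainConfig()
    if isinstance(X, pd.DataFrame):
        X_arr = X
        n = len(X)
    else:
        X_arr = np.asarray(X, dtype=float)
        n = len(X_arr)
    y = np.asarray(y, dtype=float).ravel()
    if n < cfg.k_folds:
        raise ValueError("dataset smaller than the number of folds")
    kf = KFold(n_splits=cfg.k_folds, shuffle=True, random_state=cfg.seed)
    oof = np.full(n, np.nan)
    assignment = np.full(n, -1, dtype=int)
    fold_reports: list[EvalReport] = []
    fitted: list[_BaseNetRegressor] = []
    rng = np.random.default_rng(cfg.seed)
    for fold, (train_idx, test_idx) in enumerate(kf.split(np.arange(n))):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        est = make_estimator(model_kind, cfg, seed=fold_seed)
        # inner 8:1 split of the remainder = 80% / 10% of the full set
        inner_rng = np.random.default_rng(fold_seed)
        perm = inner_rng.permutation(len(train_idx))
        n_val = max(1, int(round(len(train_idx) / 9.0)))
        val_idx = train_idx[perm[:n_val]]
        tr_idx = train_idx[perm[n_val:]]

        def _take(idx):
            return X_arr.iloc[idx] if isinstance(X_arr, pd.DataFrame) else X_arr[idx]

        est.fit(_take(tr_idx), y[tr_idx], X_val=_take(val_idx), y_val=y[val_idx])
        pred = est.predict(_take(test_idx))
        oof[test_idx] = pred
        assignment[test_idx] = fold
        fitted.append(est)
        if len(test_idx) >= 2 and np.std(y[test_idx]) > 0:
            acc_fold = (
                np.asarray(accessibility, dtype=float)[test_idx]
                if accessibility is not None
                else None
            )
            fold_reports.append(evaluate(pred, y[test_idx], acc_fold))
    pooled = evaluate(
        oof, y,
        np.asarray(accessibility, dtype=float) if accessibility is not None else None,
    )
    return CVResult(
        fold_reports=fold_reports,
        pooled=pooled,
        oof_pred=oof,
        fold_assignment=assignment,
        estimators=fitted,
    )
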