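"""Nested stacked ridge age-prediction models and Monte Carlo CV comparison.

Four nested models of increasing spatio-spectral complexity are compared:
``total_power`` ⊂ ``alpha_power`` ⊂ ``power_spectrum`` ⊂ ``spatial_patterns``,
each including all feature sets of the previous one, plus a ``dummy``
mean-predicting baseline. Each feature set is summarised by a first-level
ridge regression (penalty chosen by efficient leave-one-out GCV over a log
grid); a second-level ridge combines the per-set out-of-fold predictions.
Stacking gives every feature set one input at the second level, so adding a
set can only help through genuine information, not extra dimensionality.

Models are scored with repeated random train/test splits (Monte Carlo CV,
default 100 splits at 10% test size); the identical split sequence is shared
across models so that per-split score differences and rank statistics
("better on k/n splits") are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.dummy import DummyRegressor
from sklearn.linear_model import RidgeCV
from sklearn.model_selection import KFold, ShuffleSplit, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features import BLOCK_SLICES, FeatureTable, geometric_mean_spd, tangent_vectors, unvec_symmetric

RIDGE_ALPHAS = np.logspace(-3, 5, 17)

#: cumulative nesting of feature sets per model
MODEL_SETS: dict[str, tuple[str, ...]] = {
    "dummy": (),
    "total_power": ("total",),
    "alpha_power": ("total", "alpha"),
    "power_spectrum": ("total", "alpha", "spectrum"),
    "spatial_patterns": ("total", "alpha", "spectrum", "spatial"),
}
MODEL_ORDER = ("total_power", "alpha_power", "power_spectrum", "spatial_patterns")


@dataclass(frozen=True)
class CVConfig:
    n_splits: int = 100
    test_fraction: float = 0.1
    base_seed: int = 42
    inner_folds: int = 10

    def splitter(self) -> ShuffleSplit:
        return ShuffleSplit(
            n_splits=self.n_splits, test_size=self.test_fraction,
            random_state=self.base_seed,
        )


class _ColumnBlock(TransformerMixin, BaseEstimator):
    """Select one feature block (column slice) from the design matrix."""

    def __init__(self, columns: slice):
        self.columns = columns

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return X[:, self.columns]


class TangentTransformer(TransformerMixin, BaseEstimator):
    """Re-map vectorized band covariances through a tangent reference fitted
    on the training data (per-band affine-invariant geometric mean)."""

    def fit(self, X, y=None):
        covs = unvec_symmetric(X.reshape(X.shape[0], 5, 10))
        self.reference_ = np.stack(
            [geometric_mean_spd(covs[:, b]) for b in range(5)]
        )
        return self

    def transform(self, X):
        covs = unvec_symmetric(X.reshape(X.shape[0], 5, 10))
        out = [tangent_vectors(covs[:, b], self.reference_[b]) for b in range(5)]
        return np.concatenate(out, axis=1)


def _set_pipeline(name: str, columns: slice) -> Pipeline:
    steps = [("block", _ColumnBlock(columns))]
    if name == "spatial":
        steps.append(("tangent", TangentTransformer()))
    steps += [
        ("scale", StandardScaler()),
        ("ridge", RidgeCV(alphas=RIDGE_ALPHAS)),
    ]
    return Pipeline(steps)


class StackedRidge(RegressorMixin, BaseEstimator):
    """Two-level stacked ridge over named feature blocks.

    Level 1: one ridge pipeline per feature set, with out-of-fold predictions
    from an internal shuffled K-fold. Level 2: ridge over the per-set
    out-of-fold predictions. With a single feature set this degenerates to a
    linear recalibration of the plain ridge model.

    ``blocks`` maps set names to column slices of the design matrix
    (defaults to the standard layout); the ``spatial`` block is routed
    through the fold-fitted tangent re-mapping.
    """

    def __init__(self, sets: tuple[str, ...], inner_folds: int = 10, seed: int = 0,
                 blocks: dict | None = None):
        self.sets = sets
        self.inner_folds = inner_folds
        self.seed = seed
        self.blocks = blocks

    def _blocks(self) -> dict:
        return BLOCK_SLICES if self.blocks is None else self.blocks

    def fit(self, X, y):
        X, y = np.asarray(X, dtype=float), np.asarray(y, dtype=float)
        if len(y) < self.inner_folds:
            raise ValueError(
                f"need at least {self.inner_folds} training patients, got {len(y)}"
            )
        blocks = self._blocks()
        cv = KFold(self.inner_folds, shuffle=True, random_state=self.seed)
        oof = np.column_stack([
            cross_val_predict(_set_pipeline(s, blocks[s]), X, y, cv=cv)
            for s in self.sets
        ])
        self.level1_ = [
            _set_pipeline(s, blocks[s]).fit(X, y) for s in self.sets
        ]
        self.level2_ = RidgeCV(alphas=RIDGE_ALPHAS).fit(oof, y)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        Z = np.column_stack([p.predict(X) for p in self.level1_])
        return self.level2_.predict(Z)


def build_model(name: str, inner_folds: int = 10, seed: int = 0):
    """Instantiate a model by its nesting name (or the dummy baseline)."""
    if name == "dummy":
        return DummyRegressor(strategy="mean")
    if name not in MODEL_SETS:
        raise ValueError(f"unknown model {name!r}; pick from {sorted(MODEL_SETS)}")
    return StackedRidge(MODEL_SETS[name], inner_folds=inner_folds, seed=seed)


def _score(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    err = np.abs(y_true - y_pred)
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return float(err.mean()), r2


def crossval_scores(
    model_name: str, table: FeatureTable, cv: CVConfig = CVConfig()
) -> pd.DataFrame:
    """Monte Carlo CV scores: one (MAE, R²) row per split.

    All fitting — penalty selection, scaling, and the tangent reference —
    happens inside the training fold of each split.
    """
    X, y = table.design_matrix(), table.age_yr
    rows = []
    for split_id, (tr, te) in enumerate(cv.splitter().split(X)):
        model = build_model(model_name, cv.inner_folds, seed=cv.base_seed + split_id)
        model.fit(X[tr], y[tr])
        mae, r2 = _score(y[te], model.predict(X[te]))
        rows.append({"model": model_name, "split": split_id, "mae": mae, "r2": r2})
    return pd.DataFrame(rows)


PERCENTILES = (2.5, 25.0, 75.0, 97.5)


def _pcts(x: np.ndarray) -> dict[str, float]:
    vals = np.percentile(x, PERCENTILES)  # linear interpolation convention
    return {f"p{p:g}": float(v) for p, v in zip(PERCENTILES, vals)}


@dataclass
class ComparisonResult:
    """Paired model comparison across shared CV splits."""

    model_a: str
    model_b: str
    n_splits: int
    superiority_a: int               # splits where a strictly beats b (lower MAE)
    delta_mae: np.ndarray            # per split, mae_a - mae_b
    delta_percentiles: dict[str, float] = field(default_factory=dict)
    mae_a_percentiles: dict[str, float] = field(default_factory=dict)
    mae_b_percentiles: dict[str, float] = field(default_factory=dict)

    @property
    def median_delta(self) -> float:
        return float(np.median(self.delta_mae))

    def summary(self) -> dict:
        return {
            "model_a": self.model_a, "model_b": self.model_b,
            "n_splits": self.n_splits, "superiority_a": self.superiority_a,
            "median_delta_mae": self.median_delta,
            "delta": self.delta_percentiles,
            "mae_a": self.mae_a_percentiles, "mae_b": self.mae_b_percentiles,
        }


def compare(scores_a: pd.DataFrame, scores_b: pd.DataFrame) -> ComparisonResult:
    """Pairwise rank comparison of two models scored on identical splits."""
    a = scores_a.sort_values("split").reset_index(drop=True)
    b = scores_b.sort_values("split").reset_index(drop=True)
    if not np.array_equal(a["split"].to_numpy(), b["split"].to_numpy()):
        raise ValueError("mismatched split ids; models must share the CV splits")
    delta = a["mae"].to_numpy() - b["mae"].to_numpy()
    return ComparisonResult(
        model_a=str(a["model"].iloc[0]), model_b=str(b["model"].iloc[0]),
        n_splits=len(delta),
        superiority_a=int(np.sum(delta < 0)),
        delta_mae=delta,
        delta_percentiles=_pcts(delta),
        mae_a_percentiles=_pcts(a["mae"].to_numpy()),
        mae_b_percentiles=_pcts(b["mae"].to_numpy()),
    )


def predict_brain_age(
    train: FeatureTable, apply: FeatureTable | None,
    model_name: str = "spatial_patterns", cv: CVConfig = CVConfig(),
) -> pd.DataFrame:
    """Cross-validated brain-age table.

    Reference (train) patients receive out-of-fold predictions from a
    K-fold; held-out (apply) patients receive predictions from a model
    refit on the full reference set. The concatenated table is the input to
    the burst-suppression analysis.
    """
    if apply is not None and len(apply):
        overlap = np.intersect1d(train.patient_id, apply.patient_id)
        if overlap.size:
            raise ValueError(f"patients in both train and apply sets: {overlap[:5]}")
    X, y = train.design_matrix(), train.age_yr
    kf = KFold(cv.inner_folds, shuffle=True, random_state=cv.base_seed)
    oof = np.full(len(y), np.nan)
    for tr, te in kf.split(X):
        model = build_model(model_name, cv.inner_folds, seed=cv.base_seed)
        oof[te] = model.fit(X[tr], y[tr]).predict(X[te])
    parts = [pd.DataFrame({
        "patient_id": train.patient_id, "age_yr": train.age_yr,
        "brain_age_yr": oof, "source": "cross_validated",
        "drug": train.drug, "asa": train.asa,
        "bs_proportion": train.bs_proportion,
    })]
    if apply is not None and len(apply):
        full = build_model(model_name, cv.inner_folds, seed=cv.base_seed).fit(X, y)
        parts.append(pd.DataFrame({
            "patient_id": apply.patient_id, "age_yr": apply.age_yr,
            "brain_age_yr": full.predict(apply.design_matrix()),
            "source": "extrapolated",
            "drug": apply.drug, "asa": apply.asa,
            "bs_proportion": apply.bs_proportion,
        }))
    return pd.concat(parts, ignore_index=True)


def drug_generalization(
    table: FeatureTable, cv: CVConfig = CVConfig(),
    model_name: str = "spatial_patterns",
) -> pd.DataFrame:
    """Within-drug, cross-drug, and pooled age-prediction scores.

    Per split, each drug group is independently split into train/test with
    the shared seed; three models are fitted (propofol-train, sevoflurane-
    train, pooled-train) and evaluated on the within, crossed, pooled, and
    per-drug pooled test sets, giving seven paired score rows per split.
    """
    drugs = np.asarray(table.drug)
    idx_p, idx_s = np.flatnonzero(drugs == "propofol"), np.flatnonzero(drugs == "sevoflurane")
    if idx_p.size == 0 or idx_s.size == 0:
        raise ValueError("both drug groups must be non-empty")
    X, y = table.design_matrix(), table.age_yr
    sp_p = ShuffleSplit(cv.n_splits, test_size=cv.test_fraction, random_state=cv.base_seed)
    sp_s = ShuffleSplit(cv.n_splits, test_size=cv.test_fraction, random_state=cv.base_seed + 1)
    rows = []
    for split_id, ((trp, tep), (trs, tes)) in enumerate(
        zip(sp_p.split(idx_p), sp_s.split(idx_s))
    ):
        trp, tep = idx_p[trp], idx_p[tep]
        trs, tes = idx_s[trs], idx_s[tes]
        seed = cv.base_seed + split_id
        m_p = m_s = None
        if trp.size >= cv.inner_folds:
            m_p = build_model(model_name, cv.inner_folds, seed).fit(X[trp], y[trp])
        if trs.size >= cv.inner_folds:
            m_s = build_model(model_name, cv.inner_folds, seed).fit(X[trs], y[trs])
        tr_pool = np.concatenate([trp, trs])
        te_pool = np.concatenate([tep, tes])
        m_pool = build_model(model_name, cv.inner_folds, seed).fit(X[tr_pool], y[tr_pool])
        cells: dict[str, tuple[np.ndarray | None, np.ndarray]] = {
            "within_propofol": (m_p and m_p.predict(X[tep]), y[tep]),
            "within_sevoflurane": (m_s and m_s.predict(X[tes]), y[tes]),
            "propofol_to_sevoflurane": (m_p and m_p.predict(X[tes]), y[tes]),
            "sevoflurane_to_propofol": (m_s and m_s.predict(X[tep]), y[tep]),
            "pooled": (m_pool.predict(X[te_pool]), y[te_pool]),
            "pooled_on_propofol": (m_pool.predict(X[tep]), y[tep]),
            "pooled_on_sevoflurane": (m_pool.predict(X[tes]), y[tes]),
        }
        for cell, (pred, truth) in cells.items():
            if pred is None:    # drug group smaller than the internal folds
                mae = r2 = np.nan
            else:
                mae, r2 = _score(truth, pred)
            rows.append({
                "cell": cell, "split": split_id, "mae": mae, "r2": r2,
                "n_test": truth.size,
            })
    return pd.DataFrame(rows)
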