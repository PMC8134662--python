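"""Nested two-stage epsilon-SVR outcome models and the stratified split.

The nested predictor is

    NIHSS_30d ~ clinical features + (NIHSS_48h ~ imaging features)

an inner RBF-kernel support-vector regressor maps imaging features to the
48-hour NIHSS; its prediction joins the clinical features as one extra
column of the outer regressor for the 30-day NIHSS.  Using the short-term
score as the inner target keeps region selection tied to the primary
stroke-induced deficit and breaks the collinearity between baseline
severity and the long-term outcome.  During training the inner predictions
fed to the outer model are out-of-fold (k-fold within the training set), so
the outer model sees inner predictions of honest, test-like quality.

All standardization constants come from training rows only.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

NIHSS_MIN, NIHSS_MAX = 0.0, 42.0

CLINICAL_FEATURES = [
    "age",
    "sex",
    "nihss_baseline",
    "glucose",
    "hematocrit",
    "sbp",
    "afib",
    "htn",
    "hld",
    "treatment",
    "onset_to_admission_min",
]

DEFAULT_HYPERPARAMS = {"C": 1.0, "epsilon": 0.1, "gamma": "scale"}


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    """Deterministic stratified 80/20 partition of the cohort."""

    train_ids: list
    test_ids: list
    strata: pd.Series  # stratum label per patient id
    seed: int

    def __post_init__(self):
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


def stratified_split(
    y_30d: pd.Series,
    train_frac: float = 0.8,
    n_bins: int = 4,
    seed: int = 0,
) -> SplitSpec:
    """Split preserving the representation of stroke severity.

    Strata are quantile bins of the 30-day NIHSS (default quartiles); bins
    with fewer than 2 patients are merged into their lower neighbour.  The
    global test count is round((1−train_frac)·n); per-stratum test counts
    are the exact proportional quotas rounded with largest-remainder
    correction so the global count is hit exactly.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0,1)")
    y = pd.Series(y_30d).astype(float)
    n = len(y)
    if n < 2 * n_bins:
        raise ValueError("need at least 2 patients per stratum")

    edges = np.unique(np.quantile(y, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:
        raise ValueError("outcome is constant; cannot stratify")
    strata = pd.cut(y, bins=edges, labels=False, include_lowest=True)

    # merge any stratum with < 2 patients into its lower neighbour
    counts = strata.value_counts()
    for lab in sorted(counts.index):
        if counts[lab] < 2:
            target = lab - 1 if lab > 0 else lab + 1
            warnings.warn(
                f"stratum {lab} has {counts[lab]} patient(s); merging into {target}"
            )
            strata = strata.replace(lab, target)
            counts = strata.value_counts()

    n_test = int(round((1.0 - train_frac) * n))
    labels = sorted(strata.unique())
    quotas = {lab: (1.0 - train_frac) * (strata == lab).sum() for lab in labels}
    base = {lab: int(np.floor(q)) for lab, q in quotas.items()}
    remainder = n_test - sum(base.values())
    frac_order = sorted(labels, key=lambda lab: (-(quotas[lab] - base[lab]), lab))
    for lab in frac_order[: max(remainder, 0)]:
        base[lab] += 1
    # guard: never ask for more test patients than a stratum holds
    for lab in labels:
        base[lab] = min(base[lab], int((strata == lab).sum()) - 1)

    rng = np.random.default_rng(seed)
    test_ids: list = []
    for lab in labels:
        members = list(y.index[strata == lab])
        pick = rng.choice(len(members), size=base[lab], replace=False)
        test_ids.extend(members[i] for i in sorted(pick))
    test_set = set(test_ids)
    train_ids = [i for i in y.index if i not in test_set]
    return SplitSpec(train_ids=train_ids, test_ids=test_ids, strata=strata, seed=seed)


@dataclasses.dataclass
class FittedSVR:
    """Standardize-then-SVR pipeline plus its training manifest."""

    pipeline: Pipeline
    feature_names: list[str]
    dropped_constant: list[str]
    hyperparams: dict

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise KeyError(f"missing feature column(s): {missing}")
        return self.pipeline.predict(X[self.feature_names].to_numpy(dtype=float))


def fit_svr(X: pd.DataFrame, y, hyperparams: dict | None = None) -> FittedSVR:
    """Epsilon-SVR with RBF kernel on standardized features.

    Unstated-in-the-field defaults: C=1, epsilon=0.1, gamma='scale'
    (1/(d·Var)).  Constant feature columns are dropped with a warning
    (zero variance breaks standardization); a constant target is an error.
    """
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    X = pd.DataFrame(X)
    ya = np.asarray(y, dtype=float)
    if X.isna().any().any() or not np.all(np.isfinite(ya)):
        raise ValueError("missing values in features or target")
    if np.unique(ya).size < 2:
        raise ValueError("constant target: nothing to regress")
    variances = X.var(axis=0, ddof=0)
    constant = list(variances.index[variances == 0.0])
    if constant:
        warnings.warn(f"dropping constant feature column(s): {constant}")
        X = X.drop(columns=constant)
    if X.shape[1] == 0:
        raise ValueError("no non-constant features left")
    pipe = Pipeline(
        [("scale", StandardScaler()), ("svr", SVR(kernel="rbf", **hp))]
    )
    pipe.fit(X.to_numpy(dtype=float), ya)
    return FittedSVR(
        pipeline=pipe,
        feature_names=list(X.columns),
        dropped_constant=constant,
        hyperparams=hp,
    )


class _MeanPredictor:
    """Degenerate inner model used when the selected ROI set is empty."""

    def __init__(self, mean: float):
        self.mean = float(mean)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.full(len(X), self.mean)


@dataclasses.dataclass
class NestedModelFit:
    inner: FittedSVR | _MeanPredictor
    outer: FittedSVR
    imaging_features: list[str]
    clinical_features: list[str]
    inner_oof: bool

    @property
    def outer_input_dim(self) -> int:
        return len(self.clinical_features) + 1


INNER_PRED_COL = "nihss_48h_pred"


def fit_nested(
    clinical_X: pd.DataFrame,
    imaging_X: pd.DataFrame,
    y_48h: pd.Series,
    y_30d: pd.Series,
    train_ids: list,
    hyperparams: dict | None = None,
    oof: bool = True,
    n_folds: int = 5,
    seed: int = 0,
) -> NestedModelFit:
    """Fit the two-stage model on the training rows.

    ``imaging_X`` must already be restricted to the selected ROI features.
    With ``oof=True`` the inner predictions used as the outer model's
    training column come from k-fold cross-fitting within the training set;
    ``oof=False`` uses in-sample inner predictions.
    """
    if len(train_ids) < 2:
        raise ValueError("need at least 2 training patients")
    cX = clinical_X.loc[train_ids]
    iX = imaging_X.loc[train_ids]
    y48 = y_48h.loc[train_ids].astype(float)
    y30 = y_30d.loc[train_ids].astype(float)

    degenerate = iX.shape[1] == 0 or (iX.var(axis=0, ddof=0) == 0.0).all()
    if degenerate:
        warnings.warn(
            "selected ROI feature set is empty/constant; inner model predicts "
            "the training-mean 48-hour NIHSS"
        )
        inner: FittedSVR | _MeanPredictor = _MeanPredictor(y48.mean())
        inner_train_pred = np.full(len(train_ids), y48.mean())
    else:
        inner = fit_svr(iX, y48, hyperparams)
        if oof and len(train_ids) >= n_folds:
            inner_train_pred = np.empty(len(train_ids))
            kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
            rows = np.arange(len(train_ids))
            for tr, te in kf.split(rows):
                fold_fit = fit_svr(iX.iloc[tr], y48.iloc[tr], hyperparams)
                inner_train_pred[te] = fold_fit.predict(iX.iloc[te])
        else:
            inner_train_pred = inner.predict(iX)

    outer_X = cX.copy()
    outer_X[INNER_PRED_COL] = inner_train_pred
    outer = fit_svr(outer_X, y30, hyperparams)
    return NestedModelFit(
        inner=inner,
        outer=outer,
        imaging_features=list(imaging_X.columns),
        clinical_features=list(clinical_X.columns),
        inner_oof=bool(oof),
    )


@dataclasses.dataclass(frozen=True)
class PredictionSet:
    frame: pd.DataFrame  # columns: patient_id, observed (optional), predicted

    @property
    def predicted(self) -> np.ndarray:
        return self.frame["predicted"].to_numpy()

    @property
    def observed(self) -> np.ndarray:
        return self.frame["observed"].to_numpy()


def _clamp(pred: np.ndarray) -> np.ndarray:
    return np.clip(pred, NIHSS_MIN, NIHSS_MAX)


def predict_nested(
    fit: NestedModelFit,
    clinical_X: pd.DataFrame,
    imaging_X: pd.DataFrame,
    ids: list,
    observed: pd.Series | None = None,
) -> PredictionSet:
    """Apply inner then outer model; 30-day predictions clamped to [0, 42]."""
    cX = clinical_X.loc[ids]
    iX = imaging_X.loc[ids]
    missing = [c for c in fit.imaging_features if c not in iX.columns]
    if missing:
        raise KeyError(f"missing imaging feature column(s): {missing}")
    if isinstance(fit.inner, _MeanPredictor):
        inner_pred = fit.inner.predict(iX)
    else:
        inner_pred = fit.inner.predict(iX)
    outer_X = cX.copy()
    outer_X[INNER_PRED_COL] = inner_pred
    pred = _clamp(fit.outer.predict(outer_X))
    frame = pd.DataFrame({"patient_id": list(ids), "predicted": pred})
    if observed is not None:
        frame["observed"] = observed.loc[ids].to_numpy(dtype=float)
    return PredictionSet(frame=frame)


def fit_clinical_only(
    clinical_X: pd.DataFrame,
    y_30d: pd.Series,
    train_ids: list,
    hyperparams: dict | None = None,
) -> FittedSVR:
    """Un-nested clinical baseline (feature selection is the caller's job)."""
    return fit_svr(clinical_X.loc[train_ids], y_30d.loc[train_ids].astype(float), hyperparams)


def predict_clinical(
    fit: FittedSVR,
    clinical_X: pd.DataFrame,
    ids: list,
    observed: pd.Series | None = None,
) -> PredictionSet:
    pred = _clamp(fit.predict(clinical_X.loc[ids]))
    frame = pd.DataFrame({"patient_id": list(ids), "predicted": pred})
    if observed is not None:
        frame["observed"] = observed.loc[ids].to_numpy(dtype=float)
    return PredictionSet(frame=frame)


def encode_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Model-ready clinical feature table indexed by patient_id.

    Sex becomes a binary indicator (M=1); binary risk factors stay 0/1;
    continuous covariates are passed through (standardization happens
    inside the SVR pipeline on training statistics).
    """
    X = clinical.set_index("patient_id").copy()
    X["sex"] = (X["sex"] == "M").astype(float)
    return X[CLINICAL_FEATURES].astype(float)
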