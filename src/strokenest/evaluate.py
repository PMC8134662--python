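"""Metrics, model comparison, and the end-to-end three-arm experiment.

Three predictors of the 30-day NIHSS are compared on one shared stratified
train/test split:

* ``clinical`` — un-nested SVR on RReliefF-selected clinical features;
* ``relief``  — nested SVR whose imaging regions are selected by RReliefF
  against the 48-hour NIHSS;
* ``lsm``     — nested SVR whose imaging regions come from voxel-wise
  Brunner-Munzel lesion-symptom mapping of the 48-hour NIHSS.

Reported per model: MAE, RMSE, R² = 1 − SSres/SStot on the test set (can be
negative), and a model p-value defined as the two-sided test of zero linear
association between predicted and observed test scores.  Pairwise MAE
differences are tested with the two-sided paired Wilcoxon signed-rank on
per-patient absolute errors (NIHSS errors are non-normal and test sets are
small).  All region selection and model fitting see training rows only.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import features as features_mod
from . import lsm as lsm_mod
from . import model as model_mod
from . import relieff as relieff_mod
from .atlas import ToyAtlas
from .simulate import (
    SimulatedCohort,
    SimulationConfig,
    default_atlas,
    default_config_for_atlas,
    simulate_cohort,
)

ARMS = ("clinical", "relief", "lsm")


def _check_pair(observed, predicted, min_n=2):
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError("observed and predicted lengths differ")
    if o.size < min_n:
        raise ValueError(f"need at least {min_n} observations")
    return o, p


def mae(observed, predicted) -> float:
    o, p = _check_pair(observed, predicted)
    return float(np.mean(np.abs(o - p)))


def rmse(observed, predicted) -> float:
    o, p = _check_pair(observed, predicted)
    return float(np.sqrt(np.mean((o - p) ** 2)))


def r2(observed, predicted) -> float:
    """Coefficient of determination 1 − SSres/SStot (test-set definition)."""
    o, p = _check_pair(observed, predicted)
    ss_tot = np.sum((o - o.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("observed scores are constant; R² undefined")
    return float(1.0 - np.sum((o - p) ** 2) / ss_tot)


def model_pvalue(observed, predicted) -> float:
    """Two-sided p for zero linear association between predicted and observed."""
    o, p = _check_pair(observed, predicted, min_n=3)
    if np.unique(p).size < 2 or np.unique(o).size < 2:
        warnings.warn("constant predictions or observations; p-value set to 1")
        return 1.0
    return float(stats.pearsonr(o, p).pvalue)


def compare_mae(abs_errors_a, abs_errors_b) -> float:
    """Paired two-sided Wilcoxon signed-rank p on per-patient absolute errors."""
    a = np.asarray(abs_errors_a, dtype=float)
    b = np.asarray(abs_errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("error vectors must be paired (same patients)")
    diff = a - b
    if np.all(diff == 0):
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ExperimentConfig:
    """Everything the three-arm comparison needs, in one place."""

    seed: int = 0
    n_patients: int = 221
    atlas_shape: tuple[int, int, int] = (32, 32, 32)
    n_gm_regions: int = 24
    n_wm_tracts: int = 6
    sim_overrides: dict = dataclasses.field(default_factory=dict)
    train_frac: float = 0.8
    n_strata: int = 4
    alpha: float = 0.05
    coverage_threshold: float = 0.10
    # Relief sample size for both selection passes.  None = exhaustive
    # (deterministic one pass over every training instance): at toy scale,
    # with a few dozen feature columns, the m=10 sampled estimate's variance
    # would dominate the arm comparison the experiment is designed to make.
    relieff_m: int | None = None
    relieff_k: int = 5
    hyperparams: dict | None = None
    oof: bool = True

    def simulation_config(self, atlas: ToyAtlas) -> SimulationConfig:
        return default_config_for_atlas(
            atlas, n_patients=self.n_patients, seed=self.seed, **self.sim_overrides
        )


class ExperimentStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"experiment stage {stage!r} failed: {cause}")
        self.stage = stage


def run_experiment(
    config: ExperimentConfig,
    cohort: SimulatedCohort | None = None,
) -> dict:
    """Simulate (unless a cohort is given), split, select, fit, evaluate.

    Returns a JSON-serializable report: per-arm metrics, pairwise MAE
    comparison p-values, ROI counts, and run metadata.  Deterministic for a
    fixed config.
    """
    stage = "simulate"
    try:
        if cohort is None:
            atlas = default_atlas(
                seed=config.seed,
                grid_shape=config.atlas_shape,
                n_gm_regions=config.n_gm_regions,
                n_wm_tracts=config.n_wm_tracts,
            )
            sim_cfg = config.simulation_config(atlas)
            cohort = simulate_cohort(sim_cfg, atlas)
        atlas = cohort.atlas
        clinical = cohort.clinical
        y48 = clinical.set_index("patient_id")["nihss_48h"].astype(float)
        y30 = clinical.set_index("patient_id")["nihss_30d"].astype(float)
        clinical_X = model_mod.encode_clinical(clinical)

        stage = "split"
        split = model_mod.stratified_split(
            y30, train_frac=config.train_frac, n_bins=config.n_strata,
            seed=config.seed,
        )
        train_ids, test_ids = split.train_ids, split.test_ids
        id_index = {pid: i for i, pid in enumerate(cohort.patient_ids)}
        train_rows = [id_index[i] for i in train_ids]
        train_masks = cohort.lesions[train_rows]

        # ---- clinical feature selection (target: 30-day NIHSS, train only)
        stage = "clinical-selection"
        cw = relieff_mod.rrelieff(
            clinical_X.loc[train_ids], y30.loc[train_ids],
            m=config.relieff_m, k=config.relieff_k, seed=config.seed,
        )
        clinical_selected = relieff_mod.select_features(cw)
        if not clinical_selected:  # degenerate draw: fall back to all features
            warnings.warn("Relief selected no clinical feature; keeping all")
            clinical_selected = list(clinical_X.columns)
        clin_sel_X = clinical_X[clinical_selected]

        # ---- imaging arm A: Relief on coverage-filtered region features
        stage = "relief-selection"
        retained_regions = features_mod.coverage_filter(
            train_masks, unit="region",
            threshold=config.coverage_threshold, atlas=atlas,
        )
        fm_all = features_mod.build_feature_matrix(
            cohort.lesions, cohort.patient_ids, atlas, retained_regions
        )
        if fm_all.values.shape[1] > 0:
            iw = relieff_mod.rrelieff(
                fm_all.values.loc[train_ids], y48.loc[train_ids],
                m=config.relieff_m, k=config.relieff_k, seed=config.seed,
            )
            relief_cols = relieff_mod.select_features(iw)
        else:
            relief_cols = []
        relief_regions = relieff_mod.regions_from_selected(relief_cols, fm_all.manifest)
        relief_X = features_mod.build_feature_matrix(
            cohort.lesions, cohort.patient_ids, atlas, relief_regions
        ).values

        # ---- imaging arm B: LSM ROIs (train masks + train 48h scores only)
        stage = "lsm-selection"
        _, _, lsm_regions = lsm_mod.run_lsm(
            train_masks, y48.loc[train_ids].to_numpy(), atlas,
            alpha=config.alpha, coverage_threshold=config.coverage_threshold,
        )
        lsm_X = features_mod.build_feature_matrix(
            cohort.lesions, cohort.patient_ids, atlas, lsm_regions
        ).values

        # ---- fits
        stage = "fit"
        fit_clin = model_mod.fit_clinical_only(
            clin_sel_X, y30, train_ids, config.hyperparams
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty-ROI warnings already surfaced
            fit_relief = model_mod.fit_nested(
                clin_sel_X, relief_X, y48, y30, train_ids,
                config.hyperparams, oof=config.oof, seed=config.seed,
            )
            fit_lsm = model_mod.fit_nested(
                clin_sel_X, lsm_X, y48, y30, train_ids,
                config.hyperparams, oof=config.oof, seed=config.seed,
            )

        # ---- test-set evaluation
        stage = "evaluate"
        preds = {
            "clinical": model_mod.predict_clinical(fit_clin, clin_sel_X, test_ids, y30),
            "relief": model_mod.predict_nested(fit_relief, clin_sel_X, relief_X, test_ids, y30),
            "lsm": model_mod.predict_nested(fit_lsm, clin_sel_X, lsm_X, test_ids, y30),
        }
        per_model = {}
        abs_errors = {}
        for arm, ps in preds.items():
            o, p = ps.observed, ps.predicted
            per_model[arm] = {
                "mae": mae(o, p),
                "rmse": rmse(o, p),
                "r2": r2(o, p),
                "p_value": model_pvalue(o, p),
            }
            abs_errors[arm] = np.abs(o - p)
        pairwise = {}
        for a, b in (("clinical", "relief"), ("clinical", "lsm"), ("relief", "lsm")):
            pairwise[f"{a}_vs_{b}"] = compare_mae(abs_errors[a], abs_errors[b])

        report = {
            "models": per_model,
            "mae_difference_p": pairwise,
            "roi_counts": {
                "relief": len(relief_regions),
                "lsm": len(lsm_regions),
                "coverage_retained": len(retained_regions),
            },
            "selected": {
                "clinical_features": clinical_selected,
                "relief_regions": [int(r) for r in relief_regions],
                "lsm_regions": [int(r) for r in lsm_regions],
            },
            "metadata": {
                "seed": config.seed,
                "n_patients": int(config.n_patients),
                "n_train": len(train_ids),
                "n_test": len(test_ids),
                "alpha": config.alpha,
                "coverage_threshold": config.coverage_threshold,
                "relieff_m": config.relieff_m,
                "relieff_k": config.relieff_k,
            },
        }
    except Exception as exc:  # noqa: BLE001 - re-raise with the failing stage named
        if isinstance(exc, ExperimentStageError):
            raise
        raise ExperimentStageError(stage, exc) from exc

    for arm, met in report["models"].items():
        assert met["mae"] <= met["rmse"] + 1e-12, f"MAE > RMSE for {arm}"
    return report


def render_table(report: dict) -> str:
    """Human-readable performance table (Model, MAE, RMSE, R², p-value)."""
    lines = [f"{'Model':<12}{'MAE':>8}{'RMSE':>8}{'R2':>8}{'p-value':>12}"]
    for arm in ARMS:
        m = report["models"][arm]
        lines.append(
            f"{arm:<12}{m['mae']:>8.2f}{m['rmse']:>8.2f}{m['r2']:>8.2f}"
            f"{m['p_value']:>12.3g}"
        )
    rc = report["roi_counts"]
    lines.append(f"ROIs: relief={rc['relief']}  lsm={rc['lsm']}")
    return "\n".join(lines)


def save_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
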