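"""Voxel-wise lesion-symptom mapping of the 48-hour NIHSS.

At every brain voxel lesioned in enough patients, the 48-hour scores of the
lesioned group are compared with the intact group using the Brunner-Munzel
rank test (robust to ties and unequal variances); the resulting two-sided
p-values are corrected for multiple comparisons with the Benjamini-Hochberg
false-discovery-rate procedure; voxels surviving q <= alpha receive weight
|W|, and every atlas region containing at least one non-zero-weight voxel
becomes a region of interest for the downstream predictive models.

The per-voxel statistic uses mid-ranks.  With group sizes n1, n2, pooled
mid-ranks R, within-group mid-ranks R(i), group means R̄i and

    Si² = 1/(ni−1) · Σk (Rik − R(i)ik − R̄i + (ni+1)/2)²

the statistic and Satterthwaite-style degrees of freedom are

    W  = n1·n2·(R̄2 − R̄1) / ((n1+n2)·sqrt(n1·S1² + n2·S2²))
    df = (n1·S1² + n2·S2²)² / ((n1·S1²)²/(n1−1) + (n2·S2²)²/(n2−1))

with a two-sided p from the t distribution.  ``bm_map`` evaluates these for
all voxels at once: because the pooled scores are shared across voxels, the
per-voxel group rank structure reduces to per-score-value lesion counts,
which are a single matrix product away.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import ToyAtlas
from .features import coverage_filter


class UntestableVoxelError(ValueError):
    """A group has fewer than 2 members; the rank variances are undefined."""


@dataclasses.dataclass(frozen=True)
class BMResult:
    statistic: float
    df: float
    pvalue: float
    degenerate: bool = False


def bm_test(scores_lesioned, scores_intact) -> BMResult:
    """Brunner-Munzel test of stochastic equality between two score samples.

    Positive W means the intact group tends to larger scores.  Complete
    separation (both within-group rank variances zero) is flagged
    ``degenerate`` with W = inf·sign and p left at the conservative 1.0.
    """
    x = np.asarray(scores_lesioned, dtype=float)
    y = np.asarray(scores_intact, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise UntestableVoxelError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    R = stats.rankdata(pooled)
    R1, R2 = R[:n1], R[n1:]
    r1 = stats.rankdata(x)
    r2 = stats.rankdata(y)
    Rbar1, Rbar2 = R1.mean(), R2.mean()
    S1 = np.sum((R1 - r1 - Rbar1 + (n1 + 1) / 2) ** 2) / (n1 - 1)
    S2 = np.sum((R2 - r2 - Rbar2 + (n2 + 1) / 2) ** 2) / (n2 - 1)
    pooled_var = n1 * S1 + n2 * S2
    if pooled_var == 0.0:
        if Rbar1 == Rbar2:  # identical constant samples: no evidence either way
            return BMResult(0.0, float("nan"), 1.0, degenerate=True)
        w = float(np.sign(Rbar2 - Rbar1) * np.inf)
        return BMResult(w, float("nan"), 1.0, degenerate=True)
    W = n1 * n2 * (Rbar2 - Rbar1) / ((n1 + n2) * np.sqrt(pooled_var))
    df = pooled_var**2 / ((n1 * S1) ** 2 / (n1 - 1) + (n2 * S2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(W), df)
    return BMResult(float(W), float(df), float(min(p, 1.0)))


@dataclasses.dataclass
class VoxelStatMap:
    """Voxel-wise LSM statistics on the atlas lattice."""

    tested_mask: np.ndarray      # bool grid: voxels actually tested
    statistic: np.ndarray        # float grid: W (0 outside tested_mask)
    p: np.ndarray                # float grid: two-sided p (1 outside)
    q: np.ndarray                # float grid: BH-adjusted p (1 outside)
    degenerate_mask: np.ndarray  # bool grid: zero-rank-variance voxels

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        eye = np.eye(4)
        nib.save(nib.Nifti1Image(self.statistic.astype(np.float32), eye),
                 out_dir / "statistic.nii.gz")
        nib.save(nib.Nifti1Image(self.p.astype(np.float32), eye),
                 out_dir / "p.nii.gz")
        nib.save(nib.Nifti1Image(self.q.astype(np.float32), eye),
                 out_dir / "q.nii.gz")
        nib.save(nib.Nifti1Image(self.tested_mask.astype(np.uint8), eye),
                 out_dir / "tested_mask.nii.gz")
        nib.save(nib.Nifti1Image(self.degenerate_mask.astype(np.uint8), eye),
                 out_dir / "degenerate_mask.nii.gz")


def _exclusive_cumsum(a: np.ndarray, axis: int = 0) -> np.ndarray:
    c = np.cumsum(a, axis=axis)
    return c - a


def bm_map(
    lesion_masks: np.ndarray,
    nihss_48h,
    coverage_threshold: float = 0.10,
    min_group: int = 2,
    alpha_correction: bool = True,
) -> VoxelStatMap:
    """Brunner-Munzel statistic, p and BH q at every testable voxel.

    A voxel is tested when it passes the lesion-coverage filter (lesioned in
    at least ``coverage_threshold`` of patients) and both the lesioned and
    intact groups have at least ``min_group`` members.  Groups are
    (lesioned, intact); the per-voxel statistic equals ``bm_test`` on the
    split of the score vector at that voxel.
    """
    masks = np.asarray(lesion_masks, dtype=bool)
    scores = np.asarray(nihss_48h, dtype=float)
    n = masks.shape[0]
    if n < 4:
        raise ValueError("need at least 4 patients for voxel-wise mapping")
    if scores.shape[0] != n:
        raise ValueError("one 48-hour score per patient required")
    grid_shape = masks.shape[1:]

    covered = coverage_filter(masks, unit="voxel", threshold=coverage_threshold)
    counts = masks.sum(axis=0)
    tested = covered & (counts >= min_group) & (n - counts >= min_group)
    tested_flat = tested.reshape(-1)
    L = masks.reshape(n, -1)[:, tested_flat].astype(np.float64)  # n × V
    V = L.shape[1]

    stat = np.zeros(grid_shape, dtype=float)
    p = np.ones(grid_shape, dtype=float)
    q = np.ones(grid_shape, dtype=float)
    degen = np.zeros(grid_shape, dtype=bool)
    if V == 0:
        return VoxelStatMap(tested, stat, p, q, degen)

    # Collapse patients onto distinct score values: all per-voxel rank
    # quantities depend only on how many lesioned patients carry each value.
    uniq, inv, t_counts = np.unique(scores, return_inverse=True, return_counts=True)
    U = uniq.size
    A = np.zeros((n, U))
    A[np.arange(n), inv] = 1.0
    t = t_counts.astype(float)

    C1 = A.T @ L                      # U × V: lesioned count per value
    C0 = t[:, None] - C1              # intact count per value
    n1 = C1.sum(axis=0)               # lesioned group size per voxel
    n0 = n - n1

    # pooled mid-rank per distinct value (same for every voxel)
    r = _exclusive_cumsum(t) + (t + 1) / 2.0       # U
    # within-group mid-rank per value, per voxel
    w1 = _exclusive_cumsum(C1, axis=0) + (C1 + 1) / 2.0
    w0 = _exclusive_cumsum(C0, axis=0) + (C0 + 1) / 2.0

    with np.errstate(invalid="ignore", divide="ignore"):
        Rbar1 = (C1 * r[:, None]).sum(axis=0) / n1
        Rbar0 = (C0 * r[:, None]).sum(axis=0) / n0
        # term for each member with value u: R - R(i) - R̄i + (ni+1)/2
        term1 = (r[:, None] - w1) - Rbar1[None, :] + (n1[None, :] + 1) / 2.0
        term0 = (r[:, None] - w0) - Rbar0[None, :] + (n0[None, :] + 1) / 2.0
        S1 = (C1 * term1**2).sum(axis=0) / (n1 - 1)
        S0 = (C0 * term0**2).sum(axis=0) / (n0 - 1)
        pooled_var = n1 * S1 + n0 * S0
        degenerate = pooled_var <= 0.0
        W = np.where(
            degenerate, 0.0,
            n1 * n0 * (Rbar0 - Rbar1) / (n * np.sqrt(np.where(degenerate, 1.0, pooled_var))),
        )
        df = np.where(
            degenerate, np.nan,
            pooled_var**2
            / ((n1 * S1) ** 2 / (n1 - 1) + (n0 * S0) ** 2 / (n0 - 1)),
        )
    pv = np.ones(V)
    ok = ~degenerate
    pv[ok] = 2.0 * stats.t.sf(np.abs(W[ok]), df[ok])
    pv = np.minimum(pv, 1.0)

    qv = np.ones(V)
    if alpha_correction and ok.any():
        qv[ok] = fdr_adjust(pv[ok])

    stat.reshape(-1)[tested_flat] = W
    p.reshape(-1)[tested_flat] = pv
    q.reshape(-1)[tested_flat] = qv
    dg = np.zeros(V, dtype=bool)
    dg[degenerate] = True
    degen.reshape(-1)[tested_flat] = dg
    return VoxelStatMap(tested, stat, p, q, degen)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def threshold_to_weights(stat_map: VoxelStatMap, alpha: float = 0.05) -> np.ndarray:
    """Voxel weight map: |W| where q <= alpha (non-degenerate), else 0."""
    surviving = (
        stat_map.tested_mask
        & ~stat_map.degenerate_mask
        & (stat_map.q <= alpha)
    )
    return np.where(surviving, np.abs(stat_map.statistic), 0.0)


def lsm_rois(weight_map: np.ndarray, atlas: ToyAtlas) -> list[int]:
    """Sorted region ids containing at least one non-zero-weight voxel."""
    if weight_map.shape != atlas.shape:
        raise ValueError("weight map is not on the atlas lattice")
    hit = atlas.labels[weight_map != 0]
    return sorted(int(r) for r in np.unique(hit) if r != 0)


def run_lsm(
    lesion_masks: np.ndarray,
    nihss_48h,
    atlas: ToyAtlas,
    alpha: float = 0.05,
    coverage_threshold: float = 0.10,
) -> tuple[VoxelStatMap, np.ndarray, list[int]]:
    """Full LSM stage: map → threshold → ROI translation."""
    stat_map = bm_map(lesion_masks, nihss_48h, coverage_threshold=coverage_threshold)
    weights = threshold_to_weights(stat_map, alpha=alpha)
    rois = lsm_rois(weights, atlas)
    return stat_map, weights, rois


def save_lsm_outputs(
    out_dir: str | Path,
    stat_map: VoxelStatMap,
    weights: np.ndarray,
    rois: list[int],
) -> None:
    out_dir = Path(out_dir)
    stat_map.save(out_dir)
    nib.save(
        nib.Nifti1Image(weights.astype(np.float32), np.eye(4)),
        out_dir / "weights.nii.gz",
    )
    with open(out_dir / "rois.json", "w") as fh:
        json.dump({"roi_ids": [int(r) for r in rois]}, fh, indent=2, sort_keys=True)
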