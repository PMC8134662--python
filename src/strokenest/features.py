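"""Region-level imaging features from lesion masks.

Three feature kinds are computed against the parcellation:

* ``gm_overlap`` / ``wm_overlap`` — relative lesion overlap
  |lesion ∩ region| / |region|, one column per GM region / WM tract;
* ``wm_integrity`` — fraction of the tract cross-section spared by the
  lesion, taken (by default) as the minimum over slices along the tract's
  declared axis: a single full transection disconnects a tract, so the
  worst slice governs.

A coverage filter removes voxels (or whole regions) lesioned in fewer than
10% of patients before any statistics are run.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import atlas as atlas_mod

FEATURE_KINDS = ("gm_overlap", "wm_overlap", "wm_integrity")


def overlap_fraction(lesion_mask: np.ndarray, region_mask: np.ndarray) -> float:
    """|lesion ∩ region| / |region|; errors on an empty region."""
    region_mask = np.asarray(region_mask, dtype=bool)
    n_region = int(region_mask.sum())
    if n_region == 0:
        raise ValueError("empty region: overlap fraction undefined")
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    return float(np.logical_and(lesion_mask, region_mask).sum() / n_region)


def tract_integrity(
    lesion_mask: np.ndarray,
    tract_mask: np.ndarray,
    axis: str | int,
    mode: str = "min",
) -> float:
    """Spared cross-section fraction of a WM tract.

    Per slice s along ``axis`` that contains tract voxels, the spared
    fraction is 1 − |lesion ∩ tract ∩ s| / |tract ∩ s|.  ``mode="min"``
    (default) returns the worst slice; ``mode="mean"`` averages the slices.
    1.0 means untouched, 0.0 fully transected at some cross-section.
    """
    if isinstance(axis, str):
        axis = atlas_mod.AXES.index(axis)
    tract_mask = np.asarray(tract_mask, dtype=bool)
    if not tract_mask.any():
        raise ValueError("empty tract: integrity undefined")
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    other = tuple(i for i in range(tract_mask.ndim) if i != axis)
    tract_per_slice = tract_mask.sum(axis=other)
    hit_per_slice = np.logical_and(lesion_mask, tract_mask).sum(axis=other)
    occupied = tract_per_slice > 0
    spared = 1.0 - hit_per_slice[occupied] / tract_per_slice[occupied]
    if mode == "min":
        return float(spared.min())
    if mode == "mean":
        return float(spared.mean())
    raise ValueError(f"unknown integrity mode {mode!r}")


def coverage_filter(
    masks: np.ndarray,
    unit: str = "voxel",
    threshold: float = 0.10,
    atlas: atlas_mod.ToyAtlas | None = None,
):
    """Retain voxels/regions lesioned in at least ``threshold`` of patients.

    ``masks`` is a (n_patients, *grid) boolean stack.  With
    ``unit="voxel"`` returns a boolean grid of retained voxels; with
    ``unit="region"`` returns the sorted list of retained region ids (a
    region counts as affected in a patient when any of its voxels is
    lesioned).  The threshold is inclusive ("at least").
    """
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim < 2 or masks.shape[0] < 1:
        raise ValueError("need at least one lesion mask")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0,1)")
    n = masks.shape[0]
    if unit == "voxel":
        counts = masks.sum(axis=0)
        return counts / n >= threshold
    if unit == "region":
        if atlas is None:
            raise ValueError("region-unit filtering needs an atlas")
        retained = []
        for rid in atlas.region_ids:
            rmask = atlas.labels == rid
            affected = masks[:, rmask].any(axis=1).sum()
            if affected / n >= threshold:
                retained.append(rid)
        return sorted(retained)
    raise ValueError(f"unknown unit {unit!r}")


@dataclasses.dataclass(frozen=True)
class FeatureMatrix:
    """Patients × features table with per-column provenance.

    ``values`` is a DataFrame indexed by patient_id whose imaging columns
    are named ``r{region_id:03d}_{kind}``; ``manifest`` records
    (column, region_id, kind, provenance) with provenance "imaging" or
    "clinical".
    """

    values: pd.DataFrame
    manifest: pd.DataFrame

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.index)

    def columns_for_region(self, region_id: int) -> list[str]:
        m = self.manifest
        return list(m.loc[m["region_id"] == region_id, "column"])

    def region_of(self, column: str) -> int | None:
        row = self.manifest.loc[self.manifest["column"] == column]
        rid = row["region_id"].iloc[0]
        return None if pd.isna(rid) else int(rid)


def feature_column_name(region_id: int, kind: str) -> str:
    return f"r{region_id:03d}_{kind}"


def build_feature_matrix(
    lesions: np.ndarray,
    patient_ids: list[str],
    atlas: atlas_mod.ToyAtlas,
    region_set: list[int] | None = None,
    integrity_mode: str = "min",
) -> FeatureMatrix:
    """Imaging feature table for the given regions.

    One ``gm_overlap`` column per GM region, one ``wm_overlap`` and one
    ``wm_integrity`` column per WM tract; columns ordered by
    (region_id, kind).  Deterministic and pure.
    """
    if region_set is None:
        region_set = atlas.region_ids
    known = set(atlas.region_ids)
    for rid in region_set:
        if rid not in known:
            raise KeyError(f"unknown region id {rid}")
    region_set = sorted(set(int(r) for r in region_set))

    lesions = np.asarray(lesions, dtype=bool)
    columns: list[str] = []
    manifest_rows: list[dict] = []
    data: dict[str, np.ndarray] = {}

    for rid in region_set:
        tissue = atlas.tissue_of(rid)
        rmask = atlas.labels == rid
        if tissue == atlas_mod.GM:
            kinds = ["gm_overlap"]
        else:
            kinds = ["wm_overlap", "wm_integrity"]
        for kind in kinds:
            col = feature_column_name(rid, kind)
            if kind == "wm_integrity":
                ax = atlas.axis_of(rid)
                vals = np.array(
                    [tract_integrity(m, rmask, ax, mode=integrity_mode) for m in lesions]
                )
            else:
                vals = np.array([overlap_fraction(m, rmask) for m in lesions])
            columns.append(col)
            data[col] = vals
            manifest_rows.append(
                {"column": col, "region_id": rid, "kind": kind, "provenance": "imaging"}
            )

    values = pd.DataFrame(data, index=pd.Index(patient_ids, name="patient_id"),
                          columns=columns)
    manifest = pd.DataFrame(
        manifest_rows, columns=["column", "region_id", "kind", "provenance"]
    )
    return FeatureMatrix(values=values, manifest=manifest)
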