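"""Toy parcellation atlas: labelled GM regions and axis-aligned WM tracts.

A stand-in for a fused grey-matter/white-matter parcellation in a common
template space.  Regions live on an isotropic integer lattice (1 mm voxels,
identity affine); the brain extent is the ellipsoid inscribed in the grid.
GM regions are compact spheres, WM tracts are elongated bars that are
contiguous along a declared axis so that a per-slice cross-section is
defined everywhere the tract spans.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

AXES = ("x", "y", "z")

GM = "GM"
WM = "WM"


class AtlasSizingError(ValueError):
    """Requested regions cannot be packed disjointly into the grid."""


@dataclasses.dataclass(frozen=True)
class ToyAtlas:
    """Labelled parcellation volume plus per-region metadata.

    Attributes
    ----------
    labels : int32 array, shape ``grid_shape``
        0 = background; positive integers are region ids.
    regions : DataFrame with columns (region_id, name, tissue, axis)
        ``tissue`` is ``"GM"`` or ``"WM"``; ``axis`` is ``"x"/"y"/"z"`` for
        WM tracts and empty for GM regions.
    """

    labels: np.ndarray
    regions: pd.DataFrame

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def region_ids(self) -> list[int]:
        return [int(r) for r in self.regions["region_id"]]

    @property
    def brain_mask(self) -> np.ndarray:
        return inscribed_ellipsoid(self.shape)

    def region_mask(self, region_id: int) -> np.ndarray:
        if region_id not in set(self.region_ids):
            raise KeyError(f"unknown region id {region_id}")
        return self.labels == region_id

    def tissue_of(self, region_id: int) -> str:
        row = self.regions.loc[self.regions["region_id"] == region_id]
        if row.empty:
            raise KeyError(f"unknown region id {region_id}")
        return str(row["tissue"].iloc[0])

    def axis_of(self, region_id: int) -> str:
        row = self.regions.loc[self.regions["region_id"] == region_id]
        if row.empty:
            raise KeyError(f"unknown region id {region_id}")
        axis = row["axis"].iloc[0]
        if not isinstance(axis, str) or axis not in AXES:
            raise ValueError(f"region {region_id} has no declared tract axis")
        return axis

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        ids = self.regions["region_id"].to_numpy()
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate region ids in table")
        present = set(np.unique(self.labels)) - {0}
        if present != set(int(i) for i in ids):
            raise ValueError("label volume and region table disagree")
        for rid in ids:
            row = self.regions.loc[self.regions["region_id"] == rid].iloc[0]
            if row["tissue"] == WM:
                _check_contiguous(self.labels == rid, AXES.index(row["axis"]))

    # ---- I/O -------------------------------------------------------------

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        img = nib.Nifti1Image(self.labels.astype(np.int32), np.eye(4))
        nib.save(img, out_dir / "atlas.nii.gz")
        self.regions.to_csv(out_dir / "regions.csv", index=False)

    @classmethod
    def load(cls, in_dir: str | Path) -> "ToyAtlas":
        in_dir = Path(in_dir)
        labels = np.asarray(
            nib.load(in_dir / "atlas.nii.gz").get_fdata(), dtype=np.int32
        )
        regions = pd.read_csv(in_dir / "regions.csv", keep_default_na=False)
        regions["region_id"] = regions["region_id"].astype(int)
        return cls(labels=labels, regions=regions)


def inscribed_ellipsoid(shape: tuple[int, ...]) -> np.ndarray:
    """Boolean mask of the ellipsoid inscribed in the grid (the brain extent)."""
    grids = np.indices(shape).astype(float)
    out = np.zeros(shape, dtype=float)
    for ax, n in enumerate(shape):
        c = (n - 1) / 2.0
        a = n / 2.0 - 0.5
        out += ((grids[ax] - c) / a) ** 2
    return out <= 1.0


def _check_contiguous(mask: np.ndarray, axis: int) -> None:
    counts = mask.sum(axis=tuple(i for i in range(mask.ndim) if i != axis))
    occupied = np.nonzero(counts)[0]
    if occupied.size == 0:
        raise ValueError("empty WM tract")
    lo, hi = occupied[0], occupied[-1]
    if np.any(counts[lo : hi + 1] == 0):
        raise ValueError("WM tract has an empty cross-section inside its span")


def _ball(shape, center, radii) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    d = np.zeros(shape)
    for ax in range(len(shape)):
        d += ((grids[ax] - center[ax]) / radii[ax]) ** 2
    return d <= 1.0


def make_toy_atlas(
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    n_gm_regions: int = 6,
    n_wm_tracts: int = 2,
    seed: int = 0,
    max_tries: int = 2000,
    gm_focus: tuple[tuple[float, float, float], float, int] | None = None,
) -> ToyAtlas:
    """Pack disjoint GM spheres and axis-aligned WM bars into the brain extent.

    ``gm_focus = (center, radius, count)`` forces the first ``count`` GM
    regions to be centred inside the given ball — a whole-brain parcellation
    always has parcels inside any vascular territory, and a sparse toy
    parcellation only emulates that when told where the territory is.

    Deterministic for a fixed seed.  Raises :class:`AtlasSizingError` when the
    requested number of regions cannot be placed disjointly.
    """
    if any(s < 16 for s in grid_shape):
        raise ValueError("grid_shape must be at least 16 along every axis")
    if n_gm_regions < 2:
        raise ValueError("need at least 2 GM regions")
    if n_wm_tracts < 1:
        raise ValueError("need at least 1 WM tract")

    rng = np.random.default_rng(seed)
    brain = inscribed_ellipsoid(grid_shape)
    labels = np.zeros(grid_shape, dtype=np.int32)
    rows: list[dict] = []
    next_id = 1

    def place(mask_fn, n_wanted, make_row, check=None) -> None:
        nonlocal next_id
        placed = 0
        tries = 0
        while placed < n_wanted:
            if tries >= max_tries:
                raise AtlasSizingError(
                    f"could not pack {n_wanted} regions into grid {grid_shape} "
                    f"after {max_tries} attempts"
                )
            tries += 1
            mask = mask_fn()
            mask &= brain
            if mask.sum() < 8:
                continue
            if np.any(labels[mask] != 0):
                continue
            if check is not None:
                try:
                    check(mask)
                except ValueError:
                    continue
            labels[mask] = next_id
            rows.append(make_row(next_id))
            next_id += 1
            placed += 1

    # WM bars first (they are long and hardest to place).
    wm_axes: list[int] = []

    def wm_mask() -> np.ndarray:
        axis = int(rng.integers(0, 3))
        wm_axes.append(axis)
        n = grid_shape[axis]
        length = int(rng.integers(max(10, n // 3), max(11, 2 * n // 3)))
        start = int(rng.integers(2, n - length - 1))
        radius = float(rng.uniform(1.5, 2.5))
        # cross-section centre drawn from the interior so ellipsoid clipping
        # cannot hollow out a slice
        center = [0.0, 0.0, 0.0]
        for ax, m in enumerate(grid_shape):
            margin = m / 2.0 - 0.5 - radius - 2
            center[ax] = (m - 1) / 2.0 + rng.uniform(-margin * 0.5, margin * 0.5)
        radii = [radius] * 3
        radii[axis] = length / 2.0
        center[axis] = start + length / 2.0
        return _ball(grid_shape, center, radii)

    def wm_row(rid: int) -> dict:
        return {
            "region_id": rid,
            "name": f"WM_tract_{rid:02d}",
            "tissue": WM,
            "axis": AXES[wm_axes[-1]],
        }

    place(
        wm_mask,
        n_wm_tracts,
        wm_row,
        check=lambda m: _check_contiguous(m, wm_axes[-1]),
    )

    def gm_mask_uniform() -> np.ndarray:
        radius = float(rng.uniform(2.0, 3.5))
        center = []
        for ax, m in enumerate(grid_shape):
            half = m / 2.0 - 0.5
            margin = max(half - radius - 1, 1.0)
            center.append((m - 1) / 2.0 + rng.uniform(-margin, margin))
        return _ball(grid_shape, center, [radius] * 3)

    def gm_row(rid: int) -> dict:
        return {"region_id": rid, "name": f"GM_region_{rid:02d}", "tissue": GM, "axis": ""}

    n_focus = 0
    if gm_focus is not None:
        f_center, f_radius, n_focus = gm_focus
        if n_focus > n_gm_regions:
            raise ValueError("gm_focus count exceeds n_gm_regions")
        f_center = np.asarray(f_center, dtype=float)

        def gm_mask_focus() -> np.ndarray:
            radius = float(rng.uniform(2.0, 3.5))
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            offset = u * f_radius * rng.random() ** (1 / 3)
            return _ball(grid_shape, f_center + offset, [radius] * 3)

        place(gm_mask_focus, n_focus, gm_row)

    place(gm_mask_uniform, n_gm_regions - n_focus, gm_row)

    regions = pd.DataFrame(rows, columns=["region_id", "name", "tissue", "axis"])
    atlas = ToyAtlas(labels=labels, regions=regions)
    atlas.validate()
    return atlas
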