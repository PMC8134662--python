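"""Synthetic stroke cohort generator.

Emulates the statistical structure of an acute ischaemic stroke cohort:
ellipsoidal lesions concentrated in a middle-cerebral-artery-like territory,
integer NIHSS scores in [0, 42] at baseline / 48 hours / 30 days, a 48-hour
score driven by baseline severity plus lesion load in designated eloquent
regions and tract-integrity loss, and a 30-day score driven by the 48-hour
score plus clinical covariates with Gaussian noise.

Generative model (scores rounded and clipped to [0, 42]):

    NIHSS_48h = a0 + a1 * NIHSS_base + sum_r beta_r * overlap_r
                + sum_t gamma_t * (1 - integrity_t) + eps1
    NIHSS_30d = d0 + d48 * NIHSS_48h + sum_c d_c * z(covariate_c) + eps2

with eps1 ~ N(0, noise_sd_48), eps2 ~ N(0, noise_sd_30) and z() a fixed
population standardization so that coefficients are in NIHSS points per SD
(binary covariates enter as 0/1 indicators).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .atlas import GM, WM, ToyAtlas
from .features import overlap_fraction, tract_integrity

NIHSS_MIN, NIHSS_MAX = 0, 42

CLINICAL_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "nihss_baseline",
    "nihss_48h",
    "nihss_30d",
    "glucose",
    "hematocrit",
    "sbp",
    "afib",
    "htn",
    "hld",
    "treatment",
    "onset_to_admission_min",
]

# Fixed population (center, scale) used to standardize continuous covariates
# inside the generative 30-day model; binary covariates pass through as 0/1.
COVARIATE_SCALES: dict[str, tuple[float, float]] = {
    "age": (69.0, 14.0),
    "glucose": (7.0, 1.8),
    "hematocrit": (0.41, 0.045),
    "sbp": (150.0, 22.0),
    "onset_to_admission_min": (170.0, 90.0),
}


class SimulationConfigError(ValueError):
    """Invalid generative configuration (e.g. unknown eloquent region id)."""


@dataclasses.dataclass
class SimulationConfig:
    """Generative parameters of a synthetic cohort.

    ``eloquent_effects`` maps GM/WM region ids to beta_r (NIHSS points per
    unit relative lesion overlap); ``tract_effects`` maps WM tract ids to
    gamma_t (NIHSS points per unit integrity loss).  ``outcome_coefs`` maps
    clinical covariate names (plus ``nihss_48h``) to delta coefficients of
    the 30-day model.
    """

    n_patients: int = 221
    seed: int = 0
    eloquent_effects: dict[int, float] = dataclasses.field(default_factory=dict)
    tract_effects: dict[int, float] = dataclasses.field(default_factory=dict)
    baseline_intercept: float = 0.0   # a0
    baseline_coef: float = 0.85       # a1
    outcome_intercept: float = 1.0    # d0
    outcome_coefs: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "nihss_48h": 0.85,
            "age": 1.2,
            "sex": 0.3,
            "glucose": 0.6,
            "hematocrit": -0.4,
            "sbp": 0.4,
            "afib": 0.8,
            "htn": 0.5,
            "hld": 0.4,
            "treatment": -1.2,
            "onset_to_admission_min": 0.4,
        }
    )
    noise_sd_48: float = 3.0
    noise_sd_30: float = 2.5
    lesion_size_range: tuple[int, int] = (100, 1500)
    territory_center: tuple[float, float, float] = (10.0, 15.5, 15.5)
    territory_radius: float = 9.0
    territory_prob: float = 0.8       # P(lesion centre drawn inside territory)
    prevalences: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "sex_f": 0.48,
            "afib": 0.35,
            "htn": 0.60,
            "hld": 0.40,
            "treatment": 0.5,
        }
    )

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise SimulationConfigError("n_patients must be >= 10")
        if self.noise_sd_48 < 0 or self.noise_sd_30 < 0:
            raise SimulationConfigError("noise SDs must be >= 0")
        if any(v < 0 for v in self.eloquent_effects.values()):
            raise SimulationConfigError("eloquent effects must be >= 0")
        if any(v < 0 for v in self.tract_effects.values()):
            raise SimulationConfigError("tract effects must be >= 0")
        lo, hi = self.lesion_size_range
        if not (1 <= lo <= hi):
            raise SimulationConfigError("invalid lesion_size_range")

    def validate_against(self, atlas: ToyAtlas) -> None:
        known = set(atlas.region_ids)
        for rid in self.eloquent_effects:
            if rid not in known:
                raise SimulationConfigError(
                    f"eloquent_effects references unknown region {rid}"
                )
        for rid in self.tract_effects:
            if rid not in known:
                raise SimulationConfigError(
                    f"tract_effects references unknown region {rid}"
                )
            if atlas.tissue_of(rid) != WM:
                raise SimulationConfigError(
                    f"tract_effects region {rid} is not a WM tract"
                )

    def eloquent_set(self) -> list[int]:
        """Region ids with a strictly positive generative effect."""
        ids = {r for r, b in self.eloquent_effects.items() if b > 0}
        ids |= {t for t, g in self.tract_effects.items() if g > 0}
        return sorted(ids)

    # ---- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["eloquent_effects"] = {str(k): v for k, v in self.eloquent_effects.items()}
        d["tract_effects"] = {str(k): v for k, v in self.tract_effects.items()}
        d["lesion_size_range"] = list(self.lesion_size_range)
        d["territory_center"] = list(self.territory_center)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("eloquent_effects", "tract_effects"):
            if key in d:
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        if "lesion_size_range" in d:
            d["lesion_size_range"] = tuple(int(v) for v in d["lesion_size_range"])
        if "territory_center" in d:
            d["territory_center"] = tuple(float(v) for v in d["territory_center"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def default_atlas(
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    n_gm_regions: int = 24,
    n_wm_tracts: int = 6,
    n_territory_gm: int = 8,
) -> ToyAtlas:
    """Toy atlas whose parcellation covers the default MCA-like territory.

    The density matters: real fused GM/WM parcellations carry hundreds of
    parcels, and Relief-style feature weighting needs enough feature columns
    for nearest-neighbour distances to be informative.  The first
    ``n_territory_gm`` GM regions are centred inside the default lesion
    territory, mirroring the fact that a whole-brain parcellation always
    has parcels within a vascular territory.
    """
    base = SimulationConfig()
    from .atlas import make_toy_atlas  # local import avoids a cycle at module load

    return make_toy_atlas(
        grid_shape,
        n_gm_regions,
        n_wm_tracts,
        seed=seed,
        gm_focus=(base.territory_center, base.territory_radius, n_territory_gm),
    )


def default_config_for_atlas(
    atlas: ToyAtlas,
    n_patients: int = 221,
    seed: int = 0,
    n_eloquent_gm: int = 3,
    gm_betas: tuple[float, ...] = (10.0, 9.0, 8.0),
    tract_gamma: float = 6.0,
    **overrides,
) -> SimulationConfig:
    """Config whose eloquent regions are the GM parcels nearest the territory.

    Mirrors real anatomy, where the regions vulnerable to MCA stroke are the
    ones inside the MCA territory: the ``n_eloquent_gm`` GM regions whose
    centroids lie closest to the territory centre receive betas
    ``gm_betas``, and the closest WM tract receives ``tract_gamma``.
    """
    base = SimulationConfig(n_patients=n_patients, seed=seed, **overrides)
    center = np.asarray(base.territory_center)

    def centroid_dist(rid: int) -> float:
        pts = np.argwhere(atlas.labels == rid)
        return float(np.linalg.norm(pts.mean(axis=0) - center))

    gm_ids = [r for r in atlas.region_ids if atlas.tissue_of(r) == GM]
    wm_ids = [r for r in atlas.region_ids if atlas.tissue_of(r) == WM]
    gm_sorted = sorted(gm_ids, key=centroid_dist)
    chosen = gm_sorted[:n_eloquent_gm]
    base.eloquent_effects = {
        rid: float(b) for rid, b in zip(chosen, gm_betas)
    }
    if wm_ids and tract_gamma > 0:
        nearest_wm = min(wm_ids, key=centroid_dist)
        base.tract_effects = {nearest_wm: float(tract_gamma)}
    base.validate_against(atlas)
    return base


# ---------------------------------------------------------------------------
# lesion sampling
# ---------------------------------------------------------------------------


def sample_lesion(
    atlas: ToyAtlas,
    config: SimulationConfig,
    rng: np.random.Generator,
    max_retries: int = 20,
) -> np.ndarray:
    """Draw one ellipsoidal lesion mask on the atlas lattice.

    The target voxel count is uniform over ``lesion_size_range``; the lesion
    is the set of exactly that many voxels nearest the centre under a
    randomly anisotropic metric (ties broken lexicographically), then clipped
    to the brain extent.  Centres fall inside the configured territory with
    probability ``territory_prob``, elsewhere uniformly in the brain.
    """
    brain = atlas.brain_mask
    if not brain.any():
        raise ValueError("empty brain extent")
    center_t = np.asarray(config.territory_center, dtype=float)
    shape = atlas.shape
    coords = np.indices(shape).reshape(3, -1).T.astype(float)
    brain_flat = brain.reshape(-1)

    in_territory = (
        np.linalg.norm(coords - center_t, axis=1) <= config.territory_radius
    ) & brain_flat
    if config.territory_radius > 0 and not in_territory.any():
        raise ValueError("territory does not intersect the brain extent")

    for _ in range(max_retries):
        lo, hi = config.lesion_size_range
        size = int(rng.integers(lo, hi + 1))
        if config.territory_radius == 0:
            center = center_t
        elif rng.random() < config.territory_prob:
            idx = rng.choice(np.nonzero(in_territory)[0])
            center = coords[idx]
        else:
            idx = rng.choice(np.nonzero(brain_flat)[0])
            center = coords[idx]
        # anisotropic per-axis stretch gives jittered ellipsoid shapes
        scales = np.exp(rng.uniform(-0.5, 0.5, size=3))
        d = (((coords - center) / scales) ** 2).sum(axis=1)
        order = np.lexsort((np.arange(d.size), d))
        chosen = order[:size]
        mask = np.zeros(d.size, dtype=bool)
        mask[chosen] = True
        mask &= brain_flat
        if mask.any():
            return mask.reshape(shape)
    raise RuntimeError("could not draw a non-empty lesion inside the brain")


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------


def _clip_nihss(x: float) -> int:
    return int(np.clip(np.round(x), NIHSS_MIN, NIHSS_MAX))


def _standardize(name: str, value: float) -> float:
    if name in COVARIATE_SCALES:
        c, s = COVARIATE_SCALES[name]
        return (value - c) / s
    return float(value)


def simulate_outcomes(
    lesion_features: dict,
    covariates: dict,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[int, int, int]:
    """NIHSS triple (baseline, 48h, 30d) from the generative linear chain.

    ``lesion_features`` holds ``overlaps`` (region_id -> fraction) and
    ``integrities`` (tract_id -> fraction); ``covariates`` holds the clinical
    covariates including ``nihss_baseline``.
    """
    overlaps = lesion_features.get("overlaps", {})
    integrities = lesion_features.get("integrities", {})
    for v in overlaps.values():
        if not 0.0 <= v <= 1.0:
            raise ValueError("overlap outside [0,1]")
    for v in integrities.values():
        if not 0.0 <= v <= 1.0:
            raise ValueError("integrity outside [0,1]")

    base = int(covariates["nihss_baseline"])

    raw48 = config.baseline_intercept + config.baseline_coef * base
    for rid, beta in config.eloquent_effects.items():
        raw48 += beta * overlaps.get(rid, 0.0)
    for tid, gamma in config.tract_effects.items():
        raw48 += gamma * (1.0 - integrities.get(tid, 1.0))
    if config.noise_sd_48 > 0:
        raw48 += rng.normal(0.0, config.noise_sd_48)
    nihss_48h = _clip_nihss(raw48)

    raw30 = config.outcome_intercept
    for name, delta in config.outcome_coefs.items():
        if name == "nihss_48h":
            raw30 += delta * nihss_48h
        else:
            value = covariates[name]
            if name == "sex":
                value = 1.0 if value == "M" else 0.0
            raw30 += delta * _standardize(name, float(value))
    if config.noise_sd_30 > 0:
        raw30 += rng.normal(0.0, config.noise_sd_30)
    nihss_30d = _clip_nihss(raw30)

    return base, nihss_48h, nihss_30d


def _sample_covariates(rng: np.random.Generator, config: SimulationConfig) -> dict:
    """Clinical covariates with plausibility-anchored marginal distributions."""
    prev = config.prevalences

    def trunc_normal(mean, sd, lo, hi):
        for _ in range(100):
            v = rng.normal(mean, sd)
            if lo <= v <= hi:
                return v
        return float(np.clip(v, lo, hi))

    baseline = int(np.clip(np.round(rng.normal(15.0, 6.0)), 2, 30))
    return {
        "age": round(trunc_normal(69.0, 14.0, 30.0, 95.0), 1),
        "sex": "F" if rng.random() < prev["sex_f"] else "M",
        "nihss_baseline": baseline,
        "glucose": round(trunc_normal(7.0, 1.8, 3.5, 20.0), 2),
        "hematocrit": round(trunc_normal(0.41, 0.045, 0.25, 0.60), 3),
        "sbp": round(trunc_normal(150.0, 22.0, 90.0, 220.0), 1),
        "afib": int(rng.random() < prev["afib"]),
        "htn": int(rng.random() < prev["htn"]),
        "hld": int(rng.random() < prev["hld"]),
        "treatment": int(rng.random() < prev["treatment"]),
        "onset_to_admission_min": round(float(152.0 * np.exp(rng.normal(0.0, 0.5))), 1),
    }


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SimulatedCohort:
    """In-memory cohort: clinical table, stacked lesion masks, ground truth."""

    clinical: pd.DataFrame
    lesions: np.ndarray  # (n_patients, *grid) boolean
    config: SimulationConfig
    atlas: ToyAtlas

    @property
    def patient_ids(self) -> list[str]:
        return list(self.clinical["patient_id"])

    @property
    def ground_truth(self) -> dict:
        return {
            "eloquent_regions": self.config.eloquent_set(),
            "eloquent_effects": {str(k): v for k, v in self.config.eloquent_effects.items()},
            "tract_effects": {str(k): v for k, v in self.config.tract_effects.items()},
            "baseline_coef": self.config.baseline_coef,
            "outcome_coefs": self.config.outcome_coefs,
            "noise_sd_48": self.config.noise_sd_48,
            "noise_sd_30": self.config.noise_sd_30,
            "seed": self.config.seed,
        }

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        try:
            (out_dir / "lesions").mkdir(parents=True, exist_ok=True)
            self.atlas.save(out_dir / "atlas")
            self.clinical.to_csv(out_dir / "clinical.csv", index=False)
            with open(out_dir / "ground_truth.json", "w") as fh:
                json.dump(self.ground_truth, fh, indent=2, sort_keys=True)
            for pid, mask in zip(self.patient_ids, self.lesions):
                img = nib.Nifti1Image(mask.astype(np.uint8), np.eye(4))
                nib.save(img, out_dir / "lesions" / f"{pid}.nii.gz")
        except OSError as exc:
            raise CohortIOError(f"failed writing cohort to {out_dir}: {exc}") from exc

    @classmethod
    def load(cls, in_dir: str | Path, config: SimulationConfig | None = None) -> "SimulatedCohort":
        in_dir = Path(in_dir)
        try:
            atlas = ToyAtlas.load(in_dir / "atlas")
            clinical = pd.read_csv(in_dir / "clinical.csv")
            masks = []
            for pid in clinical["patient_id"]:
                img = nib.load(in_dir / "lesions" / f"{pid}.nii.gz")
                masks.append(np.asarray(img.get_fdata()) > 0.5)
        except OSError as exc:
            raise CohortIOError(f"failed reading cohort from {in_dir}: {exc}") from exc
        if config is None:
            config = SimulationConfig(n_patients=max(10, len(clinical)))
        return cls(clinical=clinical, lesions=np.stack(masks), config=config, atlas=atlas)


class CohortIOError(OSError):
    """I/O failure while persisting or loading a cohort (not a simulation bug)."""


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # Per-patient substream: patient i's draws do not depend on n_patients.
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def simulate_cohort(config: SimulationConfig, atlas: ToyAtlas) -> SimulatedCohort:
    """Generate a full cohort; deterministic (bit-exact) for a fixed seed."""
    config.validate_against(atlas)
    effect_regions = sorted(config.eloquent_effects)
    effect_tracts = sorted(config.tract_effects)
    region_masks = {r: atlas.region_mask(r) for r in effect_regions}
    tract_masks = {t: (atlas.region_mask(t), atlas.axis_of(t)) for t in effect_tracts}

    rows = []
    masks = []
    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i)
        cov = _sample_covariates(rng, config)
        lesion = sample_lesion(atlas, config, rng)
        overlaps = {
            r: overlap_fraction(lesion, m) for r, m in region_masks.items()
        }
        integrities = {
            t: tract_integrity(lesion, m, ax) for t, (m, ax) in tract_masks.items()
        }
        base, n48, n30 = simulate_outcomes(
            {"overlaps": overlaps, "integrities": integrities}, cov, config, rng
        )
        row = {"patient_id": f"sub-{i + 1:04d}"}
        row.update(cov)
        row["nihss_baseline"] = base
        row["nihss_48h"] = n48
        row["nihss_30d"] = n30
        rows.append(row)
        masks.append(lesion)

    clinical = pd.DataFrame(rows)[CLINICAL_COLUMNS]
    return SimulatedCohort(
        clinical=clinical, lesions=np.stack(masks), config=config, atlas=atlas
    )


def cohort_checksum(cohort: SimulatedCohort) -> str:
    """MD5 over the clinical table and every lesion mask (determinism checks)."""
    h = hashlib.md5()
    h.update(cohort.clinical.to_csv(index=False).encode())
    h.update(np.packbits(cohort.lesions.astype(np.uint8)).tobytes())
    return h.hexdigest()
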