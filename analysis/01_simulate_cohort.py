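"""Generate the synthetic study cohort.

Writes an n=221 cohort (the size of the pooled trial sample the framework
is designed for) with the default MCA-like lesion territory and known
eloquent-region effects to results/cohort/, together with the generative
ground truth used by the later recovery analyses.
"""

from pathlib import Path

from strokenest.simulate import (
    default_atlas,
    default_config_for_atlas,
    simulate_cohort,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 0


def main() -> None:
    atlas = default_atlas(seed=SEED)
    config = default_config_for_atlas(atlas, n_patients=221, seed=SEED)
    cohort = simulate_cohort(config, atlas)
    cohort.save(OUT)
    config.to_yaml(OUT / "simulation_config.yaml")

    clin = cohort.clinical
    print(f"wrote {len(clin)} patients to {OUT}")
    print(f"eloquent GM regions (beta): {config.eloquent_effects}")
    print(f"tract effects (gamma):      {config.tract_effects}")
    print("median [IQR] baseline NIHSS:",
          f"{clin.nihss_baseline.median():.0f}",
          f"[{clin.nihss_baseline.quantile(.75) - clin.nihss_baseline.quantile(.25):.0f}]")
    print("median [IQR] age:          ",
          f"{clin.age.median():.0f} [{clin.age.quantile(.75) - clin.age.quantile(.25):.0f}]")


if __name__ == "__main__":
    main()
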