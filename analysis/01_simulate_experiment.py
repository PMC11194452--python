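"""Generate the synthetic incubation experiment all later steps analyse.

Emits the sequencing-side inputs (ASV counts, taxonomy, 16S copy
numbers, design, flow-cytometry totals, leachate chemistry covariates)
as TSVs under data/experiment/, and per-treatment micrograph sets for
both sampling days under scratch/images/ (TIFFs are bulky and fully
reproducible from the seed, so they stay out of the tracked tree).
"""

from pathlib import Path

from leachresp.simulate import (
    AsvExperimentParams,
    TREATMENTS,
    simulate_asv_experiment,
    simulate_fov_set,
    treatment_fov_scenario,
    write_asv_experiment,
    write_fov_set,
)

SEED = 11
N_FOV = 2
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    exp_dir = ROOT / "data" / "experiment"
    exp = simulate_asv_experiment(AsvExperimentParams(), seed=SEED)
    write_asv_experiment(exp, exp_dir)
    counts = exp["counts"]
    print(f"experiment: {counts.shape[0]} ASVs x {counts.shape[1]} samples -> {exp_dir}")
    print(f"read depths {counts.sum(0).min()}..{counts.sum(0).max()}")

    img_root = ROOT / "scratch" / "images"
    for timepoint in ("t1", "t4"):
        for i, (plastic, light) in enumerate(TREATMENTS):
            params, groups = treatment_fov_scenario(plastic, light, timepoint)
            sample = f"{plastic}-{light}-{timepoint}"
            fovs, truth = simulate_fov_set(
                params, n_fov=N_FOV, sample_id=sample, groups=groups,
                seed=SEED * 100 + i + (0 if timepoint == "t1" else 50),
            )
            write_fov_set(fovs, truth, img_root / timepoint)
        print(f"micrographs for {timepoint}: 6 treatments x 6 probes x {N_FOV} FOVs -> {img_root / timepoint}")


if __name__ == "__main__":
    main()
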