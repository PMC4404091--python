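"""Draw the synthetic study cohort: 15 recurrence phantoms with programmed
sac growth and coil translation, 12 stable controls.

Writes scenario YAMLs, the demographics-style metadata sheet and the
closed-form ground truth to results/cohort/.  One example subject's image
volumes are rasterized into scratch/example_subject/ for inspection (the
full study rasterizes lazily in 02_measure_subjects.py).
"""

from pathlib import Path

import pandas as pd

from coilwatch import CohortEffects, make_cohort, make_subject, write_volume

SEED = 20150420
OUT = Path("results/cohort")
SCRATCH = Path("scratch/example_subject")


def main() -> None:
    effects = CohortEffects(grid_shape=(96, 96, 96))
    subjects, metadata = make_cohort(15, 12, effects, seed=SEED)

    scen_dir = OUT / "scenarios"
    scen_dir.mkdir(parents=True, exist_ok=True)
    truth_rows = []
    for scenario, truth in subjects:
        slug = scenario.subject_id.split(" ")[0]
        scenario.to_yaml(scen_dir / f"subject_{slug}.yaml")
        truth_rows.append(
            {
                "subject": scenario.subject_id,
                "cohort": scenario.cohort,
                "true_vs1m_cc": truth.true_sac_volume_cc["1-"],
                "true_vsg3_cc": truth.true_vsg_cc[3],
                "true_delta_mm": truth.true_delta_mm,
            }
        )
    metadata.to_csv(OUT / "metadata.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(OUT / "ground_truth_closed_form.csv", index=False)
    print(f"wrote {len(subjects)} scenarios to {scen_dir}")
    print(metadata.groupby("cohort").size().to_string())

    scenario, truth = subjects[0]
    images, _ = make_subject(scenario)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    for tp, entry in images.items():
        slug = tp.replace("+", "p").replace("-", "m")
        for kind, vol in entry.items():
            write_volume(vol, SCRATCH / f"{slug}_{kind}.nii.gz")
    print(f"example subject {scenario.subject_id} rasterized into {SCRATCH}")


if __name__ == "__main__":
    main()
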