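"""Cohort statistics over the measured volumes: growth per definition,
coil compaction, coil-center translation, and the ROC comparison of the
translation against clinically measured sac size.

Reads results/per_subject.csv (from 02_measure_subjects.py) and
results/cohort/metadata.csv, writes the growth-outcome table, the ROC
points, and box/ROC figures under results/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from coilwatch import SubjectVolumes, parse_size, run_study

OUT = Path("results")


def to_subject_volumes(row) -> SubjectVolumes:
    get = lambda k: None if pd.isna(row[k]) else float(row[k])
    sv = SubjectVolumes(
        subject_id=row["subject_id"], cohort=row["cohort"],
        vs1m=get("vs1m"), vs1p=get("vs1p"), vs2m=get("vs2m"), vs2p=get("vs2p"),
        vc1p=get("vc1p"), vc2m=get("vc2m"),
    )
    if not pd.isna(row["delta_mm"]):
        sv.c1p = (0.0, 0.0, 0.0)
        sv.c2m = (float(row["delta_mm"]), 0.0, 0.0)  # only the distance matters here
    return sv


def main() -> None:
    per = pd.read_csv(OUT / "per_subject.csv")
    meta = pd.read_csv(OUT / "cohort" / "metadata.csv")
    sizes = {
        row["subject"]: parse_size(row["size_mm"]) for _, row in meta.iterrows()
    }
    subjects = [to_subject_volumes(row) for _, row in per.iterrows()]
    study = run_study(subjects, clinical_sizes=sizes)

    study.summaries.to_csv(OUT / "growth_outcomes.csv", index=False)
    study.range_stats.to_csv(OUT / "range_stats.csv", index=False)
    roc_df = pd.DataFrame(
        {
            "threshold_mm": study.roc_delta.thresholds,
            "sensitivity": study.roc_delta.sensitivities,
            "specificity": study.roc_delta.specificities,
        }
    )
    roc_df.to_csv(OUT / "delta_roc.csv", index=False)

    print(study.summaries.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print(
        f"\ncoil-center translation: U={study.delta_u:.1f}, one-tailed "
        f"p={study.delta_p:.4f}; AUC={study.roc_delta.auc:.3f}, optimal "
        f"cutoff {study.roc_delta.optimal_threshold:.2f} mm"
    )
    if study.roc_size is not None:
        print(f"clinical-size AUC for comparison: {study.roc_size.auc:.3f}")

    fig_dir = OUT / "figures"
    fig_dir.mkdir(exist_ok=True)

    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    for ax, quantity, label in [
        (axes[0], "vsg_cc", "sac growth (cc)"),
        (axes[1], "vcg_cc", "coil growth (cc)"),
    ]:
        data = [
            per.loc[per.cohort == c, quantity].dropna() for c in ("recurrence", "control")
        ]
        ax.boxplot(data, tick_labels=["recurrence", "control"])
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(fig_dir / "growth_boxplots.png", dpi=150)

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(1 - study.roc_delta.specificities, study.roc_delta.sensitivities,
            marker="o", label=f"coil translation (AUC {study.roc_delta.auc:.2f})")
    if study.roc_size is not None:
        ax.plot(1 - study.roc_size.specificities, study.roc_size.sensitivities,
                marker="s", ls="--", label=f"clinical size (AUC {study.roc_size.auc:.2f})")
    ax.plot([0, 1], [0, 1], color="grey", lw=0.5)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(fig_dir / "delta_roc.png", dpi=150)
    print(f"figures -> {fig_dir}")


if __name__ == "__main__":
    main()
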