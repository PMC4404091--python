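"""Demographics of the packaged study cohort sheet: clinical sizes per
cohort, the between-cohort size comparison, and how well size alone
predicts recurrence.

Writes results/demographics.json.
"""

import json
from pathlib import Path

from coilwatch import demographics_summary, load_table1

OUT = Path("results")


def main() -> None:
    summary = demographics_summary(load_table1())
    OUT.mkdir(exist_ok=True)
    (OUT / "demographics.json").write_text(json.dumps(summary, indent=2))

    rec, ctl = summary["recurrence"], summary["control"]
    print(
        f"recurrence: {rec['n_aneurysms']} aneurysms, median size "
        f"{rec['median_size_mm']:.1f} mm, {rec['n_size_ge_10mm']} of "
        f"{rec['n_aneurysms']} at >= 10 mm, mean follow-up "
        f"{rec['mean_followup_months_per_aneurysm']:.1f} mo"
    )
    print(
        f"control: {ctl['n_aneurysms']} aneurysms in {ctl['n_patients']} "
        f"patients, median size {ctl['median_size_mm']:.1f} mm, mean "
        f"follow-up {ctl['mean_followup_months_per_aneurysm']:.1f} mo"
    )
    print(
        f"size difference (two-sided Mann-Whitney): p = "
        f"{summary['size_mannwhitney_two_sided_p']:.4f}; size ROC AUC = "
        f"{summary['size_roc_auc']:.2f}"
    )


if __name__ == "__main__":
    main()
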