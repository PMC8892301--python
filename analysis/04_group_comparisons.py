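"""Stage 4 — two-group statistical comparison of feasibility measures.

Joins the participant summaries with metadata and builds the full
AECOPD-vs-Stable report: Fisher exact for frequencies, Welch t or
Mann-Whitney U for continuous measures (routed by per-group Shapiro-Wilk),
journal-style p formatting. Also reports the BMI-quality Spearman
correlations within each group. Writes results/cohort_comparison.csv and
results/quality_correlations.csv.
"""

from pathlib import Path

import pandas as pd

from vestwear.cohort_stats import build_cohort_table, spearman_rho

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    participants = pd.read_csv(ROOT / "results" / "participant_summaries.csv")
    meta = pd.read_csv(ROOT / "results" / "cohort" / "participants.csv")

    report = build_cohort_table(participants, meta)
    report.to_csv(ROOT / "results" / "cohort_comparison.csv", index=False)

    df = meta.merge(participants, on="participant_id")
    corr_rows = []
    for group, x_var, y_var in [
        ("Stable", "bmi", "hr_signal_quality"),
        ("Stable", "bmi", "hr_data_quality"),
        ("AECOPD", "waist_circumference_cm", "rr_data_quality"),
        ("AECOPD", "bmi", "rr_data_quality"),
    ]:
        g = df[df["group"] == group]
        r = spearman_rho(g[x_var], g[y_var], x_variable=x_var, y_variable=y_var)
        corr_rows.append({"group": group, **vars(r)})
    corr = pd.DataFrame(corr_rows)
    corr.to_csv(ROOT / "results" / "quality_correlations.csv", index=False)

    print(f"{len(report)} comparison rows written")
    sig = report[report["p_value"] < 0.05]
    print(f"rows with p < .05 ({len(sig)}):")
    print(sig[["variable", "test", "p_formatted"]].to_string(index=False))
    print("\nquality-anthropometry correlations (Spearman):")
    print(corr.to_string(index=False))
    print("\nnote: p-values are unadjusted for multiple comparisons")


if __name__ == "__main__":
    main()
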