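"""Descriptive survival summaries of the simulated cohort: counts, share
ever married and observed-case age-at-marriage statistics, overall and by
each covariate (and by region cluster).

Reads scratch/cohort.csv; writes results/describe_overall.csv and one
results/describe_<covariate>.csv per grouping.
"""

from pathlib import Path

import pandas as pd

from llfrailty.describe import describe_by_group, format_summary, overall_summary

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch"
COVARIATES = [
    "cluster",
    "residence",
    "education",
    "religion",
    "wealth",
    "head_education",
    "work",
    "media",
    "head_occupation",
]


def main() -> None:
    df = pd.read_csv(SCRATCH / "cohort.csv")
    ov = overall_summary(df)
    format_summary(pd.DataFrame([ov.__dict__])).to_csv(
        OUT / "describe_overall.csv", index=False
    )
    print(
        f"overall: {ov.n_married}/{ov.n_total} ever married "
        f"({ov.pct_married_of_total:.2f}%), "
        f"median age {ov.median_age:.1f}, mean {ov.mean_age:.1f}, "
        f"range [{ov.min_age:.1f}, {ov.max_age:.1f}]"
    )
    for name in COVARIATES:
        tab = format_summary(describe_by_group(df, name))
        tab.to_csv(OUT / f"describe_{name}.csv", index=False)
    print(f"wrote per-covariate tables for {len(COVARIATES)} groupings to {OUT}")


if __name__ == "__main__":
    main()
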