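#!/usr/bin/env python
"""Group-by-criterion TMB summaries and between-group t-tests.

Renders the mean (SE) table per region — the shape of the study's summary
table — and runs the pooled-variance t-test Black vs White for each
criterion. Expect near-identical groups under paired-germline filtering
and a growing, significant gap as the database threshold loosens.
"""

import argparse
from pathlib import Path

import pandas as pd

from tmburden.cohort_stats import (
    student_t_test,
    summarize_groups,
    table1_layout,
)
from tmburden.variant_core import read_tmb_table

ORDER = ["TMB_Germline", "TMB_DB0", "TMB_DB0.001", "TMB_DB0.01"]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    df = read_tmb_table(args.results / "tmb_table.tsv")
    summary = summarize_groups(df)
    summary.to_csv(args.results / "group_summary.tsv", sep="\t", index=False)

    rows = []
    for region in df.region.unique():
        print(f"\nTMB (mutations/Mb), mean (SE) — {region}:")
        print(table1_layout(summary, region, ORDER).to_string())
        sub_r = df[df.region == region]
        for crit in ORDER:
            sub = sub_r[sub_r.criterion == crit]
            r = student_t_test(sub.loc[sub.group == "Black", "tmb"],
                               sub.loc[sub.group == "White", "tmb"])
            rows.append({"region": region, "criterion": crit,
                         "t": r.t, "df": r.df, "p": r.p})
    tt = pd.DataFrame(rows)
    tt.to_csv(args.results / "t_tests.tsv", sep="\t", index=False)
    print("\nBlack vs White t-tests:")
    print(tt.to_string(index=False))


if __name__ == "__main__":
    main()
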