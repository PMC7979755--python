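#!/usr/bin/env python
"""TMB-high classification at the 10 mutations/Mb threshold.

Counts patients at or above the approved TMB-H cutoff under each criterion
and, per database criterion, the discordant patients — TMB-H under
tumor-only filtering but not under the paired-germline gold standard, i.e.
patients who would be inappropriately selected for checkpoint-inhibitor
therapy.
"""

import argparse
from pathlib import Path

from tmburden.cohort_stats import classify_tmb_high
from tmburden.variant_core import read_tmb_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--threshold", type=float, default=10.0)
    args = ap.parse_args()

    df = read_tmb_table(args.results / "tmb_table.tsv")
    res = classify_tmb_high(df, threshold=args.threshold)
    res.counts.to_csv(args.results / "tmb_high.tsv", sep="\t", index=False)
    res.discordant.to_csv(args.results / "tmb_high_discordance.tsv",
                          sep="\t", index=False)

    exome = res.discordant[res.discordant.region == "exome"]
    print(f"TMB-H threshold: >= {args.threshold} mutations/Mb (exome)")
    for _, r in exome.iterrows():
        print(f"  {r.group:6s} {r.criterion:12s}: "
              f"{r.n_discordant} patients TMB-H under tumor-only filtering "
              "but not under paired germline")


if __name__ == "__main__":
    main()
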