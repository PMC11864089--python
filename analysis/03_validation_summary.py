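"""Summarize observed-vs-predicted agreement by wave, outcome and level.

Reads the estimate tables produced by 02_develop_models.py and reports the
mean and maximum |predicted - observed| (percentage points).  The
health-region rows are noisier than the province rows, and the perceived
outcome shows the systematic shortfall of marginal-proportion synthetic
estimation under within-area heterogeneity (see docs/methods.md), while the
low-prevalence unmet outcome tracks observation much more closely.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    report_path = ROOT / "results" / "study" / "report.csv"
    if not report_path.exists():
        print("run analysis/02_develop_models.py first", file=sys.stderr)
        return 1
    report = pd.read_csv(report_path)
    report["abs_difference"] = report["difference_pct"].abs()
    summary = (
        report.groupby(["outcome", "level", "label"])["abs_difference"]
        .agg(["mean", "max", "count"])
        .round(2)
        .reset_index()
        .rename(columns={"mean": "mean_abs_diff_pct", "max": "max_abs_diff_pct",
                         "count": "areas"})
    )
    out = ROOT / "results" / "validation_summary.csv"
    summary.to_csv(out, index=False)
    print(summary.to_string(index=False))
    print(f"\nwrote {out}")


if __name__ == "__main__":
    sys.exit(main())
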