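"""Generate the three emulated survey waves and summarize their structure.

Writes the respondent-level CSVs (bulky) under scratch/data/ and a compact
per-wave summary (sample sizes, weighted outcome prevalences) under
results/.  The development wave targets ~18% perceived-need and ~3.9%
unmet-need prevalence; the validation waves drift mildly, mirroring
year-to-year change in the real survey series.
"""

import sys
from pathlib import Path

import pandas as pd

from synthprev import generate_population, make_replicate_weights, weighted_proportion
from synthprev.studies import EXAMPLE_LABELS, example_config

ROOT = Path(__file__).resolve().parents[1]


def main(n_bootstrap: int = 100) -> None:
    rows = []
    for label in EXAMPLE_LABELS:
        ds = generate_population(example_config(label))
        ds = make_replicate_weights(ds, n_bootstrap, seed=example_config(label).seed + 1)
        ds.to_csv(ROOT / "scratch" / "data" / label)
        rows.append(
            {
                "wave": label,
                "respondents": ds.n,
                "provinces": ds.df["province_id"].nunique(),
                "health_regions": ds.df["area_id"].nunique(),
                "perceived_need_pct": round(weighted_proportion(ds, "perceived_need").value, 2),
                "unmet_need_pct": round(weighted_proportion(ds, "unmet_need").value, 2),
            }
        )
        print(f"{label}: n={ds.n}, perceived {rows[-1]['perceived_need_pct']}%, "
              f"unmet {rows[-1]['unmet_need_pct']}%")
    out = ROOT / "results" / "wave_summary.csv"
    out.parent.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    sys.exit(main())
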