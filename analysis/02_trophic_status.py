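"""Classify monthly trophic states and campaign lake categories from Chl-a.

Each lake-month gets a Carlson state from its replicate-mean chlorophyll-a;
campaign categories follow the >= 4 hypereutrophic months rule and the
oligo/meso majority rule.  Output: results/trophic/trophic_status.tsv.
"""

import pandas as pd

from limnotraj.io import monthly_mean_chla
from limnotraj.trophic import categorize_lakes, classify_trophic_state

from _common import campaign, outdir


def main():
    _, _, chla, truth = campaign()
    monthly = monthly_mean_chla(chla)
    states = monthly.apply(
        lambda row: row.dropna().map(lambda v: str(classify_trophic_state(v))),
        axis=1,
    )
    cats = categorize_lakes(monthly)
    summary = pd.DataFrame(
        {
            "category": cats.astype(str),
            "expected": {k: str(v) for k, v in truth.expected_category.items()},
            "mean_chla_ug_per_l": monthly.mean(axis=1).round(2),
            "hyper_months": states.apply(
                lambda r: (r == "hypereutrophic").sum(), axis=1
            ),
        }
    )
    out = outdir("trophic")
    states.to_csv(out / "monthly_states.tsv", sep="\t")
    summary.to_csv(out / "trophic_status.tsv", sep="\t")
    print(summary.to_string())
    agreement = (summary["category"] == summary["expected"]).mean()
    print(f"\ncategories match generator ground truth: {agreement:.0%}")


if __name__ == "__main__":
    main()
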