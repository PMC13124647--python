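"""Generate the shared synthetic campaign and export its tables.

Writes the ASV count table, sample metadata, chlorophyll-a measurements and
the generator's expected lake categories under results/synthetic/.
"""

import pandas as pd

from limnotraj.io import write_asv_table, write_chla

from _common import campaign, outdir


def main():
    table, meta, chla, truth = campaign()
    out = outdir("synthetic")
    write_asv_table(table, out / "counts.tsv")
    meta.to_csv(out / "metadata.tsv", sep="\t")
    write_chla(chla, out / "chla.csv")
    cats = pd.Series(
        {k: str(v) for k, v in truth.expected_category.items()}, name="category"
    ).rename_axis("lake")
    cats.to_csv(out / "expected_categories.tsv", sep="\t")
    n, m = table.shape
    print(f"campaign: {n} samples x {m} ASVs, depth {table.sample_totals().iloc[0]}")
    print(f"expected categories: {cats.value_counts().to_dict()}")
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
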