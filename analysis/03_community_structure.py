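"""Alpha diversity, Bray-Curtis ordination and PERMANOVA of the campaign.

Computes per-sample richness/Shannon diversity, the shared PCoA, and the
sequential PERMANOVA partition (lake, season, lake:season).  Outputs under
results/community/.
"""

from limnotraj.community import (
    alpha_diversity_table,
    bray_curtis,
    pcoa,
    permanova,
    write_distance_matrix,
)

from _common import CAMPAIGN_SEED, campaign, outdir


def main():
    table, meta, _, _ = campaign()
    out = outdir("community")

    alpha = alpha_diversity_table(table).join(meta[["lake", "season"]])
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    by_season = alpha.groupby("season")["richness"].mean().round(1)
    print("mean richness by season:")
    print(by_season.to_string())

    dm = bray_curtis(table)
    write_distance_matrix(dm, out / "bray_curtis.tsv")
    ordn = pcoa(dm)
    ordn.coordinates.iloc[:, :10].to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    print(
        f"\nPCoA: first two axes explain "
        f"{100 * ordn.variance_fraction[:2].sum():.1f}% of positive-eigenvalue variance"
    )

    res = permanova(dm, meta, n_perm=999, seed=CAMPAIGN_SEED)
    res.table.to_csv(out / "permanova.tsv", sep="\t")
    print("\nPERMANOVA (sequential SS, 999 permutations):")
    print(res.table.round(4).to_string())


if __name__ == "__main__":
    main()
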