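"""Time-lag analysis: dissimilarity vs elapsed days, per lake.

For every lake, all date-pair Bray-Curtis dissimilarities are regressed on
elapsed days with polynomials of degree 1-5 compared by AIC, and the linear
slope yields a diverging / converging / stationary verdict.
Output: results/tla/tla_summary.tsv.
"""

from limnotraj.community import bray_curtis
from limnotraj.timelag import lag_analysis_table

from _common import campaign, outdir


def main():
    table, meta, chla, truth = campaign()
    dm = bray_curtis(table)
    result = lag_analysis_table(dm, meta)
    mean_chla = chla.groupby("lake")["chla_ug_per_l"].mean()
    result = result.assign(
        mean_chla=mean_chla.round(2),
        sigma_drift=[truth.sigma_drift[l] for l in result.index],
    ).sort_values("sigma_drift")
    out = outdir("tla")
    result.to_csv(out / "tla_summary.tsv", sep="\t")
    print(result.round(4).to_string())
    diverging = result.index[result["verdict"] == "diverging"].tolist()
    print(f"\ndiverging lakes (positive significant slope): {diverging}")
    print("best model is polynomial (degree >= 2) in "
          f"{(result['best_degree'] >= 2).sum()}/{len(result)} lakes")


if __name__ == "__main__":
    main()
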