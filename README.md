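# limnotraj

Temporal community analysis for lake microeukaryote 18S ASV time series.

Small peri-urban lakes respond quickly to eutrophication, and their
microeukaryote communities (cryptophytes, ciliates, chrysophytes, green
algae, parasites, ...) reorganise along the trophic gradient. `limnotraj`
implements the statistical machinery needed to analyse a multi-lake monthly
metabarcoding campaign — the kind of design where nine lakes are sampled
monthly over 18 months at three mid-lake water columns, with chlorophyll-a
measured in triplicate:

- **Count-table handling** — validated ASV count tables, lineage filtering
  (Metazoa, plastids, unassigned, ...), and seeded rarefaction without
  replacement to a common depth.
- **Trophic annotation** — Carlson trophic states from chlorophyll-a
  (oligotrophic < 2.6, mesotrophic 2.6–7.3, eutrophic 7.3–56,
  hypereutrophic > 56 µg·L⁻¹), campaign-level lake categories, and
  trophic-mode annotation (phototroph / mixotroph / phagotroph / parasite)
  of ASVs at the class rank.
- **Community statistics** — ASV richness and Shannon diversity
  (H = −Σ pᵢ ln pᵢ), Bray–Curtis dissimilarity
  (BC = Σ|xᵢⱼ−xᵢₖ| / Σ(xᵢⱼ+xᵢₖ)), PCoA, sequential (Type-I) PERMANOVA with
  crossed `lake`, `season` and `lake:season` terms, Spearman tests, and PCA
  of environmental parameters with cos² variable loadings.
- **Trajectory analysis (MOTA)** — each lake's monthly centroids travel
  through a PCoA space shared by all lakes (minimum axes exceeding 90%
  cumulative variance); the summed Euclidean centroid-to-centroid distance
  is the trajectory length, comparable across lakes and correlated with
  mean chlorophyll-a.
- **Time-lag analysis (TLA)** — Bray–Curtis dissimilarity of every pair of
  sampling dates regressed on elapsed days; polynomials of degree 1–5
  compete by AIC, and a significantly positive linear slope marks a
  community that diverges instead of cycling back.
- **Co-occurrence networks** — per-lake core ASVs (≥ 1% relative abundance
  in ≥ 1 sample), SparCC basis correlations from log-ratio variances with
  Dirichlet resampling and iterative strong-pair exclusion, signed networks
  at |ρ| ≥ 0.6, and the usual metric battery (components including
  singletons, modules, transitivity, greedy modularity, LCC share,
  trophic-mode composition), aggregated by trophic category (mean ± SD,
  n−1).
- **Synthetic campaigns** — a generator that plants seasonal cycles, a
  dominance/chlorophyll eutrophication gradient and lake-specific
  compositional drift, with deterministic ground truth, so every pipeline
  stage is testable end to end without any sequencing data.

## Worked example

The numbered drivers under `analysis/` run a complete campaign analysis on
the default synthetic gradient (9 lakes × 18 months × 3 replicates, 300
ASVs rarefied-depth 12 287). For example:

```bash
cd analysis
python 01_simulate.py
python 04_mota.py
```

prints (abridged):

```
axes needed for > 90% cumulative variance: 64
      n_months  total_length  normalized_length  mean_chla  sigma_drift
lake
L2          18         3.147              1.000       3.46        0.192
L1          18         3.184              1.012       2.93        0.128
...
L8          18         6.283              1.997      76.74        1.200
L9          18         7.678              2.440     152.14        1.440

Spearman, trajectory length vs campaign-mean Chl-a: rho = 0.93, p = 0.0002 (n = 9 lakes)
```

The three oligo-/mesotrophic lakes have the shortest community trajectories
(normalised length ≈ 1), the two lakes that reach hypereutrophy the longest
(≈ 2–2.4×), and length correlates strongly with mean chlorophyll-a — the
planted drift-along-the-gradient structure, recovered by the pipeline.
`02_trophic_status.py` categorizes the lakes 3 / 4 / 2
(oligo-meso / meso-eu / eu-hyper) exactly as the generator's ground truth
predicts, `05_timelag.py` shows polynomial lag models beating linear ones
in every lake with divergence verdicts tracking planted drift, and
`06_networks.py` builds the nine SparCC networks and the category
mean ± SD table.

A `limnotraj` command-line interface exposes the same steps
(`limnotraj synth`, `filter`, `rarefy`, `trophic`, `betadiv`, `permanova`,
`mota`, `tla`, `network`, `aggregate`).

## Layout

```
src/limnotraj/     library: io, trophic, community, mota, timelag, network,
                   synthetic, cli (+ packaged reference/example data tables)
analysis/          numbered campaign drivers writing tables to results/
tests/             pytest suite incl. end-to-end recovery properties
scripts/           acceptance.py (see above)
docs/methods.md    models, parameters, numerical choices, limitations
```
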