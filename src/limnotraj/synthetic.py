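"""Synthetic multi-lake compositional time series with known ground truth.

The generator emulates the sampling design of the Greater-Paris peri-urban
lake survey: nine lakes spanning an eutrophication gradient, sampled monthly
over 18 months at three mid-lake water columns, with chlorophyll-a measured
in triplicate.  Latent log-abundances combine a lake-specific baseline
(dominance increasing with trophic level), a 12-month seasonal cycle with
per-ASV random phases, and per-ASV random walks whose lake-specific step SD
("drift") is the recoverable ground truth for trajectory and time-lag
analyses.  Counts are Dirichlet-multinomial so that the three water columns
carry realistic replicate-level overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io import AsvCountTable, validate_metadata
from .trophic import LakeCategory, categorize_lake, classify_trophic_state


@dataclass(frozen=True)
class LakeSpec:
    """One synthetic lake: trophic level tau in [0, 1] maps monotonically to
    expected chlorophyll-a; sigma_drift is the monthly random-walk step SD of
    the regime-drift component."""

    name: str
    tau: float
    sigma_drift: float

    def __post_init__(self):
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must be in [0, 1], got {self.tau}")
        if self.sigma_drift < 0:
            raise ValueError("sigma_drift must be >= 0")


@dataclass
class SyntheticConfig:
    """Generator parameters.

    Defaults reproduce the survey design: 9 lakes x 18 monthly time points x
    3 water-column replicates, campaign starting in June, sequencing depth
    equal to the rarefaction depth of 12287 reads.  ``seasonal_amplitude``
    bounds the per-ASV seasonal log-amplitude (drawn uniformly in [0, a]);
    dominance of a few taxa grows with tau through the baseline log-spread
    gamma(tau) = dominance_base + dominance_slope * tau.
    """

    lakes: list[LakeSpec] = field(default_factory=lambda: default_lakes())
    n_months: int = 18
    n_replicates: int = 3
    n_asvs: int = 300
    depth: int = 12287
    seasonal_amplitude: float = 1.2
    seasonal_period: int = 12
    dominance_base: float = 1.0
    dominance_slope: float = 2.0
    lake_effect_sd: float = 1.0
    overdispersion: float = 200.0
    #: mean-reversion rate (per month) of the drift walk; 1/24 bounds the
    #: cross-ASV drift spread near sqrt(12)*sigma_drift so a drifting lake
    #: keeps diverging over an 18-month campaign without collapsing into a
    #: runaway monoculture
    drift_reversion: float = 1.0 / 24.0
    start_calendar_month: int = 6
    start_year: int = 2021
    # chlorophyll-a model: lognormal around a tau- and season-dependent
    # median, ln median = ln(chla_base) + chla_tau_slope * tau
    #                     + chla_summer_boost * max(0, cos(2 pi (m - 7) / 12))
    chla_base: float = 1.2
    chla_tau_slope: float = 4.8
    chla_summer_boost: float = 1.0
    chla_noise_sd: float = 0.3
    chla_replicates: int = 3
    seed: int = 0


def default_lakes() -> list[LakeSpec]:
    """Nine lakes along the eutrophication gradient: three low-tau, four
    intermediate, two high-tau lakes, with drift proportional to tau.

    The drift scale 1.6 * tau makes monthly log-abundance steps at the
    hypereutrophic end (~1.2-1.4) correspond to order-of-magnitude swings of
    bloom taxa, while low-trophic lakes drift only weakly (~0.1-0.25)."""
    taus = [0.08, 0.12, 0.16, 0.35, 0.40, 0.45, 0.50, 0.75, 0.90]
    return [
        LakeSpec(name=f"L{i + 1}", tau=tau, sigma_drift=round(1.6 * tau, 4))
        for i, tau in enumerate(taus)
    ]


@dataclass
class GroundTruth:
    """Deterministic expectations implied by a config."""

    expected_category: dict[str, LakeCategory]
    sigma_drift: dict[str, float]
    expected_hyper_months: dict[str, int]
    seasonal_period: int
    expected_length_order: list[str]
    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)


def _calendar_months(cfg: SyntheticConfig) -> list[tuple[int, int]]:
    """(year, calendar month) for month_index 1..n_months."""
    out = []
    year, month = cfg.start_year, cfg.start_calendar_month
    for _ in range(cfg.n_months):
        out.append((year, month))
        month += 1
        if month > 12:
            month, year = 1, year + 1
    return out


def expected_monthly_chla(cfg: SyntheticConfig, lake: LakeSpec) -> np.ndarray:
    """Median chlorophyll-a per month_index (deterministic; noise-free)."""
    medians = []
    for _, month in _calendar_months(cfg):
        seasonal = max(0.0, np.cos(2 * np.pi * (month - 7) / 12))
        log_median = (
            np.log(cfg.chla_base)
            + cfg.chla_tau_slope * lake.tau
            + cfg.chla_summer_boost * seasonal
        )
        medians.append(np.exp(log_median))
    return np.array(medians)


def expected_ground_truth(cfg: SyntheticConfig) -> GroundTruth:
    """Expected categories, hypereutrophic month counts and trajectory-length
    ordering, derived deterministically from the config."""
    categories = {}
    hyper = {}
    for lake in cfg.lakes:
        medians = expected_monthly_chla(cfg, lake)
        categories[lake.name] = categorize_lake(medians)
        hyper[lake.name] = sum(
            classify_trophic_state(v).name == "HYPEREUTROPHIC" for v in medians
        )
    order = [l.name for l in sorted(cfg.lakes, key=lambda l: l.sigma_drift)]
    return GroundTruth(
        expected_category=categories,
        sigma_drift={l.name: l.sigma_drift for l in cfg.lakes},
        expected_hyper_months=hyper,
        seasonal_period=cfg.seasonal_period,
        expected_length_order=order,
    )


def generate_lake_series(
    cfg: SyntheticConfig, seed: int | None = None
) -> tuple[AsvCountTable, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (counts, metadata, chlorophyll-a, ground truth).

    Latent log-abundance of ASV i in lake l at month t:

        eta = baseline_i(l) + alpha_i cos(2 pi (m_t - phi_i) / period)
              + W_it(l)

    with baseline ~ N(0, gamma(tau)) plus a lake effect ~ N(0, lake_effect_sd),
    per-ASV amplitude alpha_i ~ U(0, seasonal_amplitude) and phase phi_i
    ~ U(0, period); W_i(l) is a per-ASV mean-reverting random walk with
    lake-specific step SD sigma_drift(l) and reversion rate drift_reversion,
    so a drifting lake's composition keeps exploring fresh directions over
    the campaign without collapsing into a runaway monoculture.  Replicate counts
    are Dirichlet-multinomial:
    Multinomial(depth, Dirichlet(theta * softmax(eta))).
    """
    if seed is None:
        seed = cfg.seed
    if cfg.depth < cfg.n_asvs:
        import warnings

        warnings.warn(
            f"depth {cfg.depth} below n_asvs {cfg.n_asvs}; rare ASVs unseen"
        )
    rng = np.random.default_rng(seed)
    months = _calendar_months(cfg)

    count_rows, sample_ids, meta_rows, chla_rows = [], [], [], []
    for lake in cfg.lakes:
        gamma = cfg.dominance_base + cfg.dominance_slope * lake.tau
        baseline = rng.normal(0.0, gamma, cfg.n_asvs)
        lake_effect = rng.normal(0.0, cfg.lake_effect_sd, cfg.n_asvs)
        alpha = rng.uniform(0.0, cfg.seasonal_amplitude, cfg.n_asvs)
        phi = rng.uniform(0.0, cfg.seasonal_period, cfg.n_asvs)
        steps = rng.normal(0.0, lake.sigma_drift, (cfg.n_months, cfg.n_asvs))
        walk = np.empty_like(steps)
        state = np.zeros(cfg.n_asvs)
        for t in range(cfg.n_months):
            state = state * (1.0 - cfg.drift_reversion) + steps[t]
            walk[t] = state

        medians = expected_monthly_chla(cfg, lake)
        for t, (year, month) in enumerate(months):
            eta = (
                baseline
                + lake_effect
                + alpha * np.cos(2 * np.pi * (month - phi) / cfg.seasonal_period)
                + walk[t]
            )
            eta -= eta.max()
            p = np.exp(eta)
            p /= p.sum()
            alpha_dir = np.clip(p * cfg.overdispersion, 1e-8, None)
            date = pd.Timestamp(year=year, month=month, day=15)
            for r in range(cfg.n_replicates):
                fractions = rng.dirichlet(alpha_dir)
                counts = rng.multinomial(cfg.depth, fractions)
                sid = f"{lake.name}-M{t + 1:02d}-W{r + 1}"
                count_rows.append(counts)
                sample_ids.append(sid)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "lake": lake.name,
                        "date": date.date().isoformat(),
                        "replicate": f"W{r + 1}",
                        "month_index": t + 1,
                    }
                )
            for r in range(cfg.chla_replicates):
                chla_rows.append(
                    {
                        "lake": lake.name,
                        "month_index": t + 1,
                        "replicate": r + 1,
                        "chla_ug_per_l": float(
                            medians[t] * np.exp(rng.normal(0.0, cfg.chla_noise_sd))
                        ),
                    }
                )

    counts_df = pd.DataFrame(
        np.vstack(count_rows),
        index=sample_ids,
        columns=[f"ASV{i + 1:04d}" for i in range(cfg.n_asvs)],
    )
    counts_df.index.name = "sample_id"
    table = AsvCountTable(counts_df)
    meta = validate_metadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    chla = pd.DataFrame(chla_rows)
    return table, meta, chla, expected_ground_truth(cfg)


def generate_correlated_counts(
    pairs: list[tuple[int, int, float]],
    n_samples: int,
    n_asvs: int,
    depth: int,
    seed: int | None = None,
    log_sd: float = 1.0,
    mean_log_spread: float = 1.0,
) -> AsvCountTable:
    """Compositional counts with planted basis (log-abundance) correlations.

    Basis abundances are log-normal: log-abundance of taxon i has SD
    ``log_sd`` and correlation rho for each planted pair (i, j, rho),
    independent otherwise.  Abundances are closed to fractions and sampled
    with a multinomial at the given depth, so only relative information
    survives — the fixture SparCC is meant to invert.
    """
    cov = np.eye(n_asvs) * log_sd**2
    for i, j, rho in pairs:
        if not -1.0 < rho < 1.0:
            raise ValueError(f"target correlation must be in (-1, 1), got {rho}")
        if i == j:
            raise ValueError("planted pair must involve two distinct taxa")
        cov[i, j] = cov[j, i] = rho * log_sd**2
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("planted covariance is not positive definite") from exc
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, mean_log_spread, n_asvs)
    z = rng.standard_normal((n_samples, n_asvs)) @ chol.T + mu
    basis = np.exp(z)
    fractions = basis / basis.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, f) for f in fractions])
    df = pd.DataFrame(
        counts,
        index=[f"S{k + 1:03d}" for k in range(n_samples)],
        columns=[f"T{k + 1:03d}" for k in range(n_asvs)],
    )
    df.index.name = "sample_id"
    return AsvCountTable(df)


def config_from_yaml(path) -> SyntheticConfig:
    """Load a :class:`SyntheticConfig` from a YAML file; the ``lakes`` key is
    a list of {name, tau, sigma_drift} mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    lakes = raw.pop("lakes", None)
    cfg = SyntheticConfig(**raw)
    if lakes is not None:
        cfg.lakes = [LakeSpec(**entry) for entry in lakes]
    return cfg
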