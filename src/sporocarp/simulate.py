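"""Synthetic fungal-inventory generator.

Emulates the statistical structure of a multi-year terricolous macrofungus
inventory: a regional species pool of two trophic guilds (ectomycorrhizal,
ECM, and saprotrophic, ST) with lognormal fruit-body sizes (ECM larger on
average), a size-number trade-off in reproductive output, strongly skewed
plot occupancy, plots arranged along a latent resource-availability
gradient, and trait-based environmental filtering of the regional pool into
local assemblages whose strength can differ between guilds and vary along
the gradient.

The filtering model: species s of guild g enters plot i (independently per
year) with probability

    p_is = min(p_max, q_s * exp(-lambda_g(r_i) * (x_s - mu_g))),
    lambda_g(r) = max(0, lambda0_g - lambda1_g * r),

where q_s is the species' base occupancy weight, x_s its log10 fruit-body
size, mu_g the guild's pool mean log10 size and r_i the plot's latent
resource score.  lambda > 0 penalizes large species, so assemblages are
smaller-bodied than the pool; lambda1 > 0 relaxes the penalty on
resource-rich plots, so assemblage mean size increases along the gradient.
Fruit-body counts are drawn negative-binomially around each species'
characteristic count (heavy right tail), which follows a log-linear
trade-off against size.

Everything is deterministic given (config, seed): per-stage RNG substreams
are spawned from the master seed, so datasets are regenerable exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    ENV_VARIABLES,
    CommunityTable,
    EnvironmentTable,
    RegionalPool,
    TraitTable,
)

GUILDS = ("ECM", "ST")


@dataclass
class SimulationConfig:
    """Study-design and process parameters of the generator.

    Defaults emulate the study conditions: 48 plots sampled over three
    years, a ~600-species regional pool split evenly between guilds, ECM
    log10 size centred well above ST, strong size filtering of the ST guild
    (saprotrophs depend on a local carbon resource) and mild filtering of
    ECM, with filtering relaxing as resource availability increases.
    """

    n_plots: int = 48
    years: tuple[int, ...] = (2009, 2010, 2011)
    n_pool: dict = field(default_factory=lambda: {"ECM": 300, "ST": 300})
    # log10 fruit-body size (mm^2) per guild
    log_size_mean: dict = field(default_factory=lambda: {"ECM": 3.2, "ST": 2.6})
    log_size_sd: dict = field(default_factory=lambda: {"ECM": 0.5, "ST": 0.5})
    # size-number trade-off: log10 count = a - b * log10 size + noise
    count_intercept: float = 2.5
    trade_off_slope: float = 0.5
    count_noise_sd: float = 0.3
    count_dispersion: float = 0.7  # negative-binomial shape (heavy tail when small)
    # base occupancy weights q_s ~ Beta(a, b): right-skewed, most species rare
    occupancy_a: float = 0.35
    occupancy_b: float = 8.0
    max_inclusion_prob: float = 0.95
    # filtering strength lambda_g(r) = max(0, lambda0 - lambda1 * r)
    lambda0: dict = field(default_factory=lambda: {"ECM": 0.5, "ST": 2.5})
    lambda1: dict = field(default_factory=lambda: {"ECM": 0.5, "ST": 0.5})
    # environment generation
    env_noise: float = 1.0  # scales all stand-variable noise sds
    age_resource_coupling: float = 0.0  # stand age mostly independent of resource
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.log_size_sd.values()):
            raise ValueError("log_size_sd entries must be >= 0")
        if not 0 < self.max_inclusion_prob <= 1:
            raise ValueError("max_inclusion_prob must be in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["years"] = list(self.years)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "years" in d:
            d["years"] = tuple(d["years"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def simulate_pool(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[RegionalPool, pd.DataFrame]:
    """Regional pool: sizes, characteristic counts and occupancy weights.

    Returns the pool trait table (guild, cap diameter) plus the full
    per-species parameter frame (log10 size, characteristic fruit-body
    count from the trade-off line, base occupancy weight q).
    """
    rows = []
    for guild in GUILDS:
        n = config.n_pool[guild]
        x = rng.normal(config.log_size_mean[guild], config.log_size_sd[guild], n)
        log_n = (
            config.count_intercept
            - config.trade_off_slope * x
            + rng.normal(0.0, config.count_noise_sd, n)
        )
        q = rng.beta(config.occupancy_a, config.occupancy_b, n)
        for i in range(n):
            rows.append({
                "species_id": f"{guild}_{i + 1:04d}",
                "guild": guild,
                "log10_size": x[i],
                "char_count": 10.0 ** log_n[i],
                "occupancy_weight": q[i],
            })
    params = pd.DataFrame(rows).set_index("species_id")
    pool_df = pd.DataFrame({
        "species_id": params.index,
        "guild": params["guild"].to_numpy(),
        # d^2 = fruit-body size, so d = 10^(log10_size / 2)
        "cap_diameter_mm": 10.0 ** (params["log10_size"].to_numpy() / 2.0),
    })
    return RegionalPool(pool_df), params


#: stand-variable generation: intercept, loading on resource r, noise sd
_ENV_MODEL = {
    "tree_count": (420.0, -80.0, 60.0),
    "volume": (450.0, 180.0, 60.0),
    "basal_area": (35.0, 10.0, 4.0),
    "mean_dbh": (0.35, 0.08, 0.03),
    "cover_shrub": (25.0, -5.0, 8.0),
    "cover_upper": (60.0, 15.0, 8.0),
}
# driven by the succession latent s instead of r
_ENV_MODEL_SUCCESSION = {
    "cover_lower": (30.0, 12.0, 6.0),
    "stand_age": (120.0, 35.0, 10.0),
}


def simulate_environment(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[EnvironmentTable, pd.DataFrame]:
    """Stand variables as linear responses to two latent axes.

    Growing-stock variables and canopy cover respond to the latent resource
    score r; stand age and the lower tree layer respond to an independent
    succession latent s (plus an optional r coupling for age), mirroring a
    resource axis (PC1) and an age axis (PC2).
    """
    n = config.n_plots
    r = rng.normal(size=n)
    s = rng.normal(size=n)
    plot_ids = [f"plot_{i + 1:03d}" for i in range(n)]
    data: dict[str, np.ndarray] = {}
    for var in ENV_VARIABLES:
        if var in _ENV_MODEL:
            a, b, sd = _ENV_MODEL[var]
            data[var] = a + b * r + rng.normal(0.0, sd * config.env_noise, n)
        else:
            a, b, sd = _ENV_MODEL_SUCCESSION[var]
            data[var] = a + b * s + rng.normal(0.0, sd * config.env_noise, n)
            if var == "stand_age":
                data[var] = data[var] + config.age_resource_coupling * r
    env = EnvironmentTable(pd.DataFrame(data, index=pd.Index(plot_ids, name="plot_id")))
    truth = pd.DataFrame(
        {"resource_latent": r, "succession_latent": s},
        index=pd.Index(plot_ids, name="plot_id"),
    )
    for guild in GUILDS:
        truth[f"lambda_{guild}"] = np.maximum(
            0.0, config.lambda0[guild] - config.lambda1[guild] * r
        )
    return env, truth


def simulate_communities(
    species_params: pd.DataFrame,
    env_truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> CommunityTable:
    """Draw multi-year plot assemblages and fruit-body counts.

    Inclusion is independent across plots and years with the filtering
    probability described in the module docstring; counts for included
    species are zero-truncated negative binomial around the species'
    characteristic count.
    """
    plots = env_truth.index.to_numpy()
    r = env_truth["resource_latent"].to_numpy()
    x = species_params["log10_size"].to_numpy()
    q = species_params["occupancy_weight"].to_numpy()
    char_count = species_params["char_count"].to_numpy()
    guild_of = species_params["guild"].to_numpy()
    species_ids = species_params.index.to_numpy()

    # per-species, per-plot inclusion probability
    p = np.empty((len(species_ids), len(plots)))
    for guild in GUILDS:
        mask = guild_of == guild
        lam = np.maximum(0.0, config.lambda0[guild] - config.lambda1[guild] * r)
        centred = x[mask] - config.log_size_mean[guild]
        p[mask] = q[mask, None] * np.exp(-np.outer(centred, lam))
    np.minimum(p, config.max_inclusion_prob, out=p)

    k = config.count_dispersion
    records = []
    for year in config.years:
        present = rng.random(p.shape) < p
        sp_idx, plot_idx = np.nonzero(present)
        if len(sp_idx) == 0:
            continue
        means = char_count[sp_idx]
        counts = rng.negative_binomial(k, k / (k + means))
        counts = np.maximum(counts, 1)
        records.append(pd.DataFrame({
            "plot_id": plots[plot_idx],
            "species_id": species_ids[sp_idx],
            "year": year,
            "count": counts,
        }))
    df = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=["plot_id", "species_id", "year", "count"])
    )
    return CommunityTable(df)


# ---------------------------------------------------------------------------
# full datasets
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """One synthetic inventory plus the generating truth."""

    config: SimulationConfig
    pool: RegionalPool
    traits: TraitTable  # observed species only
    environment: EnvironmentTable
    community: CommunityTable
    env_truth: pd.DataFrame
    species_params: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.community.write(outdir / "communities.csv")
        self.traits.df.reset_index()[["species_id", "guild", "cap_diameter_mm"]].to_csv(
            outdir / "traits.csv", index=False
        )
        self.pool.df.reset_index()[["species_id", "guild", "cap_diameter_mm"]].to_csv(
            outdir / "pool.csv", index=False
        )
        self.environment.write(outdir / "environment.csv")
        self.env_truth.reset_index().to_csv(outdir / "latent_truth.csv", index=False)
        self.config.to_yaml(outdir / "config.yaml")


def simulate_regression_data(
    rng: np.random.Generator,
    n_plots: int = 48,
    years: tuple[int, ...] = (2009, 2010, 2011),
    slope_resource: float = 2.0,
    slope_age: float = 0.0,
    guild_effect: float = 0.0,
    interaction: float = 0.0,
    plot_sd: float = 0.0,
    resid_sd_ecm: float = 1.0,
    resid_sd_st: float = 1.0,
) -> pd.DataFrame:
    """Balanced plot x year x guild response table with known effects.

    Generates directly at the regression stage (bypassing communities):
    y = 1 + guild_effect*ECM + slope_resource*r + slope_age*age
    + interaction*ECM*r + plot intercept + guild-specific noise.  Used for
    mixed-model parameter-recovery checks.
    """
    resource = rng.normal(size=n_plots)
    age = rng.normal(size=n_plots)
    plot_eff = rng.normal(0.0, plot_sd, n_plots) if plot_sd > 0 else np.zeros(n_plots)
    rows = []
    for i in range(n_plots):
        for year in years:
            for guild in ("ECM", "ST"):
                sd = resid_sd_ecm if guild == "ECM" else resid_sd_st
                g = 1.0 if guild == "ECM" else 0.0
                y = (
                    1.0
                    + guild_effect * g
                    + slope_resource * resource[i]
                    + slope_age * age[i]
                    + interaction * g * resource[i]
                    + plot_eff[i]
                    + rng.normal(0.0, sd)
                )
                rows.append({
                    "plot_id": f"p{i:03d}", "guild": guild, "year": year,
                    "resource": resource[i], "age_axis": age[i], "y": y,
                })
    return pd.DataFrame(rows)


def simulate_dataset(
    config: SimulationConfig | None = None, seed: int | None = None
) -> SimulatedDataset:
    """Generate a full dataset (pool, traits, environment, communities).

    ``seed`` overrides ``config.seed``.  Each stage consumes its own RNG
    substream spawned from the master seed, so enlarging one stage never
    perturbs another.
    """
    if config is None:
        config = SimulationConfig()
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    rng_pool, rng_env, rng_comm = (np.random.default_rng(s) for s in ss.spawn(3))
    pool, params = simulate_pool(config, rng_pool)
    env, truth = simulate_environment(config, rng_env)
    community = simulate_communities(params, truth, config, rng_comm)
    observed = sorted(community.df["species_id"].unique())
    traits = TraitTable(
        pool.df.loc[pool.df.index.isin(observed)]
        .reset_index()[["species_id", "guild", "cap_diameter_mm"]]
    )
    return SimulatedDataset(config, pool, traits, env, community, truth, params)
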