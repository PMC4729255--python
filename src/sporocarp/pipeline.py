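"""End-to-end orchestration: filter -> transform -> guild split -> nulls -> SES -> models.

Every run is driven by one :class:`PipelineConfig`, which is serialized
verbatim into the output directory so each output file is traceable to a
single configuration and master seed.  Each randomized stage consumes its
own RNG substream spawned from the master seed; reruns with the same config
and seed are bit-identical (the run log records library versions, never
wall-clock time).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .nullmodels import regional_pool_ses_table, swap_ses_table
from .regression import ModelSpec, RegressionReport, fit_mixed
from .traits import assemblage_means, attach_community_traits, occupancy_filter

logger = logging.getLogger("sporocarp")

#: response metrics fitted by default, in output order
RESPONSES = (
    "raw_mean_log_size",
    "raw_mean_log_n",
    "ses_size_regional",
    "ses_size_local",
    "ses_n_local",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending context."""


@dataclass
class PipelineConfig:
    community_path: str = "communities.csv"
    traits_path: str = "traits.csv"
    pool_path: str = "pool.csv"
    environment_path: str = "environment.csv"
    out_dir: str = "results"
    min_plots: int = 4
    n_rand: int = 100
    burn_in: int | None = None  # None -> 10 x matrix fill
    thin: int | None = None  # None -> 2 x matrix fill
    swap_mode: str = "chain"
    count_mode: str = "pooled"
    responses: tuple[str, ...] = RESPONSES
    with_three_way: bool = False
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["responses"] = list(self.responses)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "responses" in d:
            d["responses"] = tuple(d["responses"])
        return cls(**d)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


@_stage("load")
def _load(config: PipelineConfig):
    community = sio.read_community_table(config.community_path)
    traits = sio.read_trait_table(config.traits_path)
    pool = sio.read_regional_pool(config.pool_path)
    env = sio.read_environment_table(config.environment_path)
    return community, traits, pool, env


@_stage("occupancy_filter")
def _filter(community, config: PipelineConfig):
    filtered = occupancy_filter(community, config.min_plots)
    if filtered.df.empty:
        raise PipelineError(
            f"stage 'occupancy_filter' failed: no species occur on >= "
            f"{config.min_plots} plots"
        )
    return filtered


@_stage("assemblage_means")
def _means(community, traits) -> pd.DataFrame:
    frames = []
    for year in community.years:
        for guild in sio.GUILDS:
            matrix = sio.to_binary_matrix(community, traits, guild, year)
            if matrix.is_empty:
                continue
            frames.append(assemblage_means(matrix, traits))
    if not frames:
        raise PipelineError("stage 'assemblage_means' failed: no non-empty matrices")
    return pd.concat(frames, ignore_index=True)


def compute_ses(community, traits, pool, config: PipelineConfig,
                rng_regional, rng_swap) -> pd.DataFrame:
    """Both null models' SES tables, concatenated."""
    regional = regional_pool_ses_table(community, traits, pool, config.n_rand, rng_regional)
    local = swap_ses_table(
        community, traits, n_rand=config.n_rand, burn_in=config.burn_in,
        thin=config.thin, seed=rng_swap, mode=config.swap_mode,
    )
    return pd.concat([regional, local], ignore_index=True)


def build_response_table(
    means: pd.DataFrame, ses_table: pd.DataFrame, scores: sio.GradientScores
) -> pd.DataFrame:
    """One row per plot x guild x year with all response metrics and covariates."""
    out = means.rename(columns={
        "mean_log_size": "raw_mean_log_size",
        "mean_log_n_fruitbodies": "raw_mean_log_n",
    })
    key = ["plot_id", "guild", "year"]
    for name, (metric, model) in {
        "ses_size_regional": ("mean_log_size", "regional_pool"),
        "ses_size_local": ("mean_log_size", "local_swap"),
        "ses_n_local": ("mean_log_n_fruitbodies", "local_swap"),
    }.items():
        sub = ses_table[
            (ses_table["metric"] == metric) & (ses_table["null_model"] == model)
        ][key + ["ses"]].rename(columns={"ses": name})
        out = out.merge(sub, on=key, how="left")
    out = out.merge(
        scores.scores.reset_index().rename(columns={scores.scores.index.name or "index": "plot_id"}),
        on="plot_id", how="left",
    )
    return out


@_stage("regression")
def _regress(responses: tuple[str, ...], table: pd.DataFrame,
             with_three_way: bool) -> list[RegressionReport]:
    reports = []
    for response in responses:
        if response not in table.columns:
            raise PipelineError(f"stage 'regression' failed: unknown response {response!r}")
        spec = ModelSpec(response=response, three_way_interaction=with_three_way)
        reports.append(fit_mixed(table, response, spec))
    return reports


def _stars(z: float) -> str:
    az = abs(z)
    if not np.isfinite(az):
        return ""
    return "***" if az > 3.29 else "**" if az > 2.58 else "*" if az > 1.96 else ""


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write all outputs into ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    log(f"versions: numpy={np.__version__} pandas={pd.__version__}")
    log(f"master seed: {config.seed}")

    community, traits, pool, env = _load(config)
    log(f"loaded {len(community.df)} records, {len(traits.df)} trait species, "
        f"{len(pool.df)} pool species, {len(env.df)} plots")

    community = _filter(community, config)
    log(f"after occupancy filter (>= {config.min_plots} plots): "
        f"{community.df['species_id'].nunique()} species")

    traits = attach_community_traits(traits, community, config.count_mode)
    means = _means(community, traits)
    means.to_csv(out / "assemblage_means.csv", index=False)
    log(f"assemblage means: {len(means)} plot/guild/year rows")

    ss = np.random.SeedSequence(config.seed)
    s_regional, s_swap = ss.spawn(2)
    ses_table = compute_ses(
        community, traits, pool, config,
        np.random.default_rng(s_regional), np.random.default_rng(s_swap),
    )
    ses_table.to_csv(out / "ses_results.csv", index=False)
    log(f"SES rows: {len(ses_table)}")

    scores = sio.pca_gradient(env)
    scores.scores.reset_index().to_csv(out / "gradient_scores.csv", index=False)
    log("PC variance fractions: "
        + ", ".join(f"{f:.3f}" for f in scores.variance_fractions[:3]))

    table = build_response_table(means, ses_table, scores)
    table.to_csv(out / "response_table.csv", index=False)

    reports = _regress(config.responses, table, config.with_three_way)
    coef_rows, var_rows = [], []
    for rep in reports:
        for row in rep.coefficients.itertuples(index=False):
            coef_rows.append({
                "response": rep.response, "term": row.term,
                "estimate": row.estimate, "se": row.se, "z": row.z,
                "stars": _stars(row.z),
            })
        var_rows.append({"response": rep.response, "adj_r2": rep.adj_r2,
                         "n_obs": rep.n_obs, **rep.variance_components})
    pd.DataFrame(coef_rows).to_csv(out / "regression_report.csv", index=False)
    pd.DataFrame(var_rows).to_csv(out / "variance_components.csv", index=False)
    log(f"fitted {len(reports)} mixed models")

    config.to_yaml(out / "pipeline_config.yaml")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
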