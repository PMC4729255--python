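"""Core data containers and delimited-text I/O.

The canonical on-disk representation is long-format delimited text
(``plot_id,species_id,year,count``): a sparse multi-year fungal inventory is
far more robust to store long than wide.  Wide binary species-by-plot views
are derived in memory, one per trophic guild and year, with lexicographic
row/column ordering so every downstream matrix operation is reproducible.

Containers are thin dataclasses around :class:`pandas.DataFrame`; validation
happens on construction so downstream stages can assume clean inputs.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sporocarp")

GUILDS = ("ECM", "ST")

#: stand variables expected in an environment table, in canonical order
ENV_VARIABLES = (
    "tree_count",
    "volume",
    "basal_area",
    "mean_dbh",
    "cover_shrub",
    "cover_lower",
    "cover_upper",
    "stand_age",
)


class SchemaError(ValueError):
    """A required column is missing or a key constraint is violated."""


class ValidationError(ValueError):
    """A cell value violates a domain constraint."""


def _sniff_sep(path: Path) -> str:
    with open(path, newline="", encoding="utf-8") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# community observations
# ---------------------------------------------------------------------------

@dataclass
class CommunityTable:
    """Long-format fruit-body observations: one row per (plot, species, year).

    Counts are numbers of fruit bodies.  Zero-count rows are dropped on
    construction (absence is implicit in long format); duplicate
    (plot, species, year) keys and negative counts are rejected.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.df, ["plot_id", "species_id", "year", "count"], "community table")
        df = self.df.copy()
        df["plot_id"] = df["plot_id"].astype(str)
        df["species_id"] = df["species_id"].astype(str)
        try:
            df["year"] = df["year"].astype(int)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"community table: non-integer year ({exc})") from exc
        counts = pd.to_numeric(df["count"], errors="coerce")
        if counts.isna().any():
            row = int(df.index[counts.isna()][0])
            raise ValidationError(f"community table: non-numeric count at row {row}")
        if (counts < 0).any():
            row = int(df.index[counts < 0][0])
            raise ValidationError(f"community table: negative count at row {row}")
        df["count"] = counts.astype(int)
        dup = df.duplicated(subset=["plot_id", "species_id", "year"])
        if dup.any():
            key = df.loc[dup.idxmax(), ["plot_id", "species_id", "year"]].tolist()
            raise SchemaError(f"community table: duplicate (plot, species, year) key {key}")
        n_zero = int((df["count"] == 0).sum())
        if n_zero:
            logger.info("community table: dropped %d zero-count record(s)", n_zero)
            df = df[df["count"] > 0]
        self.df = df.reset_index(drop=True)

    # -- basic views -------------------------------------------------------
    @property
    def plots(self) -> list[str]:
        return sorted(self.df["plot_id"].unique())

    @property
    def species(self) -> list[str]:
        return sorted(self.df["species_id"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.df["year"].unique())

    def occupancy(self) -> pd.Series:
        """Distinct plots ever occupied, per species (pooled over years)."""
        return self.df.groupby("species_id")["plot_id"].nunique().rename("occupancy")

    def occupancy_by_year(self) -> pd.DataFrame:
        """Plots occupied per species and year."""
        return (
            self.df.groupby(["species_id", "year"])["plot_id"]
            .nunique()
            .unstack(fill_value=0)
        )

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def read_community_table(path: str | Path) -> CommunityTable:
    """Read a long-format community file (comma/tab sniffed, header required)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    return CommunityTable(df)


def write_community_table(table: CommunityTable, path: str | Path) -> None:
    table.write(path)


# ---------------------------------------------------------------------------
# species traits and the regional pool
# ---------------------------------------------------------------------------

@dataclass
class TraitTable:
    """Per-species reproductive traits, indexed by species id.

    Columns: ``guild`` (ECM or ST), ``cap_diameter_mm`` (mean cap diameter d
    of mature fruit bodies), ``fruit_body_size`` (d², mm², a biomass index);
    optionally ``mean_fruit_bodies`` (fruit bodies per occupied plot) and
    ``occupancy`` once derived from a community table.  Species with an
    unknown guild are excluded with a warning rather than failing the load.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.name != "species_id":
            _require_columns(df, ["species_id"], "trait table")
            df = df.set_index("species_id")
        df.index = df.index.astype(str)
        _require_columns(df, ["guild", "cap_diameter_mm"], "trait table")
        bad_guild = ~df["guild"].isin(GUILDS)
        if bad_guild.any():
            excluded = df.index[bad_guild].tolist()
            logger.warning(
                "trait table: excluding %d species with unknown guild: %s",
                len(excluded), excluded[:10],
            )
            df = df[~bad_guild]
        d = pd.to_numeric(df["cap_diameter_mm"], errors="coerce")
        if d.isna().any() or (d <= 0).any():
            bad = df.index[d.isna() | (d <= 0)].tolist()
            raise ValidationError(f"trait table: non-positive cap diameter for {bad[:10]}")
        df = df.copy()
        df["cap_diameter_mm"] = d.astype(float)
        df["fruit_body_size"] = df["cap_diameter_mm"] ** 2
        self.df = df.sort_index()

    def species_of(self, guild: str) -> list[str]:
        _check_guild(guild)
        return self.df.index[self.df["guild"] == guild].tolist()

    def write(self, path: str | Path) -> None:
        self.df.reset_index().to_csv(path, index=False)


def read_trait_table(path: str | Path) -> TraitTable:
    path = Path(path)
    return TraitTable(pd.read_csv(path, sep=_sniff_sep(path)))


@dataclass
class RegionalPool:
    """Trait table for the regional species pool, stratified by guild.

    The pool is the regional expectation stratum: null assemblages are drawn
    from it richness-matched, so both guild strata must be non-empty.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.name != "species_id":
            _require_columns(df, ["species_id"], "regional pool")
            df = df.set_index("species_id")
        df.index = df.index.astype(str)
        _require_columns(df, ["guild", "cap_diameter_mm"], "regional pool")
        d = pd.to_numeric(df["cap_diameter_mm"], errors="coerce")
        if d.isna().any() or (d <= 0).any():
            raise ValidationError("regional pool: non-positive cap diameter")
        df = df.copy()
        df["cap_diameter_mm"] = d.astype(float)
        df["fruit_body_size"] = df["cap_diameter_mm"] ** 2
        for guild in GUILDS:
            if not (df["guild"] == guild).any():
                raise ValidationError(f"regional pool: empty {guild} stratum")
        self.df = df.sort_index()

    def log_sizes(self, guild: str) -> np.ndarray:
        """log10 fruit-body sizes of one guild stratum, in species-id order."""
        _check_guild(guild)
        sub = self.df[self.df["guild"] == guild]
        return np.log10(sub["fruit_body_size"].to_numpy())

    def write(self, path: str | Path) -> None:
        self.df.reset_index().to_csv(path, index=False)


def read_regional_pool(path: str | Path) -> RegionalPool:
    path = Path(path)
    return RegionalPool(pd.read_csv(path, sep=_sniff_sep(path)))


def _check_guild(guild: str) -> None:
    if guild not in GUILDS:
        raise ValueError(f"unknown guild {guild!r}; expected one of {GUILDS}")


# ---------------------------------------------------------------------------
# binary species-by-plot matrices
# ---------------------------------------------------------------------------

@dataclass
class BinaryCommunityMatrix:
    """Presence/absence species-by-plot matrix for one guild and year.

    Rows are species, columns plots, both lexicographically ordered.  Row
    sums are species occupancies and column sums plot richness; the swap
    null preserves both margins exactly.
    """

    values: np.ndarray
    species: list[str]
    plots: list[str]
    guild: str
    year: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValidationError("binary matrix must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("binary matrix entries must be 0/1")
        if self.values.shape != (len(self.species), len(self.plots)):
            raise ValidationError("binary matrix shape does not match labels")

    @property
    def is_empty(self) -> bool:
        return self.values.size == 0

    @property
    def row_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.values.sum(axis=0)

    @property
    def n_ones(self) -> int:
        return int(self.values.sum())


def to_binary_matrix(
    table: CommunityTable, traits: TraitTable, guild: str, year: int
) -> BinaryCommunityMatrix:
    """Presence/absence view of one guild in one year (entry 1 iff count >= 1)."""
    _check_guild(guild)
    if year not in table.years:
        raise ValueError(f"year {year} not present in community table")
    guild_species = set(traits.species_of(guild))
    sub = table.df[(table.df["year"] == year) & table.df["species_id"].isin(guild_species)]
    if sub.empty:
        logger.warning("no %s species observed in year %s: empty matrix", guild, year)
        return BinaryCommunityMatrix(
            np.zeros((0, 0), dtype=np.int8), [], [], guild, year
        )
    species = sorted(sub["species_id"].unique())
    plots = sorted(sub["plot_id"].unique())
    mat = np.zeros((len(species), len(plots)), dtype=np.int8)
    s_idx = {s: i for i, s in enumerate(species)}
    p_idx = {p: j for j, p in enumerate(plots)}
    for rec in sub.itertuples(index=False):
        mat[s_idx[rec.species_id], p_idx[rec.plot_id]] = 1
    return BinaryCommunityMatrix(mat, species, plots, guild, year)


# ---------------------------------------------------------------------------
# environment table and the PCA resource gradient
# ---------------------------------------------------------------------------

@dataclass
class EnvironmentTable:
    """Plot-level stand variables (growing stock, cover layers, stand age)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.name != "plot_id":
            _require_columns(df, ["plot_id"], "environment table")
            df = df.set_index("plot_id")
        df.index = df.index.astype(str)
        _require_columns(df, ENV_VARIABLES, "environment table")
        self.df = df[list(ENV_VARIABLES)].astype(float).sort_index()

    def write(self, path: str | Path) -> None:
        self.df.reset_index().to_csv(path, index=False)


def read_environment_table(path: str | Path) -> EnvironmentTable:
    path = Path(path)
    return EnvironmentTable(pd.read_csv(path, sep=_sniff_sep(path)))


@dataclass
class GradientScores:
    """Principal-component scores of the stand variables.

    ``resource`` is the first component, oriented so growing-stock volume
    loads positively (large scores = high resource availability);
    ``age_axis`` is the second, oriented so stand age loads positively
    (large scores = old stands).
    """

    scores: pd.DataFrame  # index plot_id; columns resource, age_axis
    loadings: pd.DataFrame  # variables x components, correlation loadings
    variance_fractions: np.ndarray
    variables: list[str] = field(default_factory=list)


def pca_gradient(env: EnvironmentTable) -> GradientScores:
    """PCA of the z-standardized stand variables (correlation matrix).

    Missing values are mean-imputed with a warning; constant variables are
    dropped with a warning (their correlation is undefined).  Scores have
    zero mean across plots by construction.
    """
    df = env.df.copy()
    if len(df) < 3:
        raise ValidationError("pca_gradient: need at least 3 plots")
    if df.isna().any().any():
        logger.warning("environment table: mean-imputing %d missing value(s)",
                       int(df.isna().sum().sum()))
        df = df.fillna(df.mean())
    sd = df.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        logger.warning("pca_gradient: dropping constant variable(s) %s", constant)
        df = df.drop(columns=constant)
    variables = df.columns.tolist()
    X = df.to_numpy(float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    R = (Z.T @ Z) / (len(df) - 1)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    scores = Z @ evecs
    # orientation: volume up on PC1, stand_age up on PC2
    for comp, var in ((0, "volume"), (1, "stand_age")):
        if var in variables and evecs[variables.index(var), comp] < 0:
            evecs[:, comp] *= -1
            scores[:, comp] *= -1
    with np.errstate(invalid="ignore"):
        corr_loadings = evecs * np.sqrt(evals)
    frac = evals / len(variables)
    score_df = pd.DataFrame(
        {"resource": scores[:, 0], "age_axis": scores[:, 1]}, index=df.index
    )
    loading_df = pd.DataFrame(
        corr_loadings,
        index=variables,
        columns=[f"PC{i + 1}" for i in range(len(variables))],
    )
    return GradientScores(score_df, loading_df, frac, variables)
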