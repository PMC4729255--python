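"""Null models and the standardized effect size (SES).

Two nulls probe trait structure at two scales:

* **Regional-pool null** — for a plot with observed richness S, draw S
  species without replacement from the guild's stratum of the regional pool
  and take the mean log10 fruit-body size; repeat n_rand times.  Tests
  whether locally co-occurring species differ in size from a richness-matched
  random draw of the regional species list.

* **Local swap null (fixed-fixed)** — randomize the binary species-by-plot
  matrix with the independent swap algorithm: 2x2 checkerboard exchanges
  that preserve every species' occupancy (row sums) and every plot's
  richness (column sums) exactly.  Tests for residual trait-occurrence
  association within the realized matrix, free of richness artefacts.

SES = (observed - null mean) / null sd, with the sample (n-1) standard
deviation; |SES| > 2 conventionally flags deviation from the null.  The
swap chain counts only *successful* swaps; burn-in and thinning default to
10x and 2x the matrix fill (number of presences), standard practice for
sequential swap chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .io import BinaryCommunityMatrix, CommunityTable, RegionalPool, TraitTable, to_binary_matrix
from .traits import METRICS

logger = logging.getLogger("sporocarp")

DEFAULT_N_RAND = 100
#: attempt budget per requested successful swap before giving up
ATTEMPT_CAP_PER_SWAP = 1_000_000


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# independent swap
# ---------------------------------------------------------------------------

@njit(cache=False)
def _swap_kernel(m: np.ndarray, n_swaps: int, max_attempts: int, seed: int) -> int:
    """Perform up to n_swaps successful checkerboard swaps in place.

    A candidate is a random row pair and column pair; if the 2x2 submatrix
    is a checkerboard ([[1,0],[0,1]] or [[0,1],[1,0]]) it is flipped to the
    other pattern, which leaves all row and column sums unchanged.  Returns
    the number of successful swaps.
    """
    np.random.seed(seed)
    nr, nc = m.shape
    done = 0
    attempts = 0
    while done < n_swaps and attempts < max_attempts:
        attempts += 1
        r1 = np.random.randint(0, nr)
        r2 = np.random.randint(0, nr)
        c1 = np.random.randint(0, nc)
        c2 = np.random.randint(0, nc)
        if r1 == r2 or c1 == c2:
            continue
        a = m[r1, c1]
        b = m[r1, c2]
        c = m[r2, c1]
        d = m[r2, c2]
        if a == d and b == c and a != b:
            m[r1, c1] = b
            m[r1, c2] = a
            m[r2, c1] = d
            m[r2, c2] = c
            done += 1
    return done


def _swap_inplace(values: np.ndarray, n_swaps: int, rng: np.random.Generator) -> int:
    if n_swaps == 0 or values.size == 0:
        return 0
    max_attempts = n_swaps * ATTEMPT_CAP_PER_SWAP
    done = _swap_kernel(values, n_swaps, max_attempts, _kernel_seed(rng))
    if done < n_swaps:
        logger.warning(
            "independent swap: only %d of %d swaps possible within attempt budget "
            "(matrix may have no checkerboard submatrix)", done, n_swaps,
        )
    return done


def independent_swap(
    matrix: BinaryCommunityMatrix | np.ndarray,
    n_swaps: int,
    seed: int | np.random.Generator | None = None,
) -> BinaryCommunityMatrix | np.ndarray:
    """Return a copy of ``matrix`` after ``n_swaps`` successful checkerboard swaps.

    Row and column sums are preserved exactly for any number of swaps.  A
    matrix with no swappable 2x2 submatrix is returned unchanged after a
    bounded attempt budget, with a warning.
    """
    if n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")
    rng = _as_rng(seed)
    if isinstance(matrix, BinaryCommunityMatrix):
        values = matrix.values.copy()
        _swap_inplace(values, n_swaps, rng)
        return BinaryCommunityMatrix(
            values, list(matrix.species), list(matrix.plots), matrix.guild, matrix.year
        )
    values = np.asarray(matrix, dtype=np.int8).copy()
    _swap_inplace(values, n_swaps, rng)
    return values


# ---------------------------------------------------------------------------
# null distributions
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """Null values of one assemblage metric for one plot."""

    metric: str
    values: np.ndarray  # length n_randomizations
    rng_seed: int | None = None

    @property
    def n_randomizations(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        """Sample (n-1) standard deviation across randomizations."""
        return float(np.std(self.values, ddof=1))


@dataclass
class PlotNullDistributions:
    """Per-plot null distributions from one swap chain (n_rand x n_plots)."""

    metric: str
    plots: list[str]
    values: np.ndarray
    rng_seed: int | None = None

    def __getitem__(self, plot: str) -> NullDistribution:
        j = self.plots.index(plot)
        return NullDistribution(self.metric, self.values[:, j], self.rng_seed)


def regional_pool_null(
    pool: RegionalPool,
    guild: str,
    richness: int,
    n_rand: int = DEFAULT_N_RAND,
    seed: int | np.random.Generator | None = None,
) -> NullDistribution:
    """Richness-matched random draws from the guild's regional pool stratum.

    Each replicate draws ``richness`` species without replacement and
    records the mean log10 fruit-body size.
    """
    log_sizes = pool.log_sizes(guild)
    stratum_size = len(log_sizes)
    if not 1 <= richness <= stratum_size:
        raise ValueError(
            f"richness {richness} outside [1, {stratum_size}] for {guild} stratum "
            "(cannot draw without replacement)"
        )
    rng = _as_rng(seed)
    if richness == stratum_size:
        means = np.full(n_rand, log_sizes.mean())
    else:
        # n_rand independent subsets via row-wise partial permutation
        idx = np.argsort(rng.random((n_rand, stratum_size)), axis=1)[:, :richness]
        means = log_sizes[idx].mean(axis=1)
    return NullDistribution("mean_log_size", means)


def _metric_trait_vector(matrix: BinaryCommunityMatrix, traits: TraitTable, metric: str) -> np.ndarray:
    tdf = traits.df.loc[matrix.species]
    if metric == "mean_log_size":
        return np.log10(tdf["fruit_body_size"].to_numpy(float))
    if metric == "mean_log_n_fruitbodies":
        if "mean_fruit_bodies" not in tdf.columns or tdf["mean_fruit_bodies"].isna().any():
            raise KeyError("trait table lacks mean_fruit_bodies for some matrix species")
        return np.log10(tdf["mean_fruit_bodies"].to_numpy(float))
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def swap_null(
    matrix: BinaryCommunityMatrix,
    traits: TraitTable,
    metric: str = "mean_log_size",
    n_rand: int = DEFAULT_N_RAND,
    burn_in: int | None = None,
    thin: int | None = None,
    seed: int | np.random.Generator | None = None,
    mode: str = "chain",
) -> PlotNullDistributions | None:
    """Per-plot null distributions of an assemblage mean under the swap null.

    chain mode (default): one sequential Markov chain per matrix — burn_in
    successful swaps, then a sample after every ``thin`` successful swaps.
    restart mode: each replicate restarts from the observed matrix and runs
    burn_in swaps independently.  Defaults: burn_in = 10 x fill,
    thin = 2 x fill, where fill is the number of presences.

    Degenerate matrices (fewer than 2 species or 2 plots) carry no
    information for the swap null; returns None with a warning.
    """
    if matrix.is_empty or len(matrix.species) < 2 or len(matrix.plots) < 2:
        logger.warning(
            "swap null: degenerate %s/%s matrix (%d species x %d plots), skipped",
            matrix.guild, matrix.year, len(matrix.species), len(matrix.plots),
        )
        return None
    if mode not in ("chain", "restart"):
        raise ValueError(f"mode must be 'chain' or 'restart', got {mode!r}")
    rng = _as_rng(seed)
    fill = matrix.n_ones
    if burn_in is None:
        burn_in = 10 * fill
    if thin is None:
        thin = 2 * fill
    t = _metric_trait_vector(matrix, traits, metric)
    col_richness = matrix.col_sums.astype(float)
    out = np.empty((n_rand, len(matrix.plots)))
    if mode == "chain":
        m = matrix.values.copy()
        _swap_inplace(m, burn_in, rng)
        for k in range(n_rand):
            _swap_inplace(m, thin, rng)
            out[k] = (t @ m) / col_richness
    else:
        for k in range(n_rand):
            m = matrix.values.copy()
            _swap_inplace(m, burn_in, rng)
            out[k] = (t @ m) / col_richness
    return PlotNullDistributions(metric, list(matrix.plots), out)


# ---------------------------------------------------------------------------
# standardized effect size
# ---------------------------------------------------------------------------

@dataclass
class SESValue:
    """Observed value scored against a null distribution."""

    observed: float
    null_mean: float
    null_sd: float
    ses: float  # NaN when undefined
    flag: str  # "" | "zero_null_sd"

    @property
    def defined(self) -> bool:
        return self.flag == ""


def ses(observed: float, null: NullDistribution) -> SESValue:
    """SES = (observed - null mean) / null sd (sample sd, n-1).

    A constant null distribution (sd = 0) leaves the SES undefined; the
    result is flagged rather than raising.
    """
    if null.n_randomizations == 0:
        raise ValueError("null distribution is empty")
    mu, sd = null.mean, null.sd
    if sd == 0 or not np.isfinite(sd):
        return SESValue(observed, mu, sd, np.nan, "zero_null_sd")
    return SESValue(observed, mu, sd, (observed - mu) / sd, "")


# ---------------------------------------------------------------------------
# assemblage-level SES tables
# ---------------------------------------------------------------------------

_SES_COLUMNS = [
    "plot_id", "guild", "year", "metric", "null_model",
    "observed", "null_mean", "null_sd", "ses", "n_randomizations", "flag",
]


def regional_pool_ses_table(
    community: CommunityTable,
    traits: TraitTable,
    pool: RegionalPool,
    n_rand: int = DEFAULT_N_RAND,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Regional-pool SES of mean log10 fruit-body size per plot/guild/year.

    Only the size metric is scored against the regional pool: regional
    fruit-body counts are not available, so the count metric exists only
    under the local swap null.
    """
    from .traits import assemblage_means  # local import to avoid cycle

    rng = _as_rng(seed)
    rows = []
    for year in community.years:
        for guild in ("ECM", "ST"):
            matrix = to_binary_matrix(community, traits, guild, year)
            if matrix.is_empty:
                continue
            obs = assemblage_means(matrix, traits).set_index("plot_id")
            for plot in matrix.plots:
                richness = int(obs.loc[plot, "richness"])
                null = regional_pool_null(pool, guild, richness, n_rand, rng)
                s = ses(float(obs.loc[plot, "mean_log_size"]), null)
                rows.append({
                    "plot_id": plot, "guild": guild, "year": year,
                    "metric": "mean_log_size", "null_model": "regional_pool",
                    "observed": s.observed, "null_mean": s.null_mean,
                    "null_sd": s.null_sd, "ses": s.ses,
                    "n_randomizations": n_rand, "flag": s.flag,
                })
    return pd.DataFrame(rows, columns=_SES_COLUMNS)


def swap_ses_table(
    community: CommunityTable,
    traits: TraitTable,
    metrics: tuple[str, ...] = METRICS,
    n_rand: int = DEFAULT_N_RAND,
    burn_in: int | None = None,
    thin: int | None = None,
    seed: int | np.random.Generator | None = None,
    mode: str = "chain",
) -> pd.DataFrame:
    """Swap-null SES per plot/guild/year for the requested metrics."""
    from .traits import assemblage_means

    rng = _as_rng(seed)
    rows = []
    for year in community.years:
        for guild in ("ECM", "ST"):
            matrix = to_binary_matrix(community, traits, guild, year)
            if matrix.is_empty:
                continue
            obs = assemblage_means(matrix, traits).set_index("plot_id")
            for metric in metrics:
                nulls = swap_null(
                    matrix, traits, metric, n_rand, burn_in, thin, rng, mode
                )
                if nulls is None:
                    continue
                col = {"mean_log_size": "mean_log_size",
                       "mean_log_n_fruitbodies": "mean_log_n_fruitbodies"}[metric]
                for plot in matrix.plots:
                    s = ses(float(obs.loc[plot, col]), nulls[plot])
                    rows.append({
                        "plot_id": plot, "guild": guild, "year": year,
                        "metric": metric, "null_model": "local_swap",
                        "observed": s.observed, "null_mean": s.null_mean,
                        "null_sd": s.null_sd, "ses": s.ses,
                        "n_randomizations": n_rand, "flag": s.flag,
                    })
    return pd.DataFrame(rows, columns=_SES_COLUMNS)
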