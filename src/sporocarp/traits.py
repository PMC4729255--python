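"""Species-level reproductive traits and assemblage means.

Two traits per species: fruit-body size, indexed by the squared mean cap
diameter d² (mm², a biomass proxy), and the mean number of fruit bodies per
occupied plot.  Assemblage values are unweighted means of log10-transformed
species traits across the species present on a plot — the transform is
applied at the species level, before averaging, and abundance never weights
the mean.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import BinaryCommunityMatrix, CommunityTable, TraitTable

logger = logging.getLogger("sporocarp")

METRICS = ("mean_log_size", "mean_log_n_fruitbodies")


def fruit_body_size(d: float) -> float:
    """Fruit-body size index d² (mm²) from mean cap diameter d (mm)."""
    if d <= 0:
        raise ValueError(f"cap diameter must be positive, got {d}")
    return d * d


def mean_fruit_bodies(
    table: CommunityTable, species: str, mode: str = "pooled"
) -> float | dict[int, float]:
    """Mean number of fruit bodies per occupied plot for one species.

    pooled mode: total count over all years divided by the number of
    distinct plots ever occupied (one trait value per species).  per-year
    mode: for each year, that year's total divided by that year's occupied
    plots.
    """
    sub = table.df[table.df["species_id"] == species]
    if sub.empty:
        raise KeyError(f"species {species!r} not present in community table")
    if mode == "pooled":
        return float(sub["count"].sum() / sub["plot_id"].nunique())
    if mode == "per-year":
        grouped = sub.groupby("year")
        return {
            int(year): float(g["count"].sum() / g["plot_id"].nunique())
            for year, g in grouped
        }
    raise ValueError(f"mode must be 'pooled' or 'per-year', got {mode!r}")


def fruit_body_counts(table: CommunityTable, mode: str = "pooled") -> pd.Series:
    """Vectorized :func:`mean_fruit_bodies` over all species (pooled mode only
    returns a Series; per-year returns a species x year frame)."""
    if mode == "pooled":
        g = table.df.groupby("species_id")
        return (g["count"].sum() / g["plot_id"].nunique()).rename("mean_fruit_bodies")
    if mode == "per-year":
        g = table.df.groupby(["species_id", "year"])
        return (g["count"].sum() / g["plot_id"].nunique()).unstack()
    raise ValueError(f"mode must be 'pooled' or 'per-year', got {mode!r}")


def occupancy_filter(table: CommunityTable, min_plots: int = 4) -> CommunityTable:
    """Retain species recorded on at least ``min_plots`` distinct plots.

    Occupancy counts distinct plots across all years; rare species are
    removed because their mean fruit-body count is unreliable.
    """
    if min_plots < 1:
        raise ValueError("min_plots must be >= 1")
    occ = table.occupancy()
    keep = set(occ.index[occ >= min_plots])
    removed = len(occ) - len(keep)
    if removed:
        logger.info("occupancy filter (>= %d plots): removed %d of %d species",
                    min_plots, removed, len(occ))
    out = table.df[table.df["species_id"].isin(keep)]
    if out.empty:
        logger.warning("occupancy filter removed every species")
    return CommunityTable(out.reset_index(drop=True))


def attach_community_traits(
    traits: TraitTable, table: CommunityTable, count_mode: str = "pooled"
) -> TraitTable:
    """Derive mean_fruit_bodies and occupancy columns from the observations.

    Pooled count mode gives one trait value per species, used in all years;
    per-year mode stores the across-year mean of the yearly values (the
    yearly values themselves are available via :func:`fruit_body_counts`).
    """
    df = traits.df.copy()
    counts = fruit_body_counts(table, mode=count_mode)
    if count_mode == "per-year":
        counts = counts.mean(axis=1).rename("mean_fruit_bodies")
    df["mean_fruit_bodies"] = counts.reindex(df.index)
    df["occupancy"] = table.occupancy().reindex(df.index).fillna(0).astype(int)
    return TraitTable(df.reset_index())


def assemblage_means(matrix: BinaryCommunityMatrix, traits: TraitTable) -> pd.DataFrame:
    """Per-plot unweighted means of log10 species traits.

    Returns one row per plot with richness >= 1: plot_id, guild, year,
    richness, mean_log_size and (when fruit-body counts are attached)
    mean_log_n_fruitbodies.  Every species in the matrix must have traits.
    """
    if matrix.is_empty:
        return pd.DataFrame(
            columns=["plot_id", "guild", "year", "richness",
                     "mean_log_size", "mean_log_n_fruitbodies"]
        )
    missing = [s for s in matrix.species if s not in traits.df.index]
    if missing:
        raise KeyError(f"species lacking trait values: {missing[:10]}")
    tdf = traits.df.loc[matrix.species]
    log_size = np.log10(tdf["fruit_body_size"].to_numpy())
    has_counts = "mean_fruit_bodies" in tdf.columns and tdf["mean_fruit_bodies"].notna().all()
    log_n = np.log10(tdf["mean_fruit_bodies"].to_numpy()) if has_counts else None

    m = matrix.values
    richness = m.sum(axis=0)
    rows = []
    for j, plot in enumerate(matrix.plots):
        if richness[j] == 0:
            continue
        present = m[:, j] == 1
        row = {
            "plot_id": plot,
            "guild": matrix.guild,
            "year": matrix.year,
            "richness": int(richness[j]),
            "mean_log_size": float(log_size[present].mean()),
        }
        row["mean_log_n_fruitbodies"] = (
            float(log_n[present].mean()) if log_n is not None else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
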