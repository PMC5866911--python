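"""Derive standardized pairwise-THI feeding-behaviour traits from daily RFID pings.

An RFID ping is one 20-second detection of an animal's electronic ear tag at a
feeder slot, so a day holds at most 86,400 / 20 = 4320 pings per animal.  For
each animal the mean daily ping count is computed per THI category, expressed
as a deviation from the animal's sire-breed x sex mean in that category, and
standardized to mean 0 / SD 1 within the category.  The six heat-response
traits are differences of these z-scores between ordered category pairs
(cooler minus hotter, e.g. ``Normal-Alert``); an animal contributes a trait
only when it has data in both categories, and animals that experienced a
single category are excluded altogether.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .thi import CATEGORIES

logger = logging.getLogger(__name__)

#: Physical ceiling on daily pings: 86,400 s / 20 s detection interval.
MAX_PINGS_PER_DAY = 4320


def trait_names(categories: tuple[str, ...] = CATEGORIES) -> list[str]:
    """Ordered pair labels, cooler category first (``Normal-Alert``, ...)."""
    return [f"{a}-{b}" for a, b in itertools.combinations(categories, 2)]


def daily_counts(
    detections: pd.DataFrame,
    roster: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate feeder detections into one ping count per animal-day.

    Parameters
    ----------
    detections : DataFrame
        Either raw 20-s detections with columns ``animal_id``, ``timestamp``
        (counted after dropping duplicate (animal, timestamp) rows), or
        pre-aggregated counts with columns ``animal_id``, ``date``, ``pings``
        (passed through).
    roster : DataFrame, optional
        Columns ``animal_id``, ``date``: animal-days that must appear in the
        output; days without detections get a count of 0.

    Returns
    -------
    DataFrame with columns ``animal_id``, ``date``, ``pings``.
    """
    if "pings" in detections.columns:
        out = detections[["animal_id", "date", "pings"]].copy()
    else:
        df = detections.copy()
        n0 = len(df)
        df = df.drop_duplicates(subset=["animal_id", "timestamp"])
        if len(df) < n0:
            logger.info("deduplicated %d duplicate detections", n0 - len(df))
        df["date"] = pd.to_datetime(df["timestamp"]).dt.date
        out = (
            df.groupby(["animal_id", "date"], sort=True)
            .size()
            .rename("pings")
            .reset_index()
        )
    if roster is not None:
        key = roster[["animal_id", "date"]].drop_duplicates()
        out = key.merge(out, on=["animal_id", "date"], how="left")
        out["pings"] = out["pings"].fillna(0)
    out["pings"] = out["pings"].astype(int)
    if (out["pings"] < 0).any() or (out["pings"] > MAX_PINGS_PER_DAY).any():
        raise ValueError(f"ping counts must lie in [0, {MAX_PINGS_PER_DAY}]")
    return out.reset_index(drop=True)


def category_profile(pings: pd.DataFrame, days: pd.DataFrame) -> pd.DataFrame:
    """Per-animal mean daily pings within each THI category.

    Parameters
    ----------
    pings : DataFrame
        Columns ``animal_id``, ``date``, ``pings``.
    days : DataFrame
        Day classification with columns ``date``, ``category``.

    Returns
    -------
    DataFrame with columns ``animal_id``, ``category``, ``mean_pings``,
    ``n_days`` — a row only where an animal has at least one day in a category.

    Raises
    ------
    ValueError
        If any ping date is absent from ``days`` (offending dates listed).
    """
    if (pings["pings"] < 0).any() or (pings["pings"] > MAX_PINGS_PER_DAY).any():
        raise ValueError(f"ping counts must lie in [0, {MAX_PINGS_PER_DAY}]")
    merged = pings.merge(days[["date", "category"]], on="date", how="left")
    missing = merged["category"].isna()
    if missing.any():
        bad = sorted({str(d) for d in merged.loc[missing, "date"]})
        raise ValueError(f"ping dates absent from day classification: {bad}")
    prof = (
        merged.groupby(["animal_id", "category"], sort=True)["pings"]
        .agg(mean_pings="mean", n_days="count")
        .reset_index()
    )
    return prof


def standardize_deviations(profile: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Standardize per-category feeding activity against breed-sex contemporaries.

    Within each THI category, an animal's deviation is its mean daily pings
    minus the mean over all animals of the same sire breed and sex that have
    data in that category.  Deviations are divided by their sample SD (n-1
    denominator) over all animals in the category, yielding z-values with
    mean 0 and SD 1 per category.

    Parameters
    ----------
    profile : DataFrame from :func:`category_profile`.
    meta : DataFrame with columns ``animal_id``, ``sire_breed``, ``sex``.

    Returns
    -------
    DataFrame with columns ``animal_id``, ``category``, ``z``.

    Raises
    ------
    ValueError
        If a category has zero variance of deviations (degenerate category)
        or fewer than 2 animals.
    """
    df = profile.merge(meta[["animal_id", "sire_breed", "sex"]], on="animal_id", how="left")
    if df["sire_breed"].isna().any():
        bad = sorted(df.loc[df["sire_breed"].isna(), "animal_id"].unique().tolist())
        raise ValueError(f"animals missing metadata: {bad}")
    out = []
    for cat, sub in df.groupby("category", sort=True):
        if len(sub) < 2:
            raise ValueError(f"category {cat!r} has fewer than 2 animals")
        dev = sub["mean_pings"] - sub.groupby(["sire_breed", "sex"])["mean_pings"].transform("mean")
        sd = dev.std(ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError(f"degenerate category {cat!r}: zero variance of deviations")
        out.append(pd.DataFrame({
            "animal_id": sub["animal_id"].to_numpy(),
            "category": cat,
            "z": (dev / sd).to_numpy(),
        }))
    return pd.concat(out, ignore_index=True)


def pairwise_traits(
    z_values: pd.DataFrame,
    categories: tuple[str, ...] = CATEGORIES,
) -> pd.DataFrame:
    """Build the pairwise heat-response trait table from per-category z-values.

    For every ordered pair (cooler, hotter) of the four categories the trait is
    ``z(cooler) - z(hotter)``, emitted only for animals with data in both
    categories.  Animals observed in fewer than two categories are excluded.

    Returns a DataFrame indexed by ``animal_id`` whose first columns are the
    per-category z-values (``z_Normal``, ...) and remaining columns the pair
    traits (``Normal-Alert``, ...); missing entries are NaN.
    """
    wide = z_values.pivot(index="animal_id", columns="category", values="z")
    wide = wide.reindex(columns=[c for c in categories if c in wide.columns])
    multi = wide.notna().sum(axis=1) >= 2
    excluded = (~multi).sum()
    if excluded:
        logger.info("excluding %d animal(s) with a single THI category", int(excluded))
    wide = wide.loc[multi]
    out = pd.DataFrame(index=wide.index)
    for c in categories:
        out[f"z_{c}"] = wide[c] if c in wide.columns else np.nan
    for a, b in itertools.combinations(categories, 2):
        if a in wide.columns and b in wide.columns:
            out[f"{a}-{b}"] = wide[a] - wide[b]
        else:
            out[f"{a}-{b}"] = np.nan
    return out


def trait_correlations(
    traits: pd.DataFrame,
    categories: tuple[str, ...] = CATEGORIES,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pearson correlations among the six pairwise traits.

    Computed on pairwise-complete observations; entries backed by fewer than
    ``min_pairs`` complete pairs are NaN.  The result is symmetric with a unit
    diagonal.
    """
    cols = [c for c in trait_names(categories) if c in traits.columns]
    sub = traits[cols]
    corr = sub.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    return corr
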