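"""Community colour composition and colour inequality.

A species' plumage is summarised as a percentage breakdown over the ten
most common bird colours.  Site-level community composition is obtained by
summing the colour profiles of the species present and re-expressing each
colour as a percentage of the community total; with per-species profiles
that each sum to 100 this equals the unweighted mean of the present
species' profiles.  Colour inequality is the Gini coefficient of the ten
community colour percentages: 0 when every colour is equally represented,
1 when a single colour accounts for the entire community palette.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    InvalidInputError,
    MissingSpeciesError,
    UndefinedStatisticError,
)

logger = logging.getLogger(__name__)

#: Canonical colour order used everywhere in the package.
COLOURS = (
    "black",
    "blue",
    "brown",
    "green",
    "grey",
    "purple",
    "red",
    "rufous",
    "white",
    "yellow",
)

#: Raw 12-colour scheme in which grey and brown are split into light/dark
#: variants (as published in plumage-colour source tables).
VARIANT_COLOURS = (
    "black",
    "blue",
    "light_brown",
    "dark_brown",
    "green",
    "light_grey",
    "dark_grey",
    "purple",
    "red",
    "rufous",
    "white",
    "yellow",
)

#: Pigment-mechanism groupings reported as derived columns.
PIGMENT_GROUPS = {
    "melanin": ("black", "grey", "brown"),
    "carotenoid": ("red", "yellow"),
    "structural": ("blue", "purple"),
}


def merge_colour_variants(raw: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Collapse light/dark grey and light/dark brown into grey and brown.

    Accepts a single 12-colour profile (Series) or a table of profiles
    (DataFrame, one row per species).  The output carries the canonical
    10-colour columns and is renormalized to sum to 100.

    Raises
    ------
    InvalidInputError
        If any percentage is negative or a variant column is missing.
    """
    if isinstance(raw, pd.Series):
        return merge_colour_variants(raw.to_frame().T).iloc[0]
    missing = [c for c in VARIANT_COLOURS if c not in raw.columns]
    if missing:
        raise InvalidInputError(f"missing variant colour columns: {missing}")
    values = raw[list(VARIANT_COLOURS)].to_numpy(dtype=float)
    if (values < 0).any():
        raise InvalidInputError("colour percentages must be nonnegative")
    out = pd.DataFrame(index=raw.index)
    out["black"] = raw["black"]
    out["blue"] = raw["blue"]
    out["brown"] = raw["light_brown"] + raw["dark_brown"]
    out["green"] = raw["green"]
    out["grey"] = raw["light_grey"] + raw["dark_grey"]
    for c in ("purple", "red", "rufous", "white", "yellow"):
        out[c] = raw[c]
    out = out[list(COLOURS)]
    return renormalize_profiles(out)


def renormalize_profiles(table: pd.DataFrame, tol: float = 1e-6) -> pd.DataFrame:
    """Rescale each row to sum to 100, warning when the input did not.

    Raises
    ------
    InvalidInputError
        If a row sums to zero or contains a negative entry.
    """
    values = table.to_numpy(dtype=float)
    if (values < 0).any():
        raise InvalidInputError("colour percentages must be nonnegative")
    sums = values.sum(axis=1)
    if (sums <= 0).any():
        bad = table.index[sums <= 0].tolist()
        raise InvalidInputError(f"all-zero colour profile for: {bad}")
    off = np.abs(sums - 100.0) > tol
    if off.any():
        logger.warning(
            "renormalizing %d colour profile(s) not summing to 100", int(off.sum())
        )
    return table.div(sums / 100.0, axis=0)


def load_colour_table(
    path,
    sex: str | None = "male",
    sex_column: str = "sex",
    species_column: str = "species_id",
    merge_variants: bool = False,
) -> pd.DataFrame:
    """Read a species colour table CSV into a species-indexed DataFrame.

    If the file carries a sex column, rows are filtered to ``sex`` (plumage
    scores are conventionally taken from male specimens).  Profiles are
    renormalized to sum to 100.  With ``merge_variants`` the 12-colour
    light/dark scheme is collapsed first.
    """
    df = pd.read_csv(path)
    if sex_column in df.columns and sex is not None:
        df = df[df[sex_column].astype(str).str.lower() == sex.lower()]
    if species_column not in df.columns:
        raise InvalidInputError(f"colour table lacks a '{species_column}' column")
    df = df.set_index(species_column)
    if merge_variants:
        return merge_colour_variants(df)
    missing = [c for c in COLOURS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"colour table lacks colour columns: {missing}")
    return renormalize_profiles(df[list(COLOURS)])


def community_colour_percentages(
    present_species: Iterable[str], table: pd.DataFrame
) -> pd.Series:
    """Community colour percentages for one site.

    colour_k% = (sum of colour_k over present species) * 100 / (sum of all
    colours over present species).
    """
    present = list(present_species)
    if not present:
        raise EmptyInputError("community has no species present")
    unknown = [s for s in present if s not in table.index]
    if unknown:
        raise MissingSpeciesError(f"species absent from colour table: {unknown}")
    sums = table.loc[present, list(COLOURS)].sum(axis=0)
    return sums * 100.0 / sums.sum()


def gini_coefficient(values, unbiased: bool = True) -> float:
    """Gini coefficient of a nonnegative vector.

    G = sum_ij |x_i - x_j| / (2 n^2 xbar); the unbiased variant multiplies
    by n/(n-1) so that full concentration on one element yields exactly 1.

    Raises
    ------
    UndefinedStatisticError
        If all values are zero.
    InvalidInputError
        If any value is negative.
    """
    x = np.asarray(values, dtype=float).ravel()
    if (x < 0).any():
        raise InvalidInputError("Gini requires nonnegative values")
    total = x.sum()
    if total == 0:
        raise UndefinedStatisticError("Gini undefined for an all-zero vector")
    n = x.size
    xs = np.sort(x)
    # sorted-rank identity for sum_ij |x_i - x_j|
    g = (2.0 * np.sum((np.arange(1, n + 1)) * xs) - (n + 1) * total) / (n * total)
    if unbiased:
        g *= n / (n - 1)
    return float(g)


def community_composition_table(
    community: pd.DataFrame,
    colour_table: pd.DataFrame,
    unbiased_gini: bool = True,
) -> pd.DataFrame:
    """Per-site colour composition, pigment-group sums and Gini inequality.

    ``community`` is a binary site x species presence/absence DataFrame.
    Returns one row per site with the 10 colour percentage columns, the
    melanin/carotenoid/structural pigment-group sums, and ``gini``.
    """
    rows = {}
    for site_id, row in community.iterrows():
        present = row.index[row.astype(int) == 1]
        comp = community_colour_percentages(present, colour_table)
        comp["gini"] = gini_coefficient(comp[list(COLOURS)], unbiased=unbiased_gini)
        rows[site_id] = comp
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "site_id"
    for group, members in PIGMENT_GROUPS.items():
        out[group] = out[list(members)].sum(axis=1)
    return out[list(COLOURS) + list(PIGMENT_GROUPS) + ["gini"]]


def union_presence_across_visits(
    visits: pd.DataFrame,
    site_column: str = "site_id",
) -> pd.DataFrame:
    """Collapse repeated survey visits to a single presence/absence matrix.

    A species counts as present at a site if it was recorded on at least
    one visit (rows share the site id; species columns are 0/1).
    """
    grouped = visits.groupby(site_column).max()
    return (grouped > 0).astype(int)
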