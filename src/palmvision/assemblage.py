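"""Per-unit assemblage tables for primate colour vision and palm fruit colour.

This module turns species-level trait tables and species x unit occurrence
tables into the analysis table used by the structural equation models: one row
per geographic unit (botanical country or equal-area grid cell) carrying
primate richness split by colour-vision class, palm fruit-colour counts and
the proportion of conspicuous palm fruits, and environmental covariates.

Colour-vision classes
---------------------
``routine_trichromatic``
    both sexes trichromatic (catarrhines and howler monkeys),
``polymorphic``
    population-level mixture of dichromats and trichromats (mostly
    platyrrhines),
``dichromatic_or_monochromatic``
    everything else.

Fruit-colour classification
---------------------------
A palm species is *conspicuous* when its fruit is orange, red, yellow or pink
(reddish against green foliage for a trichromat) and *non-conspicuous* when
brown, black, green, blue, cream, grey, ivory, straw, white or purple.
Species whose listed colours include none of the colours primates actually
feed on (brown, green, orange, yellow, red, purple) are *excluded* from the
proportion entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "COLOUR_VOCABULARY",
    "CONSPICUOUS_COLOURS",
    "PRIMATE_DIET_COLOURS",
    "VISION_CLASSES",
    "ACTIVITY_CLASSES",
    "classify_fruit_colour",
    "build_assemblage",
    "filter_units",
    "transform_variables",
    "TransformInfo",
]

COLOUR_VOCABULARY = frozenset(
    {
        "orange", "red", "yellow", "pink",
        "brown", "black", "green", "blue", "cream", "grey", "ivory",
        "straw", "white", "purple",
    }
)

#: colours that render a fruit conspicuous to a trichromat
CONSPICUOUS_COLOURS = frozenset({"orange", "red", "yellow", "pink"})

#: fruit colours primates actually feed on; species with none of these are
#: excluded from the conspicuousness proportion
PRIMATE_DIET_COLOURS = frozenset({"brown", "green", "orange", "yellow", "red", "purple"})

VISION_CLASSES = ("routine_trichromatic", "polymorphic", "dichromatic_or_monochromatic")
ACTIVITY_CLASSES = ("diurnal", "nocturnal", "cathemeral_crepuscular")

#: covariate columns expected on the unit table (canopy height optional in
#: principle but always produced by the synthetic generator)
COVARIATE_COLUMNS = ("temp", "prec", "tseas", "pseas", "canopy_height")

_RICHNESS_COLUMNS = {
    "routine_trichromatic": "richness_trichromat",
    "polymorphic": "richness_polymorph",
    "dichromatic_or_monochromatic": "richness_other",
}


def classify_fruit_colour(colours) -> str:
    """Classify a palm species' fruit-colour set.

    Parameters
    ----------
    colours : iterable of str
        Non-empty set of colour tokens from :data:`COLOUR_VOCABULARY`.

    Returns
    -------
    str
        ``"conspicuous"``, ``"non_conspicuous"`` or ``"excluded"``.

    Notes
    -----
    Palatability is tested first against the union of listed colours; a
    species with no primate-diet colour at all is excluded. Among palatable
    species, *any* conspicuous colour in the description triggers the
    conspicuous class (a fruit displaying any reddish colour is detectable).
    A consequence is that a pink-only species is excluded: pink is
    conspicuous but not a primate-diet colour.
    """
    colours = set(colours)
    if not colours:
        raise ValueError("fruit colour set must be non-empty")
    unknown = colours - COLOUR_VOCABULARY
    if unknown:
        raise ValueError(f"unknown fruit colour token(s): {sorted(unknown)}")
    if not colours & PRIMATE_DIET_COLOURS:
        return "excluded"
    if colours & CONSPICUOUS_COLOURS:
        return "conspicuous"
    return "non_conspicuous"


def _check_referential_integrity(occ: pd.DataFrame, traits: pd.DataFrame, what: str) -> None:
    missing = set(occ["species_id"]) - set(traits["species_id"])
    if missing:
        raise ValueError(
            f"{what} occurrences reference species missing from the trait table: "
            f"{sorted(missing)[:20]}"
        )


def _palm_classes(palm_traits: pd.DataFrame) -> pd.Series:
    """Conspicuousness per palm species (index: species_id)."""
    if "conspicuousness" in palm_traits.columns:
        cls = palm_traits.set_index("species_id")["conspicuousness"]
        bad = set(cls) - {"conspicuous", "non_conspicuous", "excluded"}
        if bad:
            raise ValueError(f"unknown conspicuousness labels: {sorted(bad)}")
        return cls
    colours = palm_traits.set_index("species_id")["colours"]
    return colours.map(lambda c: classify_fruit_colour(_split_colours(c)))


def _split_colours(value) -> set:
    if isinstance(value, str):
        return {t.strip() for t in value.split(";") if t.strip()}
    return set(value)


def build_assemblage(
    occ_primates: pd.DataFrame,
    occ_palms: pd.DataFrame,
    primate_traits: pd.DataFrame,
    palm_traits: pd.DataFrame,
    units: pd.DataFrame,
    subset: str = "all",
    cathemeral_is_diurnal: bool = False,
) -> pd.DataFrame:
    """Build the per-unit analysis table.

    Parameters
    ----------
    occ_primates, occ_palms : DataFrame
        Occurrence tables with columns ``unit_id`` and ``species_id``.
        Duplicated rows are de-duplicated (presence/absence semantics).
    primate_traits : DataFrame
        Columns ``species_id``, ``vision_system``, ``activity``,
        ``frugivory_rank`` (0 = non-frugivore; 1-3 = frugivore).
    palm_traits : DataFrame
        Columns ``species_id`` and either ``colours`` (``;``-separated
        tokens or a set) or a precomputed ``conspicuousness`` column.
    units : DataFrame
        One row per ``unit_id`` with covariates, ``area`` and optionally
        ``realm``, ``row``/``col`` grid coordinates.
    subset : {"all", "diurnal_frugivores"}
        ``diurnal_frugivores`` restricts the vision-class richness counts to
        day-active species with frugivory rank 1-3; palm counts are never
        subset.
    cathemeral_is_diurnal : bool
        Whether cathemeral/crepuscular species count as day-active
        (conservative default: they do not).

    Returns
    -------
    DataFrame
        One row per unit: ``richness_trichromat``, ``richness_polymorph``,
        ``richness_other``, ``richness_total``, ``n_conspicuous``,
        ``n_nonconspicuous``, ``n_palatable_palms``, ``prop_conspicuous``
        (NaN where no palatable palm occurs), plus the unit columns.
    """
    if subset not in ("all", "diurnal_frugivores"):
        raise ValueError(f"unknown subset {subset!r}")
    occ_primates = occ_primates[["unit_id", "species_id"]].drop_duplicates()
    occ_palms = occ_palms[["unit_id", "species_id"]].drop_duplicates()
    _check_referential_integrity(occ_primates, primate_traits, "primate")
    _check_referential_integrity(occ_palms, palm_traits, "palm")

    ptr = primate_traits.set_index("species_id")
    bad_vision = set(ptr["vision_system"]) - set(VISION_CLASSES)
    if bad_vision:
        raise ValueError(f"unknown vision_system labels: {sorted(bad_vision)}")

    keep = pd.Series(True, index=ptr.index)
    if subset == "diurnal_frugivores":
        day = ptr["activity"] == "diurnal"
        if cathemeral_is_diurnal:
            day |= ptr["activity"] == "cathemeral_crepuscular"
        keep = day & ptr["frugivory_rank"].isin([1, 2, 3])

    occ_p = occ_primates[occ_primates["species_id"].map(keep)]
    vision = occ_p["species_id"].map(ptr["vision_system"])
    rich = (
        pd.crosstab(occ_p["unit_id"], vision)
        .reindex(columns=list(VISION_CLASSES), fill_value=0)
        .rename(columns=_RICHNESS_COLUMNS)
    )

    palm_cls = _palm_classes(palm_traits)
    pcls = occ_palms["species_id"].map(palm_cls)
    palm_counts = (
        pd.crosstab(occ_palms["unit_id"], pcls)
        .reindex(columns=["conspicuous", "non_conspicuous", "excluded"], fill_value=0)
        .rename(columns={"conspicuous": "n_conspicuous", "non_conspicuous": "n_nonconspicuous",
                         "excluded": "n_excluded"})
    )

    table = units.set_index("unit_id").join(rich, how="left").join(palm_counts, how="left")
    count_cols = list(_RICHNESS_COLUMNS.values()) + [
        "n_conspicuous", "n_nonconspicuous", "n_excluded"
    ]
    table[count_cols] = table[count_cols].fillna(0).astype(int)
    table["richness_total"] = (
        table["richness_trichromat"] + table["richness_polymorph"] + table["richness_other"]
    )
    table["n_palatable_palms"] = table["n_conspicuous"] + table["n_nonconspicuous"]
    with np.errstate(invalid="ignore", divide="ignore"):
        table["prop_conspicuous"] = np.where(
            table["n_palatable_palms"] > 0,
            table["n_conspicuous"] / table["n_palatable_palms"],
            np.nan,
        )
    return table.reset_index()


def filter_units(
    table: pd.DataFrame,
    focal_class: str = "richness_trichromat",
    min_focal_richness: int = 1,
    min_palatable_palms: int = 3,
) -> pd.DataFrame:
    """Keep units suitable for the structural models.

    Defaults implement the study's inclusion rule: more than zero primates of
    the focal vision class and more than two (i.e. at least three) palatable
    palm species, so the conspicuousness proportion is not dominated by
    sampling noise. Palm counts refer to non-excluded species only, since
    excluded species never enter the proportion.
    """
    if focal_class not in table.columns:
        raise KeyError(f"focal class column {focal_class!r} not in table")
    mask = (table[focal_class] >= min_focal_richness) & (
        table["n_palatable_palms"] >= min_palatable_palms
    )
    return table[mask].reset_index(drop=True)


@dataclass
class TransformInfo:
    """Scaling constants recorded by :func:`transform_variables` for inversion."""

    sqrt_columns: tuple = ()
    log_columns: tuple = ()
    minima: dict = field(default_factory=dict)
    maxima: dict = field(default_factory=dict)

    def invert(self, column: str, values):
        """Map transformed values of ``column`` back to the original scale."""
        x = np.asarray(values, dtype=float)
        x = x * (self.maxima[column] - self.minima[column]) + self.minima[column]
        if column in self.sqrt_columns:
            x = x**2
        if column in self.log_columns:
            x = np.exp(x)
        return x


def transform_variables(
    table: pd.DataFrame,
    columns: list[str],
    sqrt_columns: tuple = ("richness_trichromat", "richness_polymorph", "richness_other",
                           "richness_total"),
    log_columns: tuple = ("area",),
) -> tuple[pd.DataFrame, TransformInfo]:
    """Variance-stabilize and min-max scale the model variables.

    Richness columns are square-root transformed (to normalize counts), area
    is natural-log transformed, then every selected column is min-max scaled
    to [0, 1]. The transform is applied before scaling so normalization acts
    on the modelled scale. Scaling constants are returned for inversion.

    Raises
    ------
    ValueError
        If a selected column is constant (max equals min) — such a column
        cannot be scaled and carries no information for the model.
    """
    out = table.copy()
    info = TransformInfo(
        sqrt_columns=tuple(c for c in sqrt_columns if c in columns),
        log_columns=tuple(c for c in log_columns if c in columns),
    )
    for col in columns:
        if col not in out.columns:
            raise KeyError(f"column {col!r} not in table")
        x = out[col].to_numpy(dtype=float)
        if col in info.sqrt_columns:
            if (x < 0).any():
                raise ValueError(f"negative values in sqrt column {col!r}")
            x = np.sqrt(x)
        if col in info.log_columns:
            if (x <= 0).any():
                raise ValueError(f"non-positive values in log column {col!r}")
            x = np.log(x)
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi == lo:
            raise ValueError(f"column {col!r} is constant; cannot min-max scale")
        info.minima[col], info.maxima[col] = lo, hi
        out[col] = (x - lo) / (hi - lo)
    return out, info
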