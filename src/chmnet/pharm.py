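"""Ingredient screening and cluster-level target-protein aggregation.

Ingredients are screened on TCMSP-style scores: oral bioavailability (OB)
strictly above 0.30 and drug-likeness (DL) strictly above 0.18, with
inorganic compounds excluded.  OB is treated as a fraction on [0, 1] by
default; TCMSP itself publishes OB as a percentage, so ``ob_units="percent"``
rescales an OB column given on [0, 100].

Cluster target sets are the deduplicated union, over a community's member
herbs, of the retained ingredients' protein sets; the overlap table
intersects them with comparator (western-medicine) category sets, optionally
restricted to an annotated protein subset (e.g. immune-system proteins).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "filter_ingredients",
    "cluster_targets",
    "group_targets",
    "overlap_table",
    "overlap_counts",
]

OB_MIN_DEFAULT = 0.30
DL_MIN_DEFAULT = 0.18


def filter_ingredients(
    table: pd.DataFrame,
    ob_min: float = OB_MIN_DEFAULT,
    dl_min: float = DL_MIN_DEFAULT,
    ob_units: str = "fraction",
) -> pd.DataFrame:
    """Rows with OB > ob_min, DL > dl_min and not inorganic (strict).

    Boundary rows (OB exactly 0.30, DL exactly 0.18) are excluded: the
    screening criterion is "higher than", not "at least".  Idempotent.
    """
    if not (0 <= ob_min <= 1 and 0 <= dl_min <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    if ob_units not in ("fraction", "percent"):
        raise ValueError("ob_units must be 'fraction' or 'percent'")
    ob = table["ob"] / 100.0 if ob_units == "percent" else table["ob"]
    mask = (ob > ob_min) & (table["dl"] > dl_min)
    if "inorganic" in table.columns:
        mask &= ~table["inorganic"].astype(bool)
    return table[mask].reset_index(drop=True)


def cluster_targets(
    membership: Mapping[str, int],
    ingredients: pd.DataFrame,
    target_map: Mapping[str, Iterable[str]],
) -> dict[int, frozenset]:
    """Per-cluster protein set: union over member herbs' retained ingredients.

    ``ingredients`` must already be screened (`filter_ingredients`).  A member
    herb with zero retained ingredients contributes an empty set and triggers
    a warning, as does a retained ingredient absent from the target map.
    """
    by_herb = dict(tuple(ingredients.groupby("herb")["ingredient"]))
    out: dict[int, set] = {}
    empty_herbs, unmapped = [], []
    for herb, cid in sorted(membership.items()):
        proteins = out.setdefault(cid, set())
        ings = by_herb.get(herb)
        if ings is None or len(ings) == 0:
            empty_herbs.append(herb)
            continue
        for ing in ings:
            if ing in target_map:
                proteins.update(target_map[ing])
            else:
                unmapped.append(ing)
    if empty_herbs:
        warnings.warn(f"herbs with no retained ingredients (empty contribution): {empty_herbs}")
    if unmapped:
        warnings.warn(f"{len(unmapped)} retained ingredients missing from the target map")
    return {cid: frozenset(p) for cid, p in sorted(out.items())}


def group_targets(
    categories: Mapping[str, str], target_map: Mapping[str, Iterable[str]]
) -> dict[str, frozenset]:
    """Per-category protein union for comparator agents (drug -> category)."""
    out: dict[str, set] = {}
    for agent, cat in sorted(categories.items()):
        out.setdefault(cat, set()).update(target_map.get(agent, ()))
    return {cat: frozenset(p) for cat, p in sorted(out.items())}


def overlap_table(
    cluster_sets: Mapping[int | str, frozenset],
    comparator_sets: Mapping[str, frozenset],
    protein_subset: Iterable[str] | None = None,
    empty_symbol: str = "—",
) -> pd.DataFrame:
    """Matrix of sorted protein intersections, cluster x comparator category.

    Intersections may be restricted to ``protein_subset`` (e.g. immune-system
    annotated proteins); empty cells render as an em dash.
    """
    subset = None if protein_subset is None else frozenset(protein_subset)
    cols = list(comparator_sets)
    rows = {}
    for cid, cset in cluster_sets.items():
        cells = []
        for cat in cols:
            inter = cset & comparator_sets[cat]
            if subset is not None:
                inter &= subset
            cells.append(", ".join(sorted(inter)) if inter else empty_symbol)
        rows[cid] = cells
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def overlap_counts(
    cluster_sets: Mapping[int | str, frozenset],
    comparator_sets: Mapping[str, frozenset],
    protein_subset: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Intersection sizes with the same restriction semantics as overlap_table."""
    subset = None if protein_subset is None else frozenset(protein_subset)
    cols = list(comparator_sets)
    data = {
        cid: [
            len((cset & comparator_sets[cat]) if subset is None else (cset & comparator_sets[cat] & subset))
            for cat in cols
        ]
        for cid, cset in cluster_sets.items()
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)
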