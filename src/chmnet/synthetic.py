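"""Synthetic claims-data generators.

The real prescription records behind the 2010 Taiwan allergic-rhinitis
cohort are not publicly deposited, so every downstream stage is exercised on
synthetic data whose structure mirrors the published summaries:

* a patient cohort drawn variable-by-variable from the published grouped
  marginals (user and nonuser groups separately),
* prescription transactions with planted co-prescription communities —
  six communities including two isolated drug pairs, a size distribution
  with mode 5, mean ~5.6 herbs and 6.3% of prescriptions carrying >= 10
  herbs — providing clustering ground truth,
* an herb -> ingredient table with oral-bioavailability / drug-likeness
  scores and ingredient -> protein target maps,
* GMT-writable pathway collections, either uniform or with coverage planted
  for specific agent groups.

All generators are deterministic under a fixed seed; independent streams are
derived per stage (see ``chmnet._rng``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from ._rng import derive_rng
from .enrich import PathwayCollection

__all__ = [
    "CohortSpec",
    "PlantedCluster",
    "PlantedNetworkSpec",
    "IngredientDBSpec",
    "generate_cohort",
    "generate_prescriptions",
    "generate_ingredient_db",
    "generate_wm_targets",
    "generate_pathways",
    "dose_long_table",
    "load_spec",
    "plant_pathway_coverage",
    "default_size_dist",
    "default_cohort_spec",
    "default_network_spec",
    "default_ingredient_spec",
]

_PROB_TOL = 1e-9


def _check_probs(probs: Sequence[float], name: str) -> None:
    p = np.asarray(list(probs), dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > _PROB_TOL:
        raise ValueError(f"probability vector for {name!r} must be nonnegative and sum to 1, got sum {p.sum()!r}")


# --------------------------------------------------------------------------
# Cohort
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Group sizes and per-variable categorical probabilities.

    ``category_probs`` maps group ("user" / "nonuser") -> variable ->
    {level: probability}; each vector must sum to 1 within 1e-9.
    """

    n_users: int
    n_nonusers: int
    category_probs: Mapping[str, Mapping[str, Mapping[str, float]]]
    seed: int = 0

    def validate(self) -> None:
        if self.n_users < 0 or self.n_nonusers < 0:
            raise ValueError("group sizes must be >= 0")
        for group in ("user", "nonuser"):
            if group not in self.category_probs:
                raise ValueError(f"category_probs missing group {group!r}")
            for var, levels in self.category_probs[group].items():
                _check_probs(levels.values(), f"{group}/{var}")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per patient; every categorical drawn from its group's vector."""
    spec.validate()
    frames = []
    for group, is_user, n in (
        ("user", True, spec.n_users),
        ("nonuser", False, spec.n_nonusers),
    ):
        rng = derive_rng(spec.seed, f"cohort/{group}")
        prefix = "U" if is_user else "N"
        data = {
            "patient_id": [f"{prefix}{i:07d}" for i in range(n)],
            "chm_user": np.full(n, is_user),
        }
        for var, levels in spec.category_probs[group].items():
            names = list(levels)
            draws = rng.choice(len(names), size=n, p=np.asarray(list(levels.values()), dtype=float))
            values = np.asarray(names, dtype=object)[draws]
            if set(names) <= {"yes", "no"}:
                values = values == "yes"
            data[var] = values
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# Prescriptions with planted communities
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedCluster:
    """A planted co-prescription community."""

    herbs: tuple[str, ...]
    core: str
    co_draw: float = 0.8  # relative weight of cluster members for slot fills
    weight: float = 0.1  # probability a transaction belongs to this community
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "herbs", tuple(self.herbs))
        if len(self.herbs) < 2:
            raise ValueError("each cluster needs >= 2 herbs")
        if self.core not in self.herbs:
            raise ValueError(f"core {self.core!r} is not a member of its cluster")
        if not 0 <= self.co_draw <= 1 or self.weight < 0:
            raise ValueError("co_draw must be in [0,1] and weight >= 0")


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Transaction-generator configuration.

    Per transaction: a prescription size is drawn from ``size_dist``; a
    community is chosen with probability ``weight`` (leftover mass produces
    background-only prescriptions); the community's core herb is always
    included; each remaining slot draws a still-unused cluster member or
    background herb with relative weights (co_draw, background_mass),
    spilling to the other pool when one is exhausted.
    """

    clusters: tuple[PlantedCluster, ...]
    background_herbs: tuple[str, ...]
    size_dist: Mapping[int, float]
    n_prescriptions: int
    background_mass: float = 0.05
    n_patients: int | None = None
    with_dose: bool = False
    herb_types: Mapping[str, str] | None = None
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "clusters", tuple(self.clusters))
        object.__setattr__(self, "background_herbs", tuple(self.background_herbs))

    @property
    def all_herbs(self) -> tuple[str, ...]:
        return tuple(h for c in self.clusters for h in c.herbs) + self.background_herbs

    def membership(self) -> dict[str, int]:
        """Ground-truth community id (1-based) per planted herb."""
        return {h: cid for cid, c in enumerate(self.clusters, start=1) for h in c.herbs}

    def validate(self) -> None:
        herbs = self.all_herbs
        if len(set(herbs)) != len(herbs):
            dupes = sorted({h for h in herbs if herbs.count(h) > 1})
            raise ValueError(f"herb codes must be unique across clusters and background: {dupes}")
        _check_probs(self.size_dist.values(), "size_dist")
        if any(s < 1 for s in self.size_dist):
            raise ValueError("prescription sizes must be >= 1")
        max_size = max(s for s, p in self.size_dist.items() if p > 0)
        if max_size > len(set(herbs)):
            raise ValueError(
                f"size distribution reaches {max_size} but only {len(set(herbs))} distinct herbs exist"
            )
        if sum(c.weight for c in self.clusters) > 1 + _PROB_TOL:
            raise ValueError("cluster weights must sum to <= 1")
        if not 0 <= self.background_mass <= 1:
            raise ValueError("background_mass must lie in [0, 1]")
        if self.n_prescriptions < 0:
            raise ValueError("n_prescriptions must be >= 0")


def _fill_items(
    rng: np.random.Generator,
    size: int,
    members: Sequence[str],
    core: str | None,
    background: Sequence[str],
    p_background: float,
) -> list[str]:
    items = [core] if core is not None else []
    pool_m = [h for h in members if h != core]
    pool_b = list(background)
    while len(items) < size and (pool_m or pool_b):
        if pool_m and pool_b:
            use_bg = rng.random() < p_background
        else:
            use_bg = not pool_m
        pool = pool_b if use_bg else pool_m
        items.append(pool.pop(rng.integers(len(pool))))
    return items


def generate_prescriptions(spec: PlantedNetworkSpec) -> pd.DataFrame:
    """Transactions with planted community structure.

    Returns one row per prescription with a pipe-delimited ``herbs`` field
    (and per-item doses when ``with_dose``); no herb repeats within a
    prescription.  Deterministic under the spec seed.
    """
    spec.validate()
    rng = derive_rng(spec.seed, "prescriptions")
    sizes = np.asarray(sorted(spec.size_dist), dtype=int)
    size_p = np.asarray([spec.size_dist[s] for s in sizes], dtype=float)
    size_p = size_p / size_p.sum()
    weights = np.asarray([c.weight for c in spec.clusters], dtype=float)
    bg_only = max(0.0, 1.0 - weights.sum())
    choice_p = np.append(weights, bg_only)
    choice_p = choice_p / choice_p.sum()
    n_patients = spec.n_patients or max(1, spec.n_prescriptions // 6)
    herb_types = spec.herb_types or {}

    drawn_sizes = rng.choice(sizes, size=spec.n_prescriptions, p=size_p)
    drawn_clusters = rng.choice(len(spec.clusters) + 1, size=spec.n_prescriptions, p=choice_p)
    patient_ids = rng.integers(n_patients, size=spec.n_prescriptions)

    rows = []
    for i in range(spec.n_prescriptions):
        ci = drawn_clusters[i]
        if ci < len(spec.clusters):
            c = spec.clusters[ci]
            denom = c.co_draw + spec.background_mass
            p_bg = spec.background_mass / denom if denom > 0 else 1.0
            items = _fill_items(rng, int(drawn_sizes[i]), c.herbs, c.core, spec.background_herbs, p_bg)
        else:
            items = _fill_items(rng, int(drawn_sizes[i]), (), None, spec.background_herbs, 1.0)
        row = {
            "prescription_id": f"RX{i:07d}",
            "patient_id": f"P{patient_ids[i]:06d}",
            "herbs": "|".join(items),
        }
        if spec.with_dose:
            # herbal formulas are dosed ~4-5 g/day, single herbs ~1-1.5 g/day
            doses = [
                round(float(rng.normal(4.8, 0.5)) if herb_types.get(h) == "HF" else float(rng.normal(1.3, 0.15)), 2)
                for h in items
            ]
            row["doses"] = "|".join(f"{d:.2f}" for d in doses)
        rows.append(row)
    return pd.DataFrame(rows, columns=["prescription_id", "patient_id", "herbs"] + (["doses"] if spec.with_dose else []))


def dose_long_table(prescriptions: pd.DataFrame) -> pd.DataFrame:
    """Long format (prescription_id, herb, dose) from a wide table with doses."""
    if "doses" not in prescriptions.columns:
        raise ValueError("prescription table carries no doses")
    rows = []
    for _, r in prescriptions.iterrows():
        herbs = r["herbs"].split("|")
        doses = [float(d) for d in r["doses"].split("|")]
        rows.extend((r["prescription_id"], h, d) for h, d in zip(herbs, doses))
    return pd.DataFrame(rows, columns=["prescription_id", "herb", "dose"])


# --------------------------------------------------------------------------
# Ingredients, targets, pathways
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IngredientDBSpec:
    """Herb -> ingredient table generator configuration.

    OB and DL are Beta-distributed on [0, 1]; each ingredient receives a
    protein target set drawn uniformly from the universe.
    """

    herbs: tuple[str, ...]
    proteins: tuple[str, ...]
    ingredients_per_herb: tuple[int, int] = (78, 79)
    ob_beta: tuple[float, float] = (2.0, 3.0)
    dl_beta: tuple[float, float] = (1.2, 3.5)
    targets_per_ingredient: tuple[int, int] = (1, 4)
    inorganic_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "herbs", tuple(self.herbs))
        object.__setattr__(self, "proteins", tuple(self.proteins))

    def validate(self) -> None:
        if not self.proteins:
            raise ValueError("protein universe must be nonempty")
        if not self.herbs:
            raise ValueError("herb list must be nonempty")
        lo, hi = self.ingredients_per_herb
        if not 0 <= lo <= hi:
            raise ValueError("invalid ingredients_per_herb range")
        lo, hi = self.targets_per_ingredient
        if not 0 <= lo <= hi <= len(self.proteins):
            raise ValueError("targets_per_ingredient range exceeds the protein universe")
        if not 0 <= self.inorganic_rate <= 1:
            raise ValueError("inorganic_rate must lie in [0, 1]")


def generate_ingredient_db(spec: IngredientDBSpec) -> tuple[pd.DataFrame, dict[str, frozenset]]:
    """(ingredient table, ingredient -> protein set map).

    Every ingredient belongs to exactly one herb record; OB/DL lie in [0, 1].
    """
    spec.validate()
    rng = derive_rng(spec.seed, "ingredients")
    proteins = np.asarray(spec.proteins, dtype=object)
    rows = []
    target_map: dict[str, frozenset] = {}
    lo, hi = spec.ingredients_per_herb
    tlo, thi = spec.targets_per_ingredient
    for herb in spec.herbs:
        n_ing = int(rng.integers(lo, hi + 1))
        for j in range(n_ing):
            ing = f"{herb}::ING{j:04d}"
            ob = float(rng.beta(*spec.ob_beta))
            dl = float(rng.beta(*spec.dl_beta))
            inorganic = bool(rng.random() < spec.inorganic_rate)
            n_t = int(rng.integers(tlo, thi + 1))
            targets = frozenset(rng.choice(proteins, size=n_t, replace=False)) if n_t else frozenset()
            rows.append((herb, ing, ob, dl, inorganic))
            target_map[ing] = targets
    table = pd.DataFrame(rows, columns=["herb", "ingredient", "ob", "dl", "inorganic"])
    return table, target_map


def generate_wm_targets(
    categories: Mapping[str, Mapping] | None = None,
    proteins: Sequence[str] = (),
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, frozenset]]:
    """Comparator drugs: (drug -> category, drug -> protein set).

    Each category owns a protein pool of its configured size; member drugs
    draw their targets from that pool, so the category union approximates the
    pool.  Defaults follow the published four-category comparator set.
    """
    categories = reference.WM_CATEGORIES if categories is None else categories
    if not proteins:
        raise ValueError("protein universe must be nonempty")
    rng = derive_rng(seed, "wm-targets")
    proteins_arr = np.asarray(list(proteins), dtype=object)
    drug_category: dict[str, str] = {}
    target_map: dict[str, frozenset] = {}
    for cat in sorted(categories):
        cfg = categories[cat]
        pool = rng.choice(proteins_arr, size=min(cfg["n_proteins"], len(proteins_arr)), replace=False)
        for d in range(cfg["n_drugs"]):
            drug = f"{cat}::drug{d:02d}"
            n_t = int(rng.integers(max(1, len(pool) // 3), len(pool) + 1))
            drug_category[drug] = cat
            target_map[drug] = frozenset(rng.choice(pool, size=n_t, replace=False))
    return drug_category, target_map


def generate_pathways(
    n_pathways: int,
    size_range: tuple[int, int],
    universe: Sequence[str],
    categories: Sequence[str] = ("uncategorized",),
    seed: int = 0,
) -> PathwayCollection:
    """Uniformly drawn pathway sets over the universe, with cycled categories."""
    universe = list(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(universe):
        raise ValueError(f"size_range {size_range} exceeds the universe size {len(universe)}")
    rng = derive_rng(seed, "pathways")
    arr = np.asarray(universe, dtype=object)
    pathways, cats = {}, {}
    for i in range(n_pathways):
        name = f"PW{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        pathways[name] = frozenset(rng.choice(arr, size=size, replace=False))
        cats[name] = categories[i % len(categories)]
    return PathwayCollection(pathways=pathways, categories=cats, universe=frozenset(universe))


def plant_pathway_coverage(
    group_targets: Mapping[str, frozenset],
    universe: Sequence[str],
    blocks: Sequence[tuple[int, str, tuple[str, ...]]],
    size_range: tuple[int, int] = (20, 40),
    enriched_fraction: float = 0.8,
    seed: int = 0,
) -> PathwayCollection:
    """Pathway collection with coverage planted for named agent groups.

    ``blocks`` is a sequence of (n_pathways, category, covered_by) where
    ``covered_by`` names the groups whose target sets should cover those
    pathways.  A covered pathway draws ``enriched_fraction`` of its members
    from the covering groups' target sets (split evenly when several) and the
    rest uniformly; an uncovered block (empty covered_by) draws uniformly.
    """
    universe = list(universe)
    arr = np.asarray(universe, dtype=object)
    uni_set = frozenset(universe)
    for g, t in group_targets.items():
        if not frozenset(t) <= uni_set:
            raise ValueError(f"targets of group {g!r} fall outside the universe")
    rng = derive_rng(seed, "planted-pathways")
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(universe):
        raise ValueError(f"size_range {size_range} exceeds the universe size {len(universe)}")
    pathways, cats = {}, {}
    idx = 0
    for n_pw, category, covered_by in blocks:
        pools = [np.asarray(sorted(group_targets[g]), dtype=object) for g in covered_by]
        for _ in range(n_pw):
            name = f"PW{idx:04d}"
            idx += 1
            size = int(rng.integers(lo, hi + 1))
            members: set = set()
            if pools:
                share = int(round(enriched_fraction * size)) // len(pools)
                for pool in pools:
                    members.update(rng.choice(pool, size=min(share, len(pool)), replace=False))
            while len(members) < size:
                members.add(arr[rng.integers(len(arr))])
            pathways[name] = frozenset(members)
            cats[name] = category
    return PathwayCollection(pathways=pathways, categories=cats, universe=uni_set)


# --------------------------------------------------------------------------
# Spec files
# --------------------------------------------------------------------------

_SPEC_KINDS = {}


def _register(kind):
    def wrap(fn):
        _SPEC_KINDS[kind] = fn
        return fn

    return wrap


@_register("cohort")
def _cohort_from_dict(d: Mapping) -> CohortSpec:
    return CohortSpec(
        n_users=int(d["n_users"]),
        n_nonusers=int(d["n_nonusers"]),
        category_probs=d["category_probs"],
        seed=int(d.get("seed", 0)),
    )


@_register("prescriptions")
def _network_from_dict(d: Mapping) -> PlantedNetworkSpec:
    clusters = tuple(
        PlantedCluster(
            herbs=tuple(c["herbs"]),
            core=c["core"],
            co_draw=float(c.get("co_draw", 0.8)),
            weight=float(c.get("weight", 0.1)),
            label=c.get("label", ""),
        )
        for c in d["clusters"]
    )
    return PlantedNetworkSpec(
        clusters=clusters,
        background_herbs=tuple(d.get("background_herbs", ())),
        size_dist={int(k): float(v) for k, v in d["size_dist"].items()},
        n_prescriptions=int(d["n_prescriptions"]),
        background_mass=float(d.get("background_mass", 0.05)),
        n_patients=d.get("n_patients"),
        with_dose=bool(d.get("with_dose", False)),
        herb_types=d.get("herb_types"),
        seed=int(d.get("seed", 0)),
    )


@_register("ingredients")
def _ingredients_from_dict(d: Mapping) -> IngredientDBSpec:
    return IngredientDBSpec(
        herbs=tuple(d["herbs"]),
        proteins=tuple(d["proteins"]),
        ingredients_per_herb=tuple(d.get("ingredients_per_herb", (78, 79))),
        ob_beta=tuple(d.get("ob_beta", (2.0, 3.0))),
        dl_beta=tuple(d.get("dl_beta", (1.2, 3.5))),
        targets_per_ingredient=tuple(d.get("targets_per_ingredient", (1, 4))),
        inorganic_rate=float(d.get("inorganic_rate", 0.05)),
        seed=int(d.get("seed", 0)),
    )


def load_spec(path) -> CohortSpec | PlantedNetworkSpec | IngredientDBSpec:
    """Load and validate a generator spec from a YAML/JSON file.

    The file must carry a top-level ``kind`` field: one of ``cohort``,
    ``prescriptions`` or ``ingredients``.
    """
    import yaml

    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "kind" not in data:
        raise ValueError(f"spec file {path} must be a mapping with a 'kind' field")
    kind = data.pop("kind")
    if kind not in _SPEC_KINDS:
        raise ValueError(f"unknown spec kind {kind!r}; valid kinds: {sorted(_SPEC_KINDS)}")
    try:
        spec = _SPEC_KINDS[kind](data)
    except (KeyError, TypeError) as exc:
        raise ValueError(f"spec file {path} is missing or mistypes a field: {exc}") from exc
    spec.validate()
    return spec


# --------------------------------------------------------------------------
# Defaults: the demo study conditions
# --------------------------------------------------------------------------


def default_size_dist() -> dict[int, float]:
    """Prescription-size distribution: mode 5, ~6.3% mass at >= 10 herbs.

    Bins 1-9 follow the published histogram's visual masses; the >= 10 tail
    (6.3%) is split geometrically over 10..15 with ratio 0.1 and the vector
    is normalised.  Exactly 5.6 is incompatible with these bin masses (any
    tail split forces a mean above 5.654, since the tail's conditional mean
    must exceed 10); the steep tail ratio keeps the true mean at ~5.667,
    as close to the published average as the anchors allow.
    """
    base = {1: 0.03, 2: 0.05, 3: 0.10, 4: 0.15, 5: 0.17, 6: 0.15, 7: 0.12, 8: 0.09, 9: 0.076}
    ratio, tail_sizes = 0.1, range(10, 16)
    geo = np.array([ratio**i for i in range(len(tail_sizes))])
    geo = 0.063 * geo / geo.sum()
    dist = dict(base) | {s: float(g) for s, g in zip(tail_sizes, geo)}
    total = sum(dist.values())
    return {s: p / total for s, p in dist.items()}


def default_cohort_spec(seed: int = 0, n_users: int | None = None, n_nonusers: int | None = None) -> CohortSpec:
    """Cohort spec calibrated to the published grouped marginals."""
    probs: dict[str, dict[str, dict[str, float]]] = {"user": {}, "nonuser": {}}
    for var, levels in reference.COHORT_COUNTS.items():
        flag = var in reference.FLAG_VARIABLES
        for gi, group in enumerate(("user", "nonuser")):
            counts = {lvl: float(c[gi]) for lvl, c in levels.items()}
            total = reference.N_USERS if gi == 0 else reference.N_NONUSERS
            if flag:
                yes = counts["yes"]
                probs[group][var] = {"yes": yes / total, "no": (total - yes) / total}
            else:
                s = sum(counts.values())  # normalise by the column sum, not the
                probs[group][var] = {lvl: c / s for lvl, c in counts.items()}  # (occasionally off-by-one) group size
    return CohortSpec(
        n_users=reference.N_USERS if n_users is None else n_users,
        n_nonusers=reference.N_NONUSERS if n_nonusers is None else n_nonusers,
        category_probs=probs,
        seed=seed,
    )


def default_network_spec(
    seed: int = 0,
    n_prescriptions: int = 20_000,
    co_draw: float = 0.8,
    background_mass: float = 0.05,
    with_dose: bool = False,
) -> PlantedNetworkSpec:
    """The demo fixture: six planted communities incl. two isolated pairs.

    Community weights put the planted cores at their published prevalences
    (25.5 / 22.9 / 16.2 / 19.1 percent of prescriptions).
    """
    clusters = tuple(
        PlantedCluster(
            herbs=tuple(c["herbs"]),
            core=c["core"],
            co_draw=co_draw,
            weight=c["weight"],
            label=c["label"],
        )
        for c in reference.DEMO_CLUSTERS
    )
    return PlantedNetworkSpec(
        clusters=clusters,
        background_herbs=tuple(reference.DEMO_BACKGROUND_HERBS),
        size_dist=default_size_dist(),
        n_prescriptions=n_prescriptions,
        background_mass=background_mass,
        with_dose=with_dose,
        herb_types=reference.demo_herb_type_map(),
        seed=seed,
    )


def default_ingredient_spec(seed: int = 0, n_proteins: int = 10_000) -> IngredientDBSpec:
    """31 network herbs, ~78 ingredients each (~2,430 total), 10,000 proteins."""
    herbs = tuple(h for c in reference.DEMO_CLUSTERS for h in c["herbs"])
    proteins = tuple(f"PROT{i:05d}" for i in range(n_proteins))
    return IngredientDBSpec(herbs=herbs, proteins=proteins, seed=seed)
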