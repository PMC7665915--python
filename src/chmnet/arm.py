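"""Association-rule mining over prescription transactions.

Each prescription is a set of herb codes (duplicates collapsed).  For an
ordered herb pair A -> B:

* support(A,B)  = 100 * n(A and B) / n_transactions          (percent)
* confidence   = 100 * n(A and B) / n(A)                     (percent)
* lift         = [n(A and B) * n_transactions] / [n(A) n(B)] (dimensionless)

Lift is computed in the symmetric form above, so lift(A->B) == lift(B->A)
exactly and lift * support(B) == confidence holds to float rounding.
Support denominators are prescriptions, not patients.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AssociationRule",
    "as_transactions",
    "support",
    "item_counts",
    "pair_counts",
    "mine_pair_rules",
    "mine_itemsets",
    "top_rules",
    "prevalence_ranking",
    "mean_prescription_size",
]


@dataclass(frozen=True)
class AssociationRule:
    """One direction of a co-prescription pair with its ARM metrics."""

    antecedent: str
    consequent: str
    support: float  # percent of transactions containing both
    confidence: float  # percent
    lift: float

    @property
    def pair(self) -> tuple[str, str]:
        a, b = self.antecedent, self.consequent
        return (a, b) if a <= b else (b, a)


def as_transactions(prescriptions) -> list[frozenset]:
    """Normalise input to a list of herb-code frozensets.

    Accepts a DataFrame with a pipe-delimited ``herbs`` column, a long-format
    DataFrame with (prescription_id, herb) columns, or any iterable of item
    collections.  Duplicate codes within one prescription are collapsed.
    """
    if isinstance(prescriptions, pd.DataFrame):
        if "herbs" in prescriptions.columns:
            return [
                frozenset(str(cell).split("|")) for cell in prescriptions["herbs"].astype(str)
            ]
        if {"prescription_id", "herb"} <= set(prescriptions.columns):
            grouped = prescriptions.groupby("prescription_id", sort=True)["herb"]
            return [frozenset(v) for _, v in grouped]
        raise ValueError(
            "prescription DataFrame needs a 'herbs' column or (prescription_id, herb) columns"
        )
    return [frozenset(t) for t in prescriptions]


def _require_nonempty(transactions: Sequence[frozenset]) -> None:
    if len(transactions) == 0:
        raise ValueError("empty prescription table")


def support(prescriptions, itemset: Iterable[str]) -> float:
    """Percent of prescriptions containing every item of ``itemset``."""
    transactions = as_transactions(prescriptions)
    _require_nonempty(transactions)
    items = frozenset(itemset)
    if not items:
        raise ValueError("itemset must be nonempty")
    hits = sum(1 for t in transactions if items <= t)
    return 100.0 * hits / len(transactions)


def item_counts(transactions: Sequence[frozenset]) -> Counter:
    counts: Counter = Counter()
    for t in transactions:
        counts.update(t)
    return counts


def pair_counts(transactions: Sequence[frozenset]) -> Counter:
    counts: Counter = Counter()
    for t in transactions:
        counts.update(combinations(sorted(t), 2))
    return counts


def mine_pair_rules(
    prescriptions,
    min_support: float = 1.0,
    min_confidence: float = 15.0,
    min_lift: float = 1.0,
) -> list[AssociationRule]:
    """All ordered pair rules passing the thresholds, from exact counts.

    Both directions of every unordered pair whose pair support passes
    ``min_support`` are evaluated; each direction is retained only if its own
    confidence and the (direction-symmetric) lift pass their thresholds.
    Thresholds default to 1% support, 15% confidence, lift 1 and are fully
    configurable.
    """
    if min(min_support, min_confidence, min_lift) < 0:
        raise ValueError("thresholds must be >= 0")
    transactions = as_transactions(prescriptions)
    _require_nonempty(transactions)
    n = len(transactions)
    singles = item_counts(transactions)
    rules: list[AssociationRule] = []
    for (a, b), nab in sorted(pair_counts(transactions).items()):
        supp = 100.0 * nab / n
        if supp < min_support:
            continue
        lift = (nab * n) / (singles[a] * singles[b])
        if lift < min_lift:
            continue
        for ante, cons in ((a, b), (b, a)):
            conf = 100.0 * nab / singles[ante]
            if conf >= min_confidence:
                rules.append(
                    AssociationRule(
                        antecedent=ante, consequent=cons, support=supp, confidence=conf, lift=lift
                    )
                )
    return rules


def mine_itemsets(prescriptions, min_support: float = 1.0, max_len: int = 4) -> pd.DataFrame:
    """Frequent k-itemsets (k <= max_len) by levelwise apriori pruning.

    Pairwise mining is the default analysis surface; this exploratory
    extension relies on support anti-monotonicity to prune candidates.
    """
    if not 1 <= max_len <= 4:
        raise ValueError("max_len must be in 1..4")
    transactions = as_transactions(prescriptions)
    _require_nonempty(transactions)
    n = len(transactions)
    min_count = min_support * n / 100.0

    frequent: dict[frozenset, int] = {
        frozenset([i]): c for i, c in item_counts(transactions).items() if c >= min_count
    }
    result = dict(frequent)
    level = frequent
    for k in range(2, max_len + 1):
        items = sorted({i for s in level for i in s})
        candidates = set()
        prev = set(level)
        for s in level:
            for i in items:
                if i not in s:
                    cand = s | {i}
                    if len(cand) == k and all(cand - {j} in prev for j in cand):
                        candidates.add(cand)
        counts: Counter = Counter()
        for t in transactions:
            for cand in candidates:
                if cand <= t:
                    counts[cand] += 1
        level = {s: c for s, c in counts.items() if c >= min_count}
        result.update(level)
        if not level:
            break
    rows = [
        ("|".join(sorted(s)), len(s), 100.0 * c / n)
        for s, c in sorted(result.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    ]
    return pd.DataFrame(rows, columns=["itemset", "size", "support"])


def top_rules(
    rules: Sequence[AssociationRule], n: int = 100, collapse_direction: bool = True
) -> list[AssociationRule]:
    """Top-n rules by (support desc, confidence desc, pair name).

    With ``collapse_direction`` each unordered pair appears once, represented
    by its higher-confidence direction (antecedent-name tie-break on equal
    confidence).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pool: Iterable[AssociationRule] = rules
    if collapse_direction:
        best: dict[tuple[str, str], AssociationRule] = {}
        for r in rules:
            cur = best.get(r.pair)
            if cur is None or (r.confidence, cur.antecedent) > (cur.confidence, r.antecedent):
                best[r.pair] = r
        pool = best.values()
    ranked = sorted(pool, key=lambda r: (-r.support, -r.confidence, r.pair, r.antecedent))
    return ranked[:n]


def rules_to_frame(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.antecedent, r.consequent, r.support, r.confidence, r.lift) for r in rules],
        columns=["antecedent", "consequent", "support", "confidence", "lift"],
    )


def prevalence_ranking(
    prescriptions,
    herb_type_map: Mapping[str, str],
    dose_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-herb support (percent of prescriptions), mean dose, rank by type.

    ``herb_type_map`` labels each code ('HF' herbal formula / 'SH' single
    herb); codes missing from the map are labelled 'unknown' with a warning.
    Ties in support are resolved lexicographically.
    """
    transactions = as_transactions(prescriptions)
    _require_nonempty(transactions)
    n = len(transactions)
    counts = item_counts(transactions)
    missing = sorted(set(counts) - set(herb_type_map))
    if missing:
        warnings.warn(f"herb codes missing from type map, labelled 'unknown': {missing}")

    mean_dose: Mapping[str, float] = {}
    if dose_table is not None and {"herb", "dose"} <= set(dose_table.columns):
        mean_dose = dose_table.groupby("herb")["dose"].mean().to_dict()

    rows = [
        (
            herb,
            herb_type_map.get(herb, "unknown"),
            100.0 * c / n,
            float(mean_dose[herb]) if herb in mean_dose else float("nan"),
        )
        for herb, c in counts.items()
    ]
    out = pd.DataFrame(rows, columns=["herb", "herb_type", "support", "mean_dose"])
    out = out.sort_values(["support", "herb"], ascending=[False, True], kind="mergesort")
    out["rank_in_type"] = out.groupby("herb_type").cumcount() + 1
    return out.reset_index(drop=True)


def mean_prescription_size(prescriptions) -> float:
    """Arithmetic mean number of distinct herbs per prescription."""
    transactions = as_transactions(prescriptions)
    _require_nonempty(transactions)
    return sum(len(t) for t in transactions) / len(transactions)
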