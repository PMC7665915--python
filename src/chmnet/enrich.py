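"""Hypergeometric overrepresentation analysis (ORA) with FDR control.

For a target set of size n drawn against an annotated universe of N proteins,
a pathway with K members and overlap k is scored by the upper-tail
hypergeometric probability P(X >= k).  The tail is summed in log-binomial
arithmetic (log-gamma terms combined with logsumexp), which stays stable for
universes up to ~1e5 proteins.  Multiplicity is controlled with
Benjamini-Hochberg by default (Bonferroni available); a pathway is "covered"
by a target set when its adjusted p-value is at or below alpha (a raw-p mode
exists for sensitivity analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PathwayCollection",
    "hypergeom_upper_tail",
    "hypergeom_tail_all",
    "bh_fdr",
    "run_ora",
    "compare_coverage",
]


@dataclass(frozen=True)
class PathwayCollection:
    """Named protein sets with category paths and an annotated universe."""

    pathways: dict[str, frozenset]
    categories: dict[str, str] = field(default_factory=dict)
    universe: frozenset = frozenset()

    def __post_init__(self):
        universe = frozenset(self.universe)
        if not universe and self.pathways:
            universe = frozenset().union(*self.pathways.values())
        object.__setattr__(self, "universe", universe)
        for name, members in self.pathways.items():
            if not frozenset(members) <= self.universe:
                raise ValueError(f"pathway {name!r} has members outside the universe")

    def __len__(self) -> int:
        return len(self.pathways)

    def category(self, name: str, levels: int = 2) -> str:
        """Category path truncated to its first ``levels`` components."""
        path = self.categories.get(name, "uncategorized")
        return "/".join(path.split("/")[:levels])


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _check_bounds(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K <= N and 0 <= n <= N, got N={N}, K={K}, n={n}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"require 0 <= k <= min(n, K), got k={k}, n={n}, K={K}")


def hypergeom_tail_all(N: int, K: int, n: int) -> np.ndarray:
    """P(X >= k) for every k = 0..min(n, K), from one log-pmf evaluation.

    Entry 0 is exactly 1; the remaining entries are reverse log-sum-exp
    cumulations of the hypergeometric pmf.
    """
    _check_bounds(N, K, n, 0)
    kmax = min(n, K)
    kmin = max(0, n + K - N)
    ks = np.arange(kmin, kmax + 1)
    logp = _log_comb(K, ks) + _log_comb(N - K, n - ks) - _log_comb(N, n)
    # suffix log-sum-exp over the support; below the support the tail is 1
    suffix = np.logaddexp.accumulate(logp[::-1])[::-1]
    tails = np.ones(kmax + 1)
    tails[ks] = np.exp(suffix)
    tails[: kmin + 1] = 1.0  # at or below the support floor the tail is exactly 1
    np.clip(tails, 0.0, 1.0, out=tails)
    return tails


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail probability P(X >= k), X ~ Hypergeom(N, K, n)."""
    _check_bounds(N, K, n, k)
    if k == 0:
        return 1.0
    if k > min(n, K):  # unreachable given bounds check; kept for clarity
        return 0.0
    return float(hypergeom_tail_all(N, K, n)[k])


def bh_fdr(p_values: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Adjusted p-values in input order (BH step-up default, Bonferroni option)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("fdr_bh", "bonferroni"):
        raise ValueError("method must be 'fdr_bh' or 'bonferroni'")
    return multipletests(p, method=method)[1]


def run_ora(
    target_set: Iterable[str],
    collection: PathwayCollection,
    alpha: float = 0.05,
    method: str = "fdr_bh",
    coverage_on: str = "q",
) -> pd.DataFrame:
    """One enrichment row per pathway overlapping the target set.

    Target proteins outside the annotated universe are dropped with a
    warning.  p-values are computed for pathways with k >= 1 only, adjusted
    across exactly those tested pathways, and ``covered`` is q <= alpha
    (or raw p <= alpha with ``coverage_on="p"``).
    """
    targets = frozenset(target_set)
    outside = targets - collection.universe
    if outside:
        warnings.warn(f"{len(outside)} target proteins outside the universe were dropped")
        targets &= collection.universe
    columns = ["pathway", "category", "k", "K", "n", "N", "p", "q", "covered"]
    if not targets:
        warnings.warn("empty effective target set: no enrichment computed")
        return pd.DataFrame(columns=columns)
    if coverage_on not in ("q", "p"):
        raise ValueError("coverage_on must be 'q' or 'p'")
    N, n = len(collection.universe), len(targets)
    rows = []
    for name in sorted(collection.pathways):
        members = collection.pathways[name]
        k = len(targets & members)
        if k == 0:
            continue
        K = len(members)
        p = hypergeom_upper_tail(N, K, n, k)
        rows.append((name, collection.category(name), k, K, n, N, p))
    out = pd.DataFrame(rows, columns=columns[:-2])
    out["q"] = bh_fdr(out["p"], method=method) if len(out) else []
    out["covered"] = (out["q"] if coverage_on == "q" else out["p"]) <= alpha
    return out


def compare_coverage(
    results_by_group: Mapping[str, pd.DataFrame],
    category_filter: str | None = "Immune System",
) -> pd.DataFrame:
    """Per-category covered-pathway comparison across agent groups.

    Returns one row per (category, pathway-set kind): each group's covered
    set, the common set, and each group's exclusive set, with counts —
    the machine-readable analogue of a coverage-pattern matrix.
    """
    if len(results_by_group) < 2:
        raise ValueError("need at least two groups to compare")
    covered: dict[str, dict[str, set]] = {}
    all_categories: set[str] = set()
    for group, res in results_by_group.items():
        sets: dict[str, set] = {}
        if len(res):
            for _, row in res[res["covered"]].iterrows():
                sets.setdefault(row["category"], set()).add(row["pathway"])
            all_categories.update(res["category"].unique())
        covered[group] = sets
    if category_filter is not None:
        matching = sorted(c for c in all_categories if c.startswith(category_filter))
        if not matching:
            raise ValueError(
                f"no category matches {category_filter!r}; known categories: {sorted(all_categories)}"
            )
        categories = matching
    else:
        categories = sorted(all_categories)

    groups = list(results_by_group)
    rows = []
    for cat in categories:
        per_group = {g: covered[g].get(cat, set()) for g in groups}
        common = set.intersection(*per_group.values()) if per_group else set()
        for g in groups:
            exclusive = per_group[g] - set().union(*(per_group[h] for h in groups if h != g))
            rows.append(
                (
                    cat,
                    g,
                    len(per_group[g]),
                    "|".join(sorted(per_group[g])),
                    len(common),
                    len(exclusive),
                    "|".join(sorted(exclusive)),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["category", "group", "n_covered", "covered", "n_common", "n_exclusive", "exclusive"],
    )
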