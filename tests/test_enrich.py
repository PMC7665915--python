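"""Hypergeometric ORA, FDR adjustment, coverage comparison."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chmnet import enrich
from chmnet.enrich import PathwayCollection
from .oracles import bh_stepup_bruteforce, hypergeom_tail_enumeration


# ------------------------------------------------------------- tail prob


@pytest.mark.parametrize(
    ("N", "K", "n", "k", "expected"),
    [
        (10, 5, 4, 4, 5 / 210),  # C(5,4)C(5,0)/C(10,4)
        (6, 3, 3, 2, 0.5),  # (9 + 1)/20
        (10, 5, 4, 0, 1.0),
        (8, 8, 3, 3, 1.0),  # forced overlap
    ],
)
def test_hypergeom_examples(N, K, n, k, expected):
    assert enrich.hypergeom_upper_tail(N, K, n, k) == pytest.approx(expected, abs=1e-12)


def test_hypergeom_bounds_validation():
    for bad in [(5, 6, 2, 1), (5, 2, 6, 1), (5, 2, 2, 3), (5, 2, 2, -1)]:
        with pytest.raises(ValueError):
            enrich.hypergeom_upper_tail(*bad)


def test_hypergeom_matches_enumeration_small_grid():
    """Log-space tails agree with exact integer enumeration (N <= 25)."""
    for N in range(1, 26):
        for K in range(N + 1):
            for n in range(N + 1):
                tails = enrich.hypergeom_tail_all(N, K, n)
                for k in range(min(n, K) + 1):
                    exact = hypergeom_tail_enumeration(N, K, n, k)
                    assert tails[k] == pytest.approx(exact, abs=1e-10), (N, K, n, k)


def test_hypergeom_matches_scipy_at_scale():
    for N, K, n, k in [(10_000, 40, 1500, 15), (100_000, 200, 5000, 30), (5000, 10, 100, 3)]:
        assert enrich.hypergeom_upper_tail(N, K, n, k) == pytest.approx(
            float(stats.hypergeom.sf(k - 1, N, K, n)), rel=1e-9
        )


def test_scalar_and_vector_paths_agree():
    tails = enrich.hypergeom_tail_all(60, 20, 30)
    for k in range(0, 21, 5):
        assert enrich.hypergeom_upper_tail(60, 20, 30, k) == tails[k]


# ------------------------------------------------------------------ FDR


def test_bh_stepup_hand_example():
    q = enrich.bh_fdr([0.01, 0.02, 0.03])
    assert q == pytest.approx([0.03, 0.03, 0.03])


def test_bh_single_and_constant_inputs():
    assert enrich.bh_fdr([0.2]) == pytest.approx([0.2])
    assert enrich.bh_fdr([0.07, 0.07, 0.07]) == pytest.approx([0.07, 0.07, 0.07])


def test_bh_preserves_input_order():
    p = [0.04, 0.001, 0.9, 0.02]
    q = enrich.bh_fdr(p)
    shuffled = [p[i] for i in (2, 0, 3, 1)]
    q_shuffled = enrich.bh_fdr(shuffled)
    assert [q[i] for i in (2, 0, 3, 1)] == pytest.approx(list(q_shuffled))


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
def test_bh_matches_bruteforce_and_invariants(p):
    q = enrich.bh_fdr(p)
    assert q == pytest.approx(bh_stepup_bruteforce(p), abs=1e-12)
    assert np.all(q >= np.asarray(p) - 1e-12)
    assert np.all(q <= 1.0 + 1e-12)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)  # monotone over sorted p


def test_bonferroni_option():
    assert enrich.bh_fdr([0.01, 0.4], method="bonferroni") == pytest.approx([0.02, 0.8])
    with pytest.raises(ValueError):
        enrich.bh_fdr([0.5], method="holm")


# ------------------------------------------------------------------ ORA


@pytest.fixture
def collection():
    universe = [f"P{i:03d}" for i in range(60)]
    pathways = {
        "target-like": frozenset(universe[:10]),
        "half": frozenset(universe[5:15]),
        "far": frozenset(universe[30:40]),
        "rest": frozenset(universe[40:55]),
    }
    cats = {
        "target-like": "Immune System/Innate Immune System",
        "half": "Immune System/Cytokine Signaling",
        "far": "Metabolism/Lipids",
        "rest": "Metabolism/Lipids",
    }
    return PathwayCollection(pathways=pathways, categories=cats, universe=frozenset(universe))


def test_run_ora_exact_match_has_minimum_p(collection):
    res = enrich.run_ora(collection.pathways["target-like"], collection)
    res = res.set_index("pathway")
    assert res["p"].idxmin() == "target-like"
    assert bool(res.loc["target-like", "covered"])
    assert "far" not in res.index  # zero overlap -> not tested


def test_run_ora_invariants(collection):
    res = enrich.run_ora(set(list(collection.universe)[:20]), collection)
    assert ((res["k"] >= 1) & (res["k"] <= np.minimum(res["n"], res["K"]))).all()
    assert (res["q"] >= res["p"] - 1e-12).all()
    assert ((res["p"] > 0) & (res["p"] <= 1)).all()
    assert (res.loc[res["covered"], "k"] >= 1).all()


def test_run_ora_coverage_monotone_in_alpha(collection):
    targets = collection.pathways["target-like"] | collection.pathways["half"]
    counts = [
        enrich.run_ora(targets, collection, alpha=a)["covered"].sum() for a in (0.2, 0.05, 0.001)
    ]
    assert counts == sorted(counts, reverse=True)


def test_run_ora_drops_foreign_targets_with_warning(collection):
    with pytest.warns(UserWarning, match="outside the universe"):
        res = enrich.run_ora({"P000", "alien"}, collection)
    assert (res["n"] == 1).all()


def test_run_ora_empty_target_set(collection):
    with pytest.warns(UserWarning):
        res = enrich.run_ora({"alien"}, collection)
    assert len(res) == 0


def test_universe_growth_recomputes_consistently(collection):
    """Growing the universe leaves k, K, n fixed and p follows the formula."""
    targets = set(list(collection.universe)[:20])
    before = enrich.run_ora(targets, collection).set_index("pathway")
    bigger = PathwayCollection(
        pathways=collection.pathways,
        categories=collection.categories,
        universe=collection.universe | {f"X{i}" for i in range(40)},
    )
    after = enrich.run_ora(targets, bigger).set_index("pathway")
    assert (after["N"] == 100).all()
    for name, row in after.iterrows():
        assert row["k"] == before.loc[name, "k"]
        assert row["K"] == before.loc[name, "K"]
        assert row["n"] == before.loc[name, "n"]
        assert row["p"] == enrich.hypergeom_upper_tail(100, int(row["K"]), int(row["n"]), int(row["k"]))


def test_pathway_members_must_live_in_universe():
    with pytest.raises(ValueError, match="outside the universe"):
        PathwayCollection(pathways={"pw": frozenset({"A"})}, universe=frozenset({"B"}))


# ------------------------------------------------------------- coverage


def test_compare_coverage_identical_groups(collection):
    res = enrich.run_ora(collection.pathways["target-like"], collection)
    out = enrich.compare_coverage({"g1": res, "g2": res})
    assert (out["n_exclusive"] == 0).all()
    assert (out["n_common"] == out["n_covered"]).all()


def test_compare_coverage_empty_group(collection):
    res = enrich.run_ora(collection.pathways["target-like"], collection)
    empty = res.iloc[0:0]
    out = enrich.compare_coverage({"g1": res, "g2": empty})
    g2 = out[out["group"] == "g2"]
    assert (g2["n_covered"] == 0).all()


def test_compare_coverage_unknown_filter_lists_categories(collection):
    res = enrich.run_ora(collection.pathways["target-like"], collection)
    with pytest.raises(ValueError, match="Immune System"):
        enrich.compare_coverage({"a": res, "b": res}, category_filter="Nervous System")
    with pytest.raises(ValueError):
        enrich.compare_coverage({"only": res})


def test_category_rollup_two_levels(collection):
    assert collection.category("target-like") == "Immune System/Innate Immune System"
    assert collection.category("target-like", levels=1) == "Immune System"
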