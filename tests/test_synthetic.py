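"""Synthetic generators: determinism, planted structure, marginal fidelity."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chmnet import arm, synthetic
from chmnet.io import write_gmt
from chmnet.synthetic import (
    CohortSpec,
    IngredientDBSpec,
    PlantedCluster,
    PlantedNetworkSpec,
)


def two_cluster_spec(**overrides):
    base = dict(
        clusters=(
            PlantedCluster(herbs=("a1", "a2", "a3"), core="a1", co_draw=1.0, weight=0.5),
            PlantedCluster(herbs=("b1", "b2", "b3"), core="b1", co_draw=1.0, weight=0.5),
        ),
        background_herbs=(),
        size_dist={2: 0.5, 3: 0.5},
        n_prescriptions=500,
        background_mass=0.0,
        seed=1,
    )
    base.update(overrides)
    return PlantedNetworkSpec(**base)


# ------------------------------------------------------------------ cohort


def test_cohort_row_count_matches_published_group_sizes():
    spec = synthetic.default_cohort_spec(seed=0)
    assert spec.n_users == 33_507 and spec.n_nonusers == 55_641
    small = synthetic.default_cohort_spec(seed=0, n_users=120, n_nonusers=80)
    table = synthetic.generate_cohort(small)
    assert len(table) == 200
    assert table["chm_user"].sum() == 120


def test_cohort_determinism():
    spec = synthetic.default_cohort_spec(seed=5, n_users=400, n_nonusers=300)
    pd.testing.assert_frame_equal(synthetic.generate_cohort(spec), synthetic.generate_cohort(spec))


def test_cohort_degenerate_distribution_is_all_female():
    probs = {
        g: {"gender": {"male": 0.0, "female": 1.0}} for g in ("user", "nonuser")
    }
    table = synthetic.generate_cohort(CohortSpec(n_users=50, n_nonusers=50, category_probs=probs, seed=0))
    assert (table["gender"] == "female").all()


def test_cohort_female_share_within_three_binomial_sd():
    p = 0.564
    probs = {g: {"gender": {"male": 1 - p, "female": p}} for g in ("user", "nonuser")}
    spec = CohortSpec(n_users=10_000, n_nonusers=0, category_probs=probs, seed=1)
    table = synthetic.generate_cohort(spec)
    share = (table["gender"] == "female").mean()
    assert abs(share - p) <= 3 * np.sqrt(p * (1 - p) / 10_000)


def test_cohort_invalid_probability_vector_names_variable():
    probs = {
        "user": {"gender": {"male": 0.6, "female": 0.6}},
        "nonuser": {"gender": {"male": 0.5, "female": 0.5}},
    }
    with pytest.raises(ValueError, match="gender"):
        synthetic.generate_cohort(CohortSpec(10, 10, probs, seed=0))


def test_cohort_marginals_chi_square_goodness_of_fit():
    """Empirical category frequencies match the spec probabilities.

    Twenty seeded cohorts of 10,000; a seed fails if any variable's
    chi-square goodness-of-fit test rejects at alpha = 0.001.  At most one
    failing seed is tolerated.
    """
    failures = 0
    for seed in range(20):
        spec = synthetic.default_cohort_spec(seed=seed, n_users=5000, n_nonusers=5000)
        table = synthetic.generate_cohort(spec)
        rejected = False
        for group, is_user in (("user", True), ("nonuser", False)):
            sub = table[table["chm_user"] == is_user]
            for var, level_probs in spec.category_probs[group].items():
                values = sub[var]
                if values.dtype == bool:
                    observed = [int(values.sum()), int((~values).sum())]
                    expected = [level_probs["yes"] * len(sub), level_probs["no"] * len(sub)]
                else:
                    observed = [int((values == lvl).sum()) for lvl in level_probs]
                    expected = [p * len(sub) for p in level_probs.values()]
                if stats.chisquare(observed, expected).pvalue < 0.001:
                    rejected = True
        failures += rejected
    assert failures <= 1


# ------------------------------------------------------------ prescriptions


def test_prescriptions_deterministic_and_duplicate_free(demo_spec, demo_prescriptions):
    again = synthetic.generate_prescriptions(demo_spec)
    pd.testing.assert_frame_equal(demo_prescriptions, again)
    for cell in demo_prescriptions["herbs"]:
        items = cell.split("|")
        assert len(items) == len(set(items))


def test_degenerate_size_distribution():
    spec = synthetic.default_network_spec(seed=3, n_prescriptions=1000)
    spec = PlantedNetworkSpec(
        clusters=spec.clusters,
        background_herbs=spec.background_herbs,
        size_dist={5: 1.0},
        n_prescriptions=1000,
        seed=3,
    )
    rx = synthetic.generate_prescriptions(spec)
    assert all(len(c.split("|")) == 5 for c in rx["herbs"])


def test_pure_clusters_when_co_draw_is_one():
    spec = two_cluster_spec()
    rx = synthetic.generate_prescriptions(spec)
    clusters = [set(c.herbs) for c in spec.clusters]
    for cell in rx["herbs"]:
        items = set(cell.split("|"))
        assert any(items <= c for c in clusters)


def test_core_always_present_in_cluster_transactions():
    spec = two_cluster_spec()
    rx = synthetic.generate_prescriptions(spec)
    for cell in rx["herbs"]:
        items = set(cell.split("|"))
        assert "a1" in items or "b1" in items


def test_mean_size_tracks_published_average():
    """Empirical mean of the default size distribution is within 0.1 of 5.6."""
    spec = synthetic.default_network_spec(seed=7, n_prescriptions=50_000)
    rx = synthetic.generate_prescriptions(spec)
    assert abs(arm.mean_prescription_size(rx) - 5.6) <= 0.1


def test_size_exceeding_distinct_herbs_rejected():
    with pytest.raises(ValueError, match="distinct herbs"):
        two_cluster_spec(size_dist={10: 1.0}).validate()


def test_duplicate_herb_across_clusters_rejected():
    with pytest.raises(ValueError, match="unique"):
        two_cluster_spec(background_herbs=("a1",)).validate()


def test_core_must_belong_to_cluster():
    with pytest.raises(ValueError, match="core"):
        PlantedCluster(herbs=("x", "y"), core="z")


def test_ground_truth_membership_covers_all_cluster_herbs(demo_spec):
    membership = demo_spec.membership()
    assert len(membership) == 31
    assert set(membership.values()) == set(range(1, 7))


# ------------------------------------------------------- ingredients etc.


def test_ingredient_db_scale_and_ranges():
    spec = synthetic.default_ingredient_spec(seed=4)
    table, target_map = synthetic.generate_ingredient_db(spec)
    assert 31 * 78 <= len(table) <= 31 * 79  # ~2,432 ingredients over 31 herbs
    assert table["ob"].between(0, 1).all() and table["dl"].between(0, 1).all()
    assert table["ingredient"].is_unique
    assert set(table["ingredient"]) == set(target_map)
    # every ingredient belongs to exactly one herb record
    assert table.groupby("ingredient")["herb"].nunique().eq(1).all()


def test_ingredient_db_deterministic():
    spec = synthetic.default_ingredient_spec(seed=9)
    t1, m1 = synthetic.generate_ingredient_db(spec)
    t2, m2 = synthetic.generate_ingredient_db(spec)
    pd.testing.assert_frame_equal(t1, t2)
    assert m1 == m2


def test_ingredient_db_rejects_empty_protein_universe():
    with pytest.raises(ValueError, match="protein universe"):
        IngredientDBSpec(herbs=("h",), proteins=()).validate()


def test_pathway_generation_and_validation():
    universe = [f"P{i}" for i in range(50)]
    coll = synthetic.generate_pathways(140, (5, 10), universe, ("Immune System/Innate",), seed=2)
    assert len(coll) == 140
    assert all(m <= coll.universe for m in coll.pathways.values())
    whole = synthetic.generate_pathways(3, (50, 50), universe, seed=2)
    assert all(m == frozenset(universe) for m in whole.pathways.values())
    with pytest.raises(ValueError, match="size_range"):
        synthetic.generate_pathways(5, (60, 70), universe, seed=2)


def test_pathway_gmt_output_deterministic(tmp_path):
    universe = [f"P{i}" for i in range(30)]
    paths = []
    for name in ("a.gmt", "b.gmt"):
        coll = synthetic.generate_pathways(10, (3, 6), universe, seed=6)
        p = tmp_path / name
        write_gmt(coll, p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_spec_files_load_and_validate(tmp_path):
    good = tmp_path / "rx.yaml"
    good.write_text(
        "kind: prescriptions\n"
        "n_prescriptions: 50\n"
        "size_dist: {2: 0.5, 3: 0.5}\n"
        "background_herbs: [bg1, bg2, bg3]\n"
        "clusters:\n"
        "  - {herbs: [a1, a2, a3], core: a1, weight: 0.9}\n"
        "seed: 4\n"
    )
    spec = synthetic.load_spec(good)
    rx = synthetic.generate_prescriptions(spec)
    assert len(rx) == 50
    bad = tmp_path / "bad.yaml"
    bad.write_text("kind: prescriptions\nn_prescriptions: 10\n")
    with pytest.raises(ValueError, match="missing"):
        synthetic.load_spec(bad)
    bad.write_text("kind: nope\n")
    with pytest.raises(ValueError, match="kind"):
        synthetic.load_spec(bad)


def test_planted_coverage_enriches_named_groups():
    rng = np.random.default_rng(0)
    universe = [f"P{i}" for i in range(500)]
    targets = {"G1": frozenset(rng.choice(universe, 60, replace=False))}
    coll = synthetic.plant_pathway_coverage(
        {"G1": targets["G1"]},
        universe,
        blocks=[(5, "X/Y", ("G1",)), (5, "X/Z", ())],
        size_range=(20, 20),
        seed=1,
    )
    enriched = [len(coll.pathways[f"PW{i:04d}"] & targets["G1"]) for i in range(5)]
    background = [len(coll.pathways[f"PW{i:04d}"] & targets["G1"]) for i in range(5, 10)]
    assert min(enriched) > max(background)
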