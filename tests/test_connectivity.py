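import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cmapscreen.connectivity import (
    RankedProfile,
    ReferenceCompendium,
    drug_enrichment,
    drug_p_value,
    instance_es,
    ks_tag_score,
    query,
    read_compendium,
    scale_scores,
    write_compendium,
    write_drug_gmt,
)
from cmapscreen.errors import ValidationError
from cmapscreen.signature import Signature
from cmapscreen.synthetic import (
    default_compendium_truth,
    make_compendium,
)


# ---------------------------------------------------------------------------
# Independent oracles (plain-python, scalar loops)


def ks_brute(V, n):
    """Direct loop evaluation of both one-sided maxima."""
    t = len(V)
    a = max(j / t - V[j - 1] / n for j in range(1, t + 1))
    b = max(V[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
    return a if a > b else -b


def exact_p_brute(observed, n, t):
    """Exhaustive enumeration of all C(n, t) subsets."""
    extreme = total = 0
    for subset in itertools.combinations(range(1, n + 1), t):
        total += 1
        s = ks_brute(list(subset), n)
        if (observed <= 0 and s <= observed) or (observed > 0 and s >= observed):
            extreme += 1
    return extreme / total


def sig(up, down):
    return Signature(list(up), list(down), pd.DataFrame())


def profile_from_positions(n, up_at, down_at, instance_id="i1", drug="d1"):
    """Universe g1..gn; up tags placed at `up_at` ranks, down at `down_at`."""
    ordering = [None] * n
    up_tags = [f"u{k}" for k in range(len(up_at))]
    down_tags = [f"d{k}" for k in range(len(down_at))]
    for tag, posn in zip(up_tags, up_at):
        ordering[posn - 1] = tag
    for tag, posn in zip(down_tags, down_at):
        ordering[posn - 1] = tag
    filler = iter(f"g{k}" for k in range(n))
    ordering = [p if p is not None else next(filler) for p in ordering]
    return (
        RankedProfile(instance_id, drug, tuple(ordering)),
        sig(up_tags, down_tags),
    )


class TestKsTagScore:
    def test_top_pair(self):
        assert ks_tag_score([1, 2], 10) == pytest.approx(0.8)

    def test_bottom_pair(self):
        assert ks_tag_score([9, 10], 10) == pytest.approx(-0.9)

    def test_whole_universe(self):
        for n in (3, 10, 25):
            assert ks_tag_score(list(range(1, n + 1)), n) == pytest.approx(-1.0 / n)

    def test_matches_brute_force_n8(self):
        for n in range(1, 9):
            for t in range(1, n + 1):
                for V in itertools.combinations(range(1, n + 1), t):
                    assert ks_tag_score(list(V), n) == pytest.approx(
                        ks_brute(list(V), n), abs=1e-12
                    )

    @given(st.data())
    def test_matches_brute_force_random(self, data):
        n = data.draw(st.integers(2, 200))
        t = data.draw(st.integers(1, n))
        V = sorted(data.draw(
            st.sets(st.integers(1, n), min_size=t, max_size=t)
        ))
        assert ks_tag_score(V, n) == pytest.approx(ks_brute(V, n), abs=1e-12)

    def test_bounds(self):
        for n in range(1, 9):
            for t in range(1, n + 1):
                for V in itertools.combinations(range(1, n + 1), t):
                    assert -1.0 <= ks_tag_score(list(V), n) <= 1.0

    def test_reversal_swaps_deviations(self):
        # exact invariant under rank reversal: a_rev = b - 1/n, b_rev = a + 1/n
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 40))
            t = int(rng.integers(1, n + 1))
            V = sorted(rng.choice(np.arange(1, n + 1), size=t, replace=False))
            W = sorted(n + 1 - v for v in V)
            j = np.arange(1, t + 1)
            a = np.max(j / t - np.asarray(V) / n)
            b = np.max(np.asarray(V) / n - (j - 1) / t)
            a_rev, b_rev = b - 1 / n, a + 1 / n
            got = ks_tag_score(W, n)
            if abs(a_rev - b_rev) < 1e-9:
                # a tie: either signed value is a valid float resolution
                assert abs(got) == pytest.approx(a_rev, abs=1e-12)
            else:
                expected = a_rev if a_rev > b_rev else -b_rev
                assert got == pytest.approx(expected, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValidationError):
            ks_tag_score([], 10)
        with pytest.raises(ValidationError):
            ks_tag_score([3, 3], 10)
        with pytest.raises(ValidationError):
            ks_tag_score([5, 2], 10)
        with pytest.raises(ValidationError):
            ks_tag_score([0, 2], 10)
        with pytest.raises(ValidationError):
            ks_tag_score([2, 11], 10)


class TestInstanceEs:
    def test_combined_hand_example(self):
        profile, signature = profile_from_positions(10, [1, 2], [9, 10])
        score = instance_es(signature, profile)
        assert score.ks_up == pytest.approx(0.8)
        assert score.ks_down == pytest.approx(-0.9)
        assert score.es == pytest.approx(1.7)

    def test_reversed_profile(self):
        profile, signature = profile_from_positions(10, [9, 10], [1, 2])
        score = instance_es(signature, profile)
        assert score.es == pytest.approx(-1.7)

    def test_same_sign_zero_rule(self):
        profile, signature = profile_from_positions(10, [1, 2], [3, 4])
        score = instance_es(signature, profile)
        assert score.ks_up > 0 and score.ks_down > 0
        assert score.es == 0.0

    def test_up_only_signature(self):
        profile, _ = profile_from_positions(10, [1, 2], [])
        score = instance_es(sig(["u0", "u1"], []), profile)
        assert score.es == pytest.approx(0.8)

    def test_down_only_signature(self):
        profile, _ = profile_from_positions(10, [], [9, 10])
        score = instance_es(sig([], ["d0", "d1"]), profile)
        assert score.es == pytest.approx(0.9)

    def test_missing_tags_dropped(self):
        profile, _ = profile_from_positions(10, [1, 2], [9, 10])
        score = instance_es(sig(["u0", "u1", "absent"], ["d0", "d1"]), profile)
        assert score.ks_up == pytest.approx(0.8)

    def test_side_emptied_raises(self):
        profile, _ = profile_from_positions(10, [1, 2], [9, 10])
        with pytest.raises(ValidationError):
            instance_es(sig(["absent"], ["d0"]), profile)

    def test_es_bounds(self):
        rng = np.random.default_rng(1)
        probes = [f"g{k}" for k in range(30)]
        for _ in range(100):
            order = tuple(rng.permutation(probes))
            s = sig(probes[:5], probes[5:12])
            score = instance_es(s, RankedProfile("i", "d", order))
            assert -2.0 <= score.es <= 2.0


class TestScaleScores:
    def test_hand_example(self):
        np.testing.assert_allclose(scale_scores([0.8, -0.4, 0.2]), [1.0, -1.0, 0.25])

    def test_all_zero(self):
        np.testing.assert_allclose(scale_scores([0.0, 0.0, 0.0]), [0.0, 0.0, 0.0])

    def test_single_sided(self):
        np.testing.assert_allclose(scale_scores([0.5, 0.25]), [1.0, 0.5])

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            scale_scores([])

    @given(st.lists(st.floats(-2, 2, allow_nan=False), min_size=1, max_size=30))
    def test_range_and_extremes(self, es):
        scaled = scale_scores(es)
        assert np.all(scaled >= -1.0) and np.all(scaled <= 1.0)
        es = np.asarray(es)
        if (es > 0).any():
            assert scaled.max() == pytest.approx(1.0)
        if (es < 0).any():
            assert scaled.min() == pytest.approx(-1.0)


class TestDrugEnrichment:
    def test_top_positions(self):
        ordering = [f"i{k}" for k in range(1, 11)]
        assert drug_enrichment(ordering, ["i1", "i2"]) == pytest.approx(0.8)

    def test_bottom_positions(self):
        ordering = [f"i{k}" for k in range(1, 11)]
        assert drug_enrichment(ordering, ["i9", "i10"]) == pytest.approx(-0.9)

    def test_owns_all_instances(self):
        ordering = [f"i{k}" for k in range(1, 8)]
        assert drug_enrichment(ordering, ordering) == pytest.approx(-1 / 7)

    def test_validation(self):
        with pytest.raises(ValidationError):
            drug_enrichment(["i1"], [])
        with pytest.raises(ValidationError):
            drug_enrichment(["i1"], ["i9"])


class TestDrugPValue:
    def test_exact_bottom_pair(self):
        p = drug_p_value(-0.9, n=10, t=2, mode="exact")
        assert p == pytest.approx(1 / 45)

    def test_exact_matches_brute_enumeration(self):
        for n, t in [(6, 2), (7, 3), (8, 2), (9, 4)]:
            for subset in [(1, t), (n - t + 1, n)]:
                V = sorted(set(range(subset[0], subset[0] + t)))[:t]
                observed = ks_brute(V, n)
                assert drug_p_value(observed, n, t, mode="exact") == pytest.approx(
                    exact_p_brute(observed, n, t), abs=1e-12
                )

    def test_observed_zero_symmetric_null(self):
        assert drug_p_value(0.0, n=10, t=2, mode="exact") >= 0.5

    def test_permutation_close_to_exact(self):
        p = drug_p_value(-0.9, n=10, t=2, mode="permutation", n_perm=4400, seed=5)
        assert p == pytest.approx(1 / 45, abs=0.01)

    def test_permutation_reproducible(self):
        kw = dict(n=12, t=3, mode="permutation", n_perm=500, seed=17)
        assert drug_p_value(-0.5, **kw) == drug_p_value(-0.5, **kw)

    def test_validation(self):
        with pytest.raises(ValidationError):
            drug_p_value(0.1, 10, 2, mode="bayes")
        with pytest.raises(ValidationError):
            drug_p_value(0.1, 10, 2, mode="permutation", n_perm=50)
        with pytest.raises(ValidationError):
            drug_p_value(0.1, 10, 0, mode="exact")
        with pytest.raises(ValidationError):
            drug_p_value(0.1, 500, 10, mode="exact")  # C(500,10) too large


def _matched_signature(truth):
    return sig(truth.planted_up, truth.planted_down)


@pytest.fixture(scope="module")
def planted(default_cohort):
    _, cohort_truth = default_cohort
    comp, comp_truth = make_compendium(
        cohort_truth, default_compendium_truth(n_mimickers=2, seed=7)
    )
    return cohort_truth, comp, comp_truth


class TestQuery:
    def test_reversers_recovered(self, planted):
        cohort_truth, comp, comp_truth = planted
        res = query(_matched_signature(cohort_truth), comp, seed=3)
        hits = set(res.hits)
        assert set(comp_truth.reversers) <= hits
        null_drugs = (
            set(comp_truth.drug_names)
            - set(comp_truth.reversers)
            - set(comp_truth.mimickers)
        )
        assert len(hits & null_drugs) <= 4
        assert not hits & set(comp_truth.mimickers)

    def test_mimickers_positive(self, planted):
        cohort_truth, comp, comp_truth = planted
        res = query(_matched_signature(cohort_truth), comp, seed=3)
        by_drug = {d.drug: d for d in res.drug_results}
        for drug in comp_truth.mimickers:
            assert by_drug[drug].enrichment > 0
            assert not by_drug[drug].hit

    def test_drug_results_cover_compendium(self, planted):
        cohort_truth, comp, _ = planted
        res = query(_matched_signature(cohort_truth), comp, seed=3)
        assert sorted(d.drug for d in res.drug_results) == comp.drugs
        assert len(res.instance_scores) == comp.n_instances

    def test_scaled_and_es_bounds(self, planted):
        cohort_truth, comp, _ = planted
        res = query(_matched_signature(cohort_truth), comp, seed=3)
        for s in res.instance_scores:
            assert -2.0 <= s.es <= 2.0
            assert -1.0 <= s.scaled_score <= 1.0

    def test_invariant_to_instance_order(self, planted):
        cohort_truth, comp, _ = planted
        rng = np.random.default_rng(0)
        shuffled = ReferenceCompendium(
            comp.probe_universe,
            [comp.instances[i] for i in rng.permutation(comp.n_instances)],
        )
        a = query(_matched_signature(cohort_truth), comp, seed=3)
        b = query(_matched_signature(cohort_truth), shuffled, seed=3)
        assert a.drugs_frame().equals(b.drugs_frame())
        assert [s.instance_id for s in a.instance_scores] == [
            s.instance_id for s in b.instance_scores
        ]

    def test_single_drug_compendium(self):
        rng = np.random.default_rng(2)
        probes = [f"g{k}" for k in range(20)]
        instances = [
            RankedProfile(f"i{k}", "onlydrug", tuple(rng.permutation(probes)))
            for k in range(6)
        ]
        comp = ReferenceCompendium(probes, instances)
        res = query(sig(probes[:3], probes[3:6]), comp, seed=0)
        (drug,) = res.drug_results
        assert drug.enrichment == pytest.approx(-1 / 6)
        assert drug.p_value == 1.0
        assert not drug.hit

    def test_disjoint_universe_raises(self, planted):
        _, comp, _ = planted
        with pytest.raises(ValidationError):
            query(sig(["zzz1"], ["zzz2"]), comp, seed=0)

    def test_dropped_tags_counted(self, planted):
        cohort_truth, comp, _ = planted
        s = sig(
            list(cohort_truth.planted_up) + ["offplatform1", "offplatform2"],
            list(cohort_truth.planted_down),
        )
        res = query(s, comp, seed=3)
        assert res.dropped_up_tags == 2
        assert res.dropped_down_tags == 0

    def test_reversed_profiles_flip_reverser_sign(self, planted):
        cohort_truth, comp, comp_truth = planted
        flipped = ReferenceCompendium(
            comp.probe_universe,
            [
                RankedProfile(i.instance_id, i.drug, tuple(reversed(i.ordering)))
                for i in comp.instances
            ],
        )
        res = query(_matched_signature(cohort_truth), flipped, seed=3)
        by_drug = {d.drug: d for d in res.drug_results}
        for drug in comp_truth.reversers:
            assert by_drug[drug].enrichment > 0
            assert not by_drug[drug].hit


class TestCompendiumValidation:
    def test_not_a_permutation(self):
        probes = ["a", "b", "c"]
        with pytest.raises(ValidationError):
            ReferenceCompendium(
                probes, [RankedProfile("i1", "d", ("a", "b", "b"))]
            )

    def test_duplicate_instance_ids(self):
        probes = ["a", "b"]
        insts = [
            RankedProfile("i1", "d", ("a", "b")),
            RankedProfile("i1", "d", ("b", "a")),
        ]
        with pytest.raises(ValidationError):
            ReferenceCompendium(probes, insts)

    def test_empty(self):
        with pytest.raises(ValidationError):
            ReferenceCompendium(["a"], [])


class TestCompendiumIO:
    def test_round_trip(self, tmp_path, default_cohort):
        _, cohort_truth = default_cohort
        comp, _ = make_compendium(
            cohort_truth,
            default_compendium_truth(n_drugs=4, instances_per_drug=2, n_reversers=1),
            n_probes=50,
        )
        ranks, meta = tmp_path / "ranks.tsv", tmp_path / "instances.tsv"
        write_compendium(comp, ranks, meta)
        back = read_compendium(ranks, meta)
        assert back.probe_universe == comp.probe_universe
        assert [i.instance_id for i in back.instances] == [
            i.instance_id for i in comp.instances
        ]
        for a, b in zip(back.instances, comp.instances):
            assert a.ordering == b.ordering
            assert a.drug == b.drug

    def test_bad_rank_column(self, tmp_path):
        (tmp_path / "ranks.tsv").write_text("probe_id\ti1\npA\t1\npB\t3\n")
        (tmp_path / "inst.tsv").write_text("instance_id\tdrug\ni1\td1\n")
        with pytest.raises(ValidationError, match="i1"):
            read_compendium(tmp_path / "ranks.tsv", tmp_path / "inst.tsv")

    def test_missing_metadata(self, tmp_path):
        (tmp_path / "ranks.tsv").write_text("probe_id\ti1\npA\t1\npB\t2\n")
        (tmp_path / "inst.tsv").write_text("instance_id\tdrug\nother\td1\n")
        with pytest.raises(ValidationError):
            read_compendium(tmp_path / "ranks.tsv", tmp_path / "inst.tsv")

    def test_gmt_export(self, tmp_path):
        probes = ["a", "b"]
        comp = ReferenceCompendium(
            probes,
            [
                RankedProfile("i1", "d2", ("a", "b")),
                RankedProfile("i2", "d1", ("b", "a")),
                RankedProfile("i3", "d1", ("a", "b")),
            ],
        )
        path = tmp_path / "drugs.gmt"
        write_drug_gmt(comp, path)
        lines = path.read_text().splitlines()
        assert lines == ["d1\tna\ti2\ti3", "d2\tna\ti1"]
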