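import itertools
import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lifespan_epistasis.epistasis import (
    EpistasisCall,
    aggregate_calls,
    classify_pair,
    delta_percent,
    full_synergy,
    monotony,
    simple_synergy,
)
from lifespan_epistasis.records import group_observations

from .conftest import make_group, make_model, make_obs

nonzero_delta = st.floats(-95.0, 200.0).filter(lambda d: abs(d) > 1e-6)


def brute_force_full_synergy(deltas: dict[frozenset, float]) -> bool:
    """Independent oracle: check |d(full)| > |d(S)| + |d(S~)| for every
    bipartition by direct enumeration over all subset pairs."""
    (full,) = [s for s in deltas if len(s) == max(map(len, deltas))]
    ok = True
    for left in (frozenset(c) for r in range(1, len(full))
                 for c in itertools.combinations(sorted(full), r)):
        right = full - left
        if not right:
            continue
        if not abs(deltas[full]) > abs(deltas[left]) + abs(deltas[right]):
            ok = False
    return ok


def brute_force_monotony(lifespans: dict[frozenset, float], target: frozenset):
    """Independent oracle: recursive walk over all gene orderings."""
    known = up = down = bad = 0
    for order in itertools.permutations(sorted(target)):
        chain = [frozenset(order[:k]) for k in range(len(order) + 1)]
        if any(c not in lifespans for c in chain):
            continue
        known += 1
        vals = [lifespans[c] for c in chain]
        if all(b > a for a, b in zip(vals, vals[1:])):
            up += 1
        elif all(b < a for a, b in zip(vals, vals[1:])):
            down += 1
        else:
            bad += 1
    if known == 0:
        return known, "no_known_path"
    if bad:
        return known, "contains_dependency"
    return known, "monotonic_positive" if up else "monotonic_negative"


class TestDeltaPercent:
    @pytest.mark.parametrize("mut, wt, expected", [(40, 20, 100.0), (20, 20, 0.0), (15, 20, -25.0)])
    def test_formula(self, mut, wt, expected):
        assert delta_percent(mut, wt) == expected

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            delta_percent(-1, 20)
        with pytest.raises(ValueError):
            delta_percent(20, 0)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "d1, d2, d12, category, direction",
        [
            (30, 20, 60, "synergistic", "long-lived"),
            (30, 20, 50, "additive", "long-lived"),
            (30, 20, 40, "almost_additive", "long-lived"),
            (30, 20, 25, "dependent", "long-lived"),
            (30, 20, 10, "antagonistic", "long-lived"),
            (30, 20, -5, "antagonistic", "opposite"),
            (-30, -20, -60, "synergistic", "short-lived"),
            (-30, -20, -25, "dependent", "short-lived"),
            (-30, -20, 5, "antagonistic", "opposite"),
            # boundary equalities per the printed inequalities
            (30, 20, 30, "dependent", "long-lived"),
            (30, 20, 20, "dependent", "long-lived"),
        ],
    )
    def test_rules(self, d1, d2, d12, category, direction):
        call = classify_pair(d1, d2, d12)
        assert (call.category, call.phenotype_direction) == (category, direction)

    @pytest.mark.parametrize("d1, d2", [(30, -20), (-30, 20), (0, 20), (30, 0)])
    def test_mixed_or_zero_directions_not_assessable(self, d1, d2):
        assert classify_pair(d1, d2, 42.0).category == "not_assessable_mixed_directions"

    def test_partition_of_the_delta_axis(self):
        """Every d12 on a fine grid gets exactly one of the five categories,
        with transitions exactly at min, max, and sum."""
        d1, d2 = 30.0, 20.0
        for d12 in np.arange(-99.5, 200.0, 0.25):
            call = classify_pair(d1, d2, float(d12))
            if d12 < 0:
                expected = "antagonistic"
            elif d12 < 20:
                expected = "antagonistic"
            elif d12 <= 30:
                expected = "dependent"
            elif d12 < 50:
                expected = "almost_additive"
            elif d12 == 50:
                expected = "additive"
            else:
                expected = "synergistic"
            assert call.category == expected, d12

    @given(nonzero_delta, nonzero_delta, st.floats(-95.0, 300.0))
    def test_symmetric_in_singles(self, d1, d2, d12):
        a, b = classify_pair(d1, d2, d12), classify_pair(d2, d1, d12)
        assert (a.category, a.phenotype_direction) == (b.category, b.phenotype_direction)

    def test_additive_epsilon_band_is_configurable(self):
        assert classify_pair(30, 20, 49.6, additive_epsilon=0.01).category == "additive"
        assert classify_pair(30, 20, 49.6).category == "almost_additive"


class TestFullSynergy:
    def test_three_gene_synergy(self, triple_family_group):
        # singles +10/+20/+30, pairs +35/+45/+55, triple +90: each of the
        # three bipartition sums is 65 < 90 (verified by the brute-force
        # oracle below)
        call = full_synergy(triple_family_group, make_model(("g1", "g2", "g3")))
        assert call.category == "synergistic"
        assert call.phenotype_direction == "long-lived"
        deltas = {
            frozenset(d.source_model.gene_set): d.value_percent for d in call.evidence
        }
        assert brute_force_full_synergy(deltas)

    def test_violated_bipartition_reported(self):
        # triple at +64 loses to the {g1}|{g2,g3} split: 10 + 55 = 65 > 64
        group = make_group(
            {
                (): 20.0, ("g1",): 22.0, ("g2",): 24.0, ("g3",): 26.0,
                ("g1", "g2"): 27.0, ("g1", "g3"): 29.0, ("g2", "g3"): 31.0,
                ("g1", "g2", "g3"): 32.8,
            }
        )
        call = full_synergy(group, make_model(("g1", "g2", "g3")))
        assert call.category == "not_synergistic"
        assert call.violated_bipartition == (("g1",), ("g2", "g3"))
        assert call.detail["worst_bipartition_sum"] == pytest.approx(65.0)
        deltas = {
            frozenset(d.source_model.gene_set): d.value_percent for d in call.evidence
        }
        assert not brute_force_full_synergy(deltas)

    def test_missing_intermediate_means_insufficient(self, triple_family_group):
        obs = [o for o in triple_family_group.observations
               if o.model.canonical_name != "g2;g3"]
        (group,) = group_observations(obs)
        call = full_synergy(group, make_model(("g1", "g2", "g3")))
        assert call.category == "insufficient_data"

    def test_unobserved_combination_is_insufficient(self, double_mutant_group):
        call = full_synergy(double_mutant_group, make_model(("g1", "g9")))
        assert call.category == "insufficient_data"

    def test_no_wild_type_is_insufficient(self):
        group = make_group({("g1",): 25.0, ("g2",): 26.0, ("g1", "g2"): 30.0})
        assert full_synergy(group, make_model(("g1", "g2"))).category == "insufficient_data"

    def test_reduces_to_classify_pair_for_doubles(self):
        rng = random.Random(7)
        for _ in range(10_000):
            wt = rng.uniform(5.0, 40.0)
            d1, d2, d12 = (rng.uniform(-90.0, 200.0) for _ in range(3))
            group = make_group(
                {
                    (): wt,
                    ("g1",): wt * (1 + d1 / 100),
                    ("g2",): wt * (1 + d2 / 100),
                    ("g1", "g2"): wt * (1 + d12 / 100),
                }
            )
            call = full_synergy(group, make_model(("g1", "g2")))
            ref = classify_pair(d1, d2, d12)
            assert call.category == ref.category
            assert call.phenotype_direction == ref.phenotype_direction

    def test_mixed_sign_subsets_not_assessable(self):
        group = make_group(
            {
                (): 20.0, ("g1",): 22.0, ("g2",): 24.0, ("g3",): 18.0,
                ("g1", "g2"): 27.0, ("g1", "g3"): 29.0, ("g2", "g3"): 31.0,
                ("g1", "g2", "g3"): 38.0,
            }
        )
        call = full_synergy(group, make_model(("g1", "g2", "g3")))
        assert call.category == "not_assessable_mixed_directions"

    def test_strict_variant_requires_synergy_at_all_levels(self):
        # triple beats every bipartition, but the pair (g1,g2) is itself
        # only dependent, so the strict recursive reading refuses synergy
        group = make_group(
            {
                (): 20.0, ("g1",): 22.0, ("g2",): 24.0, ("g3",): 26.0,
                ("g1", "g2"): 23.0, ("g1", "g3"): 29.0, ("g2", "g3"): 31.0,
                ("g1", "g2", "g3"): 38.0,
            }
        )
        model = make_model(("g1", "g2", "g3"))
        assert full_synergy(group, model).category == "synergistic"
        assert full_synergy(group, model, strict=True).category == "not_synergistic"

    def test_scale_invariance(self, triple_family_group):
        """Deltas are ratios: rescaling all lifespans changes nothing."""
        model = make_model(("g1", "g2", "g3"))
        base = full_synergy(triple_family_group, model)
        for c in (0.3, 7.0):
            obs = [make_obs(tuple(sorted(o.model.gene_set)), o.lifespan_days * c)
                   for o in triple_family_group.observations]
            (scaled,) = group_observations(obs)
            call = full_synergy(scaled, model)
            assert call.category == base.category
            assert monotony(scaled, model).verdict == monotony(triple_family_group, model).verdict


class TestSimpleSynergy:
    def test_called_from_singles_and_combination_only(self):
        group = make_group(
            {(): 20.0, ("g1",): 22.0, ("g2",): 24.0, ("g3",): 26.0,
             ("g1", "g2", "g3"): 38.0}
        )
        call = simple_synergy(group, make_model(("g1", "g2", "g3")))
        assert call.category == "synergistic"  # 90 > 10+20+30, pairs not needed

    def test_not_synergistic_below_sum(self):
        group = make_group(
            {(): 20.0, ("g1",): 22.0, ("g2",): 24.0, ("g3",): 26.0,
             ("g1", "g2", "g3"): 31.0}
        )
        call = simple_synergy(group, make_model(("g1", "g2", "g3")))
        assert call.category == "not_synergistic"

    def test_missing_single_is_insufficient(self):
        group = make_group({(): 20.0, ("g1",): 22.0, ("g1", "g2"): 30.0})
        assert simple_synergy(group, make_model(("g1", "g2"))).category == "insufficient_data"

    def test_strict_full_synergy_implies_simple_synergy(self):
        """Exhaustive 3-gene search over a coarse delta grid: whenever the
        strict (recursive) full evaluation says synergistic, so does the
        simple one; the converse direction has counterexamples.  (The
        flexible bipartition-only definition does not imply simple
        synergism: dependent pairs can pull every single+pair split below
        the combination while the three singles still sum above it —
        checked by the counterexample assertion at the end.)"""
        grid = [5.0, 15.0, 40.0]
        pair_grid = [10.0, 30.0, 70.0, 130.0]
        converse_holds = True
        checked = 0
        for d1, d2, d3 in itertools.product(grid, repeat=3):
            for p12, p13, p23 in itertools.product(pair_grid, repeat=3):
                for dfull in (30.0, 70.0, 90.0, 160.0):
                    group = make_group(
                        {
                            (): 20.0,
                            ("g1",): 20 * (1 + d1 / 100),
                            ("g2",): 20 * (1 + d2 / 100),
                            ("g3",): 20 * (1 + d3 / 100),
                            ("g1", "g2"): 20 * (1 + p12 / 100),
                            ("g1", "g3"): 20 * (1 + p13 / 100),
                            ("g2", "g3"): 20 * (1 + p23 / 100),
                            ("g1", "g2", "g3"): 20 * (1 + dfull / 100),
                        }
                    )
                    model = make_model(("g1", "g2", "g3"))
                    full = full_synergy(group, model, strict=True).category
                    simple = simple_synergy(group, model).category
                    if full == "synergistic":
                        checked += 1
                        assert simple == "synergistic"
                    if simple == "synergistic" and full != "synergistic":
                        converse_holds = False
        assert checked > 0
        assert not converse_holds  # simple synergism can be a false positive

        # flexible-definition counterexample: equal singles +45, dependent
        # pairs +15, triple +90 beats every bipartition (45+15=60 < 90) yet
        # falls short of the summed singles (135)
        group = make_group(
            {(): 20.0, ("g1",): 29.0, ("g2",): 29.0, ("g3",): 29.0,
             ("g1", "g2"): 23.0, ("g1", "g3"): 23.0, ("g2", "g3"): 23.0,
             ("g1", "g2", "g3"): 38.0}
        )
        model = make_model(("g1", "g2", "g3"))
        assert full_synergy(group, model).category == "synergistic"
        assert full_synergy(group, model, strict=True).category == "not_synergistic"
        assert simple_synergy(group, model).category == "not_synergistic"


class TestMonotony:
    def test_single_known_increasing_path(self):
        group = make_group({(): 20.0, ("g1",): 25.0, ("g1", "g2"): 30.0})
        res = monotony(group, make_model(("g1", "g2")))
        assert res.verdict == "monotonic_positive"
        assert (res.paths_known, res.paths_total) == (1, 2)

    def test_one_bad_path_means_dependency(self):
        group = make_group(
            {(): 20.0, ("g1",): 25.0, ("g2",): 30.0, ("g1", "g2"): 28.0}
        )
        res = monotony(group, make_model(("g1", "g2")))
        assert res.verdict == "contains_dependency"
        assert res.paths_known == 2

    def test_decreasing_chain(self):
        group = make_group({(): 20.0, ("g1",): 15.0, ("g1", "g2"): 12.0})
        assert monotony(group, make_model(("g1", "g2"))).verdict == "monotonic_negative"

    def test_tie_is_non_monotonic_by_default(self):
        group = make_group({(): 20.0, ("g1",): 20.0, ("g1", "g2"): 30.0})
        assert monotony(group, make_model(("g1", "g2"))).verdict == "contains_dependency"

    def test_partially_known_four_mutant_chain(self):
        # a single fully assayed increasing chain; sibling branches unassayed
        group = make_group(
            {
                (): 20.0, ("g1",): 24.0, ("g1", "g2"): 28.0,
                ("g1", "g2", "g3"): 33.0, ("g1", "g2", "g3", "g4"): 40.0,
            }
        )
        res = monotony(group, make_model(("g1", "g2", "g3", "g4")))
        assert res.verdict == "monotonic_positive"
        assert (res.paths_known, res.paths_total) == (1, 24)

    def test_unreached_combination(self):
        group = make_group({(): 20.0, ("g1",): 25.0})
        res = monotony(group, make_model(("g1", "g2")))
        assert res.verdict == "no_known_path" and res.paths_known == 0

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_matches_brute_force_oracle(self, n):
        rng = random.Random(100 + n)
        genes = tuple(f"g{i}" for i in range(n))
        for trial in range(30):
            lifespans = {frozenset(): 20.0, frozenset(genes): rng.uniform(5, 60)}
            for r in range(1, n):
                for combo in itertools.combinations(genes, r):
                    if rng.random() < 0.7:
                        lifespans[frozenset(combo)] = rng.uniform(5, 60)
            group = make_group({tuple(sorted(s)): v for s, v in lifespans.items()})
            res = monotony(group, make_model(genes))
            known, verdict = brute_force_monotony(lifespans, frozenset(genes))
            assert (res.paths_known, res.verdict) == (known, verdict)
            assert res.paths_total == math.factorial(n)

    def test_fully_assayed_path_count_is_factorial(self):
        for n in range(1, 6):
            genes = tuple(f"g{i}" for i in range(n))
            lifespans = {
                tuple(sorted(c)): 20.0 + 2.0 * len(c) + 0.1 * sum(map(len, c))
                for r in range(n + 1)
                for c in itertools.combinations(genes, r)
            }
            group = make_group(lifespans)
            res = monotony(group, make_model(genes))
            assert res.paths_known == math.factorial(n)

    def test_pair_category_constrains_monotony(self):
        """With both singles positive and full data: synergistic/additive/
        almost-additive doubles are monotonic-positive; plain antagonistic
        doubles contain a dependency."""
        rng = random.Random(11)
        for _ in range(500):
            d1, d2 = rng.uniform(1, 100), rng.uniform(1, 100)
            d12 = rng.uniform(-50, 250)
            group = make_group(
                {
                    (): 20.0,
                    ("g1",): 20 * (1 + d1 / 100),
                    ("g2",): 20 * (1 + d2 / 100),
                    ("g1", "g2"): 20 * (1 + d12 / 100),
                }
            )
            model = make_model(("g1", "g2"))
            call = full_synergy(group, model)
            verdict = monotony(group, model).verdict
            if call.category in ("synergistic", "additive", "almost_additive"):
                assert verdict == "monotonic_positive"
            elif call.category == "antagonistic" and call.phenotype_direction != "opposite":
                assert verdict == "contains_dependency"


class TestAggregateCalls:
    def test_union_semantics_with_counts(self):
        model = make_model(("g1", "g2"))
        calls = [
            EpistasisCall(model, "dependent", "long-lived", experiment_key="e1"),
            EpistasisCall(model, "dependent", "long-lived", experiment_key="e2"),
            EpistasisCall(model, "synergistic", "long-lived", experiment_key="e3"),
        ]
        out = aggregate_calls(calls)
        assert out["categories"] == {"dependent": 2, "synergistic": 1}

    def test_single_call(self):
        model = make_model(("g1", "g2"))
        out = aggregate_calls([EpistasisCall(model, "additive", "long-lived")])
        assert out["categories"] == {"additive": 1}

    def test_only_insufficient_data(self):
        model = make_model(("g1", "g2"))
        calls = [EpistasisCall(model, "insufficient_data")] * 2
        assert aggregate_calls(calls)["summary"] == "Not enough data to assess"

    def test_rejects_mixed_combinations(self):
        calls = [
            EpistasisCall(make_model(("g1", "g2")), "additive"),
            EpistasisCall(make_model(("g1", "g3")), "additive"),
        ]
        with pytest.raises(ValueError):
            aggregate_calls(calls)
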