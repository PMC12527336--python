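"""Designers: pruning, exhaustive optimality, greedy heuristic, rotation."""

import math

import numpy as np
import pytest

from cocktailnet import (
    QPBIN,
    BudgetExceededError,
    DesignConfig,
    design_cocktail_series,
    design_cocktails,
    exhaustive_search,
    greedy_search,
    neutral_qppin,
    prune_network,
)
from cocktailnet.synthetic import GeneratorSpec, random_qpbin, random_qppin

from oracle_utils import brute_force_best, brute_force_best_per_size


def _random_instance(seed):
    spec = GeneratorSpec(
        n_viruses=int(3 + seed % 8),  # up to 10 viruses
        n_hosts=int(3 + (seed // 2) % 6),  # up to 8 hosts
        target_fill=0.35,
        p_antagonism=0.2,
        p_synergy=0.1,
        seed=seed,
    )
    qpbin = random_qpbin(spec)
    qppin = random_qppin(spec, qpbin.virus_names)
    return qpbin, qppin


class TestPruneNetwork:
    def test_zero_row_virus_removed(self, example_qpbin):
        values = np.vstack([example_qpbin.values, np.zeros(example_qpbin.n_hosts)])
        qpbin = QPBIN(example_qpbin.virus_names + ["dud"], example_qpbin.host_names, values)
        reduced, removed, uncoverable = prune_network(qpbin)
        assert removed == ["dud"]
        assert "dud" not in reduced.virus_names
        assert uncoverable == []

    def test_zero_column_host_flagged(self, example_qpbin):
        values = np.hstack([example_qpbin.values, np.zeros((example_qpbin.n_viruses, 1))])
        qpbin = QPBIN(example_qpbin.virus_names, example_qpbin.host_names + ["b9"], values)
        _, removed, uncoverable = prune_network(qpbin)
        assert uncoverable == ["b9"]
        assert removed == []

    def test_fixture_untouched(self, example_qpbin):
        reduced, removed, uncoverable = prune_network(example_qpbin)
        assert removed == [] and uncoverable == []
        assert reduced.virus_names == example_qpbin.virus_names


class TestExhaustiveSearch:
    def test_fixture_quantitative_winner(self, example):
        result = exhaustive_search(*example, DesignConfig(max_size=3))
        cocktail, ev = result.overall_best
        assert cocktail.sorted_names() == ("phage1", "phage4", "phage5")
        assert ev.coverage == 5
        assert ev.antagonism_burden == 0.0
        assert result.subsets_examined == 92  # C(8,1)+C(8,2)+C(8,3)

    def test_fixture_binary_minimum_cover(self, example_qpbin):
        result = exhaustive_search(example_qpbin.binarized(), None, DesignConfig(max_size=3))
        cocktail, ev = result.overall_best
        assert cocktail.size == 2
        assert "phage3" in cocktail
        assert set(cocktail.viruses) & {"phage1", "phage2"}
        assert ev.coverage == 5

    def test_singleton_cap_picks_best_phage(self, example):
        result = exhaustive_search(*example, DesignConfig(max_size=1))
        cocktail, _ = result.overall_best
        assert cocktail.viruses == ("phage3",)  # broadest host range at size 1

    def test_budget_exceeded_is_hard_error(self, example):
        with pytest.raises(BudgetExceededError, match="network_metrics"):
            exhaustive_search(*example, DesignConfig(max_size=3, enumeration_budget=10))

    def test_all_zero_network_yields_empty_cocktail(self):
        qpbin = QPBIN(["V1", "V2"], ["H1"], np.zeros((2, 1)))
        result = exhaustive_search(qpbin)
        cocktail, ev = result.overall_best
        assert cocktail.size == 0 and ev.coverage == 0
        assert result.removed_viruses == ["V1", "V2"]
        assert result.uncoverable_hosts == ["H1"]

    def test_default_config_never_exceeds_twelve(self):
        qpbin = random_qpbin(GeneratorSpec(n_viruses=13, n_hosts=4, target_fill=0.5, seed=7))
        result = exhaustive_search(qpbin, config=DesignConfig())
        assert max(result.best_per_size) <= 12
        assert result.subsets_examined == sum(math.comb(13, k) for k in range(1, 13))

    @pytest.mark.parametrize("objective", ["coverage_first", "virulence_first"])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed, objective):
        qpbin, qppin = _random_instance(seed)
        config = DesignConfig(max_size=min(4, qpbin.n_viruses), objective=objective)
        result = exhaustive_search(qpbin, qppin, config)
        expected, _ = brute_force_best(
            qpbin, qppin, config.max_size, objective, config.redundancy_mode,
            config.redundancy_target, config.tau,
        )
        assert result.overall_best[0].sorted_names() == expected

    def test_deterministic_across_runs(self, example):
        a = exhaustive_search(*example, DesignConfig(max_size=3))
        b = exhaustive_search(*example, DesignConfig(max_size=3))
        assert a.overall_best[0] == b.overall_best[0]
        assert {k: v[0] for k, v in a.best_per_size.items()} == {
            k: v[0] for k, v in b.best_per_size.items()
        }

    def test_coverage_monotone_in_size_under_neutral_qppin(self):
        qpbin = random_qpbin(GeneratorSpec(n_viruses=8, n_hosts=6, seed=3))
        result = exhaustive_search(qpbin, None, DesignConfig(max_size=5))
        coverages = [result.best_per_size[k][1].coverage for k in sorted(result.best_per_size)]
        assert coverages == sorted(coverages)


class TestGreedySearch:
    def test_fixture_full_coverage(self, example):
        result = greedy_search(*example, DesignConfig(max_size=3, algorithm="network_metrics"))
        _, ev = result.overall_best
        assert ev.coverage == 5
        assert "phage3" not in result.overall_best[0]

    def test_all_zero_network(self):
        qpbin = QPBIN(["V1"], ["H1"], np.zeros((1, 1)))
        result = greedy_search(qpbin)
        assert result.overall_best[0].size == 0
        assert result.overall_best[1].coverage == 0

    def test_modular_instance_matches_exhaustive(self):
        # disjoint host blocks of distinct sizes, equal virulence: the greedy
        # prefix of every size is the exhaustive optimum.
        viruses = [f"v{i}" for i in range(1, 5)]
        hosts = [f"h{j}" for j in range(10)]
        values = np.zeros((4, 10))
        start = 0
        for i, block in enumerate([1, 2, 3, 4]):
            values[i, start : start + block] = 0.5
            start += block
        qpbin = QPBIN(viruses, hosts, values)
        g = greedy_search(qpbin, config=DesignConfig(max_size=4, algorithm="network_metrics"))
        e = exhaustive_search(qpbin, config=DesignConfig(max_size=4))
        for k in e.best_per_size:
            assert g.best_per_size[k][0].sorted_names() == e.best_per_size[k][0].sorted_names()

    @pytest.mark.parametrize("seed", range(10))
    def test_coverage_dominated_by_exhaustive(self, seed):
        qpbin, qppin = _random_instance(seed)
        config = DesignConfig(max_size=min(4, qpbin.n_viruses))
        e = exhaustive_search(qpbin, qppin, config)
        g = greedy_search(qpbin, qppin, config)
        for k, (_, gev) in g.best_per_size.items():
            if k in e.best_per_size:
                assert gev.coverage <= e.best_per_size[k][1].coverage

    def test_deterministic_across_runs(self, example):
        runs = [greedy_search(*example, DesignConfig(max_size=3)) for _ in range(2)]
        assert runs[0].overall_best[0] == runs[1].overall_best[0]


class TestCocktailSeries:
    def test_single_series_equals_single_search(self, example):
        config = DesignConfig(max_size=3, n_cocktails=1)
        series = design_cocktail_series(*example, config)
        single = design_cocktails(*example, config)
        assert len(series) == 1
        assert series[0].overall_best[0] == single.overall_best[0]

    def test_rotation_sets_are_disjoint(self, example):
        series = design_cocktail_series(*example, DesignConfig(max_size=3, n_cocktails=2))
        assert len(series) == 2
        first = set(series[0].overall_best[0].viruses)
        second = set(series[1].overall_best[0].viruses)
        assert not first & second

    def test_exhaustion_warns_and_truncates(self, example):
        config = DesignConfig(max_size=8, n_cocktails=10)
        with pytest.warns(UserWarning, match="exhausted"):
            series = design_cocktail_series(*example, config)
        assert len(series) < 10
        used = [v for r in series for v in r.overall_best[0].viruses]
        assert len(used) == len(set(used))


class TestRedundancyPolicies:
    def test_require_min_enforces_double_coverage(self):
        # two phages hit h1, only one hits h2; with target 2 a feasible
        # cocktail must include both h1 phages.
        qpbin = QPBIN(
            ["a", "b", "c"],
            ["h1", "h2"],
            np.array([[0.8, 0.0], [0.6, 0.0], [0.0, 0.9]]),
        )
        config = DesignConfig(max_size=3, redundancy_mode="require_min", redundancy_target=2)
        result = exhaustive_search(qpbin, config=config)
        for _, ev in result.best_per_size.values():
            if ev.per_host_inhibition["h1"] > 0:
                assert ev.per_host_redundancy["h1"] >= 2

    def test_minimize_excess_breaks_tie_toward_leaner_cover(self):
        # {a1, a2} and {a0, a1} tie on coverage (3), burden (0), total
        # inhibition (exactly 1.5) and size, but {a0, a1} double-covers h2.
        # minimize_excess must pick {a1, a2}; ignoring redundancy falls
        # through to the name tie-break, which prefers {a0, a1}.
        qpbin = QPBIN(
            ["a0", "a1", "a2"],
            ["h1", "h2", "h3"],
            np.array(
                [
                    [0.0, 0.5, 0.25],  # a0 overlaps a1 on h2
                    [0.5, 0.5, 0.0],
                    [0.0, 0.0, 0.5],
                ]
            ),
        )
        lean = exhaustive_search(
            qpbin,
            config=DesignConfig(max_size=2, redundancy_mode="minimize_excess", redundancy_target=1),
        )
        assert lean.overall_best[0].sorted_names() == ("a1", "a2")
        loose = exhaustive_search(
            qpbin, config=DesignConfig(max_size=2, redundancy_mode="ignore")
        )
        assert loose.overall_best[0].sorted_names() == ("a0", "a1")
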