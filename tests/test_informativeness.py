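"""Rosenberg In / PSD / delta statistics and cumulative-PSD balancing."""

import math

import numpy as np
import pandas as pd
import pytest

from aimkit.core_io import FrequencyTable
from aimkit.informativeness import (
    balance_panel,
    cumulative_psd,
    delta_differential,
    divergence_profile,
    population_specific_divergence,
    rosenberg_in,
)
from aimkit.synthetic_data import SyntheticConfig, simulate_frequencies

from conftest import make_panel


def scalar_in(vectors):
    """Independent scalar evaluation of the In formula."""
    vectors = [list(v) for v in vectors]
    K, A = len(vectors), len(vectors[0])
    total = 0.0
    for a in range(A):
        pbar = sum(v[a] for v in vectors) / K
        term = -(pbar * math.log(pbar)) if pbar > 0 else 0.0
        for v in vectors:
            if v[a] > 0:
                term += v[a] * math.log(v[a]) / K
        total += term
    return total


class TestRosenbergIn:
    @pytest.mark.parametrize(
        "vectors,expected",
        [
            ([[1, 0], [0, 1]], math.log(2)),  # fixed opposite alleles
            ([[0.3, 0.7], [0.3, 0.7], [0.3, 0.7]], 0.0),  # identical vectors
            ([[0.9, 0.1], [0.1, 0.9]], 0.3681),  # frozen from scalar oracle
        ],
    )
    def test_reference_values(self, vectors, expected):
        assert rosenberg_in(vectors) == pytest.approx(expected, abs=1e-4)

    def test_matches_independent_scalar_evaluation(self, rng):
        for _ in range(20):
            K, A = rng.integers(2, 6), rng.integers(2, 4)
            p = rng.dirichlet(np.ones(A), size=K)
            assert rosenberg_in(p) == pytest.approx(scalar_in(p), abs=1e-12)

    def test_invariances_and_bounds(self, rng):
        for _ in range(20):
            K, A = int(rng.integers(2, 6)), int(rng.integers(2, 4))
            p = rng.dirichlet(np.ones(A), size=K)
            base = rosenberg_in(p)
            assert 0.0 <= base <= math.log(K) + 1e-12
            assert rosenberg_in(p[rng.permutation(K)]) == pytest.approx(base)  # pop order
            assert rosenberg_in(p[:, rng.permutation(A)]) == pytest.approx(base)  # allele labels

    def test_zero_iff_all_vectors_equal(self, rng):
        p = rng.dirichlet([1, 1, 1])
        assert rosenberg_in(np.tile(p, (4, 1))) == pytest.approx(0.0, abs=1e-12)
        q = np.vstack([p, rng.dirichlet([1, 1, 1])])
        if not np.allclose(q[0], q[1], atol=1e-3):
            assert rosenberg_in(q) > 0


class TestPSD:
    def test_fixed_difference_reaches_ln2(self):
        p = [[1, 0], [0, 1], [0, 1]]
        assert population_specific_divergence(p, ["a", "b", "c"], "a") == pytest.approx(
            math.log(2)
        )

    def test_zero_when_target_equals_pooled_mean(self):
        p = [[0.4, 0.6], [0.3, 0.7], [0.5, 0.5]]  # mean of others = (0.4, 0.6)
        assert population_specific_divergence(p, ["a", "b", "c"], "a") == pytest.approx(
            0.0, abs=1e-12
        )

    def test_equals_two_vector_reduction(self):
        p = [[0.8, 0.2], [0.2, 0.8], [0.2, 0.8]]
        psd = population_specific_divergence(p, ["a", "b", "c"], "a")
        assert psd == pytest.approx(rosenberg_in([[0.8, 0.2], [0.2, 0.8]]))
        assert psd == pytest.approx(0.1927, abs=1e-4)  # frozen from scalar oracle

    def test_reduction_property_on_random_fixtures(self, rng):
        for _ in range(20):
            K = int(rng.integers(3, 7))
            p = rng.dirichlet([1, 1], size=K)
            pops = [f"g{k}" for k in range(K)]
            t = int(rng.integers(K))
            pooled = np.delete(p, t, axis=0).mean(axis=0)
            expected = scalar_in([p[t], pooled])
            got = population_specific_divergence(p, pops, pops[t])
            assert got == pytest.approx(expected, abs=1e-12)

    def test_unknown_target_errors(self):
        with pytest.raises(ValueError, match="not present"):
            population_specific_divergence([[1, 0], [0, 1]], ["a", "b"], "z")


class TestDelta:
    def test_simple_and_null_cases(self):
        p = [[0.8, 0.2], [0.2, 0.8], [0.2, 0.8]]
        assert delta_differential(p, ["a", "b", "c"], "a") == pytest.approx(0.6)
        flat = [[0.5, 0.5]] * 3
        assert delta_differential(flat, ["a", "b", "c"], "a") == pytest.approx(0.0)

    def test_triallelic_maximises_over_alleles(self):
        p = [[0.7, 0.2, 0.1], [0.1, 0.5, 0.4], [0.1, 0.5, 0.4]]
        # brute force: diffs are (0.6, -0.3, -0.3) -> allele 1
        assert delta_differential(p, ["a", "b", "c"], "a") == pytest.approx(0.6)

    def test_explicit_comparator_subset(self):
        p = [[0.9, 0.1], [0.3, 0.7], [0.1, 0.9]]
        # SAS-style: target vs one chosen comparator only
        assert delta_differential(p, ["sas", "eur", "eas"], "sas", ["eur"]) == pytest.approx(0.6)
        with pytest.raises(ValueError, match="empty"):
            delta_differential(p, ["sas", "eur", "eas"], "sas", [])


class TestCumulativePSD:
    def _table(self, n_per_group=2):
        cfg = SyntheticConfig(
            seed=3,
            n_loci={g: n_per_group for g in ("AFR", "EUR", "EAS", "SAS", "OCE", "AMR")},
            n_triallelic=0,
        )
        return simulate_frequencies(cfg)

    def test_empty_subset_gives_zero_totals(self):
        ft = self._table()
        assert cumulative_psd(ft, {}) == {}

    def test_totals_match_per_snp_summation(self):
        ft = self._table(3)
        assign = {s.snp_id: s.target_group for s in ft.loci}
        totals = cumulative_psd(ft, assign)
        for g in set(assign.values()):
            manual = sum(
                population_specific_divergence(ft.freqs[j], ft.populations, g)
                for j, s in enumerate(ft.loci)
                if s.target_group == g
            )
            assert totals[g] == pytest.approx(manual)

    def test_additive_over_disjoint_subsets(self):
        ft = self._table(3)
        assign = {s.snp_id: s.target_group for s in ft.loci}
        ids = list(assign)
        a = {k: assign[k] for k in ids[::2]}
        b = {k: assign[k] for k in ids[1::2]}
        whole = cumulative_psd(ft, assign, assigned_only=False)
        part_a = cumulative_psd(ft, a, assigned_only=False)
        part_b = cumulative_psd(ft, b, assigned_only=False)
        for g in whole:
            assert whole[g] == pytest.approx(part_a.get(g, 0) + part_b.get(g, 0))

    def test_exclusion_drops_contributions(self):
        ft = self._table()
        assign = {s.snp_id: s.target_group for s in ft.loci}
        dropped = [s.snp_id for s in ft.loci if s.target_group == "AFR"]
        totals = cumulative_psd(ft, assign, exclude=dropped)
        assert totals["AFR"] == 0.0


class TestBalancePanel:
    def _candidates(self, rng, n=200, groups=("A", "B", "C", "D")):
        rows = []
        for i in range(n):
            g = groups[i % len(groups)]
            row = {"snp_id": f"rs{i:04d}", "target_group": g}
            for gg in groups:
                row[f"psd_{gg}"] = float(rng.uniform(0.05, 0.6))
            rows.append(row)
        return pd.DataFrame(rows).set_index("snp_id")

    def test_already_balanced_input_unchanged(self):
        rows = []
        for g in ("A", "B"):
            for i in range(3):
                rows.append({"snp_id": f"{g}{i}", "target_group": g, "psd_A": 0.5, "psd_B": 0.5})
        cand = pd.DataFrame(rows).set_index("snp_id")
        rep = balance_panel(cand, {"A": 3, "B": 3})
        assert rep.iterations == []
        assert rep.cumulative_before == rep.cumulative_after

    def test_infeasible_budget_names_short_group(self, rng):
        cand = self._candidates(rng, n=40)
        cand = cand[cand["target_group"] != "D"]
        with pytest.raises(ValueError, match="group D"):
            balance_panel(cand, {"A": 5, "B": 5, "C": 5, "D": 5})

    def test_beats_randomised_search(self, rng):
        cand = self._candidates(rng)
        budget = {g: 15 for g in ("A", "B", "C", "D")}
        rep = balance_panel(cand, budget)
        for g, sel in rep.selected.items():
            assert len(sel) == budget[g]
        best_random = np.inf
        for _ in range(1000):
            totals = []
            for g in budget:
                pool = cand[cand["target_group"] == g]
                pick = rng.choice(pool.index, size=budget[g], replace=False)
                totals.append(pool.loc[pick, f"psd_{g}"].sum())
            best_random = min(best_random, max(totals) - min(totals))
        assert rep.spread <= best_random

    def test_protected_snps_never_removed(self, rng):
        cand = self._candidates(rng)
        budget = {g: 15 for g in ("A", "B", "C", "D")}
        protected = [cand[cand["target_group"] == g].index[0] for g in budget]
        rep = balance_panel(cand, budget, protected=protected, initial={g: [p] for g, p in zip(budget, protected)})
        for g, p in zip(budget, protected):
            assert p in rep.selected[g]
        assert all(log["removed"] not in protected for log in rep.iterations)

    def test_cumulative_equals_member_sum(self, rng):
        cand = self._candidates(rng, n=80)
        rep = balance_panel(cand, {g: 10 for g in ("A", "B", "C", "D")})
        for g, sel in rep.selected.items():
            assert rep.cumulative_after[g] == pytest.approx(
                cand.loc[sel, f"psd_{g}"].sum()
            )


def test_divergence_profile_columns_consistent():
    cfg = SyntheticConfig(
        seed=9, n_loci={g: 1 for g in ("AFR", "EUR", "EAS", "SAS", "OCE", "AMR")}, n_triallelic=2
    )
    ft = simulate_frequencies(cfg)
    prof = divergence_profile(ft)
    assert len(prof) == 8
    for g in ft.populations:
        assert (prof[f"psd_{g}"] >= 0).all()
    assert (prof["In_global"] <= math.log(len(ft.populations)) + 1e-9).all()
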