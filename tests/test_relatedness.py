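import itertools

import numpy as np
import pandas as pd
import pytest

import sibriver as sr
from sibriver.containers import MISSING

from conftest import make_table


def ped_frame(rows):
    return sr.Pedigree(
        pd.DataFrame(rows, columns=["individual", "sire", "dam", "pop"])
    )


class TestComputeGrm:
    def test_two_individual_fixed_difference_example(self):
        g = make_table([[2, 2], [0, 0]])
        G = sr.compute_grm(g)
        np.testing.assert_allclose(G.values, [[2, -2], [-2, 2]])

    def test_all_heterozygotes_give_zero_matrix(self):
        g = make_table([[1, 1, 1]] * 4)
        G = sr.compute_grm(g)
        np.testing.assert_allclose(G.values, 0.0, atol=1e-12)

    def test_imputed_entry_contributes_zero_when_m_mean_zero(self):
        # locus 0: one 2 and one 0 among observed -> mean M = 0 -> imputed Z = 0
        g = make_table([[2, 1], [0, 1], [MISSING, 1]])
        G = sr.compute_grm(g)
        g_obs = make_table([[2, 1], [0, 1], [1, 1]])  # same after imputation
        np.testing.assert_allclose(G.values, sr.compute_grm(g_obs).values, atol=1e-12)

    def test_row_sums_zero_with_observed_freqs_complete_data(self):
        rng = np.random.default_rng(0)
        g = make_table(rng.integers(0, 3, size=(15, 40)).astype(np.int8))
        G = sr.compute_grm(g)
        np.testing.assert_allclose(G.values.sum(axis=0), 0.0, atol=1e-9)

    def test_invariant_to_global_allele_flip(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(10, 30)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.05] = MISSING
        g = make_table(calls)
        flipped = calls.copy()
        m = flipped != MISSING
        flipped[m] = 2 - flipped[m]
        gf = make_table(flipped)
        np.testing.assert_allclose(
            sr.compute_grm(g).values, sr.compute_grm(gf).values, atol=1e-10
        )

    def test_all_monomorphic_rejected(self):
        g = make_table([[2, 2], [2, 2]])
        with pytest.raises(ValueError, match="monomorphic"):
            sr.compute_grm(g)

    def test_supplied_frequencies_used_for_centering(self):
        g = make_table([[2, 2], [0, 0]])
        G = sr.compute_grm(g, freq_source="supplied", freqs=np.array([0.5, 0.5]))
        np.testing.assert_allclose(G.values, [[2, -2], [-2, 2]])

    def test_correlates_with_pedigree_relationship_on_simulation(self):
        cfg = sr.SimConfig(
            n_pops=1, n_sires=8, n_dams=8, n_offspring_sampled=50,
            contribution_alpha=0.3, n_loci=1200, frac_dup_fragment=0.0,
            frac_ld_pairs=0.0, err_rate=0.01, miss_rate=0.01, seed=31,
        )
        table, truth = sr.simulate_population(cfg)
        G = sr.compute_grm(table)
        rows = [(p, "0", "0", "pop1") for p in truth.parents.ids] + [
            (r.offspring, r.sire, r.dam, r.pop)
            for r in truth.pedigree.itertuples(index=False)
        ]
        A = sr.make_A(ped_frame(rows)).subset(table.ids)
        tri = np.triu_indices(len(table.ids), k=1)
        r = np.corrcoef(G.values[tri], A.values[tri])[0, 1]
        assert r > 0.8


class TestMakeA:
    def test_full_sibs_half_sibs_and_founders(self):
        ped = ped_frame(
            [
                ("s1", "0", "0", "p"),
                ("s2", "0", "0", "p"),
                ("d1", "0", "0", "p"),
                ("d2", "0", "0", "p"),
                ("fs_a", "s1", "d1", "p"),
                ("fs_b", "s1", "d1", "p"),
                ("hs_c", "s1", "d2", "p"),
                ("u_d", "s2", "d2", "p"),
            ]
        )
        A = sr.make_A(ped)
        assert A.loc("fs_a", "fs_b") == pytest.approx(0.5)
        assert A.loc("fs_a", "hs_c") == pytest.approx(0.25)
        assert A.loc("fs_a", "u_d") == pytest.approx(0.0)
        assert A.loc("s1", "s1") == pytest.approx(1.0)
        assert A.loc("fs_a", "fs_a") == pytest.approx(1.0)  # parents unrelated

    def test_inbred_diagonal(self):
        # offspring of full sibs: a_sd = 0.5 -> diagonal 1.25
        ped = ped_frame(
            [
                ("s", "0", "0", "p"),
                ("d", "0", "0", "p"),
                ("a", "s", "d", "p"),
                ("b", "s", "d", "p"),
                ("x", "a", "b", "p"),
            ]
        )
        A = sr.make_A(ped)
        assert A.loc("x", "x") == pytest.approx(1.25)

    def test_cycle_detected_and_listed(self):
        ped = sr.Pedigree(
            pd.DataFrame(
                {
                    "individual": ["a", "b"],
                    "sire": ["b", "a"],
                    "dam": ["0", "0"],
                    "pop": ["p", "p"],
                }
            )
        )
        with pytest.raises(ValueError, match="cycle"):
            sr.make_A(ped)

    def test_agrees_with_gene_dropping_monte_carlo(self):
        # random two-generation pedigree of 20 individuals
        rng = np.random.default_rng(5)
        founders = [f"F{i}" for i in range(8)]
        rows = [(f, "0", "0", "p") for f in founders]
        offspring = []
        for k in range(12):
            s, d = rng.choice(8, size=2, replace=False)
            rows.append((f"O{k}", founders[s], founders[d], "p"))
            offspring.append((k, s, d))
        A = sr.make_A(ped_frame(rows))

        # gene dropping: unique founder alleles propagated through the pedigree
        reps = 40000
        fa = np.arange(16).reshape(8, 2)[None, :, :].repeat(reps, axis=0)
        off = np.zeros((reps, 12, 2), dtype=int)
        pick = rng.integers(0, 2, size=(reps, 12, 2))
        for k, s, d in offspring:
            off[:, k, 0] = fa[np.arange(reps), s, pick[:, k, 0]]
            off[:, k, 1] = fa[np.arange(reps), d, pick[:, k, 1]]
        ids = [f"O{k}" for k in range(12)]
        for a, b in itertools.combinations(range(12), 2):
            # kinship = P(random allele from a IBD random allele from b)
            match = (
                (off[:, a, :, None] == off[:, b, None, :]).mean(axis=(1, 2))
            )
            est = 2 * match.mean()
            se = 2 * match.std(ddof=1) / np.sqrt(reps)
            assert abs(est - A.loc(ids[a], ids[b])) <= max(3 * se, 1e-3)


class TestCategorize:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.10, "low"),
            (0.25, "mid"),
            (0.50, "high"),
            (0.156, "mid"),
            (0.370, "mid"),
            (0.0, "low"),
        ],
    )
    def test_threshold_bands(self, value, expected):
        m = sr.RelMatrix(["a", "b"], np.array([[1.0, value], [value, 1.0]]), "genomic")
        cats = sr.categorize_relationships(m)
        assert cats[0, 1] == expected


class TestFlagCrossPop:
    def test_planted_cross_river_sib_pair_flagged(self):
        # a full-sib pair split across population labels, like a mislabeled
        # transfer: the genomic relationship stays ~0.5 across the label split
        cfg = sr.SimConfig(
            n_pops=1, n_sires=6, n_dams=6, n_offspring_sampled=40,
            contribution_alpha=5.0, n_loci=800, frac_dup_fragment=0.0,
            frac_ld_pairs=0.0, err_rate=0.0, miss_rate=0.0, seed=8,
        )
        table, truth = sr.simulate_population(cfg)
        fs = truth.pedigree.groupby(["sire", "dam"]).filter(lambda x: len(x) >= 2)
        pair = fs.groupby(["sire", "dam"])["offspring"].apply(list).iloc[0][:2]
        labels = {i: ("riverB" if i == pair[1] else "riverA") for i in table.ids}
        G = sr.compute_grm(table)
        flags, implicated = sr.flag_cross_pop_pairs(G, labels, g_min=0.35)
        flagged_pairs = {tuple(sorted((r.id1, r.id2))) for r in flags.itertuples()}
        assert tuple(sorted(pair)) in flagged_pairs
        assert set(pair) <= set(implicated)

    def test_no_strong_cross_pairs_empty(self):
        m = sr.RelMatrix(["a", "b"], np.array([[1.0, 0.1], [0.1, 1.0]]), "genomic")
        flags, implicated = sr.flag_cross_pop_pairs(m, {"a": "x", "b": "y"})
        assert flags.empty and implicated == []

    def test_same_pop_strong_pair_never_flagged(self):
        m = sr.RelMatrix(["a", "b"], np.array([[1.0, 0.9], [0.9, 1.0]]), "genomic")
        flags, _ = sr.flag_cross_pop_pairs(m, {"a": "x", "b": "x"})
        assert flags.empty


def greedy_oracle(ids, A):
    """Independent plain-python re-implementation of the selection recipe."""
    ids = list(ids)
    rel = {
        (a, b): A[i, j]
        for i, a in enumerate(ids)
        for j, b in enumerate(ids)
        if a != b
    }
    selected = [a for a in ids if all(rel[(a, b)] == 0 for b in ids if b != a)]
    remaining = [a for a in ids if a not in selected]
    while remaining:
        means = {}
        for a in remaining:
            others = [b for b in remaining if b != a]
            means[a] = sum(rel[(a, b)] for b in others) / len(others) if others else 0.0
        pick = min(remaining, key=lambda a: (means[a], a))
        selected.append(pick)
        remaining = [b for b in remaining if b != pick and rel[(pick, b)] <= 0]
    return selected


def random_relationship_matrix(rng, n):
    """Sparse symmetric non-negative matrix with unit diagonal."""
    vals = rng.choice([0.0, 0.0, 0.125, 0.25, 0.5], size=(n, n))
    A = np.triu(vals, k=1)
    A = A + A.T + np.eye(n)
    return A


class TestSelectUnrelated:
    def test_hand_traced_five_individual_example(self):
        ids = ["A", "B", "C", "D", "E"]
        A = np.eye(5)
        A[0, 1] = A[1, 0] = 0.5  # A-B full sibs
        A[0, 2] = A[2, 0] = 0.25  # C half-sib to A only
        res = sr.select_unrelated(sr.RelMatrix(ids, A, "pedigree"))
        assert res.selected == ["D", "E", "C", "B"]

    def test_identity_selects_everyone_at_step_ii(self):
        res = sr.select_unrelated(sr.RelMatrix(list("abcd"), np.eye(4), "pedigree"))
        assert res.selected == list("abcd")
        assert res.trace[0]["step"] == "ii"

    def test_two_full_sibs_keep_exactly_one(self):
        A = np.array([[1.0, 0.5], [0.5, 1.0]])
        res = sr.select_unrelated(sr.RelMatrix(["b", "a"], A, "pedigree"))
        assert len(res.selected) == 1
        assert res.selected == ["a"]  # tie on mean broken by lexicographic ID

    def test_empty_matrix(self):
        res = sr.select_unrelated(sr.RelMatrix([], np.zeros((0, 0)), "pedigree"))
        assert res.selected == []

    def test_pairwise_zero_invariant_and_oracle_equivalence(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n = int(rng.integers(2, 13))
            A = random_relationship_matrix(rng, n)
            ids = [f"x{i}" for i in range(n)]
            res = sr.select_unrelated(sr.RelMatrix(ids, A, "pedigree"))
            pos = {x: i for i, x in enumerate(ids)}
            for a, b in itertools.combinations(res.selected, 2):
                assert A[pos[a], pos[b]] == 0.0
            assert res.selected == greedy_oracle(ids, A)

    def test_size_bounded_by_maximum_independent_set(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            n = int(rng.integers(2, 12))
            A = random_relationship_matrix(rng, n)
            ids = [f"x{i}" for i in range(n)]
            res = sr.select_unrelated(sr.RelMatrix(ids, A, "pedigree"))
            best = 0
            for mask in range(1, 1 << n):
                members = [i for i in range(n) if mask >> i & 1]
                if all(
                    A[a, b] == 0 for a, b in itertools.combinations(members, 2)
                ):
                    best = max(best, len(members))
            assert 1 <= len(res.selected) <= best


class TestNeClosedForm:
    def test_printed_mean_relationship_example(self):
        est = sr.ne_from_mean_relationship(0.0078)
        assert est.delta_f == pytest.approx(0.0039)
        assert est.ne_rounded == 128

    def test_zero_mean_relationship_unbounded(self):
        est = sr.ne_from_mean_relationship(0.0)
        assert est.delta_f == 0.0 and np.isinf(est.ne) and est.ne_rounded is None

    def test_closed_form_half(self):
        est = sr.ne_from_mean_relationship(0.5)
        assert est.delta_f == 0.25 and est.ne == pytest.approx(2.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sr.ne_from_mean_relationship(-0.1)


class TestMeanRelationship:
    def test_modes(self):
        m3 = sr.RelMatrix(list("abc"), np.eye(3), "pedigree")
        assert sr.mean_relationship(m3, "full") == pytest.approx(1 / 3)
        assert sr.mean_relationship(m3, "offdiag") == 0.0
        m2 = sr.RelMatrix(list("ab"), np.array([[1, 0.5], [0.5, 1]]), "pedigree")
        assert sr.mean_relationship(m2, "offdiag") == pytest.approx(0.5)
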