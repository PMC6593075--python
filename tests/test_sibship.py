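import itertools
import math

import numpy as np
import pandas as pd
import pytest

import sibriver as sr
from sibriver.containers import MISSING
from sibriver.sibship import (
    _PAIR_COLUMNS,
    _joint_tables,
    build_families,
    king_robust,
)

from conftest import make_table


class TestSubsetForSibship:
    def test_boundary_maf_02_removed_strictly(self):
        # L0: MAF exactly 0.2 (2 alt-hom in 10, p_ref = 0.8) -> removed
        g = make_table(np.array([[0] * 2 + [2] * 8, [2] * 5 + [0] * 5]).T)
        panel = sr.subset_for_sibship(g)
        assert panel.locus_ids == ["L1"]

    def test_maf_half_retained(self):
        g = make_table(np.array([[2] * 5 + [0] * 5]).T)
        assert sr.subset_for_sibship(g).locus_ids == ["L0"]

    def test_reduces_simulated_maf_spectrum(self):
        cfg = sr.SimConfig(
            n_pops=1, n_sires=30, n_dams=30, n_offspring_sampled=60,
            contribution_alpha=5.0, n_loci=800, maf_floor=0.02,
            frac_dup_fragment=0.0, frac_ld_pairs=0.0, seed=41,
        )
        table, _ = sr.simulate_population(cfg)
        panel = sr.subset_for_sibship(table)
        assert 0 < panel.n_loci < table.n_loci


class TestPairLoglik:
    def test_single_locus_homozygous_pair_worked_example(self):
        pl = sr.pair_loglik(np.array([2]), np.array([2]), np.array([0.5]), err=0.0)
        assert math.exp(pl.loglik["U"]) == pytest.approx(0.0625)
        assert math.exp(pl.loglik["FS"]) == pytest.approx(0.140625)
        assert math.exp(pl.llr_vs_u) == pytest.approx(2.25)
        assert pl.best == "FS"

    @pytest.mark.parametrize("p", [0.1, 0.25, 0.5, 0.73, 0.9])
    @pytest.mark.parametrize("err", [0.0, 0.05, 0.3])
    def test_per_locus_distributions_sum_to_one(self, p, err):
        tables = _joint_tables(np.array([p]), err)
        for cls, tab in tables.items():
            assert tab[0].sum() == pytest.approx(1.0)
            assert (tab[0] >= 0).all()

    def test_identical_twins_llr_grows_with_locus_count(self):
        rng = np.random.default_rng(3)
        p = np.full(400, 0.5)
        g = rng.binomial(2, 0.5, 400).astype(np.int8)
        short = sr.pair_loglik(g[:100], g[:100], p[:100], err=0.01)
        long = sr.pair_loglik(g, g, p, err=0.01)
        assert 0 < short.llr_vs_u < long.llr_vs_u

    def test_total_error_collapses_all_classes(self):
        rng = np.random.default_rng(4)
        p = np.full(200, 0.4)
        g1 = rng.binomial(2, 0.4, 200).astype(np.int8)
        g2 = rng.binomial(2, 0.4, 200).astype(np.int8)
        pl = sr.pair_loglik(g1, g2, p, err=1.0)
        assert pl.loglik["FS"] == pytest.approx(pl.loglik["U"])
        assert pl.loglik["HS"] == pytest.approx(pl.loglik["U"])
        assert pl.llr_vs_u == pytest.approx(0.0)

    def test_frequency_outside_open_interval_rejected(self):
        with pytest.raises(ValueError, match="frequency"):
            sr.pair_loglik(np.array([1]), np.array([1]), np.array([1.0]))

    def test_missing_loci_skipped(self):
        pl = sr.pair_loglik(
            np.array([2, MISSING]), np.array([2, 1]), np.array([0.5, 0.5])
        )
        assert pl.n_loci == 1


class TestKingRobust:
    def test_scale_on_known_classes(self):
        cfg = sr.SimConfig(
            n_pops=1, n_sires=4, n_dams=4, n_offspring_sampled=40,
            contribution_alpha=0.5, n_loci=1200, maf_floor=0.25,
            frac_dup_fragment=0.0, frac_ld_pairs=0.0,
            err_rate=0.0, miss_rate=0.0, seed=6,
        )
        table, truth = sr.simulate_population(cfg)
        ped = truth.pedigree.set_index("offspring")
        phi2 = king_robust(table.calls)
        by_class = {"FS": [], "HS": [], "U": []}
        for i, j in itertools.combinations(range(table.n_individuals), 2):
            a, b = table.ids[i], table.ids[j]
            shared = int(ped.loc[a, "sire"] == ped.loc[b, "sire"]) + int(
                ped.loc[a, "dam"] == ped.loc[b, "dam"]
            )
            by_class[{2: "FS", 1: "HS", 0: "U"}[shared]].append(phi2[i, j])
        assert np.mean(by_class["FS"]) == pytest.approx(0.5, abs=0.06)
        assert np.mean(by_class["HS"]) == pytest.approx(0.25, abs=0.06)
        assert abs(np.mean(by_class["U"])) < 0.06


class TestClassifyPairs:
    def test_true_full_sib_pair_classified_and_strangers_unrelated(self):
        cfg = sr.SimConfig(
            n_pops=1, n_sires=5, n_dams=5, n_offspring_sampled=30,
            contribution_alpha=0.5, n_loci=900, maf_floor=0.2,
            frac_dup_fragment=0.0, frac_ld_pairs=0.0,
            err_rate=0.0, miss_rate=0.0, seed=12,
        )
        table, truth = sr.simulate_population(cfg)
        panel = sr.subset_for_sibship(table)
        pairs = sr.classify_pairs(panel, err=0.001, lr_min=3.0)
        ped = truth.pedigree.set_index("offspring")
        got = {tuple(sorted((r.id1, r.id2))): r.best for r in pairs.itertuples()}
        n_fs_ok = n_fs = n_u_ok = n_u = 0
        for (a, b), best in got.items():
            shared = int(ped.loc[a, "sire"] == ped.loc[b, "sire"]) + int(
                ped.loc[a, "dam"] == ped.loc[b, "dam"]
            )
            if shared == 2:
                n_fs += 1
                n_fs_ok += best == "FS"
            elif shared == 0:
                n_u += 1
                n_u_ok += best == "U"
        assert n_fs > 0 and n_fs_ok / n_fs >= 0.95
        assert n_u > 0 and n_u_ok / n_u >= 0.95

    def test_no_overlapping_loci_forces_unrelated_with_zero_llr(self):
        calls = np.array([[2, MISSING], [MISSING, 1]], dtype=np.int8)
        g = make_table(calls)
        pairs = sr.classify_pairs(g, freqs=np.array([0.5, 0.5]))
        assert pairs.loc[0, "best"] == "U"
        assert pairs.loc[0, "llr"] == 0.0
        assert pairs.loc[0, "n_loci"] == 0

    def test_single_individual_rejected(self):
        with pytest.raises(ValueError):
            sr.classify_pairs(make_table([[1, 2]]))


def pair_table(ids, assignments):
    """Synthetic pair-classification table from {pair: (best, llr)} records."""
    rows = []
    for a, b in itertools.combinations(ids, 2):
        best, llr = assignments.get((a, b), assignments.get((b, a), ("U", 0.0)))
        ll_u = 0.0
        ll_fs = llr if best == "FS" else -50.0
        ll_hs = llr if best == "HS" else (llr / 2 if best == "FS" else -50.0)
        rows.append((a, b, ll_fs, ll_hs, ll_u, best, llr, 100))
    return pd.DataFrame(rows, columns=_PAIR_COLUMNS)


class TestBuildFamilies:
    def test_three_trios_no_half_sib_links(self):
        ids = [f"o{k}" for k in range(9)]
        fam_assign = {}
        for fam in range(3):
            trio = ids[3 * fam : 3 * fam + 3]
            for a, b in itertools.combinations(trio, 2):
                fam_assign[(a, b)] = ("FS", 80.0)
        res = build_families(pair_table(ids, fam_assign), ids, pop="p")
        assert res.assignments["family"].nunique() == 3
        assert res.dummy_parent_counts["p"] == 6

    def test_two_families_sharing_one_parent(self):
        ids = ["a1", "a2", "b1", "b2"]
        assign = {
            ("a1", "a2"): ("FS", 90.0),
            ("b1", "b2"): ("FS", 90.0),
        }
        for x in ("a1", "a2"):
            for y in ("b1", "b2"):
                assign[(x, y)] = ("HS", 20.0)
        res = build_families(pair_table(ids, assign), ids, pop="p")
        assert res.assignments["family"].nunique() == 2
        assert res.dummy_parent_counts["p"] == 3
        parents = res.assignments.set_index("individual")
        shared = set(parents.loc["a1", ["dummy_sire", "dummy_dam"]]) & set(
            parents.loc["b1", ["dummy_sire", "dummy_dam"]]
        )
        assert len(shared) == 1

    def test_all_unrelated_get_private_parents(self):
        ids = [f"x{k}" for k in range(5)]
        res = build_families(pair_table(ids, {}), ids, pop="p")
        assert res.assignments["family"].nunique() == 5
        assert res.dummy_parent_counts["p"] == 10
        assert res.shared_parent_pairs.empty

    def test_audit_splits_component_with_strong_unrelated_pair(self):
        # chain a-b-c where a-c carries strong unrelated evidence: the weak
        # b-c edge must be cut, leaving family {a, b} and singleton {c}
        ids = ["a", "b", "c"]
        rows = [
            ("a", "b", 60.0, 30.0, 0.0, "FS", 60.0, 100),
            ("b", "c", 8.0, 4.0, 0.0, "FS", 8.0, 100),
            ("a", "c", -50.0, -25.0, 0.0, "U", 0.0, 100),
        ]
        res = build_families(pd.DataFrame(rows, columns=_PAIR_COLUMNS), ids, pop="p")
        fam = res.assignments.set_index("individual")["family"]
        assert fam["a"] == fam["b"] != fam["c"]

    def test_lone_misclassified_pair_between_large_families_ignored(self):
        # aggregate cross-family evidence stays negative despite one false link
        ids = [f"a{k}" for k in range(4)] + [f"b{k}" for k in range(4)]
        assign = {}
        for grp in ("a", "b"):
            for x, y in itertools.combinations([f"{grp}{k}" for k in range(4)], 2):
                assign[(x, y)] = ("FS", 90.0)
        assign[("a0", "b0")] = ("HS", 6.0)  # lone false positive
        res = build_families(pair_table(ids, assign), ids, pop="p")
        assert res.dummy_parent_counts["p"] == 4  # no parent shared


class TestSibshipToPedigree:
    def test_chained_a_matrix_values(self):
        ids = ["f1", "f2", "h1"]
        assign = {
            ("f1", "f2"): ("FS", 90.0),
            ("f1", "h1"): ("HS", 30.0),
            ("f2", "h1"): ("HS", 30.0),
        }
        res = build_families(pair_table(ids, assign), ids, pop="p")
        ped = sr.sibship_to_pedigree(res)
        A = sr.make_A(ped)
        assert A.loc("f1", "f2") == pytest.approx(0.5)
        assert A.loc("f1", "h1") == pytest.approx(0.25)

    def test_empty_result_gives_empty_pedigree(self):
        res = sr.SibshipResult(
            assignments=pd.DataFrame(
                columns=["individual", "pop", "family", "dummy_sire", "dummy_dam"]
            )
        )
        assert len(sr.sibship_to_pedigree(res)) == 0

    def test_dummy_parents_enter_as_unknown_parent_founders(self):
        ids = ["x", "y"]
        res = build_families(pair_table(ids, {("x", "y"): ("FS", 90.0)}), ids, pop="p")
        ped = sr.sibship_to_pedigree(res)
        dummies = ped.records[ped.records["sire"] == "0"]
        assert len(dummies) == 2


class TestReconstructInvariants:
    def test_share_both_iff_same_family_share_one_iff_half_sibs(self):
        cfg = sr.SimConfig(
            n_pops=2, n_sires=6, n_dams=6, n_offspring_sampled=35,
            contribution_alpha=0.3, n_loci=1200, frac_dup_fragment=0.0,
            frac_ld_pairs=0.0, err_rate=0.01, miss_rate=0.01, seed=19,
        )
        table, _ = sr.simulate_population(cfg)
        res = sr.reconstruct_sibship(table)
        a = res.assignments.set_index("individual")
        # dummy parent IDs are population-scoped and unique
        for pop, grp in res.assignments.groupby("pop"):
            others = res.assignments[res.assignments["pop"] != pop]
            own = set(grp["dummy_sire"]) | set(grp["dummy_dam"])
            assert not own & (set(others["dummy_sire"]) | set(others["dummy_dam"]))
        for x, y in itertools.combinations(a.index, 2):
            shared = len(
                {a.loc[x, "dummy_sire"], a.loc[x, "dummy_dam"]}
                & {a.loc[y, "dummy_sire"], a.loc[y, "dummy_dam"]}
            )
            same_family = a.loc[x, "family"] == a.loc[y, "family"]
            assert (shared == 2) == same_family
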