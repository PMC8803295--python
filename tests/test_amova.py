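"""Hierarchical AMOVA and pairwise Weir-Cockerham theta."""

import numpy as np
import pytest

import hybkit as hk


def make_table(rows, pops, ecos=None, loci=None):
    calls = np.asarray(rows)
    n, L = calls.shape[0], calls.shape[1]
    loci = loci or [f"l{j}" for j in range(L)]
    ecos = ecos or ["unknown"] * n
    return hk.GenotypeTable(
        [f"i{k}" for k in range(n)], loci, calls,
        np.asarray(pops, dtype=object), np.asarray(ecos, dtype=object))


def brute_force_components(gt, groupmap):
    """Independent oracle: nested indicator-variable ANOVA with plain loops.

    Gene copies are the units; per locus and allele the sums of squares at
    the three levels are accumulated term by term, the unbalanced
    expected-mean-square coefficients solved, and per-locus components
    combined with typed-gene-copy weights.
    """
    comps = np.zeros(3)
    wsum = 0.0
    pops = list(dict.fromkeys(gt.populations))
    for j in range(gt.n_loci):
        copies, pop_of, grp_of = [], [], []
        for i in range(gt.n_individuals):
            if gt.calls[i, j, 0] == -1:
                continue
            for c in range(2):
                copies.append(gt.calls[i, j, c])
                pop_of.append(str(gt.populations[i]))
                grp_of.append(groupmap[str(gt.populations[i])])
        if not copies:
            continue
        used_pops = list(dict.fromkeys(pop_of))
        used_grps = list(dict.fromkeys(grp_of))
        N, p, g = len(copies), len(used_pops), len(used_grps)
        if N <= p:
            continue
        n_i = {q: pop_of.count(q) for q in used_pops}
        N_g = {h: grp_of.count(h) for h in used_grps}
        grp_of_pop = {q: groupmap[q] for q in used_pops}
        ss_a = ss_b = ss_c = 0.0
        for a in sorted(set(copies)):
            x = [1.0 if c == a else 0.0 for c in copies]
            T = sum(x)
            T_pop = {q: sum(v for v, q2 in zip(x, pop_of) if q2 == q)
                     for q in used_pops}
            T_grp = {h: sum(v for v, h2 in zip(x, grp_of) if h2 == h)
                     for h in used_grps}
            ss_c += T - sum(T_pop[q] ** 2 / n_i[q] for q in used_pops)
            ss_b += (sum(T_pop[q] ** 2 / n_i[q] for q in used_pops)
                     - sum(T_grp[h] ** 2 / N_g[h] for h in used_grps))
            ss_a += (sum(T_grp[h] ** 2 / N_g[h] for h in used_grps)
                     - T ** 2 / N)
        sig_c = ss_c / (N - p)
        sum_sq = sum(n_i[q] ** 2 / N_g[grp_of_pop[q]] for q in used_pops)
        if p - g > 0:
            n1 = (N - sum_sq) / (p - g)
            sig_b = (ss_b / (p - g) - sig_c) / n1
        else:
            sig_b = 0.0
        if g - 1 > 0:
            n2 = (sum_sq - sum(n_i[q] ** 2 for q in used_pops) / N) / (g - 1)
            n3 = (N - sum(N_g[h] ** 2 for h in used_grps) / N) / (g - 1)
            sig_a = (ss_a / (g - 1) - sig_c - n2 * sig_b) / n3
        else:
            sig_a = 0.0
        comps += N * np.array([sig_a, sig_b, sig_c])
        wsum += N
    return comps / wsum


class TestHierarchicalAmova:
    def test_complete_fixation(self):
        gt = make_table([[[1, 1]]] * 4 + [[[2, 2]]] * 4,
                        ["p1"] * 4 + ["p2"] * 4)
        res = hk.hierarchical_amova(gt, groupmap={"p1": "A", "p2": "B"},
                                    n_perm=10, seed=0)
        assert res.f_st == pytest.approx(1.0)
        assert res.f_ct == pytest.approx(1.0)

    def test_identical_populations_no_positive_differentiation(self):
        # exact copies: among-level sums of squares are exactly zero, so
        # the method-of-moments components cannot be positive (they are
        # slightly negative, not zero, since the within-population mean
        # square is subtracted)
        block = [[[1, 2]], [[1, 1]], [[2, 2]], [[1, 2]]]
        gt = make_table(block * 4, sum([[f"p{k}"] * 4 for k in range(4)], []))
        res = hk.hierarchical_amova(
            gt, groupmap={"p0": "A", "p1": "A", "p2": "B", "p3": "B"},
            n_perm=10, seed=0)
        assert res.sigma_a <= 1e-12
        assert res.sigma_b <= 1e-12
        assert res.f_st <= 1e-12
        assert res.sigma_c > 0

    def test_matches_brute_force_oracle(self, fmodel_pools, six_classes):
        rng = np.random.default_rng(17)
        parts = []
        for k, cls in enumerate(["P1", "P1", "P2"]):
            g = hk.simulate_class(*fmodel_pools, six_classes[cls], 7, rng,
                                  class_name=cls, id_prefix=f"x{k}")
            g.populations[:] = f"p{k}"
            parts.append(g)
        gt = hk.GenotypeTable.concatenate(parts)
        gt = hk.apply_missingness(gt, 0.1, rng)
        groupmap = {"p0": "G1", "p1": "G1", "p2": "G2"}
        res = hk.hierarchical_amova(gt, groupmap=groupmap, n_perm=10, seed=0)
        oracle = brute_force_components(gt, groupmap)
        assert res.sigma_a == pytest.approx(oracle[0], abs=1e-12)
        assert res.sigma_b == pytest.approx(oracle[1], abs=1e-12)
        assert res.sigma_c == pytest.approx(oracle[2], abs=1e-12)

    def test_monomorphic_dataset_rejected(self):
        gt = make_table([[[1, 1]]] * 6, ["p1"] * 3 + ["p2"] * 3)
        with pytest.raises(ValueError, match="positive|usable"):
            hk.hierarchical_amova(gt, groupmap={"p1": "A", "p2": "B"},
                                  n_perm=10)

    def test_single_population_group_noted(self, two_ecotype_table):
        pops = list(dict.fromkeys(two_ecotype_table.populations))
        groupmap = {p: ("solo" if p == pops[0] else "rest") for p in pops}
        res = hk.hierarchical_amova(two_ecotype_table, groupmap=groupmap,
                                    n_perm=10, seed=0)
        assert res.notes["single_population_groups"] == [pops[0]]

    def test_one_group_matches_flat_amova_fst(self, two_ecotype_table):
        # internal consistency: with a single group the hierarchical F_ST
        # collapses to the two-level among-population statistic
        gt = two_ecotype_table
        pops = list(dict.fromkeys(gt.populations))
        one = hk.hierarchical_amova(gt, groupmap={p: "all" for p in pops},
                                    n_perm=10, seed=0)
        per_pop = hk.hierarchical_amova(
            gt, groupmap={p: p for p in pops}, n_perm=10, seed=0)
        # each pop its own group: F_CT plays the among-population role
        assert one.f_st == pytest.approx(per_pop.f_ct, abs=1e-9)
        assert one.sigma_a == 0.0

    def test_divergence_monotonicity(self, six_classes):
        f_cts = []
        for div in (0.05, 0.15, 0.35):
            cfg = hk.SimConfig(divergence=div, seed=31)
            pA, pB = hk.make_parental_frequencies(cfg)
            rng = np.random.default_rng(31)
            parts = []
            for k in range(2):
                for cls, eco in (("P1", "savanna"), ("P2", "forest")):
                    g = hk.simulate_class(pA, pB, six_classes[cls], 12, rng,
                                          class_name=cls,
                                          id_prefix=f"{cls}{k}")
                    g.populations[:] = f"{cls}-pop{k}"
                    g.ecotypes[:] = eco
                    parts.append(g)
            gt = hk.GenotypeTable.concatenate(parts)
            res = hk.hierarchical_amova(gt, groupmap="ecotype", n_perm=10,
                                        seed=0)
            f_cts.append(res.f_ct)
        assert f_cts[0] < f_cts[1] < f_cts[2]


class TestPairwiseFst:
    def test_fixed_pair_theta_one(self):
        gt = make_table([[[1, 1]]] * 4 + [[[2, 2]]] * 4,
                        ["p1"] * 4 + ["p2"] * 4)
        theta, _ = hk.pairwise_fst(gt)
        assert theta.loc["p1", "p2"] == pytest.approx(1.0)

    def test_null_split_theta_near_zero(self, fmodel_pools, six_classes):
        rng = np.random.default_rng(23)
        thetas = []
        for rep in range(40):
            gt = hk.simulate_class(*fmodel_pools, six_classes["P1"], 30,
                                   rng, class_name="p")
            halves = np.array(["h1"] * 15 + ["h2"] * 15, dtype=object)
            thetas.append(hk.wc_theta(gt.calls[halves == "h1"],
                                      gt.calls[halves == "h2"]))
        assert abs(float(np.mean(thetas))) < 0.02

    def test_estimator_recovery_at_f035(self, six_classes):
        thetas = []
        for rep in range(60):
            cfg = hk.SimConfig(seed=9000 + rep)
            pA, pB = hk.make_parental_frequencies(cfg)
            rng = np.random.default_rng(rep)
            g1 = hk.simulate_class(pA, pB, six_classes["P1"], 30, rng)
            g2 = hk.simulate_class(pA, pB, six_classes["P2"], 30, rng)
            thetas.append(hk.wc_theta(g1.calls, g2.calls))
        assert float(np.mean(thetas)) == pytest.approx(0.35, abs=0.05)

    def test_permutation_p_significant_for_diverged_pair(
            self, two_ecotype_table):
        theta, pmat = hk.pairwise_fst(two_ecotype_table, n_perm=99, seed=0)
        assert pmat.loc["s-pop0", "f-pop0"] <= 0.05

    def test_negative_not_truncated_by_default(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(1, 3, size=(12, 3, 2))
        gt = make_table(calls, ["p1"] * 6 + ["p2"] * 6)
        theta, _ = hk.pairwise_fst(gt)
        trunc, _ = hk.pairwise_fst(gt, truncate_negative=True)
        assert trunc.loc["p1", "p2"] >= 0.0
        assert trunc.loc["p1", "p2"] == max(theta.loc["p1", "p2"], 0.0)
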