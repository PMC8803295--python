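"""Gibbs-sampler class posterior: oracles on diagnostic data, symmetry,
thresholding."""

import numpy as np
import pytest

import hybkit as hk
from hybkit.classify import ClassPosteriorMatrix
from hybkit.geno_io import MISSING


def diagnostic_dataset(n_loci=20, n_ref=10, extra=()):
    """Reference pures plus hand-built focal individuals.

    ``extra``: list of (id, genotype_code) with code 'het' (1/2 at every
    locus), 'homA' (1/1) or 'homB' (2/2).
    """
    pA, pB = hk.diagnostic_frequencies(n_loci)
    loci = pA.locus_names
    ids, rows, pops, ecos = [], [], [], []
    for k in range(n_ref):
        ids += [f"refA{k}", f"refB{k}"]
        rows += [[(1, 1)] * n_loci, [(2, 2)] * n_loci]
        pops += ["refA", "refB"]
        ecos += ["savanna", "forest"]
    code_map = {"het": (1, 2), "homA": (1, 1), "homB": (2, 2)}
    for ind, code in extra:
        ids.append(ind)
        rows.append([code_map[code]] * n_loci)
        pops.append("focal")
        ecos.append("unknown")
    calls = np.array(rows)
    gt = hk.GenotypeTable(ids, loci, calls,
                          np.array(pops, dtype=object),
                          np.array(ecos, dtype=object))
    refs = {f"refA{k}": "P1" for k in range(n_ref)}
    refs.update({f"refB{k}": "P2" for k in range(n_ref)})
    return gt, refs


def closed_form_posterior(code, n_loci, classes):
    """Likelihood-ratio oracle with known diagnostic frequencies.

    With theta fixed at the diagnostic pools, P(genotype | class) factorises
    as a product over loci of phi . (lik2, lik1, lik0), each locus-term
    identical; equal class priors give the posterior by normalisation.
    """
    lik = {"het": np.array([0.0, 1.0, 0.0]),
           "homA": np.array([1.0, 0.0, 0.0]),
           "homB": np.array([0.0, 0.0, 1.0])}[code]
    weights = np.array([float(prof.as_floats() @ lik) ** n_loci
                        for _, prof in classes])
    return weights / weights.sum()


class TestClassifyDiagnostic:
    @pytest.mark.parametrize("code,best", [("het", "F1"), ("homA", "P1"),
                                           ("homB", "P2")])
    def test_pure_and_f1_recovered(self, code, best):
        classes = hk.class_profiles("six")
        gt, refs = diagnostic_dataset(extra=[("focal", code)])
        cfg = hk.McmcConfig(iterations=6000, burn_in=1000, seed=9,
                            reference_individuals=refs)
        post = hk.classify(gt, classes, cfg)
        i = post.individual_ids.index("focal")
        k = post.class_names.index(best)
        oracle = closed_form_posterior(code, 20, classes)
        assert post.probs[i, k] > 0.99
        assert post.probs[i, k] == pytest.approx(oracle[k], abs=0.01)

    def test_label_swap_symmetry(self):
        # exchanging the A/B roles of the data swaps P1<->P2 and B1<->B2
        classes = hk.class_profiles("six")
        gt, refs = diagnostic_dataset(extra=[("focal", "homA")])
        swapped_calls = np.where(gt.calls == 1, 2,
                                 np.where(gt.calls == 2, 1, gt.calls))
        eco_swap = {"savanna": "forest", "forest": "savanna",
                    "unknown": "unknown"}
        gt_swap = hk.GenotypeTable(
            list(gt.individual_ids), list(gt.locus_names), swapped_calls,
            gt.populations.copy(),
            np.array([eco_swap[e] for e in gt.ecotypes], dtype=object))
        refs_swap = {i: {"P1": "P2", "P2": "P1"}[c] for i, c in refs.items()}
        cfg = hk.McmcConfig(iterations=4000, burn_in=1000, seed=4,
                            reference_individuals=refs)
        cfg2 = hk.McmcConfig(iterations=4000, burn_in=1000, seed=4,
                             reference_individuals=refs_swap)
        p1 = hk.classify(gt, classes, cfg)
        p2 = hk.classify(gt_swap, classes, cfg2)
        i = p1.individual_ids.index("focal")
        swap_pairs = [("P1", "P2"), ("P2", "P1"), ("B1", "B2"),
                      ("B2", "B1"), ("F1", "F1"), ("F2", "F2")]
        for a, b in swap_pairs:
            ka = p1.class_names.index(a)
            kb = p2.class_names.index(b)
            assert p1.probs[i, ka] == pytest.approx(p2.probs[i, kb],
                                                    abs=0.05)

    def test_determinism_per_seed(self):
        classes = hk.class_profiles("six")
        gt, refs = diagnostic_dataset(n_ref=3, extra=[("focal", "het")])
        cfg = hk.McmcConfig(iterations=1500, burn_in=300, seed=11,
                            reference_individuals=refs)
        a = hk.classify(gt, classes, cfg)
        b = hk.classify(gt, classes, cfg)
        assert np.array_equal(a.probs, b.probs)

    def test_rows_sum_to_one(self, fmodel_pools, six_classes):
        rng = np.random.default_rng(2)
        gt = hk.simulate_class(*fmodel_pools, six_classes["F2"], 15, rng,
                               class_name="F2")
        cfg = hk.McmcConfig(iterations=1500, burn_in=300, seed=0)
        post = hk.classify(gt, hk.class_profiles("six"), cfg)
        assert np.allclose(post.probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((post.probs >= 0) & (post.probs <= 1))

    def test_all_missing_individual_flagged(self):
        classes = hk.class_profiles("six")
        gt, refs = diagnostic_dataset(n_ref=3, extra=[("blank", "het")])
        calls = gt.calls.copy()
        calls[gt.individual_ids.index("blank")] = MISSING
        gt = hk.GenotypeTable(list(gt.individual_ids), list(gt.locus_names),
                              calls, gt.populations.copy(),
                              gt.ecotypes.copy())
        cfg = hk.McmcConfig(iterations=1500, burn_in=300, seed=1,
                            reference_individuals=refs)
        post = hk.classify(gt, classes, cfg)
        assert "blank" in post.diagnostics["all_missing_individuals"]
        i = post.individual_ids.index("blank")
        # posterior ~ mixing-proportion posterior: nothing near certainty
        assert post.probs[i].max() < 0.9

    def test_config_validation(self):
        with pytest.raises(ValueError, match="burn_in"):
            hk.McmcConfig(iterations=100, burn_in=100)
        gt, _ = diagnostic_dataset(n_ref=2)
        with pytest.raises(ValueError, match="reference class"):
            hk.classify(gt, hk.class_profiles("six"),
                        hk.McmcConfig(iterations=200, burn_in=10,
                                      reference_individuals={"refA0": "Z"}))
        mono = hk.GenotypeTable(
            ["x", "y"], ["l1"], np.array([[[1, 1]], [[1, 1]]]),
            np.array(["p", "p"], dtype=object),
            np.array(["unknown", "unknown"], dtype=object))
        with pytest.raises(ValueError, match="polymorphic"):
            hk.classify(mono, hk.class_profiles("six"),
                        hk.McmcConfig(iterations=200, burn_in=10))


class TestAgainstIdealObserver:
    def test_posterior_tracks_known_frequency_oracle(self, fmodel_pools,
                                                     six_classes):
        """On simulated data the sampler's posterior-of-truth matches an
        ideal observer that knows the true pool frequencies and uses equal
        class weights, for the well-identified classes (P1, P2, F1).

        Backcross posteriors are allowed to fall below the oracle: with no
        reference individuals the latent pools are estimated from the data,
        and at small sample sizes backcross alleles blur into the nearer
        pool (an inherent property of the unsupervised model, not of this
        implementation).
        """
        pA, pB = fmodel_pools
        cfg = hk.SimConfig(n_per_class=10, n_datasets=1, seed=42)
        (gt,) = hk.build_evaluation_datasets((pA, pB), cfg)
        classes = hk.class_profiles("six")
        names = [n for n, _ in classes]
        phi = np.stack([p.as_floats() for _, p in classes])
        paS, pbS = pA.slice("A"), pB.slice("B")
        ll = np.zeros((gt.n_individuals, len(names)))
        for j, loc in enumerate(gt.locus_names):
            fa, fb = paS[loc], pbS[loc]
            a1, a2 = gt.calls[:, j, 0], gt.calls[:, j, 1]
            qa1 = np.array([fa.get(int(a), 0.0) for a in a1])
            qa2 = np.array([fa.get(int(a), 0.0) for a in a2])
            qb1 = np.array([fb.get(int(a), 0.0) for a in a1])
            qb2 = np.array([fb.get(int(a), 0.0) for a in a2])
            het = a1 != a2
            lik = np.stack([np.where(het, 2 * qa1 * qa2, qa1 * qa2),
                            np.where(het, qa1 * qb2 + qa2 * qb1, qa1 * qb1),
                            np.where(het, 2 * qb1 * qb2, qb1 * qb2)], axis=1)
            ll += np.log(lik @ phi.T + 1e-300)
        w = np.exp(ll - ll.max(axis=1, keepdims=True))
        ideal = w / w.sum(axis=1, keepdims=True)

        post = hk.classify(gt, classes,
                           hk.McmcConfig(iterations=20_000, burn_in=2_000,
                                         seed=3))
        assert not post.diagnostics["label_swap_suspected"]
        for cls in ("P1", "P2", "F1"):
            mask = gt.populations == cls
            k = names.index(cls)
            assert post.probs[mask, k].mean() == pytest.approx(
                ideal[mask, k].mean(), abs=0.1), cls
        for cls in ("B1", "B2"):
            mask = gt.populations == cls
            k = names.index(cls)
            assert post.probs[mask, k].mean() <= \
                ideal[mask, k].mean() + 0.1, cls


class TestPurityCall:
    def matrix(self, rows, names=("P1", "P2")):
        ids = [f"i{k}" for k in range(len(rows))]
        return ClassPosteriorMatrix(ids, list(names), np.array(rows))

    def test_threshold_semantics(self):
        post = self.matrix([[0.9, 0.1], [0.6, 0.4]])
        assert hk.purity_call(post, 0.85) == {"i0": "P1", "i1": "unassigned"}
        assert hk.purity_call(post, 0.55)["i1"] == "P1"

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        raw = rng.dirichlet(np.ones(6), size=40)
        post = ClassPosteriorMatrix(
            [f"i{k}" for k in range(40)],
            ["P1", "P2", "F1", "F2", "B1", "B2"], raw)
        counts = []
        for t in (0.5, 0.75, 0.85, 0.9):
            calls = hk.purity_call(post, t)
            counts.append(sum(v != "unassigned" for v in calls.values()))
        assert counts == sorted(counts, reverse=True)

    def test_tie_break_prefers_class_order(self):
        post = self.matrix([[0.5, 0.5]])
        assert hk.purity_call(post, 0.5) == {"i0": "P1"}

    def test_invalid_threshold(self):
        post = self.matrix([[1.0, 0.0]])
        with pytest.raises(ValueError):
            hk.purity_call(post, 1.5)
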