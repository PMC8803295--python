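"""Bayesian MCMC assignment of individuals to genotypic classes.

The model (NewHybrids family): each individual i carries a latent class
z_i drawn from mixing proportions pi (symmetric Dirichlet prior).  Given
its class, each locus l independently carries a latent ancestry state
w_il in {2, 1, 0 gene copies of pool-A ancestry} with P(w | z) = phi_z,
the class's exact pedigree-derived profile.  Gene copies of A (resp. B)
ancestry are draws from latent pool allele frequencies theta_A,l (resp.
theta_B,l), each with a symmetric Dirichlet prior over the alleles observed
at the locus.  Genotype likelihood given w for an observed pair (a, b):

    w = 2:  HW draw from theta_A   (a == b: tA(a)^2, else 2 tA(a) tA(b))
    w = 0:  HW draw from theta_B
    w = 1:  one copy from each pool
            (a != b: tA(a) tB(b) + tA(b) tB(a);  a == b: tA(a) tB(a))

A Gibbs sweep updates z (with w summed out), pi, w, per-copy pool-origin
indicators, and theta.  The reported posterior is the post-burn-in average
of the conditional class probabilities of z (Rao-Blackwellised), so runs
are reproducible bit-for-bit per seed.

Without anchoring the two pool labels are exchangeable.  theta is
initialised from the most frequency-divergent sample partition (savanna vs
forest ecotype labels when present, else the most differentiated population
pair); individuals with fixed, known classes (``reference_individuals``)
are the recommended anchor and keep z clamped throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_io import GenotypeTable
from .pedigrees import AncestryProfile

logger = logging.getLogger("hybkit")

_TINY = 1e-300


@dataclass
class McmcConfig:
    """Sampler configuration (defaults follow common NewHybrids practice:
    10^6 iterations, 10^5 burn-in, Dirichlet(1/2) 'Jeffreys-like' priors
    for mixing proportions and allele frequencies)."""

    iterations: int = 1_000_000
    burn_in: int = 100_000
    thin: int = 100
    seed: int = 0
    freq_prior_concentration: float = 0.5
    mixing_prior_concentration: float = 0.5
    reference_individuals: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.freq_prior_concentration <= 0 or \
                self.mixing_prior_concentration <= 0:
            raise ValueError("prior concentrations must be positive")
        if self.thin < 1:
            raise ValueError("thin must be a positive integer")


@dataclass
class ClassPosteriorMatrix:
    """Per-individual posterior probabilities over genotypic classes."""

    individual_ids: list[str]
    class_names: list[str]
    probs: np.ndarray                      # (n, K), rows sum to 1
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        rows = self.probs.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValueError("posterior rows must sum to 1")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, index=self.individual_ids,
                          columns=self.class_names)
        df.index.name = "individual"
        return df


def _encode(gt: GenotypeTable):
    """Integer-encode alleles per locus against the observed allele sets."""
    n, L = gt.n_individuals, gt.n_loci
    miss = gt.missing_mask
    allele_maps: list[dict[int, int]] = []
    n_alleles = np.zeros(L, dtype=int)
    for j in range(L):
        copies = gt.calls[:, j, :][~miss[:, j]]
        vals = np.unique(copies)
        allele_maps.append({int(a): k for k, a in enumerate(vals)})
        n_alleles[j] = len(vals)
    amax = int(n_alleles.max(initial=1))
    g1 = np.zeros((n, L), dtype=np.int64)
    g2 = np.zeros((n, L), dtype=np.int64)
    for j in range(L):
        m = allele_maps[j]
        for i in range(n):
            if not miss[i, j]:
                g1[i, j] = m[int(gt.calls[i, j, 0])]
                g2[i, j] = m[int(gt.calls[i, j, 1])]
    return g1, g2, miss, n_alleles, amax, allele_maps


def _initial_partition(gt: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of the two anchoring partitions (A-like, B-like)."""
    eco = gt.ecotypes
    a_mask = eco == "savanna"
    b_mask = eco == "forest"
    if a_mask.any() and b_mask.any():
        return a_mask, b_mask
    pops = list(dict.fromkeys(gt.populations))
    if len(pops) >= 2:
        # most-divergent population pair by mean absolute frequency contrast
        from .geno_io import allele_frequencies
        freqs = allele_frequencies(gt, "population")
        best, pair = -1.0, (pops[0], pops[-1])
        for x in range(len(pops)):
            for y in range(x + 1, len(pops)):
                d, cnt = 0.0, 0
                for loc in gt.locus_names:
                    fx = freqs.freqs.get((pops[x], loc))
                    fy = freqs.freqs.get((pops[y], loc))
                    if fx is None or fy is None:
                        continue
                    alleles = set(fx) | set(fy)
                    d += sum(abs(fx.get(a, 0.0) - fy.get(a, 0.0))
                             for a in alleles)
                    cnt += 1
                score = d / max(cnt, 1)
                if score > best:
                    best, pair = score, (pops[x], pops[y])
        return gt.populations == pair[0], gt.populations == pair[1]
    # single unlabelled population: split in half (labels then exchangeable)
    half = gt.n_individuals // 2
    a_mask = np.zeros(gt.n_individuals, dtype=bool)
    a_mask[:half] = True
    return a_mask, ~a_mask


def _init_theta(g1, g2, miss, n_alleles, amax, mask, prior, rng):
    """Posterior-mean frequencies from one partition's gene copies."""
    L = g1.shape[1]
    counts = np.zeros((L, amax))
    for g in (g1, g2):
        sub = g[mask]
        typed = ~miss[mask]
        for j in range(L):
            counts[j] += np.bincount(sub[:, j][typed[:, j]], minlength=amax)
    valid = np.arange(amax)[None, :] < n_alleles[:, None]
    theta = (counts + prior) * valid
    return theta / theta.sum(axis=1, keepdims=True)


def classify(gt: GenotypeTable,
             classes: list[tuple[str, AncestryProfile]],
             cfg: McmcConfig) -> ClassPosteriorMatrix:
    """Run the Gibbs sampler and return the class posterior matrix.

    ``classes`` must include both pure parental profiles ((1,0,0) and
    (0,0,1)); equal prior class probabilities are realised through the
    symmetric Dirichlet prior on the mixing proportions.  Individuals with
    every locus missing receive (and are flagged with) the posterior mean
    of the mixing proportions.
    """
    names = [name for name, _ in classes]
    phi = np.stack([prof.as_floats() for _, prof in classes])   # (K, 3)
    K = len(names)
    if K < 2:
        raise ValueError("need at least two genotypic classes")
    have = {tuple(np.round(p, 12)) for p in phi}
    if (1.0, 0.0, 0.0) not in have or (0.0, 0.0, 1.0) not in have:
        raise ValueError("class set must include both pure parental "
                         "profiles (1,0,0) and (0,0,1)")

    g1, g2, miss, n_alleles, amax, _ = _encode(gt)
    n, L = g1.shape
    typed = ~miss
    if not np.any(n_alleles[typed.any(axis=0)] > 1):
        raise ValueError("no polymorphic locus; data are degenerate")
    all_missing = ~typed.any(axis=1)
    if all_missing.any():
        logger.warning("%d individuals with no typed locus: posterior "
                       "equals the mixing-proportion posterior",
                       int(all_missing.sum()))

    ref_idx, ref_cls = [], []
    for ind, cls in cfg.reference_individuals.items():
        if cls not in names:
            raise ValueError(f"reference class {cls!r} not in class set")
        if ind not in gt.individual_ids:
            raise ValueError(f"reference individual {ind!r} not in data")
        ref_idx.append(gt.individual_ids.index(ind))
        ref_cls.append(names.index(cls))
    ref_idx = np.asarray(ref_idx, dtype=int)
    ref_cls = np.asarray(ref_cls, dtype=int)

    rng = np.random.default_rng(cfg.seed)
    valid = np.arange(amax)[None, :] < n_alleles[:, None]       # (L, amax)
    lam = cfg.freq_prior_concentration
    alpha = cfg.mixing_prior_concentration

    a_mask, b_mask = _initial_partition(gt)
    theta_A = _init_theta(g1, g2, miss, n_alleles, amax, a_mask, lam, rng)
    theta_B = _init_theta(g1, g2, miss, n_alleles, amax, b_mask, lam, rng)
    pi = np.full(K, 1.0 / K)
    z = rng.integers(0, K, size=n)
    if ref_idx.size:
        z[ref_idx] = ref_cls

    het = (g1 != g2) & typed
    jdx = np.arange(L)[None, :].repeat(n, axis=0)
    flat1 = jdx * amax + g1
    flat2 = jdx * amax + g2
    rows = np.arange(n)

    post_sum = np.zeros((n, K))
    n_avg = 0
    trace: list[float] = []

    for it in range(cfg.iterations):
        tA1 = theta_A[jdx, g1]
        tA2 = theta_A[jdx, g2]
        tB1 = theta_B[jdx, g1]
        tB2 = theta_B[jdx, g2]
        lik2 = np.where(het, 2.0 * tA1 * tA2, tA1 * tA2)
        lik0 = np.where(het, 2.0 * tB1 * tB2, tB1 * tB2)
        lik1 = np.where(het, tA1 * tB2 + tA2 * tB1, tA1 * tB1)
        lik2[miss] = lik1[miss] = lik0[miss] = 1.0

        # z update, with w summed out
        stacked = np.stack([lik2, lik1, lik0], axis=-1)         # (n, L, 3)
        mix = np.log(np.einsum("nlw,kw->nkl", stacked, phi) + _TINY)
        loglik = mix.sum(axis=2)                                 # (n, K)
        logpost = loglik + np.log(pi + _TINY)
        gum = rng.gumbel(size=(n, K))
        z = np.argmax(logpost + gum, axis=1)
        if ref_idx.size:
            z[ref_idx] = ref_cls

        # pi update
        cls_counts = np.bincount(z, minlength=K)
        pi = rng.dirichlet(alpha + cls_counts)

        # w update given z
        wp = phi[z][:, None, :] * stacked                       # (n, L, 3)
        wp_sum = wp.sum(axis=2, keepdims=True)
        wp = wp / np.maximum(wp_sum, _TINY)
        u = rng.random((n, L, 1))
        w_idx = (u > np.cumsum(wp, axis=2)[..., :2]).sum(axis=2)  # 0,1,2
        n_a = 2 - w_idx                                          # A copies

        # per-copy pool origins and theta update
        pa1 = tA1 * tB2
        pa2 = tA2 * tB1
        denom = np.maximum(pa1 + pa2, _TINY)
        copy1_from_a = rng.random((n, L)) < pa1 / denom
        to_a_1 = (n_a == 2) | ((n_a == 1) & (het & copy1_from_a | ~het))
        to_a_2 = (n_a == 2) | ((n_a == 1) & het & ~copy1_from_a)
        m1 = typed & to_a_1
        m2 = typed & to_a_2
        countsA = (np.bincount(flat1[m1], minlength=L * amax)
                   + np.bincount(flat2[m2], minlength=L * amax))
        m1b = typed & ~to_a_1
        m2b = typed & ~to_a_2
        countsB = (np.bincount(flat1[m1b], minlength=L * amax)
                   + np.bincount(flat2[m2b], minlength=L * amax))
        shapeA = (countsA.reshape(L, amax) + lam) * valid
        shapeB = (countsB.reshape(L, amax) + lam) * valid
        gA = rng.standard_gamma(shapeA)
        gB = rng.standard_gamma(shapeB)
        theta_A = gA / gA.sum(axis=1, keepdims=True)
        theta_B = gB / gB.sum(axis=1, keepdims=True)

        if it >= cfg.burn_in:
            cond = np.exp(logpost - logpost.max(axis=1, keepdims=True))
            cond /= cond.sum(axis=1, keepdims=True)
            if ref_idx.size:
                cond[ref_idx] = 0.0
                cond[ref_idx, ref_cls] = 1.0
            post_sum += cond
            n_avg += 1
        if it % cfg.thin == 0:
            trace.append(float(loglik[rows, z].sum()))

    probs = post_sum / n_avg
    trace_arr = np.asarray(trace)
    # label-swap check: anchored A-like individuals should carry more mass
    # on the most-A class (max phi2) than on the most-B class (max phi0)
    a_class = int(np.argmax(phi[:, 0]))
    b_class = int(np.argmax(phi[:, 2]))
    if a_mask.any():
        mass_a = float(probs[a_mask, a_class].mean())
        mass_b = float(probs[a_mask, b_class].mean())
        anchor_agreement = mass_a / (mass_a + mass_b) \
            if mass_a + mass_b > 0 else float("nan")
    else:
        anchor_agreement = float("nan")
    diagnostics = {
        "loglik_mean": float(trace_arr[len(trace_arr) // 2:].mean()),
        "loglik_sd": float(trace_arr[len(trace_arr) // 2:].std()),
        "anchor_agreement": anchor_agreement,
        "label_swap_suspected": bool(anchor_agreement < 0.5)
        if np.isfinite(anchor_agreement) else False,
        "all_missing_individuals": [gt.individual_ids[i]
                                    for i in np.flatnonzero(all_missing)],
        "n_samples_averaged": n_avg,
    }
    if diagnostics["label_swap_suspected"]:
        logger.warning("pool labels may be swapped (anchor agreement "
                       "%.3f < 0.5)", anchor_agreement)
    return ClassPosteriorMatrix(list(gt.individual_ids), names, probs,
                                diagnostics)


def purity_call(post: ClassPosteriorMatrix, threshold: float,
                ) -> dict[str, str]:
    """Threshold the posterior matrix into hard labels.

    label = argmax class if its posterior >= threshold, else
    ``"unassigned"``.  Ties broken by class order (parentals first).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if threshold <= 0.5 and len(post.class_names) > 2:
        logger.warning("threshold <= 0.5 with >2 classes does not "
                       "guarantee a unique qualifying class")
    out: dict[str, str] = {}
    for i, ind in enumerate(post.individual_ids):
        k = int(np.argmax(post.probs[i]))       # first max wins ties
        out[ind] = post.class_names[k] if post.probs[i, k] >= threshold \
            else "unassigned"
    return out


def posterior_to_tsv(post: ClassPosteriorMatrix, threshold: float = 0.85,
                     ) -> str:
    """TSV rendering: per-class posteriors, argmax class, thresholded call."""
    calls = purity_call(post, threshold)
    df = post.to_dataframe()
    df["max_class"] = [post.class_names[int(k)]
                       for k in np.argmax(post.probs, axis=1)]
    df[f"assigned_at_{threshold}"] = [calls[i] for i in post.individual_ids]
    return df.to_csv(sep="\t")
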