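"""Per-population genetic diversity: A, allelic richness, heterozygosities,
F_IS with permutation significance, and a null-allele Monte-Carlo check.

Statistics per group (population, ecotype, or custom partition), averaged
over loci:

* ``A`` — mean number of alleles per locus.
* ``A_R`` — allelic richness rarefied to g gene copies,
  ``A_R = sum_alleles [1 - C(N - N_i, g) / C(N, g)]`` (hypergeometric
  expectation of the allele count in a subsample of g copies); by default
  g is the smallest non-missing gene-copy count across the compared groups
  and loci (FSTAT convention).
* ``H_O`` — mean observed heterozygosity.
* ``H_E`` — mean unbiased expected heterozygosity,
  ``2n/(2n - 1) * (1 - sum p^2)`` (Nei 1978).
* ``F_IS`` — Weir-Cockerham within-population inbreeding coefficient f,
  multi-locus ratio-of-sums; monomorphic loci contribute nothing and an
  entirely monomorphic group reports NA.

The F_IS permutation test shuffles gene copies among individuals within
each group (destroying any heterozygote deficit while preserving allele
counts) and reports a one-tailed p for F_IS > 0, Holm-adjusted across
groups.  The null-allele check is a simplified Micro-Checker-style test:
the observed homozygote count per group x locus is compared with the
97.5th percentile of counts simulated under Hardy-Weinberg from the
observed frequencies at matched sample size (no size-stutter model and no
Brookfield frequency estimator).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .geno_io import MISSING, GenotypeTable


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Expected allele count in a subsample of ``g`` of ``sum(counts)``
    gene copies, without replacement."""
    counts = np.asarray(counts, dtype=float)
    N = counts.sum()
    if g > N:
        raise ValueError(f"rarefaction size {g} exceeds {int(N)} copies")
    miss_prob = np.zeros_like(counts)
    ok = N - counts >= g
    miss_prob[ok] = np.exp(_log_comb(N - counts[ok], g) - _log_comb(N, g))
    return float(np.sum(1.0 - miss_prob))


def _wc_f_terms(calls: np.ndarray) -> tuple[float, float]:
    """Weir-Cockerham within-population (b + c, c) sums for one group.

    ``calls``: (n, L, 2).  Summed over loci and alleles;
    f = 1 - sum(c) / sum(b + c).
    """
    sum_bc = 0.0
    sum_c = 0.0
    L = calls.shape[1]
    for j in range(L):
        col = calls[:, j, :]
        typed = col[:, 0] != MISSING
        col = col[typed]
        n = col.shape[0]
        if n < 2:
            continue
        alleles = np.unique(col)
        if len(alleles) < 2:
            continue
        het_pair = col[:, 0] != col[:, 1]
        for a in alleles:
            carries = col == a
            p = carries.sum() / (2.0 * n)
            hbar = np.mean(het_pair & carries.any(axis=1))
            b = (n / (n - 1.0)) * (p * (1.0 - p)
                                   - (2.0 * n - 1.0) / (4.0 * n) * hbar)
            c = hbar / 2.0
            sum_bc += b + c
            sum_c += c
    return sum_bc, sum_c


def _group_f(calls: np.ndarray) -> float:
    sum_bc, sum_c = _wc_f_terms(calls)
    if sum_bc == 0.0:
        return np.nan
    return 1.0 - sum_c / sum_bc


def holm_adjust(pvals: list[float], alpha: float = 0.05) -> list[bool]:
    """Holm (sequential Bonferroni) significance flags; NaN -> False."""
    idx = [i for i, p in enumerate(pvals) if not np.isnan(p)]
    order = sorted(idx, key=lambda i: pvals[i])
    m = len(order)
    out = [False] * len(pvals)
    for rank, i in enumerate(order):
        if pvals[i] <= alpha / (m - rank):
            out[i] = True
        else:
            break
    return out


def diversity_table(gt: GenotypeTable, grouping="population",
                    g: int | str = "auto") -> pd.DataFrame:
    """Diversity-row table per group.

    ``g`` is the rarefaction gene-copy count, or ``"auto"`` for the
    smallest non-missing count over all group x locus cells (recorded in
    the ``rarefaction_g`` column).
    """
    labels = gt.group_labels(grouping)
    groups = list(dict.fromkeys(labels))
    for grp in groups:
        if int((labels == grp).sum()) < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 individuals")

    # per group x locus gene-copy counts (for auto g)
    copy_counts = []
    for grp in groups:
        sub = gt.calls[labels == grp]
        for j in range(gt.n_loci):
            c = int((sub[:, j, 0] != MISSING).sum()) * 2
            if c > 0:
                copy_counts.append(c)
    if not copy_counts:
        raise ValueError("no typed data in any group")
    g_val = min(copy_counts) if g == "auto" else int(g)
    if g_val > min(copy_counts):
        raise ValueError(f"rarefaction size {g_val} exceeds the smallest "
                         f"typed gene-copy count {min(copy_counts)}")

    rows = []
    for grp in groups:
        sub = gt.calls[labels == grp]
        n_ind = sub.shape[0]
        a_per_locus, ar_per_locus, ho, he = [], [], [], []
        for j in range(gt.n_loci):
            col = sub[:, j, :]
            typed = col[:, 0] != MISSING
            col = col[typed]
            n = col.shape[0]
            if n == 0:
                continue
            vals, counts = np.unique(col.ravel(), return_counts=True)
            a_per_locus.append(len(vals))
            ar_per_locus.append(rarefied_richness(counts, g_val))
            ho.append(float(np.mean(col[:, 0] != col[:, 1])))
            p = counts / (2.0 * n)
            he.append((2.0 * n / (2.0 * n - 1.0)) * (1.0 - float(np.sum(p ** 2))))
        fis = _group_f(sub)
        rows.append({
            "population": grp,
            "N": n_ind,
            "A": float(np.mean(a_per_locus)),
            "A_R": float(np.mean(ar_per_locus)),
            "H_O": float(np.mean(ho)),
            "H_E": float(np.mean(he)),
            "F_IS": fis,
            "rarefaction_g": g_val,
        })
    return pd.DataFrame(rows)


def _permute_copies(calls: np.ndarray, rng: np.random.Generator,
                    ) -> np.ndarray:
    """Shuffle gene copies among individuals within a group, per locus."""
    out = calls.copy()
    L = calls.shape[1]
    for j in range(L):
        typed = out[:, j, 0] != MISSING
        copies = out[typed, j, :].ravel()
        rng.shuffle(copies)
        out[typed, j, :] = copies.reshape(-1, 2)
    return out


def fis_permutation_test(gt: GenotypeTable, grouping="population",
                         n_perm: int = 1000, alpha: float = 0.05,
                         seed: int = 0) -> pd.DataFrame:
    """One-tailed permutation p for F_IS > 0 per group, Holm-corrected.

    The null randomises gene copies among individuals within the group
    (random union of gametes), so any heterozygote deficit disappears
    while allele frequencies are preserved exactly.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels = gt.group_labels(grouping)
    groups = list(dict.fromkeys(labels))
    rng = np.random.default_rng(seed)
    pvals, fis_obs = [], []
    for grp in groups:
        sub = gt.calls[labels == grp]
        obs = _group_f(sub)
        fis_obs.append(obs)
        if np.isnan(obs):
            pvals.append(np.nan)
            continue
        n_ge = 0
        for _ in range(n_perm):
            f = _group_f(_permute_copies(sub, rng))
            if not np.isnan(f) and f >= obs:
                n_ge += 1
        pvals.append((n_ge + 1) / (n_perm + 1))
    return pd.DataFrame({
        "population": groups,
        "F_IS": fis_obs,
        "p_fis": pvals,
        "holm_significant": holm_adjust(pvals, alpha),
    })


def null_allele_check(gt: GenotypeTable, grouping="population",
                      n_sim: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Flag group x locus cells with homozygote excess beyond HWE.

    For each cell, ``n_sim`` datasets of matched sample size are simulated
    under Hardy-Weinberg from the observed allele frequencies; the cell is
    flagged when the observed homozygote count exceeds the simulated
    97.5th percentile.  Monomorphic cells are untestable (NA).
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    labels = gt.group_labels(grouping)
    groups = list(dict.fromkeys(labels))
    rng = np.random.default_rng(seed)
    rows = []
    for grp in groups:
        sub = gt.calls[labels == grp]
        for j, loc in enumerate(gt.locus_names):
            col = sub[:, j, :]
            typed = col[:, 0] != MISSING
            col = col[typed]
            n = col.shape[0]
            if n == 0:
                continue
            vals, counts = np.unique(col.ravel(), return_counts=True)
            if len(vals) < 2:
                rows.append({"population": grp, "locus": loc,
                             "n": n, "obs_homozygotes": np.nan,
                             "crit_975": np.nan, "flagged": None})
                continue
            obs_hom = int(np.sum(col[:, 0] == col[:, 1]))
            p = counts / counts.sum()
            draws = rng.choice(len(vals), size=(n_sim, n, 2), p=p)
            sim_hom = (draws[..., 0] == draws[..., 1]).sum(axis=1)
            crit = float(np.percentile(sim_hom, 97.5))
            rows.append({"population": grp, "locus": loc, "n": n,
                         "obs_homozygotes": obs_hom, "crit_975": crit,
                         "flagged": bool(obs_hom > crit)})
    return pd.DataFrame(rows)
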