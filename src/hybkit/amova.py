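"""Hierarchical AMOVA and pairwise Weir-Cockerham F_ST.

The hierarchical analysis partitions allele-indicator variance over three
nested levels — among groups of populations (usually the two ecotypes),
among populations within groups, and among gene copies within populations
— by the method of moments on one-hot allele indicators (the standard
F_ST-like AMOVA, not an allele-size / R_ST analysis).  With variance
components (sigma_a, sigma_b, sigma_c):

    F_CT = sigma_a / total          (between ecotypes)
    F_SC = sigma_b / (sigma_b + sigma_c)
    F_ST = (sigma_a + sigma_b) / total

Components are estimated per locus from unbalanced nested ANOVA sums of
squares and combined across loci with weights proportional to the locus's
typed gene copies; components may be negative (method of moments).
Significance is by permutation: whole populations among groups (F_CT),
individuals among populations within groups (F_SC), individuals among all
populations (F_ST).

Pairwise differentiation uses the Weir-Cockerham (1984) theta estimator,
multi-locus ratio of sums of the (a, b, c) components, with p-values from
permuting individuals between the pair.  Negative estimates are reported
as computed unless truncation is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_io import MISSING, GenotypeTable


@dataclass
class AmovaResult:
    sigma_a: float          # among groups
    sigma_b: float          # among populations within groups
    sigma_c: float          # within populations
    f_ct: float
    f_sc: float
    f_st: float
    p_fct: float = np.nan
    p_fsc: float = np.nan
    p_fst: float = np.nan
    notes: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": ["among_groups", "among_pops_within_groups",
                          "within_pops"],
            "sigma2": [self.sigma_a, self.sigma_b, self.sigma_c],
            "F": [self.f_ct, self.f_sc, self.f_st],
            "F_name": ["F_CT", "F_SC", "F_ST"],
            "p": [self.p_fct, self.p_fsc, self.p_fst],
        })


def _encode_loci(gt: GenotypeTable):
    """Per-locus integer allele codes: list of (n, 2) arrays, -1 missing."""
    out = []
    for j in range(gt.n_loci):
        col = gt.calls[:, j, :]
        typed = col[:, 0] != MISSING
        vals = np.unique(col[typed])
        lookup = {int(a): k for k, a in enumerate(vals)}
        enc = np.full_like(col, -1)
        for i in np.flatnonzero(typed):
            enc[i, 0] = lookup[int(col[i, 0])]
            enc[i, 1] = lookup[int(col[i, 1])]
        out.append((enc, len(vals)))
    return out


def _pop_counts(enc: np.ndarray, n_alleles: int, pop_idx: np.ndarray,
                n_pops: int) -> tuple[np.ndarray, np.ndarray]:
    """Allele counts T (pops x alleles) and typed copies n_i per pop."""
    typed = enc[:, 0] >= 0
    flat = (pop_idx[typed, None] * n_alleles + enc[typed]).ravel()
    T = np.bincount(flat, minlength=n_pops * n_alleles).reshape(
        n_pops, n_alleles).astype(float)
    return T, T.sum(axis=1)


def _locus_components(T: np.ndarray, n_i: np.ndarray, gasg: np.ndarray,
                      n_groups: int) -> tuple[float, float, float] | None:
    """Method-of-moments (sigma_a, sigma_b, sigma_c) for one locus.

    ``T``: pop x allele counts; ``n_i``: typed copies per pop; ``gasg``:
    group index of each pop.  Pops with no data are dropped.  Returns None
    when degrees of freedom vanish.
    """
    keep = n_i > 0
    T, n_i, gasg = T[keep], n_i[keep], gasg[keep]
    p = len(n_i)
    groups, gasg = np.unique(gasg, return_inverse=True)
    g = len(groups)
    N = n_i.sum()
    if g < 1 or N <= p:
        return None
    N_g = np.bincount(gasg, weights=n_i, minlength=g)
    Tg = np.zeros((g, T.shape[1]))
    np.add.at(Tg, gasg, T)
    T_tot = T.sum(axis=0)

    within_pop_sq = float((T ** 2 / n_i[:, None]).sum())
    group_sq = float((Tg ** 2 / N_g[:, None]).sum())
    total_sq = float((T_tot ** 2).sum() / N)

    ss_c = float(N - within_pop_sq)
    ss_b = within_pop_sq - group_sq
    ss_a = group_sq - total_sq

    df_c = N - p
    df_b = p - g
    df_a = g - 1

    sig_c = ss_c / df_c
    sum_ni2_by_group = float(np.bincount(gasg, weights=n_i ** 2 / N_g[gasg],
                                         minlength=g).sum())
    if df_b > 0:
        n_prime = (N - sum_ni2_by_group) / df_b
        sig_b = (ss_b / df_b - sig_c) / n_prime
    else:
        sig_b = 0.0
    if df_a > 0:
        n_dprime = (sum_ni2_by_group - float((n_i ** 2).sum()) / N) / df_a
        n_tprime = (N - float((N_g ** 2).sum()) / N) / df_a
        sig_a = (ss_a / df_a - sig_c - n_dprime * sig_b) / n_tprime
    else:
        sig_a = 0.0
    return sig_a, sig_b, sig_c


def _locus_stats(loci, pop_idx, n_pops):
    """Per-locus population sufficient statistics [(T, n_i), ...]."""
    return [_pop_counts(enc, n_alleles, pop_idx, n_pops)
            for enc, n_alleles in loci]


def _components_from_stats(stats, gasg) -> tuple[float, float, float]:
    """Locus-weighted components over the dataset (weights ~ typed copies)."""
    comps = np.zeros(3)
    wsum = 0.0
    for T, n_i in stats:
        res = _locus_components(T, n_i, gasg, int(gasg.max()) + 1)
        if res is None:
            continue
        w = n_i.sum()
        comps += w * np.asarray(res)
        wsum += w
    if wsum == 0:
        raise ValueError("no locus with usable data for AMOVA")
    return tuple(comps / wsum)      # type: ignore[return-value]


def _amova_components(loci, pop_idx, n_pops, gasg,
                      ) -> tuple[float, float, float]:
    return _components_from_stats(_locus_stats(loci, pop_idx, n_pops), gasg)


def _fstats(sig: tuple[float, float, float]) -> tuple[float, float, float]:
    a, b, c = sig
    total = a + b + c
    if total <= 0:
        raise ValueError("total variance is not positive "
                         "(monomorphic dataset?)")
    f_ct = a / total
    f_sc = b / (b + c) if (b + c) > 0 else np.nan
    f_st = (a + b) / total
    return f_ct, f_sc, f_st


def _resolve_groups(gt: GenotypeTable, pops: list[str], groupmap,
                    ) -> np.ndarray:
    """Group index per population; 'ecotype' uses each pop's modal label."""
    if groupmap == "ecotype":
        groupmap = {}
        for pop in pops:
            eco = gt.ecotypes[gt.populations == pop]
            vals, counts = np.unique(eco, return_counts=True)
            groupmap[pop] = str(vals[np.argmax(counts)])
    labels = [groupmap[p] for p in pops]
    uniq = list(dict.fromkeys(labels))
    return np.asarray([uniq.index(l) for l in labels])


def hierarchical_amova(gt: GenotypeTable, popmap=None, groupmap="ecotype",
                       n_perm: int = 10_000, seed: int = 0) -> AmovaResult:
    """Three-level AMOVA with permutation p-values.

    ``popmap``: per-individual population labels (default: the table's);
    ``groupmap``: dict population -> group, or ``"ecotype"``.  A group
    containing a single population contributes no among-population degrees
    of freedom at that level (noted in the result).
    """
    pop_labels = gt.populations if popmap is None else gt.group_labels(popmap)
    pops = list(dict.fromkeys(pop_labels))
    pop_idx = np.asarray([pops.index(p) for p in pop_labels])
    gasg = _resolve_groups(gt, pops, groupmap)
    n_groups = int(gasg.max()) + 1
    loci = _encode_loci(gt)

    sig = _amova_components(loci, pop_idx, len(pops), gasg)
    f_ct, f_sc, f_st = _fstats(sig)

    rng = np.random.default_rng(seed)
    # F_CT: permute whole populations among groups (undefined with 1 group);
    # population-level sufficient statistics are invariant under this
    # permutation, so they are computed once
    p_fct = np.nan
    if n_groups >= 2:
        stats = _locus_stats(loci, pop_idx, len(pops))
        ge_ct = 0
        for _ in range(n_perm):
            perm = rng.permutation(gasg)
            try:
                val = _fstats(_components_from_stats(stats, perm))[0]
            except ValueError:
                continue
            if val >= f_ct:
                ge_ct += 1
        p_fct = (ge_ct + 1) / (n_perm + 1)

    # F_SC: permute individuals among populations within their group
    group_of_ind = gasg[pop_idx]
    ge_sc = 0
    for _ in range(n_perm):
        perm_pop = pop_idx.copy()
        for grp in range(n_groups):
            m = group_of_ind == grp
            perm_pop[m] = rng.permutation(perm_pop[m])
        val = _fstats(_amova_components(loci, perm_pop, len(pops), gasg))[1]
        if not np.isnan(val) and val >= f_sc:
            ge_sc += 1
    p_fsc = (ge_sc + 1) / (n_perm + 1) if not np.isnan(f_sc) else np.nan

    # F_ST: permute individuals among all populations
    ge_st = 0
    for _ in range(n_perm):
        perm_pop = rng.permutation(pop_idx)
        val = _fstats(_amova_components(loci, perm_pop, len(pops), gasg))[2]
        if val >= f_st:
            ge_st += 1
    p_fst = (ge_st + 1) / (n_perm + 1)

    singles = [pops[i] for i in range(len(pops))
               if int((gasg == gasg[i]).sum()) == 1]
    return AmovaResult(*sig, f_ct, f_sc, f_st, p_fct, p_fsc, p_fst,
                       notes={"single_population_groups": sorted(set(singles)),
                              "n_perm": n_perm})


# ---------------------------------------------------------------------------
# Pairwise Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _wc_theta_terms(calls1: np.ndarray, calls2: np.ndarray,
                    ) -> tuple[float, float]:
    """Summed (a, a + b + c) WC84 components for a population pair."""
    sum_a = 0.0
    sum_abc = 0.0
    L = calls1.shape[1]
    r = 2.0
    for j in range(L):
        cols = []
        for calls in (calls1, calls2):
            col = calls[:, j, :]
            col = col[col[:, 0] != MISSING]
            cols.append(col)
        n1, n2 = cols[0].shape[0], cols[1].shape[0]
        if n1 < 2 or n2 < 2:
            continue
        alleles = np.unique(np.concatenate([c.ravel() for c in cols]))
        if len(alleles) < 2:
            continue
        n = np.array([n1, n2], dtype=float)
        nbar = n.mean()
        nc = (n.sum() - (n ** 2).sum() / n.sum()) / (r - 1.0)
        for a in alleles:
            p_i = np.array([np.mean(c == a) for c in cols])
            h_i = np.array([np.mean((c[:, 0] != c[:, 1])
                                    & (c == a).any(axis=1)) for c in cols])
            pbar = float((n * p_i).sum() / n.sum())
            s2 = float((n * (p_i - pbar) ** 2).sum() / ((r - 1.0) * nbar))
            hbar = float((n * h_i).sum() / n.sum())
            va = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
                / (nbar - 1.0))
            vb = (nbar / (nbar - 1.0)) * (
                pbar * (1 - pbar) - (r - 1.0) / r * s2
                - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
            vc = hbar / 2.0
            sum_a += va
            sum_abc += va + vb + vc
    return sum_a, sum_abc


def wc_theta(calls1: np.ndarray, calls2: np.ndarray) -> float:
    """Multi-locus WC84 theta between two populations' call arrays."""
    sum_a, sum_abc = _wc_theta_terms(calls1, calls2)
    if sum_abc == 0.0:
        return np.nan
    return sum_a / sum_abc


def pairwise_fst(gt: GenotypeTable, popmap=None, n_perm: int = 0,
                 seed: int = 0, truncate_negative: bool = False,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise theta matrix (and permutation p-values when requested).

    p-values permute individuals between the two populations of the pair;
    pairs sharing no typed locus report NA.  Returns (theta, p) DataFrames
    indexed by population.
    """
    pop_labels = gt.populations if popmap is None else gt.group_labels(popmap)
    pops = list(dict.fromkeys(pop_labels))
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    rng = np.random.default_rng(seed)
    theta = pd.DataFrame(0.0, index=pops, columns=pops)
    pmat = pd.DataFrame(np.nan, index=pops, columns=pops)
    for x in range(len(pops)):
        for y in range(x + 1, len(pops)):
            c1 = gt.calls[pop_labels == pops[x]]
            c2 = gt.calls[pop_labels == pops[y]]
            t = wc_theta(c1, c2)
            if truncate_negative and not np.isnan(t):
                t = max(t, 0.0)
            theta.iloc[x, y] = theta.iloc[y, x] = t
            if n_perm > 0 and not np.isnan(t):
                merged = np.concatenate([c1, c2], axis=0)
                n1 = c1.shape[0]
                ge = 0
                for _ in range(n_perm):
                    idx = rng.permutation(merged.shape[0])
                    tp = wc_theta(merged[idx[:n1]], merged[idx[n1:]])
                    if not np.isnan(tp) and tp >= t:
                        ge += 1
                pmat.iloc[x, y] = pmat.iloc[y, x] = (ge + 1) / (n_perm + 1)
    return theta, pmat
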