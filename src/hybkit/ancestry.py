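"""Maximum-likelihood hybrid index and interecotypic heterozygosity.

The hybrid index h of an individual is the proportion of its genome drawn
from parental pool B (forest); pool A (savanna) individuals sit at h ~ 0.
Given parental allele frequencies pA, pB, each of the individual's gene
copies is an independent draw from the mixture (1-h) pA + h pB, so

    l(h) = sum over loci, over the 2 copies, of log[(1-h) pA(a) + h pB(a)]

which is maximised on a fine grid with golden-section refinement; the 95%
confidence interval is the profile-likelihood set {h : l(h) >= l(h_hat) -
1.92} (chi-square_1 0.95 cutoff / 2).

Interecotypic heterozygosity Q12 is the fraction of loci carrying one gene
copy of each parental ancestry.  Per locus it is estimated as the posterior
probability of the one-copy-each ancestry state under a uniform prior over
the three states {2, 1, 0 A-copies}, using the same per-state genotype
likelihoods as the class posterior; Q12 averages this over usable loci.
F1 individuals at diagnostic markers give Q12 = 1, pure parentals 0.

In an (h, Q12) triangle plot feasible points satisfy
Q12 <= 1 - |2h - 1|; per-individual excess above the bound flags homoplasy
or genotyping artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno_io import MISSING, AlleleFreqTable, GenotypeTable

logger = logging.getLogger("hybkit")

#: half the chi-square_1 95% quantile: profile-likelihood CI cutoff
_CI_DROP = 1.92


@dataclass
class AncestryEstimate:
    """Per-individual hybrid index with CI, plus Q12."""

    individual: str
    h_hat: float
    ci_low: float
    ci_high: float
    q12: float
    n_loci_used: int
    flat_likelihood: bool = False

    @property
    def triangle_excess(self) -> float:
        """max(0, Q12 - (1 - |2h - 1|)): height above the triangle bound."""
        return max(0.0, self.q12 - (1.0 - abs(2.0 * self.h_hat - 1.0)))


def _copy_frequencies(genotypes: dict[str, tuple[int, int]],
                      pA: dict[str, dict[int, float]],
                      pB: dict[str, dict[int, float]],
                      floor: float):
    """Per-locus (pa, pb) frequency pairs for the individual's two copies.

    Loci missing in the individual or undefined in either pool are skipped.
    An allele unseen in both pools gets the documented floor frequency in
    both (keeps the likelihood finite without favouring either pool).
    """
    per_locus: list[np.ndarray] = []     # each (2, 2): rows copies, cols A/B
    used: list[str] = []
    for locus, (a1, a2) in genotypes.items():
        if a1 == MISSING or locus not in pA or locus not in pB:
            continue
        fa, fb = pA[locus], pB[locus]
        vals = np.empty((2, 2))
        for k, allele in enumerate((a1, a2)):
            qa = fa.get(allele, 0.0)
            qb = fb.get(allele, 0.0)
            if qa == 0.0 and qb == 0.0:
                logger.warning("allele %s at locus %s unseen in both "
                               "parental pools; floor %.3g applied",
                               allele, locus, floor)
                qa = qb = floor
            vals[k] = (qa, qb)
        per_locus.append(vals)
        used.append(locus)
    return per_locus, used


def _default_floor(pA_table: AlleleFreqTable, pB_table: AlleleFreqTable,
                   groupA: str, groupB: str) -> float:
    gcs = [gc for (g, _), gc in pA_table.gene_copies.items() if g == groupA]
    gcs += [gc for (g, _), gc in pB_table.gene_copies.items() if g == groupB]
    gc = max(gcs) if gcs else 100
    return 1.0 / (2.0 * gc + 1.0)


def hybrid_index(genotypes: dict[str, tuple[int, int]],
                 pA: dict[str, dict[int, float]],
                 pB: dict[str, dict[int, float]],
                 grid_step: float = 0.001,
                 floor: float = 1.0 / 201.0,
                 individual: str = "ind") -> AncestryEstimate:
    """ML hybrid index for one individual (Q12 filled in separately).

    ``genotypes`` maps locus -> (a1, a2); ``pA``/``pB`` map locus ->
    {allele: frequency}.  ``grid_step`` must be <= 0.001.
    """
    if grid_step > 0.001:
        raise ValueError("grid_step must be <= 0.001")
    per_locus, used = _copy_frequencies(genotypes, pA, pB, floor)
    if not used:
        raise ValueError(f"no usable loci for individual {individual!r}")
    vals = np.concatenate(per_locus, axis=0)          # (2L, 2)
    pa, pb = vals[:, 0], vals[:, 1]

    flat = bool(np.allclose(pa, pb))
    if flat:
        return AncestryEstimate(individual, 0.5, 0.0, 1.0, np.nan,
                                len(used), flat_likelihood=True)

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    ll = np.log((1.0 - grid)[:, None] * pa + grid[:, None] * pb
                + 1e-300).sum(axis=1)
    k = int(np.argmax(ll))

    # golden-section refinement in the bracketing grid cell
    def negll(h: float) -> float:
        return -float(np.log((1.0 - h) * pa + h * pb + 1e-300).sum())

    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    from scipy.optimize import minimize_scalar
    res = minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-7})
    h_hat = float(res.x)
    ll_max = -float(res.fun)

    keep = ll >= ll_max - _CI_DROP
    ci_low = float(grid[keep].min())
    ci_high = float(grid[keep].max())
    ci_low = min(ci_low, h_hat)
    ci_high = max(ci_high, h_hat)
    return AncestryEstimate(individual, h_hat, ci_low, ci_high, np.nan,
                            len(used))


def interecotype_heterozygosity(genotypes: dict[str, tuple[int, int]],
                                pA: dict[str, dict[int, float]],
                                pB: dict[str, dict[int, float]],
                                floor: float = 1.0 / 201.0) -> float:
    """Q12: mean posterior P(one copy of each ancestry) over usable loci."""
    q_sum, n_used = 0.0, 0
    for locus, (a1, a2) in genotypes.items():
        if a1 == MISSING or locus not in pA or locus not in pB:
            continue
        fa, fb = pA[locus], pB[locus]
        qa1, qb1 = fa.get(a1, 0.0), fb.get(a1, 0.0)
        qa2, qb2 = fa.get(a2, 0.0), fb.get(a2, 0.0)
        if qa1 == 0.0 and qb1 == 0.0:
            qa1 = qb1 = floor
        if qa2 == 0.0 and qb2 == 0.0:
            qa2 = qb2 = floor
        if a1 != a2:
            lik2 = 2.0 * qa1 * qa2
            lik0 = 2.0 * qb1 * qb2
            lik1 = qa1 * qb2 + qa2 * qb1
        else:
            lik2 = qa1 * qa1
            lik0 = qb1 * qb1
            lik1 = qa1 * qb1
        total = lik2 + lik1 + lik0
        if total > 0:
            q_sum += lik1 / total
            n_used += 1
    if n_used == 0:
        raise ValueError("no usable loci for Q12")
    return q_sum / n_used


def ancestry_table(gt: GenotypeTable,
                   pA_table: AlleleFreqTable, pB_table: AlleleFreqTable,
                   groupA: str | None = None, groupB: str | None = None,
                   grid_step: float = 0.001,
                   orientation: str = "forest-high") -> pd.DataFrame:
    """Hybrid index + Q12 for every individual of a genotype table.

    ``pA_table``/``pB_table`` hold the savanna/forest parental frequencies
    (single group each unless ``groupA``/``groupB`` name one).  With the
    default orientation forest-pure individuals sit at h ~ 1; pass
    ``orientation="savanna-high"`` to flip.
    """
    if orientation not in ("forest-high", "savanna-high"):
        raise ValueError("orientation must be forest-high or savanna-high")
    groupA = pA_table.groups[0] if groupA is None else groupA
    groupB = pB_table.groups[0] if groupB is None else groupB
    pA = pA_table.slice(groupA)
    pB = pB_table.slice(groupB)
    floor = _default_floor(pA_table, pB_table, groupA, groupB)
    rows = []
    for i, ind in enumerate(gt.individual_ids):
        genotypes = {loc: (int(gt.calls[i, j, 0]), int(gt.calls[i, j, 1]))
                     for j, loc in enumerate(gt.locus_names)}
        est = hybrid_index(genotypes, pA, pB, grid_step, floor, ind)
        est.q12 = interecotype_heterozygosity(genotypes, pA, pB, floor)
        if orientation == "savanna-high":
            est.h_hat = 1.0 - est.h_hat
            est.ci_low, est.ci_high = 1.0 - est.ci_high, 1.0 - est.ci_low
        rows.append({
            "individual": ind,
            "population": gt.populations[i],
            "h_hat": est.h_hat,
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
            "q12": est.q12,
            "n_loci_used": est.n_loci_used,
            "triangle_excess": est.triangle_excess,
            "flat_likelihood": est.flat_likelihood,
        })
    return pd.DataFrame(rows)


def triangle_report(estimates: list[AncestryEstimate]) -> pd.DataFrame:
    """Per-individual triangle-bound excess and a flag for exceeders.

    Points above the bound Q12 <= 1 - |2h - 1| cannot arise from the
    two-pool ancestry model and indicate allele homoplasy between pools.
    """
    rows = [{"individual": e.individual, "h_hat": e.h_hat, "q12": e.q12,
             "triangle_excess": e.triangle_excess,
             "above_bound": e.triangle_excess > 0.0}
            for e in estimates]
    return pd.DataFrame(rows)
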