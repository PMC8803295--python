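"""Synthetic microsatellite data: diverged parental pools and pedigree-
simulated hybrid cohorts.

Two parental gene pools (A = savanna, B = forest) are generated under the
F-model: per locus, an ancestral frequency vector is drawn from a flat
Dirichlet and each pool's frequencies from Dirichlet(ancestral * (1-F)/F),
independently, so the expected pairwise differentiation between pools is
approximately F.  Individuals of any genotypic class are then produced by
Mendelian gene-dropping through the class's explicit cross pedigree:
founder gene copies are drawn from their pool under Hardy-Weinberg, and
each transmission picks one of the parent's two copies uniformly at random,
independently per locus.

Defaults mirror the study conditions the analyses are aimed at: 11 loci,
~8 alleles per locus, between-pool divergence F = 0.35 (the observed
between-biome pairwise F_ST range is roughly 0.33-0.40), 100 individuals
per genotypic class and 5 replicate datasets.

Optional corruption steps emulate common microsatellite artifacts:
call-wise missingness, and a segregating null allele (null homozygotes
become missing calls; null heterozygotes appear as visible-allele
homozygotes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geno_io import MISSING, AlleleFreqTable, GenotypeTable
from .pedigrees import Pedigree, standard_class_sets


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic-data generator."""

    n_loci: int = 11
    alleles_per_locus: int = 8
    divergence: float = 0.35          # F-model differentiation parameter
    n_per_class: int = 100
    class_set: str = "six"            # six | twelve | fourteen
    n_datasets: int = 5
    missing_rate: float = 0.0
    null_allele_freq: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.divergence < 1.0:
            raise ValueError("divergence F must lie in (0, 1)")
        for name in ("missing_rate", "null_allele_freq"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _locus_names(n_loci: int) -> list[str]:
    return [f"loc{j + 1}" for j in range(n_loci)]


def make_parental_frequencies(cfg: SimConfig,
                              rng: np.random.Generator | None = None,
                              ) -> tuple[AlleleFreqTable, AlleleFreqTable]:
    """Draw the two parental pools' allele frequencies under the F-model.

    Returns single-group tables named ``A`` and ``B``.  The nominal
    ``gene_copies`` (2 x n_per_class) records the pool-sample size the
    frequencies stand in for; it feeds the rare-allele frequency floor in
    downstream likelihoods.
    """
    rng = cfg.rng() if rng is None else rng
    loci = _locus_names(cfg.n_loci)
    k = cfg.alleles_per_locus
    conc = (1.0 - cfg.divergence) / cfg.divergence
    pA = AlleleFreqTable(["A"], loci)
    pB = AlleleFreqTable(["B"], loci)
    nominal = 2 * cfg.n_per_class
    for loc in loci:
        ancestral = rng.dirichlet(np.ones(k))
        fA = rng.dirichlet(ancestral * conc)
        fB = rng.dirichlet(ancestral * conc)
        pA.freqs[("A", loc)] = {a + 1: float(fA[a]) for a in range(k)}
        pB.freqs[("B", loc)] = {a + 1: float(fB[a]) for a in range(k)}
        pA.gene_copies[("A", loc)] = nominal
        pB.gene_copies[("B", loc)] = nominal
    return pA, pB


def diagnostic_frequencies(n_loci: int, nominal_copies: int = 200,
                           ) -> tuple[AlleleFreqTable, AlleleFreqTable]:
    """Fully diagnostic pools: allele 1 fixed in A, allele 2 fixed in B."""
    loci = _locus_names(n_loci)
    pA = AlleleFreqTable(["A"], loci)
    pB = AlleleFreqTable(["B"], loci)
    for loc in loci:
        pA.freqs[("A", loc)] = {1: 1.0}
        pB.freqs[("B", loc)] = {2: 1.0}
        pA.gene_copies[("A", loc)] = nominal_copies
        pB.gene_copies[("B", loc)] = nominal_copies
    return pA, pB


def _pool_arrays(table: AlleleFreqTable) -> tuple[list[str], list[np.ndarray],
                                                  list[np.ndarray]]:
    """Unpack a single-group table to per-locus allele/frequency arrays."""
    (group,) = table.groups
    loci, alleles, freqs = [], [], []
    for loc in table.locus_names:
        if (group, loc) not in table.freqs:
            raise ValueError(f"pool {group!r} undefined at locus {loc!r}")
        d = table.freqs[(group, loc)]
        loci.append(loc)
        alleles.append(np.fromiter(d.keys(), dtype=np.int64))
        freqs.append(np.fromiter(d.values(), dtype=float))
    return loci, alleles, freqs


def _draw_pool_copies(alleles: list[np.ndarray], freqs: list[np.ndarray],
                      shape: tuple[int, ...], rng: np.random.Generator,
                      ) -> np.ndarray:
    """Draw gene copies per locus: result shape = shape + (n_loci,)."""
    L = len(alleles)
    out = np.empty(shape + (L,), dtype=np.int64)
    for j in range(L):
        out[..., j] = rng.choice(alleles[j], size=shape, p=freqs[j])
    return out


def simulate_class(pA: AlleleFreqTable, pB: AlleleFreqTable, ped: Pedigree,
                   n: int, rng: np.random.Generator,
                   class_name: str = "sim", id_prefix: str | None = None,
                   ) -> GenotypeTable:
    """Gene-drop ``n`` independent focal individuals of one genotypic class.

    Founder copies are Hardy-Weinberg draws from the founder's pool; each
    transmission picks one of the parent's two copies uniformly at random,
    independently per locus and per replicate.  The class name is attached
    as the population label (the truth label downstream).
    """
    ped.validate()
    lociA, allelesA, freqsA = _pool_arrays(pA)
    lociB, allelesB, freqsB = _pool_arrays(pB)
    if lociA != lociB:
        raise ValueError("parental pools disagree on the locus panel")
    L = len(lociA)
    founders = ped.founder_map
    crosses = ped.cross_map
    copies: dict[str, np.ndarray] = {}       # node -> (n, L, 2)
    for node in ped.topological_order():
        if node in founders:
            al, fr = ((allelesA, freqsA) if founders[node] == "A"
                      else (allelesB, freqsB))
            both = _draw_pool_copies(al, fr, (n, 2), rng)   # (n, 2, L)
            copies[node] = both.transpose(0, 2, 1)
        else:
            p1, p2 = crosses[node]
            out = np.empty((n, L, 2), dtype=np.int64)
            for k, parent in enumerate((p1, p2)):
                pick = rng.integers(0, 2, size=(n, L, 1))
                out[..., k] = np.take_along_axis(
                    copies[parent], pick, axis=2)[..., 0]
            copies[node] = out
    prefix = class_name if id_prefix is None else id_prefix
    ids = [f"{prefix}_{i + 1}" for i in range(n)]
    eco = {"P1": "savanna", "P2": "forest"}.get(class_name, "unknown")
    return GenotypeTable(ids, lociA, copies[ped.focal],
                         np.asarray([class_name] * n, dtype=object),
                         np.asarray([eco] * n, dtype=object))


def apply_missingness(gt: GenotypeTable, rate: float,
                      rng: np.random.Generator) -> GenotypeTable:
    """Set each call (both gene copies) missing independently with ``rate``."""
    calls = gt.calls.copy()
    drop = rng.random((gt.n_individuals, gt.n_loci)) < rate
    calls[drop] = MISSING
    return GenotypeTable(list(gt.individual_ids), list(gt.locus_names),
                         calls, gt.populations.copy(), gt.ecotypes.copy())


def apply_null_alleles(gt: GenotypeTable, null_freq: float,
                       rng: np.random.Generator,
                       loci: list[str] | None = None) -> GenotypeTable:
    """Corrupt calls with a segregating null allele at ``null_freq``.

    Each gene copy is independently a null with probability ``null_freq``
    (Hardy-Weinberg for the null).  Null homozygotes fail to amplify and
    become missing; null heterozygotes amplify only the visible copy and
    are recorded as homozygous for it.
    """
    calls = gt.calls.copy()
    cols = (range(gt.n_loci) if loci is None
            else [gt.locus_names.index(l) for l in loci])
    for j in cols:
        is_null = rng.random((gt.n_individuals, 2)) < null_freq
        typed = calls[:, j, 0] != MISSING
        both = is_null.all(axis=1) & typed
        calls[both, j, :] = MISSING
        for k in range(2):
            one = is_null[:, k] & ~is_null[:, 1 - k] & typed
            calls[one, j, k] = calls[one, j, 1 - k]
    return GenotypeTable(list(gt.individual_ids), list(gt.locus_names),
                         calls, gt.populations.copy(), gt.ecotypes.copy())


def build_evaluation_datasets(pools: tuple[AlleleFreqTable, AlleleFreqTable],
                              cfg: SimConfig,
                              ) -> list[GenotypeTable]:
    """The assignment-evaluation design: replicate truth-labelled datasets.

    Each of ``cfg.n_datasets`` datasets holds ``cfg.n_per_class`` simulated
    individuals of every class in ``cfg.class_set`` (population label = true
    class), with optional missingness and null-allele corruption applied
    after simulation.
    """
    pA, pB = pools
    classes = standard_class_sets(cfg.class_set)
    rng = cfg.rng()
    datasets = []
    for d in range(cfg.n_datasets):
        parts = [
            simulate_class(pA, pB, ped, cfg.n_per_class, rng,
                           class_name=name,
                           id_prefix=f"d{d + 1}_{name}")
            for name, ped in classes
        ]
        gt = GenotypeTable.concatenate(parts)
        if cfg.null_allele_freq > 0:
            gt = apply_null_alleles(gt, cfg.null_allele_freq, rng)
        if cfg.missing_rate > 0:
            gt = apply_missingness(gt, cfg.missing_rate, rng)
        datasets.append(gt)
    return datasets
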