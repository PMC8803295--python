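"""Genotype data model and readers/writers.

Diploid, codominant, multiallelic genotypes (microsatellites) for a set of
individuals typed at a common panel of loci, with per-individual population
and ecotype labels.  Supported interchange formats are GenePop 4.x text files
and a flat CSV genotype table; allele codes are opaque positive integers
(typically fragment sizes) and are never binned or reinterpreted here.

Missingness is per individual x locus: either both gene copies are present
or both are absent.  All downstream statistics use complete cases per locus.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hybkit")

ECOTYPES = ("savanna", "forest", "unknown")

#: sentinel allele code for a missing gene copy
MISSING = -1


class GenePopParseError(ValueError):
    """Raised when a GenePop file cannot be decoded."""


@dataclass
class GenotypeTable:
    """Diploid multiallelic genotypes for individuals x loci.

    Parameters
    ----------
    individual_ids : list of str
        Unique labels, one per row of ``calls``.
    locus_names : list of str
        Unique locus labels, one per column of ``calls``.
    calls : ndarray of shape (n_individuals, n_loci, 2), int
        Unordered allele pairs; both entries equal :data:`MISSING` at a
        missing call.  Allele codes are positive integers.
    populations : ndarray of str, shape (n_individuals,)
        Population label of each individual.
    ecotypes : ndarray of str, shape (n_individuals,)
        One of ``savanna``, ``forest`` or ``unknown``.
    """

    individual_ids: list[str]
    locus_names: list[str]
    calls: np.ndarray
    populations: np.ndarray
    ecotypes: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        self.populations = np.asarray(self.populations, dtype=object)
        self.ecotypes = np.asarray(self.ecotypes, dtype=object)
        n, L = len(self.individual_ids), len(self.locus_names)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids are not unique")
        if len(set(self.locus_names)) != L:
            raise ValueError("locus names are not unique")
        miss = self.calls == MISSING
        if np.any(miss[..., 0] != miss[..., 1]):
            raise ValueError("half-missing calls: both copies of a call "
                             "must be missing together")
        if np.any((self.calls <= 0) & ~miss):
            raise ValueError("allele codes must be positive integers")
        bad = set(self.ecotypes) - set(ECOTYPES)
        if bad:
            raise ValueError(f"unknown ecotype labels: {sorted(bad)}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the call is missing."""
        return self.calls[..., 0] == MISSING

    def population_of(self, individual: str) -> str:
        return str(self.populations[self.individual_ids.index(individual)])

    def ecotype_of(self, individual: str) -> str:
        return str(self.ecotypes[self.individual_ids.index(individual)])

    def subset(self, indices: Sequence[int] | np.ndarray) -> "GenotypeTable":
        idx = np.asarray(indices)
        return GenotypeTable(
            [self.individual_ids[i] for i in idx],
            list(self.locus_names),
            self.calls[idx].copy(),
            self.populations[idx].copy(),
            self.ecotypes[idx].copy(),
        )

    def group_labels(self, grouping) -> np.ndarray:
        """Resolve a grouping spec to one label per individual.

        ``grouping`` may be ``"population"``, ``"ecotype"``, a mapping from
        individual id to group label, or a sequence of per-individual labels.
        """
        if isinstance(grouping, str):
            if grouping == "population":
                return self.populations.copy()
            if grouping == "ecotype":
                return self.ecotypes.copy()
            raise ValueError(f"unknown grouping {grouping!r}")
        if isinstance(grouping, Mapping):
            missing = [i for i in self.individual_ids if i not in grouping]
            if missing:
                raise ValueError(f"grouping does not cover: {missing[:5]}")
            return np.asarray([grouping[i] for i in self.individual_ids],
                              dtype=object)
        arr = np.asarray(list(grouping), dtype=object)
        if arr.shape != (self.n_individuals,):
            raise ValueError("grouping length mismatch")
        return arr

    @staticmethod
    def concatenate(tables: Sequence["GenotypeTable"]) -> "GenotypeTable":
        """Stack tables that share the same locus panel."""
        loci = tables[0].locus_names
        for t in tables[1:]:
            if t.locus_names != loci:
                raise ValueError("locus panels differ between tables")
        return GenotypeTable(
            [i for t in tables for i in t.individual_ids],
            list(loci),
            np.concatenate([t.calls for t in tables], axis=0),
            np.concatenate([t.populations for t in tables]),
            np.concatenate([t.ecotypes for t in tables]),
        )


@dataclass
class AlleleFreqTable:
    """Per-group, per-locus allele frequency distributions.

    ``freqs[(group, locus)]`` maps allele code -> relative frequency; the
    pair is absent when the group has no typed copies at that locus (flagged
    undefined rather than zero-filled).  ``gene_copies[(group, locus)]`` is
    the number of non-missing gene copies behind each distribution.
    """

    groups: list[str]
    locus_names: list[str]
    freqs: dict[tuple[str, str], dict[int, float]] = field(default_factory=dict)
    gene_copies: dict[tuple[str, str], int] = field(default_factory=dict)

    def frequency(self, group: str, locus: str, allele: int) -> float:
        return self.freqs.get((group, locus), {}).get(allele, 0.0)

    def defined(self, group: str, locus: str) -> bool:
        return (group, locus) in self.freqs

    def slice(self, group: str) -> dict[str, dict[int, float]]:
        """Per-locus frequency mapping for one group."""
        return {loc: self.freqs[(group, loc)] for loc in self.locus_names
                if (group, loc) in self.freqs}


# ---------------------------------------------------------------------------
# GenePop format
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def _decode_call(token: str, lineno: int) -> tuple[int, int, int]:
    """Decode one GenePop call string -> (a1, a2, digit width)."""
    if not token.isdigit() or len(token) not in (4, 6):
        raise GenePopParseError(
            f"line {lineno}: malformed genotype token {token!r} "
            "(expected 4 or 6 digits)")
    w = len(token) // 2
    a1, a2 = int(token[:w]), int(token[w:])
    if a1 == 0:
        a1 = MISSING
    if a2 == 0:
        a2 = MISSING
    # GenePop allows half-missing; collapse to fully missing per data model
    if MISSING in (a1, a2):
        a1 = a2 = MISSING
    return a1, a2, w


def read_genepop(path: str | Path) -> GenotypeTable:
    """Read a GenePop 4.x file into a :class:`GenotypeTable`.

    The title line is ignored; locus names may be one per line or
    comma-separated on one line; ``POP`` lines delimit populations, which are
    labelled ``pop1``, ``pop2``, ... in file order (attach real labels with
    :func:`read_sample_sheet`).  2- vs 3-digit allele coding is auto-detected
    per file; mixed widths within a locus are rejected.  ``00``/``000`` codes
    a missing copy; a half-missing call is treated as fully missing.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenePopParseError("empty file")
    # locus names: lines after the title until the first POP
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            loci.extend(t.strip() for t in chunk.split(",") if t.strip())
        i += 1
    if i == len(lines):
        raise GenePopParseError("no POP line found")
    if not loci:
        raise GenePopParseError("no locus names before first POP")

    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[int]] = []
    widths: dict[int, int] = {}          # locus index -> digit width
    pop_idx = 0
    for lineno0 in range(i, len(lines)):
        line = lines[lineno0]
        lineno = lineno0 + 1
        if _POP_RE.match(line):
            pop_idx += 1
            continue
        if not line.strip():
            continue
        if "," not in line:
            raise GenePopParseError(
                f"line {lineno}: expected 'id , genotypes' (no comma found)")
        name, _, geno = line.partition(",")
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenePopParseError(
                f"line {lineno}: {len(tokens)} genotypes for "
                f"{len(loci)} loci")
        row: list[int] = []
        for j, tok in enumerate(tokens):
            a1, a2, w = _decode_call(tok, lineno)
            if widths.setdefault(j, w) != w:
                raise GenePopParseError(
                    f"line {lineno}: inconsistent allele-code width at "
                    f"locus {loci[j]!r}")
            row.extend((a1, a2))
        ids.append(name.strip())
        pops.append(f"pop{pop_idx}")
        rows.append(row)
    if not ids:
        raise GenePopParseError("zero individuals in file")

    # de-duplicate ids with a documented numeric suffix rule
    seen: dict[str, int] = {}
    uniq: list[str] = []
    for name in ids:
        if name in seen:
            seen[name] += 1
            new = f"{name}.{seen[name]}"
            logger.warning("duplicate individual id %r renamed to %r",
                           name, new)
            uniq.append(new)
        else:
            seen[name] = 0
            uniq.append(name)

    calls = np.asarray(rows, dtype=np.int64).reshape(len(ids), len(loci), 2)
    return GenotypeTable(uniq, loci, calls,
                         np.asarray(pops, dtype=object),
                         np.asarray(["unknown"] * len(ids), dtype=object))


def write_genepop(gt: GenotypeTable, path: str | Path,
                  title: str = "hybkit export") -> None:
    """Write a GenePop file (3-digit coding, populations as POP blocks)."""
    if int(np.max(gt.calls, initial=0)) > 999:
        raise ValueError("allele codes exceed 3-digit GenePop coding")
    out = [title]
    out.extend(gt.locus_names)
    # preserve first-appearance order of population labels
    order: list[str] = []
    for p in gt.populations:
        if p not in order:
            order.append(p)
    for pop in order:
        out.append("POP")
        for i in np.flatnonzero(gt.populations == pop):
            toks = []
            for j in range(gt.n_loci):
                a1, a2 = gt.calls[i, j]
                a1 = 0 if a1 == MISSING else a1
                a2 = 0 if a2 == MISSING else a2
                toks.append(f"{a1:03d}{a2:03d}")
            out.append(f"{gt.individual_ids[i]} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# CSV genotype table
# ---------------------------------------------------------------------------

def read_genotype_csv(path: str | Path) -> GenotypeTable:
    """Read a CSV with columns individual, population, ecotype, then one
    column per locus holding ``a1/a2`` calls (``NA`` or empty = missing)."""
    df = pd.read_csv(path, dtype=str).fillna("NA")
    required = ["individual", "population", "ecotype"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    loci = [c for c in df.columns if c not in required]
    calls = np.full((len(df), len(loci), 2), MISSING, dtype=np.int64)
    for j, loc in enumerate(loci):
        for i, cell in enumerate(df[loc]):
            cell = cell.strip()
            if cell in ("NA", "", "./."):
                continue
            a1, _, a2 = cell.partition("/")
            calls[i, j] = (int(a1), int(a2))
    eco = df["ecotype"].str.strip().replace({"NA": "unknown"})
    return GenotypeTable(list(df["individual"]), loci, calls,
                         df["population"].to_numpy(dtype=object),
                         eco.to_numpy(dtype=object))


def write_genotype_csv(gt: GenotypeTable, path: str | Path) -> None:
    cols: dict[str, list] = {
        "individual": gt.individual_ids,
        "population": list(gt.populations),
        "ecotype": list(gt.ecotypes),
    }
    for j, loc in enumerate(gt.locus_names):
        col = []
        for i in range(gt.n_individuals):
            a1, a2 = gt.calls[i, j]
            col.append("NA" if a1 == MISSING else f"{a1}/{a2}")
        cols[loc] = col
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path, gt: GenotypeTable,
                      ) -> tuple[GenotypeTable, dict[str, list[str]]]:
    """Attach population/ecotype labels from a delimited sample sheet.

    The sheet has columns ``individual``, ``population``, ``ecotype`` and
    optionally ``latitude``/``longitude`` (delimiter sniffed from ',' / tab /
    whitespace).  Returns a relabelled copy of ``gt`` plus a discrepancy
    report with keys ``not_genotyped`` (in sheet only) and ``not_in_sheet``
    (genotyped individuals absent from the sheet, which keep ecotype
    ``unknown``).
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    for col in ("individual", "population", "ecotype"):
        if col not in df.columns:
            raise ValueError(f"sample sheet lacks column {col!r}")
    if df["individual"].duplicated().any():
        dups = sorted(df["individual"][df["individual"].duplicated()])
        raise ValueError(f"duplicate individual rows in sheet: {dups}")
    bad = set(df["ecotype"].str.strip()) - set(ECOTYPES)
    if bad:
        raise ValueError(
            f"unknown ecotype tokens {sorted(bad)}; allowed: {ECOTYPES}")

    sheet = {r.individual: (r.population.strip(), r.ecotype.strip())
             for r in df.itertuples()}
    pops = gt.populations.copy()
    ecos = gt.ecotypes.copy()
    not_in_sheet = []
    for i, ind in enumerate(gt.individual_ids):
        if ind in sheet:
            pops[i], ecos[i] = sheet[ind]
        else:
            not_in_sheet.append(ind)
            logger.warning("individual %r not in sample sheet; ecotype "
                           "stays 'unknown'", ind)
    not_genotyped = [i for i in sheet if i not in set(gt.individual_ids)]
    report = {"not_genotyped": not_genotyped, "not_in_sheet": not_in_sheet}
    new = GenotypeTable(list(gt.individual_ids), list(gt.locus_names),
                        gt.calls.copy(), pops, ecos)
    return new, report


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(gt: GenotypeTable, grouping="population",
                       ) -> AlleleFreqTable:
    """Observed allele frequencies per group x locus.

    Frequencies are allele counts over non-missing gene copies.  A group x
    locus with no typed copies is left undefined (absent from the table)
    rather than zero-filled.
    """
    labels = gt.group_labels(grouping)
    groups = list(dict.fromkeys(labels))     # first-appearance order
    for g in groups:
        if not np.any(labels == g):          # pragma: no cover - defensive
            raise ValueError(f"empty group {g!r}")
    table = AlleleFreqTable(groups, list(gt.locus_names))
    for g in groups:
        rows = gt.calls[labels == g]         # (n_g, L, 2)
        for j, loc in enumerate(gt.locus_names):
            copies = rows[:, j, :].ravel()
            copies = copies[copies != MISSING]
            if copies.size == 0:
                continue
            vals, counts = np.unique(copies, return_counts=True)
            table.freqs[(g, loc)] = {
                int(a): c / copies.size for a, c in zip(vals, counts)}
            table.gene_copies[(g, loc)] = int(copies.size)
    return table
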