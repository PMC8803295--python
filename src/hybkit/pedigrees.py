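"""Pedigree-defined genotypic classes and their exact ancestry profiles.

A hybrid *genotypic class* (P1, P2, F1, F2, backcrosses B1-B8, F3, F4) is
defined by an explicit cross pedigree whose founders are drawn from one of
two parental gene pools, A (savanna) and B (forest).  Each class is fully
characterised, per locus, by its genotype-frequency-class profile

    phi = (phi2, phi1, phi0)

the probabilities that the focal individual carries 2, 1 or 0 gene copies of
A ancestry at a locus.  Profiles are computed exactly in rational arithmetic
by gamete recursion and are the parameters of the Bayesian class posterior.

Under this per-locus-independent model several classes are confounded:
{B1, B3}, {B5, B7}, {B6, B8} and {F2, F3, F4} share identical profiles,
which is the mechanistic reason backcross resolution collapses in the
12-class analysis.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from fractions import Fraction

import numpy as np


class PedigreeError(ValueError):
    """Structural problem with a pedigree definition."""


@dataclass(frozen=True)
class Pedigree:
    """An explicit cross pedigree.

    ``founders`` maps founder node label -> pool tag ``"A"`` or ``"B"``;
    ``crosses`` maps non-founder label -> (parent1, parent2); ``focal`` is
    the node whose offspring-class profile is sought.
    """

    founders: tuple[tuple[str, str], ...]
    crosses: tuple[tuple[str, tuple[str, str]], ...]
    focal: str

    @staticmethod
    def build(founders: dict[str, str], crosses: dict[str, tuple[str, str]],
              focal: str) -> "Pedigree":
        ped = Pedigree(tuple(sorted(founders.items())),
                       tuple(crosses.items()), focal)
        ped.validate()
        return ped

    @property
    def founder_map(self) -> dict[str, str]:
        return dict(self.founders)

    @property
    def cross_map(self) -> dict[str, tuple[str, str]]:
        return dict(self.crosses)

    def validate(self) -> None:
        founders = self.founder_map
        crosses = self.cross_map
        for tag in founders.values():
            if tag not in ("A", "B"):
                raise PedigreeError(f"founder pool tag must be A or B, "
                                    f"got {tag!r}")
        overlap = set(founders) & set(crosses)
        if overlap:
            raise PedigreeError(f"nodes both founder and cross: {overlap}")
        nodes = set(founders) | set(crosses)
        if self.focal not in nodes:
            raise PedigreeError(f"focal node {self.focal!r} undefined")
        for child, parents in crosses.items():
            if len(parents) != 2:
                raise PedigreeError(f"{child!r} needs exactly 2 parents")
            for p in parents:
                if p not in nodes:
                    raise PedigreeError(f"parent {p!r} of {child!r} undefined")
        # acyclicity via DFS
        state: dict[str, int] = {}

        def visit(n: str) -> None:
            if state.get(n) == 1:
                raise PedigreeError(f"pedigree cycle through {n!r}")
            if state.get(n) == 2:
                return
            state[n] = 1
            for p in crosses.get(n, ()):
                visit(p)
            state[n] = 2

        for n in nodes:
            visit(n)
        # the two parental lineages of the focal must not share any node;
        # this is what makes the two focal gametes independent
        if self.focal in crosses:
            p1, p2 = crosses[self.focal]
            if self.ancestors(p1) & self.ancestors(p2):
                raise PedigreeError(
                    "parental lineages of the focal individual share "
                    "ancestors; such inbred pedigrees are unsupported")

    def ancestors(self, node: str) -> set[str]:
        """``node`` and all its ancestors."""
        crosses = self.cross_map
        out: set[str] = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n in out:
                continue
            out.add(n)
            stack.extend(crosses.get(n, ()))
        return out

    def topological_order(self) -> list[str]:
        crosses = self.cross_map
        order: list[str] = []
        seen: set[str] = set()

        def visit(n: str) -> None:
            if n in seen:
                return
            for p in crosses.get(n, ()):
                visit(p)
            seen.add(n)
            order.append(n)

        for n in self.ancestors(self.focal):
            visit(n)
        return order


@dataclass(frozen=True)
class AncestryProfile:
    """phi = (phi2, phi1, phi0): exact per-locus A-ancestry distribution."""

    phi2: Fraction
    phi1: Fraction
    phi0: Fraction

    def __post_init__(self) -> None:
        total = self.phi2 + self.phi1 + self.phi0
        if total != 1:
            raise ValueError(f"profile sums to {total}, not 1")
        for p in (self.phi2, self.phi1, self.phi0):
            if not 0 <= p <= 1:
                raise ValueError("profile components must lie in [0, 1]")

    def as_floats(self) -> np.ndarray:
        """(phi2, phi1, phi0) as float64 — the classifier boundary."""
        return np.array([float(self.phi2), float(self.phi1),
                         float(self.phi0)])

    @property
    def expected_h(self) -> Fraction:
        """Expected B-pool ancestry proportion (hybrid-index scale)."""
        return self.phi0 + Fraction(1, 2) * self.phi1

    def swapped(self) -> "AncestryProfile":
        """Profile after exchanging the A and B parental labels."""
        return AncestryProfile(self.phi0, self.phi1, self.phi2)


def gamete_a_probability(ped: Pedigree, node: str | None = None) -> Fraction:
    """P(a random gamete from ``node`` carries A ancestry), exact."""
    node = ped.focal if node is None else node
    founders = ped.founder_map
    crosses = ped.cross_map
    cache: dict[str, Fraction] = {}

    def g(n: str) -> Fraction:
        if n in cache:
            return cache[n]
        if n in founders:
            val = Fraction(1) if founders[n] == "A" else Fraction(0)
        else:
            p1, p2 = crosses[n]
            val = (g(p1) + g(p2)) / 2
        cache[n] = val
        return val

    return g(node)


def expected_ancestry_profile(ped: Pedigree) -> AncestryProfile:
    """Exact phi for the focal individual of a pedigree.

    The focal's two gametes come from its two parents; since supported
    pedigrees forbid shared ancestry between the parental lineages, the two
    gametes are independent and phi factorises through the per-parent
    gamete-A probabilities.  A founder focal is a pure pool draw.
    """
    ped.validate()
    crosses = ped.cross_map
    if ped.focal in ped.founder_map:
        pure_a = ped.founder_map[ped.focal] == "A"
        one = Fraction(1)
        zero = Fraction(0)
        return (AncestryProfile(one, zero, zero) if pure_a
                else AncestryProfile(zero, zero, one))
    p1, p2 = crosses[ped.focal]
    g1 = gamete_a_probability(ped, p1)
    g2 = gamete_a_probability(ped, p2)
    return AncestryProfile(
        g1 * g2,
        g1 * (1 - g2) + (1 - g1) * g2,
        (1 - g1) * (1 - g2),
    )


def gene_drop_ancestry(ped: Pedigree, n: int, rng: np.random.Generator,
                       ) -> np.ndarray:
    """Monte-Carlo check of phi: drop ancestry tags through the pedigree.

    Returns length-3 array of observed frequencies of (2, 1, 0) focal
    A-copies over ``n`` independent replicates.  Independent of the exact
    recursion; used as its oracle.
    """
    founders = ped.founder_map
    crosses = ped.cross_map
    # copies[node] : (n, 2) boolean, True = A ancestry
    copies: dict[str, np.ndarray] = {}
    for node in ped.topological_order():
        if node in founders:
            val = founders[node] == "A"
            copies[node] = np.full((n, 2), val, dtype=bool)
        else:
            p1, p2 = crosses[node]
            pick1 = rng.integers(0, 2, size=n)
            pick2 = rng.integers(0, 2, size=n)
            copies[node] = np.stack(
                [copies[p1][np.arange(n), pick1],
                 copies[p2][np.arange(n), pick2]], axis=1)
    n_a = copies[ped.focal].sum(axis=1)
    return np.array([(n_a == 2).mean(), (n_a == 1).mean(),
                     (n_a == 0).mean()])


# ---------------------------------------------------------------------------
# Cross-definition DSL and the standard class sets
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|x|[A-Za-z0-9_]+")

#: cross expressions of the named classes over pool terminals A and B
CLASS_EXPRESSIONS: dict[str, str] = {
    "P1": "A",
    "P2": "B",
    "F1": "A x B",
    "F2": "F1 x F1",
    "B1": "F1 x A",            # backcross of F1 to savanna
    "B2": "F1 x B",            # backcross of F1 to forest
    "B3": "F2 x A",
    "B4": "F2 x B",
    "B5": "A x (F1 x A)",
    "B6": "B x (F1 x B)",
    "B7": "A x (F2 x A)",
    "B8": "B x (F2 x B)",
    "F3": "F2 x F2",
    "F4": "F3 x F3",
}

_SET_ORDER = {
    # parentals first (also the documented tie-break order), then early
    # hybrids, then backcrosses in numeric order
    "six": ["P1", "P2", "F1", "F2", "B1", "B2"],
    "twelve": ["P1", "P2", "F1", "F2", "B1", "B2",
               "B3", "B4", "B5", "B6", "B7", "B8"],
    "fourteen": ["P1", "P2", "F1", "F2", "F3", "F4", "B1", "B2",
                 "B3", "B4", "B5", "B6", "B7", "B8"],
}

#: class groups with identical phi under the per-locus-independent model;
#: {B2, B4} mirrors {B1, B3} on the forest side
CONFOUNDED_GROUPS: tuple[frozenset[str], ...] = (
    frozenset({"B1", "B3"}),
    frozenset({"B2", "B4"}),
    frozenset({"B5", "B7"}),
    frozenset({"B6", "B8"}),
    frozenset({"F2", "F3", "F4"}),
)


def parse_cross(expression: str, name: str = "focal",
                registry: dict[str, str] | None = None) -> Pedigree:
    """Parse a cross expression like ``"A x (F1 x A)"`` into a Pedigree.

    Terminals are the pool symbols ``A`` and ``B`` (each occurrence a fresh
    founder) and any class name from ``registry`` (default: the standard
    classes), which expands recursively with fresh founders, so repeated
    names denote distinct individuals.
    """
    registry = CLASS_EXPRESSIONS if registry is None else registry
    tokens = _TOKEN_RE.findall(expression)
    if "".join(tokens).replace(" ", "") != expression.replace(" ", ""):
        raise PedigreeError(f"cannot tokenise cross {expression!r}")
    founders: dict[str, str] = {}
    crosses: dict[str, tuple[str, str]] = {}
    counter = itertools.count()

    def fresh(prefix: str) -> str:
        return f"{prefix}#{next(counter)}"

    pos = 0

    def parse_term() -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise PedigreeError(f"truncated cross {expression!r}")
        tok = tokens[pos]
        if tok == "(":
            pos += 1
            node = parse_expr()
            if pos >= len(tokens) or tokens[pos] != ")":
                raise PedigreeError(f"unbalanced parentheses in "
                                    f"{expression!r}")
            pos += 1
            return node
        pos += 1
        if tok in ("A", "B"):
            node = fresh(tok)
            founders[node] = tok
            return node
        if tok in registry:
            sub = parse_cross(registry[tok], tok, registry)
            rename = {n: fresh(n) for n in
                      set(sub.founder_map) | set(sub.cross_map)}
            founders.update({rename[n]: t
                             for n, t in sub.founder_map.items()})
            crosses.update({rename[c]: (rename[p1], rename[p2])
                            for c, (p1, p2) in sub.cross_map.items()})
            return rename[sub.focal]
        raise PedigreeError(f"unknown symbol {tok!r} in {expression!r}")

    def parse_expr() -> str:
        nonlocal pos
        left = parse_term()
        while pos < len(tokens) and tokens[pos] == "x":
            pos += 1
            right = parse_term()
            node = fresh("cross")
            crosses[node] = (left, right)
            left = node
        return left

    focal = parse_expr()
    if pos != len(tokens):
        raise PedigreeError(f"trailing tokens in cross {expression!r}")
    ped = Pedigree.build(founders, crosses, focal)
    return ped


def standard_class_sets(which: str) -> list[tuple[str, Pedigree]]:
    """The six-, twelve- or fourteen-class sets as (name, pedigree) pairs.

    six = {P1, P2, F1, F2, B1, B2}; twelve adds B3-B8; fourteen adds F3, F4.
    Order is fixed: parentals, then F-generation hybrids, then backcrosses.
    """
    if which not in _SET_ORDER:
        raise ValueError(f"class set must be one of {sorted(_SET_ORDER)}, "
                         f"got {which!r}")
    return [(name, parse_cross(CLASS_EXPRESSIONS[name], name))
            for name in _SET_ORDER[which]]


def class_profiles(which: str) -> list[tuple[str, AncestryProfile]]:
    """Names and exact phi profiles for a standard class set."""
    return [(name, expected_ancestry_profile(ped))
            for name, ped in standard_class_sets(which)]


def profiles_to_tsv(profiles: list[tuple[str, AncestryProfile]]) -> str:
    """Serialise a class set's phi values as TSV (exact rationals)."""
    lines = ["class\tphi2\tphi1\tphi0"]
    for name, prof in profiles:
        lines.append(f"{name}\t{prof.phi2}\t{prof.phi1}\t{prof.phi0}")
    return "\n".join(lines) + "\n"
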