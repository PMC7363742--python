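"""Generalized kinship coefficients over up to four sampled alleles.

A *sampling pattern* is one or two groups of member ids (a multiset; the
same member may appear several times, also across groups).  One allele is
sampled independently and uniformly per slot; the pattern's coefficient is
the probability that within each group all sampled alleles are IBD.  With
two groups of two this yields the doubly-grouped coefficients
``phi_ab,cd``; single groups give ``phi_ab``, ``phi_abc``, ``phi_abcd``.

Evaluation is recursive.  The pivot is the pattern member of maximal
generation index (ties broken by smallest id), which guarantees the other
members are nondescendants of it.  For a nonfounder pivot, each of its
sampled slots independently received the pivot's paternal allele (a random
allele of the father p) or maternal allele (of the mother m), with
probability 1/2 each.  Conditioning on that assignment replaces the
pivot's slots by at most one p-slot and one m-slot per group; when both
groups end up referring to the *same* physical parental allele, their IBD
constraints merge into a single group.  Averaging over the 2^k assignments
reproduces Karigl's twelve recursion rules, including the repeated-argument
instantiations.

At an all-founder pattern the boundary values apply: any group containing
two distinct founders has probability 0 (founders unrelated); a group of
k slots of one founder with inbreeding f contributes 1, (1+f)/2,
(1+3f)/4, (1+7f)/8 for k = 1..4; two groups drawn from the same founder
(necessarily sizes 2+2) give (1+3f)/4; groups on distinct founders
multiply.  With all f = 0 these reduce to the classical outbred values.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product
from numbers import Real
from typing import Iterable, Sequence

from .pedigree import Pedigree, PedigreeError, generation_index

__all__ = ["canonicalize_pattern", "generalized_kinship", "MAX_ALLELES"]

MAX_ALLELES = 4

Pattern = tuple[tuple[str, ...], ...]


def _as_groups(pattern: Iterable) -> tuple[tuple[str, ...], ...]:
    groups = list(pattern)
    if groups and all(isinstance(g, str) for g in groups):
        groups = [tuple(groups)]  # a flat sequence of ids is one group
    return tuple(tuple(g) for g in groups)


def canonicalize_pattern(pattern: Iterable) -> Pattern:
    """Canonical representative of a sampling pattern.

    Ids are sorted within groups, groups sorted lexicographically, and
    vacuous groups (size <= 1: a single allele is trivially IBD with
    itself) are dropped.  All permutation-equivalent patterns map to the
    same canonical key; the empty pattern has coefficient 1.
    """
    groups = _as_groups(pattern)
    if len(groups) > 2:
        raise PedigreeError("sampling patterns have at most two groups")
    total = sum(len(g) for g in groups)
    if total > MAX_ALLELES:
        raise PedigreeError(f"sampling pattern has {total} slots; at most {MAX_ALLELES}")
    kept = sorted(tuple(sorted(g)) for g in groups if len(g) > 1)
    return tuple(kept)


def generalized_kinship(ped: Pedigree, pattern: Iterable) -> Real:
    """Exact generalized kinship coefficient of ``pattern`` in ``ped``."""
    canonical = canonicalize_pattern(pattern)
    for g in canonical:
        for mid in g:
            ped.member(mid)
    gen = generation_index(ped)
    return _phi(ped, canonical, gen, ped.cache("generalized_kinship"))


def _phi(ped: Pedigree, pattern: Pattern, gen, memo) -> Real:
    if not pattern:
        return Fraction(1)
    try:
        return memo[pattern]
    except KeyError:
        pass
    members = {mid for g in pattern for mid in g}
    top = max(gen[mid] for mid in members)
    if top == 0:
        value = _founder_boundary(ped, pattern)
    else:
        pivot = min(mid for mid in members if gen[mid] == top)
        value = _expand_pivot(ped, pattern, pivot, gen, memo)
    memo[pattern] = value
    return value


def _expand_pivot(ped: Pedigree, pattern: Pattern, pivot: str, gen, memo) -> Real:
    p, m = ped.parents(pivot)
    rests = [[mid for mid in g if mid != pivot] for g in pattern]
    counts = [len(g) - len(r) for g, r in zip(pattern, rests)]
    k = sum(counts)
    total: Real = Fraction(0)
    weight = Fraction(1, 2**k)
    for sigma in product("xy", repeat=k):
        # Slots of the pivot receive its paternal (x) or maternal (y) allele.
        sets = []
        pos = 0
        for c in counts:
            sets.append(frozenset(sigma[pos : pos + c]))
            pos += c
        subst = {"x": p, "y": m}
        if len(sets) == 2 and (sets[0] & sets[1]):
            # The same physical allele is constrained by both groups: the
            # two IBD constraints merge into one.
            merged = rests[0] + rests[1] + [subst[s] for s in sorted(sets[0] | sets[1])]
            new_groups = [merged]
        else:
            new_groups = [
                rest + [subst[s] for s in sorted(s_i)] for rest, s_i in zip(rests, sets)
            ]
        total += weight * _phi(ped, canonicalize_pattern(new_groups), gen, memo)
    return total


def _founder_boundary(ped: Pedigree, pattern: Pattern) -> Real:
    per_group_founder = []
    for g in pattern:
        distinct = set(g)
        if len(distinct) > 1:
            return Fraction(0)  # two distinct founders can never be IBD
        per_group_founder.append(next(iter(distinct)))
    if len(pattern) == 2 and per_group_founder[0] == per_group_founder[1]:
        # Both groups sample the same founder; sizes are necessarily (2, 2).
        f = ped.founder_f(per_group_founder[0])
        return Fraction(1, 4) * (1 + 3 * f)
    value: Real = Fraction(1)
    for g, fid in zip(pattern, per_group_founder):
        f = ped.founder_f(fid)
        k = len(g)
        if k == 2:
            value *= Fraction(1, 2) * (1 + f)
        elif k == 3:
            value *= Fraction(1, 4) * (1 + 3 * f)
        else:  # k == 4
            value *= Fraction(1, 8) * (1 + 7 * f)
    return value
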