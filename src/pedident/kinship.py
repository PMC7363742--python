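"""Pairwise kinship and inbreeding coefficients under founder inbreeding.

The kinship coefficient ``phi_ab`` is the probability that one allele
sampled at random from ``a`` and one from ``b`` (same autosomal locus) are
identical by descent within the pedigree.  The recursion is the classical
one, with the single modification that a founder's self-kinship is
``(1 + f) / 2`` where ``f`` is its assigned inbreeding coefficient.

Wright's path-counting formula is provided as an independent check:

    phi_ab = sum over common ancestors s, and non-overlapping path pairs
             (u, v) from s down to a and b, of (1 + f_s) / 2^(|u| + |v| + 1)

Results are exact :class:`~fractions.Fraction` values whenever all founder
coefficients are rational.
"""

from __future__ import annotations

from fractions import Fraction
from numbers import Real

import networkx as nx

from .pedigree import Pedigree, PedigreeError, generation_index

__all__ = ["kinship", "inbreeding", "kinship_path_formula"]

_HALF = Fraction(1, 2)


def inbreeding(ped: Pedigree, a: str) -> Real:
    """Inbreeding coefficient: assigned ``f`` for founders, else kinship of the parents."""
    m = ped.member(a)
    if m.is_founder:
        return ped.founder_f(a)
    return kinship(ped, m.father_id, m.mother_id)


def kinship(ped: Pedigree, a: str, b: str) -> Real:
    """Kinship coefficient ``phi_ab``, memoized per pedigree instance."""
    ped.member(a), ped.member(b)
    return _kinship(ped, a, b, generation_index(ped), ped.cache("kinship"))


def _kinship(ped: Pedigree, a: str, b: str, gen, memo) -> Real:
    key = (a, b) if a <= b else (b, a)
    try:
        return memo[key]
    except KeyError:
        pass
    if a == b:
        value = _HALF * (1 + inbreeding(ped, a))
    else:
        # Pivot on the later-generation argument: it cannot be an ancestor
        # of the other, so conditioning on its parental transmissions is valid.
        if (gen[a], a) < (gen[b], b):
            a, b = b, a
        parents = ped.parents(a)
        if parents is None:
            value = Fraction(0)  # two distinct founders: unrelated by assumption
        else:
            p, m = parents
            value = _HALF * (_kinship(ped, p, b, gen, memo) + _kinship(ped, m, b, gen, memo))
    memo[key] = value
    return value


def kinship_path_formula(ped: Pedigree, a: str, b: str, max_members: int = 25) -> Real:
    """Evaluate Wright's path formula by exhaustive path enumeration.

    Only intended for small pedigrees (guarded by ``max_members``); serves
    as an independent oracle for :func:`kinship`.  Requires ``a != b``.
    """
    if a == b:
        raise PedigreeError("path formula requires two distinct individuals")
    ped.member(a), ped.member(b)
    if len(ped) > max_members:
        raise PedigreeError(
            f"pedigree has {len(ped)} members; path enumeration guarded at {max_members}"
        )
    g = ped.graph()
    anc_a = nx.ancestors(g, a) | {a}
    anc_b = nx.ancestors(g, b) | {b}
    total: Real = Fraction(0)
    for s in anc_a & anc_b:
        f_s = inbreeding(ped, s)
        paths_a = [[s]] if s == a else list(nx.all_simple_paths(g, s, a))
        paths_b = [[s]] if s == b else list(nx.all_simple_paths(g, s, b))
        for u in paths_a:
            mid_u = set(u[1:])
            for v in paths_b:
                if mid_u & set(v[1:]):
                    continue  # paths may share no member except s
                total += Fraction(1, 2 ** (len(u) + len(v) - 1)) * (1 + f_s)
    return total
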