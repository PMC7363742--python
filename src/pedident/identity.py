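"""Condensed identity coefficients (Jacquard's nine states) and IBD triples.

The nine condensed states classify the IBD pattern among the four alleles
of an ordered pair (a, b), with the two alleles within each individual
unordered.  In the standard (Jacquard) numbering:

  1  all four alleles IBD
  2  a autozygous, b autozygous, no sharing between a and b
  3  a autozygous, IBD with exactly one allele of b
  4  a autozygous, no sharing with b
  5  b autozygous, IBD with exactly one allele of a
  6  b autozygous, no sharing with a
  7  a, b not autozygous, sharing two IBD pairs
  8  a, b not autozygous, sharing exactly one IBD pair
  9  no IBD among the four alleles

The coefficients Delta_1..Delta_9 are the expected state frequencies.  They
are recovered by solving a fixed 9x9 linear system whose left-hand sides
are generalized kinship coefficients: the probability of each sampling
event, conditional on each state, is an elementary counting exercise, and
the resulting matrix is invertible.  For noninbred pairs the first six
states are impossible and (kappa0, kappa1, kappa2) = (Delta9, Delta8,
Delta7).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from numbers import Real
from typing import NamedTuple, Sequence

from .karigl import generalized_kinship
from .kinship import inbreeding, kinship
from .pedigree import Pedigree, PedigreeError

__all__ = [
    "IdentityCoefficients",
    "IBDTriple",
    "StateEquationSystem",
    "InadmissibleError",
    "InbredIndividualError",
    "CONDENSED_STATES",
    "identity_state_matrix",
    "condensed_identity",
    "ibd_triple",
    "is_admissible",
]

_FLOAT_TOL = 1e-12


class InadmissibleError(ValueError):
    """An IBD triple outside the admissible region of the IBD triangle."""


class InbredIndividualError(ValueError):
    """IBD (kappa) coefficients requested for a pair involving an inbred individual."""


# Representative allele partition of the slots (a1, a2, b1, b2) for each
# condensed state, in Jacquard's order.  Within-individual symmetry makes
# the representative choice immaterial for the sampling probabilities.
CONDENSED_STATES: tuple[tuple[frozenset, ...], ...] = tuple(
    tuple(frozenset(block) for block in blocks)
    for blocks in (
        ({"a1", "a2", "b1", "b2"},),
        ({"a1", "a2"}, {"b1", "b2"}),
        ({"a1", "a2", "b1"}, {"b2"}),
        ({"a1", "a2"}, {"b1"}, {"b2"}),
        ({"b1", "b2", "a1"}, {"a2"}),
        ({"b1", "b2"}, {"a1"}, {"a2"}),
        ({"a1", "b1"}, {"a2", "b2"}),
        ({"a1", "b1"}, {"a2"}, {"b2"}),
        ({"a1"}, {"a2"}, {"b1"}, {"b2"}),
    )
)

# The eight non-normalization statistics, as (label, sampling groups).
# 'f_a'/'f_b' are state marginals (autozygosity indicators) rather than
# sampling events; the remaining rows are generalized kinship patterns,
# each group listing which individual every slot is drawn from.
_ROW_SPECS: tuple[tuple[str, tuple[tuple[str, ...], ...] | None], ...] = (
    ("1", None),
    ("f_a", None),
    ("f_b", None),
    ("phi_ab", (("a", "b"),)),
    ("phi_aab", (("a", "a", "b"),)),
    ("phi_abb", (("a", "b", "b"),)),
    ("phi_aabb", (("a", "a", "b", "b"),)),
    ("phi_ab,ab", (("a", "b"), ("a", "b"))),
    ("phi_aa,bb", (("a", "a"), ("b", "b"))),
)


def _block_of(partition, slot):
    for block in partition:
        if slot in block:
            return block
    raise AssertionError(slot)


def _state_probability(partition, groups) -> Fraction:
    """P(sampling event | state), by exact enumeration of the slot draws."""
    slots = {"a": ("a1", "a2"), "b": ("b1", "b2")}
    draws = [slots[ind] for g in groups for ind in g]
    sizes = [len(g) for g in groups]
    n = len(draws)
    hits = 0
    for combo in product((0, 1), repeat=n):
        chosen = [draws[i][c] for i, c in enumerate(combo)]
        ok = True
        pos = 0
        for size in sizes:
            blocks = {_block_of(partition, s) for s in chosen[pos : pos + size]}
            pos += size
            if len(blocks) > 1:
                ok = False
                break
        hits += ok
    return Fraction(hits, 2**n)


@dataclass(frozen=True)
class StateEquationSystem:
    """The fixed 9x9 linear system linking Delta to generalized kinship."""

    row_labels: tuple[str, ...]
    matrix: tuple[tuple[Fraction, ...], ...]

    def inverse(self) -> tuple[tuple[Fraction, ...], ...]:
        return _matrix_inverse(self.matrix)

    def solve(self, rhs: Sequence[Real]) -> tuple[Real, ...]:
        inv = self.inverse()
        return tuple(sum(c * r for c, r in zip(row, rhs)) for row in inv)


_SYSTEM: StateEquationSystem | None = None
_INVERSE: tuple[tuple[Fraction, ...], ...] | None = None


def identity_state_matrix() -> StateEquationSystem:
    """Build (once) the coefficient matrix by conditioning on the nine states."""
    global _SYSTEM
    if _SYSTEM is not None:
        return _SYSTEM
    rows = []
    for label, groups in _ROW_SPECS:
        if label == "1":
            rows.append(tuple(Fraction(1) for _ in CONDENSED_STATES))
        elif label in ("f_a", "f_b"):
            s1, s2 = ("a1", "a2") if label == "f_a" else ("b1", "b2")
            rows.append(
                tuple(
                    Fraction(int(_block_of(st, s1) is _block_of(st, s2)))
                    for st in CONDENSED_STATES
                )
            )
        else:
            rows.append(tuple(_state_probability(st, groups) for st in CONDENSED_STATES))
    _SYSTEM = StateEquationSystem(tuple(l for l, _ in _ROW_SPECS), tuple(rows))
    return _SYSTEM


def _matrix_inverse(matrix) -> tuple[tuple[Fraction, ...], ...]:
    global _INVERSE
    if _INVERSE is not None:
        return _INVERSE
    import sympy

    m = sympy.Matrix([[sympy.Rational(x) for x in row] for row in matrix])
    inv = m.inv()
    _INVERSE = tuple(
        tuple(Fraction(int(inv[i, j].p), int(inv[i, j].q)) for j in range(9))
        for i in range(9)
    )
    return _INVERSE


@dataclass(frozen=True)
class IdentityCoefficients:
    """The nine condensed identity coefficients Delta_1..Delta_9."""

    deltas: tuple[Real, ...]

    def __post_init__(self):
        if len(self.deltas) != 9:
            raise ValueError("expected nine coefficients")

    def __getitem__(self, state: int) -> Real:
        """Delta_i with Jacquard's 1-based state numbering."""
        if not 1 <= state <= 9:
            raise IndexError("condensed states are numbered 1..9")
        return self.deltas[state - 1]

    def __iter__(self):
        return iter(self.deltas)


class IBDTriple(NamedTuple):
    """(kappa0, kappa1, kappa2) for a pair of noninbred individuals."""

    kappa0: Real
    kappa1: Real
    kappa2: Real


def condensed_identity(ped: Pedigree, a: str, b: str) -> IdentityCoefficients:
    """Delta_1..Delta_9 for (a, b); ``a == b`` is allowed.

    The eight generalized-kinship left-hand sides are evaluated by the
    recursive algorithm and the state system is solved exactly (rational
    founder inbreeding gives exact Fractions).  In float mode, negative
    values within -1e-12 are clamped to zero and the vector renormalized.
    """
    ped.member(a), ped.member(b)
    system = identity_state_matrix()
    rhs = [
        Fraction(1),
        inbreeding(ped, a),
        inbreeding(ped, b),
        kinship(ped, a, b),
        generalized_kinship(ped, [(a, a, b)]),
        generalized_kinship(ped, [(a, b, b)]),
        generalized_kinship(ped, [(a, a, b, b)]),
        generalized_kinship(ped, [(a, b), (a, b)]),
        generalized_kinship(ped, [(a, a), (b, b)]),
    ]
    deltas = list(system.solve(rhs))
    if any(isinstance(d, float) for d in deltas):
        for i, d in enumerate(deltas):
            if d < 0:
                if d < -_FLOAT_TOL:
                    raise ArithmeticError(
                        f"Delta_{i + 1} = {d} is negative beyond numerical tolerance"
                    )
                deltas[i] = 0.0
        total = sum(deltas)
        deltas = [d / total for d in deltas]
    return IdentityCoefficients(tuple(deltas))


def ibd_triple(ped: Pedigree, a: str, b: str) -> IBDTriple:
    """(kappa0, kappa1, kappa2) = (Delta9, Delta8, Delta7) for a noninbred pair."""
    for mid in (a, b):
        f = inbreeding(ped, mid)
        if f > _FLOAT_TOL:
            raise InbredIndividualError(
                f"member {mid} is inbred (f = {f}); kappa coefficients are "
                "defined only for noninbred individuals"
            )
    delta = condensed_identity(ped, a, b)
    return IBDTriple(delta[9], delta[8], delta[7])


def is_admissible(triple: Sequence[Real], tol: float = _FLOAT_TOL) -> bool:
    """Thompson's inequality kappa1^2 >= 4*kappa0*kappa2 (within ``tol``)."""
    k0, k1, k2 = triple
    return bool(k1 * k1 >= 4 * k0 * k2 - tol)
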