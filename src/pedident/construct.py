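"""Constructibility solvers: pedigrees realising prescribed coefficients.

Half cousins with separation ``m`` and founder inbreeding ``f`` (the pair
joined by a single non-collapsing path of ``m`` edges whose top member has
inbreeding ``f``) have kinship ``phi = (1 + f) / 2^(m+1)``.  Inverting this
map solves kinship constructibility in one step; a chain of outbred
half-cousin layers derived from the binary expansion of ``phi`` solves it
with outbred founders; and a double half cousin relationship (fathers half
cousins, mothers half cousins, the two sides unrelated) realises any
admissible IBD triple ``(kappa0, kappa1, kappa2)`` of a noninbred pair via

    kappa0 = (1 - phi1)(1 - phi2),   kappa2 = phi1 * phi2,

where ``phi1 <= phi2`` solve ``phi^2 - U*phi + kappa2 = 0`` with
``U = 1 + kappa2 - kappa0`` and discriminant ``D = U^2 - 4*kappa2 =
kappa1^2 - 4*kappa0*kappa2`` (nonnegative exactly on the admissible
region).  The induced subdivision of the IBD triangle into quadrilaterals
``V_{m,n}`` with vertices ``v_{i,j} = ((1 - 2^-i)(1 - 2^-j), 2^-i 2^-j)``
is also computed, together with the bilinear (barycentric) weights in the
founder-inbreeding parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from numbers import Real
from typing import Sequence

from .identity import IBDTriple, InadmissibleError, is_admissible
from .pedigree import FEMALE, MALE, Member, Pedigree, PedigreeError

__all__ = [
    "INFINITE",
    "HalfCousinSpec",
    "ChainSpec",
    "DHCSolution",
    "TrianglePoint",
    "TriangleRegion",
    "kinship_to_half_cousin",
    "build_half_cousin",
    "kinship_chain",
    "build_chain",
    "ibd_to_dhc",
    "build_dhc",
    "triangle_vertex",
    "triangle_regions",
    "stationary_inbreeding",
]

#: Sentinel separation for unrelated ("infinitely distant") half cousins.
INFINITE = math.inf

_TOL = 1e-12


@dataclass(frozen=True)
class HalfCousinSpec:
    """Half cousins with separation ``m`` and founder inbreeding ``f``."""

    m: Real  # nonnegative integer, or INFINITE
    founder_f: Real

    def kinship(self) -> Real:
        if self.m == INFINITE:
            return Fraction(0)
        return Fraction(1, 2 ** (int(self.m) + 1)) * (1 + self.founder_f)


@dataclass(frozen=True)
class ChainSpec:
    """Layer increments of a chained half-cousin construction.

    Layer ``i`` (from the bottom) is a half-cousin relationship with
    separation ``increments[i] - 1`` and outbred top member; the achieved
    kinship is ``sum 2^(-s_k)`` over the partial sums ``s_k``.  ``exact``
    is False when a non-dyadic target was truncated, in which case
    ``residual`` is the remainder.
    """

    increments: tuple[int, ...]
    exact: bool = True
    residual: Real = Fraction(0)

    def kinship(self) -> Real:
        total, s = Fraction(0), 0
        for t in self.increments:
            s += t
            total += Fraction(1, 2**s)
        return total


@dataclass(frozen=True)
class DHCSolution:
    """Double-half-cousin parameters realising a target IBD triple."""

    m: Real
    n: Real
    f1: Real
    f2: Real
    U: Real
    D: Real
    phi1: Real
    phi2: Real

    def kappa(self) -> IBDTriple:
        k0 = (1 - self.phi1) * (1 - self.phi2)
        k2 = self.phi1 * self.phi2
        return IBDTriple(k0, 1 - k0 - k2, k2)


class TrianglePoint(tuple):
    """A point (kappa0, kappa2) in the IBD triangle."""

    def __new__(cls, kappa0: Real, kappa2: Real):
        return super().__new__(cls, (kappa0, kappa2))

    @property
    def kappa0(self) -> Real:
        return self[0]

    @property
    def kappa2(self) -> Real:
        return self[1]


@dataclass(frozen=True)
class TriangleRegion:
    """Subdivision cell A_{m,n} containing a point, with its bilinear weights.

    ``vertices`` are (v_{m,n}, v_{m,n+1}, v_{m+1,n}, v_{m+1,n+1}) and
    ``weights`` the matching coefficients (f1*f2, f1*(1-f2), (1-f1)*f2,
    (1-f1)*(1-f2)), so that the weighted vertex sum reproduces the point.
    """

    m: Real
    n: Real
    vertices: tuple[TrianglePoint, TrianglePoint, TrianglePoint, TrianglePoint]
    weights: tuple[Real, Real, Real, Real]
    f1: Real
    f2: Real


# -- kinship -> half cousins ------------------------------------------


def _exact_fraction(phi: Real) -> Fraction:
    return phi if isinstance(phi, Fraction) else Fraction(phi)


def kinship_to_half_cousin(phi: Real, prefer_inbred: bool = False) -> HalfCousinSpec:
    """Invert ``phi = (1 + f) / 2^(m+1)``.

    ``m = ceil(log2(1/phi)) - 1`` and ``f = phi * 2^(m+1) - 1``; the
    endpoints map to ``(0, 1)`` for ``phi = 1`` and ``(INFINITE, 0)`` for
    ``phi = 0``.  For dyadic ``phi = 2^-k`` the natural output ``(k-1, 0)``
    is returned; ``prefer_inbred`` selects the equivalent completely inbred
    solution ``(k, 1)``.
    """
    if not 0 <= phi <= 1:
        raise ValueError(f"kinship coefficient {phi} outside [0, 1]")
    if phi == 0:
        return HalfCousinSpec(INFINITE, Fraction(0))
    if phi == 1:
        return HalfCousinSpec(0, Fraction(1))
    x = _exact_fraction(phi)
    # smallest t with 2^t * phi >= 1, so that m = t - 1 and f in [0, 1)
    t = 0
    scaled = x
    while scaled < 1:
        scaled *= 2
        t += 1
    m = t - 1
    f = x * 2 ** (m + 1) - 1
    if prefer_inbred and f == 0 and m >= 0:
        m, f = m + 1, Fraction(1)
    if not isinstance(phi, (Fraction, int)):
        f = float(f)
    return HalfCousinSpec(m, f)


class _Builder:
    """Incremental member list with unique ids."""

    def __init__(self, selfing_allowed: bool = False):
        self.members: list[Member] = []
        self.finb: dict[str, Real] = {}
        self.selfing_allowed = selfing_allowed

    def add(self, mid, father=None, mother=None, sex=0) -> str:
        self.members.append(Member(mid, father, mother, sex))
        return mid

    def pedigree(self) -> Pedigree:
        return Pedigree(
            self.members, founder_inbreeding=self.finb, selfing_allowed=self.selfing_allowed
        ).check()


def _grow_path(b: _Builder, top: str, length: int, sex: int, prefix: str) -> str:
    """Grow a descent path of ``length`` edges below ``top``; fresh mates each step."""
    current = top
    current_sex = next(m.sex for m in b.members if m.id == top)
    for i in range(length):
        if current_sex == FEMALE:
            mate = b.add(f"{prefix}S{i}", sex=MALE)
            father, mother = mate, current
        else:
            mate = b.add(f"{prefix}S{i}", sex=FEMALE)
            father, mother = current, mate
        current = b.add(f"{prefix}{i}", father, mother, sex=sex)
        current_sex = sex
    return current


def build_half_cousin(
    spec: HalfCousinSpec | Sequence[Real],
    focal_sex: int = MALE,
    prefix: str = "HC_",
) -> tuple[Pedigree, tuple[str, str]]:
    """Materialise a half-cousin relationship as an actual pedigree.

    The canonical shape splits the path as evenly as possible between the
    two sides (odd remainder to ``a``'s side).  ``m = 0`` yields the
    degenerate pair (a, a) on a single founder; ``m = INFINITE`` yields two
    unrelated founders.  Path members carry ``focal_sex`` so the focal pair
    can serve as the fathers (or mothers) of a larger construction.
    """
    if not isinstance(spec, HalfCousinSpec):
        spec = HalfCousinSpec(*spec)
    b = _Builder()
    if spec.m == INFINITE:
        a = b.add(f"{prefix}a", sex=focal_sex)
        bb = b.add(f"{prefix}b", sex=focal_sex)
        return b.pedigree(), (a, bb)
    m = int(spec.m)
    if m < 0:
        raise ValueError("separation must be nonnegative")
    top = b.add(f"{prefix}T", sex=focal_sex)
    if spec.founder_f:
        b.finb[top] = spec.founder_f
    if m == 0:
        return b.pedigree(), (top, top)
    la = (m + 1) // 2
    lb = m - la
    a = _grow_path(b, top, la, focal_sex, f"{prefix}A")
    bb = _grow_path(b, top, lb, focal_sex, f"{prefix}B") if lb else top
    return b.pedigree(), (a, bb)


# -- kinship -> finite chain ------------------------------------------


def kinship_chain(phi: Real, max_terms: int = 53) -> ChainSpec:
    """Increments of the binary-expansion exponents of ``phi``.

    A dyadic ``phi`` with at most ``max_terms`` one-bits is represented
    exactly; otherwise the expansion is truncated and the remainder is
    recorded in ``residual`` (bounded by ``2^-s_k``).
    """
    if not 0 < phi <= 1:
        raise ValueError(
            "kinship_chain requires 0 < phi <= 1 (phi = 0 is realised by "
            "infinitely distant half cousins)"
        )
    x = _exact_fraction(phi)
    exponents: list[int] = []
    k = 0
    while x > 0 and len(exponents) < max_terms:
        x *= 2
        k += 1
        if x >= 1:
            exponents.append(k)
            x -= 1
    residual = x / 2**k
    increments = [exponents[0]] + [
        b - a for a, b in zip(exponents, exponents[1:])
    ]
    if not isinstance(phi, (Fraction, int)):
        residual = float(residual)
    return ChainSpec(tuple(increments), exact=(residual == 0), residual=residual)


def build_chain(spec: ChainSpec) -> tuple[Pedigree, tuple[str, str]]:
    """Build the layered chain pedigree realising ``spec.kinship()``.

    Layer ``i`` (bottom = 1) is a half-cousin relationship with separation
    ``t_i - 1`` and outbred top; the top member of each layer is a child of
    the focal pair of the layer above.  Whenever some ``t_i = 1`` the layer
    collapses to a single individual and the construction requires selfing.
    """
    ts = spec.increments
    if not ts:
        raise ValueError("empty chain")
    needs_selfing = any(t == 1 for t in ts)
    b = _Builder(selfing_allowed=needs_selfing)
    k = len(ts)
    above: tuple[str, str] | None = None  # focal pair of the layer above
    for layer in range(k, 0, -1):
        sep = ts[layer - 1] - 1
        prefix = f"L{layer}_"
        if above is None:
            top = b.add(f"{prefix}T", sex=MALE)
        else:
            pa, pb = above
            father, mother = (pa, pb)
            if father != mother:
                sexes = {m.id: m.sex for m in b.members}
                if sexes[father] == FEMALE or sexes[mother] == MALE:
                    father, mother = mother, father
            top = b.add(f"{prefix}T", father, mother, sex=MALE)
        if sep == 0:
            above = (top, top)
            continue
        la = (sep + 1) // 2
        lb = sep - la
        a = _grow_path(b, top, la, MALE, f"{prefix}A")
        if lb:
            bb = _grow_path(b, top, lb, FEMALE, f"{prefix}B")
        else:
            bb = top
        # ensure the focal pair can parent the next layer down
        if bb == top and la >= 1:
            # parent/child pair: make the child female so the pair is mixed
            idx = [m.id for m in b.members].index(a)
            b.members[idx] = Member(a, b.members[idx].father_id, b.members[idx].mother_id, FEMALE)
        above = (a, bb)
    ped = b.pedigree()
    return ped, above


# -- IBD triple -> double half cousins --------------------------------


def _sqrt_exact(x: Real) -> Real:
    """Exact Fraction square root when possible, else float."""
    if isinstance(x, Fraction):
        np_, dp_ = math.isqrt(x.numerator), math.isqrt(x.denominator)
        if np_ * np_ == x.numerator and dp_ * dp_ == x.denominator:
            return Fraction(np_, dp_)
    return math.sqrt(x)


def _snap_dyadic(phi: float, tol: float = 1e-9) -> Real:
    """Snap a float kinship value to a nearby power of two (float noise guard)."""
    if phi <= 0 or phi >= 1:
        return phi
    k = round(-math.log2(phi))
    if k >= 1 and abs(phi * 2**k - 1) < tol:
        return Fraction(1, 2**k)
    return phi


def ibd_to_dhc(target: Sequence[Real], tol: float = _TOL) -> DHCSolution:
    """Solve for double-half-cousin parameters realising ``target``.

    ``U = 1 + kappa2 - kappa0``, ``D = U^2 - 4*kappa2``; the parental
    kinships are ``phi1 = (U - sqrt(D))/2 <= phi2 = (U + sqrt(D))/2``, each
    then inverted to a (separation, founder f) pair.  Raises
    :class:`InadmissibleError` when ``D < -tol``; ``D`` within ``[-tol, 0)``
    is clamped to the parabolic boundary.
    """
    k0, k1, k2 = target
    U = 1 + k2 - k0
    D = U * U - 4 * k2
    if D < -tol:
        raise InadmissibleError(
            f"kappa = ({k0}, {k1}, {k2}) violates kappa1^2 >= 4*kappa0*kappa2 (D = {D})"
        )
    if D < 0:
        D = type(U)(0)
    s = _sqrt_exact(D)
    phi1 = (U - s) / 2
    phi2 = (U + s) / 2
    if isinstance(phi1, float):
        phi1 = _snap_dyadic(phi1)
    if isinstance(phi2, float):
        phi2 = _snap_dyadic(phi2)
    phi1 = max(phi1, 0)
    phi2 = min(phi2, 1)
    spec1 = kinship_to_half_cousin(phi1)
    spec2 = kinship_to_half_cousin(phi2)
    return DHCSolution(
        m=spec1.m,
        n=spec2.m,
        f1=spec1.founder_f,
        f2=spec2.founder_f,
        U=U,
        D=D,
        phi1=phi1,
        phi2=phi2,
    )


def build_dhc(sol: DHCSolution) -> tuple[Pedigree, tuple[str, str]]:
    """Materialise a double-half-cousin pedigree from a solver solution.

    The fathers form half cousins HC_m^{f1} and the mothers HC_n^{f2},
    the two sides unrelated; the focal pair is noninbred by construction.
    Infinite separations reduce to unrelated founders on that side.
    """
    fb = _Builder()
    fathers_ped, (fa, fbid) = build_half_cousin(
        HalfCousinSpec(sol.m, sol.f1), focal_sex=MALE, prefix="F"
    )
    mothers_ped, (ma, mb) = build_half_cousin(
        HalfCousinSpec(sol.n, sol.f2), focal_sex=FEMALE, prefix="M"
    )
    members = list(fathers_ped.members) + list(mothers_ped.members)
    finb = dict(fathers_ped.founder_inbreeding)
    finb.update(mothers_ped.founder_inbreeding)
    members.append(Member("a", fa, ma))
    members.append(Member("b", fbid, mb))
    ped = Pedigree(members, founder_inbreeding=finb).check()
    return ped, ("a", "b")


# -- IBD triangle subdivision -----------------------------------------


def triangle_vertex(i: Real, j: Real) -> TrianglePoint:
    """Vertex ``v_{i,j} = ((1 - 2^-i)(1 - 2^-j), 2^-i * 2^-j)`` (indices may be INFINITE)."""
    wi = Fraction(0) if i == INFINITE else Fraction(1, 2 ** int(i))
    wj = Fraction(0) if j == INFINITE else Fraction(1, 2 ** int(j))
    return TrianglePoint((1 - wi) * (1 - wj), wi * wj)


def _region_for(point: TrianglePoint, m: Real, n: Real, phi1: Real, phi2: Real) -> TriangleRegion:
    def clamp01(x: Real) -> Real:
        return min(max(x, 0), 1)

    f1 = clamp01(phi1 * 2 ** (int(m) + 1) - 1) if m != INFINITE else Fraction(0)
    f2 = clamp01(phi2 * 2 ** (int(n) + 1) - 1) if n != INFINITE else Fraction(0)
    m1 = INFINITE if m == INFINITE else m + 1
    n1 = INFINITE if n == INFINITE else n + 1
    vertices = (
        triangle_vertex(m, n),
        triangle_vertex(m, n1),
        triangle_vertex(m1, n),
        triangle_vertex(m1, n1),
    )
    g1, g2 = 1 - f1, 1 - f2
    weights = (f1 * f2, f1 * g2, g1 * f2, g1 * g2)
    return TriangleRegion(m=m, n=n, vertices=vertices, weights=weights, f1=f1, f2=f2)


def _in_convex_polygon(point, polygon) -> bool:
    """Boundary-inclusive membership in a convex polygon (exact rational)."""
    px, py = point
    sign = 0
    n = len(polygon)
    for idx in range(n):
        x1, y1 = polygon[idx]
        x2, y2 = polygon[(idx + 1) % n]
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if cross == 0:
            continue
        s = 1 if cross > 0 else -1
        if sign == 0:
            sign = s
        elif s != sign:
            return False
    return True


def triangle_regions(point: Sequence[Real], tol: float = _TOL) -> list[TriangleRegion]:
    """All subdivision cells A_{m,n} (m >= n) containing ``point``.

    Interior points belong to exactly one cell; points on cell borders to
    several.  Membership is decided by exact rational half-plane tests
    against the quadrilateral V_{m,n}.  Raises :class:`InadmissibleError`
    for points outside the admissible region.
    """
    k0, k2 = point
    k1 = 1 - k0 - k2
    if k0 < -tol or k2 < -tol or k0 + k2 > 1 + tol or not is_admissible((k0, k1, k2), tol):
        raise InadmissibleError(f"point ({k0}, {k2}) is not admissible")
    k0 = _exact_fraction(max(k0, 0))
    k2 = _exact_fraction(max(k2, 0))
    pt = TrianglePoint(k0, k2)
    regions: list[TriangleRegion] = []
    if k2 == 0:
        # Bottom edge: A_{INF,n} is the segment [v_{INF,n}, v_{INF,n+1}].
        if k0 == 1:
            v = TrianglePoint(Fraction(1), Fraction(0))
            regions.append(
                TriangleRegion(INFINITE, INFINITE, (v, v, v, v),
                               (Fraction(0),) * 3 + (Fraction(1),),
                               Fraction(0), Fraction(0))
            )
            return regions
        phi2 = 1 - k0
        n = 0
        while Fraction(1, 2 ** (n + 1)) > phi2:
            n += 1
        # phi2 in (2^-(n+1), 2^-n]; boundary phi2 = 2^-(n+1) also lies in cell n+1
        candidates = [n]
        if phi2 == Fraction(1, 2 ** (n + 1)):
            candidates.append(n + 1)
        for nn in candidates:
            f2 = phi2 * 2 ** (nn + 1) - 1
            v_a, v_b = triangle_vertex(INFINITE, nn), triangle_vertex(INFINITE, nn + 1)
            regions.append(
                TriangleRegion(
                    INFINITE, nn,
                    (v_a, v_b, v_a, v_b),
                    (Fraction(0), Fraction(0), f2, 1 - f2),
                    Fraction(0), f2,
                )
            )
        return regions
    U = 1 + k2 - k0
    D = U * U - 4 * k2
    if D < 0:
        D = Fraction(0)
    s = _sqrt_exact(D)
    phi1, phi2 = (U - s) / 2, (U + s) / 2
    bound = max(0, math.ceil(math.log2(1 / float(k2)))) + 1
    for m in range(bound + 1):
        for n in range(m + 1):
            poly = [
                triangle_vertex(m, n),
                triangle_vertex(m + 1, n),
                triangle_vertex(m + 1, n + 1),
                triangle_vertex(m, n + 1),
            ]
            dedup: list[TrianglePoint] = []
            for p in poly:
                if p not in dedup:
                    dedup.append(p)
            if _in_convex_polygon(pt, dedup):
                regions.append(_region_for(pt, m, n, phi1, phi2))
    return regions


def stationary_inbreeding(m: int) -> Fraction:
    """Fixed point of ``f -> (1 + f) / 2^(m+1)``: ``f* = 1 / (2^(m+1) - 1)``.

    A breeding scheme of repeated half-cousin matings at separation ``m``
    maintains this inbreeding level indefinitely (m = 1, sequential
    half-sib mating, gives f* = 1/7).
    """
    if m < 0 or m != int(m):
        raise ValueError("separation must be a nonnegative integer")
    return Fraction(1, 2 ** (int(m) + 1) - 1)
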