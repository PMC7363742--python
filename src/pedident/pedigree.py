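"""Pedigree representation, validation, PED-format I/O and fixture factories.

A :class:`Pedigree` is a directed acyclic parent graph.  Members without
recorded parents are *founders*; each founder may carry an assigned
inbreeding coefficient ``f`` in ``[0, 1]`` summarising an unrecorded
ancestry.  Founders are assumed mutually unrelated.  Coefficients computed
elsewhere in the package are exact (:class:`fractions.Fraction`) whenever
the founder coefficients are rationals, and float otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Real
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "MISSING",
    "MALE",
    "FEMALE",
    "UNKNOWN",
    "Member",
    "Pedigree",
    "PedigreeError",
    "parse_ped",
    "write_ped",
    "parse_founder_inbreeding",
    "write_founder_inbreeding",
    "validate",
    "generation_index",
    "standard_pedigree",
    "random_pedigree",
]

MISSING = "0"
MALE = 1
FEMALE = 2
UNKNOWN = 0

_STANDARD_NAMES = (
    "parent_offspring",
    "full_sibs",
    "half_sibs",
    "grandparent",
    "avuncular",
    "half_avuncular",
    "first_cousins",
    "quadruple_half_first_cousins",
    "fig1_sibs",
    "fig11_middle",
    "fig11_right",
)


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees or unresolvable references."""


@dataclass(frozen=True)
class Member:
    """One pedigree member.

    ``father_id`` and ``mother_id`` are either both ``None`` (founder) or
    both present (nonfounder).  ``sex`` uses the linkage PED convention:
    1 = male, 2 = female, 0 = unknown.
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: int = UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """A single connected (or not) pedigree with optional founder inbreeding.

    Instances are treated as immutable once constructed; derived quantities
    (generation indices, kinship values, generalized kinship values) are
    cached on the instance.
    """

    def __init__(
        self,
        members: Iterable[Member],
        founder_inbreeding: Mapping[str, Real] | None = None,
        selfing_allowed: bool = False,
    ) -> None:
        self._members: dict[str, Member] = {}
        for m in members:
            if m.id in self._members:
                raise PedigreeError(f"duplicate member id {m.id!r}")
            if m.id == MISSING:
                raise PedigreeError(f"member id {MISSING!r} is reserved for missing parents")
            self._members[m.id] = m
        self.founder_inbreeding: dict[str, Real] = dict(founder_inbreeding or {})
        self.selfing_allowed = bool(selfing_allowed)
        self._caches: dict[str, dict] = {}
        self._generation: dict[str, int] | None = None

    # -- basic access -------------------------------------------------

    @property
    def members(self) -> tuple[Member, ...]:
        return tuple(self._members.values())

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._members)

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, member_id: str) -> bool:
        return member_id in self._members

    def member(self, member_id: str) -> Member:
        try:
            return self._members[member_id]
        except KeyError:
            raise PedigreeError(f"unknown member id {member_id!r}") from None

    def parents(self, member_id: str) -> tuple[str, str] | None:
        m = self.member(member_id)
        if m.is_founder:
            return None
        return (m.father_id, m.mother_id)

    @property
    def founders(self) -> tuple[str, ...]:
        return tuple(m.id for m in self._members.values() if m.is_founder)

    def is_founder(self, member_id: str) -> bool:
        return self.member(member_id).is_founder

    def founder_f(self, member_id: str) -> Real:
        """Assigned inbreeding coefficient of a founder (default 0)."""
        return self.founder_inbreeding.get(member_id, Fraction(0))

    def cache(self, name: str) -> dict:
        return self._caches.setdefault(name, {})

    # -- graph structure ----------------------------------------------

    def graph(self) -> "nx.DiGraph":
        """Parent -> child directed graph (edges point down the pedigree)."""
        g = nx.DiGraph()
        g.add_nodes_from(self._members)
        for m in self._members.values():
            if not m.is_founder:
                for p in (m.father_id, m.mother_id):
                    if p in self._members:
                        g.add_edge(p, m.id)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return (
            set(self._members.values()) == set(other._members.values())
            and {k: Fraction(v) for k, v in self.founder_inbreeding.items() if v}
            == {k: Fraction(v) for k, v in other.founder_inbreeding.items() if v}
            and self.selfing_allowed == other.selfing_allowed
        )

    def __repr__(self) -> str:
        return f"<Pedigree of {len(self)} members, {len(self.founders)} founders>"

    # -- validation ---------------------------------------------------

    def validate(self) -> list[str]:
        return validate(self)

    def check(self) -> "Pedigree":
        """Raise :class:`PedigreeError` unless the pedigree is valid."""
        problems = self.validate()
        if problems:
            raise PedigreeError("; ".join(problems))
        return self


def validate(ped: Pedigree) -> list[str]:
    """Return a list of invariant violations (empty when the pedigree is valid)."""
    problems: list[str] = []
    ids = set(ped.ids)
    for m in ped.members:
        present = [p for p in (m.father_id, m.mother_id) if p is not None]
        if len(present) == 1:
            problems.append(f"member {m.id}: exactly one parent recorded")
            continue
        for p in present:
            if p not in ids:
                problems.append(f"member {m.id}: parent {p} not in pedigree")
        if m.father_id is not None and m.father_id == m.mother_id and not ped.selfing_allowed:
            problems.append(f"member {m.id}: selfing ({m.father_id}) without selfing_allowed")
        if not ped.selfing_allowed and not m.is_founder:
            father = ped._members.get(m.father_id)
            mother = ped._members.get(m.mother_id)
            if father is not None and father.sex == FEMALE:
                problems.append(f"member {m.id}: father {father.id} has female sex")
            if mother is not None and mother.sex == MALE:
                problems.append(f"member {m.id}: mother {mother.id} has male sex")
    g = ped.graph()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        problems.append(
            "cycle in parent graph through " + ", ".join(edge[0] for edge in cycle)
        )
    for fid, f in ped.founder_inbreeding.items():
        if fid not in ids:
            problems.append(f"founder inbreeding for unknown id {fid}")
        elif not ped.member(fid).is_founder:
            problems.append(f"founder inbreeding assigned to nonfounder {fid}")
        if not 0 <= f <= 1:
            problems.append(f"founder inbreeding f={f} for {fid} outside [0, 1]")
    return problems


def generation_index(ped: Pedigree) -> dict[str, int]:
    """Index with founders at 0 and ``index(child) = 1 + max(parent indices)``.

    Strictly increasing along every parent -> child edge; used to pick
    recursion pivots that are guaranteed nondescendants of the rest.
    """
    if ped._generation is not None:
        return ped._generation
    g = ped.graph()
    if not nx.is_directed_acyclic_graph(g):
        raise PedigreeError("cycle in parent graph")
    index: dict[str, int] = {}
    for node in nx.topological_sort(g):
        parents = ped.parents(node)
        if parents is None:
            index[node] = 0
        else:
            index[node] = 1 + max(index[p] for p in parents)
    ped._generation = index
    return index


# -- PED-format I/O ---------------------------------------------------


def parse_ped(text: str, founder_inbreeding_text: str | None = None,
              selfing_allowed: bool = False) -> Pedigree:
    """Parse whitespace-separated PED-style text: ``id father mother [sex]``.

    ``0`` denotes a missing parent.  An optional header line starting with
    ``id`` (case-insensitive) is skipped.  Raises :class:`PedigreeError` on
    duplicate ids, dangling parents, half-recorded parents or cycles.
    """
    members = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        cols = line.split()
        if lineno == 1 and cols[0].lower() in {"id", "iid", "indiv"}:
            continue
        if len(cols) not in (3, 4):
            raise PedigreeError(f"line {lineno}: expected 3 or 4 columns, got {len(cols)}")
        mid, fid, mo = cols[:3]
        sex = UNKNOWN
        if len(cols) == 4:
            try:
                sex = int(cols[3])
            except ValueError:
                raise PedigreeError(f"line {lineno}: sex code {cols[3]!r} not 0/1/2") from None
            if sex not in (MALE, FEMALE, UNKNOWN):
                raise PedigreeError(f"line {lineno}: sex code {sex} not 0/1/2")
        members.append(
            Member(
                id=mid,
                father_id=None if fid == MISSING else fid,
                mother_id=None if mo == MISSING else mo,
                sex=sex,
            )
        )
    finb = (
        parse_founder_inbreeding(founder_inbreeding_text)
        if founder_inbreeding_text is not None
        else None
    )
    return Pedigree(members, founder_inbreeding=finb, selfing_allowed=selfing_allowed).check()


def parse_founder_inbreeding(text: str) -> dict[str, Fraction]:
    """Parse the two-column companion table ``id  f`` (f as fraction or decimal)."""
    table: dict[str, Fraction] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        cols = line.split()
        if len(cols) != 2:
            raise PedigreeError(f"founder table line {lineno}: expected 2 columns")
        if lineno == 1 and cols[0].lower() == "id":
            continue
        try:
            f = Fraction(cols[1])
        except (ValueError, ZeroDivisionError):
            raise PedigreeError(
                f"founder table line {lineno}: cannot parse f={cols[1]!r}"
            ) from None
        table[cols[0]] = f
    return table


def write_ped(ped: Pedigree) -> str:
    """Emit 4-column PED text in topological order (parents before children)."""
    ped.check()
    gen = generation_index(ped)
    order = sorted(ped.ids, key=lambda i: (gen[i], list(ped.ids).index(i)))
    lines = []
    for mid in order:
        m = ped.member(mid)
        lines.append(
            f"{m.id} {m.father_id or MISSING} {m.mother_id or MISSING} {m.sex}"
        )
    return "\n".join(lines) + "\n"


def write_founder_inbreeding(ped: Pedigree) -> str:
    """Companion two-column table for annotated founders (may be empty)."""
    lines = [f"{fid} {f}" for fid, f in ped.founder_inbreeding.items()]
    return "\n".join(lines) + ("\n" if lines else "")


# -- fixture factories ------------------------------------------------


def _apply_founder_f(ped: Pedigree, founder_f: Mapping[str, Real] | None) -> Pedigree:
    if not founder_f:
        return ped
    founders = set(ped.founders)
    for fid in founder_f:
        if fid not in founders:
            raise PedigreeError(f"founder_f key {fid!r} is not a founder of this fixture")
    ped.founder_inbreeding.update(founder_f)
    return ped.check()


def standard_pedigree(
    name: str, founder_f: Mapping[str, Real] | None = None
) -> tuple[Pedigree, tuple[str, str]]:
    """Named textbook pedigree and its focal pair ``(a, b)``.

    Available names: parent_offspring, full_sibs, half_sibs, grandparent,
    avuncular, half_avuncular, first_cousins, quadruple_half_first_cousins,
    fig1_sibs (full sibs, both parental founders completely inbred),
    fig11_middle (maternal half sibs whose fathers are father-and-son, the
    elder father completely inbred) and fig11_right (crossing half-avuncular
    paths through two completely inbred founders).  ``founder_f`` overrides
    or adds founder inbreeding values.
    """
    M = Member
    defaults: dict[str, Real] = {}
    if name == "parent_offspring":
        members = [M("F", sex=MALE), M("M", sex=FEMALE), M("C", "F", "M")]
        focal = ("F", "C")
    elif name in ("full_sibs", "fig1_sibs"):
        members = [
            M("F", sex=MALE),
            M("M", sex=FEMALE),
            M("C1", "F", "M"),
            M("C2", "F", "M"),
        ]
        focal = ("C1", "C2")
        if name == "fig1_sibs":
            defaults = {"F": Fraction(1), "M": Fraction(1)}
    elif name == "half_sibs":
        members = [
            M("F1", sex=MALE),
            M("F2", sex=MALE),
            M("M", sex=FEMALE),
            M("C1", "F1", "M"),
            M("C2", "F2", "M"),
        ]
        focal = ("C1", "C2")
    elif name == "grandparent":
        members = [
            M("GF", sex=MALE),
            M("GM", sex=FEMALE),
            M("P", "GF", "GM", sex=MALE),
            M("S", sex=FEMALE),
            M("C", "P", "S"),
        ]
        focal = ("GF", "C")
    elif name == "avuncular":
        members = [
            M("GF", sex=MALE),
            M("GM", sex=FEMALE),
            M("U", "GF", "GM", sex=MALE),
            M("P", "GF", "GM", sex=MALE),
            M("S", sex=FEMALE),
            M("N", "P", "S", sex=MALE),
        ]
        focal = ("U", "N")
    elif name == "half_avuncular":
        members = [
            M("G", sex=MALE),
            M("W1", sex=FEMALE),
            M("W2", sex=FEMALE),
            M("U", "G", "W1", sex=MALE),
            M("P", "G", "W2", sex=MALE),
            M("S", sex=FEMALE),
            M("N", "P", "S"),
        ]
        focal = ("U", "N")
    elif name == "first_cousins":
        members = [
            M("GF", sex=MALE),
            M("GM", sex=FEMALE),
            M("P1", "GF", "GM", sex=MALE),
            M("P2", "GF", "GM", sex=FEMALE),
            M("S1", sex=FEMALE),
            M("S2", sex=MALE),
            M("C1", "P1", "S1"),
            M("C2", "S2", "P2"),
        ]
        focal = ("C1", "C2")
    elif name == "quadruple_half_first_cousins":
        # Four outbred founder grandparents; each parent of a is a half sib
        # of each parent of b through a distinct grandparent.
        members = [
            M("G1", sex=MALE),
            M("G2", sex=MALE),
            M("G3", sex=FEMALE),
            M("G4", sex=FEMALE),
            M("FA", "G1", "G3", sex=MALE),
            M("MA", "G2", "G4", sex=FEMALE),
            M("FB", "G1", "G4", sex=MALE),
            M("MB", "G2", "G3", sex=FEMALE),
            M("A", "FA", "MA"),
            M("B", "FB", "MB"),
        ]
        focal = ("A", "B")
    elif name == "fig11_middle":
        members = [
            M("E", sex=MALE),  # elder father, completely inbred
            M("S1", sex=FEMALE),
            M("Y", "E", "S1", sex=MALE),  # younger father, son of E
            M("M", sex=FEMALE),  # shared mother
            M("A", "E", "M"),
            M("B", "Y", "M"),
        ]
        focal = ("A", "B")
        defaults = {"E": Fraction(1)}
    elif name == "fig11_right":
        # a is a half sib of b's mother through inbred founder T1, and
        # b is a half sib of a's mother through inbred founder T2.
        members = [
            M("T1", sex=MALE),
            M("T2", sex=MALE),
            M("W1", sex=FEMALE),
            M("W2", sex=FEMALE),
            M("S", "T1", "W1", sex=FEMALE),  # b's mother, child of T1
            M("T", "T2", "W2", sex=FEMALE),  # a's mother, child of T2
            M("A", "T1", "T"),
            M("B", "T2", "S"),
        ]
        focal = ("A", "B")
        defaults = {"T1": Fraction(1), "T2": Fraction(1)}
    else:
        raise PedigreeError(
            f"unknown standard pedigree {name!r}; choose from {', '.join(_STANDARD_NAMES)}"
        )
    ped = Pedigree(members, founder_inbreeding=defaults).check()
    return _apply_founder_f(ped, founder_f), focal


def random_pedigree(
    rng,
    n_members: int = 10,
    founder_f_choices: Sequence[Real] = (0, 0, Fraction(1, 4), Fraction(1, 2), 1),
    p_founder: float = 0.35,
) -> Pedigree:
    """Random valid pedigree for property tests and Monte-Carlo checks.

    Members are added one at a time; each new member is a founder with
    probability ``p_founder`` (always until two founders of opposite use
    exist), otherwise a child of two distinct previously added members.
    Founder inbreeding values are drawn from ``founder_f_choices`` so exact
    rational arithmetic applies downstream.  No selfing.
    """
    members: list[Member] = []
    finb: dict[str, Real] = {}
    for i in range(n_members):
        mid = f"I{i}"
        if len(members) < 2 or rng.random() < p_founder:
            members.append(Member(mid))
            f = founder_f_choices[int(rng.integers(0, len(founder_f_choices)))]
            if f:
                finb[mid] = f
        else:
            fa, mo = rng.choice(len(members), size=2, replace=False)
            members.append(Member(mid, members[fa].id, members[mo].id))
    return Pedigree(members, founder_inbreeding=finb).check()
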