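"""Pedigree data model, validation, kinship coefficients, and affected-pair
enumeration.

A :class:`Pedigree` is a validated, acyclic parent–offspring graph over
:class:`Individual` records.  Kinship coefficients are computed by the
classical recursive algorithm on a topological order, which handles
individuals related through multiple lines of descent (common in deep
multigenerational genealogies) without enumerating paths.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Optional

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "RelativePair",
    "validate_pedigree",
    "kinship_coefficient",
    "enumerate_affected_pairs",
]


class PedigreeError(ValueError):
    """Raised when a pedigree is structurally invalid."""


@dataclass(frozen=True)
class Individual:
    """One person in a pedigree.

    ``father_id`` and ``mother_id`` are either both ``None`` (a founder) or
    both refer to other individuals.  ``sex`` is one of ``"male"``,
    ``"female"`` or ``"unknown"``; unknown-sex parents are permitted (real
    genealogies have gaps) and the opposite-sex parent check is only applied
    when both parents have recorded sexes.
    """

    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "unknown"
    birth_year: Optional[int] = None
    death_year: Optional[int] = None
    attained_age: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"invalid sex {self.sex!r} for individual {self.id!r}")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    def lifespan(self) -> Optional[float]:
        """Attained age, falling back to death_year - birth_year."""
        if self.attained_age is not None:
            return float(self.attained_age)
        if self.birth_year is not None and self.death_year is not None:
            return float(self.death_year - self.birth_year)
        return None


@dataclass(frozen=True)
class RelativePair:
    """An unordered pair of (affected) relatives annotated with kinship."""

    id_a: str
    id_b: str
    kinship: float
    relationship_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError("a relative pair must join two distinct individuals")
        if self.kinship < 0:
            raise ValueError("kinship cannot be negative")


class Pedigree:
    """A validated collection of individuals forming an acyclic
    parent–offspring graph.

    Construction validates the graph (see :func:`validate_pedigree`);
    founders and a topological order (parents before children) are cached.
    Kinship queries are memoized on the instance.
    """

    def __init__(self, members: Iterable[Individual]):
        members = list(members)
        if not members:
            raise PedigreeError("pedigree must contain at least one individual")
        self._members: dict[str, Individual] = {}
        for ind in members:
            if ind.id in self._members:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self._members[ind.id] = ind
        self._validate_parents()
        self._order = self._toposort()
        self._depth = {iid: 0 for iid in self._order}
        for iid in self._order:
            ind = self._members[iid]
            if not ind.is_founder:
                self._depth[iid] = 1 + max(
                    self._depth[ind.father_id], self._depth[ind.mother_id]
                )
        self._kin_cache: dict[tuple[str, str], float] = {}

    # -- validation -----------------------------------------------------

    def _validate_parents(self) -> None:
        for ind in self._members.values():
            f, m = ind.father_id, ind.mother_id
            if (f is None) != (m is None):
                raise PedigreeError(
                    f"individual {ind.id!r} has exactly one recorded parent; "
                    "parents must be both known or both unknown"
                )
            if f is None:
                continue
            if f == ind.id or m == ind.id:
                raise PedigreeError(f"individual {ind.id!r} listed as its own parent")
            if f == m:
                raise PedigreeError(
                    f"individual {ind.id!r} has the same individual as both parents"
                )
            for pid, role, want in ((f, "father", "male"), (m, "mother", "female")):
                if pid not in self._members:
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.id!r} is not in the pedigree"
                    )
                psex = self._members[pid].sex
                if psex != "unknown" and psex != want:
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.id!r} has recorded sex {psex!r}"
                    )

    def _toposort(self) -> list[str]:
        ts = TopologicalSorter(
            {
                iid: [p for p in (ind.father_id, ind.mother_id) if p is not None]
                for iid, ind in self._members.items()
            }
        )
        try:
            return list(ts.static_order())
        except CycleError as exc:
            raise PedigreeError(f"pedigree contains a cycle: {exc.args[1]}") from exc

    # -- basic accessors ------------------------------------------------

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, iid: str) -> bool:
        return iid in self._members

    def __getitem__(self, iid: str) -> Individual:
        return self._members[iid]

    @property
    def members(self) -> list[Individual]:
        return [self._members[iid] for iid in self._order]

    @property
    def ids(self) -> list[str]:
        """Ids in topological order (parents before children)."""
        return list(self._order)

    @property
    def founders(self) -> list[str]:
        return [iid for iid in self._order if self._members[iid].is_founder]

    # -- kinship --------------------------------------------------------

    def kinship(self, i: str, j: str) -> float:
        """Kinship coefficient phi(i, j): the probability that a random
        allele from i and a random allele from j are identical by descent.

        Recursive definition: for i == j, phi = (1 + phi(father, mother))/2;
        otherwise recurse on the individual that cannot be an ancestor of the
        other (the deeper one), phi(i, j) = [phi(f_i, j) + phi(m_i, j)]/2,
        with phi = 0 once a founder is reached on the recursing side.
        """
        for iid in (i, j):
            if iid not in self._members:
                raise KeyError(f"unknown individual id {iid!r}")
        return self._kin(i, j)

    def _kin(self, i: str, j: str) -> float:
        if i > j:
            i, j = j, i
        key = (i, j)
        cached = self._kin_cache.get(key)
        if cached is not None:
            return cached
        if i == j:
            ind = self._members[i]
            if ind.is_founder:
                phi = 0.5
            else:
                phi = 0.5 * (1.0 + self._kin(ind.father_id, ind.mother_id))
        else:
            # recurse on the deeper individual: it cannot be an ancestor of
            # the shallower one
            a, b = (i, j) if self._depth[i] >= self._depth[j] else (j, i)
            ind = self._members[a]
            if ind.is_founder:
                phi = 0.0
            else:
                phi = 0.5 * (self._kin(ind.father_id, b) + self._kin(ind.mother_id, b))
        self._kin_cache[key] = phi
        return phi

    def components(self) -> list[set[str]]:
        """Weakly-connected components of the parent-offspring graph.

        Individuals in different components have kinship zero; callers can
        use this to skip cross-component pair work.
        """
        parent = {iid: iid for iid in self._members}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for ind in self._members.values():
            for p in (ind.father_id, ind.mother_id):
                if p is not None:
                    parent[find(ind.id)] = find(p)
        groups: dict[str, set[str]] = {}
        for iid in self._members:
            groups.setdefault(find(iid), set()).add(iid)
        return list(groups.values())

    def inbreeding(self, i: str) -> float:
        """Inbreeding coefficient of i (kinship of i's parents)."""
        ind = self._members[i]
        if ind.is_founder:
            return 0.0
        return self._kin(ind.father_id, ind.mother_id)

    # -- relationships --------------------------------------------------

    def relationship_class(self, i: str, j: str) -> str:
        """A coarse structural label for a pair (used only for reporting)."""
        a, b = self._members[i], self._members[j]
        if j in (a.father_id, a.mother_id) or i in (b.father_id, b.mother_id):
            return "parent_offspring"
        if not a.is_founder and not b.is_founder:
            pa = {a.father_id, a.mother_id}
            pb = {b.father_id, b.mother_id}
            shared = pa & pb
            if len(shared) == 2:
                return "full_sib"
            if len(shared) == 1:
                return "half_sib"
        phi = self._kin(i, j)
        if phi == 0.25:
            return "first_degree_equivalent"
        if phi == 0.125:
            return "second_degree_equivalent"
        if phi == 0.0625:
            return "third_degree_equivalent"
        if phi == 0.0:
            return "unrelated"
        return "other"


def validate_pedigree(members: Iterable[Individual]) -> Pedigree:
    """Validate a collection of individuals and return a :class:`Pedigree`.

    Raises :class:`PedigreeError` on cycles, dangling parent references,
    self-parenting, or an individual recorded as both parents of a child.
    Idempotent: validating an already-validated pedigree's members returns
    an equivalent pedigree.
    """
    if isinstance(members, Pedigree):
        members = members.members
    return Pedigree(members)


def kinship_coefficient(ped: Pedigree, i: str, j: str) -> float:
    """Kinship coefficient phi(i, j) in ``ped`` (see :meth:`Pedigree.kinship`)."""
    return ped.kinship(i, j)


def enumerate_affected_pairs(
    ped: Pedigree,
    affected: Iterable[str],
    min_kinship: Optional[float] = None,
    classify: bool = False,
) -> list[RelativePair]:
    """All unordered pairs of affected individuals related at or above a
    kinship threshold.

    With ``min_kinship=None`` (default) any pair with phi > 0 is kept;
    with an explicit threshold, pairs with phi >= min_kinship are kept.
    A pair related through multiple lines of descent appears once, carrying
    the full (summed-path) kinship coefficient.
    """
    affected = sorted(set(affected))
    for iid in affected:
        if iid not in ped:
            raise KeyError(f"affected id {iid!r} not in pedigree")
    pairs: list[RelativePair] = []
    for a, b in itertools.combinations(affected, 2):
        phi = ped.kinship(a, b)
        keep = phi > 0.0 if min_kinship is None else phi >= min_kinship
        if keep:
            pairs.append(
                RelativePair(
                    a,
                    b,
                    phi,
                    ped.relationship_class(a, b) if classify else None,
                )
            )
    return pairs
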