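"""Pedigree structures and PED-like text I/O.

A pedigree is a set of individuals with optional parents (both present or
both absent), sex, affection status and an optional single-marker genotype.
Construction validates acyclicity and parent presence; loop detection (for
linkage, which requires zero-loop pedigrees) is exposed separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AFFECTED = 2
UNAFFECTED = 1
UNKNOWN = 0


class MendelianError(ValueError):
    """Marker genotypes inconsistent with transmission in a named trio."""


@dataclass(frozen=True)
class Individual:
    id: str
    father: str | None
    mother: str | None
    sex: int                      # 1 male, 2 female, 0 unknown
    affected: int                 # 2 affected, 1 unaffected, 0 unknown
    genotype: tuple[int, int] | None = None   # marker alleles (1-based), None = untyped

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


class Pedigree:
    """Loop-checked collection of individuals in topological order."""

    def __init__(self, members: list[Individual], family_id: str = "FAM1"):
        self.family_id = family_id
        ids = [m.id for m in members]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids")
        by_id = {m.id: m for m in members}
        for m in members:
            if (m.father is None) != (m.mother is None):
                raise ValueError(f"{m.id}: both parents or neither must be given")
            for p in (m.father, m.mother):
                if p is not None and p not in by_id:
                    raise ValueError(f"{m.id}: missing parent {p}")
        self.members = self._toposort(members, by_id)
        self.by_id = {m.id: m for m in self.members}

    @staticmethod
    def _toposort(members: list[Individual], by_id: dict) -> list[Individual]:
        order: list[Individual] = []
        state: dict[str, int] = {}

        def visit(mid: str) -> None:
            st = state.get(mid, 0)
            if st == 1:
                raise ValueError(f"pedigree cycle involving {mid}")
            if st == 2:
                return
            state[mid] = 1
            m = by_id[mid]
            if m.father is not None:
                visit(m.father)
                visit(m.mother)
            state[mid] = 2
            order.append(m)

        for m in members:
            visit(m.id)
        return order

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    def children_of(self, father: str, mother: str) -> list[Individual]:
        return [m for m in self.members if m.father == father and m.mother == mother]

    def has_loops(self) -> bool:
        """True when the marriage graph contains a cycle.

        Nodes are individuals plus one union node per parental pair; edges
        connect each union to both parents and to each child.  A pedigree is
        loop-free iff this graph is a forest.
        """
        parent = {}

        def find(x):
            while parent.get(x, x) != x:
                parent[x] = parent.get(parent[x], parent[x])
                x = parent[x]
            return x

        def union(a, b) -> bool:
            ra, rb = find(a), find(b)
            if ra == rb:
                return False  # edge closes a cycle
            parent[ra] = rb
            return True

        unions: dict[tuple[str, str], str] = {}
        for m in self.members:
            if m.is_founder:
                continue
            key = (m.father, m.mother)
            if key not in unions:
                unions[key] = f"__u{len(unions)}"
                if not union(unions[key], m.father):
                    return True
                if not union(unions[key], m.mother):
                    return True
            if not union(unions[key], m.id):
                return True
        return False

    def check_mendelian(self) -> None:
        """Raise :class:`MendelianError` naming the first offending trio."""
        for m in self.members:
            if m.is_founder or m.genotype is None:
                continue
            fa = self.by_id[m.father]
            mo = self.by_id[m.mother]
            if fa.genotype is None or mo.genotype is None:
                continue
            ok = any(
                {a, b} == set(m.genotype) or (a, b) == m.genotype or (b, a) == m.genotype
                for a in fa.genotype for b in mo.genotype
            )
            if not ok:
                raise MendelianError(
                    f"genotype of {m.id} inconsistent with parents "
                    f"{m.father} x {m.mother}"
                )

    def to_ped(self) -> str:
        """Six-column PED text plus two marker-allele columns (0 = missing)."""
        lines = []
        for m in self.members:
            g = m.genotype if m.genotype is not None else (0, 0)
            lines.append("\t".join(map(str, [
                self.family_id, m.id, m.father or "0", m.mother or "0",
                m.sex, m.affected, g[0], g[1],
            ])))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_ped(cls, text: str) -> "Pedigree":
        members = []
        family_id = "FAM1"
        for ln in text.splitlines():
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.split()
            if len(parts) < 6:
                raise ValueError(f"malformed PED line: {ln!r}")
            family_id, iid, fa, mo, sex, aff = parts[:6]
            genotype = None
            if len(parts) >= 8:
                a1, a2 = int(parts[6]), int(parts[7])
                if a1 > 0 and a2 > 0:
                    genotype = (a1, a2)
            members.append(Individual(
                id=iid, father=None if fa == "0" else fa,
                mother=None if mo == "0" else mo,
                sex=int(sex), affected=int(aff), genotype=genotype,
            ))
        return cls(members, family_id=family_id)

    def with_genotypes(self, genotypes: dict[str, tuple[int, int] | None]) -> "Pedigree":
        members = [
            Individual(m.id, m.father, m.mother, m.sex, m.affected,
                       genotypes.get(m.id, m.genotype))
            for m in self.members
        ]
        return Pedigree(members, family_id=self.family_id)

    def with_affection(self, affection: dict[str, int]) -> "Pedigree":
        members = [
            Individual(m.id, m.father, m.mother, m.sex,
                       affection.get(m.id, m.affected), m.genotype)
            for m in self.members
        ]
        return Pedigree(members, family_id=self.family_id)
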