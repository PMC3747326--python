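"""Genealogy data model, file I/O, Malécot kinship and genetic distance.

The central object is :class:`Genealogy`, a validated parent-link DAG over
:class:`Individual` records.  Relatedness between two members is measured by
the Malécot coefficient of kinship ``phi(a, b)``: the probability that one
allele sampled at random from ``a`` and one from ``b`` are identical by
descent through the recorded pedigree.  Founders (members with no recorded
parents) are assumed unrelated and non-inbred, so for example full siblings
of unrelated parents have ``phi = 1/4``, avunculars ``1/8`` and first
cousins ``1/16``.

Genetic distance between two members is the minimum number of meioses on a
genealogical path connecting them through a common ancestor: 1 for
parent/offspring, 2 for siblings or grandparent/grandchild, 3 for
avunculars, 4 for first cousins, and so on.  Pairs with no common ancestor
are *unreachable* and carry kinship zero.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "Individual",
    "Genealogy",
    "PairKinship",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
]

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

_SEX_CODES = {"1": MALE, "2": FEMALE, "0": UNKNOWN}
_SEX_TO_CODE = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}

#: attribute-table columns recognised beyond the structural ones
ATTRIBUTE_COLUMNS = (
    "birth_year",
    "birth_in_state",
    "has_death_record",
    "is_case",
    "age_at_diagnosis",
    "gleason",
    "metastatic",
    "survival_months",
    "other_primary_count",
    "bmi",
    "cause_of_death_phenotype",
)

_BOOL_ATTRS = {
    "birth_in_state",
    "has_death_record",
    "is_case",
    "metastatic",
    "cause_of_death_phenotype",
}
_INT_ATTRS = {"birth_year", "gleason", "survival_months", "other_primary_count"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree file or genealogy."""


@dataclass
class Individual:
    """One genealogy member with parent links and open attributes."""

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = UNKNOWN
    birth_year: int | None = None
    birth_in_state: bool | None = None
    has_death_record: bool = False
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.father_id == self.id or self.mother_id == self.id:
            raise PedigreeError(f"individual {self.id!r} listed as its own parent")
        if self.father_id is not None and self.father_id == self.mother_id:
            raise PedigreeError(
                f"individual {self.id!r} has identical father and mother "
                f"{self.father_id!r}"
            )
        if self.sex not in (MALE, FEMALE, UNKNOWN):
            raise PedigreeError(f"invalid sex {self.sex!r} for {self.id!r}")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    @property
    def parent_ids(self) -> tuple[str | None, str | None]:
        return (self.father_id, self.mother_id)


class PairKinship:
    """Sparse map from unordered id pairs to (kinship, genetic distance).

    Only pairs with a common ancestor are stored; every other pair of the
    covered id set implicitly carries ``phi = 0`` and unreachable distance
    (``None``).
    """

    def __init__(self, ids: Iterable[str], related: Mapping[tuple[str, str], tuple[float, int]]):
        self.ids = frozenset(ids)
        self._related = dict(related)
        n = len(self.ids)
        self.n_pairs = n * (n - 1) // 2

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def get(self, a: str, b: str) -> tuple[float, int | None]:
        """Return ``(phi, distance)``; distance is None when unreachable."""
        if a not in self.ids or b not in self.ids:
            raise KeyError(f"pair ({a!r}, {b!r}) outside the covered id set")
        return self._related.get(self._key(a, b), (0.0, None))

    def nonzero_items(self) -> Iterator[tuple[tuple[str, str], tuple[float, int]]]:
        return iter(self._related.items())

    def __len__(self) -> int:
        return self.n_pairs

    @property
    def n_related_pairs(self) -> int:
        return len(self._related)


class Genealogy:
    """A validated, acyclic parent-link graph over individuals.

    Kinship and ancestor queries are memoised on the instance, so repeated
    calls (for instance across Monte Carlo control replicates) amortise the
    recursion cost.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self.individuals[ind.id] = ind
        self._validate()
        self._children: dict[str, list[str]] = {i: [] for i in self.individuals}
        for ind in self.individuals.values():
            for p in ind.parent_ids:
                if p is not None:
                    self._children[p].append(ind.id)
        self._depth: dict[str, int] = {}
        self._compute_depths()
        self._ancestors: dict[str, dict[str, int]] = {}
        self._kin: dict[tuple[str, str], float] = {}

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.individuals)
        for ind in self.individuals.values():
            for role, pid in zip(("father", "mother"), ind.parent_ids):
                if pid is None:
                    continue
                parent = self.individuals.get(pid)
                if parent is None:
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.id!r} not present in the pedigree"
                    )
                want = MALE if role == "father" else FEMALE
                if parent.sex not in (want, UNKNOWN):
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.id!r} has recorded sex {parent.sex}"
                    )
                g.add_edge(pid, ind.id)  # parent -> child
        try:
            cycle = nx.find_cycle(g, orientation="original")
        except nx.NetworkXNoCycle:
            return
        raise PedigreeError(
            f"parent links contain a cycle through individual {cycle[0][0]!r}"
        )

    def _compute_depths(self) -> None:
        # generation depth = longest parent chain above; founders are 0
        order: list[str] = []
        seen: dict[str, int] = {}

        def visit(i: str) -> None:
            stack = [(i, iter([p for p in self.individuals[i].parent_ids if p]))]
            seen[i] = 1
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if seen.get(p, 0) == 0:
                        seen[p] = 1
                        stack.append((p, iter([q for q in self.individuals[p].parent_ids if q])))
                        advanced = True
                        break
                if not advanced:
                    order.append(node)
                    stack.pop()

        for i in self.individuals:
            if seen.get(i, 0) == 0:
                visit(i)
        for i in order:  # parents appear before children
            ps = [p for p in self.individuals[i].parent_ids if p is not None]
            self._depth[i] = 1 + max(self._depth[p] for p in ps) if ps else 0

    # -- basic queries ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, i: str) -> bool:
        return i in self.individuals

    def __getitem__(self, i: str) -> Individual:
        try:
            return self.individuals[i]
        except KeyError:
            raise KeyError(f"unknown individual id {i!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genealogy):
            return NotImplemented
        return self.individuals == other.individuals

    @property
    def founders(self) -> list[str]:
        return [i for i, ind in self.individuals.items() if ind.is_founder]

    def children_of(self, i: str) -> list[str]:
        self[i]
        return list(self._children[i])

    def depth(self, i: str) -> int:
        self[i]
        return self._depth[i]

    def topological_order(self) -> list[str]:
        """Ids ordered so every parent precedes its children."""
        return sorted(self.individuals, key=lambda i: (self._depth[i], i))

    def descendants(self, i: str) -> set[str]:
        """Transitive closure of child links below ``i`` (excluding ``i``)."""
        self[i]
        out: set[str] = set()
        stack = [i]
        while stack:
            for c in self._children[stack.pop()]:
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return out

    # -- ancestors & genetic distance -----------------------------------

    def ancestor_meioses(self, i: str) -> dict[str, int]:
        """Map every ancestor of ``i`` (including ``i`` itself, at 0) to the
        minimum meiosis count from ``i`` up to that ancestor."""
        cached = self._ancestors.get(i)
        if cached is not None:
            return cached
        self[i]
        anc = {i: 0}
        for p in self.individuals[i].parent_ids:
            if p is None:
                continue
            for a, d in self.ancestor_meioses(p).items():
                nd = d + 1
                if anc.get(a, nd + 1) > nd:
                    anc[a] = nd
        self._ancestors[i] = anc
        return anc

    def genetic_distance(self, a: str, b: str) -> int | None:
        """Minimum meioses linking ``a`` and ``b`` through a common ancestor.

        Returns ``None`` when the pair shares no common ancestor.  A parent
        and its child are at distance 1, siblings at 2, avunculars at 3,
        first cousins at 4.
        """
        if a == b:
            raise ValueError("genetic distance requires two distinct individuals")
        da, db = self.ancestor_meioses(a), self.ancestor_meioses(b)
        if len(db) < len(da):
            da, db = db, da
        best: int | None = None
        for c, d1 in da.items():
            d2 = db.get(c)
            if d2 is not None and (best is None or d1 + d2 < best):
                best = d1 + d2
        return best

    # -- Malécot kinship -------------------------------------------------

    def kinship(self, a: str, b: str) -> float:
        """Malécot coefficient of kinship ``phi(a, b)``.

        Computed by the standard recursion: ``phi(a, a) = (1 + phi(father_a,
        mother_a)) / 2`` and, for distinct individuals with ``a`` the one of
        greater generation depth, ``phi(a, b) = (phi(father_a, b) +
        phi(mother_a, b)) / 2``; missing parents contribute 0 and distinct
        founders have ``phi = 0``.  Inbreeding loops are handled exactly.
        """
        self[a], self[b]
        return self._kinship(a, b)

    def _kinship(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        phi = self._kin.get(key)
        if phi is not None:
            return phi
        if a == b:
            ind = self.individuals[a]
            f, m = ind.parent_ids
            phi = 0.5 * (1.0 + (self._kinship(f, m) if f and m else 0.0))
        elif self.ancestor_meioses(a).keys().isdisjoint(self.ancestor_meioses(b)):
            phi = 0.0
        else:
            # expand the deeper member: it cannot be an ancestor of the other
            if self._depth[a] < self._depth[b]:
                a, b = b, a
            f, m = self.individuals[a].parent_ids
            phi = 0.5 * (
                (self._kinship(f, b) if f else 0.0)
                + (self._kinship(m, b) if m else 0.0)
            )
        self._kin[key] = phi
        return phi

    def all_pairs_kinship(self, ids: Iterable[str]) -> PairKinship:
        """Kinship and genetic distance for every unordered pair in ``ids``.

        Pairs sharing no common ancestor are not enumerated individually: a
        shared-ancestor index prefilters the candidate pairs, so cost scales
        with the number of related pairs rather than with all ``n**2``.
        """
        id_list = sorted(set(ids))
        for i in id_list:
            self[i]
        by_ancestor: dict[str, list[str]] = {}
        for i in id_list:
            for a in self.ancestor_meioses(i):
                by_ancestor.setdefault(a, []).append(i)
        candidates: set[tuple[str, str]] = set()
        for members in by_ancestor.values():
            if len(members) < 2:
                continue
            for x in range(len(members) - 1):
                for y in range(x + 1, len(members)):
                    candidates.add((members[x], members[y]))
        related: dict[tuple[str, str], tuple[float, int]] = {}
        for a, b in candidates:
            phi = self._kinship(a, b)
            dist = self.genetic_distance(a, b)
            related[(a, b)] = (phi, dist)
        return PairKinship(id_list, related)

    # -- eligibility filter ----------------------------------------------

    def ancestral_subset(self, birth_cutoff_year: int) -> set[str]:
        """Ids with ancestral genealogy data: born strictly before the
        cutoff year, both parents recorded, all four grandparent slots
        filled, and at least six of the eight great-grandparent slots filled
        (slots counted positionally through the parent links)."""
        out: set[str] = set()
        for i, ind in self.individuals.items():
            if ind.birth_year is None or ind.birth_year >= birth_cutoff_year:
                continue
            parents = [p for p in ind.parent_ids if p is not None]
            if len(parents) != 2:
                continue
            grandparents = []
            for p in parents:
                grandparents.extend(q for q in self.individuals[p].parent_ids)
            if sum(q is not None for q in grandparents) != 4:
                continue
            ggp_filled = 0
            for q in grandparents:
                ggp_filled += sum(
                    r is not None for r in self.individuals[q].parent_ids
                )
            if ggp_filled >= 6:
                out.add(i)
        return out


# -- file I/O -------------------------------------------------------------


def _parse_bool(v) -> bool | None:
    if pd.isna(v) or v == "":
        return None
    if isinstance(v, str):
        s = v.strip().lower()
        if s in ("1", "true", "t", "yes"):
            return True
        if s in ("0", "false", "f", "no"):
            return False
        raise PedigreeError(f"cannot parse boolean attribute value {v!r}")
    return bool(int(v))


def read_pedigree(
    pedigree_path: str | Path | io.TextIOBase,
    attribute_path: str | Path | io.TextIOBase | None = None,
) -> Genealogy:
    """Load a genealogy from a FAM-style pedigree table plus an optional
    per-individual attribute CSV.

    The pedigree table is whitespace-delimited with columns ``id father
    mother sex`` where sex is coded 1=male, 2=female, 0=unknown and ``0``
    (or empty) denotes a missing parent.  The attribute CSV is keyed by
    ``id``; rows for ids absent from the pedigree are rejected.
    """
    ped = pd.read_csv(
        pedigree_path,
        sep=r"\s+",
        header=None,
        names=["id", "father", "mother", "sex"],
        dtype=str,
        comment="#",
    )
    if ped.isna().any().any():
        raise PedigreeError("pedigree table has missing fields (expect 4 columns)")
    individuals: dict[str, Individual] = {}
    for row in ped.itertuples(index=False):
        if row.id in individuals:
            raise PedigreeError(f"duplicate individual id {row.id!r}")
        sex = _SEX_CODES.get(row.sex)
        if sex is None:
            raise PedigreeError(f"invalid sex code {row.sex!r} for {row.id!r}")
        individuals[row.id] = Individual(
            id=row.id,
            father_id=None if row.father == "0" else row.father,
            mother_id=None if row.mother == "0" else row.mother,
            sex=sex,
        )
    if attribute_path is not None:
        attrs = pd.read_csv(attribute_path, dtype=str)
        if "id" not in attrs.columns:
            raise PedigreeError("attribute table must have an 'id' column")
        for rec in attrs.to_dict("records"):
            i = rec.pop("id")
            ind = individuals.get(i)
            if ind is None:
                raise PedigreeError(
                    f"attribute row for id {i!r} absent from the pedigree table"
                )
            for k, v in rec.items():
                if pd.isna(v) or v == "":
                    continue
                if k in _BOOL_ATTRS:
                    v = _parse_bool(v)
                elif k in _INT_ATTRS:
                    v = int(float(v))
                else:
                    try:
                        v = float(v)
                    except ValueError:
                        pass
                if k == "birth_year":
                    ind.birth_year = v
                elif k == "birth_in_state":
                    ind.birth_in_state = v
                elif k == "has_death_record":
                    ind.has_death_record = bool(v)
                else:
                    ind.attributes[k] = v
    return Genealogy(individuals.values())


def write_pedigree(
    g: Genealogy,
    pedigree_path: str | Path,
    attribute_path: str | Path | None = None,
) -> None:
    """Write the FAM-style pedigree table and (optionally) the attribute CSV
    in the same dialect :func:`read_pedigree` accepts."""
    order = g.topological_order()
    with open(pedigree_path, "w") as fh:
        for i in order:
            ind = g[i]
            fh.write(
                f"{i} {ind.father_id or '0'} {ind.mother_id or '0'} "
                f"{_SEX_TO_CODE[ind.sex]}\n"
            )
    if attribute_path is None:
        return
    rows = []
    for i in order:
        ind = g[i]
        row: dict = {"id": i}
        row["birth_year"] = ind.birth_year
        row["birth_in_state"] = (
            None if ind.birth_in_state is None else int(ind.birth_in_state)
        )
        row["has_death_record"] = int(ind.has_death_record)
        for k in ATTRIBUTE_COLUMNS[3:]:
            v = ind.attributes.get(k)
            if isinstance(v, bool):
                v = int(v)
            row[k] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in df.columns:
        if col == "id":
            continue
        df[col] = df[col].astype("Float64")
        if col in _INT_ATTRS or col in _BOOL_ATTRS:
            df[col] = df[col].astype("Int64")
    df.to_csv(attribute_path, index=False)
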