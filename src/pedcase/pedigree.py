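"""Pedigree data model and identity-by-descent computations.

A pedigree is a directed acyclic parentage graph over individuals.  This
module provides loading/validation of delimited pedigree tables, kinship
(coancestry) computation by the standard tabular recursion, inbreeding
coefficients, cohort summaries, and detection of ancestors shared between
a proband's paternal and maternal lineages (pedigree loops).

Kinship phi(i, j) is the probability that one allele drawn at random from
i and one from j are identical by descent.  The tabular recursion, applied
in topological (parents-first) order, is

    phi(i, i) = (1 + phi(sire_i, dam_i)) / 2
    phi(i, j) = (phi(sire_i, j) + phi(dam_i, j)) / 2     for j earlier than i

with unknown parents contributing 0.  The inbreeding coefficient is
F_i = phi(sire_i, dam_i), i.e. the kinship of the parents.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "KinshipMatrix",
    "PedigreeError",
    "CycleError",
    "load_pedigree",
    "write_pedigree",
    "kinship",
    "kinship_matrix",
    "inbreeding_coefficient",
    "cohort_mean_inbreeding",
    "common_lineage_ancestors",
]

SEXES = ("male", "female", "unknown")
PHENOTYPES = ("affected", "unaffected", "unknown")

#: dense kinship matrices are only built up to this many individuals;
#: beyond it, use the memoized pairwise `kinship` instead
MAX_DENSE = 20_000


class PedigreeError(ValueError):
    """Structural or validation problem in a pedigree."""


class CycleError(PedigreeError):
    """The parentage graph contains a directed cycle."""


@dataclass(frozen=True)
class Individual:
    """One animal record.

    ``sire``/``dam`` are ``None`` when the parent is unknown.
    ``death_age_months`` is ``None`` for animals with no recorded death.
    ``vital_status`` (dead/alive/unknown), when present, overrides the
    default inference from ``death_age_months``; ``cause`` distinguishes
    natural deaths from culling.
    """

    id: str
    sire: Optional[str] = None
    dam: Optional[str] = None
    sex: str = "unknown"
    birth_year: Optional[int] = None
    death_age_months: Optional[float] = None
    phenotype: str = "unknown"
    cause: Optional[str] = None
    vital_status: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeError("individual id must be non-empty")
        if self.sire == self.id or self.dam == self.id:
            raise PedigreeError(f"individual {self.id!r} is its own parent")
        if self.sex not in SEXES:
            raise PedigreeError(f"invalid sex {self.sex!r} for {self.id!r}")
        if self.phenotype not in PHENOTYPES:
            raise PedigreeError(
                f"invalid phenotype {self.phenotype!r} for {self.id!r}"
            )
        if self.death_age_months is not None and self.death_age_months < 0:
            raise PedigreeError(f"negative death age for {self.id!r}")


class Pedigree:
    """A validated pedigree with a fixed topological order.

    The order is computed by Kahn's algorithm with ties broken by input
    order, so the same file always yields the same ordering.
    """

    def __init__(
        self, individuals: Iterable[Individual], auto_founders: bool = True
    ) -> None:
        inds: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in inds:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            inds[ind.id] = ind
        # resolve referenced-but-absent parents
        missing: list[str] = []
        for ind in list(inds.values()):
            for pid in (ind.sire, ind.dam):
                if pid is not None and pid not in inds:
                    missing.append(pid)
        if missing:
            if not auto_founders:
                raise PedigreeError(
                    f"parent id(s) referenced but absent: {sorted(set(missing))}"
                )
            for pid in missing:
                if pid not in inds:
                    inds[pid] = Individual(id=pid)
        self._check_sex_consistency(inds)
        self._inds = inds
        self.order: list[str] = self._toposort(inds)
        self._rank = {iid: k for k, iid in enumerate(self.order)}
        self._kin_cache: dict[tuple[str, str], float] = {}
        self._progeny: Optional[dict[str, list[str]]] = None

    @staticmethod
    def _check_sex_consistency(inds: dict[str, Individual]) -> None:
        as_sire = {i.sire for i in inds.values() if i.sire is not None}
        as_dam = {i.dam for i in inds.values() if i.dam is not None}
        both = as_sire & as_dam
        if both:
            raise PedigreeError(
                f"id(s) used as both sire and dam: {sorted(both)}"
            )
        for pid in as_sire:
            if inds[pid].sex == "female":
                raise PedigreeError(f"female {pid!r} listed as a sire")
        for pid in as_dam:
            if inds[pid].sex == "male":
                raise PedigreeError(f"male {pid!r} listed as a dam")

    @staticmethod
    def _toposort(inds: dict[str, Individual]) -> list[str]:
        input_pos = {iid: k for k, iid in enumerate(inds)}
        children: dict[str, list[str]] = {iid: [] for iid in inds}
        indeg = {iid: 0 for iid in inds}
        for ind in inds.values():
            for pid in (ind.sire, ind.dam):
                if pid is not None:
                    children[pid].append(ind.id)
                    indeg[ind.id] += 1
        heap = [(input_pos[i], i) for i, d in indeg.items() if d == 0]
        heapq.heapify(heap)
        order: list[str] = []
        while heap:
            _, iid = heapq.heappop(heap)
            order.append(iid)
            for c in children[iid]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    heapq.heappush(heap, (input_pos[c], c))
        if len(order) < len(inds):
            g = nx.DiGraph()
            for ind in inds.values():
                for pid in (ind.sire, ind.dam):
                    if pid is not None:
                        g.add_edge(pid, ind.id)
            cyc = nx.find_cycle(g)
            raise CycleError(
                f"parentage cycle involving individual {cyc[0][0]!r}"
            )
        return order

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self._inds)

    def __contains__(self, iid: str) -> bool:
        return iid in self._inds

    def __getitem__(self, iid: str) -> Individual:
        try:
            return self._inds[iid]
        except KeyError:
            raise KeyError(f"no individual {iid!r} in pedigree") from None

    def __iter__(self):
        return iter(self.order)

    @property
    def individuals(self) -> Sequence[Individual]:
        return [self._inds[i] for i in self.order]

    def founders(self) -> list[str]:
        return [
            i.id
            for i in self._inds.values()
            if i.sire is None and i.dam is None
        ]

    def rank(self, iid: str) -> int:
        return self._rank[iid]

    def ancestors(self, iid: str, include_self: bool = False) -> set[str]:
        """All ancestors of ``iid`` reachable through known parents."""
        seen: set[str] = set()
        stack = [iid]
        while stack:
            cur = self._inds[stack.pop()]
            for pid in (cur.sire, cur.dam):
                if pid is not None and pid not in seen:
                    seen.add(pid)
                    stack.append(pid)
        if include_self:
            seen.add(iid)
        return seen

    def progeny(self, iid: str) -> list[str]:
        """Offspring that list ``iid`` as sire or dam (built lazily)."""
        if self._progeny is None:
            prog: dict[str, list[str]] = {i: [] for i in self._inds}
            for ind in self.individuals:
                for pid in (ind.sire, ind.dam):
                    if pid is not None:
                        prog[pid].append(ind.id)
            self._progeny = prog
        return self._progeny[self[iid].id]

    def with_individuals(self, extra: Iterable[Individual]) -> "Pedigree":
        """A new pedigree with additional individuals appended."""
        return Pedigree(list(self.individuals) + list(extra))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind in self.individuals:
            rows.append(
                {
                    "id": ind.id,
                    "sire": ind.sire or "0",
                    "dam": ind.dam or "0",
                    "sex": ind.sex,
                    "birth_year": ind.birth_year,
                    "death_age_months": ind.death_age_months,
                    "phenotype": ind.phenotype,
                    "cause": ind.cause,
                    "vital_status": ind.vital_status,
                }
            )
        return pd.DataFrame(rows)


def _norm_parent(v) -> Optional[str]:
    if v is None:
        return None
    s = str(v).strip()
    if s in ("", "0", "nan", "NA", "<NA>", "None"):
        return None
    return s


def _norm_opt_num(v, cast):
    if v is None:
        return None
    s = str(v).strip()
    if s in ("", "nan", "NA", "<NA>", "None"):
        return None
    return cast(float(s))


def load_pedigree(
    source, sep: Optional[str] = None, auto_founders: bool = True
) -> Pedigree:
    """Read a pedigree from delimited text (comma/tab auto-detected).

    The header must include ``id``, ``sire`` and ``dam``; ``sex``,
    ``birth_year``, ``death_age_months``, ``phenotype``, ``cause`` and
    ``vital_status`` are optional.  Unknown parents are encoded as "0" or
    an empty field.  With ``auto_founders`` (default), a parent id that
    has no row of its own is created as a founder; otherwise it is an
    error.
    """
    df = pd.read_csv(
        source, sep=sep, engine="python", dtype=str, keep_default_na=False
    )
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"id", "sire", "dam"}
    if not required.issubset(df.columns):
        raise PedigreeError(
            f"pedigree table must have columns {sorted(required)}; "
            f"got {list(df.columns)}"
        )
    inds = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        inds.append(
            Individual(
                id=str(rec["id"]).strip(),
                sire=_norm_parent(rec.get("sire")),
                dam=_norm_parent(rec.get("dam")),
                sex=(rec.get("sex") or "unknown").strip() or "unknown",
                birth_year=_norm_opt_num(rec.get("birth_year"), int),
                death_age_months=_norm_opt_num(
                    rec.get("death_age_months"), float
                ),
                phenotype=(rec.get("phenotype") or "unknown").strip()
                or "unknown",
                cause=_norm_parent(rec.get("cause")),
                vital_status=_norm_parent(rec.get("vital_status")),
            )
        )
    return Pedigree(inds, auto_founders=auto_founders)


def write_pedigree(ped: Pedigree, path, sep: str = ",") -> None:
    """Write a pedigree back to delimited text (round-trips load_pedigree)."""
    df = ped.to_frame()
    df.to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class KinshipMatrix:
    """Dense symmetric kinship matrix over ``ids`` (topological order)."""

    ids: tuple[str, ...]
    values: np.ndarray

    def loc(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Full kinship matrix by the tabular recursion in topological order.

    Equivalent to the coancestry obtained from the Cholesky-based direct
    construction of the numerator relationship matrix (A = 2 * phi).
    Dense output is limited to ``MAX_DENSE`` individuals; use
    :func:`kinship` for per-pair values on larger pedigrees.
    """
    n = len(ped)
    if n > MAX_DENSE:
        raise PedigreeError(
            f"dense kinship matrix limited to {MAX_DENSE} individuals "
            f"(got {n}); use kinship(ped, a, b) instead"
        )
    rank = ped._rank
    si = np.full(n, -1, dtype=np.int64)
    di = np.full(n, -1, dtype=np.int64)
    for k, iid in enumerate(ped.order):
        ind = ped[iid]
        if ind.sire is not None:
            si[k] = rank[ind.sire]
        if ind.dam is not None:
            di[k] = rank[ind.dam]
    K = np.zeros((n, n))
    for i in range(n):
        s, d = si[i], di[i]
        if s >= 0 and d >= 0:
            row = 0.5 * (K[s, :i] + K[d, :i])
            diag = 0.5 * (1.0 + K[s, d])
        elif s >= 0:
            row = 0.5 * K[s, :i]
            diag = 0.5
        elif d >= 0:
            row = 0.5 * K[d, :i]
            diag = 0.5
        else:
            row = np.zeros(i)
            diag = 0.5
        K[i, :i] = row
        K[:i, i] = row
        K[i, i] = diag
    return KinshipMatrix(ids=tuple(ped.order), values=K)


def kinship(ped: Pedigree, a: str, b: str) -> float:
    """Pairwise kinship by memoized recursion (no dense matrix needed)."""
    for iid in (a, b):
        if iid not in ped:
            raise KeyError(f"no individual {iid!r} in pedigree")
    rank = ped._rank
    cache = ped._kin_cache

    def phi(x: Optional[str], y: Optional[str]) -> float:
        if x is None or y is None:
            return 0.0
        if rank[x] < rank[y]:
            x, y = y, x
        key = (x, y)
        v = cache.get(key)
        if v is not None:
            return v
        ind = ped[x]
        if x == y:
            v = 0.5 * (1.0 + phi(ind.sire, ind.dam))
        else:
            v = 0.5 * (phi(ind.sire, y) + phi(ind.dam, y))
        cache[key] = v
        return v

    return phi(a, b)


def inbreeding_coefficient(ped: Pedigree, iid: str) -> float:
    """F = kinship of the parents; 0 if either parent is unknown."""
    ind = ped[iid]
    if ind.sire is None or ind.dam is None:
        return 0.0
    return kinship(ped, ind.sire, ind.dam)


def cohort_mean_inbreeding(
    ped: Pedigree, birth_year: int, sex: Optional[str] = None
) -> float:
    """Mean F over individuals born in ``birth_year`` (optionally one sex)."""
    cohort = [
        i.id
        for i in ped.individuals
        if i.birth_year == birth_year and (sex is None or i.sex == sex)
    ]
    if not cohort:
        raise PedigreeError(
            f"empty cohort: no individuals born {birth_year}"
            + (f" with sex {sex!r}" if sex else "")
        )
    return float(np.mean([inbreeding_coefficient(ped, i) for i in cohort]))


def common_lineage_ancestors(ped: Pedigree, proband: str) -> set[str]:
    """Ancestors present in both the paternal and maternal lineages.

    Returns the intersection of the sire-side and dam-side ancestor sets
    (each side including the parent itself).  Every returned id implies at
    least one pedigree loop through the proband and is a candidate source
    of autozygosity.
    """
    ind = ped[proband]
    if ind.sire is None or ind.dam is None:
        raise PedigreeError(
            f"proband {proband!r} must have both parents known to search "
            "for lineage loops"
        )
    paternal = ped.ancestors(ind.sire, include_self=True)
    maternal = ped.ancestors(ind.dam, include_self=True)
    return paternal & maternal
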