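"""Pedigree handling and pedigree-based kinship matrices.

Families are described in LINKAGE/PED-style records (family id, individual
id, father, mother, sex).  The kinship coefficient phi between two
individuals is the probability that two alleles, one drawn at random from
each, are identical by descent.  Under a polygenic model the additive
genetic covariance among relatives is ``2 * K * sigma_g^2`` with ``K`` the
matrix of kinship coefficients, which is what the mixed-model engine uses
as its genetic kernel.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeError",
    "PedRecord",
    "Pedigree",
    "KinshipMatrix",
    "parse_pedigree",
    "write_pedigree",
    "kinship_matrix",
]

MISSING_PARENT = "0"

SEX_UNKNOWN = 0


class PedigreeError(ValueError):
    """Structural or validation problem in a pedigree."""


@dataclass(frozen=True)
class PedRecord:
    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: int  # 1 = male, 2 = female, 0 = unknown

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """A validated multi-family pedigree.

    Invariants enforced at construction:

    * individual ids are unique across the whole pedigree;
    * each individual either has both parents missing (founder) or both
      parents present as records of the same family;
    * the parent-child graph is acyclic.
    """

    def __init__(self, records: Sequence[PedRecord]):
        self.records: list[PedRecord] = list(records)
        self._by_id: dict[str, PedRecord] = {}
        for idx, rec in enumerate(self.records):
            if rec.individual_id in self._by_id:
                raise PedigreeError(
                    f"duplicate individual id {rec.individual_id!r} (row {idx + 1})"
                )
            self._by_id[rec.individual_id] = rec
        self._validate_parents()
        self._topo_order = self._topological_order()

    # -- validation -----------------------------------------------------

    def _validate_parents(self) -> None:
        for idx, rec in enumerate(self.records):
            parents = (rec.father_id, rec.mother_id)
            n_missing = sum(p is None for p in parents)
            if n_missing == 1:
                raise PedigreeError(
                    f"individual {rec.individual_id!r} (row {idx + 1}) has exactly "
                    "one known parent; both must be present or both missing"
                )
            if n_missing == 2:
                continue
            for role, pid in zip(("father", "mother"), parents):
                if pid not in self._by_id:
                    raise PedigreeError(
                        f"unknown {role} id {pid!r} for individual "
                        f"{rec.individual_id!r} (row {idx + 1})"
                    )
                if self._by_id[pid].family_id != rec.family_id:
                    raise PedigreeError(
                        f"{role} {pid!r} of {rec.individual_id!r} belongs to a "
                        "different family"
                    )

    def _topological_order(self) -> list[str]:
        # Kahn's algorithm on parent -> child edges; a leftover node means a cycle.
        children = collections.defaultdict(list)
        n_parents = {rec.individual_id: 0 for rec in self.records}
        for rec in self.records:
            if rec.is_founder:
                continue
            n_parents[rec.individual_id] = 2
            children[rec.father_id].append(rec.individual_id)
            children[rec.mother_id].append(rec.individual_id)
        queue = collections.deque(
            rec.individual_id for rec in self.records if rec.is_founder
        )
        order: list[str] = []
        while queue:
            iid = queue.popleft()
            order.append(iid)
            for child in children[iid]:
                n_parents[child] -= 1
                if n_parents[child] == 0:
                    queue.append(child)
        if len(order) != len(self.records):
            stuck = sorted(set(n_parents) - set(order))
            raise PedigreeError(
                f"cyclic ancestry involving individual(s): {', '.join(stuck[:5])}"
            )
        return order

    # -- access ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def __getitem__(self, individual_id: str) -> PedRecord:
        return self._by_id[individual_id]

    @property
    def individual_ids(self) -> list[str]:
        return [rec.individual_id for rec in self.records]

    @property
    def founders(self) -> list[PedRecord]:
        return [rec for rec in self.records if rec.is_founder]

    @property
    def family_ids(self) -> list[str]:
        """Family ids in first-appearance order."""
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.family_id, None)
        return list(seen)

    def family_of(self, individual_id: str) -> str:
        return self._by_id[individual_id].family_id

    def members(self, family_id: str) -> list[str]:
        return [r.individual_id for r in self.records if r.family_id == family_id]

    def topological_order(self) -> list[str]:
        """Individual ids with every parent preceding its children."""
        return list(self._topo_order)


def _parse_parent(token: str) -> str | None:
    return None if token == MISSING_PARENT else token


def parse_pedigree(path: str | Path, header: bool = False) -> Pedigree:
    """Read a whitespace-delimited PED-like file.

    Columns: FID IID FATHER MOTHER SEX, with ``"0"`` coding a missing
    parent.  Extra columns are ignored.  Set ``header=True`` if the first
    line is a header row.
    """
    records: list[PedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) < 4:
                raise PedigreeError(
                    f"{path}: line {lineno}: expected at least 4 columns, "
                    f"got {len(tokens)}"
                )
            sex = SEX_UNKNOWN
            if len(tokens) >= 5:
                try:
                    sex = int(tokens[4])
                except ValueError as exc:
                    raise PedigreeError(
                        f"{path}: line {lineno}: sex must be integer-coded"
                    ) from exc
                if sex not in (0, 1, 2):
                    raise PedigreeError(
                        f"{path}: line {lineno}: sex code {sex} not in {{0,1,2}}"
                    )
            records.append(
                PedRecord(
                    family_id=tokens[0],
                    individual_id=tokens[1],
                    father_id=_parse_parent(tokens[2]),
                    mother_id=_parse_parent(tokens[3]),
                    sex=sex,
                )
            )
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    """Write a pedigree as a headerless PED-like file."""
    with open(path, "w") as fh:
        for rec in ped.records:
            fh.write(
                f"{rec.family_id}\t{rec.individual_id}\t"
                f"{rec.father_id or MISSING_PARENT}\t"
                f"{rec.mother_id or MISSING_PARENT}\t{rec.sex}\n"
            )


@dataclass
class KinshipMatrix:
    """Symmetric matrix of kinship coefficients indexed by individual id."""

    ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match id count")
        self._index = {iid: i for i, iid in enumerate(self.ids)}

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self._index[i], self._index[j]])

    def subset(self, ids: Iterable[str]) -> "KinshipMatrix":
        ids = list(ids)
        idx = [self._index[i] for i in ids]
        return KinshipMatrix(ids, self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy())


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Kinship coefficients by the standard recursive (tabular) method.

    Individuals are processed in topological order so parents are always
    available before their children:

    * founder: phi_ii = 1/2 and phi with any earlier individual is 0
      (founders are assumed unrelated, also across families);
    * non-founder with parents f, m: phi_ii = (1 + phi_fm) / 2 and, for any
      earlier individual j, phi_ij = (phi_fj + phi_mj) / 2.

    Inbred pedigrees are handled by the same recursion (phi_ii > 1/2).
    """
    ids = ped.individual_ids
    index = {iid: i for i, iid in enumerate(ids)}
    n = len(ids)
    phi = np.zeros((n, n))
    done: list[int] = []
    for iid in ped.topological_order():
        i = index[iid]
        rec = ped[iid]
        if rec.is_founder:
            phi[i, i] = 0.5
        else:
            f = index[rec.father_id]
            m = index[rec.mother_id]
            phi[i, i] = 0.5 * (1.0 + phi[f, m])
            if done:
                prev = np.array(done)
                vals = 0.5 * (phi[f, prev] + phi[m, prev])
                phi[i, prev] = vals
                phi[prev, i] = vals
        done.append(i)
    return KinshipMatrix(ids, phi)
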