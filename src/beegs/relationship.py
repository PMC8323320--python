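"""Honey-bee numerator relationship matrix with pseudo-fathers and worker groups.

The numerator relationship is defined as ``a = 2 f`` where ``f`` is the
kinship (probability of identity by descent of two randomly drawn alleles)
under honey-bee transmission rules:

* a queen's genome is half a gamete of her dam and half the genome of her
  sire drone; drones are haploid and hatch from unfertilized eggs, so a
  drone *is* a single gamete of its dam (a drone-producing queen, DPQ),
  and all its sperm are identical;
* the pedigree sire of a queen is a *pseudo-father*: the group of sister
  DPQ resident on her mating station.  Which member DPQ produced the sire
  drone is unknown, so the pseudo-father acts as the uniform mixture over
  its members;
* a *worker group* is the expectation over infinitely many workers of one
  colony; each worker is a gamete of the colony queen plus the genome of
  one of the queen's stored drones.

These rules give the tabular recursions implemented here.  For a queen
with dam ``D`` and pseudo-father ``S``::

    a(Q, X) = (a(D, X) + a(S, X)) / 2          for earlier entities X
    a(Q, Q) = 1 + F_Q,   F_Q = a(D, S) / 2

A pseudo-father of ``n_D`` sister DPQ (shared dam ``D`` mated at station
``S``) has the member mean as off-diagonal rows and the full member-grid
mean as its diagonal::

    A_pp = (1 + F_d)/n_D + (n_D - 1)/n_D * A_db

where ``F_d = a(D, S)/2`` is the members' inbreeding coefficient and
``A_db`` the relationship between two sister DPQ.  Sisters (and likewise
two workers of one colony) may share the same sire drone (the dam stores
``n_drones`` drones) or distinct drones reared from the same or different
station DPQ, giving::

    A_db = a(D, D)/4 + a(D, S)/2 + s/4
    s    = 2/n_drones + (1 - 1/n_drones) * a(S, S)

The same grid value ``s`` yields the worker-group diagonal
``a(W, W) = a(Q, Q)/4 + a(Q, S)/2 + s/4`` whose base-population value is
the mean worker-worker relationship ``A_ii`` (0.32 for the default 12
drones from 8 unrelated DPQ).

A Monte-Carlo gene-dropping kinship estimator implementing the same
transmission rules serves as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeEntry",
    "Pedigree",
    "RelationshipMatrix",
    "build_numerator_A",
    "kinship_gene_drop",
    "extract_submatrix",
]

QUEEN = "queen"
PSEUDOFATHER = "pseudofather"
WORKER_GROUP = "worker_group"

_KINDS = (QUEEN, PSEUDOFATHER, WORKER_GROUP)


class MissingParentError(KeyError):
    """A referenced parent is absent from the pedigree and not flagged base."""


@dataclass(frozen=True)
class PedigreeEntry:
    """One entity of the bee pedigree.

    ``dam``/``sire`` are ids of earlier entries or ``None`` for unknown
    (base) parents.  ``sire`` is always a pseudo-father id.  For a
    pseudo-father, ``n_members`` is the number of resident sister DPQ and
    ``dam``/``sire`` are the parents *of the members*.  For a worker
    group, ``dam`` is the colony queen and ``sire`` her mating station's
    pseudo-father.  ``n_drones`` is the number of drones stored by the
    relevant dam (the colony queen for a worker group, the members' dam
    for a pseudo-father).  ``n_sire_members`` sizes an *unrecorded* base
    mating station (unknown ``sire``): its resident DPQ are taken to be
    unrelated and non-inbred, so its group self-relationship is
    ``1/n_sire_members``.
    """

    id: str
    kind: str
    dam: str | None = None
    sire: str | None = None
    year: int = 0
    n_members: int = 8
    n_drones: int = 12
    n_sire_members: int = 8
    #: explicit paternal group: ids of the individual DPQ of the mating
    #: station (used instead of ``sire`` when pseudo-fathers are kept as
    #: individual queens, e.g. to verify merging invariance)
    sire_group: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        # normalize ids to plain str (numpy str_ etc. would break the
        # mating-key bookkeeping used by the builder and the oracle)
        object.__setattr__(self, "id", str(self.id))
        if self.dam is not None:
            object.__setattr__(self, "dam", str(self.dam))
        if self.sire is not None:
            object.__setattr__(self, "sire", str(self.sire))
        if self.sire_group is not None:
            object.__setattr__(
                self, "sire_group", tuple(str(m) for m in self.sire_group)
            )
        if self.kind not in _KINDS:
            raise ValueError(f"unknown entity kind {self.kind!r}")
        if self.sire is not None and self.sire_group is not None:
            raise ValueError("give either sire or sire_group, not both")
        if self.kind == PSEUDOFATHER and self.n_members < 1:
            raise ValueError("pseudo-father needs at least one member DPQ")
        if self.n_drones < 1:
            raise ValueError("a fertilized queen stores at least one drone")


class Pedigree:
    """Ordered collection of pedigree entries (parents precede offspring)."""

    def __init__(self, entries: Iterable[PedigreeEntry] = ()):
        self.entries: list[PedigreeEntry] = []
        self.index: dict[str, int] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: PedigreeEntry) -> None:
        if entry.id in self.index:
            raise ValueError(f"duplicate id {entry.id!r}")
        parents = [entry.dam, entry.sire, *(entry.sire_group or ())]
        for parent in parents:
            if parent is not None and parent not in self.index:
                raise MissingParentError(
                    f"parent {parent!r} of {entry.id!r} not in pedigree"
                )
        self.index[entry.id] = len(self.entries)
        self.entries.append(entry)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.index

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        """Export as the CSV dialect used throughout the package."""
        return pd.DataFrame(
            {
                "id": [e.id for e in self.entries],
                "dam_id": [e.dam for e in self.entries],
                "pseudo_sire_id": [e.sire for e in self.entries],
                "type": [e.kind for e in self.entries],
                "year": [e.year for e in self.entries],
                "n_members": [e.n_members for e in self.entries],
                "n_drones": [e.n_drones for e in self.entries],
                "n_sire_members": [e.n_sire_members for e in self.entries],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        ped = cls()
        defaults = {"n_members": 8, "n_drones": 12, "n_sire_members": 8}
        for row in frame.itertuples(index=False):
            kwargs = {}
            for key, default in defaults.items():
                value = getattr(row, key, None)
                kwargs[key] = int(value) if value is not None and not pd.isna(value) else default
            dam = None if pd.isna(row.dam_id) else str(row.dam_id)
            sire = None if pd.isna(row.pseudo_sire_id) else str(row.pseudo_sire_id)
            ped.add(
                PedigreeEntry(
                    id=str(row.id),
                    kind=str(row.type),
                    dam=dam,
                    sire=sire,
                    year=int(row.year),
                    **kwargs,
                )
            )
        return ped


@dataclass
class RelationshipMatrix:
    """Dense symmetric numerator relationship matrix over pedigree entities."""

    ids: list[str]
    A: np.ndarray
    F: np.ndarray  # inbreeding coefficients (NaN for group entities)

    def __post_init__(self) -> None:
        self.index = {eid: i for i, eid in enumerate(self.ids)}

    def loc(self, id_a: str, id_b: str) -> float:
        return float(self.A[self.index[id_a], self.index[id_b]])

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        return extract_submatrix(self, ids)

    def to_coordinate_frame(self, atol: float = 0.0) -> pd.DataFrame:
        """Lower-triangle coordinate (i, j, value) text representation."""
        ii, jj = np.tril_indices(len(self.ids))
        vals = self.A[ii, jj]
        keep = np.abs(vals) > atol
        return pd.DataFrame(
            {
                "id_i": np.asarray(self.ids, dtype=object)[ii[keep]],
                "id_j": np.asarray(self.ids, dtype=object)[jj[keep]],
                "value": vals[keep],
            }
        )


def build_numerator_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Build the bee-specific numerator relationship matrix by tabular recursion.

    Entities must be ordered so that parents precede offspring (enforced
    by :class:`Pedigree`).  Unknown parents are base: unrelated,
    non-inbred; an unknown mating station behaves as a base
    pseudo-father of ``n_sire_members`` unrelated DPQ.

    Entities deriving their paternal contribution from the same mating
    (queen daughters, the worker group, and a pseudo-father of daughter
    DPQ all drawn from one dam's spermatheca) may share the very same
    stored drone, which the plain parent-average recursion cannot
    express.  The builder therefore inserts one latent *mating node* per
    dam's mating: its relationships to everything else are the mating
    station's, but its self-relationship is the shared-spermatheca grid
    value ``2/n_drones + (1 - 1/n_drones) * a(S, S)``.  Offspring recurse
    on (dam, mating node), which propagates the extra sib co-ancestry to
    all descendants and keeps the matrix positive semidefinite by
    construction (the node is the exchangeable-family common factor).
    The returned matrix contains only the real entities.
    """
    n = len(pedigree)
    idx = pedigree.index
    # augmented matrix: real entities (0..n-1 in pedigree order) first,
    # latent mating nodes appended as they are created
    size = n
    A = np.zeros((2 * n + 1, 2 * n + 1))
    F = np.full(n, np.nan)
    mating_node: dict[object, int] = {}

    def station_row_and_grid(e: PedigreeEntry) -> tuple[np.ndarray, float]:
        if e.sire_group is not None:
            g = np.array([idx[m] for m in e.sire_group], dtype=np.intp)
            return A[g, :].mean(axis=0), float(A[np.ix_(g, g)].mean())
        if e.sire is not None:
            s = idx[e.sire]
            return A[s, :].copy(), float(A[s, s])
        return np.zeros(A.shape[0]), 1.0 / e.n_sire_members

    def get_mating_node(e: PedigreeEntry) -> int:
        nonlocal size
        sire_key = e.sire_group if e.sire_group is not None else e.sire
        # an unknown-dam entity gets a private node; the key must not
        # collide with the node of the entity's own mating as a dam
        key = (
            (e.dam, sire_key)
            if e.dam is not None
            else (("<unknown dam of>", e.id), sire_key)
        )
        if key in mating_node:
            return mating_node[key]
        row, a_ss = station_row_and_grid(e)
        c = size
        size += 1
        A[c, :c] = row[:c]
        A[:c, c] = row[:c]
        A[c, c] = 2.0 / e.n_drones + (1.0 - 1.0 / e.n_drones) * a_ss
        mating_node[key] = c
        return c

    for k, e in enumerate(pedigree.entries):
        d = idx[e.dam] if e.dam is not None else None
        is_base = d is None and e.sire is None and e.sire_group is None
        if is_base:
            c = None
        else:
            c = get_mating_node(e)
        dam_row = A[d, :size] if d is not None else np.zeros(size)
        node_row = A[c, :size] if c is not None else np.zeros(size)
        row = 0.5 * (dam_row + node_row)
        A[k, :k] = row[:k]
        A[k, k + 1 : size] = row[k + 1 : size]
        A[k + 1 : size, k] = row[k + 1 : size]
        A[:k, k] = row[:k]

        a_dc = A[d, c] if (d is not None and c is not None) else 0.0
        a_dd = A[d, d] if d is not None else 1.0
        a_cc = A[c, c] if c is not None else 0.0
        # covariance of two distinct offspring of this mating
        pair = 0.25 * a_dd + 0.5 * a_dc + 0.25 * a_cc

        if e.kind == QUEEN:
            F[k] = 0.5 * a_dc
            A[k, k] = 1.0 + F[k]
        elif e.kind == PSEUDOFATHER:
            if is_base:
                A[k, k] = 1.0 / e.n_members
            else:
                f_member = 0.5 * a_dc
                A[k, k] = (1.0 + f_member) / e.n_members + (
                    (e.n_members - 1.0) / e.n_members
                ) * pair
        else:  # worker group: infinite-size mean of the mating's offspring
            if d is None:
                raise MissingParentError(f"worker group {e.id!r} lacks a queen")
            A[k, k] = pair

    return RelationshipMatrix(ids=pedigree.ids, A=A[:n, :n].copy(), F=F)


def extract_submatrix(A: RelationshipMatrix, ids: Sequence[str]) -> np.ndarray:
    """Principal submatrix of ``A`` in the given id order."""
    try:
        sel = np.array([A.index[i] for i in ids], dtype=np.intp)
    except KeyError as err:
        raise KeyError(f"unknown id {err.args[0]!r}") from None
    return A.A[np.ix_(sel, sel)]


# ---------------------------------------------------------------------------
# Gene-dropping Monte-Carlo oracle


class UnderpoweredError(ValueError):
    """Too few gene-drop replicates for a meaningful estimate."""


class _DropState:
    """Realized single-locus genomes for all replicates of one gene drop."""

    def __init__(self, pedigree: Pedigree, n_rep: int, rng: np.random.Generator):
        self.ped = pedigree
        self.n = n_rep
        self.rng = rng
        self._next_founder = 0
        # queens: (n_rep, 2); pseudo-fathers: (n_rep, n_members, 2)
        self.genomes: dict[str, np.ndarray] = {}
        # spermatheca of each fertilized dam: (n_rep, n_drones) allele ids
        self._sperm: dict[str, np.ndarray] = {}
        for e in pedigree.entries:
            if e.kind == WORKER_GROUP:
                continue  # workers are sampled on demand
            self._realize(e)

    def _founders(self, shape: tuple[int, ...]) -> np.ndarray:
        count = int(np.prod(shape))
        ids = np.arange(self._next_founder, self._next_founder + count)
        self._next_founder += count
        return np.broadcast_to(ids.reshape(shape), (self.n, *shape)).copy()

    def _station_member_genomes(self, e: PedigreeEntry) -> np.ndarray:
        """(n_rep, n_members, 2) genomes of the sire station's DPQ."""
        if e.sire_group is not None:
            return np.stack([self.genomes[m] for m in e.sire_group], axis=1)
        if e.sire is not None:
            return self.genomes[e.sire]
        # unrecorded base station: unrelated non-inbred DPQ, cached per
        # *mating* so that all offspring of one dam share it
        key = f"__base_station__{e.dam}__{e.id if e.dam is None else ''}"
        if key not in self._sperm:  # reuse dict for cache bookkeeping
            self._sperm[key] = self._founders((e.n_sire_members, 2))
        return self._sperm[key]

    def _spermatheca(self, e: PedigreeEntry) -> np.ndarray:
        """Allele ids of the dam's stored drones for the mating producing e."""
        dam_key = e.dam if e.dam is not None else f"<unknown dam of {e.id}>"
        cache_id = f"__mating__{(dam_key, e.sire if e.sire_group is None else e.sire_group)}"
        if cache_id not in self._sperm:
            members = self._station_member_genomes(e)
            n_members = members.shape[1]
            rng = self.rng
            m_idx = rng.integers(0, n_members, size=(self.n, e.n_drones))
            a_idx = rng.integers(0, 2, size=(self.n, e.n_drones))
            rows = np.arange(self.n)[:, None]
            self._sperm[cache_id] = members[rows, m_idx, a_idx]
        return self._sperm[cache_id]

    def _gamete_of(self, dam_id: str | None) -> np.ndarray:
        if dam_id is None:
            return self._founders(())
        dam = self.genomes[dam_id]
        pick = self.rng.integers(0, 2, size=self.n)
        return dam[np.arange(self.n), pick]

    def _offspring(self, e: PedigreeEntry, count: int) -> np.ndarray:
        """(n_rep, count, 2) genomes of daughters of e's (dam, sire) mating."""
        rng = self.rng
        out = np.empty((self.n, count, 2), dtype=np.int64)
        if e.dam is None and e.sire is None:
            return self._founders((count, 2))
        if e.dam is not None:
            dam = self.genomes[e.dam]
            pick = rng.integers(0, 2, size=(self.n, count))
            maternal = dam[np.arange(self.n)[:, None], pick]
        else:
            maternal = self._founders((count,))
        sperm = self._spermatheca(e)
        s_idx = rng.integers(0, sperm.shape[1], size=(self.n, count))
        paternal = sperm[np.arange(self.n)[:, None], s_idx]
        out[..., 0] = maternal
        out[..., 1] = paternal
        return out

    def _realize(self, e: PedigreeEntry) -> None:
        if e.kind == QUEEN:
            self.genomes[e.id] = self._offspring(e, 1)[:, 0, :]
        elif e.kind == PSEUDOFATHER:
            self.genomes[e.id] = self._offspring(e, e.n_members)

    def sample_allele(self, entity_id: str) -> np.ndarray:
        """One uniformly drawn allele of the entity per replicate."""
        e = self.ped.entries[self.ped.index[entity_id]]
        rng = self.rng
        rows = np.arange(self.n)
        if e.kind == QUEEN:
            g = self.genomes[entity_id]
            return g[rows, rng.integers(0, 2, size=self.n)]
        if e.kind == PSEUDOFATHER:
            g = self.genomes[entity_id]
            m = rng.integers(0, g.shape[1], size=self.n)
            a = rng.integers(0, 2, size=self.n)
            return g[rows, m, a]
        # worker group: sample one worker, then one of its two alleles
        queen = self.genomes[e.dam]
        maternal = queen[rows, rng.integers(0, 2, size=self.n)]
        sperm = self._spermatheca(e)
        paternal = sperm[rows, rng.integers(0, sperm.shape[1], size=self.n)]
        worker = np.stack([maternal, paternal], axis=1)
        return worker[rows, rng.integers(0, 2, size=self.n)]


def kinship_gene_drop(
    pedigree: Pedigree,
    pair: tuple[str, str],
    n_replicates: int = 100_000,
    seed: int | np.random.Generator | None = 0,
) -> tuple[float, float]:
    """Monte-Carlo numerator relationship ``2 * P(IBD)`` with standard error.

    Drops single-locus founder alleles through the pedigree honoring the
    honey-bee transmission rules, then draws one random allele of each
    entity of the pair per replicate (independently, also for a diagonal
    pair).  Returns ``(a_hat, se)`` on the ``a = 2 f`` scale.
    """
    if n_replicates < 1000:
        raise UnderpoweredError("use at least 1000 gene-drop replicates")
    for ent in pair:
        if ent not in pedigree:
            raise KeyError(f"unknown id {ent!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    state = _DropState(pedigree, n_replicates, rng)
    x = state.sample_allele(pair[0])
    y = state.sample_allele(pair[1])
    p = float(np.mean(x == y))
    se = 2.0 * np.sqrt(p * (1.0 - p) / n_replicates)
    return 2.0 * p, se
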