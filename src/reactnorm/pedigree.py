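"""Pedigrees, numerator relationship matrices and hybrid incidence.

The additive relationship matrix A is built with the tabular (recursive)
method: for individual *i* with parents *s*, *d*,

    a_ii = 1 + 0.5 * a_sd          (inbreeding from related parents)
    a_ij = 0.5 * (a_js + a_jd)     for any j preceding i

Unknown parents are treated as unrelated, non-inbred founders.  For hybrid
individuals (one parent from each of two parental species) the model does
not carry an own additive effect per hybrid; instead each hybrid record is
linked to the general-combining-ability contributions of its two parents,
one per parental species (``a_H = g_E + g_J``).  With outbred, unrelated
parents the relationship among those contributions is the identity, and the
covariance of each contribution is half the corresponding coefficient
covariance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "HybridIncidence",
    "build_A",
    "mendelian_variance",
    "hybrid_incidence",
    "PedigreeError",
]

UNKNOWN = -1


class PedigreeError(ValueError):
    """Invalid pedigree: cycles, missing parents or taxon inconsistencies."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree (parents always precede offspring).

    ``sire`` / ``dam`` are integer indices into ``ids`` (``-1`` = unknown).
    ``taxon`` carries a label per individual (e.g. EL / JL / HL).
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    taxon: list
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.sire = np.asarray(self.sire, dtype=int)
        self.dam = np.asarray(self.dam, dtype=int)
        self._index = {i: k for k, i in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise PedigreeError("duplicate individual ids in pedigree")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, id_):
        try:
            return self._index[id_]
        except KeyError:
            raise PedigreeError(f"unknown individual id: {id_!r}") from None

    def has_offspring(self) -> np.ndarray:
        """Boolean mask: True where the individual appears as a parent."""
        mask = np.zeros(self.n, dtype=bool)
        for p in (self.sire, self.dam):
            mask[p[p >= 0]] = True
        return mask

    @classmethod
    def from_records(cls, records, taxa=None) -> "Pedigree":
        """Build from (id, sire_id, dam_id[, taxon]) tuples.

        ``None`` or ``""`` denotes an unknown parent.  Records are
        topologically sorted; a referenced parent must itself appear as an
        individual.  Cycles raise :class:`PedigreeError`.
        """
        rows = []
        for rec in records:
            if len(rec) == 3:
                i, s, d = rec
                t = ""
            else:
                i, s, d, t = rec[:4]
            rows.append((i, s, d, t))
        ids = [r[0] for r in rows]
        idset = set(ids)
        if len(idset) != len(ids):
            raise PedigreeError("duplicate individual ids in pedigree")

        def norm(p):
            if p is None or (isinstance(p, float) and np.isnan(p)) or p == "":
                return None
            return p

        parents = {}
        for i, s, d, t in rows:
            s, d = norm(s), norm(d)
            for p in (s, d):
                if p is not None and p not in idset:
                    raise PedigreeError(f"parent {p!r} of {i!r} is not in the pedigree")
            parents[i] = (s, d)

        # Kahn topological sort
        order: list = []
        n_parents_left = {
            i: sum(p is not None for p in parents[i]) for i in ids
        }
        children: dict = {i: [] for i in ids}
        for i in ids:
            for p in parents[i]:
                if p is not None:
                    children[p].append(i)
        queue = [i for i in ids if n_parents_left[i] == 0]
        seen = set()
        while queue:
            i = queue.pop(0)
            order.append(i)
            seen.add(i)
            for c in children[i]:
                n_parents_left[c] -= 1
                if n_parents_left[c] == 0:
                    queue.append(c)
        if len(order) != len(ids):
            raise PedigreeError("pedigree contains a cycle")

        idx = {i: k for k, i in enumerate(order)}
        sire = np.array(
            [idx[parents[i][0]] if parents[i][0] is not None else UNKNOWN for i in order]
        )
        dam = np.array(
            [idx[parents[i][1]] if parents[i][1] is not None else UNKNOWN for i in order]
        )
        taxmap = {r[0]: r[3] for r in rows}
        if taxa is not None:
            taxmap.update(taxa)
        return cls(ids=order, sire=sire, dam=dam, taxon=[taxmap[i] for i in order])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Pedigree":
        """Build from a table with columns id, sire, dam[, taxon]."""
        for col in ("id", "sire", "dam"):
            if col not in df.columns:
                raise PedigreeError(f"pedigree table lacks required column {col!r}")
        tax = df["taxon"] if "taxon" in df.columns else [""] * len(df)
        recs = list(zip(df["id"], df["sire"], df["dam"], tax))
        return cls.from_records(recs)

    def to_dataframe(self) -> pd.DataFrame:
        def name(k):
            return "" if k == UNKNOWN else self.ids[k]

        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": [name(k) for k in self.sire],
                "dam": [name(k) for k in self.dam],
                "taxon": self.taxon,
            }
        )


@dataclass
class RelationshipMatrix:
    """Dense numerator relationship matrix with its individual ordering."""

    ids: list
    matrix: np.ndarray

    def submatrix(self, indices) -> np.ndarray:
        indices = np.asarray(indices, dtype=int)
        return self.matrix[np.ix_(indices, indices)]


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method."""
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        a_sd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        if i == 0:
            continue
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return RelationshipMatrix(ids=list(ped.ids), matrix=A)


def mendelian_variance(ped: Pedigree, A: RelationshipMatrix) -> np.ndarray:
    """Mendelian-sampling variance coefficient d_i for each individual.

    Conditional on its parents' additive values, individual *i*'s value is
    ``N(0.5*(u_s + u_d), d_i * Sigma)`` with

        d_i = a_ii - 0.25 (a_ss + a_dd) - 0.5 a_sd    (both parents known)
        d_i = a_ii - 0.25 a_pp                        (one parent known)
        d_i = a_ii                                    (founder)
    """
    M = A.matrix
    d = np.empty(ped.n)
    for i in range(ped.n):
        s, t = ped.sire[i], ped.dam[i]
        v = M[i, i]
        if s >= 0:
            v -= 0.25 * M[s, s]
        if t >= 0:
            v -= 0.25 * M[t, t]
        if s >= 0 and t >= 0:
            v -= 0.5 * M[s, t]
        d[i] = v
    return d


@dataclass
class HybridIncidence:
    """Links each hybrid individual to its two parental-species parents.

    ``e_parents`` / ``j_parents`` list the distinct parents of the first and
    second parental species appearing as parents of hybrids; ``e_of`` /
    ``j_of`` map each hybrid (by position in ``hybrids``) to an index into
    those lists.  The contribution covariance for each side is
    ``Sigma ⊗ 0.5·I`` (outbred unrelated parents).
    """

    hybrids: list
    e_parents: list
    j_parents: list
    e_of: np.ndarray
    j_of: np.ndarray


def hybrid_incidence(
    ped: Pedigree, hybrid_taxon: str = "HL", species: tuple = ("EL", "JL")
) -> HybridIncidence:
    """Incidence structures mapping hybrids to parental-species contributions.

    Pure-species individuals are excluded.  A hybrid with two same-species
    parents (or an unknown parent) raises :class:`PedigreeError`.
    """
    sp_e, sp_j = species
    hybrids, e_ids, j_ids = [], [], []
    e_seen: dict = {}
    j_seen: dict = {}
    e_of, j_of = [], []
    for i in range(ped.n):
        if ped.taxon[i] != hybrid_taxon:
            continue
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 or d < 0:
            raise PedigreeError(
                f"hybrid {ped.ids[i]!r} must have two known parents"
            )
        tax = {ped.taxon[s]: s, ped.taxon[d]: d}
        if set(tax) != {sp_e, sp_j}:
            raise PedigreeError(
                f"hybrid {ped.ids[i]!r} needs one {sp_e} and one {sp_j} parent, "
                f"got taxa {sorted(ped.taxon[p] for p in (s, d))}"
            )
        pe, pj = tax[sp_e], tax[sp_j]
        if pe not in e_seen:
            e_seen[pe] = len(e_ids)
            e_ids.append(ped.ids[pe])
        if pj not in j_seen:
            j_seen[pj] = len(j_ids)
            j_ids.append(ped.ids[pj])
        hybrids.append(ped.ids[i])
        e_of.append(e_seen[pe])
        j_of.append(j_seen[pj])
    return HybridIncidence(
        hybrids=hybrids,
        e_parents=e_ids,
        j_parents=j_ids,
        e_of=np.asarray(e_of, dtype=int),
        j_of=np.asarray(j_of, dtype=int),
    )
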