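"""Pedigree data model and numerator-relationship (A) matrix kernels.

The pedigree is the backbone of an animal-model genetic evaluation: Wright's
numerator relationship matrix A describes expected additive-genetic covariance
between animals, and Henderson's mixed-model equations only ever need its
sparse inverse.  This module provides

* :class:`Pedigree` — an ordered animal/sire/dam table with birth metadata,
* :func:`prune_pedigree` — ancestor-horizon pruning around focal animals,
* :func:`tabular_A` — dense A by the tabular method (diagonals 1 + F),
* :func:`a_inverse` — sparse A⁻¹ by Henderson's rules with inbreeding from the
  Meuwissen–Luo recursion, optionally with unknown-parent groups absorbed
  Quaas–Pollak style,
* :func:`assign_upg` — deterministic unknown-parent-group assignment from
  birth year and origin.

Animals are kept in a canonical order (topological: birth year, then id) so
every matrix produced downstream shares one indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = 0  #: parent code for "unknown" in pedigree files


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycles, ordering, unknown ids)."""


@dataclass
class RelationshipMatrix:
    """A symmetric relationship kernel with its animal index.

    Parameters
    ----------
    values : dense ndarray or scipy sparse matrix
    ids : animal identifiers indexing rows/columns
    kind : label for provenance ("A", "A22", "Ainv", "G", "Gblend", "Hinv")
    group_ids : ids of unknown-parent-group columns appended after animals
        (only for augmented inverses).
    """

    values: object
    ids: list
    kind: str = "A"
    group_ids: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.ids)

    def toarray(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)

    def index_of(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([lookup[a] for a in ids], dtype=int)
        except KeyError as err:  # pragma: no cover - message path
            raise KeyError(f"animal {err.args[0]!r} not in relationship matrix") from err

    def submatrix(self, ids) -> "RelationshipMatrix":
        idx = self.index_of(ids)
        dense = self.toarray()
        return RelationshipMatrix(dense[np.ix_(idx, idx)], list(ids), kind=self.kind)


class Pedigree:
    """Ordered pedigree: parents precede offspring, ids unique, acyclic.

    ``sire``/``dam`` hold positional indices into the animal list, or -1 for
    an unknown parent.  Construction validates ordering and uniqueness.
    """

    def __init__(self, ids, sire_idx, dam_idx, birth_year=None, origin=None):
        self.ids = list(ids)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise PedigreeError("duplicate animal ids")
        self.sire = np.asarray(sire_idx, dtype=int)
        self.dam = np.asarray(dam_idx, dtype=int)
        if self.sire.shape != (n,) or self.dam.shape != (n,):
            raise PedigreeError("parent index arrays must match animal count")
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            bad = (par >= np.arange(n)) & (par >= 0)
            if bad.any():
                raise PedigreeError(
                    f"{name} must precede offspring in ordering "
                    f"(violated at position {int(np.where(bad)[0][0])})"
                )
        self.birth_year = (
            np.zeros(n, dtype=int) if birth_year is None else np.asarray(birth_year, dtype=int)
        )
        self.origin = ["base"] * n if origin is None else list(origin)
        self._pos = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def position(self, animal) -> int:
        try:
            return self._pos[animal]
        except KeyError as err:
            raise KeyError(f"animal {animal!r} not in pedigree") from err

    def positions(self, animals) -> np.ndarray:
        return np.array([self.position(a) for a in animals], dtype=int)

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        """Build from a table with columns animal, sire, dam[, birth_year, origin].

        Parent code 0 (or missing) means unknown.  Rows are re-sorted into the
        canonical order: birth year, then original file order.
        """
        df = frame.copy()
        for col in ("animal", "sire", "dam"):
            if col not in df.columns:
                raise PedigreeError(f"pedigree table missing column {col!r}")
        if "birth_year" not in df.columns:
            df["birth_year"] = 0
        if "origin" not in df.columns:
            df["origin"] = "base"
        df["sire"] = df["sire"].fillna(UNKNOWN)
        df["dam"] = df["dam"].fillna(UNKNOWN)
        df = df.sort_values(["birth_year"], kind="stable").reset_index(drop=True)
        pos = {a: i for i, a in enumerate(df["animal"])}

        def parent_idx(col):
            out = np.full(len(df), -1, dtype=int)
            for i, p in enumerate(df[col]):
                if p != UNKNOWN:
                    if p not in pos:
                        raise PedigreeError(f"parent {p!r} has no pedigree row")
                    out[i] = pos[p]
            return out

        return cls(
            df["animal"].tolist(),
            parent_idx("sire"),
            parent_idx("dam"),
            df["birth_year"].to_numpy(),
            df["origin"].tolist(),
        )

    def to_frame(self) -> pd.DataFrame:
        def back(par):
            return [self.ids[p] if p >= 0 else UNKNOWN for p in par]

        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": back(self.sire),
                "dam": back(self.dam),
                "birth_year": self.birth_year,
                "origin": self.origin,
            }
        )

    # -------------------------------------------------------------- algebra
    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F by the Meuwissen & Luo recursion."""
        n = len(self)
        F = np.zeros(n)
        L = np.zeros(n)  # work: L row of the Cholesky of A
        D = np.zeros(n)
        point = np.zeros(n, dtype=int)
        for i in range(n):
            s, d = self.sire[i], self.dam[i]
            Fs = F[s] if s >= 0 else -1.0  # convention: F of unknown parent = -1
            Fd = F[d] if d >= 0 else -1.0
            D[i] = 0.5 - 0.25 * (Fs + Fd)
            if s < 0 or d < 0:
                F[i] = 0.0
                continue
            # trace ancestors of i accumulating L contributions
            fi = -1.0
            L[i] = 1.0
            j = i
            anc_next = np.full(n, -1, dtype=int)  # linked list by decreasing index
            while j != -1:
                k = j
                r = 0.5 * L[k]
                for par in (self.sire[k], self.dam[k]):
                    if par >= 0:
                        if L[par] != 0.0:
                            L[par] += r
                        else:
                            L[par] = r
                            # insert par into list after position
                            m = k
                            while anc_next[m] != -1 and anc_next[m] > par:
                                m = anc_next[m]
                            anc_next[par] = anc_next[m]
                            anc_next[m] = par
                fi += L[k] * L[k] * D[k]
                L[k] = 0.0
                j = anc_next[k]
            F[i] = fi
        return F

    def mendelian_variance_weights(self, inbred: bool = True) -> np.ndarray:
        """Within-family (Mendelian sampling) variance d_i as fraction of σ²_a."""
        n = len(self)
        F = self.inbreeding() if inbred else np.zeros(n)
        d = np.empty(n)
        for i in range(n):
            s, dd = self.sire[i], self.dam[i]
            Fs = F[s] if s >= 0 else -1.0
            Fd = F[dd] if dd >= 0 else -1.0
            d[i] = 0.5 - 0.25 * (Fs + Fd)
        return d


def prune_pedigree(ped: Pedigree, focal_ids, max_generations: int) -> Pedigree:
    """Restrict a pedigree to focal animals plus ancestors within a horizon.

    Parents beyond ``max_generations`` become unknown; the canonical ordering
    of retained animals is preserved.
    """
    if max_generations < 0:
        raise ValueError("max_generations must be >= 0")
    depth = {}
    for a in focal_ids:
        depth[ped.position(a)] = 0
    frontier = list(depth)
    while frontier:
        nxt = []
        for i in frontier:
            if depth[i] >= max_generations:
                continue
            for p in (ped.sire[i], ped.dam[i]):
                if p >= 0 and depth.get(p, np.inf) > depth[i] + 1:
                    depth[p] = depth[i] + 1
                    nxt.append(p)
        frontier = nxt
    keep = sorted(depth)
    old2new = {old: new for new, old in enumerate(keep)}

    def remap(par, i):
        return old2new.get(par, -1) if par >= 0 else -1

    sire = np.array([remap(ped.sire[i], i) for i in keep], dtype=int)
    dam = np.array([remap(ped.dam[i], i) for i in keep], dtype=int)
    # parents outside the horizon (depth == max) were not walked: their parents
    # may be in `keep` only if reached via a shorter path — remap handles both.
    return Pedigree(
        [ped.ids[i] for i in keep],
        sire,
        dam,
        ped.birth_year[keep],
        [ped.origin[i] for i in keep],
    )


def tabular_A(ped: Pedigree) -> RelationshipMatrix:
    """Wright's numerator relationship matrix by the tabular method."""
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[:i, s]
        if d >= 0:
            row += 0.5 * A[:i, d]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(A, ped.ids, kind="A")


def assign_upg(ped: Pedigree, n_groups: int, year_range=None) -> dict:
    """Partition unknown-parent slots into genetic groups by birth year × origin.

    Groups are equal-width birth-year bins within each origin; boundary years
    go to the earlier bin.  Returns ``{"n_groups", "group_of"}`` where
    ``group_of[(i, which)]`` maps an unknown slot (animal position, "sire" or
    "dam") to a group index in ``0..n_groups-1``.
    """
    origins = sorted(set(ped.origin))
    if n_groups < len(origins):
        raise ValueError(f"n_groups={n_groups} < number of origins ({len(origins)})")
    per_origin = {o: n_groups // len(origins) for o in origins}
    for o in origins[: n_groups % len(origins)]:
        per_origin[o] += 1
    if year_range is None:
        year_range = (int(ped.birth_year.min()), int(ped.birth_year.max()))
    y0, y1 = year_range
    base = {}
    acc = 0
    for o in origins:
        base[o] = acc
        acc += per_origin[o]

    def group_for(i):
        o = ped.origin[i]
        k = per_origin[o]
        y = int(np.clip(ped.birth_year[i], y0, y1))
        width = (y1 - y0 + 1) / k  # equal-width year bins within origin
        # a year falling exactly on a bin edge belongs to the earlier bin
        b = int(np.ceil((y - y0 + 1) / width)) - 1
        return base[o] + min(max(b, 0), k - 1)

    group_of = {}
    for i in range(len(ped)):
        if ped.sire[i] < 0:
            group_of[(i, "sire")] = group_for(i)
        if ped.dam[i] < 0:
            group_of[(i, "dam")] = group_for(i)
    return {"n_groups": n_groups, "group_of": group_of}


def a_inverse(ped: Pedigree, groups: dict | None = None, inbred: bool = True) -> RelationshipMatrix:
    """Sparse A⁻¹ by Henderson's rules with Meuwissen–Luo inbreeding.

    With ``groups`` (from :func:`assign_upg`), unknown parents are replaced by
    group codes and the Quaas–Pollak augmented inverse is returned: group
    equations are appended after the animal equations.
    """
    n = len(ped)
    d = ped.mendelian_variance_weights(inbred=inbred)
    ng = groups["n_groups"] if groups else 0
    dim = n + ng
    rows, cols, vals = [], [], []
    for i in range(n):
        parents = []
        for which, p in (("sire", ped.sire[i]), ("dam", ped.dam[i])):
            if p >= 0:
                parents.append(p)
            elif groups:
                parents.append(n + groups["group_of"][(i, which)])
            # without groups an unknown parent simply contributes nothing
        inv_d = 1.0 / d[i]
        rows.append(i), cols.append(i), vals.append(inv_d)
        for p in parents:
            rows.append(i), cols.append(p), vals.append(-0.5 * inv_d)
            rows.append(p), cols.append(i), vals.append(-0.5 * inv_d)
            for q in parents:
                rows.append(p), cols.append(q), vals.append(0.25 * inv_d)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(dim, dim)).tocsr()
    return RelationshipMatrix(
        Ainv,
        ped.ids,
        kind="Ainv",
        group_ids=[f"upg{g}" for g in range(ng)],
    )
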