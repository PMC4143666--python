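"""Pedigree parsing and kinship-based covariance structure.

Every association model in this package places a person-level random
intercept with covariance ``sigma^2 * Sigma_kin`` on the trait, where
``Sigma_kin`` is block-diagonal by pedigree.  This module builds that
matrix from PLINK-style FAM/PED files using the standard kinship
recursion in topological (parents-before-children) order:

    phi_jj = 1/2 * (1 + phi_fm)          (f, m the parents of j)
    phi_jk = 1/2 * (phi_kf + phi_km)     (k not a descendant of j)

The exported matrix defaults to the numerator-relationship convention
``2 * phi`` so that the scaling variance component is the additive
genetic variance; the raw kinship scale ``phi`` is also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeError",
    "PedigreeTable",
    "KinshipMatrix",
    "read_pedigree",
    "write_fam",
    "kinship_matrix",
]

_SEX_CODES = {1: "male", 2: "female"}
_MISSING = "0"


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass
class PedigreeTable:
    """Individuals with parent links and sex, grouped into pedigrees.

    ``df`` has columns ``fid, iid, father, mother, sex`` with missing
    parents stored as ``None`` and sex as ``"male"``/``"female"``.
    Row order is preserved from the source and is the tie-break order
    for all downstream deterministic computations.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        _validate_pedigree(self.df)

    @property
    def n_individuals(self) -> int:
        return len(self.df)

    @property
    def pedigree_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["fid"]))

    def founders(self) -> pd.DataFrame:
        mask = self.df["father"].isna() & self.df["mother"].isna()
        return self.df[mask]

    def pedigree(self, fid: str) -> pd.DataFrame:
        sub = self.df[self.df["fid"] == fid]
        if sub.empty:
            raise PedigreeError(f"unknown pedigree id {fid!r}")
        return sub

    def topological_order(self) -> list[int]:
        """Row indices, parents before children (Kahn; input-order ties)."""
        return _topological_order(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PedigreeTable):
            return NotImplemented
        return self.df.equals(other.df)


def _validate_pedigree(df: pd.DataFrame) -> None:
    required = ["fid", "iid", "father", "mother", "sex"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PedigreeError(f"pedigree table lacks columns {missing}")
    dup = df.duplicated(subset=["fid", "iid"])
    if dup.any():
        bad = df.loc[dup, ["fid", "iid"]].iloc[0]
        raise PedigreeError(
            f"duplicate individual id {bad['iid']!r} within pedigree {bad['fid']!r}"
        )
    bad_sex = set(df["sex"]) - {"male", "female"}
    if bad_sex:
        raise PedigreeError(f"invalid sex codes {sorted(bad_sex)}; expected male/female")
    members: dict[str, set[str]] = {}
    for fid, iid in zip(df["fid"], df["iid"]):
        members.setdefault(fid, set()).add(iid)
    for _, row in df.iterrows():
        for col in ("father", "mother"):
            parent = row[col]
            if parent is not None and parent not in members[row["fid"]]:
                raise PedigreeError(
                    f"individual {row['iid']!r} in pedigree {row['fid']!r} "
                    f"references absent parent {parent!r}"
                )
    _topological_order(df)  # raises on cyclic parentage


def _topological_order(df: pd.DataFrame) -> list[int]:
    index_of = {(f, i): k for k, (f, i) in enumerate(zip(df["fid"], df["iid"]))}
    n = len(df)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for k, row in enumerate(df.itertuples(index=False)):
        for parent in (row.father, row.mother):
            if parent is not None:
                p = index_of[(row.fid, parent)]
                children[p].append(k)
                indeg[k] += 1
    import heapq

    ready = [k for k in range(n) if indeg[k] == 0]
    heapq.heapify(ready)
    order: list[int] = []
    while ready:
        k = heapq.heappop(ready)
        order.append(k)
        for c in children[k]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, c)
    if len(order) != n:
        stuck = df["iid"][indeg > 0].tolist()
        raise PedigreeError(f"cyclic parentage involving individuals {stuck}")
    return order


def read_pedigree(
    path,
    dialect: str = "fam",
    on_missing_parent: str = "materialize",
) -> PedigreeTable:
    """Read a PLINK FAM/PED pedigree file.

    Columns are whitespace-delimited ``FID IID PAT MAT SEX`` with any
    trailing columns (phenotype, genotypes in PED) ignored.  ``"0"``
    codes a missing parent; sex must be 1 (male) or 2 (female).

    Parameters
    ----------
    on_missing_parent:
        ``"materialize"`` adds individuals who appear only as parents
        as founders of unknown-but-required sex (inferred from the
        parental role) with a warning; ``"error"`` raises instead.
    """
    if dialect not in ("fam", "ped"):
        raise ValueError(f"unknown pedigree dialect {dialect!r}")
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 5:
                raise PedigreeError(f"{path}:{ln}: expected >= 5 columns, got {len(parts)}")
            fid, iid, pat, mat, sex = parts[:5]
            try:
                sex_label = _SEX_CODES[int(sex)]
            except (KeyError, ValueError):
                raise PedigreeError(
                    f"{path}:{ln}: invalid sex code {sex!r} (expected 1 or 2)"
                ) from None
            rows.append(
                {
                    "fid": fid,
                    "iid": iid,
                    "father": None if pat == _MISSING else pat,
                    "mother": None if mat == _MISSING else mat,
                    "sex": sex_label,
                }
            )
    df = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex"])
    df = _resolve_missing_parents(df, on_missing_parent, str(path))
    return PedigreeTable(df)


def _resolve_missing_parents(df: pd.DataFrame, policy: str, origin: str) -> pd.DataFrame:
    if policy not in ("materialize", "error"):
        raise ValueError(f"unknown missing-parent policy {policy!r}")
    members: dict[str, set[str]] = {}
    for fid, iid in zip(df["fid"], df["iid"]):
        members.setdefault(fid, set()).add(iid)
    extra = []
    for row in df.itertuples(index=False):
        for col, sex in (("father", "male"), ("mother", "female")):
            parent = getattr(row, col)
            if parent is not None and parent not in members.get(row.fid, set()):
                if policy == "error":
                    raise PedigreeError(
                        f"{origin}: individual {row.iid!r} in pedigree {row.fid!r} "
                        f"references absent parent {parent!r}"
                    )
                members.setdefault(row.fid, set()).add(parent)
                extra.append(
                    {"fid": row.fid, "iid": parent, "father": None, "mother": None, "sex": sex}
                )
    if extra:
        warnings.warn(
            f"{origin}: materialized {len(extra)} parent-only individuals as founders",
            stacklevel=3,
        )
        df = pd.concat([pd.DataFrame(extra), df], ignore_index=True)
    return df


def write_fam(ped: PedigreeTable, path) -> None:
    """Write a PedigreeTable in FAM format (phenotype column set to -9)."""
    inv_sex = {"male": 1, "female": 2}
    with open(path, "w") as fh:
        for row in ped.df.itertuples(index=False):
            fh.write(
                f"{row.fid}\t{row.iid}\t{row.father or _MISSING}\t"
                f"{row.mother or _MISSING}\t{inv_sex[row.sex]}\t-9\n"
            )


@dataclass
class KinshipMatrix:
    """Relatedness matrix ``Sigma_kin``, block-diagonal by pedigree.

    ``ids`` orders individuals; ``values`` is dense symmetric PSD;
    ``blocks`` maps pedigree id to the contiguous index range of its
    members.  ``scale`` records whether entries are kinship
    coefficients ``phi`` or numerator relationships ``2*phi``.
    """

    ids: list[str]
    values: np.ndarray
    blocks: dict[str, slice]
    scale: str = "numerator"
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise PedigreeError(
                "individual ids must be globally unique to index a kinship matrix"
            )
        self._index = {iid: k for k, iid in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        try:
            return np.array([self._index[i] for i in ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"individual {exc.args[0]!r} absent from kinship matrix") from None

    def block_view(self, pedigree_id: str) -> np.ndarray:
        """Dense kinship block of one pedigree."""
        if pedigree_id not in self.blocks:
            raise KeyError(f"unknown pedigree id {pedigree_id!r}")
        sl = self.blocks[pedigree_id]
        return self.values[sl, sl]

    def block_ids(self, pedigree_id: str) -> list[str]:
        sl = self.blocks[pedigree_id]
        return self.ids[sl]

    def to_sparse_tsv(self, path) -> None:
        """Write nonzero entries as (id1, id2, coefficient), upper triangle."""
        with open(path, "w") as fh:
            fh.write("id1\tid2\tcoefficient\n")
            for fid, sl in self.blocks.items():
                block = self.values[sl, sl]
                ids = self.ids[sl]
                for a in range(block.shape[0]):
                    for b in range(a, block.shape[1]):
                        if block[a, b] != 0.0:
                            fh.write(f"{ids[a]}\t{ids[b]}\t{block[a, b]:.10g}\n")

    def to_dense_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", float_format="%.10g"
        )


def kinship_matrix(ped: PedigreeTable, scale: str = "numerator") -> KinshipMatrix:
    """Compute ``Sigma_kin`` from a pedigree by the kinship recursion.

    ``scale="phi"`` returns kinship coefficients (non-inbred self
    coefficient 0.5); ``scale="numerator"`` returns ``2*phi`` (the
    additive/numerator relationship matrix, diagonal >= 1).  Individuals
    are reordered so each pedigree occupies one contiguous block; the
    within-block order follows the input row order.
    """
    if scale not in ("phi", "numerator"):
        raise ValueError(f"unknown kinship scale {scale!r}")
    df = ped.df
    order = ped.topological_order()
    topo_rank = {k: r for r, k in enumerate(order)}
    index_of = {(f, i): k for k, (f, i) in enumerate(zip(df["fid"], df["iid"]))}

    ids: list[str] = []
    blocks: dict[str, slice] = {}
    block_arrays: list[np.ndarray] = []
    start = 0
    for fid in ped.pedigree_ids:
        rows = np.flatnonzero((df["fid"] == fid).to_numpy())
        local = {int(k): j for j, k in enumerate(rows)}
        m = len(rows)
        phi = np.zeros((m, m))
        # parents precede children in topo_rank, so phi of parents is final
        for k in sorted(rows, key=lambda k: topo_rank[int(k)]):
            j = local[int(k)]
            row = df.iloc[int(k)]
            f = index_of[(fid, row["father"])] if row["father"] is not None else None
            mth = index_of[(fid, row["mother"])] if row["mother"] is not None else None
            jf = local[f] if f is not None else None
            jm = local[mth] if mth is not None else None
            phi[j, j] = 0.5 * (1.0 + (phi[jf, jm] if jf is not None and jm is not None else 0.0))
            for other_k in rows:
                jo = local[int(other_k)]
                if jo == j or topo_rank[int(other_k)] > topo_rank[int(k)]:
                    continue
                val = 0.0
                if jf is not None:
                    val += 0.5 * phi[jo, jf]
                if jm is not None:
                    val += 0.5 * phi[jo, jm]
                phi[j, jo] = phi[jo, j] = val
        block_arrays.append(phi if scale == "phi" else 2.0 * phi)
        blocks[fid] = slice(start, start + m)
        ids.extend(df["iid"].iloc[rows].tolist())
        start += m

    n = start
    values = np.zeros((n, n))
    for fid, arr in zip(blocks, block_arrays):
        sl = blocks[fid]
        values[sl, sl] = arr
    return KinshipMatrix(ids=ids, values=values, blocks=blocks, scale=scale)
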