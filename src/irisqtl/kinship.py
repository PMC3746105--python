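"""Pedigree kinship coefficients and the relatedness matrix.

The kinship coefficient phi(i, j) is the probability that an allele
sampled from i and an allele sampled from j at the same locus are
identical by descent.  It is computed by the standard tabular recursion
over a pedigree processed in topological (parents-first) order:

    phi(i, i) = 0.5 * (1 + phi(father_i, mother_i))
    phi(i, j) = 0.5 * (phi(father_i, j) + phi(mother_i, j))   (j older)

with founders pairwise unrelated and non-inbred (phi = 0.5 on the
diagonal) and unknown parents treated as unique unrelated founders.
The relatedness matrix K = 2 phi (the numerator relationship matrix) is
the covariance kernel of the polygenic random effect in the mixed-model
association tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeRecord",
    "Pedigree",
    "KinshipMatrix",
    "kinship_from_pedigree",
    "relatedness",
    "read_pedigree",
    "write_pedigree",
    "write_kinship",
    "read_kinship",
]

_UNKNOWN = {"", "NA", "0", "na", "None", None, 0}


@dataclass(frozen=True)
class PedigreeRecord:
    individual_id: str
    sire_id: str | None
    dam_id: str | None
    sex: str = ""
    group: str = ""


class Pedigree:
    """A validated, acyclic pedigree.

    Parents referenced but never listed are added as founders.  Raises
    on cycles (an individual that is its own ancestor) and on a parent
    appearing both as sire and dam of different matings with
    inconsistent sexes.
    """

    def __init__(self, records):
        recs = []
        for r in records:
            if isinstance(r, PedigreeRecord):
                recs.append(r)
            else:
                ind, sire, dam, *rest = r
                sex = rest[0] if len(rest) > 0 else ""
                group = rest[1] if len(rest) > 1 else ""
                recs.append(
                    PedigreeRecord(
                        str(ind),
                        None if sire in _UNKNOWN else str(sire),
                        None if dam in _UNKNOWN else str(dam),
                        str(sex),
                        str(group),
                    )
                )
        by_id = {}
        for r in recs:
            if r.individual_id in by_id:
                raise ValueError(f"duplicate individual {r.individual_id!r}")
            by_id[r.individual_id] = r
        # implicit founders for parents without their own record
        for r in list(by_id.values()):
            for p in (r.sire_id, r.dam_id):
                if p is not None and p not in by_id:
                    by_id[p] = PedigreeRecord(p, None, None)
        # sire/dam sex consistency
        sires = {r.sire_id for r in by_id.values() if r.sire_id}
        dams = {r.dam_id for r in by_id.values() if r.dam_id}
        both = sires & dams
        if both:
            raise ValueError(f"individuals used as both sire and dam: {sorted(both)}")
        self.records = list(by_id.values())
        self._topo = self._topological_order(by_id)

    @staticmethod
    def _topological_order(by_id):
        order, state = [], {}  # state: 1 visiting, 2 done

        def visit(i, stack):
            if state.get(i) == 2:
                return
            if state.get(i) == 1:
                raise ValueError(f"pedigree cycle involving {i!r}")
            state[i] = 1
            r = by_id[i]
            for p in (r.sire_id, r.dam_id):
                if p is not None:
                    visit(p, stack)
            state[i] = 2
            order.append(i)

        for i in sorted(by_id):
            visit(i, [])
        return order

    @property
    def ids(self):
        return [r.individual_id for r in self.records]

    def founders(self):
        return [r.individual_id for r in self.records if r.sire_id is None and r.dam_id is None]

    def __len__(self):
        return len(self.records)


@dataclass
class KinshipMatrix:
    ids: list
    phi: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != (len(self.ids), len(self.ids)):
            raise ValueError("phi shape must match ids")
        if not np.allclose(self.phi, self.phi.T):
            raise ValueError("phi must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi, index=self.ids, columns=self.ids)

    def coefficient(self, i, j) -> float:
        a, b = self.ids.index(i), self.ids.index(j)
        return float(self.phi[a, b])


def kinship_from_pedigree(ped: Pedigree) -> KinshipMatrix:
    """Pairwise kinship coefficients by the tabular recursion."""
    order = ped._topo
    pos = {v: i for i, v in enumerate(order)}
    parents = {r.individual_id: (r.sire_id, r.dam_id) for r in ped.records}
    n = len(order)
    phi = np.zeros((n, n))
    for i, ind in enumerate(order):
        f, m = parents[ind]
        fi = pos[f] if f is not None else None
        mi = pos[m] if m is not None else None
        # off-diagonals with all earlier individuals
        for j in range(i):
            v = 0.0
            if fi is not None:
                v += 0.5 * phi[fi, j]
            if mi is not None:
                v += 0.5 * phi[mi, j]
            phi[i, j] = phi[j, i] = v
        self_phi = 0.5
        if fi is not None and mi is not None:
            self_phi = 0.5 * (1.0 + phi[fi, mi])
        phi[i, i] = self_phi
    # report in the pedigree's own id order
    ids = ped.ids
    perm = [pos[i] for i in ids]
    return KinshipMatrix(ids=ids, phi=phi[np.ix_(perm, perm)])


def relatedness(kin: KinshipMatrix, psd_tol: float = 1e-8) -> np.ndarray:
    """Numerator relationship matrix K = 2 phi, verified PSD.

    Non-inbred individuals have K diagonal 1; parent-offspring pairs
    have K off-diagonal 0.5.  Raises if an eigenvalue falls below
    ``-psd_tol`` (a valid pedigree always yields a PSD matrix).
    """
    K = 2.0 * np.asarray(kin.phi, dtype=float)
    evals = np.linalg.eigvalsh(K)
    if evals.min() < -psd_tol:
        raise ValueError(f"relatedness matrix not PSD (min eigenvalue {evals.min():.3g})")
    return K


# ---------------------------------------------------------------------------
# TSV I/O: pedigree as `id  sire  dam  sex  group` with NA/0 unknown;
# kinship as a square table with id header row and column.


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    rows = [
        (r["id"], r.get("sire", "NA"), r.get("dam", "NA"), r.get("sex", ""), r.get("group", ""))
        for _, r in df.iterrows()
    ]
    return Pedigree(rows)


def write_pedigree(ped: Pedigree, path) -> None:
    pd.DataFrame(
        [
            {
                "id": r.individual_id,
                "sire": r.sire_id or "NA",
                "dam": r.dam_id or "NA",
                "sex": r.sex,
                "group": r.group,
            }
            for r in ped.records
        ]
    ).to_csv(path, sep="\t", index=False)


def write_kinship(kin: KinshipMatrix, path) -> None:
    kin.to_frame().to_csv(path, sep="\t", index_label="id")


def read_kinship(path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return KinshipMatrix(ids=list(df.index), phi=df.to_numpy())
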