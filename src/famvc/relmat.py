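"""Genomic and environmental relationship matrices.

Five symmetric n x n design matrices drive the variance partitioning:

* ``GRM_g`` — realized genomic relatedness from SNP dosages (Yang-style
  allele-frequency standardization),
* ``GRM_kin`` — ``GRM_g`` with entries below a threshold (default 0.025)
  set to zero, capturing genetic sharing specific to close relatives,
* ``ERM_Family`` / ``ERM_Sib`` / ``ERM_Couple`` — 0/1 indicators of shared
  nuclear-family, full-sibling and couple environments with unit diagonal.

Also provided: relationship-degree classification from realized relatedness,
greedy relatedness pruning, leading GRM eigenvectors for structure
correction, and GCTA-compatible binary GRM I/O.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, NumericalError
from .genio import GenotypeMatrix, Pedigree

__all__ = [
    "RelationshipMatrix",
    "compute_grm",
    "threshold_grm",
    "build_erm",
    "classify_degree",
    "degree_bounds",
    "grm_prune",
    "grm_eigenvectors",
    "read_gcta_grm",
    "write_gcta_grm",
]

KIN_THRESHOLD_DEFAULT = 0.025
#: Relatedness below which a pair is treated as unrelated (0.5 ** 5.5).
UNRELATED_BOUND = 0.5 ** 5.5


@dataclass
class RelationshipMatrix:
    """A symmetric relatedness/design matrix over an ordered id list.

    ``kind`` is one of ``GRM_g``, ``GRM_kin``, ``ERM_Family``, ``ERM_Sib``,
    ``ERM_Couple`` or ``Identity``.
    """

    ids: list[str]
    values: np.ndarray
    kind: str
    #: per-pair SNP counts used in GRM entries (optional, for GCTA export)
    n_snps: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    def validate(self) -> None:
        v = self.values
        if v.shape != (self.n, self.n):
            raise ConsistencyError("matrix shape does not match id list")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ConsistencyError("relationship matrix is not symmetric")

    def subset(self, ids: Sequence[str]) -> "RelationshipMatrix":
        pos = {iid: i for i, iid in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids])
        sub = self.values[np.ix_(idx, idx)]
        nn = self.n_snps[np.ix_(idx, idx)] if self.n_snps is not None else None
        return RelationshipMatrix(list(ids), sub, self.kind, nn)

    def to_tsv(self, path: str | Path) -> None:
        """Dense TSV export (ids as header and first column); small n only."""
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        df.to_csv(path, sep="\t", index_label="iid")


# ---------------------------------------------------------------------------
# GRM construction
# ---------------------------------------------------------------------------


def compute_grm(geno: GenotypeMatrix) -> RelationshipMatrix:
    """Realized genomic relationship matrix from minor-allele dosages.

    The off-diagonal entry for individuals j, k averages
    ``(x_j - 2p)(x_k - 2p) / (2p(1-p))`` over SNPs non-missing in *both*;
    the diagonal entry is ``1 + mean((x^2 - (1+2p)x + 2p^2) / (2p(1-p)))``
    over SNPs non-missing in that individual, i.e. one plus the estimated
    inbreeding coefficient.
    """
    p = geno.freq
    if ((p <= 0.0) | (p >= 1.0)).any():
        raise NumericalError(
            "monomorphic SNP in GRM computation (apply QC first)")
    d = geno.dosage
    denom = 2.0 * p * (1.0 - p)
    obs = ~np.isnan(d)
    z = np.where(obs, (d - 2.0 * p) / np.sqrt(denom), 0.0)

    counts = obs.astype(np.float64) @ obs.T.astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        grm = (z @ z.T) / counts

    # diagonal uses its own (inbreeding) form, not the squared z-score
    num = np.where(obs, (d * d - (1.0 + 2.0 * p) * d + 2.0 * p * p) / denom, 0.0)
    n_i = obs.sum(axis=1)
    diag = 1.0 + num.sum(axis=1) / n_i
    np.fill_diagonal(grm, diag)
    return RelationshipMatrix(list(geno.sample_ids), grm, "GRM_g", counts)


def threshold_grm(grm: RelationshipMatrix,
                  t: float = KIN_THRESHOLD_DEFAULT) -> RelationshipMatrix:
    """Zero all off-diagonal entries strictly below ``t`` (kind GRM_kin)."""
    v = grm.values.copy()
    off = v < t
    np.fill_diagonal(off, False)
    v[off] = 0.0
    return RelationshipMatrix(list(grm.ids), v, "GRM_kin", grm.n_snps)


# ---------------------------------------------------------------------------
# environmental relationship matrices
# ---------------------------------------------------------------------------

_ERM_KINDS = {"couple": "ERM_Couple", "sib": "ERM_Sib", "family": "ERM_Family"}


def build_erm(ped: Pedigree, kind: str,
              ids: Sequence[str] | None = None) -> RelationshipMatrix:
    """0/1 shared-environment indicator matrix with unit diagonal.

    ``kind``: ``couple`` (pairs with a common offspring in the dataset),
    ``sib`` (full siblings), or ``family`` (parent-offspring, couple or
    full-sib pairs).  ``ids`` fixes the row order; ids absent from the
    pedigree become singletons (zero off-diagonals) with a warning.
    """
    if kind not in _ERM_KINDS:
        raise ValueError(f"unknown ERM kind {kind!r}")
    if ids is None:
        ids = ped.ids
    ids = list(ids)
    known = set(ped.ids)
    missing = [i for i in ids if i not in known]
    if missing:
        warnings.warn(
            f"{len(missing)} individual(s) absent from the pedigree are "
            "treated as environmental singletons", stacklevel=2)
    if kind == "couple":
        pairs = ped.couple_pairs()
    elif kind == "sib":
        pairs = ped.full_sib_pairs()
    else:
        pairs = ped.nuclear_family_pairs()

    pos = {iid: i for i, iid in enumerate(ids)}
    v = np.eye(len(ids))
    for a, b in pairs:
        ia, ib = pos.get(a), pos.get(b)
        if ia is not None and ib is not None:
            v[ia, ib] = v[ib, ia] = 1.0
    return RelationshipMatrix(ids, v, _ERM_KINDS[kind])


# ---------------------------------------------------------------------------
# degree classification and pruning
# ---------------------------------------------------------------------------


def degree_bounds(i: int) -> tuple[float, float]:
    """Half-open relatedness interval (0.5^(i+0.5), 0.5^(i-0.5)] for degree i."""
    return 0.5 ** (i + 0.5), 0.5 ** (i - 0.5)


def classify_degree(r: float) -> int | str:
    """Relationship degree for realized relatedness ``r``.

    Degree i covers ``0.5**(i+0.5) < r <= 0.5**(i-0.5)`` for i = 1..5;
    ``r <= 0.5**5.5`` (~0.022) is "unrelated"; values above the first-degree
    upper bound (duplicates/MZ twins) collapse to degree 1 with a warning.
    """
    if r <= UNRELATED_BOUND:
        return "unrelated"
    if r > 0.5 ** 0.5:
        warnings.warn(
            f"relatedness {r:.3f} exceeds the 1st-degree upper bound; "
            "treating as 1st degree", stacklevel=2)
        return 1
    for i in range(1, 6):
        lo, hi = degree_bounds(i)
        if lo < r <= hi:
            return i
    raise AssertionError("unreachable: degree intervals partition (0.022, 1]")


def grm_prune(grm: RelationshipMatrix, cutoff: float) -> list[str]:
    """Greedily drop individuals until no off-diagonal exceeds ``cutoff``.

    While any off-diagonal entry is strictly above the cutoff, the
    individual involved in the most such pairs is removed (ties broken by
    dropping the later-ordered id).  Returns the retained ids in their
    original order.
    """
    if not 0.0 < cutoff <= 1.5:
        raise ValueError(f"cutoff must be in (0, 1.5], got {cutoff}")
    adj = grm.values > cutoff
    np.fill_diagonal(adj, False)
    alive = np.ones(grm.n, dtype=bool)
    deg = adj.sum(axis=1)
    while True:
        deg_alive = np.where(alive, deg, -1)
        worst = int(deg_alive.max())
        if worst <= 0:
            break
        # np.argmax returns the first max; we want the last-ordered id
        cand = np.nonzero(deg_alive == worst)[0]
        drop = int(cand[-1])
        alive[drop] = False
        deg -= adj[:, drop]
        deg[drop] = 0
    return [iid for iid, a in zip(grm.ids, alive) if a]


def grm_eigenvectors(grm: RelationshipMatrix, k: int = 20) -> np.ndarray:
    """Orthonormal eigenvectors for the ``k`` largest eigenvalues.

    Sign convention: each vector's largest-magnitude loading is positive
    (first such index on exact ties), making the output deterministic up to
    eigenvalue degeneracy.
    """
    if k > grm.n:
        raise ValueError(f"k={k} exceeds matrix size n={grm.n}")
    w, u = np.linalg.eigh(grm.values)
    u = u[:, ::-1][:, :k]
    for j in range(u.shape[1]):
        i = int(np.argmax(np.abs(u[:, j])))
        if u[i, j] < 0:
            u[:, j] = -u[:, j]
    return u


# ---------------------------------------------------------------------------
# GCTA binary GRM I/O
# ---------------------------------------------------------------------------


def write_gcta_grm(grm: RelationshipMatrix, prefix: str | Path) -> None:
    """Write the GCTA triplet: .grm.bin / .grm.N.bin (float32 lower
    triangle, row-major, diagonal included) and two-column .grm.id."""
    prefix = Path(prefix)
    n = grm.n
    tri = np.tril_indices(n)
    grm.values[tri].astype("<f4").tofile(f"{prefix}.grm.bin")
    counts = grm.n_snps if grm.n_snps is not None else np.ones((n, n))
    np.asarray(counts)[tri].astype("<f4").tofile(f"{prefix}.grm.N.bin")
    with open(f"{prefix}.grm.id", "w") as fh:
        for iid in grm.ids:
            fh.write(f"{iid}\t{iid}\n")


def read_gcta_grm(prefix: str | Path, kind: str = "GRM_g") -> RelationshipMatrix:
    """Read a GCTA binary GRM triplet back into a RelationshipMatrix."""
    prefix = Path(prefix)
    ids = [line.split()[1] for line in open(f"{prefix}.grm.id")]
    n = len(ids)
    tri = np.tril_indices(n)
    vals = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    if vals.size != n * (n + 1) // 2:
        raise ConsistencyError(
            f"{prefix}.grm.bin holds {vals.size} entries; expected "
            f"{n * (n + 1) // 2} for {n} ids")
    m = np.zeros((n, n))
    m[tri] = vals
    m = m + m.T - np.diag(np.diag(m))
    nn = None
    npath = Path(f"{prefix}.grm.N.bin")
    if npath.exists():
        nvals = np.fromfile(npath, dtype="<f4")
        if nvals.size == n * (n + 1) // 2:
            nn = np.zeros((n, n))
            nn[tri] = nvals
            nn = nn + nn.T - np.diag(np.diag(nn))
    return RelationshipMatrix(ids, m, kind, nn)
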