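"""Kinship structure: realized relatedness (GRM), IBS fractions and
pedigree-based relative classification.

In a full two-panel diallel every pair of hybrids falls into one of three
classes: *self*, *close* (exactly one shared haploid parent; expected fraction
of identical diploid genotypes f = 0.5) or *distant* (no shared parent;
f = 0.25^2 + 0.5^2 + 0.25^2 = 0.375 for independent hybrids at a site with
allele frequency one half).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .simulate import GenotypeMatrix, Pedigree

__all__ = ["Grm", "PairClass", "compute_grm", "ibs_fraction", "classify_pair",
           "count_relatives"]


class PairClass(Enum):
    SELF = "self"
    CLOSE = "close"
    DISTANT = "distant"

    @property
    def expected_ibs(self) -> float | None:
        """Expected fraction of sites identical by genotype state."""
        return {"self": 1.0, "close": 0.5, "distant": 0.375}[self.value]


@dataclass(frozen=True)
class Grm:
    """Realized genetic relatedness matrix K = X X^T / c.

    c is the mean diagonal of X X^T, so mean(diag(K)) = 1.  By default X is
    the column-centred dosage matrix: the uncentred product carries a
    near-rank-one common covariance (all dosages have mean ~1) that is not
    genetic covariance and measurably inflates variance-ratio estimates.
    ``centered=False`` records that raw dosages were used instead.  No
    allele-frequency standardization is applied in either case (frequencies
    in a two-founder diallel are close to one half).
    """

    individuals: np.ndarray
    K: np.ndarray
    c: float
    centered: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "individuals",
                           np.asarray(self.individuals, dtype=object))
        K = np.asarray(self.K, dtype=np.float64)
        object.__setattr__(self, "K", K)
        if K.shape != (len(self.individuals),) * 2:
            raise ValueError("K shape inconsistent with individuals")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("K must be symmetric")
        object.__setattr__(self, "_index",
                           {h: i for i, h in enumerate(self.individuals)})

    def index_of(self, individual: str) -> int:
        try:
            return self._index[individual]
        except KeyError:
            raise KeyError(f"unknown individual: {individual!r}") from None

    def submatrix(self, rows, cols) -> np.ndarray:
        ri = [self.index_of(h) for h in rows]
        ci = [self.index_of(h) for h in cols]
        return self.K[np.ix_(ri, ci)]


def compute_grm(G: GenotypeMatrix, center: bool = True) -> Grm:
    """K = X X^T / c with c the average diagonal of X X^T.

    ``center=True`` (default) subtracts column means from X first; pass
    ``center=False`` for the raw-dosage product.
    """
    if G.n_individuals == 0 or G.n_sites == 0:
        raise ValueError("empty genotype matrix")
    X = G.G.astype(np.float64)
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    XXt = X @ X.T
    c = float(np.mean(np.diag(XXt)))
    if c <= 0:
        raise ValueError("degenerate genotypes: mean diagonal of XX^T is zero")
    return Grm(individuals=G.individuals.copy(), K=XXt / c, c=c, centered=center)


def ibs_fraction(g_i: np.ndarray, g_j: np.ndarray) -> float:
    """Fraction of sites at which two diploid genotypes are identical."""
    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    if g_i.shape != g_j.shape or g_i.ndim != 1 or len(g_i) == 0:
        raise ValueError("dosage vectors must be 1-D, non-empty and equal length")
    return float(np.mean(g_i == g_j))


def classify_pair(ped: Pedigree, i: str, j: str) -> PairClass:
    """Classify a hybrid pair as self / close / distant by shared parents."""
    a_i, b_i = ped.parents_of(i)
    a_j, b_j = ped.parents_of(j)
    if i == j:
        return PairClass.SELF
    shared = int(a_i == a_j) + int(b_i == b_j)
    if shared == 2:
        raise ValueError(
            f"hybrids {i!r} and {j!r} share both parents; duplicate cross in pedigree"
        )
    return PairClass.CLOSE if shared == 1 else PairClass.DISTANT


def count_relatives(ped: Pedigree, i: str) -> tuple[int, int]:
    """(n_close, n_distant) relatives of hybrid ``i`` in a full diallel.

    In an n_a x n_alpha diallel each hybrid has (n_a - 1) + (n_alpha - 1)
    close relatives and (n_a - 1)(n_alpha - 1) distant ones.
    """
    a_i, b_i = ped.parents_of(i)
    n_close = 0
    n_distant = 0
    for h, a, b in zip(ped.hybrid_id, ped.parent_a, ped.parent_alpha):
        if h == i:
            continue
        if (a == a_i) != (b == b_i):
            n_close += 1
        elif a != a_i and b != b_i:
            n_distant += 1
        else:
            raise ValueError("duplicate cross in pedigree")
    return n_close, n_distant
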