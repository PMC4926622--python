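"""Pairwise incidence-based beta diversity.

Implements the Simpson turnover dissimilarity

    beta_sim = min(b, c) / (a + min(b, c))

with matching components a = species shared by the two sites, b and c =
species unique to each site, together with the Sorensen dissimilarity
beta_sor = (b + c) / (2a + b + c) and its nestedness-resultant component
beta_sne = beta_sor - beta_sim.  beta_sim isolates spatial turnover: it is
insensitive to richness differences, so a fauna strictly nested inside
another scores 0.  All three are computed in exact integer arithmetic up to
the final division, which keeps the additive partition
beta_sor = beta_sim + beta_sne exact to float rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .core_io import DissimilarityMatrix, OccurrenceMatrix

__all__ = [
    "PairComponents",
    "pair_components",
    "simpson_dissimilarity",
    "sorensen_family",
    "pairwise_matrix",
    "to_similarity",
]


@dataclass(frozen=True)
class PairComponents:
    """Matching components of one site pair.

    ``shared`` species occur in both sites; ``only_i`` / ``only_j`` occur in
    exactly one.  (Named to avoid colliding with the decay intercept ``a``.)
    """

    shared: int
    only_i: int
    only_j: int

    def __post_init__(self) -> None:
        if min(self.shared, self.only_i, self.only_j) < 0:
            raise ValueError("matching components must be non-negative")


def pair_components(x_i: np.ndarray, x_j: np.ndarray) -> PairComponents:
    """Exact set-overlap counts for two equal-length binary incidence rows."""
    x_i = np.asarray(x_i)
    x_j = np.asarray(x_j)
    if x_i.shape != x_j.shape or x_i.ndim != 1:
        raise ValueError("incidence vectors must be 1-D and equal length")
    xi = x_i.astype(bool)
    xj = x_j.astype(bool)
    return PairComponents(
        shared=int(np.count_nonzero(xi & xj)),
        only_i=int(np.count_nonzero(xi & ~xj)),
        only_j=int(np.count_nonzero(~xi & xj)),
    )


def _check_nonempty(c: PairComponents) -> None:
    if c.shared == 0 and c.only_i == 0 and c.only_j == 0:
        raise ValueError("beta diversity undefined: both assemblages are empty")


def simpson_dissimilarity(c: PairComponents) -> float:
    """Turnover-only dissimilarity; 0 for nested or identical assemblages,
    1 for complete turnover (no shared species, both sites occupied)."""
    _check_nonempty(c)
    m = min(c.only_i, c.only_j)
    if m == 0:
        return 0.0
    return float(Fraction(m, c.shared + m))


def sorensen_family(c: PairComponents) -> tuple[float, float, float]:
    """(beta_sor, beta_sim, beta_sne) for one pair; beta_sne = beta_sor - beta_sim."""
    _check_nonempty(c)
    m = min(c.only_i, c.only_j)
    sor = Fraction(c.only_i + c.only_j, 2 * c.shared + c.only_i + c.only_j)
    sim = Fraction(m, c.shared + m) if m else Fraction(0)
    sne = sor - sim
    return float(sor), float(sim), float(sne)


_INDEX_POS = {"sor": 0, "sim": 1, "sne": 2}


def pairwise_matrix(occ: OccurrenceMatrix, index: str = "sim") -> DissimilarityMatrix:
    """Square pairwise dissimilarity matrix for one index of the Sorensen
    family (``sim`` | ``sor`` | ``sne``)."""
    if index not in _INDEX_POS:
        raise ValueError(f"unknown index {index!r}; expected sim, sor or sne")
    empties = occ.empty_sites()
    if empties:
        raise ValueError(f"empty sites present (turnover undefined): {empties}")
    x = occ.incidence.astype(np.int64)
    shared = x @ x.T
    r = x.sum(axis=1)
    only_i = r[:, None] - shared
    only_j = r[None, :] - shared
    pos = _INDEX_POS[index]
    n = occ.n_sites
    out = np.zeros((n, n), dtype=float)
    iu = np.triu_indices(n, k=1)
    for i, j in zip(*iu):
        a = int(shared[i, j])
        b = int(only_i[i, j])
        c = int(only_j[i, j])
        mn = min(b, c)
        sor = Fraction(b + c, 2 * a + b + c)
        sim = Fraction(mn, a + mn) if mn else Fraction(0)
        vals = (float(sor), float(sim), float(sor - sim))
        out[i, j] = out[j, i] = vals[pos]
    return DissimilarityMatrix(occ.site_ids, out)


def to_similarity(d: DissimilarityMatrix) -> DissimilarityMatrix:
    """Entrywise complement 1 - d; turns beta_sim into the similarity used by
    distance-decay fitting (and back: the transform is an involution)."""
    kind = "similarity" if d.kind == "dissimilarity" else "dissimilarity"
    return DissimilarityMatrix(d.site_ids, 1.0 - d.values, kind)
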