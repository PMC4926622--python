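"""Compositional turnover: clustering and constrained ordination.

The beta_sim dissimilarity matrix is explored two ways:

* UPGMA (average-linkage) agglomerative clustering, to delimit groups of
  territories with similar faunas, exported as a Newick dendrogram and as
  flat labels at a chosen cut;
* constrained analysis of principal coordinates (CAP, also known as
  db-RDA): the dissimilarity matrix is embedded by principal coordinates
  (double-centering of -d^2/2), the resulting axes are regressed on
  predictor columns, and the share of total inertia captured by the fitted
  values is the model's constrained variation.  Significance comes from a
  permutation test on the pseudo-F statistic

      pseudo-F = (constrained / q) / (residual / (n - q - 1)),

  permuting site identities of the dissimilarity matrix.  CAP is preferred
  here precisely because it accepts any ecologically meaningful
  dissimilarity, so beta_sim enters the ordination unchanged.

beta_sim is non-Euclidean, so some PCoA eigenvalues are negative.  The
default policy discards the negative axes and reports the discarded share
of total absolute inertia; a Lingoes correction (adding a constant to all
squared off-diagonal dissimilarities) is available by flag.

Spatial predictors follow trend-surface analysis: the nine terms of a
third-degree polynomial in mean longitude and latitude.  Model selection
ranks terms by their marginal (leave-one-out) contribution to constrained
variation, then admits them in that order while the sequential permutation
test stays below alpha, capped at ``max_terms`` to keep predictor sets
balanced.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .core_io import DissimilarityMatrix

__all__ = [
    "ClusterResult",
    "PcoaEmbedding",
    "CapModel",
    "upgma",
    "cut_clusters",
    "gower_pcoa",
    "trend_surface_terms",
    "TREND_SURFACE_LABELS",
    "cap_fit",
    "permutation_test",
    "rank_by_marginal_contribution",
    "select_model",
    "partition_composition",
    "single_covariate_test",
]


# ---------------------------------------------------------------------------
# UPGMA clustering


@dataclass(frozen=True)
class ClusterResult:
    """Average-linkage agglomeration of a dissimilarity matrix."""

    site_ids: tuple[str, ...]
    merge_tree: tuple[tuple[int, int, float], ...]  # scipy-style cluster ids
    linkage_matrix: np.ndarray
    newick: str

    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merge_tree])


def _newick_from_linkage(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Ultrametric Newick: a leaf-to-node path length is half the merge
    height (cophenetic convention)."""
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    text = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + k
        height[node] = h / 2.0
        la = height[node] - height[a]
        lb = height[node] - height[b]
        text[node] = f"({text[a]}:{la:.10g},{text[b]}:{lb:.10g})"
    return text[2 * n - 2] + ";"


def upgma(d: DissimilarityMatrix) -> ClusterResult:
    """UPGMA: merge heights equal the mean pairwise dissimilarity between
    the merged groups, hence are monotone non-decreasing."""
    if d.n_sites < 2:
        raise ValueError("clustering needs at least 2 sites")
    Z = linkage(d.condensed(), method="average")
    merges = tuple((int(a), int(b), float(h)) for a, b, h, _ in Z)
    return ClusterResult(
        site_ids=d.site_ids,
        merge_tree=merges,
        linkage_matrix=Z,
        newick=_newick_from_linkage(Z, d.site_ids),
    )


def cut_clusters(c: ClusterResult, k: int) -> dict[str, int]:
    """Flat labels (1..k) from cutting the merge tree into k groups."""
    n = len(c.site_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    flat = cut_tree(c.linkage_matrix, n_clusters=k).ravel()
    return {s: int(g) + 1 for s, g in zip(c.site_ids, flat)}


# ---------------------------------------------------------------------------
# PCoA


@dataclass(frozen=True)
class PcoaEmbedding:
    """Principal-coordinates embedding of a dissimilarity matrix."""

    site_ids: tuple[str, ...]
    axes: np.ndarray               # [n, m], columns scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray        # positive, descending (retained axes)
    all_eigenvalues: np.ndarray    # full spectrum, descending
    negative_eigenvalue_policy: str
    represented_inertia: float     # sum of retained eigenvalues
    discarded_abs_share: float     # |negative| / total absolute inertia

    @property
    def total_inertia(self) -> float:
        return self.represented_inertia


def gower_pcoa(
    d: DissimilarityMatrix, neg_eigen_policy: str = "discard"
) -> PcoaEmbedding:
    """Eigendecomposition of the Gower-centred matrix -J d^2 J / 2.

    ``discard`` keeps only axes with positive eigenvalues (recording the
    discarded share of absolute inertia); ``lingoes`` adds the smallest
    constant to all squared off-diagonal dissimilarities that makes the
    spectrum non-negative, then re-embeds.
    """
    n = d.n_sites
    if n < 3:
        raise ValueError("PCoA needs at least 3 sites")
    D2 = d.values ** 2
    if neg_eigen_policy not in ("discard", "lingoes"):
        raise ValueError(f"unknown negative-eigenvalue policy {neg_eigen_policy!r}")
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    G = (G + G.T) / 2.0
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]

    if neg_eigen_policy == "lingoes" and vals[-1] < -1e-12:
        c = -vals[-1]
        D2c = D2 + 2.0 * c
        np.fill_diagonal(D2c, 0.0)
        G = -0.5 * J @ D2c @ J
        G = (G + G.T) / 2.0
        vals, vecs = np.linalg.eigh(G)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]

    tol = max(abs(vals).max(), 1.0) * 1e-10
    pos = vals > tol
    retained = vals[pos]
    axes = vecs[:, pos] * np.sqrt(retained)[None, :]
    neg_share = float(abs(vals[vals < -tol]).sum() / abs(vals).sum()) if abs(vals).sum() else 0.0
    return PcoaEmbedding(
        site_ids=d.site_ids,
        axes=axes,
        eigenvalues=retained,
        all_eigenvalues=vals,
        negative_eigenvalue_policy=neg_eigen_policy,
        represented_inertia=float(retained.sum()),
        discarded_abs_share=neg_share,
    )


# ---------------------------------------------------------------------------
# trend surface


TREND_SURFACE_LABELS = (
    "Long", "Long^2", "Long^3", "Lat", "Lat^2", "Lat^3",
    "Long*Lat", "Long^2*Lat", "Long*Lat^2",
)


def trend_surface_terms(
    lat: np.ndarray, long: np.ndarray, center: bool = True
) -> pd.DataFrame:
    """The nine terms of a third-degree polynomial of mean longitude and
    latitude.  Coordinates are mean-centred by default to tame collinearity;
    the column span (hence any CAP fit on the full set) is unchanged."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(long, dtype=float)
    if lat.shape != lon.shape or lat.ndim != 1:
        raise ValueError("lat and long must be 1-D and aligned")
    if center:
        lat = lat - lat.mean()
        lon = lon - lon.mean()
    cols = {
        "Long": lon, "Long^2": lon ** 2, "Long^3": lon ** 3,
        "Lat": lat, "Lat^2": lat ** 2, "Lat^3": lat ** 3,
        "Long*Lat": lon * lat, "Long^2*Lat": lon ** 2 * lat,
        "Long*Lat^2": lon * lat ** 2,
    }
    return pd.DataFrame(cols, columns=list(TREND_SURFACE_LABELS))


# ---------------------------------------------------------------------------
# CAP / db-RDA


@dataclass(frozen=True)
class CapModel:
    """A constrained-ordination fit."""

    retained_terms: tuple[str, ...]
    constrained_pct: float
    pseudo_F: float
    df: tuple[int, int]
    p_perm: float | None = None
    n_perm: int | None = None
    term_table: tuple[dict, ...] = ()
    total_inertia: float = float("nan")

    def to_report_rows(self):
        rows = [dict(r) for r in self.term_table]
        rows.append({
            "Variable": "Model",
            "Variation (%)": self.constrained_pct,
            "Pseudo-F": self.pseudo_F,
            "d.f.": f"{self.df[0]}; {self.df[1]}",
            "p": self.p_perm,
        })
        return rows


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(str(c) for c in X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, tuple(f"x{j}" for j in range(X.shape[1]))


def _drop_aliased(X: np.ndarray, names: tuple[str, ...]):
    keep: list[int] = []
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            warnings.warn(f"dropping constant predictor {names[j]}")
            continue
        cand = np.column_stack([np.ones(X.shape[0]), X[:, keep + [j]]])
        if np.linalg.matrix_rank(cand) == len(keep) + 2:
            keep.append(j)
        else:
            warnings.warn(f"dropping aliased predictor {names[j]}")
    return X[:, keep], tuple(names[j] for j in keep)


def _constrained_ss(Y: np.ndarray, X: np.ndarray) -> float:
    """Sum of squares of fitted values from regressing the (centred) PCoA
    axes Y on [1, X]; equals the constrained inertia."""
    Xc = np.column_stack([np.ones(len(Y)), X])
    beta, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
    fitted = Xc @ beta
    fitted = fitted - fitted.mean(axis=0)
    return float((fitted ** 2).sum())


def cap_fit(
    d: DissimilarityMatrix | PcoaEmbedding,
    X,
    n_perm: int = 0,
    seed: int | None = None,
    neg_eigen_policy: str = "discard",
) -> CapModel:
    """Constrained analysis of principal coordinates.

    Accepts either a dissimilarity matrix (embedded on the fly) or a
    pre-computed :class:`PcoaEmbedding`.  ``n_perm`` > 0 adds a whole-model
    permutation p-value (seed mandatory).
    """
    emb = d if isinstance(d, PcoaEmbedding) else gower_pcoa(d, neg_eigen_policy)
    Y = emb.axes
    n = Y.shape[0]
    Xm, names = _as_matrix(X)
    if Xm.shape[0] != n:
        raise ValueError("predictor rows not aligned with sites")
    Xm, names = _drop_aliased(Xm, names)
    q = Xm.shape[1]
    if q == 0:
        raise ValueError("no usable predictors (all constant or aliased)")
    if n <= q + 1:
        raise ValueError(f"need n > q + 1 (n={n}, q={q})")
    total = emb.represented_inertia
    constrained = _constrained_ss(Y, Xm)
    residual = total - constrained
    F = (constrained / q) / (residual / (n - q - 1))
    p = None
    if n_perm:
        p = _model_permutation_p(Y, Xm, F, n_perm, seed)
    return CapModel(
        retained_terms=names,
        constrained_pct=100.0 * constrained / total,
        pseudo_F=F,
        df=(q, n - q - 1),
        p_perm=p,
        n_perm=n_perm or None,
        total_inertia=total,
    )


def _pseudo_f(Y: np.ndarray, X: np.ndarray, total: float) -> float:
    n, q = X.shape
    constrained = _constrained_ss(Y, X)
    return (constrained / q) / ((total - constrained) / (n - q - 1))


def _model_permutation_p(
    Y: np.ndarray, X: np.ndarray, F_obs: float, n_perm: int,
    seed: int | None, exhaustive: bool = False,
) -> float:
    """Permute site identities (rows of the embedding, equivalently
    simultaneous row/column permutation of d) and recompute pseudo-F."""
    n = Y.shape[0]
    total = float((Y ** 2).sum())  # PCoA axes are centred by construction
    if exhaustive:
        hits = sum(
            _pseudo_f(Y[list(perm)], X, total) >= F_obs - 1e-12
            for perm in itertools.permutations(range(n))
        )
        return hits / math.factorial(n)
    if seed is None:
        raise ValueError("seed required for the permutation test")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        hits += _pseudo_f(Y[perm], X, total) >= F_obs - 1e-12
    return (hits + 1) / (n_perm + 1)


def permutation_test(
    d: DissimilarityMatrix | PcoaEmbedding,
    X,
    term_order: Sequence[str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> dict:
    """Sequential per-term and whole-model permutation tests.

    Terms are added in ``term_order`` (default: the given column order); the
    k-th term's statistic is the sequential pseudo-F

        F_k = (SS_k / 1) / (residual_full / (n - q - 1)),

    where SS_k is the extra constrained inertia of term k given terms
    1..k-1.  Rows of the embedding are freely permuted.  ``exhaustive``
    enumerates all n! permutations (small n only) and then needs no seed.
    """
    if n_perm < 99 and not exhaustive:
        raise ValueError("n_perm must be >= 99")
    emb = d if isinstance(d, PcoaEmbedding) else gower_pcoa(d)
    Y = emb.axes
    n = Y.shape[0]
    if isinstance(X, pd.DataFrame):
        Xdf = X
    else:
        Xm0, names0 = _as_matrix(X)
        Xdf = pd.DataFrame(Xm0, columns=list(names0))
    if term_order is None:
        term_order = [str(c) for c in Xdf.columns]
    Xm = Xdf[list(term_order)].to_numpy(dtype=float)
    q = Xm.shape[1]
    total = emb.represented_inertia
    resid_df = n - q - 1

    def seq_stats(Yp: np.ndarray) -> tuple[np.ndarray, float]:
        ss_prev = 0.0
        seq = np.empty(q)
        for k in range(q):
            ss_k = _constrained_ss(Yp, Xm[:, : k + 1])
            seq[k] = ss_k - ss_prev
            ss_prev = ss_k
        resid = total - ss_prev
        Fs = (seq / 1.0) / (resid / resid_df)
        F_model = (ss_prev / q) / (resid / resid_df)
        return Fs, F_model

    F_terms, F_model = seq_stats(Y)

    if exhaustive:
        perms = list(itertools.permutations(range(n)))
        hits_t = np.zeros(q)
        hits_m = 0
        for perm in perms:
            Fp, Fm = seq_stats(Y[list(perm)])
            hits_t += Fp >= F_terms - 1e-12
            hits_m += Fm >= F_model - 1e-12
        p_terms = hits_t / len(perms)
        p_model = hits_m / len(perms)
    else:
        if seed is None:
            raise ValueError("seed required for the permutation test")
        rng = np.random.default_rng(seed)
        hits_t = np.zeros(q)
        hits_m = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Fp, Fm = seq_stats(Y[perm])
            hits_t += Fp >= F_terms - 1e-12
            hits_m += Fm >= F_model - 1e-12
        p_terms = (hits_t + 1) / (n_perm + 1)
        p_model = (hits_m + 1) / (n_perm + 1)

    return {
        "terms": list(term_order),
        "F_terms": F_terms,
        "p_terms": np.asarray(p_terms, dtype=float),
        "F_model": float(F_model),
        "p_model": float(p_model),
        "n_perm": (math.factorial(n) if exhaustive else n_perm),
    }


def rank_by_marginal_contribution(
    d: DissimilarityMatrix | PcoaEmbedding, X: pd.DataFrame
) -> list[tuple[str, float]]:
    """Rank predictors by how much the full model's constrained variation
    drops when each is removed alone; descending, ties broken by name."""
    emb = d if isinstance(d, PcoaEmbedding) else gower_pcoa(d)
    full = cap_fit(emb, X).constrained_pct
    contribs = []
    for col in X.columns:
        rest = X.drop(columns=[col])
        reduced = cap_fit(emb, rest).constrained_pct if rest.shape[1] else 0.0
        contribs.append((str(col), full - reduced))
    return sorted(contribs, key=lambda t: (-t[1], t[0]))


def select_model(
    d: DissimilarityMatrix | PcoaEmbedding,
    X_candidates: pd.DataFrame,
    alpha: float = 0.05,
    max_terms: int = 4,
    n_perm: int = 999,
    seed: int | None = None,
) -> CapModel:
    """Forward admission in marginal-contribution order.

    Candidates are ranked by marginal contribution to the full model, then
    admitted one at a time while the sequential permutation p stays below
    ``alpha``, stopping at the first non-significant term or at
    ``max_terms`` (keeps competing predictor sets comparable in size).
    """
    emb = d if isinstance(d, PcoaEmbedding) else gower_pcoa(d)
    ranked = [name for name, _ in rank_by_marginal_contribution(emb, X_candidates)]
    seq = permutation_test(emb, X_candidates, term_order=ranked,
                           n_perm=n_perm, seed=seed)
    chosen: list[str] = []
    for name, p in zip(ranked, seq["p_terms"]):
        if p >= alpha or len(chosen) >= max_terms:
            break
        chosen.append(name)
    if not chosen:
        warnings.warn("no significant predictor; returning empty model")
        return CapModel(retained_terms=(), constrained_pct=0.0, pseudo_F=0.0,
                        df=(0, emb.axes.shape[0] - 1), p_perm=None,
                        total_inertia=emb.represented_inertia)
    model = cap_fit(emb, X_candidates[chosen], n_perm=n_perm, seed=seed)
    table = tuple(
        {
            "Variable": name,
            "Variation (%)": cap_fit(emb, X_candidates[[name]]).constrained_pct,
            "Pseudo-F": float(seq["F_terms"][ranked.index(name)]),
            "p": float(seq["p_terms"][ranked.index(name)]),
        }
        for name in chosen
    )
    return CapModel(**{**vars(model), "term_table": table})


def partition_composition(
    d: DissimilarityMatrix | PcoaEmbedding,
    X_A: pd.DataFrame,
    X_E: pd.DataFrame,
    X_S: pd.DataFrame,
):
    """Variation partitioning of constrained inertia among the A, E and S
    predictor sets: the seven combination CAP models feed the same
    inclusion–exclusion solve as the richness partition."""
    from .richness_models import PartitionResult, partition_from_r2, SET_KEYS

    emb = d if isinstance(d, PcoaEmbedding) else gower_pcoa(d)
    sets = {"A": X_A, "E": X_E, "S": X_S}
    r2: dict = {}
    for key in SET_KEYS:
        frames = [sets[part] for part in key.split("+")]
        Xall = pd.concat(frames, axis=1)
        r2[key] = cap_fit(emb, Xall).constrained_pct if Xall.shape[1] else 0.0
    return PartitionResult(fractions=partition_from_r2(r2), source_r2=r2)


def single_covariate_test(
    d: DissimilarityMatrix | PcoaEmbedding,
    z: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """CAP with one covariate (e.g. richness, log area): (pseudo_F, p)."""
    z = np.asarray(z, dtype=float)
    if np.ptp(z) == 0:
        raise ValueError("constant covariate")
    m = cap_fit(d, z[:, None], n_perm=n_perm, seed=seed)
    return m.pseudo_F, m.p_perm
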