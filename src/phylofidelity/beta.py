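"""Pairwise phylogenetic beta diversity: UniFrac, interassemblage MPD/MNTD,
and phylogenetic community dissimilarity (PCD).

UniFrac here is the unweighted, rootless variant: the fraction of the branch
length of the pair's union spanning subtree that is *not* shared between the
two assemblages' own (rootless) spanning subtrees.  MPD_beta averages
patristic distances over all cross-assemblage pairs, conspecific pairs
contributing 0; MNTD_beta averages each species' distance to its nearest
neighbour in the *other* assemblage, the two directions weighted by
assemblage size.

PCD asks how much of the variance of a neutral (Brownian) trait in one
assemblage remains after conditioning on the trait values in the other.  With
V the correlation-scaled phylogenetic covariance, the conditional covariance
of A given B is ``V_AA - V_AB V_BB^-1 V_BA`` and D(A|B) is the mean of its
diagonal.  PCD normalises the size-weighted sum of D(A|B) and D(B|A) by its
Monte-Carlo expectation under random assemblages of matching richness drawn
from the species pool, and factorises as PCD = PCDc x PCDp, where PCDc is the
purely compositional (star-phylogeny) component.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from .alpha import _edge_tip_matrix, _indicator, _site_matrix
from .tree import DistanceMatrix, Phylogeny, patristic_distances, phylo_covariance

__all__ = ["unifrac", "mpd_beta", "mntd_beta", "pcd", "beta_table"]


# ----------------------------------------------------------------- small sets
def _edge_sets(tree: Phylogeny, indicators: np.ndarray):
    """Per-column edge membership of the rootless spanning subtree.

    An edge (indexed by its child node, root excluded) belongs to the
    spanning subtree of a tip set S iff the number of members below it is in
    (0, |S|): edges with all of S below them form the stem-to-root path and
    are excluded.
    """
    M1 = _edge_tip_matrix(tree)[1:]
    counts = M1 @ indicators
    sizes = indicators.sum(axis=0)
    return (counts > 0) & (counts < sizes[None, :])


def unifrac(A, B, tree: Phylogeny) -> float:
    """Unweighted rootless UniFrac between two tip-label sets, in [0, 1]."""
    A, B = set(A), set(B)
    if not A or not B:
        raise ValueError("assemblages must be nonempty")
    tree._require_lengths()
    labels = tree.tip_labels
    ind = np.column_stack([_indicator(A, labels), _indicator(B, labels)])
    union = np.maximum(ind[:, 0], ind[:, 1])[:, None]
    inside = _edge_sets(tree, ind)
    inside_u = _edge_sets(tree, union)[:, 0]
    lengths = tree.blen[1:]
    total = float(lengths[inside_u].sum())
    shared = float(lengths[inside[:, 0] & inside[:, 1]].sum())
    if total == 0:
        return 0.0
    return (total - shared) / total


def mpd_beta(A, B, dist: DistanceMatrix) -> float:
    """Mean patristic distance over all ordered cross pairs (i in A, j in B);
    species shared by both assemblages contribute zero-distance pairs."""
    A, B = list(set(A)), list(set(B))
    if not A or not B:
        raise ValueError("assemblages must be nonempty")
    sub = dist.values[np.ix_(dist.index_of(A), dist.index_of(B))]
    return float(sub.mean())


def mntd_beta(A, B, dist: DistanceMatrix) -> float:
    """Size-weighted symmetrised nearest-cross-neighbour distance."""
    A, B = list(set(A)), list(set(B))
    if not A or not B:
        raise ValueError("assemblages must be nonempty")
    sub = dist.values[np.ix_(dist.index_of(A), dist.index_of(B))]
    a_side = sub.min(axis=1)
    b_side = sub.min(axis=0)
    return float((a_side.sum() + b_side.sum()) / (len(A) + len(B)))


# ------------------------------------------------------------------------ PCD
def _cond_var_profile(V: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Conditional variance of every pool member given the set ``idx``:
    diag(V) - diag(V[:, idx] V[idx, idx]^-1 V[idx, :])."""
    sub = V[np.ix_(idx, idx)]
    try:
        L = cholesky(sub, lower=True)
    except np.linalg.LinAlgError:
        warnings.warn("singular conditioning block in PCD; adding 1e-10 ridge")
        L = cholesky(sub + 1e-10 * np.eye(len(idx)), lower=True)
    W = np.linalg.solve(L, V[idx, :])
    prof = np.diag(V) - (W**2).sum(axis=0)
    return np.maximum(prof, 0.0)


def _correlation_v(tree: Phylogeny) -> tuple:
    Cov = phylo_covariance(tree)
    d = np.sqrt(np.diag(Cov.values))
    V = Cov.values / np.outer(d, d)
    np.fill_diagonal(V, 1.0)
    return Cov.labels, V


def _random_profiles(V: np.ndarray, sizes, n_rand: int, seed, order=None):
    """Monte-Carlo mean conditional-variance profile (phylogenetic and
    compositional) for random assemblages of each richness in ``sizes``.

    ``order`` maps draw positions to V indices; drawing in sorted-label space
    makes the expectation depend only on the seed and the label set, not on a
    tree's internal tip ordering.
    """
    n = V.shape[0]
    out = {}
    for r in sorted(set(int(s) for s in sizes)):
        rng = np.random.default_rng(np.random.SeedSequence([_seed_int(seed), r]))
        acc = np.zeros(n)
        acc_c = np.zeros(n)
        for _ in range(n_rand):
            idx = rng.choice(n, size=r, replace=False)
            if order is not None:
                idx = order[idx]
            acc += _cond_var_profile(V, idx)
            member = np.zeros(n)
            member[idx] = 1.0
            acc_c += 1.0 - member
        out[r] = (acc / n_rand, acc_c / n_rand)
    return out


def _seed_int(seed) -> int:
    if seed is None:
        return int(np.random.SeedSequence().entropy % (2**31))
    return int(seed)


def pcd(A, B, tree: Phylogeny, n_rand: int = 999, seed=None) -> dict:
    """PCD between two assemblages, with components PCDc and PCDp.

    The random-assemblage expectation in the denominator is estimated from
    ``n_rand`` uniform draws from the tree's tip pool; the same draws serve
    both orientations, so the measure is symmetric given the same seed.
    """
    A, B = set(A), set(B)
    if not A or not B:
        raise ValueError("assemblages must be nonempty")
    labels, V = _correlation_v(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    ia = np.array(sorted(index[s] for s in A))
    ib = np.array(sorted(index[s] for s in B))
    order = np.argsort(np.asarray(labels, dtype=object))
    prof = _random_profiles(V, [len(ia), len(ib)], n_rand, seed, order=order)

    qa = _cond_var_profile(V, ib)  # condition on B, read off A
    qb = _cond_var_profile(V, ia)
    d_ab, d_ba = qa[ia].mean(), qb[ib].mean()
    e_ab = prof[len(ib)][0][ia].mean()
    e_ba = prof[len(ia)][0][ib].mean()
    na, nb = len(ia), len(ib)
    pcd_val = (na * d_ab + nb * d_ba) / (na * e_ab + nb * e_ba)

    shared = len(A & B)
    dc_ab, dc_ba = (na - shared) / na, (nb - shared) / nb
    ec_ab = prof[len(ib)][1][ia].mean()
    ec_ba = prof[len(ia)][1][ib].mean()
    pcdc = (na * dc_ab + nb * dc_ba) / (na * ec_ab + nb * ec_ba)
    pcdp = pcd_val / pcdc if pcdc > 0 else np.nan
    return {"PCD": float(pcd_val), "PCDc": float(pcdc), "PCDp": float(pcdp)}


# ------------------------------------------------------------------ the table
def beta_table(
    matrix: pd.DataFrame,
    tree: Phylogeny,
    metrics=("unif", "mpd", "mntd", "pcd"),
    n_rand: int = 999,
    seed=None,
) -> pd.DataFrame:
    """All four beta measures for every unordered site pair of the matrix.

    Output columns: site1, site2, then Unif / MPD_beta / MNTD_beta /
    PCD, PCDc, PCDp as requested.
    """
    tree._require_lengths()
    metrics = [m.lower() for m in metrics]
    labels = tree.tip_labels
    B = _site_matrix(matrix, labels)
    sites = list(matrix.index)
    pairs = list(combinations(range(len(sites)), 2))
    out = pd.DataFrame(
        {
            "site1": [sites[i] for i, _ in pairs],
            "site2": [sites[j] for _, j in pairs],
        }
    )
    sizes = B.sum(axis=0)

    if "unif" in metrics:
        lengths = tree.blen[1:]
        inside = _edge_sets(tree, B)
        shared = (inside * lengths[:, None]).T @ inside
        U = np.zeros((B.shape[0], len(pairs)))
        for k, (i, j) in enumerate(pairs):
            U[:, k] = np.maximum(B[:, i], B[:, j])
        inside_u = _edge_sets(tree, U)
        denom = lengths @ inside_u
        vals = np.empty(len(pairs))
        for k, (i, j) in enumerate(pairs):
            vals[k] = 0.0 if denom[k] == 0 else (denom[k] - shared[i, j]) / denom[k]
        out["Unif"] = vals

    if "mpd" in metrics or "mntd" in metrics:
        D = patristic_distances(tree).values
        if "mpd" in metrics:
            T = B.T @ D @ B
            out["MPD_beta"] = [
                T[i, j] / (sizes[i] * sizes[j]) for i, j in pairs
            ]
        if "mntd" in metrics:
            idxs = [np.flatnonzero(B[:, s]) for s in range(B.shape[1])]
            vals = np.empty(len(pairs))
            for k, (i, j) in enumerate(pairs):
                sub = D[np.ix_(idxs[i], idxs[j])]
                vals[k] = (sub.min(axis=1).sum() + sub.min(axis=0).sum()) / (
                    sizes[i] + sizes[j]
                )
            out["MNTD_beta"] = vals

    if "pcd" in metrics:
        _, V = _correlation_v(tree)
        index = {lab: i for i, lab in enumerate(labels)}
        col_idx = [
            np.array([index[sp] for sp in matrix.columns[matrix.iloc[s].astype(bool)]])
            for s in range(len(sites))
        ]
        order = np.argsort(np.asarray(labels, dtype=object))
        prof = _random_profiles(V, sizes, n_rand, seed, order=order)
        qs = [_cond_var_profile(V, idx) for idx in col_idx]
        pcd_v = np.empty(len(pairs))
        pcdc_v = np.empty(len(pairs))
        for k, (i, j) in enumerate(pairs):
            ia, ib = col_idx[i], col_idx[j]
            na, nb = len(ia), len(ib)
            d_ab, d_ba = qs[j][ia].mean(), qs[i][ib].mean()
            e_ab = prof[nb][0][ia].mean()
            e_ba = prof[na][0][ib].mean()
            pcd_v[k] = (na * d_ab + nb * d_ba) / (na * e_ab + nb * e_ba)
            shared_n = np.intersect1d(ia, ib, assume_unique=True).size
            dc = (na - shared_n) / na, (nb - shared_n) / nb
            ec_ab = prof[nb][1][ia].mean()
            ec_ba = prof[na][1][ib].mean()
            pcdc_v[k] = (na * dc[0] + nb * dc[1]) / (na * ec_ab + nb * ec_ba)
        out["PCD"] = pcd_v
        out["PCDc"] = pcdc_v
        with np.errstate(invalid="ignore", divide="ignore"):
            out["PCDp"] = np.where(pcdc_v > 0, pcd_v / pcdc_v, np.nan)
    return out
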