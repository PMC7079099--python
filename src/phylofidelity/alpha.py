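"""Per-site phylogenetic alpha diversity (PD, MPD, MNTD) and tip-shuffle SES.

Faith's PD is computed *without the root*: it sums the branch lengths of the
subtree spanning the assemblage's tips and excludes the stem path between
that subtree's basal node (the assemblage's most recent common ancestor) and
the tree root.  MPD is the mean patristic distance over all unordered pairs
of assemblage members; MNTD the mean, over members, of the distance to the
nearest other member.

The null model for the standardized effect size shuffles the tip labels of
the phylogeny (one shared permutation per null replicate, applied to every
site) while holding species composition fixed:
SES = (X_obs - mean(X_null)) / sd(X_null).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import DistanceMatrix, Phylogeny, patristic_distances

__all__ = ["faith_pd", "mpd", "mntd", "alpha_table", "ses", "SESResult"]


def _edge_tip_matrix(tree: Phylogeny) -> np.ndarray:
    """Boolean (n_nodes x n_tips): entry [v, t] is True iff tip t lies in the
    subtree below node v (the edge above v)."""
    M = np.zeros((tree.n_nodes, tree.n_tips), dtype=bool)
    pos = {int(t): k for k, t in enumerate(tree.tip_ids)}
    for v in range(tree.n_nodes - 1, -1, -1):
        if tree.is_tip(v):
            M[v, pos[v]] = True
        if v > 0:
            M[tree.parent[v]] |= M[v]
    return M


def _indicator(community, labels) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(labels)}
    missing = [s for s in community if s not in index]
    if missing:
        raise KeyError(f"species not among tips: {sorted(missing)}")
    ind = np.zeros(len(labels), dtype=np.float64)
    for s in community:
        ind[index[s]] = 1.0
    return ind


def faith_pd(community, tree: Phylogeny) -> float:
    """Rootless Faith's PD of a set of tip labels (requires >= 2 species)."""
    community = set(community)
    if len(community) < 2:
        raise ValueError("PD without the root is undefined for singleton sites")
    tree._require_lengths()
    ind = _indicator(community, tree.tip_labels)
    M = _edge_tip_matrix(tree)
    counts = M[1:] @ ind
    r = ind.sum()
    inside = (counts > 0) & (counts < r)
    return float(tree.blen[1:][inside].sum())


def mpd(community, dist: DistanceMatrix) -> float:
    """Mean pairwise patristic distance over unordered distinct pairs."""
    community = list(set(community))
    if len(community) < 2:
        raise ValueError("MPD requires at least 2 species")
    idx = dist.index_of(community)
    sub = dist.values[np.ix_(idx, idx)]
    r = len(idx)
    return float(sub.sum() / (r * (r - 1)))


def mntd(community, dist: DistanceMatrix) -> float:
    """Mean distance from each member to its nearest other member."""
    community = list(set(community))
    if len(community) < 2:
        raise ValueError("MNTD requires at least 2 species")
    idx = dist.index_of(community)
    sub = dist.values[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


# ------------------------------------------------------------------ vectorised
def _site_matrix(matrix: pd.DataFrame, labels) -> np.ndarray:
    """Map a site-by-species 0/1 DataFrame onto tip order -> (n_tips, n_sites)."""
    index = {lab: i for i, lab in enumerate(labels)}
    B = np.zeros((len(labels), matrix.shape[0]))
    for j, sp in enumerate(matrix.columns):
        if sp not in index:
            raise KeyError(f"species {sp!r} not among tips")
        B[index[sp]] = np.maximum(B[index[sp]], matrix.iloc[:, j].to_numpy())
    return B


def _alpha_from_arrays(B: np.ndarray, lengths: np.ndarray, M1: np.ndarray, D: np.ndarray):
    sizes = B.sum(axis=0)
    counts = M1 @ B
    pd_vals = lengths @ ((counts > 0) & (counts < sizes[None, :]))
    DB = D @ B
    tot = (B * DB).sum(axis=0)
    mpd_vals = tot / (sizes * (sizes - 1))
    mntd_vals = np.empty(B.shape[1])
    for s in range(B.shape[1]):
        idx = np.flatnonzero(B[:, s])
        sub = D[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, np.inf)
        mntd_vals[s] = sub.min(axis=1).mean()
    return pd_vals, mpd_vals, mntd_vals


def alpha_table(matrix: pd.DataFrame, tree: Phylogeny) -> pd.DataFrame:
    """PD, MPD and MNTD for every site of a presence/absence matrix."""
    tree._require_lengths()
    sizes = matrix.sum(axis=1)
    if (sizes < 2).any():
        raise ValueError("all sites need >= 2 species")
    labels = tree.tip_labels
    B = _site_matrix(matrix, labels)
    M = _edge_tip_matrix(tree)
    D = patristic_distances(tree).values
    pd_vals, mpd_vals, mntd_vals = _alpha_from_arrays(B, tree.blen[1:], M[1:], D)
    return pd.DataFrame(
        {"PD": pd_vals, "MPD": mpd_vals, "MNTD": mntd_vals}, index=matrix.index
    )


@dataclass
class SESResult:
    """Observed values, tip-shuffle null draws and standardized effect sizes."""

    metric: str
    obs: pd.Series
    nulls: pd.DataFrame  # n_null rows x sites
    ses: pd.Series


def ses(
    metric: str,
    matrix: pd.DataFrame,
    tree: Phylogeny,
    n_null: int = 999,
    seed=None,
) -> SESResult:
    """Tip-shuffle standardized effect size for PD, MPD or MNTD.

    Each null replicate applies one uniform permutation of the tree's tip
    labels, shared across all sites, and recomputes the metric.  Sites where
    the null has zero spread get an undefined (NaN) SES with a warning.
    """
    metric = metric.upper()
    if metric not in ("PD", "MPD", "MNTD"):
        raise ValueError(f"unknown metric {metric!r}")
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    tree._require_lengths()
    rng = np.random.default_rng(seed)
    labels = tree.tip_labels
    B = _site_matrix(matrix, labels)
    M1 = _edge_tip_matrix(tree)[1:]
    D = patristic_distances(tree).values
    lengths = tree.blen[1:]
    col = {"PD": 0, "MPD": 1, "MNTD": 2}[metric]
    obs = _alpha_from_arrays(B, lengths, M1, D)[col]
    n = len(labels)
    nulls = np.empty((n_null, B.shape[1]))
    for k in range(n_null):
        perm = rng.permutation(n)
        Bp = np.zeros_like(B)
        Bp[perm] = B
        nulls[k] = _alpha_from_arrays(Bp, lengths, M1, D)[col]
    mu, sd = nulls.mean(axis=0), nulls.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (obs - mu) / sd, np.nan)
    if (sd == 0).any():
        warnings.warn(
            "null distribution has zero spread for some sites; SES undefined there"
        )
    return SESResult(
        metric=metric,
        obs=pd.Series(obs, index=matrix.index, name=metric),
        nulls=pd.DataFrame(nulls, columns=matrix.index),
        ses=pd.Series(z, index=matrix.index, name=f"SES_{metric}"),
    )
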