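"""Continuous trait simulation (BM / OU) and phylogenetic signal estimation.

Traits evolve along the chronogram from a root state of 0.  Under Brownian
motion a branch of length t adds Normal(0, sigma2 * t) noise; under
Ornstein-Uhlenbeck with selection strength alpha toward an optimum of 0, the
child state is ``parent * exp(-alpha t)`` plus Normal noise with the exact
transition variance ``sigma2 (1 - exp(-2 alpha t)) / (2 alpha)``.  With
alpha = 0 the OU recursion reduces to BM exactly (same draws, same output).

Signal is quantified by Pagel's lambda (maximum likelihood, with the upper
bound ``root_age / max_offdiag(C)`` so values above 1 are allowed, and a
chi-square df-1 likelihood-ratio test against lambda = 0) and by Blomberg's
K (observed MSE0/MSE against its Brownian expectation, significance by
tip-shuffle permutation).  Both estimators are invariant to shifting and
positively scaling the trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .tree import Phylogeny, phylo_covariance

__all__ = [
    "TraitVector",
    "SignalEstimate",
    "simulate_bm",
    "simulate_ou",
    "simulate_traits_many",
    "reshuffle_trait",
    "estimate_lambda",
    "estimate_k",
    "LambdaEstimator",
    "KEstimator",
]


@dataclass
class TraitVector:
    """Tip-label -> value map plus generation metadata."""

    values: pd.Series
    model: str = "BM"
    sigma2: float = np.nan
    alpha: float = 0.0
    seed: object = None
    shuffled: bool = False


@dataclass
class SignalEstimate:
    """Point estimate of lambda or K with its significance test."""

    statistic: str
    estimate: float
    loglik: float | None = None
    p_value: float = np.nan
    n_perm: int | None = None
    extra: dict = field(default_factory=dict)


# ------------------------------------------------------------------ simulation
def _branch_moments(tree: Phylogeny, sigma2: float, alpha: float):
    t = tree.blen.copy()
    t[0] = 0.0
    if alpha == 0.0:
        decay = np.ones_like(t)
        sd = np.sqrt(sigma2 * t)
    else:
        decay = np.exp(-alpha * t)
        sd = np.sqrt(sigma2 * (1.0 - np.exp(-2.0 * alpha * t)) / (2.0 * alpha))
    return decay, sd


def simulate_traits_many(
    tree: Phylogeny, sigma2: float, n_traits: int, seed=None, alpha: float = 0.0
) -> pd.DataFrame:
    """Simulate ``n_traits`` independent traits; tips as rows, traits as
    columns.  One Normal draw per (node, trait), consumed in node preorder, so
    the alpha = 0 output is bit-identical to plain BM with the same seed."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    tree._require_lengths()
    rng = np.random.default_rng(seed)
    decay, sd = _branch_moments(tree, sigma2, alpha)
    z = rng.standard_normal((tree.n_nodes, n_traits))
    x = np.zeros((tree.n_nodes, n_traits))
    for i in range(1, tree.n_nodes):
        x[i] = x[tree.parent[i]] * decay[i] + sd[i] * z[i]
    return pd.DataFrame(
        x[tree.tip_ids],
        index=tree.tip_labels,
        columns=[f"trait_{k + 1}" for k in range(n_traits)],
    )


def simulate_bm(tree: Phylogeny, sigma2: float, seed=None) -> TraitVector:
    vals = simulate_traits_many(tree, sigma2, 1, seed=seed, alpha=0.0).iloc[:, 0]
    return TraitVector(vals.rename("trait"), "BM", sigma2, 0.0, seed)


def simulate_ou(tree: Phylogeny, sigma2: float, alpha: float, seed=None) -> TraitVector:
    vals = simulate_traits_many(tree, sigma2, 1, seed=seed, alpha=alpha).iloc[:, 0]
    return TraitVector(vals.rename("trait"), "OU" if alpha > 0 else "BM", sigma2, alpha, seed)


def reshuffle_trait(trait: TraitVector, seed=None) -> TraitVector:
    """Permute trait values uniformly over tips (destroys any signal)."""
    rng = np.random.default_rng(seed)
    vals = pd.Series(
        rng.permutation(trait.values.to_numpy()),
        index=trait.values.index,
        name=trait.values.name,
    )
    return TraitVector(vals, trait.model, trait.sigma2, trait.alpha, seed, shuffled=True)


# ------------------------------------------------------------- Pagel's lambda
class LambdaEstimator:
    """ML estimation of Pagel's lambda on a fixed tree.

    Lambda multiplies all off-diagonal entries of the Brownian covariance C.
    The phylogenetic mean and the rate sigma2 are profiled out analytically;
    only lambda is searched, on [0, lambda_max] with lambda_max =
    root_age / max_offdiag(C).  On (near-)ultrametric trees C and the
    identity commute after forcing the diagonal to the root age, so the
    likelihood is evaluated in O(n) per lambda from one eigendecomposition.
    """

    def __init__(self, tree: Phylogeny, tol: float = 1e-8):
        cov = phylo_covariance(tree)
        self.labels = list(cov.labels)
        C = cov.values.copy()
        self.n = C.shape[0]
        off = C - np.diag(np.diag(C))
        max_off = off.max()
        T = float(np.diag(C).max())
        self.lam_max = T / max_off if max_off > 0 else 1.0
        self.tol = tol
        self._ultra = tree.is_ultrametric(1e-8)
        if self._ultra:
            self.T = float(np.diag(C).mean())
            np.fill_diagonal(C, self.T)
            w, U = np.linalg.eigh(C)
            self.w = w
            self.U = U
            self.one_t = U.T @ np.ones(self.n)
        else:
            self.C = C
            self.diagC = np.diag(C).copy()

    def _loglik(self, lam: float, x: np.ndarray) -> float:
        n = self.n
        if self._ultra:
            s = lam * self.w + (1.0 - lam) * self.T
            if np.any(s <= 0):
                return -np.inf
            xt = self.U.T @ x
            ot = self.one_t
            mu = (ot * xt / s).sum() / ((ot * ot / s).sum())
            r = xt - mu * ot
            q = (r * r / s).sum()
            logdet = np.log(s).sum()
        else:
            S = lam * self.C + (1.0 - lam) * np.diag(self.diagC)
            try:
                cf = cho_factor(S, lower=True)
            except np.linalg.LinAlgError:
                return -np.inf
            one = np.ones(n)
            Sx = cho_solve(cf, x)
            So = cho_solve(cf, one)
            mu = (one @ Sx) / (one @ So)
            r = x - mu
            q = r @ cho_solve(cf, r)
            logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        if q <= 0:
            return -np.inf
        sigma2 = q / n
        return -0.5 * (n * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet)

    def estimate(self, x: np.ndarray) -> SignalEstimate:
        x = np.asarray(x, dtype=np.float64)
        if x.std() == 0:
            raise ValueError("trait is constant; lambda undefined")
        hi = self.lam_max * (1.0 - 1e-10)
        res = minimize_scalar(
            lambda lam: -self._loglik(lam, x),
            bounds=(0.0, hi),
            method="bounded",
            options={"xatol": self.tol},
        )
        cands = [(float(res.x), -float(res.fun))]
        for lam in (0.0, hi):
            cands.append((lam, self._loglik(lam, x)))
        lam_hat, ll_hat = max(cands, key=lambda c: c[1])
        ll0 = self._loglik(0.0, x)
        lrt = max(0.0, 2.0 * (ll_hat - ll0))
        p = float(chi2.sf(lrt, df=1))
        return SignalEstimate(
            "lambda",
            float(lam_hat),
            loglik=float(ll_hat),
            p_value=p,
            extra={"loglik_lambda0": float(ll0), "lambda_max": self.lam_max},
        )

    def estimate_many(self, X: pd.DataFrame) -> pd.DataFrame:
        idx = [self.labels.index(l) for l in X.index] if list(X.index) != self.labels else None
        rows = []
        for col in X.columns:
            x = X[col].to_numpy()
            if idx is not None:
                xx = np.empty_like(x)
                for k, i in enumerate(idx):
                    xx[i] = x[k]
                x = xx
            est = self.estimate(x)
            rows.append((est.estimate, est.loglik, est.p_value))
        return pd.DataFrame(rows, index=X.columns, columns=["lambda", "loglik", "p"])


def estimate_lambda(trait: TraitVector, tree: Phylogeny) -> SignalEstimate:
    if tree.n_tips < 4:
        raise ValueError("need at least 4 tips")
    est = LambdaEstimator(tree)
    x = trait.values.reindex(est.labels).to_numpy()
    if np.isnan(x).any():
        raise ValueError("trait missing values for some tips")
    return est.estimate(x)


# -------------------------------------------------------------- Blomberg's K
class KEstimator:
    """Blomberg's K on a fixed tree, with tip-shuffle permutation test."""

    def __init__(self, tree: Phylogeny):
        cov = phylo_covariance(tree)
        self.labels = list(cov.labels)
        C = cov.values
        self.n = n = C.shape[0]
        self._cf = cho_factor(C, lower=True)
        one = np.ones(n)
        self._Cinv_one = cho_solve(self._cf, one)
        self._one_Cinv_one = float(one @ self._Cinv_one)
        self.expected_ratio = (np.trace(C) - n / self._one_Cinv_one) / (n - 1)

    def _ratio(self, X: np.ndarray) -> np.ndarray:
        """MSE0/MSE for each column of X (phylogenetic GLS mean removed)."""
        a_hat = (self._Cinv_one @ X) / self._one_Cinv_one
        R = X - a_hat[None, :]
        mse0 = (R * R).sum(axis=0)
        mse = (R * cho_solve(self._cf, R)).sum(axis=0)
        return mse0 / mse

    def estimate(self, x: np.ndarray, n_perm: int = 999, seed=None) -> SignalEstimate:
        x = np.asarray(x, dtype=np.float64)
        if x.std() == 0:
            raise ValueError("trait is constant; K undefined")
        obs = float(self._ratio(x[:, None])[0])
        k = obs / self.expected_ratio
        p = np.nan
        if n_perm > 0:
            rng = np.random.default_rng(seed)
            P = np.empty((self.n, n_perm))
            for j in range(n_perm):
                P[:, j] = x[rng.permutation(self.n)]
            null = self._ratio(P)
            p = (1.0 + (null >= obs).sum()) / (n_perm + 1.0)
        return SignalEstimate("K", float(k), p_value=float(p), n_perm=n_perm or None)

    def estimate_many(self, X: pd.DataFrame) -> pd.Series:
        Xv = X.reindex(self.labels).to_numpy()
        return pd.Series(self._ratio(Xv) / self.expected_ratio, index=X.columns, name="K")


def estimate_k(
    trait: TraitVector, tree: Phylogeny, n_perm: int = 999, seed=None
) -> SignalEstimate:
    if tree.n_tips < 4:
        raise ValueError("need at least 4 tips")
    est = KEstimator(tree)
    x = trait.values.reindex(est.labels).to_numpy()
    if np.isnan(x).any():
        raise ValueError("trait missing values for some tips")
    return est.estimate(x, n_perm=n_perm, seed=seed)
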